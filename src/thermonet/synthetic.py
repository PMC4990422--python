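"""Study-design-faithful synthetic data generation.

The experimental design mirrored here: 20 titration datasets of duplex
unwinding (Ded1p-eIF4A: 4, Ded1p-eIF4G: 3, eIF4A-eIF4G: 4,
Ded1p-eIF4A-eIF4G: 9), each the titration of one component with the
others fixed, with at least one titration per constituent component and
ATP in every complex class; reactions use trace duplex (0.5 nM), and the
base condition echoes 0.1 uM Ded1p, 2 uM eIF4A, 0.1 uM eIF4G, 4 mM ATP.
Time courses follow the two-rate unwinding/annealing law with i.i.d.
Gaussian noise on the fraction unwound; three replicates per curve and
ten time points yield >3000 simulated data points.

The ground-truth parameter set is the packaged default model parameter
set: an illustrative set chosen to reproduce the qualitative regime of
the system (the triple complex is the most stable and the major species
at physiological concentrations; Ded1p oligomerizes cooperatively;
eIF4G inhibits Ded1p alone), not fitted constants from any experiment.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import ModelGraph, ModelError, ParameterSet
from .speciation import compile_model
from .kinetics import (
    TimeCourse,
    fit_unwinding_timecourse,
    quadratic_isotherm,
    predict_k_unw_batch,
)
from .inference import Dataset

__all__ = [
    "DesignSpec",
    "GroundTruth",
    "TitrationPlan",
    "default_ground_truth",
    "make_design",
    "simulate_timecourses",
    "simulate_k_unw",
    "build_synthetic_study",
    "simulate_mst_series",
    "simulate_atpase_series",
]

#: component order used throughout the synthetic design
COMP_IDS = ("D", "A", "G", "T")

#: default sampling times in minutes
DEFAULT_TIMES = (0.5, 1.0, 2.0, 4.0, 7.0, 12.0, 20.0, 30.0, 45.0, 60.0)


@dataclass(frozen=True)
class GroundTruth:
    """Parameters used for simulation, with a provenance note."""

    params: ParameterSet
    k_ann: float = 0.025  # 1/min, annealing rate constant
    note: str = (
        "illustrative ground truth: reproduces the qualitative regime of the "
        "system; not fitted experimental constants"
    )


@dataclass(frozen=True)
class TitrationPlan:
    """One dataset skeleton: what is varied, over which grid, at what background."""

    id: str
    complex_class: str  # "DA", "DG", "AG" or "DAG"
    varied: str
    grid: tuple[float, ...]
    fixed: Mapping[str, float]


@dataclass(frozen=True)
class DesignSpec:
    """The synthetic study design.

    ``class_counts`` fixes the number of datasets per complex class; the
    default titration plans satisfy them and bracket the ground-truth
    constants.  Noise is absolute Gaussian on the fraction unwound.
    """

    class_counts: Mapping[str, int] = field(
        default_factory=lambda: {"DA": 4, "DG": 3, "AG": 4, "DAG": 9}
    )
    n_concentrations: int = 8
    n_replicates: int = 3
    times: tuple[float, ...] = DEFAULT_TIMES
    sigma: float = 0.03
    atp_base: float = 4e-3
    substrate: str = "16bp-25nt-3p"

    @property
    def n_datasets(self) -> int:
        return sum(self.class_counts.values())

    def n_points(self, n_datasets: int | None = None) -> int:
        n = n_datasets if n_datasets is not None else self.n_datasets
        return n * self.n_concentrations * self.n_replicates * len(self.times)


def default_ground_truth(model: ModelGraph) -> GroundTruth:
    return GroundTruth(model.default_parameters())


def _grid(lo: float, hi: float, n: int) -> tuple[float, ...]:
    return tuple(np.geomspace(lo, hi, n))


def _default_plans(spec: DesignSpec) -> list[TitrationPlan]:
    n = spec.n_concentrations
    T = spec.atp_base
    d_grid = _grid(1.25e-8, 1.6e-6, n)
    a_grid = _grid(5e-8, 8e-6, n)
    g_grid = _grid(1.25e-8, 1.6e-6, n)
    g_fine = _grid(6.25e-9, 8e-7, n)
    t_grid = _grid(1.5e-5, 4e-3, n)
    plans = {
        "DA": [
            TitrationPlan("DA-D", "DA", "D", d_grid, {"A": 2e-6, "T": T}),
            TitrationPlan("DA-A", "DA", "A", a_grid, {"D": 1e-7, "T": T}),
            TitrationPlan("DA-T", "DA", "T", t_grid, {"D": 1e-7, "A": 2e-6}),
            TitrationPlan("DA-A2", "DA", "A", a_grid, {"D": 3e-7, "T": T}),
        ],
        "DG": [
            TitrationPlan("DG-D", "DG", "D", _grid(2.5e-8, 3.2e-6, n), {"G": 1e-7, "T": T}),
            TitrationPlan("DG-G", "DG", "G", g_grid, {"D": 2e-7, "T": T}),
            TitrationPlan("DG-T", "DG", "T", t_grid, {"D": 2e-7, "G": 1e-7}),
        ],
        "AG": [
            TitrationPlan("AG-A", "AG", "A", a_grid, {"G": 1e-7, "T": T}),
            TitrationPlan("AG-G", "AG", "G", g_fine, {"A": 2e-6, "T": T}),
            TitrationPlan("AG-T", "AG", "T", t_grid, {"A": 2e-6, "G": 1e-7}),
            TitrationPlan("AG-A2", "AG", "A", a_grid, {"G": 3e-7, "T": T}),
        ],
        "DAG": [
            TitrationPlan("DAG-D", "DAG", "D", _grid(6.25e-9, 8e-7, n), {"A": 2e-6, "G": 1e-7, "T": T}),
            TitrationPlan("DAG-A", "DAG", "A", a_grid, {"D": 1e-7, "G": 1e-7, "T": T}),
            TitrationPlan("DAG-G", "DAG", "G", g_fine, {"D": 1e-7, "A": 2e-6, "T": T}),
            TitrationPlan("DAG-T", "DAG", "T", t_grid, {"D": 1e-7, "A": 2e-6, "G": 1e-7}),
            TitrationPlan("DAG-D2", "DAG", "D", _grid(6.25e-9, 8e-7, n), {"A": 5e-7, "G": 1e-7, "T": T}),
            TitrationPlan("DAG-A2", "DAG", "A", a_grid, {"D": 3e-7, "G": 1e-7, "T": T}),
            TitrationPlan("DAG-G2", "DAG", "G", g_fine, {"D": 1e-7, "A": 5e-7, "T": T}),
            TitrationPlan("DAG-D3", "DAG", "D", _grid(6.25e-9, 8e-7, n), {"A": 2e-6, "G": 3e-7, "T": T}),
            TitrationPlan("DAG-T2", "DAG", "T", t_grid, {"D": 3e-7, "A": 2e-6, "G": 1e-7}),
        ],
    }
    out: list[TitrationPlan] = []
    for cls, count in spec.class_counts.items():
        pool = plans.get(cls, [])
        if count > len(pool):
            raise ModelError(f"no default plans for {count} datasets of class {cls}")
        out.extend(pool[:count])
    return out


def make_design(spec: DesignSpec | None = None) -> list[TitrationPlan]:
    """Deterministic dataset skeletons satisfying the class breakdown.

    Every complex class includes at least one titration of each of its
    protein constituents and of ATP; grids bracket the ground-truth
    constants.
    """
    spec = spec or DesignSpec()
    plans = _default_plans(spec)
    counts: dict[str, int] = {}
    for p in plans:
        counts[p.complex_class] = counts.get(p.complex_class, 0) + 1
    if counts != dict(spec.class_counts):
        raise ModelError(f"design class counts {counts} != spec {dict(spec.class_counts)}")
    return plans


def _plan_conditions(plan: TitrationPlan) -> np.ndarray:
    cond = np.zeros((len(plan.grid), len(COMP_IDS)))
    for j, c in enumerate(COMP_IDS):
        cond[:, j] = plan.fixed.get(c, 0.0)
    cond[:, COMP_IDS.index(plan.varied)] = plan.grid
    return cond


def simulate_k_unw(
    model: ModelGraph,
    truth: GroundTruth,
    plans: Sequence[TitrationPlan],
) -> list[np.ndarray]:
    """Noise-free observed unwinding rate constants for every plan condition."""
    cm = compile_model(model, truth.params)
    out = []
    for plan in plans:
        cond = _plan_conditions(plan)
        totals = np.zeros((cond.shape[0], len(cm.comp_ids)))
        for j, c in enumerate(COMP_IDS):
            totals[:, cm.comp_ids.index(c)] = cond[:, j]
        out.append(predict_k_unw_batch(model, truth.params, totals, cm))
    return out


def simulate_timecourses(
    model: ModelGraph,
    truth: GroundTruth,
    plans: Sequence[TitrationPlan],
    spec: DesignSpec | None = None,
    seed: int = 0,
) -> dict[str, list[TimeCourse]]:
    """Noisy unwinding progress curves for the whole design.

    F(t) follows the two-rate law with the predicted k_unw and the
    ground-truth annealing rate; Gaussian noise (sd ``spec.sigma``) is
    added per point and clipped to [-0.05, 1.05].
    """
    spec = spec or DesignSpec()
    rng = np.random.default_rng(seed)
    t = np.asarray(spec.times)
    k_per_plan = simulate_k_unw(model, truth, plans)
    out: dict[str, list[TimeCourse]] = {}
    for plan, k_unw in zip(plans, k_per_plan):
        curves = []
        for i, conc in enumerate(plan.grid):
            ku = float(k_unw[i])
            k_obs = ku + truth.k_ann
            amp = ku / k_obs if k_obs > 0 else 0.0
            clean = amp * -np.expm1(-k_obs * t)
            for rep in range(spec.n_replicates):
                noisy = np.clip(clean + rng.normal(0.0, spec.sigma, t.size), -0.05, 1.05)
                meta = {c: plan.fixed.get(c, 0.0) for c in COMP_IDS}
                meta[plan.varied] = conc
                meta.update(substrate=spec.substrate, replicate=rep, dataset=plan.id,
                            k_unw_true=ku, k_ann_true=truth.k_ann)
                curves.append(TimeCourse(t, noisy, meta))
        out[plan.id] = curves
    return out


def build_synthetic_study(
    model: ModelGraph,
    truth: GroundTruth | None = None,
    spec: DesignSpec | None = None,
    seed: int = 0,
) -> list[Dataset]:
    """Full pipeline input: simulate time courses and reduce them to datasets.

    Each curve is fit with the two-rate unwinding law; the per-condition
    replicate k_unw values become the dataset observations.
    """
    spec = spec or DesignSpec()
    truth = truth or default_ground_truth(model)
    plans = make_design(spec)
    courses = simulate_timecourses(model, truth, plans, spec, seed)
    datasets = []
    for plan in plans:
        curves = courses[plan.id]
        obs = np.empty((len(plan.grid), spec.n_replicates))
        for j, tc in enumerate(curves):
            i, rep = divmod(j, spec.n_replicates)
            obs[i, rep] = fit_unwinding_timecourse(tc).k_unw
        datasets.append(Dataset(
            id=plan.id,
            varied=plan.varied,
            comp_ids=COMP_IDS,
            conditions=_plan_conditions(plan),
            observations=obs,
            substrate=spec.substrate,
            complex_class=plan.complex_class,
        ))
    return datasets


def simulate_mst_series(
    K: float,
    fixed_site_conc: float,
    grid: Sequence[float],
    sigma: float = 0.02,
    seed: int = 0,
    amplitude: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic (ligand depletion) dose-response with relative Gaussian noise."""
    x = np.asarray(grid, dtype=float)
    if (x < 0).any():
        raise ModelError("titrant grid must be non-negative")
    rng = np.random.default_rng(seed)
    y = amplitude * quadratic_isotherm(x, K, fixed_site_conc)
    return x, y + rng.normal(0.0, sigma * amplitude, x.size)


def simulate_atpase_series(
    K_half: float,
    k_cat: float,
    enzyme_conc: float,
    grid: Sequence[float],
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Michaelis-Menten initial rates V0 = k_cat * E * S / (K_half + S) + noise."""
    S = np.asarray(grid, dtype=float)
    if (S < 0).any():
        raise ModelError("substrate grid must be non-negative")
    rng = np.random.default_rng(seed)
    vmax = k_cat * enzyme_conc
    v = vmax * S / (K_half + S)
    return S, v + rng.normal(0.0, sigma * vmax, S.size)
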