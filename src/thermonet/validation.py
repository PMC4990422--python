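"""End-to-end validation experiments on synthetic data.

These runners exercise the full pipeline — design, simulation, fitting,
profiling — and measure how well it recovers known ground truth:

* :func:`recovery_experiment`: the 20-dataset study at fraction-unwound
  noise sd 0.03; every free parameter is profiled and parameters that the
  design determines at the tested precision (two-sided 95% CI no wider
  than the recovery tolerance) must be recovered within that tolerance.
* :func:`coverage_experiment`: many replicate scaled-down designs with
  known observation noise; the 95% profile CI of a focal parameter should
  cover the truth at close to nominal frequency.
* :func:`limit_experiment`: a design saturated in ATP cannot determine an
  ATP-binding constant on both sides; its profile must come out as a
  one-sided limit.

Each experiment is a pure function of (model, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import ModelGraph
from .inference import Dataset, fit_global, profile_parameter, ProfileCurve
from .synthetic import (
    COMP_IDS,
    DesignSpec,
    GroundTruth,
    TitrationPlan,
    _plan_conditions,
    build_synthetic_study,
    default_ground_truth,
    make_design,
    simulate_k_unw,
)

__all__ = [
    "RecoveryResult",
    "recovery_experiment",
    "coverage_experiment",
    "limit_experiment",
    "simulate_rate_datasets",
    "reduced_plans",
]

#: recovery tolerance: |log10(fit/truth)| for binding constants
K_TOL_DEX = 0.3
#: recovery tolerance: relative error for rate constants
KMAX_TOL_REL = 0.15


def simulate_rate_datasets(
    model: ModelGraph,
    truth: GroundTruth,
    plans: Sequence[TitrationPlan],
    seed: int = 0,
    sigma_rel: float = 0.05,
    sigma_floor: float = 2e-3,
    noise: bool = True,
) -> list[Dataset]:
    """Datasets with noise applied directly to observed rate constants.

    Used by the calibration experiments, where a known observation noise
    (relative sd ``sigma_rel`` with floor ``sigma_floor``, 1/min) keeps
    the chi-square scale exact.  With ``noise=False`` the observations
    are the exact model predictions (the stated sigma is still attached).
    """
    rng = np.random.default_rng(seed)
    k_clean = simulate_k_unw(model, truth, plans)
    out = []
    for plan, k in zip(plans, k_clean):
        sig = np.maximum(sigma_rel * k, sigma_floor)
        obs = k + rng.normal(0.0, sig) if noise else k.copy()
        out.append(Dataset(
            id=plan.id, varied=plan.varied, comp_ids=COMP_IDS,
            conditions=_plan_conditions(plan),
            observations=obs[:, None],
            complex_class=plan.complex_class,
            sigma_known=sig,
        ))
    return out


def reduced_plans(low_atp: bool = False) -> list[TitrationPlan]:
    """Scaled-down design: the Ded1p-eIF4A subsystem (3 datasets).

    With ``low_atp`` every reaction stays at or below 10 uM ATP, an order
    of magnitude under the ATP K_1/2 of RNA-bound Ded1p: the design then
    probes only the linear (k_max * T / K) regime of that constant.
    """
    plans = [p for p in make_design(DesignSpec()) if p.id in ("DA-D", "DA-A")]
    if low_atp:
        plans = [replace_fixed(p, T=1e-5) for p in plans]
        grid = tuple(np.geomspace(1e-6, 1e-5, 8))
    else:
        grid = tuple(np.geomspace(1.5e-5, 4e-3, 8))
    plans.append(TitrationPlan("DA-T", "DA", "T", grid, {"D": 1e-7, "A": 2e-6}))
    return plans


def replace_fixed(plan: TitrationPlan, **fixed) -> TitrationPlan:
    new_fixed = dict(plan.fixed) | fixed
    return TitrationPlan(plan.id, plan.complex_class, plan.varied, plan.grid, new_fixed)


#: free parameters of the reduced Ded1p-eIF4A experiments; the remaining
#: constants are held at truth so the focal profiles stay cheap
REDUCED_FREE = ("DA", "DRT", "k_DA", "k_D3")


def _freeze_all_but(model: ModelGraph, truth: GroundTruth, free: Sequence[str]) -> list[str]:
    names = [g.id for g in model.groups] + [a.rate for a in model.active]
    return [n for n in names if n not in free]


@dataclass
class RecoveryResult:
    """Outcome of the full-design parameter-recovery experiment."""

    r2: float
    chi2: float
    n_obs: int
    errors_dex: dict[str, float]  # log10(fit / truth) for K parameters
    errors_rel: dict[str, float]  # fit/truth - 1 for k_max parameters
    identifiable: list[str]  # parameters determined at the tested precision
    profiles: dict[str, ProfileCurve] = field(default_factory=dict)

    @property
    def max_identifiable_K_error_dex(self) -> float:
        vals = [abs(v) for n, v in self.errors_dex.items() if n in self.identifiable]
        return max(vals, default=np.nan)

    @property
    def max_identifiable_kmax_error_rel(self) -> float:
        vals = [abs(v) for n, v in self.errors_rel.items() if n in self.identifiable]
        return max(vals, default=np.nan)


def recovery_experiment(
    model: ModelGraph,
    seed: int = 1,
    n_starts: int = 3,
    profile: bool = True,
) -> RecoveryResult:
    """Ground-truth recovery on the default 20-dataset synthetic study.

    A parameter counts as identifiable at the tested precision when its
    95% profile CI is two-sided and no wider than the recovery tolerance
    band (0.3 decades for K, 15% for k_max); the experiment then requires
    those parameters to land within tolerance.
    """
    truth = default_ground_truth(model)
    datasets = build_synthetic_study(model, truth, seed=seed)
    result = fit_global(model, datasets, n_starts=n_starts, seed=seed)

    errors_dex, errors_rel = {}, {}
    for name in result.free_parameters:
        kind, key = name.split(":", 1)
        fit_v = result.parameter_value(name)
        if kind == "K":
            errors_dex[name] = float(np.log10(fit_v / truth.params.K[key]))
        else:
            errors_rel[name] = float(fit_v / truth.params.k_max[key] - 1.0)

    identifiable: list[str] = []
    profiles: dict[str, ProfileCurve] = {}
    if profile:
        for name in result.free_parameters:
            prof = profile_parameter(model, datasets, result, name, max_nfev=40)
            profiles[name] = prof
            if prof.ci_lower is None or prof.ci_upper is None:
                continue
            half_width_dex = 0.5 * np.log10(prof.ci_upper / prof.ci_lower)
            tol = K_TOL_DEX if name.startswith("K:") else np.log10(1 + KMAX_TOL_REL)
            if half_width_dex <= tol:
                identifiable.append(name)
    return RecoveryResult(
        r2=result.r2, chi2=result.chi2, n_obs=result.n_obs,
        errors_dex=errors_dex, errors_rel=errors_rel,
        identifiable=identifiable, profiles=profiles,
    )


def coverage_experiment(
    model: ModelGraph,
    n_replicates: int = 50,
    seed: int = 0,
    parameter: str = "K:DA",
    n_starts: int = 1,
) -> dict:
    """Coverage of the 95% profile CI over replicate scaled-down designs.

    Each replicate simulates the Ded1p-eIF4A subsystem with known noise,
    fits its four free parameters from a generic start, and profiles the
    focal parameter.  Returns the covered count; a CI missing one side
    counts as covering on that side.
    """
    truth = default_ground_truth(model)
    frozen = _freeze_all_but(model, truth, REDUCED_FREE)
    plans = reduced_plans()
    key = parameter.split(":", 1)[1]
    true_v = truth.params.K.get(key, truth.params.k_max.get(key))
    rng = np.random.default_rng(seed)
    covered = 0
    intervals = []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        datasets = simulate_rate_datasets(model, truth, plans, seed=rep_seed)
        result = fit_global(model, datasets, init=truth.params, frozen=frozen,
                            n_starts=n_starts, seed=rep_seed)
        prof = profile_parameter(model, datasets, result, parameter,
                                 step_dex=0.3, max_nfev=30)
        lo = prof.ci_lower if prof.ci_lower is not None else 0.0
        hi = prof.ci_upper if prof.ci_upper is not None else np.inf
        intervals.append((lo, hi))
        if lo <= true_v <= hi:
            covered += 1
    return {
        "parameter": parameter,
        "true_value": true_v,
        "covered": covered,
        "n_replicates": n_replicates,
        "coverage": covered / n_replicates,
        "intervals": intervals,
    }


def limit_experiment(model: ModelGraph, seed: int = 0) -> ProfileCurve:
    """Profile of an ATP-binding constant the design cannot bound above.

    With every reaction at or below a tenth of the true ATP K_1/2 of
    RNA-bound Ded1p, the data only see the linear regime where the rate
    and binding constants enter as the ratio k_max * T / K: weakening the
    constant is absorbed exactly by a larger rate constant, while
    tightening it predicts saturation curvature the flat titration
    contradicts.  The profile therefore crosses the 95% threshold below
    the optimum only and the constant is reported as a lower limit
    (K greater than the bound), the behavior of ATP-binding constants
    whose affinity lies beyond the probed concentration range.
    """
    truth = default_ground_truth(model)
    frozen = _freeze_all_but(model, truth, REDUCED_FREE)
    plans = reduced_plans(low_atp=True)
    datasets = simulate_rate_datasets(model, truth, plans, seed=seed)
    result = fit_global(model, datasets, init=truth.params, frozen=frozen,
                        n_starts=2, seed=seed)
    grid = 10.0 ** np.linspace(-6.0, -1.0, 11)
    return profile_parameter(model, datasets, result, "K:DRT", grid=grid, max_nfev=60)
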