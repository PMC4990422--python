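"""Global fitting of the thermodynamic framework to titration datasets.

A *dataset* collects all unwinding reactions for the titration of one
component (a protein or ATP) with the others held constant.  The global
fit adjusts the free linkage-group constants and the maximal rate
constants of the active complexes, in log space, to minimize

    chi^2 = sum over conditions  (k_obs - k_calc)^2 / sigma^2

across all datasets simultaneously, under rapid-equilibrium binding
(k_calc from equilibrium occupancies).  Cycle constraints are satisfied
by construction at every iterate because only group constants are ever
varied; dependent reaction constants are derived, never fitted.

Confidence intervals come from chi-square profiling: one parameter is
scanned, all others are re-optimized, and the 95% interval is where the
relative chi-square crosses an F-statistic threshold.  Parameters whose
profile never crosses on one side within the search bounds are reported
as one-sided limits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .network import ModelGraph, ModelError, ParameterSet
from .speciation import compile_model
from .kinetics import predict_k_unw_batch

__all__ = [
    "Dataset",
    "GlobalFitResult",
    "ProfileCurve",
    "chi_square",
    "fit_global",
    "profile_parameter",
    "report",
]

#: optimizer box bounds in log10 units
K_BOUNDS = (-12.0, 0.0)
KMAX_BOUNDS = (-4.0, 3.0)


@dataclass
class Dataset:
    """One titration dataset: conditions and replicate observed k_unw.

    ``conditions`` is an (n, c) array of component totals (molar) in the
    order ``comp_ids``; ``observations`` an (n, r) array of replicate
    observed unwinding rate constants (1/min).
    """

    id: str
    varied: str
    comp_ids: tuple[str, ...]
    conditions: np.ndarray
    observations: np.ndarray
    substrate: str = "16bp-25nt-3p"
    complex_class: str = ""
    sigma_known: np.ndarray | None = None  # overrides replicate spread when set

    def __post_init__(self):
        self.conditions = np.atleast_2d(np.asarray(self.conditions, dtype=float))
        self.observations = np.atleast_2d(np.asarray(self.observations, dtype=float))
        if self.varied not in self.comp_ids:
            raise ModelError(f"dataset {self.id}: varied component {self.varied!r} not in {self.comp_ids}")
        if self.conditions.shape[0] != self.observations.shape[0]:
            raise ModelError(f"dataset {self.id}: conditions/observations mismatch")
        if self.conditions.shape[0] < 3:
            raise ModelError(f"dataset {self.id}: need at least 3 titration points")

    @property
    def n_points(self) -> int:
        return self.conditions.shape[0]

    def observed(self) -> np.ndarray:
        """Per-condition observed k_unw: replicate median.

        The median is robust against the occasional degenerate time-course
        fit (a near-flat noisy curve can be fit by an arbitrarily fast,
        low-amplitude exponential).
        """
        return np.median(self.observations, axis=1)

    def sigma(self, sigma_min: float = 1e-3, rel_floor: float = 0.03) -> np.ndarray:
        """Per-condition uncertainty: robust replicate spread with floors.

        1.4826 * MAD scales the median absolute deviation to a normal
        standard deviation; division by sqrt(n) gives the uncertainty of
        the central value.  Absolute and relative floors guard conditions
        whose replicates agree by chance.
        """
        if self.sigma_known is not None:
            return np.asarray(self.sigma_known, dtype=float)
        n_rep = self.observations.shape[1]
        med = self.observed()
        if n_rep > 1:
            mad = np.median(np.abs(self.observations - med[:, None]), axis=1)
            sem = 1.4826 * mad / np.sqrt(n_rep)
        else:
            sem = np.zeros(self.n_points)
        return np.maximum.reduce([sem, np.full(self.n_points, sigma_min),
                                  rel_floor * np.abs(med)])


@dataclass(frozen=True)
class ProfileCurve:
    """Relative chi-square profile of one parameter with 95% bounds."""

    parameter: str
    values: np.ndarray
    rel_chi2: np.ndarray
    threshold: float
    ci_lower: float | None
    ci_upper: float | None

    @property
    def one_sided(self) -> bool:
        return (self.ci_lower is None) != (self.ci_upper is None)

    @property
    def limit_direction(self) -> str | None:
        """"le": only an upper bound is constrained; "ge": only a lower bound."""
        if not self.one_sided:
            return None
        return "le" if self.ci_lower is None else "ge"


@dataclass
class GlobalFitResult:
    """Best-fit parameters, chi-square, and observed-vs-calculated table."""

    best_fit: ParameterSet
    chi2: float
    per_dataset_chi2: dict[str, float]
    obs_vs_calc: pd.DataFrame
    r2: float
    free_parameters: tuple[str, ...]
    n_obs: int
    n_starts: int
    converged: bool
    profiles: dict[str, ProfileCurve] = field(default_factory=dict)

    def parameter_value(self, name: str) -> float:
        kind, key = name.split(":", 1)
        return self.best_fit.K[key] if kind == "K" else self.best_fit.k_max[key]


def _stack_conditions(datasets: Sequence[Dataset]) -> tuple[np.ndarray, tuple[str, ...], np.ndarray]:
    comp_ids = datasets[0].comp_ids
    for d in datasets:
        if d.comp_ids != comp_ids:
            raise ModelError("datasets disagree on component order")
    conds = np.vstack([d.conditions for d in datasets])
    lengths = np.array([d.n_points for d in datasets])
    return conds, comp_ids, lengths


def _predict_all(model, params, datasets, cm=None) -> np.ndarray:
    conds, comp_ids, _ = _stack_conditions(datasets)
    cm = cm or compile_model(model, params)
    totals = np.zeros((conds.shape[0], len(cm.comp_ids)))
    for j, c in enumerate(comp_ids):
        totals[:, cm.comp_ids.index(c)] = conds[:, j]
    return predict_k_unw_batch(model, params, totals, cm)


def chi_square(
    model: ModelGraph,
    params: ParameterSet,
    datasets: Sequence[Dataset],
    sigma_min: float = 1e-3,
    rel_floor: float = 0.03,
) -> tuple[float, dict[str, float]]:
    """Total and per-dataset chi-square of the model prediction."""
    pred = _predict_all(model, params, datasets)
    out: dict[str, float] = {}
    pos = 0
    for d in datasets:
        p = pred[pos:pos + d.n_points]
        r = (d.observed() - p) / d.sigma(sigma_min, rel_floor)
        out[d.id] = float(r @ r)
        pos += d.n_points
    return float(sum(out.values())), out


class _FitProblem:
    """Packs/unpacks the log10 parameter vector and evaluates residuals."""

    def __init__(self, model, datasets, init, frozen, sigma_min, rel_floor):
        self.model = model
        self.datasets = list(datasets)
        self.base = init.copy()
        frozen = set(frozen) | set(init.fixed)
        self.names = (
            [f"K:{g.id}" for g in model.groups if g.id not in frozen]
            + [f"k:{a.rate}" for a in model.active if a.rate not in frozen]
        )
        self.lo = np.array([K_BOUNDS[0] if n.startswith("K:") else KMAX_BOUNDS[0] for n in self.names])
        self.hi = np.array([K_BOUNDS[1] if n.startswith("K:") else KMAX_BOUNDS[1] for n in self.names])
        self.obs = np.concatenate([d.observed() for d in self.datasets])
        self.sig = np.concatenate([d.sigma(sigma_min, rel_floor) for d in self.datasets])

    def x0(self) -> np.ndarray:
        vals = []
        for n in self.names:
            kind, key = n.split(":", 1)
            vals.append(self.base.K[key] if kind == "K" else self.base.k_max[key])
        return np.log10(vals)

    def params(self, x: np.ndarray) -> ParameterSet:
        K = dict(self.base.K)
        kmax = dict(self.base.k_max)
        for n, v in zip(self.names, x):
            kind, key = n.split(":", 1)
            (K if kind == "K" else kmax)[key] = 10.0 ** float(v)
        return ParameterSet(K, kmax, self.base.fixed)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        pred = _predict_all(self.model, self.params(x), self.datasets)
        return (self.obs - pred) / self.sig

    def solve(self, x0: np.ndarray, max_nfev: int | None = None):
        return least_squares(
            self.residuals, np.clip(x0, self.lo, self.hi),
            bounds=(self.lo, self.hi), method="trf",
            ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=max_nfev,
        )


def _default_init(model: ModelGraph, datasets: Sequence[Dataset]) -> ParameterSet:
    """Generic starting point: mid-range constants, rates at the observed maximum."""
    base = model.default_parameters()
    kmax0 = max(float(np.max(d.observations)) for d in datasets)
    K = {g.id: (g.K_half if g.fixed else 1e-6) for g in model.groups}
    kmax = {a.rate: max(kmax0, 1e-3) for a in model.active}
    return ParameterSet(K, kmax, base.fixed)  # type: ignore[arg-type]


def fit_global(
    model: ModelGraph,
    datasets: Sequence[Dataset],
    init: ParameterSet | None = None,
    frozen: Sequence[str] = (),
    n_starts: int = 10,
    seed: int = 0,
    sigma_min: float = 1e-3,
    rel_floor: float = 0.03,
    max_nfev: int | None = None,
) -> GlobalFitResult:
    """Simultaneous least-squares fit of all datasets in log-parameter space.

    ``n_starts`` seeded restarts perturb the starting point by 0.5 decades
    (the first start is unperturbed); the best local minimum is retained.
    Groups flagged fixed in the parameter set and names in ``frozen`` are
    held at their initial values.
    """
    if not datasets:
        raise ModelError("no datasets to fit")
    init = init or _default_init(model, datasets)
    prob = _FitProblem(model, datasets, init, frozen, sigma_min, rel_floor)
    rng = np.random.default_rng(seed)
    x0 = prob.x0()
    best = None
    for start in range(max(1, n_starts)):
        xs = x0 if start == 0 else x0 + rng.normal(0.0, 0.5, x0.size)
        try:
            sol = prob.solve(xs, max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ModelError("global fit failed from every start")

    params = prob.params(best.x)
    total, per_ds = chi_square(model, params, datasets, sigma_min, rel_floor)
    pred = _predict_all(model, params, datasets)
    rows = []
    pos = 0
    for d in datasets:
        mean = d.observed()
        sig = d.sigma(sigma_min, rel_floor)
        for i in range(d.n_points):
            rows.append({
                "dataset": d.id,
                "varied": d.varied,
                "concentration": d.conditions[i, d.comp_ids.index(d.varied)],
                "observed": mean[i],
                "sigma": sig[i],
                "calculated": pred[pos + i],
            })
        pos += d.n_points
    table = pd.DataFrame(rows)
    obs = table["observed"].to_numpy()
    calc = table["calculated"].to_numpy()
    ss_res = float(np.sum((obs - calc) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return GlobalFitResult(
        best_fit=params,
        chi2=total,
        per_dataset_chi2=per_ds,
        obs_vs_calc=table,
        r2=r2,
        free_parameters=tuple(prob.names),
        n_obs=int(table.shape[0]),
        n_starts=n_starts,
        converged=bool(best.success),
    )


def profile_threshold(chi2_opt: float, n_obs: int, n_free: int, alpha: float = 0.05) -> float:
    """95% relative chi-square threshold, F-statistic based (one profiled parameter)."""
    dof = max(n_obs - n_free, 1)
    return chi2_opt * (1.0 + stats.f.ppf(1.0 - alpha, 1, dof) / dof)


def profile_parameter(
    model: ModelGraph,
    datasets: Sequence[Dataset],
    result: GlobalFitResult,
    parameter: str,
    grid: Sequence[float] | None = None,
    alpha: float = 0.05,
    step_dex: float = 0.25,
    max_steps: int = 14,
    sigma_min: float = 1e-3,
    rel_floor: float = 0.03,
    max_nfev: int = 60,
) -> ProfileCurve:
    """Chi-square profile of one parameter with re-optimization of the rest.

    With ``grid=None`` the profile walks outward from the optimum in
    ``step_dex`` decade steps until the threshold is crossed or a bound is
    reached; a side that never crosses is reported as unbounded, making
    the parameter a one-sided limit.
    """
    if parameter not in result.free_parameters:
        raise ModelError(f"{parameter!r} is not a free parameter of the fit")
    # re-optimize exactly the parameters the original fit varied
    all_names = [f"K:{g.id}" for g in model.groups] + [f"k:{a.rate}" for a in model.active]
    frozen = [n.split(":", 1)[1] for n in all_names if n not in result.free_parameters]
    prob = _FitProblem(model, datasets, result.best_fit, frozen, sigma_min, rel_floor)
    idx = prob.names.index(parameter)
    keep = [i for i in range(len(prob.names)) if i != idx]
    x_opt = prob.x0()
    chi2_opt = max(float(2 * 0.5 * np.sum(prob.residuals(x_opt) ** 2)), 1e-30)
    thresh = profile_threshold(chi2_opt, prob.obs.size, len(prob.names), alpha)

    lo_b, hi_b = prob.lo[idx], prob.hi[idx]

    def chi2_at(logv: float) -> float:
        sub_lo, sub_hi = prob.lo[keep], prob.hi[keep]

        def res(y):
            x = np.empty(len(prob.names))
            x[keep] = y
            x[idx] = logv
            return prob.residuals(x)

        sol = least_squares(res, np.clip(x_opt[keep], sub_lo, sub_hi),
                            bounds=(sub_lo, sub_hi), method="trf",
                            ftol=1e-9, xtol=1e-9, max_nfev=max_nfev)
        return float(2 * sol.cost)

    if grid is not None:
        values = np.asarray(sorted(grid), dtype=float)
        rel = np.array([chi2_at(np.log10(v)) for v in values]) / chi2_opt
    else:
        logs = [x_opt[idx]]
        rels = [1.0]
        for sign in (-1, +1):
            v = x_opt[idx]
            for _ in range(max_steps):
                v += sign * step_dex
                if v < lo_b or v > hi_b:
                    break
                r = chi2_at(v) / chi2_opt
                logs.append(v)
                rels.append(r)
                if r > thresh / chi2_opt * 1.5:
                    break
        order = np.argsort(logs)
        values = 10.0 ** np.asarray(logs)[order]
        rel = np.asarray(rels)[order]

    rel_thresh = thresh / chi2_opt
    opt_pos = int(np.argmin(rel))

    def crossing(side: int) -> float | None:
        if side < 0:
            vs, rs = values[:opt_pos + 1][::-1], rel[:opt_pos + 1][::-1]
        else:
            vs, rs = values[opt_pos:], rel[opt_pos:]
        for (v0, r0), (v1, r1) in zip(zip(vs, rs), zip(vs[1:], rs[1:])):
            if (r0 <= rel_thresh < r1):
                # chi2 is locally quadratic in the log parameter, so
                # sqrt(rel - 1) is locally linear: interpolate there
                s0, s1 = np.sqrt(max(r0 - 1, 0.0)), np.sqrt(r1 - 1)
                st = np.sqrt(rel_thresh - 1)
                t = (st - s0) / (s1 - s0) if s1 > s0 else 0.5
                return float(10 ** (np.log10(v0) + t * (np.log10(v1) - np.log10(v0))))
        return None

    return ProfileCurve(
        parameter=parameter,
        values=values,
        rel_chi2=np.maximum(rel, 1.0),
        threshold=rel_thresh,
        ci_lower=crossing(-1),
        ci_upper=crossing(+1),
    )


def report(result: GlobalFitResult, outdir: str | Path, plot: bool = False) -> dict[str, Path]:
    """Write machine-readable fit reports (JSON parameters, CSV table).

    Content is a deterministic function of the result.  Raises on an
    empty observed-vs-calculated table.
    """
    if result.obs_vs_calc.empty:
        raise ModelError("result has an empty observed-vs-calculated table")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name in result.free_parameters:
        entry: dict = {"estimate": result.parameter_value(name)}
        prof = result.profiles.get(name)
        if prof is not None:
            entry["ci_95"] = [prof.ci_lower, prof.ci_upper]
            if prof.one_sided:
                entry["limit"] = prof.limit_direction
                entry["bound"] = prof.ci_upper if prof.limit_direction == "le" else prof.ci_lower
        entries[name] = entry
    payload = {
        "chi2": result.chi2,
        "r2": result.r2,
        "n_obs": result.n_obs,
        "per_dataset_chi2": dict(sorted(result.per_dataset_chi2.items())),
        "parameters": dict(sorted(entries.items())),
        "fixed": result.best_fit.to_dict(),
    }
    params_path = outdir / "parameters.json"
    params_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    table_path = outdir / "obs_vs_calc.csv"
    result.obs_vs_calc.to_csv(table_path, index=False)
    paths = {"parameters": params_path, "obs_vs_calc": table_path}
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        t = result.obs_vs_calc
        ax.errorbar(t["observed"], t["calculated"], xerr=t["sigma"], fmt="o", ms=3, alpha=0.6)
        lim = [0, max(t["observed"].max(), t["calculated"].max()) * 1.05]
        ax.plot(lim, lim, "k-", lw=1)
        ax.set_xlabel("observed k_unw (1/min)")
        ax.set_ylabel("calculated k_unw (1/min)")
        ax.set_title(f"R$^2$ = {result.r2:.3f}")
        fig.tight_layout()
        plot_path = outdir / "obs_vs_calc.png"
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
        paths["plot"] = plot_path
    return paths
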