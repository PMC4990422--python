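"""Kinetic and binding observables: fitting and prediction.

Pre-steady-state duplex unwinding with simultaneous strand annealing
follows

    F(t) = A * (1 - exp(-(k_unw + k_ann) * t)),   A = k_unw / (k_unw + k_ann)

where ``F`` is the fraction of duplex unwound, ``k_unw`` the observed
unwinding rate constant and ``k_ann`` the annealing rate constant that
caps the reaction amplitude below one.  The module also fits functional
binding isotherms (hyperbolic or Hill), Michaelis-Menten ATPase
titrations, and the quadratic (ligand-depletion) binding isotherm used
for tight complexes in MST experiments, and predicts observed unwinding
rate constants from equilibrium speciation: under rapid-equilibrium
binding, the prediction is the occupancy-weighted sum of the maximal
rate constants of the active complexes over the trace substrate pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .network import ModelGraph, ModelError, ParameterSet
from .speciation import CompiledModel, ConcentrationState, substrate_partition_batch

__all__ = [
    "TimeCourse",
    "UnwindingFit",
    "IsothermFit",
    "ATPaseFit",
    "QuadraticBindingFit",
    "FitError",
    "fit_unwinding_timecourse",
    "fit_hill_isotherm",
    "fit_michaelis_menten",
    "fit_quadratic_binding",
    "quadratic_isotherm",
    "predict_k_unw",
    "predict_k_unw_batch",
]


class FitError(RuntimeError):
    """A curve fit failed or the data are degenerate."""


@dataclass(frozen=True)
class TimeCourse:
    """One unwinding reaction progress curve.

    Times in minutes, fraction unwound dimensionless.  ``meta`` carries
    the reaction condition (component concentrations in molar, substrate
    and replicate ids).
    """

    times: np.ndarray
    fraction_unwound: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fraction_unwound, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fraction_unwound", f)
        if t.ndim != 1 or t.shape != f.shape:
            raise ModelError("times and fractions must be matching 1-d arrays")
        if not (np.diff(t) > 0).all():
            raise ModelError("times must be strictly increasing")


@dataclass(frozen=True)
class UnwindingFit:
    """Observed unwinding and annealing rate constants (1/min)."""

    k_unw: float
    k_ann: float
    k_unw_stderr: float
    k_ann_stderr: float

    @property
    def amplitude(self) -> float:
        return self.k_unw / (self.k_unw + self.k_ann) if self.k_unw + self.k_ann > 0 else 0.0

    @property
    def k_obs(self) -> float:
        """Observed exponential rate constant, k_unw + k_ann."""
        return self.k_unw + self.k_ann


@dataclass(frozen=True)
class IsothermFit:
    """Functional binding isotherm: k = k_max * x^n / (K^n + x^n)."""

    K_half: float
    k_max: float
    hill_n: float
    K_half_stderr: float
    k_max_stderr: float
    hill_n_stderr: float


@dataclass(frozen=True)
class ATPaseFit:
    """Michaelis-Menten fit of an ATP or RNA titration of ATPase rates."""

    K_half: float
    v_max: float
    K_half_stderr: float
    v_max_stderr: float
    enzyme_conc: float | None = None

    @property
    def k_cat(self) -> float | None:
        return self.v_max / self.enzyme_conc if self.enzyme_conc else None


@dataclass(frozen=True)
class QuadraticBindingFit:
    """Tight-binding (ligand depletion) isotherm fit."""

    K_prime_half: float
    amplitude: float
    fixed_site_conc: float
    K_stderr: float
    amplitude_stderr: float


def _two_rate_curve(t, k_unw, k_ann):
    k = k_unw + k_ann
    with np.errstate(over="ignore"):
        decay = -np.expm1(-k * t)
    amp = np.where(k > 0, k_unw / np.where(k > 0, k, 1.0), 0.0)
    return amp * decay


def fit_unwinding_timecourse(tc: TimeCourse) -> UnwindingFit:
    """Least-squares fit of the two-rate (unwinding + annealing) law.

    Initial guesses are deterministic: the observed exponential rate from
    the early log-linear slope, the annealing rate from the plateau
    deficit.
    """
    t, f = tc.times, tc.fraction_unwound
    if t.size < 4:
        raise FitError("need at least 4 time points")
    if np.allclose(f, 0.0, atol=1e-12):
        raise FitError("all-zero signal")
    plateau = float(np.clip(np.mean(f[t >= t[-1] / 2]), 1e-6, 1.0))
    # early-time slope of the exponential approach: F ~ A k t
    head = slice(0, max(2, t.size // 3))
    slope = max(float(np.polyfit(t[head], f[head], 1)[0]), 1e-9)
    k_obs0 = float(np.clip(slope / plateau, 1e-6, 1e3))
    k_unw0 = plateau * k_obs0
    k_ann0 = max(k_obs0 - k_unw0, 1e-9)
    try:
        popt, pcov = curve_fit(
            _two_rate_curve, t, f, p0=[k_unw0, k_ann0],
            bounds=([0.0, 0.0], [1e4, 1e4]), maxfev=10000,
            ftol=1e-12, xtol=1e-12, gtol=1e-12,
        )
    except RuntimeError as exc:
        raise FitError(f"unwinding fit did not converge: {exc}") from exc
    err = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return UnwindingFit(float(popt[0]), float(popt[1]), float(err[0]), float(err[1]))


def fit_hill_isotherm(
    doses: Sequence[float],
    responses: Sequence[float],
    fix_n: float | None = None,
) -> IsothermFit:
    """Fit a (Hill) binding isotherm to dose-response data.

    ``fix_n=1`` recovers the hyperbolic isotherm.  Raises on degenerate
    (flat) responses.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 4:
        raise FitError("need at least 4 doses")
    if np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        raise FitError("degenerate (constant) responses")
    ymax = float(y.max())
    K0 = float(x[np.argmin(np.abs(y - ymax / 2))]) or float(np.median(x))

    def hill(x, K, kmax, n):
        xn = np.power(np.clip(x, 0, None), n)
        return kmax * xn / (np.power(K, n) + xn)

    if fix_n is not None:
        popt, pcov = curve_fit(
            lambda x, K, kmax: hill(x, K, kmax, fix_n), x, y,
            p0=[K0, ymax], bounds=([1e-15, 0], [1.0, np.inf]), maxfev=20000,
        )
        err = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        return IsothermFit(float(popt[0]), float(popt[1]), float(fix_n),
                           float(err[0]), float(err[1]), 0.0)
    popt, pcov = curve_fit(
        hill, x, y, p0=[K0, ymax, 1.5],
        bounds=([1e-15, 0, 0.1], [1.0, np.inf, 10.0]), maxfev=20000,
    )
    err = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return IsothermFit(float(popt[0]), float(popt[1]), float(popt[2]),
                       float(err[0]), float(err[1]), float(err[2]))


def fit_michaelis_menten(
    substrate: Sequence[float],
    rates: Sequence[float],
    enzyme_conc: float | None = None,
) -> ATPaseFit:
    """Fit V = Vmax * S / (K_half + S); used for ATP and RNA titrations."""
    S = np.asarray(substrate, dtype=float)
    v = np.asarray(rates, dtype=float)
    if S.size < 4:
        raise FitError("need at least 4 substrate concentrations")
    if np.ptp(v) < 1e-12 * max(1.0, np.abs(v).max()):
        raise FitError("degenerate (constant) rates")
    vmax0 = float(v.max())
    K0 = float(S[np.argmin(np.abs(v - vmax0 / 2))]) or float(np.median(S))
    popt, pcov = curve_fit(
        lambda S, K, vmax: vmax * S / (K + S), S, v,
        p0=[K0, vmax0], bounds=([1e-15, 0], [np.inf, np.inf]), maxfev=20000,
    )
    err = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return ATPaseFit(float(popt[0]), float(popt[1]), float(err[0]), float(err[1]), enzyme_conc)


def quadratic_isotherm(x, K, a):
    """Bound fraction of fixed sites at concentration ``a`` titrated by ``x``.

    f = ((a + x + K) - sqrt((a + x + K)^2 - 4 a x)) / (2 a); reduces to the
    hyperbola x/(x+K) as a -> 0 and to a stoichiometric breakpoint at
    x = a as K -> 0.
    """
    x = np.asarray(x, dtype=float)
    s = a + x + K
    disc = np.clip(s * s - 4 * a * x, 0.0, None)
    return (s - np.sqrt(disc)) / (2 * a)


def fit_quadratic_binding(
    titrant: Sequence[float],
    signal: Sequence[float],
    fixed_site_conc: float,
) -> QuadraticBindingFit:
    """Fit the tight-binding isotherm with a floating signal amplitude."""
    if not fixed_site_conc > 0:
        raise FitError("fixed_site_conc must be positive")
    x = np.asarray(titrant, dtype=float)
    y = np.asarray(signal, dtype=float)
    if x.size < 4:
        raise FitError("need at least 4 titrant concentrations")
    popt, pcov = curve_fit(
        lambda x, K, amp: amp * quadratic_isotherm(x, K, fixed_site_conc),
        x, y, p0=[fixed_site_conc / 4, max(float(y.max()), 1e-12)],
        bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
    )
    err = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return QuadraticBindingFit(float(popt[0]), float(popt[1]), float(fixed_site_conc),
                               float(err[0]), float(err[1]))


# -- rate prediction from speciation --------------------------------------

def predict_k_unw(
    model: ModelGraph,
    params: ParameterSet,
    state: ConcentrationState,
    cm: CompiledModel | None = None,
) -> float:
    """Observed unwinding rate constant predicted from complex occupancies.

    k_pred = sum over active complexes i of k_max,i times the fraction of
    trace substrate bound in complex i in its required ATP state.  The
    active-complex roster (with ATP requirements) comes from the model:
    classes listing several expanded species (the eIF4A ATP sub-states of
    the Ded1p-eIF4A complex) contribute all of them with one rate.
    """
    return float(predict_k_unw_batch(model, params, [state], cm)[0])


def predict_k_unw_batch(
    model: ModelGraph,
    params: ParameterSet,
    states: Sequence[ConcentrationState] | np.ndarray,
    cm: CompiledModel | None = None,
) -> np.ndarray:
    missing = [a.rate for a in model.active if a.rate not in params.k_max]
    if missing:
        raise ModelError(f"missing rate parameters: {missing}")
    part = substrate_partition_batch(model, params, states, cm)
    n = next(iter(part.values())).shape[0]
    k = np.zeros(n)
    for a in model.active:
        occ = sum(part[sid] for sid in a.species)
        k += params.k_max[a.rate] * occ
    return k
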