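"""Equilibrium speciation of the binding network.

Given total (or buffered free) concentrations of every component, the
solver finds the free concentrations that satisfy mass balance under
mass-action equilibrium, then reports the concentration of every complex
and the fraction of each component residing in it.

The root finding runs in log free-concentration space, which keeps every
concentration positive, with a damped Newton iteration started at
``free = total``.  RNA and ATP are buffered by default (free
concentration fixed at the stated value): unwinding experiments use trace
duplex substrate and ATP far above its K_1/2, so neither is measurably
depleted by binding.  Conserved mode is available for both.

Substrate partitioning for rate prediction uses the trace limit
explicitly: protein speciation is solved with the substrate absent, and
the substrate is then distributed over the protein states in proportion
to their binding weights.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .network import ModelGraph, ModelError, ParameterSet

__all__ = [
    "ConcentrationState",
    "SpeciationResult",
    "SolverError",
    "compile_model",
    "solve_speciation",
    "solve_speciation_batch",
    "substrate_partition",
    "prevalence_report",
    "titration_curve",
]

#: sentinel for ln(0); finite so that 0 * LOG_ZERO == 0 in stoichiometry sums
LOG_ZERO = -1.0e6


class SolverError(RuntimeError):
    """Speciation iteration failed to reach the requested tolerance."""


@dataclass(frozen=True)
class ConcentrationState:
    """Total concentrations (molar) plus buffering flags.

    ``buffered`` components have their *free* concentration pinned at the
    stated value instead of being conserved.  ``None`` selects the model
    default: RNA and ATP buffered, proteins conserved.
    """

    totals: Mapping[str, float]
    buffered: frozenset[str] | None = None
    temperature: float = 298.15

    def resolve_buffered(self, model: ModelGraph) -> frozenset[str]:
        if self.buffered is not None:
            return frozenset(self.buffered)
        return frozenset({model.rna_id, model.atp_id}) - {None}

    def label(self) -> str:
        return ", ".join(f"{c}={v:.3g}" for c, v in sorted(self.totals.items()))


@dataclass
class SpeciationResult:
    """Free concentrations, per-species concentrations and occupancies."""

    free: dict[str, float]
    concentrations: dict[str, float]
    fractions_by_component: dict[str, dict[str, float]]
    residuals: dict[str, float]
    state: ConcentrationState

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"concentration": pd.Series(self.concentrations)}
        ).rename_axis("species")


@dataclass(frozen=True)
class CompiledModel:
    """Stoichiometry matrix and association weights for fast evaluation.

    ``explicit_free`` marks components whose free form is itself a roster
    species (free proteins); their free pool is already inside the
    stoichiometric sum and must not be added again in mass balance.
    """

    species_ids: tuple[str, ...]
    comp_ids: tuple[str, ...]
    N: np.ndarray  # (n_species, n_components)
    lnQ: np.ndarray  # (n_species,)  ln association weight
    explicit_free: np.ndarray  # (n_components,) bool


def compile_model(model: ModelGraph, params: ParameterSet) -> CompiledModel:
    comp_ids = tuple(c.id for c in model.components)
    rna, atp = model.rna_id, model.atp_id
    N = np.zeros((len(model.species), len(comp_ids)))
    for i, s in enumerate(model.species):
        comp = s.composition(rna, atp)
        for j, c in enumerate(comp_ids):
            N[i, j] = comp.get(c, 0)
    lnQ = -model.species_ln_energy(params)
    explicit_free = np.array([
        any((N[i] == np.eye(len(comp_ids))[j]).all() for i in range(N.shape[0]))
        for j in range(len(comp_ids))
    ])
    return CompiledModel(tuple(s.id for s in model.species), comp_ids, N, lnQ, explicit_free)


def _ln(x: np.ndarray) -> np.ndarray:
    out = np.full_like(x, LOG_ZERO, dtype=float)
    np.log(x, out=out, where=x > 0)
    return out


def solve_speciation_batch(
    cm: CompiledModel,
    totals: np.ndarray,
    conserved: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> np.ndarray:
    """Solve many concentration states at once.

    Parameters
    ----------
    totals : (m, C) array
        Total concentration for conserved components, fixed free
        concentration for buffered ones.
    conserved : (C,) boolean array
        Which components obey mass balance.

    Returns
    -------
    ln_free : (m, C) array (LOG_ZERO where the concentration is zero).
    """
    totals = np.atleast_2d(np.asarray(totals, dtype=float))
    if (totals < 0).any():
        raise ModelError("negative total concentration")
    m, C = totals.shape
    N = cm.N
    ln_tot = _ln(totals)
    ln_free = ln_tot.copy()  # buffered columns stay fixed; start free = total
    cons_idx = np.flatnonzero(conserved)
    active = totals[:, cons_idx] > 0  # (m, U)
    if cons_idx.size == 0 or not active.any():
        return ln_free

    Nc = N[:, cons_idx]  # (S, U)
    add_free = ~cm.explicit_free[cons_idx]  # free pool not already a species
    U = cons_idx.size
    lnQ = cm.lnQ
    ln_tot_c = ln_tot[:, cons_idx]
    # fixed contribution of buffered components to ln S
    lf_buf = ln_free.copy()
    lf_buf[:, cons_idx] = 0.0
    buf_part = lf_buf @ N.T  # (m, S)

    def res(x):
        xa = np.where(active, x, LOG_ZERO)
        with np.errstate(over="ignore"):
            S = np.exp(np.clip(lnQ[None, :] + buf_part + xa @ Nc.T, None, 700.0))
        f = np.exp(xa) * add_free
        tot_calc = f + S @ Nc
        F = np.where(active, _ln(tot_calc) - ln_tot_c, 0.0)
        return F, S, f, tot_calc

    x = np.where(active, ln_tot_c, LOG_ZERO)
    F, S, f, tot_calc = res(x)
    # damped multiplicative warm-up: globally stable (if slow) for binding
    # polynomials, it brings badly scaled starting points into Newton's basin
    for _ in range(400):
        if (np.abs(F).max(axis=1) < 0.3).all():
            break
        x = x - 0.25 * np.clip(F, -20.0, 20.0)
        F, S, f, tot_calc = res(x)
    for _ in range(max_iter):
        if (np.abs(F).max(axis=1) < tol).all():
            break
        J = np.einsum("ms,su,sv->muv", S, Nc, Nc)
        J[:, np.arange(U), np.arange(U)] += f
        J /= np.maximum(tot_calc, 1e-300)[:, :, None]
        inact = ~active
        if inact.any():
            for u in range(U):
                rows = inact[:, u]
                J[rows, u, :] = 0.0
                J[rows, :, u] = 0.0
                J[rows, u, u] = 1.0
        try:
            step = np.linalg.solve(J, -F[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = -F
        np.clip(step, -6.0, 6.0, out=step)
        # Newton is a descent direction for ||F||^2: per-state backtracking
        old = (F * F).sum(axis=1)
        scale = np.ones(m)
        x_new = x.copy()
        done = old < tol * tol
        for _bt in range(30):
            x_try = x + scale[:, None] * step
            F_try = res(x_try)[0]
            improved = (F_try * F_try).sum(axis=1) <= old * (1.0 - 1e-12) + 1e-300
            take = (improved | done) & ~np.isnan(F_try).any(axis=1)
            x_new[take] = x_try[take]
            done = done | take
            if done.all():
                break
            scale[~done] *= 0.5
        if not done.all():
            # stalled states (near-singular Jacobian at stoichiometric
            # corners): fall back to the damped multiplicative update
            stuck = ~done
            x_new[stuck] = (x - 0.3 * np.clip(F, -20.0, 20.0))[stuck]
        x = x_new
        F, S, f, tot_calc = res(x)
    # rescue pass: near-singular stoichiometric corners (two components
    # locked by an ultra-tight complex) can defeat the batched iteration;
    # a trust-region root find from the stalled point handles them
    bad = np.flatnonzero(np.abs(F).max(axis=1) > max(tol * 100, 1e-10))
    if bad.size:
        from scipy.optimize import root as _root

        for i in bad:
            act = active[i]

            def res_i(xi):
                xa = np.where(act, xi, LOG_ZERO)
                with np.errstate(over="ignore"):
                    Si = np.exp(np.clip(lnQ + buf_part[i] + Nc @ xa, None, 700.0))
                    fi = np.exp(np.clip(xa, None, 700.0)) * add_free
                tci = fi + Si @ Nc
                return np.where(act, _ln(np.atleast_2d(tci))[0] - ln_tot_c[i], xi - LOG_ZERO)

            xi = x[i].copy()
            for _ in range(3000):
                Fi = res_i(xi)
                if np.abs(Fi).max() < tol:
                    break
                xi = xi - 0.25 * np.clip(Fi, -20.0, 20.0)
            sol = _root(res_i, xi, method="hybr", tol=1e-14)
            cand = sol.x if np.abs(res_i(sol.x)).max() <= np.abs(res_i(xi)).max() else xi
            if np.abs(res_i(cand)).max() < np.abs(F[i]).max():
                x[i] = cand
                F[i] = np.where(act, res_i(cand), 0.0)
    worst = float(np.abs(F).max())
    if worst > max(tol * 100, 1e-9):
        raise SolverError(f"speciation did not converge (max residual {worst:.3e})")
    ln_free[:, cons_idx] = np.where(active, x, LOG_ZERO)
    return ln_free


def _species_concentrations(cm: CompiledModel, ln_free: np.ndarray) -> np.ndarray:
    return np.exp(cm.lnQ[None, :] + ln_free @ cm.N.T)


def solve_speciation(
    model: ModelGraph,
    params: ParameterSet,
    state: ConcentrationState,
    tol: float = 1e-12,
) -> SpeciationResult:
    """Solve one state and report concentrations, fractions and residuals."""
    cm = compile_model(model, params)
    buffered = state.resolve_buffered(model)
    totals = np.array([[float(state.totals.get(c, 0.0)) for c in cm.comp_ids]])
    conserved = np.array([c not in buffered for c in cm.comp_ids])
    ln_free = solve_speciation_batch(cm, totals, conserved, tol=tol)
    S = _species_concentrations(cm, ln_free)[0]
    free = {c: float(np.exp(ln_free[0, j])) if ln_free[0, j] > LOG_ZERO / 2 else 0.0
            for j, c in enumerate(cm.comp_ids)}

    fractions: dict[str, dict[str, float]] = {}
    residuals: dict[str, float] = {}
    for j, c in enumerate(cm.comp_ids):
        total = totals[0, j]
        if not conserved[j]:
            continue
        bound = float(S @ cm.N[:, j])
        calc = bound + (0.0 if cm.explicit_free[j] else free[c])
        residuals[c] = abs(calc - total) / total if total > 0 else abs(calc)
        if total > 0:
            frac = {sid: float(cm.N[i, j] * S[i] / total)
                    for i, sid in enumerate(cm.species_ids) if cm.N[i, j] > 0}
            if not cm.explicit_free[j]:
                frac["free " + c] = free[c] / total
            fractions[c] = frac
    return SpeciationResult(
        free=free,
        concentrations={sid: float(S[i]) for i, sid in enumerate(cm.species_ids)},
        fractions_by_component=fractions,
        residuals=residuals,
        state=state,
    )


def substrate_partition(
    model: ModelGraph,
    params: ParameterSet,
    state: ConcentrationState,
    cm: CompiledModel | None = None,
) -> dict[str, float]:
    """Trace-substrate distribution of RNA over complexes.

    Protein speciation is solved with the RNA absent; the substrate is
    then partitioned over RNA-binding states proportionally to their
    association weights.  Returns fractions per RNA-containing species
    plus ``"free"``; values sum to 1.
    """
    part = substrate_partition_batch(model, params, [state], cm)
    return {k: float(v[0]) for k, v in part.items()}


def substrate_partition_batch(
    model: ModelGraph,
    params: ParameterSet,
    states: Sequence[ConcentrationState] | np.ndarray,
    cm: CompiledModel | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized :func:`substrate_partition` over many states."""
    cm = cm or compile_model(model, params)
    comp_ids = cm.comp_ids
    rna_j = comp_ids.index(model.rna_id)
    if isinstance(states, np.ndarray):
        totals = states
        buffered = frozenset({model.rna_id, model.atp_id})
    else:
        buffered = states[0].resolve_buffered(model) | {model.rna_id}
        totals = np.array([[float(s.totals.get(c, 0.0)) for c in comp_ids] for s in states])
    conserved = np.array([c not in (buffered | {model.rna_id}) for c in comp_ids])

    no_rna = cm.N[:, rna_j] == 0
    cm_prot = CompiledModel(
        tuple(np.array(cm.species_ids)[no_rna]), comp_ids, cm.N[no_rna],
        cm.lnQ[no_rna], cm.explicit_free,
    )
    totals_prot = totals.copy()
    totals_prot[:, rna_j] = 0.0
    ln_free = solve_speciation_batch(cm_prot, totals_prot, conserved)

    with_rna = ~no_rna
    Nr = cm.N[with_rna].copy()
    Nr[:, rna_j] = 0  # weight per unit free RNA
    lnW = cm.lnQ[with_rna][None, :] + ln_free @ Nr.T  # (m, S_R)
    lnZ = logsumexp(np.concatenate([np.zeros((lnW.shape[0], 1)), lnW], axis=1), axis=1)
    frac = np.exp(lnW - lnZ[:, None])
    out = {sid: frac[:, k] for k, sid in enumerate(np.array(cm.species_ids)[with_rna])}
    out["free"] = np.exp(-lnZ)
    return out


def prevalence_report(
    model: ModelGraph,
    params: ParameterSet,
    states: Sequence[ConcentrationState],
    focal: str,
) -> pd.DataFrame:
    """Fraction of a focal protein across complex classes, one row per state.

    Classes partition the focal component's pool by the set of partner
    proteins present: alone (free or oligomeric), with eIF4A, with eIF4G,
    or with both.  Rows sum to one.
    """
    if focal not in model.protein_ids:
        raise ModelError(f"focal component {focal!r} is not a protein of the model")
    others = [p for p in model.protein_ids if p != focal]
    labels = ["free/oligomer"] + [
        "+" + "+".join(combo)
        for k in range(1, len(others) + 1)
        for combo in itertools.combinations(others, k)
    ]
    rows = []
    for state in states:
        res = solve_speciation(model, params, state)
        frac = res.fractions_by_component[focal]
        row = dict.fromkeys(labels, 0.0)
        for sid, f in frac.items():
            if sid.startswith("free "):
                row["free/oligomer"] += f
                continue
            sp = model.species_by_id(sid)
            partners = [p for p in others if p in dict(sp.proteins)]
            label = "free/oligomer" if not partners else "+" + "+".join(partners)
            row[label] += f
        rows.append(row)
    return pd.DataFrame(rows, index=[s.label() for s in states])[labels]


def titration_curve(
    model: ModelGraph,
    params: ParameterSet,
    vary: str,
    grid: Sequence[float],
    fixed: ConcentrationState,
    observable: Iterable[str],
    normalize_by: str | None = None,
) -> pd.DataFrame:
    """Occupancy of a set of complexes as one component is titrated.

    Returns a frame with the varied concentration and the summed
    concentration of the observable species; if ``normalize_by`` names a
    component, occupancy is expressed as the fraction of that component's
    total held in the observable set.
    """
    grid = list(grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ModelError("titration grid must be strictly increasing")
    observable = list(observable)
    for sid in observable:
        model.species_by_id(sid)
    records = []
    for x in grid:
        totals = dict(fixed.totals)
        totals[vary] = x
        res = solve_speciation(model, params, ConcentrationState(totals, fixed.buffered, fixed.temperature))
        occ = sum(res.concentrations[sid] for sid in observable)
        rec = {vary: x, "concentration": occ}
        if normalize_by is not None:
            total = totals.get(normalize_by, 0.0)
            weight = sum(
                res.concentrations[sid] * dict(model.species_by_id(sid).proteins).get(normalize_by, 0)
                + (res.concentrations[sid] if normalize_by == model.rna_id and model.species_by_id(sid).rna else 0)
                for sid in observable
            )
            rec["occupancy"] = weight / total if total > 0 else np.nan
        records.append(rec)
    return pd.DataFrame(records, columns=[vary, "concentration"] + (["occupancy"] if normalize_by else []))
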