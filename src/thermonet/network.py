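"""Declarative binding network for multi-protein RNA-helicase complexes.

The model describes every complex that Ded1p (D), eIF4A (A) and eIF4G (G)
can form with each other, with substrate RNA (R) and with ATP (T), as a
graph whose nodes are complexes ("species") and whose edges are single
binding transitions.  Each transition carries an equilibrium dissociation
constant K_1/2.  Energy conservation (detailed balance) requires the free
energy of a complex to be independent of the binding path taken to reach
it; the network therefore carries far fewer independent constants than
reactions.  Independence is encoded through *linkage groups*: every
species declares a set of interaction features (e.g. the D-A contact, ATP
on the Ded1p site of an RNA-bound complex), each feature corresponds to
one linkage group with a single free K_1/2, and every reaction constant is
derived from the feature energies.  Cycle closure then holds exactly, by
construction.
"""

from __future__ import annotations

import io
import itertools
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

__all__ = [
    "R_GAS_KJ",
    "ModelError",
    "Component",
    "Species",
    "BindingReaction",
    "LinkageGroup",
    "ActiveComplex",
    "CycleConstraint",
    "FreeEnergy",
    "ModelGraph",
    "ParameterSet",
    "load_model",
    "serialize_model",
    "default_model",
]

#: molar gas constant in kJ / (mol K)
R_GAS_KJ = 8.314462618e-3

#: standard-state concentration, molar
C_STANDARD = 1.0


class ModelError(ValueError):
    """Raised when a model document violates a structural invariant."""


@dataclass(frozen=True)
class Component:
    """A molecular building block of the network.

    Parameters
    ----------
    id : str
        Short symbol, e.g. ``"D"`` for Ded1p.
    kind : str
        One of ``"protein"``, ``"rna"``, ``"nucleotide"``.
    binds_atp : bool
        True for helicases that carry an ATP site (Ded1p, eIF4A).
    collapse_atp : bool
        If True, ATP sub-states of this component are merged when the
        network is displayed or counted in collapsed form (the usual
        convention for eIF4A).
    """

    id: str
    kind: str
    binds_atp: bool = False
    collapse_atp: bool = False
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("protein", "rna", "nucleotide"):
            raise ModelError(f"unknown component kind {self.kind!r}")
        if self.binds_atp and self.kind != "protein":
            raise ModelError(f"only proteins bind ATP ({self.id})")


@dataclass(frozen=True)
class Species:
    """One complex: a protein core plus optional RNA and per-site ATP.

    ``proteins`` maps protein component ids to stoichiometry (the Ded1p
    oligomer is ``{"D": 2}`` or ``{"D": 3}``).  ``atp_sites`` records, for
    every ATP-binding protein present, whether its site is occupied.
    ``features`` lists the linkage-group features whose energies sum to
    the standard formation free energy of the complex from free
    components.
    """

    proteins: tuple[tuple[str, int], ...]
    rna: bool
    atp_sites: tuple[tuple[str, bool], ...]
    features: frozenset[str] = frozenset()

    @property
    def id(self) -> str:
        core = "".join(p if n == 1 else f"{p}{n}" for p, n in self.proteins)
        tags = []
        if self.rna:
            tags.append("R")
        for comp, occ in self.atp_sites:
            if occ:
                tags.append(f"T{comp}")
        return core + ("-" + "-".join(tags) if tags else "")

    @property
    def oligomer_state(self) -> int:
        return max(n for _, n in self.proteins)

    @property
    def n_atp(self) -> int:
        return sum(1 for _, occ in self.atp_sites if occ)

    def composition(self, rna_id: str = "R", atp_id: str = "T") -> Counter:
        c = Counter(dict(self.proteins))
        if self.rna:
            c[rna_id] += 1
        c[atp_id] += self.n_atp
        return +c

    def atp_occupied(self, comp: str) -> bool:
        return dict(self.atp_sites).get(comp, False)

    def collapsed_id(self, collapse: frozenset[str]) -> str:
        """Display id with ATP sub-states of ``collapse`` components merged."""
        core = "".join(p if n == 1 else f"{p}{n}" for p, n in self.proteins)
        tags = []
        if self.rna:
            tags.append("R")
        for comp, occ in self.atp_sites:
            if occ and comp not in collapse:
                tags.append(f"T{comp}")
        return core + ("-" + "-".join(tags) if tags else "")


@dataclass(frozen=True)
class BindingReaction:
    """A reversible binding step ``reactant + ligand <=> product``.

    ``ligand`` is ``"R"``, ``"T@<site>"`` (reservoir ligands) or the id of
    another species (protein-protein association).  The dissociation
    constant is derived from the linkage-group energies; ``linkage_group``
    names the group the reaction belongs to.
    """

    id: str
    reactant: str
    ligand: str
    product: str
    linkage_group: str

    @property
    def is_reservoir_ligand(self) -> bool:
        return self.ligand == "R" or self.ligand.startswith("T@")

    def equation(self) -> str:
        lig = self.ligand.split("@")[0] if self.is_reservoir_ligand else self.ligand
        return f"{self.reactant} + {lig} <=> {self.product}"


@dataclass
class LinkageGroup:
    """A set of thermodynamically linked binding steps with one free K_1/2.

    ``representative`` names the reaction whose K_1/2 *is* the group
    parameter; the constants of all other member reactions are derived
    through cycle closure.
    """

    id: str
    representative: str
    K_half: float | None = None
    fixed: bool = False
    description: str = ""


@dataclass(frozen=True)
class ActiveComplex:
    """An unwinding-competent complex class with its rate constant symbol.

    ``species`` lists the expanded species that contribute with the same
    maximal unwinding rate constant (e.g. both eIF4A ATP sub-states of the
    Ded1p-eIF4A complex, whose eIF4A ATP status is irrelevant for
    activity).
    """

    rate: str
    species: tuple[str, ...]
    k_max: float | None = None
    description: str = ""


@dataclass(frozen=True)
class CycleConstraint:
    """A closed thermodynamic cycle: sum of oriented log-K terms is zero.

    ``member_reactions`` holds ``(reaction_id, coefficient)`` pairs; the
    oriented sum of ``coefficient * ln K`` over members must vanish.
    """

    member_reactions: tuple[tuple[str, int], ...]

    def residual(self, lnK: Mapping[str, float]) -> float:
        return abs(sum(c * lnK[r] for r, c in self.member_reactions))


@dataclass(frozen=True)
class FreeEnergy:
    """Standard formation free energy of a complex from free components."""

    species: str
    delta_G: float  # kJ/mol
    temperature: float  # K
    reference_state: str = "1 M"


@dataclass
class ParameterSet:
    """Free parameters of the framework.

    One dissociation constant (molar) per linkage group, one maximal
    unwinding rate constant (1/min) per active complex class.  Constants
    of individual reactions are always derived, never stored.  ``fixed``
    marks groups held at externally measured values during fitting.
    """

    K: dict[str, float]
    k_max: dict[str, float]
    fixed: frozenset[str] = frozenset()

    def __post_init__(self):
        for k, v in itertools.chain(self.K.items(), self.k_max.items()):
            if not (v > 0 and np.isfinite(v)):
                raise ModelError(f"parameter {k} must be positive, got {v!r}")

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.K), dict(self.k_max), self.fixed)

    def updated(self, K: Mapping[str, float] = (), k_max: Mapping[str, float] = ()) -> "ParameterSet":
        new = self.copy()
        new.K.update(K)
        new.k_max.update(k_max)
        return ParameterSet(new.K, new.k_max, self.fixed)

    @property
    def free_K(self) -> list[str]:
        return [g for g in self.K if g not in self.fixed]

    def cooperativity(self, first: str = "DD1", second: str = "DD2") -> float:
        """Ded1p oligomerization cooperativity: K(first step) / K(second step)."""
        return self.K[first] / self.K[second]

    def to_dict(self) -> dict:
        return {
            "K_half": {k: float(v) for k, v in self.K.items()},
            "k_max": {k: float(v) for k, v in self.k_max.items()},
            "fixed": sorted(self.fixed),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        return cls(dict(d["K_half"]), dict(d["k_max"]), frozenset(d.get("fixed", ())))


class ModelGraph:
    """The validated binding network.

    Construct through :func:`load_model` (or :meth:`from_dict`); direct
    construction skips no validation but requires fully formed objects.
    """

    def __init__(
        self,
        components: Sequence[Component],
        species: Sequence[Species],
        reactions: Sequence[BindingReaction],
        groups: Sequence[LinkageGroup],
        active: Sequence[ActiveComplex] = (),
        capable: Sequence[str] = (),
    ):
        self.components = list(components)
        self.species = sorted(species, key=self._species_sort_key)
        self.reactions = list(reactions)
        self.groups = list(groups)
        self.active = list(active)
        self.capable = tuple(capable)
        self._by_id = {s.id: s for s in self.species}
        self._comp_by_id = {c.id: c for c in self.components}
        self._group_by_id = {g.id: g for g in self.groups}
        self._rxn_by_id = {r.id: r for r in self.reactions}
        self.validate()

    # -- identity ---------------------------------------------------------

    def _species_sort_key(self, s: Species):
        order = {c.id: i for i, c in enumerate(self.components)}
        counts = tuple(dict(s.proteins).get(c.id, 0) for c in self.components if c.kind == "protein")
        return (sum(counts), counts, s.rna, tuple(sorted(s.atp_sites)))

    def species_by_id(self, sid: str) -> Species:
        try:
            return self._by_id[sid]
        except KeyError:
            raise ModelError(f"unknown species {sid!r}") from None

    def component(self, cid: str) -> Component:
        try:
            return self._comp_by_id[cid]
        except KeyError:
            raise ModelError(f"unknown component {cid!r}") from None

    def group(self, gid: str) -> LinkageGroup:
        return self._group_by_id[gid]

    def reaction(self, rid: str) -> BindingReaction:
        return self._rxn_by_id[rid]

    @property
    def rna_id(self) -> str | None:
        return next((c.id for c in self.components if c.kind == "rna"), None)

    @property
    def atp_id(self) -> str | None:
        return next((c.id for c in self.components if c.kind == "nucleotide"), None)

    @property
    def protein_ids(self) -> list[str]:
        return [c.id for c in self.components if c.kind == "protein"]

    @property
    def collapse_components(self) -> frozenset[str]:
        return frozenset(c.id for c in self.components if c.collapse_atp)

    # -- validation -------------------------------------------------------

    def _ligand_composition(self, ligand: str) -> Counter:
        if ligand == self.rna_id:
            return Counter({self.rna_id: 1})
        if ligand.startswith(f"{self.atp_id}@"):
            site = ligand.split("@", 1)[1]
            if site not in self._comp_by_id or not self._comp_by_id[site].binds_atp:
                raise ModelError(f"ATP ligand targets non-ATP-binding site {site!r}")
            return Counter({self.atp_id: 1})
        if ligand in self._by_id:
            return self._by_id[ligand].composition(self.rna_id, self.atp_id)
        raise ModelError(f"unknown ligand {ligand!r}")

    def validate(self) -> None:
        ids = [c.id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ModelError("duplicate component ids")
        if sum(c.kind == "rna" for c in self.components) > 1:
            raise ModelError("more than one RNA component")
        if sum(c.kind == "nucleotide" for c in self.components) > 1:
            raise ModelError("more than one nucleotide component")

        sids = [s.id for s in self.species]
        if len(set(sids)) != len(sids):
            raise ModelError("duplicate species ids")
        for s in self.species:
            if not s.proteins:
                raise ModelError(f"species {s.id} contains no protein")
            for p, n in s.proteins:
                if self.component(p).kind != "protein":
                    raise ModelError(f"species {s.id}: {p} is not a protein")
                if n > 1 and len(s.proteins) > 1:
                    raise ModelError(f"species {s.id}: oligomer mixed with other proteins")
            for comp, _ in s.atp_sites:
                if comp not in dict(s.proteins) or not self.component(comp).binds_atp:
                    raise ModelError(f"species {s.id}: invalid ATP site {comp}")

        for r in self.reactions:
            want = self.species_by_id(r.reactant).composition(self.rna_id, self.atp_id) + self._ligand_composition(r.ligand)
            have = self.species_by_id(r.product).composition(self.rna_id, self.atp_id)
            if want != have:
                raise ModelError(
                    f"reaction {r.id} ({r.equation()}): inconsistent stoichiometry "
                    f"{dict(want)} != {dict(have)}"
                )
            if r.linkage_group not in self._group_by_id:
                raise ModelError(f"reaction {r.id}: unknown linkage group {r.linkage_group}")

        members = Counter(r.linkage_group for r in self.reactions)
        for g in self.groups:
            if members[g.id] == 0:
                raise ModelError(f"linkage group {g.id} has no member reactions")
            rep = self._rxn_by_id.get(g.representative)
            if rep is None or rep.linkage_group != g.id:
                raise ModelError(f"group {g.id}: representative must be a member reaction")

        known = set(self._group_by_id)
        for s in self.species:
            if not s.features <= known:
                raise ModelError(f"species {s.id}: unknown features {s.features - known}")

        graph = nx.Graph()
        graph.add_nodes_from(self._by_id)
        for r in self.reactions:
            graph.add_edge(r.reactant, r.product)
            if not r.is_reservoir_ligand:
                graph.add_edge(r.ligand, r.product)
        if len(self.species) and not nx.is_connected(graph):
            raise ModelError("species graph is disconnected")

        for a in self.active:
            for sid in a.species:
                self.species_by_id(sid)
        for sid in self.capable:
            self.species_by_id(sid)

        # the feature/representative system must be solvable
        self._rep_solve_order()

    # -- energies ---------------------------------------------------------

    def reaction_feature_delta(self, r: BindingReaction) -> dict[str, int]:
        """Signed feature change of a reaction (product - reactant - ligand)."""
        delta: Counter = Counter(self.species_by_id(r.product).features)
        delta.subtract(self.species_by_id(r.reactant).features)
        if not r.is_reservoir_ligand:
            delta.subtract(self.species_by_id(r.ligand).features)
        return {f: c for f, c in delta.items() if c}

    def _rep_solve_order(self) -> list[str]:
        """Order in which group energies can be solved from representatives."""
        deltas = {g.id: self.reaction_feature_delta(self.reaction(g.representative)) for g in self.groups}
        for gid, d in deltas.items():
            if d.get(gid) != 1:
                raise ModelError(f"group {gid}: representative does not introduce the feature once")
        order: list[str] = []
        solved: set[str] = set()
        pending = {g.id for g in self.groups}
        while pending:
            ready = sorted(g for g in pending if set(deltas[g]) - {g} <= solved)
            if not ready:
                raise ModelError(f"linkage groups not triangularly solvable: {sorted(pending)}")
            order.extend(ready)
            solved.update(ready)
            pending -= set(ready)
        return order

    def feature_energies(self, params: ParameterSet) -> dict[str, float]:
        """Per-feature energies in ln(K/1M) units, solved from group K_1/2."""
        missing = [g.id for g in self.groups if g.id not in params.K]
        if missing:
            raise ModelError(f"incomplete parameter set, missing groups: {missing}")
        e: dict[str, float] = {}
        for gid in self._rep_solve_order():
            delta = self.reaction_feature_delta(self.reaction(self.group(gid).representative))
            e[gid] = float(np.log(params.K[gid] / C_STANDARD)) - sum(
                c * e[f] for f, c in delta.items() if f != gid
            )
        return e

    def species_ln_energy(self, params: ParameterSet) -> np.ndarray:
        """ln-unit formation energy of every species (ordered as self.species)."""
        e = self.feature_energies(params)
        return np.array([sum(e[f] for f in s.features) for s in self.species])

    def reaction_lnK(self, params: ParameterSet) -> dict[str, float]:
        """Derived ln(K_1/2 / 1M) of every reaction."""
        e = self.feature_energies(params)
        return {
            r.id: sum(c * e[f] for f, c in self.reaction_feature_delta(r).items())
            for r in self.reactions
        }

    def reaction_K_half(self, params: ParameterSet) -> dict[str, float]:
        return {rid: float(np.exp(v)) for rid, v in self.reaction_lnK(params).items()}

    def free_energy(self, params: ParameterSet, species: str | Species, temperature: float = 298.15) -> FreeEnergy:
        """Standard formation free energy DG0 = RT * sum(ln K_half,i / 1M) along any path."""
        sid = species if isinstance(species, str) else species.id
        s = self.species_by_id(sid)
        e = self.feature_energies(params)
        dG = R_GAS_KJ * temperature * sum(e[f] for f in s.features)
        return FreeEnergy(sid, float(dG), temperature)

    # -- enumeration ------------------------------------------------------

    def enumerate_species(self, collapsed: bool = True) -> list[str]:
        """Stable listing of complexes; ATP sub-states of flagged components merged."""
        if not collapsed:
            return [s.id for s in self.species]
        collapse = self.collapse_components
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(s.collapsed_id(collapse), None)
        return list(seen)

    def enumerate_reactions(self) -> list[str]:
        return [r.equation() for r in self.reactions]

    # -- cycles -----------------------------------------------------------

    def derive_cycle_constraints(self) -> tuple[list[CycleConstraint], int]:
        """Exact cycle basis of the reaction network.

        Every reaction is a linear relation on species energies.  Gaussian
        elimination over rationals finds the reactions that are linear
        combinations of previous ones; each dependency is one independent
        cycle.  Returns the cycles and the number of energetically
        independent reactions (= reactions - cycles).
        """
        index = {s.id: i for i, s in enumerate(self.species)}
        n = len(self.species)
        pivots: list[tuple[int, list[Fraction], dict[str, Fraction]]] = []
        cycles: list[CycleConstraint] = []
        for r in self.reactions:
            row = [Fraction(0)] * n
            row[index[r.product]] += 1
            row[index[r.reactant]] -= 1
            if not r.is_reservoir_ligand:
                row[index[r.ligand]] -= 1
            combo: dict[str, Fraction] = {r.id: Fraction(1)}
            for piv_col, piv_row, piv_combo in pivots:
                if row[piv_col]:
                    f = row[piv_col] / piv_row[piv_col]
                    for j in range(n):
                        row[j] -= f * piv_row[j]
                    for rid, c in piv_combo.items():
                        combo[rid] = combo.get(rid, Fraction(0)) - f * c
            lead = next((j for j in range(n) if row[j]), None)
            if lead is None:
                denom = np.lcm.reduce([c.denominator for c in combo.values()])
                ints = {rid: int(c * denom) for rid, c in combo.items() if c}
                cycles.append(CycleConstraint(tuple(sorted(ints.items()))))
            else:
                pivots.append((lead, row, combo))
        return cycles, len(pivots)

    def check_cycle_closure(self, params: ParameterSet) -> float:
        """Largest |oriented sum of ln K| over the cycle basis (should be ~0)."""
        cycles, _ = self.derive_cycle_constraints()
        lnK = self.reaction_lnK(params)
        return max((c.residual(lnK) for c in cycles), default=0.0)

    # -- defaults and (de)serialization -----------------------------------

    def default_parameters(self) -> ParameterSet:
        """Packaged illustrative parameter values (also the synthetic ground truth)."""
        K = {g.id: g.K_half for g in self.groups}
        if any(v is None for v in K.values()):
            free = [g for g, v in K.items() if v is None]
            raise ModelError(f"model declares no default K for groups: {free}")
        kmax = {a.rate: a.k_max for a in self.active}
        if any(v is None for v in kmax.values()):
            raise ModelError("model declares no default k_max for some active complexes")
        fixed = frozenset(g.id for g in self.groups if g.fixed)
        return ParameterSet(K, kmax, fixed)  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        return {
            "components": [
                {
                    "id": c.id, "kind": c.kind, "binds_atp": c.binds_atp,
                    "collapse_atp": c.collapse_atp, "name": c.name,
                }
                for c in self.components
            ],
            "species": [
                {
                    "id": s.id,
                    "proteins": {p: n for p, n in s.proteins},
                    "rna": s.rna,
                    "atp_sites": {c: occ for c, occ in s.atp_sites},
                    "features": sorted(s.features),
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "id": r.id, "reactant": r.reactant, "ligand": r.ligand,
                    "product": r.product, "group": r.linkage_group,
                }
                for r in self.reactions
            ],
            "groups": [
                {
                    "id": g.id, "representative": g.representative,
                    "K_half": g.K_half, "fixed": g.fixed, "description": g.description,
                }
                for g in self.groups
            ],
            "active": [
                {
                    "rate": a.rate, "species": list(a.species),
                    "k_max": a.k_max, "description": a.description,
                }
                for a in self.active
            ],
            "capable": list(self.capable),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelGraph":
        try:
            components = [
                Component(
                    id=c["id"], kind=c["kind"], binds_atp=c.get("binds_atp", False),
                    collapse_atp=c.get("collapse_atp", False), name=c.get("name", ""),
                )
                for c in d["components"]
            ]
            comp_order = {c.id: i for i, c in enumerate(components)}
            species = []
            for s in d["species"]:
                proteins = tuple(sorted(s["proteins"].items(), key=lambda kv: comp_order.get(kv[0], 99)))
                atp = tuple(sorted(s.get("atp_sites", {}).items(), key=lambda kv: comp_order.get(kv[0], 99)))
                sp = Species(proteins, bool(s.get("rna", False)), atp, frozenset(s.get("features", ())))
                if "id" in s and s["id"] != sp.id:
                    raise ModelError(f"species id {s['id']!r} does not match composition ({sp.id})")
                species.append(sp)
            reactions = [
                BindingReaction(
                    id=r["id"], reactant=r["reactant"], ligand=r["ligand"],
                    product=r["product"], linkage_group=r["group"],
                )
                for r in d["reactions"]
            ]
            groups = [
                LinkageGroup(
                    id=g["id"], representative=g["representative"],
                    K_half=g.get("K_half"), fixed=g.get("fixed", False),
                    description=g.get("description", ""),
                )
                for g in d["groups"]
            ]
            active = [
                ActiveComplex(
                    rate=a["rate"], species=tuple(a["species"]),
                    k_max=a.get("k_max"), description=a.get("description", ""),
                )
                for a in d.get("active", ())
            ]
        except KeyError as exc:
            raise ModelError(f"model document missing key {exc}") from exc
        return cls(components, species, reactions, groups, active, tuple(d.get("capable", ())))

    def __eq__(self, other) -> bool:
        return isinstance(other, ModelGraph) and self.to_dict() == other.to_dict()


def load_model(source: str | Path | Mapping | io.TextIOBase) -> ModelGraph:
    """Load and validate a model from a YAML/JSON document, path or dict."""
    if isinstance(source, Mapping):
        return ModelGraph.from_dict(source)
    if isinstance(source, io.TextIOBase):
        return ModelGraph.from_dict(yaml.safe_load(source))
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ModelError("model document is not a mapping")
    return ModelGraph.from_dict(data)


def serialize_model(model: ModelGraph) -> str:
    """Serialize to YAML with stable key and entry order (round-trip safe)."""
    return yaml.safe_dump(model.to_dict(), sort_keys=False, default_flow_style=None)


def default_model() -> ModelGraph:
    """The packaged Ded1p / eIF4A / eIF4G / RNA / ATP network.

    28 distinct complexes in collapsed display (eIF4A ATP sub-states
    merged), 40 expanded species, 108 binding reactions in 16 linkage
    groups, with six active unwinding complex classes.
    """
    from importlib.resources import files

    return load_model(yaml.safe_load(files("thermonet.data").joinpath("default_model.yaml").read_text()))
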