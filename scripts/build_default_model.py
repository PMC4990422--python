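"""Regenerate src/thermonet/data/default_model.yaml.

The packaged network is a curated, explicit roster (so its counts are
auditable) built from three stated rules:

1. Reservoir-ligand additions: RNA binds every complex with an open RNA
   interface; ATP binds every open helicase site (eIF4A and monomeric or
   trimeric Ded1p; the dimer is an assembly intermediate without its own
   ATP site).
2. Pairwise association closure over monomer-core complexes: any two
   complexes built on single-copy protein cores associate whenever their
   merged composition is itself a roster species (at most one RNA and one
   ATP per site).  eIF4A and eIF4G only engage the Ded1p monomer.
3. Ded1p oligomerizes on its RNA substrate: the second and third
   protomers add to RNA-bound intermediates (D-R + D -> D2-R + D -> D3-R).
   Off-RNA oligomer states are reached by RNA/ATP exchange on the
   assembled oligomer, not by assembly.

Run:  python scripts/build_default_model.py
"""

import itertools
from pathlib import Path

import yaml

# species encoded as (nD, A, G, r, tD, tA)
D = (1, 0, 0, 0, 0, 0)
DR = (1, 0, 0, 1, 0, 0)
D2R = (2, 0, 0, 1, 0, 0)
D3R = (3, 0, 0, 1, 0, 0)


def build_species():
    S = []
    for A, G in itertools.product([0, 1], repeat=2):
        for nD in [0, 1]:
            if nD == 0 and not (A or G):
                continue
            for r in [0, 1]:
                for tD in ([0, 1] if nD else [0]):
                    for tA in ([0, 1] if A else [0]):
                        S.append((nD, A, G, r, tD, tA))
    S += [(2, 0, 0, 0, 0, 0), D2R]
    S += [(3, 0, 0, r, tD, 0) for r in [0, 1] for tD in [0, 1]]
    return sorted(set(S))


def sid(s):
    nD, A, G, r, tD, tA = s
    core = ("D" if nD == 1 else f"D{nD}" if nD else "") + ("A" if A else "") + ("G" if G else "")
    tags = (["R"] if r else []) + (["TD"] if tD else []) + (["TA"] if tA else [])
    return core + ("-" + "-".join(tags) if tags else "")


def features(s):
    nD, A, G, r, tD, tA = s
    f = set()
    if nD >= 2:
        f.add("DD1")
        if nD == 3:
            f.add("DD2")
        if r:
            f.add("D2R" if nD == 2 else "D3R")
        if tD:
            f.add("D3T")
        return f
    if nD and A:
        f.add("DA")
    if nD and G:
        f.add("DG")
    if A and G:
        f.add("AG")
    if nD and A and G:
        f.add("DAG")
    if r:
        f.add("DR" if nD else "AR" if A else "GR")
    if tD:
        f.add("DT")
        if r:
            f.add("DRT")
    if tA:
        f.add("AT")
        if G:
            f.add("ATG")
    return f


# group id -> (primary feature precedence handled by order below)
PRECEDENCE = ["DAG", "ATG", "DRT", "DD2", "DD1", "D3T", "D3R", "D2R",
              "DA", "DG", "AG", "DT", "AT", "DR", "AR", "GR"]

GROUP_META = {
    "DR":  (3e-7, False, "RNA binding to the Ded1p interface of monomer-core complexes"),
    "AR":  (1e-5, False, "RNA binding to eIF4A-only complexes"),
    "GR":  (5e-7, True,  "RNA binding to eIF4G alone (fixed at the prior measurement)"),
    "DT":  (3e-4, True,  "ATP binding to Ded1p without RNA (fixed at the prior measurement)"),
    "DRT": (1e-4, False, "ATP binding to RNA-bound Ded1p, reused across its complexes"),
    "AT":  (3e-4, False, "ATP binding to eIF4A"),
    "ATG": (1e-4, False, "ATP binding to eIF4A within eIF4G-scaffolded complexes"),
    "DA":  (2e-6, False, "Ded1p monomer - eIF4A association"),
    "DG":  (4e-7, False, "Ded1p monomer - eIF4G association"),
    "AG":  (5e-8, False, "eIF4A - eIF4G association"),
    "DAG": (5e-9, False, "Ded1p binding to the preformed eIF4A-eIF4G complex"),
    "D2R": (5e-7, True,  "RNA binding to the Ded1p dimer (prior oligomer framework)"),
    "DD1": (1e-6, True,  "second Ded1p protomer joining RNA-bound Ded1p"),
    "DD2": (5e-8, True,  "third Ded1p protomer joining the RNA-bound dimer (cooperative)"),
    "D3R": (1e-7, True,  "RNA binding to the assembled Ded1p trimer"),
    "D3T": (1e-4, True,  "ATP binding to the Ded1p trimer"),
}

REPRESENTATIVES = {
    "DR": ("D", "R", "D-R"),
    "AR": ("A", "R", "A-R"),
    "GR": ("G", "R", "G-R"),
    "DT": ("D", "T@D", "D-TD"),
    "DRT": ("D-R", "T@D", "D-R-TD"),
    "AT": ("A", "T@A", "A-TA"),
    "ATG": ("AG", "T@A", "AG-TA"),
    "DA": ("A", "D", "DA"),
    "DG": ("G", "D", "DG"),
    "AG": ("A", "G", "AG"),
    "DAG": ("AG", "D", "DAG"),
    "D2R": ("D2", "R", "D2-R"),
    "DD1": ("D-R", "D", "D2-R"),
    "DD2": ("D2-R", "D", "D3-R"),
    "D3R": ("D3", "R", "D3-R"),
    "D3T": ("D3", "T@D", "D3-TD"),
}

ACTIVE = [
    ("k_D3", ["D3-R-TD"], 1.2,
     "Ded1p trimer on RNA with ATP"),
    ("k_DA", ["DA-R-TD", "DA-R-TD-TA"], 1.0,
     "Ded1p-eIF4A on RNA with ATP on Ded1p; the eIF4A ATP state is irrelevant"),
    ("k_DAG", ["DAG-R-TD-TA"], 1.5,
     "Ded1p-eIF4A-eIF4G on RNA with ATP on both helicases"),
    ("k_DG", ["DG-R-TD"], 0.005,
     "Ded1p-eIF4G on RNA with ATP on Ded1p"),
    ("k_A", ["A-R-TA"], 0.03,
     "eIF4A alone on RNA with ATP"),
    ("k_AG", ["AG-R-TA"], 0.12,
     "eIF4A-eIF4G on RNA with ATP on eIF4A"),
]


def build_reactions(S):
    Sset = set(S)
    rxns = []
    for s in S:
        nD, A, G, r, tD, tA = s
        if not r and (nD, A, G, 1, tD, tA) in Sset:
            rxns.append((s, "R", (nD, A, G, 1, tD, tA)))
        if nD and not tD and (nD, A, G, r, 1, tA) in Sset:
            rxns.append((s, "T@D", (nD, A, G, r, 1, tA)))
        if A and not tA and (nD, A, G, r, tD, 1) in Sset:
            rxns.append((s, "T@A", (nD, A, G, r, tD, 1)))
    for s1, s2 in itertools.combinations_with_replacement(S, 2):
        if s1[0] > 1 or s2[0] > 1:
            continue
        n1, A1, G1, r1, t1, a1 = s1
        n2, A2, G2, r2, t2, a2 = s2
        if A1 + A2 > 1 or G1 + G2 > 1 or r1 + r2 > 1 or t1 + t2 > 1 or a1 + a2 > 1:
            continue
        p = (n1 + n2, A1 + A2, G1 + G2, r1 + r2, t1 + t2, a1 + a2)
        if p in Sset and p[0] <= 1:
            big, small = (s1, s2) if s1 >= s2 else (s2, s1)
            rxns.append((big, sid(small), p))
    rxns.append((DR, "D", D2R))
    rxns.append((D2R, "D", D3R))
    return rxns


def main():
    S = build_species()
    rxns = build_reactions(S)
    assert len(S) == 40 and len(rxns) == 108

    rxn_entries = []
    group_of = {}
    for i, (reac, lig, prod) in enumerate(sorted(
            rxns, key=lambda t: (S.index(t[2]), S.index(t[0]), str(t[1])))):
        ligf = (features(next(s for s in S if sid(s) == lig))
                if lig not in ("R", "T@D", "T@A") else set())
        pos = features(prod) - features(reac) - ligf
        group = next(f for f in PRECEDENCE if f in pos)
        rid = f"r{i + 1:03d}"
        rxn_entries.append({
            "id": rid,
            "reactant": sid(reac),
            "ligand": lig if isinstance(lig, str) else sid(lig),
            "product": sid(prod),
            "group": group,
        })
        group_of[(sid(reac), lig if isinstance(lig, str) else sid(lig), sid(prod))] = rid

    groups = []
    for gid in PRECEDENCE:
        K, fixed, desc = GROUP_META[gid]
        reac, lig, prod = REPRESENTATIVES[gid]
        rep = group_of.get((reac, lig, prod)) or group_of[(lig, reac, prod)]
        groups.append({"id": gid, "representative": rep, "K_half": K,
                       "fixed": fixed, "description": desc})

    capable = [sid(s) for s in S if s[3] and (
        (s[0] == 3 and s[4]) or
        (s[0] == 1 and s[2] and not s[1] and s[4]) or
        (s[0] == 0 and s[1] and s[5]) or
        (s[0] == 1 and s[1] and (s[4] or s[5])))]
    assert len(capable) == 10

    doc = {
        "components": [
            {"id": "D", "kind": "protein", "binds_atp": True, "collapse_atp": False, "name": "Ded1p"},
            {"id": "A", "kind": "protein", "binds_atp": True, "collapse_atp": True, "name": "eIF4A"},
            {"id": "G", "kind": "protein", "binds_atp": False, "collapse_atp": False, "name": "eIF4G"},
            {"id": "R", "kind": "rna", "binds_atp": False, "collapse_atp": False,
             "name": "RNA substrate (16 bp duplex, 25 nt 3' overhang)"},
            {"id": "T", "kind": "nucleotide", "binds_atp": False, "collapse_atp": False, "name": "ATP"},
        ],
        "species": [
            {"id": sid(s),
             "proteins": ({"D": s[0]} if s[0] else {}) | ({"A": 1} if s[1] else {}) | ({"G": 1} if s[2] else {}),
             "rna": bool(s[3]),
             "atp_sites": ({"D": bool(s[4])} if s[0] in (1, 3) else {}) | ({"A": bool(s[5])} if s[1] else {}),
             "features": sorted(features(s))}
            for s in S
        ],
        "reactions": rxn_entries,
        "groups": groups,
        "active": [
            {"rate": rate, "species": sp, "k_max": k, "description": desc}
            for rate, sp, k, desc in ACTIVE
        ],
        "capable": capable,
    }

    out = Path(__file__).resolve().parents[1] / "src" / "thermonet" / "data" / "default_model.yaml"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(yaml.safe_dump(doc, sort_keys=False, default_flow_style=None))
    print(f"wrote {out} ({len(S)} species, {len(rxns)} reactions, {len(groups)} groups)")


if __name__ == "__main__":
    main()
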