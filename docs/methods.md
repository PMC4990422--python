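# Methods

## The model

The framework treats every complex of Ded1p (D), eIF4A (A), eIF4G (G),
substrate RNA (R) and ATP (T) as a thermodynamic state connected to its
neighbors by reversible binding steps, each with an equilibrium
dissociation constant K_1/2 (molar). Free energy is a state function, so
around any closed cycle of binding steps the oriented product of
association constants is one — equivalently the formation free energy of
a complex is independent of the binding path. The model enforces this
*by construction*: every species declares a set of interaction features
(e.g. the D–A contact, ATP on the Ded1p site of an RNA-bound complex),
each feature carries one energy, and the constant of every one of the
108 reactions is derived from the species energies. Sixteen features =
sixteen linkage groups = sixteen independent constants; each group's
free parameter is, concretely, the K_1/2 of a designated representative
reaction (e.g. the DAG group's parameter is the K_1/2 of Ded1p binding
the preformed eIF4A–eIF4G complex). Cycle-closure residuals are at
machine precision (~1e-15 in ln K) and are still verified, over an
exact rational cycle basis, in the test suite.

### The complex roster

The exact species/reaction roster of the original framework is not
published in the available text, so the packaged roster is one explicit,
auditable reconstruction built from three rules:

1. RNA binds every complex with an open RNA interface; ATP binds every
   open helicase site (eIF4A, and monomeric or trimeric Ded1p).
2. Any two monomer-core complexes associate whenever their merged
   composition is a roster species (one RNA, one ATP per site); eIF4A
   and eIF4G engage only the Ded1p monomer, and all protein–protein
   contacts are one-to-one.
3. Ded1p oligomerizes on its RNA substrate: protomers add to RNA-bound
   intermediates (D·R + D → D₂·R + D → D₃·R). Off-RNA oligomer states
   exist but are reached by RNA/ATP exchange, not assembly. The dimer
   is an assembly intermediate with an RNA interface and no ATP site.

This yields 40 expanded species, 28 complexes in the collapsed display
(eIF4A·ATP sub-states merged), and 108 reactions in 16 groups. RNA
binds each monomer-core complex through a single dominant interface
(Ded1p if present, else eIF4A, else eIF4G), which is what lets one
RNA-affinity constant serve a whole family of complexes; likewise one
ATP constant serves all RNA-bound Ded1p sites. These reuse assumptions
are the declared linkages that reduce 37 cycle-independent constants to
16.

### Activity logic

Ten complexes could in principle unwind (RNA-bound, at least one
ATP-loaded helicase, built on an unwinding-competent core — the Ded1p
trimer, D·G, D·A in three ATP states, D·A·G in three ATP states, A, and
A·G; the bare Ded1p monomer is not an unwinding unit). Functional
evidence collapses these to six active classes: ATP on eIF4A is
irrelevant for D·A (both sub-states share one rate constant), and D·A·G
is active only with ATP on both helicases. Each class has one maximal
rate constant k_max (1/min).

## Equilibrium speciation

Speciation solves mass balance over the binding polynomial in log
free-concentration space (positivity for free), with a damped
multiplicative warm-up (globally stable for these monotone systems),
Newton iteration with a per-state sum-of-squares line search, and a
trust-region root-find rescue for the rare near-singular corner in which
an ultra-tight complex stoichiometrically locks two components.
Tolerance is 1e-12 on log mass-balance residuals. RNA and ATP default
to buffered (free = stated concentration): unwinding reactions use 0.5
nM duplex (trace) and millimolar ATP, so neither is depleted. For rate
prediction, protein speciation is solved with the substrate absent and
the substrate is partitioned over binding states in proportion to their
weights — the exact trace limit.

## Kinetics

Pre-steady-state unwinding with simultaneous strand annealing follows
F(t) = A(1 − exp(−(k_unw + k_ann)t)) with A = k_unw/(k_unw + k_ann);
this is the integrated two-state law for d[unwound]/dt =
k_unw(1 − F) − k_ann·F, and the fit is validated against that ODE in the
tests rather than re-derived. Initial guesses are deterministic (early
slope, plateau deficit). The observed rate constant of a reaction is
predicted as k = Σ_i k_max,i · f_i with f_i the fraction of substrate
bound in active class i in its required ATP state (rapid-equilibrium
assumption: binding equilibrates fast relative to strand separation).

Accompanying assays use standard forms: Hill (n fixable to 1),
Michaelis–Menten for ATP/RNA titrations of ATPase rates, and the
quadratic ligand-depletion isotherm for tight binding at fixed site
concentrations (the MST regime, 36 nM labeled sites).

## Global fitting and uncertainty

All titration datasets are fit simultaneously by bounded least squares
(scipy trust-region reflective) on log10 parameters — K in [1e-12, 1] M,
k_max in [1e-4, 1e3] /min — with seeded multi-start (default 10
restarts, 0.5-decade perturbations). Only group constants are varied, so
every iterate satisfies all cycle constraints exactly. Per-condition
observations are replicate medians; uncertainties are scaled median
absolute deviations (1.4826·MAD/√n) with configurable absolute (1e-3
/min) and relative (3%) floors. The median/MAD choice is deliberate: a
noisy near-flat progress curve is occasionally fit by an arbitrarily
fast, low-amplitude exponential, and a mean/SD reduction is destroyed by
those degenerate estimates while the median ignores them.

Confidence intervals come from profiling: one parameter is scanned, all
parameters the original fit varied are re-optimized, and the 95% bound
is where relative χ² crosses the F-based threshold
χ²_opt·(1 + F₀.₀₅(1, N−p)/(N−p)). The crossing is interpolated in
√(relχ²−1), which is exact where χ² is locally quadratic in the log
parameter — linear interpolation at 0.25-decade steps underestimates
interval widths severely. A profile that fails to cross within the
bounds on one side is reported as a one-sided limit ("le"/"ge").

Parameters differ enormously in how well a k_unw-only design can
determine them: constants that act mainly through thermodynamic linkage
(e.g. eIF4A's ATP affinity outside eIF4G complexes) carry 95% intervals
of ±0.5 decade or more. The recovery experiment therefore classifies a
parameter as *identifiable at the tested precision* when its two-sided
95% CI half-width is at most the recovery tolerance (0.3 decades for K,
15% for k_max), and requires those parameters to land within tolerance;
the CIs themselves are calibration-checked by the coverage experiment.

## Synthetic data

The generator reproduces the study design: 20 datasets (Ded1p–eIF4A 4,
Ded1p–eIF4G 3, eIF4A–eIF4G 4, triple complex 9), each the titration of
one component over an 8-point log grid bracketing the relevant constants
with the others fixed at regimes echoing the experiments (0.1 µM Ded1p,
2 µM eIF4A, 0.1 µM eIF4G, 4 mM ATP, trace duplex); every class titrates
each of its protein constituents and ATP. Three replicates of ten
time points per condition give 4800 raw points. Noise is i.i.d. Gaussian
with sd 0.03 on the fraction unwound (typical gel-quantification
scatter), clipped to [−0.05, 1.05]; annealing uses a single rate
constant (0.025 /min), treating annealing as a substrate property. All
generators are pure functions of (design, seed).

The ground truth is the packaged default parameter set — illustrative
values chosen for the qualitative regime of the system, not fitted
constants: the triple complex is the most stable species (Ded1p binds
preformed eIF4A–eIF4G at 5 nM, consistent with a tight-binding MST
measurement), Ded1p trimerizes cooperatively (functional Hill
coefficient ~1.8–2), eIF4G alone inhibits Ded1p by sequestering the
monomer, and at ~1 µM Ded1p/eIF4G with excess eIF4A most of both
proteins resides in the triple complex. Passing recovery tests show the
*pipeline* is unbiased and calibrated under this design and noise model;
they do not validate the illustrative constants against experiment, and
real data would add systematic errors (pipetting correlations,
temperature drift, active-fraction uncertainty) the generator does not
emulate.

## Scaled-down calibration experiments

Profile-CI coverage is measured on 50 replicate designs of the
Ded1p–eIF4A subsystem (Ded1p, eIF4A and ATP titrations; four free
parameters, others held at truth) with known observation noise (5%
relative, 0.002 /min floor) applied directly to rate constants, keeping
the χ² scale exact; the focal constant is the Ded1p–eIF4A K_1/2. The
limit demonstration uses the same subsystem with every reaction at or
below a tenth of the ATP K_1/2 of RNA-bound Ded1p, so the data see only
the linear k_max·T/K regime and the constant is reported as a lower
limit. Problem sizes throughout (8-point grids, 3 datasets, 50
replicates) were chosen as the smallest that make the statistical
checks sharp.

## Known limitations

* The roster is one consistent reconstruction of an unpublished list;
  other rosters satisfying the same counts exist.
* ATP hydrolysis is not modeled for any complex; the Ded1p-alone
  oligomer pathway is represented by equilibrium-effective constants
  from the prior framework, held fixed during fitting.
* The single-interface RNA rule and ATP-constant reuse are idealized
  linkages; real complexes may show avidity or context-dependent
  affinities the 16-parameter structure cannot express.
* Rapid-equilibrium prediction ignores binding kinetics; systems where
  complex assembly is slower than strand separation would need the full
  kinetic treatment.
* Temperature enters only through ΔG° reporting (default 298.15 K);
  constants themselves are temperature-independent inputs.
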