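# Methods

`gelsolv` packages the computational analyses behind a small-molecule
drug–ligand hydrogel solubilization study of the sulindac–meglumine (SUL–MEG)
type: component miscibility screening by Hansen solubility parameters,
phase-solubility analysis of 1:1 complexation with negative (A_N) deviation,
and dissolution/supersaturation analytics under sample-and-replace paddle
protocols. This note records the models, the defaults and why, the numerical
choices, and the known limitations.

## Hansen solubility parameters (group contribution)

The total solubility parameter is split into dispersion, polar and
hydrogen-bonding parts, δ² = δd² + δp² + δh², each estimated additively
from per-functional-group increments:

    δd = Σ nᵢF_dᵢ / V,   δp = √(Σ nᵢF_pᵢ²) / V,   δh = √(Σ nᵢE_hᵢ / V),
    V  = Σ nᵢVᵢ,

with F in MPa^0.5·cm³/mol, E_h in J/mol and V in cm³/mol (1 J/cm³ = 1 MPa
closes the units). Summations weight each group by its occurrence count nᵢ.
Because δp sums *squares* of increments inside the root, it is not invariant
under duplication of the whole molecule; δd and δh are. The literal
sum-of-squares convention is kept; symmetry corrections for repeated polar
groups are deliberately not applied.

The default table pairs the Hoftyzer–van Krevelen molar attraction constants
with the Fedors molar-volume increments (provenance noted in the CSV header).
Fedors volumes are negative for branch carbons; per-row validation therefore
rejects only V = 0 and requires the *total* molar volume of a composition to
be positive. Two curated rows are documented in the table itself: a sulfinyl
(S=O) entry, absent from the published tables, and per-atom aromatic CH/C
values derived from the phenyl/phenylene/trisubstituted-benzene aggregates.

Fragmentation is an explicit input (a `group,count` CSV); no automatic
structure fragmentation is attempted, since fragmentation ambiguity would
dominate the error budget. Shipped fragmentations cover sulindac and
meglumine.

**Known limitation.** The study that motivates the package computed δ with
closed-source software and reports 23.74 (SUL) and 25.89 (MEG) MPa^0.5. The
shipped sulindac fragmentation reproduces 23.44 (−1.3%). Meglumine cannot be
reproduced by these equations with any published table dialect: five
hydroxyls at E_h = 20 kJ/mol each give δh ≈ 29.8 MPa^0.5 over the Fedors
volume, already above the reported *total*; the package computes
δ ≈ 38.0 (+47%). Matching 25.89 would require an OH hydrogen-bond energy
near 2.5 kJ/mol, which no published table supports. The discrepancy is
reported, not absorbed: polyol δ values from additive methods are known to
run high, and the miscibility screen is only trustworthy when both
components' δ come from the same dialect.

Miscibility uses the conventional cutoff: the pair is predicted miscible
when Δδ = |δ_a − δ_b| is strictly below 7 MPa^0.5.

## 1:1 complexation phase solubility

With a drug D (intrinsic solubility S0) and ligand L forming a soluble 1:1
complex, K₁:₁ = [DL]/([D][L]) and mass balances [D]_T = [D]+[DL],
[L]_T = [L]+[DL], excess solid drug pins [D] at S0 and total solubility is
linear in total ligand (the Higuchi–Connors A_L diagram):

    S_T = S0 + (K·S0/(1+K·S0))·L_T,    K₁:₁ = slope/(S0·(1−slope)).

All model math is in mM and mM⁻¹; converters handle µg/mL given an explicit
molar mass (never inferred). S0 defaults to the measured intrinsic
solubility rather than the regression intercept — the model fixes the
intercept there — with `s0_from_intercept` to switch. Speciation at given
totals solves the quadratic K(D_T−C)(L_T−C) = C for the root in
[0, min(D_T, L_T)], in product form to avoid cancellation; mass balances and
the equilibrium identity hold to 1e−9 relative throughout the physically
relevant range (K ≲ 10³ mM⁻¹; far beyond that, the free-drug subtraction
hits double-precision conditioning).

**A_N deviation.** At high ligand concentration the diagram may bend below
the line. Following the free-ligand aggregation hypothesis, the package
models this as a saturating effective ligand pool,

    L_eff = L_T/(1 + β·L_T),

substituted into the linear law; β = 0 recovers A_L exactly, β > 0 gives a
strictly concave, everywhere-lower curve. A dimerization equilibrium would
be an alternative; it was not implemented because the data shapes of
interest do not distinguish the two.

**Breakpoint detection.** Candidate breakpoints are the observed ligand
concentrations. For each candidate, a line *anchored at (0, S0)* is fitted
to the points at or below it — anchoring at the model-fixed intercept stops
chance tilt of a short low-concentration fit from being amplified by
extrapolation. The candidate qualifies when (i) every point above it falls
below the extrapolated line (one-sided sign criterion) and (ii) the first
two points above fall short by more than
max(0.15·prediction, 2.58·SE of the extrapolated prediction) — a relative
deviation floor plus a one-sided ~99.5% significance margin. The smallest
qualifying candidate wins (earliest onset); none ⇒ A_L with the breakpoint
at the data maximum. The 15% floor is the detector's operating point, set by
a power analysis against the generator's noise model so that triplicate
assays at 5% CV neither fire early on smooth curvature nor miss a genuine
onset; it is a tunable argument. A monotone-decreasing tail still returns
A_N but warns that B-type behaviour is outside the A-type model.

Because the saturation model is smooth, "the onset" is a convention, not a
sharp point. The generators therefore emit as ground truth the breakpoint
the detector reports on the *noiseless* means, and noisy-data detection is
judged against that (within one grid step). On the default grid with
β = 0.2 mM⁻¹ the noiseless onset is 1.5625 mM.

**K₁:₁ estimation.** Ordinary least squares of S_T on L_T inside the linear
range (default: up to the detected breakpoint), slope checked to lie in
(0, 1), then inverted. On genuinely linear diagrams with 5% assay noise and
8 points the median |relative error| of K is ~2–4%. On smoothly aggregating
(A_N) diagrams K is biased low by ~25% even when the fit is restricted below
the detected onset, because no exactly linear region exists — an inherent
limitation of slope inversion there, stated by the analysis driver rather
than hidden.

## Dissolution and supersaturation

Sample-and-replace protocols withdraw an aliquot v at each timepoint and
replace it with fresh medium, so the sampled concentration under-counts what
has dissolved. The unique mass-consistent correction is

    A_n = C_n·V + v·Σ_{i<n} C_i   (µg; reported in mg and % of dose),

which at every index equals drug mass in the vessel plus everything removed
before. v = 0 reduces to naive C·V. Percentages above 100 are possible only
through measurement noise and are flagged. No interpolation between
timepoints is performed anywhere (exact-match lookups), to avoid inventing
kinetics; fold enhancements are presented rounded half-up to two decimals.
One published fold (546.48) is a truncation of 546.4851 rather than a
half-up rounding; the package keeps half-up and the comparison tolerance at
that check is the printed precision.

Two protocol presets mirror the study conditions: sink (900 mL, 2 mL
aliquots, 2.1 mg dose, 37 °C, 100 rpm) and non-sink (200 mL, 2 mL, 80 mg).
Dialysis-bag transport in the non-sink assay is not modelled; measured
medium concentrations are taken as given.

## Synthetic data

The generators exist so every pipeline stage is testable with known truth.

*Phase solubility*: noiseless means from the aggregation model on a doubling
grid 0.0488–25 mM (10 points — the shape of a study with a linear region to
~6.25 mM plus a deviated tail); defaults K₁:₁ = 1.5 mM⁻¹ (no constant is
published for the motivating system; this is a mid-range 1:1 value),
S0 = 0.033 mM (11.77 µg/mL at 356.41 g/mol), β = 0 (A_L) unless enabled.
Observations multiply the mean by (1 + ε̄), where ε̄ averages `replicates`
draws of Normal(0, noise_cv) truncated at −0.99 — multiplicative because
concentration assays scale with signal, truncated so concentrations stay
positive, and averaged in triplicate by default as bench assays are.
`replicates=1` gives single measurements whose recorded CV calibrates to
noise_cv (checked at 5%: empirical CV within [0.04, 0.06] over 200 seeds).

*Dissolution*: between samples the vessel concentration relaxes first-order
toward a plateau C_inf with rate k, capped so cumulative dissolution never
exceeds the dose; at each sample time the pre-dilution concentration is
recorded (noise on the record only), the withdrawn mass tallied, and the
vessel diluted by (V−v)/V. The kinetic form is a stand-in chosen to exercise
the accounting — the motivating study fits no kinetic model — with defaults
k = 0.074 min⁻¹ (a fast, hydrogel-like profile passing ~77% at 20 min) and
C_inf = dose/V. The emitted dissolved-mass ledger is exact, so the
correction formula can be verified to machine precision (the round-trip
oracle, the package's central dissolution test).

What passing these tests shows — and does not. The synthetic data share the
estimators' model families by construction; recovery results demonstrate
correctness of the implementations and their noise robustness, not that
real diagrams follow the saturation model, that real assay noise is 5%
multiplicative Gaussian, or that real dissolution is first-order.

## Numerical and interface conventions

- Strict `<` on the 7 MPa^0.5 miscibility threshold; ties are
  "immiscibility-risk".
- Breakpoint ties: smallest qualifying candidate (earliest onset).
- Speciation root via the numerically stable product form; K = 0 or a zero
  total short-circuits to no complex.
- Validation errors carry the offending file/row or argument name; CSV
  readers reject missing columns by name.
- Exit codes of the `gelsolv` CLI: 0 success, 2 validation/schema error,
  64 usage error. Every simulation output carries its seed in a sidecar
  `.truth.json`.
- Problem sizes in the test suite and acceptance script (200 seeds for the
  recovery studies, 10-point grids, 9-point release series) match the study
  shapes and keep each study under a minute.
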