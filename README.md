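# gelsolv

Solubilization analytics for small-molecule drug–ligand hydrogels: Hansen
solubility parameters and miscibility screening, 1:1 complexation
phase-solubility analysis (Higuchi–Connors) with A_N-deviation handling, and
dissolution/supersaturation metrics under sample-and-replace paddle
protocols.

The package targets formulation scientists working on systems like the
sulindac–meglumine hydrogel: a poorly soluble (BCS-II) drug co-assembled
with a hydrophilic ligand, where three questions recur —

1. **Are the components miscible?** Group-contribution Hansen parameters
   (δ² = δd² + δp² + δh², each from per-functional-group increments) and the
   Δδ < 7 MPa^0.5 screen.
2. **How strongly do they complex in solution?** From a phase-solubility
   diagram S_T(L_T) = S0 + [K·S0/(1+K·S0)]·L_T, the constant
   K₁:₁ = slope/(S0·(1−slope)); with detection of the A_N negative deviation
   at high ligand concentration (modelled as free-ligand aggregation,
   L_eff = L_T/(1+β·L_T)) and restriction of the fit to the linear range.
3. **How much and how fast is drug released, and is supersaturation held?**
   Withdrawal-corrected cumulative release
   A_n = C_n·V + v·Σ_{i<n}C_i, fold enhancements, C_max and AUC.

A seeded synthetic-data module generates phase-solubility diagrams and
dissolution runs with exact ground truth, so every estimator is testable
without external data. Full model details and design choices are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import gelsolv as g

# 1. Miscibility from the published Hansen parameters
screen = g.miscibility_screen(23.74, 25.89)
print(screen.delta_diff, screen.verdict)          # 2.15 miscible

# ... or from shipped group-contribution fixtures
p = g.compute_hansen(g.sulindac_composition())
print(round(p.delta_total, 2))                    # 23.44

# 2. K1:1 from a simulated A_N phase-solubility diagram
data, truth = g.gen_phase_solubility(
    g.PhaseSolSimConfig(beta=0.2, noise_cv=0.05, seed=20260926)
)
bp, cls = g.detect_breakpoint(data)
fit = g.fit_K11(data)
print(cls, bp)                                    # A_N 1.5625
print(round(fit.K11, 3), round(fit.r_squared, 4)) # 1.111 0.989

# 3. Release accounting and supersaturation folds
series, rel_truth = g.gen_dissolution(g.DissolutionSimConfig(noise_cv=0.0))
profile = g.cumulative_release(g.sink_protocol(), series)
print(round(profile.percent_at(20), 2))           # 77.39
print(g.enhancement_ratio(3640.24, 11.77))        # 309.28
```

Reading the output: Δδ = 2.15 MPa^0.5 is far below the 7 MPa^0.5 cutoff, so
the pair is predicted miscible. The simulated diagram is classified A_N with
deviation onset at 1.56 mM ligand; the slope of the retained linear region
inverts to K₁:₁ ≈ 1.11 mM⁻¹ (generated with 1.5 — slope inversion reads low
on smoothly aggregating diagrams; see the methods note). The simulated
paddle run releases 77.4% of the dose by 20 min after correcting for the
2 mL aliquots withdrawn and replaced at each timepoint, and the published
apparent solubilities give the 309.28-fold enhancement of the physical
mixture over crystalline drug.

The same operations are scriptable: `gelsolv hsp --composition sulindac
--json`, `gelsolv phasesol fit data.csv --s0 0.033`, `gelsolv release
data.csv --protocol sink --at 20,120`, `gelsolv simulate phasesol -o sim.csv`,
and `gelsolv reproduce` (recomputes the desk-reproducible study numbers from
the shipped fixtures and reports pass/fail per check).

## Analysis drivers

Narrative scripts under `analysis/` run the three studies end to end and
write tables under `results/`:

- `01_hansen_miscibility.py` — δ components for both molecules, Δδ screen,
  comparison with the published values (and an honest account of where the
  meglumine value cannot be reproduced).
- `02_phase_solubility.py` — simulated A_N diagram, breakpoint detection and
  K₁:₁ recovery over 200 seeds.
- `03_release_supersaturation.py` — fold enhancements from published
  concentrations; simulated sink-condition release for three kinetic
  profiles with the withdrawal correction verified against exact truth.

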