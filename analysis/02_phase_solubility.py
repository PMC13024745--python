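#!/usr/bin/env python
"""Phase-solubility analysis on synthetic A_N diagrams with known truth.

Simulates the doubling ligand grid (0.0488–25 mM) with 1:1 complexation
(K = 1.5 mM⁻¹, S0 = 0.033 mM) plus free-ligand aggregation (β = 0.2 mM⁻¹),
then runs the full pipeline — breakpoint detection, diagram classification,
restricted least squares, K₁:₁ inversion — and summarises estimator
performance over 200 seeds. Writes results/phase_solubility_fit.csv and
results/k11_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import gelsolv as g

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260926


def main() -> None:
    OUT.mkdir(exist_ok=True)
    grid = g.default_ligand_grid()

    # one worked diagram
    data, truth = g.gen_phase_solubility(
        g.PhaseSolSimConfig(beta=0.2, noise_cv=0.05, seed=SEED)
    )
    bp, cls = g.detect_breakpoint(data)
    fit = g.fit_K11(data)
    pd.DataFrame(
        {
            "ligand_mM": data.ligand_total,
            "observed_mM": data.drug_total,
            "noiseless_mM": truth.noiseless,
            "linear_law_mM": g.predict_total_solubility(
                truth.K11, truth.S0, data.ligand_total
            ),
        }
    ).to_csv(OUT / "phase_solubility_fit.csv", index=False)
    print(f"worked diagram: class {cls}, breakpoint {bp:.4g} mM "
          f"(noiseless-data onset {truth.breakpoint:.4g} mM)")
    print(f"  K11 = {fit.K11:.3f}/mM (true 1.5), slope {fit.slope:.4f}, "
          f"r^2 {fit.r_squared:.4f}, fit on {fit.n_points} points "
          f"<= {fit.linear_range[1]:.4g} mM")

    # estimator performance across seeds
    rng_seeds = np.random.SeedSequence(SEED).generate_state(200) % (2**31)
    rows = []
    for s in rng_seeds:
        d, tr = g.gen_phase_solubility(
            g.PhaseSolSimConfig(beta=0.2, noise_cv=0.05, seed=int(s))
        )
        bp_s, cls_s = g.detect_breakpoint(d)
        f = g.fit_K11(d)
        i_det = int(np.argmin(np.abs(grid - bp_s)))
        i_true = int(np.argmin(np.abs(grid - tr.breakpoint)))
        rows.append(
            {
                "seed": int(s),
                "class": cls_s,
                "breakpoint_mM": bp_s,
                "onset_within_one_step": abs(i_det - i_true) <= 1,
                "K11_rel_err": abs(f.K11 - tr.K11) / tr.K11,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "k11_recovery.csv", index=False)
    print(f"\nover {len(df)} seeds (triplicate assay, 5% CV):")
    print(f"  A_N classified:           {100 * (df['class'] == 'A_N').mean():.1f}%")
    print(f"  onset within one step:    {100 * df['onset_within_one_step'].mean():.1f}%")
    print(f"  median K11 rel. error:    {100 * df['K11_rel_err'].median():.1f}%")

    # contrast: K recovery on genuinely linear (A_L) diagrams
    lin_grid = grid[:8]
    lin_errs = []
    for s in rng_seeds:
        d, tr = g.gen_phase_solubility(
            g.PhaseSolSimConfig(
                K11=1.5, S0=0.033, ligand_grid=lin_grid,
                beta=0.0, noise_cv=0.05, seed=int(s),
            )
        )
        f = g.fit_K11(d, linear_range=(float(lin_grid[0]), float(lin_grid[-1])))
        lin_errs.append(abs(f.K11 - tr.K11) / tr.K11)
    print(f"  median K11 rel. error on A_L (beta = 0) diagrams: "
          f"{100 * float(np.median(lin_errs)):.1f}%")
    print(
        "\nFinding: the anchored-line breakpoint rule recovers the deviation "
        "onset almost always. K11 itself is recovered to a few percent on "
        "genuinely linear diagrams, but is biased low (~25% here) under "
        "smooth aggregation: the saturation model has no exactly linear "
        "region, so even the retained low-concentration slope sits below "
        "the true complexation slope — an inherent limitation of slope "
        "inversion on A_N data, not an effect of assay noise."
    )


if __name__ == "__main__":
    main()
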