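#!/usr/bin/env python
"""Hansen solubility parameters of the two gel components and their Δδ screen.

Computes group-contribution δd/δp/δh/δ for sulindac (the BCS-II drug) and
meglumine (the hydrophilic ligand/gelator) from the shipped fragmentations,
screens the pair for miscibility, and compares with the published values
(δ = 23.74 / 25.89 MPa^0.5, Δδ = 2.15). Writes results/hansen_parameters.csv.
"""

import dataclasses
from pathlib import Path

import pandas as pd

import gelsolv as g

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ref = g.reference_values()["delta_total_mpa_sqrt"]
    rows = []
    params = {}
    for comp in (g.sulindac_composition(), g.meglumine_composition()):
        p = g.compute_hansen(comp)
        params[comp.molecule_name] = p
        rows.append(
            {
                "molecule": comp.molecule_name,
                **dataclasses.asdict(p),
                "delta_published": ref[comp.molecule_name],
                "rel_dev_pct": 100 * (p.delta_total / ref[comp.molecule_name] - 1),
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "hansen_parameters.csv", index=False)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.2f}"))

    print()
    own = g.miscibility_screen(params["sulindac"], params["meglumine"])
    pub = g.miscibility_screen(ref["sulindac"], ref["meglumine"])
    print(f"Δδ from published deltas: {pub.delta_diff:.2f} MPa^0.5 -> {pub.verdict}")
    print(f"Δδ from computed deltas:  {own.delta_diff:.2f} MPa^0.5 -> {own.verdict}")
    print(
        "\nFinding: sulindac reproduces the published δ within ~1.3%; meglumine "
        "does not (+47%), because five hydroxyls contribute a hydrogen-bonding "
        "term that alone exceeds the published total — see docs/methods.md. "
        "The screen therefore agrees with the published verdict only when fed "
        "the published δ pair; the computed pair inherits the meglumine "
        "overestimate and flags an immiscibility risk, illustrating how "
        "table-dialect differences dominate this screen for polyols."
    )


if __name__ == "__main__":
    main()
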