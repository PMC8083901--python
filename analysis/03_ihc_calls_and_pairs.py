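#!/usr/bin/env python
"""Turn per-core IHC scores into patient-level over/under calls and
enumerate the distinct stain pairs of the 29-stain panel.

The packaged panel holds 21 proteins, 8 of them assayed in two cellular
compartments; excluding same-protein pairs, 29 stains combine into 398
distinct pairs. Writes results/ihc_calls.csv and results/stain_pairs.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from slmarker import call_stains, enumerate_stain_pairs, load_panel
from slmarker.ihc import read_scores

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    args = parser.parse_args()

    panel = load_panel()
    scores = read_scores(args.data / "ihc_scores.csv")
    calls = call_stains(scores, panel)
    pairs = enumerate_stain_pairs(panel)

    outdir = ROOT / "results"
    calls.reset_index().to_csv(outdir / "ihc_calls.csv", index=False)
    pd.DataFrame([(a.stain_id, b.stain_id) for a, b in pairs],
                 columns=["stain_a", "stain_b"]).to_csv(
        outdir / "stain_pairs.tsv", sep="\t", index=False)

    n_proteins = len({s.protein for s in panel})
    print(f"called {calls.shape[0]} patients on {calls.shape[1]} stains "
          f"({n_proteins} proteins)")
    print(f"{len(panel)} stains -> {len(pairs)} distinct pairs "
          f"(same-protein pairs excluded)")
    over_rates = (calls == "over").mean().sort_values()
    print("over-call prevalence range: "
          f"{over_rates.iloc[0]:.2f} ({over_rates.index[0]}) to "
          f"{over_rates.iloc[-1]:.2f} ({over_rates.index[-1]})")


if __name__ == "__main__":
    main()
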