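#!/usr/bin/env python
"""Two-marker combinations of the survival screen's significant markers.

Markers whose pattern subset showed reduced hazard (HR < 1) contribute the
complement of that subset, so every component of a combination points at
excess risk; the joint risk group is the intersection, subject to the
>=5-patient rule, and is tested with a stage-adjusted Cox model.

Writes results/combinations.tsv and prints the significant combinations.
"""

import argparse
from pathlib import Path

import pandas as pd

from slmarker import MarkerDefinition, combine_markers
from slmarker.ihc import parse_marker_label

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--top", type=int, default=8,
                        help="combine only the strongest N significant markers")
    args = parser.parse_args()

    screen = pd.read_csv(ROOT / "results" / "survival_screen.tsv", sep="\t")
    calls = pd.read_csv(ROOT / "results" / "ihc_calls.csv", dtype=str).set_index("patient_id")
    clinical = pd.read_csv(args.data / "clinical.csv", dtype={"patient_id": str})

    sig = (
        screen[(screen["status"] == "tested") & (screen["p"] < args.alpha)]
        .sort_values("p")
        .head(args.top)
    )
    markers = []
    for _, r in sig.iterrows():
        m = parse_marker_label(r["marker"])
        orientation = "protective" if r["hr"] < 1 else "risk"
        markers.append(MarkerDefinition(m.stain_ids, m.risk_pattern, orientation))

    rows = []
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            res = combine_markers(markers[i], markers[j], calls, clinical)
            row = {"combination": res.display_label(), "n": res.n,
                   "n_risk": res.n_risk, "status": res.status}
            if res.adjusted is not None:
                row.update(hr_adj=res.adjusted.hr("marker"),
                           ci_low_adj=res.adjusted.ci("marker")[0],
                           ci_high_adj=res.adjusted.ci("marker")[1],
                           p_adj=res.adjusted.p("marker"),
                           lr_chi2_adj=res.adjusted.lr_chi2)
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(ROOT / "results" / "combinations.tsv", sep="\t", index=False,
                 float_format="%.6g")

    ok = frame[frame["status"] == "tested"] if len(frame) else frame
    print(f"{len(markers)} significant markers -> {len(frame)} combinations, "
          f"{len(ok)} testable")
    if len(ok):
        best = ok[ok["p_adj"] < args.alpha].sort_values("p_adj")
        for _, r in best.head(10).iterrows():
            print(f"  {r['combination']}: n_risk={int(r['n_risk'])}/{int(r['n'])} "
                  f"adjusted HR={r['hr_adj']:.2f} "
                  f"({r['ci_low_adj']:.2f}-{r['ci_high_adj']:.2f}) p={r['p_adj']:.3g}")


if __name__ == "__main__":
    main()
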