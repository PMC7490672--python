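#!/usr/bin/env python
"""Derive the three wrist cut-point sets from the matched epoch table.

Runs the ROC threshold search, the cumulative-logit (proportional-odds)
model and exact univariate k-means on the pooled wrist cpm values, and
writes the per-class summary (n, bounds, mean, SD) for each method to
results/cutpoints.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from accelcal.calibrate import kmeans_calibrate, olr_calibrate, roc_calibrate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--matched", type=Path, default=ROOT / "scratch" / "matched.csv")
    args = ap.parse_args()

    if not args.matched.exists():
        raise SystemExit(f"{args.matched} not found - run analysis/02_preprocess.py first")
    df = pd.read_csv(args.matched)
    wrist = df["wrist_cpm"].to_numpy()
    labels = df["hip_label"].to_numpy()

    frames = []
    for name, res in (
        ("roc", roc_calibrate(wrist, labels)),
        ("olr", olr_calibrate(wrist, labels)),
        ("kmeans", kmeans_calibrate(wrist)),
    ):
        print(
            f"{name:7s} SB <= {res.cuts.t1:6d}  LPA <= {res.cuts.t2:6d}  "
            f"MPA <= {res.cuts.t3:6d}  VPA >= {res.cuts.t3 + 1:6d} cpm"
        )
        tab = res.per_class.copy()
        tab.insert(0, "method", name)
        frames.append(tab)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    out = results / "cutpoints.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
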