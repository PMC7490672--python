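#!/usr/bin/env python
"""Agreement with the hip reference and daily activity estimates.

Labels every matched epoch with each derived wrist cut-point set,
computes per-class and overall agreement (sensitivity, specificity,
FPR, FNR, kappa, correct classification; 4-level and MVPA-grouped),
summarizes daily minutes per intensity level, and tests each wrist
method's daily estimates against the hip reference with a paired
bootstrap.  All tables go to results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from accelcal.calibrate import kmeans_calibrate, olr_calibrate, roc_calibrate
from accelcal.cutpoints import LEVEL_NAMES, label_series
from accelcal.validate import agreement_report, compare_methods, estimate_table, summarize_tally

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--matched", type=Path, default=ROOT / "scratch" / "matched.csv")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    if not args.matched.exists():
        raise SystemExit(f"{args.matched} not found - run analysis/02_preprocess.py first")
    df = pd.read_csv(args.matched)
    wrist = df["wrist_cpm"].to_numpy()
    labels = df["hip_label"].to_numpy()
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    tally = summarize_tally(np.bincount(labels, minlength=4))
    print("hip-labeled epoch shares (%):", tally["percent"], f"(n={tally['total']})")

    calibrations = {
        "roc": roc_calibrate(wrist, labels),
        "olr": olr_calibrate(wrist, labels),
        "kmeans": kmeans_calibrate(wrist),
    }
    agreement_frames, day_frames = [], [df.assign(method="hip", label=labels)]
    for name, res in calibrations.items():
        comp = label_series(wrist, res.cuts)
        rep = agreement_report(labels, comp, method=name)
        agreement_frames.append(rep.to_frame())
        day_frames.append(df.assign(method=name, label=comp))
        print(
            f"{name:7s} correct classification {rep.overall_accuracy:5.2f}% "
            f"(grouped {rep.grouped_accuracy:5.2f}%), kappa {rep.overall_kappa:.3f}"
        )
    pd.concat(agreement_frames, ignore_index=True).to_csv(
        results / "agreement.csv", index=False
    )

    day_labels = pd.concat(day_frames, ignore_index=True)[
        ["participant_id", "day", "method", "label"]
    ]
    daily = estimate_table(day_labels, epoch_length=15)
    daily.to_csv(results / "daily.csv", index=False)

    rows = []
    for name in calibrations:
        for cls in (*LEVEL_NAMES, "MVPA"):
            cmp = compare_methods(
                day_labels, "hip", name, cls, epoch_length=15, seed=args.seed
            )
            rows.append({"method": name, "class": cls, **cmp})
    diffs = pd.DataFrame(rows)
    diffs.to_csv(results / "method_differences.csv", index=False)
    same = diffs[diffs["no_difference"]]
    print(
        "daily estimates with no detectable difference from the hip reference:",
        ", ".join(f"{r['method']}/{r['class']}" for _, r in same.iterrows()) or "none",
    )
    print(f"wrote {results / 'agreement.csv'}, {results / 'daily.csv'}, "
          f"{results / 'method_differences.csv'}")


if __name__ == "__main__":
    main()
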