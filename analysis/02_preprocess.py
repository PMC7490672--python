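#!/usr/bin/env python
"""Wear-time filtering, hip/wrist alignment and the exclusion rule.

Reads the simulated study written by 01_simulate.py, flags non-wear
with the Choi zero-run rule, intersects worn epochs across placements,
applies the participant exclusion rule, and labels each matched epoch
with the Butte hip reference.  The pooled matched table (one row per
epoch) goes to scratch/; the recruitment-funnel counts go to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from accelcal.cutpoints import BUTTE_HIP, label_series
from accelcal.io import read_manifest
from accelcal.preprocess import align_pairs, detect_nonwear_choi, exclude_participants

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "scratch" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "matched.csv")
    args = ap.parse_args()

    manifest = args.data / "manifest.csv"
    if not manifest.exists():
        raise SystemExit(f"{manifest} not found - run analysis/01_simulate.py first")

    series = read_manifest(manifest)
    by_key: dict = {}
    for s in series:
        by_key.setdefault((s.participant_id, s.day_index), {})[s.placement] = s

    tables, roster = [], []
    for (pid, day), pair in sorted(by_key.items()):
        hip, wrist = pair["hip"], pair["wrist"]
        tables.append(
            align_pairs(hip, wrist, detect_nonwear_choi(hip), detect_nonwear_choi(wrist))
        )
        roster.append({"participant_id": pid, "day": day})
    matched = pd.concat(tables, ignore_index=True)
    n_before = len(matched)
    matched, log = exclude_participants(matched, pd.DataFrame(roster))
    matched["hip_label"] = label_series(matched["hip_cpm"].to_numpy(), BUTTE_HIP)
    matched.to_csv(args.out, index=False)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    funnel = pd.DataFrame(
        [
            {"stage": "enrolled participants", "n": len({r["participant_id"] for r in roster})},
            {"stage": "excluded participants", "n": len(log)},
            {"stage": "analyzable participants", "n": matched["participant_id"].nunique()},
            {"stage": "aligned epochs", "n": n_before},
            {"stage": "matched epochs after exclusion", "n": len(matched)},
        ]
    )
    funnel.to_csv(results / "data_flow.csv", index=False)

    print(f"wrote {args.out}")
    print(funnel.to_string(index=False))


if __name__ == "__main__":
    main()
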