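"""Agreement statistics and daily physical-activity estimates.

Each candidate wrist method is compared epoch-by-epoch against the hip
reference: a confusion matrix (rows = reference, columns = comparison),
one-vs-rest sensitivity / specificity / FPR / FNR per class, a
binarized per-class Cohen kappa, overall correct-classification and
multiclass kappa, and the same block on the 3-level scale with MPA and
VPA merged into MVPA.  Daily time in each level (minutes of wear) is
summarized per method across participant-days; method-vs-reference
differences use a paired percentile bootstrap.

Division-by-zero metrics (e.g. sensitivity when the reference class is
absent) are reported as NaN — an explicit "undefined" marker — never
silently as 0 or 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cutpoints import LEVEL_NAMES, LEVEL_NAMES_3, group_mvpa
from .util import round_half_up

__all__ = [
    "confusion",
    "one_vs_rest_metrics",
    "cohen_kappa",
    "overall_agreement",
    "AgreementReport",
    "agreement_report",
    "daily_time",
    "estimate_table",
    "compare_methods",
    "summarize_tally",
]


def confusion(reference, comparison, n_classes: int = 4) -> np.ndarray:
    """Confusion matrix of (reference, comparison) label pairs."""
    ref = np.asarray(reference, dtype=np.int64)
    comp = np.asarray(comparison, dtype=np.int64)
    if ref.shape != comp.shape:
        raise ValueError("reference and comparison labels differ in length")
    if ref.size == 0:
        warnings.warn("empty label sequences: zero confusion matrix", stacklevel=2)
        return np.zeros((n_classes, n_classes), dtype=np.int64)
    if ref.min() < 0 or ref.max() >= n_classes or comp.min() < 0 or comp.max() >= n_classes:
        raise ValueError(f"labels out of range for {n_classes} classes")
    return np.bincount(ref * n_classes + comp, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes
    )


def _pct(num: float, den: float) -> float:
    return np.nan if den == 0 else 100.0 * num / den


def one_vs_rest_metrics(m: np.ndarray, cls: int) -> dict:
    """Sensitivity, specificity, FPR and FNR (%) for one class.

    The matrix is collapsed to 2x2 for ``cls``; 0/0 divisions yield NaN.
    """
    m = np.asarray(m)
    tp = m[cls, cls]
    fn = m[cls, :].sum() - tp
    fp = m[:, cls].sum() - tp
    tn = m.sum() - tp - fn - fp
    sens = _pct(tp, tp + fn)
    spec = _pct(tn, tn + fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "fpr": 100.0 - spec if np.isfinite(spec) else np.nan,
        "fnr": 100.0 - sens if np.isfinite(sens) else np.nan,
    }


def cohen_kappa(reference, comparison, n_classes: Optional[int] = None) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e).

    ``p_e`` is the marginal-product chance agreement.  Returns NaN when
    both labelings are the same constant (p_e = 1, κ undefined).
    """
    ref = np.asarray(reference, dtype=np.int64)
    comp = np.asarray(comparison, dtype=np.int64)
    if ref.shape != comp.shape or ref.size == 0:
        raise ValueError("need equal-length non-empty label sequences")
    if n_classes is None:
        n_classes = int(max(ref.max(), comp.max())) + 1
    m = confusion(ref, comp, n_classes)
    n = m.sum()
    p_o = np.trace(m) / n
    p_e = float(np.dot(m.sum(axis=1), m.sum(axis=0))) / (n * n)
    if p_e >= 1.0:
        return np.nan
    return float((p_o - p_e) / (1.0 - p_e))


def overall_agreement(m: np.ndarray) -> float:
    """Correct-classification % = trace / total x 100 (NaN when empty)."""
    m = np.asarray(m)
    total = m.sum()
    return np.nan if total == 0 else float(100.0 * np.trace(m) / total)


@dataclass
class AgreementReport:
    """Per-class and overall agreement of one wrist method vs the reference."""

    method: str
    per_class: pd.DataFrame  # class, sensitivity, specificity, fpr, fnr, kappa
    overall_accuracy: float
    overall_kappa: float
    per_class_grouped: pd.DataFrame  # 3-level scale (SB, LPA, MVPA)
    grouped_accuracy: float
    grouped_kappa: float
    matrix: np.ndarray
    matrix_grouped: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table mirroring the agreement-report layout."""
        rows = []
        for _, r in self.per_class.iterrows():
            for metric in ("sensitivity", "specificity", "fpr", "fnr", "kappa"):
                rows.append((self.method, "4-level", r["class"], metric, r[metric]))
        for _, r in self.per_class_grouped.iterrows():
            for metric in ("sensitivity", "specificity", "fpr", "fnr", "kappa"):
                rows.append((self.method, "3-level", r["class"], metric, r[metric]))
        rows.append((self.method, "4-level", "overall", "correct_classification", self.overall_accuracy))
        rows.append((self.method, "4-level", "overall", "kappa", self.overall_kappa))
        rows.append((self.method, "3-level", "overall", "correct_classification", self.grouped_accuracy))
        rows.append((self.method, "3-level", "overall", "kappa", self.grouped_kappa))
        return pd.DataFrame(rows, columns=["method", "scale", "class", "metric", "value"])


def _per_class_block(ref, comp, names) -> pd.DataFrame:
    n = len(names)
    m = confusion(ref, comp, n)
    rows = []
    for k, name in enumerate(names):
        met = one_vs_rest_metrics(m, k)
        ref_bin = (np.asarray(ref) == k).astype(np.int64)
        comp_bin = (np.asarray(comp) == k).astype(np.int64)
        met["kappa"] = cohen_kappa(ref_bin, comp_bin, 2)
        rows.append({"class": name, **met})
    return pd.DataFrame(rows)


def agreement_report(reference, comparison, method: str = "") -> AgreementReport:
    """Full agreement block (4-level and MVPA-grouped) for one method."""
    ref = np.asarray(reference, dtype=np.int64)
    comp = np.asarray(comparison, dtype=np.int64)
    m4 = confusion(ref, comp, 4)
    ref3, comp3 = group_mvpa(ref), group_mvpa(comp)
    m3 = confusion(ref3, comp3, 3)
    return AgreementReport(
        method=method,
        per_class=_per_class_block(ref, comp, LEVEL_NAMES),
        overall_accuracy=overall_agreement(m4),
        overall_kappa=cohen_kappa(ref, comp, 4),
        per_class_grouped=_per_class_block(ref3, comp3, LEVEL_NAMES_3),
        grouped_accuracy=overall_agreement(m3),
        grouped_kappa=cohen_kappa(ref3, comp3, 3),
        matrix=m4,
        matrix_grouped=m3,
    )


def daily_time(labels, epoch_length: int) -> dict:
    """Minutes per intensity level for one participant-day of worn epochs."""
    lab = np.asarray(labels, dtype=np.int64)
    per_min = epoch_length / 60.0
    counts = np.bincount(lab, minlength=4) if lab.size else np.zeros(4, dtype=int)
    out = {name: counts[k] * per_min for k, name in enumerate(LEVEL_NAMES)}
    out["MVPA"] = out["MPA"] + out["VPA"]
    out["wear"] = lab.size * per_min
    return out


def estimate_table(day_labels: pd.DataFrame, epoch_length: int) -> pd.DataFrame:
    """Per-method daily-minute summary across participant-days.

    ``day_labels`` has columns ``participant_id``, ``day``, ``method``,
    ``label``; one row per worn epoch.  Returns one row per method and
    class with mean (SD) daily minutes and percent of mean wear time.
    """
    rows = []
    for method, g in day_labels.groupby("method", sort=False):
        per_day = []
        for (pid, day), gg in g.groupby(["participant_id", "day"]):
            per_day.append(daily_time(gg["label"].to_numpy(), epoch_length))
        df = pd.DataFrame(per_day)
        mean_wear = df["wear"].mean()
        for cls in (*LEVEL_NAMES, "MVPA"):
            mean = df[cls].mean()
            sd = df[cls].std(ddof=1) if len(df) > 1 else np.nan
            rows.append(
                {
                    "method": method,
                    "class": cls,
                    "n_days": len(df),
                    "mean_minutes": mean,
                    "sd_minutes": sd,
                    "pct_of_wear": _pct(mean, mean_wear),
                }
            )
    return pd.DataFrame(rows)


def compare_methods(
    day_labels: pd.DataFrame,
    reference: str,
    comparison: str,
    cls: str,
    epoch_length: int,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Paired mean difference in daily minutes with a bootstrap 95% CI.

    Resamples participant-days with replacement (percentile interval,
    ``n_boot`` draws).  "No difference" is declared when the interval
    covers zero.
    """
    def per_day_minutes(method):
        g = day_labels[day_labels["method"] == method]
        out = {}
        for (pid, day), gg in g.groupby(["participant_id", "day"]):
            out[(pid, day)] = daily_time(gg["label"].to_numpy(), epoch_length)[cls]
        return out

    ref_min = per_day_minutes(reference)
    comp_min = per_day_minutes(comparison)
    keys = sorted(set(ref_min) & set(comp_min))
    if len(keys) < 2:
        raise ValueError("need at least 2 paired participant-days")
    diffs = np.array([comp_min[k] - ref_min[k] for k in keys])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(diffs), size=(n_boot, len(diffs)))
    boots = diffs[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "mean_difference": float(diffs.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_pairs": len(diffs),
        "no_difference": bool(lo <= 0.0 <= hi),
    }


def summarize_tally(class_counts: Sequence[int]) -> dict:
    """Epoch-tally arithmetic: total, MVPA count and per-class shares.

    Given per-class epoch counts (SB, LPA, MPA, VPA) returns the total,
    the MVPA count (MPA + VPA) and percentages rounded half-up to one
    decimal — the layout of the study's descriptive epoch table.
    """
    c = np.asarray(class_counts, dtype=np.int64)
    if c.shape != (4,) or c.min() < 0:
        raise ValueError("need four nonnegative per-class counts")
    total = int(c.sum())
    pct = (
        [float(round_half_up(100.0 * x / total, 1)) for x in c]
        if total
        else [np.nan] * 4
    )
    return {
        "counts": {name: int(c[k]) for k, name in enumerate(LEVEL_NAMES)},
        "total": total,
        "mvpa": int(c[2] + c[3]),
        "percent": {name: pct[k] for k, name in enumerate(LEVEL_NAMES)},
        "mvpa_percent": float(round_half_up(100.0 * (c[2] + c[3]) / total, 1))
        if total
        else np.nan,
    }
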