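"""Epoch-level preprocessing: vector magnitude, reintegration, cpm
conversion, non-wear detection and hip/wrist alignment.

The pipeline consumes ActiGraph-style epoch count series.  Raw 30 Hz
accelerations are assumed already integrated into per-epoch counts (the
count-generation step is proprietary and happens upstream); this module
starts at 15-s or 60-s epochs, computes the per-epoch vector magnitude
VM = sqrt(x^2 + y^2 + z^2), re-integrates to coarser epochs by
summation, scales counts to a per-minute basis (cpm), flags non-wear
with the Choi zero-run rule, intersects the worn epochs of a hip/wrist
pair into a matched table, and applies the participant exclusion rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .util import round_half_up

__all__ = [
    "EpochSeries",
    "ChoiParams",
    "vector_magnitude",
    "reintegrate",
    "to_cpm",
    "detect_nonwear_choi",
    "align_pairs",
    "exclude_participants",
]


@dataclass
class EpochSeries:
    """One placement's per-epoch counts for one participant-day.

    Exactly one of ``values`` (precomputed VM) or ``axes`` (per-axis
    triplets, shape ``(n, 3)``) must be set; if both are present the VM
    column wins and the axis data are ignored with a notice.
    """

    participant_id: str
    day_index: int
    placement: str
    epoch_length: int  # seconds
    values: Optional[np.ndarray] = None
    axes: Optional[np.ndarray] = None
    start_time: str = "09:00:00"

    def __post_init__(self) -> None:
        if self.placement not in ("hip", "wrist"):
            raise ValueError(f"placement must be 'hip' or 'wrist', got {self.placement!r}")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive seconds")
        if self.values is None and self.axes is None:
            raise ValueError("EpochSeries needs VM values or axis triplets")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=np.int64)
            if self.values.ndim != 1 or self.values.size == 0:
                raise ValueError("values must be a non-empty 1-D array")
            if self.values.min() < 0:
                raise ValueError("counts must be nonnegative")
        if self.axes is not None:
            self.axes = np.asarray(self.axes, dtype=np.int64)
            if self.axes.ndim != 2 or self.axes.shape[1] != 3 or self.axes.shape[0] == 0:
                raise ValueError("axes must be a non-empty (n, 3) array")
            if self.axes.min() < 0:
                raise ValueError("counts must be nonnegative")
        if self.values is not None and self.axes is not None:
            if len(self.values) != len(self.axes):
                raise ValueError("values and axes lengths differ")

    @property
    def n_epochs(self) -> int:
        return len(self.values) if self.values is not None else len(self.axes)


@dataclass(frozen=True)
class ChoiParams:
    """Choi non-wear rule parameters, on the 1-minute grid.

    A non-wear interval is >= ``window_min`` consecutive zero-count
    minutes, allowing embedded nonzero interruptions of at most
    ``spike_tolerance_min`` minutes when flanked by >= ``flank_min``
    zero minutes on both sides.
    """

    window_min: int = 90
    spike_tolerance_min: int = 2
    flank_min: int = 30


def vector_magnitude(series: EpochSeries) -> EpochSeries:
    """Compute per-epoch VM = sqrt(x^2 + y^2 + z^2), rounded half-up.

    If the series already carries VM values they are returned unchanged
    (ActiLife exports sometimes include both; the VM column wins).
    """
    if series.values is not None:
        return series
    if series.axes is None:
        raise ValueError("missing axis data: no axis1/axis2/axis3 columns")
    ax = series.axes.astype(np.float64)
    vm = round_half_up(np.sqrt(np.sum(ax * ax, axis=1))).astype(np.int64)
    return replace(series, values=vm, axes=None)


def reintegrate(series: EpochSeries, target_epoch_length: int) -> EpochSeries:
    """Collapse to a coarser epoch grid by summing constituent epochs.

    ``target_epoch_length`` must be a positive integer multiple of the
    source epoch length; a trailing partial window is dropped with a
    warning so that total counts are conserved over complete windows.
    """
    src = series.epoch_length
    if target_epoch_length < src:
        raise ValueError(
            f"cannot disaggregate: target {target_epoch_length}s < source {src}s"
        )
    if target_epoch_length % src != 0:
        raise ValueError(
            f"target epoch {target_epoch_length}s is not a multiple of source {src}s"
        )
    s = vector_magnitude(series)
    ratio = target_epoch_length // src
    if ratio == 1:
        return s
    n = s.n_epochs
    n_full = (n // ratio) * ratio
    if n_full < n:
        warnings.warn(
            f"dropping trailing partial window of {n - n_full} epochs", stacklevel=2
        )
    vals = s.values[:n_full].reshape(-1, ratio).sum(axis=1)
    return replace(s, values=vals, epoch_length=target_epoch_length)


def to_cpm(series: EpochSeries) -> np.ndarray:
    """Counts-per-minute values: ``cpm_i = VM_i * 60 / epoch_length``.

    15-s epochs scale by 4; 60-s epochs pass through unchanged.
    """
    s = vector_magnitude(series)
    if 60 % s.epoch_length == 0:
        return s.values * (60 // s.epoch_length)
    return s.values * (60.0 / s.epoch_length)


def _minute_zero_runs(zero: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean minute mask as (start, length, is_zero)."""
    runs = []
    i, n = 0, len(zero)
    while i < n:
        j = i
        while j < n and zero[j] == zero[i]:
            j += 1
        runs.append((i, j - i, bool(zero[i])))
        i = j
    return runs


def detect_nonwear_choi(series: EpochSeries, params: ChoiParams = ChoiParams()) -> np.ndarray:
    """Per-epoch wear mask (True = worn) from the Choi zero-run rule.

    The rule is evaluated on a 60-s grid derived from the data (counts
    summed per minute); the resulting minute mask is expanded back to
    the source epoch grid.  A trailing partial minute is treated as
    worn.  The series must cover a contiguous span of epochs.
    """
    s = vector_magnitude(series)
    if s.epoch_length > 60 or 60 % s.epoch_length != 0:
        raise ValueError(
            "Choi detection requires an epoch length dividing 60 s; "
            "re-integrate or split the series first"
        )
    per_min = 60 // s.epoch_length
    n = s.n_epochs
    n_min = n // per_min
    minute_counts = s.values[: n_min * per_min].reshape(-1, per_min).sum(axis=1)
    zero = minute_counts == 0

    runs = _minute_zero_runs(zero)
    # Absorb short nonzero spikes flanked by long zero runs, iterating to a
    # fixpoint because merging zero runs can enable further absorption.
    changed = True
    while changed:
        changed = False
        for k in range(1, len(runs) - 1):
            start, length, is_zero = runs[k]
            if is_zero or length > params.spike_tolerance_min:
                continue
            if runs[k - 1][1] >= params.flank_min and runs[k + 1][1] >= params.flank_min:
                merged = (
                    runs[k - 1][0],
                    runs[k - 1][1] + length + runs[k + 1][1],
                    True,
                )
                runs = runs[: k - 1] + [merged] + runs[k + 2 :]
                changed = True
                break

    nonwear_min = np.zeros(n_min, dtype=bool)
    for start, length, is_zero in runs:
        if is_zero and length >= params.window_min:
            nonwear_min[start : start + length] = True

    wear = np.ones(n, dtype=bool)
    wear[: n_min * per_min] = ~np.repeat(nonwear_min, per_min)
    return wear


def align_pairs(
    hip: EpochSeries,
    wrist: EpochSeries,
    hip_wear: Optional[np.ndarray] = None,
    wrist_wear: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Matched epoch table for one participant-day.

    Keeps only epochs worn on both placements (wear masks default to
    all-worn) and expresses counts in cpm.  Columns: ``participant_id``,
    ``day``, ``epoch``, ``hip_cpm``, ``wrist_cpm``.
    """
    if (
        hip.participant_id != wrist.participant_id
        or hip.day_index != wrist.day_index
    ):
        raise ValueError("hip and wrist series are not the same participant-day")
    if hip.epoch_length != wrist.epoch_length or hip.n_epochs != wrist.n_epochs:
        raise ValueError(
            "mismatched epoch grids: "
            f"hip {hip.n_epochs}x{hip.epoch_length}s vs "
            f"wrist {wrist.n_epochs}x{wrist.epoch_length}s"
        )
    n = hip.n_epochs
    hip_wear = np.ones(n, dtype=bool) if hip_wear is None else np.asarray(hip_wear, bool)
    wrist_wear = (
        np.ones(n, dtype=bool) if wrist_wear is None else np.asarray(wrist_wear, bool)
    )
    if len(hip_wear) != n or len(wrist_wear) != n:
        raise ValueError("wear mask length does not match the series")
    both = hip_wear & wrist_wear
    if not both.any():
        warnings.warn(
            f"empty hip/wrist wear intersection for participant "
            f"{hip.participant_id} day {hip.day_index}",
            stacklevel=2,
        )
    idx = np.flatnonzero(both)
    return pd.DataFrame(
        {
            "participant_id": hip.participant_id,
            "day": hip.day_index,
            "epoch": idx,
            "hip_cpm": to_cpm(hip)[idx],
            "wrist_cpm": to_cpm(wrist)[idx],
        }
    )


def exclude_participants(
    matched: pd.DataFrame,
    roster: pd.DataFrame,
    max_consecutive_invalid_days: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the participant exclusion rule.

    A day is *invalid* when it contributed no matched worn epochs.  A
    participant is excluded when every enrolled day is invalid, or when
    invalid days form a run longer than ``max_consecutive_invalid_days``
    (the latter can only bite in protocols longer than the default
    3-day collection).

    Parameters
    ----------
    matched : DataFrame
        Pooled matched epoch table (``participant_id``, ``day`` columns).
    roster : DataFrame
        Enrolled participant-days (``participant_id``, ``day``), one row
        each, including days that yielded no data.

    Returns
    -------
    (filtered, log) : the matched table restricted to retained
        participants, and an exclusion log with one row per excluded
        participant and the reason.
    """
    counts = (
        matched.groupby(["participant_id", "day"]).size()
        if len(matched)
        else pd.Series(dtype=int)
    )
    excluded = []
    for pid, grp in roster.groupby("participant_id"):
        days = sorted(grp["day"].tolist())
        valid = [counts.get((pid, d), 0) > 0 for d in days]
        if not any(valid):
            excluded.append((pid, "no valid matched epochs on any day"))
            continue
        run = best = 0
        for v in valid:
            run = run + 1 if not v else 0
            best = max(best, run)
        if best > max_consecutive_invalid_days:
            excluded.append(
                (pid, f"{best} consecutive days without valid matched epochs")
            )
    log = pd.DataFrame(excluded, columns=["participant_id", "reason"])
    keep = ~matched["participant_id"].isin(set(log["participant_id"]))
    return matched[keep].reset_index(drop=True), log
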