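"""Intensity cut-point sets and epoch classification.

Physical-activity intensity is an ordinal four-level scale — sedentary
behavior (SB), light (LPA), moderate (MPA) and vigorous (VPA) physical
activity — assigned by thresholding vector-magnitude counts per minute
(cpm).  A :class:`CutPointSet` holds three ordered integer boundaries
``t1 < t2 < t3`` that tile the nonnegative integer cpm axis into

    SB  = [0, t1]      LPA = [t1+1, t2]
    MPA = [t2+1, t3]   VPA = [t3+1, inf)

with no gaps or overlaps.  The shipped hip reference is the Butte
preschool set (820 / 3908 / 6112 cpm); the published MPA upper bound is
6112 and the VPA description "greater than 6113" leaves a one-count
gap, which this module closes by taking VPA = >= 6113 cpm so that
classification is a total function.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IntensityLabel",
    "CutPointSet",
    "JohanssonWrist",
    "BUTTE_HIP",
    "JOHANSSON_MVPA_LOWER",
    "LEVEL_NAMES",
    "LEVEL_NAMES_3",
    "classify",
    "label_series",
    "group_mvpa",
]


class IntensityLabel(IntEnum):
    """Ordinal physical-activity intensity level."""

    SB = 0
    LPA = 1
    MPA = 2
    VPA = 3


LEVEL_NAMES = ("SB", "LPA", "MPA", "VPA")
#: Labels on the 3-level scale obtained by merging MPA and VPA into MVPA.
LEVEL_NAMES_3 = ("SB", "LPA", "MVPA")

#: Johansson wrist MVPA lower bound (cpm); the SB/LPA boundaries of that
#: calibration are not redistributed here and must be user-supplied.
JOHANSSON_MVPA_LOWER = 16716


@dataclass(frozen=True)
class CutPointSet:
    """Three ordered integer cpm boundaries defining a 4-level partition.

    Parameters
    ----------
    name : str
        Identifier (e.g. ``"butte_hip"``, ``"kmeans_wrist"``).
    placement : str
        Device placement the set applies to, ``"hip"`` or ``"wrist"``.
    t1, t2, t3 : int
        Upper bounds (inclusive, in cpm) of SB, LPA and MPA.
    """

    name: str
    placement: str
    t1: int
    t2: int
    t3: int

    def __post_init__(self) -> None:
        if self.placement not in ("hip", "wrist"):
            raise ValueError(f"placement must be 'hip' or 'wrist', got {self.placement!r}")
        for t in (self.t1, self.t2, self.t3):
            if int(t) != t:
                raise ValueError("cut points must be integers on the cpm grid")
        if not (0 <= self.t1 < self.t2 < self.t3):
            raise ValueError(
                f"cut points must satisfy 0 <= t1 < t2 < t3, got "
                f"({self.t1}, {self.t2}, {self.t3})"
            )

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([self.t1, self.t2, self.t3])

    def intervals(self) -> list[tuple[int, float]]:
        """Closed class intervals ``[(lo, hi), ...]`` on the cpm grid."""
        return [
            (0, self.t1),
            (self.t1 + 1, self.t2),
            (self.t2 + 1, self.t3),
            (self.t3 + 1, np.inf),
        ]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "placement": self.placement,
            "t1": int(self.t1),
            "t2": int(self.t2),
            "t3": int(self.t3),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutPointSet":
        return cls(d["name"], d["placement"], int(d["t1"]), int(d["t2"]), int(d["t3"]))


#: Butte et al. preschool hip reference (vector-magnitude cpm).
BUTTE_HIP = CutPointSet("butte_hip", "hip", 820, 3908, 6112)


@dataclass(frozen=True)
class JohanssonWrist:
    """Partial wrist reference: fixed MVPA floor, user-supplied SB bound.

    The source calibration published SB and MVPA boundaries only, so
    classification is on the 3-level scale SB / LPA / MVPA with
    ``LPA = (sb_upper, mvpa_lower)`` and ``MVPA = [mvpa_lower, inf)``.
    """

    sb_upper: int
    mvpa_lower: int = JOHANSSON_MVPA_LOWER
    name: str = "johansson_wrist"

    def __post_init__(self) -> None:
        if not 0 <= self.sb_upper < self.mvpa_lower:
            raise ValueError("require 0 <= sb_upper < mvpa_lower")

    def label_series_3(self, cpm: Sequence[float]) -> np.ndarray:
        """3-level labels (0=SB, 1=LPA, 2=MVPA) for a cpm sequence."""
        arr = _as_cpm_array(cpm)
        return np.searchsorted(
            np.array([self.sb_upper, self.mvpa_lower - 1]), arr, side="left"
        ).astype(np.int8)


def _as_cpm_array(cpm: Sequence[float]) -> np.ndarray:
    arr = np.asarray(cpm)
    if arr.size and arr.min() < 0:
        idx = int(np.argmin(arr))
        raise ValueError(f"negative cpm value {arr.flat[idx]} at epoch {idx}")
    return arr


def classify(cpm: float, cuts: CutPointSet) -> IntensityLabel:
    """Intensity level of a single cpm value under ``cuts``.

    Boundary semantics: a value equal to an upper bound belongs to the
    lower class (Butte 820 -> SB, 821 -> LPA, 6112 -> MPA, 6113 -> VPA).
    """
    if cpm < 0:
        raise ValueError(f"negative cpm value {cpm}")
    return IntensityLabel(int(np.searchsorted(cuts.thresholds, cpm, side="left")))


def label_series(cpm: Sequence[float], cuts: CutPointSet) -> np.ndarray:
    """Elementwise :func:`classify`; returns int8 codes, length preserved."""
    arr = _as_cpm_array(cpm)
    return np.searchsorted(cuts.thresholds, arr, side="left").astype(np.int8)


def group_mvpa(labels: Iterable[int]) -> np.ndarray:
    """Collapse the 4-level scale to SB / LPA / MVPA (codes 0/1/2)."""
    arr = np.asarray(labels)
    return np.minimum(arr, 2).astype(np.int8)
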