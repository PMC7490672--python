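"""Synthetic paired hip/wrist epoch-count generator.

Real calibration data for this design (preschoolers wearing hip and
wrist devices simultaneously over 3 preschool days) are not publicly
deposited, so the pipeline ships a generator with the statistical
structure the analysis assumes:

* a sticky 4-state Markov chain at 15-s resolution produces bouts of
  the ordinal intensity states SB/LPA/MPA/VPA, with stationary
  occupancy defaulting to the observed preschool-day shares
  (64.2 / 28.0 / 5.5 / 2.3 %);
* per-state right-skewed (lognormal, integerized) hip counts whose
  mass sits inside the matching Butte cpm interval, with a small
  zero-inflation term for sedentary epochs;
* a strictly monotone hip->wrist linkage ``g`` (default ``g(x)=3.2x``,
  motivated by wrist cut points landing near 3x their hip analogues)
  with multiplicative lognormal noise of unit median;
* occasional zero-count non-wear blocks on whole-minute boundaries.

With ``pure=True`` the emission clips each state's counts strictly
inside its Butte interval, so hip classification recovers the state
sequence exactly — the noise-free regime used by the recovery checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .cutpoints import BUTTE_HIP, CutPointSet
from .preprocess import EpochSeries
from .util import round_half_up, substream

__all__ = [
    "TABLE_OCCUPANCY",
    "ActivityStateModel",
    "StateEmission",
    "CountEmissionModel",
    "NonwearModel",
    "SimulationConfig",
    "ParticipantDay",
    "StudyData",
    "simulate_states",
    "emit_counts",
    "inject_nonwear",
    "simulate_study",
]

#: Preschool-day stationary occupancy targets for SB/LPA/MPA/VPA.
TABLE_OCCUPANCY = (0.642, 0.280, 0.055, 0.023)


class InvalidModelError(ValueError):
    """A simulation model violates its invariants."""


@dataclass(frozen=True)
class ActivityStateModel:
    """4-state Markov chain at epoch resolution."""

    transition: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=np.float64)
        p = np.asarray(self.initial, dtype=np.float64)
        object.__setattr__(self, "transition", t)
        object.__setattr__(self, "initial", p)
        if t.shape != (4, 4) or p.shape != (4,):
            raise InvalidModelError("transition must be 4x4 and initial length-4")
        if t.min() < 0 or p.min() < 0:
            raise InvalidModelError("probabilities must be nonnegative")
        if np.max(np.abs(t.sum(axis=1) - 1.0)) > 1e-12:
            raise InvalidModelError("transition rows must sum to 1 within 1e-12")
        if abs(p.sum() - 1.0) > 1e-12:
            raise InvalidModelError("initial distribution must sum to 1")

    @classmethod
    def sticky(
        cls,
        stationary: Sequence[float] = TABLE_OCCUPANCY,
        persistence: float = 0.9,
    ) -> "ActivityStateModel":
        """Chain ``P = rho*I + (1-rho) * 1 pi^T`` with stationary ``pi``.

        ``persistence`` (rho) controls bout length: mean sojourn is
        roughly ``1 / (1 - rho)`` epochs (2.5 min at the 0.9 default on
        a 15-s grid), emulating short-burst preschool activity.
        """
        pi = np.asarray(stationary, dtype=np.float64)
        pi = pi / pi.sum()
        if not 0 <= persistence < 1:
            raise InvalidModelError("persistence must be in [0, 1)")
        trans = persistence * np.eye(4) + (1 - persistence) * np.tile(pi, (4, 1))
        return cls(trans, pi)

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.transition.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, k])
        return v / v.sum()


@dataclass(frozen=True)
class StateEmission:
    """Lognormal hip-count parameters for one state, on the cpm scale."""

    median_cpm: float
    sigma: float
    zero_prob: float = 0.0


@dataclass(frozen=True)
class CountEmissionModel:
    """State-conditional hip counts plus the monotone wrist linkage.

    ``wrist_g`` must be strictly increasing on [0, inf); the default is
    ``g(x) = wrist_scale * x`` applied to the per-epoch hip count.
    Wrist counts are ``round(g(hip) * exp(eps))`` with
    ``eps ~ N(0, noise_sigma^2)`` (unit-median multiplicative noise);
    with ``noise_sigma = 0`` the linkage is exactly deterministic.
    """

    states: tuple[StateEmission, StateEmission, StateEmission, StateEmission] = (
        StateEmission(120.0, 0.85, zero_prob=0.25),  # SB
        StateEmission(1790.0, 0.30),  # LPA
        StateEmission(4900.0, 0.11),  # MPA
        StateEmission(9500.0, 0.15),  # VPA
    )
    wrist_scale: float = 3.2
    wrist_g: Optional[Callable[[np.ndarray], np.ndarray]] = None
    noise_sigma: float = 0.2
    pure: bool = False
    #: In pure mode, shrink each class interval toward its center by this
    #: fraction per side before clipping, so class supports are separated
    #: by real gaps rather than touching at the cut points.
    pure_shrink: float = 0.25
    reference_cuts: CutPointSet = BUTTE_HIP

    def __post_init__(self) -> None:
        for s in self.states:
            if s.median_cpm < 0 or s.sigma < 0 or not 0 <= s.zero_prob <= 1:
                raise InvalidModelError(
                    "state emission parameters must be nonnegative with zero_prob in [0,1]"
                )
        if self.noise_sigma < 0:
            raise InvalidModelError("noise_sigma must be nonnegative")
        if self.wrist_g is None and self.wrist_scale <= 0:
            raise InvalidModelError("wrist_scale must be positive")

    def g(self, x: np.ndarray) -> np.ndarray:
        if self.wrist_g is not None:
            return self.wrist_g(x)
        return self.wrist_scale * np.asarray(x, dtype=np.float64)

    def count_intervals(self, epoch_length: int) -> list[tuple[int, Optional[int]]]:
        """Per-state closed count intervals on the epoch grid.

        Derived from the reference cpm cut points: a count c maps to
        cpm = c * 60 / epoch_length, so the SB interval at 15 s is
        [0, 205] (205 -> 820 cpm) and LPA starts at 206 (-> 824 cpm).
        """
        f = epoch_length / 60.0
        t = self.reference_cuts
        return [
            (0, int(np.floor(t.t1 * f))),
            (int(np.floor(t.t1 * f)) + 1, int(np.floor(t.t2 * f))),
            (int(np.floor(t.t2 * f)) + 1, int(np.floor(t.t3 * f))),
            (int(np.floor(t.t3 * f)) + 1, None),
        ]

    def pure_intervals(self, epoch_length: int) -> list[tuple[int, int]]:
        """Interior clipping intervals for pure emission.

        Bounded classes shrink toward their center by ``pure_shrink`` per
        side (SB keeps its zero floor — zero counts are genuinely
        sedentary); the open VPA interval becomes
        ``[lo * (1 + shrink), 3 * lo]``.  The gaps this leaves between
        class supports are what make the emission well separated.
        """
        s = self.pure_shrink
        out = []
        for k, (lo, hi) in enumerate(self.count_intervals(epoch_length)):
            if hi is None:  # VPA
                out.append((int(np.ceil(lo * (1 + s))), int(3 * lo)))
            else:
                width = hi - lo
                new_lo = 0 if k == 0 else int(np.ceil(lo + s * width))
                out.append((new_lo, int(np.floor(hi - s * width))))
        return out


@dataclass(frozen=True)
class NonwearModel:
    """Occasional whole-minute zero blocks emulating device removal."""

    block_prob: float = 0.05  # per participant-day
    min_minutes: int = 90
    max_minutes: int = 180
    placement: str = "both"  # "hip" | "wrist" | "both"

    def __post_init__(self) -> None:
        if not 0 <= self.block_prob <= 1:
            raise InvalidModelError("block_prob must be in [0, 1]")
        if not 0 < self.min_minutes <= self.max_minutes:
            raise InvalidModelError("need 0 < min_minutes <= max_minutes")
        if self.placement not in ("hip", "wrist", "both"):
            raise InvalidModelError("placement must be hip, wrist or both")


@dataclass(frozen=True)
class SimulationConfig:
    """Full study-generation configuration; the seed determines everything."""

    n_participants: int = 34
    n_days: int = 3
    day_length_min: int = 300
    epoch_length: int = 15
    seed: int = 0
    state_model: ActivityStateModel = field(
        default_factory=ActivityStateModel.sticky
    )
    emission: CountEmissionModel = field(default_factory=CountEmissionModel)
    nonwear: Optional[NonwearModel] = field(default_factory=NonwearModel)
    #: Extra enrolled participants who never yield valid matched data
    #: (device refusal); used to replicate the recruitment funnel.
    n_noncompliant: int = 0

    def __post_init__(self) -> None:
        if (self.day_length_min * 60) % self.epoch_length != 0:
            raise InvalidModelError(
                "day_length_min * 60 must be divisible by epoch_length"
            )
        if self.n_participants < 1 or self.n_days < 1:
            raise InvalidModelError("need at least one participant and one day")

    @property
    def epochs_per_day(self) -> int:
        return self.day_length_min * 60 // self.epoch_length


@dataclass
class ParticipantDay:
    """Paired series for one participant-day plus simulation ground truth."""

    participant_id: str
    day: int
    hip: EpochSeries
    wrist: EpochSeries
    truth: pd.DataFrame  # columns: state, hip_worn, wrist_worn


@dataclass
class StudyData:
    config: SimulationConfig
    days: list[ParticipantDay]

    @property
    def n_epochs(self) -> int:
        return sum(d.hip.n_epochs for d in self.days)


def simulate_states(
    model: ActivityStateModel, n_epochs: int, seed_or_rng
) -> np.ndarray:
    """Sample an intensity-state path of length ``n_epochs`` (int8 codes)."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    cum = np.cumsum(model.transition, axis=1)
    u = rng.random(n_epochs)
    states = np.empty(n_epochs, dtype=np.int8)
    states[0] = np.searchsorted(np.cumsum(model.initial), u[0], side="right")
    for i in range(1, n_epochs):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i], side="right")
    return states


def emit_counts(
    states: Sequence[int],
    emission: CountEmissionModel,
    seed_or_rng,
    epoch_length: int = 15,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (hip, wrist) integer count series for a state path."""
    st = np.asarray(states, dtype=np.int64)
    if st.size == 0:
        raise ValueError("states must be non-empty")
    if st.min() < 0 or st.max() > 3:
        raise InvalidModelError("states must be codes 0..3")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    n = st.size
    f = epoch_length / 60.0  # cpm -> per-epoch counts

    hip_cpm = np.empty(n, dtype=np.float64)
    for k in range(4):
        mask = st == k
        m = int(mask.sum())
        if m == 0:
            continue
        p = emission.states[k]
        draws = np.exp(rng.normal(np.log(max(p.median_cpm, 1e-12)), p.sigma, size=m))
        if p.zero_prob > 0:
            draws[rng.random(m) < p.zero_prob] = 0.0
        hip_cpm[mask] = draws

    hip = round_half_up(hip_cpm * f).astype(np.int64)
    if emission.pure:
        for k, (lo, hi) in enumerate(emission.pure_intervals(epoch_length)):
            mask = st == k
            hip[mask] = np.clip(hip[mask], lo, hi)

    noise = (
        np.exp(rng.normal(0.0, emission.noise_sigma, size=n))
        if emission.noise_sigma > 0
        else 1.0
    )
    gw = emission.g(hip.astype(np.float64))
    if np.any(np.diff(emission.g(np.arange(0.0, 10.0))) <= 0):
        raise InvalidModelError("wrist linkage g must be strictly increasing")
    wrist = round_half_up(gw * noise).astype(np.int64)
    if hip.min() < 0 or wrist.min() < 0:
        raise InvalidModelError("emission produced negative counts")
    return hip, wrist


def inject_nonwear(
    values: np.ndarray,
    model: NonwearModel,
    rng: np.random.Generator,
    epoch_length: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Overwrite at most one whole-minute-aligned block with zeros.

    Returns ``(values, worn_mask)``; the mask is the ground truth the
    non-wear detector is later compared against.  Blocks longer than the
    day are clipped with a warning.
    """
    vals = np.asarray(values, dtype=np.int64).copy()
    n = vals.size
    worn = np.ones(n, dtype=bool)
    if rng.random() >= model.block_prob:
        return vals, worn
    per_min = max(60 // epoch_length, 1)
    day_min = n * epoch_length // 60
    dur = int(rng.integers(model.min_minutes, model.max_minutes + 1))
    if dur > day_min:
        warnings.warn(f"non-wear block {dur} min clipped to day length {day_min} min")
        dur = day_min
    start_min = int(rng.integers(0, day_min - dur + 1))
    a, b = start_min * per_min, (start_min + dur) * per_min
    vals[a:b] = 0
    worn[a:b] = False
    return vals, worn


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate the full paired study dataset deterministically from the seed."""
    days: list[ParticipantDay] = []
    n_total = config.n_participants + config.n_noncompliant
    width = len(str(n_total))
    for p in range(n_total):
        pid = f"P{p + 1:0{width}d}"
        compliant = p < config.n_participants
        for d in range(config.n_days):
            rng = substream(config.seed, f"participant{p}/day{d}")
            states = simulate_states(config.state_model, config.epochs_per_day, rng)
            hip, wrist = emit_counts(states, config.emission, rng, config.epoch_length)
            hip_worn = np.ones(states.size, dtype=bool)
            wrist_worn = np.ones(states.size, dtype=bool)
            if not compliant:
                # Device refusal: the wrist unit is never worn this day.
                wrist = np.zeros_like(wrist)
                wrist_worn[:] = False
            elif config.nonwear is not None and config.nonwear.block_prob > 0:
                blk_rng = substream(config.seed, f"nonwear/participant{p}/day{d}")
                if config.nonwear.placement in ("hip", "both"):
                    hip, hw = inject_nonwear(
                        hip, config.nonwear, blk_rng, config.epoch_length
                    )
                    hip_worn &= hw
                if config.nonwear.placement in ("wrist", "both"):
                    if config.nonwear.placement == "both":
                        # same block on both devices (child removed together)
                        wrist = np.where(hip_worn, wrist, 0)
                        wrist_worn &= hip_worn
                    else:
                        wrist, ww = inject_nonwear(
                            wrist, config.nonwear, blk_rng, config.epoch_length
                        )
                        wrist_worn &= ww
            truth = pd.DataFrame(
                {"state": states, "hip_worn": hip_worn, "wrist_worn": wrist_worn}
            )
            days.append(
                ParticipantDay(
                    pid,
                    d,
                    EpochSeries(pid, d, "hip", config.epoch_length, values=hip),
                    EpochSeries(pid, d, "wrist", config.epoch_length, values=wrist),
                    truth,
                )
            )
    return StudyData(config, days)
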