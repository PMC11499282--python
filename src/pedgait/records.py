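"""Core data containers shared across the pipeline.

Times are seconds from recording start internally; timestamps become
ISO-8601 only at file boundaries. All intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

AGE_GROUPS = ("3-5", "6-11", "12-17")
SPEED_CLASSES = ("natural", "fast", "slow")
INTENSITY_LEVELS = ("sedentary", "light", "moderate", "vigorous")


def age_group_of(age_years: float) -> str:
    """Map an age in years onto the study's three age strata."""
    if 3 <= age_years < 6:
        return "3-5"
    if 6 <= age_years < 12:
        return "6-11"
    if 12 <= age_years <= 17:
        return "12-17"
    raise ValueError(f"age {age_years} outside supported range 3-17")


@dataclass(frozen=True)
class SubjectProfile:
    """A study participant: identity, age stratum and stature.

    Height feeds the inverted-pendulum spatial model (pendulum length is a
    fixed anthropometric fraction of height).
    """

    subject_id: str
    age_years: float
    height_m: float
    sex: str = "F"

    def __post_init__(self) -> None:
        if not (0.8 <= self.height_m <= 2.1):
            raise ValueError(f"height_m {self.height_m} outside [0.8, 2.1]")
        age_group_of(self.age_years)  # raises if out of range

    @property
    def age_group(self) -> str:
        return age_group_of(self.age_years)


@dataclass
class AccelRecording:
    """Tri-axial acceleration in g, uniformly sampled.

    ``data`` has shape (n_samples, 3); ``start_time`` anchors sample 0 on
    the wall clock. ``site`` is the wear location ('lumbar' or 'wrist').
    """

    data: np.ndarray
    fs_hz: float
    start_time: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2024-01-01"))
    site: str = "lumbar"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("data must have shape (n, 3)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


@dataclass(frozen=True)
class ContactEvent:
    """A gait event: initial contact (heel strike) or final contact (toe off)."""

    time_s: float
    kind: str  # 'IC' | 'FC'
    foot: str = "unknown"  # 'L' | 'R' | 'unknown'


@dataclass
class Stride:
    """One gait cycle: consecutive same-foot initial contacts.

    Spatial fields stay None until the inverted-pendulum step runs.
    """

    start_ic_s: float
    end_ic_s: float
    stride_time_s: float
    step_time_s: float
    cadence_spm: float
    double_support_s: Optional[float] = None
    stride_length_m: Optional[float] = None
    speed_mps: Optional[float] = None
    foot: str = "unknown"


def strides_to_frame(strides: Sequence[Stride]) -> pd.DataFrame:
    """Tabulate strides; empty input yields an empty frame with the schema."""
    cols = [
        "start_ic_s", "end_ic_s", "stride_time_s", "step_time_s",
        "cadence_spm", "double_support_s", "stride_length_m", "speed_mps", "foot",
    ]
    if not strides:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in strides])


@dataclass
class GaitBout:
    """A contiguous walking episode, half-open [start_s, end_s)."""

    start_s: float
    end_s: float
    strides: list = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_gait_cycles(self) -> int:
        return len(self.strides)


@dataclass
class GaitTruth:
    """Planted ground truth for one simulated walkway pass."""

    event_times: list  # (time_s, kind, foot) tuples, strictly increasing
    stride_times_s: np.ndarray
    stride_lengths_m: np.ndarray
    speeds_mps: np.ndarray
    cadence_spm: np.ndarray
    pass_speed_class: str
    vertical_axis: int = 2
    vertical_sign: int = 1

    def __post_init__(self) -> None:
        times = [e[0] for e in self.event_times]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event_times must be strictly increasing")
        for name in ("stride_times_s", "stride_lengths_m", "speeds_mps", "cadence_spm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be positive")
        if not np.allclose(self.cadence_spm, 120.0 / self.stride_times_s):
            raise ValueError("cadence inconsistent with stride times")

    @property
    def ic_times(self) -> np.ndarray:
        return np.array([t for t, k, _ in self.event_times if k == "IC"])


@dataclass
class FreeLivingTruth:
    """Planted schedule for a simulated free-living recording.

    Intervals are seconds from recording start, half-open, non-overlapping
    within each list; nonwear never overlaps gait.
    """

    bout_intervals: list  # [(start_s, end_s), ...]
    nonwear_intervals: list
    intensity_labels: pd.Series  # index: epoch start (s), values in INTENSITY_LEVELS + 'nonwear'
    epoch_len_s: float = 60.0

    def __post_init__(self) -> None:
        for name in ("bout_intervals", "nonwear_intervals"):
            iv = sorted(getattr(self, name))
            setattr(self, name, iv)
            if any(b0 < a1 for (_, a1), (b0, _) in zip(iv, iv[1:])):
                raise ValueError(f"{name} overlap")
        for gs, ge in self.bout_intervals:
            for ns, ne in self.nonwear_intervals:
                if gs < ne and ns < ge:
                    raise ValueError("gait bout overlaps nonwear block")


@dataclass
class ReferenceWalkRecord:
    """Per-pass summary from the reference walkway comparator."""

    cadence_spm: float
    gait_speed_mps: float
    stride_time_s: float
    stride_length_m: float
    pass_speed_class: str = "natural"
    subject_id: str = ""
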