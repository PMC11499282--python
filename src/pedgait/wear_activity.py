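"""Epoch activity counts, non-wear detection (Choi) and intensity classes.

Counts are an open surrogate for proprietary device counts: each axis is
band-pass filtered to the human-movement band, rectified with a small dead
band (so sensor noise on a stationary device sums to exactly zero), clipped
and summed per epoch. Vector-magnitude cut-points mapping counts to
sedentary / light / moderate / vigorous are calibrated against the
synthetic generator's class energies and shipped in config; an optional
two-regression mode first splits epochs on the coefficient of variation of
sub-epoch counts and applies one of two MET regression equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import AccelRecording


@dataclass(frozen=True)
class CountParams:
    """Band-pass + rectify + clip + sum surrogate count definition."""

    band_hz: tuple = (0.25, 2.5)
    deadband_g: float = 0.075
    clip_g: float = 8.0
    epoch_len_s: float = 60.0


@dataclass(frozen=True)
class ChoiParams:
    """Canonical sustained-zero non-wear parameters (minutes)."""

    window_min: int = 90
    spike_tolerance_min: int = 2
    flanking_zero_min: int = 30

    def __post_init__(self) -> None:
        if self.spike_tolerance_min >= self.window_min:
            raise ValueError("spike tolerance must be below the window length")


@dataclass(frozen=True)
class CutPoints:
    """Vector-magnitude count thresholds (per epoch) separating intensities.

    Calibrated once against the synthetic generator's activity-class
    energies (see docs); sedentary < c1 <= light < c2 <= moderate < c3.
    """

    c1: float = 4.0
    c2: float = 14.0
    c3: float = 35.0

    def __post_init__(self) -> None:
        if not (0 <= self.c1 < self.c2 < self.c3):
            raise ValueError("cut-points must be ordered 0 <= c1 < c2 < c3")


def epoch_counts(recording: AccelRecording, params: CountParams = CountParams()) -> pd.DataFrame:
    """Per-epoch surrogate counts per axis plus vector magnitude.

    Returns a frame indexed by epoch start (s) with columns
    ``counts_x/y/z`` (g·s per epoch) and ``vector_magnitude``.
    """
    fs = recording.fs_hz
    ep = params.epoch_len_s
    if recording.duration_s < ep:
        raise ValueError("epoch longer than recording")
    sos = sps.butter(4, params.band_hz, btype="bandpass", fs=fs, output="sos")
    n_ep = int(recording.duration_s // ep)
    spe = int(round(ep * fs))
    x = recording.data[: n_ep * spe].reshape(n_ep, spe, 3)
    counts = np.empty((n_ep, 3))
    # each epoch is filtered in isolation so a stationary epoch sums to
    # exactly zero regardless of its neighbours; chunked to bound memory
    chunk = 256
    for i0 in range(0, n_ep, chunk):
        filt = sps.sosfiltfilt(sos, x[i0:i0 + chunk], axis=1)
        r = np.abs(filt)
        r[r < params.deadband_g] = 0.0
        np.clip(r, 0.0, params.clip_g, out=r)
        counts[i0:i0 + chunk] = r.sum(axis=1) / fs
    out = pd.DataFrame(
        counts, columns=["counts_x", "counts_y", "counts_z"],
        index=np.arange(n_ep) * ep,
    )
    out.index.name = "epoch_start_s"
    out["vector_magnitude"] = np.linalg.norm(counts, axis=1)
    return out


def detect_wear(epochs: pd.DataFrame, params: ChoiParams = ChoiParams()) -> pd.DataFrame:
    """Flag wear/non-wear per epoch from sustained zero-count runs (Choi).

    A run of >= ``window_min`` consecutive zero-VM epochs is non-wear; up to
    ``spike_tolerance_min`` nonzero epochs may interrupt the run provided
    each spike is flanked by >= ``flanking_zero_min`` zero epochs on both
    sides. Assumes 1-minute epochs and a contiguous index.
    """
    vm = epochs["vector_magnitude"].to_numpy()
    n = vm.size
    zero = vm == 0
    nonwear = np.zeros(n, dtype=bool)

    i = 0
    while i < n:
        if not zero[i]:
            i += 1
            continue
        # grow a candidate run from i, absorbing tolerable spikes
        j = i
        spikes = 0
        end = j
        while j < n:
            if zero[j]:
                j += 1
                end = j
                continue
            # count the contiguous nonzero spike starting at j
            k = j
            while k < n and not zero[k]:
                k += 1
            spike_len = k - j
            before = _zeros_back(zero, j)
            after = _zeros_fwd(zero, k)
            if (
                spikes + spike_len <= params.spike_tolerance_min
                and before >= params.flanking_zero_min
                and after >= params.flanking_zero_min
            ):
                spikes += spike_len
                j = k
            else:
                break
        if end - i >= params.window_min:
            nonwear[i:end] = True
        i = max(end, i + 1)

    out = epochs.copy()
    out["wear"] = ~nonwear
    return out


def _zeros_back(zero: np.ndarray, j: int) -> int:
    c = 0
    j -= 1
    while j >= 0 and zero[j]:
        c += 1
        j -= 1
    return c


def _zeros_fwd(zero: np.ndarray, k: int) -> int:
    c = 0
    while k < zero.size and zero[k]:
        c += 1
        k += 1
    return c


@dataclass(frozen=True)
class TwoRegressionParams:
    """Optional CV-split MET regression mode (both equations configurable)."""

    cv_threshold: float = 0.1
    low_cv_coeffs: tuple = (2.0, 0.1)   # METs = a + b * vm
    high_cv_coeffs: tuple = (1.0, 0.15)
    met_cuts: tuple = (1.5, 3.0, 6.0)


def classify_intensity(
    epochs: pd.DataFrame,
    cutpoints: CutPoints = CutPoints(),
    two_regression: TwoRegressionParams | None = None,
    sub_epoch_cv: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign an intensity class per epoch and keep non-wear separate.

    Default mode thresholds vector-magnitude counts on the configured
    cut-points. The two-regression mode maps counts to METs through one of
    two regression equations chosen by the CV of sub-epoch counts, then
    applies MET thresholds.
    """
    if "wear" not in epochs:
        raise ValueError("wear flags must be computed first")
    out = epochs.copy()
    vm = out["vector_magnitude"].to_numpy()
    if two_regression is None:
        cls = np.select(
            [vm < cutpoints.c1, vm < cutpoints.c2, vm < cutpoints.c3],
            ["sedentary", "light", "moderate"],
            default="vigorous",
        )
    else:
        cv = (
            sub_epoch_cv.reindex(out.index).fillna(0.0).to_numpy()
            if sub_epoch_cv is not None
            else np.zeros(vm.size)
        )
        a_lo, b_lo = two_regression.low_cv_coeffs
        a_hi, b_hi = two_regression.high_cv_coeffs
        mets = np.where(cv <= two_regression.cv_threshold, a_lo + b_lo * vm, a_hi + b_hi * vm)
        t1, t2, t3 = two_regression.met_cuts
        cls = np.select(
            [mets < t1, mets < t2, mets < t3],
            ["sedentary", "light", "moderate"],
            default="vigorous",
        )
    cls = np.where(out["wear"].to_numpy(), cls, "nonwear")
    out["intensity"] = cls
    return out


def daily_activity_summary(epochs: pd.DataFrame, epoch_len_s: float = 60.0) -> pd.DataFrame:
    """Per-day wear hours, class minutes, MVPA, sedentary time and total VM.

    Non-wear epochs are excluded from every total. Day index is the
    calendar day number from recording start (epoch_start // 86400).
    """
    df = epochs.copy()
    df["day"] = (df.index.to_numpy() // 86400).astype(int)
    min_per_ep = epoch_len_s / 60.0
    rows = []
    for day, g in df.groupby("day"):
        wear = g["wear"]
        mins = {
            lvl: float((g["intensity"] == lvl).sum() * min_per_ep)
            for lvl in ("sedentary", "light", "moderate", "vigorous", "nonwear")
        }
        rows.append(
            dict(
                day=day,
                wear_h=float(wear.sum() * min_per_ep / 60.0),
                sedentary_min=mins["sedentary"],
                light_min=mins["light"],
                moderate_min=mins["moderate"],
                vigorous_min=mins["vigorous"],
                nonwear_min=mins["nonwear"],
                mvpa_min=mins["moderate"] + mins["vigorous"],
                total_vm=float(g.loc[wear, "vector_magnitude"].sum()),
            )
        )
    return pd.DataFrame(rows).set_index("day")
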