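"""Gait event detection and temporal/spatial metric extraction.

The detector follows the established trunk-accelerometry recipe: the
vertical acceleration is detrended, low-pass filtered and integrated, then
smoothed/differentiated with a Gaussian-derivative continuous wavelet
whose scale is tied to the dominant step frequency. Initial contacts (IC)
are local minima of the first-stage transform; final contacts (FC) are
local maxima of the differentiated transform. Implausible events are
discarded against static physiological step/stride-time bounds that are
kept constant across walking speeds.

Spatial metrics use the inverted-pendulum model: the vertical
center-of-mass excursion ``h`` per step comes from doubly integrating the
high-pass-filtered vertical acceleration, and the step length is
``2 * sqrt(2*l*h - h**2)`` with pendulum length ``l`` a fixed fraction of
the participant's height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import integrate
from scipy import signal as sps

from .records import AccelRecording, ContactEvent, Stride

G_MPS2 = 9.80665


@dataclass(frozen=True)
class GaitParams:
    """Tunable detector parameters; defaults are held fixed across speed classes."""

    stride_time_bounds_s: tuple = (0.25, 2.25)
    step_time_bounds_s: tuple = (0.1, 1.5)
    highpass_cutoff_hz: float = 0.7
    lowpass_cutoff_hz: float = 10.0
    leg_length_factor: float = 0.53
    wavelet: str = "gaus1"
    #: dominant-frequency search band for the wavelet scale (Hz)
    step_freq_band_hz: tuple = (0.6, 4.0)
    min_peak_prominence_frac: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.stride_time_bounds_s
        if not (0 < lo < hi):
            raise ValueError("invalid stride_time bounds")
        if not (0 < self.leg_length_factor < 1):
            raise ValueError("leg_length_factor must be in (0, 1)")


def find_vertical_axis(recording: AccelRecording) -> tuple[int, int]:
    """Identify the gravity-bearing axis and the sign making gravity positive.

    Returns ``(axis_index, sign)`` for the axis whose low-frequency
    component has the largest absolute mean.
    """
    if recording.duration_s < 1.0:
        raise ValueError("recording must be at least 1 s")
    x = recording.data
    if recording.fs_hz > 2.0:
        sos = sps.butter(2, 0.5, btype="lowpass", fs=recording.fs_hz, output="sos")
        grav = sps.sosfiltfilt(sos, x, axis=0)
    else:
        grav = x
    means = grav.mean(axis=0)
    if np.allclose(means, 0.0, atol=1e-6) and np.allclose(x, 0.0):
        raise ValueError("all-zero signal")
    axis = int(np.argmax(np.abs(means)))
    sign = 1 if means[axis] >= 0 else -1
    return axis, sign


def vertical_acceleration(recording: AccelRecording) -> np.ndarray:
    """Gravity-positive vertical acceleration (g), axis auto-detected."""
    axis, sign = find_vertical_axis(recording)
    return sign * recording.data[:, axis]


def _dominant_frequency(x: np.ndarray, fs: float, band: tuple) -> float:
    """Location of the largest spectral peak within ``band`` (Hz)."""
    f, p = sps.periodogram(x, fs=fs, detrend="linear")
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any() or p[sel].max() <= 0:
        return 2.0  # fall back to a typical pediatric step frequency
    return float(f[sel][np.argmax(p[sel])])


def _cwt_row(x: np.ndarray, scale: float, wavelet: str, fs: float) -> np.ndarray:
    coefs, _ = pywt.cwt(x, [scale], wavelet, sampling_period=1.0 / fs)
    return coefs[0]


def prune_close_events(indices, prominences, min_gap: int) -> list:
    """Enforce the minimum step-time bound on candidate IC sample indices.

    Of any pair closer than ``min_gap`` samples, the less prominent event
    is discarded (an "impossible step" under the physiological bounds).
    """
    depth = dict(zip(indices, prominences))
    kept: list[int] = []
    for i in indices:
        if kept and i - kept[-1] < min_gap:
            if depth[i] > depth[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(int(i))
    return kept


def detect_contact_events(
    vertical_accel: np.ndarray,
    fs_hz: float,
    params: GaitParams = GaitParams(),
) -> list[ContactEvent]:
    """Detect IC and FC events from the vertical acceleration (g).

    Pipeline: detrend -> low-pass -> cumulative integration -> CWT
    (Gaussian-derivative wavelet, scale from the dominant step frequency).
    IC = minima of the first transform; FC = maxima of the differentiated
    transform. Events violating the step-time bound are pruned (the
    shallower minimum of an offending pair is dropped); feet are assigned
    by alternation, labels arbitrary up to a swap.
    """
    x = np.asarray(vertical_accel, dtype=float)
    if fs_hz < 20:
        raise ValueError("fs_hz must be >= 20")
    if x.size / fs_hz < 2 * params.stride_time_bounds_s[1]:
        raise ValueError("signal shorter than two maximal strides")

    x = sps.detrend(x, type="constant") * G_MPS2
    if params.lowpass_cutoff_hz < fs_hz / 2:
        sos = sps.butter(4, params.lowpass_cutoff_hz, btype="lowpass", fs=fs_hz, output="sos")
        x = sps.sosfiltfilt(sos, x)
    if np.std(x) < 1e-4:  # no motion content
        return []

    vel = integrate.cumulative_trapezoid(x, dx=1.0 / fs_hz, initial=0.0)
    vel = sps.detrend(vel, type="linear")

    f_step = _dominant_frequency(vel, fs_hz, params.step_freq_band_hz)
    scale = pywt.central_frequency(params.wavelet) * fs_hz / f_step
    scale = max(scale, 1.0)

    w1 = _cwt_row(vel, scale, params.wavelet, fs_hz)
    # sign convention: make w1 track the smoothed acceleration so that IC
    # impact decelerations appear as minima
    if np.corrcoef(w1, x)[0, 1] < 0:
        w1 = -w1
    w2 = _cwt_row(np.gradient(w1, 1.0 / fs_hz), scale, params.wavelet, fs_hz)
    if np.corrcoef(w2, np.gradient(x, 1.0 / fs_hz))[0, 1] < 0:
        w2 = -w2

    prom1 = params.min_peak_prominence_frac * np.std(w1)
    ic_idx, ic_props = sps.find_peaks(-w1, prominence=prom1)
    prom2 = params.min_peak_prominence_frac * np.std(w2)
    fc_idx, _ = sps.find_peaks(w2, prominence=prom2)

    min_gap = int(round(params.step_time_bounds_s[0] * fs_hz))
    kept = prune_close_events(ic_idx, ic_props["prominences"], min_gap)

    events = [ContactEvent(time_s=i / fs_hz, kind="IC") for i in kept]
    events += [ContactEvent(time_s=i / fs_hz, kind="FC") for i in fc_idx]
    events.sort(key=lambda e: e.time_s)

    # foot assignment by alternation over ICs; FC belongs to the foot that
    # struck two ICs earlier (it is lifting off after double support)
    feet = ("L", "R")
    ic_times = [e.time_s for e in events if e.kind == "IC"]
    foot_of_ic = {t: feet[k % 2] for k, t in enumerate(ic_times)}
    out = []
    for e in events:
        if e.kind == "IC":
            out.append(ContactEvent(e.time_s, "IC", foot_of_ic[e.time_s]))
        else:
            prev = [t for t in ic_times if t <= e.time_s]
            if len(prev) >= 2:
                out.append(ContactEvent(e.time_s, "FC", foot_of_ic[prev[-2]]))
            elif prev:
                out.append(ContactEvent(e.time_s, "FC", "unknown"))
            # FC before any IC carries no stride information; drop it
    return out


def temporal_metrics(
    events: list[ContactEvent],
    params: GaitParams = GaitParams(),
) -> list[Stride]:
    """Form strides from consecutive same-foot ICs and compute temporal metrics.

    Fewer than 3 ICs signals "no strides" (empty list), not an error.
    Strides spanning a gap (step time outside bounds) are not formed.
    """
    ics = [e for e in events if e.kind == "IC"]
    fcs = [e for e in events if e.kind == "FC"]
    if len(ics) < 3:
        return []
    lo_step, hi_step = params.step_time_bounds_s
    lo_stride, hi_stride = params.stride_time_bounds_s
    fc_times = np.array([e.time_s for e in fcs])

    strides: list[Stride] = []
    for k in range(len(ics) - 2):
        t0, t1, t2 = ics[k].time_s, ics[k + 1].time_s, ics[k + 2].time_s
        step1, step2 = t1 - t0, t2 - t1
        stride_time = t2 - t0
        if not (lo_step <= step1 <= hi_step and lo_step <= step2 <= hi_step):
            continue
        if not (lo_stride <= stride_time <= hi_stride):
            continue
        ds = None
        if fc_times.size:
            parts = []
            for t_contra in (t1, t2):
                after = fc_times[(fc_times > t_contra) & (fc_times < t_contra + hi_step)]
                if after.size:
                    parts.append(after[0] - t_contra)
            if parts:
                ds = float(np.sum(parts))
        strides.append(
            Stride(
                start_ic_s=t0,
                end_ic_s=t2,
                stride_time_s=stride_time,
                step_time_s=step1,
                cadence_spm=120.0 / stride_time,
                double_support_s=ds,
                foot=ics[k].foot,
            )
        )
    return strides


def _vertical_displacement(vertical_accel_g: np.ndarray, fs_hz: float, cutoff_hz: float) -> np.ndarray:
    """Doubly integrated, drift-corrected vertical displacement (m)."""
    a = sps.detrend(np.asarray(vertical_accel_g, dtype=float), type="constant") * G_MPS2
    sos = sps.butter(4, cutoff_hz, btype="highpass", fs=fs_hz, output="sos")
    a = sps.sosfiltfilt(sos, a)
    v = integrate.cumulative_trapezoid(a, dx=1.0 / fs_hz, initial=0.0)
    v = sps.sosfiltfilt(sos, v)
    d = integrate.cumulative_trapezoid(v, dx=1.0 / fs_hz, initial=0.0)
    return sps.sosfiltfilt(sos, d)


def step_length_from_excursion(h: float, pendulum_m: float) -> float:
    """Inverted-pendulum chord length for vertical CoM excursion ``h``."""
    if h >= 2 * pendulum_m:
        raise ValueError("excursion exceeds pendulum geometry")
    return 2.0 * np.sqrt(2.0 * pendulum_m * h - h * h)


def spatial_metrics(
    strides: list[Stride],
    vertical_accel: np.ndarray,
    fs_hz: float,
    height_m: float,
    params: GaitParams = GaitParams(),
) -> list[Stride]:
    """Attach inverted-pendulum stride length and speed to each stride.

    Per step, the CoM excursion is the max-min of the drift-corrected
    displacement within the step; the stride length is the sum of its two
    step lengths. Strides whose excursion is geometrically impossible
    (h >= 2l) are flagged invalid and excluded.
    """
    if height_m <= 0:
        raise ValueError("height_m must be positive")
    if not strides:
        return []
    disp = _vertical_displacement(vertical_accel, fs_hz, params.highpass_cutoff_hz)
    pendulum = params.leg_length_factor * height_m

    out: list[Stride] = []
    for s in strides:
        lengths = []
        mid = s.start_ic_s + s.step_time_s
        ok = True
        for a, b in ((s.start_ic_s, mid), (mid, s.end_ic_s)):
            i0, i1 = int(round(a * fs_hz)), int(round(b * fs_hz))
            i1 = min(i1, disp.size)
            if i1 - i0 < 2:
                ok = False
                break
            h = float(disp[i0:i1].max() - disp[i0:i1].min())
            if h >= 2 * pendulum:
                ok = False
                break
            lengths.append(step_length_from_excursion(h, pendulum))
        if not ok:
            continue
        s.stride_length_m = float(np.sum(lengths))
        s.speed_mps = s.stride_length_m / s.stride_time_s
        out.append(s)
    return out


def analyze_pass(
    recording: AccelRecording,
    height_m: float,
    params: GaitParams = GaitParams(),
) -> list[Stride]:
    """Full single-pass pipeline: axis detection, events, temporal + spatial."""
    vert = vertical_acceleration(recording)
    events = detect_contact_events(vert, recording.fs_hz, params)
    strides = temporal_metrics(events, params)
    return spatial_metrics(strides, vert, recording.fs_hz, height_m, params)
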