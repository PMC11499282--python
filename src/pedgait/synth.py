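"""Synthetic accelerometry with planted ground truth.

Generates the three kinds of input the analysis pipeline consumes:

* staged walkway passes (natural / fast / slow) with per-stride truth,
* multi-day free-living recordings with labeled gait bouts, non-wear
  blocks and activity-intensity classes,
* Likert questionnaire response sheets.

The walking signal is deliberately minimal: gravity on the vertical axis,
a pendulum-consistent sinusoidal center-of-mass component at step
frequency, and a short half-sine impulse at each initial contact. The
vertical CoM excursion per step is exactly the value the inverted-pendulum
geometry implies for the planted step length, so an analyzer sharing that
geometry can recover the planted spatial metrics. Every call draws all
randomness from one generator seeded by the config; identical configs give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import (
    INTENSITY_LEVELS,
    SPEED_CLASSES,
    AccelRecording,
    FreeLivingTruth,
    GaitTruth,
    ReferenceWalkRecord,
    SubjectProfile,
)

#: anthropometric pendulum-length fraction of stature; shared with the analyzer
LEG_LENGTH_FACTOR = 0.53

#: IC impact transient width (s) — short relative to any plausible step time
IC_IMPULSE_WIDTH_S = 0.05

# Step-length fraction of height per staged speed class; together with the
# class cadence this fixes the planted gait speed.
STEP_LENGTH_FRAC = {"natural": 0.41, "fast": 0.50, "slow": 0.33}
CADENCE_SCALE = {"natural": 1.0, "fast": 1.25, "slow": 0.75}

# Per-axis movement noise sd (g) of non-gait activity classes; epoch-level
# energy is ordered sedentary < light < moderate < vigorous by construction.
ACTIVITY_SD_G = {"sedentary": 0.05, "light": 0.15, "moderate": 0.4, "vigorous": 0.8}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the simulator; one seeded generator per call, no global state."""

    fs_hz: float = 64.0
    noise_sd_g: float = 0.01
    seed: int = 0
    ic_impulse_amp_g: float = 0.1
    vertical_axis: int = 2
    vertical_sign: int = 1
    # free-living day schedule (times in hours from local midnight)
    wake_start_h: float = 7.0
    wake_span_h: float = 14.0
    bouts_per_day: int = 8
    bout_len_log_mu: float = math.log(60.0)  # log-seconds; median 60 s
    bout_len_log_sigma: float = 0.6
    nonwear_blocks_per_day: int = 1
    nonwear_block_min: float = 120.0
    epoch_len_s: float = 60.0
    # arm/trunk movement accompanying free-living gait (horizontal axes only)
    gait_horizontal_sd_g: float = 0.3

    def __post_init__(self) -> None:
        if self.fs_hz <= 8:
            raise ValueError("fs_hz too low for gait content")
        if self.noise_sd_g < 0:
            raise ValueError("noise_sd_g must be >= 0")
        if self.vertical_axis not in (0, 1, 2) or self.vertical_sign not in (-1, 1):
            raise ValueError("invalid vertical axis/sign")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _natural_cadence_spm(profile: SubjectProfile) -> float:
    """Typical self-selected cadence by age stratum (younger = faster)."""
    return {"3-5": 132.0, "6-11": 122.0, "12-17": 112.0}[profile.age_group]


def pendulum_excursion(step_length_m: float, pendulum_m: float) -> float:
    """Vertical CoM excursion h implied by step length under the pendulum model.

    Inverse of ``step_length = 2 * sqrt(2*l*h - h**2)``.
    """
    half = step_length_m / 2.0
    if half >= pendulum_m:
        raise ValueError("step length incompatible with pendulum length")
    return pendulum_m - math.sqrt(pendulum_m**2 - half**2)


def _walk_vertical_accel(
    t: np.ndarray,
    ic_times: np.ndarray,
    step_period_s: float,
    excursion_m: float,
    impulse_amp_g: float,
) -> np.ndarray:
    """Dynamic vertical acceleration (g) of the synthetic walk, gravity excluded.

    CoM displacement is ``(h/2) * cos(omega * (t - t_ic))`` so its
    acceleration minima fall exactly on the planted IC times and its
    excursion within each step is ``h``.
    """
    g = 9.80665
    omega = 2 * math.pi / step_period_s
    phase = omega * (t - ic_times[0])
    accel = -(excursion_m / 2.0) * omega**2 * np.cos(phase) / g
    # zero outside the walking span (half a period beyond the end ICs)
    pad = step_period_s / 2.0
    mask = (t >= ic_times[0] - pad) & (t <= ic_times[-1] + pad)
    accel = np.where(mask, accel, 0.0)
    half_w = IC_IMPULSE_WIDTH_S / 2.0
    for tc in ic_times:
        sel = np.abs(t - tc) <= half_w
        accel[sel] += impulse_amp_g * np.cos(math.pi * (t[sel] - tc) / IC_IMPULSE_WIDTH_S)
    return accel


def simulate_walk_pass(
    profile: SubjectProfile,
    speed_class: str,
    duration_s: float,
    cfg: SimConfig,
    cadence_spm: Optional[float] = None,
    step_length_m: Optional[float] = None,
) -> tuple[AccelRecording, GaitTruth]:
    """Simulate one staged walkway pass with known per-stride truth.

    Parameters default to class- and age-typical values; ``cadence_spm`` and
    ``step_length_m`` override them for controlled experiments.
    """
    if speed_class not in SPEED_CLASSES:
        raise ValueError(f"speed_class must be one of {SPEED_CLASSES}")
    if duration_s < 5:
        raise ValueError("duration_s must be >= 5")
    if cadence_spm is None:
        cadence_spm = _natural_cadence_spm(profile) * CADENCE_SCALE[speed_class]
    if step_length_m is None:
        step_length_m = STEP_LENGTH_FRAC[speed_class] * profile.height_m

    step_period = 60.0 / cadence_spm
    if duration_s < 2 * step_period:
        raise ValueError("duration too short for one stride")
    n_steps = int(round(duration_s * cadence_spm / 60.0))
    ic_times = step_period / 2.0 + step_period * np.arange(n_steps)
    ic_times = ic_times[ic_times < duration_s]
    n_steps = ic_times.size

    pendulum = LEG_LENGTH_FACTOR * profile.height_m
    excursion = pendulum_excursion(step_length_m, pendulum)

    stride_time = 2 * step_period
    # FC of the foot that struck at IC_{k-1} occurs a quarter step period
    # after IC_k (end of the double-support phase)
    events = []
    feet = ["L", "R"]
    for k, t_ic in enumerate(ic_times):
        events.append((float(t_ic), "IC", feet[k % 2]))
        if k >= 1:
            events.append((float(t_ic + step_period / 4.0), "FC", feet[(k - 1) % 2]))
    events.sort(key=lambda e: e[0])

    n_strides = max(n_steps - 2, 0)
    truth = GaitTruth(
        event_times=events,
        stride_times_s=np.full(n_strides, stride_time),
        stride_lengths_m=np.full(n_strides, 2 * step_length_m),
        speeds_mps=np.full(n_strides, 2 * step_length_m / stride_time),
        cadence_spm=np.full(n_strides, cadence_spm),
        pass_speed_class=speed_class,
        vertical_axis=cfg.vertical_axis,
        vertical_sign=cfg.vertical_sign,
    )

    n = int(round(duration_s * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz
    vert = _walk_vertical_accel(t, ic_times, step_period, excursion, cfg.ic_impulse_amp_g)

    rng = cfg.rng()
    data = np.zeros((n, 3))
    axes = [0, 1, 2]
    axes.remove(cfg.vertical_axis)
    ml_axis, ap_axis = axes
    # mild mediolateral sway at stride frequency, AP component at step frequency
    data[:, ml_axis] = 0.05 * np.sin(2 * math.pi * t / stride_time)
    data[:, ap_axis] = 0.10 * np.sin(2 * math.pi * t / step_period + 1.0)
    data[:, cfg.vertical_axis] = cfg.vertical_sign * (1.0 + vert)
    if cfg.noise_sd_g > 0:
        data += rng.normal(0.0, cfg.noise_sd_g, size=data.shape)

    rec = AccelRecording(data=data, fs_hz=cfg.fs_hz, site="lumbar", subject_id=profile.subject_id)
    return rec, truth


def simulate_reference_walkway(
    truth: GaitTruth,
    noise_sd: float = 0.0,
    seed: int = 0,
    subject_id: str = "",
) -> ReferenceWalkRecord:
    """Emulate the instrumented-walkway comparator for one pass.

    Reports the pass means of the planted truth plus zero-mean Gaussian
    measurement noise of sd ``noise_sd`` (in each metric's own units, scaled
    by the metric's magnitude so one knob serves all four metrics).
    """
    if truth.stride_times_s.size == 0:
        raise ValueError("empty truth")
    rng = np.random.default_rng(seed)
    means = {
        "cadence_spm": float(np.mean(truth.cadence_spm)),
        "gait_speed_mps": float(np.mean(truth.speeds_mps)),
        "stride_time_s": float(np.mean(truth.stride_times_s)),
        "stride_length_m": float(np.mean(truth.stride_lengths_m)),
    }
    if noise_sd > 0:
        for k in means:
            means[k] += rng.normal(0.0, noise_sd * abs(means[k]))
    return ReferenceWalkRecord(
        pass_speed_class=truth.pass_speed_class, subject_id=subject_id, **means
    )


# ---------------------------------------------------------------------------
# free-living days
# ---------------------------------------------------------------------------

def _bandlimited_noise(rng, n, fs, sd, lo=0.3, hi=4.0):
    """White noise band-passed to the human-movement band, rescaled to sd."""
    if n < 30:
        return rng.normal(0.0, sd, n)
    x = rng.normal(0.0, 1.0, n)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    s = y.std()
    return y * (sd / s) if s > 0 else y


def _snap(value_s: float, epoch_len_s: float) -> float:
    return round(value_s / epoch_len_s) * epoch_len_s


def build_day_schedule(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Lay out one day: nonwear blocks, gait bouts, and activity classes.

    All intervals are snapped to epoch boundaries so epoch-level labels are
    exact. Returns dict with 'nonwear', 'bouts', 'activity' interval lists
    (seconds from midnight); activity entries are (start, end, level).
    """
    ep = cfg.epoch_len_s
    wake0 = _snap(cfg.wake_start_h * 3600, ep)
    wake1 = _snap((cfg.wake_start_h + cfg.wake_span_h) * 3600, ep)
    if wake1 > 86400:
        raise ValueError("wake span crosses midnight")

    nonwear = []
    slots = [(wake0, wake1)]

    def take(duration, rng):
        """Carve an epoch-aligned interval out of a random free slot."""
        order = rng.permutation(len(slots))
        for i in order:
            s0, s1 = slots[i]
            if s1 - s0 >= duration + 2 * ep:
                start = _snap(s0 + ep + rng.uniform(0, s1 - s0 - duration - 2 * ep), ep)
                start = min(max(start, s0 + ep), s1 - duration - ep)
                slots.pop(i)
                slots.extend([(s0, start), (start + duration, s1)])
                return (start, start + duration)
        return None

    for _ in range(cfg.nonwear_blocks_per_day):
        iv = take(_snap(cfg.nonwear_block_min * 60.0, ep), rng)
        if iv is None:
            raise ValueError("schedule infeasible: nonwear exceeds wake span")
        nonwear.append(iv)

    bouts = []
    for _ in range(cfg.bouts_per_day):
        dur = max(ep, _snap(rng.lognormal(cfg.bout_len_log_mu, cfg.bout_len_log_sigma), ep))
        iv = take(dur, rng)
        if iv is None:
            raise ValueError("schedule infeasible: requested bouts exceed wake span")
        bouts.append(iv)

    # fill remaining wake slots with activity classes, one class per slot
    activity = []
    levels = list(INTENSITY_LEVELS)
    probs = np.array([0.55, 0.25, 0.15, 0.05])
    for s0, s1 in sorted(slots):
        t = s0
        while t < s1:
            seg = min(_snap(rng.uniform(600, 2400), ep), s1 - t)
            seg = max(seg, ep)
            seg = min(seg, s1 - t)
            lvl = levels[rng.choice(4, p=probs)]
            activity.append((t, t + seg, lvl))
            t += seg
    return {
        "nonwear": sorted(nonwear),
        "bouts": sorted(bouts),
        "activity": sorted(activity),
        "wake": (wake0, wake1),
    }


def simulate_free_living_days(
    profile: SubjectProfile,
    n_days: int,
    cfg: SimConfig,
    site: str = "lumbar",
) -> tuple[AccelRecording, FreeLivingTruth]:
    """Simulate ``n_days`` of continuous at-home wear with labeled truth.

    Lumbar recordings follow the study's wear instructions: the device is
    removed for sleep, so nights are gravity-only non-wear. Wrist devices
    are worn continuously; sleep appears as stillness punctuated by brief
    position shifts (every ~20 min) so that sustained-zero non-wear logic
    does not mistake sleep for non-wear. Days start at local midnight and
    are half-open.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if site not in ("lumbar", "wrist"):
        raise ValueError("site must be 'lumbar' or 'wrist'")
    rng = cfg.rng()
    fs = cfg.fs_hz
    ep = cfg.epoch_len_s
    n = int(round(n_days * 86400 * fs))
    data = np.zeros((n, 3))
    data[:, cfg.vertical_axis] = cfg.vertical_sign * 1.0  # gravity baseline

    axes = [0, 1, 2]
    axes.remove(cfg.vertical_axis)
    ml_axis, ap_axis = axes

    bout_intervals: list[tuple[float, float]] = []
    nonwear_intervals: list[tuple[float, float]] = []
    epoch_starts = np.arange(0, n_days * 86400, ep)
    labels = pd.Series("sedentary", index=epoch_starts)

    def sl(a, b):
        return slice(int(round(a * fs)), int(round(b * fs)))

    def label(a, b, value):
        labels.loc[(labels.index >= a) & (labels.index < b)] = value

    step_period = 60.0 / _natural_cadence_spm(profile)
    step_len = STEP_LENGTH_FRAC["natural"] * profile.height_m
    pendulum = LEG_LENGTH_FACTOR * profile.height_m
    excursion = pendulum_excursion(step_len, pendulum)

    for day in range(n_days):
        off = day * 86400
        sched = build_day_schedule(cfg, rng)
        wake0, wake1 = sched["wake"]

        if site == "lumbar":
            night = [(off, off + wake0), (off + wake1, off + 86400)]
        else:
            night = []
            for a, b in [(off, off + wake0), (off + wake1, off + 86400)]:
                # sleep: still, with a 1-min position shift every ~20 min
                t0 = a + 1200
                while t0 < b - 60:
                    seg = sl(t0, t0 + 60)
                    for ax in range(3):
                        data[seg, ax] += _bandlimited_noise(
                            rng, seg.stop - seg.start, fs, ACTIVITY_SD_G["sedentary"]
                        )
                    t0 += _snap(rng.uniform(900, 1500), ep)
        for a, b in night:
            if site == "lumbar":
                nonwear_intervals.append((a, b))
                label(a, b, "nonwear")

        for a, b in sched["nonwear"]:
            nonwear_intervals.append((off + a, off + b))
            label(off + a, off + b, "nonwear")
            if site == "wrist":
                pass  # device off-body: gravity-only regardless of site

        for a, b, lvl in sched["activity"]:
            seg = sl(off + a, off + b)
            for ax in range(3):
                data[seg, ax] += _bandlimited_noise(rng, seg.stop - seg.start, fs, ACTIVITY_SD_G[lvl])
            label(off + a, off + b, lvl)

        for a, b in sched["bouts"]:
            bout_intervals.append((off + a, off + b))
            label(off + a, off + b, "moderate")
            seg = sl(off + a, off + b)
            t_rel = np.arange(seg.stop - seg.start) / fs
            n_steps = int((b - a) // step_period)
            if n_steps < 2:
                continue
            ic_rel = step_period / 2.0 + step_period * np.arange(n_steps)
            ic_rel = ic_rel[ic_rel < (b - a)]
            vert = _walk_vertical_accel(
                t_rel, ic_rel, step_period, excursion, cfg.ic_impulse_amp_g
            )
            data[seg, cfg.vertical_axis] += cfg.vertical_sign * vert
            if site == "wrist":
                data[seg, cfg.vertical_axis] += _bandlimited_noise(
                    rng, seg.stop - seg.start, fs, cfg.gait_horizontal_sd_g
                )
            for ax in (ml_axis, ap_axis):
                data[seg, ax] += _bandlimited_noise(
                    rng, seg.stop - seg.start, fs, cfg.gait_horizontal_sd_g
                )

    # merge lumbar nights adjacent across midnight
    nonwear_intervals.sort()
    merged: list[tuple[float, float]] = []
    for iv in nonwear_intervals:
        if merged and iv[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
        else:
            merged.append(iv)

    if cfg.noise_sd_g > 0:
        chunk = int(86400 * fs)  # one day at a time to bound peak memory
        for i0 in range(0, n, chunk):
            i1 = min(i0 + chunk, n)
            data[i0:i1] += rng.normal(0.0, cfg.noise_sd_g, size=(i1 - i0, 3))

    rec = AccelRecording(data=data, fs_hz=fs, site=site, subject_id=profile.subject_id)
    truth = FreeLivingTruth(
        bout_intervals=bout_intervals,
        nonwear_intervals=merged,
        intensity_labels=labels,
        epoch_len_s=ep,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# questionnaire
# ---------------------------------------------------------------------------

LIKERT_LEVELS = ("strongly disagree", "disagree", "neutral", "agree", "strongly agree")


def simulate_questionnaire(
    n_subjects: int,
    response_distribution,
    seed: int = 0,
    n_items: int = 10,
) -> pd.DataFrame:
    """Draw i.i.d. Likert responses (levels 0-4) for each subject and item.

    ``response_distribution`` is a length-5 probability vector over the
    levels from 'strongly disagree' (0) to 'strongly agree' (4).
    """
    p = np.asarray(response_distribution, dtype=float)
    if p.shape != (5,) or np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("response_distribution must be 5 nonnegative probs summing to 1")
    rng = np.random.default_rng(seed)
    resp = rng.choice(5, size=(n_subjects, n_items), p=p)
    return pd.DataFrame(
        resp,
        index=[f"S{i:03d}" for i in range(n_subjects)],
        columns=[f"Q{j + 1}" for j in range(n_items)],
    )


# ---------------------------------------------------------------------------
# statistical-simulation helpers (study-condition generators for validation)
# ---------------------------------------------------------------------------

def simulate_agreement_matrix(
    n: int,
    k: int,
    sd_subject: float,
    sd_rater: float,
    sd_error: float,
    seed: int = 0,
    mean: float = 1.2,
) -> np.ndarray:
    """Two-way random-effects data: y_ij = mu + s_i + r_j + e_ij.

    The theoretical absolute-agreement ICC is
    sd_subject**2 / (sd_subject**2 + sd_rater**2 + sd_error**2).
    """
    rng = np.random.default_rng(seed)
    s = rng.normal(0, sd_subject, (n, 1))
    r = rng.normal(0, sd_rater, (1, k))
    e = rng.normal(0, sd_error, (n, k))
    return mean + s + r + e


def simulate_setting_dataset(
    n_subjects: int = 40,
    n_home_days: int = 5,
    clinic_effect: float = 0.07,
    sd_subject: float = 0.12,
    sd_day: float = 0.06,
    seed: int = 0,
    base_speed: float = 1.15,
) -> pd.DataFrame:
    """Long-format gait-speed data with a planted in-clinic minus at-home effect.

    Each subject contributes one in-clinic (natural walk) value and
    ``n_home_days`` daily at-home values; a subject-level random intercept
    induces the repeated-measures correlation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    groups = ["3-5", "6-11", "12-17"]
    group_shift = {"3-5": -0.08, "6-11": 0.0, "12-17": 0.08}
    for i in range(n_subjects):
        g = groups[i % 3]
        u = rng.normal(0, sd_subject)
        rows.append(
            dict(subject=f"S{i:03d}", age_group=g, setting="in_clinic",
                 value=base_speed + group_shift[g] + u + clinic_effect + rng.normal(0, sd_day))
        )
        for d in range(n_home_days):
            rows.append(
                dict(subject=f"S{i:03d}", age_group=g, setting="at_home",
                     value=base_speed + group_shift[g] + u + rng.normal(0, sd_day))
            )
    return pd.DataFrame(rows)


def simulate_age_group_values(
    n_per_group: int = 15,
    group_means=(1.0, 1.0, 1.0),
    sd: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject daily-mean values by age group for ANOVA validation."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, m in zip(("3-5", "6-11", "12-17"), group_means):
        for v in rng.normal(m, sd, n_per_group):
            rows.append(dict(age_group=g, value=v))
    return pd.DataFrame(rows)
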