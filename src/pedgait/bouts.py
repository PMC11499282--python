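"""Free-living gait-bout detection.

When the timing of walking is unknown, a window-level classifier runs
first and positive windows are merged into bouts; each bout is then passed
through the gait module to populate strides. Two detectors are provided:

* :class:`BoutClassifier` — a gradient-boosted tree classifier (LightGBM)
  over per-window summary features, trained on labeled synthetic windows
  (scikit-learn estimator API; composes with sklearn model selection).
* :func:`band_power_bout_detector` — a deterministic fallback that
  thresholds spectral concentration in the step-frequency band, so the
  pipeline runs with no trained model at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .gait import GaitParams, analyze_pass
from .records import AccelRecording, GaitBout

FEATURE_NAMES = (
    "mean_x", "mean_y", "mean_z",
    "sd_x", "sd_y", "sd_z",
    "sma",
    "dom_freq_hz", "dom_power", "dom_power_ratio",
    "step_lag_autocorr",
)


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry for feature extraction."""

    window_s: float = 3.0
    overlap: float = 0.5

    @property
    def hop_s(self) -> float:
        return self.window_s * (1.0 - self.overlap)


def window_starts(duration_s: float, cfg: WindowConfig) -> np.ndarray:
    """Start times of the full windows fitting in ``duration_s``."""
    n = int(np.floor((duration_s - cfg.window_s) / cfg.hop_s)) + 1
    if n < 1:
        raise ValueError("recording shorter than one window")
    return np.arange(n) * cfg.hop_s


def _window_feature_block(x3: np.ndarray, fs: float) -> np.ndarray:
    """Summary features of a block of windows, shape (n_windows, wlen, 3).

    Vectorized across windows: spectral features come from one batched FFT
    of the dynamic vector magnitude, the step-lag autocorrelation from the
    Wiener-Khinchin inverse transform at the dominant-period lag.
    """
    nw, wlen, _ = x3.shape
    means = x3.mean(axis=1)
    sds = x3.std(axis=1)
    dyn = x3 - means[:, None, :]
    sma = np.abs(dyn).sum(axis=(1, 2)) / wlen
    # spectral features use the gravity-bearing axis (largest |mean|): during
    # gait it carries the periodic CoM component; the signed signal keeps the
    # step frequency (a vector norm would rectify and double it)
    grav_axis = np.abs(means).argmax(axis=1)
    sig = dyn[np.arange(nw)[:, None], np.arange(wlen)[None, :], grav_axis[:, None]]

    f = np.fft.rfftfreq(wlen, 1.0 / fs)
    spec = np.fft.rfft(sig, axis=1)
    p = (np.abs(spec) ** 2) / (fs * wlen)
    band = (f >= 0.5) & (f <= 5.0)
    pb = p[:, band]
    idx = pb.argmax(axis=1)
    dom_p = pb[np.arange(nw), idx]
    dom_f = f[band][idx]
    tot = p[:, 1:].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(tot > 0, dom_p / tot, 0.0)
    dom_f = np.where(dom_p > 0, dom_f, 0.0)

    # autocorrelation at the dominant-period lag (biased, normalized)
    ac_full = np.fft.irfft(np.abs(spec) ** 2, n=wlen, axis=1)
    var = ac_full[:, 0]
    lags = np.clip(np.rint(np.where(dom_f > 0, fs / np.maximum(dom_f, 1e-9), 0)).astype(int), 0, wlen - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ac = np.where((lags > 0) & (var > 0), ac_full[np.arange(nw), lags] / np.maximum(var, 1e-30), 0.0)

    return np.column_stack([means, sds, sma, dom_f, dom_p, ratio, ac])


class WindowFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless sliding-window featurizer (sklearn transformer).

    ``transform`` maps an :class:`AccelRecording` to an (n_windows, 11)
    feature matrix; :meth:`feature_frame` additionally returns window
    start times.
    """

    def __init__(self, window_s: float = 3.0, overlap: float = 0.5):
        self.window_s = window_s
        self.overlap = overlap

    def fit(self, X=None, y=None):
        return self

    def transform(self, recording: AccelRecording) -> np.ndarray:
        return self.feature_frame(recording)[FEATURE_NAMES].to_numpy()

    def feature_frame(self, recording: AccelRecording) -> pd.DataFrame:
        cfg = WindowConfig(self.window_s, self.overlap)
        fs = recording.fs_hz
        starts = window_starts(recording.duration_s, cfg)
        wlen = int(round(cfg.window_s * fs))
        hop = int(round(cfg.hop_s * fs))
        view = np.lib.stride_tricks.sliding_window_view(recording.data, wlen, axis=0)
        view = view[::hop].transpose(0, 2, 1)[: starts.size]  # (nw, wlen, 3)
        blocks = []
        chunk = 20000  # bound the materialized copy for multi-day recordings
        for i0 in range(0, starts.size, chunk):
            blocks.append(_window_feature_block(np.ascontiguousarray(view[i0:i0 + chunk]), fs))
        out = pd.DataFrame(np.concatenate(blocks), columns=list(FEATURE_NAMES))
        out.insert(0, "start_s", starts)
        return out


def extract_features(recording: AccelRecording, window_cfg: WindowConfig = WindowConfig()) -> pd.DataFrame:
    """Per-window features with start times; deterministic in the input."""
    return WindowFeatureExtractor(window_cfg.window_s, window_cfg.overlap).feature_frame(recording)


class BoutClassifier(ClassifierMixin, BaseEstimator):
    """Gradient-boosted tree gait/not-gait window classifier.

    Thin sklearn-style wrapper around LightGBM with a fixed seed for
    reproducible training; serializable with joblib/pickle.
    """

    def __init__(self, n_estimators: int = 100, learning_rate: float = 0.1,
                 num_leaves: int = 15, seed: int = 0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.num_leaves = num_leaves
        self.seed = seed

    def fit(self, X, y):
        import lightgbm as lgb

        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if np.unique(y).size < 2:
            raise ValueError("both classes must be present in training labels")
        self.model_ = lgb.LGBMClassifier(
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            num_leaves=self.num_leaves,
            random_state=self.seed,
            deterministic=True,
            n_jobs=1,
            verbose=-1,
        )
        self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))


def train_bout_classifier(features, labels, seed: int = 0) -> BoutClassifier:
    """Convenience wrapper: fit a :class:`BoutClassifier` on window features."""
    return BoutClassifier(seed=seed).fit(features, labels)


def label_windows(starts: np.ndarray, window_s: float, intervals) -> np.ndarray:
    """1 where a window's majority overlaps any ground-truth gait interval."""
    labels = np.zeros(starts.size, dtype=int)
    for i, t0 in enumerate(starts):
        t1 = t0 + window_s
        cover = sum(max(0.0, min(t1, b) - max(t0, a)) for a, b in intervals)
        labels[i] = int(cover >= window_s / 2.0)
    return labels


def band_power_bout_detector(
    features: pd.DataFrame,
    freq_band_hz: tuple = (1.0, 3.0),
    min_power_ratio: float = 0.5,
    min_autocorr: float = 0.6,
    min_sd_g: float = 0.05,
) -> np.ndarray:
    """Deterministic fallback: a window is gait when the gravity-axis signal
    is periodic (spectrally concentrated and autocorrelated at the step lag)
    with its dominant frequency in the step band and real motion present."""
    in_band = features["dom_freq_hz"].between(*freq_band_hz)
    concentrated = features["dom_power_ratio"] >= min_power_ratio
    periodic = features["step_lag_autocorr"] >= min_autocorr
    moving = features[["sd_x", "sd_y", "sd_z"]].max(axis=1) >= min_sd_g
    return (in_band & concentrated & periodic & moving).to_numpy().astype(int)


def windows_to_bouts(
    starts: np.ndarray,
    predictions: np.ndarray,
    window_s: float,
    merge_gap_s: float = 3.0,
) -> list[tuple[float, float]]:
    """Merge positive windows into half-open intervals, bridging short gaps."""
    intervals = [(float(t0), float(t0 + window_s)) for t0, p in zip(starts, predictions) if p]
    if not intervals:
        return []
    merged = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a - merged[-1][1] <= merge_gap_s:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(iv) for iv in merged]


def detect_gait_bouts(
    recording: AccelRecording,
    model: BoutClassifier | None = None,
    height_m: float | None = None,
    window_cfg: WindowConfig = WindowConfig(),
    merge_gap_s: float = 3.0,
    gait_params: GaitParams = GaitParams(),
) -> list[GaitBout]:
    """Detect walking bouts and populate their strides.

    With ``model`` None the deterministic band-power fallback is used.
    Bouts too short for the gait detector keep an empty stride list.
    """
    feats = extract_features(recording, window_cfg)
    if model is not None:
        preds = model.predict(feats[list(FEATURE_NAMES)].to_numpy())
    else:
        preds = band_power_bout_detector(feats)
    intervals = windows_to_bouts(
        feats["start_s"].to_numpy(), preds, window_cfg.window_s, merge_gap_s
    )
    fs = recording.fs_hz
    bouts: list[GaitBout] = []
    for a, b in intervals:
        bout = GaitBout(start_s=a, end_s=b)
        if height_m is not None and (b - a) >= 2 * gait_params.stride_time_bounds_s[1]:
            seg = AccelRecording(
                data=recording.data[int(a * fs): int(b * fs)],
                fs_hz=fs, site=recording.site, subject_id=recording.subject_id,
            )
            try:
                strides = analyze_pass(seg, height_m, gait_params)
            except ValueError:
                strides = []
            for s in strides:  # rebase stride times onto the recording clock
                s.start_ic_s += a
                s.end_ic_s += a
            bout.strides = strides
        bouts.append(bout)
    return bouts


def interval_jaccard(a: list, b: list) -> float:
    """Jaccard overlap of two interval sets (total intersection / union length)."""

    def total(ivs):
        return sum(e - s for s, e in ivs)

    inter = 0.0
    for s1, e1 in a:
        for s2, e2 in b:
            inter += max(0.0, min(e1, e2) - max(s1, s2))
    union = total(a) + total(b) - inter
    return inter / union if union > 0 else 1.0
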