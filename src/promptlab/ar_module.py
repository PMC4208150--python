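"""Windowed feature extraction and Gaussian-mixture activity classification.

The recognizer mirrors a phone-side activity recognition module: the 50 Hz
tri-axial stream is cut into contiguous non-overlapping 3-s windows (150
samples), each window is reduced to 12 time- and frequency-domain features,
and a per-class Gaussian mixture scores the feature vector; the label is the
class with the highest mixture log-likelihood. A GPS-derived mean speed per
window, when available, overrides grossly inconsistent labels (e.g., a
"jogging" call at 0 m/s becomes standing still).

Feature vector (in order):
    mean_x, mean_y, mean_z, sd_x, sd_y, sd_z,
    mean |a|, sd |a|, signal magnitude area,
    dominant frequency of mean-removed |a| (Hz),
    spectral energy, spectral entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram
from scipy.special import logsumexp
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler

from .labels import ACTIVITIES, BUS, JOGGING, STANDING, WALKING
from .synth_streams import SAMPLE_RATE, SensorStream

WINDOW_SAMPLES = 150  # 3 s at 50 Hz
WINDOW_SECONDS = WINDOW_SAMPLES / SAMPLE_RATE

FEATURE_NAMES = (
    "mean_x", "mean_y", "mean_z", "sd_x", "sd_y", "sd_z",
    "mean_mag", "sd_mag", "sma", "dom_freq", "spec_energy", "spec_entropy",
)


@dataclass(frozen=True)
class Window:
    """One contiguous 3-s block of 150 tri-axial samples."""

    index: int
    start_time: float
    samples: np.ndarray  # (150, 3)

    def __post_init__(self) -> None:
        if self.samples.shape != (WINDOW_SAMPLES, 3):
            raise ValueError(f"window needs shape (150, 3), got {self.samples.shape}")


@dataclass(frozen=True)
class WindowLabel:
    """Per-window classifier output."""

    index: int
    label: str
    logliks: dict[str, float] | None = None


def segment_windows(stream: SensorStream) -> list[Window]:
    """Cut a stream into floor(n/150) contiguous non-overlapping windows.

    A trailing remainder shorter than one window is discarded; a stream
    shorter than one window is an error.
    """
    if stream.sample_rate != SAMPLE_RATE:
        raise ValueError(f"expected a {SAMPLE_RATE} Hz stream")
    n = stream.n_samples
    if n < WINDOW_SAMPLES:
        raise ValueError(f"stream has {n} samples; at least {WINDOW_SAMPLES} required")
    n_win = n // WINDOW_SAMPLES
    xyz = np.column_stack([stream.x, stream.y, stream.z])
    return [
        Window(index=i, start_time=float(stream.t[i * WINDOW_SAMPLES]),
               samples=xyz[i * WINDOW_SAMPLES:(i + 1) * WINDOW_SAMPLES])
        for i in range(n_win)
    ]


def extract_features(window: Window) -> np.ndarray:
    """12-feature summary of one window (see module docstring for the order)."""
    s = window.samples
    means = s.mean(axis=0)
    sds = s.std(axis=0)
    mag = np.sqrt((s ** 2).sum(axis=1))
    sma = np.abs(s).sum(axis=1).mean()
    centered = mag - mag.mean()
    freqs, psd = periodogram(centered, fs=SAMPLE_RATE)
    total = psd.sum()
    if total > 0:
        dom_freq = float(freqs[int(np.argmax(psd))])
        p = psd[psd > 0] / total
        entropy = float(-(p * np.log(p)).sum())
    else:  # constant window: no spectral content
        dom_freq = 0.0
        entropy = 0.0
    return np.array([
        *means, *sds, mag.mean(), mag.std(), sma, dom_freq, total, entropy,
    ])


def extract_features_stream(stream: SensorStream) -> tuple[np.ndarray, list[Window]]:
    """Features for every window of a stream: (n_windows, 12) array plus windows."""
    windows = segment_windows(stream)
    return np.array([extract_features(w) for w in windows]), windows


@dataclass
class ClassifierModel:
    """Per-class Gaussian mixtures over standardized feature space.

    Persists to JSON (weights, means, covariances, scaler statistics, class
    order) so a saved model can be reloaded and applied without retraining.
    """

    class_order: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    mixtures: dict[str, dict] = field(default_factory=dict)
    n_components: int = 2
    seed: int = 0

    def _check_trained(self) -> None:
        if not self.mixtures:
            raise ValueError("classifier model has no fitted mixtures")

    def class_logliks(self, fv: np.ndarray) -> dict[str, float]:
        """Mixture log-likelihood of one feature vector under each class."""
        self._check_trained()
        zv = (np.asarray(fv, dtype=float) - self.scaler_mean) / self.scaler_scale
        out = {}
        for lbl in self.class_order:
            mix = self.mixtures[lbl]
            comps = [
                np.log(w) + multivariate_normal.logpdf(zv, mean=m, cov=c,
                                                       allow_singular=True)
                for w, m, c in zip(mix["weights"], mix["means"], mix["covariances"])
            ]
            out[lbl] = float(logsumexp(comps))
        return out

    def to_json(self, path) -> None:
        doc = {
            "class_order": list(self.class_order),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "n_components": self.n_components,
            "seed": self.seed,
            "mixtures": {
                lbl: {"weights": np.asarray(m["weights"]).tolist(),
                      "means": np.asarray(m["means"]).tolist(),
                      "covariances": np.asarray(m["covariances"]).tolist()}
                for lbl, m in self.mixtures.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            doc = json.load(fh)
        mixtures = {
            lbl: {"weights": np.array(m["weights"]),
                  "means": np.array(m["means"]),
                  "covariances": np.array(m["covariances"])}
            for lbl, m in doc["mixtures"].items()
        }
        return cls(class_order=tuple(doc["class_order"]),
                   scaler_mean=np.array(doc["scaler_mean"]),
                   scaler_scale=np.array(doc["scaler_scale"]),
                   mixtures=mixtures, n_components=doc["n_components"],
                   seed=doc["seed"])


def train_classifier(features_by_class: dict[str, np.ndarray], k: int = 2,
                     seed: int = 0) -> ClassifierModel:
    """Fit one k-component full-covariance Gaussian mixture per class.

    Features are z-scored with statistics pooled over all training windows.
    Each class needs at least 5*k feature vectors. Deterministic for a fixed
    seed.
    """
    class_order = tuple(lbl for lbl in ACTIVITIES if lbl in features_by_class)
    if not class_order:
        raise ValueError("no training classes supplied")
    for lbl in class_order:
        n = len(features_by_class[lbl])
        if n < 5 * k:
            raise ValueError(f"class {lbl!r} has {n} vectors; needs >= {5 * k} for k={k}")
    pooled = np.vstack([features_by_class[lbl] for lbl in class_order])
    scaler = StandardScaler().fit(pooled)
    scale = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)

    model = ClassifierModel(class_order=class_order, scaler_mean=scaler.mean_,
                            scaler_scale=scale, n_components=k, seed=seed)
    for lbl in class_order:
        z = (features_by_class[lbl] - scaler.mean_) / scale
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             reg_covar=1e-4, random_state=seed, n_init=1).fit(z)
        model.mixtures[lbl] = {"weights": gm.weights_, "means": gm.means_,
                               "covariances": gm.covariances_}
    return model


def classify_window(model: ClassifierModel, fv: np.ndarray,
                    index: int = 0) -> WindowLabel:
    """Label one feature vector by maximum mixture log-likelihood.

    Ties break toward the earlier class in the fixed order
    (standing_still < walking < jogging < bus).
    """
    logliks = model.class_logliks(fv)
    best = max(model.class_order, key=lambda lbl: (logliks[lbl], -model.class_order.index(lbl)))
    return WindowLabel(index=index, label=best, logliks=logliks)


def speed_validate(label: str, mean_speed: float | None,
                   stand_max: float = 0.3, walk_max: float = 2.2,
                   bus_min: float = 5.0) -> str:
    """Override an accelerometer label when grossly inconsistent with speed.

    Rules (m/s): speed < stand_max -> standing_still; speed > bus_min -> bus;
    speed in [stand_max, walk_max] with a jogging/bus label -> walking;
    speed > walk_max with a standing label -> walking. A missing speed is a
    pass-through.
    """
    if mean_speed is None:
        return label
    if mean_speed < 0:
        raise ValueError(f"negative speed {mean_speed}")
    if mean_speed < stand_max:
        return STANDING
    if mean_speed > bus_min:
        return BUS
    if mean_speed <= walk_max and label in (JOGGING, BUS):
        return WALKING
    if mean_speed > walk_max and label == STANDING:
        return WALKING
    return label


def window_mean_speeds(stream: SensorStream) -> list[float | None]:
    """Mean 1 Hz speed over each 3-s window (None when no trace exists)."""
    n_win = stream.n_samples // WINDOW_SAMPLES
    if stream.speed is None:
        return [None] * n_win
    out: list[float | None] = []
    for i in range(n_win):
        sec = stream.speed[3 * i: 3 * (i + 1)]
        out.append(float(np.mean(sec)) if len(sec) else None)
    return out


def classify_stream(model: ClassifierModel, stream: SensorStream,
                    use_speed: bool = True) -> list[WindowLabel]:
    """Classify every window of a stream, optionally speed-validated."""
    feats, windows = extract_features_stream(stream)
    speeds = window_mean_speeds(stream) if use_speed else [None] * len(windows)
    out = []
    for w, fv, sp in zip(windows, feats, speeds):
        wl = classify_window(model, fv, index=w.index)
        validated = speed_validate(wl.label, sp)
        out.append(WindowLabel(index=w.index, label=validated, logliks=wl.logliks))
    return out


def variance_frequency_baseline(stream: SensorStream) -> list[WindowLabel]:
    """Threshold baseline on (sd |a|, dominant frequency) per window.

    Independent of the mixture classifier: standing when the magnitude sd is
    below 0.05 g; otherwise jogging / walking / bus by decreasing sd band
    (>0.45 g, >0.2 g, else bus). Used as a cross-check on clean streams.
    """
    feats, windows = extract_features_stream(stream)
    sd_mag = feats[:, FEATURE_NAMES.index("sd_mag")]
    out = []
    for w, sd in zip(windows, sd_mag):
        if sd < 0.05:
            lbl = STANDING
        elif sd > 0.45:
            lbl = JOGGING
        elif sd > 0.2:
            lbl = WALKING
        else:
            lbl = BUS
        out.append(WindowLabel(index=w.index, label=lbl))
    return out
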