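"""Scripted activity ground truth and synthetic tri-axial accelerometer streams.

The generator emulates the sensing layer of a phone-based activity
recognition stack: a participant follows a script of activity bouts
(standing still, walking, jogging, riding a bus) while the phone records
50 Hz tri-axial acceleration and a 1 Hz GPS-derived speed trace. Each
activity is modelled as a gravity offset plus a sinusoidal oscillation on
the vertical axis with additive Gaussian noise — the simplest signal model
whose per-window variance and dominant frequency separate the four classes.

Units are g throughout; gravity sits on the z axis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .labels import ACTIVITIES, BUS, JOGGING, MOVING, STANDING, WALKING, check_label

SAMPLE_RATE = 50  # Hz, fixed by the recording pipeline
SPEED_RATE = 1  # Hz for the GPS speed trace


# ---------------------------------------------------------------------------
# Scripts

@dataclass(frozen=True)
class ActivityBout:
    """One ground-truth bout: a label held for ``duration`` seconds."""

    label: str
    duration: float

    def __post_init__(self) -> None:
        check_label(self.label)
        if not self.duration > 0:
            raise ValueError(f"bout duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class ActivityScript:
    """An ordered sequence of activity bouts; doubles as the gold standard."""

    name: str
    bouts: tuple[ActivityBout, ...]

    def __post_init__(self) -> None:
        if not self.bouts:
            raise ValueError("script must contain at least one bout")
        object.__setattr__(self, "bouts", tuple(self.bouts))

    @property
    def total_duration(self) -> float:
        return float(sum(b.duration for b in self.bouts))

    def boundaries(self) -> np.ndarray:
        """Cumulative bout boundaries in seconds, including 0 and the end."""
        return np.concatenate([[0.0], np.cumsum([b.duration for b in self.bouts])])

    def label_at(self, t: float) -> str:
        """Ground-truth label at time ``t`` (end-exclusive per bout)."""
        if t < 0 or t >= self.total_duration:
            raise ValueError(f"t={t} outside script span [0, {self.total_duration})")
        edges = self.boundaries()
        i = int(np.searchsorted(edges, t, side="right")) - 1
        return self.bouts[i].label

    def to_yaml(self, path) -> None:
        doc = {"name": self.name,
               "bouts": [{"label": b.label, "duration": float(b.duration)} for b in self.bouts]}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ActivityScript":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        bouts = tuple(ActivityBout(b["label"], float(b["duration"])) for b in doc["bouts"])
        return cls(name=str(doc.get("name", "script")), bouts=bouts)


def make_task1_script() -> ActivityScript:
    """The timed laboratory protocol: nine alternating 30-s bouts.

    Stand/walk/stand/jog/stand/walk/stand/jog/stand, 270 s total.
    """
    order = (STANDING, WALKING, STANDING, JOGGING, STANDING,
             WALKING, STANDING, JOGGING, STANDING)
    return ActivityScript("task1", tuple(ActivityBout(lbl, 30.0) for lbl in order))


TASK2_ORDER = (WALKING, STANDING, BUS, STANDING, JOGGING,
               STANDING, BUS, STANDING, WALKING, STANDING)


def make_task2_script(durations) -> ActivityScript:
    """The semi-structured protocol: fixed ten-bout order, caller durations.

    The protocol fixes the order (walk, stand, bus, stand, jog, stand, bus,
    stand, walk, stand) but not how long each task takes, so the ten bout
    durations are supplied by the caller.
    """
    durations = list(durations)
    if len(durations) != len(TASK2_ORDER):
        raise ValueError(f"task 2 needs {len(TASK2_ORDER)} durations, got {len(durations)}")
    return ActivityScript("task2", tuple(
        ActivityBout(lbl, float(d)) for lbl, d in zip(TASK2_ORDER, durations)))


def make_free_living_script(seed: int, n_bouts: int = 24,
                            min_duration: float = 10.0,
                            max_duration: float = 300.0) -> ActivityScript:
    """A randomized stand-in for a free-living day.

    Bout labels follow a first-order Markov chain (no self-transitions;
    moving activities return to standing still with probability 0.6),
    durations are log-uniform on [min_duration, max_duration] seconds.
    """
    rng = np.random.default_rng(seed)
    bouts = []
    label = STANDING
    for _ in range(n_bouts):
        duration = float(np.exp(rng.uniform(np.log(min_duration), np.log(max_duration))))
        bouts.append(ActivityBout(label, duration))
        if label == STANDING:
            label = MOVING[rng.integers(len(MOVING))]
        elif rng.random() < 0.6:
            label = STANDING
        else:
            others = [m for m in MOVING if m != label]
            label = others[rng.integers(len(others))]
    return ActivityScript(f"free_living_{seed}", tuple(bouts))


# ---------------------------------------------------------------------------
# Signal model

@dataclass(frozen=True)
class ActivityParams:
    """Per-class signal parameters: gravity mean, oscillation and noise (g-units)."""

    gravity: tuple[float, float, float]
    freq_hz: float
    amplitude: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.freq_hz < 0:
            raise ValueError("oscillation frequency must be >= 0")


@dataclass(frozen=True)
class SignalModel:
    """Signal parameters for every activity class plus the speed model.

    ``jitter_sd`` is a per-stream gravity offset (drawn once per stream)
    emulating small orientation/calibration differences between recordings.
    """

    params: dict[str, ActivityParams]
    speeds: dict[str, float] = field(default_factory=lambda: {
        STANDING: 0.0, WALKING: 1.4, JOGGING: 2.8, BUS: 8.0})
    speed_noise_sd: float = 0.05
    jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        missing = set(ACTIVITIES) - set(self.params)
        if missing:
            raise ValueError(f"signal model missing classes: {sorted(missing)}")
        a = self.params
        if not (a[STANDING].amplitude < a[WALKING].amplitude < a[JOGGING].amplitude):
            raise ValueError("amplitudes must satisfy standing < walking < jogging")
        if self.jitter_sd < 0 or self.speed_noise_sd < 0:
            raise ValueError("sds must be >= 0")

    @classmethod
    def default(cls) -> "SignalModel":
        g = (0.0, 0.0, 1.0)
        return cls(params={
            STANDING: ActivityParams(g, 0.0, 0.0, 0.01),
            WALKING: ActivityParams(g, 2.0, 0.4, 0.05),
            JOGGING: ActivityParams(g, 3.0, 0.9, 0.08),
            BUS: ActivityParams(g, 0.5, 0.1, 0.05),
        })

    def noiseless(self) -> "SignalModel":
        """A copy with all stochastic terms removed (oscillations kept)."""
        quiet = {lbl: replace(p, noise_sd=0.0) for lbl, p in self.params.items()}
        return replace(self, params=quiet, speed_noise_sd=0.0, jitter_sd=0.0)


# ---------------------------------------------------------------------------
# Streams

@dataclass
class SensorStream:
    """A 50 Hz tri-axial acceleration recording with optional context traces.

    ``speed`` is a 1 Hz GPS-derived speed trace (m/s) spanning the same
    interval; ``lat``/``lon`` are per-sample synthetic GPS coordinates
    (constant within a bout, semantically inert).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    speed: np.ndarray | None = None
    lat: np.ndarray | None = None
    lon: np.ndarray | None = None
    sample_rate: int = SAMPLE_RATE
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x", "y", "z"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"axis {name} length != t length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.x ** 2 + self.y ** 2 + self.z ** 2)

    def copy(self) -> "SensorStream":
        return SensorStream(
            t=self.t.copy(), x=self.x.copy(), y=self.y.copy(), z=self.z.copy(),
            speed=None if self.speed is None else self.speed.copy(),
            lat=None if self.lat is None else self.lat.copy(),
            lon=None if self.lon is None else self.lon.copy(),
            sample_rate=self.sample_rate, provenance=dict(self.provenance))

    # -- CSV serialization: header t,x,y,z[,speed][,lat,lon], 6-decimal floats.
    #    The 1 Hz speed trace is repeated across each second's 50 samples.
    def to_csv(self, path_or_buf) -> None:
        cols = {"t": self.t, "x": self.x, "y": self.y, "z": self.z}
        if self.speed is not None:
            cols["speed"] = np.repeat(self.speed, self.sample_rate)[: self.n_samples]
        if self.lat is not None:
            cols["lat"] = self.lat
            cols["lon"] = self.lon
        pd.DataFrame(cols).to_csv(path_or_buf, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path_or_buf, sample_rate: int = SAMPLE_RATE) -> "SensorStream":
        df = pd.read_csv(path_or_buf)
        for col in ("t", "x", "y", "z"):
            if col not in df.columns:
                raise ValueError(f"stream CSV missing column {col!r}")
        speed = df["speed"].to_numpy()[::sample_rate] if "speed" in df.columns else None
        return cls(
            t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy(),
            z=df["z"].to_numpy(), speed=speed,
            lat=df["lat"].to_numpy() if "lat" in df.columns else None,
            lon=df["lon"].to_numpy() if "lon" in df.columns else None,
            sample_rate=sample_rate)


def bout_sample_counts(script: ActivityScript, sample_rate: int = SAMPLE_RATE) -> np.ndarray:
    """Samples per bout; durations rounded to the nearest whole sample."""
    return np.array([int(round(b.duration * sample_rate)) for b in script.bouts])


def synthesize_stream(script: ActivityScript, model: SignalModel | None = None,
                      seed: int = 0) -> SensorStream:
    """Generate a deterministic synthetic stream for a script.

    Per sample: acceleration = gravity mean + per-stream jitter +
    amplitude*sin(2*pi*f*t + phase) on the vertical axis + Gaussian noise,
    with parameters switching at bout boundaries. The oscillation phase is
    randomized per bout from the stream seed. The speed trace is
    piecewise-constant per bout plus small noise, sampled at 1 Hz.
    """
    model = model or SignalModel.default()
    rng = np.random.default_rng(seed)
    counts = bout_sample_counts(script)
    n = int(counts.sum())
    t = np.arange(n) / SAMPLE_RATE
    x = np.empty(n)
    y = np.empty(n)
    z = np.empty(n)
    lat = np.empty(n)
    lon = np.empty(n)
    jitter = rng.normal(0.0, model.jitter_sd, size=3) if model.jitter_sd > 0 else np.zeros(3)

    # per-bout, bout-constant synthetic GPS fix near an arbitrary campus origin
    base_lat, base_lon = 37.24, 127.08

    start = 0
    bout_speed = np.empty(len(script.bouts))
    for i, (bout, cnt) in enumerate(zip(script.bouts, counts)):
        p = model.params[bout.label]
        phase = rng.uniform(0.0, 2.0 * np.pi)
        seg = slice(start, start + cnt)
        ts = t[seg]
        osc = p.amplitude * np.sin(2.0 * np.pi * p.freq_hz * ts + phase)
        noise = rng.normal(0.0, p.noise_sd, size=(cnt, 3)) if p.noise_sd > 0 else np.zeros((cnt, 3))
        x[seg] = p.gravity[0] + jitter[0] + noise[:, 0]
        y[seg] = p.gravity[1] + jitter[1] + noise[:, 1]
        z[seg] = p.gravity[2] + jitter[2] + osc + noise[:, 2]
        lat[seg] = base_lat + 1e-4 * i
        lon[seg] = base_lon + 1e-4 * i
        bout_speed[i] = model.speeds[bout.label]
        start += cnt

    n_sec = n // SAMPLE_RATE
    sec_mid = np.arange(n_sec) + 0.5
    edges = np.cumsum(counts) / SAMPLE_RATE
    bout_of_sec = np.searchsorted(edges, sec_mid, side="right").clip(max=len(counts) - 1)
    speed = bout_speed[bout_of_sec]
    if model.speed_noise_sd > 0:
        speed = np.clip(speed + rng.normal(0.0, model.speed_noise_sd, size=n_sec), 0.0, None)

    return SensorStream(t=t, x=x, y=y, z=z, speed=speed, lat=lat, lon=lon,
                        provenance={"script": script.name, "seed": int(seed)})


def inject_prompt_vibration(stream: SensorStream, at: float, duration: float,
                            amplitude: float = 0.5, freq_hz: float = 20.0) -> SensorStream:
    """Return a copy with a high-frequency vibration burst over [at, at+duration).

    Emulates the phone's vibration alert, which is visible in the
    accelerometer trace as a short high-frequency, high-variance burst.
    Samples outside the burst are bit-identical to the input.
    """
    if at < 0 or at + duration > stream.duration:
        raise ValueError(
            f"burst [{at}, {at + duration}) outside stream span [0, {stream.duration})")
    out = stream.copy()
    i0 = int(round(at * stream.sample_rate))
    i1 = int(round((at + duration) * stream.sample_rate))
    ts = out.t[i0:i1]
    burst = amplitude * np.sin(2.0 * np.pi * freq_hz * ts)
    for axis in (out.x, out.y, out.z):
        axis[i0:i1] = axis[i0:i1] + burst
    return out


# ---------------------------------------------------------------------------
# Ground-truth helpers (window-level oracle views of a script)

def window_truth_labels(script: ActivityScript, n_windows: int,
                        window_s: float = 3.0) -> list[str]:
    """Ground-truth label per window, taken at the window midpoint."""
    return [script.label_at((i + 0.5) * window_s) for i in range(n_windows)]


def boundary_windows(script: ActivityScript, n_windows: int,
                     window_s: float = 3.0) -> set[int]:
    """Indices of windows that straddle a bout boundary."""
    edges = script.boundaries()[1:-1]
    out: set[int] = set()
    for e in edges:
        i = int(e // window_s)
        if i * window_s < e < (i + 1) * window_s and i < n_windows:
            out.add(i)
    return out


def stand_vs_move_oracle(stream: SensorStream, window_samples: int = 150,
                         sd_threshold: float = 0.05) -> list[bool]:
    """Variance-threshold oracle: True where a 3-s window is non-standing."""
    mag = stream.magnitude()
    n_win = len(mag) // window_samples
    win = mag[: n_win * window_samples].reshape(n_win, window_samples)
    return list(win.std(axis=1) > sd_threshold)
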