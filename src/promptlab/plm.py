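"""The prompted-labeling engine.

Per-window classifier output is smoothed into stable activity states (a
state changes only after three consecutive identical 3-s detections, i.e.
9 s of agreement); a transition from any moving activity into standing
still triggers a prompt asking the user to label the activity they just
finished. A prompt left unanswered for 20 s is recorded as missed. On every
transition the previous activity's raw samples are saved as a labeled
segment and appended to a plain-text device log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np

from .ar_module import WINDOW_SAMPLES, WINDOW_SECONDS, WindowLabel
from .labels import STANDING, check_label
from .synth_streams import SAMPLE_RATE, SensorStream

DEFAULT_TIMEOUT = 20.0  # s of no interaction before a prompt is missed

#: Reference epoch used to render sample times as absolute timestamps.
LOG_EPOCH = datetime(2014, 1, 1, 0, 0, 0)


@dataclass
class StableState:
    """An activity confirmed by >= 3 consecutive identical window labels.

    The state extends until the next state is committed, so isolated one- or
    two-window runs of a different label are absorbed into the surrounding
    state rather than splitting it.
    """

    label: str
    start_window: int
    end_window: int

    @property
    def start_time(self) -> float:
        return self.start_window * WINDOW_SECONDS

    @property
    def end_time(self) -> float:
        return (self.end_window + 1) * WINDOW_SECONDS

    @property
    def n_windows(self) -> int:
        return self.end_window - self.start_window + 1


@dataclass(frozen=True)
class TransitionEvent:
    """A stable moving activity followed by a stable standing-still state."""

    previous_activity: str
    time: float  # start of the standing-still state, seconds
    prev_start_window: int
    prev_end_window: int

    def __post_init__(self) -> None:
        check_label(self.previous_activity)
        if self.previous_activity == STANDING:
            raise ValueError("a transition's previous activity cannot be standing_still")


@dataclass(frozen=True)
class PromptEvent:
    """One prompt's lifecycle: answered with a label and latency, or missed."""

    trigger_time: float
    status: str  # "answered" | "missed"
    response_latency: float | None = None
    user_label: str | None = None
    timeout: float = DEFAULT_TIMEOUT

    @property
    def answered(self) -> bool:
        return self.status == "answered"

    @property
    def resolution_time(self) -> float:
        """When the prompt left the screen (answer time or timeout)."""
        return self.trigger_time + (self.response_latency if self.answered else self.timeout)


@dataclass
class LabeledSegment:
    """A saved activity episode: raw samples plus all available labels."""

    ar_label: str
    start_sample: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    user_label: str | None = None
    observer_label: str | None = None
    response_time: float | None = None

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabeledSegment):
            return NotImplemented
        scalar = ("ar_label", "start_sample", "user_label", "observer_label",
                  "response_time")
        arrays = ("t", "x", "y", "z", "lat", "lon")
        return all(getattr(self, f) == getattr(other, f) for f in scalar) and all(
            np.array_equal(getattr(self, f), getattr(other, f)) for f in arrays)


# ---------------------------------------------------------------------------
# Smoothing and transition detection

def smooth_detections(labels) -> list[StableState]:
    """Collapse per-window labels into stable states.

    Scanning left to right, a new stable state is committed when three
    consecutive windows share a label that differs from the current stable
    label; shorter runs never change state (they are absorbed). Windows
    before the first stable state belong to no state.

    Accepts ``WindowLabel`` objects or plain label strings.
    """
    seq = [lbl.label if isinstance(lbl, WindowLabel) else check_label(lbl)
           for lbl in labels]
    if not seq:
        raise ValueError("empty label sequence")
    states: list[StableState] = []
    run_label: str | None = None
    run_start = 0
    run_len = 0
    for i, lbl in enumerate(seq):
        if lbl == run_label:
            run_len += 1
        else:
            run_label, run_start, run_len = lbl, i, 1
        current = states[-1] if states else None
        if run_len >= 3 and (current is None or lbl != current.label):
            if current is not None:
                current.end_window = run_start - 1
            states.append(StableState(label=lbl, start_window=run_start, end_window=i))
    if states:
        states[-1].end_window = len(seq) - 1
    return states


def detect_transitions(states: list[StableState]) -> list[TransitionEvent]:
    """One event per adjacency (moving stable state -> standing-still state)."""
    events = []
    for prev, nxt in zip(states, states[1:]):
        if prev.label != STANDING and nxt.label == STANDING:
            events.append(TransitionEvent(
                previous_activity=prev.label, time=nxt.start_time,
                prev_start_window=prev.start_window, prev_end_window=prev.end_window))
    return events


# ---------------------------------------------------------------------------
# Prompt lifecycle

def run_prompt(event: TransitionEvent, response: tuple[float, str] | None,
               timeout: float = DEFAULT_TIMEOUT,
               trigger_time: float | None = None) -> PromptEvent:
    """Resolve one prompt: answered iff a response arrives within the timeout.

    The timeout boundary is inclusive — a response at exactly ``timeout``
    seconds still counts as answered.
    """
    if timeout <= 0:
        raise ValueError("timeout must be > 0")
    trigger = event.time if trigger_time is None else trigger_time
    if response is None:
        return PromptEvent(trigger, "missed", timeout=timeout)
    latency, label = response
    if latency < 0:
        raise ValueError(f"negative response latency {latency}")
    if latency > timeout:
        return PromptEvent(trigger, "missed", timeout=timeout)
    return PromptEvent(trigger, "answered", response_latency=float(latency),
                       user_label=check_label(label), timeout=timeout)


def run_prompt_session(events: list[TransitionEvent], responder,
                       timeout: float = DEFAULT_TIMEOUT) -> list[PromptEvent]:
    """Deliver one prompt per transition, never overlapping.

    A transition arriving while a prompt is still on screen is queued and
    delivered when the open prompt resolves. ``responder(event)`` returns
    ``(latency, label)`` or ``None``.
    """
    prompts = []
    busy_until = -np.inf
    for ev in events:
        trigger = max(ev.time, busy_until)
        prompt = run_prompt(ev, responder(ev), timeout=timeout, trigger_time=trigger)
        busy_until = prompt.resolution_time
        prompts.append(prompt)
    return prompts


def extract_segment(stream: SensorStream, event: TransitionEvent,
                    prompt: PromptEvent) -> LabeledSegment:
    """Save the previous stable state's raw samples as a labeled segment."""
    s0 = event.prev_start_window * WINDOW_SAMPLES
    s1 = (event.prev_end_window + 1) * WINDOW_SAMPLES
    if s0 < 0 or s1 > stream.n_samples:
        raise ValueError(f"segment samples [{s0}, {s1}) outside stream of "
                         f"{stream.n_samples} samples")
    sl = slice(s0, s1)
    zeros = np.zeros(s1 - s0)
    return LabeledSegment(
        ar_label=event.previous_activity, start_sample=s0,
        t=stream.t[sl].copy(), x=stream.x[sl].copy(), y=stream.y[sl].copy(),
        z=stream.z[sl].copy(),
        lat=stream.lat[sl].copy() if stream.lat is not None else zeros,
        lon=stream.lon[sl].copy() if stream.lon is not None else zeros,
        user_label=prompt.user_label if prompt.answered else None,
        response_time=prompt.response_latency if prompt.answered else None)


# ---------------------------------------------------------------------------
# Device log: UTF-8, tab-separated, one record per sample

def _iso(seconds: float, epoch: datetime) -> str:
    ts = epoch + timedelta(seconds=float(seconds))
    return ts.strftime("%Y-%m-%dT%H:%M:%S.") + f"{ts.microsecond // 1000:03d}"


def _parse_iso(text: str, epoch: datetime, lineno: int) -> float:
    try:
        ts = datetime.strptime(text, "%Y-%m-%dT%H:%M:%S.%f")
    except ValueError as exc:
        raise ValueError(f"line {lineno}: bad timestamp {text!r}") from exc
    return (ts - epoch).total_seconds()


def write_log(segments: list[LabeledSegment], path, epoch: datetime = LOG_EPOCH) -> None:
    """Write the device log: a ``#SEG`` header per segment, then one
    tab-separated record per sample (timestamp, x, y, z, lat, lon)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#PROMPTLAB-LOG\tv1\n")
        for seg in segments:
            end_s = seg.t[-1] + 1.0 / SAMPLE_RATE if seg.n_samples else seg.t
            rt = "NA" if seg.response_time is None else repr(float(seg.response_time))
            fh.write("#SEG\t{}\t{}\t{}\t{}\t{}\n".format(
                _iso(seg.t[0], epoch), _iso(end_s, epoch), seg.ar_label,
                seg.user_label or "NA", rt))
            for i in range(seg.n_samples):
                fh.write("{}\t{!r}\t{!r}\t{!r}\t{!r}\t{!r}\n".format(
                    _iso(seg.t[i], epoch), float(seg.x[i]), float(seg.y[i]),
                    float(seg.z[i]), float(seg.lat[i]), float(seg.lon[i])))


def read_log(path, epoch: datetime = LOG_EPOCH) -> list[LabeledSegment]:
    """Parse a device log back into segments (inverse of :func:`write_log`).

    Strict: every segment must carry exactly the number of sample records
    implied by its header interval at 50 Hz; a malformed or surplus line
    raises ``ValueError`` naming the line number.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#PROMPTLAB-LOG"):
        raise ValueError("line 1: missing log header")
    segments: list[LabeledSegment] = []
    i = 1
    while i < len(lines):
        lineno = i + 1
        parts = lines[i].split("\t")
        if parts[0] != "#SEG" or len(parts) != 6:
            raise ValueError(f"line {lineno}: expected '#SEG' header, got {lines[i]!r}")
        t0 = _parse_iso(parts[1], epoch, lineno)
        t1 = _parse_iso(parts[2], epoch, lineno)
        ar_label = check_label(parts[3])
        user_label = None if parts[4] == "NA" else check_label(parts[4])
        response_time = None if parts[5] == "NA" else float(parts[5])
        n = int(round((t1 - t0) * SAMPLE_RATE))
        rows = []
        for j in range(n):
            lineno = i + 2 + j
            if lineno - 1 >= len(lines):
                raise ValueError(f"line {lineno}: unexpected end of file "
                                 f"(segment needs {n} records)")
            fields = lines[lineno - 1].split("\t")
            if len(fields) != 6 or fields[0].startswith("#"):
                raise ValueError(f"line {lineno}: malformed sample record")
            try:
                rows.append((_parse_iso(fields[0], epoch, lineno),
                             *(float(v) for v in fields[1:])))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed sample record") from exc
        i += 1 + n
        if i < len(lines) and not lines[i].startswith("#SEG"):
            raise ValueError(f"line {i + 1}: expected '#SEG' header or end of file")
        arr = np.array(rows) if rows else np.empty((0, 6))
        segments.append(LabeledSegment(
            ar_label=ar_label, start_sample=int(round(t0 * SAMPLE_RATE)),
            t=arr[:, 0], x=arr[:, 1], y=arr[:, 2], z=arr[:, 3],
            lat=arr[:, 4], lon=arr[:, 5],
            user_label=user_label, response_time=response_time))
    return segments
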