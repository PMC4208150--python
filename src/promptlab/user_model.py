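"""Simulated respondent and observer.

The respondent is a stochastic stand-in for a study participant: each
prompt is missed outright with probability ``miss_probability`` (the phone
is out of reach, the alert unheard); otherwise the response latency is
log-normal (positive and right-skewed, as response times are) and the
supplied label equals the true activity except with probability
``label_error_probability``, in which case it is uniform over the other
classes.

The observer reproduces the human researcher who notes when each scripted
activity starts and ends — the gold standard the prompted labels are
compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import ACTIVITIES, check_label
from .plm import TransitionEvent
from .synth_streams import ActivityScript


@dataclass(frozen=True)
class RespondentProfile:
    """Stochastic model of one participant's prompt behaviour.

    ``latency_median`` is the median answer time in seconds;
    ``latency_sigma`` the log-scale sd of the log-normal latency.
    """

    miss_probability: float = 0.0
    latency_median: float = 4.2
    latency_sigma: float = 0.4
    label_error_probability: float = 0.0

    def __post_init__(self) -> None:
        for name in ("miss_probability", "label_error_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.latency_median <= 0:
            raise ValueError("latency_median must be > 0")
        if self.latency_sigma < 0:
            raise ValueError("latency_sigma must be >= 0")


def respond(event: TransitionEvent, truth_label: str, profile: RespondentProfile,
            rng: np.random.Generator) -> tuple[float, str] | None:
    """One simulated prompt response: ``(latency, label)`` or ``None`` (missed).

    A fixed number of random variates is drawn per call regardless of the
    outcome, so runs with the same seed stay aligned across profiles:
    lowering the miss probability can only turn misses into answers.
    """
    check_label(truth_label)
    u_miss = rng.random()
    z = rng.standard_normal()
    u_err = rng.random()
    u_choice = rng.random()
    if u_miss < profile.miss_probability:
        return None
    latency = float(profile.latency_median * np.exp(profile.latency_sigma * z))
    if u_err < profile.label_error_probability:
        others = [lbl for lbl in ACTIVITIES if lbl != truth_label]
        label = others[int(u_choice * len(others))]
    else:
        label = truth_label
    return latency, label


@dataclass(frozen=True)
class ObserverLog:
    """The observer's record: (label, start s, end s) intervals partitioning
    the scripted session."""

    entries: tuple[tuple[str, float, float], ...]

    @property
    def total_duration(self) -> float:
        return self.entries[-1][2]

    def lookup(self, t: float) -> str:
        """Observer label at time ``t`` (intervals end-exclusive)."""
        if t < 0 or t >= self.total_duration:
            raise ValueError(f"t={t} outside observed span [0, {self.total_duration})")
        for label, start, end in self.entries:
            if start <= t < end:
                return label
        raise AssertionError("observer intervals do not partition the session")

    def label_for_span(self, start: float, end: float) -> str:
        """Observer label for a saved segment: the bout covering its midpoint."""
        return self.lookup((start + end) / 2.0)


def make_observer_log(script: ActivityScript) -> ObserverLog:
    """Cumulative-time intervals matching the script exactly."""
    entries = []
    t = 0.0
    for bout in script.bouts:
        entries.append((bout.label, t, t + bout.duration))
        t += bout.duration
    return ObserverLog(entries=tuple(entries))
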