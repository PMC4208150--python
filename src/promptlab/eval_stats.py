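"""Evaluation statistics for prompted-labeling runs.

Three summaries are produced: per-group prompt bookkeeping (delivered,
missed, mean answer latency over answered prompts only), pairwise percent
agreement between label sources (recognizer vs. prompted user label vs.
human observer), and CSUQ usability questionnaire subscale summaries
(18 seven-point Likert items grouped into OVERALL, SYSUSE, INFOQUAL and
INTERQUAL).

Percentages are rounded half-up to two decimals. Missed prompts contribute
no user label: pairings involving the user label drop those pairs before
comparison, while recognizer-vs-observer comparisons keep every segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .plm import PromptEvent

#: CSUQ subscales as 1-based inclusive item ranges.
CSUQ_SUBSCALES: dict[str, tuple[int, int]] = {
    "OVERALL": (1, 18),
    "SYSUSE": (1, 8),
    "INFOQUAL": (9, 15),
    "INTERQUAL": (16, 18),
}
CSUQ_ITEMS = 18


def round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"),
                                           rounding=ROUND_HALF_UP))


def pairwise_agreement(a, b) -> tuple[int, float]:
    """(n_same, percent agreement) between two equal-length label lists.

    Pairs where either label is ``None`` (e.g. missed prompts) are excluded
    before comparison; the remaining set must be non-empty.
    """
    a, b = list(a), list(b)
    if len(a) != len(b):
        raise ValueError(f"label lists differ in length: {len(a)} vs {len(b)}")
    pairs = [(u, v) for u, v in zip(a, b) if u is not None and v is not None]
    if not pairs:
        raise ValueError("no comparable label pairs (all excluded or empty)")
    n_same = sum(u == v for u, v in pairs)
    return n_same, round_half_up(100.0 * n_same / len(pairs))


def agreement_table(ar_labels, prompt_labels, observer_labels) -> dict[str, dict]:
    """The three pairings reported for a run, as
    ``{pairing: {n_compared, n_same, pct_same}}``.

    ``prompt_labels`` may contain ``None`` for missed prompts (those pairs
    are dropped); recognizer-vs-observer keeps all segments. An observer
    list of ``None`` (free-living: no observer) yields only the
    recognizer-vs-prompt pairing.
    """
    def entry(a, b):
        pairs = [(u, v) for u, v in zip(a, b) if u is not None and v is not None]
        n_same = sum(u == v for u, v in pairs)
        return {"n_compared": len(pairs), "n_same": n_same,
                "pct_same": round_half_up(100.0 * n_same / len(pairs)) if pairs else None}

    out = {"ar_vs_prompt": entry(ar_labels, prompt_labels)}
    if any(lbl is not None for lbl in observer_labels):
        out["ar_vs_observer"] = entry(ar_labels, observer_labels)
        out["prompt_vs_observer"] = entry(prompt_labels, observer_labels)
    return out


@dataclass(frozen=True)
class PromptSummary:
    """Prompt bookkeeping for one group: counts plus answered-only mean latency."""

    delivered: int
    missed: int
    mean_latency: float | None

    @property
    def answered(self) -> int:
        return self.delivered - self.missed


def _summarize(events: list[PromptEvent]) -> PromptSummary:
    latencies = [e.response_latency for e in events if e.answered]
    return PromptSummary(
        delivered=len(events), missed=sum(not e.answered for e in events),
        mean_latency=float(np.mean(latencies)) if latencies else None)


def summarize_prompts(events: list[PromptEvent],
                      grouping=None) -> dict[str, PromptSummary]:
    """Per-group prompt summaries plus a ``"total"`` row equal to the column sums.

    ``grouping`` is an optional per-event key (e.g. participant id); without
    it only the total is returned. Missed prompts never enter the mean
    latency.
    """
    out: dict[str, PromptSummary] = {}
    if grouping is not None:
        grouping = list(grouping)
        if len(grouping) != len(events):
            raise ValueError("grouping length must match events")
        for key in dict.fromkeys(grouping):
            out[str(key)] = _summarize(
                [e for e, g in zip(events, grouping) if g == key])
    out["total"] = _summarize(events)
    return out


def csuq_summary(responses) -> dict[str, dict[str, float]]:
    """CSUQ subscale summaries over participants.

    ``responses`` is a (participants x 18) array of Likert answers in 1..7.
    Each participant is first reduced to a subscale mean; the reported mean,
    median and sd (sample sd, n-1) are taken across those per-participant
    means, one row per subscale.
    """
    r = np.asarray(responses, dtype=float)
    if r.ndim != 2 or r.shape[1] != CSUQ_ITEMS:
        raise ValueError(f"responses must be (participants, {CSUQ_ITEMS})")
    if np.any((r < 1) | (r > 7)):
        raise ValueError("Likert responses must lie in 1..7")
    out = {}
    for name, (lo, hi) in CSUQ_SUBSCALES.items():
        per_participant = r[:, lo - 1:hi].mean(axis=1)
        sd = float(np.std(per_participant, ddof=1)) if len(per_participant) > 1 else 0.0
        out[name] = {"mean": float(np.mean(per_participant)),
                     "median": float(np.median(per_participant)),
                     "sd": sd}
    return out
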