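"""Counterpart matching: link voice and web entries recording the same event.

Participants were asked to record each intake event twice — first by voice,
then on a web form — but the two records carry no shared key, so pairs must
be recovered from timestamps.  The procedure is two deterministic window
passes, run within participant and on submitted entries only:

* **Step 1** links a voice entry and a web entry when their *intake*
  timestamps are within ``intake_window_minutes`` (default 5) of each other
  and the web *submission* follows the voice submission by at most
  ``submission_window_minutes`` (default 30).  The intake slack exists
  because the voice side accepts relative phrases ("just now", "ten minutes
  ago") that rarely agree to the minute with a typed time.
* **Step 2** takes the voice entries left unmatched — typically because the
  voice assistant misheard the stated intake time — and links each to the
  nearest *subsequent* web submission within the same 30-minute window.

Matching is one-to-one.  Voice entries are processed in ascending
submission order; ties among feasible web partners are broken by smallest
absolute intake difference, then earliest web submission, then entry id.
Both window boundaries are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .diary_io import DiaryDataset, DiaryEntry

__all__ = [
    "MatchingConfig",
    "CounterpartPair",
    "match_step1",
    "match_step2",
    "match_counterparts",
]


@dataclass(frozen=True)
class MatchingConfig:
    """Window widths (minutes) for the two matching passes."""

    intake_window_minutes: float = 5.0
    submission_window_minutes: float = 30.0

    def __post_init__(self) -> None:
        if self.intake_window_minutes < 0 or self.submission_window_minutes < 0:
            raise ValueError("window widths must be nonnegative")


@dataclass(frozen=True)
class CounterpartPair:
    """A linked (alexa, web) entry pair and the pass that produced it."""

    alexa_entry_id: str
    web_entry_id: str
    match_step: int
    intake_ts_exact_match: bool


def _minutes(delta) -> float:
    return delta.total_seconds() / 60.0


def _check_sources(entries: Iterable[DiaryEntry], expected: str) -> None:
    for e in entries:
        if e.source != expected:
            raise ValueError(
                f"entry {e.entry_id} has source {e.source!r}; expected {expected!r}"
            )


def _alexa_order(entries: Sequence[DiaryEntry]) -> list[DiaryEntry]:
    return sorted(entries, key=lambda e: (e.submission_ts, e.entry_id))


def _make_pair(a: DiaryEntry, w: DiaryEntry, step: int) -> CounterpartPair:
    return CounterpartPair(
        alexa_entry_id=a.entry_id,
        web_entry_id=w.entry_id,
        match_step=step,
        intake_ts_exact_match=(a.intake_ts == w.intake_ts),
    )


def match_step1(
    alexa: Sequence[DiaryEntry],
    web: Sequence[DiaryEntry],
    config: MatchingConfig = MatchingConfig(),
) -> list[CounterpartPair]:
    """Window pass 1: intake times within the intake window, web submission
    0..submission_window minutes after the voice submission.  One-to-one,
    within participant."""
    _check_sources(alexa, "alexa")
    _check_sources(web, "web")
    used_web: set[str] = set()
    pairs: list[CounterpartPair] = []
    web_by_pid: dict[str, list[DiaryEntry]] = {}
    for w in web:
        web_by_pid.setdefault(w.participant_id, []).append(w)
    for a in _alexa_order(alexa):
        candidates = []
        for w in web_by_pid.get(a.participant_id, []):
            if w.entry_id in used_web:
                continue
            intake_diff = abs(_minutes(w.intake_ts - a.intake_ts))
            sub_diff = _minutes(w.submission_ts - a.submission_ts)
            if (
                intake_diff <= config.intake_window_minutes
                and 0 <= sub_diff <= config.submission_window_minutes
            ):
                candidates.append((intake_diff, w.submission_ts, w.entry_id, w))
        if candidates:
            candidates.sort(key=lambda c: c[:3])
            w = candidates[0][3]
            used_web.add(w.entry_id)
            pairs.append(_make_pair(a, w, 1))
    return pairs


def match_step2(
    unmatched_alexa: Sequence[DiaryEntry],
    web: Sequence[DiaryEntry],
    already_used_web: set[str],
    config: MatchingConfig = MatchingConfig(),
) -> list[CounterpartPair]:
    """Window pass 2: nearest subsequent web submission within the
    submission window, skipping web entries already linked in pass 1."""
    _check_sources(unmatched_alexa, "alexa")
    _check_sources(web, "web")
    used_web = set(already_used_web)
    pairs: list[CounterpartPair] = []
    web_by_pid: dict[str, list[DiaryEntry]] = {}
    for w in web:
        web_by_pid.setdefault(w.participant_id, []).append(w)
    for a in _alexa_order(unmatched_alexa):
        candidates = []
        for w in web_by_pid.get(a.participant_id, []):
            if w.entry_id in used_web:
                continue
            sub_diff = _minutes(w.submission_ts - a.submission_ts)
            if 0 <= sub_diff <= config.submission_window_minutes:
                candidates.append((sub_diff, w.entry_id, w))
        if candidates:
            candidates.sort(key=lambda c: c[:2])
            w = candidates[0][2]
            used_web.add(w.entry_id)
            pairs.append(_make_pair(a, w, 2))
    return pairs


def match_counterparts(
    alexa: DiaryDataset,
    web: DiaryDataset,
    config: MatchingConfig = MatchingConfig(),
) -> list[CounterpartPair]:
    """Full two-pass counterpart matching over two diary datasets.

    Partial entries never participate.  Returns step-1 pairs followed by
    step-2 pairs; deterministic for fixed input.
    """
    alexa_sub = [e for e in alexa.submitted() if e.source == "alexa"]
    web_sub = [e for e in web.submitted() if e.source == "web"]
    step1 = match_step1(alexa_sub, web_sub, config)
    matched_alexa = {p.alexa_entry_id for p in step1}
    used_web = {p.web_entry_id for p in step1}
    leftovers = [e for e in alexa_sub if e.entry_id not in matched_alexa]
    step2 = match_step2(leftovers, web_sub, used_web, config)
    return step1 + step2
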