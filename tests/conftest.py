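"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from voicediary import DiaryDataset, DiaryEntry, ErrorModelConfig

BASE = datetime(2023, 5, 1, 8, 0)


def make_entry(
    entry_id: str,
    source: str,
    intake: datetime,
    sub: datetime,
    items=("a cup of tea",),
    pid: str = "P1",
    status: str = "submitted",
) -> DiaryEntry:
    return DiaryEntry(entry_id, pid, source, intake, sub, tuple(items), status)


def ts(minutes: int) -> datetime:
    """Minutes past 08:00 on the fixture day."""
    return BASE + timedelta(minutes=minutes)


@pytest.fixture
def noiseless_config() -> ErrorModelConfig:
    return ErrorModelConfig().noiseless


@pytest.fixture
def small_dataset() -> DiaryDataset:
    return DiaryDataset(
        [
            make_entry("A1", "alexa", ts(0), ts(5), ("a cup of coffee with milk", "toast")),
            make_entry("A2", "alexa", ts(60), ts(65), ("two bagels",), pid="P2"),
            make_entry("A3", "alexa", ts(120), ts(125), (), status="partial"),
        ],
        provenance="fixture",
    )


# ---------------------------------------------------------------------------
# Exhaustive matching oracle: enumerate every feasible one-to-one
# assignment and pick the one whose per-voice-entry choice keys (in
# ascending submission order) are lexicographically best.  Same stated
# objective as the library's sequential matcher, independent computation.


def _feasible1(a, w, cfg):
    d = abs((w.intake_ts - a.intake_ts).total_seconds()) / 60
    s = (w.submission_ts - a.submission_ts).total_seconds() / 60
    return d <= cfg.intake_window_minutes and 0 <= s <= cfg.submission_window_minutes


def _key1(a, w):
    return (0, abs((w.intake_ts - a.intake_ts).total_seconds()), w.submission_ts, w.entry_id)


def _feasible2(a, w, cfg):
    s = (w.submission_ts - a.submission_ts).total_seconds() / 60
    return 0 <= s <= cfg.submission_window_minutes


def _key2(a, w):
    return (0, (w.submission_ts - a.submission_ts).total_seconds(), w.entry_id)


def _enumerate_best(alexa, web, used, cfg, feasible, key):
    order = sorted(alexa, key=lambda e: (e.submission_ts, e.entry_id))
    best = {"key": None, "assign": None}

    def rec(i, used_ids, keys, assign):
        if i == len(order):
            k = tuple(keys)
            if best["key"] is None or k < best["key"]:
                best["key"], best["assign"] = k, dict(assign)
            return
        a = order[i]
        for w in web:
            if (
                w.participant_id == a.participant_id
                and w.entry_id not in used_ids
                and feasible(a, w, cfg)
            ):
                used_ids.add(w.entry_id)
                keys.append(key(a, w))
                assign[a.entry_id] = w.entry_id
                rec(i + 1, used_ids, keys, assign)
                used_ids.remove(w.entry_id)
                keys.pop()
                assign.pop(a.entry_id)
        keys.append((1,))
        rec(i + 1, used_ids, keys, assign)
        keys.pop()

    rec(0, set(used), [], {})
    return best["assign"]


def oracle_match(alexa_ds, web_ds, cfg):
    """Exhaustive two-pass counterpart matching; returns
    {alexa_id: (web_id, step)}."""
    alexa = list(alexa_ds.submitted())
    web = list(web_ds.submitted())
    s1 = _enumerate_best(alexa, web, set(), cfg, _feasible1, _key1)
    left = [a for a in alexa if a.entry_id not in s1]
    s2 = _enumerate_best(left, web, set(s1.values()), cfg, _feasible2, _key2)
    return {**{k: (v, 1) for k, v in s1.items()}, **{k: (v, 2) for k, v in s2.items()}}


def random_matching_instance(rng: np.random.Generator, n_alexa: int, n_web: int):
    """A random single-participant instance with overlapping timestamp windows."""

    def mk(i, src):
        sub = BASE + timedelta(minutes=int(rng.integers(0, 240)))
        intake = sub - timedelta(minutes=int(rng.integers(0, 40)))
        return DiaryEntry(f"{src[0].upper()}{i:02d}", "P1", src, intake, sub, ("item",))

    return (
        DiaryDataset([mk(i, "alexa") for i in range(n_alexa)]),
        DiaryDataset([mk(i, "web") for i in range(n_web)]),
    )
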