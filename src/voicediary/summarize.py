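"""Summary statistics over matched, compared and classified diary data.

This module computes the quantities a relative-validity analysis of a
dual-entry food diary reports: per-source use summaries (median and IQR of
submitted entry counts, with a paired two-tailed t test on per-participant
counts), intake-timestamp agreement between counterpart entries (overall
and per-participant exact-match proportions, plus a Bland-Altman-style
table of signed time differences against web intake time of day),
percentage tables over the 11-way discrepancy classification with the
denominators a reader expects, partial-attempt summaries, and the
end-to-end pipeline that strings the stages together.

Quartiles use linear interpolation between order statistics; percentages
are emitted raw alongside one-decimal and integer roundings so either
display convention can be checked.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import PairClassification, classify_pair
from .diary_io import DiaryDataset, format_timestamp, read_diary
from .matching import CounterpartPair, MatchingConfig, match_counterparts
from .text_compare import compare_word_sets

__all__ = [
    "median_iqr",
    "paired_t",
    "percentage",
    "use_summary",
    "timestamp_agreement",
    "category_percentages",
    "partial_attempt_summary",
    "run_pipeline",
]

QUARTILE_METHOD = "linear"  # numpy interpolation convention


def median_iqr(values: Sequence[float]) -> dict:
    """Median and IQR (Q1-Q3, linear interpolation) of ``values``."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return {"n": 0, "median": None, "q1": None, "q3": None}
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method=QUARTILE_METHOD)
    return {"n": int(arr.size), "median": float(med), "q1": float(q1), "q3": float(q3)}


def paired_t(x: Sequence[float], y: Sequence[float]) -> dict:
    """Classical paired two-tailed t test on paired observations.

    Computed from the closed form on the differences:
    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``n - 1`` degrees of freedom.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired t test requires equal-length samples")
    n = x.size
    if n < 2:
        raise ValueError("paired t test requires at least 2 pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        t = 0.0 if float(np.mean(d)) == 0.0 else float("inf") * np.sign(np.mean(d))
        p = 1.0 if t == 0.0 else 0.0
    else:
        t = float(np.mean(d) / (sd / np.sqrt(n)))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return {"t": t, "p": p, "df": n - 1, "n": n}


def percentage(numerator: int, denominator: int) -> Optional[dict]:
    """A percentage with its parts; ``None`` when the denominator is zero."""
    if denominator == 0:
        return None
    pct = 100.0 * numerator / denominator
    return {
        "numerator": int(numerator),
        "denominator": int(denominator),
        "pct": pct,
        "pct_1dp": round(pct, 1),
        "pct_int": int(round(pct)),
    }


# ---------------------------------------------------------------------------
# Use summary


def _submitted_counts(ds: DiaryDataset, participants: Sequence[str]) -> list[int]:
    counts = {p: 0 for p in participants}
    for e in ds.submitted():
        counts.setdefault(e.participant_id, 0)
        counts[e.participant_id] += 1
    return [counts[p] for p in participants]


def use_summary(alexa: DiaryDataset, web: DiaryDataset) -> dict:
    """Median/IQR of submitted entries per participant for each source,
    with a paired two-tailed t test on the per-participant counts.

    Participants are the union across both datasets (a participant with
    entries in only one source counts 0 in the other).  With fewer than 2
    participants the t test is omitted with a warning entry.
    """
    participants = sorted(set(alexa.participants()) | set(web.participants()))
    a_counts = _submitted_counts(alexa, participants)
    w_counts = _submitted_counts(web, participants)
    out = {
        "participants": participants,
        "alexa": median_iqr(a_counts),
        "web": median_iqr(w_counts),
        "alexa_counts": a_counts,
        "web_counts": w_counts,
    }
    if len(participants) >= 2:
        out["paired_t"] = paired_t(w_counts, a_counts)
    else:
        out["paired_t"] = None
        out["warning"] = "paired t test omitted: fewer than 2 participants"
    return out


# ---------------------------------------------------------------------------
# Timestamp agreement


def timestamp_agreement(
    pairs: Sequence[CounterpartPair],
    alexa: DiaryDataset,
    web: DiaryDataset,
) -> dict:
    """Intake-timestamp agreement across counterpart pairs.

    Returns the overall exact-match count and proportion, the median/IQR of
    per-participant exact-match proportions, and a Bland-Altman-style table
    with one row per pair: signed difference (alexa intake minus web
    intake, minutes) against the web intake time of day.  The web time is
    taken as the reference because typed times are rarely misheard.
    """
    if not pairs:
        raise ValueError("timestamp_agreement requires at least one pair")
    a_by_id = alexa.by_id()
    w_by_id = web.by_id()
    rows = []
    for p in pairs:
        a = a_by_id[p.alexa_entry_id]
        w = w_by_id[p.web_entry_id]
        diff_min = (a.intake_ts - w.intake_ts).total_seconds() / 60.0
        rows.append(
            {
                "alexa_entry_id": p.alexa_entry_id,
                "web_entry_id": p.web_entry_id,
                "participant_id": a.participant_id,
                "web_intake_ts": format_timestamp(w.intake_ts),
                "web_intake_minute_of_day": w.intake_ts.hour * 60 + w.intake_ts.minute,
                "diff_minutes": diff_min,
                "exact": bool(p.intake_ts_exact_match),
            }
        )
    table = pd.DataFrame(rows)
    n_exact = int(table["exact"].sum())
    per_part = table.groupby("participant_id")["exact"].mean()
    return {
        "n_pairs": len(pairs),
        "n_exact": n_exact,
        "proportion_exact": n_exact / len(pairs),
        "per_participant": median_iqr(per_part.tolist()),
        "bland_altman": table,
    }


# ---------------------------------------------------------------------------
# Category percentage tables

# categories 2-7 form the "same item but different information" subset
_DIFFERING_CATEGORIES = (2, 3, 4, 5, 6, 7)
_CATEGORY_NAMES = {
    1: "same_semantically",
    2: "different_detail",
    3: "alexa_less_detail",
    4: "alexa_more_detail",
    5: "alexa_misspelling",
    6: "web_misspelling",
    7: "alexa_entry_issue",
    8: "major_entry_issue",
    9: "extra_alexa_garbage",
    10: "extra_alexa_food",
    11: "extra_web_item",
}


def category_percentages(classifications: Sequence[PairClassification]) -> dict:
    """Percentage table over the discrepancy classification.

    Denominators follow reporting convention: the same-item share is given
    against both the web and the voice item totals of same-event pairs;
    per-category shares of the "differing" subset use the categories 2-7
    total; the major-entry-issue share uses the voice item total; the
    to/two share uses the voice-misspelling (category 5) count.
    """
    n_reviewed = len(classifications)
    n_different = sum(1 for c in classifications if c.different_event)
    counts = {c: 0 for c in _CATEGORY_NAMES}
    n_to_two = 0
    n_both_sides = 0
    for c in classifications:
        if c.different_event:
            continue
        for ic in c.items:
            counts[ic.category] += 1
            if ic.category == 5 and ic.is_to_two:
                n_to_two += 1
            if ic.both_sides_misspelt:
                n_both_sides += 1
    aligned_total = sum(counts[c] for c in range(1, 9))
    n_web_items = aligned_total + counts[11]
    n_alexa_items = aligned_total + counts[9] + counts[10]
    n_differing = sum(counts[c] for c in _DIFFERING_CATEGORIES)
    out = {
        "n_pairs_reviewed": n_reviewed,
        "different_event": percentage(n_different, n_reviewed),
        "n_web_items": n_web_items,
        "n_alexa_items": n_alexa_items,
        "n_extra_web_items": counts[11],
        "n_extra_alexa_items": counts[9] + counts[10],
        "counts": {_CATEGORY_NAMES[c]: counts[c] for c in sorted(counts)},
        "same_of_web_items": percentage(counts[1], n_web_items),
        "same_of_alexa_items": percentage(counts[1], n_alexa_items),
        "n_differing_items": n_differing,
        "differing": {
            _CATEGORY_NAMES[c]: percentage(counts[c], n_differing)
            for c in _DIFFERING_CATEGORIES
        },
        "major_issue_of_alexa_items": percentage(counts[8], n_alexa_items),
        "to_two_of_alexa_misspellings": percentage(n_to_two, counts[5]),
        "n_both_sides_misspelt": n_both_sides,
    }
    return out


def partial_attempt_summary(alexa: DiaryDataset) -> dict:
    """Median/IQR of per-participant partial (unsubmitted) voice attempts."""
    participants = alexa.participants()
    counts = {p: 0 for p in participants}
    for e in alexa:
        if e.status == "partial":
            counts[e.participant_id] += 1
    values = [counts[p] for p in sorted(counts)] if counts else [0]
    return median_iqr(values)


# ---------------------------------------------------------------------------
# Pipeline


def _wordset_rows(
    pairs: Sequence[CounterpartPair], alexa: DiaryDataset, web: DiaryDataset
) -> pd.DataFrame:
    a_by_id, w_by_id = alexa.by_id(), web.by_id()
    rows = []
    for p in pairs:
        a, w = a_by_id[p.alexa_entry_id], w_by_id[p.web_entry_id]
        c = compare_word_sets(" ".join(w.items), " ".join(a.items))
        rows.append(
            {
                "alexa_entry_id": a.entry_id,
                "web_entry_id": w.entry_id,
                "participant_id": a.participant_id,
                "n_web_only": c.n_web_only,
                "n_both": c.n_both,
                "n_alexa_only": c.n_alexa_only,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "alexa_entry_id", "web_entry_id", "participant_id",
            "n_web_only", "n_both", "n_alexa_only",
        ],
    )


def _class_rows(classifications: Sequence[PairClassification]) -> pd.DataFrame:
    rows = []
    for c in classifications:
        base = {
            "alexa_entry_id": c.pair.alexa_entry_id if c.pair else "",
            "web_entry_id": c.pair.web_entry_id if c.pair else "",
        }
        if c.different_event:
            rows.append({**base, "different_event": True, "category": "",
                         "web_index": "", "alexa_index": "",
                         "both_sides_misspelt": "", "is_to_two": ""})
            continue
        for ic in c.items:
            rows.append(
                {
                    **base,
                    "different_event": False,
                    "category": ic.category,
                    "web_index": "" if ic.web_index is None else ic.web_index,
                    "alexa_index": "" if ic.alexa_index is None else ic.alexa_index,
                    "both_sides_misspelt": ic.both_sides_misspelt,
                    "is_to_two": ic.is_to_two,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "alexa_entry_id", "web_entry_id", "different_event", "category",
            "web_index", "alexa_index", "both_sides_misspelt", "is_to_two",
        ],
    )


def _wordset_aggregate(wordsets: pd.DataFrame) -> dict:
    if wordsets.empty:
        return {"n_pairs": 0}
    return {
        "n_pairs": int(len(wordsets)),
        "total_web_only": int(wordsets["n_web_only"].sum()),
        "total_both": int(wordsets["n_both"].sum()),
        "total_alexa_only": int(wordsets["n_alexa_only"].sum()),
        "mean_web_only": float(wordsets["n_web_only"].mean()),
        "mean_both": float(wordsets["n_both"].mean()),
        "mean_alexa_only": float(wordsets["n_alexa_only"].mean()),
    }


def run_pipeline(
    alexa: str | Path | DiaryDataset,
    web: str | Path | DiaryDataset,
    config: MatchingConfig = MatchingConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """Read, match, compare, classify and summarize one paired dataset.

    ``alexa``/``web`` may be file paths or in-memory datasets.  When
    ``out_dir`` is given the intermediates are written there as
    ``pairs.csv``, ``wordsets.csv``, ``classes.csv``, ``bland_altman.csv``
    and ``report.json``.  Fully deterministic for fixed input.
    """

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if not isinstance(alexa, DiaryDataset):
        alexa = _stage("read(alexa)", read_diary, alexa)
    if not isinstance(web, DiaryDataset):
        web = _stage("read(web)", read_diary, web)

    pairs = _stage("match", match_counterparts, alexa, web, config)
    a_by_id, w_by_id = alexa.by_id(), web.by_id()
    wordsets = _stage("compare", _wordset_rows, pairs, alexa, web)
    classifications = [
        _stage(
            "classify",
            classify_pair,
            list(w_by_id[p.web_entry_id].items),
            list(a_by_id[p.alexa_entry_id].items),
            p,
        )
        for p in pairs
    ]

    report: dict = {
        "quartile_method": QUARTILE_METHOD,
        "matching_config": {
            "intake_window_minutes": config.intake_window_minutes,
            "submission_window_minutes": config.submission_window_minutes,
        },
        "use_summary": _stage("summarize", use_summary, alexa, web),
        "partial_attempts": partial_attempt_summary(alexa),
        "n_pairs": len(pairs),
        "n_pairs_step1": sum(1 for p in pairs if p.match_step == 1),
        "n_pairs_step2": sum(1 for p in pairs if p.match_step == 2),
        "wordsets": _wordset_aggregate(wordsets),
        "categories": category_percentages(classifications),
    }
    if pairs:
        agreement = _stage("summarize", timestamp_agreement, pairs, alexa, web)
        bland_altman = agreement.pop("bland_altman")
        report["timestamp_agreement"] = agreement
    else:
        bland_altman = pd.DataFrame()
        report["timestamp_agreement"] = None

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {
                    "alexa_entry_id": p.alexa_entry_id,
                    "web_entry_id": p.web_entry_id,
                    "match_step": p.match_step,
                    "intake_ts_exact_match": p.intake_ts_exact_match,
                }
                for p in pairs
            ],
            columns=[
                "alexa_entry_id", "web_entry_id", "match_step",
                "intake_ts_exact_match",
            ],
        ).to_csv(out_dir / "pairs.csv", index=False, lineterminator="\n")
        wordsets.to_csv(out_dir / "wordsets.csv", index=False, lineterminator="\n")
        _class_rows(classifications).to_csv(
            out_dir / "classes.csv", index=False, lineterminator="\n"
        )
        bland_altman.to_csv(
            out_dir / "bland_altman.csv", index=False, lineterminator="\n"
        )
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return report
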