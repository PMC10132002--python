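"""Synthetic paired-diary generator with ground truth.

No raw diary data ship with this package, so the pipeline is exercised on
synthetic cohorts that emulate the structure the analysis assumes: each
participant experiences intake events over a 7-day window and records each
event twice — by voice first, then on a web form.  The voice channel
passes through a text-level transcription-error model (homophone
substitutions such as "two" -> "to", detail loss/gain/swap, recognizable
and essence-destroying garbles, stray fragments from restarted attempts,
abandoned partial attempts, grossly misheard intake times), while the web
channel is taken as faithful apart from optional extra items and stylistic
rewrites ("1 x apple" for "one apple").

Every generated corruption is recorded in a :class:`GroundTruth` object as
a category code from the 11-way discrepancy taxonomy, so classifier and
matcher output can be scored against known truth.

Category codes
    1 same item semantically; 2 same item, different detail; 3 voice side
    has less detail; 4 voice side has more detail; 5 voice-side misspelling
    (homophone); 6 web-side misspelling; 7 recognizable voice entry issue
    (item still identifiable); 8 major entry issue (essence lost); 9 extra
    voice item that is meaningless; 10 extra voice item recognizable as
    food; 11 extra web item.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

from . import _vocab as V
from .diary_io import DiaryDataset, DiaryEntry
from .text_compare import normalize_token

__all__ = ["ErrorModelConfig", "GroundTruth", "generate_cohort", "corrupt_item",
           "sample_timestamps"]

_QUANTITY_WORDS = ("one", "two", "three", "four", "five", "six", "eight")
_QUANTITY_VALUES = {"one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
                    "six": 6, "eight": 8}


@dataclass(frozen=True)
class ErrorModelConfig:
    """Rates governing voice-side corruption, delays, and missingness.

    The per-item category probabilities must sum to at most 1; the
    remainder is the probability the voice text is semantically identical
    to the web text (category 1).  ``submission_delay_minutes`` is
    ``(offset, exponential_scale)``: the web submission follows the voice
    submission by ``offset`` plus an exponential draw, in whole minutes —
    with the default scale of 10 about 5% of delays exceed the 30-minute
    matching window, producing unmatchable entries as observed in practice.
    """

    p_homophone: float = 0.10
    p_less_detail: float = 0.11
    p_more_detail: float = 0.02
    p_diff_detail: float = 0.026
    p_minor_garble: float = 0.062
    p_major_garble: float = 0.048
    p_extra_alexa_garbage: float = 0.03
    p_extra_web_item: float = 0.11
    p_partial: float = 0.30
    p_no_web: float = 0.19
    intake_jitter_minutes: int = 5
    submission_delay_minutes: tuple[float, float] = (1.0, 10.0)
    p_timestamp_misheard: float = 0.02
    p_web_style: float = 0.0

    def __post_init__(self) -> None:
        probs = {
            "p_homophone": self.p_homophone,
            "p_less_detail": self.p_less_detail,
            "p_more_detail": self.p_more_detail,
            "p_diff_detail": self.p_diff_detail,
            "p_minor_garble": self.p_minor_garble,
            "p_major_garble": self.p_major_garble,
            "p_extra_alexa_garbage": self.p_extra_alexa_garbage,
            "p_extra_web_item": self.p_extra_web_item,
            "p_partial": self.p_partial,
            "p_no_web": self.p_no_web,
            "p_timestamp_misheard": self.p_timestamp_misheard,
            "p_web_style": self.p_web_style,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        cat_sum = (self.p_homophone + self.p_less_detail + self.p_more_detail
                   + self.p_diff_detail + self.p_minor_garble + self.p_major_garble)
        if cat_sum > 1.0 + 1e-12:
            raise ValueError(f"per-item category probabilities sum to {cat_sum} > 1")
        if self.intake_jitter_minutes < 0:
            raise ValueError("intake_jitter_minutes must be nonnegative")
        off, scale = self.submission_delay_minutes
        if off < 0 or scale < 0:
            raise ValueError("submission delay parameters must be nonnegative")

    @property
    def noiseless(self) -> "ErrorModelConfig":
        """A copy with every error rate zero and a fixed 10-minute delay."""
        return ErrorModelConfig(
            p_homophone=0, p_less_detail=0, p_more_detail=0, p_diff_detail=0,
            p_minor_garble=0, p_major_garble=0, p_extra_alexa_garbage=0,
            p_extra_web_item=0, p_partial=0, p_no_web=0,
            intake_jitter_minutes=0, submission_delay_minutes=(10.0, 0.0),
            p_timestamp_misheard=0, p_web_style=0,
        )


@dataclass
class GroundTruth:
    """Realized event links and per-item category labels for one cohort."""

    links: dict[str, str] = field(default_factory=dict)  # alexa id -> web id
    item_labels: dict[tuple[str, int], int] = field(default_factory=dict)
    true_rates: dict[int, int] = field(default_factory=dict)

    def _count(self, category: int) -> None:
        self.true_rates[category] = self.true_rates.get(category, 0) + 1

    def label(self, entry_id: str, index: int, category: int) -> None:
        self.item_labels[(entry_id, index)] = category
        self._count(category)


# ---------------------------------------------------------------------------
# Item grammar


@dataclass(frozen=True)
class _Item:
    """Structured intake item: quantity + container + head noun + modifiers."""

    quantity_word: str          # "a"/"an"/"one"/"two"/...
    noun: str                   # singular food noun
    container: Optional[str] = None
    adjective: Optional[str] = None
    accompaniment: Optional[str] = None

    def render(self, style: str = "voice") -> str:
        qty = self.quantity_word
        n = _QUANTITY_VALUES.get(qty, 1)
        parts: list[str]
        if style == "web" and qty in ("a", "an", "one"):
            lead = "1 x"
        elif style == "web" and qty in _QUANTITY_VALUES:
            lead = f"{_QUANTITY_VALUES[qty]} x"
        else:
            lead = qty
        if self.container is not None:
            cont = V.pluralize(self.container) if n > 1 else self.container
            head = self.noun if self.adjective is None else f"{self.adjective} {self.noun}"
            parts = [lead, cont, "of", head]
        else:
            noun = V.pluralize(self.noun) if n > 1 else self.noun
            head = noun if self.adjective is None else f"{self.adjective} {noun}"
            parts = [lead, head]
        if self.accompaniment is not None:
            parts += ["with", self.accompaniment]
        return " ".join(parts)


def _article_for(word: str) -> str:
    return "an" if word[0] in "aeiou" else "a"


def _sample_item(rng: np.random.Generator, *, force_homophone_qty: bool = False) -> _Item:
    """Draw one structured item from the grammar.

    Every item carries a container or an adjective (or both) so that each
    corruption branch has a valid target and a garbled item still shares a
    content word with its web counterpart.
    """
    noun = str(rng.choice(V.FOOD_NOUNS))
    if force_homophone_qty:
        # Spoken quantities with homophone wrong-forms; "two" dominates, as
        # the to/two confusion does in real transcripts.
        qty = "two" if rng.random() < 0.7 else str(
            rng.choice([w for w in V.HOMOPHONE_QUANTITY_WORDS if w != "two"]))
    else:
        n = int(rng.choice([1, 1, 1, 2, 2, 3], p=None))
        if n == 1:
            qty = "one" if rng.random() < 0.4 else None  # None -> article
        else:
            qty = {2: "two", 3: "three"}[n]
        if qty is None:
            qty = _article_for(noun)
    container = str(rng.choice(V.CONTAINERS)) if rng.random() < 0.5 else None
    adjective = str(rng.choice(V.ADJECTIVES)) if rng.random() < 0.4 else None
    if container is None and adjective is None:
        container = str(rng.choice(V.CONTAINERS))
    if container is not None and qty in ("a", "an"):
        qty = _article_for(container)
    accompaniment = None
    if rng.random() < 0.3:
        accompaniment = str(rng.choice([w for w in V.ACCOMPANIMENTS if w != noun]))
    return _Item(qty, noun, container, adjective, accompaniment)


# ---------------------------------------------------------------------------
# Corruption

_BRANCH_CATEGORIES = (5, 3, 4, 2, 7, 8)


def _branch_probs(config: ErrorModelConfig) -> list[float]:
    return [config.p_homophone, config.p_less_detail, config.p_more_detail,
            config.p_diff_detail, config.p_minor_garble, config.p_major_garble]


def _sample_category(config: ErrorModelConfig, rng: np.random.Generator) -> int:
    u = rng.random()
    acc = 0.0
    for cat, p in zip(_BRANCH_CATEGORIES, _branch_probs(config)):
        acc += p
        if u < acc:
            return cat
    return 1


def _garble(word: str, rng: np.random.Generator) -> str:
    g = V.GARBLE_TABLE.get(word)
    if g is None:  # deterministic fallback distortion: drop one inner letter
        g = word[:1] + word[2:] if len(word) > 2 else word + word[-1]
    return g


def _corrupt_structured(
    item: _Item, category: int, rng: np.random.Generator
) -> tuple[_Item, Optional[tuple[str, str]]]:
    """Apply the edit for ``category`` to a structured item.

    Returns the corrupted structure plus an optional token rewrite
    (old_word, new_word) to apply to the rendered text (used for the
    homophone and garble branches, which operate on surface forms).
    """
    if category == 1:
        return item, None
    if category == 5:
        wrong = V.QUANTITY_TO_WRONG[item.quantity_word]
        return item, (item.quantity_word, wrong)
    if category == 3:
        droppable = [f for f, v in (("container", item.container),
                                    ("adjective", item.adjective),
                                    ("accompaniment", item.accompaniment)) if v]
        which = droppable[int(rng.integers(len(droppable)))]
        out = replace(item, **{which: None})
        if out.container is None and item.quantity_word in ("a", "an"):
            out = replace(out, quantity_word=_article_for(out.noun))
        return out, None
    if category == 4:
        choices = [a for a in V.ADJECTIVES if a != item.adjective]
        return replace(item, adjective=str(rng.choice(choices))), None
    if category == 2:
        if item.container is not None:
            alt = [c for c in V.CONTAINERS if c != item.container]
            return replace(item, container=str(rng.choice(alt))), None
        alt = [a for a in V.ADJECTIVES if a != item.adjective]
        return replace(item, adjective=str(rng.choice(alt))), None
    if category == 7:
        target = item.container if item.container is not None else item.adjective
        n = _QUANTITY_VALUES.get(item.quantity_word, 1)
        rendered = (V.pluralize(target) if (target == item.container and n > 1)
                    else target)
        garbled = (V.pluralize(_garble(target, rng))
                   if rendered != target else _garble(target, rng))
        return item, (rendered, garbled)
    if category == 8:
        n = _QUANTITY_VALUES.get(item.quantity_word, 1)
        rendered = V.pluralize(item.noun) if (item.container is None and n > 1) else item.noun
        return item, (rendered, str(rng.choice(V.MAJOR_GARBLE_WORDS)))
    raise ValueError(f"unknown corruption category {category}")


def _render_corrupted(item: _Item, category: int, rng: np.random.Generator) -> str:
    struct, rewrite = _corrupt_structured(item, category, rng)
    text = struct.render("voice")
    if rewrite is not None:
        old, new = rewrite
        words = text.split()
        idx = words.index(old)
        words[idx] = new
        text = " ".join(words)
    return text


def _parse_item_text(text: str) -> Optional[_Item]:
    """Best-effort inverse of :meth:`_Item.render` for vocabulary texts."""
    words = text.split()
    if not words:
        return None
    qty = words[0].lower()
    if qty not in _QUANTITY_VALUES and qty not in ("a", "an"):
        return None
    rest = words[1:]
    accompaniment = None
    if len(rest) >= 2 and rest[-2] == "with":
        accompaniment = rest[-1]
        rest = rest[:-2]
    container = adjective = None
    if "of" in rest:
        k = rest.index("of")
        cont_norm = normalize_token(rest[k - 1]) if k >= 1 else ""
        if cont_norm in V.CONTAINERS:
            container = cont_norm
            rest = rest[k + 1:]
    if len(rest) == 2 and rest[0] in V.ADJECTIVES:
        adjective, rest = rest[0], rest[1:]
    if len(rest) != 1:
        return None
    noun = normalize_token(rest[0])
    if not V.is_food_noun(noun):
        return None
    return _Item(qty, noun, container, adjective, accompaniment)


def corrupt_item(
    item_text: str, error_config: ErrorModelConfig, rng: np.random.Generator
) -> tuple[str, int]:
    """Pass one vocabulary item text through the transcription-error model.

    Samples one corruption branch from the configured per-item
    probabilities and applies it, returning the corrupted text and the
    category code (1-8) of the edit actually applied.  If the sampled
    branch has no valid target in the text (e.g. a homophone substitution
    on an item whose quantity has no homophone), the text is returned
    unchanged as category 1; the cohort generator avoids this by
    constructing items compatible with the branch it draws.
    """
    category = _sample_category(error_config, rng)
    if category == 1:
        return item_text, 1
    item = _parse_item_text(item_text)
    if item is None:
        return item_text, 1
    if category == 5 and item.quantity_word not in V.QUANTITY_TO_WRONG:
        return item_text, 1
    if category == 3 and not (item.container or item.adjective or item.accompaniment):
        return item_text, 1
    return _render_corrupted(item, category, rng), category


# ---------------------------------------------------------------------------
# Timestamps


def _truncate_minute(ts: datetime) -> datetime:
    return ts.replace(second=0, microsecond=0)


def sample_timestamps(
    event_ts: datetime, error_config: ErrorModelConfig, rng: np.random.Generator
) -> tuple[datetime, datetime, datetime, datetime]:
    """Sample the four timestamps for one dual-recorded event.

    Returns ``(alexa_intake, alexa_sub, web_intake, web_sub)``.  The web
    intake time is the true event time; the voice intake time jitters
    within ``intake_jitter_minutes`` of it (relative phrases like "ten
    minutes ago" are imprecise) unless the misheard branch fires, in which
    case it is shifted by hours.  The web submission strictly follows the
    voice submission.
    """
    event_ts = _truncate_minute(event_ts)
    web_intake = event_ts
    if rng.random() < error_config.p_timestamp_misheard:
        hours = int(rng.integers(2, 49)) * (1 if rng.random() < 0.5 else -1)
        alexa_intake = event_ts + timedelta(hours=hours)
    else:
        j = error_config.intake_jitter_minutes
        if j > 0 and rng.random() >= 0.7:  # 70% of relative phrases land exact
            offset = int(rng.integers(1, j + 1)) * (1 if rng.random() < 0.5 else -1)
        else:
            offset = 0
        alexa_intake = event_ts + timedelta(minutes=offset)
    alexa_sub = event_ts + timedelta(minutes=int(rng.integers(1, 16)))
    off, scale = error_config.submission_delay_minutes
    delay = off + (float(rng.exponential(scale)) if scale > 0 else 0.0)
    delay_min = max(1, int(round(delay)))
    web_sub = alexa_sub + timedelta(minutes=delay_min)
    return alexa_intake, alexa_sub, web_intake, web_sub


# ---------------------------------------------------------------------------
# Cohort generation


def generate_cohort(
    n_participants: int,
    days: int,
    events_per_day: float,
    error_config: ErrorModelConfig = ErrorModelConfig(),
    seed: int = 0,
) -> tuple[DiaryDataset, DiaryDataset, GroundTruth]:
    """Generate one paired cohort: voice dataset, web dataset, ground truth.

    Per participant, daily event counts are Poisson(``events_per_day``)
    with event times uniform over 07:00-22:00 of each study day.  Every
    event produces a voice record (submitted, or partial with probability
    ``p_partial``) and — unless the participant is a web non-user — a web
    record submitted after the voice one.  All randomness flows from one
    seeded generator, so output is bitwise reproducible.
    """
    if n_participants <= 0 or days <= 0 or events_per_day <= 0:
        raise ValueError("n_participants, days and events_per_day must be positive")
    rng = np.random.default_rng(seed)
    start = datetime(2023, 5, 1)
    alexa_entries: list[DiaryEntry] = []
    web_entries: list[DiaryEntry] = []
    truth = GroundTruth()
    a_seq = w_seq = 0
    for p in range(n_participants):
        pid = f"P{p + 1:03d}"
        no_web = rng.random() < error_config.p_no_web
        for day in range(days):
            n_events = int(rng.poisson(events_per_day))
            minutes = sorted(int(m) for m in rng.integers(7 * 60, 22 * 60, n_events))
            for m in minutes:
                event_ts = start + timedelta(days=day, minutes=m)
                a_intake, a_sub, w_intake, w_sub = sample_timestamps(
                    event_ts, error_config, rng)
                n_items = 1 + int(rng.random() < 0.35) + int(rng.random() < 0.1)
                categories = [_sample_category(error_config, rng)
                              for _ in range(n_items)]
                items = [_sample_item(rng, force_homophone_qty=(c == 5))
                         for c in categories]
                web_texts = [it.render(
                    "web" if rng.random() < error_config.p_web_style else "voice")
                    for it in items]
                alexa_texts = [_render_corrupted(it, c, rng)
                               for it, c in zip(items, categories)]
                is_partial = rng.random() < error_config.p_partial

                a_seq += 1
                a_id = f"A{a_seq:05d}"
                if is_partial:
                    if rng.random() < 0.5:
                        a_items: tuple[str, ...] = ()
                    else:  # cut off mid-item
                        words = alexa_texts[0].split()
                        k = int(rng.integers(1, len(words) + 1))
                        a_items = (" ".join(words[:k]),)
                    alexa_entries.append(DiaryEntry(
                        a_id, pid, "alexa", a_intake, a_sub, a_items, "partial"))
                else:
                    a_items = tuple(alexa_texts)
                    extra_alexa = rng.random() < error_config.p_extra_alexa_garbage
                    if extra_alexa:
                        a_items = a_items + (str(rng.choice(V.GARBAGE_FRAGMENTS)),)
                    alexa_entries.append(DiaryEntry(
                        a_id, pid, "alexa", a_intake, a_sub, a_items, "submitted"))

                if not no_web:
                    w_seq += 1
                    w_id = f"W{w_seq:05d}"
                    w_items = tuple(web_texts)
                    extra_web = rng.random() < error_config.p_extra_web_item
                    if extra_web:
                        w_items = w_items + (
                            _sample_item(rng).render("voice"),)
                    web_entries.append(DiaryEntry(
                        w_id, pid, "web", w_intake, w_sub, w_items, "submitted"))
                    if not is_partial:
                        truth.links[a_id] = w_id
                        for idx, c in enumerate(categories):
                            truth.label(a_id, idx, c)
                        if extra_alexa:
                            truth.label(a_id, len(categories), 9)
                        if extra_web:
                            truth.label(w_id, len(web_texts), 11)

    prov = (f"generate_cohort(n_participants={n_participants}, days={days}, "
            f"events_per_day={events_per_day}, seed={seed})")
    return (
        DiaryDataset(alexa_entries, provenance=prov),
        DiaryDataset(web_entries, provenance=prov),
        truth,
    )
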