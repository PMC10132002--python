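"""Rule-based discrepancy classification of counterpart entry pairs.

The manual route to comparing counterpart entries is a two-step review:
first screen each pair for whether its item sets are *completely*
different (in which case the pair most likely links two different intake
events and is set aside), then assign every food/drink item to one of 11
categories describing how the voice record differs from the web record.

The original review involves human judgment; this module is an explicit,
deterministic rule-based surrogate.  Items are aligned across the pair by
a maximum-similarity one-to-one assignment, and each aligned pair passes
through a fixed decision cascade:

1. normalized word sets equal               -> 1  (same semantically)
2. difference fully explained by homophones -> 5 (voice misspelt) or
                                               6 (web misspelt)
3. voice content a proper subset of web     -> 3  (less detail)
4. web content a proper subset of voice     -> 4  (more detail)
5. unknown near-miss token, food preserved  -> 7  (recognizable garble)
6. a web food noun missing on voice side    -> 8  (major entry issue)
7. otherwise                                -> 2  (different detail)

Unaligned voice items become category 10 if they contain a known food
noun, else 9; unaligned web items become category 11.  The cascade order
resolves overlaps between category definitions — e.g. a subset relation
caused purely by a homophone counts as a misspelling, not as less detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

from . import _vocab as V
from .matching import CounterpartPair
from .text_compare import normalized_set

__all__ = [
    "ItemAlignment",
    "ItemClassification",
    "PairClassification",
    "screen_pair",
    "align_items",
    "classify_item_pair",
    "classify_pair",
    "content_tokens",
]


def content_tokens(text: str) -> set[str]:
    """Normalized tokens that carry food content: no pure numbers, no glue words."""
    return {
        t
        for t in normalized_set(text)
        if not t.isdigit() and t not in V.FUNCTION_WORDS
    }


def _levenshtein(a: str, b: str) -> int:
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _homophone_pairs(web_only: set[str], alexa_only: set[str]) -> list[tuple[str, str, str]]:
    """Pairs (web_token, alexa_token, wrong_side) linked by the homophone table."""
    out = []
    for a in alexa_only:
        right = V.HOMOPHONE_WRONG_TO_RIGHT.get(a)
        if right is not None and right in web_only:
            out.append((right, a, "alexa"))
    for w in web_only:
        right = V.HOMOPHONE_WRONG_TO_RIGHT.get(w)
        if right is not None and right in alexa_only:
            out.append((w, right, "web"))
        elif right is not None:
            # both sides hold a wrong form of the same word ("too" vs "to")
            for a in alexa_only:
                if V.HOMOPHONE_WRONG_TO_RIGHT.get(a) == right:
                    out.append((w, a, "both"))
    return out


# ---------------------------------------------------------------------------
# Step 1: different-event screen


def screen_pair(web_items: Sequence[str], alexa_items: Sequence[str]) -> bool:
    """True when the pair most likely links two *different* intake events.

    The screen is the coarsest possible: the pair is flagged only when no
    web item shares a single content token with any voice item.
    """
    web_content = set().union(*(content_tokens(t) for t in web_items)) if web_items else set()
    alexa_content = (
        set().union(*(content_tokens(t) for t in alexa_items)) if alexa_items else set()
    )
    return not (web_content & alexa_content)


# ---------------------------------------------------------------------------
# Item alignment


@dataclass(frozen=True)
class ItemAlignment:
    """One-to-one alignment of a pair's item lists, with leftovers."""

    aligned: tuple[tuple[int, int], ...]  # (web index, alexa index)
    extra_web: tuple[int, ...]
    extra_alexa: tuple[int, ...]


def _similarity(web_text: str, alexa_text: str) -> tuple[float, bool]:
    """Token-overlap score with homophone credit, and whether the pair
    clears the alignment floor (>=1 shared content token or homophone pair)."""
    web = normalized_set(web_text)
    alexa = normalized_set(alexa_text)
    shared = web & alexa
    hom = _homophone_pairs(web - alexa, alexa - web)
    score = float(len(shared) + len(hom))
    floor = bool((content_tokens(web_text) & content_tokens(alexa_text)) or hom)
    return score, floor


def align_items(
    web_items: Sequence[str], alexa_items: Sequence[str]
) -> ItemAlignment:
    """Maximum-similarity one-to-one alignment of the two item lists.

    Exhaustive over injective assignments (item lists are short), scoring
    only pairs that clear the similarity floor; ties break toward the
    lexicographically smallest aligned index list.
    """
    n_web, n_alexa = len(web_items), len(alexa_items)
    sim = [[_similarity(w, a) for a in alexa_items] for w in web_items]
    best_score = -1.0
    best: tuple[tuple[int, int], ...] = ()
    web_idx = range(n_web)
    if n_web <= n_alexa:
        for perm in permutations(range(n_alexa), n_web):
            pairs = tuple(
                (w, a)
                for w, a in zip(web_idx, perm)
                if sim[w][a][1]
            )
            score = sum(sim[w][a][0] for w, a in pairs)
            if score > best_score or (score == best_score and pairs < best):
                best_score, best = score, pairs
    else:
        for perm in permutations(range(n_web), n_alexa):
            pairs = tuple(
                sorted((w, a) for a, w in enumerate(perm) if sim[w][a][1])
            )
            score = sum(sim[w][a][0] for w, a in pairs)
            if score > best_score or (score == best_score and pairs < best):
                best_score, best = score, pairs
    used_web = {w for w, _ in best}
    used_alexa = {a for _, a in best}
    return ItemAlignment(
        aligned=best,
        extra_web=tuple(i for i in range(n_web) if i not in used_web),
        extra_alexa=tuple(i for i in range(n_alexa) if i not in used_alexa),
    )


# ---------------------------------------------------------------------------
# Per-item category cascade


@dataclass(frozen=True)
class ItemClassification:
    """Category assignment for one aligned item pair or one extra item."""

    category: int
    web_index: Optional[int] = None
    alexa_index: Optional[int] = None
    both_sides_misspelt: bool = False
    is_to_two: bool = False  # homophone was the to/two confusion

    def __post_init__(self) -> None:
        if not 1 <= self.category <= 11:
            raise ValueError(f"category must be 1-11, got {self.category}")
        if self.category <= 8 and (self.web_index is None or self.alexa_index is None):
            raise ValueError("categories 1-8 require both item indices")
        if self.category in (9, 10) and (
            self.alexa_index is None or self.web_index is not None
        ):
            raise ValueError("categories 9-10 are alexa-only")
        if self.category == 11 and (
            self.web_index is None or self.alexa_index is not None
        ):
            raise ValueError("category 11 is web-only")


def classify_item_pair(web_item: str, alexa_item: str) -> ItemClassification:
    """Assign one aligned (web, voice) item pair to a category 1-8."""
    web = normalized_set(web_item)
    alexa = normalized_set(alexa_item)
    if web == alexa:
        return ItemClassification(1, 0, 0)

    web_only, alexa_only = web - alexa, alexa - web
    hom = _homophone_pairs(web_only, alexa_only)
    covered_web = {p[0] for p in hom}
    covered_alexa = {p[1] for p in hom}
    if hom and web_only <= covered_web and alexa_only <= covered_alexa:
        sides = {p[2] for p in hom}
        both = "both" in sides or sides >= {"alexa", "web"}
        # when both sides misspell, keep the partition exclusive: report 5
        category = 5 if ("alexa" in sides or "both" in sides) else 6
        to_two = any(
            (wrong == "to" and right == "2")
            for right, wrong, side in hom
            if side == "alexa"
        )
        return ItemClassification(
            category, 0, 0, both_sides_misspelt=both, is_to_two=to_two
        )

    web_content = content_tokens(web_item)
    alexa_content = content_tokens(alexa_item)
    if alexa_content < web_content:
        return ItemClassification(3, 0, 0)
    if web_content < alexa_content:
        return ItemClassification(4, 0, 0)

    web_foods = {t for t in web_content if V.is_food_noun(t)}
    alexa_foods = {t for t in alexa_content if V.is_food_noun(t)}
    alexa_unknown = [t for t in alexa_content - web_content if t not in V.KNOWN_WORDS]
    if web_foods <= alexa_content and alexa_unknown:
        near = all(
            any(_levenshtein(t, w) <= 2 for w in web_content - alexa_content)
            for t in alexa_unknown
        )
        if near:
            return ItemClassification(7, 0, 0)
    if web_foods - alexa_content:
        return ItemClassification(8, 0, 0)
    return ItemClassification(2, 0, 0)


@dataclass
class PairClassification:
    """Classification of one counterpart pair: screen outcome plus items."""

    pair: Optional[CounterpartPair]
    different_event: bool
    items: list[ItemClassification] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.different_event and self.items:
            raise ValueError("a different-event pair carries no item classifications")

    def category_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for ic in self.items:
            counts[ic.category] = counts.get(ic.category, 0) + 1
        return counts


def classify_pair(
    web_items: Sequence[str],
    alexa_items: Sequence[str],
    pair: Optional[CounterpartPair] = None,
) -> PairClassification:
    """Screen, align and classify one counterpart pair's item lists."""
    if not web_items or not alexa_items:
        raise ValueError("classify_pair requires non-empty item lists")
    if screen_pair(web_items, alexa_items):
        return PairClassification(pair=pair, different_event=True)
    alignment = align_items(web_items, alexa_items)
    out: list[ItemClassification] = []
    for w, a in alignment.aligned:
        ic = classify_item_pair(web_items[w], alexa_items[a])
        out.append(
            ItemClassification(
                ic.category, w, a,
                both_sides_misspelt=ic.both_sides_misspelt,
                is_to_two=ic.is_to_two,
            )
        )
    for a in alignment.extra_alexa:
        foods = {t for t in content_tokens(alexa_items[a]) if V.is_food_noun(t)}
        out.append(ItemClassification(10 if foods else 9, None, a))
    for w in alignment.extra_web:
        out.append(ItemClassification(11, w, None))
    return PairClassification(pair=pair, different_event=False, items=out)
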