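"""Automated word-set comparison of counterpart entry texts.

The automated route to comparing a voice-entered and a web-entered
description of the same intake event is deliberately simple and objective:
lowercase and tokenize both texts, normalize each token (number words and
indefinite articles become digit strings, plural nouns become singular),
build the two token *sets*, and count the tokens that appear in the web
set only, the voice set only, and both.  It is a pessimistic measure of
agreement — "1 x apple" and "one apple" share only two of three tokens —
but it needs no human judgment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "WordSetComparison",
    "tokenize",
    "normalize_token",
    "normalized_set",
    "compare_word_sets",
    "NUMBER_WORDS",
]

_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")

# Number words one..twenty plus tens, and the indefinite articles, all
# mapped to digit strings.  Diary quantities are small; larger numbers are
# left verbatim.
NUMBER_WORDS: dict[str, str] = {
    "a": "1",
    "an": "1",
    "one": "1",
    "two": "2",
    "three": "3",
    "four": "4",
    "five": "5",
    "six": "6",
    "seven": "7",
    "eight": "8",
    "nine": "9",
    "ten": "10",
    "eleven": "11",
    "twelve": "12",
    "thirteen": "13",
    "fourteen": "14",
    "fifteen": "15",
    "sixteen": "16",
    "seventeen": "17",
    "eighteen": "18",
    "nineteen": "19",
    "twenty": "20",
    "thirty": "30",
    "forty": "40",
    "fifty": "50",
    "sixty": "60",
    "seventy": "70",
    "eighty": "80",
    "ninety": "90",
}

# Words that end in 's' (or would otherwise be mangled by the suffix
# rules) but are already singular.  Mass nouns and containers dominate.
_SINGULAR_EXCEPTIONS = frozenset(
    {
        "glass",
        "cheese",
        "juice",
        "rice",
        "hummus",
        "houmous",
        "couscous",
        "muesli",
        "gas",
        "is",
        "as",
        "its",
        "this",
        "his",
        "was",
        "has",
        "less",
        "plus",
    }
)

# Irregular plurals worth handling for food text.
_IRREGULAR_PLURALS = {
    "tomatoes": "tomato",
    "potatoes": "potato",
    "loaves": "loaf",
    "halves": "half",
    "leaves": "leaf",
    "cookies": "cookie",
    "smoothies": "smoothie",
}


def tokenize(text: str) -> list[str]:
    """Lowercase ``text`` and split on runs of non-alphanumeric characters."""
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if t]


def _singularize(token: str) -> str:
    if token in _SINGULAR_EXCEPTIONS or len(token) <= 2:
        return token
    if token in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[token]
    if token.endswith("ies"):
        # "berries" -> "berry", but short stems are -s plurals: "pies" -> "pie"
        return token[:-3] + "y" if len(token) > 4 else token[:-1]
    if token.endswith("es"):
        base = token[:-2]
        # "glasses" -> "glass", "sandwiches" -> "sandwich", "boxes" -> "box",
        # "hummuses" -> "hummus"; bases like "chees(e)" are left for the -s rule
        if base.endswith(("ss", "x", "z", "ch", "sh", "us")):
            return base
    if token.endswith("s") and not token.endswith(("ss", "us")):
        return token[:-1]
    return token


def normalize_token(token: str) -> str:
    """Normalize one lowercase token: number words to digits, plurals to singular.

    Idempotent: ``normalize_token(normalize_token(t)) == normalize_token(t)``.
    """
    token = token.lower()
    if token in NUMBER_WORDS:
        return NUMBER_WORDS[token]
    if token.isdigit():
        return token
    return _singularize(token)


def normalized_set(text: str) -> set[str]:
    """The set of normalized tokens in ``text`` (duplicates collapse)."""
    return {normalize_token(t) for t in tokenize(text)}


@dataclass(frozen=True)
class WordSetComparison:
    """Word-set overlap counts for one counterpart pair.

    ``n_web_only = |web \\ alexa|``, ``n_alexa_only = |alexa \\ web|``,
    ``n_both = |web ∩ alexa|`` over the normalized token sets.
    """

    n_web_only: int
    n_alexa_only: int
    n_both: int
    web_words: frozenset[str]
    alexa_words: frozenset[str]


def compare_word_sets(web_text: str, alexa_text: str) -> WordSetComparison:
    """Compare the normalized word sets of a web and a voice entry text."""
    web = frozenset(normalized_set(web_text))
    alexa = frozenset(normalized_set(alexa_text))
    return WordSetComparison(
        n_web_only=len(web - alexa),
        n_alexa_only=len(alexa - web),
        n_both=len(web & alexa),
        web_words=web,
        alexa_words=alexa,
    )
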