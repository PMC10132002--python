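"""Built-in food/drink vocabulary and error tables.

A small closed vocabulary drives both sides of the artifact: the synthetic
generator composes item texts from it ("quantity + container + item +
modifiers", e.g. "a cup of coffee with milk"), and the rule-based
discrepancy classifier uses the same word lists to decide whether a token
is a food noun, a known word, or a transcription garble.

All words are stored in their normalized (singular, lowercase) form.
"""

from __future__ import annotations

from .text_compare import NUMBER_WORDS, normalize_token

# ~60 food and drink head nouns (singular).
FOOD_NOUNS: tuple[str, ...] = (
    "coffee", "tea", "milk", "water", "juice", "smoothie", "beer", "wine",
    "cola", "lemonade", "toast", "bagel", "bread", "croissant", "cereal",
    "porridge", "yoghurt", "banana", "apple", "pear", "orange", "grape",
    "strawberry", "blueberry", "melon", "salad", "soup", "sandwich",
    "cheese", "ham", "chicken", "beef", "steak", "fish", "salmon", "tuna",
    "egg", "bacon", "sausage", "pasta", "spaghetti", "lasagne", "pizza",
    "rice", "curry", "noodle", "burger", "chip", "crisp", "chocolate",
    "biscuit", "cookie", "cake", "muffin", "pie", "pancake", "waffle",
    "butter", "jam", "honey", "tomato", "potato", "carrot", "pea",
    "hummus", "cracker", "almond", "sugar",
)

# ~8 containers / serving units.
CONTAINERS: tuple[str, ...] = (
    "cup", "mug", "glass", "bowl", "plate", "bottle", "slice", "bar", "piece",
)

# ~15 descriptive modifiers (adjectives).
ADJECTIVES: tuple[str, ...] = (
    "hot", "cold", "large", "small", "fresh", "brown", "white", "wholemeal",
    "grilled", "fried", "roasted", "skimmed", "sparkling", "toasted", "creamy",
)

# Foods that plausibly accompany another item ("... with milk").
ACCOMPANIMENTS: tuple[str, ...] = (
    "milk", "sugar", "butter", "jam", "honey", "cheese", "salad",
)

# Homophone confusions the speech transcriber makes, as wrong-form ->
# normalized correct form.  The number-word entries dominate in practice:
# a spoken quantity "two" is transcribed as the word "to".
HOMOPHONE_WRONG_TO_RIGHT: dict[str, str] = {
    "to": "2",
    "too": "2",
    "for": "4",
    "ate": "8",
    "won": "1",
    "pair": "pear",
    "stake": "steak",
}

# Spoken-quantity words that have a homophone wrong form.
HOMOPHONE_QUANTITY_WORDS: tuple[str, ...] = ("one", "two", "four", "eight")
QUANTITY_TO_WRONG: dict[str, str] = {
    "one": "won",
    "two": "to",
    "four": "for",
    "eight": "ate",
}

# Recognizable transcription garbles (word -> garbled form, edit distance
# <= 2, garble not itself a vocabulary word).
GARBLE_TABLE: dict[str, str] = {
    "cup": "cap",
    "mug": "mog",
    "glass": "glas",
    "bowl": "ball",
    "plate": "plat",
    "bottle": "bottel",
    "slice": "slise",
    "bar": "barr",
    "piece": "peace",
    "hot": "hod",
    "cold": "colt",
    "large": "larg",
    "small": "smal",
    "fresh": "frish",
    "brown": "braun",
    "white": "wite",
    "wholemeal": "holemeal",
    "grilled": "griled",
    "fried": "frid",
    "roasted": "rosted",
    "skimmed": "skimed",
    "sparkling": "sparklin",
    "toasted": "tosted",
    "creamy": "creamey",
}

# Non-food words that replace the head noun when the transcription loses
# the essence of the item entirely ("cough with milk").
MAJOR_GARBLE_WORDS: tuple[str, ...] = (
    "cough", "sock", "clock", "wrench", "carpet", "pillow", "ladder", "stapler",
)

# Meaningless fragments left behind when a participant stops and restarts.
GARBAGE_FRAGMENTS: tuple[str, ...] = ("two", "the", "one", "um", "er", "and")

# Tokens carrying no food content: glue words plus the web form's "x"
# quantity notation.  Pure digit tokens are also excluded from content
# comparisons (handled separately).
FUNCTION_WORDS: frozenset[str] = frozenset(
    {"of", "with", "and", "the", "in", "on", "at", "x", "some", "to", "too", "for"}
)

# Every known (normalized) vocabulary word; used to decide whether an
# unexpected token is a garble (unknown) or a legitimate detail swap.
KNOWN_WORDS: frozenset[str] = frozenset(
    {normalize_token(w) for w in FOOD_NOUNS}
    | set(CONTAINERS)
    | set(ADJECTIVES)
    | set(NUMBER_WORDS.values())
    | set(FUNCTION_WORDS)
)

_ES_ENDINGS = ("s", "x", "z", "ch", "sh")
_IRREGULAR_SINGULAR_TO_PLURAL = {
    "tomato": "tomatoes",
    "potato": "potatoes",
    "loaf": "loaves",
    "half": "halves",
    "leaf": "leaves",
}
_VOWELS = "aeiou"


def pluralize(word: str) -> str:
    """Render the plural of a singular vocabulary word."""
    if word in _IRREGULAR_SINGULAR_TO_PLURAL:
        return _IRREGULAR_SINGULAR_TO_PLURAL[word]
    if word.endswith("y") and len(word) > 1 and word[-2] not in _VOWELS:
        return word[:-1] + "ies"
    if word.endswith(_ES_ENDINGS):
        return word + "es"
    return word + "s"


def is_food_noun(normalized_token: str) -> bool:
    return normalized_token in _FOOD_SET


_FOOD_SET = frozenset(normalize_token(w) for w in FOOD_NOUNS)
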