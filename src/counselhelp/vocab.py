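"""Default synthetic vocabulary, toy dictionary, and feature group map.

The synthetic corpora are whitespace-tokenized Latin-alphabet pseudo-words.
Each *leaf* emission category owns a small pool of pseudo-words (e.g. the
``anx`` pool is ``anx01 .. anx06``); a bundled toy dictionary mirrors those
pools with literal and stem entries, plus LIWC-style union categories
(``NegEmo = anx + anger + sad`` and so on).  Because the dictionary captures
the pools exactly, category proportions computed from emitted tokens are
unbiased estimates of the generator's latent per-document rates — the lever
behind every parameter-recovery test.

Nothing here is proprietary dictionary content: all words are synthetic.
"""

from __future__ import annotations

from .lexicon import CategoryLexicon

# ---------------------------------------------------------------------------
# Leaf emission categories: name -> (pool size, (lo, hi) default rate range).
# Rates are per-token emission probabilities drawn uniformly per document.
# ---------------------------------------------------------------------------

LEAF_CATEGORIES: dict[str, tuple[int, tuple[float, float]]] = {
    # function words (the LSM substrate)
    "preps":   (6, (0.030, 0.070)),
    "auxverb": (6, (0.020, 0.050)),
    "adverb":  (6, (0.015, 0.040)),
    "conj":    (6, (0.020, 0.050)),
    "article": (4, (0.010, 0.030)),
    "quant":   (4, (0.005, 0.020)),
    "negate":  (4, (0.004, 0.015)),
    "ipron":   (4, (0.015, 0.040)),
    "i":       (3, (0.010, 0.040)),
    "we":      (3, (0.002, 0.010)),
    "you":     (3, (0.005, 0.020)),
    # emotion leaves
    "posfeel": (6, (0.005, 0.025)),
    "love":    (5, (0.002, 0.008)),
    "anx":     (6, (0.002, 0.012)),
    "anger":   (5, (0.001, 0.008)),
    "sad":     (6, (0.002, 0.012)),
    # cognitive
    "insight":    (6, (0.004, 0.015)),
    "cause":      (6, (0.004, 0.015)),
    "tentat":     (6, (0.004, 0.015)),
    "certain":    (4, (0.002, 0.008)),
    "inhibition": (4, (0.001, 0.006)),
    "inclusive":  (4, (0.004, 0.012)),
    # biological
    "body":   (5, (0.002, 0.008)),
    "health": (5, (0.002, 0.010)),
    # perceptual
    "see":  (4, (0.002, 0.008)),
    "hear": (4, (0.002, 0.008)),
    "feel": (4, (0.002, 0.010)),
    # social
    "humans":  (4, (0.002, 0.008)),
    "family":  (5, (0.002, 0.012)),
    "friends": (4, (0.002, 0.008)),
    # drives
    "achieve": (5, (0.002, 0.010)),
    "power":   (4, (0.002, 0.008)),
    # personal concerns
    "work":       (5, (0.002, 0.012)),
    "leisure":    (4, (0.002, 0.008)),
    "money":      (4, (0.001, 0.008)),
    "psychology": (5, (0.003, 0.012)),
    # informal
    "assent": (4, (0.001, 0.008)),
    "nonfl":  (4, (0.001, 0.006)),
    "swear":  (3, (0.0005, 0.003)),
    # time orientation
    "past":    (5, (0.004, 0.015)),
    "present": (5, (0.006, 0.020)),
    "future":  (4, (0.002, 0.010)),
    # relativity
    "motion": (4, (0.002, 0.010)),
    "space":  (5, (0.004, 0.015)),
    "time":   (5, (0.004, 0.015)),
    # numerals (digit tokens)
    "number": (6, (0.002, 0.010)),
}

#: digit pseudo-words for the ``number`` pool (real numerals so the
#: stylistic numeral counter sees them).
_NUMBER_POOL = ["3", "7", "12", "25", "100", "2020"]

#: leaf categories whose dictionary representation uses a stem entry
#: (``anx*``) instead of listing every pool word; exercises the stem path.
_STEM_LEAVES = {
    "preps", "adverb", "anx", "sad", "insight", "tentat", "family",
    "work", "past", "space", "posfeel",
}


def leaf_pool(name: str) -> list[str]:
    """Word pool for a leaf category."""
    if name == "number":
        return list(_NUMBER_POOL)
    n, _ = LEAF_CATEGORIES[name]
    return [f"{name}{k:02d}" for k in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Dictionary layout: column category -> leaf categories it covers.
# Ordered: this order is the feature-column order per speaker.
# ---------------------------------------------------------------------------

FUNCTION_WORD_LEAVES = [
    "preps", "auxverb", "adverb", "conj", "article", "quant", "negate",
    "ipron", "i", "we", "you",
]

DICTIONARY_LAYOUT: dict[str, list[str]] = {
    "Funct":   FUNCTION_WORD_LEAVES,
    "Ppron":   ["i", "we", "you"],
    "I":       ["i"],
    "We":      ["we"],
    "You":     ["you"],
    "Ipron":   ["ipron"],
    "Article": ["article"],
    "Preps":   ["preps"],
    "AuxVerb": ["auxverb"],
    "Adverb":  ["adverb"],
    "Conj":    ["conj"],
    "Quant":   ["quant"],
    "Negate":  ["negate"],
    "Affect":  ["posfeel", "love", "anx", "anger", "sad"],
    "PosEmo":  ["posfeel", "love"],
    "NegEmo":  ["anx", "anger", "sad"],
    "Anx":     ["anx"],
    "Anger":   ["anger"],
    "Sad":     ["sad"],
    "Love":    ["love"],
    "CogMech": ["insight", "cause", "tentat", "certain", "inhibition",
                "inclusive"],
    "Insight":    ["insight"],
    "Cause":      ["cause"],
    "Tentat":     ["tentat"],
    "Certain":    ["certain"],
    "Inhibition": ["inhibition"],
    "Inclusive":  ["inclusive"],
    "Bio":    ["body", "health"],
    "Body":   ["body"],
    "Health": ["health"],
    "Percept": ["see", "hear", "feel"],
    "See":     ["see"],
    "Hear":    ["hear"],
    "Feel":    ["feel"],
    "Social":  ["humans", "family", "friends"],
    "Humans":  ["humans"],
    "Family":  ["family"],
    "Friends": ["friends"],
    "Drives":  ["achieve", "power"],
    "Achieve": ["achieve"],
    "Power":   ["power"],
    "Work":       ["work"],
    "Leisure":    ["leisure"],
    "Money":      ["money"],
    "Psychology": ["psychology"],
    "Informal": ["assent", "nonfl", "swear"],
    "Assent":   ["assent"],
    "Nonfl":    ["nonfl"],
    "Swear":    ["swear"],
    "Past":    ["past"],
    "Present": ["present"],
    "Future":  ["future"],
    "Relativ": ["motion", "space", "time"],
    "Motion":  ["motion"],
    "Space":   ["space"],
    "Time":    ["time"],
    "Number":  ["number"],
}


def default_lexicon() -> CategoryLexicon:
    """Toy dictionary mirroring the synthetic vocabulary (stems + literals)."""
    cats: dict[str, set[str]] = {}
    for col, leaves in DICTIONARY_LAYOUT.items():
        entries: set[str] = set()
        for leaf in leaves:
            if leaf in _STEM_LEAVES:
                entries.add(f"{leaf}*")
            else:
                entries.update(leaf_pool(leaf))
        cats[col] = entries
    return CategoryLexicon(categories=cats, source="counselhelp-toy",
                           language="synthetic")


# ---------------------------------------------------------------------------
# Language style matching: the 9 function-word categories, as dictionary
# column names.  Personal pronouns enter as the union category Ppron.
# ---------------------------------------------------------------------------

LSM_CATEGORIES = [
    "Preps", "AuxVerb", "Adverb", "Conj", "Article", "Quant", "Negate",
    "Ppron", "Ipron",
]

#: 7-dimension emotion vector column order: overall emotion, positive,
#: negative, anxiety, anger, sadness, love.
EMOTION_CATEGORIES = ["Affect", "PosEmo", "NegEmo", "Anx", "Anger", "Sad",
                      "Love"]

# ---------------------------------------------------------------------------
# Feature type groups (the Table-2-style row labels).
# ---------------------------------------------------------------------------

STYLISTIC_COLUMNS = [
    "WordCount", "SentenceCount", "WordPerSentence", "Period", "Colon",
    "Quote", "Parenth", "OtherP", "RateFourCharWord", "Numerals",
]

TYPE_GROUPS: dict[str, list[str]] = {
    "stylistic": STYLISTIC_COLUMNS[:9] + [
        "Funct", "Article", "AuxVerb", "Adverb", "Conj", "Quant", "Negate",
        "Ipron",
    ],
    "numbers": ["Numerals", "Number"],
    "personal pronouns": ["Ppron", "I", "We", "You"],
    "prepositions": ["Preps"],
    "affective processes": ["Affect", "PosEmo", "NegEmo", "Anx", "Anger",
                            "Sad", "Love"],
    "cognitive processes": ["CogMech", "Insight", "Cause", "Tentat",
                            "Certain", "Inhibition", "Inclusive"],
    "biological processes": ["Bio", "Body", "Health"],
    "perceptual processes": ["Percept", "See", "Hear", "Feel"],
    "social processes": ["Social", "Humans", "Family", "Friends"],
    "drives": ["Drives", "Achieve", "Power"],
    "personal concerns": ["Work", "Leisure", "Money", "Psychology"],
    "informal language": ["Informal", "Assent", "Nonfl", "Swear"],
    "time orientations": ["Past", "Present", "Future"],
    "relativity": ["Relativ", "Motion", "Space", "Time"],
}


def default_group_map() -> dict[str, tuple[str, str]]:
    """Map every feature column to its (source, type) tag.

    Speaker columns are prefixed ``counselee:`` / ``counselor:``; synchrony
    columns ``sync:``.
    """
    base: dict[str, str] = {}
    for type_name, cols in TYPE_GROUPS.items():
        for c in cols:
            base[c] = type_name
    gm: dict[str, tuple[str, str]] = {}
    for col, type_name in base.items():
        gm[f"counselee:{col}"] = ("counselee", type_name)
        gm[f"counselor:{col}"] = ("counselor", type_name)
    gm["sync:SymptomsSIM"] = ("synchrony", "SymptomsSIM")
    gm["sync:FactorsSIM"] = ("synchrony", "FactorsSIM")
    for cat in LSM_CATEGORIES:
        gm[f"sync:LSM_{cat}"] = ("synchrony", "LSM")
    gm["sync:LSM_mean"] = ("synchrony", "LSM")
    gm["sync:AffectSIM"] = ("synchrony", "AffectSIM")
    return gm


# ---------------------------------------------------------------------------
# Topics: 7 symptom + 7 factor pseudo-word pools, with 2 seed words each.
# ---------------------------------------------------------------------------

N_TOPICS = 7
SYMPTOM_TOPIC_NAMES = [
    "depression_anxiety", "suffering", "social_phobia", "lack_of_interest",
    "suicidal_tendency", "worry_afraid", "anger_topic",
]
FACTOR_TOPIC_NAMES = [
    "love_rel", "marriage", "psychotherapy", "work_life", "interpersonal",
    "character", "family_rel",
]
TOPIC_POOL_SIZE = 8


def topic_pool(partition: str, index: int) -> list[str]:
    """Word pool for topic ``index`` (0-based) of ``partition``."""
    tag = {"symptom": "symp", "factor": "fact"}[partition]
    return [f"{tag}{index + 1}w{k:02d}" for k in range(1, TOPIC_POOL_SIZE + 1)]


def topic_lexicons(partition: str) -> dict[str, set[str]]:
    names = SYMPTOM_TOPIC_NAMES if partition == "symptom" else FACTOR_TOPIC_NAMES
    return {nm: set(topic_pool(partition, i)) for i, nm in enumerate(names)}


def topic_seeds(partition: str, n_seeds: int = 2) -> dict[str, list[str]]:
    names = SYMPTOM_TOPIC_NAMES if partition == "symptom" else FACTOR_TOPIC_NAMES
    return {nm: topic_pool(partition, i)[:n_seeds]
            for i, nm in enumerate(names)}


# ---------------------------------------------------------------------------
# Filler vocabulary: absorbs the remaining probability mass.  A mix of
# short and long pseudo-words so length-based stylistic counters vary.
# ---------------------------------------------------------------------------

def filler_pool(n: int = 160) -> list[str]:
    short = [f"w{k}" for k in range(1, n // 2 + 1)]          # len 2-3
    long_ = [f"filler{k:03d}" for k in range(1, n - n // 2 + 1)]
    return short + long_


def synthetic_stopwords() -> set[str]:
    """Stop-word list for the synthetic language: closed-class glue.

    Function words and filler are the synthetic analogue of a natural
    stop-word list; removing them before embedding training (and only
    there) leaves the content vocabulary whose co-occurrence carries
    topic signal.
    """
    words: set[str] = set(filler_pool())
    for leaf in FUNCTION_WORD_LEAVES:
        words.update(leaf_pool(leaf))
    return words
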