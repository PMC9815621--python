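"""Category dictionaries and tokenization.

Psycholinguistic word counting (LIWC-style) rests on two primitives: a
category lexicon mapping named categories to word/stem entry sets, and a
deterministic tokenizer that separates word tokens from punctuation and
marks sentence boundaries.  Both live here; everything downstream
(category proportions, function-word style matching, emotion vectors)
consumes these types.

The on-disk dictionary dialect is the classic ``.dic`` layout::

    %
    1<TAB>NegEmo
    2<TAB>PosEmo
    %
    sad<TAB>1
    happi*<TAB>2

Entries ending in ``*`` are stem patterns matching any token that extends
the stem.  A token may match entries in several categories (LIWC
semantics); matching is case-normalized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence


class LexiconError(ValueError):
    """Malformed dictionary content."""


class TokenizerError(KeyError):
    """Unknown tokenizer id."""


# --------------------------------------------------------------------------
# Category lexicon
# --------------------------------------------------------------------------

@dataclass
class CategoryLexicon:
    """Named categories mapping to entry sets (literals and stem patterns).

    ``categories`` preserves declaration order.  Entries are stored
    lowercase; stem entries keep their single trailing ``*``.
    """

    categories: dict[str, set[str]]
    source: str = ""
    language: str = ""

    def __post_init__(self) -> None:
        for name, entries in self.categories.items():
            if not name:
                raise LexiconError("empty category name")
            for e in entries:
                _validate_entry(e)

    @property
    def names(self) -> list[str]:
        return list(self.categories)

    def __contains__(self, category: str) -> bool:
        return category in self.categories

    def __len__(self) -> int:
        return len(self.categories)

    def matcher(self) -> "LexiconMatcher":
        return LexiconMatcher(self)


def _validate_entry(entry: str) -> None:
    if not entry:
        raise LexiconError("empty lexicon entry")
    stars = entry.count("*")
    if stars > 1 or (stars == 1 and not entry.endswith("*")):
        raise LexiconError(
            f"entry {entry!r}: stem patterns carry exactly one trailing '*'"
        )
    if entry == "*":
        raise LexiconError("bare '*' entry matches everything; not allowed")


class LexiconMatcher:
    """Pre-indexed matcher: literal hash lookup plus per-category stem lists.

    Kept separate from :class:`CategoryLexicon` so the lexicon itself stays a
    plain serializable value object.
    """

    def __init__(self, lexicon: CategoryLexicon) -> None:
        self.lexicon = lexicon
        self._literals: dict[str, dict[str, None]] = {}
        self._stems: dict[str, list[str]] = {}
        self._cache: dict[str, tuple[str, ...]] = {}
        for cat, entries in lexicon.categories.items():
            lits: dict[str, None] = {}
            stems: list[str] = []
            for e in entries:
                if e.endswith("*"):
                    stems.append(e[:-1])
                else:
                    lits[e] = None
            self._literals[cat] = lits
            self._stems[cat] = stems

    def match(self, token: str, category: str) -> bool:
        if category not in self._literals:
            raise LexiconError(f"unknown category {category!r}")
        t = token.lower()
        if t in self._literals[category]:
            return True
        return any(t.startswith(s) for s in self._stems[category])

    def categories_of(self, token: str) -> tuple[str, ...]:
        t = token.lower()
        hit = self._cache.get(t)
        if hit is None:
            hit = tuple(
                cat for cat in self.lexicon.categories
                if t in self._literals[cat]
                or any(t.startswith(s) for s in self._stems[cat])
            )
            self._cache[t] = hit
        return hit


def match_category(token: str, lexicon: CategoryLexicon, category: str) -> bool:
    """True iff ``token`` equals a literal entry or extends a stem entry."""
    return lexicon.matcher().match(token, category)


# --------------------------------------------------------------------------
# .dic dialect parsing / serialization
# --------------------------------------------------------------------------

def parse_dictionary(source: str | Path) -> CategoryLexicon:
    """Parse a LIWC-``.dic``-dialect dictionary from a path or literal text.

    Raises :class:`LexiconError` on duplicate category ids/names or on an
    entry referencing an undeclared category id.
    """
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
        name = source.name
    else:
        p = Path(source)
        # Heuristic: a short, existing path is a file; otherwise literal text.
        if "\n" not in source and p.is_file():
            text = p.read_text(encoding="utf-8")
            name = p.name
        else:
            text = source
            name = "<string>"
    if not text.strip():
        raise LexiconError("empty dictionary source")

    lines = text.splitlines()
    # Split on '%' delimiter lines: header is between the first two.
    delim = [i for i, ln in enumerate(lines) if ln.strip() == "%"]
    if len(delim) < 2:
        raise LexiconError("missing '%' header delimiters")
    header = lines[delim[0] + 1 : delim[1]]
    body = lines[delim[1] + 1 :]

    id_to_name: dict[str, str] = {}
    categories: dict[str, set[str]] = {}
    for ln in header:
        if not ln.strip():
            continue
        parts = re.split(r"\t+|\s{2,}", ln.strip())
        if len(parts) != 2:
            raise LexiconError(f"malformed header line: {ln!r}")
        cid, cname = parts
        if cid in id_to_name:
            raise LexiconError(f"duplicate category id {cid!r}")
        if cname in categories:
            raise LexiconError(f"duplicate category name {cname!r}")
        id_to_name[cid] = cname
        categories[cname] = set()

    for ln in body:
        if not ln.strip():
            continue
        parts = re.split(r"\t+|\s{2,}", ln.strip())
        if len(parts) < 2:
            raise LexiconError(f"malformed entry line: {ln!r}")
        word = parts[0].lower()
        _validate_entry(word)
        ids: list[str] = []
        for tok in parts[1:]:
            ids.extend(x for x in tok.split(",") if x)
        for cid in ids:
            if cid not in id_to_name:
                raise LexiconError(
                    f"entry {word!r} references undeclared category id {cid!r}"
                )
            categories[id_to_name[cid]].add(word)
    return CategoryLexicon(categories=categories, source=name)


def serialize_dictionary(lexicon: CategoryLexicon) -> str:
    """Render a lexicon back to the ``.dic`` dialect (inverse of parsing)."""
    names = lexicon.names
    ids = {name: str(i + 1) for i, name in enumerate(names)}
    out = ["%"]
    out += [f"{ids[n]}\t{n}" for n in names]
    out.append("%")
    word_ids: dict[str, list[str]] = {}
    for n in names:
        for w in sorted(lexicon.categories[n]):
            word_ids.setdefault(w, []).append(ids[n])
    for w in sorted(word_ids):
        out.append(f"{w}\t{','.join(word_ids[w])}")
    return "\n".join(out) + "\n"


def read_stopwords(path: str | Path) -> set[str]:
    """One word per line; blank lines and '#' comments ignored."""
    words = set()
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        w = ln.strip().lower()
        if w and not w.startswith("#"):
            words.add(w)
    return words


# --------------------------------------------------------------------------
# Tokenization
# --------------------------------------------------------------------------

#: Punctuation that terminates a sentence.
SENTENCE_TERMINALS = {".", "!", "?"}

_TOKEN_RE = re.compile(r"[A-Za-z0-9_']+|[^\sA-Za-z0-9_']", re.UNICODE)


@dataclass
class TokenSequence:
    """Word tokens with punctuation routed to a parallel stream.

    ``sentence_boundaries`` holds, for each sentence, the index into
    ``tokens`` one past its last word token.  A trailing run of words with
    no terminal punctuation counts as a final sentence.
    """

    tokens: list[str] = field(default_factory=list)
    punctuation_marks: list[str] = field(default_factory=list)
    sentence_boundaries: list[int] = field(default_factory=list)

    @property
    def n_words(self) -> int:
        return len(self.tokens)

    @property
    def n_sentences(self) -> int:
        return len(self.sentence_boundaries)


def _simple_tokenize(raw: str) -> TokenSequence:
    tokens: list[str] = []
    punct: list[str] = []
    boundaries: list[int] = []
    words_since_boundary = 0
    for m in _TOKEN_RE.finditer(raw):
        sym = m.group(0)
        if sym[0].isalnum() or sym[0] in "_'":
            tokens.append(sym.lower())
            words_since_boundary += 1
        else:
            punct.append(sym)
            if sym in SENTENCE_TERMINALS and words_since_boundary > 0:
                boundaries.append(len(tokens))
                words_since_boundary = 0
    if words_since_boundary > 0:
        boundaries.append(len(tokens))
    return TokenSequence(tokens, punct, boundaries)


_TOKENIZERS: dict[str, Callable[[str], TokenSequence]] = {
    "simple": _simple_tokenize,
}


def register_tokenizer(name: str, fn: Callable[[str], TokenSequence]) -> None:
    _TOKENIZERS[name] = fn


def tokenize(raw: str, tokenizer_id: str = "simple") -> TokenSequence:
    """Tokenize ``raw`` with a registered tokenizer (default whitespace/punct).

    Deterministic; punctuation symbols go to ``punctuation_marks`` and
    sentence boundaries are recorded at terminal punctuation.
    """
    try:
        fn = _TOKENIZERS[tokenizer_id]
    except KeyError:
        raise TokenizerError(
            f"unknown tokenizer {tokenizer_id!r}; registered: "
            f"{sorted(_TOKENIZERS)}"
        ) from None
    return fn(raw)
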