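"""Token normalisation chain for title and abstract text.

The chain that feeds the bag-of-words encoder is, in order:

1. rule-based tokenisation (whitespace + punctuation boundaries, keeping
   hyphenated terms and decimal numbers whole);
2. masking of chemical mentions with a single ``@CHEM`` token, so the
   classifier cannot key on specific drug names;
3. lower-casing, stripping punctuation characters inside tokens,
   replacing all-digit tokens with ``##``, stop-word removal, and
   Porter stemming.

The tokeniser and the chemical recogniser are pluggable; the defaults
shipped here are a documented rule set and a dictionary masker over a
plain-text lexicon, both fully deterministic.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .porter import porter_stem

CHEM_MASK = "@CHEM"
DIGIT_MASK = "##"

#: Tokens exempt from every normalisation stage.
PROTECTED_TOKENS = frozenset({CHEM_MASK, DIGIT_MASK})

# A token is: a number possibly containing internal . or , digit groups,
# or a word possibly joined by internal hyphens, or any single
# non-space character (punctuation stands alone).
_TOKEN_RE = re.compile(r"\d+(?:[.,]\d+)+|\w+(?:-\w+)*|\S", re.UNICODE)

_ALL_DIGIT_RE = re.compile(r"\d+$")


@dataclass(frozen=True)
class TokenSequence:
    """Ordered tokens of one text field (title or abstract)."""

    field_name: str
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(t == "" for t in self.tokens):
            raise ValueError("TokenSequence must not contain empty tokens")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class EntitySpanSet:
    """Non-overlapping (start, end) token-index spans, ends inclusive."""

    spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in sorted(self.spans):
            if end < start:
                raise ValueError(f"span ({start},{end}) has end < start")
            if start <= prev_end:
                raise ValueError("spans overlap")
            prev_end = end

    def validate_for(self, seq: TokenSequence) -> None:
        for start, end in self.spans:
            if start < 0 or end >= len(seq):
                raise ValueError(f"span ({start},{end}) out of bounds for {len(seq)} tokens")


def tokenize_field(text: str, field_name: str = "title") -> TokenSequence:
    """Split raw field text into tokens with the default rule set.

    Hyphenated terms ("half-life") and decimal numbers ("5.2") stay
    whole; other punctuation becomes single-character tokens.
    """
    return TokenSequence(field_name, tuple(_TOKEN_RE.findall(text)))


def mask_entities(
    seq: TokenSequence, spans: EntitySpanSet, mask: str = CHEM_MASK
) -> TokenSequence:
    """Replace each entity span by exactly one mask token."""
    spans.validate_for(seq)
    starts = {s: e for s, e in spans.spans}
    out: list[str] = []
    i = 0
    while i < len(seq):
        if i in starts:
            out.append(mask)
            i = starts[i] + 1
        else:
            out.append(seq.tokens[i])
            i += 1
    return TokenSequence(seq.field_name, tuple(out))


def _is_punct_char(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P") or ch in "$+<=>^`|~"


def _strip_punct(token: str) -> str:
    return "".join(ch for ch in token if not _is_punct_char(ch))


def load_stopwords() -> frozenset[str]:
    """The frozen English stop-word list shipped with the package."""
    text = resources.files("pktriage.data").joinpath("stopwords.txt").read_text()
    return frozenset(w for w in text.split() if w)


def normalize_tokens(
    seq: TokenSequence,
    stopwords: Iterable[str] | None = None,
    *,
    stem: bool = True,
    collapse_digits: bool = True,
) -> TokenSequence:
    """Lower-case, strip punctuation, collapse digits, drop stop-words, stem.

    Stages run in exactly that order; the digit test applies after
    punctuation stripping, so "3.5" -> "35" -> "##".  Mask tokens
    (``@CHEM``, ``##``) pass through unchanged.
    """
    stop = frozenset(stopwords) if stopwords is not None else load_stopwords()
    out: list[str] = []
    for tok in seq.tokens:
        if tok in PROTECTED_TOKENS:
            out.append(tok)
            continue
        tok = tok.lower()
        tok = _strip_punct(tok)
        if not tok:
            continue
        if collapse_digits and _ALL_DIGIT_RE.fullmatch(tok):
            out.append(DIGIT_MASK)
            continue
        if tok in stop:
            continue
        out.append(porter_stem(tok) if stem else tok)
    return TokenSequence(seq.field_name, tuple(out))


# ---------------------------------------------------------------------------
# Chemical-mention detection (dictionary masker)

class DictionaryMasker:
    """Deterministic dictionary-based chemical recogniser.

    Matches case-insensitively against a lexicon of (possibly
    multi-word) chemical names, preferring the longest match at each
    position.  Stands behind the same span contract an external NER
    adapter would implement.
    """

    def __init__(self, lexicon: Iterable[str] | None = None):
        if lexicon is None:
            lexicon = load_chemical_lexicon()
        self._entries: dict[tuple[str, ...], None] = {}
        for name in lexicon:
            parts = tuple(name.lower().split())
            if parts:
                self._entries[parts] = None
        self._max_len = max((len(p) for p in self._entries), default=0)

    def __call__(self, seq: TokenSequence) -> EntitySpanSet:
        lowered = [t.lower() for t in seq.tokens]
        spans: list[tuple[int, int]] = []
        i = 0
        n = len(lowered)
        while i < n:
            matched = 0
            for width in range(min(self._max_len, n - i), 0, -1):
                if tuple(lowered[i : i + width]) in self._entries:
                    matched = width
                    break
            if matched:
                spans.append((i, i + matched - 1))
                i += matched
            else:
                i += 1
        return EntitySpanSet(tuple(spans))


def load_chemical_lexicon() -> list[str]:
    text = resources.files("pktriage.data").joinpath("chemical_lexicon.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def detect_chemicals(
    seq: TokenSequence, masker: Callable[[TokenSequence], EntitySpanSet] | None = None
) -> EntitySpanSet:
    """Locate chemical mentions with the configured masker (default: dictionary)."""
    if masker is None:
        masker = DictionaryMasker()
    return masker(seq)


# ---------------------------------------------------------------------------
# The full chain, as one configurable callable

@dataclass
class TextPreprocessor:
    """Tokenise -> mask chemicals -> normalise, for one text field.

    Parameters
    ----------
    mask_chemicals:
        Apply the chemical masker before normalisation (masking operates
        on raw surface forms, so it precedes stemming).
    stem, collapse_digits:
        Toggle the corresponding normalisation stages.
    """

    mask_chemicals: bool = True
    stem: bool = True
    collapse_digits: bool = True
    stopwords: frozenset[str] = field(default_factory=load_stopwords)
    masker: Callable[[TokenSequence], EntitySpanSet] | None = None
    tokenizer: Callable[[str, str], TokenSequence] = tokenize_field

    def __post_init__(self) -> None:
        if self.masker is None and self.mask_chemicals:
            self.masker = DictionaryMasker()

    def __call__(self, text: str, field_name: str = "title") -> list[str]:
        seq = self.tokenizer(text, field_name)
        if self.mask_chemicals and self.masker is not None and len(seq):
            seq = mask_entities(seq, self.masker(seq))
        seq = normalize_tokens(
            seq, self.stopwords, stem=self.stem, collapse_digits=self.collapse_digits
        )
        return list(seq.tokens)
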