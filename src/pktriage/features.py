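"""Field-selected, n-gram-augmented bag-of-words document encoding.

Documents are encoded over a vocabulary built from a configurable set of
fields: title/abstract text runs through the normalisation chain of
:mod:`pktriage.preprocess` (optionally expanded with bigrams/trigrams),
while metadata fields contribute single namespaced terms such as
``publication_type=Review`` with no further processing.  Terms must
appear in at least ``min_df`` documents to enter the vocabulary, and
each document vector is divided by its total in-vocabulary term count
(L1 norm).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import DocumentRecord
from .preprocess import TextPreprocessor

NGRAM_JOIN = "_"
NAMESPACE_SEP = "="

TEXT_FIELDS = ("title", "abstract")

#: singular namespace key used for each metadata list/scalar field
METADATA_FIELDS = {
    "authors": "author",
    "journal": "journal",
    "publication_types": "publication_type",
    "keywords": "keyword",
    "mesh_terms": "mesh_term",
    "chemicals": "chemical",
    "affiliations": "affiliation",
}

#: the best-performing field combination: title, abstract, MeSH terms
#: and publication type.
OPTIMAL_FIELDS = ("title", "abstract", "mesh_terms", "publication_types")

ALL_FIELDS = TEXT_FIELDS + tuple(METADATA_FIELDS)


def make_ngrams(tokens: Sequence[str], n: int) -> list[str]:
    """Join every window of ``n`` consecutive tokens with ``_``."""
    if n < 1:
        raise ValueError("n-gram order must be >= 1")
    if n == 1:
        return list(tokens)
    return [NGRAM_JOIN.join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


def field_terms(record: DocumentRecord, field: str) -> list[str]:
    """Metadata field values as single namespaced terms, unprocessed."""
    if field not in METADATA_FIELDS:
        raise ValueError(
            f"unknown metadata field {field!r}; expected one of {sorted(METADATA_FIELDS)}"
        )
    ns = METADATA_FIELDS[field]
    value = getattr(record, field)
    values = [value] if isinstance(value, str) else list(value)
    return [f"{ns}{NAMESPACE_SEP}{v}" for v in values if v]


def document_terms(
    record: DocumentRecord,
    fields: Sequence[str],
    ngram_orders: Sequence[int],
    preprocessor: TextPreprocessor,
) -> list[str]:
    """All BoW terms of one document for the given field selection.

    N-grams are generated from the normalised title/abstract tokens only;
    metadata fields always contribute unigram terms.
    """
    terms: list[str] = []
    for fname in fields:
        if fname in TEXT_FIELDS:
            tokens = preprocessor(getattr(record, fname), fname)
            for n in sorted(set(ngram_orders)):
                terms.extend(make_ngrams(tokens, n))
        else:
            terms.extend(field_terms(record, fname))
    return terms


@dataclass
class Vocabulary:
    """Dense term -> column map with per-term document frequencies."""

    term_index: dict[str, int]
    doc_freq: dict[str, int]
    min_df: int
    fields_included: tuple[str, ...]
    ngram_orders: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.term_index)

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# min_df={self.min_df}\n")
            fh.write(f"# fields={','.join(self.fields_included)}\n")
            fh.write(f"# ngram_orders={','.join(map(str, self.ngram_orders))}\n")
            for term, idx in sorted(self.term_index.items(), key=lambda kv: kv[1]):
                fh.write(f"{term}\t{idx}\t{self.doc_freq[term]}\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "Vocabulary":
        meta = {}
        term_index: dict[str, int] = {}
        doc_freq: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                # metadata lines are "# key=value"; note the term "##"
                # itself legitimately starts a data line
                if line.startswith("# "):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key] = val
                    continue
                term, idx, df = line.split("\t")
                term_index[term] = int(idx)
                doc_freq[term] = int(df)
        return cls(
            term_index=term_index,
            doc_freq=doc_freq,
            min_df=int(meta.get("min_df", 1)),
            fields_included=tuple(f for f in meta.get("fields", "").split(",") if f),
            ngram_orders=tuple(int(n) for n in meta.get("ngram_orders", "1").split(",") if n),
        )


def build_vocabulary(
    docs_terms: Sequence[Sequence[str]],
    min_df: int = 1,
    fields_included: Sequence[str] = OPTIMAL_FIELDS,
    ngram_orders: Sequence[int] = (1,),
) -> Vocabulary:
    """Build a vocabulary keeping terms present in >= ``min_df`` documents.

    Column order is lexicographic, so the layout is deterministic.
    """
    if not docs_terms:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    df: dict[str, int] = {}
    for terms in docs_terms:
        for term in set(terms):
            df[term] = df.get(term, 0) + 1
    kept = sorted(t for t, c in df.items() if c >= min_df)
    if not kept:
        raise ValueError(
            f"vocabulary is empty at min_df={min_df}; lower min_df or enlarge the corpus"
        )
    return Vocabulary(
        term_index={t: i for i, t in enumerate(kept)},
        doc_freq={t: df[t] for t in kept},
        min_df=min_df,
        fields_included=tuple(fields_included),
        ngram_orders=tuple(ngram_orders),
    )


def encode_bow(docs_terms: Sequence[Sequence[str]], vocab: Vocabulary) -> sp.csr_matrix:
    """Sparse count matrix over the vocabulary, L1-normalised per row.

    Each cell holds count/T, with T the document's total number of
    in-vocabulary term occurrences; documents with T=0 yield zero rows.
    """
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for terms in docs_terms:
        counts: dict[int, int] = {}
        for term in terms:
            j = vocab.term_index.get(term)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        total = sum(counts.values())
        for j in sorted(counts):
            indices.append(j)
            data.append(counts[j] / total)
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.int64), np.asarray(indptr, dtype=np.int64)),
        shape=(len(docs_terms), len(vocab)),
    )


class BowVectorizer(TransformerMixin, BaseEstimator):
    """Bag-of-words document vectoriser over a configurable field set.

    Parameters
    ----------
    fields : sequence of str, default OPTIMAL_FIELDS
        Fields to encode. Title/abstract pass through the token
        normalisation chain; metadata fields become single namespaced
        terms.
    ngram_orders : sequence of int, default (1,)
        Which n-gram orders to generate from the normalised text tokens.
    min_df : int, default 20
        Minimum number of documents a term must occur in.
    mask_chemicals, stem, collapse_digits : bool
        Stages of the normalisation chain.

    Attributes
    ----------
    vocabulary_ : Vocabulary
        Fitted term -> column map (lexicographic, dense).
    """

    def __init__(
        self,
        fields: Sequence[str] = OPTIMAL_FIELDS,
        ngram_orders: Sequence[int] = (1,),
        min_df: int = 20,
        mask_chemicals: bool = True,
        stem: bool = True,
        collapse_digits: bool = True,
    ):
        self.fields = fields
        self.ngram_orders = ngram_orders
        self.min_df = min_df
        self.mask_chemicals = mask_chemicals
        self.stem = stem
        self.collapse_digits = collapse_digits

    def _validate(self) -> None:
        for f in self.fields:
            if f not in ALL_FIELDS:
                raise ValueError(f"unknown field {f!r}; expected one of {ALL_FIELDS}")
        if any(n not in (1, 2, 3) for n in self.ngram_orders):
            raise ValueError("ngram_orders must be drawn from {1, 2, 3}")

    def _preprocessor(self) -> TextPreprocessor:
        return TextPreprocessor(
            mask_chemicals=self.mask_chemicals,
            stem=self.stem,
            collapse_digits=self.collapse_digits,
        )

    def _terms(self, records: Sequence[DocumentRecord]) -> list[list[str]]:
        prep = self._preprocessor()
        return [
            document_terms(r, tuple(self.fields), tuple(self.ngram_orders), prep)
            for r in records
        ]

    def fit(self, records: Sequence[DocumentRecord], y=None) -> "BowVectorizer":
        self._validate()
        self.vocabulary_ = build_vocabulary(
            self._terms(records),
            min_df=self.min_df,
            fields_included=tuple(self.fields),
            ngram_orders=tuple(self.ngram_orders),
        )
        return self

    def transform(self, records: Sequence[DocumentRecord]) -> sp.csr_matrix:
        if not hasattr(self, "vocabulary_"):
            raise ValueError("BowVectorizer is not fitted; call fit first")
        return encode_bow(self._terms(records), self.vocabulary_)

    def fit_transform(self, records: Sequence[DocumentRecord], y=None) -> sp.csr_matrix:
        self._validate()
        terms = self._terms(records)
        self.vocabulary_ = build_vocabulary(
            terms,
            min_df=self.min_df,
            fields_included=tuple(self.fields),
            ngram_orders=tuple(self.ngram_orders),
        )
        return encode_bow(terms, self.vocabulary_)
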