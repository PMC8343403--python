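"""Pluggable embedding providers and pooling into fixed-length blocks.

Token-level providers return one d-dimensional vector per token of a
field, defined as the element-wise sum of the encoder's last four hidden
layers; document-level providers return a single vector per document.
Two pooling compositions turn variable-length token sets into
fixed-length document blocks:

* ``mean``: per-field token mean, title and abstract concatenated (2d);
* ``mean_minmax``: per-field mean, element-wise min and max concatenated
  (6d).

Real transformer encoders (e.g. a biomedical BERT for token vectors, or
a citation-trained document encoder) plug in behind the provider
contract; the package ships a deterministic hashing stub so every stage
is testable without downloading weights.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import DocumentRecord
from .preprocess import tokenize_field

POOL_MODES = ("mean", "mean_minmax", "doc_level")


@dataclass(frozen=True)
class EmbeddingSet:
    """T x d matrix of per-token vectors for one field."""

    field_name: str
    matrix: np.ndarray  # shape (T, d); T may be 0

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2:
            raise ValueError("EmbeddingSet matrix must be 2-D (T tokens x d dims)")
        if m.size and not np.all(np.isfinite(m)):
            raise ValueError("EmbeddingSet entries must be finite")

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class PooledRepresentation:
    """Fixed-length pooled document vector with its pooling mode."""

    vector: np.ndarray
    mode: str

    @property
    def dimension(self) -> int:
        return self.vector.shape[0]


class EmbeddingProvider(Protocol):
    """Contract every embedding adapter implements."""

    kind: str  # "token_level" | "document_level"
    dimension: int

    def embed_tokens(self, tokens: Sequence[str], field_name: str) -> EmbeddingSet: ...

    def embed_document(self, record: DocumentRecord) -> np.ndarray: ...


def _token_seed(token: str, dimension: int, salt: int) -> int:
    digest = hashlib.sha256(f"{salt}|{dimension}|{token}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


# token vectors are pure functions of (token, dimension, seed); a shared
# process-wide cache keeps repeated corpus encodings cheap
_VECTOR_CACHE: dict[tuple[str, int, int], np.ndarray] = {}


class HashingTokenEmbedder:
    """Deterministic token-level stub provider.

    Each token's vector is drawn from a normal distribution seeded by a
    hash of (token string, dimension, seed), so identical corpora give
    identical matrices and the vector depends only on the surface form.
    """

    kind = "token_level"

    def __init__(self, dimension: int = 768, seed: int = 0):
        self.dimension = dimension
        self.seed = seed

    def _vector(self, token: str) -> np.ndarray:
        key = (token, self.dimension, self.seed)
        vec = _VECTOR_CACHE.get(key)
        if vec is None:
            rng = np.random.RandomState(_token_seed(token, self.dimension, self.seed))
            vec = rng.normal(size=self.dimension)
            _VECTOR_CACHE[key] = vec
        return vec

    def embed_tokens(self, tokens: Sequence[str], field_name: str) -> EmbeddingSet:
        if not tokens:
            return EmbeddingSet(field_name, np.empty((0, self.dimension)))
        return EmbeddingSet(field_name, np.vstack([self._vector(t) for t in tokens]))

    def embed_document(self, record: DocumentRecord) -> np.ndarray:
        raise TypeError("token-level provider has no document-level embedding")


class HashingDocumentEmbedder:
    """Deterministic document-level stub provider (one vector per record)."""

    kind = "document_level"

    def __init__(self, dimension: int = 768, seed: int = 0):
        self.dimension = dimension
        self.seed = seed

    def embed_tokens(self, tokens: Sequence[str], field_name: str) -> EmbeddingSet:
        raise TypeError("document-level provider has no token-level embeddings")

    def embed_document(self, record: DocumentRecord) -> np.ndarray:
        text = f"{record.title}\n{record.abstract}"
        rng = np.random.RandomState(_token_seed(text, self.dimension, self.seed))
        return rng.normal(size=self.dimension)


# ---------------------------------------------------------------------------
# Pooling

def _field_stats(es: EmbeddingSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = es.dimension
    if es.matrix.shape[0] == 0:
        z = np.zeros(d)
        return z, z.copy(), z.copy()
    return es.matrix.mean(axis=0), es.matrix.min(axis=0), es.matrix.max(axis=0)


def pool_mean(title: EmbeddingSet, abstract: EmbeddingSet) -> PooledRepresentation:
    """Concatenate per-field token means -> 2d vector; empty field -> zeros."""
    if title.dimension != abstract.dimension:
        raise ValueError(
            f"dimension mismatch: title d={title.dimension}, abstract d={abstract.dimension}"
        )
    t_mean, _, _ = _field_stats(title)
    a_mean, _, _ = _field_stats(abstract)
    return PooledRepresentation(np.concatenate([t_mean, a_mean]), "mean")


def pool_mean_minmax(title: EmbeddingSet, abstract: EmbeddingSet) -> PooledRepresentation:
    """Per field concat(mean, min, max); fields concatenated -> 6d vector."""
    if title.dimension != abstract.dimension:
        raise ValueError(
            f"dimension mismatch: title d={title.dimension}, abstract d={abstract.dimension}"
        )
    blocks = []
    for es in (title, abstract):
        mean, mn, mx = _field_stats(es)
        blocks.extend([mean, mn, mx])
    return PooledRepresentation(np.concatenate(blocks), "mean_minmax")


def embed_document(
    record: DocumentRecord, provider: EmbeddingProvider, mode: str = "mean"
) -> PooledRepresentation:
    """Pooled dense representation of one record.

    Token-level providers embed the raw tokenised (un-stemmed, un-masked)
    title and abstract and pool per ``mode``; document-level providers
    return their single vector (mode must be ``doc_level``).
    """
    if mode not in POOL_MODES:
        raise ValueError(f"unknown pooling mode {mode!r}; expected one of {POOL_MODES}")
    if provider.kind == "document_level":
        if mode != "doc_level":
            raise ValueError("document-level providers only support mode='doc_level'")
        return PooledRepresentation(provider.embed_document(record), "doc_level")
    if mode == "doc_level":
        raise ValueError("mode 'doc_level' requires a document-level provider")
    title = provider.embed_tokens(tokenize_field(record.title, "title").tokens, "title")
    abstract = provider.embed_tokens(
        tokenize_field(record.abstract, "abstract").tokens, "abstract"
    )
    if mode == "mean":
        return pool_mean(title, abstract)
    return pool_mean_minmax(title, abstract)


def concat_blocks(bow_row: sp.spmatrix, pooled: PooledRepresentation) -> sp.csr_matrix:
    """Sparse BoW block followed by the dense pooled block (one document)."""
    dense = sp.csr_matrix(pooled.vector[None, :])
    return sp.hstack([sp.csr_matrix(bow_row), dense], format="csr")


class EmbeddingPooler(TransformerMixin, BaseEstimator):
    """Transformer producing the pooled dense block for a record list.

    Parameters
    ----------
    provider : EmbeddingProvider or None
        Defaults to the deterministic hashing stub at d=768.
    mode : {"mean", "mean_minmax", "doc_level"}
    """

    def __init__(self, provider: EmbeddingProvider | None = None, mode: str = "mean"):
        self.provider = provider
        self.mode = mode

    def _resolved_provider(self) -> EmbeddingProvider:
        if self.provider is not None:
            return self.provider
        if self.mode == "doc_level":
            return HashingDocumentEmbedder()
        return HashingTokenEmbedder()

    def fit(self, records: Sequence[DocumentRecord], y=None) -> "EmbeddingPooler":
        provider = self._resolved_provider()
        if self.mode == "doc_level":
            self.dimension_ = provider.dimension
        elif self.mode == "mean":
            self.dimension_ = 2 * provider.dimension
        elif self.mode == "mean_minmax":
            self.dimension_ = 6 * provider.dimension
        else:
            raise ValueError(f"unknown pooling mode {self.mode!r}")
        return self

    def transform(self, records: Sequence[DocumentRecord]) -> np.ndarray:
        if not hasattr(self, "dimension_"):
            self.fit(records)
        provider = self._resolved_provider()
        if not records:
            return np.empty((0, self.dimension_))
        return np.vstack(
            [embed_document(r, provider, self.mode).vector for r in records]
        )
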