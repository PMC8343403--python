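"""End-to-end document triage: vectoriser + boosted classifier.

``DocumentVectorizer`` concatenates the sparse L1-normalised BoW block
with an optional dense pooled-embedding block; ``TriagePipeline`` fits
that representation together with the class-weighted boosted ensemble,
using a held-out dev set for F1 early stopping.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import scipy.sparse as sp
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .classifier import GradientBoostedTriage, _as_binary
from .corpus import DocumentRecord, RELEVANT, NOT_RELEVANT
from .embeddings import EmbeddingPooler, EmbeddingProvider
from .features import BowVectorizer, OPTIMAL_FIELDS, Vocabulary


class DocumentVectorizer(TransformerMixin, BaseEstimator):
    """BoW block, optionally concatenated with a pooled embedding block.

    Column layout: the V vocabulary columns first (lexicographic), then
    the pooled block, so column V+k is pooled entry k.
    """

    def __init__(
        self,
        fields: Sequence[str] = OPTIMAL_FIELDS,
        ngram_orders: Sequence[int] = (1,),
        min_df: int = 20,
        mask_chemicals: bool = True,
        embedding_mode: str | None = None,
        embedding_provider: EmbeddingProvider | None = None,
    ):
        self.fields = fields
        self.ngram_orders = ngram_orders
        self.min_df = min_df
        self.mask_chemicals = mask_chemicals
        self.embedding_mode = embedding_mode
        self.embedding_provider = embedding_provider

    def _make_parts(self):
        bow = BowVectorizer(
            fields=self.fields,
            ngram_orders=self.ngram_orders,
            min_df=self.min_df,
            mask_chemicals=self.mask_chemicals,
        )
        pooler = None
        if self.embedding_mode is not None:
            pooler = EmbeddingPooler(
                provider=self.embedding_provider, mode=self.embedding_mode
            )
        return bow, pooler

    def fit(self, records: Sequence[DocumentRecord], y=None) -> "DocumentVectorizer":
        self.bow_, self.pooler_ = self._make_parts()
        self.bow_.fit(records)
        if self.pooler_ is not None:
            self.pooler_.fit(records)
        return self

    def transform(self, records: Sequence[DocumentRecord]) -> sp.csr_matrix:
        X = self.bow_.transform(records)
        if self.pooler_ is not None:
            dense = self.pooler_.transform(records)
            X = sp.hstack([X, sp.csr_matrix(dense)], format="csr")
        return sp.csr_matrix(X)

    @property
    def vocabulary_(self):
        return self.bow_.vocabulary_


class TriagePipeline(ClassifierMixin, BaseEstimator):
    """Fitted vocabulary + preprocessing + boosted ensemble + threshold.

    ``fit`` takes training records/labels plus a dev split used only for
    early stopping.  Prediction returns canonical label strings;
    ``predict_proba`` the probability of the Relevant class.
    """

    def __init__(
        self,
        fields: Sequence[str] = OPTIMAL_FIELDS,
        ngram_orders: Sequence[int] = (1,),
        min_df: int = 20,
        mask_chemicals: bool = True,
        embedding_mode: str | None = None,
        embedding_provider: EmbeddingProvider | None = None,
        learning_rate: float = 0.1,
        n_estimators: int = 2000,
        patience: int = 100,
        max_depth: int = 4,
        colsample_bytree: float = 1.0,
        class_weighting: bool = True,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.fields = fields
        self.ngram_orders = ngram_orders
        self.min_df = min_df
        self.mask_chemicals = mask_chemicals
        self.embedding_mode = embedding_mode
        self.embedding_provider = embedding_provider
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.patience = patience
        self.max_depth = max_depth
        self.colsample_bytree = colsample_bytree
        self.class_weighting = class_weighting
        self.threshold = threshold
        self.random_state = random_state

    def fit(
        self,
        records: Sequence[DocumentRecord],
        y,
        dev_records: Sequence[DocumentRecord] | None = None,
        dev_y=None,
    ) -> "TriagePipeline":
        self.vectorizer_ = DocumentVectorizer(
            fields=self.fields,
            ngram_orders=self.ngram_orders,
            min_df=self.min_df,
            mask_chemicals=self.mask_chemicals,
            embedding_mode=self.embedding_mode,
            embedding_provider=self.embedding_provider,
        )
        X = self.vectorizer_.fit(records).transform(records)
        self.classifier_ = GradientBoostedTriage(
            learning_rate=self.learning_rate,
            n_estimators=self.n_estimators,
            patience=self.patience,
            max_depth=self.max_depth,
            colsample_bytree=self.colsample_bytree,
            class_weighting=self.class_weighting,
            threshold=self.threshold,
            random_state=self.random_state,
        )
        eval_set = None
        if dev_records is not None:
            X_dev = self.vectorizer_.transform(dev_records)
            eval_set = (X_dev, _as_binary(dev_y))
        self.classifier_.fit(X, _as_binary(y), eval_set=eval_set)
        self.classes_ = np.array([NOT_RELEVANT, RELEVANT])
        return self

    def predict_proba(self, records: Sequence[DocumentRecord]) -> np.ndarray:
        X = self.vectorizer_.transform(records)
        return self.classifier_.predict_proba(X)

    def predict(self, records: Sequence[DocumentRecord]) -> np.ndarray:
        proba = self.predict_proba(records)[:, 1]
        return np.where(proba >= self.threshold, RELEVANT, NOT_RELEVANT)


# ---------------------------------------------------------------------------
# Persistence: booster in the engine's native format + vocabulary sidecar +
# a JSON manifest holding the preprocessing/classifier configuration.

def save_pipeline(pipe: TriagePipeline, directory: Union[str, Path]) -> None:
    """Persist a fitted pipeline (booster, vocabulary, config manifest)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pipe.classifier_.booster_.save_model(str(directory / "booster.json"))
    pipe.vectorizer_.vocabulary_.save(directory / "vocabulary.txt")
    config = {
        k: v for k, v in pipe.get_params().items() if k != "embedding_provider"
    }
    config["fields"] = list(config["fields"])
    config["ngram_orders"] = list(config["ngram_orders"])
    manifest = {
        "config": config,
        "best_iteration": pipe.classifier_.best_iteration_,
        "n_features": pipe.classifier_.n_features_in_,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_pipeline(directory: Union[str, Path]) -> TriagePipeline:
    """Reconstruct a pipeline saved by :func:`save_pipeline`.

    Custom embedding providers are not persisted; the default hashing
    provider is reconstructed for embedding modes.
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = dict(manifest["config"])
    config["fields"] = tuple(config["fields"])
    config["ngram_orders"] = tuple(config["ngram_orders"])
    pipe = TriagePipeline(**config)

    pipe.vectorizer_ = DocumentVectorizer(
        fields=config["fields"],
        ngram_orders=config["ngram_orders"],
        min_df=config["min_df"],
        mask_chemicals=config["mask_chemicals"],
        embedding_mode=config["embedding_mode"],
    )
    bow, pooler = pipe.vectorizer_._make_parts()
    bow.vocabulary_ = Vocabulary.load(directory / "vocabulary.txt")
    if pooler is not None:
        pooler.fit([])
    pipe.vectorizer_.bow_ = bow
    pipe.vectorizer_.pooler_ = pooler

    clf = GradientBoostedTriage(
        learning_rate=config["learning_rate"],
        n_estimators=config["n_estimators"],
        patience=config["patience"],
        max_depth=config["max_depth"],
        colsample_bytree=config["colsample_bytree"],
        class_weighting=config["class_weighting"],
        threshold=config["threshold"],
        random_state=config["random_state"],
    )
    clf.booster_ = xgb.Booster()
    clf.booster_.load_model(str(directory / "booster.json"))
    clf.best_iteration_ = manifest["best_iteration"]
    clf.n_features_in_ = manifest["n_features"]
    clf.classes_ = np.array([0, 1])
    pipe.classifier_ = clf
    pipe.classes_ = np.array([NOT_RELEVANT, RELEVANT])
    return pipe
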