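"""Metrics, inter-annotator agreement, bootstrap comparison and CV tuning.

Pipeline configurations are compared by repeatedly (default 200 times)
splitting the labelled corpus into temp-training (60%), temp-dev (20%)
and temp-test (20%) with stratified sampling, fitting on temp-training
with F1 early stopping on temp-dev, and recording precision, recall and
F1 for the Relevant class on temp-test.  The resulting metric
distributions are summarised as median, 95% CI (empirical 2.5th/97.5th
percentiles, linear interpolation between closest ranks) and the F1
interquartile spread (IQV) on the percent scale.

Hyperparameters of the final pipeline are chosen by exhaustive grid
search with stratified five-fold cross-validation; early stopping inside
each fold reuses the fold's held-out part as the dev set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, train_test_split

from .classifier import _as_binary
from .corpus import DocumentRecord
from .pipeline import TriagePipeline

logger = logging.getLogger(__name__)


def _iteration_seed(master_seed: int, iteration: int) -> int:
    """Independent per-iteration seed derived from a master seed + counter."""
    return int((master_seed * 1_000_003 + iteration * 7919 + 1) % (2**31))


# ---------------------------------------------------------------------------
# Metrics

@dataclass(frozen=True)
class MetricTriple:
    """Precision, recall and F1 for the Relevant class, each in [0, 1]."""

    precision: float
    recall: float
    f1: float


def precision_recall_f1(y_true, y_pred) -> MetricTriple:
    """Standard P/R/F1 with Relevant as the positive class.

    Degenerate denominators (no predicted or no true positives) yield 0.
    """
    yt, yp = _as_binary(y_true), _as_binary(y_pred)
    if yt.shape[0] != yp.shape[0]:
        raise ValueError(f"length mismatch: {yt.shape[0]} true vs {yp.shape[0]} predicted")
    p, r, f1, _ = precision_recall_fscore_support(
        yt, yp, average="binary", pos_label=1, zero_division=0
    )
    return MetricTriple(float(p), float(r), float(f1))


# ---------------------------------------------------------------------------
# Inter-annotator agreement

@dataclass(frozen=True)
class AgreementResult:
    """Observed agreement, chance agreement and Cohen's kappa."""

    p_observed: float
    p_expected: float
    kappa: float


def cohen_kappa(labels_a, labels_b) -> AgreementResult:
    """Chance-corrected agreement K = (p_o - p_e) / (1 - p_e).

    p_o is the fraction of documents both annotators labelled
    identically; p_e sums the products of the per-class marginal
    proportions of the two annotators.
    """
    a, b = _as_binary(labels_a), _as_binary(labels_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] == 0:
        raise ValueError("cannot compute agreement on empty label vectors")
    n = a.shape[0]
    p_o = float(np.mean(a == b))
    p_e = float(np.mean(a) * np.mean(b) + np.mean(1 - a) * np.mean(1 - b))
    if p_e == 1.0:
        raise ValueError("chance agreement p_e = 1; kappa is undefined")
    return AgreementResult(p_o, p_e, (p_o - p_e) / (1 - p_e))


def pairwise_kappa(label_sets: Sequence[Sequence]) -> tuple[float, float]:
    """Mean +/- SD of Cohen's kappa over all annotator pairs."""
    ks = [
        cohen_kappa(label_sets[i], label_sets[j]).kappa
        for i, j in itertools.combinations(range(len(label_sets)), 2)
    ]
    return float(np.mean(ks)), float(np.std(ks))


# ---------------------------------------------------------------------------
# Bootstrap comparison

@dataclass
class BootstrapSummary:
    """Per-iteration metric samples plus median / 95% CI / F1 IQV."""

    samples: pd.DataFrame  # columns: precision, recall, f1; one row per iteration

    @property
    def n_iterations(self) -> int:
        return len(self.samples)

    def summary(self) -> pd.DataFrame:
        """Median and empirical 95% CI per metric; IQV on the percent scale."""
        rows = []
        for metric in ("precision", "recall", "f1"):
            s = self.samples[metric].to_numpy()
            lo, med, hi = np.percentile(s, [2.5, 50, 97.5])
            rows.append({"metric": metric, "median": med, "ci_low": lo, "ci_high": hi})
        out = pd.DataFrame(rows).set_index("metric")
        f1 = self.samples["f1"].to_numpy()
        out.attrs["f1_iqv_percent"] = float(
            (np.percentile(f1, 75) - np.percentile(f1, 25)) * 100
        )
        return out

    @property
    def median_f1(self) -> float:
        return float(np.median(self.samples["f1"]))


def summarize_metrics(samples: pd.DataFrame) -> pd.DataFrame:
    """Summarise a per-iteration metric table (see BootstrapSummary.summary)."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to summarise")
    return BootstrapSummary(samples).summary()


def stratified_three_way_split(
    indices: np.ndarray,
    y: np.ndarray,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint stratified (train, dev, test) index partition."""
    f_train, f_dev, f_test = fractions
    if abs(f_train + f_dev + f_test - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rest, test = train_test_split(
        indices, test_size=f_test, stratify=y, random_state=seed
    )
    rel_dev = f_dev / (f_train + f_dev)
    train, dev = train_test_split(
        rest, test_size=rel_dev, stratify=y[rest], random_state=seed + 1
    )
    return train, dev, test


def bootstrap_compare(
    records: Sequence[DocumentRecord],
    y,
    pipeline_params: dict | None = None,
    n_iterations: int = 200,
    split: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> BootstrapSummary:
    """Distribution of test-set metrics over repeated stratified splits.

    Each iteration draws its own 60/20/20 stratified split, fits the
    configured pipeline on temp-training with temp-dev early stopping,
    and records the Relevant-class metrics on temp-test.  The split
    stream depends only on (seed, iteration), so two configurations run
    with the same seed see identical splits and are directly comparable.
    """
    pipeline_params = dict(pipeline_params or {})
    yb = _as_binary(y)
    if yb.sum() == 0 or yb.sum() == yb.shape[0]:
        raise ValueError("bootstrap comparison requires both classes in the corpus")
    indices = np.arange(len(records))
    rows = []
    for it in range(n_iterations):
        it_seed = _iteration_seed(seed, it)
        try:
            tr, dv, te = stratified_three_way_split(indices, yb, split, seed=it_seed)
        except ValueError as exc:
            raise ValueError(
                f"iteration {it}: stratified split failed ({exc}); "
                "a stratum is too small for the requested fractions"
            ) from exc
        pipe = TriagePipeline(**{**pipeline_params, "random_state": it_seed})
        pipe.fit(
            [records[i] for i in tr], yb[tr],
            dev_records=[records[i] for i in dv], dev_y=yb[dv],
        )
        pred = _as_binary(pipe.predict([records[i] for i in te]))
        m = precision_recall_f1(yb[te], pred)
        logger.info(
            "bootstrap iteration=%d sizes=%d/%d/%d best_iteration=%d f1=%.3f",
            it, len(tr), len(dv), len(te), pipe.classifier_.best_iteration_, m.f1,
        )
        rows.append({"precision": m.precision, "recall": m.recall, "f1": m.f1})
    return BootstrapSummary(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Grid search

def _doublings(start: int, stop: int) -> tuple[int, ...]:
    out = []
    v = start
    while v <= stop:
        out.append(v)
        v *= 2
    return tuple(out)


@dataclass(frozen=True)
class HyperGrid:
    """Cartesian hyperparameter grid.

    Defaults cover min_df 2..512 (doubling), max_depth 2..64 (doubling)
    and colsample_bytree {1/3, 2/3, 1}; the number of boosting rounds is
    set by early stopping, not the grid.
    """

    min_df: tuple[int, ...] = _doublings(2, 512)
    max_depth: tuple[int, ...] = _doublings(2, 64)
    colsample_bytree: tuple[float, ...] = (1 / 3, 2 / 3, 1.0)

    def points(self) -> list[dict]:
        pts = [
            {"min_df": d, "max_depth": m, "colsample_bytree": c}
            for d in self.min_df
            for m in self.max_depth
            for c in self.colsample_bytree
        ]
        if not pts:
            raise ValueError("hyperparameter grid is empty")
        return pts


def grid_search_cv(
    records: Sequence[DocumentRecord],
    y,
    grid: HyperGrid | None = None,
    k_folds: int = 5,
    pipeline_params: dict | None = None,
    seed: int = 0,
) -> tuple[dict, float, pd.DataFrame]:
    """Exhaustive grid search with stratified k-fold CV.

    For each grid point the mean Relevant-class F1 across folds is
    computed, with early stopping inside each fold on that fold's
    held-out part.  Ties are broken toward smaller min_df, then smaller
    max_depth, then larger colsample_bytree.  Returns (best point, its
    mean F1, the full results table).
    """
    grid = grid or HyperGrid()
    pipeline_params = dict(pipeline_params or {})
    yb = _as_binary(y)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(records)), yb))
    results = []
    for point in grid.points():
        f1s = []
        for fold_i, (tr, va) in enumerate(folds):
            pipe = TriagePipeline(
                **{**pipeline_params, **point, "random_state": _iteration_seed(seed, fold_i)}
            )
            pipe.fit(
                [records[i] for i in tr], yb[tr],
                dev_records=[records[i] for i in va], dev_y=yb[va],
            )
            pred = _as_binary(pipe.predict([records[i] for i in va]))
            f1s.append(precision_recall_f1(yb[va], pred).f1)
        results.append({**point, "mean_f1": float(np.mean(f1s))})
    table = pd.DataFrame(results)
    best_row = min(
        results,
        key=lambda r: (-r["mean_f1"], r["min_df"], r["max_depth"], -r["colsample_bytree"]),
    )
    best = {k: best_row[k] for k in ("min_df", "max_depth", "colsample_bytree")}
    return best, best_row["mean_f1"], table
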