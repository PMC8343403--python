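"""Class-weighted gradient-boosted trees with F1-based early stopping.

The ensemble is a weighted sum of decision trees fitted sequentially to
the negative gradient of the average cross-entropy loss,

    H_L(x) = sum_{l=1..L} eta * w_l * f_l(x),

where eta is the learning rate and the per-learner weights w_l are
absorbed into the trees' fitted leaf values by the boosting engine
(XGBoost).  Class imbalance is handled by weighting each sample
inversely to its class frequency, so at 20% prevalence every positive
sample's loss is scaled by a factor of five.  Boosting stops early when
the F1 score on a held-out dev set has not improved for ``patience``
rounds, and the returned ensemble is truncated to the best-dev-F1
iteration.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.sparse as sp
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import f1_score

from .corpus import RELEVANT


def _as_binary(y) -> np.ndarray:
    """Map labels to {0,1} with 'Relevant' (or 1/True) as the positive class."""
    arr = np.asarray(y)
    if arr.dtype.kind in "UOS":
        return (arr == RELEVANT).astype(np.int32)
    return arr.astype(np.int32)


def compute_sample_weights(y) -> np.ndarray:
    """Per-sample weights inversely proportional to class frequency.

    A sample of a class with frequency p receives weight 1/p, so the
    weights sum to (number of classes) x n.  Requires both classes.
    """
    yb = _as_binary(y)
    n = yb.shape[0]
    n_pos = int(yb.sum())
    if n_pos == 0 or n_pos == n:
        raise ValueError("sample weighting requires both classes to be present")
    w = np.where(yb == 1, n / n_pos, n / (n - n_pos))
    return w.astype(float)


class GradientBoostedTriage(ClassifierMixin, BaseEstimator):
    """Gradient-boosted decision-tree classifier for document triage.

    Parameters
    ----------
    learning_rate : float, default 0.1
        Shrinkage eta applied to each weak learner's contribution.
    n_estimators : int, default 2000
        Maximum number of boosting rounds (L_max).
    patience : int, default 100
        Early-stopping window: boosting halts once the dev-set F1 has
        not improved for this many rounds.  Must satisfy
        1 <= patience < n_estimators.
    max_depth : int, default 4
    colsample_bytree : float, default 1.0
        Fraction of features each tree subsamples.
    class_weighting : bool, default True
        Weight samples inversely to class frequency.
    threshold : float, default 0.5
        Probability cut-off for the positive ("Relevant") label.
    random_state : int, default 0

    Attributes
    ----------
    booster_ : xgboost.Booster
    best_iteration_ : int
        Index of the best dev-F1 round; the ensemble is truncated there.
    n_features_in_ : int
    classes_ : ndarray of [0, 1]
    """

    def __init__(
        self,
        learning_rate: float = 0.1,
        n_estimators: int = 2000,
        patience: int = 100,
        max_depth: int = 4,
        colsample_bytree: float = 1.0,
        class_weighting: bool = True,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.patience = patience
        self.max_depth = max_depth
        self.colsample_bytree = colsample_bytree
        self.class_weighting = class_weighting
        self.threshold = threshold
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def _validate_params(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 < self.colsample_bytree <= 1):
            raise ValueError("colsample_bytree must be in (0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.patience >= self.n_estimators:
            raise ValueError("patience must be < n_estimators")

    def fit(self, X, y, eval_set: tuple | None = None, sample_weight=None):
        """Fit the boosted ensemble.

        ``eval_set=(X_dev, y_dev)`` enables F1 early stopping; the dev
        set must contain positive samples, otherwise F1 is undefined as
        a stopping signal.  Without an eval set the full
        ``n_estimators`` rounds are trained.
        """
        self._validate_params()
        yb = _as_binary(y)
        if sample_weight is None and self.class_weighting:
            sample_weight = compute_sample_weights(yb)
        if sample_weight is not None:
            sample_weight = np.asarray(sample_weight, dtype=float)
            # mean-normalise so the predictions are invariant to a
            # constant rescaling of the weights (the engine's L2 leaf
            # penalty is otherwise sensitive to the absolute scale)
            sample_weight = sample_weight / sample_weight.mean()

        params = {
            "objective": "binary:logistic",
            "eta": self.learning_rate,
            "max_depth": self.max_depth,
            "colsample_bytree": self.colsample_bytree,
            "tree_method": "hist",
            "nthread": 1,
            "seed": int(self.random_state),
        }
        dtrain = xgb.DMatrix(X, label=yb, weight=sample_weight)

        if eval_set is not None:
            X_dev, y_dev = eval_set
            yd = _as_binary(y_dev)
            if yd.sum() == 0:
                raise ValueError(
                    "dev set has no positive samples; F1 early stopping is undefined"
                )
            ddev = xgb.DMatrix(X_dev, label=yd)
            thr = self.threshold

            def f1_eval(preds: np.ndarray, dmat: xgb.DMatrix):
                labels = dmat.get_label()
                return "f1", f1_score(labels, preds >= thr, zero_division=0)

            self.booster_ = xgb.train(
                params,
                dtrain,
                num_boost_round=self.n_estimators,
                evals=[(ddev, "dev")],
                custom_metric=f1_eval,
                maximize=True,
                early_stopping_rounds=self.patience,
                verbose_eval=False,
            )
            self.best_iteration_ = int(self.booster_.best_iteration)
            self.best_score_ = float(self.booster_.best_score)
        else:
            self.booster_ = xgb.train(params, dtrain, num_boost_round=self.n_estimators)
            self.best_iteration_ = self.n_estimators - 1

        self.n_features_in_ = dtrain.num_col()
        self.classes_ = np.array([0, 1])
        return self

    # -- prediction --------------------------------------------------------

    def _check_fitted_X(self, X) -> xgb.DMatrix:
        if not hasattr(self, "booster_"):
            raise ValueError("classifier is not fitted; call fit first")
        n_cols = X.shape[1]
        if n_cols != self.n_features_in_:
            raise ValueError(
                f"feature-column mismatch: model was fitted on {self.n_features_in_} "
                f"columns, got {n_cols}"
            )
        return xgb.DMatrix(X)

    def predict_proba(self, X) -> np.ndarray:
        """Probability of each class, column 1 = P(Relevant)."""
        if X.shape[0] == 0:
            return np.empty((0, 2))
        dmat = self._check_fitted_X(X)
        p = self.booster_.predict(dmat, iteration_range=(0, self.best_iteration_ + 1))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        """Binary labels: 1 (Relevant) iff P(Relevant) >= threshold."""
        if X.shape[0] == 0:
            return np.empty(0, dtype=np.int32)
        p = self.predict_proba(X)[:, 1]
        return (p >= self.threshold).astype(np.int32)

    def feature_gains(self) -> dict[int, float]:
        """Total gain per feature column index, from the fitted booster."""
        if not hasattr(self, "booster_"):
            raise ValueError("classifier is not fitted; call fit first")
        raw = self.booster_.get_score(importance_type="gain")
        return {int(k[1:]): v for k, v in raw.items()}
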