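"""Metrics, kappa, bootstrap protocol, summaries and grid search."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from pktriage.corpus import DocumentRecord
from pktriage.evaluate import (
    HyperGrid,
    bootstrap_compare,
    cohen_kappa,
    grid_search_cv,
    pairwise_kappa,
    precision_recall_f1,
    stratified_three_way_split,
    summarize_metrics,
)


class TestPrecisionRecallF1:
    def test_harmonic_mean(self):
        # 2 TP, 0 FP, 2 FN: P=1, R=0.5, F1=2/3
        y_true = [1, 1, 1, 1, 0, 0]
        y_pred = [1, 1, 0, 0, 0, 0]
        m = precision_recall_f1(y_true, y_pred)
        assert (m.precision, m.recall) == (1.0, 0.5)
        assert m.f1 == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        m = precision_recall_f1([1, 0, 1], [1, 0, 1])
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_degenerate_no_predicted_positives(self):
        m = precision_recall_f1([1, 1, 0], [0, 0, 0])
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            precision_recall_f1([1, 0], [1])

    def test_f1_between_min_and_max(self):
        rng = np.random.RandomState(0)
        for _ in range(50):
            yt, yp = rng.randint(0, 2, 30), rng.randint(0, 2, 30)
            m = precision_recall_f1(yt, yp)
            if m.precision + m.recall > 0:
                assert min(m.precision, m.recall) - 1e-12 <= m.f1
                assert m.f1 <= max(m.precision, m.recall) + 1e-12


class TestCohenKappa:
    def test_identical_vectors(self):
        assert cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0]).kappa == pytest.approx(1.0)

    def test_chance_level_agreement(self):
        # p_o = p_e = 0.5 -> K = 0
        res = cohen_kappa([1, 1, 0, 0], [1, 0, 1, 0])
        assert res.p_observed == pytest.approx(res.p_expected)
        assert res.kappa == pytest.approx(0.0)

    def test_worked_example(self):
        """2x2 counts 40/10/5/45 give p_o=0.85, p_e=0.5, K=0.7."""
        a = [1] * 40 + [1] * 10 + [0] * 5 + [0] * 45
        b = [1] * 40 + [0] * 10 + [1] * 5 + [0] * 45
        res = cohen_kappa(a, b)
        assert res.p_observed == pytest.approx(0.85)
        assert res.p_expected == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.7)

    def test_symmetry(self):
        rng = np.random.RandomState(1)
        for _ in range(25):
            a, b = rng.randint(0, 2, 40), rng.randint(0, 2, 40)
            if (a == b).all():
                continue
            assert cohen_kappa(a, b).kappa == pytest.approx(cohen_kappa(b, a).kappa)

    def test_matches_independent_implementation(self):
        rng = np.random.RandomState(2)
        for _ in range(25):
            a, b = rng.randint(0, 2, 60), rng.randint(0, 2, 60)
            if np.mean(a == b) == 1.0:
                continue
            assert cohen_kappa(a, b).kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_degenerate_pe_one_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            cohen_kappa([1, 1], [1, 1])

    def test_pairwise_mean_sd(self):
        sets = [[1, 0, 1, 0, 1], [1, 0, 1, 0, 0], [1, 0, 0, 0, 1]]
        mean, sd = pairwise_kappa(sets)
        assert -1 <= mean <= 1 and sd >= 0


class TestSummarize:
    def test_constant_samples(self):
        df = pd.DataFrame({"precision": [0.5] * 10, "recall": [0.5] * 10, "f1": [0.5] * 10})
        s = summarize_metrics(df)
        assert (s["ci_high"] - s["ci_low"] == 0).all()
        assert s.attrs["f1_iqv_percent"] == 0.0

    def test_percentile_rule_on_grid(self):
        # samples k/200, k=1..200: linear-interpolation median is 0.5025
        vals = np.arange(1, 201) / 200
        df = pd.DataFrame({"precision": vals, "recall": vals, "f1": vals})
        s = summarize_metrics(df)
        assert s.loc["f1", "median"] == pytest.approx(0.5025)

    def test_symmetric_samples_median_equals_mean(self):
        vals = np.linspace(0.2, 0.8, 41)
        df = pd.DataFrame({"precision": vals, "recall": vals, "f1": vals})
        s = summarize_metrics(df)
        assert s.loc["f1", "median"] == pytest.approx(vals.mean())

    def test_ci_brackets_median(self):
        rng = np.random.RandomState(0)
        vals = rng.rand(200)
        df = pd.DataFrame({"precision": vals, "recall": vals, "f1": vals})
        s = summarize_metrics(df)
        assert (s["ci_low"] <= s["median"]).all() and (s["median"] <= s["ci_high"]).all()

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"precision": [0.5], "recall": [0.5], "f1": [0.5]})
        with pytest.raises(ValueError):
            summarize_metrics(df)


class TestSplits:
    def test_sizes_60_20_20(self):
        y = np.array([1] * 20 + [0] * 80)
        tr, dv, te = stratified_three_way_split(np.arange(100), y, seed=0)
        assert (len(tr), len(dv), len(te)) == (60, 20, 20)

    def test_partition_and_stratification(self):
        y = np.array([1] * 20 + [0] * 80)
        idx = np.arange(100)
        for seed in range(10):
            tr, dv, te = stratified_three_way_split(idx, y, seed=seed)
            combined = np.sort(np.concatenate([tr, dv, te]))
            np.testing.assert_array_equal(combined, idx)  # disjoint union
            for part, frac in ((tr, 0.6), (dv, 0.2), (te, 0.2)):
                n_pos = y[part].sum()
                assert abs(n_pos - 20 * frac) <= 1  # within one document of 20%

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            stratified_three_way_split(np.arange(10), np.arange(10) % 2, (0.5, 0.2, 0.2))


class TestBootstrapCompare:
    def test_samples_shape_and_determinism(self, small_corpus):
        records, y = small_corpus
        kwargs = dict(pipeline_params={"min_df": 2}, n_iterations=3, seed=4)
        r1 = bootstrap_compare(records, y, **kwargs)
        r2 = bootstrap_compare(records, y, **kwargs)
        assert r1.n_iterations == 3
        pd.testing.assert_frame_equal(r1.samples, r2.samples)

    def test_single_class_rejected(self, small_corpus):
        records, y = small_corpus
        with pytest.raises(ValueError, match="both classes"):
            bootstrap_compare(records, np.zeros_like(y), n_iterations=1)

    def test_summary_permutation_invariant(self, small_corpus):
        records, y = small_corpus
        r = bootstrap_compare(records, y, {"min_df": 2}, n_iterations=4, seed=1)
        shuffled = r.samples.sample(frac=1, random_state=0).reset_index(drop=True)
        pd.testing.assert_frame_equal(r.summary(), summarize_metrics(shuffled))


class TestHyperGrid:
    def test_default_grid_is_full_cartesian_product(self):
        grid = HyperGrid()
        assert grid.min_df == (2, 4, 8, 16, 32, 64, 128, 256, 512)
        assert grid.max_depth == (2, 4, 8, 16, 32, 64)
        assert len(grid.colsample_bytree) == 3
        assert len(grid.points()) == 9 * 6 * 3

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            HyperGrid(min_df=()).points()


class TestGridSearchCV:
    def test_single_point_grid_returned(self, small_corpus):
        records, y = small_corpus
        grid = HyperGrid(min_df=(2,), max_depth=(4,), colsample_bytree=(1.0,))
        best, f1, table = grid_search_cv(records, y, grid, k_folds=3, seed=0)
        assert best == {"min_df": 2, "max_depth": 4, "colsample_bytree": 1.0}
        assert len(table) == 1 and 0 <= f1 <= 1

    def test_min_df_must_retain_signal_column(self):
        """When the only informative token sits in few documents, the grid
        must prefer a min_df small enough to keep its column."""
        rng = np.random.RandomState(0)
        records, y = [], []
        for i in range(40):
            relevant = i < 8
            words = [f"w{rng.randint(6)}" for _ in range(8)]
            if relevant:
                words.append("zelboraf")  # appears only in the 8 relevant docs
            records.append(
                DocumentRecord(pmid=str(i), title=" ".join(rng.permutation(words)))
            )
            y.append(int(relevant))
        grid = HyperGrid(min_df=(2, 16), max_depth=(2,), colsample_bytree=(1.0,))
        best, _, table = grid_search_cv(
            records, np.array(y), grid, k_folds=4,
            pipeline_params={"fields": ("title",)}, seed=3,
        )
        assert best["min_df"] == 2
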