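"""Connectivity, folds, classifier, permutation FI, RFE, aggregation."""

import numpy as np
import pandas as pd
import pytest

from cellherit.config import ClassifierConfig, SimConfig
from cellherit.fmri import (
    ConnectivityClassifier,
    aggregate_fi,
    compute_connectivity,
    fi_to_matrix,
    make_folds,
    mean_preserved_runs,
    permutation_fi,
    preserved_run_correlation,
    rfe,
    topn_enrichment,
    train_eval,
    upper_triangle,
)
from cellherit.simulate import ConnectivityDataset, generate_fmri

LOGISTIC = ClassifierConfig(backend="logistic", seed=0)


def _dataset(seed=0, n_rois=8, ts_length=60, n_cases=12, n_controls=12, delta=()):
    cfg = SimConfig(seed=seed, n_rois=n_rois, ts_length=ts_length,
                    n_cases=n_cases, n_controls=n_controls,
                    delta_pairs=list(delta))
    return generate_fmri(cfg)[0]


class TestConnectivity:
    def test_duplicated_roi_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        ts = np.column_stack([x, x, rng.standard_normal(100)])
        c = compute_connectivity(ts)
        assert c[0, 1] == pytest.approx(1.0)
        np.testing.assert_array_equal(np.diag(c), 1.0)

    def test_anticorrelated_pair(self):
        x = np.random.default_rng(1).standard_normal(50)
        c = compute_connectivity(np.column_stack([x, -x]))
        assert c[0, 1] == pytest.approx(-1.0)

    def test_independent_series_near_zero(self):
        t = 2000
        ts = np.random.default_rng(2).standard_normal((t, 5))
        c = compute_connectivity(ts)
        off = upper_triangle(c)
        assert np.all(np.abs(off) < 3 / np.sqrt(t))

    def test_zero_variance_roi_named(self):
        ts = np.random.default_rng(3).standard_normal((30, 3))
        ts[:, 1] = 4.2
        with pytest.raises(ValueError, match=r"\[1\]"):
            compute_connectivity(ts)

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError, match="3 time points"):
            compute_connectivity(np.ones((2, 4)))

    def test_symmetric_and_psd(self):
        ts = np.random.default_rng(4).standard_normal((80, 6))
        c = compute_connectivity(ts)
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        assert np.linalg.eigvalsh(c).min() > -1e-10


class TestMakeFolds:
    def test_46_plus_46_split_sizes(self):
        """5 portions from 46 cases + 46 controls: 10/9/9/9/9 per class."""
        ds = _dataset(n_cases=46, n_controls=46, n_rois=4, ts_length=30)
        folds = make_folds(ds, n_folds=5, seed=0)
        for cls in (0, 1):
            sizes = sorted(np.bincount(folds[ds.labels == cls]), reverse=True)
            assert sizes == [10, 9, 9, 9, 9]

    def test_single_fold_rejected(self):
        ds = _dataset(n_cases=6, n_controls=6, n_rois=4, ts_length=30)
        with pytest.raises(ValueError, match="n_folds"):
            make_folds(ds, n_folds=1)

    def test_small_class_rejected(self):
        ds = _dataset(n_cases=3, n_controls=8, n_rois=4, ts_length=30)
        with pytest.raises(ValueError, match="class 1"):
            make_folds(ds, n_folds=5)

    def test_deterministic_under_seed(self):
        ds = _dataset(n_cases=10, n_controls=10, n_rois=4, ts_length=30)
        np.testing.assert_array_equal(
            make_folds(ds, 5, seed=3), make_folds(ds, 5, seed=3)
        )


class TestTrainEval:
    def test_separable_single_feature_gives_perfect_auc(self):
        y = np.repeat([0, 1], 20)
        x = (y * 2.0 - 1.0)[:, None] + 0.01 * np.random.default_rng(0).standard_normal((40, 1))
        _, auc, e_orig = train_eval(x, y, x, y, LOGISTIC)
        assert auc == 1.0
        assert e_orig < 0.5

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(1)
        aucs = []
        for rep in range(20):
            x = rng.standard_normal((60, 10))
            y = rng.permutation(np.repeat([0, 1], 30))
            x_test = rng.standard_normal((40, 10))
            y_test = rng.permutation(np.repeat([0, 1], 20))
            _, auc, _ = train_eval(x, y, x_test, y_test, LOGISTIC)
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.07

    def test_mlp_backend_trains(self):
        y = np.repeat([0, 1], 30)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((60, 5)) + 1.5 * y[:, None]
        cfg = ClassifierConfig(backend="mlp", max_iter=300, seed=0)
        _, auc, _ = train_eval(x, y, x, y, cfg)
        assert auc > 0.9


class TestPermutationFi:
    def test_informative_feature_has_fi_above_one(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 40)
        x = rng.standard_normal((80, 3))
        x[:, 0] += 2.0 * y
        clf = ConnectivityClassifier(LOGISTIC).fit(x, y)
        y_ev = np.repeat([0, 1], 25)
        x_ev = rng.standard_normal((50, 3))
        x_ev[:, 0] += 2.0 * y_ev
        fi = permutation_fi(clf, x_ev, y_ev, n_perm=200, seed=1)
        assert fi[0] > 1.0

    def test_fi_ratio_arithmetic(self):
        """FI = mean permuted error / original error once the gate opens;
        FI = 0 when the original error sits inside the permutation interval."""
        from cellherit.fmri import fi_from_errors

        rng = np.random.default_rng(0)
        perm = 0.8 + 0.001 * rng.standard_normal(1000)
        assert fi_from_errors(0.4, perm) == pytest.approx(perm.mean() / 0.4, rel=1e-12)
        assert fi_from_errors(0.4, perm) == pytest.approx(2.0, rel=1e-2)
        # gate closed: e_orig within the central 95% of permuted errors
        assert fi_from_errors(0.8, perm) == 0.0

    def test_uninformative_feature_usually_gated_to_zero(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 30)
        x = rng.standard_normal((60, 2))
        x[:, 0] += 1.5 * y
        clf = ConnectivityClassifier(LOGISTIC).fit(x, y)
        zeros = 0
        for rep in range(40):
            x_ev = rng.standard_normal((40, 2))
            y_ev = np.repeat([0, 1], 20)
            x_ev[:, 0] += 1.5 * y_ev
            fi = permutation_fi(clf, x_ev, y_ev, n_perm=100,
                                seed=rep, features=[1])
            zeros += fi[1] == 0
        assert zeros >= 30  # ~95% nominal

    def test_fi_matrix_embedding_symmetric(self):
        fi = np.array([1.0, 2.0, 3.0])  # 3 ROIs: pairs (0,1),(0,2),(1,2)
        mat = fi_to_matrix(fi, [4, 6, 7], n_total=9)
        assert mat[4, 6] == mat[6, 4] == 1.0
        assert mat[4, 7] == 2.0 and mat[6, 7] == 3.0
        assert mat.sum() == 2 * 6.0


class TestRfe:
    def test_run_count_and_preserved_runs(self):
        ds = _dataset(seed=5, n_rois=5, n_cases=8, n_controls=8,
                      delta=[(0, 3, 0.8)])
        folds = make_folds(ds, n_folds=2, seed=0)
        trace = rfe(ds, folds, fold=0, config=LOGISTIC, n_perm=50,
                    min_rois=2, seed=0)
        assert len(trace.runs) == 3  # 5 -> 4 -> 3 -> 2
        counts = trace.preserved_runs
        assert counts.max() == 3 and counts.min() == 1
        assert sorted(counts)[::-1][:2] == [3, 3]  # the two survivors

    def test_three_rois_single_elimination(self):
        ds = _dataset(seed=6, n_rois=3, n_cases=8, n_controls=8)
        folds = make_folds(ds, n_folds=2, seed=0)
        trace = rfe(ds, folds, fold=0, config=LOGISTIC, n_perm=20, min_rois=2)
        assert len(trace.runs) == 1

    def test_signal_rois_survive_noise_rois(self):
        """The planted-pair ROIs are eliminated later than pure-noise ROIs
        in most seeds."""
        wins = 0
        for seed in range(10):
            ds = _dataset(seed=100 + seed, n_rois=6, n_cases=16, n_controls=16,
                          ts_length=150, delta=[(1, 4, 0.9)])
            folds = make_folds(ds, n_folds=2, seed=seed)
            trace = rfe(ds, folds, fold=0, config=LOGISTIC, n_perm=60,
                        min_rois=2, seed=seed)
            counts = trace.preserved_runs
            signal = counts[[1, 4]].mean()
            noise = np.delete(counts, [1, 4]).mean()
            wins += signal > noise
        assert wins >= 8

    def test_too_few_rois_rejected(self):
        ds = _dataset(seed=7, n_rois=3, n_cases=6, n_controls=6)
        ds2 = ConnectivityDataset(
            series=[s[:, :2] for s in ds.series],
            labels=ds.labels, subject_ids=ds.subject_ids,
            roi_meta=ds.roi_meta.iloc[:2],
        )
        folds = make_folds(ds2, n_folds=2, seed=0)
        with pytest.raises(ValueError, match="3 ROIs"):
            rfe(ds2, folds, fold=0, config=LOGISTIC, n_perm=20)


class TestAggregateFi:
    def _trace(self, fi_mats, aucs):
        from cellherit.fmri import RFERun, RFETrace
        n = fi_mats[0].shape[0]
        trace = RFETrace(fold=0, n_rois=n)
        for i, (m, a) in enumerate(zip(fi_mats, aucs)):
            trace.runs.append(RFERun(i, list(range(n)), 0, a, 0.5, m))
        return trace

    def test_single_model_scaling(self):
        fi = np.array([[0, 4.0], [4.0, 0]])
        agg = aggregate_fi([self._trace([fi], [0.5])])
        np.testing.assert_allclose(agg, fi / 4.0 * 0.5)

    def test_two_identical_models_double(self):
        fi = np.array([[0, 2.0], [2.0, 0]])
        single = aggregate_fi([self._trace([fi], [0.7])])
        double = aggregate_fi([self._trace([fi, fi], [0.7, 0.7])])
        np.testing.assert_allclose(double, 2 * single)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        mats = []
        for _ in range(3):
            m = np.abs(rng.standard_normal((4, 4)))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            mats.append(m)
        a = aggregate_fi([self._trace(mats, [0.5, 0.6, 0.7])])
        b = aggregate_fi([self._trace(mats[::-1], [0.7, 0.6, 0.5])])
        np.testing.assert_allclose(a, b)

    def test_all_zero_matrix_skipped_with_warning(self):
        fi = np.array([[0, 1.0], [1.0, 0]])
        zero = np.zeros((2, 2))
        with pytest.warns(UserWarning, match="all-zero"):
            agg = aggregate_fi([self._trace([zero, fi], [0.9, 0.5])])
        np.testing.assert_allclose(agg, fi / 1.0 * 0.5)

    def test_nothing_to_aggregate_rejected(self):
        zero = np.zeros((2, 2))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="aggregate"):
                aggregate_fi([self._trace([zero], [0.5])])


class TestTopnEnrichment:
    def test_full_grid_for_76_rois(self):
        rng = np.random.default_rng(0)
        m = np.abs(rng.standard_normal((76, 76)))
        m = (m + m.T) / 2
        res = topn_enrichment(m, flagged_rois={0, 1, 2})
        assert len(res) == 2888
        assert res["n"].iloc[0] == 2
        assert res["n"].iloc[-1] == 5776

    def test_all_rois_flagged_gives_p_one(self):
        rng = np.random.default_rng(1)
        m = np.abs(rng.standard_normal((6, 6)))
        m = (m + m.T) / 2
        res = topn_enrichment(m, flagged_rois=set(range(6)))
        assert (res["p_hypergeometric"] == 1.0).all()

    def test_planted_top_connection_significant_at_small_n(self):
        m = np.zeros((20, 20))
        m[2, 7] = m[7, 2] = 5.0  # flagged pair dominates the ranking
        m[1, 3] = m[3, 1] = 0.1
        res = topn_enrichment(m, flagged_rois={2, 7})
        assert res.loc[res["n"] == 2, "overlap"].iloc[0] == 2
        assert res.loc[res["n"] == 2, "p_hypergeometric"].iloc[0] < 0.05

    def test_empty_flagged_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            topn_enrichment(np.zeros((4, 4)), flagged_rois=set())


class TestPreservedRunCorrelation:
    def test_identical_and_negated_traces(self):
        a = np.array([5.0, 3.0, 1.0, 4.0])
        r, _ = preserved_run_correlation(a, a)
        assert r == pytest.approx(1.0)
        r, _ = preserved_run_correlation(a, -a)
        assert r == pytest.approx(-1.0)

    def test_subset_restriction_and_minimum(self):
        a = np.arange(10.0)
        b = np.arange(10.0)[::-1]
        r, _ = preserved_run_correlation(a, b, roi_subset=[0, 3, 7, 9])
        assert r == pytest.approx(-1.0)
        with pytest.raises(ValueError, match="at least 3"):
            preserved_run_correlation(a, b, roi_subset=[0, 1])

    def test_independent_traces_uncorrelated(self):
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(100):
            r, _ = preserved_run_correlation(
                rng.integers(1, 20, size=38).astype(float),
                rng.integers(1, 20, size=38).astype(float),
            )
            rs.append(r)
        assert abs(np.mean(rs)) < 0.06
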