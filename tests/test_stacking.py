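"""Stacked generalization: folds, OOF fits, blending, meta stage, learner search."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import LinearRegression

import stackdose as sd
from stackdose import stacking as st


def mean_spec():
    return st.LearnerSpec("mean", lambda: DummyRegressor(strategy="mean"))


def exhaustive_learner_subset(names, scorer):
    best = None
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(sorted(names), r):
            s = scorer(frozenset(combo))
            key = (s, len(combo), combo)
            if best is None or key < best[0]:
                best = (key, frozenset(combo))
    return best[1], best[0][0]


class TestMakeFolds:
    def test_even_split(self):
        folds = st.make_folds(10, k=5, seed=0)
        assert sorted(np.bincount(folds)) == [2, 2, 2, 2, 2]

    def test_pigeonhole_sizes(self):
        folds = st.make_folds(11, k=5, seed=1)
        assert sorted(np.bincount(folds)) == [2, 2, 2, 2, 3]

    def test_partition_and_determinism(self):
        a = st.make_folds(57, k=5, seed=3)
        b = st.make_folds(57, k=5, seed=3)
        assert np.array_equal(a, b)
        assert set(a) == set(range(5))

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            st.make_folds(3, k=5)


class TestOutOfFold:
    def test_mean_learner_oof_equals_complementary_fold_means(self):
        """Hand-computable oracle on 6 rows, k=3: the OOF prediction of a
        training-mean learner for fold j is the mean of the other folds."""
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        X = np.zeros((6, 1))
        folds = np.array([0, 0, 1, 1, 2, 2])
        res = st.fit_base_out_of_fold(mean_spec(), X, y, folds)
        expected = np.array([4.5, 4.5, 3.5, 3.5, 2.5, 2.5])  # complements: {3..6},{1,2,5,6},{1..4}
        assert np.allclose(res.oof, expected)
        assert np.all(res.val_rmses >= 0)

    def test_deterministic_given_folds(self, noiseless_cohort):
        X = noiseless_cohort.feature_frame().to_numpy(float)[:100]
        y = noiseless_cohort.dose[:100]
        folds = st.make_folds(100, seed=4)
        spec = st.default_pool(7)["RF"]
        a = st.fit_base_out_of_fold(spec, X, y, folds)
        b = st.fit_base_out_of_fold(spec, X, y, folds)
        assert np.array_equal(a.oof, b.oof)
        assert np.array_equal(a.val_rmses, b.val_rmses)

    def test_failure_names_learner_and_fold(self):
        class Broken:
            def fit(self, X, y):
                raise RuntimeError("boom")

        spec = st.LearnerSpec("broken", Broken)
        with pytest.raises(RuntimeError, match="'broken' failed on fold 0"):
            st.fit_base_out_of_fold(spec, np.zeros((10, 1)), np.arange(10.0),
                                    st.make_folds(10, k=5, seed=0))


class TestBlending:
    def test_identical_fold_predictions_invariant_to_mode(self):
        P = np.tile(np.array([1.0, 2.0, 3.0]), (4, 1))
        r = np.array([0.3, 0.5, 0.2, 0.4])
        assert np.allclose(st.blend_test_predictions(P, "arithmetic"), [1, 2, 3])
        assert np.allclose(st.blend_test_predictions(P, "inverse_rmse", r), [1, 2, 3])

    def test_equal_rmses_reduce_to_arithmetic(self, rng):
        P = rng.normal(size=(5, 8))
        r = np.full(5, 0.37)
        assert np.allclose(
            st.blend_test_predictions(P, "inverse_rmse", r),
            st.blend_test_predictions(P, "arithmetic"),
        )

    def test_reciprocal_normalization(self):
        P = np.array([[1.0, 1.0], [4.0, 4.0]])
        out = st.blend_test_predictions(P, "inverse_rmse", np.array([0.5, 0.25]))
        # weights (1/3, 2/3)
        assert np.allclose(out, 1.0 / 3 + 4.0 * 2 / 3)

    def test_zero_rmse_suggests_arithmetic(self):
        P = np.ones((2, 3))
        with pytest.raises(ValueError, match="arithmetic"):
            st.blend_test_predictions(P, "inverse_rmse", np.array([0.0, 0.5]))

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="unknown blend mode"):
            st.blend_test_predictions(np.ones((1, 2)), "geometric")


@pytest.fixture(scope="module")
def data():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(80, 4))
    y = X[:, 0] + np.sin(X[:, 1]) + rng.normal(0, 0.3, 80) + 3
    Xt = rng.normal(size=(12, 4))
    return X, y, Xt


class TestStackedDataset:

    def test_single_learner_shape(self, data):
        X, y, Xt = data
        pool = {"MLR": st.default_pool(0)["MLR"]}
        stacked = st.build_stacked_dataset(pool, X, y, Xt, seed=1)
        assert stacked.Z.shape == (80, 1)
        assert stacked.Z_test.shape == (12, 1)
        assert stacked.val_rmses["MLR"].shape == (5,)

    def test_column_correspondence_under_pool_reordering(self, data):
        X, y, Xt = data
        full = st.default_pool(3)
        a = st.build_stacked_dataset({k: full[k] for k in ("MLR", "SGD", "KRR")}, X, y, Xt, seed=2)
        b = st.build_stacked_dataset({k: full[k] for k in ("KRR", "MLR", "SGD")}, X, y, Xt, seed=2)
        for name in ("MLR", "SGD", "KRR"):
            assert np.allclose(a.Z[name], b.Z[name])
            assert np.allclose(a.Z_test[name], b.Z_test[name])

    def test_leakage_guard_detects_corrupted_fold(self, data):
        X, y, Xt = data
        stacked = st.build_stacked_dataset({"MLR": st.default_pool(0)["MLR"]}, X, y, Xt, seed=3)
        rec = stacked.fold_records["MLR"][0]
        rec["train_indices"] = np.concatenate([rec["train_indices"], rec["val_indices"][:1]])
        with pytest.raises(AssertionError, match="leakage"):
            stacked.check_no_leakage()

    def test_remode_preserves_train_matrix(self, data):
        X, y, Xt = data
        stacked = st.build_stacked_dataset({"MLR": st.default_pool(0)["MLR"],
                                            "SGD": st.default_pool(0)["SGD"]},
                                           X, y, Xt, seed=4, mode="inverse_rmse")
        re = stacked.with_mode("arithmetic")
        assert re.Z is stacked.Z
        assert re.mode == "arithmetic"
        # modes genuinely differ unless fold RMSEs are exactly equal
        assert re.Z_test.shape == stacked.Z_test.shape


class TestMetaStage:
    def test_perfect_feature_column_recovered_by_linear_meta(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(1, 6, 50)
        yt = rng.uniform(1, 6, 10)
        stacked = st.StackedDataset(
            Z=pd.DataFrame({"perfect": y, "junk": rng.normal(size=50)}),
            Z_test=pd.DataFrame({"perfect": yt, "junk": rng.normal(size=10)}),
            val_rmses={}, fold_assignment=np.zeros(50, int), mode="arithmetic",
            fold_records={},
        )
        meta = st.LearnerSpec("lin", LinearRegression)
        pred = st.fit_meta_and_predict(stacked, y, meta=meta)
        assert np.allclose(pred, yt, atol=1e-8)

    def test_constant_target_gives_constant_predictions(self):
        rng = np.random.default_rng(1)
        y = np.full(40, 3.0)
        stacked = st.StackedDataset(
            Z=pd.DataFrame({"a": rng.normal(size=40)}),
            Z_test=pd.DataFrame({"a": rng.normal(size=8)}),
            val_rmses={}, fold_assignment=np.zeros(40, int), mode="arithmetic",
            fold_records={},
        )
        pred = st.fit_meta_and_predict(stacked, y)  # SVR-RBF meta, epsilon 0.1
        assert np.allclose(pred, 3.0, atol=0.15)

    def test_meta_swap_leaves_stacked_data_untouched(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = X[:, 0] + rng.normal(0, 0.2, 60) + 3
        stacked = st.build_stacked_dataset({"MLR": st.default_pool(0)["MLR"]},
                                           X, y, rng.normal(size=(5, 3)), seed=0)
        z_before = stacked.Z.copy()
        st.fit_meta_and_predict(stacked, y, meta=st.LearnerSpec("lin", LinearRegression))
        st.fit_meta_and_predict(stacked, y)  # default SVR meta
        assert stacked.Z.equals(z_before)

    def test_unknown_learner_rejected(self):
        stacked = st.StackedDataset(
            Z=pd.DataFrame({"a": np.arange(10.0)}), Z_test=pd.DataFrame({"a": np.arange(3.0)}),
            val_rmses={}, fold_assignment=np.zeros(10, int), mode="arithmetic", fold_records={},
        )
        with pytest.raises(ValueError, match="unknown learners"):
            st.fit_meta_and_predict(stacked, np.arange(10.0), learners=["b"])


class TestLearnerSearch:
    def _toy_stack(self, seed, learners=("MLR", "KRR", "SGD"), n=60):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        y = X[:, 0] + np.sin(X[:, 1]) + rng.normal(0, 0.4, n) + 3
        Xt = rng.normal(size=(10, 4))
        pool = {k: v for k, v in st.default_pool(seed).items() if k in learners}
        stacked = st.build_stacked_dataset(pool, X, y, Xt, seed=seed)
        return pool, stacked, y

    def test_matches_exhaustive_search_on_toy_pools(self):
        matches = 0
        for i in range(20):
            pool, stacked, y = self._toy_stack(2000 + i)
            scorer = st.stack_cv_scorer(stacked, y, k=5, seed=i)
            learners, _, score = st.heuristic_learner_search(pool, stacked, y, k=5, seed=i)
            oracle_set, oracle_score = exhaustive_learner_subset(list(pool), scorer)
            if frozenset(learners) == oracle_set or score == pytest.approx(oracle_score, abs=1e-12):
                matches += 1
        assert matches >= 19

    def test_oracle_learner_always_selected(self):
        """A pool member that predicts the target's true function is kept."""
        for seed in range(3):
            rng = np.random.default_rng(700 + seed)
            X = rng.normal(size=(80, 3))
            y = X @ np.array([1.0, -0.5, 0.25]) + 4.0  # exactly linear, noise-free
            Xt = rng.normal(size=(10, 3))
            pool = {"MLR": st.default_pool(seed)["MLR"], "mean": mean_spec()}
            stacked = st.build_stacked_dataset(pool, X, y, Xt, seed=seed)
            learners, _, _ = st.heuristic_learner_search(pool, stacked, y, k=5, seed=seed)
            assert "MLR" in learners

    def test_singleton_pool(self):
        pool, stacked, y = self._toy_stack(9, learners=("MLR",))
        learners, trace, _ = st.heuristic_learner_search(pool, stacked, y, k=5, seed=9)
        assert learners == ["MLR"]

    def test_lock_invariants_and_pass_bound(self):
        pool, stacked, y = self._toy_stack(11, learners=("MLR", "KRR", "SGD"))
        _, trace, _ = st.heuristic_learner_search(pool, stacked, y, k=5, seed=11)
        fwd, bwd = set(), set()
        for ev in trace:
            if ev["accepted"]:
                (fwd if ev["direction"] == "forward" else bwd).add(ev["item"])
        assert fwd.isdisjoint(bwd)
        if trace:
            assert max(ev["pass"] for ev in trace) <= 2 * len(pool)


class TestPipeline:
    def test_holdout_disjoint_and_result_serializable(self, small_cohort):
        cfg = st.PipelineConfig(seed=5, variant="weighted", selection="filter",
                                pool=("MLR", "SGD", "RF"))
        res = st.run_pipeline(small_cohort, cfg)
        holdout = set(res.extra["holdout_indices"])
        assert len(holdout) == 64
        payload = res.to_json()
        assert "weighted" in payload
        assert res.report.d_test == 64

    def test_deterministic_rerun(self, noiseless_cohort):
        cfg = st.PipelineConfig(seed=2, variant="heuristic", selection="none",
                                pool=("MLR", "SGD", "KRR"))
        a = st.run_pipeline(noiseless_cohort, cfg)
        b = st.run_pipeline(noiseless_cohort, cfg)
        assert a.to_json() == b.to_json()

    def test_noise_free_cohort_fully_recovered(self, noiseless_cohort):
        """With a deterministic dose model the stack predicts every holdout
        patient within the ±20% ideal window."""
        cfg = st.PipelineConfig(seed=3, variant="heuristic", selection="none")
        res = st.run_pipeline(noiseless_cohort, cfg)
        assert res.report.err_pct == 100.0

    def test_excluded_variables_not_in_features(self, small_cohort):
        cfg = st.PipelineConfig(seed=1, variant="traditional", selection="none",
                                pool=("MLR", "SGD"))
        res = st.run_pipeline(small_cohort, cfg)
        assert set(res.features).isdisjoint(res.excluded)

    def test_too_small_cohort_rejected(self):
        tiny = sd.generate_cohort(sd.default_config(n=6, seed=0))
        with pytest.raises(ValueError, match="too small"):
            st.run_pipeline(tiny, st.PipelineConfig())

    def test_unknown_variant_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="variant"):
            st.run_pipeline(small_cohort, st.PipelineConfig(variant="bagged"))
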