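import dataclasses

import numpy as np
import pandas as pd
import pytest

from dooit import doo_core
from dooit.doo_core import (
    TrialResult,
    evaluate_trial,
    gamma_base,
    loco_splits,
    pareto_front,
    permutation_importance,
    run_doo,
    run_dooit,
    RunSeeds,
    select_1se,
    split_train_test,
    standardize,
)


class TestSplit:
    def test_80_20_partition(self):
        train, test = split_train_test(100, seed=3)
        assert len(train) == 80 and len(test) == 20

    def test_partition_laws(self):
        train, test = split_train_test(53, seed=9)
        assert sorted(set(train) | set(test)) == list(range(53))
        assert set(train) & set(test) == set()

    def test_deterministic_per_seed(self):
        a = split_train_test(40, seed=7)
        b = split_train_test(40, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        c = split_train_test(40, seed=8)
        assert not np.array_equal(a[1], c[1])

    def test_too_small(self):
        with pytest.raises(ValueError):
            split_train_test(5)


class TestStandardize:
    def test_hand_computed_z_scores(self):
        _, Xs = standardize(np.array([[1.0], [2.0], [3.0]]))
        expected = np.array([[-1.224744871391589], [0.0], [1.224744871391589]])
        assert Xs == pytest.approx(expected, abs=1e-12)

    def test_idempotent_on_standardized_data(self, rng):
        X = rng.normal(size=(50, 3))
        _, Xs = standardize(X)
        _, Xss = standardize(Xs)
        assert Xss == pytest.approx(Xs, abs=1e-12)

    def test_frozen_transform_reapplied(self, rng):
        X = rng.normal(size=(30, 2))
        tf, _ = standardize(X)
        other = rng.normal(size=(10, 2))
        assert tf.transform(other) == pytest.approx((other - tf.mean_) / tf.scale_)

    def test_constant_column_named(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "flat": [5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(df)


class TestGammaBase:
    def test_unit_square_corners(self):
        # squared pairwise distances {1,1,1,1,2,2}: median 1 -> gamma_base 1
        X = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        assert gamma_base(X) == pytest.approx(1.0)

    def test_homogeneity(self, rng):
        X = rng.normal(size=(20, 4))
        assert gamma_base(2 * X) == pytest.approx(gamma_base(X) / 4)

    def test_identical_rows_rejected(self):
        with pytest.raises(ValueError, match="median"):
            gamma_base(np.ones((3, 2)))


class TestEvaluateTrial:
    def test_deterministic(self, small_qspr):
        table, _ = small_qspr
        feats = ["x00", "x01", "x02"]
        a = evaluate_trial(table, table.log_x, feats, 0.4, 10.0, 0.0, fold_seed=5)
        b = evaluate_trial(table, table.log_x, feats, 0.4, 10.0, 0.0, fold_seed=5)
        assert a == b

    def test_linear_target_low_error(self, rng):
        X = rng.normal(size=(150, 1))
        y = 0.7 * X[:, 0]
        table = pd.DataFrame(X, columns=["f"])
        t = evaluate_trial(table, y, ["f"], nu=0.8, c=100.0, log10_gamma_scale=0.0)
        assert t.cv_mae < 0.05

    def test_high_nu_forces_many_support_vectors(self, rng):
        X = rng.normal(size=(200, 3))
        y = np.sin(X[:, 0]) + rng.normal(0, 0.1, 200)
        t = evaluate_trial(pd.DataFrame(X, columns=list("abc")), y, list("abc"),
                           nu=0.8, c=10.0, log10_gamma_scale=0.0)
        assert all(f["sv_ratio"] >= 0.75 for f in t.folds)

    def test_failure_is_flagged_not_raised(self, small_qspr):
        table, _ = small_qspr
        # nu > 1 is outside the domain: libsvm refuses, trial records failure
        t = evaluate_trial(table, table.log_x, ["x00"], nu=1.5, c=1.0,
                           log10_gamma_scale=0.0)
        assert t.failed and t.error


class TestParetoFront:
    @staticmethod
    def oracle(trials):
        """Quadratic all-pairs domination check, written independently."""
        front = []
        for t in trials:
            dominated = False
            for u in trials:
                better_or_equal = u.cv_mae <= t.cv_mae and u.sv_ratio <= t.sv_ratio
                strictly = u.cv_mae < t.cv_mae or u.sv_ratio < t.sv_ratio
                if better_or_equal and strictly:
                    dominated = True
                    break
            if not dominated:
                front.append(t)
        return front

    @staticmethod
    def cloud(rng, n):
        return [
            TrialResult(trial_id=i, nu=0.5, c=1.0, log10_gamma_scale=0.0,
                        cv_mae=float(rng.uniform(0, 1)), cv_mae_se=0.01,
                        sv_ratio=float(rng.uniform(0.01, 1)))
            for i in range(n)
        ]

    def test_single_trial(self, rng):
        (t,) = self.cloud(rng, 1)
        assert pareto_front([t]) == [t]

    def test_strict_domination(self):
        a = TrialResult(0, 0.5, 1, 0, cv_mae=0.1, sv_ratio=0.2)
        b = TrialResult(1, 0.5, 1, 0, cv_mae=0.2, sv_ratio=0.3)
        assert pareto_front([a, b]) == [a]

    def test_duplicates_all_retained(self):
        a = TrialResult(0, 0.5, 1, 0, cv_mae=0.1, sv_ratio=0.2)
        b = TrialResult(1, 0.5, 1, 0, cv_mae=0.1, sv_ratio=0.2)
        assert pareto_front([a, b]) == [a, b]

    def test_matches_oracle_on_random_clouds(self, rng):
        for _ in range(20):
            trials = self.cloud(rng, int(rng.integers(1, 300)))
            got = {t.trial_id for t in pareto_front(trials)}
            want = {t.trial_id for t in self.oracle(trials)}
            assert got == want

    def test_failed_trials_excluded(self):
        ok = TrialResult(0, 0.5, 1, 0, cv_mae=0.3, sv_ratio=0.5)
        bad = TrialResult(1, 0.5, 1, 0, failed=True)
        assert pareto_front([ok, bad]) == [ok]
        with pytest.raises(ValueError):
            pareto_front([bad])


class TestSelect1SE:
    def _t(self, tid, mae, sv, se=0.0):
        return TrialResult(tid, 0.5, 1, 0, cv_mae=mae, cv_mae_se=se, sv_ratio=sv)

    def test_simpler_model_within_band_wins(self):
        front = [self._t(0, 0.070, 0.50, se=0.004), self._t(1, 0.0735, 0.30)]
        assert select_1se(front).trial_id == 1  # threshold 0.074 admits both

    def test_single_member_front(self):
        only = self._t(0, 0.07, 0.5, se=0.004)
        assert select_1se([only]) is only

    def test_sv_tie_breaks_to_lower_mae(self):
        front = [self._t(0, 0.071, 0.30, se=0.0), self._t(1, 0.070, 0.30, se=0.002)]
        assert select_1se(front).trial_id == 1

    def test_selected_satisfies_threshold(self, rng):
        for _ in range(50):
            front = pareto_front(TestParetoFront.cloud(rng, 40))
            best = min(front, key=lambda t: t.cv_mae)
            sel = select_1se(front)
            assert sel.cv_mae <= best.cv_mae + best.cv_mae_se


class TestPermutationImportance:
    class Constant:
        def predict(self, X):
            return np.zeros(len(X))

    def test_constant_model_zero_importance(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        imps = permutation_importance(self.Constant(), X, y, n_repeats=5, seed=1)
        assert all(v["mean"] == 0.0 for v in imps.values())

    def test_repeat_count(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        imps = permutation_importance(self.Constant(), X, rng.normal(size=30),
                                      n_repeats=10, seed=1)
        assert all(len(v["repeats"]) == 10 for v in imps.values())

    def test_planted_feature_dominates_noise(self, rng):
        class Oracle:
            def predict(self, X):
                return np.asarray(X)[:, 0]

        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["signal", "noise"])
        y = X["signal"].to_numpy()
        means = []
        for s in range(20):
            imps = permutation_importance(Oracle(), X, y, n_repeats=5, seed=s)
            assert imps["signal"]["mean"] > 10 * abs(imps["noise"]["mean"])
            means.append(imps["noise"]["mean"])
        # noise importance is statistically indistinguishable from zero
        assert abs(np.mean(means)) <= 2 * np.std(means, ddof=1) / np.sqrt(len(means)) + 1e-12

    def test_single_row_rejected(self, rng):
        X = pd.DataFrame([[1.0]], columns=["a"])
        with pytest.raises(ValueError):
            permutation_importance(self.Constant(), X, [0.0])


class TestRunDoo:
    def test_trial_count_and_totality(self, small_qspr):
        table, _ = small_qspr
        trials = run_doo(table, table.log_x, ["x00", "x01"], n_trials=10,
                         sampler_seed=1, fold_seed=2)
        assert len(trials) == 10
        assert all(t.failed or np.isfinite(t.cv_mae) for t in trials)

    def test_random_search_minimum_is_monotone_in_budget(self, small_qspr):
        table, _ = small_qspr
        kw = dict(sampler_seed=4, fold_seed=5, sampler="random")
        few = run_doo(table, table.log_x, ["x00", "x01"], n_trials=8, **kw)
        many = run_doo(table, table.log_x, ["x00", "x01"], n_trials=24, **kw)
        # same seeded stream: the first 8 proposals coincide
        for a, b in zip(few, many):
            assert (a.nu, a.c, a.log10_gamma_scale) == (b.nu, b.c, b.log10_gamma_scale)
        assert min(t.cv_mae for t in many) <= min(t.cv_mae for t in few)


@pytest.fixture(scope="module")
def trace(small_qspr):
    table, _ = small_qspr
    pool = [c for c in table.columns if c.startswith("x")]
    return run_dooit(
        table.loc[:60, pool], table.log_x[:61],
        table.loc[61:, pool], table.log_x[61:],
        pool, min_features=3, n_trials=12, seeds=RunSeeds(1, 2, 3),
    )


class TestRunDooit:
    def test_trace_length(self, trace):
        assert len(trace.candidates) == 6 - 3 + 1

    def test_strictly_nested_decreasing_feature_sets(self, trace):
        sets = [set(c.feature_names) for c in trace.candidates]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller < bigger and len(bigger) - len(smaller) == 1

    def test_eliminated_feature_bookkeeping(self, trace):
        for cand, nxt in zip(trace.candidates, trace.candidates[1:]):
            assert cand.eliminated in cand.feature_names
            assert cand.eliminated not in nxt.feature_names
        assert trace.candidates[-1].eliminated is None

    def test_importance_keys_match_features(self, trace):
        for cand in trace.candidates:
            assert sorted(cand.importances) == sorted(cand.feature_names)

    def test_pool_not_larger_than_min_features_rejected(self, small_qspr):
        table, _ = small_qspr
        with pytest.raises(ValueError):
            run_dooit(table, table.log_x, table, table.log_x, ["x00"], min_features=1)


class TestLocoSplits:
    def test_one_split_per_solute(self):
        # eleven organic acids -> eleven held-out-compound splits
        ids = [f"acid{i}" for i in range(11) for _ in range(3)]
        splits = loco_splits(ids)
        assert len(splits) == 11

    def test_each_row_tested_exactly_once(self):
        ids = ["a", "b", "a", "c", "b", "c", "c"]
        splits = loco_splits(ids)
        tested = np.concatenate([test for _, test in splits])
        assert sorted(tested.tolist()) == list(range(len(ids)))
        for train, test in splits:
            assert set(np.array(ids)[train]) & set(np.array(ids)[test]) == set()

    def test_single_solute_rejected(self):
        with pytest.raises(ValueError):
            loco_splits(["only"] * 5)
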