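import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fusionda as fd
from fusionda.validation import RDCVResult, _fold_assignment


class TestNMC:
    def test_identity_and_full_flip(self):
        assert fd.nmc([0, 1, 1, 0], [0, 1, 1, 0]) == 0
        assert fd.nmc([0, 1, 1, 0], [1, 0, 0, 1]) == 4

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1))
    def test_direct_count_oracle(self, pairs):
        y, yhat = zip(*pairs)
        assert fd.nmc(y, yhat) == sum(a != b for a, b in pairs)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fd.nmc([0, 1], [0])


class TestAUROC:
    def test_perfect_separation(self):
        assert fd.auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties(self):
        assert fd.auroc([0, 1, 0, 1], [3.0, 3.0, 3.0, 3.0]) == 0.5

    def test_worked_example(self):
        assert fd.auroc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(100))
    def test_brute_force_pair_oracle(self, seed):
        """Rank formulation equals explicit counting over all case-control
        pairs (ties one half)."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 20)
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.normal(size=n), 1)  # rounding forces ties
        total = 0.0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                total += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        expected = total / (np.sum(y == 1) * np.sum(y == 0))
        assert fd.auroc(y, s) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fd.auroc([1, 1], [0.1, 0.2])


class TestDQ2:
    def test_exact_predictions(self):
        assert fd.dq2([0, 1, 1, 0], [0.0, 1.0, 1.0, 0.0]) == 1.0

    def test_overshoot_not_penalized(self):
        base = fd.dq2([0, 1], [0.0, 1.0])
        assert fd.dq2([0, 1], [0.0, 1.3]) == base == 1.0
        assert fd.dq2([0, 1], [-0.4, 1.0]) == 1.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_at_least_raw_q2_equality_iff_no_overshoot(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        y = rng.integers(0, 2, size=n).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        yhat = rng.normal(loc=y, scale=0.7)
        raw_q2 = 1.0 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        val = fd.dq2(y, yhat)
        assert val >= raw_q2 - 1e-12
        overshoot = np.any(((y == 1) & (yhat > 1)) | ((y == 0) & (yhat < 0)))
        if not overshoot:
            assert val == pytest.approx(raw_q2, abs=1e-12)
        else:
            assert val > raw_q2


class TestFoldAssignment:
    def test_stratified_folds_cover_and_balance(self):
        labels = np.array([1] * 16 + [0] * 12)
        fold = _fold_assignment(labels, 7, np.random.default_rng(0), True)
        assert set(fold) == set(range(7))
        for f in range(7):
            # every outer-training set keeps both classes
            tr = labels[fold != f]
            assert 0 < tr.sum() < tr.size


class TestRunRDCV:
    def test_seeded_determinism(self, cohort28):
        cfg = fd.RDCVConfig(repetitions=3, seed=5)
        a = fd.run_rdcv(cohort28, cfg)
        b = fd.run_rdcv(cohort28, cfg)
        np.testing.assert_array_equal(a.predictions, b.predictions)
        np.testing.assert_array_equal(a.chosen_components, b.chosen_components)
        np.testing.assert_array_equal(a.segment_coefs, b.segment_coefs)
        assert a.merits == b.merits

    def test_segment_count_and_shapes(self, cohort28):
        cfg = fd.RDCVConfig(repetitions=4, seed=2)
        res = fd.run_rdcv(cohort28, cfg)
        assert res.n_segments == 4 * cfg.outer_folds
        assert res.predictions.shape == (4, 28)
        assert res.segment_coefs.shape == (28, 37)
        assert np.isfinite(res.predictions).all()
        assert (res.chosen_components >= 1).all()
        assert (res.chosen_components <= cfg.a_max).all()

    def test_separated_regime_high_auroc(self, cohort28):
        """At the published effect sizes the per-repetition AUROC is high."""
        res = fd.run_rdcv(cohort28, fd.RDCVConfig(repetitions=10, seed=3))
        assert np.mean([m.auroc for m in res.merits]) > 0.65

    def test_label_shuffled_data_near_chance(self, null_overrides):
        overall = []
        for seed in range(3):
            d = fd.generate_cohort(
                fd.CohortConfig(seed=seed, effect_overrides=null_overrides)
            )
            res = fd.run_rdcv(d, fd.RDCVConfig(repetitions=10, seed=seed))
            overall.append(fd.classification_summary(res).loc["overall", "mean"])
        assert abs(np.mean(overall) - 50.0) < 15.0

    def test_no_leakage_through_scaling_and_model(self, cohort28, rng):
        """Corrupting held-out rows changes their predictions but not the
        parameters learned from training rows."""
        train = cohort28.subset(np.arange(0, 20))
        scaling = fd.fit_scaling(train)
        fused_train = fd.apply_scaling(scaling, train)
        model = fd.fit_plsda(fused_train.values, train.labels, 2)
        scaling2 = fd.fit_scaling(train)
        assert np.array_equal(scaling.means, scaling2.means)
        corrupted = cohort28.subset(np.arange(20, 28))
        for blk in corrupted.blocks:
            corrupted.blocks[blk] = corrupted.blocks[blk] * 1e6
        preds_corrupt = fd.predict_response(
            model, fd.apply_scaling(scaling, corrupted).values
        )
        preds_clean = fd.predict_response(
            model,
            fd.apply_scaling(
                scaling, cohort28.subset(np.arange(20, 28))
            ).values,
        )
        assert not np.allclose(preds_corrupt, preds_clean)

    def test_infeasible_folds_rejected(self, cohort28):
        with pytest.raises(ValueError):
            fd.run_rdcv(cohort28, fd.RDCVConfig(outer_folds=20, seed=0))


class TestClassificationSummary:
    def _fake_result(self, pc):
        return RDCVResult(
            labels=np.array([0, 1]),
            columns=["a"],
            predictions=np.zeros((len(pc), 2)),
            merits=[],
            percent_correct=pd.DataFrame(pc, columns=["case", "control", "overall"]),
            chosen_components=np.ones((len(pc), 1), dtype=int),
            segment_coefs=np.ones((len(pc), 1)),
        )

    def test_all_perfect(self):
        s = fd.classification_summary(self._fake_result([[100, 100, 100]] * 3))
        assert (s["mean"] == 100).all()
        assert (s["sd"] == 0).all()

    def test_two_point_sd(self):
        s = fd.classification_summary(self._fake_result([[90, 80, 85], [100, 80, 91]]))
        assert s.loc["case", "mean"] == pytest.approx(95.0)
        assert s.loc["case", "sd"] == pytest.approx(7.0710678, rel=1e-6)


class TestPermutationTest:
    def test_strong_signal_hits_resolution_floor(self, cohort28):
        cfg = fd.RDCVConfig(repetitions=2, seed=9)
        perm = fd.permutation_test(cohort28, cfg, n_perm=19, perm_repetitions=1)
        assert len(perm.null) == 19
        assert perm.pvalues["auroc"] == pytest.approx(1 / 20)
        assert all(0 < p <= 1 for p in perm.pvalues.values())

    def test_determinism(self, cohort28):
        cfg = fd.RDCVConfig(repetitions=1, seed=4)
        a = fd.permutation_test(cohort28, cfg, n_perm=5)
        b = fd.permutation_test(cohort28, cfg, n_perm=5)
        pd.testing.assert_frame_equal(a.null, b.null)
        assert a.pvalues == b.pvalues

    def test_invalid_counts(self, cohort28):
        with pytest.raises(ValueError):
            fd.permutation_test(cohort28, fd.RDCVConfig(seed=0), n_perm=0)
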