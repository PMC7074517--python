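import numpy as np
import pytest

import fusionda as fd


@pytest.fixture()
def class_data(rng):
    return rng.normal(size=(20, 6)) * [1, 2, 3, 1, 1, 5] + [10, 0, -4, 2, 2, 100]


class TestFitSimca:
    def test_centroid_has_zero_statistics(self, class_data):
        model = fd.fit_simca(class_data, 3)
        stats = fd.simca_statistics(model, class_data.mean(axis=0))
        assert stats["t2_red"].iloc[0] == pytest.approx(0.0, abs=1e-20)
        assert stats["q_red"].iloc[0] == pytest.approx(0.0, abs=1e-20)
        assert fd.simca_distance(model, class_data.mean(axis=0)) == 0.0

    def test_full_rank_has_zero_residuals(self, class_data):
        model = fd.fit_simca(class_data, 6)
        assert np.allclose(model.calibration_q, 0.0, atol=1e-20)

    def test_loadings_orthonormal(self, class_data):
        model = fd.fit_simca(class_data, 4)
        G = model.loadings.T @ model.loadings
        assert np.abs(G - np.eye(4)).max() < 1e-8

    def test_t2_matches_explicit_mahalanobis(self, class_data):
        """T2 equals the Mahalanobis distance computed with the explicit
        score covariance matrix."""
        model = fd.fit_simca(class_data, 3)
        Z = (class_data - model.means) / model.sds
        scores = Z @ model.loadings
        cov = np.cov(scores, rowvar=False)
        t2_direct = np.array([s @ np.linalg.solve(cov, s) for s in scores])
        np.testing.assert_allclose(model.calibration_t2, t2_direct, rtol=1e-8)

    def test_too_many_components_rejected(self, class_data):
        with pytest.raises(ValueError):
            fd.fit_simca(class_data, 20)

    def test_zero_variance_column_rejected(self, class_data):
        bad = class_data.copy()
        bad[:, 2] = 7.0
        with pytest.raises(ValueError):
            fd.fit_simca(bad, 2)


class TestDistance:
    def test_unit_reduced_statistics_give_sqrt_two(self, class_data, rng):
        """A sample whose raw T2 and Q equal the stored 95th percentiles has
        d = sqrt(2) by direct substitution."""
        model = fd.fit_simca(class_data, 3)
        probe = rng.normal(size=6)
        stats = fd.simca_statistics(model, probe)
        model.t2_95 = stats["t2_red"].iloc[0] * model.t2_95
        model.q_95 = stats["q_red"].iloc[0] * model.q_95
        assert fd.simca_distance(model, probe) == pytest.approx(np.sqrt(2.0), rel=1e-10)

    def test_independent_pipeline_oracle(self, class_data, rng):
        """d matches a from-scratch recomputation of T2, Q, and the
        percentile normalization."""
        model = fd.fit_simca(class_data, 2)
        samples = rng.normal(size=(5, 6)) * 3
        Z = (samples - model.means) / model.sds
        scores = Z @ model.loadings
        t2 = np.sum(scores**2 / model.score_var, axis=1)
        q = np.sum((Z - scores @ model.loadings.T) ** 2, axis=1)
        expected = np.sqrt((t2 / model.t2_95) ** 2 + (q / model.q_95) ** 2)
        np.testing.assert_allclose(fd.simca_distance(model, samples), expected, rtol=1e-10)

    def test_monotone_in_each_reduced_coordinate(self):
        t = np.linspace(0, 3, 10)
        d_fixed_q = np.hypot(t, 1.0)
        d_fixed_t = np.hypot(1.0, t)
        assert np.all(np.diff(d_fixed_q) > 0)
        assert np.all(np.diff(d_fixed_t) > 0)

    def test_dimension_mismatch(self, class_data):
        model = fd.fit_simca(class_data, 2)
        with pytest.raises(ValueError):
            fd.simca_distance(model, np.zeros(4))


class TestClassify:
    def test_strict_threshold(self, class_data, rng):
        model = fd.fit_simca(class_data, 2)
        probe = rng.normal(size=6) * 2
        d = fd.simca_distance(model, probe)
        model.threshold = d  # d == threshold -> rejected
        assert not fd.simca_classify(model, probe)
        model.threshold = d + 1e-9
        assert fd.simca_classify(model, probe)

    def test_centroid_accepted(self, class_data):
        model = fd.fit_simca(model_data := class_data, 2)
        assert fd.simca_classify(model, model_data.mean(axis=0))

    def test_acceptance_region_is_quarter_disk(self):
        """{d < 2} in the (T2_red, Q_red) quarter-plane is the radius-2
        quarter disk."""
        t2r, qr = np.meshgrid(np.linspace(0, 3, 61), np.linspace(0, 3, 61))
        inside = np.hypot(t2r, qr) < 2.0
        disk = t2r**2 + qr**2 < 4.0
        np.testing.assert_array_equal(inside, disk)

    def test_percentile_self_consistency(self, rng):
        X = rng.normal(size=(200, 8))
        model = fd.fit_simca(X, 3)
        stats = fd.simca_statistics(model, X)
        assert np.mean(stats["t2_red"] <= 1.0) >= 0.95
        assert np.mean(stats["q_red"] <= 1.0) >= 0.95


class TestAssess:
    def test_efficiency_arithmetic(self):
        assert fd.SIMCAAssessment(100.0, 100.0).efficiency == 100.0
        assert fd.SIMCAAssessment(100.0, 0.0).efficiency == 0.0
        assert fd.SIMCAAssessment(90.0, 40.0).efficiency == pytest.approx(60.0)

    def test_separated_classes(self, rng):
        inn = rng.normal(size=(30, 4))
        out = rng.normal(size=(20, 4)) + 25
        model = fd.fit_simca(inn, 2)
        a = fd.assess(model, inn, out)
        assert a.sensitivity >= 90.0
        assert a.specificity == 100.0

    def test_empty_inputs_rejected(self, rng):
        inn = rng.normal(size=(10, 3))
        model = fd.fit_simca(inn, 1)
        with pytest.raises(ValueError):
            fd.assess(model, inn, np.empty((0, 3)))

    def test_out_of_class_uses_class_scaling(self, class_data, rng):
        """Shifting out-of-class samples away from the class center must
        increase their distances — they are scaled by the class model."""
        model = fd.fit_simca(class_data, 2)
        out = class_data[:5]
        d_near = fd.simca_distance(model, out)
        d_far = fd.simca_distance(model, out + 50 * model.sds)
        assert np.all(d_far > d_near)


class TestSelectNpc:
    def test_single_candidate(self, rng):
        inn = rng.normal(size=(14, 5))
        out = rng.normal(size=(6, 5)) + 10
        assert fd.select_npc(inn, out, cv_folds=7, a_max=1) == 1

    def test_planted_low_rank_structure(self, rng):
        """With a planted rank-2 class, CV efficiency peaks at or below
        rank + 2 and then declines."""
        n, p, rank = 40, 10, 2
        scores = rng.normal(size=(n, rank)) * [4.0, 2.5]
        load = np.linalg.qr(rng.normal(size=(p, rank)))[0]
        inn = scores @ load.T + 0.3 * rng.normal(size=(n, p))
        out = inn[:20] + 3.0 * rng.normal(size=(20, p)) + 2.0
        curve = fd.efficiency_curve(inn, out, cv_folds=7, a_max=8)
        best = int(curve.loc[curve["efficiency"].idxmax(), "n_components"])
        assert best <= rank + 2
        assert fd.select_npc(inn, out, cv_folds=7, a_max=8) == best

    def test_default_generator_classes_separable(self, cohort28):
        tbl = cohort28.to_frame()
        inn = tbl.loc[cohort28.labels == 1]
        out = tbl.loc[cohort28.labels == 0]
        curve = fd.efficiency_curve(inn, out, cv_folds=7, a_max=5)
        best = curve.loc[curve["efficiency"].idxmax()]
        assert best["sensitivity"] >= 80.0
        assert best["specificity"] >= 80.0

    def test_infeasible_folds(self, rng):
        with pytest.raises(ValueError):
            fd.efficiency_curve(rng.normal(size=(5, 3)), rng.normal(size=(3, 3)), cv_folds=6)
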