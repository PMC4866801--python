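import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from peagrade.discriminant import (
    DEFECT_LABELS,
    SingularCovarianceError,
    accuracy,
    anova_f,
    classify,
    fit_lda,
    forward_select,
    mahalanobis_summary,
    record_label,
    screen_features,
)
from peagrade.features import FEATURE_NAMES

from conftest import make_record


def records_1d(feature, class_values, grades=None, **kwargs):
    """Build records varying a single feature; class_values maps grade -> values."""
    out = []
    i = 0
    for grade, values in class_values.items():
        for v in values:
            out.append(make_record({feature: v}, sample_id=f"r{i}", grade=grade, **kwargs))
            i += 1
    return out


class TestAnova:
    def test_worked_example_f2(self):
        # groups {0,1} and {1,2}: SSB=1 (df 1), SSW=1 (df 2) -> F = 2
        f, p, df = anova_f([np.array([0.0, 1.0]), np.array([1.0, 2.0])])
        assert f == pytest.approx(2.0)
        assert df == (1, 2)
        # dual route: scipy.stats.f_oneway as independent oracle
        f_sp, p_sp = stats.f_oneway([0.0, 1.0], [1.0, 2.0])
        assert f == pytest.approx(f_sp)
        assert p == pytest.approx(p_sp)

    def test_equal_group_means_give_zero(self):
        f, p, _ = anova_f([np.array([1.0, 3.0]), np.array([0.0, 4.0])])
        assert f == 0.0
        assert p == 1.0

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            anova_f([np.array([1.0]), np.array([1.0, 2.0])])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_scipy_on_random_groups(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.normal(), 1, rng.integers(2, 8)) for _ in range(3)]
        f, p, _ = anova_f(groups)
        f_sp, p_sp = stats.f_oneway(*groups)
        assert f == pytest.approx(f_sp, rel=1e-10)
        assert p == pytest.approx(p_sp, rel=1e-8)


class TestScreen:
    def test_report_shape_and_rank(self):
        rng = np.random.default_rng(1)
        recs = records_1d(
            "violet_factor",
            {"White": rng.normal(0, 1, 5), "Blue": rng.normal(3, 1, 5)},
        )
        # give the other features independent variation
        for r in recs:
            r.std_features = rng.normal(size=13)
            r.std_features[0] = r.raw_features[0]
        rep = screen_features(recs)
        assert rep.f_statistics.shape == (13,)
        assert np.all(rep.f_statistics >= 0)
        assert np.all((rep.p_values >= 0) & (rep.p_values <= 1))
        assert np.all(np.diff(rep.singular_values) <= 1e-12)

    def test_duplicated_column_not_full_rank(self):
        rng = np.random.default_rng(2)
        recs = []
        for i in range(10):
            v = rng.normal(size=13)
            v[1] = v[0]  # duplicate column
            recs.append(
                make_record({}, sample_id=f"r{i}", grade="White" if i < 5 else "Blue")
            )
            recs[-1].std_features = v
        assert not screen_features(recs).full_rank

    def test_group_with_one_record_errors(self):
        recs = records_1d("area", {"White": [1.0, 2.0], "Blue": [3.0]})
        with pytest.raises(ValueError):
            screen_features(recs)


class TestFitLDA:
    def test_pooled_variance_of_two_unit_variance_classes(self):
        recs = records_1d(
            "area",
            {"White": [-1.0, 0.0, 1.0], "Blue": [9.0, 10.0, 11.0]},
        )
        model = fit_lda(recs, ["area"], ["White", "Blue"])
        assert model.pooled_cov[0, 0] == pytest.approx(1.0)
        np.testing.assert_allclose(model.class_means.ravel(), [0.0, 10.0])

    def test_parameter_recovery_on_simulation(self):
        rng = np.random.default_rng(42)
        recs = records_1d(
            "area",
            {"White": rng.normal(0, 1, 200), "Blue": rng.normal(10, 1, 200)},
        )
        model = fit_lda(recs, ["area"], ["White", "Blue"])
        assert abs(model.class_means[0, 0] - 0.0) < 0.2
        assert abs(model.class_means[1, 0] - 10.0) < 0.2

    def test_rank_bound_singularity(self):
        rng = np.random.default_rng(0)
        recs = []
        for i, grade in enumerate(["White", "White", "Blue", "Blue"]):
            r = make_record({}, sample_id=f"r{i}", grade=grade)
            r.std_features = rng.normal(size=13)
            recs.append(r)
        with pytest.raises(SingularCovarianceError):
            fit_lda(recs, ["area", "perimeter", "volume"], ["White", "Blue"])

    def test_class_with_one_record_errors(self):
        recs = records_1d("area", {"White": [1.0, 2.0], "Blue": [3.0]})
        with pytest.raises(ValueError):
            fit_lda(recs, ["area"], ["White", "Blue"])


class TestClassify:
    def _model_1d(self):
        recs = records_1d(
            "area",
            {"White": [-1.0, 0.0, 1.0], "Blue": [9.0, 10.0, 11.0]},
        )
        return fit_lda(recs, ["area"], ["White", "Blue"])

    def test_record_at_class_mean(self):
        model = self._model_1d()
        pred = classify(model, make_record({"area": 10.0}))
        assert pred.predicted_label == "Blue"
        assert pred.nearest_distance == pytest.approx(0.0)

    def test_1d_distances(self):
        model = self._model_1d()
        pred = classify(model, make_record({"area": 4.0}))
        assert pred.distances["White"] == pytest.approx(4.0)
        assert pred.distances["Blue"] == pytest.approx(6.0)
        assert pred.predicted_label == "White"

    def test_tie_broken_by_declared_order(self):
        model = self._model_1d()
        pred = classify(model, make_record({"area": 5.0}))
        assert pred.distances["White"] == pytest.approx(pred.distances["Blue"])
        assert pred.predicted_label == "White"

    @given(st.integers(0, 10**6))
    @settings(max_examples=200, deadline=None)
    def test_argmin_distance_equals_argmax_score(self, seed):
        # nearest-Mahalanobis = max linear discriminant score (equal priors)
        rng = np.random.default_rng(seed)
        p, k = rng.integers(1, 4), rng.integers(2, 5)
        a = rng.normal(size=(p, p))
        cov = a @ a.T + np.eye(p) * 0.5
        means = rng.normal(scale=3, size=(k, p))
        labels = [f"c{i}" for i in range(k)]
        from peagrade.discriminant import LDAModel
        from scipy import linalg

        cho = linalg.cho_factor(cov)
        model = LDAModel(
            feature_names=tuple(FEATURE_NAMES[:p]),
            class_labels=tuple(labels),
            class_means=means,
            pooled_cov=cov,
            pooled_cov_inv=linalg.cho_solve(cho, np.eye(p)),
            _cho=cho,
        )
        x = rng.normal(scale=3, size=p)
        d = model.mahalanobis_distances(x)
        s = model.discriminant_scores(x)
        d_sorted = np.sort(d)
        if d_sorted[1] - d_sorted[0] < 1e-9:  # numerical tie: either argmin is valid
            return
        assert int(np.argmin(d)) == int(np.argmax(s))

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        recs = []
        for i in range(40):
            grade = "White" if i < 20 else "Blue"
            mu = 0.0 if i < 20 else 3.0
            r = make_record({}, sample_id=f"r{i}", grade=grade)
            r.std_features = np.zeros(13)
            r.std_features[:3] = rng.normal(mu, 1, 3)
            recs.append(r)
        feats = list(FEATURE_NAMES[:3])
        model = fit_lda(recs, feats, ["White", "Blue"])
        x = rng.normal(size=3)
        probe = make_record({})
        probe.std_features = np.zeros(13)
        probe.std_features[:3] = x
        d_before = classify(model, probe).distances

        A = rng.normal(size=(3, 3)) + np.eye(3) * 2
        b = rng.normal(size=3)
        for r in recs:
            r.std_features[:3] = A @ r.std_features[:3] + b
        model_t = fit_lda(recs, feats, ["White", "Blue"])
        probe.std_features[:3] = A @ x + b
        d_after = classify(model_t, probe).distances
        for c in d_before:
            assert d_before[c] == pytest.approx(d_after[c], rel=1e-8)

    def test_two_gaussian_accuracy_matches_phi(self):
        # equal-covariance classes at Mahalanobis separation 4:
        # asymptotic accuracy Phi(2) ~ 0.9772
        rng = np.random.default_rng(11)
        n_train, n_test = 2000, 50_000
        train = records_1d(
            "area",
            {"White": rng.normal(0, 1, n_train), "Blue": rng.normal(4, 1, n_train)},
        )
        model = fit_lda(train, ["area"], ["White", "Blue"])
        x = np.concatenate([rng.normal(0, 1, n_test), rng.normal(4, 1, n_test)])
        true = np.array([0] * n_test + [1] * n_test)
        d0 = np.abs(x - model.class_means[0, 0])
        d1 = np.abs(x - model.class_means[1, 0])
        acc = np.mean((d1 < d0) == true)
        assert acc == pytest.approx(stats.norm.cdf(2.0), abs=0.005)


class TestForwardSelect:
    def _recs(self, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(60):
            grade = "White" if i < 30 else "Blue"
            r = make_record({}, sample_id=f"r{i}", grade=grade)
            v = np.zeros(13)
            v[0] = (0 if i < 30 else 8) + rng.normal()  # separates perfectly
            v[1] = rng.normal()  # pure noise
            v[2] = rng.normal()  # pure noise
            r.std_features = v
            recs.append(r)
        return recs

    def test_perfect_first_feature_is_sufficient(self):
        recs = self._recs()
        sel = forward_select(
            recs, [FEATURE_NAMES[0], FEATURE_NAMES[1], FEATURE_NAMES[2]], ["White", "Blue"]
        )
        assert sel == [FEATURE_NAMES[0]]

    def test_noise_candidate_never_retained(self):
        for seed in range(5):
            recs = self._recs(seed)
            sel = forward_select(
                recs, [FEATURE_NAMES[0], FEATURE_NAMES[1]], ["White", "Blue"]
            )
            assert FEATURE_NAMES[1] not in sel

    def test_output_is_subsequence_of_input(self, small_records):
        cal = [r for r in small_records if r.split == "calibration"]
        candidates = list(FEATURE_NAMES)
        sel = forward_select(cal, candidates, sorted({r.grade for r in cal}))
        positions = [candidates.index(f) for f in sel]
        assert positions == sorted(positions)

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            forward_select([], [], ["a", "b"])


class TestMahalanobisSummary:
    def test_records_at_class_means(self):
        recs = records_1d(
            "area", {"White": [-1.0, 0.0, 1.0], "Blue": [9.0, 10.0, 11.0]}
        )
        model = fit_lda(recs, ["area"], ["White", "Blue"])
        at_means = [
            make_record({"area": 0.0}, sample_id="a"),
            make_record({"area": 10.0}, sample_id="b"),
        ]
        s = mahalanobis_summary(model, at_means)
        assert s.nondefective_mean == pytest.approx(0.0)
        assert s.nondefective_se == pytest.approx(0.0)
        assert s.defective_n == 0 and s.defective_mean is None

    def test_single_record_se_missing(self):
        recs = records_1d(
            "area", {"White": [-1.0, 0.0, 1.0], "Blue": [9.0, 10.0, 11.0]}
        )
        model = fit_lda(recs, ["area"], ["White", "Blue"])
        only = [make_record({"area": 3.0}, sample_id="a", defective=True)]
        s = mahalanobis_summary(model, only)
        assert s.defective_n == 1
        assert s.defective_se is None

    def test_defective_group_lies_farther(self):
        # colour-shifted defective samples sit farther from every class mean
        rng = np.random.default_rng(4)
        recs = []
        for i in range(40):
            grade = "White" if i < 20 else "Blue"
            mu = 0.0 if i < 20 else 6.0
            r = make_record({"area": rng.normal(mu, 1)}, sample_id=f"r{i}", grade=grade)
            recs.append(r)
        model = fit_lda(recs, ["area"], ["White", "Blue"])
        probes = []
        for i in range(30):
            defective = i % 2 == 0
            mu = 3.0 if defective else 0.0  # defect shifts toward the midpoint
            probes.append(
                make_record(
                    {"area": rng.normal(mu, 0.3)}, sample_id=f"p{i}", defective=defective
                )
            )
        s = mahalanobis_summary(model, probes)
        assert s.defective_mean > s.nondefective_mean

    def test_label_helper(self):
        r = make_record({}, defective=True)
        assert record_label(r, "defect") == DEFECT_LABELS[0]
        assert record_label(r, "grade") == "White"
        with pytest.raises(ValueError):
            record_label(r, "colour")
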