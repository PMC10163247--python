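import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bf_backward, bf_decide_1d
from treecloud import (
    CloudClassifier,
    CloudParams,
    backward_generate,
    classify_max,
    fit_classifier,
    forward_drops,
    membership_1d,
    membership_nd,
    predict_cloud,
)

SQRT_HALF_PI = np.sqrt(np.pi / 2)


class TestBackwardGenerate:
    def test_constant_sample(self):
        p = backward_generate([3.7] * 10)
        assert p.Ex == pytest.approx(3.7)
        assert p.En == pytest.approx(0.0, abs=1e-12)
        assert p.He == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        p = backward_generate([0, 1, 2, 3, 4])
        assert p.Ex == pytest.approx(2.0)
        assert p.En == pytest.approx(SQRT_HALF_PI * 1.2)  # ~1.50398
        assert p.He == pytest.approx(np.sqrt(2.5 - (SQRT_HALF_PI * 1.2) ** 2))

    @given(shift=st.floats(-100, 100))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_translation_equivariance(self, shift):
        x = np.array([0.2, 1.4, -0.7, 3.3, 2.2, 0.9])
        p0 = backward_generate(x)
        p1 = backward_generate(x + shift)
        assert p1.Ex == pytest.approx(p0.Ex + shift, abs=1e-9)
        assert p1.En == pytest.approx(p0.En, abs=1e-9)
        assert p1.He == pytest.approx(p0.He, abs=1e-9)

    def test_matches_direct_formula_oracle(self, rng):
        import warnings

        for _ in range(50):
            x = rng.normal(size=rng.integers(2, 30))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                p = backward_generate(x)
            ex, en, he = bf_backward(x)
            assert p.Ex == pytest.approx(ex, rel=1e-12, abs=1e-12)
            assert p.En == pytest.approx(en, rel=1e-12, abs=1e-12)
            assert p.He == pytest.approx(he, rel=1e-12, abs=1e-12)

    def test_light_tailed_sample_clamps_hyper_entropy(self):
        # two-point samples have S^2 < En^2: the clamp warning fires
        with pytest.warns(UserWarning, match="clamped"):
            p = backward_generate([0.0, 1.0, 0.0, 1.0])
        assert p.He == 0.0

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            backward_generate([1.0])


class TestForwardDrops:
    def test_zero_hyper_entropy_gives_pure_gaussian_kernel(self):
        p = CloudParams(5, 2, 0)
        x, m = forward_drops(p, 100, seed=0)
        np.testing.assert_allclose(m, np.exp(-((x - 5) ** 2) / 8.0))

    def test_zero_entropy_pins_all_drops_at_expectation(self):
        x, m = forward_drops(CloudParams(1.5, 0, 0), 10, seed=0)
        assert np.all(x == 1.5) and np.all(m == 1.0)

    def test_seeded_determinism(self):
        p = CloudParams(0, 1, 0.3)
        a = forward_drops(p, 1, seed=42)
        b = forward_drops(p, 1, seed=42)
        assert a[0] == b[0] and a[1] == b[1]

    def test_roundtrip_parameter_recovery(self):
        errs = []
        for seed in range(20):
            x, _ = forward_drops(CloudParams(5, 2, 0.4), 10000, seed=seed)
            p = backward_generate(x)
            errs.append([abs(p.Ex - 5), abs(p.En - 2), abs(p.He - 0.4)])
        mean_err = np.mean(errs, axis=0)
        assert mean_err[0] < 0.06 and mean_err[1] < 0.06 and mean_err[2] < 0.15

    def test_recovery_improves_with_sample_size(self):
        def mean_errors(n):
            errs = []
            for seed in range(20):
                x, _ = forward_drops(CloudParams(5, 2, 0.4), n, seed=seed)
                p = backward_generate(x)
                errs.append([abs(p.Ex - 5), abs(p.En - 2), abs(p.He - 0.4)])
            return np.mean(errs, axis=0)

        small, large = mean_errors(1000), mean_errors(100000)
        assert np.all(large < small)


class TestMembership:
    def test_peak_at_expectation(self):
        assert membership_1d(CloudParams(3, 1.5, 0), 3.0) == 1.0

    def test_deterministic_hand_value(self):
        assert membership_1d(CloudParams(0, 1, 0), 1.0) == pytest.approx(
            np.exp(-0.5)
        )

    def test_symmetry_about_expectation(self):
        p = CloudParams(2, 0.7, 0.1)
        assert membership_1d(p, 2.9) == pytest.approx(membership_1d(p, 1.1))

    def test_zero_entropy_away_from_peak(self):
        with pytest.warns(UserWarning):
            assert membership_1d(CloudParams(0, 0, 0), 1.0) == 0.0

    def test_stochastic_mode_converges_to_stable_estimate(self):
        p = CloudParams(5, 2, 0.4)
        for x0 in np.linspace(-1, 11, 13):
            a = membership_1d(p, x0, "stochastic", m_draws=1000, seed=3)
            b = membership_1d(p, x0, "stochastic", m_draws=10000, seed=103)
            assert abs(a - b) < 0.01

    def test_nd_reduces_to_1d(self):
        p = CloudParams(0.5, 0.2, 0)
        assert membership_nd((p,), [0.9]) == pytest.approx(membership_1d(p, 0.9))

    def test_nd_joint_peak(self):
        dims = tuple(CloudParams(v, 1, 0) for v in (0, 2, 4))
        assert membership_nd(dims, [0, 2, 4]) == pytest.approx(1.0)

    def test_nd_product_hand_value(self):
        dims = (CloudParams(0, 1, 0), CloudParams(0, 1, 0))
        assert membership_nd(dims, [1, 1]) == pytest.approx(np.exp(-1))

    def test_nd_missing_dimension_excluded(self):
        dims = (CloudParams(0, 1, 0), CloudParams(10, 1, 0))
        with pytest.warns(UserWarning):
            m = membership_nd(dims, [1, np.nan])
        assert m == pytest.approx(np.exp(-0.5))

    def test_nd_all_missing_unclassifiable(self):
        dims = (CloudParams(0, 1, 0),)
        assert np.isnan(membership_nd(dims, [np.nan]))


def two_species_classifier(ex_a=0.0, ex_b=4.0, en=1.0):
    return CloudClassifier(
        ("x",),
        {"A": (CloudParams(ex_a, en, 0.1),), "B": (CloudParams(ex_b, en, 0.1),)},
    )


class TestClassifyMax:
    def test_peak_assignment(self):
        clf = two_species_classifier()
        res = classify_max(clf, pd.DataFrame({"x": [0.0]}))[0]
        assert res.winner == "A" and res.memberships["A"] == pytest.approx(1.0)

    def test_hand_membership_pair(self):
        clf = two_species_classifier()
        res = classify_max(clf, pd.DataFrame({"x": [1.0]}))[0]
        assert res.memberships["A"] == pytest.approx(np.exp(-0.5))
        assert res.memberships["B"] == pytest.approx(np.exp(-4.5))
        assert res.winner == "A" and not res.tie_flag

    def test_symmetric_tie_flagged_lexicographic(self):
        clf = two_species_classifier(ex_a=0.0, ex_b=2.0)
        res = classify_max(clf, pd.DataFrame({"x": [1.0]}))[0]
        assert res.tie_flag and res.winner == "A"

    def test_decisions_match_grid_oracle(self, rng):
        """Deterministic max-membership decisions coincide with the
        brute-force minimal squared-deviation rule over a dense grid."""
        for _ in range(50):
            params = {
                "A": CloudParams(rng.uniform(-5, 5), rng.uniform(0.2, 3), 0.1),
                "B": CloudParams(rng.uniform(-5, 5), rng.uniform(0.2, 3), 0.1),
            }
            clf = CloudClassifier(("x",), {k: (v,) for k, v in params.items()})
            grid = np.linspace(-10, 10, 1000)
            pred = predict_cloud(clf, pd.DataFrame({"x": grid}))
            oracle = [bf_decide_1d(x, params) for x in grid]
            assert list(pred) == oracle


class TestFitClassifier:
    def test_constant_class_collapses_to_point_cloud(self):
        df = pd.DataFrame(
            {"label": ["A"] * 3 + ["B"] * 3, "x": [2.0, 2.0, 2.0, 0.0, 1.0, 2.0]}
        )
        clf = fit_classifier(df, ("x",))
        pa = clf.species_params["A"][0]
        assert pa.En == 0.0 and pa.He == 0.0

    def test_delegates_to_backward_generator(self):
        df = pd.DataFrame(
            {"label": ["A"] * 5 + ["B"] * 5, "x": [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]}
        )
        clf = fit_classifier(df, ("x",))
        expect = backward_generate([0, 1, 2, 3, 4])
        assert clf.species_params["A"][0] == expect

    def test_three_feature_dimensions(self, winter_samples):
        clf = fit_classifier(winter_samples, ("b2", "b3", "b4"))
        assert clf.n_dims == 3
        assert all(len(p) == 3 for p in clf.species_params.values())

    def test_undersized_class_rejected(self):
        df = pd.DataFrame({"label": ["A", "B", "B"], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fit_classifier(df, ("x",))


def test_classifier_json_roundtrip():
    clf = two_species_classifier()
    back = CloudClassifier.from_json(clf.to_json())
    assert back.feature_ids == clf.feature_ids
    assert back.species_params == clf.species_params
    assert back.mode == clf.mode
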