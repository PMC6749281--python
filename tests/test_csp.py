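import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fbcsp_select import (
    band_features,
    class_mean_covariance,
    normalized_covariance,
    solve_csp,
)


def _random_psd(rng, d):
    A = rng.standard_normal((d, d + 3))
    E = A @ A.T
    return E / np.trace(E)


class TestNormalizedCovariance:
    def test_orthogonal_unit_rows(self):
        X = np.stack([np.tile([1.0, -1.0], 25), np.tile([1.0, 1.0], 25)])
        assert np.allclose(normalized_covariance(X), np.eye(2) / 2, atol=1e-12)

    def test_trace_is_one(self, rng):
        cov = normalized_covariance(rng.standard_normal((4, 80)))
        assert np.trace(cov) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)

    def test_elementwise_oracle(self, rng):
        X = rng.standard_normal((3, 50))
        raw = np.array(
            [[sum(X[a, n] * X[b, n] for n in range(50)) for b in range(3)] for a in range(3)]
        )
        expected = raw / np.trace(raw)
        assert np.allclose(normalized_covariance(X), expected, atol=1e-12)

    def test_zero_trial_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalized_covariance(np.zeros((3, 40)))


class TestClassMeanCovariance:
    def test_identical_trials(self, rng):
        cov = _random_psd(rng, 3)
        E1, E2 = class_mean_covariance(np.stack([cov] * 4), [1, 1, 2, 2])
        assert np.allclose(E1, cov) and np.allclose(E2, cov)

    def test_two_trial_mean(self, rng):
        A, B = _random_psd(rng, 3), _random_psd(rng, 3)
        E1, _ = class_mean_covariance(np.stack([A, B, A]), [1, 1, 2])
        assert np.allclose(E1, (A + B) / 2)

    def test_mean_of_trace_one_matrices_has_trace_one(self, rng):
        covs = np.stack([_random_psd(rng, 4) for _ in range(10)])
        E1, E2 = class_mean_covariance(covs, np.repeat([1, 2], 5))
        assert np.trace(E1) == pytest.approx(1.0, abs=1e-12)
        assert np.trace(E2) == pytest.approx(1.0, abs=1e-12)

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            class_mean_covariance(np.stack([_random_psd(rng, 2)] * 3), [1, 1, 1])


class TestSolveCSP:
    def test_isotropic_pair(self):
        pair = solve_csp(np.eye(3) / 3, np.eye(3) / 3)
        assert pair.j_max == pytest.approx(1.0, abs=1e-12)
        assert pair.j_min == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_closed_form(self):
        pair = solve_csp(np.diag([0.8, 0.2]), np.diag([0.2, 0.8]))
        assert pair.j_max == pytest.approx(4.0, abs=1e-12)
        assert pair.j_min == pytest.approx(0.25, abs=1e-12)
        assert abs(pair.p_max[0]) > 100 * abs(pair.p_max[1])  # aligned with e1
        assert abs(pair.p_min[1]) > 100 * abs(pair.p_min[0])

    def test_monte_carlo_upper_bound(self, rng):
        E1, E2 = _random_psd(rng, 4), _random_psd(rng, 4)
        pair = solve_csp(E1, E2)
        P = rng.standard_normal((100_000, 4))
        J = np.einsum("na,ab,nb->n", P, E1, P) / np.einsum("na,ab,nb->n", P, E2, P)
        assert pair.j_max >= J.max() - 1e-6
        assert pair.j_min <= J.min() + 1e-6

    def test_generalized_eigen_identity(self, rng):
        E1, E2 = _random_psd(rng, 5), _random_psd(rng, 5)
        pair = solve_csp(E1, E2)
        for p, lam in ((pair.p_max, pair.j_max), (pair.p_min, pair.j_min)):
            res = np.linalg.norm(E1 @ p - lam * (E2 @ p)) / np.linalg.norm(E1 @ p)
            assert res < 1e-8

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), d=st.integers(2, 5))
    def test_label_swap_inverts_spectrum(self, seed, d):
        g = np.random.default_rng(seed)
        E1, E2 = _random_psd(g, d), _random_psd(g, d)
        fwd, rev = solve_csp(E1, E2), solve_csp(E2, E1)
        assert rev.j_max == pytest.approx(1.0 / fwd.j_min, rel=1e-9)
        assert rev.j_min == pytest.approx(1.0 / fwd.j_max, rel=1e-9)

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            solve_csp(_random_psd(rng, 3), _random_psd(rng, 4))

    def test_asymmetric_input_rejected(self, rng):
        E = _random_psd(rng, 3)
        bad = E.copy()
        bad[0, 1] += 0.2
        with pytest.raises(ValueError, match="symmetric"):
            solve_csp(bad, E)


class TestBandFeatures:
    def test_unit_variance_channel_gives_zero(self, rng):
        from fbcsp_select import SpatialFilterPair

        X = rng.standard_normal((2, 400))
        X[0] = (X[0] - X[0].mean()) / X[0].std()
        pair = SpatialFilterPair(
            p_max=np.array([1.0, 0.0]), p_min=np.array([0.0, 1.0]), j_max=4.0, j_min=0.25
        )
        feats = band_features(X, pair)
        assert feats.v_max == pytest.approx(0.0, abs=1e-9)

    def test_scaling_shifts_by_log4(self, rng):
        X = rng.standard_normal((3, 100))
        pair = solve_csp(_random_psd(rng, 3), _random_psd(rng, 3))
        base, scaled = band_features(X, pair), band_features(2.0 * X, pair)
        assert scaled.v_max - base.v_max == pytest.approx(np.log(4.0), abs=1e-10)
        assert scaled.v_min - base.v_min == pytest.approx(np.log(4.0), abs=1e-10)

    def test_two_step_oracle(self, rng):
        X = rng.standard_normal((3, 60))
        pair = solve_csp(_random_psd(rng, 3), _random_psd(rng, 3))
        feats = band_features(X, pair)
        assert feats.v_max == pytest.approx(np.log((pair.p_max @ X).var()), abs=1e-12)
        assert feats.v_min == pytest.approx(np.log((pair.p_min @ X).var()), abs=1e-12)

    def test_sign_invariance(self, rng):
        import dataclasses

        X = rng.standard_normal((3, 60))
        pair = solve_csp(_random_psd(rng, 3), _random_psd(rng, 3))
        flipped = dataclasses.replace(pair, p_max=-pair.p_max, p_min=-pair.p_min)
        assert band_features(X, pair) == band_features(X, flipped)

    def test_dimension_mismatch_rejected(self, rng):
        pair = solve_csp(_random_psd(rng, 3), _random_psd(rng, 3))
        with pytest.raises(ValueError, match="match"):
            band_features(rng.standard_normal((4, 60)), pair)
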