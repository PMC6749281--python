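import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fbcsp_select import (
    BandSpec,
    DegenerateChannelError,
    EpochSet,
    SupportSetError,
    SynthConfig,
    TDPChannelSelector,
    bandpass,
    fisher_ratio,
    fisher_ratios,
    generate_session,
    pearson,
    select_principle_channel,
    supporting_set,
    tdp,
    tdp_matrix,
)


def _tdp_oracle(x, p):
    """Independent evaluation: difference p times, population variance, log."""
    x = list(map(float, x))
    for _ in range(p):
        x = [b - a for a, b in zip(x, x[1:])]
    mean = sum(x) / len(x)
    var = sum((v - mean) ** 2 for v in x) / len(x)
    return math.log(max(var, 1e-12))


class TestTDP:
    def test_alternating_unit_signal(self):
        assert tdp(np.tile([1.0, -1.0], 10), 0) == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp_floor(self):
        assert tdp(np.arange(10.0), 1) == pytest.approx(math.log(1e-12), abs=1e-12)

    @pytest.mark.parametrize("p", [0, 1, 2])
    def test_matches_oracle(self, p):
        x = [0.5, -1.2, 0.3, 2.0, -0.7]
        assert tdp(x, p) == pytest.approx(_tdp_oracle(x, p), abs=1e-12)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            tdp([1.0, 2.0, 3.0], 2)

    def test_matrix_agrees_with_scalar(self, rng):
        data = rng.standard_normal((4, 3, 50))
        mat = tdp_matrix(data)
        for i, k, p in [(0, 0, 0), (2, 1, 1), (3, 2, 2)]:
            assert mat[i, k, p] == pytest.approx(tdp(data[i, k], p), abs=1e-12)


def _fisher_oracle(tdps, labels, k):
    """Direct evaluation of the Fisher ratio, symbol by symbol."""
    i1 = [i for i, c in enumerate(labels) if c == 1]
    i2 = [i for i, c in enumerate(labels) if c == 2]
    num = den = 0.0
    for p in range(3):
        m1 = sum(tdps[i, k, p] for i in i1) / len(i1)
        m2 = sum(tdps[i, k, p] for i in i2) / len(i2)
        num += (m1 - m2) ** 2
        den += sum((tdps[i, k, p] - m1) ** 2 for i in i1) / len(i1)
        den += sum((tdps[i, k, p] - m2) ** 2 for i in i2) / len(i2)
    return num / den


class TestFisherRatio:
    def test_identical_class_distributions_give_zero(self):
        tdps = np.tile(np.arange(4.0)[:, None, None], (1, 2, 3))
        labels = np.array([1, 2, 1, 2])
        tdps[labels == 2] = tdps[labels == 1]
        assert fisher_ratio(tdps, labels, 0) == pytest.approx(0.0, abs=1e-15)

    def test_shift_invariance(self, rng):
        tdps = rng.standard_normal((10, 3, 3))
        labels = np.repeat([1, 2], 5)
        shifted = tdps + np.array([5.0, -3.0, 11.0])
        assert fisher_ratio(shifted, labels, 1) == pytest.approx(
            fisher_ratio(tdps, labels, 1), rel=1e-9
        )

    def test_scale_invariance(self, rng):
        tdps = rng.standard_normal((10, 2, 3))
        labels = np.repeat([1, 2], 5)
        assert fisher_ratio(2.5 * tdps, labels, 0) == pytest.approx(
            fisher_ratio(tdps, labels, 0), rel=1e-9
        )

    def test_toy_matches_direct_evaluation(self, rng):
        tdps = rng.standard_normal((4, 2, 3))
        labels = np.array([1, 1, 2, 2])
        for k in range(2):
            assert fisher_ratio(tdps, labels, k) == pytest.approx(
                _fisher_oracle(tdps, labels, k), rel=1e-12
            )

    def test_degenerate_channel_raises(self):
        tdps = np.zeros((4, 1, 3))
        with pytest.raises(DegenerateChannelError):
            fisher_ratio(tdps, [1, 1, 2, 2], 0)


class TestPrincipleChannel:
    def test_variance_shift_channel_wins(self, rng):
        n = 40
        data = rng.standard_normal((n, 2, 100))
        labels = np.repeat([1, 2], n // 2)
        data[labels == 2, 0, :] *= 3.0  # class-dependent power on channel 0 only
        epochs = EpochSet(data=data, labels=labels, fs=100.0)
        _, kp = select_principle_channel(epochs)
        assert kp == 0

    def test_tie_breaks_to_lowest_index(self, rng):
        trial = rng.standard_normal((20, 1, 80))
        data = np.tile(trial, (1, 3, 1))  # channels are identical copies
        epochs = EpochSet(data=data, labels=np.repeat([1, 2], 10), fs=100.0)
        _, kp = select_principle_channel(epochs)
        assert kp == 0

    def test_recovers_simulated_erd_channel(self):
        epochs, truth = generate_session(SynthConfig(seed=42))
        filtered = bandpass(epochs, BandSpec(0.5, 40.0))
        _, kp = select_principle_channel(filtered)
        assert kp in truth.dominant_channels()


class TestPearson:
    def test_self_and_negated(self, rng):
        x = rng.standard_normal(50)
        assert pearson(x, x) == pytest.approx(1.0, abs=1e-12)
        assert pearson(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_textbook_example(self):
        r, _ = stats.pearsonr([1, 2, 3, 4], [1, 2, 3, 5])
        assert pearson([1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(r, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson(np.ones(10), np.arange(10.0))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
    )
    def test_invariance_under_positive_affine_maps(self, seed, a, b):
        g = np.random.default_rng(seed)
        x, y = g.standard_normal(30), g.standard_normal(30)
        assert pearson(a * x + b, y) == pytest.approx(pearson(x, y), abs=1e-9)
        assert pearson(-x, y) == pytest.approx(-pearson(x, y), abs=1e-12)


class TestSupportingSet:
    def _toy_epochs(self, rng):
        """Channels 1, 2 are scaled copies of channel 0 plus tiny noise; 3 is independent."""
        n, N = 12, 120
        base = rng.standard_normal((n, N))
        data = np.stack(
            [
                base,
                2.0 * base + 0.01 * rng.standard_normal((n, N)),
                0.5 * base + 0.01 * rng.standard_normal((n, N)),
                rng.standard_normal((n, N)),
            ],
            axis=1,
        )
        return EpochSet(data=data, labels=np.repeat([1, 2], n // 2), fs=100.0)

    def test_correlated_copies_selected(self, rng):
        epochs = self._toy_epochs(rng)
        sel = supporting_set(epochs, 0, 0.6)
        assert sel.support == (0, 1, 2)
        # direct check of the class-mean threshold rule
        for q in (1, 2):
            assert sel.mean_corr[q, 0] >= 0.6 and sel.mean_corr[q, 1] >= 0.6
        assert not (sel.mean_corr[3, 0] >= 0.6 and sel.mean_corr[3, 1] >= 0.6)

    def test_permissive_threshold_keeps_all_positive_channels(self, rng):
        epochs = self._toy_epochs(rng)
        sel = supporting_set(epochs, 0, 1e-6)
        assert set(sel.support) >= {0, 1, 2}

    def test_threshold_one_with_noisy_channels_fails(self, rng):
        epochs = self._toy_epochs(rng)
        with pytest.raises(SupportSetError, match="lower the threshold"):
            supporting_set(epochs, 3, 1.0)

    def test_threshold_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            supporting_set(self._toy_epochs(rng), 0, 1.0 + 1e-9)

    def test_monotone_in_threshold(self, easy_broadband):
        _, kp = select_principle_channel(easy_broadband)
        supports = [
            set(supporting_set(easy_broadband, kp, t).support)
            for t in (0.3, 0.5, 0.7, 0.8)
        ]
        for wide, narrow in zip(supports, supports[1:]):
            assert wide >= narrow


class TestTDPChannelSelectorEstimator:
    def test_transform_subsets_channels(self, small_session):
        epochs, _ = small_session
        sel = TDPChannelSelector(threshold=0.6)
        out = sel.fit(epochs.data, epochs.labels).transform(epochs.data)
        assert out.shape[0] == epochs.n_trials
        assert out.shape[1] == len(sel.selection_.support)
        assert sel.get_params() == {"threshold": 0.6}

    def test_channel_count_checked(self, small_session):
        epochs, _ = small_session
        sel = TDPChannelSelector(threshold=0.6).fit(epochs.data, epochs.labels)
        with pytest.raises(ValueError, match="channels"):
            sel.transform(epochs.data[:, :3, :])
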