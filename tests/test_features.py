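"""Entropy definitions, probability estimation, moments, vector assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from eegcad.features import (
    ProbabilityEstimate,
    build_feature_vector,
    compute_feature,
    estimate_probabilities,
    log_energy_entropy,
    renyi_entropy,
    shannon_entropy,
    statistical_features,
    threshold_entropy,
)
from eegcad.preprocessing import Segment
from eegcad.wavelet import dwt_decompose


def _uniform_pe(k: int) -> ProbabilityEstimate:
    return ProbabilityEstimate(p=np.full(k, 1.0 / k), k=k,
                               bin_edges=np.linspace(0, 1, k + 1))


class TestProbabilityEstimate:
    def test_degenerate_array_single_bin(self):
        pe = estimate_probabilities(np.array([3.0, 3.0, 3.0]), 256)
        np.testing.assert_array_equal(pe.p, [1.0])
        assert pe.k == 1

    def test_two_equal_groups(self):
        pe = estimate_probabilities(np.array([0.0] * 4 + [1.0] * 4), 2)
        np.testing.assert_allclose(np.sort(pe.p), [0.5, 0.5])

    def test_uniform_draws_concentrate(self):
        x = np.random.default_rng(5).uniform(0, 1, 1000)
        pe = estimate_probabilities(x, 10)
        assert pe.k == 10
        assert np.all(np.abs(pe.p - 0.1) < 0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_probabilities(np.array([]), 10)

    @given(hnp.arrays(np.float64, st.integers(2, 200),
                      elements=st.floats(-1e6, 1e6)),
           st.integers(1, 64))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_probabilities_sum_to_one(self, x, n_bins):
        pe = estimate_probabilities(x, n_bins)
        assert pe.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pe.p > 0)


class TestEntropies:
    def test_shannon_certainty_is_zero(self):
        assert shannon_entropy(_uniform_pe(1)) == 0.0

    def test_shannon_fair_coin_is_one_bit(self):
        assert shannon_entropy(_uniform_pe(2)) == pytest.approx(1.0)

    def test_shannon_uniform_maximum(self):
        assert shannon_entropy(_uniform_pe(8)) == pytest.approx(3.0)

    def test_log_energy_certainty(self):
        assert log_energy_entropy(_uniform_pe(1)) == 0.0

    def test_log_energy_fair_coin(self):
        assert log_energy_entropy(_uniform_pe(2)) == pytest.approx(2 * np.log(0.25))

    @pytest.mark.parametrize("k", [2, 5, 16, 100])
    def test_log_energy_uniform_closed_form(self, k):
        assert log_energy_entropy(_uniform_pe(k)) == pytest.approx(-2 * k * np.log(k))

    @pytest.mark.parametrize("alpha", [0.5, 2.0, 3.0])
    def test_renyi_uniform_invariance(self, alpha):
        assert renyi_entropy(_uniform_pe(7), alpha) == pytest.approx(np.log(7))

    def test_renyi_collision_entropy(self):
        assert renyi_entropy(_uniform_pe(2), 2.0) == pytest.approx(-np.log(0.5))

    def test_renyi_limit_is_shannon_in_nats(self, rng):
        p = rng.dirichlet(np.ones(12))
        pe = ProbabilityEstimate(p=p / p.sum(), k=12, bin_edges=np.arange(13.0))
        shannon_nats = shannon_entropy(pe) * np.log(2)
        for alpha in (1 - 1e-4, 1 + 1e-4):
            assert abs(renyi_entropy(pe, alpha) - shannon_nats) < 1e-3

    def test_renyi_alpha_one_rejected(self):
        with pytest.raises(ValueError, match="shannon"):
            renyi_entropy(_uniform_pe(4), 1.0)

    @given(st.integers(2, 40), st.integers(0, 10 ** 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_renyi_non_increasing_in_alpha(self, k, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(k))
        pe = ProbabilityEstimate(p=p / p.sum(), k=k, bin_edges=np.arange(k + 1.0))
        alphas = [0.25, 0.5, 0.9, 1.5, 2.0, 4.0]
        values = [renyi_entropy(pe, a) for a in alphas]
        assert all(a >= b - 1e-10 for a, b in zip(values, values[1:]))

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_shannon_bounded_by_log_k(self, seed):
        x = np.random.default_rng(seed).standard_normal(300)
        pe = estimate_probabilities(x, 32)
        h = shannon_entropy(pe)
        assert -1e-12 <= h <= np.log2(pe.k) + 1e-12

    def test_entropy_scale_invariance(self, rng):
        x = rng.standard_normal(2000)
        for fn in ("shannon", "renyi"):
            base = compute_feature(x, fn)
            scaled = compute_feature(123.4 * x + 5.0, fn)
            assert scaled == pytest.approx(base, abs=1e-12)

    def test_integer_array_oracle(self, rng):
        # with one bin per unique value, histogram probabilities equal direct
        # frequency counts, so the entropy matches exact counting
        lo, hi = -3, 6
        x = np.concatenate([np.arange(lo, hi + 1),
                            rng.integers(lo, hi + 1, 400)]).astype(float)
        k = hi - lo + 1
        pe = estimate_probabilities(x, k)
        _, counts = np.unique(x, return_counts=True)
        p_direct = counts / x.size
        expected = -(p_direct * np.log2(p_direct)).sum()
        assert shannon_entropy(pe) == pytest.approx(expected, abs=1e-12)


class TestThreshold:
    def test_zeros_count_zero(self):
        assert threshold_entropy(np.zeros(100), 0.2) == 0

    def test_hand_enumeration(self):
        # 0.2 itself is not strictly greater than the threshold
        assert threshold_entropy(np.array([0.1, 0.25, -0.3, 0.2]), 0.2) == 2

    def test_zero_threshold_counts_nonzeros(self):
        x = np.array([0.0, -1.0, 0.0, 2.0, 3.0])
        assert threshold_entropy(x, 0.0) == 3

    def test_scale_dependence(self, rng):
        x = rng.standard_normal(1000)
        assert threshold_entropy(10 * x, 0.2) > threshold_entropy(0.01 * x, 0.2)


class TestStatisticalFeatures:
    def test_population_moments(self):
        out = statistical_features(np.array([1.0, 2.0, 3.0]))
        assert out["mean"] == pytest.approx(2.0)
        assert out["variance"] == pytest.approx(2.0 / 3.0)
        assert out["std"] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_symmetric_skewness_zero(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert abs(statistical_features(x)["skewness"]) < 1e-12

    def test_gaussian_kurtosis_near_three(self):
        x = np.random.default_rng(3).standard_normal(10000)
        assert statistical_features(x)["kurtosis"] == pytest.approx(3.0, abs=0.2)

    def test_zero_variance_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = statistical_features(np.full(10, 2.0))
        assert out["skewness"] == 0.0 and out["kurtosis"] == 0.0


@pytest.fixture(scope="module")
def coeffs16():
    g = np.random.default_rng(11)
    seg = Segment(data=g.standard_normal((16, 1024)), fs=256.0,
                  subject_id="s0", start_s=30.0, label="autistic",
                  channel_labels=[f"CH{i}" for i in range(16)])
    return dwt_decompose(seg, "db4", 4)


class TestBuildFeatureVector:
    def test_detail_band_vector_length(self, coeffs16):
        fv = build_feature_vector(coeffs16, ("D1", "D2", "D3", "D4"), "shannon")
        assert fv.values.size == 64
        assert fv.label == "autistic"
        assert fv.feature_names[0] == "CH0.D1.shannon"

    def test_full_selection_single_channel(self, rng):
        seg = Segment(data=rng.standard_normal((1, 1024)), fs=256.0,
                      subject_id="s", start_s=0.0, label="normal",
                      channel_labels=["C3"])
        wc = dwt_decompose(seg, "db4", 4)
        fv = build_feature_vector(
            wc, ("ORIG", "D1", "D2", "D3", "D4", "A4"), "shannon")
        assert fv.values.size == 6

    def test_deterministic(self, coeffs16):
        a = build_feature_vector(coeffs16, ("D1", "D2"), "renyi")
        b = build_feature_vector(coeffs16, ("D1", "D2"), "renyi")
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_selection_rejected(self, coeffs16):
        with pytest.raises(ValueError, match="non-empty"):
            build_feature_vector(coeffs16, (), "shannon")

    def test_unknown_coefficient_rejected(self, coeffs16):
        with pytest.raises(ValueError, match="D9"):
            build_feature_vector(coeffs16, ("D9",), "shannon")
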