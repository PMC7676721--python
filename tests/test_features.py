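"""Feature extraction: moments, power/energy, five entropies and table
assembly, checked against hand values and brute-force embedding oracles."""

import numpy as np
import pytest

from conftest import apen_bruteforce, sampen_bruteforce
from tqeeg.features import (
    FEATURE_NAMES,
    FeatureConfig,
    approximate_entropy,
    energy,
    extract_features,
    fuzzy_entropy,
    moment_features,
    power,
    sample_entropy,
    shannon_entropy,
    subband_features,
    tsallis_entropy,
)
from tqeeg.tqwt import TQWTParams


class TestMoments:
    def test_hand_values(self):
        mu, var, _, _ = moment_features([1, 2, 3])
        assert mu == 2.0
        assert var == 1.0  # N-1 denominator

    def test_symmetric_sequence_has_zero_skewness(self):
        assert moment_features([-1.0, 0.0, 1.0])[2] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis_is_three(self, rng):
        x = rng.standard_normal(10**6)
        assert moment_features(x)[3] == pytest.approx(3.0, abs=0.05)

    def test_constant_sequence_guard(self):
        mu, var, skew, kurt = moment_features(np.full(50, 2.5))
        assert (mu, var, skew, kurt) == (2.5, 0.0, 0.0, 3.0)


class TestPowerEnergy:
    def test_hand_values(self):
        assert energy([3, 4]) == 25.0
        assert power([3, 4]) == 12.5

    def test_zeros_and_ones(self):
        assert energy(np.zeros(10)) == 0.0
        assert power(np.ones(17)) == 1.0
        assert energy(np.ones(17)) == 17.0

    def test_energy_equals_n_times_power(self, rng):
        for n in (5, 100, 768):
            x = rng.standard_normal(n)
            assert energy(x) == pytest.approx(n * power(x), rel=1e-14)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            power([])


class TestHistogramEntropies:
    def _uniform_16_bins(self):
        # 10 samples per bin center: every bin gets equal mass
        return np.repeat(np.arange(16, dtype=float), 10)

    def test_uniform_bins_closed_forms(self):
        x = self._uniform_16_bins()
        assert tsallis_entropy(x) == pytest.approx(1 - 1 / 16, rel=1e-12)
        assert shannon_entropy(x) == pytest.approx(np.log(16), rel=1e-12)

    def test_constant_sequence_gives_zero(self):
        x = np.full(30, 3.3)
        assert shannon_entropy(x) == 0.0
        assert tsallis_entropy(x) == 0.0

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(500)
        for f in (shannon_entropy, tsallis_entropy):
            assert f(3.7 * x - 11.0) == pytest.approx(f(x), rel=1e-12)

    def test_tsallis_limits_to_shannon_as_q_to_one(self, rng):
        x = rng.standard_normal(2000)
        cfg = FeatureConfig(q_tsallis=1 + 1e-6)
        assert tsallis_entropy(x, cfg) == pytest.approx(shannon_entropy(x), abs=1e-3)

    def test_verbatim_tsallis_variant_differs(self, rng):
        x = rng.standard_normal(500)
        std = tsallis_entropy(x)
        verbatim = tsallis_entropy(x, FeatureConfig(tsallis_verbatim=True))
        assert std != verbatim


class TestEmbeddingEntropies:
    def test_constant_sequence(self):
        x = np.full(60, 1.0)
        assert approximate_entropy(x) == 0.0
        assert sample_entropy(x) == 0.0

    def test_matches_bruteforce_oracles(self, rng):
        cfg = FeatureConfig()
        for _ in range(15):
            n = int(rng.integers(30, 300))
            x = rng.standard_normal(n)
            assert approximate_entropy(x, cfg) == pytest.approx(
                apen_bruteforce(x), abs=1e-12
            )
            assert sample_entropy(x, cfg) == pytest.approx(
                sampen_bruteforce(x), abs=1e-12
            )

    def test_periodic_signal_more_regular_than_noise(self, rng):
        periodic = np.tile([1.0, 2.0], 50)
        periodic = periodic + 1e-9 * rng.standard_normal(100)  # break exact ties
        noise = rng.standard_normal(100)
        noise = noise / noise.std() * periodic.std()
        assert approximate_entropy(periodic) < approximate_entropy(noise)

    def test_sampen_offset_invariance(self, rng):
        x = rng.standard_normal(150)
        assert sample_entropy(x + 123.4) == pytest.approx(sample_entropy(x), abs=1e-12)

    def test_sampen_zero_match_sentinel(self):
        # sequence with one m-pair match but no (m+1)-matches at tol 0.2*SD
        x = np.array([12.0, 10, 5, 6, 0, 1, 0, 3, 16, 12, 18])
        assert sample_entropy(x) == np.inf

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError):
            approximate_entropy([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            sample_entropy([1.0, 2.0, 3.0])


class TestFuzzyEntropy:
    def test_midpoint_memberships_closed_form(self):
        # min-max normalization sends {0, 1, 2} -> {0, 0.5, 1}; only the
        # midpoints contribute ln 2 each
        x = np.array([0.0, 2.0] + [1.0] * 10)
        k = 2.0
        expected = k * 10 * np.log(2)
        assert fuzzy_entropy(x) == pytest.approx(expected, rel=1e-9)

    def test_extreme_memberships_vanish(self):
        x = np.array([0.0, 1.0] * 20)
        assert fuzzy_entropy(x) == pytest.approx(0.0, abs=1e-8)

    def test_linear_in_k(self, rng):
        x = rng.standard_normal(100)
        f1 = fuzzy_entropy(x, FeatureConfig(K_fuzzy=1.0))
        f2 = fuzzy_entropy(x, FeatureConfig(K_fuzzy=2.0))
        assert f2 == pytest.approx(2.0 * f1, rel=1e-12)


def test_every_entropy_is_nonnegative(rng):
    cfg = FeatureConfig()
    for _ in range(20):
        x = rng.standard_normal(int(rng.integers(20, 200)))
        for f in (shannon_entropy, tsallis_entropy, approximate_entropy,
                  sample_entropy, fuzzy_entropy):
            assert f(x, cfg) >= -1e-9


class TestSubbandFeatures:
    def test_consistent_with_individual_functions(self, rng):
        x = rng.standard_normal(200)
        feats = subband_features(x)
        assert set(feats) == set(FEATURE_NAMES)
        assert feats["apen"] == pytest.approx(approximate_entropy(x), abs=1e-12)
        assert feats["sampen"] == pytest.approx(sample_entropy(x), abs=1e-12)
        assert feats["energy"] == pytest.approx(energy(x), rel=1e-14)
        assert feats["variance"] == pytest.approx(np.var(x, ddof=1), rel=1e-12)

    def test_undefined_sampen_capped_to_finite(self):
        x = np.array([12.0, 10, 5, 6, 0, 1, 0, 3, 16, 12, 18])
        feats = subband_features(x)
        assert np.isfinite(feats["sampen"])
        assert feats["sampen"] > 0


class TestExtractFeatures:
    def test_table_shape_and_columns(self, rng):
        epochs = rng.standard_normal((10, 3, 768))
        table = extract_features(epochs, TQWTParams(Q=1, r=3, J=8))
        assert table.shape == (10, 9 * 11)  # 8 highpass + 1 lowpass subbands
        assert "sb1_apen" in table.columns and "sb9_variance" in table.columns

    def test_zero_epochs_give_zero_moment_columns(self):
        epochs = np.zeros((2, 2, 256))
        table = extract_features(epochs, TQWTParams(Q=1, r=3, J=4))
        for feat in ("mean", "variance", "power", "energy"):
            assert np.all(table[[c for c in table if c.endswith(feat)]] == 0)

    def test_row_order_follows_epoch_order(self, rng):
        epochs = rng.standard_normal((6, 2, 256))
        p = TQWTParams(Q=1, r=3, J=4)
        table = extract_features(epochs, p)
        perm = [3, 1, 5, 0, 2, 4]
        table_perm = extract_features(epochs[perm], p)
        np.testing.assert_allclose(
            table_perm.to_numpy(), table.to_numpy()[perm], rtol=1e-12
        )

    def test_labels_attached_and_stack_mode(self, rng):
        epochs = rng.standard_normal((4, 2, 256))
        labels = ["fear", "anger", "fear", "anger"]
        table = extract_features(
            epochs, TQWTParams(Q=1, r=3, J=4), labels=labels,
            group="NC", channel_mode="stack",
        )
        assert list(table["label"]) == labels
        assert (table["group"] == "NC").all()
        assert table.shape[1] == 2 * 5 * 11 + 2  # channels x subbands x features

    def test_label_count_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="label"):
            extract_features(
                rng.standard_normal((3, 2, 256)),
                TQWTParams(Q=1, r=3, J=4),
                labels=["fear"],
            )
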