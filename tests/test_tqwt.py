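"""Tunable-Q wavelet transform: parameter rules, depth limit, perfect
reconstruction, tight-frame energy bookkeeping and frequency partitions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tqeeg.tqwt import (
    TQWTParams,
    decompose,
    derive_filter_params,
    frequency_response,
    max_levels,
    read_subbands,
    reconstruct,
    subband_frequency_range,
    write_subbands,
)


class TestFilterParams:
    @pytest.mark.parametrize(
        "Q, r, alpha, beta",
        [(1, 3, 2 / 3, 1.0), (3, 3, 5 / 6, 0.5)],
    )
    def test_hand_derived_values(self, Q, r, alpha, beta):
        a, b = derive_filter_params(Q, r)
        assert a == pytest.approx(alpha, abs=1e-15)
        assert b == pytest.approx(beta, abs=1e-15)

    @given(Q=st.floats(1, 50), r=st.floats(1.01, 20))
    @settings(max_examples=200, derandomize=True)
    def test_constraints_hold_for_any_valid_input(self, Q, r):
        a, b = derive_filter_params(Q, r)
        assert 0 < a < 1
        assert 0 < b <= 1
        assert a + b > 1
        assert b == pytest.approx(2 / (Q + 1), rel=1e-14)
        assert a == pytest.approx(1 - b / r, rel=1e-14)

    @pytest.mark.parametrize("Q, r", [(0.5, 3), (0.99, 3), (1, 1.0), (1, 0.5)])
    def test_out_of_domain_rejected(self, Q, r):
        with pytest.raises(ValueError):
            derive_filter_params(Q, r)


class TestMaxLevels:
    def test_reference_depth_for_study_geometry(self):
        # 768-sample epoch, Q=1, r=3 -> alpha=2/3, beta=1 -> 11 levels
        a, b = derive_filter_params(1, 3)
        assert max_levels(768, a, b) == 11

    def test_higher_q_gives_deeper_cascade(self):
        a, b = derive_filter_params(3, 3)
        assert max_levels(768, a, b) == 21

    def test_shortest_admissible_signal_gives_zero(self):
        a, b = derive_filter_params(1, 3)
        assert max_levels(8, a, b) == 0  # N = 8/beta exactly: log(1) = 0

    def test_too_short_signal_raises(self):
        a, b = derive_filter_params(1, 3)
        with pytest.raises(ValueError, match="too short"):
            max_levels(7, a, b)

    def test_closed_form_matches_bruteforce_level_counting(self, rng):
        # deepest J with beta*N*alpha^J >= 8, counted by repeated multiplication
        for _ in range(1000):
            n = int(rng.integers(16, 5000))
            q = float(rng.uniform(1, 10))
            r = float(rng.uniform(1.5, 8))
            a, b = derive_filter_params(q, r)
            if b * n / 8.0 < 1:
                continue
            j, prod = 0, a
            while b * n * prod >= 8.0:
                j += 1
                prod *= a
            assert max_levels(n, a, b) == j


class TestDecompose:
    def test_study_geometry_yields_twelve_subbands(self, rng):
        x = rng.standard_normal(768)
        sb = decompose(x, TQWTParams(Q=1, r=3, J=11))
        assert len(sb.subbands) == 12

    def test_subband_count_is_levels_plus_one(self, rng):
        x = rng.standard_normal(768)
        for j in (1, 4, 8):
            assert len(decompose(x, TQWTParams(Q=2, r=3, J=j))) == j + 1

    def test_zero_signal_gives_zero_subbands(self):
        sb = decompose(np.zeros(768), TQWTParams(Q=1, r=3, J=5))
        assert all(np.all(band == 0) for band in sb.subbands)

    def test_impulse_energy_is_conserved(self):
        x = np.zeros(768)
        x[100] = 1.0
        sb = decompose(x, TQWTParams(Q=1, r=3, J=3))
        assert sum(e for e in sb.energies) == pytest.approx(1.0, rel=1e-8)

    def test_depth_beyond_maximum_raises(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            decompose(rng.standard_normal(768), TQWTParams(Q=1, r=3, J=12))

    def test_nonfinite_input_raises(self):
        x = np.zeros(768)
        x[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            decompose(x, TQWTParams(Q=1, r=3, J=3))

    def test_complex_input_rejected(self):
        with pytest.raises(ValueError, match="complex"):
            decompose(np.zeros(768, dtype=complex), TQWTParams(Q=1, r=3, J=3))

    def test_linearity(self, rng):
        p = TQWTParams(Q=2, r=3, J=5)
        x, y = rng.standard_normal(768), rng.standard_normal(768)
        sxy = decompose(2.0 * x - 0.5 * y, p)
        sx, sy = decompose(x, p), decompose(y, p)
        for bxy, bx, by in zip(sxy.subbands, sx.subbands, sy.subbands):
            np.testing.assert_allclose(bxy, 2.0 * bx - 0.5 * by, atol=1e-10)


class TestReconstruct:
    @pytest.mark.parametrize("Q", range(1, 7))
    @pytest.mark.parametrize("J", range(1, 9))
    def test_perfect_reconstruction_over_study_grid(self, Q, J, rng):
        x = rng.standard_normal(768)
        y = reconstruct(decompose(x, TQWTParams(Q=Q, r=3, J=J)))
        assert np.max(np.abs(y - x)) / np.max(np.abs(x)) < 1e-8

    @pytest.mark.parametrize("Q", range(1, 7))
    @pytest.mark.parametrize("J", range(1, 9))
    def test_energy_conservation_over_study_grid(self, Q, J, rng):
        x = rng.standard_normal(768)
        sb = decompose(x, TQWTParams(Q=Q, r=3, J=J))
        assert sb.energies.sum() == pytest.approx(np.sum(x**2), rel=1e-8)

    def test_odd_length_round_trip(self, rng):
        x = rng.standard_normal(767)
        sb = decompose(x, TQWTParams(Q=2, r=3, J=4))
        y = reconstruct(sb)
        assert y.shape == x.shape
        assert np.max(np.abs(y - x)) / np.max(np.abs(x)) < 1e-8

    def test_zero_subbands_reconstruct_to_zero(self):
        sb = decompose(np.zeros(768), TQWTParams(Q=1, r=3, J=5))
        assert np.all(reconstruct(sb) == 0)

    def test_inconsistent_subband_lengths_raise(self, rng):
        sb = decompose(rng.standard_normal(768), TQWTParams(Q=1, r=3, J=5))
        sb.subbands[2] = sb.subbands[2][:-4]
        with pytest.raises(ValueError, match="inconsistent"):
            reconstruct(sb)


class TestFrequencyPartition:
    def test_first_highpass_band_covers_full_range_when_beta_is_one(self):
        # Q=1 -> beta=1: level 1 spans (0, fs/2)
        lo, hi = subband_frequency_range(TQWTParams(Q=1, r=3, J=11), 1, fs=128)
        assert lo == 0.0
        assert hi == 64.0

    def test_lowpass_edge_closed_form(self):
        _, hi = subband_frequency_range(TQWTParams(Q=1, r=3, J=11), 12, fs=128)
        assert hi == pytest.approx(64 * (2 / 3) ** 11, rel=1e-12)

    def test_upper_edges_scale_geometrically_by_alpha(self):
        p = TQWTParams(Q=3, r=3, J=6)
        for j in range(1, p.J):
            _, hi_j = subband_frequency_range(p, j, fs=128)
            _, hi_next = subband_frequency_range(p, j + 1, fs=128)
            assert hi_next == pytest.approx(p.alpha * hi_j, rel=1e-12)

    def test_level_out_of_range_raises(self):
        with pytest.raises(IndexError):
            subband_frequency_range(TQWTParams(Q=1, r=3, J=5), 7, fs=128)

    def test_level_responses_are_power_complementary(self):
        # the J+1 equivalent responses partition energy: sum of squares = 1
        p = TQWTParams(Q=2, r=3, J=4)
        total = np.zeros(2048)
        for level in range(1, p.J + 2):
            fr = frequency_response(p, level, n_points=2048)
            total += fr.magnitude**2
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_response_vanishes_outside_nominal_band(self):
        p = TQWTParams(Q=2, r=3, J=4)
        fr = frequency_response(p, 3, n_points=4096)
        lo, hi = subband_frequency_range(p, 3, fs=2 * math.pi)  # fs/2 = pi
        outside = (fr.omega_grid < lo - 1e-9) | (fr.omega_grid > hi + 1e-9)
        assert np.all(fr.magnitude[outside] == 0.0)


def test_subband_dump_round_trip(tmp_path, rng):
    sb = decompose(rng.standard_normal(256), TQWTParams(Q=2, r=3, J=3), fs=128)
    path = tmp_path / "subbands.csv"
    write_subbands(sb, path)
    back = read_subbands(path)
    assert back.params == sb.params
    assert back.original_length == sb.original_length
    for a, b in zip(back.subbands, sb.subbands):
        np.testing.assert_array_equal(a, b)
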