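import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from envsync.envelope import build_envelopes, detect_extrema, spline_envelope

from .conftest import brute_force_extrema

FS = 256


class TestDetectExtrema:
    def test_single_turning_point_per_half_wave(self):
        x = np.array([0, 1, 2, 1, 0, -1, -2, -1], float)
        e = detect_extrema(x, min_separation=1)
        assert list(e.max_idx) == [2] and list(e.max_val) == [2.0]
        assert list(e.min_idx) == [6] and list(e.min_val) == [-2.0]

    def test_slow_sine_keeps_every_cycle(self):
        t = np.arange(10 * FS) / FS
        e = detect_extrema(np.sin(2 * np.pi * 2 * t), min_separation=20)
        assert np.all(np.diff(e.max_idx) == 128)  # 2 Hz period at 256 Hz
        oracle = brute_force_extrema(np.sin(2 * np.pi * 2 * t), 20)
        assert list(e.max_idx) == oracle

    def test_fast_sine_separation_skips_cycles(self):
        t = np.arange(10 * FS) / FS
        x = np.sin(2 * np.pi * 20 * t)  # period 12.8 samples < min_separation
        e = detect_extrema(x, min_separation=20)
        assert np.all(np.diff(e.max_idx) >= 20)
        assert len(e.max_idx) < 10 * 20  # some cycles dropped

    def test_half_wave_sign_rule(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(2000)
        e = detect_extrema(x, min_separation=5)
        assert np.all(e.max_val > 0)
        assert np.all(e.min_val < 0)

    def test_constant_signal_empty_and_warns(self):
        with pytest.warns(UserWarning, match="no half-wave extrema"):
            e = detect_extrema(np.zeros(100))
        assert e.max_idx.size == 0 and e.min_idx.size == 0

    @given(st.integers(0, 2**31 - 1), st.integers(1, 40))
    def test_separation_invariant_random_signals(self, seed, sep):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(1500)
        e = detect_extrema(x, min_separation=sep)
        for idx in (e.max_idx, e.min_idx):
            assert np.all(np.diff(idx) >= sep)
            assert np.all(np.diff(idx) > 0)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle_on_smooth_signals(self, seed):
        # narrowband smooth signals: one local max per half-wave, where the
        # half-wave and local-extremum views of the scheme coincide
        rng = np.random.default_rng(seed)
        t = np.arange(4 * FS) / FS
        f = rng.uniform(3, 10)
        x = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) * rng.uniform(0.5, 2)
        e = detect_extrema(x, min_separation=7)
        assert list(e.max_idx) == brute_force_extrema(x, 7, positive=True)
        assert list(e.min_idx) == brute_force_extrema(x, 7, positive=False)


class TestSplineEnvelope:
    def test_equal_knots_give_constant(self):
        out = spline_envelope(np.array([0, 100]), np.array([1.0, 1.0]), 101)
        np.testing.assert_allclose(out, 1.0)

    def test_interpolates_knots_exactly(self):
        rng = np.random.default_rng(9)
        idx = np.sort(rng.choice(500, size=12, replace=False))
        val = rng.standard_normal(12)
        out = spline_envelope(idx, val, 500)
        np.testing.assert_allclose(out[idx], val, atol=1e-12)

    def test_held_constant_outside_outer_knots(self):
        out = spline_envelope(np.array([100, 200, 300]), np.array([1.0, 5.0, 2.0]), 400)
        np.testing.assert_allclose(out[:100], 1.0)
        np.testing.assert_allclose(out[301:], 2.0)

    def test_fewer_than_two_knots_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            spline_envelope(np.array([5]), np.array([1.0]), 100)


class TestBuildEnvelopes:
    t = np.arange(60 * FS) / FS

    def test_pure_tone_envelopes_are_plus_minus_one(self):
        env = build_envelopes(np.cos(2 * np.pi * 20 * self.t), 20)
        core = slice(2 * FS, -2 * FS)
        assert np.abs(env.upper[core] - 1).max() < 0.05
        assert np.abs(env.lower[core] + 1).max() < 0.05

    def test_am_tone_recovers_both_modulators(self):
        mod = 1 + 0.5 * np.cos(2 * np.pi * 1 * self.t)
        env = build_envelopes(mod * np.cos(2 * np.pi * 20 * self.t), 20)
        core = slice(2 * FS, -2 * FS)
        assert np.abs(env.upper[core] - mod[core]).max() < 0.05
        assert np.abs(env.lower[core] + mod[core]).max() < 0.05

    def test_symmetric_am_upper_mirrors_lower(self):
        mod = 1 + 0.5 * np.cos(2 * np.pi * 1 * self.t)
        env = build_envelopes(mod * np.cos(2 * np.pi * 20 * self.t), 20)
        core = slice(2 * FS, -2 * FS)
        # max |upper + lower| below 5% of the envelope amplitude
        assert np.abs(env.upper[core] + env.lower[core]).max() < 0.05 * 1.5

    def test_constant_input_rejected(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                build_envelopes(np.zeros(1000))
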