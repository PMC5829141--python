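"""Wavelet decomposition, MTP, PLF and band summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from audlfp import EpochSet, band_window_mean, morlet_tfr, mtp, plf
from audlfp.tfr import SpectralMap, morlet_wavelet


def epochs_from(data, fs=1000.0, t0=-0.5, **kw):
    defaults = dict(region="AC", condition="conscious", stimulus="click_train",
                    validate_span=False)
    defaults.update(kw)
    return EpochSet(np.atleast_2d(np.asarray(data, dtype=float)), fs=fs, t0=t0,
                    **defaults)


def direct_tfr(data, fs, freqs, n_cycles=7.0):
    """Independent oracle: per-trial time-domain convolution (np.convolve)."""
    data = np.atleast_2d(data)
    out = np.empty((data.shape[0], len(freqs), data.shape[1]), complex)
    for k, f in enumerate(freqs):
        w = morlet_wavelet(f, fs, n_cycles)
        h = (len(w) - 1) // 2
        for n in range(data.shape[0]):
            full = np.convolve(data[n], w, mode="full")
            out[n, k] = full[h:h + data.shape[1]]
        if h >= data.shape[1]:
            out[:, k] = np.nan
        elif h > 0:
            out[:, k, :h] = np.nan
            out[:, k, -h:] = np.nan
    return out


class TestMorletTFR:
    def test_zero_input_gives_zero_valid_coeffs(self):
        es = epochs_from(np.zeros((3, 1500)))
        tfr = morlet_tfr(es, np.array([10.0, 40.0]))
        vals = tfr.coeffs[~np.isnan(tfr.coeffs)]
        assert np.allclose(np.abs(vals), 0.0)

    def test_peak_frequency_of_a_40hz_cosine(self):
        fs = 1000.0
        t = np.arange(1500) / fs - 0.5
        es = epochs_from(np.cos(2 * np.pi * 40.0 * t))
        tfr = morlet_tfr(es, np.arange(10.0, 101.0, 1.0))
        power = np.nanmean(np.abs(tfr.coeffs[0]) ** 2, axis=1)
        assert tfr.freqs[np.argmax(power)] == 40.0

    def test_unit_sinusoid_amplitude_independent_of_frequency(self):
        # the normalization makes |W| read as signal amplitude at any freq
        fs = 1000.0
        t = np.arange(4000) / fs
        for f in (8.0, 40.0, 90.0):
            es = epochs_from(np.cos(2 * np.pi * f * t), t0=0.0,
                             stimulus="click_train")
            tfr = morlet_tfr(es, np.array([f]))
            mid = np.abs(tfr.coeffs[0, 0, 1800:2200])
            assert np.nanmean(mid) == pytest.approx(1.0, rel=1e-3)

    def test_equal_amplitude_tones_have_equal_power(self):
        fs = 1000.0
        t = np.arange(3000) / fs
        x = np.cos(2 * np.pi * 20 * t) + np.cos(2 * np.pi * 60 * t)
        es = epochs_from(x, t0=0.0)
        tfr = morlet_tfr(es, np.array([20.0, 60.0]))
        p20, p60 = np.nanmean(np.abs(tfr.coeffs[0]) ** 2, axis=1)
        assert p20 == pytest.approx(p60, rel=0.02)

    def test_matches_direct_convolution_oracle(self, rng):
        fs = 512.0
        data = rng.normal(0, 1, (8, 512))
        freqs = np.array([20.0, 40.0, 80.0])
        es = epochs_from(data, fs=fs, t0=-0.5)
        fast = morlet_tfr(es, freqs).coeffs
        slow = direct_tfr(data, fs, freqs)
        valid = ~np.isnan(slow)
        assert np.array_equal(valid, ~np.isnan(fast))
        err = np.max(np.abs(fast[valid] - slow[valid])) / np.max(np.abs(slow[valid]))
        assert err < 1e-6

    def test_nyquist_violation_rejected(self):
        es = epochs_from(np.zeros((1, 1500)))
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_tfr(es, np.array([400.0, 600.0]))


class TestMTP:
    def test_single_trial_identity(self, rng):
        es = epochs_from(rng.normal(0, 5, (1, 1500)))
        tfr = morlet_tfr(es, np.array([40.0]))
        m = mtp(tfr)
        np.testing.assert_allclose(m.values[0], np.abs(tfr.coeffs[0, 0]) ** 2)

    def test_quadratic_scaling(self, rng):
        data = rng.normal(0, 5, (6, 1500))
        f = np.array([40.0])
        m1 = mtp(morlet_tfr(epochs_from(data), f)).values
        m2 = mtp(morlet_tfr(epochs_from(2.0 * data), f)).values
        np.testing.assert_allclose(m2, 4.0 * m1, rtol=1e-10)

    def test_matches_brute_force_trial_mean(self, rng):
        data = rng.normal(0, 5, (12, 1500))
        tfr = morlet_tfr(epochs_from(data), np.array([35.0, 40.0]))
        expected = np.mean(np.abs(tfr.coeffs) ** 2, axis=0)
        np.testing.assert_allclose(mtp(tfr).values, expected, rtol=1e-12)


class TestPLF:
    def test_identical_trials_give_plf_one(self, rng):
        x = rng.normal(0, 5, 1500)
        es = epochs_from(np.tile(x, (5, 1)))
        p = plf(morlet_tfr(es, np.array([40.0])))
        vals = p.values[~np.isnan(p.values)]
        np.testing.assert_allclose(vals, 1.0, atol=1e-12)

    def test_four_opposed_phasors_cancel(self):
        fs = 1000.0
        t = np.arange(1500) / fs
        trials = [np.cos(2 * np.pi * 40 * t + ph)
                  for ph in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)]
        es = epochs_from(np.stack(trials), t0=0.0)
        p = plf(morlet_tfr(es, np.array([40.0])))
        assert abs(p.values[0, 750]) < 1e-10

    def test_random_phases_match_rayleigh_expectation(self):
        # mean resultant of N unit phasors with uniform phases:
        # E[R] ~= sqrt(pi)/2 / sqrt(N)
        fs, n_trials, reps = 1000.0, 120, 20
        t = np.arange(1200) / fs
        vals = []
        rng = np.random.default_rng(2024)
        for _ in range(reps):
            phases = rng.uniform(0, 2 * np.pi, n_trials)
            es = epochs_from(np.cos(2 * np.pi * 40 * t[None, :] + phases[:, None]),
                             t0=0.0)
            vals.append(plf(morlet_tfr(es, np.array([40.0]))).values[0, 600])
        expected = np.sqrt(np.pi) / 2 / np.sqrt(n_trials)
        # Rayleigh sd of R is ~0.042 at N=120; 20 reps -> se ~0.0095
        assert np.mean(vals) == pytest.approx(expected, abs=0.02)

    def test_amplitude_rescaling_invariance(self, rng):
        data = rng.normal(0, 5, (6, 1500))
        scales = rng.uniform(0.2, 5.0, size=(6, 1))
        f = np.array([40.0])
        p1 = plf(morlet_tfr(epochs_from(data), f)).values
        p2 = plf(morlet_tfr(epochs_from(scales * data), f)).values
        valid = ~np.isnan(p1)
        np.testing.assert_allclose(p1[valid], p2[valid], rtol=1e-9)
        assert np.nanmax(p1) <= 1.0 + 1e-12 and np.nanmin(p1) >= 0.0

    def test_single_trial_rejected(self, rng):
        tfr = morlet_tfr(epochs_from(rng.normal(0, 1, (1, 1500))), np.array([40.0]))
        with pytest.raises(ValueError, match="two trials"):
            plf(tfr)


class TestBandWindowMean:
    def make_map(self, values, freqs, times):
        return SpectralMap(values=np.asarray(values, dtype=float), kind="MTP",
                           freqs=np.asarray(freqs, dtype=float),
                           times=np.asarray(times, dtype=float), n_trials=1)

    def test_constant_map(self):
        m = self.make_map(np.full((5, 10), 3.25), np.arange(5), np.arange(10) / 10)
        assert band_window_mean(m, (1, 3), (0.1, 0.5)) == 3.25

    def test_single_cell(self):
        vals = np.arange(50, dtype=float).reshape(5, 10)
        m = self.make_map(vals, np.arange(5), np.arange(10) / 10)
        assert band_window_mean(m, (2, 2), (0.3, 0.3)) == vals[2, 3]

    def test_empty_intersection_rejected(self):
        m = self.make_map(np.ones((5, 10)), np.arange(5), np.arange(10) / 10)
        with pytest.raises(ValueError, match="intersect"):
            band_window_mean(m, (100, 200), (0.1, 0.5))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(-1e6, 1e6, allow_nan=False),
           f_lo=st.integers(0, 4), f_len=st.integers(0, 4),
           t_lo=st.integers(0, 9), t_len=st.integers(0, 9))
    def test_constant_map_mean_is_the_constant_for_any_rectangle(
            self, c, f_lo, f_len, t_lo, t_len):
        m = self.make_map(np.full((5, 10), c), np.arange(5), np.arange(10) / 10)
        got = band_window_mean(m, (f_lo, min(f_lo + f_len, 4)),
                               (t_lo / 10, min(t_lo + t_len, 9) / 10))
        assert got == pytest.approx(c, rel=1e-12, abs=1e-12)

    def test_nan_cells_excluded(self):
        vals = np.ones((3, 4))
        vals[0, 0] = np.nan
        m = self.make_map(vals, np.arange(3), np.arange(4))
        assert band_window_mean(m, (0, 2), (0, 3)) == 1.0
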