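"""Evoked-peak quantification, baseline significance and T/C ratios."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from audlfp import (
    PRESETS,
    PairParams,
    PeakSpec,
    RunConfig,
    average_erp,
    compute_ig,
    detect_peak,
    gen_pair_epochs,
    peak_significance,
)
from audlfp.io import EpochSet


def pair_epochs(data, fs=1000.0, t0=-3.5, region="AC"):
    return EpochSet(np.atleast_2d(np.asarray(data, dtype=float)), fs=fs, t0=t0,
                    region=region, condition="conscious", stimulus="sound_pair")


class TestAverageERP:
    def test_identical_trials_return_the_trial(self, rng):
        x = rng.normal(0, 5, 4600)
        es = pair_epochs(np.tile(x, (7, 1)))
        np.testing.assert_allclose(average_erp(es), x)

    def test_opposite_trials_cancel(self, rng):
        x = rng.normal(0, 5, 4600)
        es = pair_epochs(np.stack([x, -x]))
        np.testing.assert_allclose(average_erp(es), 0.0, atol=1e-12)

    def test_noise_shrinks_as_inverse_sqrt_n(self):
        # resampling oracle: rms deviation from the clean kernel ~ 1/sqrt(N)
        from audlfp.simulate import pair_kernel

        p = PairParams(n_trials=120, seed=11)
        es = gen_pair_epochs(p)
        t = es.times
        clean = pair_kernel(t, p) + pair_kernel(t - p.isi, p)  # gates default to 1
        rms = {}
        for n in (30, 120):
            sub = es.data[:n]
            rms[n] = np.sqrt(np.mean((sub.mean(axis=0) - clean) ** 2))
        ratio = rms[30] / rms[120]
        assert ratio == pytest.approx(2.0, rel=0.35)


class TestDetectPeak:
    spec_neg = PeakSpec("N25", "negative", (0.010, 0.040), "AC")
    spec_pos = PeakSpec("P40", "positive", (0.025, 0.060), "AC")

    def test_noise_free_kernel_recovers_construction(self):
        # well-separated lobes: no cross-lobe leakage at the peak
        p = PairParams(latN=0.035, latP=0.075, noise_amp=0.0, n_trials=1, seed=0)
        es = gen_pair_epochs(p)
        lat, amp, boundary = detect_peak(es.times, es.data[0], self.spec_neg, 0.0)
        assert not boundary
        assert lat == pytest.approx(p.latN, abs=1.0 / p.fs)
        assert amp == pytest.approx(p.ampN, rel=1e-3)

    def test_flat_waveform_is_boundary_flagged_with_zero_amplitude(self):
        t = np.arange(4600) / 1000.0 - 3.5
        lat, amp, boundary = detect_peak(t, np.zeros_like(t), self.spec_neg, 0.0)
        assert boundary and amp == 0.0

    def test_deeper_of_two_lobes_wins(self):
        # exhaustive extremum-scan oracle on a two-lobe waveform
        t = np.arange(4600) / 1000.0 - 3.5
        w = (-8.0 * np.exp(-0.5 * ((t - 0.020) / 0.004) ** 2)
             - 5.0 * np.exp(-0.5 * ((t - 0.033) / 0.004) ** 2))
        lat, amp, boundary = detect_peak(t, w, self.spec_neg, 0.0)
        assert not boundary
        assert lat == pytest.approx(0.020, abs=0.001)
        assert amp == pytest.approx(-8.0, abs=0.05)  # small cross-lobe leakage
        interior = (t >= 0.010) & (t <= 0.040)
        base = w[np.argmin(np.abs(t))]
        assert amp == pytest.approx(w[interior].min() - base, rel=1e-9)

    def test_equal_depth_tie_resolves_to_earliest(self):
        t = np.arange(4600) / 1000.0 - 3.5
        w = (-6.0 * np.exp(-0.5 * ((t - 0.018) / 0.003) ** 2)
             - 6.0 * np.exp(-0.5 * ((t - 0.032) / 0.003) ** 2))
        lat, _, _ = detect_peak(t, w, self.spec_neg, 0.0)
        assert lat == pytest.approx(0.018, abs=0.001)

    def test_empty_window_rejected(self):
        t = np.arange(100) / 1000.0
        with pytest.raises(ValueError, match="window"):
            detect_peak(t, np.zeros_like(t), PeakSpec("N25", "negative",
                        (0.2, 0.3), "AC"), 0.5)

    def test_polarity_label_consistency_enforced(self):
        with pytest.raises(ValueError, match="polarity"):
            PeakSpec("N25", "positive", (0.01, 0.04), "AC")


class TestPeakSignificance:
    def test_noise_free_peak_is_maximally_significant(self):
        es = gen_pair_epochs(PairParams(noise_amp=0.0, n_trials=20, seed=0))
        p = peak_significance(es, 0.025, 0.0, (-3.0, -2.0))
        assert p == 0.0

    def test_tiny_peak_is_rarely_significant(self):
        # amplitude at 0.1x the noise sd: power against alpha=0.01 ~ none
        hits = 0
        for seed in range(40):
            es = gen_pair_epochs(PairParams(ampN=-2.0, ampP=1.5, noise_amp=20.0,
                                            n_trials=120, seed=seed))
            p = peak_significance(es, 0.025, 0.0, (-3.0, -2.0))
            hits += p < 0.01
        assert hits <= 2  # >= 95% non-significant

    def test_control_period_must_fit(self):
        es = gen_pair_epochs(PairParams(noise_amp=0.0, n_trials=2, seed=0))
        with pytest.raises(ValueError, match="control period"):
            peak_significance(es, 0.025, 0.0, (-4.0, -3.6))

    def test_too_few_null_windows_rejected(self):
        es = gen_pair_epochs(PairParams(noise_amp=0.0, n_trials=2, seed=0))
        with pytest.raises(ValueError, match="null windows"):
            peak_significance(es, 0.025, 0.0, (-3.0, -2.95))


class TestComputeIG:
    def test_noise_free_ratio_equals_gate_exactly(self, config):
        pre = PRESETS[("PFC", "conscious")]
        p = replace(pre.pair, noise_amp=0.0, n_trials=2)
        ig = compute_ig(gen_pair_epochs(p, region="PFC"), config)
        assert ig.tc_ratio["N35"] == pytest.approx(p.gateN, abs=1e-6)
        assert ig.tc_ratio["P70"] == pytest.approx(p.gateP, abs=1e-6)

    def test_noise_free_ac_ratio_with_overlapping_lobes(self, config):
        # N25/P40 Gaussian lobes overlap slightly; the ratio deviation from
        # the generative gate is bounded by the cross-lobe leakage
        pre = PRESETS[("AC", "conscious")]
        p = replace(pre.pair, noise_amp=0.0, n_trials=2)
        ig = compute_ig(gen_pair_epochs(p, region="AC"), config)
        assert ig.tc_ratio["N25"] == pytest.approx(p.gateN, abs=0.01)
        assert ig.tc_ratio["P40"] == pytest.approx(p.gateP, abs=0.01)

    def test_no_gating_recovers_ratio_one(self, config):
        vals = []
        for seed in range(20):
            p = PairParams(gateN=1.0, gateP=1.0, seed=seed)
            ig = compute_ig(gen_pair_epochs(p, region="AC"), config)
            vals.append(ig.tc_ratio["N25"])
        assert np.nanmean(vals) == pytest.approx(1.0, abs=0.03)

    def test_full_gating_suppresses_t_response(self, config):
        # gateN = 0: the T-window negative peak is pure noise; either it is
        # non-significant (ratio undefined) or its ratio sits near the floor
        vals = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(10):
                p = PairParams(gateN=0.0, gateP=0.0, seed=seed)
                ig = compute_ig(gen_pair_epochs(p, region="AC"), config)
                if not np.isnan(ig.tc_ratio["N25"]):
                    vals.append(abs(ig.tc_ratio["N25"]))
        assert all(v <= 0.1 for v in vals)

    def test_ratio_invariant_under_global_rescale(self, config):
        p = PairParams(gateN=0.6, gateP=0.4, seed=3)
        es = gen_pair_epochs(p, region="AC")
        scaled = EpochSet(5.0 * es.data, fs=es.fs, t0=es.t0, region=es.region,
                          condition=es.condition, stimulus=es.stimulus,
                          session_id=es.session_id)
        r1 = compute_ig(es, config).tc_ratio
        r2 = compute_ig(scaled, config).tc_ratio
        for label in r1:
            assert r1[label] == pytest.approx(r2[label], rel=1e-9)

    def test_regional_gating_strength_ordering(self, config):
        # conscious gating deepens from AC to PFC (both polarities, by preset
        # construction; the pipeline must preserve the ordering)
        means = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for region in ("AC", "HP", "AMY", "PFC"):
                pre = PRESETS[(region, "conscious")]
                vals = []
                for seed in range(8):
                    ig = compute_ig(gen_pair_epochs(replace(pre.pair, seed=seed),
                                                    region=region), config)
                    vals.append(ig.tc_ratio[list(ig.tc_ratio)[0]])
                means[region] = np.nanmean(vals)
        assert means["AC"] > means["HP"] > means["AMY"] > means["PFC"]

    def test_wrong_stimulus_rejected(self, config, rng):
        es = EpochSet(rng.normal(0, 1, (2, 1501)), fs=1000.0, t0=-0.5,
                      region="AC", condition="conscious", stimulus="click_train")
        with pytest.raises(ValueError, match="sound_pair"):
            compute_ig(es, config)

    def test_non_significant_peak_yields_nan_not_zero(self, config):
        p = PairParams(ampN=-0.5, ampP=0.4, seed=0)  # buried in noise
        with pytest.warns(UserWarning, match="undefined"):
            ig = compute_ig(gen_pair_epochs(p, region="AC"), config)
        assert any(np.isnan(v) for v in ig.tc_ratio.values())
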