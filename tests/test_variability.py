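import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from weanwave.signals import BreathSeries, middle_window
from weanwave.synthetic import gen_fgn
from weanwave.variability import (
    FEATURE_NAMES,
    FeatureConfig,
    dfa,
    extract_features,
    poincare,
    rsbi,
    sample_entropy,
)

from .oracles import naive_sample_entropy, rotated_poincare


class TestPoincare:
    def test_alternating_series_closed_form(self):
        a, b = 3.0, 7.0
        # odd length -> even number of lagged pairs, so the +/-d jumps
        # cancel exactly and the closed form d/sqrt(2) is exact
        res = poincare([a, b] * 10 + [a])
        assert res.sd1 == pytest.approx(abs(a - b) / math.sqrt(2), abs=1e-12)
        assert res.sd2 == pytest.approx(0.0, abs=1e-12)
        assert not res.ratio_defined

    def test_constant_series_zero_variability(self):
        res = poincare(np.full(50, 4.2))
        assert res.sd1 == 0.0 and res.sd2 == 0.0
        assert math.isnan(res.ratio)

    def test_iid_normal_isotropic_cloud(self, rng):
        res = poincare(rng.standard_normal(100_000))
        assert res.sd1 == pytest.approx(1.0, abs=0.02)
        assert res.sd2 == pytest.approx(1.0, abs=0.02)
        assert res.ratio == pytest.approx(1.0, abs=0.02)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_closed_form_equals_rotation_construction(self, seed):
        x = np.random.default_rng(seed).normal(
            loc=80.0, scale=5.0, size=np.random.default_rng(seed).integers(3, 400)
        )
        res = poincare(x)
        sd1_rot, sd2_rot = rotated_poincare(x)
        assert res.sd1 == pytest.approx(sd1_rot, abs=1e-10)
        assert res.sd2 == pytest.approx(sd2_rot, abs=1e-10)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            poincare([1.0, 2.0])


class TestSampleEntropy:
    def test_constant_series_perfectly_regular(self):
        res = sample_entropy(np.full(60, 2.0), m=2, r=0.5)
        assert res.sampen == 0.0

    def test_small_series_matches_counting_oracle(self):
        x = [1, 2, 3, 2, 1, 2, 3, 2, 1]
        expected, a, b = naive_sample_entropy(x, m=2, r=0.5)
        res = sample_entropy(x, m=2, r=0.5)
        assert res.a_count == a and res.b_count == b
        assert res.sampen == pytest.approx(expected, abs=1e-12)

    def test_fast_path_equals_naive_oracle_exactly(self, rng):
        x = rng.uniform(size=1000)
        expected, a, b = naive_sample_entropy(x, m=2)
        res = sample_entropy(x, m=2)
        assert (res.a_count, res.b_count) == (a, b)
        assert res.sampen == expected

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.5, 50.0), st.floats(-10.0, 10.0))
    def test_affine_invariance_with_relative_tolerance(self, seed, scale, shift):
        x = np.random.default_rng(seed).standard_normal(300)
        base = sample_entropy(x, m=2, r_frac=0.2)
        scaled = sample_entropy(scale * x + shift, m=2, r_frac=0.2)
        assert scaled.sampen == pytest.approx(base.sampen, rel=1e-9)

    def test_increases_with_noise_amplitude(self):
        # SampEn of a periodic signal grows (statistically) with added noise
        t = np.arange(400)
        base = np.sin(2 * np.pi * t / 25)
        levels = (0.05, 0.3, 1.0)
        means = []
        for amp in levels:
            vals = []
            for seed in range(30):
                noisy = base + amp * np.random.default_rng(seed).standard_normal(len(t))
                vals.append(sample_entropy(noisy, m=2, r=0.2 * np.std(base)).sampen)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_no_matches_flagged_undefined(self):
        # strictly increasing with huge steps and tiny r: B > 0 impossible
        x = np.cumsum(np.arange(1.0, 30.0))
        res = sample_entropy(x, m=2, r=1e-6)
        assert not res.defined and math.isnan(res.sampen)

    def test_stride_subsamples(self):
        x = np.random.default_rng(0).standard_normal(1000)
        res = sample_entropy(x, stride=4)
        assert res.n_used == 250

    @pytest.mark.parametrize(
        "kwargs", [dict(r=-0.1), dict(r=0.0)], ids=["negative-r", "zero-r"]
    )
    def test_bad_tolerance_errors(self, kwargs):
        with pytest.raises(ValueError):
            sample_entropy(np.arange(50.0), **kwargs)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="short"):
            sample_entropy([1.0, 2.0, 3.0], m=2, r=0.5)


class TestDFA:
    def test_white_noise_alpha_near_half(self):
        vals = [
            dfa(np.random.default_rng(s).standard_normal(4096)).alpha1
            for s in range(1, 21)
        ]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_integrated_noise_alpha_near_three_halves(self):
        vals = [
            dfa(np.cumsum(np.random.default_rng(s).standard_normal(4096))).alpha1
            for s in range(1, 21)
        ]
        assert np.mean(vals) == pytest.approx(1.5, abs=0.1)

    def test_fgn_recovers_hurst(self):
        vals = [dfa(gen_fgn(0.9, 4096, seed=s)).alpha1 for s in range(1, 21)]
        assert np.mean(vals) == pytest.approx(0.9, abs=0.07)
        assert np.mean(vals) > 0.5

    def test_fluctuation_matches_explicit_loop(self):
        from weanwave.variability import _fluctuation

        x = np.random.default_rng(3).standard_normal(512)
        profile = np.cumsum(x - x.mean())
        n = 16
        k = len(profile) // n
        residuals = []
        for i in range(k):
            box = profile[i * n : (i + 1) * n]
            coeffs = np.polyfit(np.arange(n), box, 1)
            residuals.extend(box - np.polyval(coeffs, np.arange(n)))
        expected = float(np.sqrt(np.mean(np.square(residuals))))
        assert _fluctuation(profile, n) == pytest.approx(expected, abs=1e-10)

    def test_constant_input_flagged_undefined(self):
        res = dfa(np.zeros(2048))
        assert not res.defined

    def test_short_series_errors(self):
        with pytest.raises(ValueError, match="short"):
            dfa(np.random.default_rng(0).standard_normal(100))

    def test_scale_bands_need_three_sizes(self):
        x = np.random.default_rng(0).standard_normal(2048)
        with pytest.raises(ValueError, match="3 box sizes"):
            dfa(x, (10, 20), (40, 80, 160))


class TestRsbi:
    @pytest.mark.parametrize(
        "rate,vt_l,expected", [(20, 0.5, 40.0), (35, 0.25, 140.0)]
    )
    def test_arithmetic(self, rate, vt_l, expected):
        window = 60.0
        onsets = np.arange(rate) * (60.0 / rate) + 0.1
        breaths = BreathSeries(
            onsets, np.full(rate, vt_l * 1000), np.full(rate, 1.0), np.full(rate, 1.0)
        )
        assert rsbi(breaths, window) == pytest.approx(expected)

    def test_zero_breaths_errors(self):
        with pytest.raises(ValueError, match="at least one breath"):
            rsbi(BreathSeries.empty(), 60.0)

    def test_zero_tidal_volume_errors(self):
        breaths = BreathSeries([1.0, 2.0], [0.0, 0.0], [1, 1], [1, 1])
        with pytest.raises(ValueError, match="tidal volume"):
            rsbi(breaths, 60.0)

    def test_generator_round_trip(self):
        from weanwave.synthetic import BreathParams, gen_breaths

        errors = []
        for seed in range(10):
            params = BreathParams(resp_rate=20.0, tv_mean_ml=450.0)
            b = gen_breaths(600.0, params, seed=seed)
            expected = 20.0 / 0.450
            errors.append(rsbi(b, 600.0) / expected - 1.0)
        assert abs(np.mean(errors)) < 0.02


class TestExtractFeatures:
    def test_full_record_has_all_features(self, small_cohort):
        records, _ = small_cohort
        rec = middle_window(records[0], 60.0)
        vec = extract_features(rec, FeatureConfig(window_s=60.0))
        assert set(vec.values) == set(FEATURE_NAMES)
        assert not any(vec.mask.values())
        assert vec.rsbi > 0

    def test_missing_channel_masks_its_features(self, small_cohort):
        records, _ = small_cohort
        rec = middle_window(records[0], 60.0)
        rec.waveforms.pop("PPG")
        vec = extract_features(rec, FeatureConfig(window_s=60.0))
        ppg = [n for n in FEATURE_NAMES if n.startswith("ppg_")]
        assert all(vec.mask[n] for n in ppg)
        others = [n for n in FEATURE_NAMES if not n.startswith("ppg_")]
        assert not any(vec.mask[n] for n in others)

    def test_deterministic(self, small_cohort):
        records, _ = small_cohort
        rec = middle_window(records[1], 60.0)
        fc = FeatureConfig(window_s=60.0)
        s1 = extract_features(rec, fc).to_series()
        s2 = extract_features(rec, fc).to_series()
        assert s1.equals(s2)
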