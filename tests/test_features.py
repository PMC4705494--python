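import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.regression.linear_model import burg as sm_burg

from hrvbp import FEATURE_NAMES, FeatureConfig, RRSeries, extract_all
from hrvbp.features import (approximate_entropy, burg_ar,
                            correlation_dimension, dfa, poincare, rqa,
                            sample_entropy, spectral, time_domain,
                            triangular)

from .oracles import apen_brute, rqa_brute, sampen_brute


def two_tone(mu=850, a_lf=0.0, f_lf=0.1, a_hf=0.0, f_hf=0.25, sd=0.0,
             duration=300, seed=0):
    """Direct two-tone RR construction (independent of the generator)."""
    rng = np.random.default_rng(seed)
    t, rr = 0.0, []
    while t < duration:
        v = (mu + a_lf * np.sin(2 * np.pi * f_lf * t)
             + a_hf * np.sin(2 * np.pi * f_hf * t)
             + sd * rng.standard_normal())
        rr.append(v)
        t += v / 1000.0
    return RRSeries(np.array(rr))


class TestTimeDomain:
    def test_constant_series_zero_variability(self):
        td = time_domain(np.full(100, 800.0))
        assert td == {"MeanRR": 800.0, "STDNN": 0.0, "RMSSD": 0.0,
                      "NN50": 0.0, "pNN50": 0.0}

    def test_hand_computed_values(self):
        td = time_domain(np.array([800.0, 860.0, 865.0, 920.0]))
        assert td["RMSSD"] == pytest.approx(np.sqrt(6650 / 3), abs=1e-9)
        assert td["STDNN"] == pytest.approx(np.sqrt(7218.75 / 3), abs=1e-9)
        assert td["NN50"] == 2
        assert td["pNN50"] == pytest.approx(200 / 3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            time_domain(np.array([800.0]))

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(400, 1500), min_size=3, max_size=60),
           st.floats(0.5, 3.0))
    def test_scaling_and_pnn50_identity(self, rr, c):
        rr = np.asarray(rr)
        td, tds = time_domain(rr), time_domain(c * rr)
        for k in ("STDNN", "RMSSD"):
            assert tds[k] == pytest.approx(c * td[k], rel=1e-9, abs=1e-9)
        assert td["pNN50"] == pytest.approx(
            100 * td["NN50"] / (rr.size - 1), abs=1e-12)


class TestTriangular:
    def test_single_bin_degenerate(self, caplog):
        out = triangular(np.full(50, 800.0))
        assert out["HRVtri"] == 1.0 and out["TINN"] == 0.0

    def test_two_equal_bins(self):
        bw = 1000.0 / 128.0
        rr = np.concatenate([np.full(50, 800.0), np.full(50, 800.0 + bw)])
        assert triangular(rr + 1e-6)["HRVtri"] == pytest.approx(2.0)

    def test_exact_triangle_width(self):
        # histogram counts 1,2,3,4,3,2,1 with zero-count bins at the ends
        bw = 1000.0 / 128.0
        base = 800.0 + bw / 2
        counts = [0, 2, 4, 6, 8, 6, 4, 2, 0]
        rr = np.concatenate([np.full(c, base + i * bw)
                             for i, c in enumerate(counts)])
        out = triangular(rr)
        assert out["TINN"] == pytest.approx(8 * bw, rel=1e-9)


class TestSpectral:
    def test_hf_tone_concentrates_in_hf_band(self):
        s = two_tone(a_hf=30, f_hf=0.25, sd=2, seed=1)
        sp = spectral(s)
        assert sp["HF"] > 10 * sp["LF"]
        assert sp["LFHF"] < 0.1

    def test_lf_tone_concentrates_in_lf_band(self):
        s = two_tone(a_lf=30, f_lf=0.10, sd=2, seed=2)
        sp = spectral(s)
        assert sp["LFHF"] > 10

    def test_band_power_scales_with_amplitude_squared(self):
        p1 = spectral(two_tone(a_hf=20, f_hf=0.25, sd=5, seed=3))["HF"]
        p2 = spectral(two_tone(a_hf=40, f_hf=0.25, sd=5, seed=3))["HF"]
        assert p2 / p1 == pytest.approx(4.0, rel=0.10)

    def test_sinusoid_power_near_parseval(self):
        # one-sided band power of an A-amplitude tone is close to A^2/2
        sp = spectral(two_tone(a_hf=30, f_hf=0.25, sd=1, seed=4))
        assert sp["HF"] == pytest.approx(450.0, rel=0.15)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="2 minutes"):
            spectral(two_tone(duration=60))

    def test_burg_matches_statsmodels(self, rng):
        x = rng.standard_normal(500)
        x = x + 0.6 * np.roll(x, 1)
        rho_m, s2_m = burg_ar(x - x.mean(), 8)
        rho_s, s2_s = sm_burg(x, order=8, demean=True)
        np.testing.assert_allclose(rho_m, rho_s, atol=1e-12)
        assert s2_m == pytest.approx(s2_s, rel=0.01)


class TestPoincare:
    def test_constant_series(self):
        out = poincare(np.full(20, 800.0))
        assert out["SD1"] == 0.0 and out["SD2"] == 0.0

    def test_hand_computed_sd1(self):
        out = poincare(np.array([800.0, 860.0, 865.0, 920.0]))
        assert out["SD1"] == pytest.approx(np.sqrt(925.0 / 2), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_sd1_sd2_identities(self, seed):
        rr = 800 + 50 * np.random.default_rng(seed).standard_normal(200)
        out = poincare(rr)
        sdsd = np.std(np.diff(rr), ddof=1)
        stdnn = np.std(rr, ddof=1)
        assert out["SD1"] == pytest.approx(sdsd / np.sqrt(2), abs=1e-9)
        assert out["SD1"] ** 2 + out["SD2"] ** 2 == pytest.approx(
            2 * stdnn ** 2, abs=1e-9)


class TestEntropies:
    def test_constant_series_zero_entropy(self):
        rr = np.full(100, 800.0)
        assert sample_entropy(rr, 2) == 0.0
        assert approximate_entropy(rr, 2) == pytest.approx(0.0, abs=1e-12)

    def test_periodic_alternation_sampen_zero(self):
        rr = np.tile([800.0, 900.0], 60)
        assert sample_entropy(rr, 2) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 150))
        rr = 800 + 30 * rng.standard_normal(n)
        r = 0.2 * np.std(rr, ddof=1)
        assert sample_entropy(rr, 2, r) == pytest.approx(
            sampen_brute(rr, 2, r), abs=1e-10, nan_ok=True)
        assert approximate_entropy(rr, 2, r) == pytest.approx(
            apen_brute(rr, 2, r), abs=1e-10)


class TestCorrelationDimension:
    def test_limit_cycle_dimension_near_one(self):
        s = two_tone(a_hf=50, f_hf=0.23, sd=0.5, duration=300, seed=5)
        assert correlation_dimension(s.rr) == pytest.approx(1.0, abs=0.3)

    def test_white_noise_does_not_saturate(self, rng):
        d2 = correlation_dimension(rng.standard_normal(400))
        assert d2 > 3.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            correlation_dimension(np.full(100, 800.0))


class TestDFA:
    def test_white_noise_exponent(self):
        vals = [dfa(np.random.default_rng(s).standard_normal(1000))["DFA1"]
                for s in range(20)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)

    def test_random_walk_exponent(self):
        vals = [dfa(np.cumsum(np.random.default_rng(s).standard_normal(
            1000)))["DFA1"] for s in range(20)]
        assert np.mean(vals) == pytest.approx(1.5, abs=0.15)

    def test_scale_invariance(self, rng):
        rr = 800 + 20 * rng.standard_normal(400)
        a, b = dfa(rr), dfa(3.7 * rr)
        assert a["DFA1"] == pytest.approx(b["DFA1"], abs=1e-9)
        assert a["DFA2"] == pytest.approx(b["DFA2"], abs=1e-9)

    def test_dfa2_missing_when_short(self):
        out = dfa(800 + np.random.default_rng(0).standard_normal(150))
        assert np.isfinite(out["DFA1"]) and np.isnan(out["DFA2"])


class TestRQA:
    def test_periodic_series_fully_deterministic(self):
        rr = np.tile([800.0, 900.0], 51)[:101]  # even vector count
        out = rqa(rr, m=10, tau=1)
        assert out["RPDET"] == pytest.approx(100.0)
        assert out["RPREC"] > 0

    def test_huge_radius_gives_full_recurrence(self, rng):
        rr = 800 + 10 * rng.standard_normal(80)
        out = rqa(rr, m=10, tau=1, r_factor=1e6)
        assert out["RPREC"] == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(65, 120))
        rr = 800 + 25 * rng.standard_normal(n)
        m, tau, lmin = 5, 1, 2
        r = np.sqrt(m) * np.std(rr, ddof=1)
        mine = rqa(rr, m=m, tau=tau, r_factor=1.0, lmin=lmin)
        ref = rqa_brute(rr, m, tau, r, lmin)
        for k in ("RPREC", "RPDET", "RPLmean", "RPLmax", "RPShan"):
            assert mine[k] == pytest.approx(ref[k], abs=1e-9, nan_ok=True), k


class TestExtractAll:
    def test_feature_names_and_order(self):
        s = two_tone(a_lf=15, a_hf=15, sd=5, seed=6)
        vec = extract_all(s)
        assert list(vec.index) == list(FEATURE_NAMES)
        assert len(vec) == 22
        assert vec.notna().all()

    def test_deterministic(self):
        s = two_tone(a_lf=15, a_hf=15, sd=5, seed=7)
        a, b = extract_all(s), extract_all(s)
        assert a.equals(b)

    def test_constant_series_missing_with_reason(self, caplog):
        import logging
        s = RRSeries(np.full(150, 800.0))
        with caplog.at_level(logging.INFO, logger="hrvbp.features"):
            vec = extract_all(s)
        assert vec["MeanRR"] == 800.0
        assert vec["STDNN"] == 0.0
        # D2 needs 200 beats -> missing, and the reason is logged
        assert np.isnan(vec["D2"])
        assert any("D2" in r.message for r in caplog.records)

    def test_unknown_feature_rejected(self):
        s = two_tone(sd=5, duration=150, seed=8)
        with pytest.raises(ValueError, match="unknown feature"):
            extract_all(s, features=["NotAFeature"])

    def test_subset_extraction_matches_full(self):
        s = two_tone(a_hf=20, sd=5, seed=9)
        full = extract_all(s)
        sub = extract_all(s, features=["RMSSD", "HF"])
        assert sub["RMSSD"] == full["RMSSD"]
        assert sub["HF"] == full["HF"]
        assert np.isnan(sub["ApEn"])
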