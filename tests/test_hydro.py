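import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agrocycle.hydro import (TIFN, HydroThresholds, PearsonIIIParams,
                             build_hydro_scenario, cdf_pearson3,
                             classify_hydro_year, fit_pearson3,
                             generate_precip_record, monte_carlo_years,
                             quantile_pearson3, tifn_defuzzify)


class TestTIFN:
    def test_crisp_identity(self):
        assert tifn_defuzzify(TIFN(2.0, 2.0, 2.0, 1.0, 0.0)) == pytest.approx(2.0)

    def test_symmetric_support(self):
        assert tifn_defuzzify(TIFN(1.5, 2.0, 2.5, 1.0, 0.0)) == pytest.approx(2.0)

    def test_hand_example(self):
        # (1 + 4 + 3)/4 * (1 + 0.8 - 0.1)/2 = 2 * 0.85
        assert tifn_defuzzify(TIFN(1.0, 2.0, 3.0, 0.8, 0.1)) == pytest.approx(1.7)

    def test_invalid_support(self):
        with pytest.raises(ValueError):
            TIFN(3.0, 2.0, 1.0)

    def test_invalid_degrees(self):
        with pytest.raises(ValueError):
            TIFN(1.0, 2.0, 3.0, 0.8, 0.5)

    @given(delta=st.floats(0.01, 5.0), w=st.floats(0.1, 1.0))
    def test_monotone_in_upper_and_w(self, delta, w):
        base = tifn_defuzzify(TIFN(1.0, 2.0, 3.0, 0.5, 0.2))
        assert tifn_defuzzify(TIFN(1.0, 2.0, 3.0 + delta, 0.5, 0.2)) > base
        wider = tifn_defuzzify(TIFN(1.0, 2.0, 3.0, min(0.5 + w / 2, 0.8), 0.2))
        assert wider >= base

    def test_antitone_in_v(self):
        lo_v = tifn_defuzzify(TIFN(1.0, 2.0, 3.0, 0.5, 0.1))
        hi_v = tifn_defuzzify(TIFN(1.0, 2.0, 3.0, 0.5, 0.4))
        assert hi_v < lo_v


class TestPearsonIII:
    def test_moment_recovery(self):
        true = PearsonIIIParams(mean=550.0, cv=0.25, cs=0.5)
        series = generate_precip_record(100_000, 550.0, 0.25, 0.5, seed=11)
        fit = fit_pearson3(series)
        assert fit.mean == pytest.approx(true.mean, rel=0.02)
        assert fit.cv == pytest.approx(true.cv, rel=0.02)
        assert fit.cs == pytest.approx(true.cs, rel=0.1)

    def test_constant_series_raises(self):
        with pytest.raises(ValueError):
            fit_pearson3([500.0, 500.0, 500.0, 500.0])

    def test_scale_equivariance(self):
        series = generate_precip_record(500, 550.0, 0.25, 0.5, seed=3)
        f1 = fit_pearson3(series)
        f2 = fit_pearson3(3.0 * series)
        assert f2.mean == pytest.approx(3.0 * f1.mean)
        assert f2.cv == pytest.approx(f1.cv)
        assert f2.cs == pytest.approx(f1.cs)

    def test_zero_skew_median_is_mean(self):
        p = PearsonIIIParams(mean=500.0, cv=0.2, cs=0.0)
        assert quantile_pearson3(p, 0.5) == pytest.approx(500.0, abs=1e-6)

    def test_quantiles_monotone(self):
        p = PearsonIIIParams(mean=553.2, cv=0.25, cs=0.5)
        q25, q50, q75 = (quantile_pearson3(p, x) for x in (0.25, 0.50, 0.75))
        assert q25 > q50 > q75

    def test_cdf_quantile_round_trip(self):
        p = PearsonIIIParams(mean=553.2, cv=0.25, cs=0.8)
        for prob in np.linspace(0.01, 0.99, 25):
            q = quantile_pearson3(p, prob)
            assert cdf_pearson3(p, q) == pytest.approx(1.0 - prob, abs=1e-8)

    def test_quantile_bounds(self):
        p = PearsonIIIParams(mean=500.0, cv=0.2, cs=0.5)
        with pytest.raises(ValueError):
            quantile_pearson3(p, 0.0)

    def test_record_positive_and_reproducible(self):
        a = generate_precip_record(1000, 300.0, 0.6, 1.5, seed=5)
        b = generate_precip_record(1000, 300.0, 0.6, 1.5, seed=5)
        assert np.all(a > 0)
        np.testing.assert_array_equal(a, b)

    def test_clt_mean_check(self):
        n = 10_000
        series = generate_precip_record(n, 550.0, 0.2, 0.0, seed=17)
        se = 550.0 * 0.2 / np.sqrt(n)
        assert abs(series.mean() - 550.0) < 3 * se


class TestClassification:
    thresholds = HydroThresholds(p25=448.1, p75=271.2)

    def test_wet_year(self):
        assert classify_hydro_year(512.6, self.thresholds) == "wet"

    def test_normal_year(self):
        assert classify_hydro_year(419.5, self.thresholds) == "normal"

    def test_dry_year(self):
        assert classify_hydro_year(212.9, self.thresholds) == "dry"

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            HydroThresholds(p25=200.0, p75=300.0)

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        for p in rng.uniform(0, 1000, size=200):
            assert classify_hydro_year(p, self.thresholds) in ("wet", "normal", "dry")


class TestMonteCarlo:
    def test_proportions(self):
        p = PearsonIIIParams(mean=553.2, cv=0.25, cs=0.5)
        n = 100_000
        _, _, props = monte_carlo_years(p, n, seed=1)
        for cls, expected in (("wet", 0.25), ("normal", 0.50), ("dry", 0.25)):
            sigma = np.sqrt(expected * (1 - expected) / n)
            assert abs(props[cls] - expected) < 3 * sigma, (cls, props[cls])

    def test_single_draw(self):
        p = PearsonIIIParams(mean=500.0, cv=0.2, cs=0.3)
        draws, labels, props = monte_carlo_years(p, 1, seed=2)
        assert len(draws) == 1 and len(labels) == 1
        assert sum(props.values()) == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        p = PearsonIIIParams(mean=500.0, cv=0.2, cs=0.3)
        d1, l1, _ = monte_carlo_years(p, 50, seed=9)
        d2, l2, _ = monte_carlo_years(p, 50, seed=9)
        np.testing.assert_array_equal(d1, d2)
        assert l1 == l2


class TestHydroScenario:
    def test_stage_distribution(self):
        sc = build_hydro_scenario("normal", 400.0, [0.2, 0.3, 0.5],
                                  season_fraction=0.5, n_crops=2)
        assert len(sc.rain_st) == 2
        assert sc.rain_st[0].sum() == pytest.approx(200.0)
        np.testing.assert_allclose(sc.rain_st[0], [40.0, 60.0, 100.0])

    def test_greenhouse_gets_zero(self):
        sc = build_hydro_scenario("wet", 600.0, [0.5, 0.5], n_crops=2,
                                  greenhouse=[True, False])
        assert sc.rain_st[0].sum() == 0.0
        assert sc.rain_st[1].sum() > 0.0
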