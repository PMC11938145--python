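import json

import numpy as np
import pytest

from agrocycle import synthetic
from agrocycle.production import amendment_factor
from agrocycle.synthetic import (StudyConfig, fit_amendment, fit_n_response,
                                 forward_treatment, generate_amendment_design,
                                 generate_design, generate_observations,
                                 generate_parameters)


class TestDesign:
    def test_nine_treatments(self, design):
        assert len(design) == 9
        assert [t.id for t in design] == [f"T{i}" for i in range(1, 10)]

    def test_in_pairs_bijective(self, design):
        pairs = {(t.irrigation_level, t.nitrogen_level) for t in design}
        assert len(pairs) == 9

    def test_t5_pairing(self, design):
        t5 = next(t for t in design if t.id == "T5")
        assert (t5.irrigation_level, t5.nitrogen_level, t5.additive_level) == \
            ("I2", "N2", "B3S3")

    def test_t1_pairing(self, design):
        t1 = next(t for t in design if t.id == "T1")
        assert (t1.irrigation_level, t1.nitrogen_level, t1.additive_level) == \
            ("I1", "N1", "B3S3")

    def test_b2s2_rates(self, design):
        t = next(t for t in design if t.additive_level == "B2S2")
        assert t.biochar_rate == (15.0, 30.0, 20.0)
        assert t.straw_rate == (15.0, 30.0, 20.0)

    def test_rates_nonnegative(self, design):
        for t in design:
            assert min(t.biochar_rate) >= 0 and min(t.straw_rate) >= 0

    def test_factor_values(self, design):
        assert {t.irrigation_factor for t in design} == {1.0, 0.75, 0.5}
        assert {t.nitrogen_factor for t in design} == {1.5, 1.0, 0.5}


class TestParameters:
    def test_same_seed_identical(self):
        cfg = StudyConfig(seed=123)
        b1 = generate_parameters(cfg)
        b2 = generate_parameters(cfg)
        assert json.dumps(b1.to_dict(), sort_keys=True) == \
            json.dumps(b2.to_dict(), sort_keys=True)

    def test_different_seed_differs(self):
        a = generate_parameters(StudyConfig(seed=1)).to_dict()
        b = generate_parameters(StudyConfig(seed=2)).to_dict()
        assert json.dumps(a) != json.dumps(b)

    def test_tomato_lambda_defaults(self, bundle):
        np.testing.assert_allclose(bundle.crops[0].jensen.lam,
                                   [0.086, 0.314, 0.532, 0.208, 0.163])

    def test_n_response_vertex_formula(self):
        # vertex of a quadratic with a=-0.1, b=48 sits at 240 kg/ha
        assert -48.0 / (2 * -0.1) == pytest.approx(240.0)

    def test_concavity_and_vertex_range(self):
        for seed in range(5):
            b = generate_parameters(StudyConfig(seed=seed))
            for crop in b.crops:
                j = crop.jensen
                assert j.a < 0
                vertex = -j.b / (2 * j.a)
                assert 0 < vertex <= 2 * crop.recommended_n
                assert j.c > 0

    def test_lambda_positive_interior_max(self, bundle):
        for crop in bundle.crops:
            lam = crop.jensen.lam
            assert np.all(lam > 0)
            assert 0 < int(np.argmax(lam)) < len(lam) - 1

    def test_prices_positive(self, bundle):
        assert all(c.price > 0 for c in bundle.crops)
        for v in vars(bundle.prices).values():
            if isinstance(v, float):
                assert v >= 0


class TestObservations:
    def test_zero_noise_matches_forward_model(self, bundle, design):
        obs = generate_observations(bundle, design, 0.0, seed=0)
        assert len(obs) == 9 * 3 * 3
        by_key = {(o.treatment_id, o.crop, o.replicate): o for o in obs}
        for spec in design:
            for c, crop in enumerate(bundle.crops):
                truth = forward_treatment(bundle, c, spec)
                for rep in (1, 2, 3):
                    o = by_key[(spec.id, crop.name, rep)]
                    assert o.yield_st == pytest.approx(truth["yield_st"])
                    assert o.biomass == pytest.approx(truth["biomass"])
                    np.testing.assert_allclose(o.eta, truth["eta"])

    def test_seed_reproducibility(self, bundle, design):
        o1 = generate_observations(bundle, design, 0.05, seed=4)
        o2 = generate_observations(bundle, design, 0.05, seed=4)
        assert all(a.yield_st == b.yield_st for a, b in zip(o1, o2))

    def test_negative_noise_rejected(self, bundle, design):
        with pytest.raises(ValueError):
            generate_observations(bundle, design, -0.1, seed=0)

    def test_all_nonnegative(self, bundle, design):
        for o in generate_observations(bundle, design, 0.3, seed=8):
            assert o.yield_st >= 0 and o.biomass >= 0
            assert 0 <= o.quality <= 1


class TestRecovery:
    def test_n_response_exact_at_zero_noise(self, bundle, design):
        obs = generate_observations(bundle, design, 0.0, seed=0)
        for c, crop in enumerate(bundle.crops):
            a, b, c0 = fit_n_response(obs, bundle, design, c)
            assert a == pytest.approx(crop.jensen.a, rel=1e-6)
            assert b == pytest.approx(crop.jensen.b, rel=1e-6)
            assert c0 == pytest.approx(crop.jensen.c, rel=1e-6)

    def test_n_response_error_shrinks_with_noise(self, bundle, design):
        errs = []
        for cv in (0.08, 0.02, 0.0):
            obs = generate_observations(bundle, design, cv, seed=10)
            a, b, c0 = fit_n_response(obs, bundle, design, 1)
            true = bundle.crops[1].jensen
            errs.append(abs(a - true.a) / abs(true.a)
                        + abs(b - true.b) / abs(true.b))
        assert errs[2] < 1e-9
        assert errs[2] <= errs[1] <= errs[0] * 1.5  # noisy fits drift, trend holds

    def test_amendment_exact_on_grid(self, bundle):
        cfg = StudyConfig(seed=42)
        grid = generate_amendment_design(cfg)
        crop_idx = 1
        crop = bundle.crops[crop_idx]
        xs, ys, alphas = [], [], []
        for spec in grid:
            truth = forward_treatment(bundle, crop_idx, spec)
            xs.append(spec.biochar_rate[crop_idx])
            ys.append(spec.straw_rate[crop_idx])
            alphas.append(truth["yield_st1"] / truth["yield_st"] - 1.0)
        fit = fit_amendment(xs, ys, alphas)
        true = crop.amend_yield
        np.testing.assert_allclose(fit.as_array(), true.as_array(), atol=1e-8)

    def test_amendment_fit_predicts_alpha(self, bundle):
        cfg = StudyConfig(seed=42)
        grid = generate_amendment_design(cfg)
        crop = bundle.crops[0]
        xs = [s.biochar_rate[0] for s in grid]
        ys = [s.straw_rate[0] for s in grid]
        alphas = [amendment_factor(crop.amend_yield, x, y) for x, y in zip(xs, ys)]
        fit = fit_amendment(xs, ys, alphas)
        for x, y, a in zip(xs, ys, alphas):
            assert amendment_factor(fit, x, y) == pytest.approx(a, abs=1e-9)


class TestFrames:
    def test_design_frame(self, design):
        df = synthetic.design_to_frame(design)
        assert len(df) == 9
        assert "treatment" in df.columns

    def test_observation_frame(self, bundle, design):
        obs = generate_observations(bundle, design, 0.0, seed=0)
        df = synthetic.observations_to_frame(obs)
        assert len(df) == len(obs)
        assert "eta_mm_stage1" in df.columns


def test_config_validation():
    with pytest.raises(ValueError):
        StudyConfig(seed=0, n_crops=0)
    with pytest.raises(ValueError):
        StudyConfig(seed=0, noise_cv=-0.1)
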