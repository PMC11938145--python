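import numpy as np
import pytest

from agrocycle.hydro import HydroScenario
from agrocycle.optimize import (ConstraintBounds, DecisionVector,
                                MembershipSpec, brute_force_oracle,
                                build_constraints, evaluate_objectives,
                                membership, scalarize_maxmin, soil_water_bounds,
                                solve, solve_single_objective)
from agrocycle.params import (CropParams, EmissionFactors, EnergyParams,
                              GrayWaterParams, JensenParams, ParameterBundle,
                              PriceSet, QualityCoeffs, SequestrationParams,
                              SoilParams, StrawAllocation, StrawYieldParams,
                              UsageSet)

from conftest import make_toy

EQUAL_ALLOC = StrawAllocation(0.25, 0.25, 0.25, 0.25)


def manual_bundle():
    """One-crop, two-stage instance simple enough to audit by hand."""
    crop = CropParams(
        name="toy", price=0.004, greenhouse=False,
        recommended_n=240.0, full_irrigation=200.0,
        etm=np.array([100.0, 100.0]),
        jensen=JensenParams(lam=[0.3, 0.4], a=-0.1, b=48.0, c=2000.0),
        quality=QualityCoeffs(fc=0.5),
        straw=StrawYieldParams(omega=1.0, xi=1.0, psi=1.0),
        energy=EnergyParams(hv=3.6, zeta_the=1.0, zeta_com=1.0, rho_com=0.5,
                            rho_gas=0.5, eta_gas=0.2, eta_pyr=0.1, eta_gas_ele=0.0),
        usage=UsageSet(d_see=0, d_fer=0, d_pes=0, d_fue=0, d_fil=0, d_lab=0,
                       d_ele_lig=0, h_lig=0, d_ele_irr=0, d_ele_rol=0, tau_rol=0),
        emission=EmissionFactors(sigma_see=0, sigma_fer=0, sigma_pes=0,
                                 sigma_fue=0, sigma_fil=0, sigma_lab=0,
                                 omicron=1.0, nu=0.0, nu_fer=0.0),
        seq=SequestrationParams(cc=0.0, cq_biochar=0.0, cq_straw=0.0),
        exp_rain=np.zeros(2),
    )
    prices = PriceSet(straw=0.0002, biochar=0.001, ele_sal=0.0005,
                      ele_pur=0.001, wat=0.0005, fer=0.004)
    return ParameterBundle(crops=[crop], prices=prices,
                           gray=GrayWaterParams(nu_lrnf=0.1, c_max=0.01, c_n=0.0))


def manual_hydro():
    return HydroScenario(label="normal", annual_mm=0.0,
                         rain_st=[np.zeros(2)], rain_st1=[np.zeros(2)])


class TestSoilWaterBounds:
    def test_w_min(self):
        soil = SoilParams(bulk_density=1.2, z_r=40.0, theta_rwp=0.1272,
                          theta_fc=0.3054)
        w_min, _ = soil_water_bounds(soil)
        assert w_min == pytest.approx(61.056)

    def test_w_max(self):
        soil = SoilParams(bulk_density=1.2, z_r=40.0, theta_rwp=0.1272,
                          theta_fc=0.3054)
        _, w_max = soil_water_bounds(soil)
        assert w_max == pytest.approx(146.592)

    def test_ordering(self):
        w_min, w_max = soil_water_bounds(SoilParams())
        assert w_min < w_max


class TestMembership:
    spec_max = MembershipSpec("max", best=100.0, worst=0.0)
    spec_min = MembershipSpec("min", best=1.0, worst=5.0)

    def test_endpoints(self):
        assert membership(100.0, self.spec_max) == 1.0
        assert membership(0.0, self.spec_max) == 0.0
        assert membership(1.0, self.spec_min) == 1.0
        assert membership(5.0, self.spec_min) == 0.0

    def test_midpoint(self):
        assert membership(50.0, self.spec_max) == pytest.approx(0.5)
        assert membership(3.0, self.spec_min) == pytest.approx(0.5)

    def test_clipping(self):
        assert membership(150.0, self.spec_max) == 1.0
        assert membership(-10.0, self.spec_max) == 0.0

    def test_equal_anchors_rejected(self):
        with pytest.raises(ValueError):
            MembershipSpec("max", best=1.0, worst=1.0)

    def test_scalarize(self):
        assert scalarize_maxmin([0.7, 0.4, 0.9, 0.6]) == pytest.approx(0.4)
        assert scalarize_maxmin([1.0, 1.0, 1.0, 1.0]) == 1.0
        assert scalarize_maxmin([0.9, 0.4, 0.7, 0.6]) == \
            scalarize_maxmin([0.4, 0.9, 0.6, 0.7])


class TestDecisionVector:
    def test_round_trip(self):
        d = DecisionVector(i_st=[[40.0, 50.0]], i_st1=[[45.0, 55.0]],
                           n_st=[200.0], n_st1=[180.0], allocation=EQUAL_ALLOC)
        x = d.to_array()
        d2 = DecisionVector.from_array(x, 1, 2, allocation=EQUAL_ALLOC)
        np.testing.assert_allclose(d2.i_st, d.i_st)
        np.testing.assert_allclose(d2.n_st1, d.n_st1)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            DecisionVector(i_st=[[-1.0]], i_st1=[[0.0]], n_st=[0.0],
                           n_st1=[0.0], allocation=EQUAL_ALLOC)


class TestConstraints:
    def test_allocation_sum_residual_free_mode(self):
        b = manual_bundle()
        bounds = ConstraintBounds(w_min=[5.0], w_max=[150.0],
                                  n_min=[50.0], n_max=[400.0])
        cons, (lo, hi) = build_constraints(b, bounds, None, manual_hydro(),
                                           free_allocation=True)
        alloc_c = next(c for c in cons if c["name"] == "allocation_sum")
        x = np.concatenate([np.full(4, 50.0), [200.0, 200.0],
                            [0.3, 0.3, 0.3, 0.3]])
        assert alloc_c["fun"](x) == pytest.approx(-0.2)

    def test_boundary_irrigation_feasible(self):
        b = manual_bundle()
        bounds = ConstraintBounds(w_min=[5.0], w_max=[150.0],
                                  n_min=[50.0], n_max=[400.0])
        cons, (lo, hi) = build_constraints(b, bounds, EQUAL_ALLOC, manual_hydro())
        x = hi.copy()  # irrigation at W_max everywhere
        for c in cons:
            if c["type"] == "ineq":
                assert c["fun"](x) >= -1e-9

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValueError):
            ConstraintBounds(w_min=[100.0], w_max=[50.0], n_min=[0.0], n_max=[1.0])


class TestEvaluateObjectives:
    def test_matches_hand_spreadsheet(self):
        b = manual_bundle()
        d = DecisionVector(i_st=[[50.0, 50.0]], i_st1=[[50.0, 50.0]],
                           n_st=[200.0], n_st1=[200.0], allocation=EQUAL_ALLOC)
        obj = evaluate_objectives(d, b, manual_hydro())

        # independent arithmetic, not via the package ops
        ym = -0.1 * 200 ** 2 + 48 * 200 + 2000          # 7600
        y0 = ym * 0.5 ** 0.3 * 0.5 ** 0.4               # deficit both stages
        q0 = y0
        y1 = y0                                          # no amendment effect
        revenue = (0.004 * y0 + 0.004 * y1               # crops
                   + 0.0002 * 0.25 * q0                  # straw sold, stage 1
                   + 0.0002 * q0                         # all straw sold, stage 2
                   + 0.0005 * (0.125 * q0 + 0.125 * q0))  # electricity
        mat0 = 0.004 * 200                               # fertilizer only
        mat1 = mat0 + 0.001 * 0.075 * q0 + 0.0002 * 0.25 * q0
        water = 0.0005 * 10 * 100                        # per stage
        cost = mat0 + mat1 + 2 * water
        assert obj.neb == pytest.approx(revenue - cost, rel=1e-12)
        assert obj.tcq == pytest.approx(0.5)
        blue = 10 * 200 / (y0 + y1)
        gray = 0.1 * 400 / ((y0 + y1) * 0.01)
        assert obj.wf == pytest.approx(blue + gray, rel=1e-12)
        assert obj.cf == pytest.approx(2 * 28.0 / (y0 + y1), rel=1e-12)

    def test_output_price_monotonicity(self):
        b = manual_bundle()
        d = DecisionVector(i_st=[[50.0, 50.0]], i_st1=[[50.0, 50.0]],
                           n_st=[200.0], n_st1=[200.0], allocation=EQUAL_ALLOC)
        neb1 = evaluate_objectives(d, b, manual_hydro()).neb
        b.crops[0].price *= 2
        neb2 = evaluate_objectives(d, b, manual_hydro()).neb
        assert neb2 > neb1


class TestSolver:
    def test_single_objective_matches_analytic_vertex(self):
        # fertilizer price/emissions decoupled from N so the NEB optimum in N
        # is the production-quadratic vertex at 240 kg/ha
        b = manual_bundle()
        b.prices.fer = 0.0
        bounds = ConstraintBounds(w_min=[5.0], w_max=[100.0],
                                  n_min=[100.0], n_max=[400.0])
        dec, value = solve_single_objective(b, bounds, EQUAL_ALLOC,
                                            manual_hydro(), "neb", seed=0,
                                            n_starts=4)
        assert dec.n_st[0] == pytest.approx(240.0, abs=0.5)
        assert dec.n_st1[0] == pytest.approx(240.0, abs=0.5)
        # NEB strictly increases with water here, so irrigation caps out
        np.testing.assert_allclose(dec.i_st[0], [100.0, 100.0], atol=0.5)

    def test_solve_beats_oracle_on_toys(self):
        for seed in (1, 2):
            b, bounds, hydro = make_toy(seed)
            res = solve(b, bounds, EQUAL_ALLOC, hydro, seed=seed, n_starts=2)
            dec, lam_grid = brute_force_oracle(b, bounds, EQUAL_ALLOC, hydro,
                                               res.payoff, grid_resolution=4)
            assert res.lam >= lam_grid - 1e-6

    def test_deterministic_given_seed(self):
        b, bounds, hydro = make_toy(5)
        r1 = solve(b, bounds, EQUAL_ALLOC, hydro, seed=3, n_starts=2)
        r2 = solve(b, bounds, EQUAL_ALLOC, hydro, seed=3, n_starts=2)
        assert r1.lam == pytest.approx(r2.lam, abs=1e-12)
        np.testing.assert_allclose(r1.decision.to_array(), r2.decision.to_array())

    def test_memberships_in_unit_interval(self):
        b, bounds, hydro = make_toy(6)
        res = solve(b, bounds, EQUAL_ALLOC, hydro, seed=1, n_starts=2)
        for mu in res.memberships.values():
            assert 0.0 <= mu <= 1.0
        assert res.lam == pytest.approx(min(res.memberships.values()), abs=1e-9)

    def test_bounds_respected(self):
        b, bounds, hydro = make_toy(8)
        res = solve(b, bounds, EQUAL_ALLOC, hydro, seed=2, n_starts=2)
        d = res.decision
        assert np.all(d.i_st >= bounds.w_min[0] - 1e-6)
        assert np.all(d.i_st <= bounds.w_max[0] + 1e-6)
        assert np.all(d.n_st >= bounds.n_min - 1e-6)
        assert np.all(d.n_st <= bounds.n_max + 1e-6)

    def test_relaxing_n_max_does_not_hurt(self):
        b, bounds, hydro = make_toy(9)
        res1 = solve(b, bounds, EQUAL_ALLOC, hydro, seed=1, n_starts=2)
        relaxed = ConstraintBounds(w_min=bounds.w_min, w_max=bounds.w_max,
                                   n_min=bounds.n_min, n_max=bounds.n_max * 1.2)
        res2 = solve(b, relaxed, EQUAL_ALLOC, hydro, seed=1, n_starts=2,
                     membership_specs=res1.payoff,
                     warm_starts=[res1.decision.to_array()])
        assert res2.lam >= res1.lam - 1e-6

    def test_oracle_grid_guard(self):
        b, bounds, hydro = make_toy(1)
        spec = {k: MembershipSpec("max", 1.0, 0.0) for k in ("neb", "tcq")}
        spec.update({k: MembershipSpec("min", 0.0, 1.0) for k in ("wf", "cf")})
        with pytest.raises(ValueError, match="guard"):
            brute_force_oracle(b, bounds, EQUAL_ALLOC, hydro, spec,
                               grid_resolution=50)
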