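"""Objective assembly, constraint system and the fuzzy max-min solver.

The decision is per-crop, per-growth-stage irrigation and per-crop nitrogen
for both system stages (plus, optionally, the four straw-allocation
weights).  The four objectives (NEB, TCQ, WF, CF) are composed from the
production, straw, economics, quality and footprint modules, scalarized by
linear fuzzy memberships anchored to a payoff table of single-objective
optima, and solved max-min (maximize the smallest membership) with a
multistart SLSQP.  A brute-force grid oracle backs the solver in tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import economics, footprints, production, quality, straw
from .hydro import HydroScenario
from .params import ParameterBundle, SoilParams, StrawAllocation

__all__ = [
    "DecisionVector",
    "ConstraintBounds",
    "MembershipSpec",
    "ObjectiveVector",
    "SolveResult",
    "soil_water_bounds",
    "build_constraints",
    "evaluate_objectives",
    "membership",
    "scalarize_maxmin",
    "solve",
    "solve_single_objective",
    "brute_force_oracle",
]

OBJECTIVE_NAMES = ("neb", "tcq", "wf", "cf")
OBJECTIVE_SENSES = {"neb": "max", "tcq": "max", "wf": "min", "cf": "min"}


@dataclass
class DecisionVector:
    """Water-nitrogen-straw decision for both system stages.

    ``i_st``/``i_st1`` are (n_crops, n_stages) irrigation arrays in mm;
    ``n_st``/``n_st1`` per-crop nitrogen in kg/ha; ``allocation`` the straw
    split.
    """

    i_st: np.ndarray
    i_st1: np.ndarray
    n_st: np.ndarray
    n_st1: np.ndarray
    allocation: StrawAllocation

    def __post_init__(self):
        self.i_st = np.atleast_2d(np.asarray(self.i_st, dtype=float))
        self.i_st1 = np.atleast_2d(np.asarray(self.i_st1, dtype=float))
        self.n_st = np.atleast_1d(np.asarray(self.n_st, dtype=float))
        self.n_st1 = np.atleast_1d(np.asarray(self.n_st1, dtype=float))
        for arr in (self.i_st, self.i_st1, self.n_st, self.n_st1):
            if np.any(arr < -1e-12):
                raise ValueError("decision variables must be non-negative")

    @property
    def n_crops(self) -> int:
        return self.i_st.shape[0]

    @property
    def n_stages(self) -> int:
        return self.i_st.shape[1]

    def to_array(self, free_allocation: bool = False) -> np.ndarray:
        parts = [self.i_st.ravel(), self.i_st1.ravel(), self.n_st, self.n_st1]
        if free_allocation:
            parts.append(self.allocation.as_array())
        return np.concatenate(parts)

    @classmethod
    def from_array(cls, x, n_crops: int, n_stages: int,
                   allocation: StrawAllocation | None = None,
                   free_allocation: bool = False) -> "DecisionVector":
        x = np.asarray(x, dtype=float)
        k = n_crops * n_stages
        i_st = x[:k].reshape(n_crops, n_stages)
        i_st1 = x[k:2 * k].reshape(n_crops, n_stages)
        n_st = x[2 * k:2 * k + n_crops]
        n_st1 = x[2 * k + n_crops:2 * k + 2 * n_crops]
        if free_allocation:
            pr = np.clip(x[2 * k + 2 * n_crops: 2 * k + 2 * n_crops + 4], 0.0, 1.0)
            total = pr.sum()
            pr = pr / total if total > 0 else np.full(4, 0.25)
            alloc = StrawAllocation(*pr)
        else:
            if allocation is None:
                raise ValueError("allocation required when not free")
            alloc = allocation
        return cls(i_st=i_st, i_st1=i_st1, n_st=n_st, n_st1=n_st1, allocation=alloc)


@dataclass
class ConstraintBounds:
    """Box bounds and supply limits for the constraint system."""

    w_min: np.ndarray  # per crop, mm per stage
    w_max: np.ndarray
    n_min: np.ndarray  # per crop, kg/ha
    n_max: np.ndarray
    ap_st: float = 1e6
    ap_st1: float = 1e6
    tae_st: float = 1e7
    tae_st1: float = 1e7
    supply_fraction: float = 1.0

    def __post_init__(self):
        self.w_min = np.atleast_1d(np.asarray(self.w_min, dtype=float))
        self.w_max = np.atleast_1d(np.asarray(self.w_max, dtype=float))
        self.n_min = np.atleast_1d(np.asarray(self.n_min, dtype=float))
        self.n_max = np.atleast_1d(np.asarray(self.n_max, dtype=float))
        if np.any(self.w_min >= self.w_max):
            raise ValueError("need W_min < W_max for every crop")
        if np.any(self.n_min > self.n_max):
            raise ValueError("need N_min <= N_max for every crop")
        if not 0 < self.supply_fraction <= 1:
            raise ValueError("supply fraction must be in (0, 1]")


@dataclass
class MembershipSpec:
    """Linear membership anchors for one objective."""

    sense: str   # "max" or "min"
    best: float
    worst: float

    def __post_init__(self):
        if self.sense not in ("max", "min"):
            raise ValueError("sense must be 'max' or 'min'")
        if self.best == self.worst:
            raise ValueError("membership anchors must differ")


@dataclass
class ObjectiveVector:
    neb: float   # 10^3 yuan/ha
    tcq: float   # unitless in [0, 1]
    wf: float    # m3/kg
    cf: float    # kg CO2e/kg

    def as_dict(self) -> dict:
        return {"neb": self.neb, "tcq": self.tcq, "wf": self.wf, "cf": self.cf}


@dataclass
class SolveResult:
    decision: DecisionVector
    objectives: ObjectiveVector
    lam: float
    memberships: dict
    payoff: dict
    residuals: dict = field(default_factory=dict)


def soil_water_bounds(soil: SoilParams) -> tuple:
    """Per-stage irrigation bounds (mm) from soil water limits.

    ``W_min = 10 * rho_soil * z_r * theta_RWP`` and
    ``W_max = 10 * rho_soil * z_r * theta_FC``.
    """
    soil.validate()
    w_min = 10.0 * soil.bulk_density * soil.z_r * soil.theta_rwp
    w_max = 10.0 * soil.bulk_density * soil.z_r * soil.theta_fc
    return float(w_min), float(w_max)


# ---------------------------------------------------------------------------
# Objective composition
# ---------------------------------------------------------------------------


def evaluate_objectives(decision: DecisionVector, bundle: ParameterBundle,
                        hydro: HydroScenario, details: bool = False):
    """Compose the full two-stage system model into (NEB, TCQ, WF, CF).

    Evaluation is unconditional: infeasible decisions still evaluate unless
    they break a mathematical precondition (e.g. zero total yield), which
    raises.  Amendment quadratics operate on t/ha amounts.
    """
    bundle = bundle if _is_crisp(bundle) else bundle.crisp()
    alloc = decision.allocation
    pr = alloc

    total_rev = 0.0
    total_cost = 0.0
    cq0, cq1 = [], []
    wf_sum = 0.0
    cf_sum = 0.0
    per_crop = []

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c, crop in enumerate(bundle.crops):
            i0 = decision.i_st[c]
            i1 = decision.i_st1[c]
            n0 = float(decision.n_st[c])
            n1 = float(decision.n_st1[c])
            p0 = np.asarray(hydro.rain_st[c], dtype=float)
            p1 = np.asarray(hydro.rain_st1[c], dtype=float)
            if crop.greenhouse:
                p0 = np.zeros_like(p0)
                p1 = np.zeros_like(p1)

            # --- initial-stage production
            eta0 = np.minimum(p0 + i0, crop.etm)
            ym0 = production.nitrogen_potential_yield(crop.jensen, n0)
            y0 = production.jensen_yield(ym0, eta0, crop.etm, crop.jensen.lam)
            q0 = production.biomass_production(crop.area_st, y0, crop.straw.omega,
                                               crop.straw.xi, crop.straw.psi)

            # --- straw allocation & conversion
            y_straw = straw.straw_returned(pr.pr_straw, q0)
            q_com = straw.electricity_combustion(crop.energy, pr.pr_ele, q0)
            q_gas = straw.electricity_gasification(crop.energy, pr.pr_ele, q0)
            y_biochar = straw.biochar_output(crop.energy, pr.pr_biochar, q0, q_gas)

            # amendment amounts in t/ha of recycle-stage land
            xb = y_biochar / 1000.0 / crop.area_st1
            xs = y_straw / 1000.0 / crop.area_st1
            a_yield = production.amendment_factor(crop.amend_yield, xb, xs)
            a_tcq = production.amendment_factor(crop.amend_tcq, xb, xs)
            a_co2 = production.amendment_factor(crop.amend_co2, xb, xs)
            a_ch4 = production.amendment_factor(crop.amend_ch4, xb, xs)
            a_n2o = production.amendment_factor(crop.amend_n2o, xb, xs)

            # --- recycling-stage production (water/N response amended)
            eta1 = np.minimum(p1 + i1, crop.etm)
            ym1 = production.nitrogen_potential_yield(crop.jensen, n1)
            y1_base = production.jensen_yield(ym1, eta1, crop.etm, crop.jensen.lam)
            y1 = production.recycled_stage_value(y1_base, a_yield)
            q1 = production.biomass_production(crop.area_st1, y1, crop.straw.omega,
                                               crop.straw.xi, crop.straw.psi)

            # --- revenue
            s_st, s_st1 = straw.straw_sale_revenue(bundle.prices.straw, pr.pr_sell, q0, q1)
            e_rev = straw.electricity_revenue(bundle.prices.ele_sal, q_com, q_gas)
            total_rev += (crop.price * crop.area_st * y0
                          + crop.price * crop.area_st1 * y1
                          + s_st + s_st1 + e_rev)

            # --- costs (per-ha, area applied once)
            u0 = _with_fertilizer(crop.usage, n0)
            u1 = _with_fertilizer(crop.usage, n1)
            mat0 = economics.material_cost(u0, bundle.prices, "initial")
            mat1 = economics.material_cost(u1, bundle.prices, "recycle",
                                           biochar_amt=y_biochar / crop.area_st1,
                                           straw_amt=y_straw / crop.area_st1)
            ele0 = economics.electricity_cost(u0, bundle.prices, float(i0.sum()))
            ele1 = economics.electricity_cost(u1, bundle.prices, float(i1.sum()))
            wat0 = economics.water_cost(bundle.prices.wat, float(i0.sum()))
            wat1 = economics.water_cost(bundle.prices.wat, float(i1.sum()))
            total_cost += (crop.area_st * (mat0 + ele0 + wat0)
                           + crop.area_st1 * (mat1 + ele1 + wat1))

            # --- quality
            c0 = quality.crop_quality(crop.quality, n0, float(i0.sum()))
            c1 = quality.recycled_quality(
                quality.crop_quality(crop.quality, n1, float(i1.sum())),
                crop.amend_tcq, xb, xs)
            cq0.append(c0)
            cq1.append(c1)

            # --- carbon footprint (per-ha inventory)
            co2_0 = footprints.co2_emissions(u0, crop.emission, 1.0)
            ch4_0 = footprints.ch4_emissions(1.0, crop.emission.omicron)
            n2o_0 = footprints.n2o_emissions(1.0, crop.emission.nu, n0, crop.emission.nu_fer)
            co2_1 = footprints.co2_emissions(u1, crop.emission, 1.0, "recycle", a_co2)
            ch4_1 = footprints.ch4_emissions(1.0, crop.emission.omicron, "recycle", a_ch4)
            n2o_1 = footprints.n2o_emissions(1.0, crop.emission.nu, n1,
                                             crop.emission.nu_fer, "recycle", a_n2o)
            f_tce = footprints.total_ghg(co2_0, ch4_0, n2o_0, co2_1, ch4_1, n2o_1,
                                         crop.emission.gwp_ch4, crop.emission.gwp_n2o)
            f_cs = footprints.carbon_sequestration(
                y0, y1, crop.seq,
                biochar_kg=y_biochar / crop.area_st1,
                straw_kg=y_straw / crop.area_st1)
            cf_c = footprints.carbon_footprint(f_tce, f_cs, y0, y1)
            cf_sum += cf_c

            # --- water footprint
            y_total = y0 + y1
            g = footprints.green_wf(float(p0.sum() + p1.sum()), y_total)
            b = footprints.blue_wf(float(i0.sum() + i1.sum()), y_total)
            gr = footprints.gray_wf(bundle.gray, n0, n1, y_total)
            wf_c = footprints.water_footprint(g, b, gr)
            wf_sum += wf_c

            per_crop.append({
                "crop": crop.name, "yield_st": y0, "yield_st1": y1,
                "biomass_st": q0, "biomass_st1": q1,
                "straw_returned": y_straw, "biochar": y_biochar,
                "ele_com": q_com, "ele_gas": q_gas,
                "cq_st": c0, "cq_st1": c1,
                "f_tce": f_tce, "f_cs": f_cs, "cf": cf_c,
                "green_wf": g, "blue_wf": b, "gray_wf": gr, "wf": wf_c,
            })

        tcq = quality.total_comprehensive_quality(bundle.crop_weights_st, cq0, cq1,
                                                  bundle.crop_weights_st1)

    area_total = sum(cr.area_st for cr in bundle.crops)
    neb = economics.net_economic_benefit(total_rev, total_cost) / area_total
    obj = ObjectiveVector(neb=neb, tcq=tcq, wf=wf_sum, cf=cf_sum)
    if details:
        return obj, {"per_crop": per_crop, "revenue": total_rev, "cost": total_cost}
    return obj


def _with_fertilizer(usage, n_applied):
    """Copy of a UsageSet with the fertilizer amount set to the N decision."""
    import copy
    u = copy.copy(usage)
    u.d_fer = n_applied
    return u


def _is_crisp(bundle) -> bool:
    # cheap check: bundles straight from the generator are always crisp;
    # fuzzy bundles must be .crisp()-ed by the caller or here.
    from .hydro import TIFN
    for crop in bundle.crops:
        for v in vars(crop).values():
            if isinstance(v, TIFN):
                return False
    return not any(isinstance(v, TIFN) for v in vars(bundle.prices).values())


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------


def build_constraints(bundle: ParameterBundle, bounds: ConstraintBounds,
                      allocation: StrawAllocation | None,
                      hydro: HydroScenario, free_allocation: bool = False):
    """Named residual callables over the packed decision array.

    Inequality residuals are feasible when >= 0; the allocation-sum residual
    is an equality.  Box bounds (irrigation, nitrogen, non-negativity) are
    returned separately as (lo, hi) arrays.
    """
    n_c, n_t = bundle.n_crops, bundle.n_stages

    def unpack(x):
        return DecisionVector.from_array(x, n_c, n_t, allocation=allocation,
                                         free_allocation=free_allocation)

    def ele_st_residual(x):
        d = unpack(x)
        demand = sum(
            crop.area_st * economics.electricity_demand_kwh(
                _with_fertilizer(crop.usage, d.n_st[c]), float(d.i_st[c].sum()))
            for c, crop in enumerate(bundle.crops))
        return bounds.ap_st - demand

    def ele_st1_residual(x):
        d = unpack(x)
        demand, gen = 0.0, 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for c, crop in enumerate(bundle.crops):
                demand += crop.area_st1 * economics.electricity_demand_kwh(
                    _with_fertilizer(crop.usage, d.n_st1[c]), float(d.i_st1[c].sum()))
                p0 = np.zeros(n_t) if crop.greenhouse else np.asarray(hydro.rain_st[c])
                eta0 = np.minimum(p0 + d.i_st[c], crop.etm)
                ym0 = production.nitrogen_potential_yield(crop.jensen, float(d.n_st[c]))
                y0 = production.jensen_yield(ym0, eta0, crop.etm, crop.jensen.lam)
                q0 = production.biomass_production(crop.area_st, y0, crop.straw.omega,
                                                   crop.straw.xi, crop.straw.psi)
                gen += straw.electricity_combustion(crop.energy, d.allocation.pr_ele, q0)
                gen += straw.electricity_gasification(crop.energy, d.allocation.pr_ele, q0)
        return bounds.ap_st1 + gen - demand

    def allocation_residual(x):
        if free_allocation:
            # raw weights from the tail of the packed array (pre-normalization)
            return 1.0 - float(np.sum(np.asarray(x)[-4:]))
        d = unpack(x)
        return 1.0 - float(d.allocation.as_array().sum())

    constraints = [
        {"name": "electricity_st", "type": "ineq", "fun": ele_st_residual},
        {"name": "electricity_st1", "type": "ineq", "fun": ele_st1_residual},
        {"name": "supply_cap_st", "type": "ineq",
         "fun": lambda x: bounds.supply_fraction * bounds.tae_st - bounds.ap_st},
        {"name": "supply_cap_st1", "type": "ineq",
         "fun": lambda x: bounds.supply_fraction * bounds.tae_st1 - bounds.ap_st1},
        {"name": "allocation_sum", "type": "eq", "fun": allocation_residual},
    ]

    # box bounds over the packed array
    lo = np.concatenate([np.repeat(bounds.w_min, n_t), np.repeat(bounds.w_min, n_t),
                         bounds.n_min, bounds.n_min])
    hi = np.concatenate([np.repeat(bounds.w_max, n_t), np.repeat(bounds.w_max, n_t),
                         bounds.n_max, bounds.n_max])
    if free_allocation:
        lo = np.concatenate([lo, np.zeros(4)])
        hi = np.concatenate([hi, np.ones(4)])
    return constraints, (lo, hi)


# ---------------------------------------------------------------------------
# Fuzzy scalarization
# ---------------------------------------------------------------------------


def membership(value: float, spec: MembershipSpec) -> float:
    """Linear membership in [0, 1]; 1 at the best anchor, 0 at the worst."""
    if spec.sense == "max":
        mu = (value - spec.worst) / (spec.best - spec.worst)
    else:
        mu = (spec.worst - value) / (spec.worst - spec.best)
    return float(min(max(mu, 0.0), 1.0))


def scalarize_maxmin(memberships) -> float:
    """Max-min (Zimmermann) scalarization: the smallest membership."""
    mus = np.asarray(list(memberships), dtype=float)
    if np.any((mus < -1e-12) | (mus > 1 + 1e-12)):
        raise ValueError("memberships must lie in [0, 1]")
    return float(mus.min())


def _objective_value(obj: ObjectiveVector, name: str) -> float:
    return getattr(obj, name)


def _lambda_of(x, unpack, bundle, hydro, specs) -> float:
    try:
        obj = evaluate_objectives(unpack(x), bundle, hydro)
    except (ValueError, FloatingPointError):
        return -np.inf
    return scalarize_maxmin(membership(_objective_value(obj, k), specs[k])
                            for k in OBJECTIVE_NAMES)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------


def solve_single_objective(bundle: ParameterBundle, bounds: ConstraintBounds,
                           allocation: StrawAllocation, hydro: HydroScenario,
                           objective: str, seed: int = 0, n_starts: int = 4):
    """Optimize one objective alone; returns ``(DecisionVector, value)``.

    This is the payoff-table building block of :func:`solve`, exposed for
    validation against analytic optima.
    """
    if objective not in OBJECTIVE_NAMES:
        raise ValueError(f"unknown objective {objective!r}")
    bundle = bundle.crisp()
    rng = np.random.default_rng(seed)
    n_c, n_t = bundle.n_crops, bundle.n_stages
    constraints, (lo, hi) = build_constraints(bundle, bounds, allocation, hydro, False)
    scipy_cons = [{"type": c["type"], "fun": c["fun"]} for c in constraints
                  if c["name"] != "allocation_sum"]
    sign = -1.0 if OBJECTIVE_SENSES[objective] == "max" else 1.0

    def unpack(x):
        return DecisionVector.from_array(x, n_c, n_t, allocation=allocation)

    def fun(x):
        try:
            v = _objective_value(evaluate_objectives(unpack(x), bundle, hydro), objective)
        except (ValueError, FloatingPointError):
            return 1e12
        return sign * v

    best_x, best_v = None, np.inf
    for x0 in _starting_points(lo, hi, n_starts, rng, False, allocation):
        res = minimize(fun, x0, method="SLSQP", bounds=list(zip(lo, hi)),
                       constraints=scipy_cons,
                       options={"maxiter": 150, "ftol": 1e-10})
        if res.fun < best_v and _feasible(res.x, scipy_cons):
            best_x, best_v = np.clip(res.x, lo, hi), res.fun
    if best_x is None:
        raise RuntimeError(f"no feasible point found for objective {objective}")
    return unpack(best_x), sign * best_v


def solve(bundle: ParameterBundle, bounds: ConstraintBounds,
          allocation: StrawAllocation, hydro: HydroScenario,
          seed: int = 0, n_starts: int = 8, free_allocation: bool = False,
          membership_specs: dict | None = None,
          warm_starts: list | None = None) -> SolveResult:
    """Two-phase fuzzy multi-objective solve.

    Phase 1 solves each single objective to build the payoff table that
    anchors the linear memberships; phase 2 maximizes the minimum
    membership.  Multistart SLSQP throughout; deterministic for a given
    seed.
    """
    bundle = bundle.crisp()
    rng = np.random.default_rng(seed)
    n_c, n_t = bundle.n_crops, bundle.n_stages
    constraints, (lo, hi) = build_constraints(bundle, bounds, allocation, hydro,
                                              free_allocation)
    scipy_cons = [{"type": c["type"], "fun": c["fun"]} for c in constraints
                  if free_allocation or c["name"] != "allocation_sum"]

    def unpack(x):
        return DecisionVector.from_array(x, n_c, n_t, allocation=allocation,
                                         free_allocation=free_allocation)

    def eval_obj(x, name):
        try:
            return _objective_value(evaluate_objectives(unpack(x), bundle, hydro), name)
        except (ValueError, FloatingPointError):
            return np.nan

    starts = _starting_points(lo, hi, n_starts, rng, free_allocation, allocation)
    if warm_starts:
        starts = [np.clip(np.asarray(w, dtype=float), lo, hi)
                  for w in warm_starts] + starts
    box = list(zip(lo, hi))

    # ---- phase 1: payoff table
    single_solutions = {}
    for name in OBJECTIVE_NAMES:
        sign = -1.0 if OBJECTIVE_SENSES[name] == "max" else 1.0

        def fun(x, _s=sign, _n=name):
            v = eval_obj(x, _n)
            return _s * v if np.isfinite(v) else 1e12

        best_x, best_v = None, np.inf
        for x0 in starts:
            res = minimize(fun, x0, method="SLSQP", bounds=box,
                           constraints=scipy_cons,
                           options={"maxiter": 100, "ftol": 1e-8})
            if res.fun < best_v and _feasible(res.x, scipy_cons):
                best_x, best_v = res.x, res.fun
        if best_x is None:
            raise RuntimeError(f"no feasible point found for objective {name}")
        single_solutions[name] = np.clip(best_x, lo, hi)

    if membership_specs is None:
        membership_specs = payoff_membership_specs(single_solutions, unpack, bundle, hydro)

    # ---- phase 2: max-min over the memberships
    def neg_lambda(x):
        lam = _lambda_of(x, unpack, bundle, hydro, membership_specs)
        return -lam if np.isfinite(lam) else 1e12

    phase2_starts = list(single_solutions.values()) + starts[:max(2, n_starts // 2)]
    best_x, best_lam = None, -np.inf
    for x0 in phase2_starts:
        res = minimize(neg_lambda, x0, method="SLSQP", bounds=box,
                       constraints=scipy_cons,
                       options={"maxiter": 150, "ftol": 1e-8})
        cand = np.clip(res.x, lo, hi)
        lam = _lambda_of(cand, unpack, bundle, hydro, membership_specs)
        if lam > best_lam and _feasible(cand, scipy_cons):
            best_x, best_lam = cand, lam
    if best_x is None:
        raise RuntimeError("no feasible decision found")

    decision = unpack(best_x)
    obj = evaluate_objectives(decision, bundle, hydro)
    mus = {k: membership(_objective_value(obj, k), membership_specs[k])
           for k in OBJECTIVE_NAMES}
    residuals = {c["name"]: float(c["fun"](best_x)) for c in constraints}
    return SolveResult(decision=decision, objectives=obj, lam=best_lam,
                       memberships=mus,
                       payoff={k: membership_specs[k] for k in OBJECTIVE_NAMES},
                       residuals=residuals)


def payoff_membership_specs(single_solutions, unpack, bundle, hydro) -> dict:
    """Membership anchors from the payoff table of single-objective optima."""
    table = {}
    for name, x in single_solutions.items():
        table[name] = evaluate_objectives(unpack(x), bundle, hydro)
    specs = {}
    for name in OBJECTIVE_NAMES:
        vals = [_objective_value(table[k], name) for k in OBJECTIVE_NAMES]
        own = _objective_value(table[name], name)
        if OBJECTIVE_SENSES[name] == "max":
            best, worst = own, min(vals)
        else:
            best, worst = own, max(vals)
        if abs(best - worst) < 1e-12:
            worst = best - 1e-6 if OBJECTIVE_SENSES[name] == "max" else best + 1e-6
        specs[name] = MembershipSpec(sense=OBJECTIVE_SENSES[name], best=best, worst=worst)
    return specs


def _starting_points(lo, hi, n_starts, rng, free_allocation, allocation):
    mid = 0.5 * (lo + hi)
    pts = [mid]
    for _ in range(max(n_starts - 1, 0)):
        pts.append(lo + rng.random(len(lo)) * (hi - lo))
    if free_allocation:
        for p in pts:
            p[-4:] = allocation.as_array() if allocation is not None else 0.25
    return pts


def _feasible(x, scipy_cons, tol: float = 1e-6) -> bool:
    for c in scipy_cons:
        v = c["fun"](x)
        if c["type"] == "ineq" and v < -tol:
            return False
        if c["type"] == "eq" and abs(v) > tol:
            return False
    return True


def brute_force_oracle(bundle: ParameterBundle, bounds: ConstraintBounds,
                       allocation: StrawAllocation, hydro: HydroScenario,
                       membership_specs: dict, grid_resolution: int = 4,
                       max_points: int = 200_000):
    """Exhaustive grid search over the decision box; returns the best grid
    decision and its max-min membership.

    Guarded against combinatorial blow-up; meant for small (toy) instances
    only.  Infeasible grids return ``(None, -inf)``.
    """
    bundle = bundle.crisp()
    n_c, n_t = bundle.n_crops, bundle.n_stages
    constraints, (lo, hi) = build_constraints(bundle, bounds, allocation, hydro, False)
    scipy_cons = [{"type": c["type"], "fun": c["fun"]} for c in constraints
                  if c["name"] != "allocation_sum"]
    dims = len(lo)
    if grid_resolution ** dims > max_points:
        raise ValueError(f"grid of {grid_resolution}^{dims} points exceeds the "
                         f"{max_points} guard")
    axes = [np.linspace(lo[i], hi[i], grid_resolution) for i in range(dims)]

    def unpack(x):
        return DecisionVector.from_array(x, n_c, n_t, allocation=allocation)

    best_x, best_lam = None, -np.inf
    for point in itertools.product(*axes):
        x = np.asarray(point)
        if not _feasible(x, scipy_cons):
            continue
        lam = _lambda_of(x, unpack, bundle, hydro, membership_specs)
        if lam > best_lam:
            best_x, best_lam = x, lam
    if best_x is None:
        return None, -np.inf
    return unpack(best_x), best_lam
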