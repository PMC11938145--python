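"""Synthetic study instances.

Generates parameter bundles, the 9-treatment factorial trial design, noisy
"measured" observations from the forward model, and annual precipitation
records, so every downstream stage is testable without external data.
Also houses the inverse helpers that refit generating coefficients from
observations (used for validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import production, quality as quality_mod, footprints
from .hydro import generate_precip_record  # noqa: F401  (re-exported)
from .params import (AmendmentCoeffs, CropParams, EmissionFactors, EnergyParams,
                     GrayWaterParams, JensenParams, ParameterBundle, PriceSet,
                     QualityCoeffs, SequestrationParams, SoilParams,
                     StrawYieldParams, UsageSet)

__all__ = [
    "StudyConfig",
    "TreatmentSpec",
    "TreatmentObservation",
    "generate_design",
    "generate_amendment_design",
    "generate_parameters",
    "generate_observations",
    "generate_precip_record",
    "forward_treatment",
    "fit_n_response",
    "fit_amendment",
    "design_to_frame",
    "observations_to_frame",
]

# Trial-design factor levels: irrigation and nitrogen multipliers, and the
# additive pairing of each treatment id (biochar level, straw level).
IRRIGATION_LEVELS = {"I1": 1.0, "I2": 0.75, "I3": 0.5}
NITROGEN_LEVELS = {"N1": 1.5, "N2": 1.0, "N3": 0.5}
TREATMENT_LAYOUT = {
    "T1": ("I1", "N1", "B3S3"),
    "T2": ("I1", "N2", "B1S1"),
    "T3": ("I1", "N3", "B2S2"),
    "T4": ("I2", "N1", "B2S2"),
    "T5": ("I2", "N2", "B3S3"),
    "T6": ("I2", "N3", "B1S1"),
    "T7": ("I3", "N1", "B1S1"),
    "T8": ("I3", "N2", "B2S2"),
    "T9": ("I3", "N3", "B3S3"),
}
# Per-crop additive rates (t/ha), tomato-corn-soybean ordering; the three
# additive levels trade biochar against straw along a fixed total.
ADDITIVE_RATES = {
    "B1S1": {"biochar": (30.0, 60.0, 40.0), "straw": (0.0, 0.0, 0.0)},
    "B2S2": {"biochar": (15.0, 30.0, 20.0), "straw": (15.0, 30.0, 20.0)},
    "B3S3": {"biochar": (0.0, 0.0, 0.0), "straw": (30.0, 60.0, 40.0)},
}

# Stage-wise water sensitivity exponents at system start (5 stages).
DEFAULT_LAMBDAS = {
    "tomato": (0.086, 0.314, 0.532, 0.208, 0.163),
    "corn": (0.101, 0.225, 0.447, 0.621, 0.307),
    "soybean": (0.018, 0.685, 0.812, 0.416, 0.124),
}
DEFAULT_CROP_NAMES = ("tomato", "corn", "soybean")
DEFAULT_CROP_PRICES = (0.004, 0.0022, 0.005)  # 10^3 yuan/kg


@dataclass
class StudyConfig:
    """Knobs for one synthetic study instance."""

    seed: int = 0
    n_crops: int = 3
    n_stages: int = 5
    n_replicates: int = 3
    noise_cv: float = 0.05
    recommended_n: tuple = (200.0, 240.0, 120.0)   # kg/ha per crop
    full_irrigation: tuple = (240.0, 180.0, 150.0)  # mm per crop
    precip_mean: float = 553.2
    precip_cv: float = 0.25
    precip_cs: float = 0.5
    season_fraction: float = 0.6

    def __post_init__(self):
        if self.n_crops < 1 or self.n_stages < 1:
            raise ValueError("need at least one crop and one stage")
        if self.noise_cv < 0:
            raise ValueError("noise CV cannot be negative")
        if any(n <= 0 for n in self.recommended_n[: self.n_crops]):
            raise ValueError("recommended N must be positive")


@dataclass(frozen=True)
class TreatmentSpec:
    """One factorial treatment: irrigation x nitrogen x additive levels."""

    id: str
    irrigation_level: str
    nitrogen_level: str
    additive_level: str
    irrigation_factor: float
    nitrogen_factor: float
    biochar_rate: tuple  # per crop, t/ha
    straw_rate: tuple    # per crop, t/ha


@dataclass
class TreatmentObservation:
    """Simulated 'measured' outcome for one treatment x replicate x crop."""

    treatment_id: str
    replicate: int
    crop: str
    yield_st: float       # kg/ha
    yield_st1: float      # kg/ha
    quality: float        # [0, 1]
    quality_st1: float
    biomass: float        # kg
    co2: float            # kg/ha
    ch4: float
    n2o: float
    eta: np.ndarray       # per-stage actual ET, mm


def _additive_rates(level: str, n_crops: int) -> tuple:
    rates = ADDITIVE_RATES[level]
    bio = rates["biochar"]
    strw = rates["straw"]
    if n_crops <= 3:
        return tuple(bio[:n_crops]), tuple(strw[:n_crops])
    # extend cyclically past the canonical three crops
    bio = tuple(bio[i % 3] for i in range(n_crops))
    strw = tuple(strw[i % 3] for i in range(n_crops))
    return bio, strw


def generate_design(config: StudyConfig) -> list:
    """The nine-treatment factorial with the canonical (I, N, additive) pairing."""
    design = []
    for tid, (ilev, nlev, alev) in TREATMENT_LAYOUT.items():
        bio, strw = _additive_rates(alev, config.n_crops)
        design.append(TreatmentSpec(
            id=tid, irrigation_level=ilev, nitrogen_level=nlev, additive_level=alev,
            irrigation_factor=IRRIGATION_LEVELS[ilev],
            nitrogen_factor=NITROGEN_LEVELS[nlev],
            biochar_rate=bio, straw_rate=strw))
    return design


def generate_amendment_design(config: StudyConfig) -> list:
    """3x3 biochar-straw grid at fixed (I2, N2), for amendment-surface fitting.

    The factorial trial only visits three additive points per crop, which
    cannot identify a six-coefficient quadratic; this grid can.
    """
    bio_max, strw_max = _additive_rates("B1S1", config.n_crops)[0], \
        _additive_rates("B3S3", config.n_crops)[1]
    design = []
    k = 0
    for fb in (0.0, 0.5, 1.0):
        for fs in (0.0, 0.5, 1.0):
            k += 1
            design.append(TreatmentSpec(
                id=f"G{k}", irrigation_level="I2", nitrogen_level="N2",
                additive_level="grid",
                irrigation_factor=IRRIGATION_LEVELS["I2"],
                nitrogen_factor=NITROGEN_LEVELS["N2"],
                biochar_rate=tuple(fb * b for b in bio_max),
                straw_rate=tuple(fs * s for s in strw_max)))
    return design


# ---------------------------------------------------------------------------
# Parameter generation
# ---------------------------------------------------------------------------


def generate_parameters(config: StudyConfig) -> ParameterBundle:
    """Deterministic-for-seed parameter bundle with the assumed sign structure.

    Jensen exponents with interior-stage maxima, concave N-response
    quadratics with vertex in (0, 2x recommended N], bounded amendment
    quadratics on the design range, positive prices and factors.
    """
    rng = np.random.default_rng(config.seed)
    crops = []
    for c in range(config.n_crops):
        name = DEFAULT_CROP_NAMES[c] if c < 3 else f"crop{c + 1}"
        rec_n = config.recommended_n[c] if c < len(config.recommended_n) else 180.0
        full_i = config.full_irrigation[c] if c < len(config.full_irrigation) else 200.0
        lam = _lambda_vector(name, config.n_stages, rng)

        # concave N response: vertex inside (0, 2*recN], positive intercept
        vertex = rec_n * rng.uniform(1.0, 1.3)
        peak = rng.uniform(6500.0, 11500.0)
        c0 = peak * rng.uniform(0.35, 0.55)
        a = (c0 - peak) / vertex ** 2
        b = -2.0 * a * vertex
        jensen = JensenParams(lam=lam, a=a, b=b, c=c0)

        # potential ET split over stages, heavier where sensitivity is high
        et_total = rng.uniform(350.0, 500.0)
        frac = (lam + 0.2) * rng.uniform(0.8, 1.2, size=config.n_stages)
        frac = frac / frac.sum()
        etm = et_total * frac

        greenhouse = (c == 0 and config.n_crops >= 2)
        if greenhouse:
            exp_rain = np.zeros(config.n_stages)
        else:
            rain_frac = rng.dirichlet(np.full(config.n_stages, 4.0))
            exp_rain = config.precip_mean * config.season_fraction * rain_frac

        qual = _quality_coeffs(rec_n, full_i, rng)
        bio_max = ADDITIVE_RATES["B1S1"]["biochar"][c % 3]
        strw_max = ADDITIVE_RATES["B3S3"]["straw"][c % 3]
        amend_yield = _concave_amendment(bio_max, strw_max, rng, lo=0.08, hi=0.16)
        amend_tcq = _concave_amendment(bio_max, strw_max, rng, lo=0.05, hi=0.12)
        amend_co2 = _mitigation_amendment(rng)
        amend_ch4 = _mitigation_amendment(rng)
        amend_n2o = _mitigation_amendment(rng)

        price = DEFAULT_CROP_PRICES[c] if c < 3 else 0.003
        crops.append(CropParams(
            name=name, price=price * rng.uniform(0.95, 1.05),
            greenhouse=greenhouse, recommended_n=rec_n, full_irrigation=full_i,
            etm=etm, jensen=jensen, quality=qual,
            amend_yield=amend_yield, amend_tcq=amend_tcq,
            amend_co2=amend_co2, amend_ch4=amend_ch4, amend_n2o=amend_n2o,
            straw=StrawYieldParams(omega=rng.uniform(0.9, 1.5),
                                   xi=rng.uniform(0.75, 0.95),
                                   psi=rng.uniform(0.85, 1.0)),
            energy=EnergyParams(hv=rng.uniform(13.0, 17.0)),
            usage=UsageSet(),
            emission=EmissionFactors(omicron=rng.uniform(1.0, 3.0),
                                     nu=rng.uniform(0.4, 1.2)),
            seq=SequestrationParams(),
            soil=SoilParams(),
            exp_rain=exp_rain,
        ))
    return ParameterBundle(crops=crops, prices=PriceSet(), gray=GrayWaterParams())


def _lambda_vector(name: str, n_stages: int, rng) -> np.ndarray:
    if name in DEFAULT_LAMBDAS and n_stages == 5:
        return np.array(DEFAULT_LAMBDAS[name])
    # random positive exponents peaking at an interior stage
    peak_stage = int(rng.integers(1, max(n_stages - 1, 1))) if n_stages > 2 else 0
    lam = rng.uniform(0.05, 0.25, size=n_stages)
    lam[peak_stage] = rng.uniform(0.45, 0.85)
    return lam


def _quality_coeffs(rec_n: float, full_i: float, rng) -> QualityCoeffs:
    # concave bowl with max near the recommended inputs, range within [0, 1]
    n_opt = rec_n * rng.uniform(0.9, 1.2)
    i_opt = full_i * rng.uniform(0.8, 1.1)
    f_max = rng.uniform(0.65, 0.9)
    pen_n = rng.uniform(0.1, 0.25)
    pen_i = rng.uniform(0.1, 0.25)
    kn = pen_n / n_opt ** 2
    ki = pen_i / i_opt ** 2
    return QualityCoeffs(ac=-kn, bc=-ki, cc=2 * kn * n_opt, dc=2 * ki * i_opt,
                         ec=0.0, fc=f_max - kn * n_opt ** 2 - ki * i_opt ** 2)


def _concave_amendment(bio_max: float, strw_max: float, rng,
                       lo: float, hi: float) -> AmendmentCoeffs:
    # alpha(0,0) = 0; each input contributes a concave hump peaking inside
    # the design range
    ab = rng.uniform(lo, hi)
    asw = rng.uniform(lo * 0.5, hi * 0.5)
    x0 = bio_max * rng.uniform(0.6, 1.0)
    y0 = strw_max * rng.uniform(0.6, 1.0)
    return AmendmentCoeffs(a=-ab / x0 ** 2, b=-asw / y0 ** 2, c=0.0,
                           d=2 * ab / x0, e=2 * asw / y0, f=0.0)


def _mitigation_amendment(rng) -> AmendmentCoeffs:
    # mild linear mitigation of emissions per t/ha of amendment
    return AmendmentCoeffs(d=-rng.uniform(0.002, 0.004), e=-rng.uniform(0.001, 0.003))


# ---------------------------------------------------------------------------
# Forward model and observations
# ---------------------------------------------------------------------------


def stage_irrigation(crop: CropParams, irrigation_factor: float) -> np.ndarray:
    """Split a seasonal irrigation total over stages proportional to ET demand."""
    total = irrigation_factor * crop.full_irrigation
    frac = crop.etm / crop.etm.sum()
    return total * frac


def forward_treatment(bundle: ParameterBundle, crop_idx: int,
                      spec: TreatmentSpec) -> dict:
    """Noise-free forward-model outcome of one treatment for one crop."""
    crop = bundle.crops[crop_idx]
    n_applied = spec.nitrogen_factor * crop.recommended_n
    irr = stage_irrigation(crop, spec.irrigation_factor)
    rain = np.zeros_like(crop.etm) if crop.greenhouse else crop.exp_rain
    eta = np.minimum(rain + irr, crop.etm)
    ym = production.nitrogen_potential_yield(crop.jensen, n_applied)
    y0 = production.jensen_yield(ym, eta, crop.etm, crop.jensen.lam)
    xb = spec.biochar_rate[crop_idx]
    xs = spec.straw_rate[crop_idx]
    a_yield = production.amendment_factor(crop.amend_yield, xb, xs)
    y1 = production.recycled_stage_value(y0, a_yield)
    q0 = production.biomass_production(crop.area_st, y0, crop.straw.omega,
                                       crop.straw.xi, crop.straw.psi)
    cq0 = quality_mod.crop_quality(crop.quality, n_applied, float(irr.sum()))
    cq1 = quality_mod.recycled_quality(cq0, crop.amend_tcq, xb, xs)
    import copy
    u = copy.copy(crop.usage)
    u.d_fer = n_applied
    co2 = footprints.co2_emissions(u, crop.emission, crop.area_st)
    ch4 = footprints.ch4_emissions(crop.area_st, crop.emission.omicron)
    n2o = footprints.n2o_emissions(crop.area_st, crop.emission.nu, n_applied,
                                   crop.emission.nu_fer)
    return {"yield_st": y0, "yield_st1": y1, "quality": cq0, "quality_st1": cq1,
            "biomass": q0, "co2": co2, "ch4": ch4, "n2o": n2o, "eta": eta,
            "n_applied": n_applied, "irrigation": irr}


def generate_observations(bundle: ParameterBundle, design: list,
                          noise_cv: float, seed: int) -> list:
    """Noisy observations: truth x (1 + Gaussian(cv)), truncated at zero.

    ``noise_cv = 0`` reproduces the forward model exactly; replicates share
    treatment-level truth and differ only by noise.
    """
    if noise_cv < 0:
        raise ValueError("noise CV cannot be negative")
    rng = np.random.default_rng(seed)
    n_reps = 3
    obs = []
    for spec in design:
        for c, crop in enumerate(bundle.crops):
            truth = forward_treatment(bundle, c, spec)
            for rep in range(1, n_reps + 1):
                obs.append(TreatmentObservation(
                    treatment_id=spec.id, replicate=rep, crop=crop.name,
                    yield_st=_noisy(truth["yield_st"], noise_cv, rng),
                    yield_st1=_noisy(truth["yield_st1"], noise_cv, rng),
                    quality=min(_noisy(truth["quality"], noise_cv, rng), 1.0),
                    quality_st1=min(_noisy(truth["quality_st1"], noise_cv, rng), 1.0),
                    biomass=_noisy(truth["biomass"], noise_cv, rng),
                    co2=_noisy(truth["co2"], noise_cv, rng),
                    ch4=_noisy(truth["ch4"], noise_cv, rng),
                    n2o=_noisy(truth["n2o"], noise_cv, rng),
                    eta=np.array([_noisy(v, noise_cv, rng) for v in truth["eta"]]),
                ))
    return obs


def _noisy(value: float, cv: float, rng) -> float:
    if cv == 0.0:
        return float(value)
    return float(max(value * (1.0 + cv * rng.standard_normal()), 0.0))


# ---------------------------------------------------------------------------
# Inverse helpers (validation)
# ---------------------------------------------------------------------------


def fit_n_response(observations: list, bundle: ParameterBundle, design: list,
                   crop_idx: int) -> tuple:
    """Refit the N-response quadratic (a, b, c) from observations.

    Divides each observed initial-stage yield by its (known-parameter)
    Jensen water factor computed from the observed stage ET, then solves
    the quadratic least-squares problem in applied N.  Exact at zero noise.
    """
    crop = bundle.crops[crop_idx]
    specs = {s.id: s for s in design}
    rows, ys = [], []
    for o in observations:
        if o.crop != crop.name:
            continue
        spec = specs[o.treatment_id]
        n_applied = spec.nitrogen_factor * crop.recommended_n
        ratios = np.clip(np.asarray(o.eta) / crop.etm, 0.0, 1.0)
        j = float(np.prod(ratios ** crop.jensen.lam))
        if j <= 0:
            continue
        rows.append([n_applied ** 2, n_applied, 1.0])
        ys.append(o.yield_st / j)
    coef, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(ys), rcond=None)
    return tuple(coef)


def fit_amendment(biochar_amts, straw_amts, alphas) -> AmendmentCoeffs:
    """Least-squares fit of the six-coefficient amendment quadratic.

    Needs at least six well-spread (biochar, straw) points; on the 3x3
    grid of :func:`generate_amendment_design` the fit is exact at zero
    noise.
    """
    x = np.asarray(biochar_amts, dtype=float)
    y = np.asarray(straw_amts, dtype=float)
    a = np.asarray(alphas, dtype=float)
    design = np.column_stack([x * x, y * y, x * y, x, y, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, a, rcond=None)
    return AmendmentCoeffs(*coef)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def design_to_frame(design: list) -> pd.DataFrame:
    rows = []
    for s in design:
        rows.append({
            "treatment": s.id, "irrigation_level": s.irrigation_level,
            "nitrogen_level": s.nitrogen_level, "additive_level": s.additive_level,
            "irrigation_factor": s.irrigation_factor,
            "nitrogen_factor": s.nitrogen_factor,
            "biochar_t_ha": ";".join(f"{b:g}" for b in s.biochar_rate),
            "straw_t_ha": ";".join(f"{b:g}" for b in s.straw_rate),
        })
    return pd.DataFrame(rows)


def observations_to_frame(observations: list) -> pd.DataFrame:
    rows = []
    for o in observations:
        row = {
            "treatment": o.treatment_id, "replicate": o.replicate, "crop": o.crop,
            "yield_st_kg_ha": o.yield_st, "yield_st1_kg_ha": o.yield_st1,
            "quality": o.quality, "quality_st1": o.quality_st1,
            "biomass_kg": o.biomass, "co2_kg_ha": o.co2, "ch4_kg_ha": o.ch4,
            "n2o_kg_ha": o.n2o,
        }
        for t, v in enumerate(o.eta):
            row[f"eta_mm_stage{t + 1}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
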