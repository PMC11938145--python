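"""Environmental objectives: carbon footprint and water footprint.

Carbon: a CO2/CH4/N2O inventory over both system stages (GWP 28 for CH4 and
298 for N2O), minus carbon sequestered by crop residue, biochar and
returned straw; expressed per kg of production.  Negative values mean the
system is a net sink.

Water: green (effective rainfall), blue (irrigation) and gray (nitrogen
dilution) components, each in m3 per kg of production.
"""

from __future__ import annotations

import numpy as np

from .params import EmissionFactors, GrayWaterParams, SequestrationParams, UsageSet
from .production import amendment_factor

__all__ = [
    "co2_emissions",
    "ch4_emissions",
    "n2o_emissions",
    "total_ghg",
    "carbon_sequestration",
    "carbon_footprint",
    "green_wf",
    "blue_wf",
    "gray_wf",
    "water_footprint",
]


def co2_emissions(usage: UsageSet, factors: EmissionFactors, area: float,
                  stage: str = "initial", amendment_alpha: float = 0.0) -> float:
    """CO2 (kg) from material and labour inputs.

    The recycling stage scales the initial inventory by ``(1 + alpha)``;
    amendment effects typically make ``alpha`` negative (mitigation).
    """
    if stage not in ("initial", "recycle"):
        raise ValueError("stage must be 'initial' or 'recycle'")
    base = area * (factors.sigma_see * usage.d_see + factors.sigma_fer * usage.d_fer
                   + factors.sigma_pes * usage.d_pes + factors.sigma_fue * usage.d_fue
                   + factors.sigma_fil * usage.d_fil + factors.sigma_lab * usage.d_lab)
    if stage == "recycle":
        base *= (1.0 + amendment_alpha)
    return float(base)


def ch4_emissions(area: float, omicron: float, stage: str = "initial",
                  amendment_alpha: float = 0.0) -> float:
    """CH4 (kg) = area * per-area factor, amended in the recycling stage."""
    if area < 0 or omicron < 0:
        raise ValueError("inputs cannot be negative")
    base = area * omicron
    if stage == "recycle":
        base *= (1.0 + amendment_alpha)
    return float(base)


def n2o_emissions(area: float, nu: float, d_fer: float, nu_fer: float,
                  stage: str = "initial", amendment_alpha: float = 0.0) -> float:
    """N2O (kg) = area * (crop factor + fertilizer * factor), amended in recycle."""
    if min(area, nu, d_fer, nu_fer) < 0:
        raise ValueError("inputs cannot be negative")
    base = area * (nu + d_fer * nu_fer)
    if stage == "recycle":
        base *= (1.0 + amendment_alpha)
    return float(base)


def total_ghg(co2_st: float, ch4_st: float, n2o_st: float,
              co2_st1: float = 0.0, ch4_st1: float = 0.0, n2o_st1: float = 0.0,
              gwp_ch4: float = 28.0, gwp_n2o: float = 298.0) -> float:
    """Total CO2-equivalent emissions over both stages (kg CO2e)."""
    if min(co2_st, ch4_st, n2o_st, co2_st1, ch4_st1, n2o_st1) < 0:
        raise ValueError("emissions cannot be negative")
    return float(co2_st + gwp_ch4 * ch4_st + gwp_n2o * n2o_st
                 + co2_st1 + gwp_ch4 * ch4_st1 + gwp_n2o * n2o_st1)


def carbon_sequestration(yield_st: float, yield_st1: float, seq: SequestrationParams,
                         biochar_kg: float = 0.0, straw_kg: float = 0.0,
                         area_st: float = 1.0, area_st1: float = 1.0) -> float:
    """Carbon sequestered (kg) by crop residue, biochar and returned straw.

    Crop term: ``Y * Cc * A * (1 - W) * (1 + Rrsr) / Hc`` per stage; the
    recycling stage adds ``biochar * Cq_biochar + straw * Cq_straw`` scaled
    by area.
    """
    seq.validate()
    if min(yield_st, yield_st1, biochar_kg, straw_kg) < 0:
        raise ValueError("inputs cannot be negative")
    crop_factor = seq.cc * (1.0 - seq.w) * (1.0 + seq.rrsr) / seq.hc
    f_st = yield_st * crop_factor * area_st
    f_st1 = (yield_st1 * crop_factor + biochar_kg * seq.cq_biochar
             + straw_kg * seq.cq_straw) * area_st1
    return float(f_st + f_st1)


def carbon_footprint(f_tce, f_cs, yield_st, yield_st1) -> float:
    """Per-crop carbon footprint summed over crops (kg CO2e / kg).

    Accepts scalars or per-crop arrays; each crop contributes
    ``(f_TCE - f_CS) / (Y_st + Y_st1)``.  Negative values (net sink) are
    legitimate.
    """
    f_tce = np.atleast_1d(np.asarray(f_tce, dtype=float))
    f_cs = np.atleast_1d(np.asarray(f_cs, dtype=float))
    y0 = np.atleast_1d(np.asarray(yield_st, dtype=float))
    y1 = np.atleast_1d(np.asarray(yield_st1, dtype=float))
    total = y0 + y1
    if np.any(total <= 0):
        raise ValueError("total yield must be positive for every crop")
    return float(np.sum((f_tce - f_cs) / total))


def green_wf(p_mm_both_stages: float, yield_total: float) -> float:
    """Green water footprint: 10 * effective rainfall / yield (m3/kg)."""
    if yield_total <= 0:
        raise ValueError("total yield must be positive")
    if p_mm_both_stages < 0:
        raise ValueError("rainfall cannot be negative")
    return float(10.0 * p_mm_both_stages / yield_total)


def blue_wf(i_mm_both_stages: float, yield_total: float) -> float:
    """Blue water footprint: 10 * irrigation / yield (m3/kg)."""
    if yield_total <= 0:
        raise ValueError("total yield must be positive")
    if i_mm_both_stages < 0:
        raise ValueError("irrigation cannot be negative")
    return float(10.0 * i_mm_both_stages / yield_total)


def gray_wf(gray: GrayWaterParams, n_st: float, n_st1: float, yield_total: float) -> float:
    """Gray water footprint: leached N diluted to the acceptable concentration.

    ``nu_LRNF * (N_st + N_st1) / (Y * (C_max - C_n))`` with concentrations
    in kg/m3 (use :meth:`GrayWaterParams.from_mg_per_l` for mg/L inputs).
    """
    gray.validate()
    if yield_total <= 0:
        raise ValueError("total yield must be positive")
    if n_st < 0 or n_st1 < 0:
        raise ValueError("nitrogen cannot be negative")
    return float(gray.nu_lrnf * (n_st + n_st1) / (yield_total * (gray.c_max - gray.c_n)))


def water_footprint(green: float, blue: float, gray_: float) -> float:
    """Total water footprint = green + blue + gray (m3/kg)."""
    if min(green, blue, gray_) < 0:
        raise ValueError("footprint components cannot be negative")
    return float(green + blue + gray_)
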