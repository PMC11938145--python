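"""Net economic benefit: revenues minus material, electricity and water costs.

All monetary quantities are 10^3 yuan; costs are maintained per hectare and
multiplied by area exactly once, at aggregation.
"""

from __future__ import annotations

import numpy as np

from .params import PriceSet, UsageSet

__all__ = [
    "material_cost",
    "electricity_cost",
    "water_cost",
    "total_revenue",
    "net_economic_benefit",
]

MM_TO_M3_PER_HA = 10.0  # 1 mm depth over 1 ha = 10 m3


def material_cost(usage: UsageSet, prices: PriceSet, stage: str,
                  biochar_amt: float = 0.0, straw_amt: float = 0.0) -> float:
    """Material cost (10^3 yuan/ha) for one crop in one stage.

    Initial stage sums seed, fertilizer, pesticide, fuel, film and labour;
    the recycling stage adds biochar and straw amounts (kg/ha) valued at
    their purchase prices.
    """
    if stage not in ("initial", "recycle"):
        raise ValueError("stage must be 'initial' or 'recycle'")
    base = (prices.see * usage.d_see + prices.fer * usage.d_fer
            + prices.pes * usage.d_pes + prices.fue * usage.d_fue
            + prices.fil * usage.d_fil + prices.lab * usage.d_lab)
    if stage == "recycle":
        base += prices.biochar * biochar_amt + prices.straw * straw_amt
    return float(base)


def electricity_cost(usage: UsageSet, prices: PriceSet, total_irrigation_mm: float,
                     stage: str = "initial") -> float:
    """Electricity cost (10^3 yuan/ha): lighting + irrigation pumping + rollers."""
    if total_irrigation_mm < 0:
        raise ValueError("irrigation cannot be negative")
    v_irr = MM_TO_M3_PER_HA * total_irrigation_mm
    kwh = (usage.d_ele_lig * usage.h_lig
           + usage.d_ele_irr * v_irr
           + usage.d_ele_rol * usage.tau_rol)
    return float(prices.ele_pur * kwh)


def electricity_demand_kwh(usage: UsageSet, total_irrigation_mm: float) -> float:
    """Electricity demand (kWh/ha) behind :func:`electricity_cost`."""
    v_irr = MM_TO_M3_PER_HA * total_irrigation_mm
    return float(usage.d_ele_lig * usage.h_lig + usage.d_ele_irr * v_irr
                 + usage.d_ele_rol * usage.tau_rol)


def water_cost(price_wat: float, total_irrigation_mm: float) -> float:
    """Irrigation water cost (10^3 yuan/ha) at price per m3."""
    if total_irrigation_mm < 0 or price_wat < 0:
        raise ValueError("inputs cannot be negative")
    return float(price_wat * MM_TO_M3_PER_HA * total_irrigation_mm)


def total_revenue(areas, yields_st, yields_st1, crop_prices,
                  straw_rev: float = 0.0, ele_rev: float = 0.0) -> float:
    """System revenue (10^3 yuan): crop sales over both stages plus straw
    and electricity revenues.

    ``areas`` may be a scalar pair-per-crop sequence or (area_st, area_st1)
    tuples; when a flat sequence is given the same area serves both stages.
    """
    areas = np.asarray(areas, dtype=float)
    y0 = np.asarray(yields_st, dtype=float)
    y1 = np.asarray(yields_st1, dtype=float)
    p = np.asarray(crop_prices, dtype=float)
    if not (len(y0) == len(y1) == len(p)):
        raise ValueError("crop vectors must have equal length")
    if areas.ndim == 1:
        a0 = a1 = areas
    else:
        a0, a1 = areas[:, 0], areas[:, 1]
    crop_rev = float(np.sum(p * a0 * y0) + np.sum(p * a1 * y1))
    return crop_rev + float(straw_rev) + float(ele_rev)


def net_economic_benefit(revenue: float, cost: float) -> float:
    """NEB = revenue - cost (10^3 yuan); may be negative."""
    return float(revenue - cost)
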