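"""Crop production stage.

Irrigation quota from soil moisture, field water balance, the Jensen
multiplicative water-production model with a quadratic nitrogen response,
price-equivalent yield, straw biomass, and quadratic amendment effects
that lift (or depress) recycling-stage values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import AmendmentCoeffs, JensenParams, SoilParams

__all__ = [
    "CropStageWater",
    "full_irrigation_quota",
    "actual_et_from_balance",
    "nitrogen_potential_yield",
    "jensen_yield",
    "equivalent_yield",
    "amendment_factor",
    "recycled_stage_value",
    "biomass_production",
]


@dataclass
class CropStageWater:
    """Per-stage water-balance terms, all mm.

    ``dw`` (soil-water storage change) may take either sign; everything
    else is non-negative and potential ET must be positive.
    """

    p: np.ndarray
    i: np.ndarray
    g: np.ndarray = None
    d: np.ndarray = None
    r: np.ndarray = None
    dw: np.ndarray = None
    etm: np.ndarray = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        n = len(self.p)
        for name in ("g", "d", "r", "dw"):
            v = getattr(self, name)
            setattr(self, name, np.zeros(n) if v is None else np.asarray(v, dtype=float))
        if self.etm is not None:
            self.etm = np.asarray(self.etm, dtype=float)
            if np.any(self.etm <= 0):
                raise ValueError("potential ET must be positive in every stage")


def full_irrigation_quota(soil: SoilParams) -> float:
    """Irrigation quota (mm) filling the wetted layer to 90 % of field capacity.

    ``I = 10 * (0.9*theta_fc - theta_v) * z_r * wetting_ratio``.  If the soil
    is already at or above the target the quota is zero (with a warning).
    """
    soil.validate()
    deficit = 0.9 * soil.theta_fc - soil.theta_v
    if deficit <= 0:
        warnings.warn("pre-irrigation water content at/above 90% of field capacity; quota is 0 mm")
        return 0.0
    return 10.0 * deficit * soil.z_r * soil.wetting_ratio


def actual_et_from_balance(stage_water: CropStageWater, t: int) -> float:
    """Actual ET for stage ``t`` by closing the field water balance.

    ``ET_a = P + I + G - D - R - dW``; a negative result signals
    inconsistent balance inputs and raises.
    """
    eta = (stage_water.p[t] + stage_water.i[t] + stage_water.g[t]
           - stage_water.d[t] - stage_water.r[t] - stage_water.dw[t])
    if eta < 0:
        raise ValueError(f"water balance yields negative ET_a={eta:.3f} mm at stage {t}")
    return float(eta)


def nitrogen_potential_yield(jensen: JensenParams, n_applied: float) -> float:
    """Potential (fully watered) yield from the concave N-response quadratic."""
    if n_applied < 0:
        raise ValueError("N application cannot be negative")
    y = jensen.a * n_applied ** 2 + jensen.b * n_applied + jensen.c
    if y < 0:
        warnings.warn(f"N-response quadratic negative at N={n_applied}; flooring yield at 0")
        return 0.0
    return float(y)


def jensen_yield(y_m: float, et_a, et_m, lam) -> float:
    """Jensen water-production yield ``Y = Y_m * prod((ETa/ETm)^lambda)``.

    Ratios are clipped to [0, 1]: over-irrigation beyond potential ET is not
    rewarded.  A zero ratio in any stage with a positive exponent drives the
    yield to zero.
    """
    et_a = np.asarray(et_a, dtype=float)
    et_m = np.asarray(et_m, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if not (len(et_a) == len(et_m) == len(lam)):
        raise ValueError("stage vectors must have equal length")
    if np.any(et_m <= 0):
        raise ValueError("potential ET must be positive")
    if np.any(et_a < 0):
        raise ValueError("actual ET cannot be negative")
    ratios = np.clip(et_a / et_m, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        # 0^0 := 1 (stage with zero sensitivity ignores its ratio)
        factors = np.where((ratios == 0.0) & (lam == 0.0), 1.0, ratios ** lam)
    return float(y_m * np.prod(factors))


def equivalent_yield(yield_kg_ha: float, price_crop: float, price_tomato: float) -> float:
    """Yield rescaled by price relative to the reference crop (tomato)."""
    if price_tomato <= 0:
        raise ValueError("reference (tomato) price must be positive")
    return float(yield_kg_ha * price_crop / price_tomato)


def amendment_factor(coeffs: AmendmentCoeffs, biochar_amt: float, straw_amt: float) -> float:
    """Quadratic amendment response ``a x^2 + b y^2 + c x y + d x + e y + f``."""
    if biochar_amt < 0 or straw_amt < 0:
        raise ValueError("amendment amounts cannot be negative")
    x, y = biochar_amt, straw_amt
    return float(coeffs.a * x * x + coeffs.b * y * y + coeffs.c * x * y
                 + coeffs.d * x + coeffs.e * y + coeffs.f)


def recycled_stage_value(base: float, alpha: float) -> float:
    """Recycling-stage value ``(1 + alpha) * base``; ``alpha <= -1`` is nonphysical."""
    if base < 0:
        raise ValueError("base value cannot be negative")
    if alpha <= -1.0:
        raise ValueError(f"amendment factor {alpha} would drive the value negative")
    return float((1.0 + alpha) * base)


def biomass_production(area_ha: float, yield_kg_ha: float, omega: float,
                       xi: float, psi: float) -> float:
    """Collectable straw biomass (kg) = area * yield * omega * xi * psi."""
    for v in (area_ha, yield_kg_ha, omega, xi, psi):
        if v < 0:
            raise ValueError("biomass factors cannot be negative")
    return float(area_ha * yield_kg_ha * omega * xi * psi)
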