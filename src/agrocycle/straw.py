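"""Straw circular-economy stage.

A single biomass pool per crop is split by four allocation weights into
field return, biochar feedstock, power-generation feedstock, and direct
sale; conversion formulas give electricity (combustion and gasification
routes), biochar mass and the associated revenues.
"""

from __future__ import annotations

import csv
import warnings
from importlib import resources

from .params import EnergyParams, StrawAllocation

__all__ = [
    "straw_returned",
    "electricity_combustion",
    "electricity_gasification",
    "biochar_output",
    "electricity_revenue",
    "straw_sale_revenue",
    "load_scenario_weights",
]

MJ_PER_KWH = 3.6  # conversion inside the electricity formulas


def straw_returned(pr_straw: float, q_biomass: float) -> float:
    """Straw mass (kg) crushed and returned to the field."""
    if not 0.0 <= pr_straw <= 1.0:
        raise ValueError("return fraction must lie in [0, 1]")
    if q_biomass < 0:
        raise ValueError("biomass cannot be negative")
    return float(pr_straw * q_biomass)


def electricity_combustion(params: EnergyParams, pr_ele: float, q_biomass: float) -> float:
    """Electricity (kWh) from direct combustion of the power-generation share.

    ``Hv * zeta_the * rho_com * pr_ele * Q / 3.6`` with Hv in MJ/kg.
    """
    if q_biomass < 0:
        raise ValueError("biomass cannot be negative")
    return float(params.hv * params.zeta_the * params.rho_com * pr_ele * q_biomass / 3.6)


def electricity_gasification(params: EnergyParams, pr_ele: float, q_biomass: float) -> float:
    """Electricity (kWh) from the gasification route (extra mechanical->electrical step)."""
    if q_biomass < 0:
        raise ValueError("biomass cannot be negative")
    return float(params.hv * params.zeta_the * params.zeta_com * params.rho_gas
                 * pr_ele * q_biomass / 3.6)


def biochar_output(params: EnergyParams, pr_biochar: float, q_biomass: float,
                   q_ele_gas: float) -> float:
    """Biochar mass (kg): gasification byproduct (net of the electricity
    offset) plus purpose-made pyrolysis char.

    The gasification term ``eta_gas*pr*Q - eta_gas_ele*Q_ele_gas`` floors at
    zero — a large electricity draw cannot consume char that was never made.
    """
    if q_biomass < 0 or q_ele_gas < 0:
        raise ValueError("inputs cannot be negative")
    gas_term = params.eta_gas * pr_biochar * q_biomass - params.eta_gas_ele * q_ele_gas
    if gas_term < 0:
        warnings.warn("gasification biochar term negative; flooring at 0")
        gas_term = 0.0
    return float(gas_term + params.eta_pyr * pr_biochar * q_biomass)


def electricity_revenue(price_sell: float, q_ele_com: float, q_ele_gas: float) -> float:
    """Revenue (10^3 yuan) from selling generated electricity."""
    if min(price_sell, q_ele_com, q_ele_gas) < 0:
        raise ValueError("inputs cannot be negative")
    return float(price_sell * (q_ele_com + q_ele_gas))


def straw_sale_revenue(price: float, pr_sell: float, q_st: float, q_st1: float):
    """Straw sale revenue (10^3 yuan) for both system stages.

    Initial stage sells the ``pr_sell`` share of collected biomass; in the
    recycling stage all collected straw is sold.  Returns
    ``(initial, recycle)``.
    """
    if min(price, pr_sell, q_st, q_st1) < 0:
        raise ValueError("inputs cannot be negative")
    return float(price * pr_sell * q_st), float(price * q_st1)


def load_scenario_weights() -> dict:
    """Packaged straw-allocation weighting scenarios, name -> StrawAllocation."""
    out = {}
    with resources.files("agrocycle.data").joinpath("scenarios.csv").open() as fh:
        for row in csv.DictReader(fh):
            out[row["scenario"]] = StrawAllocation(
                pr_straw=float(row["pr_straw"]),
                pr_biochar=float(row["pr_biochar"]),
                pr_ele=float(row["pr_ele"]),
                pr_sell=float(row["pr_sell"]),
            )
    return out
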