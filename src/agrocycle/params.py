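"""Parameter containers for one study instance.

Every biophysical, economic and emission coefficient the pipeline needs is
collected into a :class:`ParameterBundle`.  Fields may hold either crisp
floats or :class:`~agrocycle.hydro.TIFN` fuzzy numbers; :meth:`ParameterBundle.crisp`
defuzzifies everything before the model is evaluated.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, fields, is_dataclass

import numpy as np

from .hydro import TIFN, tifn_defuzzify

__all__ = [
    "SoilParams",
    "JensenParams",
    "AmendmentCoeffs",
    "QualityCoeffs",
    "StrawYieldParams",
    "EnergyParams",
    "PriceSet",
    "UsageSet",
    "EmissionFactors",
    "SequestrationParams",
    "GrayWaterParams",
    "StrawAllocation",
    "CropParams",
    "ParameterBundle",
]


@dataclass
class SoilParams:
    """Soil water properties used for irrigation quotas and bounds.

    Water contents are volumetric fractions (cm3/cm3); ``bulk_density`` in
    g/cm3; ``z_r`` wetted-layer depth in cm.
    """

    theta_fc: float = 0.3054
    theta_rwp: float = 0.1272
    theta_v: float = 0.18
    bulk_density: float = 1.20
    z_r: float = 40.0
    wetting_ratio: float = 0.6

    def validate(self) -> None:
        if not (0.0 < self.theta_rwp < self.theta_fc < 1.0):
            raise ValueError("need 0 < wilting point < field capacity < 1")
        if self.z_r <= 0:
            raise ValueError("wetted-layer depth must be positive")


@dataclass
class JensenParams:
    """Stage-wise water sensitivity exponents plus the N-response quadratic.

    ``lam[t]`` are the Jensen exponents; potential yield is
    ``a*N**2 + b*N + c`` with ``a < 0`` (concave response).
    """

    lam: np.ndarray
    a: float
    b: float
    c: float

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        if np.any(self.lam < 0):
            raise ValueError("Jensen exponents must be non-negative")


@dataclass
class AmendmentCoeffs:
    """Generic quadratic response to biochar (x) and straw (y) amounts.

    ``alpha(x, y) = a x^2 + b y^2 + c x y + d x + e y + f``.  The same form
    serves yield, quality and the three gas-specific amendment effects.
    """

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    e: float = 0.0
    f: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e, self.f], dtype=float)


@dataclass
class QualityCoeffs:
    """Quadratic crop-quality surface in applied N and seasonal irrigation."""

    ac: float = 0.0
    bc: float = 0.0
    cc: float = 0.0
    dc: float = 0.0
    ec: float = 0.0
    fc: float = 0.0


@dataclass
class StrawYieldParams:
    omega: float = 1.2   # grass-to-grain ratio
    xi: float = 0.9      # straw recovery coefficient, <= 1
    psi: float = 1.0     # straw-to-biomass ratio

    def validate(self) -> None:
        if min(self.omega, self.xi, self.psi) <= 0:
            raise ValueError("straw yield parameters must be positive")
        if self.xi > 1:
            raise ValueError("recovery coefficient cannot exceed 1")


@dataclass
class EnergyParams:
    """Straw-to-energy conversion coefficients.

    ``hv`` is the heating value in MJ/kg; the electricity formulas divide
    by 3.6 (MJ per kWh) to deliver kWh.
    """

    hv: float = 15.0          # heating value, MJ/kg
    zeta_the: float = 0.30    # internal-combustion thermal efficiency
    zeta_com: float = 0.85    # mechanical -> electrical conversion
    rho_com: float = 0.5      # share of power-generation straw burned directly
    rho_gas: float = 0.5      # share gasified
    eta_gas: float = 0.25     # gasification biochar coefficient
    eta_pyr: float = 0.30     # pyrolysis biochar coefficient
    eta_gas_ele: float = 1e-4 # biochar offset per kWh gasification electricity

    def validate(self) -> None:
        for name in ("zeta_the", "zeta_com"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.hv <= 0:
            raise ValueError("heating value must be positive")


@dataclass
class PriceSet:
    """Prices, all in 10^3 yuan per unit (kg, kWh, m3 or h)."""

    crop: dict = field(default_factory=dict)  # crop name -> 10^3 yuan/kg
    straw: float = 0.0002
    biochar: float = 0.0015
    ele_sal: float = 0.00045
    ele_pur: float = 0.00055
    wat: float = 0.0004
    see: float = 0.04
    fer: float = 0.004
    pes: float = 0.06
    fue: float = 0.007
    fil: float = 0.012
    lab: float = 0.01


@dataclass
class UsageSet:
    """Per-hectare input usages (kg/ha, h/ha) and electricity intensities."""

    d_see: float = 3.0
    d_fer: float = 0.0      # overridden by the N decision in the composer
    d_pes: float = 6.0
    d_fue: float = 40.0
    d_fil: float = 30.0
    d_lab: float = 120.0
    d_ele_lig: float = 0.4     # lighting draw, kW/h
    h_lig: float = 150.0       # lighting hours, h/ha
    d_ele_irr: float = 0.25    # kWh per m3 pumped
    d_ele_rol: float = 60.0    # roller draw, kW/ha
    tau_rol: float = 0.8       # roller efficiency


@dataclass
class EmissionFactors:
    """GHG inventory coefficients (kg gas per unit input) and GWP factors."""

    sigma_see: float = 1.2
    sigma_fer: float = 8.3    # N fertilizer production + transport
    sigma_pes: float = 19.1
    sigma_fue: float = 3.94
    sigma_fil: float = 22.7
    sigma_lab: float = 0.3    # kg CO2 per labour hour
    omicron: float = 2.0      # CH4 kg/ha
    nu: float = 0.8           # crop N2O kg/ha baseline
    nu_fer: float = 0.0157    # fertilizer N2O kg per kg N
    gwp_ch4: float = 28.0
    gwp_n2o: float = 298.0


@dataclass
class SequestrationParams:
    cc: float = 0.12       # net carbon retention rate per kg yield
    hc: float = 0.45       # economic coefficient (harvest index)
    rrsr: float = 0.12     # root-shoot ratio
    w: float = 0.14        # grain moisture fraction
    cq_biochar: float = 0.65  # kg C fixed per kg biochar
    cq_straw: float = 0.09    # kg C fixed per kg straw returned

    def validate(self) -> None:
        if not 0 < self.hc <= 1:
            raise ValueError("harvest index must be in (0, 1]")
        if not 0 <= self.w < 1:
            raise ValueError("moisture fraction must be in [0, 1)")


@dataclass
class GrayWaterParams:
    """Nitrogen-leaching grey-water parameters; concentrations in kg/m3."""

    nu_lrnf: float = 0.1
    c_max: float = 0.01
    c_n: float = 0.0

    def validate(self) -> None:
        if not self.c_max > self.c_n >= 0:
            raise ValueError("need C_max > C_n >= 0")
        if not 0 <= self.nu_lrnf <= 1:
            raise ValueError("leaching fraction must be in [0, 1]")

    @classmethod
    def from_mg_per_l(cls, nu_lrnf: float, c_max_mg_l: float, c_n_mg_l: float) -> "GrayWaterParams":
        # mg/L -> kg/m3 is a factor of 1e-3
        return cls(nu_lrnf=nu_lrnf, c_max=c_max_mg_l * 1e-3, c_n=c_n_mg_l * 1e-3)


@dataclass(frozen=True)
class StrawAllocation:
    """Fractions of collected biomass sent to each straw pathway."""

    pr_straw: float
    pr_biochar: float
    pr_ele: float
    pr_sell: float

    def __post_init__(self):
        vals = self.as_array()
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("allocation fractions must lie in [0, 1]")
        if abs(float(vals.sum()) - 1.0) > 1e-9:
            raise ValueError(f"allocation fractions must sum to 1, got {vals.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pr_straw, self.pr_biochar, self.pr_ele, self.pr_sell], dtype=float)


@dataclass
class CropParams:
    """Everything specific to one crop in the rotation."""

    name: str
    price: float                       # 10^3 yuan/kg
    area_st: float = 1.0               # ha, initial stage
    area_st1: float = 1.0              # ha, recycling stage
    greenhouse: bool = False
    recommended_n: float = 200.0       # kg/ha
    full_irrigation: float = 240.0     # mm over the season
    etm: np.ndarray = None             # potential ET per stage, mm
    jensen: JensenParams = None
    quality: QualityCoeffs = field(default_factory=QualityCoeffs)
    amend_yield: AmendmentCoeffs = field(default_factory=AmendmentCoeffs)
    amend_tcq: AmendmentCoeffs = field(default_factory=AmendmentCoeffs)
    amend_co2: AmendmentCoeffs = field(default_factory=AmendmentCoeffs)
    amend_ch4: AmendmentCoeffs = field(default_factory=AmendmentCoeffs)
    amend_n2o: AmendmentCoeffs = field(default_factory=AmendmentCoeffs)
    straw: StrawYieldParams = field(default_factory=StrawYieldParams)
    energy: EnergyParams = field(default_factory=EnergyParams)
    usage: UsageSet = field(default_factory=UsageSet)
    emission: EmissionFactors = field(default_factory=EmissionFactors)
    seq: SequestrationParams = field(default_factory=SequestrationParams)
    soil: SoilParams = field(default_factory=SoilParams)
    exp_rain: np.ndarray = None        # per-stage effective rainfall in the trial year, mm

    def __post_init__(self):
        if self.etm is not None:
            self.etm = np.asarray(self.etm, dtype=float)
        if self.exp_rain is not None:
            self.exp_rain = np.asarray(self.exp_rain, dtype=float)

    @property
    def n_stages(self) -> int:
        return len(self.etm)


@dataclass
class ParameterBundle:
    """All coefficients for one study instance (possibly fuzzy-valued)."""

    crops: list
    prices: PriceSet = field(default_factory=PriceSet)
    gray: GrayWaterParams = field(default_factory=GrayWaterParams)
    crop_weights_st: np.ndarray = None    # TCQ crop weights, initial stage
    crop_weights_st1: np.ndarray = None   # TCQ crop weights, recycling stage
    ap_st: float = 1e6                    # available power, kWh
    ap_st1: float = 1e6
    tae_st: float = 1e7                   # total local supply, kWh
    tae_st1: float = 1e7
    supply_fraction: float = 1.0          # AP <= a * TAE

    def __post_init__(self):
        n = len(self.crops)
        if self.crop_weights_st is None:
            self.crop_weights_st = np.full(n, 1.0 / n)
        if self.crop_weights_st1 is None:
            self.crop_weights_st1 = np.asarray(self.crop_weights_st, dtype=float).copy()
        self.crop_weights_st = np.asarray(self.crop_weights_st, dtype=float)
        self.crop_weights_st1 = np.asarray(self.crop_weights_st1, dtype=float)

    @property
    def n_crops(self) -> int:
        return len(self.crops)

    @property
    def n_stages(self) -> int:
        return self.crops[0].n_stages

    def crisp(self) -> "ParameterBundle":
        """Return a copy with every TIFN field defuzzified."""
        return _crisp_obj(self)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return _to_jsonable(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _crisp_obj(obj):
    if isinstance(obj, TIFN):
        return tifn_defuzzify(obj)
    if is_dataclass(obj) and not isinstance(obj, type):
        kwargs = {f.name: _crisp_obj(getattr(obj, f.name)) for f in fields(obj)}
        return type(obj)(**kwargs)
    if isinstance(obj, dict):
        return {k: _crisp_obj(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return type(obj)(_crisp_obj(v) for v in obj)
    return obj


def _to_jsonable(obj):
    if isinstance(obj, TIFN):
        return {"tifn": [obj.l, obj.m, obj.u, obj.w, obj.v]}
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj
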