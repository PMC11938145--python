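"""Parameter and precipitation uncertainty.

Two independent pieces live here:

* triangular intuitionistic fuzzy numbers (:class:`TIFN`) with an
  accuracy-function defuzzification, used to turn fuzzy model parameters
  into crisp ones before optimization;
* Pearson type III frequency analysis of annual precipitation —
  method-of-moments fitting, exceedance quantiles, hydrological-year
  classification (wet / normal / dry) and Monte-Carlo year sampling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TIFN",
    "PearsonIIIParams",
    "HydroThresholds",
    "HydroScenario",
    "tifn_defuzzify",
    "fit_pearson3",
    "quantile_pearson3",
    "cdf_pearson3",
    "sample_pearson3",
    "classify_hydro_year",
    "monte_carlo_years",
    "build_hydro_scenario",
]

HYDRO_CLASSES = ("wet", "normal", "dry")


@dataclass(frozen=True)
class TIFN:
    """Triangular intuitionistic fuzzy number ``<(l, m, u); w, v>``.

    ``l <= m <= u`` is the triangular support, ``w`` the maximum membership
    degree and ``v`` the minimum non-membership degree with ``w + v <= 1``.
    """

    l: float
    m: float
    u: float
    w: float = 1.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if not (self.l <= self.m <= self.u):
            raise ValueError(f"TIFN support must satisfy l <= m <= u, got ({self.l}, {self.m}, {self.u})")
        if not (0.0 <= self.w <= 1.0 and 0.0 <= self.v <= 1.0):
            raise ValueError("membership degrees must lie in [0, 1]")
        if self.w + self.v > 1.0 + 1e-12:
            raise ValueError("w + v must not exceed 1")

    def defuzzify(self) -> float:
        return tifn_defuzzify(self)


def tifn_defuzzify(x: TIFN) -> float:
    """Crisp value of a TIFN via the accuracy function.

    Uses the value-index form ``(l + 2m + u)/4`` scaled by the accuracy
    factor ``(1 + w - v)/2``.  A crisp number, encoded as
    ``(m, m, m; 1, 0)``, maps to ``m`` exactly.
    """
    if not isinstance(x, TIFN):
        return float(x)
    return (x.l + 2.0 * x.m + x.u) / 4.0 * (1.0 + x.w - x.v) / 2.0


def crispen(value):
    """Return ``value`` with any TIFN replaced by its defuzzified float.

    Recurses through lists/tuples/dicts so whole parameter structures can
    be made crisp in one pass.
    """
    if isinstance(value, TIFN):
        return tifn_defuzzify(value)
    if isinstance(value, dict):
        return {k: crispen(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        out = [crispen(v) for v in value]
        return type(value)(out)
    return value


# ---------------------------------------------------------------------------
# Pearson type III precipitation model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PearsonIIIParams:
    """P-III law for annual precipitation, in hydrological (mean, Cv, Cs) form."""

    mean: float
    cv: float
    cs: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.cv <= 0:
            raise ValueError("Cv must be positive")

    @property
    def std(self) -> float:
        return self.mean * self.cv

    def frozen(self):
        """scipy ``pearson3`` distribution with these moments."""
        return stats.pearson3(self.cs, loc=self.mean, scale=self.std)


def fit_pearson3(annual_series) -> PearsonIIIParams:
    """Method-of-moments fit of a P-III law to an annual series (mm).

    Uses the unbiased sample standard deviation and bias-corrected skew,
    the common convention in hydrological frequency analysis.
    """
    x = np.asarray(annual_series, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 years to fit")
    mean = float(np.mean(x))
    std = float(np.std(x, ddof=1))
    if std == 0.0:
        raise ValueError("constant series has no spread to fit")
    cs = float(stats.skew(x, bias=False))
    return PearsonIIIParams(mean=mean, cv=std / mean, cs=cs)


def quantile_pearson3(params: PearsonIIIParams, exceedance_prob: float) -> float:
    """Precipitation with exceedance probability ``p`` (guarantee rate).

    ``Pr(X >= value) = p``; strictly decreasing in ``p``.
    """
    p = float(exceedance_prob)
    if not 0.0 < p < 1.0:
        raise ValueError("exceedance probability must be in (0, 1)")
    return float(params.frozen().ppf(1.0 - p))


def cdf_pearson3(params: PearsonIIIParams, value: float) -> float:
    return float(params.frozen().cdf(value))


def sample_pearson3(params: PearsonIIIParams, n: int, rng) -> np.ndarray:
    """Draw ``n`` strictly positive annual totals; non-positive draws are redrawn.

    For skew/Cv combinations whose support dips below zero the law puts a
    little mass there; redrawing truncates it (documented behaviour).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dist = params.frozen()
    out = np.asarray(dist.rvs(size=n, random_state=rng), dtype=float)
    for _ in range(100):
        bad = out <= 0.0
        if not bad.any():
            break
        out[bad] = dist.rvs(size=int(bad.sum()), random_state=rng)
    else:
        raise RuntimeError("could not draw positive precipitation; parameters imply mostly non-positive support")
    return out


def generate_precip_record(n_years: int, mean: float, cv: float, cs: float, seed: int) -> np.ndarray:
    """Synthetic annual precipitation record (mm) from a P-III law."""
    params = PearsonIIIParams(mean=mean, cv=cv, cs=cs)
    rng = np.random.default_rng(seed)
    return sample_pearson3(params, n_years, rng)


# ---------------------------------------------------------------------------
# Hydrological-year classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HydroThresholds:
    """Precipitation at the 25 % and 75 % exceedance guarantee rates (mm)."""

    p25: float
    p75: float

    def __post_init__(self) -> None:
        if not self.p25 > self.p75:
            raise ValueError("P25 threshold must exceed P75 threshold")

    @classmethod
    def from_params(cls, params: PearsonIIIParams) -> "HydroThresholds":
        return cls(p25=quantile_pearson3(params, 0.25), p75=quantile_pearson3(params, 0.75))


def classify_hydro_year(p_annual: float, thresholds: HydroThresholds) -> str:
    """Label one annual total as ``wet`` / ``normal`` / ``dry``."""
    if p_annual >= thresholds.p25:
        return "wet"
    if p_annual <= thresholds.p75:
        return "dry"
    return "normal"


def monte_carlo_years(params: PearsonIIIParams, n: int, seed: int,
                      thresholds: HydroThresholds | None = None):
    """Monte-Carlo sample of classified hydrological years.

    Returns ``(draws, labels, proportions)`` where proportions is a dict over
    the three classes.  Thresholds default to the 25 %/75 % quantiles of the
    same law, so proportions concentrate near (0.25, 0.50, 0.25).
    """
    rng = np.random.default_rng(seed)
    draws = sample_pearson3(params, n, rng)
    thr = thresholds or HydroThresholds.from_params(params)
    labels = [classify_hydro_year(p, thr) for p in draws]
    counts = Counter(labels)
    proportions = {k: counts.get(k, 0) / n for k in HYDRO_CLASSES}
    return draws, labels, proportions


# ---------------------------------------------------------------------------
# Per-stage rainfall scenarios for the optimizer
# ---------------------------------------------------------------------------


@dataclass
class HydroScenario:
    """Classified precipitation regime with per-crop, per-stage effective rainfall.

    ``rain_st[c]`` / ``rain_st1[c]`` are mm arrays over growth stages for
    crop ``c`` in the initial and recycling stage.  Greenhouse crops carry
    all-zero rainfall.
    """

    label: str
    annual_mm: float
    rain_st: list = field(default_factory=list)
    rain_st1: list = field(default_factory=list)


def build_hydro_scenario(label: str, annual_mm: float, stage_fractions,
                         season_fraction: float = 0.6,
                         greenhouse: list | None = None,
                         n_crops: int | None = None) -> HydroScenario:
    """Distribute an annual total over growth stages for each crop.

    ``stage_fractions`` may be one vector shared by all crops or one per
    crop; fractions are normalized to sum to 1.  ``season_fraction`` is the
    share of annual rainfall falling within the growing season (effective
    rainfall).  Crops flagged greenhouse receive zero rainfall.
    """
    fracs = np.asarray(stage_fractions, dtype=float)
    if fracs.ndim == 1:
        if n_crops is None:
            raise ValueError("n_crops required with a shared fraction vector")
        fracs = np.tile(fracs, (n_crops, 1))
    fracs = fracs / fracs.sum(axis=1, keepdims=True)
    n_crops = fracs.shape[0]
    gh = greenhouse or [False] * n_crops
    rain = []
    for c in range(n_crops):
        if gh[c]:
            rain.append(np.zeros(fracs.shape[1]))
        else:
            rain.append(annual_mm * season_fraction * fracs[c])
    return HydroScenario(label=label, annual_mm=float(annual_mm),
                         rain_st=[r.copy() for r in rain],
                         rain_st1=[r.copy() for r in rain])
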