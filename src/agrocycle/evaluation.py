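"""Model-agreement metrics and coordination-degree analysis.

Agreement between simulated and observed series is scored with R^2,
normalized RMSE (percent of the observed mean) and the Willmott
consistency index.  Synergy among the four objective subsystems is scored
with the coupling coordination degree model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "r_squared",
    "nrmse",
    "wci",
    "coordination_degree",
    "coordination_grade",
    "scenario_compare",
]

DEFAULT_GRADE_BANDS = (
    (0.8, "advanced"),
    (0.6, "secondary"),
    (0.4, "basic"),
    (0.2, "marginal"),
    (0.0, "discoordinated"),
)


def _paired(simulated, observed):
    s = np.asarray(simulated, dtype=float)
    o = np.asarray(observed, dtype=float)
    if s.shape != o.shape or s.ndim != 1:
        raise ValueError("simulated and observed must be equal-length 1-D series")
    if s.size < 2:
        raise ValueError("need at least two pairs")
    return s, o


def r_squared(simulated, observed) -> float:
    """Squared Pearson correlation between simulated and observed values."""
    s, o = _paired(simulated, observed)
    sd = s - s.mean()
    od = o - o.mean()
    denom = np.sqrt(np.sum(sd ** 2) * np.sum(od ** 2))
    if denom == 0:
        raise ValueError("zero variance in one of the series")
    return float((np.sum(sd * od) / denom) ** 2)


def nrmse(simulated, observed) -> float:
    """RMSE normalized by the observed mean, in percent."""
    s, o = _paired(simulated, observed)
    om = o.mean()
    if om == 0:
        raise ValueError("observed mean is zero; nRMSE undefined")
    return float(100.0 * np.sqrt(np.mean((s - o) ** 2)) / om)


def wci(simulated, observed) -> float:
    """Willmott consistency index in [0, 1]; 1 means perfect agreement."""
    s, o = _paired(simulated, observed)
    om = o.mean()
    denom = np.sum((np.abs(s - om) + np.abs(o - om)) ** 2)
    if denom == 0:
        raise ValueError("degenerate series; WCI denominator is zero")
    return float(1.0 - np.sum((s - o) ** 2) / denom)


# ---------------------------------------------------------------------------
# Coupling coordination degree
# ---------------------------------------------------------------------------


@dataclass
class CoordinationResult:
    coupling: float     # C
    composite: float    # T
    degree: float       # D = sqrt(C*T)
    grade: str


def coordination_degree(subsystem_scores, weights=None,
                        grade_bands=DEFAULT_GRADE_BANDS) -> CoordinationResult:
    """Coupling coordination of normalized subsystem scores.

    ``C = [prod(u) / (mean(u)^k)]^(1/k)``, ``T = sum(beta*u)``,
    ``D = sqrt(C*T)``.  Scores must lie in [0, 1] with min-type objectives
    already inverted so larger is better.
    """
    u = np.asarray(subsystem_scores, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("subsystem scores must lie in [0, 1]")
    k = u.size
    beta = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, dtype=float)
    if abs(beta.sum() - 1.0) > 1e-9 or np.any(beta < 0):
        raise ValueError("weights must be non-negative and sum to 1")
    mean_u = u.mean()
    if mean_u == 0:
        c = 0.0
    else:
        c = float((np.prod(u) / mean_u ** k) ** (1.0 / k))
    t = float(beta @ u)
    d = float(np.sqrt(c * t))
    return CoordinationResult(coupling=c, composite=t, degree=d,
                              grade=coordination_grade(d, grade_bands))


def coordination_grade(degree: float, grade_bands=DEFAULT_GRADE_BANDS) -> str:
    for threshold, label in grade_bands:
        if degree >= threshold:
            return label
    return grade_bands[-1][1]


def normalize_objectives(values: dict, anchors: dict) -> np.ndarray:
    """Min-max normalize an objective dict to [0, 1] subsystem scores.

    ``anchors[name] = (best, worst)``; min-type objectives are handled by
    their anchors (worst > best), yielding ``u = (worst - x)/(worst - best)``.
    """
    out = []
    for name, x in values.items():
        best, worst = anchors[name]
        if best == worst:
            raise ValueError(f"degenerate anchors for {name}")
        u = (x - worst) / (best - worst)
        out.append(min(max(u, 0.0), 1.0))
    return np.asarray(out)


def scenario_compare(results: dict) -> pd.DataFrame:
    """Rank scenario results by coordination degree.

    ``results`` maps a scenario label to a dict that includes at least
    ``degree`` plus any objective values; returns a frame sorted by degree
    with percent difference against the best scenario.
    """
    if not results:
        raise ValueError("no scenarios to compare")
    rows = []
    for label, vals in results.items():
        row = {"scenario": label}
        row.update(vals)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("degree", ascending=False).reset_index(drop=True)
    best = df.loc[0, "degree"]
    df["pct_vs_best"] = 100.0 * (df["degree"] - best) / best if best != 0 else 0.0
    df["rank"] = np.arange(1, len(df) + 1)
    return df
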