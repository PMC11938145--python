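"""Comprehensive crop quality and the weighting machinery behind it.

The quality objective is a weighted composite of per-crop quadratic quality
surfaces over both system stages.  Indicator and scenario weights come from
AHP (principal eigenvector with Saaty consistency test), entropy weighting,
and a game-theoretic least-squares combination of weight sets.
"""

from __future__ import annotations

import warnings

import numpy as np

from .params import AmendmentCoeffs, QualityCoeffs
from .production import amendment_factor

__all__ = [
    "crop_quality",
    "recycled_quality",
    "total_comprehensive_quality",
    "ahp_weights",
    "entropy_weights",
    "game_combination",
    "saaty_pairwise_from_weights",
]

# Saaty random consistency index, indexed by matrix order (0- and 1-based
# entries are placeholders; 2x2 matrices are always consistent).
SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24,
            7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

_SAATY_SCALE = np.array([1/9, 1/8, 1/7, 1/6, 1/5, 1/4, 1/3, 1/2,
                         1, 2, 3, 4, 5, 6, 7, 8, 9])


def crop_quality(coeffs: QualityCoeffs, n_applied: float, total_irrigation: float,
                 clip: bool = True) -> float:
    """Quality score of one crop from applied N and seasonal irrigation.

    ``Cq = ac N^2 + bc I^2 + cc N + dc I + ec N I + fc``, clipped to [0, 1]
    (scores are normalized composites; a warning is emitted on clipping).
    """
    if n_applied < 0 or total_irrigation < 0:
        raise ValueError("N and irrigation cannot be negative")
    n, i = n_applied, total_irrigation
    cq = (coeffs.ac * n * n + coeffs.bc * i * i + coeffs.cc * n
          + coeffs.dc * i + coeffs.ec * n * i + coeffs.fc)
    if clip and not 0.0 <= cq <= 1.0:
        warnings.warn(f"quality score {cq:.3f} outside [0,1]; clipping")
        cq = min(max(cq, 0.0), 1.0)
    return float(cq)


def recycled_quality(cq_st: float, amend: AmendmentCoeffs,
                     biochar_amt: float, straw_amt: float) -> float:
    """Recycling-stage quality ``(1 + alpha_TCQ) * Cq``, clipped to [0, 1]."""
    if not 0.0 <= cq_st <= 1.0:
        raise ValueError("initial-stage quality must lie in [0, 1]")
    alpha = amendment_factor(amend, biochar_amt, straw_amt)
    if alpha <= -1.0:
        raise ValueError(f"quality amendment factor {alpha} is nonphysical")
    return float(min(max((1.0 + alpha) * cq_st, 0.0), 1.0))


def total_comprehensive_quality(crop_weights_st, cq_st, cq_st1,
                                crop_weights_st1=None) -> float:
    """TCQ = 0.5 * sum(w_st * Cq_st) + 0.5 * sum(w_st1 * Cq_st1)."""
    w0 = np.asarray(crop_weights_st, dtype=float)
    w1 = w0 if crop_weights_st1 is None else np.asarray(crop_weights_st1, dtype=float)
    q0 = np.asarray(cq_st, dtype=float)
    q1 = np.asarray(cq_st1, dtype=float)
    if not (len(w0) == len(q0) and len(w1) == len(q1)):
        raise ValueError("weights and quality vectors must have matching length")
    return float(0.5 * np.sum(w0 * q0) + 0.5 * np.sum(w1 * q1))


def ahp_weights(pairwise_matrix):
    """Principal-eigenvector AHP weights plus the Saaty consistency ratio.

    Returns ``(weights, cr, consistent)``.  The matrix must be square,
    positive and reciprocal; ``CR < 0.1`` flags an acceptable judgement
    matrix.
    """
    m = np.asarray(pairwise_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("pairwise matrix must be square")
    n = m.shape[0]
    if np.any(m <= 0):
        raise ValueError("pairwise matrix must be positive")
    if not np.allclose(m * m.T, np.ones_like(m), rtol=1e-6):
        raise ValueError("pairwise matrix must be reciprocal (m[i,j]*m[j,i] = 1)")
    eigvals, eigvecs = np.linalg.eig(m)
    k = int(np.argmax(eigvals.real))
    lam_max = float(eigvals[k].real)
    w = np.abs(eigvecs[:, k].real)
    w = w / w.sum()
    if n <= 2:
        cr = 0.0
    else:
        ci = (lam_max - n) / (n - 1)
        ri = SAATY_RI.get(n)
        if ri is None:
            raise ValueError(f"no Saaty RI tabulated for order {n}")
        cr = ci / ri
    return w, cr, cr < 0.1


def entropy_weights(indicator_matrix, benefit=None):
    """Objective indicator weights by the entropy method.

    Columns are min-max normalized (cost-type columns flipped first via the
    ``benefit`` boolean mask), column entropies computed, and weights taken
    proportional to ``1 - e_j``.
    """
    x = np.asarray(indicator_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 alternatives (rows)")
    m, k = x.shape
    if benefit is None:
        benefit = [True] * k
    norm = np.empty_like(x)
    for j in range(k):
        col = x[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            raise ValueError(f"indicator column {j} is constant; entropy undefined")
        norm[:, j] = (col - lo) / (hi - lo) if benefit[j] else (hi - col) / (hi - lo)
    # shift away from exact zeros so p*ln(p) is defined
    norm = norm + 1e-12
    p = norm / norm.sum(axis=0, keepdims=True)
    e = -np.sum(p * np.log(p), axis=0) / np.log(m)
    div = 1.0 - e
    if div.sum() <= 0:
        raise ValueError("all indicators carry identical information")
    return div / div.sum()


def game_combination(weight_sets):
    """Game-theoretic combination of weight vectors.

    Solves the least-squares Nash-equilibrium system
    ``sum_l alpha_l (w_k . w_l) = w_k . w_k`` for the combination
    coefficients, normalizes them to sum to 1 and returns the combined
    (re-normalized, non-negative) weight vector.
    """
    ws = [np.asarray(w, dtype=float) for w in weight_sets]
    if len(ws) < 2:
        raise ValueError("need at least two weight vectors")
    k = len(ws[0])
    if any(len(w) != k for w in ws):
        raise ValueError("weight vectors must share a length")
    mat = np.array([[float(wi @ wj) for wj in ws] for wi in ws])
    rhs = np.array([float(wi @ wi) for wi in ws])
    try:
        alpha = np.linalg.solve(mat, rhs)
    except np.linalg.LinAlgError:
        alpha = np.full(len(ws), 1.0 / len(ws))
    if abs(alpha.sum()) < 1e-12:
        alpha = np.full(len(ws), 1.0 / len(ws))
    alpha = alpha / alpha.sum()
    combined = np.sum([a * w for a, w in zip(alpha, ws)], axis=0)
    combined = np.clip(combined, 0.0, None)
    total = combined.sum()
    if total <= 0:
        raise ValueError("combined weights degenerate")
    return combined / total


def saaty_pairwise_from_weights(weights) -> np.ndarray:
    """Reciprocal judgement matrix whose entries are weight ratios rounded
    to the nearest Saaty scale value.

    Used to reconstruct plausible expert matrices for the shipped
    straw-allocation scenarios; rounding introduces a small, positive
    consistency ratio while preserving the priority order.
    """
    w = np.asarray(weights, dtype=float)
    n = len(w)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ratio = w[i] / w[j]
            snapped = _SAATY_SCALE[np.argmin(np.abs(_SAATY_SCALE - ratio))]
            m[i, j] = snapped
            m[j, i] = 1.0 / snapped
    return m
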