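"""Accuracy-maximizing decision boundaries for the drift-diffusion observer.

For a fixed duration distribution, the expected accuracy of an observer with
boundaries (b_l, b_u) and noise c is

    sum_t P(t) * [ P(same|t) if t == S else 1 - P(same|t) ].

When the standard is rare and noise is high, the global optimum degenerates:
any b_u = b_l yields P(same) = 0 everywhere — the always-"different"
strategy, with accuracy 1 - P(standard). The search below detects that
regime and canonicalizes the collapsed solution to b_l = b_u = S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import DDMParams, DurationDesign, p_same_ddm

__all__ = [
    "OptimalBoundaries",
    "expected_accuracy",
    "optimal_boundaries",
    "optimality_curve",
    "collapse_onset",
]

#: A solution is called collapsed when the optimal separation is below this,
#: or when the achieved accuracy is within 1e-6 of the always-"different"
#: accuracy 1 - P(standard).
_COLLAPSE_SEPARATION = 1e-4
_COLLAPSE_ACCURACY_TOL = 1e-6


@dataclass(frozen=True)
class OptimalBoundaries:
    c: float
    b_l: float
    b_u: float
    accuracy: float
    collapsed: bool


def _accuracy_arrays(design: DurationDesign):
    durations = np.asarray(design.durations, dtype=float)
    probs = design.probabilities
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("design probabilities must sum to 1")
    is_standard = np.isclose(durations, design.standard)
    if not is_standard.any():
        raise ValueError("standard duration is not in the design")
    # count-specified designs use exact integer weighting (dot(counts, .)/N),
    # so degenerate cases like the always-"different" strategy come out exact
    if design.counts is not None:
        weights = np.asarray(design.counts, dtype=float)
        total = weights.sum()
    else:
        weights = probs
        total = 1.0
    return durations, weights, total, is_standard


def expected_accuracy(params: DDMParams, design: DurationDesign) -> float:
    """Probability of a correct response for a ddm observer on ``design``."""
    durations, weights, total, is_standard = _accuracy_arrays(design)
    ps = p_same_ddm(params, durations)
    correct = np.where(is_standard, ps, 1.0 - ps)
    return float(np.dot(weights, correct) / total)


def _accuracy_of(b_l: float, b_u: float, c: float, design: DurationDesign) -> float:
    durations, weights, total, is_standard = _accuracy_arrays(design)
    sd = c * np.sqrt(durations)
    from scipy.special import ndtr

    ps = ndtr((b_u - durations) / sd) - ndtr((b_l - durations) / sd)
    correct = np.where(is_standard, ps, 1.0 - ps)
    return float(np.dot(weights, correct) / total)


def optimal_boundaries(
    c: float,
    design: DurationDesign,
    warm_start: Optional[tuple] = None,
) -> OptimalBoundaries:
    """Accuracy-maximizing boundaries for noise level ``c``.

    Nelder-Mead in (log b_l, log separation) space, run from a symmetric
    start around the standard (half-width scaled to the noise level) and,
    when given, a warm start from a neighboring solution; the best result is
    kept. Collapsed optima are reported canonically as b_l = b_u = S with
    the ``collapsed`` flag set.
    """
    if c <= 0:
        raise ValueError("noise level c must be strictly positive")
    S = design.standard
    durations, weights, total, is_standard = _accuracy_arrays(design)
    p_standard = float(weights[is_standard].sum() / total)

    def neg(v):
        if np.any(np.abs(v) > 50):
            return 1.0
        b_l = math.exp(v[0])
        b_u = b_l + math.exp(v[1])
        return -_accuracy_of(b_l, b_u, c, design)

    half = max(c * math.sqrt(S), 0.02)
    b_l0 = max(S - half, 0.25 * S)
    starts = [np.array([math.log(b_l0), math.log(max(S + half - b_l0, 1e-3))])]
    if warm_start is not None:
        b_l_w, b_u_w = warm_start
        if b_u_w - b_l_w > 1e-8 and b_l_w > 0:
            starts.insert(0, np.array([math.log(b_l_w), math.log(b_u_w - b_l_w)]))
    best = None
    for v0 in starts:
        res = minimize(
            neg,
            v0,
            method="Nelder-Mead",
            options=dict(xatol=1e-8, fatol=1e-11, maxiter=4000),
        )
        if best is None or res.fun < best.fun:
            best = res
    b_l = math.exp(best.x[0])
    b_u = b_l + math.exp(best.x[1])
    accuracy = -float(best.fun)
    collapsed_accuracy = 1.0 - p_standard
    collapsed = (b_u - b_l) < _COLLAPSE_SEPARATION or accuracy <= (
        collapsed_accuracy + _COLLAPSE_ACCURACY_TOL
    )
    if collapsed:
        return OptimalBoundaries(
            c=c, b_l=S, b_u=S, accuracy=collapsed_accuracy, collapsed=True
        )
    return OptimalBoundaries(c=c, b_l=b_l, b_u=b_u, accuracy=accuracy, collapsed=False)


def optimality_curve(
    noise_grid: Sequence[float], design: DurationDesign
) -> pd.DataFrame:
    """Optimal boundaries across a grid of noise levels.

    Each grid point is searched from the previous point's solution (warm
    start) plus the symmetric-around-S restart. Returns a DataFrame with
    columns c, b_l, b_u, accuracy, collapsed.
    """
    grid = np.asarray(noise_grid, dtype=float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("noise grid must be strictly positive and increasing")
    rows = []
    warm = None
    for c in grid:
        sol = optimal_boundaries(c, design, warm_start=warm)
        warm = None if sol.collapsed else (sol.b_l, sol.b_u)
        rows.append(
            {
                "c": sol.c,
                "b_l": sol.b_l,
                "b_u": sol.b_u,
                "accuracy": sol.accuracy,
                "collapsed": sol.collapsed,
            }
        )
    return pd.DataFrame(rows)


def collapse_onset(curve: pd.DataFrame) -> Optional[float]:
    """Smallest grid noise level whose optimum is collapsed, or None."""
    collapsed = curve[curve["collapsed"]]
    if collapsed.empty:
        return None
    return float(collapsed["c"].iloc[0])
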