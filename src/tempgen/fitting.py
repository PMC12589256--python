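"""Maximum-likelihood fitting of temporal generalization models.

Trial-level binary responses are Bernoulli draws from a model's psychometric
curve, so the log-likelihood of a parameter set is the sum over trials of
``r*log(p) + (1-r)*log(1-p)`` with ``p = P("same"|t)``. Because the curve is
evaluated only at the design's durations, the likelihood depends on the data
through the per-duration counts of "same"/"different" responses alone; the
optimizer works on that aggregate, which makes fits cheap regardless of trial
count.

Optimization is multi-start Nelder-Mead (8 starting points, all combinations
of two values per parameter) in a log-transformed space that enforces the
parameter constraints smoothly: cg/mcg optimize (log B, log sigma_B, log k)
so all three parameters stay positive, ddm/bsu optimize
(log b_l, log(b_u - b_l), log noise) so the boundary ordering b_u > b_l can
never be violated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .models import (
    MODEL_IDS,
    PARAM_NAMES,
    DurationDesign,
    make_params,
    p_same,
)

__all__ = [
    "TrialData",
    "FitResult",
    "ConstrainedFitResult",
    "log_likelihood",
    "initial_starts",
    "fit_mle",
    "fit_shared",
    "aic",
    "compare_aic",
    "likelihood_ratio_log10",
    "summed_likelihood_ratio_log10",
    "winner_table",
    "PROB_CLAMP",
]

logger = logging.getLogger(__name__)

#: Probabilities are clamped to [PROB_CLAMP, 1 - PROB_CLAMP] inside the
#: likelihood so that a perfectly (mis)predicted trial cannot produce -inf.
PROB_CLAMP = 1e-12

_DEFAULT_OPTIONS = dict(xatol=1e-6, fatol=1e-6, maxiter=2000)


@dataclass(frozen=True)
class TrialData:
    """Trial-level data of one participant in one condition.

    ``durations`` are probe durations in seconds; ``responses`` are binary
    judgments (1 = "same", 0 = "different").
    """

    durations: np.ndarray
    responses: np.ndarray
    participant: str = "p0"
    condition: str = "c0"

    def __post_init__(self):
        durations = np.asarray(self.durations, dtype=float)
        responses = np.asarray(self.responses)
        if durations.ndim != 1 or responses.ndim != 1:
            raise ValueError("durations and responses must be 1-D")
        if len(durations) != len(responses):
            raise ValueError("durations and responses must have equal length")
        if np.any(durations <= 0):
            raise ValueError("all durations must be strictly positive")
        if not np.isin(responses, [0, 1]).all():
            raise ValueError("responses must be binary (0/1)")
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "responses", responses.astype(np.int64))

    def __len__(self) -> int:
        return len(self.durations)

    def aggregate(self):
        """Unique durations with per-duration totals and "same" counts."""
        uniq, inverse = np.unique(self.durations, return_inverse=True)
        n_total = np.bincount(inverse, minlength=len(uniq))
        n_same = np.bincount(inverse, weights=self.responses, minlength=len(uniq))
        return uniq, n_same.astype(np.int64), n_total.astype(np.int64)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one multi-start maximum-likelihood fit."""

    model_id: str
    params: object
    log_lik: float
    n_starts: int
    best_start_index: int
    converged: bool
    n_trials: int
    participant: str = "p0"
    condition: str = "c0"

    def to_dict(self) -> dict:
        params = (
            {name: getattr(self.params, name) for name in PARAM_NAMES[self.model_id]}
            if self.params is not None
            else None
        )
        return {
            "model_id": self.model_id,
            "participant": self.participant,
            "condition": self.condition,
            "params": params,
            "log_lik": self.log_lik,
            "n_starts": self.n_starts,
            "best_start_index": self.best_start_index,
            "converged": self.converged,
            "n_trials": self.n_trials,
        }


@dataclass(frozen=True)
class ConstrainedFitResult:
    """Joint fit across conditions with one parameter shared."""

    model_id: str
    shared_param: str
    params_by_condition: Dict[str, object]
    log_lik: float
    n_free_params: int
    aic: float
    converged: bool
    n_trials: int


def _clamped_probs(model_id, params, t, standard):
    p = np.asarray(p_same(model_id, params, t, standard), dtype=float)
    return np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)


def log_likelihood(model_id, params, trials: TrialData, standard: float) -> float:
    """Bernoulli log-likelihood (nats) of ``params`` on ``trials``.

    Probabilities are clamped to ``[1e-12, 1 - 1e-12]`` before the logs, so a
    deterministic model that predicts every trial correctly scores ~0 rather
    than exactly 0, and one that mispredicts scores a large finite negative
    number rather than -inf.
    """
    if len(trials) == 0:
        raise ValueError("cannot evaluate a likelihood on empty data")
    uniq, n_same, n_total = trials.aggregate()
    p = _clamped_probs(model_id, params, uniq, standard)
    n_diff = n_total - n_same
    return float(np.sum(n_same * np.log(p) + n_diff * np.log1p(-p)))


# ---------------------------------------------------------------------------
# Parameter-space transforms used by the optimizer.
# ---------------------------------------------------------------------------

#: Smallest boundary separation allowed when converting a start with
#: b_u <= b_l into log-separation space.
_MIN_START_SEPARATION = 1e-3


def _to_vector(model_id, params) -> np.ndarray:
    a, b, noise = params.as_tuple()
    if model_id in ("ddm", "bsu"):
        sep = max(b - a, _MIN_START_SEPARATION)
        return np.array([math.log(a), math.log(sep), math.log(noise)])
    return np.array([math.log(a), math.log(b), math.log(noise)])


def _from_vector(model_id, v):
    if model_id in ("ddm", "bsu"):
        b_l = math.exp(v[0])
        b_u = b_l + math.exp(v[1])
        return make_params(model_id, (b_l, b_u, math.exp(v[2])))
    return make_params(model_id, (math.exp(v[0]), math.exp(v[1]), math.exp(v[2])))


def initial_starts(model_id: str, design: DurationDesign) -> list:
    """The 8 starting parameter sets: all combinations of two values each.

    cg/mcg: B in {0.1, 0.5}, k in {0.05, 0.5}, sigma_B in {0.05, 0.5}.
    bsu/ddm: b_l in {1.25*min(durations), mean(durations)}, b_u in
    {0.75*max(durations), mean(durations)}, and noise in {0.1, 0.5} (bsu)
    or {0.05, 0.5} (ddm). The duration mean is the unweighted mean of the
    unique probe durations.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    starts = []
    if model_id in ("cg", "mcg"):
        for B in (0.1, 0.5):
            for k in (0.05, 0.5):
                for sigma_B in (0.05, 0.5):
                    starts.append(make_params(model_id, (B, sigma_B, k)))
        return starts
    durations = np.asarray(design.durations, dtype=float)
    mean_d = float(durations.mean())
    b_l_values = (1.25 * float(durations.min()), mean_d)
    b_u_values = (0.75 * float(durations.max()), mean_d)
    noise_values = (0.05, 0.5) if model_id == "ddm" else (0.1, 0.5)
    for b_l in b_l_values:
        for b_u in b_u_values:
            for noise in noise_values:
                # a start at b_u <= b_l is nudged to a thin positive separation
                b_u_eff = max(b_u, b_l + _MIN_START_SEPARATION)
                starts.append(make_params(model_id, (b_l, b_u_eff, noise)))
    return starts


def _negative_ll_factory(model_id, trials, standard):
    uniq, n_same, n_total = trials.aggregate()
    n_diff = n_total - n_same

    def negll(v):
        if np.any(np.abs(v) > 50):  # guard against overflow in exp
            return 1e12
        params = _from_vector(model_id, v)
        p = _clamped_probs(model_id, params, uniq, standard)
        return -float(np.sum(n_same * np.log(p) + n_diff * np.log1p(-p)))

    return negll


def fit_mle(
    model_id: str,
    trials: TrialData,
    standard: float,
    starts: Optional[Sequence] = None,
    xatol: float = 1e-6,
    fatol: float = 1e-6,
    maxiter: int = 2000,
) -> FitResult:
    """Multi-start Nelder-Mead maximum-likelihood fit.

    Runs one Nelder-Mead search per start (default: the canonical 8-point
    grid) and returns the best. Deterministic given ``(trials, starts)``.
    Ties between starts go to the lowest start index. If no start yields a
    finite likelihood, a non-converged ``FitResult`` with ``params=None`` and
    ``log_lik=-inf`` is returned instead of raising, so batch campaigns can
    record the failure and continue.
    """
    if len(trials) == 0:
        raise ValueError("cannot fit an empty dataset")
    if starts is None:
        uniq = np.unique(trials.durations)
        design = DurationDesign(
            durations=tuple(uniq),
            standard=standard if np.any(np.isclose(uniq, standard)) else uniq[0],
            counts=tuple(1 for _ in uniq),
        )
        starts = initial_starts(model_id, design)
    negll = _negative_ll_factory(model_id, trials, standard)
    best = None
    best_index = -1
    options = dict(xatol=xatol, fatol=fatol, maxiter=maxiter)
    for i, start in enumerate(starts):
        v0 = _to_vector(model_id, start)
        res = minimize(negll, v0, method="Nelder-Mead", options=options)
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
            best_index = i
    if best is None:
        logger.warning(
            "fit failure: no finite likelihood for model %s on %s/%s",
            model_id,
            trials.participant,
            trials.condition,
        )
        return FitResult(
            model_id=model_id,
            params=None,
            log_lik=-np.inf,
            n_starts=len(starts),
            best_start_index=-1,
            converged=False,
            n_trials=len(trials),
            participant=trials.participant,
            condition=trials.condition,
        )
    return FitResult(
        model_id=model_id,
        params=_from_vector(model_id, best.x),
        log_lik=-float(best.fun),
        n_starts=len(starts),
        best_start_index=best_index,
        converged=bool(best.success),
        n_trials=len(trials),
        participant=trials.participant,
        condition=trials.condition,
    )


# ---------------------------------------------------------------------------
# Shared-parameter (constrained) fits across conditions.
# ---------------------------------------------------------------------------


def fit_shared(
    model_id: str,
    trials_by_condition: Mapping[str, TrialData],
    standard: float,
    shared_param: str,
    maxiter: int = 8000,
) -> ConstrainedFitResult:
    """Joint fit with one named parameter forced equal across conditions.

    The joint likelihood is maximized over 1 shared + 2 per-condition free
    parameters in log-natural space (each coordinate is the log of one named
    parameter; a large penalty enforces b_u > b_l for ddm/bsu). The search is
    warm-started from the unconstrained per-condition fits and, as a second
    start, from the first canonical start point.
    """
    names = PARAM_NAMES[model_id]
    if shared_param not in names:
        raise ValueError(f"unknown parameter {shared_param!r} for model {model_id!r}")
    conditions = list(trials_by_condition)
    if len(conditions) < 2:
        raise ValueError("shared-parameter fits need at least 2 conditions")
    shared_idx = names.index(shared_param)
    free_idx = [i for i in range(3) if i != shared_idx]
    aggregates = []
    for cond in conditions:
        uniq, n_same, n_total = trials_by_condition[cond].aggregate()
        aggregates.append((uniq, n_same, n_total - n_same))
    n_trials = sum(len(trials_by_condition[c]) for c in conditions)

    def build_params(theta):
        out = []
        for j in range(len(conditions)):
            vals = [0.0, 0.0, 0.0]
            vals[shared_idx] = math.exp(theta[0])
            vals[free_idx[0]] = math.exp(theta[1 + 2 * j])
            vals[free_idx[1]] = math.exp(theta[2 + 2 * j])
            out.append(vals)
        return out

    def negll(theta):
        if np.any(np.abs(theta) > 50):
            return 1e12
        total = 0.0
        for vals, (uniq, n_same, n_diff) in zip(build_params(theta), aggregates):
            if model_id in ("ddm", "bsu") and vals[1] <= vals[0]:
                return 1e8 * (1.0 + vals[0] - vals[1])
            params = make_params(model_id, vals)
            p = _clamped_probs(model_id, params, uniq, standard)
            total -= float(np.sum(n_same * np.log(p) + n_diff * np.log1p(-p)))
        return total

    # warm start from unconstrained fits
    theta_starts = []
    per_cond = [
        fit_mle(model_id, trials_by_condition[c], standard) for c in conditions
    ]
    if all(f.params is not None for f in per_cond):
        logs = [
            [math.log(getattr(f.params, n)) for n in names] for f in per_cond
        ]
        warm = [float(np.mean([lg[shared_idx] for lg in logs]))]
        for lg in logs:
            warm.extend([lg[free_idx[0]], lg[free_idx[1]]])
        theta_starts.append(np.array(warm))
    uniq0 = aggregates[0][0]
    default_design = DurationDesign(
        durations=tuple(uniq0),
        standard=standard if np.any(np.isclose(uniq0, standard)) else uniq0[0],
        counts=tuple(1 for _ in uniq0),
    )
    start0 = initial_starts(model_id, default_design)[0]
    vals0 = [math.log(v) for v in start0.as_tuple()]
    theta_starts.append(
        np.array([vals0[shared_idx]] + [vals0[i] for i in free_idx] * len(conditions))
    )

    best = None
    for theta0 in theta_starts:
        res = minimize(
            negll,
            theta0,
            method="Nelder-Mead",
            options=dict(xatol=1e-6, fatol=1e-6, maxiter=maxiter),
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("shared-parameter fit failed to find a finite likelihood")
    params_by_condition = {
        cond: make_params(model_id, vals)
        for cond, vals in zip(conditions, build_params(best.x))
    }
    n_free = 3 * len(conditions) - (len(conditions) - 1)
    log_lik = -float(best.fun)
    return ConstrainedFitResult(
        model_id=model_id,
        shared_param=shared_param,
        params_by_condition=params_by_condition,
        log_lik=log_lik,
        n_free_params=n_free,
        aic=aic(log_lik, n_free),
        converged=bool(best.success),
        n_trials=n_trials,
    )


# ---------------------------------------------------------------------------
# Model-comparison bookkeeping.
# ---------------------------------------------------------------------------


def aic(log_lik: float, n_free_params: int) -> float:
    """Akaike information criterion: ``2k - 2*log_lik``."""
    if n_free_params < 1:
        raise ValueError("n_free_params must be >= 1")
    return 2.0 * n_free_params - 2.0 * log_lik


def compare_aic(results: Mapping[str, float]) -> Dict[str, float]:
    """Delta-AIC table: each entry minus the minimum AIC."""
    best = min(results.values())
    return {name: value - best for name, value in results.items()}


def likelihood_ratio_log10(fit_a: FitResult, fit_b: FitResult) -> float:
    """log10 of the likelihood ratio of two fits on identical data."""
    if fit_a.n_trials != fit_b.n_trials:
        raise ValueError("fits compare different numbers of trials")
    return (fit_a.log_lik - fit_b.log_lik) / math.log(10.0)


def summed_likelihood_ratio_log10(fits_a: Sequence[FitResult], fits_b: Sequence[FitResult]) -> float:
    """Sum of per-participant log10 likelihood ratios."""
    if len(fits_a) != len(fits_b):
        raise ValueError("mismatched fit lists")
    return sum(likelihood_ratio_log10(a, b) for a, b in zip(fits_a, fits_b))


def winner_table(fits_by_participant: Mapping[str, Mapping[str, FitResult]]) -> dict:
    """Per-model counts/percentages of participants best fit by each model.

    Every participant must have a fit for all four models; participants whose
    every fit failed are excluded with a warning. Ties between models break
    toward the fixed order ddm, bsu, mcg, cg.
    """
    counts = {m: 0 for m in MODEL_IDS}
    n_scored = 0
    for participant, fits in fits_by_participant.items():
        missing = [m for m in MODEL_IDS if m not in fits]
        if missing:
            raise ValueError(f"participant {participant!r} lacks fits for {missing}")
        ok = {m: fits[m] for m in MODEL_IDS if np.isfinite(fits[m].log_lik)}
        if not ok:
            logger.warning("participant %s excluded: all fits failed", participant)
            continue
        winner = max(ok, key=lambda m: (ok[m].log_lik, -MODEL_IDS.index(m)))
        counts[winner] += 1
        n_scored += 1
    percentages = {
        m: (100.0 * counts[m] / n_scored if n_scored else float("nan"))
        for m in MODEL_IDS
    }
    return {"counts": counts, "percentages": percentages, "n_participants": n_scored}
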