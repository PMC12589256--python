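"""Closed-form psychophysical functions for temporal generalization.

In a temporal generalization task an observer judges, on every trial, whether
a probe interval of duration ``t`` has the *same* duration as a previously
learned standard ``S``. All four models implemented here share the same
architecture: a noisy decision variable is compared against two decision
boundaries, and the probe is called "same" whenever the variable lands between
them. They differ in where the noise enters and how it scales with duration.

* ``ddm`` — drift-diffusion observer. The decision variable at probe offset is
  normal with mean ``t`` and standard deviation ``c * sqrt(t)`` (diffusion
  noise accumulates over the probe); both boundaries sit above the starting
  point and are expressed as boundary-to-drift ratios in seconds.
* ``bsu`` — free asymmetric boundaries with *linear* noise growth: the noisy
  estimate of the probe has standard deviation ``k * t`` (Weber scaling).
* ``cg`` — symmetric boundaries around the standard, with trial-to-trial
  variability in both the remembered standard (Weber fraction ``k``) and the
  boundary itself (``sigma_B``); the decision is made on the normalized
  difference ``(t - s) / s``.
* ``mcg`` — the modified variant of ``cg`` in which the *objective* standard
  replaces the memory sample in the normalizing denominator.

All functions are pure and vectorized over ``t``. Probabilities are returned
unclamped; clamping for log-likelihoods is the fitting module's concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.special import ndtr

__all__ = [
    "DurationDesign",
    "DDMParams",
    "BSUParams",
    "CGParams",
    "MODEL_IDS",
    "PARAM_NAMES",
    "p_same_ddm",
    "p_same_bsu",
    "p_same_mcg",
    "p_same_cg",
    "p_same",
    "response_probabilities",
    "make_params",
]

#: Canonical model order, also used for deterministic tie-breaking downstream.
MODEL_IDS = ("ddm", "bsu", "mcg", "cg")

PARAM_NAMES = {
    "ddm": ("b_l", "b_u", "c"),
    "bsu": ("b_l", "b_u", "k"),
    "mcg": ("B", "sigma_B", "k"),
    "cg": ("B", "sigma_B", "k"),
}


def _check_durations(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("probe durations must be finite and strictly positive")
    return t


@dataclass(frozen=True)
class DurationDesign:
    """An experiment design: probe durations, their frequencies, and the standard.

    Parameters
    ----------
    durations
        Probe durations in seconds, strictly positive and strictly increasing.
    counts
        Per-duration trial counts (non-negative integers). Mutually exclusive
        with ``probs``; probabilities are derived as ``counts / sum(counts)``.
    probs
        Per-duration presentation probabilities (sum to 1 within 1e-12).
    standard
        The true standard duration ``S`` in seconds; must be one of
        ``durations``.
    """

    durations: tuple
    standard: float
    counts: tuple = None
    probs: tuple = None

    def __post_init__(self):
        durations = tuple(float(d) for d in self.durations)
        object.__setattr__(self, "durations", durations)
        if len(durations) == 0:
            raise ValueError("design needs at least one duration")
        if any(d <= 0 for d in durations):
            raise ValueError("all durations must be strictly positive")
        if any(b <= a for a, b in zip(durations, durations[1:])):
            raise ValueError("durations must be strictly increasing")
        if not any(abs(d - self.standard) < 1e-12 for d in durations):
            raise ValueError(
                f"standard {self.standard} is not a member of the duration set"
            )
        if (self.counts is None) == (self.probs is None):
            raise ValueError("provide exactly one of counts or probs")
        if self.counts is not None:
            counts = tuple(int(c) for c in self.counts)
            if len(counts) != len(durations):
                raise ValueError("counts must align with durations")
            if any(c != orig or c < 0 for c, orig in zip(counts, self.counts)):
                raise ValueError("counts must be non-negative integers")
            if sum(counts) == 0:
                raise ValueError("design needs at least one trial")
            object.__setattr__(self, "counts", counts)
        else:
            probs = tuple(float(p) for p in self.probs)
            if len(probs) != len(durations):
                raise ValueError("probs must align with durations")
            if any(p < 0 for p in probs):
                raise ValueError("probabilities must be non-negative")
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError("probabilities must sum to 1 within 1e-12")
            object.__setattr__(self, "probs", probs)

    @property
    def probabilities(self) -> np.ndarray:
        if self.probs is not None:
            return np.asarray(self.probs, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        return counts / counts.sum()

    @property
    def n_trials(self) -> int:
        if self.counts is None:
            raise ValueError("design specified by probabilities has no trial count")
        return int(sum(self.counts))

    @property
    def p_standard(self) -> float:
        idx = self.standard_index
        return float(self.probabilities[idx])

    @property
    def standard_index(self) -> int:
        return min(
            range(len(self.durations)),
            key=lambda i: abs(self.durations[i] - self.standard),
        )


@dataclass(frozen=True)
class DDMParams:
    """Drift-diffusion observer parameters.

    ``b_l``/``b_u`` are the lower/upper boundary-to-drift ratios (seconds);
    ``c`` is the diffusion-to-drift ratio (s^0.5) controlling how fast the
    decision variable's spread grows with the probe duration. Drift itself is
    normalized out of the parameterization.
    """

    b_l: float
    b_u: float
    c: float

    def __post_init__(self):
        if not (self.b_l > 0 and self.c > 0):
            raise ValueError("b_l and c must be strictly positive")
        if not self.b_u > self.b_l:
            raise ValueError("upper boundary must exceed lower boundary")

    def as_tuple(self):
        return (self.b_l, self.b_u, self.c)


@dataclass(frozen=True)
class BSUParams:
    """Free-boundary model with linear (Weber) noise growth.

    ``b_l``/``b_u`` are the boundaries in seconds and ``k`` the Weber fraction
    scaling the probe-estimate noise as ``k * t``.
    """

    b_l: float
    b_u: float
    k: float

    def __post_init__(self):
        if not (self.b_l > 0 and self.k > 0):
            raise ValueError("b_l and k must be strictly positive")
        if not self.b_u > self.b_l:
            raise ValueError("upper boundary must exceed lower boundary")

    def as_tuple(self):
        return (self.b_l, self.b_u, self.k)


@dataclass(frozen=True)
class CGParams:
    """Parameters of the Church–Gibbon model and its modified variant.

    ``B`` is the mean boundary relative to the standard, ``sigma_B`` its
    trial-to-trial standard deviation, and ``k`` the Weber fraction of the
    standard-memory samples. Maximum-likelihood fitting constrains all three
    strictly positive; the model functions additionally accept the degenerate
    sigma_B = 0 or k = 0 cases (not both), which are useful closed-form
    checks.
    """

    B: float
    sigma_B: float
    k: float

    def __post_init__(self):
        if not self.B > 0:
            raise ValueError("B must be strictly positive")
        if self.sigma_B < 0 or self.k < 0:
            raise ValueError("sigma_B and k must be non-negative")
        if self.sigma_B == 0 and self.k == 0:
            raise ValueError("sigma_B and k cannot both be zero")

    def as_tuple(self):
        return (self.B, self.sigma_B, self.k)


ParamSet = Union[DDMParams, BSUParams, CGParams]

PARAM_CLASSES = {"ddm": DDMParams, "bsu": BSUParams, "mcg": CGParams, "cg": CGParams}


def make_params(model_id: str, values) -> ParamSet:
    """Build the parameter set for ``model_id`` from a sequence or mapping."""
    cls = PARAM_CLASSES[_check_model_id(model_id)]
    if isinstance(values, dict):
        return cls(**values)
    return cls(*values)


def _check_model_id(model_id: str) -> str:
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    return model_id


def p_same_ddm(params: DDMParams, t):
    """P("same" | t) for the drift-diffusion observer.

    The decision variable at probe offset is normal(t, (c*sqrt(t))^2);
    "same" is reported when it lands between the boundaries::

        P = Phi((b_u - t) / (c*sqrt(t))) - Phi((b_l - t) / (c*sqrt(t)))
    """
    t = _check_durations(t)
    sd = params.c * np.sqrt(t)
    return ndtr((params.b_u - t) / sd) - ndtr((params.b_l - t) / sd)


def p_same_bsu(params: BSUParams, t):
    """P("same" | t) with linear noise growth: sd of the estimate is k*t."""
    t = _check_durations(t)
    sd = params.k * t
    return ndtr((params.b_u - t) / sd) - ndtr((params.b_l - t) / sd)


def p_same_mcg(params: CGParams, t, S: float):
    """P("same" | t) for the modified Church–Gibbon model.

    The normalized difference uses the objective standard ``S`` in the
    denominator::

        z_i = (t * (1 + (-1)^i * B) - S) / sqrt(t^2 sigma_B^2 + S^2 k^2)
        P   = Phi(z_2) - Phi(z_1)
    """
    t = _check_durations(t)
    if S <= 0:
        raise ValueError("standard duration must be strictly positive")
    B, sigma_B, k = params.as_tuple()
    denom = np.sqrt(t**2 * sigma_B**2 + S**2 * k**2)
    z1 = (t * (1.0 - B) - S) / denom
    z2 = (t * (1.0 + B) - S) / denom
    return ndtr(z2) - ndtr(z1)


def p_same_cg(params: CGParams, t, S: float):
    """P("same" | t) for the original Church–Gibbon model.

    Both the standard memory sample and the boundary vary from trial to trial,
    which gives the two z-scores *different* denominators — the source of the
    model's asymmetric generalization gradient::

        z_i = ((1 + (-1)^i B) - t/S)
              / sqrt(k^2 sigma_B^2 + k^2 (1 + (-1)^i B)^2 + sigma_B^2)
        P   = Phi(z_2) - Phi(z_1)
    """
    t = _check_durations(t)
    if S <= 0:
        raise ValueError("standard duration must be strictly positive")
    B, sigma_B, k = params.as_tuple()
    lo = 1.0 - B
    hi = 1.0 + B
    denom1 = math.sqrt(k**2 * sigma_B**2 + k**2 * lo**2 + sigma_B**2)
    denom2 = math.sqrt(k**2 * sigma_B**2 + k**2 * hi**2 + sigma_B**2)
    ratio = t / S
    z1 = (lo - ratio) / denom1
    z2 = (hi - ratio) / denom2
    return ndtr(z2) - ndtr(z1)


def p_same(model_id: str, params: ParamSet, t, S: float = None):
    """Dispatch P("same" | t) for any model.

    ``S`` is required for the cg/mcg family and ignored by ddm/bsu (their
    boundaries are absolute, not standard-relative).
    """
    _check_model_id(model_id)
    if model_id == "ddm":
        return p_same_ddm(params, t)
    if model_id == "bsu":
        return p_same_bsu(params, t)
    if S is None:
        raise ValueError(f"model {model_id!r} requires the standard duration S")
    if model_id == "mcg":
        return p_same_mcg(params, t, S)
    return p_same_cg(params, t, S)


def response_probabilities(model_id: str, params: ParamSet, design: DurationDesign):
    """P("same") at every duration of ``design``, in design order."""
    t = np.asarray(design.durations, dtype=float)
    return np.asarray(p_same(model_id, params, t, design.standard), dtype=float)
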