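"""Synthetic temporal generalization data.

Responses are Bernoulli draws from a model's psychometric curve over a fixed
experiment design. The module also houses the machinery that turns a cohort
of fitted parameter sets into sampling distributions (gamma / exponential per
parameter, with an outlier filter) and draws new "synthetic participants"
from them, including the redraw rule that keeps ddm/bsu boundary separations
away from the degenerate always-"different" regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np

from .fitting import TrialData
from .models import (
    MODEL_IDS,
    PARAM_NAMES,
    DurationDesign,
    make_params,
    response_probabilities,
)

__all__ = [
    "ParamDist",
    "ParamDists",
    "make_design",
    "simulate_trials",
    "fit_param_distributions",
    "sample_parameters",
    "default_param_dists",
]

_EXP1_DURATIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.7, 0.8)


def _as_rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ParamDist:
    """One parameter's sampling distribution: gamma(shape, scale) or
    exponential(mean)."""

    family: str
    shape: float = None
    scale: float = None
    mean: float = None

    def __post_init__(self):
        if self.family == "gamma":
            if not (self.shape and self.scale and self.shape > 0 and self.scale > 0):
                raise ValueError("gamma requires positive shape and scale")
        elif self.family == "exponential":
            if not (self.mean and self.mean > 0):
                raise ValueError("exponential requires a positive mean")
        else:
            raise ValueError("family must be 'gamma' or 'exponential'")

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "gamma":
            return rng.gamma(self.shape, self.scale, size=size)
        return rng.exponential(self.mean, size=size)

    def to_dict(self) -> dict:
        if self.family == "gamma":
            return {"family": "gamma", "shape": self.shape, "scale": self.scale}
        return {"family": "exponential", "mean": self.mean}


@dataclass(frozen=True)
class ParamDists:
    """Per-parameter distributions for one model's free parameters."""

    model_id: str
    dists: Mapping[str, ParamDist]

    def __post_init__(self):
        names = PARAM_NAMES[self.model_id]
        if set(self.dists) != set(names):
            raise ValueError(
                f"dists must cover exactly the parameters {names} of {self.model_id}"
            )

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "dists": {k: v.to_dict() for k, v in self.dists.items()},
        }


def _gamma_from_moments(mean: float, sd: float) -> ParamDist:
    shape = (mean / sd) ** 2
    return ParamDist("gamma", shape=shape, scale=sd**2 / mean)


def default_param_dists(model_id: str) -> ParamDists:
    """Shipped fixture distributions for simulation campaigns.

    The ddm entries are gamma distributions moment-matched to the empirical
    auditory-modality parameter means/SDs (b_l 0.27 +- 0.06 s, b_u 0.54 +-
    0.09 s, c 0.17 +- 0.06 s^0.5). The bsu and cg/mcg entries are synthetic
    but field-plausible choices following the same family conventions (gamma
    for boundaries and bsu's Weber fraction, exponential for the cg/mcg noise
    parameters, which pile up near zero in fits); see docs/methods.md.
    """
    if model_id == "ddm":
        dists = {
            "b_l": _gamma_from_moments(0.27, 0.06),
            "b_u": _gamma_from_moments(0.54, 0.09),
            "c": _gamma_from_moments(0.17, 0.06),
        }
    elif model_id == "bsu":
        dists = {
            "b_l": _gamma_from_moments(0.27, 0.08),
            "b_u": _gamma_from_moments(0.65, 0.25),
            "k": _gamma_from_moments(0.40, 0.15),
        }
    elif model_id in ("cg", "mcg"):
        dists = {
            "B": _gamma_from_moments(0.45, 0.18),
            "sigma_B": ParamDist("exponential", mean=0.10),
            "k": ParamDist("exponential", mean=0.30),
        }
    else:
        raise ValueError(f"unknown model_id {model_id!r}")
    return ParamDists(model_id=model_id, dists=dists)


def make_design(name: str) -> DurationDesign:
    """Named experiment designs.

    ``exp1``
        Standard 0.4 s; probes 0.1-0.8 s; 30 trials per non-standard probe
        and 45 standard trials (225 total, standard in 20% of trials).
    ``exp1_x3``
        The same with every count tripled (675 trials).
    ``exp2``
        One contrast-collapsed half of the learning experiment: 30 trials per
        non-standard probe and 60 standard trials (240 total, standard 25%).
    ``exp2_block``
        A single 80-trial block (10 per non-standard probe, 20 standard).
    ``exp2_tertile``
        Two consecutive blocks (160 trials).
    ``balanced``
        Probability-specified design with P(standard) = 0.5 and the other six
        probes equally likely (used by the optimality analysis).
    """
    if name == "exp1":
        counts = (30, 30, 30, 45, 30, 30, 30)
    elif name == "exp1_x3":
        counts = (90, 90, 90, 135, 90, 90, 90)
    elif name == "exp2":
        counts = (30, 30, 30, 60, 30, 30, 30)
    elif name == "exp2_block":
        counts = (10, 10, 10, 20, 10, 10, 10)
    elif name == "exp2_tertile":
        counts = (20, 20, 20, 40, 20, 20, 20)
    elif name == "balanced":
        probs = tuple(0.5 if abs(d - 0.4) < 1e-12 else 0.5 / 6 for d in _EXP1_DURATIONS)
        return DurationDesign(durations=_EXP1_DURATIONS, standard=0.4, probs=probs)
    else:
        raise ValueError(f"unknown design name {name!r}")
    return DurationDesign(durations=_EXP1_DURATIONS, standard=0.4, counts=counts)


def simulate_trials(
    model_id: str,
    params,
    design: DurationDesign,
    seed: Union[int, np.random.Generator, None],
    participant: str = "sim",
    condition: str = "sim",
) -> TrialData:
    """Simulate one synthetic dataset: Bernoulli responses from P("same"|t).

    The design must specify integer per-duration counts; trials are emitted
    grouped by duration (fits are order-invariant, and shuffling is the
    caller's concern if a trial sequence is needed).
    """
    if design.counts is None:
        raise ValueError("simulation needs a design with integer trial counts")
    rng = _as_rng(seed)
    probs = response_probabilities(model_id, params, design)
    if np.any(probs < 0) or np.any(probs > 1):
        raise RuntimeError("model produced probabilities outside [0, 1]")
    durations = []
    responses = []
    for d, count, p in zip(design.durations, design.counts, probs):
        durations.append(np.full(count, d))
        responses.append(rng.random(count) < p)
    return TrialData(
        durations=np.concatenate(durations),
        responses=np.concatenate(responses).astype(int),
        participant=participant,
        condition=condition,
    )


def fit_param_distributions(
    estimates: Sequence, model_id: str, min_points: int = 5
) -> ParamDists:
    """Fit sampling distributions to a cohort of estimated parameter sets.

    A parameter *vector* is discarded when any of its entries lies more than
    3 interquartile ranges from that parameter's median. On the survivors,
    gamma distributions (maximum likelihood, location fixed at 0) are fitted
    to all ddm/bsu parameters and to cg/mcg's mean boundary B; exponential
    distributions (mean = sample mean) to cg/mcg's sigma_B and k.
    """
    names = PARAM_NAMES[model_id]
    values = np.array(
        [[getattr(p, n) for n in names] for p in estimates], dtype=float
    )
    if len(values) < 10:
        raise ValueError("need at least 10 parameter vectors")
    med = np.median(values, axis=0)
    q75, q25 = np.percentile(values, [75, 25], axis=0)
    iqr = q75 - q25
    keep = np.all(np.abs(values - med) <= 3.0 * iqr, axis=1)
    survivors = values[keep]
    if len(survivors) < min_points:
        raise ValueError(
            f"only {len(survivors)} vectors survive the 3*IQR filter (need {min_points})"
        )
    dists = {}
    for j, name in enumerate(names):
        x = survivors[:, j]
        if model_id in ("cg", "mcg") and name in ("sigma_B", "k"):
            dists[name] = ParamDist("exponential", mean=float(np.mean(x)))
        else:
            shape, scale = _fit_gamma(x)
            dists[name] = ParamDist("gamma", shape=shape, scale=scale)
    return ParamDists(model_id=model_id, dists=dists)


def _fit_gamma(x: np.ndarray) -> tuple:
    """Gamma MLE with location fixed at 0; falls back to moment matching
    (and to a near-point-mass for degenerate zero-variance samples)."""
    from scipy.stats import gamma as gamma_dist

    mean = float(np.mean(x))
    var = float(np.var(x))
    if var <= 1e-12 * mean**2:
        shape = 1e6
        return shape, mean / shape
    try:
        shape, _, scale = gamma_dist.fit(x, floc=0)
        return float(shape), float(scale)
    except Exception:
        return mean**2 / var, var / mean


def sample_parameters(
    model_id: str,
    dists: ParamDists,
    seed: Union[int, np.random.Generator, None],
    min_separation: float = 0.1,
    max_attempts: int = 10_000,
):
    """Draw one parameter set, independently per parameter.

    For ddm/bsu the whole vector is redrawn until the boundary separation
    ``b_u - b_l`` is at least ``min_separation`` (0.1 s by default) so the
    simulated observer does not sit in the always-"different" regime.
    """
    if dists.model_id != model_id:
        raise ValueError("dists were fitted for a different model")
    rng = _as_rng(seed)
    names = PARAM_NAMES[model_id]
    for _ in range(max_attempts):
        vals = {n: float(dists.dists[n].sample(rng)) for n in names}
        if model_id in ("ddm", "bsu"):
            if vals["b_u"] - vals["b_l"] < min_separation:
                continue
        if any(v <= 0 for v in vals.values()):
            continue  # exponential can return 0.0 at double-precision edge
        return make_params(model_id, vals)
    raise RuntimeError(
        f"could not satisfy b_u - b_l >= {min_separation} in {max_attempts} draws "
        f"from {dists.to_dict()}"
    )
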