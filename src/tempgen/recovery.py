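"""Parameter- and model-recovery simulation campaigns.

Parameter recovery: draw parameters from the cohort distributions, simulate a
dataset, refit the generating model, and correlate simulated against
estimated values — an identifiability diagnostic. Model recovery: simulate
from each candidate model and fit all candidates, tabulating which wins by
maximum likelihood (all models have three free parameters, so this equals
minimum AIC) into a confusion matrix whose columns (generating model) sum
to 1.

Every campaign is reproducible from a single seed: per-simulation random
streams are fanned out with ``numpy.random.SeedSequence.spawn``, so results
do not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .fitting import fit_mle
from .models import MODEL_IDS, PARAM_NAMES, DurationDesign
from .simulate import ParamDists, sample_parameters, simulate_trials

__all__ = [
    "RecoveryResult",
    "ConfusionMatrix",
    "parameter_recovery",
    "model_recovery",
    "bootstrap_correlation_null",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of one parameter-recovery campaign.

    ``table`` has one row per simulation with columns ``sim_<param>``,
    ``est_<param>``, ``fit_ok`` and ``kept``. Simulations are dropped
    (``kept=False``) when any estimated parameter exceeds five times the
    largest *simulated* value of that parameter in the campaign, or when the
    fit failed outright. ``correlations``/``regressions`` (Pearson r and
    least-squares intercept/slope of estimated on simulated) and the
    cross-parameter correlation matrix of estimates are computed on the kept
    set only.
    """

    model_id: str
    table: pd.DataFrame
    correlations: Dict[str, float]
    regressions: Dict[str, tuple]
    est_corr: pd.DataFrame
    n_sims: int
    n_kept: int
    n_excluded: int


@dataclass(frozen=True)
class ConfusionMatrix:
    """generating-model (columns) x best-fitting-model (rows) proportions."""

    proportions: pd.DataFrame
    counts: pd.DataFrame
    n_per_model: int

    def hit_rate(self, model_id: str) -> float:
        return float(self.proportions.loc[model_id, model_id])


def _spawn_seeds(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def parameter_recovery(
    model_id: str,
    dists: ParamDists,
    n_sims: int,
    design: DurationDesign,
    seed: int,
    min_separation: float = 0.1,
    exclusion_factor: float = 5.0,
) -> RecoveryResult:
    """Run a parameter-recovery campaign of ``n_sims`` simulations."""
    if n_sims < 2:
        raise ValueError("need at least 2 simulations")
    names = PARAM_NAMES[model_id]
    standard = design.standard
    rows = []
    for child in _spawn_seeds(seed, n_sims):
        rng = np.random.default_rng(child)
        params = sample_parameters(model_id, dists, rng, min_separation=min_separation)
        trials = simulate_trials(model_id, params, design, rng)
        fit = fit_mle(model_id, trials, standard)
        row = {f"sim_{n}": getattr(params, n) for n in names}
        if fit.params is not None:
            row.update({f"est_{n}": getattr(fit.params, n) for n in names})
            row["fit_ok"] = True
        else:
            row.update({f"est_{n}": np.nan for n in names})
            row["fit_ok"] = False
        rows.append(row)
    table = pd.DataFrame(rows)
    kept = table["fit_ok"].to_numpy().copy()
    for n in names:
        limit = exclusion_factor * table[f"sim_{n}"].max()
        kept &= ~(table[f"est_{n}"] > limit).to_numpy()
    table["kept"] = kept
    survivors = table[table["kept"]]
    correlations = {}
    regressions = {}
    for n in names:
        x = survivors[f"sim_{n}"].to_numpy()
        y = survivors[f"est_{n}"].to_numpy()
        if len(x) >= 2 and np.std(x) > 0 and np.std(y) > 0:
            correlations[n] = float(np.corrcoef(x, y)[0, 1])
            slope, intercept = np.polyfit(x, y, 1)
            regressions[n] = (float(intercept), float(slope))
        else:
            correlations[n] = np.nan
            regressions[n] = (np.nan, np.nan)
    est = survivors[[f"est_{n}" for n in names]]
    est_corr = est.corr()
    est_corr.index = list(names)
    est_corr.columns = list(names)
    return RecoveryResult(
        model_id=model_id,
        table=table,
        correlations=correlations,
        regressions=regressions,
        est_corr=est_corr,
        n_sims=n_sims,
        n_kept=int(kept.sum()),
        n_excluded=int(n_sims - kept.sum()),
    )


def model_recovery(
    dists_by_model: Mapping[str, ParamDists],
    n_per_model: int,
    design: DurationDesign,
    seed: int,
    min_separation: float = 0.1,
) -> ConfusionMatrix:
    """Simulate from every model, fit all four, and tabulate the winners.

    The winner of each simulated dataset is the model with the highest
    maximized log-likelihood (ties break toward the fixed order ddm, bsu,
    mcg, cg). Datasets on which every fit fails are dropped from their
    column's denominator with a warning. Seeds fan out per generating model
    and then per simulation, so campaigns that share a seed are paired
    simulation-by-simulation even if the design differs (e.g. 225 vs 675
    trials).
    """
    missing = [m for m in MODEL_IDS if m not in dists_by_model]
    if missing:
        raise ValueError(f"missing parameter distributions for {missing}")
    standard = design.standard
    counts = pd.DataFrame(0, index=list(MODEL_IDS), columns=list(MODEL_IDS))
    top_seeds = _spawn_seeds(seed, len(MODEL_IDS))
    for gen_model, gen_seed in zip(MODEL_IDS, top_seeds):
        for child in gen_seed.spawn(n_per_model):
            rng = np.random.default_rng(child)
            params = sample_parameters(
                gen_model, dists_by_model[gen_model], rng, min_separation=min_separation
            )
            trials = simulate_trials(gen_model, params, design, rng)
            fits = {m: fit_mle(m, trials, standard) for m in MODEL_IDS}
            finite = {m: f for m, f in fits.items() if np.isfinite(f.log_lik)}
            if not finite:
                logger.warning("all fits failed on a %s-generated dataset", gen_model)
                continue
            winner = max(
                finite, key=lambda m: (finite[m].log_lik, -MODEL_IDS.index(m))
            )
            counts.loc[winner, gen_model] += 1
    proportions = counts / counts.sum(axis=0)
    return ConfusionMatrix(
        proportions=proportions, counts=counts, n_per_model=n_per_model
    )


def bootstrap_correlation_null(
    recovery: RecoveryResult,
    param_x: str,
    param_y: str,
    n_participants: int,
    n_iter: int,
    observed_r: float,
    seed: int,
) -> dict:
    """Bootstrap null distribution for a cross-parameter correlation.

    Resamples ``n_participants`` kept simulations (with replacement) from the
    parameter-recovery campaign ``n_iter`` times, computing the Pearson
    correlation between the two named *estimated* parameters in each
    resample. The p value is the fraction of null correlations at least as
    large as ``observed_r``.
    """
    survivors = recovery.table[recovery.table["kept"]]
    if len(survivors) < n_participants:
        raise ValueError(
            f"only {len(survivors)} kept simulations; need at least {n_participants}"
        )
    x = survivors[f"est_{param_x}"].to_numpy()
    y = survivors[f"est_{param_y}"].to_numpy()
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.integers(0, len(x), size=n_participants)
        null[i] = np.corrcoef(x[idx], y[idx])[0, 1]
    p_value = float(np.mean(null >= observed_r))
    return {"p_value": p_value, "null": null, "observed_r": observed_r}
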