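"""Trial-data ingest/egress and participant screening.

Trial files are plain CSV (UTF-8, header required) with columns
``participant, condition, duration, response``; responses may be 1/0 or the
tokens same/different (case-insensitive). Durations are seconds by default;
pass ``units="ms"`` to divide by 1,000 on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .fitting import TrialData, fit_mle
from .models import MODEL_IDS

__all__ = [
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "ScreenResult",
    "screen_flat_participants",
]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("participant", "condition", "duration", "response")
_RESPONSE_TOKENS = {"1": 1, "0": 0, "same": 1, "different": 0}


def read_trials(path, units: str = "s") -> Dict[Tuple[str, str], TrialData]:
    """Read a trial CSV into TrialData grouped by participant x condition.

    Groups preserve file order. Raises ``ValueError`` naming the offending
    row (1-based, excluding the header) on missing columns, non-positive
    durations, or unknown response tokens.
    """
    if units not in ("s", "ms"):
        raise ValueError("units must be 's' or 'ms'")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    durations = pd.to_numeric(df["duration"], errors="coerce")
    bad = durations.isna() | (durations <= 0)
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ValueError(f"non-positive or unparseable duration at row {row}")
    if units == "ms":
        durations = durations / 1000.0
    responses = df["response"].str.strip().str.lower().map(_RESPONSE_TOKENS)
    if responses.isna().any():
        row = int(responses.isna().idxmax()) + 1
        raise ValueError(f"unknown response token at row {row}")
    out: Dict[Tuple[str, str], TrialData] = {}
    df = df.assign(_duration=durations.to_numpy(), _response=responses.to_numpy())
    for (participant, condition), group in df.groupby(
        ["participant", "condition"], sort=False
    ):
        out[(str(participant), str(condition))] = TrialData(
            durations=group["_duration"].to_numpy(),
            responses=group["_response"].to_numpy().astype(int),
            participant=str(participant),
            condition=str(condition),
        )
    return out


def trials_to_frame(trials: Iterable[TrialData]) -> pd.DataFrame:
    if isinstance(trials, TrialData):
        trials = [trials]
    frames = []
    for t in trials:
        frames.append(
            pd.DataFrame(
                {
                    "participant": t.participant,
                    "condition": t.condition,
                    "duration": t.durations,
                    "response": t.responses,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_trials(trials, path) -> None:
    """Write TrialData (one or many) to the canonical CSV dialect.

    Responses are written as 1/0 and durations in seconds with shortest-
    roundtrip float formatting, so files written here re-read and re-write
    bit-identically.
    """
    if isinstance(trials, dict):
        trials = list(trials.values())
    trials_to_frame(trials).to_csv(path, index=False)


@dataclass(frozen=True)
class ScreenResult:
    keep: bool
    p_value: float
    log_lik_constant: float
    log_lik_best: float
    best_model: str
    reason: str


def screen_flat_participants(
    trials: TrialData, standard: float, alpha: float = 0.01
) -> ScreenResult:
    """Flag participants whose psychometric curve is flat.

    A flat curve — "same" probability independent of the probe duration —
    indicates the participant was not responding to the intervals. The
    screen is a likelihood-ratio test of a one-parameter constant-probability
    model against the best of the four psychometric models (chi-square, 2
    degrees of freedom): the participant is *excluded* when the constant
    model is not rejected at ``alpha``. ``alpha=0`` disables the screen
    (every participant kept). Degenerate data (a single response category
    throughout) are excluded outright.
    """
    if len(np.unique(trials.durations)) < 2:
        raise ValueError("screening needs at least 2 distinct durations")
    y = trials.responses
    n = len(y)
    n_same = int(y.sum())
    if n_same == 0 or n_same == n:
        return ScreenResult(
            keep=False,
            p_value=1.0,
            log_lik_constant=0.0,
            log_lik_best=0.0,
            best_model="",
            reason="degenerate: single response category",
        )
    if alpha == 0:
        return ScreenResult(
            keep=True,
            p_value=np.nan,
            log_lik_constant=np.nan,
            log_lik_best=np.nan,
            best_model="",
            reason="screen disabled (alpha=0)",
        )
    p_hat = n_same / n
    ll0 = n_same * np.log(p_hat) + (n - n_same) * np.log(1 - p_hat)
    fits = {m: fit_mle(m, trials, standard) for m in MODEL_IDS}
    finite = {m: f.log_lik for m, f in fits.items() if np.isfinite(f.log_lik)}
    if not finite:
        return ScreenResult(
            keep=False,
            p_value=1.0,
            log_lik_constant=float(ll0),
            log_lik_best=-np.inf,
            best_model="",
            reason="all model fits failed",
        )
    best_model = max(finite, key=lambda m: (finite[m], -MODEL_IDS.index(m)))
    ll1 = finite[best_model]
    stat = max(2.0 * (ll1 - ll0), 0.0)
    p_value = float(chi2.sf(stat, df=2))
    keep = p_value < alpha
    reason = "curve modulated by duration" if keep else "flat psychometric curve"
    if not keep:
        logger.warning(
            "participant %s/%s screened out: %s (p=%.3g)",
            trials.participant,
            trials.condition,
            reason,
            p_value,
        )
    return ScreenResult(
        keep=keep,
        p_value=p_value,
        log_lik_constant=float(ll0),
        log_lik_best=float(ll1),
        best_model=best_model,
        reason=reason,
    )
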