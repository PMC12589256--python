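"""scikit-learn style estimators for the four temporal generalization models.

Each estimator wraps the multi-start maximum-likelihood machinery in
:mod:`tempgen.fitting` behind the familiar fit/predict interface: ``X`` is a
column of probe durations in seconds (shape ``(n, 1)`` or ``(n,)``) and ``y``
the binary same/different judgments. After fitting, the maximized parameters
are available both as a parameter dataclass (``params_``) and as individual
trailing-underscore attributes, and ``predict_proba`` evaluates the fitted
psychometric curve. ``score`` returns the total Bernoulli log-likelihood in
nats, so estimators compose directly with sklearn model selection (higher is
better).

>>> est = DriftDiffusionEstimator(standard=0.4).fit(X, y)
>>> est.params_, est.log_lik_
"""

from __future__ import annotations

from typing import ClassVar, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import fitting
from .fitting import FitResult, TrialData
from .models import PARAM_NAMES, p_same

__all__ = [
    "TemporalGeneralizationEstimator",
    "DriftDiffusionEstimator",
    "BSUEstimator",
    "ModifiedChurchGibbonEstimator",
    "ChurchGibbonEstimator",
    "ESTIMATORS",
]


def _validate_X(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("X must be a single column of probe durations")
        X = X[:, 0]
    elif X.ndim != 1:
        raise ValueError("X must be 1-D or a single column")
    if np.any(X <= 0) or not np.all(np.isfinite(X)):
        raise ValueError("probe durations must be finite and strictly positive")
    return X


class TemporalGeneralizationEstimator(BaseEstimator):
    """Base class; subclasses set ``model_id``.

    Parameters
    ----------
    standard
        The true standard duration S in seconds (the learned reference).
    starts
        Optional explicit list of starting parameter sets; by default the
        canonical 8-point grid derived from the training durations.
    xatol, fatol, maxiter
        Nelder-Mead convergence controls, applied per start.
    """

    model_id: ClassVar[str]

    def __init__(
        self,
        standard: float = 0.4,
        starts: Optional[Sequence] = None,
        xatol: float = 1e-6,
        fatol: float = 1e-6,
        maxiter: int = 2000,
    ):
        self.standard = standard
        self.starts = starts
        self.xatol = xatol
        self.fatol = fatol
        self.maxiter = maxiter

    def fit(self, X, y):
        durations = _validate_X(X)
        y = np.asarray(y)
        trials = TrialData(durations=durations, responses=y)
        result = fitting.fit_mle(
            self.model_id,
            trials,
            self.standard,
            starts=self.starts,
            xatol=self.xatol,
            fatol=self.fatol,
            maxiter=self.maxiter,
        )
        self.result_ = result
        self.params_ = result.params
        self.log_lik_ = result.log_lik
        self.n_starts_ = result.n_starts
        self.best_start_index_ = result.best_start_index
        self.converged_ = result.converged
        self.n_trials_ = result.n_trials
        self.n_features_in_ = 1
        self.classes_ = np.array([0, 1])
        if result.params is not None:
            for name in PARAM_NAMES[self.model_id]:
                setattr(self, f"{name}_", getattr(result.params, name))
        return self

    def predict_proba(self, X):
        """Column-stacked [P("different"), P("same")] at each duration."""
        check_is_fitted(self, "params_")
        t = _validate_X(X)
        ps = np.asarray(p_same(self.model_id, self.params_, t, self.standard))
        return np.column_stack([1.0 - ps, ps])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y) -> float:
        """Total Bernoulli log-likelihood (nats) of ``y`` under the fit."""
        check_is_fitted(self, "params_")
        durations = _validate_X(X)
        trials = TrialData(durations=durations, responses=np.asarray(y))
        return fitting.log_likelihood(self.model_id, self.params_, trials, self.standard)


class DriftDiffusionEstimator(TemporalGeneralizationEstimator):
    """Drift-diffusion observer: noise grows with sqrt(t)."""

    model_id = "ddm"


class BSUEstimator(TemporalGeneralizationEstimator):
    """Free asymmetric boundaries with linear (Weber) noise growth."""

    model_id = "bsu"


class ModifiedChurchGibbonEstimator(TemporalGeneralizationEstimator):
    """Symmetric relative boundaries; objective standard in the denominator."""

    model_id = "mcg"


class ChurchGibbonEstimator(TemporalGeneralizationEstimator):
    """The original Church-Gibbon model with noisy standard memory."""

    model_id = "cg"


ESTIMATORS = {
    "ddm": DriftDiffusionEstimator,
    "bsu": BSUEstimator,
    "mcg": ModifiedChurchGibbonEstimator,
    "cg": ChurchGibbonEstimator,
}
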