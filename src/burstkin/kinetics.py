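"""End-to-end kinetics estimator: waiting times -> promoter model.

Chains Kaplan-Meier estimation, parsimonious multiexponential
regression and closed-form inversion into one sklearn-style estimator.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .inversion import KineticsReport, kinetics_report
from .regression import MultiExponentialSurvival

__all__ = ["BurstKineticsEstimator"]


class BurstKineticsEstimator(BaseEstimator):
    """Infer promoter switching rates from pooled inter-initiation
    waiting times.

    Fits the smallest accepted N-exponential survival (N = number of
    promoter states), inverts the closed forms for the telegraph (N=2)
    or non-obligatory pause (N=3) model, and propagates near-optimal
    solutions into min/max error intervals on every rate and derived
    quantity.

    Parameters mirror :class:`burstkin.regression.MultiExponentialSurvival`.

    Attributes
    ----------
    n_states_ : int
    report_ : KineticsReport
    rates_ : KineticRates
    derived_ : DerivedKinetics
    regression_ : fitted MultiExponentialSurvival
    """

    def __init__(
        self,
        n_components="auto",
        alpha: float = 0.6,
        n_starts: int = 30,
        ks_cutoff: float = 10.0,
        overflow_ratio: float = 2.0,
        n_max: int = 4,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.alpha = alpha
        self.n_starts = n_starts
        self.ks_cutoff = ks_cutoff
        self.overflow_ratio = overflow_ratio
        self.n_max = n_max
        self.random_state = random_state

    def fit(self, X, event_observed=None):
        """X: waiting times (seconds) or a WaitingTimeSet."""
        reg = MultiExponentialSurvival(
            n_components=self.n_components,
            alpha=self.alpha,
            n_starts=self.n_starts,
            ks_cutoff=self.ks_cutoff,
            overflow_ratio=self.overflow_ratio,
            n_max=self.n_max,
            random_state=self.random_state,
        )
        reg.fit(X, event_observed=event_observed)
        self.regression_ = reg
        self.n_states_ = reg.n_components_
        self.report_ = kinetics_report(reg.fit_, self.overflow_ratio)
        self.rates_ = self.report_.rates
        self.derived_ = self.report_.derived
        return self

    def predict_survival(self, times) -> np.ndarray:
        return self.regression_.predict_survival(times)
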