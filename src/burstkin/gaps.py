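"""Postmitotic activation delays as a mixed gamma (Erlang mixture).

After mitosis a nucleus takes a random delay before its first
initiation event, modelled as 1, 2 or 3 sequential exponential steps of
common mean duration b: the delay is then a mixture of Erlang(k, b)
laws with weights (p1, p2, 1-p1-p2) and survival

    S(t) = p1 e^{-t/b} + p2 (1 - P(2, t/b)) + (1-p1-p2)(1 - P(3, t/b)),

with P the regularized lower incomplete gamma function.  This is
exactly the equal-timescale limit of the three-exponential family
(lambda_i -> -1/b), which is why the multiexponential fitting machinery
of :mod:`burstkin.regression` is reused to fit it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special
from sklearn.base import BaseEstimator

from .survival import WaitingTimeSet, km_survival

__all__ = [
    "GapParams",
    "GapDelayModel",
    "gap_survival",
    "sample_gap",
    "fit_gap",
    "equal_lambda_limit_check",
]


@dataclass(frozen=True)
class GapParams:
    """Mixture weights of 1 and 2 steps (3 steps gets the remainder) and
    the mean step duration b in seconds."""

    p1: float
    p2: float
    b: float

    def __post_init__(self) -> None:
        if self.p1 < 0 or self.p2 < 0 or self.p1 + self.p2 > 1 + 1e-12:
            raise ValueError("need p1, p2 >= 0 and p1 + p2 <= 1")
        if self.b <= 0:
            raise ValueError("mean step duration b must be positive")

    @property
    def p3(self) -> float:
        return max(0.0, 1.0 - self.p1 - self.p2)

    def survival(self, t) -> np.ndarray:
        return gap_survival(t, self)

    def sample(self, n: int, rng) -> np.ndarray:
        return sample_gap(self, n, rng)

    def to_dict(self) -> dict:
        return {"p1": self.p1, "p2": self.p2, "b": self.b}


def gap_survival(t, params: GapParams) -> np.ndarray:
    """Survival of the mixed-gamma delay at times t >= 0.

    The Erlang(k) survival is 1 - P(k, t/b) with P the regularized
    incomplete gamma (the k=3 term's gamma(3, x)/2 is exactly the
    regularization by Gamma(3) = 2), so S(0) = 1 automatically.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    x = t / params.b
    return (
        params.p1 * np.exp(-x)
        + params.p2 * (1.0 - special.gammainc(2, x))
        + params.p3 * (1.0 - special.gammainc(3, x))
    )


def sample_gap(params: GapParams, n: int, seed) -> np.ndarray:
    """Draw n delays: pick k in {1, 2, 3} with probabilities
    (p1, p2, p3), then an Erlang(k, b) duration."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    k = rng.choice([1, 2, 3], size=n, p=[params.p1, params.p2, params.p3])
    return rng.gamma(shape=k, scale=params.b)


class GapDelayModel(BaseEstimator):
    """Sklearn-style fitter of the mixed-gamma delay distribution.

    Fits (p1, p2, b) by minimizing the same mixed linear/log objective
    used for the multiexponential survival regression, applied to the
    Kaplan-Meier estimate of the observed onset delays.

    Attributes
    ----------
    params_ : GapParams
    objective_ : float
    """

    def __init__(
        self, alpha: float = 0.6, n_starts: int = 20, min_at_risk: int = 30, random_state: int = 0
    ):
        self.alpha = alpha
        self.n_starts = n_starts
        self.min_at_risk = min_at_risk
        self.random_state = random_state

    def fit(self, X, y=None):
        onsets = np.asarray(X, dtype=float).ravel()
        if onsets.size < 50:
            raise ValueError(f"need at least 50 onset delays, got {onsets.size}")
        wt = WaitingTimeSet(onsets, np.zeros(onsets.size, dtype=bool))
        surv = km_survival(wt)
        # extreme-tail points (few subjects at risk) have exploding
        # log-scale variance and would bias the mixture weights
        keep = (surv.S > 0) & (surv.n_at_risk >= min(self.min_at_risk, onsets.size // 2))
        t = surv.times[keep]
        S_e = surv.S[keep]
        # rank-uniform thinning keeps the fit O(1) in sample size
        if t.size > 1000:
            sel = np.unique(np.linspace(0, t.size - 1, 1000).astype(int))
            t, S_e = t[sel], S_e[sel]
        log_Se = np.log(S_e)
        alpha = self.alpha

        def decode(theta):
            # softmax over (p1, p2, p3) against fixed zero logit; b = exp
            logits = np.array([theta[0], theta[1], 0.0])
            logits -= logits.max()
            w = np.exp(logits)
            p = w / w.sum()
            return GapParams(p1=float(p[0]), p2=float(p[1]), b=float(np.exp(theta[2])))

        def fun(theta):
            try:
                params = decode(theta)
            except ValueError:
                return np.inf
            S = np.clip(gap_survival(t, params), 1e-300, None)
            lin = np.mean((S - S_e) ** 2)
            log = np.mean((np.log(S) - log_Se) ** 2)
            return alpha * lin + (1.0 - alpha) * log

        rng = np.random.default_rng(self.random_state)
        mean_t = float(onsets.mean())
        best = None
        for s in range(self.n_starts):
            if s == 0:
                theta0 = np.array([0.0, 0.0, np.log(mean_t / 2.0)])
            else:
                theta0 = np.array(
                    [rng.normal(0, 1.5), rng.normal(0, 1.5), np.log(mean_t) + rng.normal(-1.0, 1.0)]
                )
            res = optimize.minimize(
                fun, theta0, method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-12, "adaptive": True},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError("mixed-gamma fit failed to converge on all starts")
        self.params_ = decode(best.x)
        self.objective_ = float(best.fun)
        return self

    def predict_survival(self, times) -> np.ndarray:
        return gap_survival(np.asarray(times, dtype=float), self.params_)


def fit_gap(onsets: Sequence[float], alpha: float = 0.6, n_starts: int = 20, seed: int = 0) -> GapParams:
    """Fit (p1, p2, b) to observed onset delays (thin wrapper over
    :class:`GapDelayModel`)."""
    return GapDelayModel(alpha=alpha, n_starts=n_starts, random_state=seed).fit(onsets).params_


def _erlang_mixture_survival(t: np.ndarray, params: GapParams) -> np.ndarray:
    """Independent closed form of the equal-timescale limit: the
    Erlang(k) survival written as its truncated exponential series
    e^{-x} sum_{j<k} x^j / j! (the Jordan-block form of the confluent
    three-exponential family as all lambda_i -> -1/b)."""
    x = np.asarray(t, dtype=float) / params.b
    e = np.exp(-x)
    s1 = e
    s2 = e * (1.0 + x)
    s3 = e * (1.0 + x + 0.5 * x**2)
    return params.p1 * s1 + params.p2 * s2 + params.p3 * s3


def equal_lambda_limit_check(
    params: GapParams,
    tol: float = 1e-6,
    t_grid: Optional[np.ndarray] = None,
) -> bool:
    """True iff the mixed-gamma survival coincides (within tol, sup norm)
    with the equal-timescale limit of the three-exponential family on
    the test grid."""
    if t_grid is None:
        t_grid = np.linspace(0.0, 10.0 * params.b, 201)
    diff = np.abs(gap_survival(t_grid, params) - _erlang_mixture_survival(t_grid, params))
    return bool(np.max(diff) <= tol)
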