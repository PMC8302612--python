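"""Multiexponential regression of waiting-time survival functions.

The survival function of inter-initiation waiting times under an
N-state promoter model is a sum of N exponentials.  This module fits
such sums to a Kaplan-Meier estimate by minimizing a mixed
linear/logarithmic least-squares objective,

    O = (alpha/n) sum (S - S_e)^2 + ((1-alpha)/n) sum (log S - log S_e)^2,

with multiple initial guesses followed by local optimization.  A fit is
accepted when the parametric curve stays inside the 95% Greenwood band
of the empirical survival; the number of exponentials N — hence the
number of promoter states — is the smallest N with an accepted fit
(principle of parsimony).  The alternative obligatory-pause model is
fitted on its constrained manifold sum_i A_i lambda_i = 0 (density zero
at t = 0: every initiation must traverse the pause).  Suboptimal local
optima within an overflow ratio of the best objective supply
per-parameter error intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .models import MultiExpParams
from .survival import SurvivalEstimate, WaitingTimeSet, km_survival

__all__ = [
    "FitConfig",
    "MultiExpFit",
    "MultiExponentialSurvival",
    "objective",
    "fit_multiexp",
    "accept_fit",
    "select_num_states",
    "fit_constrained_obligatory",
    "modified_ks_test",
    "error_intervals",
]


@dataclass(frozen=True)
class FitConfig:
    """Regression settings.

    alpha weighs linear-scale against log-scale squared differences
    (0.6 balances short against long waiting times); ks_cutoff (s)
    restricts both the acceptance check and the modified KS test to
    times where the deconvolution grid resolves intervals reliably;
    overflow_ratio bounds the suboptimal solutions kept for error
    intervals.
    """

    alpha: float = 0.6
    n_starts: int = 30
    ks_cutoff: float = 10.0
    overflow_ratio: float = 2.0
    n_max: int = 4
    maxiter: int = 2000
    xatol: float = 1e-8
    fatol: float = 1e-10
    max_eval_points: int = 2000
    min_at_risk: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.overflow_ratio <= 1.0:
            raise ValueError("overflow_ratio must exceed 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be positive")


@dataclass(frozen=True)
class MultiExpFit:
    """Result of a multiexponential regression."""

    best: MultiExpParams
    objective: float
    suboptimal: tuple  # of (MultiExpParams, objective)
    accepted: bool
    error_intervals: Optional[dict] = None
    ks_p: Optional[float] = None
    constrained: bool = False

    def to_dict(self) -> dict:
        return {
            "N": self.best.n_exp,
            "A": list(self.best.amplitudes),
            "lambda": list(self.best.exponents),
            "objective": self.objective,
            "accepted": bool(self.accepted),
            "constrained": self.constrained,
            "ks_p": self.ks_p,
            "intervals": self.error_intervals,
        }


def objective(
    params: MultiExpParams,
    surv: SurvivalEstimate,
    alpha: float = 0.6,
) -> float:
    """Mixed linear/log objective between a parametric survival and the
    empirical estimate, averaged over grid points with S_e > 0 (points
    where the empirical survival has reached zero carry no log term and
    are excluded)."""
    S_e = surv.S
    keep = S_e > 0
    t = surv.times[keep]
    S_e = S_e[keep]
    n = t.size
    if n == 0:
        raise ValueError("no informative grid points (empirical survival is zero everywhere)")
    S = np.clip(params.survival(t), 1e-300, None)
    lin = np.mean((S - S_e) ** 2)
    log = np.mean((np.log(S) - np.log(S_e)) ** 2)
    return float(alpha * lin + (1.0 - alpha) * log)


def _eval_grid(
    surv: SurvivalEstimate, max_points: int, min_at_risk: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Informative grid (S_e > 0) for the optimizer.

    Points where fewer than ``min_at_risk`` subjects remain at risk are
    dropped: the log-scale variance of the Kaplan-Meier estimate there
    grows like 1/at_risk and those few extreme-tail points would
    otherwise dominate the log term of the objective.  The grid is then
    thinned rank-uniformly to at most ``max_points`` so huge samples
    stay tractable.  The acceptance check always uses the full grid.
    """
    keep = surv.S > 0
    if min_at_risk:
        keep &= surv.n_at_risk >= min_at_risk
    t = surv.times[keep]
    S_e = surv.S[keep]
    if max_points and t.size > max_points:
        idx = np.unique(np.linspace(0, t.size - 1, max_points).astype(int))
        t, S_e = t[idx], S_e[idx]
    return t, S_e


def _pack_objective(surv: SurvivalEstimate, alpha: float, max_points: int = 0, min_at_risk: int = 0):
    """Vectorized objective over raw optimizer coordinates (see
    _decode); returns (fun, n_grid) for unconstrained N-exponential fits."""
    t, S_e = _eval_grid(surv, max_points, min_at_risk)
    log_Se = np.log(S_e)
    n = t.size

    def fun(theta: np.ndarray, N: int) -> float:
        A, lam = _decode(theta, N)
        S = np.exp(t[:, None] * lam) @ A
        S = np.clip(S, 1e-300, None)
        lin = np.mean((S - S_e) ** 2)
        log = np.mean((np.log(S) - log_Se) ** 2)
        return alpha * lin + (1.0 - alpha) * log

    return fun, n


def _decode(theta: np.ndarray, N: int) -> Tuple[np.ndarray, np.ndarray]:
    """Free coordinates -> (amplitudes, exponents).

    Amplitudes are a softmax of N-1 logits against a fixed zero logit
    (positive, summing to one without hard boundaries); exponents are
    -exp(z) (negative without boundaries).
    """
    logits = np.concatenate([theta[: N - 1], [0.0]])
    logits = logits - logits.max()
    w = np.exp(logits)
    A = w / w.sum()
    lam = -np.exp(np.clip(theta[N - 1 :], -700.0, 700.0))
    return A, lam


def _encode(A: np.ndarray, lam: np.ndarray) -> np.ndarray:
    A = np.clip(A, 1e-12, None)
    logits = np.log(A) - np.log(A[-1])
    return np.concatenate([logits[:-1], np.log(-lam)])


def _amplitudes_nnls(t: np.ndarray, S_e: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Nonnegative least squares of S_e on the exponential design at
    fixed exponents, renormalized to sum to one."""
    X = np.exp(t[:, None] * lam)
    A, _ = optimize.nnls(X, S_e)
    if A.sum() <= 0:
        A = np.ones_like(A)
    return A / A.sum()


def _dedupe(solutions: List[Tuple[MultiExpParams, float]], rtol: float = 1e-3):
    """Collapse converged starts that landed on the same local optimum."""
    out: List[Tuple[MultiExpParams, float]] = []
    for params, obj in sorted(solutions, key=lambda s: s[1]):
        dup = False
        for p0, o0 in out:
            if p0.n_exp == params.n_exp and np.isclose(obj, o0, rtol=rtol):
                if np.allclose(p0.exponents, params.exponents, rtol=5e-2) and np.allclose(
                    p0.amplitudes, params.amplitudes, atol=5e-2
                ):
                    dup = True
                    break
        if not dup:
            out.append((params, obj))
    return out


def fit_multiexp(
    surv: SurvivalEstimate,
    N: int,
    config: Optional[FitConfig] = None,
) -> MultiExpFit:
    """Fit an N-exponential survival by multi-start local optimization.

    The 2N-1 free parameters are A_1..A_{N-1} (sum-to-one enforced) and
    lambda_1..lambda_N.  Initial exponent guesses are log-spaced across
    the observed time range with random jitter; initial amplitudes come
    from nonnegative least squares at the fixed exponents.  All distinct
    local optima are retained for error-interval construction.
    """
    config = config or FitConfig()
    if N < 2:
        raise ValueError("N must be at least 2 (use a plain exponential fit otherwise)")
    t, S_e = _eval_grid(surv, config.max_eval_points, config.min_at_risk)
    if t.size < 2 * N - 1:
        raise ValueError(f"survival has {t.size} informative points; need at least {2 * N - 1}")
    fun, _ = _pack_objective(surv, config.alpha, config.max_eval_points, config.min_at_risk)
    rng = np.random.default_rng(config.seed)

    t_lo = max(t.min(), 1e-6)
    t_hi = max(t.max(), t_lo * 10)
    log_rate_lo, log_rate_hi = np.log(1.0 / t_hi), np.log(1.0 / t_lo)

    solutions: List[Tuple[MultiExpParams, float]] = []
    n_fail = 0
    for s in range(config.n_starts):
        if s == 0:
            z = np.linspace(log_rate_lo, log_rate_hi, N + 2)[1:-1]
        else:
            z = np.sort(rng.uniform(log_rate_lo, log_rate_hi, size=N))
        lam = -np.exp(z)[::-1]  # descending (slowest first)
        A = _amplitudes_nnls(t, S_e, lam)
        theta0 = _encode(A, lam)
        res = optimize.minimize(
            fun,
            theta0,
            args=(N,),
            method="Nelder-Mead",
            options={
                "maxiter": config.maxiter,
                "xatol": config.xatol,
                "fatol": config.fatol,
                "adaptive": True,
            },
        )
        if not np.isfinite(res.fun):
            n_fail += 1
            continue
        A_fit, lam_fit = _decode(res.x, N)
        if np.any(lam_fit >= 0) or not np.all(np.isfinite(lam_fit)):
            n_fail += 1
            continue
        order = np.argsort(lam_fit)[::-1]
        A_fit, lam_fit = A_fit[order], _separate(lam_fit[order])
        solutions.append((MultiExpParams(tuple(A_fit), tuple(lam_fit)), float(res.fun)))
    if not solutions:
        raise RuntimeError(
            f"multiexponential fit failed to converge on all {config.n_starts} starts "
            f"({n_fail} rejected); inspect the survival estimate or widen the time range"
        )
    solutions = _dedupe(solutions)
    best, best_obj = solutions[0]
    fit = MultiExpFit(
        best=best,
        objective=best_obj,
        suboptimal=tuple(solutions),
        accepted=accept_fit_params(best, surv, config.ks_cutoff),
    )
    return replace(fit, error_intervals=error_intervals(fit, config.overflow_ratio))


def _separate(lam: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Nudge numerically coincident exponents apart so the mixture form
    stays well defined (nested models collapse components)."""
    lam = np.sort(lam)[::-1]
    for i in range(1, lam.size):
        if lam[i] > lam[i - 1] * (1 + rtol):
            lam[i] = lam[i - 1] * (1 + max(rtol, 1e-9))
    return lam


def accept_fit_params(
    params: MultiExpParams,
    surv: SurvivalEstimate,
    ks_cutoff: float = 10.0,
    slack: float = 1e-9,
    max_violation_frac: float = 0.05,
) -> bool:
    """True iff the parametric survival lies within the 95% Greenwood
    band at (essentially) every grid time at or beyond the cutoff.

    Grid points where the empirical survival has reached zero carry a
    degenerate band and are skipped.  Because the band is pointwise, the
    true curve is expected to graze outside somewhere on a dense grid;
    up to ``max_violation_frac`` of the grid points may violate the band
    before the fit is rejected, which approximates a simultaneous check.
    """
    mask = (surv.times >= ks_cutoff) & (surv.S > 0)
    if not mask.any():
        raise ValueError("no informative grid times at or beyond the cutoff")
    S = params.survival(surv.times[mask])
    bad = (S < surv.ci_lower[mask] - slack) | (S > surv.ci_upper[mask] + slack)
    return bool(bad.mean() <= max_violation_frac)


def accept_fit(fit: MultiExpFit, surv: SurvivalEstimate, ks_cutoff: float = 10.0) -> bool:
    """Acceptance check of a finished fit (see accept_fit_params)."""
    return accept_fit_params(fit.best, surv, ks_cutoff)


def select_num_states(
    surv: SurvivalEstimate,
    config: Optional[FitConfig] = None,
) -> MultiExpFit:
    """Increase N starting from 2 until a fit is accepted; return it.

    Rejected fits are kept on the result's ``rejected_`` attribute-like
    tuple via the returned fit's provenance (the caller can refit at any
    N).  Raises if no N up to config.n_max is acceptable.
    """
    config = config or FitConfig()
    rejected: List[MultiExpFit] = []
    for N in range(2, config.n_max + 1):
        try:
            fit = fit_multiexp(surv, N, config)
        except ValueError:
            continue
        if fit.accepted:
            return fit
        rejected.append(fit)
    raise RuntimeError(
        f"no multiexponential fit accepted up to N={config.n_max}; best objectives: "
        + ", ".join(f"N={f.best.n_exp}: {f.objective:.3e}" for f in rejected)
        + "; more data or a wider confidence band may be needed"
    )


def fit_constrained_obligatory(
    surv: SurvivalEstimate,
    config: Optional[FitConfig] = None,
) -> MultiExpFit:
    """Three-exponential fit restricted to the obligatory-pause manifold
    sum_i A_i lambda_i = 0 (waiting-time density vanishes at t = 0, as
    it must when every initiation traverses the pause).

    Free coordinates are lambda_1..lambda_3 and A_1; A_2 is solved from
    the constraint and A_3 = 1 - A_1 - A_2, so only four of the five
    distribution parameters are free.
    """
    config = config or FitConfig()
    t, S_e = _eval_grid(surv, config.max_eval_points, config.min_at_risk)
    log_Se = np.log(S_e)
    alpha = config.alpha

    # exponents are confined to (a broad margin around) the observed time
    # range: otherwise the optimizer satisfies the constraint in the
    # degenerate limit lambda_3 -> -inf, A_3 -> 0, which is just a free
    # biexponential with an invisible instantaneous component
    t_lo_b = max(t.min(), 1e-6)
    t_hi_b = max(t.max(), t_lo_b * 10)
    z_lo, z_hi = np.log(1.0 / t_hi_b) - 5.0, np.log(1.0 / t_lo_b) + 5.0

    def decode(theta: np.ndarray):
        lam = -np.exp(np.clip(theta[:3], z_lo, z_hi))
        A1 = 1.0 / (1.0 + np.exp(-np.clip(theta[3], -500.0, 500.0)))
        denom = lam[1] - lam[2]
        if abs(denom) < 1e-14:
            return None
        A2 = -(lam[2] + A1 * (lam[0] - lam[2])) / denom
        A = np.array([A1, A2, 1.0 - A1 - A2])
        return A, lam

    def fun(theta: np.ndarray) -> float:
        dec = decode(theta)
        if dec is None:
            return np.inf
        A, lam = dec
        S = np.exp(t[:, None] * lam) @ A
        if np.any(S <= 0):
            return np.inf
        lin = np.mean((S - S_e) ** 2)
        log = np.mean((np.log(S) - log_Se) ** 2)
        return alpha * lin + (1.0 - alpha) * log

    rng = np.random.default_rng(config.seed)
    t_lo = max(t.min(), 1e-6)
    t_hi = max(t.max(), t_lo * 10)
    log_rate_lo, log_rate_hi = np.log(1.0 / t_hi), np.log(1.0 / t_lo)
    solutions: List[Tuple[MultiExpParams, float]] = []
    for s in range(config.n_starts):
        if s == 0:
            z = np.linspace(log_rate_lo, log_rate_hi, 5)[1:-1]
            a1_logit = 0.0
        else:
            z = np.sort(rng.uniform(log_rate_lo, log_rate_hi, size=3))
            a1_logit = float(rng.normal(0.0, 1.0))
        theta0 = np.concatenate([z, [a1_logit]])
        res = optimize.minimize(
            fun,
            theta0,
            method="Nelder-Mead",
            options={
                "maxiter": config.maxiter,
                "xatol": config.xatol,
                "fatol": config.fatol,
                "adaptive": True,
            },
        )
        dec = decode(res.x)
        if dec is None or not np.isfinite(res.fun):
            continue
        A, lam = dec
        if np.any(lam >= 0):
            continue
        order = np.argsort(lam)[::-1]
        try:
            params = MultiExpParams(tuple(A[order]), tuple(_separate(lam[order])))
        except ValueError:
            continue
        solutions.append((params, float(res.fun)))
    if not solutions:
        raise RuntimeError("constrained obligatory-pause fit failed on all starts")
    solutions = _dedupe(solutions)
    best, best_obj = solutions[0]
    fit = MultiExpFit(
        best=best,
        objective=best_obj,
        suboptimal=tuple(solutions),
        accepted=accept_fit_params(best, surv, config.ks_cutoff),
        constrained=True,
    )
    return replace(fit, error_intervals=error_intervals(fit, config.overflow_ratio))


def modified_ks_test(
    wt: WaitingTimeSet,
    params: MultiExpParams,
    cutoff: float = 10.0,
) -> float:
    """One-sided one-sample Kolmogorov-Smirnov p-value of the observed
    waiting times beyond the cutoff against the fitted law truncated at
    the cutoff and renormalized.

    Short intervals are excluded because small absolute errors at the
    high-probability short times would dominate the KS statistic for
    every model; the discriminating structure lives in the tail.  The
    one-sided statistic is D- = sup_t (F_fit - F_emp): it detects data
    with a heavier tail than the fit, the direction in which a missing
    promoter state manifests.
    """
    x = wt.observed()
    x = x[x > cutoff]
    if x.size < 30:
        raise ValueError(f"need at least 30 observed waiting times above the cutoff, got {x.size}")
    S_c = float(params.survival(np.asarray(cutoff)))
    if S_c <= 0:
        raise ValueError("fitted survival vanishes at the cutoff")

    def cdf(v):
        return 1.0 - params.survival(np.asarray(v, dtype=float)) / S_c

    res = stats.ks_1samp(x, cdf, alternative="less")
    return float(res.pvalue)


def error_intervals(fit: MultiExpFit, overflow_ratio: float = 2.0) -> dict:
    """Per-parameter (min, max) over all retained solutions whose
    objective is at most overflow_ratio times the best objective.

    Parameters are matched across solutions by their descending-exponent
    order; a lone solution yields degenerate (point) intervals.
    """
    if not fit.suboptimal:
        raise ValueError("no retained solutions")
    limit = overflow_ratio * fit.objective
    kept = [p for p, o in fit.suboptimal if o <= limit or np.isclose(o, limit)]
    if not kept:
        kept = [fit.best]
    N = fit.best.n_exp
    kept = [p for p in kept if p.n_exp == N]
    out = {}
    for i in range(N):
        A_i = [p.amplitudes[i] for p in kept]
        lam_i = [p.exponents[i] for p in kept]
        out[f"A{i + 1}"] = (float(min(A_i)), float(max(A_i)))
        out[f"lambda{i + 1}"] = (float(min(lam_i)), float(max(lam_i)))
    return out


class MultiExponentialSurvival(BaseEstimator):
    """Sklearn-style estimator: waiting times in, promoter-state count
    and multiexponential survival parameters out.

    Parameters
    ----------
    n_components : int or "auto"
        Number of exponentials; "auto" selects the smallest accepted N
        starting from 2 (parsimony).
    alpha : float
        Linear-vs-log weight of the objective (default 0.6).
    n_starts : int
        Multi-start count of the local optimizer.
    ks_cutoff : float
        Time cutoff (s) of the acceptance check and modified KS test.
    overflow_ratio : float
        Suboptimal-solution filter for error intervals.
    constrained : bool
        Fit on the obligatory-pause manifold (forces n_components=3).
    random_state : int
        Seed of the multi-start draw.

    Attributes
    ----------
    fit_ : MultiExpFit
    params_ : MultiExpParams
    n_components_ : int
    accepted_ : bool
    error_intervals_ : dict
    ks_p_ : float or None (set when raw waiting times were supplied)
    survival_ : SurvivalEstimate (the Kaplan-Meier input)
    """

    def __init__(
        self,
        n_components="auto",
        alpha: float = 0.6,
        n_starts: int = 30,
        ks_cutoff: float = 10.0,
        overflow_ratio: float = 2.0,
        n_max: int = 4,
        constrained: bool = False,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.alpha = alpha
        self.n_starts = n_starts
        self.ks_cutoff = ks_cutoff
        self.overflow_ratio = overflow_ratio
        self.n_max = n_max
        self.constrained = constrained
        self.random_state = random_state

    def _config(self) -> FitConfig:
        return FitConfig(
            alpha=self.alpha,
            n_starts=self.n_starts,
            ks_cutoff=self.ks_cutoff,
            overflow_ratio=self.overflow_ratio,
            n_max=self.n_max,
            seed=self.random_state,
        )

    def fit(self, X, event_observed=None):
        """Fit from raw waiting times.

        Parameters
        ----------
        X : array-like of shape (n,) or WaitingTimeSet
            Waiting times in seconds.
        event_observed : array-like of bool, optional
            True where the interval was observed (False = right-censored).
            Ignored when X is a WaitingTimeSet.
        """
        if isinstance(X, WaitingTimeSet):
            wt = X
        else:
            X = np.asarray(X, dtype=float).ravel()
            if event_observed is None:
                event_observed = np.ones(X.size, dtype=bool)
            wt = WaitingTimeSet(X, ~np.asarray(event_observed, dtype=bool))
        surv = km_survival(wt)
        self.fit_from_survival(surv)
        try:
            self.ks_p_ = modified_ks_test(wt, self.params_, self.ks_cutoff)
        except ValueError:
            self.ks_p_ = None
        self.fit_ = replace(self.fit_, ks_p=self.ks_p_)
        return self

    def fit_from_survival(self, surv: SurvivalEstimate):
        """Fit from a precomputed Kaplan-Meier survival estimate."""
        config = self._config()
        if self.constrained:
            fit = fit_constrained_obligatory(surv, config)
        elif self.n_components == "auto":
            fit = select_num_states(surv, config)
        else:
            fit = fit_multiexp(surv, int(self.n_components), config)
        self.survival_ = surv
        self.fit_ = fit
        self.params_ = fit.best
        self.n_components_ = fit.best.n_exp
        self.accepted_ = fit.accepted
        self.error_intervals_ = fit.error_intervals
        self.objective_ = fit.objective
        self.ks_p_ = None
        return self

    def predict_survival(self, times) -> np.ndarray:
        """Parametric survival S(t) at the given times."""
        return self.params_.survival(np.asarray(times, dtype=float))
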