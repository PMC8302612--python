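"""Waiting-time extraction and nonparametric survival estimation.

From the deconvolved event train of each nucleus, the analysis window is
restricted to the stable part of the signal (frames above 1/5 of the
trace maximum), inter-initiation waiting times are collected across all
nuclei of a genotype, and their survival function is estimated by the
Kaplan-Meier product-limit method with Greenwood 95% bands.  The final
interval of each train (last event to window end) is right-censored by
default, so long waiting times are not silently discarded.

Trace-level summary statistics (integral amplitude, cumulative
activation and t50) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .models import InitiationEventTrain
from .signal import FluorescenceTrace

__all__ = [
    "WaitingTimeSet",
    "SurvivalEstimate",
    "window_trace",
    "extract_waiting_times",
    "pool_genotype",
    "km_survival",
    "integral_amplitude",
    "activation_stats",
]


@dataclass(frozen=True)
class WaitingTimeSet:
    """Observed (and right-censored) inter-initiation intervals, pooled
    over the nuclei of one genotype."""

    values: np.ndarray
    censored: np.ndarray
    genotype: str = ""
    nucleus_ids: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        c = np.asarray(self.censored, dtype=bool)
        if v.shape != c.shape or v.ndim != 1:
            raise ValueError("values and censored flags must be 1-d and of equal length")
        if np.any(v <= 0):
            raise ValueError("waiting times must be positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "censored", c)

    @property
    def n_observed(self) -> int:
        return int((~self.censored).sum())

    def observed(self) -> np.ndarray:
        return self.values[~self.censored]

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.nucleus_ids) if len(self.nucleus_ids) == self.values.size else [None] * self.values.size
        return pd.DataFrame(
            {
                "delta_t_s": self.values,
                "censored": self.censored,
                "genotype": self.genotype,
                "nucleus_id": ids,
            }
        )


@dataclass(frozen=True)
class SurvivalEstimate:
    """Kaplan-Meier estimate with pointwise Greenwood 95% bounds."""

    times: np.ndarray
    S: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    n_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "S": self.S,
                "lo": self.ci_lower,
                "hi": self.ci_upper,
                "n_risk": self.n_at_risk,
            }
        )


def window_trace(trace: FluorescenceTrace) -> Optional[Tuple[float, float]]:
    """Stable-signal window of a trace: first and last frame with
    intensity at or above 1/5 of the trace maximum.

    Returns None for an all-zero trace (nothing to analyze).
    """
    y = trace.intensities
    if y.size == 0 or np.all(y <= 0):
        return None
    thr = y.max() / 5.0
    above = np.flatnonzero(y >= thr)
    return float(trace.frame_times[above[0]]), float(trace.frame_times[above[-1]])


def extract_waiting_times(
    train: InitiationEventTrain,
    window: Tuple[float, float],
    censor_final: bool = True,
    genotype: str = "",
) -> WaitingTimeSet:
    """Inter-event intervals of one train inside the analysis window.

    Differences between consecutive events are observed values; the
    final interval from the last event to the window end is appended as
    right-censored when ``censor_final`` is true.  The interval from the
    window start to the first event is not a renewal interval from a
    known event and is discarded.
    """
    t0, t1 = window
    if t1 < t0:
        raise ValueError("invalid window")
    ev = train.event_times
    ev = ev[(ev >= t0) & (ev <= t1)]
    obs = np.diff(ev)
    obs = obs[obs > 0]
    vals = [obs]
    cens = [np.zeros(obs.size, dtype=bool)]
    if censor_final and ev.size and t1 - ev[-1] > 0:
        vals.append(np.array([t1 - ev[-1]]))
        cens.append(np.array([True]))
    values = np.concatenate(vals) if vals else np.empty(0)
    censored = np.concatenate(cens) if cens else np.empty(0, bool)
    ids = tuple([train.nucleus_id] * values.size)
    return WaitingTimeSet(values, censored, genotype=genotype, nucleus_ids=ids)


def pool_genotype(sets: Iterable[WaitingTimeSet]) -> WaitingTimeSet:
    """Concatenate waiting-time sets of the same genotype, preserving
    censoring flags and nucleus provenance."""
    sets = list(sets)
    if not sets:
        return WaitingTimeSet(np.empty(0), np.empty(0, bool))
    genotypes = {s.genotype for s in sets}
    if len(genotypes) > 1:
        raise ValueError(f"cannot pool mixed genotypes: {sorted(genotypes)}")
    return WaitingTimeSet(
        np.concatenate([s.values for s in sets]),
        np.concatenate([s.censored for s in sets]),
        genotype=sets[0].genotype,
        nucleus_ids=tuple(i for s in sets for i in s.nucleus_ids),
    )


def km_survival(wt: WaitingTimeSet, ci_transform: str = "plain") -> SurvivalEstimate:
    """Kaplan-Meier product-limit survival of the pooled waiting times.

    The variance is Greenwood's formula; the 95% band is the plain
    normal approximation S +/- 1.96 sqrt(var), clipped to [0, 1]
    (``ci_transform="loglog"`` gives the exponential-Greenwood band
    instead, which never degenerates at S near 0 or 1).
    """
    if wt.n_observed < 1:
        raise ValueError("survival estimation needs at least one observed (uncensored) waiting time")
    kmf = KaplanMeierFitter()
    kmf.fit(wt.values, event_observed=~wt.censored)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    S = kmf.survival_function_at_times(times).to_numpy()
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
    var = S**2 * np.cumsum(terms)
    var = np.where(np.isfinite(var), var, 0.0)
    z = stats.norm.ppf(0.975)
    if ci_transform == "plain":
        lo = np.clip(S - z * np.sqrt(var), 0.0, 1.0)
        hi = np.clip(S + z * np.sqrt(var), 0.0, 1.0)
    elif ci_transform == "loglog":
        ci = kmf.confidence_interval_survival_function_
        grid = ci.index.to_numpy(dtype=float)
        lo = np.interp(times, grid, ci.iloc[:, 0].to_numpy())
        hi = np.interp(times, grid, ci.iloc[:, 1].to_numpy())
    else:
        raise ValueError("ci_transform must be 'plain' or 'loglog'")
    return SurvivalEstimate(
        times=times,
        S=S,
        ci_lower=lo,
        ci_upper=hi,
        n_at_risk=n,
        n_events=int(d.sum()),
    )


def integral_amplitude(trace: FluorescenceTrace, t_max: float = 1800.0) -> float:
    """Area under the intensity curve over the first ``t_max`` seconds
    (trapezoidal rule); a proxy for the nucleus's total mRNA output."""
    if trace.frame_times.size == 0:
        raise ValueError("empty trace")
    mask = trace.frame_times <= trace.frame_times[0] + t_max
    t = trace.frame_times[mask]
    y = trace.intensities[mask]
    if t.size < 2:
        return 0.0
    return float(np.trapezoid(y, t))


def activation_stats(
    onsets: Sequence[Optional[float]],
    n_total: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray, Optional[float]]:
    """Cumulative activation curve and t50 of a cohort.

    Parameters
    ----------
    onsets : sequence of float or None
        First-activation time per nucleus; None for nuclei that never
        activate.
    n_total : int, optional
        Cohort size (defaults to len(onsets)).

    Returns
    -------
    times, fraction : ndarray
        Step-function support and cumulative fraction of active nuclei.
    t50 : float or None
        First time at which the fraction reaches 0.5; None if it never
        does.
    """
    onsets = list(onsets)
    if n_total is None:
        n_total = len(onsets)
    if n_total == 0:
        raise ValueError("n_total must be positive")
    active = np.sort(np.asarray([o for o in onsets if o is not None], dtype=float))
    fraction = np.arange(1, active.size + 1) / n_total
    t50 = None
    reached = np.flatnonzero(fraction >= 0.5)
    if reached.size:
        t50 = float(active[reached[0]])
    return active, fraction, t50
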