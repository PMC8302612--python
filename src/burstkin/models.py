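"""Promoter-state Markov models and their inter-initiation waiting-time law.

A promoter is modelled as a continuous-time Markov chain over the states
(OFF, ON) or (OFF, ON, PAUSE); RNA polymerase II initiation events are
emitted as a Poisson process of rate ``k_ini`` while the promoter occupies
ON.  The interval between two successive initiation events is then
distributed as the first-passage law of a Markov-modulated Poisson process
started in ON, whose survival function is a sum of ``n_states``
exponentials.  This module provides the exact forward map from kinetic
rates to that multiexponential law, a Gillespie simulator of event trains,
and the steady-state quantities (state durations/probabilities, burst
size) derived from the rates.

State ordering is fixed throughout as (OFF, ON) and (OFF, ON, PAUSE); the
3-state topology is the non-obligatory pause model: OFF <-> ON <-> PAUSE,
with no direct OFF <-> PAUSE transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PromoterModel",
    "MultiExpParams",
    "InitiationEventTrain",
    "DerivedKinetics",
    "DegenerateEigenvaluesError",
    "build_model",
    "forward_distribution",
    "simulate_event_train",
    "derived_kinetics",
]

#: index of the states in every generator matrix
STATE_ORDER_2 = ("OFF", "ON")
STATE_ORDER_3 = ("OFF", "ON", "PAUSE")

#: relative eigenvalue-gap threshold below which the spectral (distinct
#: eigenvalue) decomposition of the waiting-time law is refused
DEGENERACY_RTOL = 1e-10


class DegenerateEigenvaluesError(ValueError):
    """Raised when the waiting-time generator has (numerically) repeated
    eigenvalues, so the distinct-exponential decomposition does not exist.

    Perturb the rates slightly, or — if the repeated timescales are the
    object of interest — use the mixed-gamma (equal-timescale) limit in
    :mod:`burstkin.gaps`.
    """


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0.0:
        raise ValueError(f"rate {name!r} must be strictly positive and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class PromoterModel:
    """A 2- or 3-state promoter with initiation from the ON state.

    Parameters
    ----------
    n_states : int
        2 (telegraph, OFF <-> ON) or 3 (non-obligatory pause,
        OFF <-> ON <-> PAUSE).
    k1_plus, k1_minus : float
        OFF -> ON and ON -> OFF switching rates, 1/s.
    k_ini : float
        Initiation rate while ON, 1/s.
    k2_plus, k2_minus : float, optional
        PAUSE -> ON and ON -> PAUSE rates, 1/s; 3-state only.
    """

    n_states: int
    k1_plus: float
    k1_minus: float
    k_ini: float
    k2_plus: Optional[float] = None
    k2_minus: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_states not in (2, 3):
            raise ValueError(f"n_states must be 2 or 3, got {self.n_states}")
        _require_positive("k1_plus", self.k1_plus)
        _require_positive("k1_minus", self.k1_minus)
        _require_positive("k_ini", self.k_ini)
        if self.n_states == 2:
            if self.k2_plus is not None or self.k2_minus is not None:
                raise ValueError("pause rates k2_plus/k2_minus are not allowed for a 2-state model")
        else:
            if self.k2_plus is None or self.k2_minus is None:
                raise ValueError("a 3-state model requires both k2_plus and k2_minus")
            _require_positive("k2_plus", self.k2_plus)
            _require_positive("k2_minus", self.k2_minus)

    @property
    def state_names(self) -> tuple:
        return STATE_ORDER_2 if self.n_states == 2 else STATE_ORDER_3

    @property
    def on_index(self) -> int:
        return 1

    def generator(self) -> np.ndarray:
        """Generator matrix Q with rows summing to zero, states in
        :attr:`state_names` order (Q[i, j] is the i -> j rate)."""
        if self.n_states == 2:
            return np.array(
                [
                    [-self.k1_plus, self.k1_plus],
                    [self.k1_minus, -self.k1_minus],
                ]
            )
        return np.array(
            [
                [-self.k1_plus, self.k1_plus, 0.0],
                [self.k1_minus, -(self.k1_minus + self.k2_minus), self.k2_minus],
                [0.0, self.k2_plus, -self.k2_plus],
            ]
        )

    def initiation_rates(self) -> np.ndarray:
        """Per-state initiation-rate vector (non-zero only at ON)."""
        r = np.zeros(self.n_states)
        r[self.on_index] = self.k_ini
        return r

    def to_dict(self) -> dict:
        d = {
            "n_states": self.n_states,
            "k1_plus": self.k1_plus,
            "k1_minus": self.k1_minus,
            "k_ini": self.k_ini,
        }
        if self.n_states == 3:
            d["k2_plus"] = self.k2_plus
            d["k2_minus"] = self.k2_minus
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PromoterModel":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


def build_model(
    k1_plus: float,
    k1_minus: float,
    k_ini: float,
    k2_plus: Optional[float] = None,
    k2_minus: Optional[float] = None,
) -> PromoterModel:
    """Validate a named rate set and return the corresponding model.

    The number of states is inferred: passing either pause rate makes the
    model 3-state (then both are required).
    """
    n_states = 2 if (k2_plus is None and k2_minus is None) else 3
    return PromoterModel(
        n_states=n_states,
        k1_plus=k1_plus,
        k1_minus=k1_minus,
        k_ini=k_ini,
        k2_plus=k2_plus,
        k2_minus=k2_minus,
    )


@dataclass(frozen=True)
class MultiExpParams:
    """Amplitudes and exponents of a multiexponential survival function
    S(t) = sum_i A_i exp(lambda_i t), with sum A_i = 1 and lambda_i < 0.

    Exponents are sorted descending (lambda_1 closest to zero), so the
    dominant — slowest — timescale comes first.
    """

    amplitudes: tuple
    exponents: tuple

    def __post_init__(self) -> None:
        A = np.asarray(self.amplitudes, dtype=float)
        lam = np.asarray(self.exponents, dtype=float)
        if A.shape != lam.shape or A.ndim != 1 or A.size == 0:
            raise ValueError("amplitudes and exponents must be 1-d and of equal length")
        if not np.isclose(A.sum(), 1.0, atol=1e-9):
            raise ValueError(f"amplitudes must sum to 1, got {A.sum()!r}")
        if np.any(lam >= 0) or not np.all(np.isfinite(lam)):
            raise ValueError("exponents must be negative and finite")
        order = np.argsort(lam)[::-1]
        object.__setattr__(self, "amplitudes", tuple(A[order]))
        object.__setattr__(self, "exponents", tuple(lam[order]))

    @property
    def n_exp(self) -> int:
        return len(self.amplitudes)

    def survival(self, t) -> np.ndarray:
        """Evaluate S(t) on scalar or array t >= 0."""
        t = np.asarray(t, dtype=float)
        A = np.asarray(self.amplitudes)
        lam = np.asarray(self.exponents)
        return np.exp(t[..., None] * lam) @ A

    def density(self, t) -> np.ndarray:
        """Probability density -dS/dt."""
        t = np.asarray(t, dtype=float)
        A = np.asarray(self.amplitudes)
        lam = np.asarray(self.exponents)
        return -(np.exp(t[..., None] * lam) @ (A * lam))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n waiting times, valid when all amplitudes are nonnegative
        (the law is then a plain mixture of exponentials)."""
        A = np.asarray(self.amplitudes)
        if np.any(A < -1e-12):
            raise ValueError("direct mixture sampling requires nonnegative amplitudes")
        A = np.clip(A, 0.0, None)
        A = A / A.sum()
        comp = rng.choice(self.n_exp, size=n, p=A)
        scale = -1.0 / np.asarray(self.exponents)
        return rng.exponential(scale[comp])


@dataclass(frozen=True)
class InitiationEventTrain:
    """Sorted Pol II initiation times for one nucleus, seconds from the
    window start."""

    nucleus_id: object
    event_times: np.ndarray
    window: tuple

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", t)
        t0, t1 = self.window
        if t1 < t0:
            raise ValueError("window end precedes window start")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("event times must be strictly increasing")
            if t[0] < t0 or t[-1] > t1:
                raise ValueError("event times must lie within the window")

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)


@dataclass(frozen=True)
class DerivedKinetics:
    """Steady-state quantities of a promoter model: mean state durations
    (s), occupancy probabilities, and — for the 2-state model — the burst
    size k_ini / k1_minus (transcripts per ON period)."""

    n_states: int
    T_ON: float
    T_OFF: float
    p_ON: float
    p_OFF: float
    burst_size: Optional[float] = None
    T_PAUSE: Optional[float] = None
    p_PAUSE: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "n_states": self.n_states,
            "T_ON": self.T_ON,
            "T_OFF": self.T_OFF,
            "p_ON": self.p_ON,
            "p_OFF": self.p_OFF,
        }
        if self.burst_size is not None:
            d["burst_size"] = self.burst_size
        if self.n_states == 3:
            d["T_PAUSE"] = self.T_PAUSE
            d["p_PAUSE"] = self.p_PAUSE
        return d


def forward_distribution(model: PromoterModel) -> MultiExpParams:
    """Exact waiting-time law between successive initiation events.

    With Q the state generator and R = diag(initiation rates), the
    interval survival of the Markov-modulated Poisson process started in
    ON (the state just after an event) is

        S(t) = <ON| exp((Q - R) t) |1>,

    a sum of n_states exponentials whose exponents are the eigenvalues of
    M = Q - R.  Amplitudes follow from the spectral decomposition of M.

    Raises
    ------
    DegenerateEigenvaluesError
        If two eigenvalues of M coincide to relative tolerance 1e-10; the
        mixture-of-distinct-exponentials form then does not exist.
    """
    Q = model.generator()
    M = Q - np.diag(model.initiation_rates())
    lam, V = np.linalg.eig(M)
    # M is similar to a symmetric matrix for these chain topologies, so the
    # spectrum is real; discard numerical imaginary dust.
    if np.max(np.abs(lam.imag)) > 1e-9 * np.max(np.abs(lam.real)):
        raise DegenerateEigenvaluesError(
            "complex eigenvalues encountered; the waiting-time law is not a "
            "real mixture of exponentials for these rates"
        )
    lam = lam.real
    V = V.real
    scale = np.max(np.abs(lam))
    diffs = np.abs(lam[:, None] - lam[None, :])
    np.fill_diagonal(diffs, np.inf)
    if diffs.min() < DEGENERACY_RTOL * scale:
        raise DegenerateEigenvaluesError(
            "repeated eigenvalues of Q - R; perturb the rates or use the "
            "equal-timescale mixed-gamma limit (burstkin.gaps)"
        )
    W = np.linalg.inv(V)
    e_on = np.zeros(model.n_states)
    e_on[model.on_index] = 1.0
    ones = np.ones(model.n_states)
    # S(t) = sum_i (e_on . v_i)(w_i . 1) e^{lam_i t}
    amplitudes = (e_on @ V) * (W @ ones)
    return MultiExpParams(amplitudes=tuple(amplitudes), exponents=tuple(lam))


def simulate_event_train(
    model: PromoterModel,
    duration: float,
    seed,
    nucleus_id: object = 0,
    t_start: float = 0.0,
    initial_state: Optional[int] = None,
) -> InitiationEventTrain:
    """Gillespie simulation of the promoter chain over ``duration`` seconds.

    Dwell times are exponential per state; while ON, initiation events are
    emitted as a Poisson process of rate ``k_ini`` (initiation does not
    reset the promoter state).  The chain starts from its stationary
    distribution unless ``initial_state`` is given.

    Parameters
    ----------
    seed : int or numpy.random.Generator
        Source of randomness; a fixed integer gives identical trains.
    """
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    window = (t_start, t_start + duration)
    if duration == 0:
        return InitiationEventTrain(nucleus_id, np.empty(0), window)

    Q = model.generator()
    n = model.n_states
    exit_rates = -np.diag(Q)
    jump_probs = [np.clip(Q[i], 0.0, None) / exit_rates[i] for i in range(n)]
    if initial_state is None:
        state = int(rng.choice(n, p=stationary_distribution(model)))
    else:
        state = int(initial_state)

    t = 0.0
    events = []
    on = model.on_index
    k_ini = model.k_ini
    while t < duration:
        dwell = rng.exponential(1.0 / exit_rates[state])
        t_next = min(t + dwell, duration)
        if state == on:
            # Poisson events during the ON dwell, truncated at the window end
            n_ev = rng.poisson(k_ini * (t_next - t))
            if n_ev:
                events.append(t + (t_next - t) * np.sort(rng.random(n_ev)))
        t = t + dwell
        if t < duration:
            state = int(rng.choice(n, p=jump_probs[state]))
    times = np.concatenate(events) if events else np.empty(0)
    # strictly increasing: drop ties at float resolution (vanishingly rare)
    times = np.unique(times)
    return InitiationEventTrain(nucleus_id, times + t_start, window)


def stationary_distribution(model: PromoterModel) -> np.ndarray:
    """Steady-state occupancy of the promoter chain (ignores initiation,
    which does not change the state)."""
    Q = model.generator()
    n = model.n_states
    a = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


def derived_kinetics(model: PromoterModel) -> DerivedKinetics:
    """Mean state durations, occupancy probabilities and burst size.

    For the telegraph model: T_OFF = 1/k1+, T_ON = 1/k1-,
    p_ON = k1+/(k1+ + k1-), burst size = k_ini/k1-.  For the 3-state
    model the ON state exits at total rate k1- + k2-, and occupancies
    follow from the cyclic balance of the OFF <-> ON <-> PAUSE chain.
    """
    if model.n_states == 2:
        p_on = model.k1_plus / (model.k1_plus + model.k1_minus)
        return DerivedKinetics(
            n_states=2,
            T_ON=1.0 / model.k1_minus,
            T_OFF=1.0 / model.k1_plus,
            p_ON=p_on,
            p_OFF=1.0 - p_on,
            burst_size=model.k_ini / model.k1_minus,
        )
    k1p, k1m = model.k1_plus, model.k1_minus
    k2p, k2m = model.k2_plus, model.k2_minus
    denom = k1p * k2p + k1m * k2p + k1p * k2m
    return DerivedKinetics(
        n_states=3,
        T_ON=1.0 / (k1m + k2m),
        T_OFF=1.0 / k1p,
        T_PAUSE=1.0 / k2p,
        p_OFF=k1m * k2p / denom,
        p_PAUSE=k1p * k2m / denom,
        p_ON=k1p * k2p / denom,
    )
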