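"""Closed-form reverse engineering of promoter rates from fitted
multiexponential waiting-time parameters.

The 2N-1 distribution parameters (amplitudes and exponents of the
N-exponential survival) determine the 2N-1 kinetic rates of the N-state
promoter model uniquely (within a well-posedness domain).  Writing
amplitude-weighted power sums S_k = sum_i A_i lambda_i^k and plain power
sums L_k = sum_i lambda_i^k, the telegraph model inverts as

    k_ini = -S1,   k1- = S1 - S2/S1,   k1+ = (S3 S1 - S2^2) / (S1 (S1^2 - S2)),

and the 3-state non-obligatory pause model inverts through the
discriminant D = (S1 L1 - S2)^2 - 4 L3 S1, with the two square-root
branches assigning the OFF and PAUSE labels.  Outputs are canonicalized
so that PAUSE is the longer-lived inactive state (T_PAUSE >= T_OFF);
amplitudes are label-symmetric, so the labelling is a convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .models import DerivedKinetics, MultiExpParams, PromoterModel, derived_kinetics
from .regression import MultiExpFit

__all__ = [
    "MomentSums",
    "KineticRates",
    "KineticsReport",
    "moment_sums",
    "invert_two_state",
    "invert_three_state",
    "invert",
    "kinetics_report",
]

#: relative tolerance below which a denominator/discriminant is treated
#: as zero and the inversion flagged ill-posed
ILL_POSED_RTOL = 1e-12


@dataclass(frozen=True)
class MomentSums:
    """Power sums of the multiexponential parameters: S_k amplitude
    weighted, L_k plain (L_k only used by the 3-state inversion)."""

    S1: float
    S2: float
    S3: float
    L1: Optional[float] = None
    L2: Optional[float] = None
    L3: Optional[float] = None


@dataclass(frozen=True)
class KineticRates:
    """Inverted promoter switching rates with a validity flag.

    ``valid`` is False when the distribution parameters fall outside the
    model's well-posedness domain (nonpositive rate, vanishing
    denominator or negative discriminant); ``reason`` then says why.
    """

    n_states: int
    k1_plus: float
    k1_minus: float
    k_ini: float
    k2_plus: Optional[float] = None
    k2_minus: Optional[float] = None
    valid: bool = True
    reason: str = ""

    def to_model(self) -> PromoterModel:
        if not self.valid:
            raise ValueError(f"rates are not valid: {self.reason}")
        return PromoterModel(
            n_states=self.n_states,
            k1_plus=self.k1_plus,
            k1_minus=self.k1_minus,
            k_ini=self.k_ini,
            k2_plus=self.k2_plus,
            k2_minus=self.k2_minus,
        )

    def to_dict(self) -> dict:
        d = {
            "n_states": self.n_states,
            "k1_plus": self.k1_plus,
            "k1_minus": self.k1_minus,
            "k_ini": self.k_ini,
            "valid": bool(self.valid),
        }
        if self.n_states == 3:
            d["k2_plus"] = self.k2_plus
            d["k2_minus"] = self.k2_minus
        if not self.valid:
            d["reason"] = self.reason
        return d


def moment_sums(params: MultiExpParams) -> MomentSums:
    """Exact power sums of amplitudes and exponents."""
    A = np.asarray(params.amplitudes)
    lam = np.asarray(params.exponents)
    S = [float(A @ lam**k) for k in (1, 2, 3)]
    if params.n_exp == 3:
        L = [float(np.sum(lam**k)) for k in (1, 2, 3)]
        return MomentSums(*S, *L)
    return MomentSums(*S)


def _invalid(n_states: int, reason: str) -> KineticRates:
    return KineticRates(
        n_states=n_states,
        k1_plus=np.nan,
        k1_minus=np.nan,
        k_ini=np.nan,
        k2_plus=np.nan if n_states == 3 else None,
        k2_minus=np.nan if n_states == 3 else None,
        valid=False,
        reason=reason,
    )


def invert_two_state(params: MultiExpParams) -> KineticRates:
    """Telegraph-model rates from biexponential survival parameters."""
    if params.n_exp != 2:
        raise ValueError("two-state inversion requires exactly 2 exponentials")
    m = moment_sums(params)
    scale = abs(m.S1) + abs(m.S2)
    if abs(m.S1) < ILL_POSED_RTOL * scale:
        return _invalid(2, "ill-posed: S1 ~ 0")
    denom = m.S1 * (m.S1**2 - m.S2)
    if abs(denom) < ILL_POSED_RTOL * max(abs(m.S1) ** 3, abs(m.S1 * m.S2)):
        return _invalid(2, "ill-posed: vanishing denominator S1 (S1^2 - S2)")
    k_ini = -m.S1
    k1_minus = m.S1 - m.S2 / m.S1
    k1_plus = (m.S3 * m.S1 - m.S2**2) / denom
    rates = KineticRates(2, k1_plus, k1_minus, k_ini)
    if min(k_ini, k1_minus, k1_plus) <= 0 or not np.isfinite([k_ini, k1_minus, k1_plus]).all():
        return _invalid(2, f"nonpositive rate: k_ini={k_ini:.3g}, k1-={k1_minus:.3g}, k1+={k1_plus:.3g}")
    return rates


def invert_three_state(params: MultiExpParams) -> KineticRates:
    """Non-obligatory-pause rates from triexponential survival parameters.

    The two square-root branches are assigned so that the returned
    k2_plus <= k1_plus, i.e. PAUSE is the longer-lived inactive state.
    """
    if params.n_exp != 3:
        raise ValueError("three-state inversion requires exactly 3 exponentials")
    # extended precision: the discriminant and branch expressions suffer
    # catastrophic cancellation in float64 when the two inactive-state
    # exit rates are close
    A = np.asarray(params.amplitudes, dtype=np.longdouble)
    lam = np.asarray(params.exponents, dtype=np.longdouble)
    S1, S2, S3 = A @ lam, A @ lam**2, A @ lam**3
    L1, L2, L3 = lam.sum(), (lam**2).sum(), (lam**3).sum()
    if abs(S1) < ILL_POSED_RTOL * (abs(S1) + abs(S2)):
        return _invalid(3, "ill-posed: S1 ~ 0")
    # characteristic-polynomial coefficients of the exponent set, from
    # the power sums via Newton's identities: the inversion lives on the
    # elementary symmetric functions e_k, not the power sums themselves
    e1 = L1
    e2 = (L1**2 - L2) / 2.0
    e3 = (L1**3 - 3.0 * L1 * L2 + 2.0 * L3) / 6.0
    disc = (S1 * e1 - S2) ** 2 - 4.0 * e3 * S1
    if disc < 0:
        return _invalid(3, f"ill-posed: negative discriminant {disc:.3g}")
    root = np.sqrt(disc)
    if root < ILL_POSED_RTOL * abs(S1 * e1 - S2):
        return _invalid(3, "ill-posed: OFF and PAUSE exit rates coincide (zero discriminant)")
    k_ini = -S1
    # the +/- root branches give the (entry, exit) rate pairs of the two
    # inactive states; S1 < 0 so -root/S1 >= 0 picks the faster exit
    k2_plus = 0.5 * (-e1 + S2 / S1 - root / S1)
    k1_plus = 0.5 * (-e1 + S2 / S1 + root / S1)
    numer = -(S1**2) * e1 + S1 * S2 + S1 * e2 - e3 + S2**2 / S1 - S3
    k2_minus = 0.5 * (S1 - S2 / S1 + numer / root)
    k1_minus = 0.5 * (S1 - S2 / S1 - numer / root)
    k1_plus, k1_minus, k_ini, k2_plus, k2_minus = (
        float(v) for v in (k1_plus, k1_minus, k_ini, k2_plus, k2_minus)
    )
    vals = [k1_plus, k1_minus, k_ini, k2_plus, k2_minus]
    if min(vals) <= 0 or not np.isfinite(vals).all():
        return _invalid(
            3,
            "nonpositive rate: "
            + ", ".join(
                f"{n}={v:.3g}"
                for n, v in zip(["k1+", "k1-", "k_ini", "k2+", "k2-"], vals)
            ),
        )
    # canonical labelling: PAUSE lives longer than OFF
    if 1.0 / k2_plus < 1.0 / k1_plus:
        k1_plus, k2_plus = k2_plus, k1_plus
        k1_minus, k2_minus = k2_minus, k1_minus
    return KineticRates(3, k1_plus, k1_minus, k_ini, k2_plus=k2_plus, k2_minus=k2_minus)


def invert(params: MultiExpParams) -> KineticRates:
    """Dispatch to the inversion matching the number of exponentials."""
    if params.n_exp == 2:
        return invert_two_state(params)
    if params.n_exp == 3:
        return invert_three_state(params)
    raise ValueError(f"no closed-form inversion for N={params.n_exp}")


@dataclass(frozen=True)
class KineticsReport:
    """Final inference product: best-fit rates, derived steady-state
    quantities, and min/max intervals over near-optimal solutions."""

    rates: KineticRates
    derived: Optional[DerivedKinetics]
    rate_intervals: Dict[str, Tuple[float, float]]
    derived_intervals: Dict[str, Tuple[float, float]]
    n_solutions_used: int
    flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "model": f"{self.rates.n_states}state",
            "rates": self.rates.to_dict(),
            "derived": self.derived.to_dict() if self.derived else None,
            "rate_intervals": {k: list(v) for k, v in self.rate_intervals.items()},
            "derived_intervals": {k: list(v) for k, v in self.derived_intervals.items()},
            "n_solutions_used": self.n_solutions_used,
            "flagged": self.flagged,
        }


def kinetics_report(fit: MultiExpFit, overflow_ratio: float = 2.0) -> KineticsReport:
    """Invert the best fit and every near-optimal solution, reporting
    per-rate and per-derived-quantity min/max envelopes (the error bars:
    smallest and largest values among optimal and close-to-optimal
    solutions)."""
    best_rates = invert(fit.best)
    limit = overflow_ratio * fit.objective
    pool = [p for p, o in fit.suboptimal if o <= limit or np.isclose(o, limit)]
    inverted = [r for r in (invert(p) for p in pool if p.n_exp == fit.best.n_exp) if r.valid]
    flagged = not best_rates.valid
    if flagged and not inverted:
        return KineticsReport(best_rates, None, {}, {}, 0, flagged=True)
    use = inverted if inverted else [best_rates]
    rate_names = ["k1_plus", "k1_minus", "k_ini"] + (
        ["k2_plus", "k2_minus"] if best_rates.n_states == 3 else []
    )
    rate_intervals = {
        name: (
            float(min(getattr(r, name) for r in use)),
            float(max(getattr(r, name) for r in use)),
        )
        for name in rate_names
    }
    derived_all = [derived_kinetics(r.to_model()).to_dict() for r in use]
    derived_keys = [k for k in derived_all[0] if k != "n_states"]
    derived_intervals = {
        k: (float(min(d[k] for d in derived_all)), float(max(d[k] for d in derived_all)))
        for k in derived_keys
    }
    derived_best = derived_kinetics(best_rates.to_model()) if best_rates.valid else derived_kinetics(use[0].to_model())
    return KineticsReport(
        rates=best_rates,
        derived=derived_best,
        rate_intervals=rate_intervals,
        derived_intervals=derived_intervals,
        n_solutions_used=len(use),
        flagged=flagged,
    )
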