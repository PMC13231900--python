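"""One-compartment IV-infusion model with allometric and maturation covariates.

The structural model for a neonate with body weight ``WT`` (kg) and
postmenstrual age ``PMA`` (weeks) is

    CL = TVCL * (WT/70)^0.75 * PMA^H / (PMA^H + TM50^H) * exp(eta_CL)
    V  = TVV  * (WT/70)                                 * exp(eta_V)

with the allometric exponents fixed a priori at 0.75 (clearance) and 1
(volume), and the renal-maturation sigmoid fixed at TM50 = 47.7 weeks,
Hill = 3.4 (glomerular-filtration maturation values from the literature;
sparse neonatal data cannot estimate them).  Random effects eta are
normal with variances omega2; the residual error is log-additive.

Concentration-time profiles are the closed-form superposition of
constant-rate infusion segments: with elimination rate constant
k = CL/V and a dose infused at rate R starting at t0 for duration d,

    C(t) = (R/CL) * (1 - exp(-k (t-t0)))                          t0 < t <= t0+d
    C(t) = (R/CL) * (1 - exp(-k d)) * exp(-k (t-t0-d))            t  > t0+d

and doses superpose by linearity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Covariates

__all__ = [
    "REFERENCE_WT",
    "ALLOMETRIC_EXP_CL",
    "ALLOMETRIC_EXP_V",
    "PopModelParams",
    "IndividualParams",
    "Regimen",
    "maturation_fraction",
    "individual_clearance",
    "individual_volume",
    "concentration",
    "steady_state_window",
]

#: Allometric reference body weight, kg.
REFERENCE_WT = 70.0
ALLOMETRIC_EXP_CL = 0.75
ALLOMETRIC_EXP_V = 1.0


@dataclass(frozen=True)
class PopModelParams:
    """Population (typical) parameters and variance components.

    ``tvcl`` is clearance in L/h for a fully matured 70-kg reference;
    ``tvv`` the volume in L/70 kg.  ``tm50`` (weeks) and ``hill`` are the
    maturation parameters, fixed by design and never estimated.
    ``omega2_cl``/``omega2_v`` are variances of the log-normal
    interindividual random effects; ``sigma2`` the variance of the
    log-domain residual.
    """

    tvcl: float
    tvv: float
    omega2_cl: float
    omega2_v: float
    sigma2: float
    tm50: float = 47.7
    hill: float = 3.4
    fixed: tuple[str, ...] = ("tm50", "hill")

    def __post_init__(self) -> None:
        for name in ("tvcl", "tvv", "tm50", "hill"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("omega2_cl", "omega2_v", "sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class IndividualParams:
    """Realised clearance (L/h) and volume (L) of one subject."""

    cl: float
    v: float
    eta_cl: float = 0.0
    eta_v: float = 0.0

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v > 0):
            raise ValueError(f"cl and v must be > 0, got cl={self.cl}, v={self.v}")

    @property
    def ke(self) -> float:
        """Elimination rate constant, 1/h."""
        return self.cl / self.v


@dataclass(frozen=True)
class Regimen:
    """A maintenance regimen: ``dose_per_kg`` mg/kg every ``interval`` h."""

    dose_per_kg: float
    interval: float
    infusion_duration: float = 0.5
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.dose_per_kg > 0 and self.interval > 0 and self.infusion_duration > 0):
            raise ValueError("dose_per_kg, interval and infusion_duration must be > 0")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.dose_per_kg:g} mg/kg q{self.interval:g}h"
            )


def maturation_fraction(pma, tm50: float = 47.7, hill: float = 3.4):
    """Sigmoidal maturation of clearance: ``pma^hill / (pma^hill + tm50^hill)``.

    Strictly increasing in PMA, equal to 0.5 at ``pma == tm50`` and
    approaching 1 as PMA grows.  Accepts scalars or arrays.
    """
    pma = np.asarray(pma, dtype=float)
    if np.any(pma <= 0) or tm50 <= 0 or hill <= 0:
        raise ValueError("pma, tm50 and hill must all be > 0")
    # computed on the log scale as a logistic to avoid overflow at large hill
    out = 1.0 / (1.0 + np.exp(hill * (np.log(tm50) - np.log(pma))))
    return out if out.ndim else float(out)


def individual_clearance(params: PopModelParams, cov: Covariates, eta_cl: float = 0.0) -> float:
    """Clearance in L/h: allometric weight scaling x maturation x exp(eta)."""
    mat = maturation_fraction(cov.pma, params.tm50, params.hill)
    return params.tvcl * (cov.wt / REFERENCE_WT) ** ALLOMETRIC_EXP_CL * mat * np.exp(eta_cl)


def individual_volume(params: PopModelParams, cov: Covariates, eta_v: float = 0.0) -> float:
    """Volume of distribution in L: linear in weight x exp(eta)."""
    return params.tvv * (cov.wt / REFERENCE_WT) ** ALLOMETRIC_EXP_V * np.exp(eta_v)


def _conc_profile(t, cl, v, dose_times, dose_rates, dose_durations):
    """Vectorised closed-form concentration for arrays of times.

    ``t`` may be any shape; dose arrays are 1-D. Returns an array of
    ``t``'s shape. ``cl``/``v`` may be scalars or arrays broadcastable
    with ``t``.
    """
    t = np.asarray(t, dtype=float)
    k = cl / v
    total = np.zeros(np.broadcast_shapes(t.shape, np.shape(k)), dtype=float)
    for t0, rate, dur in zip(dose_times, dose_rates, dose_durations):
        dt = t - t0
        during = (dt > 0) & (dt <= dur)
        after = dt > dur
        infusing = np.where(during, (rate / cl) * -np.expm1(-k * np.clip(dt, 0.0, dur)), 0.0)
        done = np.where(
            after,
            (rate / cl) * -np.expm1(-k * dur) * np.exp(-k * np.maximum(dt - dur, 0.0)),
            0.0,
        )
        total = total + infusing + done
    return total


def concentration(t, ind: IndividualParams, doses) -> float | np.ndarray:
    """Blood concentration (mg/L) at time(s) ``t`` under superposed infusions.

    ``t`` is hours since the first dose; may be a scalar or array.
    Times before any dose contribute zero.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("concentration is only defined for t >= 0")
    doses = list(doses)
    out = _conc_profile(
        t_arr,
        ind.cl,
        ind.v,
        np.array([d.time for d in doses]),
        np.array([d.rate for d in doses]),
        np.array([d.infusion_duration for d in doses]),
    )
    return out if out.ndim else float(out)


def n_doses_to_steady_state(ke, interval, rel_tol: float = 1e-3):
    """Smallest number of prior doses after which the pre-dose concentration
    changes by less than ``rel_tol`` (relative) between consecutive intervals.

    The pre-dose level after n doses is proportional to ``1 - exp(-n k tau)``,
    so the relative change from dose n to n+1 is
    ``exp(-n k tau) (1 - exp(-k tau)) / (1 - exp(-(n+1) k tau))``.
    Vectorised over ``ke``.
    """
    ke = np.asarray(ke, dtype=float)
    ktau = ke * interval
    # closed-form bound: exp(-n ktau) * (1 - exp(-ktau)) < rel_tol is sufficient
    with np.errstate(divide="ignore"):
        n = np.ceil(np.log((1.0 - np.exp(-ktau)) / rel_tol) / ktau)
    n = np.maximum(n, 1).astype(int)
    return n if n.ndim else int(n)


def steady_state_window(ind: IndividualParams, regimen: Regimen, rel_tol: float = 1e-3) -> float:
    """Start time (h) of the first dosing interval at effective steady state.

    Steady state is declared once the pre-dose concentration changes by
    less than 0.1% (default) between consecutive intervals — roughly
    seven half-lives of cumulative dosing.
    """
    n = n_doses_to_steady_state(ind.ke, regimen.interval, rel_tol)
    return float(n) * regimen.interval
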