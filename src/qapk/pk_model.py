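"""Mechanistic two-compartment PK model of an antibody quality attribute.

The drug circulates as two interconverting variants — the *original* form and
a *modified* form carrying the quality attribute (a deamidated residue, a
high-mannose glycan, ...). Each variant distributes between a central
(plasma) and a peripheral (tissue) compartment and is eliminated from the
central compartment; the original form may additionally convert to the
modified form in vivo. Amounts evolve as the linear system

    dAC0/dt   = -(kCP + ktr + kcl0) * AC0   + kPC * AP0
    dAP0/dt   = -(kPC + ktr)        * AP0   + kCP * AC0
    dACmod/dt = -(kCP + kclmod)     * ACmod + ktr * AC0 + kPC * APmod
    dAPmod/dt = -kPC                * APmod + ktr * AP0 + kCP * ACmod

with an IV bolus split between the forms by the initial modified fraction
``f``: AC0(0) = (1-f)*Dose, ACmod(0) = f*Dose, and empty peripheral
compartments. Central concentrations are amounts divided by the distribution
volume V, shared by both forms.

Two attribute archetypes constrain the generic model:

* deamidation-like — modification does not alter clearance (kclmod = kcl0);
* man5-like — the modification is not formed in circulation (ktr = 0) but
  clears faster (kclmod > kcl0).

Both archetypes admit closed-form solutions (exposed here as oracles): under
equal clearance the central modified fraction follows 1-(1-f)*exp(-ktr*t),
and with ktr = 0 each form follows an independent biexponential decay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "AttributeModelParams",
    "Trajectory",
    "BiexpCoefficients",
    "DegenerateEigenvaluesError",
    "reference_params",
    "rhs",
    "rate_matrix",
    "simulate",
    "simulate_analytic",
    "biexp_coefficients",
    "central_unit_bolus",
    "unit_bolus_auc",
    "modified_fraction_equal_clearance",
    "apply_constraints",
]

# default ODE solver tolerances (relative; absolute is scaled by Dose)
RTOL = 1e-10
ATOL_PER_DOSE = 1e-13


class DegenerateEigenvaluesError(ValueError):
    """Raised when the two-compartment eigenrates coincide."""


@dataclass(frozen=True)
class AttributeModelParams:
    """Rate constants and dosing inputs of the two-form model.

    Parameters
    ----------
    k_cp, k_pc : float
        Central<->peripheral distribution rate constants (1/day), shared by
        both forms.
    k_tr : float
        Original->modified conversion rate constant (1/day).
    k_cl0, k_clmod : float
        Central-compartment clearance rate constants of the original and
        modified forms (1/day).
    volume : float
        Central distribution volume V (L).
    dose : float
        IV bolus amount (mass units; concentrations inherit mass/L).
    f : float
        Initial modified fraction of the dose, in [0, 1]. ``100*f`` is the
        attribute's "initial level" in percent.
    """

    k_cp: float
    k_pc: float
    k_tr: float
    k_cl0: float
    k_clmod: float
    volume: float
    dose: float = 1.0
    f: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_cp", "k_pc", "k_tr", "k_cl0", "k_clmod"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.volume <= 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must be in [0, 1], got {self.f}")

    @property
    def initial_state(self) -> np.ndarray:
        """Amounts (AC0, AP0, ACmod, APmod) immediately after the bolus."""
        return np.array([(1.0 - self.f) * self.dose, 0.0, self.f * self.dose, 0.0])


#: Published best-fit parameter sets for the two archetypal attributes of a
#: clinical IgG1 (rates in 1/day, V in L). Used as defaults throughout.
_REFERENCE = {
    "deamidation": AttributeModelParams(
        k_cp=0.17, k_pc=0.093, k_tr=0.01, k_cl0=0.13, k_clmod=0.13, volume=3.34
    ),
    "man5": AttributeModelParams(
        k_cp=0.18, k_pc=0.096, k_tr=0.0, k_cl0=0.127, k_clmod=0.295, volume=3.32
    ),
}


def reference_params(attribute: str, *, dose: float = 1.0, f: float = 0.0) -> AttributeModelParams:
    """Return the published parameter set for ``attribute`` with dosing inputs.

    ``attribute`` is ``"deamidation"`` or ``"man5"``.
    """
    try:
        base = _REFERENCE[attribute]
    except KeyError:
        raise ValueError(
            f"unknown attribute {attribute!r}; expected one of {sorted(_REFERENCE)}"
        ) from None
    return replace(base, dose=dose, f=f)


def rate_matrix(p: AttributeModelParams) -> np.ndarray:
    """Coefficient matrix M with d(state)/dt = M @ state, state = (AC0, AP0, ACmod, APmod)."""
    return np.array(
        [
            [-(p.k_cp + p.k_tr + p.k_cl0), p.k_pc, 0.0, 0.0],
            [p.k_cp, -(p.k_pc + p.k_tr), 0.0, 0.0],
            [p.k_tr, 0.0, -(p.k_cp + p.k_clmod), p.k_pc],
            [0.0, p.k_tr, p.k_cp, -p.k_pc],
        ]
    )


def rhs(state: Sequence[float], p: AttributeModelParams) -> np.ndarray:
    """Time-derivatives of the four amounts. Pure function of state and rates."""
    ac0, ap0, acm, apm = state
    return np.array(
        [
            -(p.k_cp + p.k_tr + p.k_cl0) * ac0 + p.k_pc * ap0,
            -(p.k_pc + p.k_tr) * ap0 + p.k_cp * ac0,
            -(p.k_cp + p.k_clmod) * acm + p.k_tr * ac0 + p.k_pc * apm,
            -p.k_pc * apm + p.k_tr * ap0 + p.k_cp * acm,
        ]
    )


@dataclass(frozen=True)
class Trajectory:
    """Simulated amounts over a time grid, with derived central concentrations."""

    times: np.ndarray  # days
    ac0: np.ndarray
    ap0: np.ndarray
    acmod: np.ndarray
    apmod: np.ndarray
    volume: float

    @property
    def c0(self) -> np.ndarray:
        """Central concentration of the original form (mass/L)."""
        return self.ac0 / self.volume

    @property
    def cmod(self) -> np.ndarray:
        """Central concentration of the modified form (mass/L)."""
        return self.acmod / self.volume

    @property
    def c_total(self) -> np.ndarray:
        return (self.ac0 + self.acmod) / self.volume

    @property
    def total_amount(self) -> np.ndarray:
        """Drug amount summed over forms and compartments."""
        return self.ac0 + self.ap0 + self.acmod + self.apmod

    @property
    def modified_fraction_central(self) -> np.ndarray:
        """ACmod / (AC0 + ACmod); NaN where no drug is in the central compartment."""
        tot = self.ac0 + self.acmod
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.acmod / np.where(tot > 0, tot, 1.0), np.nan)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_days": self.times,
                "AC0": self.ac0,
                "AP0": self.ap0,
                "ACmod": self.acmod,
                "APmod": self.apmod,
                "C0": self.c0,
                "Cmod": self.cmod,
            }
        )


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] != 0.0:
        raise ValueError(f"times must start at 0 (bolus instant), got {times[0]}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


def simulate(p: AttributeModelParams, times: Sequence[float]) -> Trajectory:
    """Integrate the four-state system over ``times`` (days, starting at 0).

    Uses a stiff-capable integrator at rtol 1e-10 so downstream agreement
    checks against the closed forms are solver-noise free.
    """
    times = _check_times(times)
    y0 = p.initial_state
    atol = ATOL_PER_DOSE * max(p.dose, 1.0)
    sol = solve_ivp(
        lambda _t, y: rhs(y, p),
        (0.0, float(times[-1])) if times[-1] > 0 else (0.0, 1.0),
        y0,
        t_eval=times if times[-1] > 0 else None,
        method="LSODA",
        rtol=RTOL,
        atol=atol,
        jac=lambda _t, _y: rate_matrix(p),
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed ({sol.message}) for params {p}")
    if times[-1] > 0:
        y = sol.y
    else:  # degenerate single-point grid: just the initial condition
        y = y0[:, None]
    return Trajectory(times=times, ac0=y[0], ap0=y[1], acmod=y[2], apmod=y[3], volume=p.volume)


def simulate_analytic(p: AttributeModelParams, times: Sequence[float]) -> Trajectory:
    """Exact eigen-solution of the linear system (fast path for fitting).

    The rate matrix is block lower-triangular in the (original, modified)
    form pairs, with generically distinct eigenvalues; amounts are evaluated
    as V * exp(L t) * V^-1 * y0 at every requested time.
    """
    times = _check_times(times)
    M = rate_matrix(p)
    lam, vec = np.linalg.eig(M)
    coef = np.linalg.solve(vec, p.initial_state)
    y = (vec * coef) @ np.exp(np.outer(lam, times))
    y = np.real_if_close(y, tol=1e6)
    y = np.asarray(y, dtype=float)
    return Trajectory(times=times, ac0=y[0], ap0=y[1], acmod=y[2], apmod=y[3], volume=p.volume)


@dataclass(frozen=True)
class BiexpCoefficients:
    """Unit-bolus central profile A*exp(-lam1*t) + B*exp(-lam2*t) of a
    plain two-compartment model (one form, no conversion)."""

    lam1: float  # fast (distribution) eigenrate, 1/day
    lam2: float  # slow (terminal) eigenrate, 1/day
    amp1: float  # A
    amp2: float  # B = 1 - A


def biexp_coefficients(k_cp: float, k_pc: float, k_cl: float) -> BiexpCoefficients:
    """Eigen-decomposition of the one-form two-compartment submodel.

    With a = k_cp + k_cl and b = k_pc the eigenrates are
    ((a+b) +- sqrt((a+b)^2 - 4*b*k_cl)) / 2 and the central unit-bolus
    amplitudes are A = (lam1 - k_pc)/(lam1 - lam2), B = 1 - A.
    """
    if min(k_cp, k_pc, k_cl) < 0:
        raise ValueError("rate constants must be >= 0")
    a = k_cp + k_cl
    b = k_pc
    s = a + b
    disc = s * s - 4.0 * b * k_cl
    if disc <= 0:
        # disc == 0 only on a measure-zero parameter set; the biexponential
        # form degenerates to (A + C*t)*exp(-lam*t) which we do not model.
        raise DegenerateEigenvaluesError(
            f"repeated eigenrate at k_cp={k_cp}, k_pc={k_pc}, k_cl={k_cl}"
        )
    root = np.sqrt(disc)
    lam1 = 0.5 * (s + root)
    lam2 = 0.5 * (s - root)
    amp1 = (lam1 - k_pc) / (lam1 - lam2)
    return BiexpCoefficients(lam1=lam1, lam2=lam2, amp1=amp1, amp2=1.0 - amp1)


def central_unit_bolus(coef: BiexpCoefficients, t: np.ndarray | float) -> np.ndarray:
    """Central amount per unit dose at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    return coef.amp1 * np.exp(-coef.lam1 * t) + coef.amp2 * np.exp(-coef.lam2 * t)


def _exp_integral(lam: float, t0: float, t1: float) -> float:
    # integral of exp(-lam t) over [t0, t1], stable at lam -> 0
    if lam == 0.0:
        return t1 - t0
    return (np.exp(-lam * t0) - np.exp(-lam * t1)) / lam


def unit_bolus_auc(coef: BiexpCoefficients, window: tuple[float, float]) -> float:
    """Integral of the unit-bolus central profile over ``window`` (days)."""
    t0, t1 = window
    if not 0 <= t0 < t1:
        raise ValueError(f"window must satisfy 0 <= start < end, got {window}")
    return coef.amp1 * _exp_integral(coef.lam1, t0, t1) + coef.amp2 * _exp_integral(
        coef.lam2, t0, t1
    )


def modified_fraction_equal_clearance(f: float, k_tr: float, t: np.ndarray | float) -> np.ndarray:
    """Closed-form central modified fraction under kclmod = kcl0.

    When both forms clear at the same rate the conversion acts as a uniform
    relabelling and the central fraction obeys 1 - (1-f)*exp(-k_tr*t),
    independent of the distribution and clearance rates.
    """
    t = np.asarray(t, dtype=float)
    return 1.0 - (1.0 - f) * np.exp(-k_tr * t)


_KINDS = ("deamidation", "man5")


def apply_constraints(p: AttributeModelParams, attribute_kind: str) -> AttributeModelParams:
    """Impose the archetype's mechanistic constraint on a parameter set.

    ``"deamidation"`` (deamidation-like): modification does not change
    clearance, so kclmod is rewritten to kcl0. ``"man5"`` (man5-like): the
    modification is not formed in circulation, so ktr is rewritten to 0.
    Distribution rates are shared between forms by construction.
    """
    if attribute_kind == "deamidation":
        return replace(p, k_clmod=p.k_cl0)
    if attribute_kind == "man5":
        return replace(p, k_tr=0.0)
    raise ValueError(f"unknown attribute_kind {attribute_kind!r}; expected one of {_KINDS}")
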