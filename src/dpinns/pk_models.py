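"""Pharmacokinetic structural models.

Two systems are provided:

* a one-compartment IV-bolus model, ``dC/dt = -ke C``, ``C(0) = Dose/Vd`` —
  the proof-of-concept system with a closed-form solution used as a test
  oracle throughout the package;
* a minimal physiologically-based pharmacokinetic (mPBPK) model for
  monoclonal antibodies with four compartments (plasma, tight-tissue ISF,
  leaky-tissue ISF, lymph), convection-driven distribution governed by
  vascular/lymphatic reflection coefficients, zero-order IV infusion input
  and elimination from plasma only.

State order for the mPBPK model is fixed as (plasma, tight, leaky, lymph);
concentrations are mg/L, volumes L, flows L/h, times h.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "OneCompartmentParams", "MPBPKPhysiology", "MPBPKEstimands",
    "InfusionSchedule", "ODEModelSpec",
    "onecomp_rhs", "onecomp_initial", "onecomp_closed_form",
    "mpbpk_rhs", "mpbpk_matrices", "mpbpk_solve",
    "load_reference_physiology", "scale_physiology", "constrain_reflection",
    "MODEL_REGISTRY", "get_model",
]


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class OneCompartmentParams:
    """Volume of distribution Vd (L), elimination rate ke (1/h), dose (mg)."""
    Vd: float
    ke: float
    dose: float

    def __post_init__(self):
        if self.Vd <= 0:
            raise ValueError("Vd must be positive")
        if self.ke <= 0:
            raise ValueError("ke must be positive")
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")


@dataclass(frozen=True)
class MPBPKPhysiology:
    body_weight: float   # kg
    V_plasma: float      # L
    V_lymph: float       # L
    V_tight: float       # L (accessible ISF, tight tissues)
    V_leaky: float       # L (accessible ISF, leaky tissues)
    L: float             # total lymph flow, L/h
    L1: float            # lymph flow to tight tissues, L/h
    L2: float            # lymph flow to leaky tissues, L/h
    sigma_L: float       # lymphatic capillary reflection coefficient

    def __post_init__(self):
        for name in ("body_weight", "V_plasma", "V_lymph", "V_tight",
                     "V_leaky", "L", "L1", "L2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not np.isclose(self.L1 + self.L2, self.L, rtol=1e-9):
            raise ValueError("lymph flows must satisfy L1 + L2 = L")
        if not 0 <= self.sigma_L < 1:
            raise ValueError("sigma_L must lie in [0, 1)")


@dataclass(frozen=True)
class MPBPKEstimands:
    """Plasma clearance and vascular reflection coefficients.

    Tight endothelium reflects more than leaky endothelium, hence the
    physical ordering constraint 0 < sigma2 < sigma1 < 1.
    """
    CLp: float      # L/h
    sigma1: float   # tight-tissue vascular reflection
    sigma2: float   # leaky-tissue vascular reflection

    def __post_init__(self):
        if self.CLp <= 0:
            raise ValueError("CLp must be positive")
        if not (0 < self.sigma2 < self.sigma1 < 1):
            raise ValueError("require 0 < sigma2 < sigma1 < 1")


@dataclass(frozen=True)
class InfusionSchedule:
    dose: float    # mg
    T_inf: float   # h

    def __post_init__(self):
        if self.T_inf <= 0:
            raise ValueError("T_inf must be positive")
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")


@dataclass
class ODEModelSpec:
    """Generic contract for an ODE system used by the fitters."""
    name: str
    n_states: int
    parameter_names: Sequence[str]
    rhs: Callable  # (state, t, params) -> derivative
    initial_condition: Callable  # (params) -> state
    observed_states: Sequence[int] = field(default_factory=lambda: [0])


# ---------------------------------------------------------------------------
# one-compartment IV bolus

def onecomp_rhs(C, t, p: OneCompartmentParams):
    """First-order elimination: dC/dt = -ke * C."""
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("non-finite concentration")
    return -p.ke * C


def onecomp_initial(p: OneCompartmentParams) -> float:
    """Instantaneous distribution of an IV bolus: C(0) = Dose / Vd."""
    return p.dose / p.Vd


def onecomp_closed_form(t, p: OneCompartmentParams):
    """Analytic solution C(t) = (Dose/Vd) exp(-ke t); the oracle for
    numeric solves and surrogate fits."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    return (p.dose / p.Vd) * np.exp(-p.ke * t)


# ---------------------------------------------------------------------------
# minimal PBPK for monoclonal antibodies

def mpbpk_rhs(state, t, phys: MPBPKPhysiology, est: MPBPKEstimands,
              inf: InfusionSchedule):
    """Right-hand side of the 4-state mPBPK system.

    The zero-order infusion input Dose/T_inf is active for t in [0, T_inf]
    and zero afterwards.  Elimination (CLp) acts on plasma only.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    Cp, Ct, Cl, Cly = state
    input_rate = inf.dose / inf.T_inf if t <= inf.T_inf else 0.0
    dCp = (input_rate + Cly * phys.L
           - Cp * phys.L1 * (1 - est.sigma1)
           - Cp * phys.L2 * (1 - est.sigma2)
           - Cp * est.CLp) / phys.V_plasma
    dCt = (phys.L1 * (1 - est.sigma1) * Cp
           - phys.L1 * (1 - phys.sigma_L) * Ct) / phys.V_tight
    dCl = (phys.L2 * (1 - est.sigma2) * Cp
           - phys.L2 * (1 - phys.sigma_L) * Cl) / phys.V_leaky
    dCly = (phys.L1 * (1 - phys.sigma_L) * Ct
            + phys.L2 * (1 - phys.sigma_L) * Cl
            - Cly * phys.L) / phys.V_lymph
    return np.array([dCp, dCt, dCl, dCly])


def mpbpk_matrices(phys: MPBPKPhysiology, est: MPBPKEstimands):
    """System matrix A and unit-input vector b of the linear system
    dC/dt = A C + b * input_rate (state order plasma, tight, leaky, lymph)."""
    A = np.array([
        [-(phys.L1 * (1 - est.sigma1) + phys.L2 * (1 - est.sigma2)
           + est.CLp) / phys.V_plasma, 0.0, 0.0, phys.L / phys.V_plasma],
        [phys.L1 * (1 - est.sigma1) / phys.V_tight,
         -phys.L1 * (1 - phys.sigma_L) / phys.V_tight, 0.0, 0.0],
        [phys.L2 * (1 - est.sigma2) / phys.V_leaky, 0.0,
         -phys.L2 * (1 - phys.sigma_L) / phys.V_leaky, 0.0],
        [0.0, phys.L1 * (1 - phys.sigma_L) / phys.V_lymph,
         phys.L2 * (1 - phys.sigma_L) / phys.V_lymph,
         -phys.L / phys.V_lymph],
    ])
    b = np.array([1.0 / phys.V_plasma, 0.0, 0.0, 0.0])
    return A, b


def mpbpk_solve(times, phys: MPBPKPhysiology, est: MPBPKEstimands,
                inf: InfusionSchedule, method: str = "expm"):
    """Solve the mPBPK system from a drug-free initial state.

    The system is linear and time-invariant on each side of the infusion
    switch, so the default path uses the eigendecomposition of the system
    matrix (exact up to floating point and orders of magnitude faster than
    time stepping); ``method='ivp'`` falls back to scipy's LSODA for
    cross-checking.

    Returns an array of shape (len(times), 4).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("negative time")
    A, b = mpbpk_matrices(phys, est)
    rate = inf.dose / inf.T_inf

    if method == "ivp":
        def f(t, y):
            return A @ y + b * (rate if t <= inf.T_inf else 0.0)
        out = np.empty((len(times), 4))
        sol = solve_ivp(f, (0.0, max(float(times.max()), inf.T_inf)), np.zeros(4),
                        t_eval=np.unique(np.concatenate([times, [inf.T_inf]])),
                        rtol=1e-10, atol=1e-12, max_step=inf.T_inf)
        for i, t in enumerate(times):
            j = np.argmin(np.abs(sol.t - t))
            out[i] = sol.y[:, j]
        return out

    lam, V = np.linalg.eig(A)
    Vinv = np.linalg.inv(V)
    # particular solution during infusion: C_part = -A^{-1} b rate
    c_part = -np.linalg.solve(A, b) * rate

    def expAt(t):
        # V diag(e^{lam t}) V^{-1}, vectorised over t
        return np.real(np.einsum("ij,tj,jk->tik", V, np.exp(np.outer(t, lam)), Vinv))

    out = np.empty((len(times), 4))
    pre = times <= inf.T_inf
    if np.any(pre):
        # C(t) = e^{At}(C0 - C_part) + C_part, C0 = 0
        out[pre] = np.einsum("tij,j->ti", expAt(times[pre]), -c_part) + c_part
    if np.any(~pre):
        c_end = np.einsum("tij,j->ti", expAt(np.array([inf.T_inf])), -c_part)[0] + c_part
        out[~pre] = np.einsum("tij,j->ti", expAt(times[~pre] - inf.T_inf), c_end)
    return out


# ---------------------------------------------------------------------------
# physiology scaling & constraints

def load_reference_physiology() -> dict:
    """Reference (70 kg) mPBPK physiological constants, shipped as a CSV
    resource so values can be corrected without code changes."""
    with importlib.resources.files("dpinns.data").joinpath(
            "mpbpk_reference_physiology.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["parameter"], df["value"]))


_REF_CACHE: dict | None = None


def scale_physiology(body_weight: float, reference: dict | None = None) -> MPBPKPhysiology:
    """Scale reference volumes and flows linearly with body weight.

    Accessible ISF is split into tight/leaky fractions after applying the
    antibody availability factor; lymph flow partitions as L1 + L2 = L.
    """
    global _REF_CACHE
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    if reference is None:
        if _REF_CACHE is None:
            _REF_CACHE = load_reference_physiology()
        reference = _REF_CACHE
    s = body_weight / reference["reference_weight"]
    v_isf = reference["V_isf_total"] * reference["isf_availability"] * s
    L = reference["L_total"] * s
    L1 = L * reference["L1_fraction"]
    return MPBPKPhysiology(
        body_weight=body_weight,
        V_plasma=reference["V_plasma"] * s,
        V_lymph=reference["V_lymph"] * s,
        V_tight=v_isf * reference["tight_fraction"],
        V_leaky=v_isf * (1.0 - reference["tight_fraction"]),
        L=L, L1=L1, L2=L - L1,
        sigma_L=reference["sigma_L"],
    )


def constrain_reflection(sigma1_raw, sigma2_raw):
    """Map unconstrained reals to reflection coefficients with
    0 < sigma2 < sigma1 < 1:  sigma1 = invlogit(raw1),
    sigma2 = sigma1 * invlogit(raw2)."""
    from scipy.special import expit
    s1 = expit(sigma1_raw)
    return s1, s1 * expit(sigma2_raw)


# ---------------------------------------------------------------------------
# registry

def _onecomp_spec() -> ODEModelSpec:
    return ODEModelSpec(
        name="onecomp_iv_bolus", n_states=1, parameter_names=["Vd", "ke"],
        rhs=onecomp_rhs, initial_condition=onecomp_initial,
        observed_states=[0])


def _mpbpk_spec() -> ODEModelSpec:
    return ODEModelSpec(
        name="mpbpk_mab", n_states=4,
        parameter_names=["CLp", "sigma1", "sigma2"],
        rhs=mpbpk_rhs, initial_condition=lambda p: np.zeros(4),
        observed_states=[0])


MODEL_REGISTRY = {
    "onecomp_iv_bolus": _onecomp_spec,
    "mpbpk_mab": _mpbpk_spec,
}


def get_model(name: str) -> ODEModelSpec:
    try:
        return MODEL_REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered models: "
            f"{sorted(MODEL_REGISTRY)}") from None
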