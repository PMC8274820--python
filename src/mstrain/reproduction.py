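"""Controlled basic reproduction numbers, sensitivities and control efficiency.

Closed forms
------------
Baseline model (A drops out entirely — neutral mutation cannot change R0):

    R0(u_T) = beta_C * (xi*(u_T + mu) + gamma) / ((gamma + mu) * (u_T + mu))

Extended model, with ``beta_bar = max_i beta_Ci``, ``B_bar = B_C / beta_bar``,
``P_DFE(u_P) = u_P / (delta + mu + u_P)``:

    R0(u_T, u_P) = beta_bar * (gamma + xi*mu) / ((gamma + mu) * mu)
                   * rho( Q(u_P) N(u_T) )
    Q(u_P) = B_bar @ (E - P_DFE(u_P) * Psi)
    N(u_T) = (xi*mu*E + gamma * A @ Delta(u_T)) / (gamma + xi*mu)
    Delta(u_T) = inv(Z + (mu + u_T) E) @ (Z + mu E)

Both are cross-checked against an independent next-generation construction
``rho(F V^-1)`` built from the Jacobians of new-infection and transition
terms at the disease-free equilibrium.

First-order control sensitivities (around zero control) use the left/right
dominant eigenvectors w0, v0 of ``Q(0) N(0) = B_bar @ A_bar``, where
``A_bar = (xi*mu*E + gamma*A) / (gamma + xi*mu)`` is a convex combination of
the identity and A (hence shares A's dominant eigenvectors when beta is
uniform, with w0 the all-ones vector):

    R1_T = - w0' [R0*E - (xi/(gamma+mu)) B_C] inv(Z + mu E) v0
    R1_P = - R0 / (delta + mu) * w0' Psi v0

Both coefficients are non-positive: each control is unconditionally locally
efficient.  Whether a control can actually eliminate the infection is a
separate, conditional question governed by the large-control limit
``xi/(gamma+mu) * max_i beta_Ci (1 - psi_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import optimize

from .models import BaselineParams, ExtendedParams
from .strainspace import dominant_eigenpair, is_irreducible

__all__ = [
    "R0Report",
    "SensitivityReport",
    "EfficiencyVerdict",
    "CriticalControl",
    "r0_baseline",
    "r0_extended",
    "ng_oracle",
    "sensitivity_baseline",
    "sensitivity_extended",
    "classify_efficiency",
    "r0_limit",
    "critical_control",
]


@dataclass(frozen=True)
class R0Report:
    """Controlled R0 together with its spectral decomposition."""

    value: float
    rho: float
    Q: np.ndarray
    N: np.ndarray
    Delta: np.ndarray
    beta_bar: float
    B_bar: np.ndarray
    model: str

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class SensitivityReport:
    """First-order expansion of R0 around zero control.

    ``R0(u_T, u_P) = R0_at_zero + R1_T u_T + R1_P u_P + O(||u||^2)``.
    Derived mean durations: acute stage ``theta_A = 1/(gamma + mu)``, time on
    (failing) treatment ``tau_i = 1/(zeta_i + mu)``, one prophylaxis cycle
    ``1/(delta + mu)``.
    """

    R0_at_zero: float
    R1_T: float
    R1_P: Optional[float]
    w0: Optional[np.ndarray]
    v0: Optional[np.ndarray]
    theta_A: float
    tau: Optional[np.ndarray]
    prophylaxis_duration: Optional[float]


@dataclass(frozen=True)
class EfficiencyVerdict:
    """Local and global control-efficiency classification.

    ``globally_efficient`` records whether driving both controls to infinity
    pushes R0 below 1 (the floor is set by the least-controllable strain);
    ``preferred_control`` compares |R1_T| with |R1_P| near zero control.
    """

    locally_efficient_T: bool
    locally_efficient_P: Optional[bool]
    globally_efficient: bool
    global_lhs: float
    global_rhs: float
    preferred_control: Optional[str]
    comparison_lhs: Optional[float] = None
    comparison_rhs: Optional[float] = None


@dataclass(frozen=True)
class CriticalControl:
    """Smallest control rate driving R0 to 1, if it exists."""

    value: Optional[float]
    grid_value: Optional[float]
    grid: np.ndarray
    r0_on_grid: np.ndarray
    which: str


# ---------------------------------------------------------------------------
# closed forms

def r0_baseline(params: BaselineParams) -> R0Report:
    """Closed-form controlled R0 of the baseline model (independent of A)."""
    g, m, uT = params.gamma, params.mu, params.u_T
    value = params.beta_C * (params.xi * (uT + m) + g) / ((g + m) * (uT + m))
    E = np.eye(params.n)
    return R0Report(value=float(value), rho=1.0, Q=E, N=E, Delta=E,
                    beta_bar=params.beta_C, B_bar=E, model="baseline")


def _extended_matrices(params: ExtendedParams):
    g, m, xi = params.gamma, params.mu, params.xi
    E = np.eye(params.n)
    beta_bar = float(params.beta_C.max())
    if beta_bar <= 0:
        raise ValueError("at least one beta_Ci must be positive")
    B_bar = np.diag(params.beta_C / beta_bar)
    P_dfe = params.u_P / (params.delta + m + params.u_P)
    Q = B_bar @ (E - P_dfe * np.diag(params.psi))
    Delta = np.diag((params.zeta + m) / (params.zeta + m + params.u_T))
    N = (xi * m * E + g * (params.A.entries @ Delta)) / (g + xi * m)
    return beta_bar, B_bar, Q, N, Delta


def r0_extended(params: ExtendedParams) -> R0Report:
    """Closed-form controlled R0 of the extended model."""
    g, m, xi = params.gamma, params.mu, params.xi
    if m <= 0:
        raise ValueError("mu must be positive for the R0 closed form")
    beta_bar, B_bar, Q, N, Delta = _extended_matrices(params)
    rho = float(np.max(np.abs(np.linalg.eigvals(Q @ N))))
    value = beta_bar * (g + xi * m) / ((g + m) * m) * rho
    return R0Report(value=float(value), rho=rho, Q=Q, N=N, Delta=Delta,
                    beta_bar=beta_bar, B_bar=B_bar, model="extended")


# ---------------------------------------------------------------------------
# next-generation oracle

def ng_oracle(model: str, params) -> float:
    """R0 via the next-generation method, ``rho(F V^-1)``.

    F is the Jacobian of new-infection inflows and V the (negated) Jacobian
    of the remaining transitions, both over the infected compartments only,
    evaluated at the model's disease-free equilibrium.  Serves as the
    independent cross-check for the closed forms.
    """
    n = params.n
    g, m, xi = params.gamma, params.mu, params.xi
    A = params.A.entries
    if model == "baseline":
        # infected block [I_A, I_C]; S_DFE = 1
        beta = np.full(n, params.beta_C)
        F = np.zeros((2 * n, 2 * n))
        F[:n, :n] = np.diag(xi * beta)
        F[:n, n:] = beta[:, None] * A
        V = np.zeros((2 * n, 2 * n))
        V[:n, :n] = (g + m) * np.eye(n)
        V[n:, :n] = -g * np.eye(n)
        V[n:, n:] = (params.u_T + m) * np.eye(n)
    elif model == "extended":
        # infected block [I_A, I_C, T]
        S = (params.delta + m) / (params.delta + m + params.u_P)
        P = 1.0 - S
        eff = params.beta_C * (S + (1.0 - params.psi) * P)
        F = np.zeros((3 * n, 3 * n))
        F[:n, :n] = np.diag(xi * eff)
        F[:n, n:2 * n] = eff[:, None] * A
        V = np.zeros((3 * n, 3 * n))
        V[:n, :n] = (g + m) * np.eye(n)
        V[n:2 * n, :n] = -g * np.eye(n)
        V[n:2 * n, n:2 * n] = (params.u_T + m) * np.eye(n)
        V[n:2 * n, 2 * n:] = -np.diag(params.zeta)
        V[2 * n:, n:2 * n] = -params.u_T * np.eye(n)
        V[2 * n:, 2 * n:] = np.diag(params.zeta + m)
    else:
        raise ValueError(f"unknown model tag {model!r}")
    K = F @ np.linalg.inv(V)
    return float(np.max(np.abs(np.linalg.eigvals(K))))


# ---------------------------------------------------------------------------
# sensitivities

def sensitivity_baseline(params: BaselineParams) -> SensitivityReport:
    """Expansion of baseline R0 in u_T: R0(0) and R1 = -beta_C*gamma/(mu^2*(gamma+mu))."""
    g, m, xi = params.gamma, params.mu, params.xi
    if m <= 0:
        raise ValueError("mu must be positive")
    R0_0 = params.beta_C * (g + xi * m) / (m * (g + m))
    R1 = -params.beta_C * g / (m ** 2 * (g + m))
    return SensitivityReport(
        R0_at_zero=float(R0_0), R1_T=float(R1), R1_P=None, w0=None, v0=None,
        theta_A=1.0 / (g + m), tau=None, prophylaxis_duration=None,
    )


def sensitivity_extended(params: ExtendedParams) -> SensitivityReport:
    """First-order sensitivities of extended R0 in both controls at (0, 0)."""
    if not is_irreducible(params.A):
        raise ValueError("sensitivity expansion requires an irreducible mutation matrix")
    g, m, xi = params.gamma, params.mu, params.xi
    n = params.n
    E = np.eye(n)
    at_zero = params.with_controls(u_T=0.0, u_P=0.0)
    beta_bar, B_bar, Q0, N0, _ = _extended_matrices(at_zero)
    M = Q0 @ N0  # = B_bar @ A_bar, A_bar = (xi*mu*E + gamma*A)/(gamma + xi*mu)
    pair = dominant_eigenpair(M, warn_reducible=False)
    w0, v0 = pair.w, pair.v
    R0_0 = beta_bar * (g + xi * m) / ((g + m) * m) * pair.rho
    B_C = np.diag(params.beta_C)
    inv_Zmu = np.diag(1.0 / (params.zeta + m))
    R1_T = -float(w0 @ (R0_0 * E - xi / (g + m) * B_C) @ inv_Zmu @ v0)
    R1_P = -R0_0 / (params.delta + m) * float(w0 @ np.diag(params.psi) @ v0)
    return SensitivityReport(
        R0_at_zero=float(R0_0), R1_T=R1_T, R1_P=float(R1_P), w0=w0, v0=v0,
        theta_A=1.0 / (g + m), tau=1.0 / (params.zeta + m),
        prophylaxis_duration=1.0 / (params.delta + m),
    )


def r0_limit(params: ExtendedParams) -> float:
    """Large-control limit of R0: ``xi/(gamma+mu) * max_i beta_Ci (1 - psi_i)``.

    This floor cannot be lowered by any amount of treatment or prophylaxis;
    elimination is possible for some finite controls iff it is below 1.
    """
    return float(params.xi / (params.gamma + params.mu)
                 * np.max(params.beta_C * (1.0 - params.psi)))


def classify_efficiency(params) -> EfficiencyVerdict:
    """Classify the controls' local and global efficiency.

    Baseline: treatment is always locally efficient and globally efficient
    iff ``xi * beta_C < gamma + mu``.  Extended: joint global efficiency iff
    ``xi * max_i beta_Ci (1 - psi_i) < gamma + mu``; the locally preferred
    control is the one with the larger |R1| coefficient.
    """
    g, m, xi = params.gamma, params.mu, params.xi
    if isinstance(params, BaselineParams):
        lhs, rhs = xi * params.beta_C, g + m
        return EfficiencyVerdict(
            locally_efficient_T=True, locally_efficient_P=None,
            globally_efficient=bool(lhs < rhs), global_lhs=float(lhs),
            global_rhs=float(rhs), preferred_control=None,
        )
    sens = sensitivity_extended(params)
    lhs = xi * float(np.max(params.beta_C * (1.0 - params.psi)))
    rhs = g + m
    # comparison of local efficiencies: |R1_T| vs |R1_P| scaled by 1/R0
    cmp_T = abs(sens.R1_T) / sens.R0_at_zero
    cmp_P = abs(sens.R1_P) / sens.R0_at_zero
    if np.isclose(cmp_T, cmp_P, rtol=1e-12, atol=1e-15):
        preferred = "tie"
    else:
        preferred = "treatment" if cmp_T > cmp_P else "prophylaxis"
    return EfficiencyVerdict(
        locally_efficient_T=bool(sens.R1_T <= 0),
        locally_efficient_P=bool(sens.R1_P <= 0),
        globally_efficient=bool(lhs < rhs), global_lhs=float(lhs),
        global_rhs=float(rhs), preferred_control=preferred,
        comparison_lhs=float(cmp_T), comparison_rhs=float(cmp_P),
    )


# ---------------------------------------------------------------------------
# critical control

def _r0_at(params, which: str, u: float) -> float:
    if isinstance(params, BaselineParams):
        if which != "u_T":
            raise ValueError("baseline model has only the u_T control")
        return r0_baseline(replace(params, u_T=u)).value
    if which == "u_T":
        return r0_extended(params.with_controls(u_T=u)).value
    if which == "u_P":
        return r0_extended(params.with_controls(u_P=u)).value
    raise ValueError(f"unknown control {which!r}")


def critical_control(params, which: str = "u_T", grid_step: float = 0.01,
                     grid_max: float = 2.0) -> CriticalControl:
    """Smallest control rate with R0 = 1, by bisection on the monotone R0 map.

    The other control stays at the value stored in ``params``.  Returns
    ``value=None`` when the large-control limit of R0 exceeds 1 (elimination
    impossible: the control is only conditionally globally efficient).
    ``grid_value`` is the first multiple of ``grid_step`` with R0 <= 1, the
    resolution at which scenario sweeps are reported.
    """
    r0_zero = _r0_at(params, which, 0.0)
    if r0_zero <= 1.0:
        raise ValueError(f"R0 at zero {which} is {r0_zero:.6g} <= 1; nothing to solve")
    grid = np.round(np.arange(0.0, grid_max + grid_step / 2, grid_step), 10)
    r0_grid = np.array([_r0_at(params, which, u) for u in grid])

    hi = 1.0
    for _ in range(60):
        if _r0_at(params, which, hi) < 1.0:
            break
        hi *= 2.0
        if hi > 1e7:
            break
    if _r0_at(params, which, hi) >= 1.0:
        return CriticalControl(value=None, grid_value=None, grid=grid,
                               r0_on_grid=r0_grid, which=which)
    root = optimize.brentq(lambda u: _r0_at(params, which, u) - 1.0, 0.0, hi,
                           xtol=1e-12, rtol=1e-14)
    if root > grid[-1]:
        grid = np.round(np.arange(0.0, root + 2 * grid_step, grid_step), 10)
        r0_grid = np.array([_r0_at(params, which, u) for u in grid])
    below = np.flatnonzero(r0_grid <= 1.0)
    grid_value = float(grid[below[0]]) if below.size else None
    return CriticalControl(value=float(root), grid_value=grid_value, grid=grid,
                           r0_on_grid=r0_grid, which=which)
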