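"""Disease-free and endemic equilibria of the multi-strain SI models.

For the baseline model with an irreducible mutation matrix the endemic
equilibrium exists, is unique for R0 > 1, and is fully explicit: writing
``v`` for the stationary strain distribution (dominant right eigenvector of
A, sum 1) and ``c = 1 - 1/R0``,

    I_Ai* = mu/(gamma+mu) * c * v_i
    I_Ci* = gamma*mu / ((gamma+mu)*(u_T+mu)) * c * v_i
    T*    = gamma*u_T / ((gamma+mu)*(u_T+mu)) * c
    S*    = 1/R0

so the total prevalence is ``Pi = 1 - S* = (R0-1)/R0`` and the endemic
strain frequencies are exactly ``v`` — the population-level strain
distribution is inherited from the within-host mutation process alone.
The chronic compartment is a fixed point of the mutation matrix,
``I_C* = A I_C*``: at equilibrium the chance of meeting a chronic carrier
of strain i equals the chance of catching strain i from a random chronic
carrier.

A reducible A replaces the single equilibrium by a family parameterized by
the (at most k, one per closed irreducible block) unit-eigenvalue
eigenvectors.  The extended model has no closed form and is solved
numerically (long-time integration polished by Newton).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from . import simulate as _simulate
from .models import (BaselineParams, ExtendedParams, ModelState,
                     collapse_extended, rhs_baseline, rhs_extended)
from .reproduction import r0_baseline, r0_extended
from .strainspace import dominant_eigenpair, is_irreducible, normal_form

__all__ = [
    "DiseaseFreeEquilibrium",
    "EndemicEquilibrium",
    "EquilibriumFamily",
    "dfe",
    "endemic_baseline",
    "acute_chronic_ratio",
    "endemic_family",
    "endemic_extended_numeric",
]


@dataclass(frozen=True)
class DiseaseFreeEquilibrium:
    S_DFE: float
    P_DFE: float = 0.0

    def state(self, n: int, model: str) -> ModelState:
        zeros = np.zeros(n)
        if model == "baseline":
            return ModelState(I_A=zeros, I_C=zeros.copy(), T=0.0, S=self.S_DFE)
        return ModelState(I_A=zeros, I_C=zeros.copy(), T=np.zeros(n),
                          S=self.S_DFE, P=self.P_DFE)


@dataclass(frozen=True)
class EndemicEquilibrium:
    """Endemic steady state with its derived epidemiological quantities."""

    state: ModelState
    R0: float
    prevalence: float
    acute_chronic_ratio: Optional[float]
    source: str
    residual: float


@dataclass(frozen=True)
class EquilibriumFamily:
    """Eigenvector-parameterized endemic equilibria of a reducible model."""

    basis: list
    dimension: int
    params: BaselineParams

    def combine(self, weights) -> EndemicEquilibrium:
        """Equilibrium from a weighted combination of the basis eigenvectors.

        The combined strain-frequency vector must be non-negative with a
        positive sum (it is renormalized to sum 1); combinations leaving the
        physical region are rejected rather than silently clipped.
        """
        weights = np.asarray(weights, dtype=float)
        if weights.size != self.dimension:
            raise ValueError(f"need {self.dimension} weights, got {weights.size}")
        vbar = sum(w * eq for w, eq in zip(weights, self._vectors))
        if np.any(vbar < -1e-12):
            raise ValueError("combination has negative strain frequencies; "
                             "not a physical equilibrium")
        s = vbar.sum()
        if s <= 0:
            raise ValueError("combination has zero total frequency")
        return _baseline_from_v(self.params, vbar / s, source="closed_form")

    @property
    def _vectors(self):
        return [eq._v for eq in self.basis]


def dfe(model: str, params) -> DiseaseFreeEquilibrium:
    """Disease-free equilibrium: S = 1 (baseline) or the prophylaxis-shifted split."""
    if model == "baseline":
        return DiseaseFreeEquilibrium(S_DFE=1.0, P_DFE=0.0)
    if model == "extended":
        d, m, uP = params.delta, params.mu, params.u_P
        S = (d + m) / (d + m + uP)
        return DiseaseFreeEquilibrium(S_DFE=S, P_DFE=1.0 - S)
    raise ValueError(f"unknown model tag {model!r}")


def _baseline_from_v(params: BaselineParams, v: np.ndarray,
                     source: str) -> EndemicEquilibrium:
    g, m, uT = params.gamma, params.mu, params.u_T
    R0 = r0_baseline(params).value
    c = 1.0 - 1.0 / R0
    I_A = m / (g + m) * c * v
    I_C = g * m / ((g + m) * (uT + m)) * c * v
    T = g * uT / ((g + m) * (uT + m)) * c
    state = ModelState(I_A=I_A, I_C=I_C, T=float(T), S=1.0 / R0)
    residual = float(np.linalg.norm(rhs_baseline(state.to_vector(), params)))
    eq = EndemicEquilibrium(
        state=state, R0=R0, prevalence=c,
        acute_chronic_ratio=acute_chronic_ratio(params), source=source,
        residual=residual,
    )
    object.__setattr__(eq, "_v", v)
    return eq


def endemic_baseline(params: BaselineParams) -> EndemicEquilibrium:
    """Closed-form endemic equilibrium of the baseline model (irreducible A, R0 > 1)."""
    R0 = r0_baseline(params).value
    if R0 <= 1.0:
        raise ValueError(f"R0 = {R0:.6g} <= 1: no endemic equilibrium exists")
    if not is_irreducible(params.A):
        raise ValueError("mutation matrix is reducible; use endemic_family "
                         "for the equilibrium family")
    v = dominant_eigenpair(params.A).v
    return _baseline_from_v(params, v, source="closed_form")


def acute_chronic_ratio(params: BaselineParams) -> float:
    """Ratio of transmissions caused by acute vs chronic carriers at equilibrium.

    ``r_AC = xi * (u_T + mu) / gamma`` — together with the prevalence, this
    pair of observable quantities identifies xi and beta_C from data.
    """
    if params.gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(params.xi * (params.u_T + params.mu) / params.gamma)


def endemic_family(params: BaselineParams) -> EquilibriumFamily:
    """Family of endemic equilibria for a reducible mutation matrix.

    Each unit-eigenvalue eigenvector of A generates one basis equilibrium;
    general members are convex combinations (see
    :meth:`EquilibriumFamily.combine`).  Basis vectors that cannot be scaled
    non-negative are kept as reported by the eigensolver and flagged by a
    negative-component check in ``combine``.
    """
    R0 = r0_baseline(params).value
    if R0 <= 1.0:
        raise ValueError(f"R0 = {R0:.6g} <= 1: no endemic equilibria exist")
    decomp = normal_form(params.A)
    basis = []
    for col in decomp.unit_eigenvectors.T:
        vec = col.copy()
        if vec.sum() < 0:
            vec = -vec
        # scale to sum 1 when the vector is (essentially) one-signed
        if abs(vec.sum()) > 1e-9:
            vec = vec / vec.sum()
        basis.append(_baseline_from_v(params, vec, source="closed_form"))
    return EquilibriumFamily(basis=basis, dimension=decomp.q, params=params)


def endemic_extended_numeric(params: ExtendedParams,
                             x0: Optional[np.ndarray] = None,
                             newton_tol: float = 1e-12,
                             max_iter: int = 100) -> EndemicEquilibrium:
    """Numeric endemic equilibrium of the extended model.

    Seeds a damped-Newton solve either from ``x0``, from the collapsed
    baseline closed form (when the parameters reduce), or from a long-time
    integration; the conservation law replaces one redundant equation so the
    Jacobian is regular.  Falls back to the integration state (flagged via
    ``source``) if Newton fails to reach the residual tolerance.
    """
    n = params.n
    report = r0_extended(params)
    if report.value <= 1.0:
        raise ValueError(f"R0 = {report.value:.6g} <= 1: no endemic equilibrium; "
                         "the disease-free equilibrium is the long-time limit")
    if x0 is None:
        x0 = _initial_guess(params)

    def G(x):
        r = rhs_extended(x, params)
        r[-1] = x.sum() - 1.0  # conservation replaces the redundant equation
        return r

    sol = optimize.root(G, x0, method="hybr", tol=newton_tol,
                        options={"maxfev": max_iter * (params.dim + 1)})
    x = sol.x
    residual = float(np.linalg.norm(rhs_extended(x, params)))
    source = "numeric"
    if (not sol.success) or residual > 1e-9 or np.any(x < -1e-9):
        x = _simulate.steady_state("extended", params,
                                   ModelState.from_vector(x0, n, "extended")).state.to_vector()
        residual = float(np.linalg.norm(rhs_extended(x, params)))
        source = "numeric_integration_fallback"
    x = np.where((x < 0) & (x > -1e-9), 0.0, x)
    state = ModelState.from_vector(x, n, "extended")
    prevalence = float(state.I_A.sum() + state.I_C.sum() + np.sum(state.T))
    return EndemicEquilibrium(state=state, R0=report.value, prevalence=prevalence,
                              acute_chronic_ratio=None, source=source,
                              residual=residual)


def _initial_guess(params: ExtendedParams) -> np.ndarray:
    n = params.n
    try:
        base = collapse_extended(params)
        eq = endemic_baseline(base)
        T_i = params.u_T * eq.state.I_C / (params.zeta + params.mu)
        guess = ModelState(I_A=eq.state.I_A, I_C=eq.state.I_C, T=T_i,
                           S=eq.state.S, P=0.0).to_vector()
        return guess / guess.sum()
    except ValueError:
        pass
    x0 = np.zeros(params.dim)
    x0[0] = 0.01  # 1% acutely infected with strain 1
    x0[3 * n] = 0.99
    res = _simulate.steady_state("extended", params,
                                 ModelState.from_vector(x0, n, "extended"),
                                 t_max=2e4, rhs_tol=1e-8)
    return res.state.to_vector()
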