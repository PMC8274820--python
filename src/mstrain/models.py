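"""Compartmental SI models of a chronic multi-strain infection.

Two model variants share one structure.  The *baseline* model tracks, as
population fractions, acutely infected hosts ``I_Ai`` and chronically
infected hosts ``I_Ci`` per founding strain i, a single treated compartment
``T`` (treatment assumed fully effective), and susceptibles ``S``:

    dI_Ai/dt = phi_i(X) S - (gamma + mu) I_Ai
    dI_Ci/dt = gamma I_Ai - (u_T + mu) I_Ci
    dT/dt    = u_T sum_i I_Ci - mu T
    dS/dt    = mu - sum_i phi_i(X) S - mu S

with force of infection ``phi_i = beta_C (xi I_Ai + sum_j alpha_ij I_Cj)``.
The *extended* model gives each strain its own transmissibility ``beta_Ci``,
splits treatment into per-strain compartments ``T_i`` that fail (revert to
chronic infection) at rate ``zeta_i``, and adds a prophylaxed compartment
``P`` which strain i infects only at the reduced rate ``(1 - psi_i) phi_i``.

Inflow equals outflow (turnover rate ``mu``), so every state lives on the
probability simplex and the right-hand sides sum to zero exactly.

State vector ordering is fixed for all I/O and Jacobians:
``[I_A1..I_An, I_C1..I_Cn, T (or T_1..T_n), S]`` plus ``P`` for the extended
model — length ``2n + 2`` (baseline) or ``3n + 2`` (extended).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import yaml

from .strainspace import MutationMatrix, matrix_from_yaml, matrix_to_yaml

__all__ = [
    "BaselineParams",
    "ExtendedParams",
    "ModelState",
    "force_of_infection",
    "rhs_baseline",
    "rhs_extended",
    "collapse_extended",
    "params_to_yaml",
    "params_from_yaml",
]


def _check_rate(value: float, name: str) -> float:
    value = float(value)
    if value < 0 or not np.isfinite(value):
        raise ValueError(f"{name} must be a finite non-negative rate, got {value}")
    return value


def _check_rate_vector(value, name: str, n: int) -> np.ndarray:
    v = np.asarray(value, dtype=float)
    if v.ndim == 0:
        v = np.full(n, float(v))
    if v.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {v.shape}")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite and non-negative")
    return v


@dataclass(frozen=True)
class BaselineParams:
    """Rates of the baseline model (phenotypically neutral strains).

    beta_C : chronic-stage transmissibility (per unit time); acute-stage
        transmissibility is ``beta_A = xi * beta_C``.
    xi : acute/chronic transmissibility ratio (dimensionless).
    gamma : inverse duration of the acute stage.
    mu : population turnover (mortality) rate.
    u_T : rate of enrollment of chronic cases into treatment (control).
    A : within-host mutation matrix.
    """

    beta_C: float
    xi: float
    gamma: float
    mu: float
    u_T: float
    A: MutationMatrix

    def __post_init__(self):
        for name in ("beta_C", "xi", "gamma", "mu", "u_T"):
            object.__setattr__(self, name, _check_rate(getattr(self, name), name))
        if not isinstance(self.A, MutationMatrix):
            object.__setattr__(self, "A", MutationMatrix(self.A))

    @property
    def n(self) -> int:
        return self.A.n

    @property
    def beta_A(self) -> float:
        return self.xi * self.beta_C

    @property
    def dim(self) -> int:
        return 2 * self.n + 2


@dataclass(frozen=True)
class ExtendedParams:
    """Rates of the extended model (variable phenotypes, treatment failure, prophylaxis).

    beta_C : length-n per-strain chronic transmissibilities (a scalar is
        broadcast to all strains).
    zeta : length-n treatment failure rates; treated hosts infected by strain
        i revert to chronic infection at rate ``zeta_i``.
    psi : length-n prophylaxis protection levels in [0, 1]; ``psi_i = 1``
        blocks strain i completely.
    delta : inverse duration of one prophylaxis cycle.
    u_T, u_P : treatment / prophylaxis enrollment rates (controls).
    xi, gamma, mu, A : as in :class:`BaselineParams`.
    """

    beta_C: np.ndarray
    xi: float
    gamma: float
    mu: float
    u_T: float
    u_P: float
    zeta: np.ndarray
    psi: np.ndarray
    delta: float
    A: MutationMatrix

    def __post_init__(self):
        if not isinstance(self.A, MutationMatrix):
            object.__setattr__(self, "A", MutationMatrix(self.A))
        n = self.A.n
        for name in ("xi", "gamma", "mu", "u_T", "u_P", "delta"):
            object.__setattr__(self, name, _check_rate(getattr(self, name), name))
        object.__setattr__(self, "beta_C", _check_rate_vector(self.beta_C, "beta_C", n))
        object.__setattr__(self, "zeta", _check_rate_vector(self.zeta, "zeta", n))
        psi = _check_rate_vector(self.psi, "psi", n)
        if np.any(psi > 1):
            raise ValueError("psi entries must lie in [0, 1]")
        object.__setattr__(self, "psi", psi)

    @property
    def n(self) -> int:
        return self.A.n

    @property
    def dim(self) -> int:
        return 3 * self.n + 2

    def with_controls(self, u_T: Optional[float] = None, u_P: Optional[float] = None):
        """Copy with one or both control rates replaced."""
        kw = {}
        if u_T is not None:
            kw["u_T"] = u_T
        if u_P is not None:
            kw["u_P"] = u_P
        return replace(self, **kw) if kw else self


@dataclass(frozen=True)
class ModelState:
    """Compartment fractions on the simplex.

    ``T`` is a scalar for the baseline layout and a length-n vector for the
    extended layout; ``P`` exists only in the extended layout.
    """

    I_A: np.ndarray
    I_C: np.ndarray
    T: np.ndarray | float
    S: float
    P: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "I_A", np.atleast_1d(np.asarray(self.I_A, float)))
        object.__setattr__(self, "I_C", np.atleast_1d(np.asarray(self.I_C, float)))
        if np.ndim(self.T) > 0:
            object.__setattr__(self, "T", np.asarray(self.T, float))

    @property
    def n(self) -> int:
        return self.I_A.size

    @property
    def model(self) -> str:
        return "baseline" if self.P is None else "extended"

    def to_vector(self) -> np.ndarray:
        parts = [self.I_A, self.I_C, np.atleast_1d(self.T), [self.S]]
        if self.P is not None:
            parts.append([self.P])
        return np.concatenate([np.asarray(p, float) for p in parts])

    @classmethod
    def from_vector(cls, x, n: int, model: str) -> "ModelState":
        x = np.asarray(x, dtype=float)
        if model == "baseline":
            if x.size != 2 * n + 2:
                raise ValueError(f"baseline state needs length {2 * n + 2}, got {x.size}")
            return cls(I_A=x[:n], I_C=x[n:2 * n], T=float(x[2 * n]), S=float(x[2 * n + 1]))
        if model == "extended":
            if x.size != 3 * n + 2:
                raise ValueError(f"extended state needs length {3 * n + 2}, got {x.size}")
            return cls(I_A=x[:n], I_C=x[n:2 * n], T=x[2 * n:3 * n],
                       S=float(x[3 * n]), P=float(x[3 * n + 1]))
        raise ValueError(f"unknown model tag {model!r}")

    def validate(self, atol: float = 1e-9) -> "ModelState":
        x = self.to_vector()
        if np.any(x < -atol):
            raise ValueError(f"state has negative component {x.min()}")
        if abs(x.sum() - 1.0) > max(atol, 1e-9):
            raise ValueError(f"state components sum to {x.sum()}, not 1")
        return self

    def compartment_names(self) -> list[str]:
        n = self.n
        names = [f"I_A{i + 1}" for i in range(n)] + [f"I_C{i + 1}" for i in range(n)]
        if self.P is None:
            names += ["T"]
        else:
            names += [f"T{i + 1}" for i in range(n)]
        names += ["S"]
        if self.P is not None:
            names += ["P"]
        return names


# ---------------------------------------------------------------------------
# right-hand sides (operate on raw vectors for integrator speed)

def force_of_infection(state, params) -> np.ndarray:
    """Per-strain force of infection ``phi_i = beta_Ci (xi I_Ai + sum_j alpha_ij I_Cj)``.

    For :class:`BaselineParams` all ``beta_Ci`` equal ``beta_C``.
    """
    n = params.n
    x = state.to_vector() if isinstance(state, ModelState) else np.asarray(state, float)
    I_A, I_C = x[:n], x[n:2 * n]
    beta = params.beta_C if isinstance(params, ExtendedParams) else params.beta_C
    return np.asarray(beta) * (params.xi * I_A + params.A.entries @ I_C)


def rhs_baseline(state, params: BaselineParams) -> np.ndarray:
    """Time derivative of the baseline state vector; components sum to 0."""
    n = params.n
    x = state.to_vector() if isinstance(state, ModelState) else np.asarray(state, float)
    if x.size != 2 * n + 2:
        raise ValueError(f"baseline state needs length {2 * n + 2}, got {x.size}")
    I_A, I_C = x[:n], x[n:2 * n]
    T, S = x[2 * n], x[2 * n + 1]
    phi = params.beta_C * (params.xi * I_A + params.A.entries @ I_C)
    dI_A = phi * S - (params.gamma + params.mu) * I_A
    dI_C = params.gamma * I_A - (params.u_T + params.mu) * I_C
    dT = params.u_T * I_C.sum() - params.mu * T
    dS = params.mu - phi.sum() * S - params.mu * S
    return np.concatenate([dI_A, dI_C, [dT, dS]])


def rhs_extended(state, params: ExtendedParams) -> np.ndarray:
    """Time derivative of the extended state vector; components sum to 0."""
    n = params.n
    x = state.to_vector() if isinstance(state, ModelState) else np.asarray(state, float)
    if x.size != 3 * n + 2:
        raise ValueError(f"extended state needs length {3 * n + 2}, got {x.size}")
    I_A, I_C, T = x[:n], x[n:2 * n], x[2 * n:3 * n]
    S, P = x[3 * n], x[3 * n + 1]
    phi = params.beta_C * (params.xi * I_A + params.A.entries @ I_C)
    escape = (1.0 - params.psi) * phi
    dI_A = phi * S + escape * P - (params.gamma + params.mu) * I_A
    dI_C = params.gamma * I_A + params.zeta * T - (params.u_T + params.mu) * I_C
    dT = params.u_T * I_C - (params.zeta + params.mu) * T
    dS = params.mu - params.u_P * S - phi.sum() * S + params.delta * P - params.mu * S
    dP = params.u_P * S - escape.sum() * P - (params.delta + params.mu) * P
    return np.concatenate([dI_A, dI_C, dT, [dS, dP]])


def collapse_extended(params: ExtendedParams) -> BaselineParams:
    """Reduce an extended parameter set to the baseline model it degenerates to.

    Requires uniform ``beta_C``, all-zero ``zeta`` and ``u_P = 0`` (so the
    per-strain treated compartments aggregate into one and ``P`` stays empty).
    """
    if np.ptp(params.beta_C) > 0:
        raise ValueError("cannot collapse: beta_C is not uniform across strains")
    if np.any(params.zeta > 0):
        raise ValueError("cannot collapse: zeta has nonzero treatment-failure rates")
    if params.u_P > 0:
        raise ValueError("cannot collapse: u_P is nonzero (prophylaxis active)")
    return BaselineParams(
        beta_C=float(params.beta_C[0]), xi=params.xi, gamma=params.gamma,
        mu=params.mu, u_T=params.u_T, A=params.A,
    )


# ---------------------------------------------------------------------------
# YAML serialization (keys mirror the model's parameter-table symbols)

def params_to_yaml(params) -> str:
    if isinstance(params, BaselineParams):
        doc = {
            "model": "baseline",
            "beta_C": params.beta_C, "xi": params.xi, "gamma": params.gamma,
            "mu": params.mu, "u_T": params.u_T,
            "mutation_matrix": yaml.safe_load(matrix_to_yaml(params.A)),
        }
    elif isinstance(params, ExtendedParams):
        doc = {
            "model": "extended",
            "beta_C": params.beta_C.tolist(), "xi": params.xi,
            "gamma": params.gamma, "mu": params.mu,
            "u_T": params.u_T, "u_P": params.u_P,
            "zeta": params.zeta.tolist(), "psi": params.psi.tolist(),
            "delta": params.delta,
            "mutation_matrix": yaml.safe_load(matrix_to_yaml(params.A)),
        }
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    return yaml.safe_dump(doc, sort_keys=False)


_BASELINE_KEYS = {"model", "beta_C", "xi", "gamma", "mu", "u_T", "mutation_matrix"}
_EXTENDED_KEYS = _BASELINE_KEYS | {"u_P", "zeta", "psi", "delta"}


def params_from_yaml(source):
    """Parse a parameter set from YAML text or a mapping; unknown keys rejected."""
    doc = yaml.safe_load(source) if isinstance(source, str) else dict(source)
    if not isinstance(doc, dict):
        raise ValueError("parameter YAML must be a mapping")
    model = doc.get("model", "baseline")
    allowed = _BASELINE_KEYS if model == "baseline" else _EXTENDED_KEYS
    if model not in {"baseline", "extended"}:
        raise ValueError(f"unknown model tag {model!r}")
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    missing = {"beta_C", "xi", "gamma", "mu", "u_T", "mutation_matrix"} - set(doc)
    if model == "extended":
        missing |= {"delta"} - set(doc)
    if missing:
        raise ValueError(f"missing parameter keys: {sorted(missing)}")
    A = matrix_from_yaml(doc["mutation_matrix"])
    common = dict(xi=doc["xi"], gamma=doc["gamma"], mu=doc["mu"], u_T=doc["u_T"], A=A)
    if model == "baseline":
        return BaselineParams(beta_C=doc["beta_C"], **common)
    return ExtendedParams(
        beta_C=doc["beta_C"], u_P=doc.get("u_P", 0.0),
        zeta=doc.get("zeta", np.zeros(A.n)), psi=doc.get("psi", np.zeros(A.n)),
        delta=doc["delta"], **common,
    )
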