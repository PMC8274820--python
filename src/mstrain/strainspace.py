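"""Within-host strain space: column-stochastic mutation matrices and their spectra.

A chronically infected host founded by strain *j* carries, on average, a
fraction ``alpha[i, j]`` of strain *i* in its viral population.  Collecting
these fractions gives an n x n column-stochastic matrix ``A`` whose dominant
right eigenvector is the stationary strain-frequency distribution at the
endemic equilibrium.  This module builds the two structured parametrizations
used throughout the package — the *uniform* form (the founder retains a
fraction ``pi_i`` of itself, the rest spread evenly over all other strains)
and the *nearest-neighbor* form (strains ordered by genetic similarity,
mutation only to adjacent strains) — inverts them from target frequency
vectors, and provides the Perron–Frobenius machinery (dominant eigenpairs,
irreducibility, block-triangular normal form) the epidemiological results
rest on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import yaml
from scipy import linalg

__all__ = [
    "MutationMatrix",
    "RetentionProfile",
    "SpectralPair",
    "ReducibleDecomposition",
    "FeasibilityError",
    "ReducibilityWarning",
    "build_uniform_matrix",
    "build_neighbor_matrix",
    "pis_from_frequencies",
    "dominant_eigenpair",
    "closed_form_eigenvector_uniform",
    "is_irreducible",
    "normal_form",
    "convex_combination",
    "matrix_to_csv",
    "matrix_from_csv",
    "matrix_to_yaml",
    "matrix_from_yaml",
]

#: entries below this are treated as structural zeros of the sparsity digraph
_ZERO_TOL = 1e-14
_COLSUM_TOL = 1e-12


class FeasibilityError(ValueError):
    """Raised when an inverse parametrization yields retention values outside [0, 1]."""


class ReducibilityWarning(UserWarning):
    """The mutation matrix is reducible; the unit eigenvalue may not be simple."""


def _as_vector(x, name: str) -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class RetentionProfile:
    """Per-strain within-host retention probabilities.

    ``pi[i]`` is the average fraction of the founding strain *i* remaining in
    the chronic-stage viral population of a host infected by strain *i*; the
    complement ``1 - pi[i]`` is the mass lost to mutation.
    """

    pi: np.ndarray

    def __post_init__(self):
        pi = _as_vector(self.pi, "pi")
        if np.any(pi < 0) or np.any(pi > 1):
            bad = int(np.argmax((pi < 0) | (pi > 1)))
            raise ValueError(f"retention pi[{bad}] = {pi[bad]} outside [0, 1]")
        object.__setattr__(self, "pi", pi)

    @property
    def n(self) -> int:
        return self.pi.size


@dataclass(frozen=True)
class MutationMatrix:
    """Column-stochastic within-host mutation matrix A.

    Entry ``entries[i, j]`` is the average fraction of strain *i* in a host
    founded by strain *j*; each column sums to 1 and every diagonal entry is
    strictly positive (a founder never fully disappears from its own host).
    """

    entries: np.ndarray
    topology: str = "general"

    def __post_init__(self):
        A = np.asarray(self.entries, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"mutation matrix must be square, got shape {A.shape}")
        if A.shape[0] < 1:
            raise ValueError("mutation matrix needs at least one strain")
        if np.any(A < -_ZERO_TOL) or np.any(A > 1 + 1e-12):
            raise ValueError("mutation matrix entries must lie in [0, 1]")
        colsums = A.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _COLSUM_TOL):
            j = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValueError(
                f"column {j} sums to {colsums[j]!r}, not 1 (tolerance {_COLSUM_TOL})"
            )
        if np.any(np.diag(A) <= 0):
            i = int(np.argmax(np.diag(A) <= 0))
            raise ValueError(f"diagonal entry alpha[{i},{i}] must be strictly positive")
        if self.topology not in {"uniform", "neighbor", "general"}:
            raise ValueError(f"unknown topology tag {self.topology!r}")
        object.__setattr__(self, "entries", A)

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.array(self.entries, dtype=dtype)


@dataclass(frozen=True)
class SpectralPair:
    """Dominant eigentriple (rho, right v, left w) with sum(v) = 1 and w.v = 1."""

    rho: float
    v: np.ndarray
    w: np.ndarray


@dataclass(frozen=True)
class ReducibleDecomposition:
    """Block-triangular normal form of a reducible mutation matrix.

    ``permutation`` reorders strains so the permuted matrix is block upper
    triangular with ``k = len(blocks)`` irreducible diagonal blocks;
    ``unit_eigenvectors`` (n x q, q <= k) spans the eigenvalue-1 eigenspace.
    """

    permutation: np.ndarray
    blocks: list = field(default_factory=list)
    unit_eigenvectors: np.ndarray = None

    @property
    def k(self) -> int:
        return len(self.blocks)

    @property
    def q(self) -> int:
        return self.unit_eigenvectors.shape[1]


# ---------------------------------------------------------------------------
# constructors

def build_uniform_matrix(pi) -> MutationMatrix:
    """Uniform-mutation matrix: diagonal pi_j, off-diagonal (1-pi_j)/(n-1) down column j."""
    pi = pi.pi if isinstance(pi, RetentionProfile) else RetentionProfile(pi).pi
    n = pi.size
    if n < 2:
        raise ValueError("uniform topology needs at least two strains")
    A = np.tile((1.0 - pi) / (n - 1), (n, 1))
    np.fill_diagonal(A, pi)
    if np.any(pi <= 0):
        raise ValueError("uniform topology requires pi_i in (0, 1]")
    return MutationMatrix(A, topology="uniform")


def build_neighbor_matrix(pi) -> MutationMatrix:
    """Nearest-neighbor (tridiagonal) mutation matrix.

    Column j keeps ``pi_j`` on the diagonal; interior columns split the lost
    mass ``(1 - pi_j)/2`` between the two adjacent strains, while the boundary
    columns 1 and n give the full ``1 - pi_j`` to their single neighbor.
    """
    pi = pi.pi if isinstance(pi, RetentionProfile) else RetentionProfile(pi).pi
    n = pi.size
    if n < 2:
        raise ValueError("neighbor topology needs at least two strains")
    if np.any(pi <= 0):
        raise ValueError("neighbor topology requires pi_i in (0, 1]")
    A = np.diag(pi)
    A[1, 0] = 1.0 - pi[0]
    A[n - 2, n - 1] = 1.0 - pi[n - 1]
    for j in range(1, n - 1):
        A[j - 1, j] = (1.0 - pi[j]) / 2.0
        A[j + 1, j] = (1.0 - pi[j]) / 2.0
    return MutationMatrix(A, topology="neighbor")


def pis_from_frequencies(v, pi_n: float, topology: str) -> RetentionProfile:
    """Invert a target strain-frequency vector into a retention profile.

    Because the stationary frequencies ``v`` fix only n - 1 degrees of
    freedom, the last retention ``pi_n`` is chosen freely and the remaining
    ones follow in closed form:

    * uniform:  ``pi_j = 1 - (1 - pi_n) v_n / v_j`` for j < n;
    * neighbor: ``pi_1 = 1 - (1 - pi_n) v_n / v_1`` and
      ``pi_j = 1 - 2 (1 - pi_n) v_n / v_j`` for 1 < j < n.

    Feeding the result to the matching builder yields a matrix whose dominant
    right eigenvector is ``v``.  Raises :class:`FeasibilityError` when the
    requested frequencies force some retention outside [0, 1].
    """
    v = _as_vector(v, "v")
    n = v.size
    if n < 2:
        raise ValueError("need at least two strains")
    if np.any(v <= 0):
        raise ValueError("frequency vector must be strictly positive")
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequency vector must sum to 1, got {v.sum()}")
    if not 0.0 < pi_n < 1.0:
        raise ValueError(f"pi_n must lie in (0, 1), got {pi_n}")
    if topology not in {"uniform", "neighbor"}:
        raise ValueError(f"unknown topology {topology!r}")

    loss = (1.0 - pi_n) * v[-1]
    pi = np.empty(n)
    pi[-1] = pi_n
    pi[0] = 1.0 - loss / v[0]
    if topology == "uniform":
        pi[1:-1] = 1.0 - loss / v[1:-1]
    else:
        pi[1:-1] = 1.0 - 2.0 * loss / v[1:-1]
    bad = np.flatnonzero((pi < 0) | (pi > 1))
    if bad.size:
        j = int(bad[0])
        raise FeasibilityError(
            f"target frequencies infeasible for {topology} topology: "
            f"pi[{j}] = {pi[j]:.6g} outside [0, 1]; increase pi_n or reshape v"
        )
    return RetentionProfile(pi)


# ---------------------------------------------------------------------------
# spectra

def dominant_eigenpair(A, warn_reducible: bool = True) -> SpectralPair:
    """Dominant eigentriple of a (mutation) matrix by dense eigendecomposition.

    For a column-stochastic matrix the dominant eigenvalue is 1 and the left
    eigenvector is proportional to the all-ones vector; the right eigenvector,
    normalized to sum 1, is the stationary strain distribution.  Also accepts
    plain non-negative matrices (e.g. ``B_C_bar @ A_bar`` in the sensitivity
    analysis), where the Perron root may be below 1.
    """
    M = np.asarray(A.entries if isinstance(A, MutationMatrix) else A, dtype=float)
    vals, lefts, rights = linalg.eig(M, left=True, right=True)
    moduli = np.abs(vals)
    rho = moduli.max()
    # among eigenvalues of maximal modulus pick the real (Perron) one
    near = np.flatnonzero(moduli > rho - 1e-9)
    idx = near[np.argmax(vals[near].real)]
    if warn_reducible:
        n_dom = np.count_nonzero(np.abs(vals - vals[idx]) < 1e-9)
        if n_dom > 1:
            warnings.warn(
                "dominant eigenvalue is not simple (reducible mutation "
                "structure); use normal_form for the full equilibrium family",
                ReducibilityWarning,
                stacklevel=2,
            )
    v = rights[:, idx].real
    if v.sum() < 0:
        v = -v
    s = v.sum()
    if abs(s) < 1e-12:
        raise ValueError("dominant right eigenvector has zero sum; matrix degenerate")
    v = v / s
    w = lefts[:, idx].real
    wv = float(w @ v)
    if abs(wv) < 1e-14:
        raise ValueError("left/right dominant eigenvectors are orthogonal; "
                         "eigenvalue defective")
    w = w / wv
    return SpectralPair(rho=float(vals[idx].real), v=v, w=w)


def closed_form_eigenvector_uniform(pi) -> np.ndarray:
    """Stationary frequencies of the uniform-mutation matrix in closed form.

    ``v_i`` is proportional to ``prod_{j != i} (1 - pi_j)``, so pairwise
    ratios obey ``v_i / v_j = (1 - pi_j) / (1 - pi_i)``.
    """
    pi = pi.pi if isinstance(pi, RetentionProfile) else RetentionProfile(pi).pi
    if np.any(pi >= 1):
        raise ZeroDivisionError(
            "closed form undefined when some pi_i = 1 (matrix reducible); "
            "use the numeric eigenpair"
        )
    one_minus = 1.0 - pi
    # leave-one-out products, computed without cancellation for small n
    v = np.array([np.prod(np.delete(one_minus, i)) for i in range(pi.size)])
    return v / v.sum()


def _sparsity_digraph(A: np.ndarray) -> nx.DiGraph:
    # edge j -> i whenever alpha_ij > 0: founder j seeds strain i
    G = nx.DiGraph()
    n = A.shape[0]
    G.add_nodes_from(range(n))
    rows, cols = np.nonzero(A > _ZERO_TOL)
    G.add_edges_from(zip(cols, rows))
    return G


def is_irreducible(A) -> bool:
    """True iff the sparsity digraph (edge j -> i when alpha_ij > 0) is strongly connected."""
    M = np.asarray(A.entries if isinstance(A, MutationMatrix) else A, dtype=float)
    return nx.is_strongly_connected(_sparsity_digraph(M))


def normal_form(A) -> ReducibleDecomposition:
    """Permutation to block upper-triangular normal form plus the unit eigenspace.

    The strongly connected components of the sparsity digraph are ordered so
    that the permuted matrix has its k irreducible blocks on the diagonal and
    all remaining mass strictly above; the eigenvalue-1 eigenspace (dimension
    q <= k) is returned as an orthonormal basis.
    """
    M = np.asarray(A.entries if isinstance(A, MutationMatrix) else A, dtype=float)
    G = _sparsity_digraph(M)
    cond = nx.condensation(G)
    # edge j->i carries mass from block(j) into block(i); listing targets first
    # (reverse topological order) puts that mass above the diagonal
    order = list(reversed(list(nx.topological_sort(cond))))
    blocks = [sorted(cond.nodes[b]["members"]) for b in order]
    perm = np.concatenate([np.asarray(b, dtype=int) for b in blocks])
    basis = linalg.null_space(M - np.eye(M.shape[0]), rcond=1e-9)
    return ReducibleDecomposition(
        permutation=perm, blocks=blocks, unit_eigenvectors=basis
    )


def convex_combination(A, alpha: float) -> MutationMatrix:
    """``alpha * E + (1 - alpha) * A`` — stochastic, with A's dominant eigenvectors."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    M = np.asarray(A.entries if isinstance(A, MutationMatrix) else A, dtype=float)
    out = alpha * np.eye(M.shape[0]) + (1.0 - alpha) * M
    topo = A.topology if isinstance(A, MutationMatrix) else "general"
    return MutationMatrix(out, topology="general" if alpha > 0 else topo)


# ---------------------------------------------------------------------------
# I/O

def matrix_to_csv(A: MutationMatrix, path) -> None:
    """Write the entries as a headerless n x n CSV (entry (i, j) = alpha_ij)."""
    np.savetxt(path, A.entries, delimiter=",", fmt="%.17g")


def matrix_from_csv(path, topology: str = "general") -> MutationMatrix:
    entries = np.loadtxt(path, delimiter=",", ndmin=2)
    return MutationMatrix(entries, topology=topology)


def matrix_to_yaml(A: MutationMatrix) -> str:
    doc = {"topology": A.topology, "entries": A.entries.tolist()}
    return yaml.safe_dump(doc, sort_keys=False)


def matrix_from_yaml(source) -> MutationMatrix:
    """Build from a YAML block: either explicit ``entries`` or ``{topology, pi}``."""
    doc = yaml.safe_load(source) if isinstance(source, str) else dict(source)
    if not isinstance(doc, dict):
        raise ValueError("mutation-matrix YAML must be a mapping")
    topology = doc.get("topology", "general")
    if "entries" in doc:
        return MutationMatrix(np.asarray(doc["entries"], dtype=float), topology=topology)
    if "pi" in doc:
        pi = RetentionProfile(doc["pi"])
        if topology == "uniform":
            return build_uniform_matrix(pi)
        if topology == "neighbor":
            return build_neighbor_matrix(pi)
        raise ValueError("pi-based construction requires topology 'uniform' or 'neighbor'")
    raise ValueError("mutation-matrix YAML needs either 'entries' or 'pi'")
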