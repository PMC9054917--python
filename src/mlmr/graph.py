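"""Similarity-graph construction for manifold-regularized learning.

The graph pipeline turns an ``n x d`` feature matrix into the unnormalized
graph Laplacian used as the intrinsic-smoothness penalty:

1. a Gaussian kernel matrix ``U`` with ``U_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))``;
2. a kernel-induced distance ``H_ij = sqrt(U_ii + U_jj - 2 U_ij)``;
3. a binary adjacency ``B`` from one of three sparsifiers
   (epsilon-neighborhood, k-nearest-neighbor, b-matching);
4. edge weights ``W`` over the surviving edges;
5. degrees ``D`` and the Laplacian ``L = D - W``.

All matrices are dense ``numpy`` arrays; this module targets the moderate
problem sizes (a few thousand instances) for which the closed-form
Laplacian-RLS solver downstream is practical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.spatial.distance import cdist

from .exceptions import InfeasibleGraphError, InvalidInputError, InvalidParameterError

__all__ = [
    "KernelConfig",
    "SparsifierConfig",
    "AffinityGraph",
    "gaussian_kernel",
    "kernel_cross",
    "kernel_to_distance",
    "sparsify_eps",
    "sparsify_knn",
    "sparsify_bmatch",
    "edge_weights",
    "laplacian",
    "build_graph",
    "median_heuristic_sigma",
    "export_edges",
]

# exact b-matching via integer programming is used up to this many nodes
BMATCH_EXACT_MAX_N = 12


@dataclass(frozen=True)
class KernelConfig:
    """Gaussian-kernel settings.

    Parameters
    ----------
    sigma : float
        Bandwidth of the Gaussian kernel, in feature-space distance units.
    """

    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be a positive real, got {self.sigma!r}")


@dataclass(frozen=True)
class SparsifierConfig:
    """Which sparsifier to apply and its parameter.

    ``method`` is one of ``eps``, ``knn`` or ``bmatch``; exactly the
    parameter matching the method is consulted.  ``eps_mode`` selects
    between the literal thresholding rule ``1 - H_ij <= eps`` ("as_printed")
    and the conventional epsilon-ball rule ``H_ij <= eps`` (default).
    """

    method: Literal["eps", "knn", "bmatch"] = "knn"
    eps: float = 0.5
    k: int = 10
    b: int = 10
    eps_mode: Literal["as_printed", "conventional"] = "conventional"

    def __post_init__(self) -> None:
        if self.method not in ("eps", "knn", "bmatch"):
            raise InvalidParameterError(f"unknown sparsifier method {self.method!r}")
        if self.eps_mode not in ("as_printed", "conventional"):
            raise InvalidParameterError(f"unknown eps_mode {self.eps_mode!r}")
        if self.method == "eps" and not (0.0 <= self.eps <= 1.0) and self.eps_mode == "as_printed":
            raise InvalidParameterError("eps must lie in [0, 1] for as_printed mode")
        if self.method == "knn" and self.k < 1:
            raise InvalidParameterError("k must be a positive integer")
        if self.method == "bmatch" and self.b < 1:
            raise InvalidParameterError("b must be a positive integer")


@dataclass
class AffinityGraph:
    """Bundle of the matrices produced by the graph pipeline.

    Attributes
    ----------
    U : symmetric kernel matrix with unit diagonal, entries in [0, 1]
    H : symmetric kernel-induced distance matrix, zero diagonal
    B : binary symmetric adjacency with zero diagonal
    W : symmetric non-negative edge weights
    D : diagonal degree matrix
    L : unnormalized Laplacian ``D - W``
    meta : provenance (sparsifier used, solver guarantees, weight scheme)
    """

    U: np.ndarray
    H: np.ndarray
    B: np.ndarray
    W: np.ndarray
    D: np.ndarray
    L: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.U.shape[0]


def _check_features(X: np.ndarray, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError(f"{name} must be 2-D, got shape {X.shape}")
    if np.isnan(X).any():
        raise InvalidInputError(f"{name} contains NaN feature values")
    return X


def gaussian_kernel(X: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    """Full Gaussian kernel matrix ``U_ij = exp(-||x_i-x_j||^2 / (2 sigma^2))``."""
    X = _check_features(X)
    if X.shape[0] < 2:
        raise InvalidInputError("need at least two instances to build a graph")
    sq = cdist(X, X, metric="sqeuclidean")
    U = np.exp(-sq / (2.0 * cfg.sigma**2))
    U = 0.5 * (U + U.T)
    np.fill_diagonal(U, 1.0)
    return U


def kernel_cross(X_test: np.ndarray, X_train: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    """``e x n`` Gaussian kernel between test and training instances."""
    X_test = _check_features(X_test, "X_test")
    X_train = _check_features(X_train, "X_train")
    if X_test.shape[1] != X_train.shape[1]:
        raise InvalidInputError(
            f"feature dimension mismatch: test d={X_test.shape[1]}, train d={X_train.shape[1]}"
        )
    sq = cdist(X_test, X_train, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * cfg.sigma**2))


def kernel_to_distance(U: np.ndarray) -> np.ndarray:
    """Kernel-induced distance ``H_ij = sqrt(U_ii + U_jj - 2 U_ij)``.

    For a Gaussian kernel (unit diagonal) this is ``sqrt(2 - 2 U_ij)`` and
    lies in ``[0, sqrt(2)]``.  Slightly negative radicands from round-off
    are clamped to zero with a warning.
    """
    U = np.asarray(U, dtype=float)
    d = np.diag(U)
    rad = d[:, None] + d[None, :] - 2.0 * U
    if rad.min() < -1e-9:
        warnings.warn(
            f"negative radicand ({rad.min():.3g}) in kernel-to-distance; clamping to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    H = np.sqrt(np.clip(rad, 0.0, None))
    np.fill_diagonal(H, 0.0)
    return 0.5 * (H + H.T)


def sparsify_eps(
    H: np.ndarray,
    eps: float,
    eps_mode: Literal["as_printed", "conventional"] = "conventional",
) -> np.ndarray:
    """Epsilon-neighborhood adjacency.

    ``conventional`` keeps an edge when ``H_ij <= eps`` (the usual
    epsilon-ball rule).  ``as_printed`` keeps an edge when
    ``1 - H_ij <= eps``, a literal alternative thresholding of the
    kernel-induced distance that retains the *large*-distance pairs;
    both are exposed because the two rules select complementary edge
    sets and the intended one is ambiguous in parts of the literature.
    """
    H = np.asarray(H, dtype=float)
    if eps_mode == "as_printed":
        if not (0.0 <= eps <= 1.0):
            raise InvalidParameterError("eps must lie in [0, 1] for as_printed mode")
        B = (1.0 - H <= eps).astype(np.int8)
    elif eps_mode == "conventional":
        B = (H <= eps).astype(np.int8)
    else:
        raise InvalidParameterError(f"unknown eps_mode {eps_mode!r}")
    np.fill_diagonal(B, 0)
    return B


def sparsify_knn(H: np.ndarray, k: int) -> np.ndarray:
    """k-nearest-neighbor adjacency, symmetrized with ``max(B_ij, B_ji)``.

    Each row keeps its ``k`` smallest off-diagonal distances before the
    symmetrizing max-merge; distance ties break toward the smaller
    instance index so the output is deterministic.
    """
    H = np.asarray(H, dtype=float)
    n = H.shape[0]
    if not (1 <= k < n):
        raise InvalidParameterError(f"k must satisfy 1 <= k < n, got k={k}, n={n}")
    Hd = H.copy()
    np.fill_diagonal(Hd, np.inf)
    # stable sort => ties broken by smaller column index
    order = np.argsort(Hd, axis=1, kind="stable")
    B = np.zeros((n, n), dtype=np.int8)
    rows = np.repeat(np.arange(n), k)
    B[rows, order[:, :k].ravel()] = 1
    B = np.maximum(B, B.T)
    np.fill_diagonal(B, 0)
    return B


def _bmatch_exact(H: np.ndarray, b: int) -> np.ndarray | None:
    """Minimum-weight b-matching by integer programming (small n only)."""
    n = H.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    m = ii.size
    cost = H[ii, jj]
    A = np.zeros((n, m))
    for e in range(m):
        A[ii[e], e] = 1.0
        A[jj[e], e] = 1.0
    res = milp(
        c=cost,
        constraints=LinearConstraint(A, b, b),
        integrality=np.ones(m),
        bounds=Bounds(0, 1),
    )
    if not res.success:
        return None
    x = np.round(res.x).astype(np.int8)
    B = np.zeros((n, n), dtype=np.int8)
    B[ii, jj] = x
    B = B + B.T
    return B


def _bmatch_circulant(n: int, b: int) -> np.ndarray:
    """Deterministic feasible b-regular graph (requires n*b even, b < n)."""
    B = np.zeros((n, n), dtype=np.int8)
    half = b // 2
    for off in range(1, half + 1):
        idx = np.arange(n)
        B[idx, (idx + off) % n] = 1
        B[idx, (idx - off) % n] = 1
    if b % 2 == 1:  # n must be even here since n*b is even
        idx = np.arange(n)
        B[idx, (idx + n // 2) % n] = 1
    return B


def _bmatch_greedy(H: np.ndarray, b: int) -> np.ndarray:
    """Greedy edge selection by ascending distance with alternating repair.

    Always returns a feasible b-regular adjacency; falls back to a
    circulant b-regular graph if the repair stalls.
    """
    n = H.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    order = np.lexsort((jj, ii, H[ii, jj]))  # weight, then smaller indices
    B = np.zeros((n, n), dtype=np.int8)
    deg = np.zeros(n, dtype=int)
    for e in order:
        i, j = int(ii[e]), int(jj[e])
        if deg[i] < b and deg[j] < b:
            B[i, j] = B[j, i] = 1
            deg[i] += 1
            deg[j] += 1
    # repair: raise the degree of two deficit slots at a time, either by a
    # direct edge between deficit nodes or by rewiring an existing edge
    # (s, t) into (u, s) + (v, t)
    for _ in range(4 * n * b):
        deficit = np.flatnonzero(deg < b)
        if deficit.size == 0:
            return B
        u = int(deficit[0])
        if deg[u] <= b - 2:
            v = u  # two open slots on the same node
        elif deficit.size >= 2:
            v = int(deficit[1])
        else:
            return _bmatch_circulant(n, b)  # odd total deficit: infeasible state
        if u != v and not B[u, v]:
            B[u, v] = B[v, u] = 1
            deg[u] += 1
            deg[v] += 1
            continue
        rewired = False
        es, et = np.nonzero(np.triu(B, k=1))
        for s, t in zip(es, et):
            s, t = int(s), int(t)
            if s in (u, v) or t in (u, v):
                continue
            for a, c in ((s, t), (t, s)):
                if not B[u, a] and not B[v, c] and (u != a) and (v != c):
                    B[s, t] = B[t, s] = 0
                    B[u, a] = B[a, u] = 1
                    B[v, c] = B[c, v] = 1
                    deg[u] += 1
                    deg[v] += 1
                    rewired = True
                    break
            if rewired:
                break
        if not rewired:
            return _bmatch_circulant(n, b)
    return _bmatch_circulant(n, b)


def sparsify_bmatch(
    H: np.ndarray, b: int, *, exact_max_n: int = BMATCH_EXACT_MAX_N
) -> tuple[np.ndarray, dict]:
    """b-matching adjacency: every node keeps exactly ``b`` edges.

    Minimizes the total retained distance ``sum_ij B_ij H_ij`` subject to
    ``sum_j B_ij = b``, ``B = B^T`` and a zero diagonal.  The problem is
    solved exactly by integer programming for ``n <= exact_max_n`` and by
    a deterministic greedy-with-repair heuristic above that size.

    Returns
    -------
    (B, info) : the adjacency and a dict with keys ``solver`` and
        ``optimal`` recording whether the output is certified optimal.
    """
    H = np.asarray(H, dtype=float)
    n = H.shape[0]
    if not (1 <= b < n):
        raise InfeasibleGraphError(f"b must satisfy 1 <= b < n, got b={b}, n={n}")
    if (n * b) % 2 != 0:
        raise InfeasibleGraphError(f"no b-regular graph exists: n*b = {n * b} is odd")
    if n <= exact_max_n:
        B = _bmatch_exact(H, b)
        if B is not None:
            return B, {"solver": "milp", "optimal": True}
    B = _bmatch_greedy(H, b)
    return B, {"solver": "greedy+repair", "optimal": False}


def edge_weights(
    H: np.ndarray,
    U: np.ndarray,
    B: np.ndarray,
    scheme: Literal["distance", "similarity"] = "distance",
) -> np.ndarray:
    """Edge weights over the sparsified graph.

    ``distance`` sets ``W_ij = H_ij B_ij`` (weighting edges by the
    kernel-induced distance); ``similarity`` sets ``W_ij = U_ij B_ij``
    (the standard similarity weighting).  Both are exposed because
    either reading is defensible; the default is ``distance``.
    """
    B = np.asarray(B)
    if scheme == "distance":
        return np.asarray(H, dtype=float) * B
    if scheme == "similarity":
        W = np.asarray(U, dtype=float) * B
        np.fill_diagonal(W, 0.0)
        return W
    raise InvalidParameterError(f"unknown weight scheme {scheme!r}")


def laplacian(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree matrix and unnormalized Laplacian ``L = D - W``."""
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T, atol=1e-10):
        raise InvalidInputError("weight matrix must be symmetric")
    if W.min() < 0:
        raise InvalidInputError("weight matrix must be non-negative")
    D = np.diag(W.sum(axis=1))
    return D, D - W


def median_heuristic_sigma(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance, a standard bandwidth default."""
    X = _check_features(X)
    d = cdist(X, X)
    iu = np.triu_indices(d.shape[0], k=1)
    med = float(np.median(d[iu]))
    return med if med > 0 else 1.0


def build_graph(
    X: np.ndarray,
    kernel_cfg: KernelConfig | None = None,
    sparsifier_cfg: SparsifierConfig | None = None,
    weight_scheme: Literal["distance", "similarity"] = "distance",
) -> AffinityGraph:
    """Run the full pipeline: kernel -> distance -> sparsify -> weights -> Laplacian."""
    kernel_cfg = kernel_cfg or KernelConfig()
    sparsifier_cfg = sparsifier_cfg or SparsifierConfig()
    U = gaussian_kernel(X, kernel_cfg)
    H = kernel_to_distance(U)
    meta: dict = {
        "sparsifier": sparsifier_cfg.method,
        "weight_scheme": weight_scheme,
        "sigma": kernel_cfg.sigma,
    }
    if sparsifier_cfg.method == "eps":
        B = sparsify_eps(H, sparsifier_cfg.eps, sparsifier_cfg.eps_mode)
        meta["eps"] = sparsifier_cfg.eps
        meta["eps_mode"] = sparsifier_cfg.eps_mode
    elif sparsifier_cfg.method == "knn":
        k = min(sparsifier_cfg.k, X.shape[0] - 1)
        B = sparsify_knn(H, k)
        meta["k"] = k
    else:
        B, info = sparsify_bmatch(H, sparsifier_cfg.b)
        meta["b"] = sparsifier_cfg.b
        meta.update(info)
    W = edge_weights(H, U, B, weight_scheme)
    D, L = laplacian(W)
    return AffinityGraph(U=U, H=H, B=B, W=W, D=D, L=L, meta=meta)


def export_edges(graph: AffinityGraph, path) -> None:
    """Write the weighted edge list as TSV (0-based ``i``, ``j``, ``weight``)."""
    ii, jj = np.nonzero(np.triu(graph.B, k=1))
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{graph.W[i, j]:.10g}\n")
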