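"""Multi-label manifold regularization (Laplacian RLS) with reliance weighting.

The model learns one scoring function per label in the RKHS of a Gaussian
kernel by minimizing

    (1/l) tr((Psi F - Y)^T (Psi F - Y)) + gamma_A ||f||_K^2
        + (gamma_I / n^2) tr(F^T L F)

over score matrices ``F = K Xi Theta``, where ``Psi`` masks the loss to the
``l`` labeled instances, ``L`` is the graph Laplacian built from all ``n``
instances, and ``Xi`` is a diagonal matrix of per-instance reliance weights
that lets labeled instances influence out-of-sample predictions more than
unlabeled ones.  The coefficient matrix has the closed form

    Theta = (Psi K Xi + l gamma_A I + (l gamma_I / n^2) L K Xi)^{-1} Y,

computed here by a linear solve.  With uniform reliance weights
``nu1 = nu2 = 1`` (``Xi = I``) the model is the plain multi-label
Laplacian-RLS ("ML-MR"); with ``nu1 = 1 > nu2 > 0`` it is the
reliance-weighted variant ("ML-MRRW").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .exceptions import (
    InvalidInputError,
    InvalidParameterError,
    NoLabeledInstancesError,
    NumericalError,
)
from .graph import AffinityGraph, KernelConfig, SparsifierConfig, build_graph, kernel_cross

__all__ = [
    "HyperParams",
    "LabelMask",
    "ModelState",
    "build_psi",
    "build_reliance",
    "objective_value",
    "fit",
    "fit_pipeline",
    "predict_scores",
    "transductive_scores",
    "threshold_labels",
    "save_model",
    "load_model",
]

# condition number beyond which the closed-form solve is not trusted
CONDITION_LIMIT = 1e12


@dataclass(frozen=True)
class HyperParams:
    """Regularization and reliance-weight hyperparameters.

    gamma_A : ambient-space (RKHS norm) penalty; must be > 0 so the
        minimizer is unique.
    gamma_I : intrinsic (graph-smoothness) penalty; 0 degenerates to
        weighted kernel RLS.
    nu1, nu2 : uniform reliance weights for labeled / unlabeled training
        instances.  ``nu1 = nu2 = 1`` gives the unweighted model;
        ``nu1 = 1, nu2 = 0.1`` is the recommended weighted setting.
    """

    gamma_A: float = 0.01
    gamma_I: float = 0.1
    nu1: float = 1.0
    nu2: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_A <= 0:
            raise InvalidParameterError("gamma_A must be strictly positive")
        if self.gamma_I < 0:
            raise InvalidParameterError("gamma_I must be non-negative")
        if self.nu1 < 0 or self.nu2 < 0:
            raise InvalidParameterError(
                "reliance weights must be non-negative to keep the weighted kernel PSD"
            )


@dataclass
class LabelMask:
    """Labeled/unlabeled bookkeeping in a labeled-first internal ordering.

    ``order`` maps internal position -> external index, so
    ``X[order]`` puts labeled instances first.  ``inverse`` undoes it.
    """

    order: np.ndarray
    inverse: np.ndarray
    l: int
    u: int

    @property
    def n(self) -> int:
        return self.l + self.u

    @property
    def psi(self) -> np.ndarray:
        """Diagonal of the loss mask: 1 for the first ``l`` positions."""
        p = np.zeros(self.n)
        p[: self.l] = 1.0
        return p


def build_psi(labeled: np.ndarray) -> LabelMask:
    """Build the loss mask from a boolean labeled-instance indicator.

    Labeled instances are moved (stably) to the front of the internal
    ordering; outputs are mapped back to the caller's order on request.
    """
    labeled = np.asarray(labeled, dtype=bool)
    l = int(labeled.sum())
    if l == 0:
        raise NoLabeledInstancesError("at least one labeled instance is required")
    order = np.concatenate([np.flatnonzero(labeled), np.flatnonzero(~labeled)])
    inverse = np.empty_like(order)
    inverse[order] = np.arange(order.size)
    return LabelMask(order=order, inverse=inverse, l=l, u=order.size - l)


def build_reliance(mask: LabelMask, nu1: float, nu2: float) -> np.ndarray:
    """Uniform reliance-weight diagonal: ``nu1`` for labeled, ``nu2`` for unlabeled."""
    if nu1 < 0 or nu2 < 0:
        raise InvalidParameterError("reliance weights must be non-negative")
    xi = np.full(mask.n, float(nu2))
    xi[: mask.l] = float(nu1)
    return xi


def objective_value(
    F: np.ndarray,
    Y: np.ndarray,
    mask: LabelMask,
    L_lap: np.ndarray,
    hyper: HyperParams,
    f_norm_sq: float,
) -> float:
    """Regularized empirical risk for a candidate score matrix ``F``.

    All arrays are in the internal (labeled-first) ordering.  ``f_norm_sq``
    is the squared RKHS norm of the candidate, ``tr(Theta^T K Theta)`` for a
    kernel expansion.  Used as an independent oracle target in tests.
    """
    F = np.asarray(F, dtype=float)
    Y = np.asarray(Y, dtype=float)
    R = mask.psi[:, None] * F - Y
    loss = np.trace(R.T @ R) / mask.l
    smooth = np.trace(F.T @ L_lap @ F) * hyper.gamma_I / mask.n**2
    return float(loss + hyper.gamma_A * f_norm_sq + smooth)


@dataclass
class ModelState:
    """A fitted model: expansion coefficients plus everything needed to predict."""

    theta: np.ndarray  # n x L, internal order
    xi: np.ndarray  # length-n reliance diagonal, internal order
    X_train: np.ndarray  # n x d, internal order
    kernel_cfg: KernelConfig
    hyper: HyperParams
    mask: LabelMask
    condition: float = np.nan

    @property
    def n_labels(self) -> int:
        return self.theta.shape[1]


def fit(
    K: np.ndarray,
    L_lap: np.ndarray,
    Y: np.ndarray,
    mask: LabelMask,
    xi: np.ndarray,
    hyper: HyperParams,
    X_train: np.ndarray | None = None,
    kernel_cfg: KernelConfig | None = None,
) -> ModelState:
    """Solve the closed-form coefficient system.

    ``(Psi K Xi + l gamma_A I + (l gamma_I / n^2) L K Xi) Theta = Y``

    All matrices must be in the internal labeled-first ordering.  The
    system is solved directly (never by forming the inverse) and its
    condition number is checked against :data:`CONDITION_LIMIT`.
    """
    K = np.asarray(K, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, l = mask.n, mask.l
    if K.shape != (n, n):
        raise InvalidInputError(f"kernel must be {n}x{n}, got {K.shape}")
    if Y.shape[0] != n:
        raise InvalidInputError(f"label matrix must have {n} rows, got {Y.shape[0]}")
    if np.any(Y[l:] != 0):
        raise InvalidInputError("unlabeled rows of Y must be all-zero")
    KXi = K * xi[None, :]
    A = mask.psi[:, None] * KXi + l * hyper.gamma_A * np.eye(n)
    if hyper.gamma_I != 0:
        A += (l * hyper.gamma_I / n**2) * (L_lap @ KXi)
    cond = float(np.linalg.cond(A))
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise NumericalError(
            f"coefficient system is ill-conditioned (cond ~ {cond:.3g}); "
            "increase gamma_A or check the kernel bandwidth"
        )
    theta = scipy.linalg.solve(A, Y)
    if not np.all(np.isfinite(theta)):
        raise NumericalError("non-finite coefficients from the linear solve")
    return ModelState(
        theta=theta,
        xi=np.asarray(xi, dtype=float),
        X_train=np.asarray(X_train, dtype=float) if X_train is not None else None,
        kernel_cfg=kernel_cfg,
        hyper=hyper,
        mask=mask,
        condition=cond,
    )


def fit_pipeline(
    X: np.ndarray,
    Y_partial: np.ndarray,
    kernel_cfg: KernelConfig | None = None,
    sparsifier_cfg: SparsifierConfig | None = None,
    hyper: HyperParams | None = None,
    weight_scheme: str = "distance",
) -> tuple[ModelState, AffinityGraph]:
    """Convenience composition: graph construction then the closed-form fit.

    ``Y_partial`` holds entries in {-1, 0, +1}; all-zero rows mark
    unlabeled instances.  The Gaussian kernel matrix of the graph doubles
    as the RKHS kernel ``K``.  Returns the fitted model together with the
    graph (whose matrices are in the internal labeled-first order).
    """
    X = np.asarray(X, dtype=float)
    Y_partial = np.asarray(Y_partial, dtype=float)
    if X.shape[0] != Y_partial.shape[0]:
        raise InvalidInputError("feature and label row counts differ")
    hyper = hyper or HyperParams()
    kernel_cfg = kernel_cfg or KernelConfig()
    labeled = np.any(Y_partial != 0, axis=1)
    mask = build_psi(labeled)
    Xo = X[mask.order]
    Yo = Y_partial[mask.order]
    graph = build_graph(Xo, kernel_cfg, sparsifier_cfg, weight_scheme)
    xi = build_reliance(mask, hyper.nu1, hyper.nu2)
    model = fit(graph.U, graph.L, Yo, mask, xi, hyper, X_train=Xo, kernel_cfg=kernel_cfg)
    return model, graph


def predict_scores(model: ModelState, X_test: np.ndarray) -> np.ndarray:
    """Out-of-sample decision scores ``F = K_e Xi Theta``."""
    if model.X_train is None or model.kernel_cfg is None:
        raise InvalidInputError("model was fitted without training features; cannot predict")
    K_e = kernel_cross(X_test, model.X_train, model.kernel_cfg)
    return (K_e * model.xi[None, :]) @ model.theta


def transductive_scores(model: ModelState, K: np.ndarray) -> np.ndarray:
    """Training-set scores ``F = K Xi Theta`` mapped back to the caller's order."""
    F = (K * model.xi[None, :]) @ model.theta
    return F[model.mask.inverse]


def threshold_labels(F: np.ndarray) -> np.ndarray:
    """Decision rule: score > 0 -> +1, otherwise -1 (ties at 0 map to -1)."""
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise InvalidInputError("scores must be finite")
    return np.where(F > 0, 1, -1).astype(np.int8)


_FORMAT_VERSION = 1


def save_model(model: ModelState, path: str | Path) -> None:
    """Serialize a fitted model to a single ``.npz`` archive."""
    np.savez(
        path,
        format_version=_FORMAT_VERSION,
        theta=model.theta,
        xi=model.xi,
        X_train=model.X_train,
        order=model.mask.order,
        l=model.mask.l,
        sigma=model.kernel_cfg.sigma,
        gamma_A=model.hyper.gamma_A,
        gamma_I=model.hyper.gamma_I,
        nu1=model.hyper.nu1,
        nu2=model.hyper.nu2,
        condition=model.condition,
    )


def load_model(path: str | Path) -> ModelState:
    with np.load(path) as z:
        if int(z["format_version"]) != _FORMAT_VERSION:
            raise InvalidInputError(f"unsupported model format version {z['format_version']}")
        order = z["order"]
        inverse = np.empty_like(order)
        inverse[order] = np.arange(order.size)
        l = int(z["l"])
        mask = LabelMask(order=order, inverse=inverse, l=l, u=order.size - l)
        return ModelState(
            theta=z["theta"],
            xi=z["xi"],
            X_train=z["X_train"],
            kernel_cfg=KernelConfig(sigma=float(z["sigma"])),
            hyper=HyperParams(
                gamma_A=float(z["gamma_A"]),
                gamma_I=float(z["gamma_I"]),
                nu1=float(z["nu1"]),
                nu2=float(z["nu2"]),
            ),
            mask=mask,
            condition=float(z["condition"]),
        )
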