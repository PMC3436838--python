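"""Per-visit comparison methods: least squares, ridge, lasso, trace-norm only.

The first three decouple over visits -- each visit's coefficient matrix is
fitted from that visit's feature matrix alone.  The trace-norm-only variant
is the joint solver with the row-group penalty switched off.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import scipy.linalg

from .core import (
    CoefficientTensor,
    GenotypeMatrix,
    ModelHyperparameters,
    PhenotypeTensor,
)
from . import solver

__all__ = [
    "Method",
    "BaselineSpec",
    "fit_linear_regression",
    "fit_ridge",
    "fit_lasso",
    "fit_trace_only",
    "fit_baseline_tensor",
]


class Method(str, Enum):
    LR = "lr"
    RR = "rr"
    LASSO = "lasso"
    TRACE_ONLY = "trace_only"


@dataclass(frozen=True)
class BaselineSpec:
    """Which baseline to run and with what penalty.

    ``penalty`` is ignored for LR; for TRACE_ONLY it is the trace-norm
    weight.  ``penalty_grid``, when given, asks the evaluation harness to
    tune the penalty on an inner cross-validation split.
    """

    method: Method
    penalty: float = 1.0
    solver_tol: float = 1e-6
    solver_max_iter: int = 1000
    penalty_grid: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        method = Method(self.method)
        object.__setattr__(self, "method", method)
        if self.penalty < 0:
            raise ValueError("penalty must be nonnegative")
        if self.solver_tol <= 0 or self.solver_max_iter < 1:
            raise ValueError("invalid solver controls")

    def with_penalty(self, penalty: float) -> "BaselineSpec":
        return BaselineSpec(self.method, penalty, self.solver_tol,
                            self.solver_max_iter, None)


def fit_linear_regression(X_t: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares coefficients for one visit.

    ``X_t`` is d x n (features x subjects), ``Y`` is n x c.
    """
    X_t = np.asarray(X_t, dtype=float)
    Y = np.asarray(Y, dtype=float)
    B, *_ = np.linalg.lstsq(X_t.T, Y, rcond=None)
    return B


def fit_ridge(X_t: np.ndarray, Y: np.ndarray, penalty: float) -> np.ndarray:
    """Closed-form ridge: ``(X_t X_t^T + penalty I)^{-1} X_t Y``."""
    if penalty <= 0:
        raise ValueError("ridge penalty must be positive")
    X_t = np.asarray(X_t, dtype=float)
    Y = np.asarray(Y, dtype=float)
    d = X_t.shape[0]
    A = X_t @ X_t.T + penalty * np.eye(d)
    return scipy.linalg.solve(A, X_t @ Y, assume_a="pos")


def fit_lasso(X_t: np.ndarray, Y: np.ndarray, penalty: float,
              solver_tol: float = 1e-6, solver_max_iter: int = 1000) -> np.ndarray:
    """Elementwise-l1 penalized least squares, by proximal gradient descent.

    Minimizes ``||X_t^T B - Y||_F^2 + penalty * sum|B|``; the problem is
    separable per SNP column, but one matrix-valued ISTA loop with step
    1/L (L the Lipschitz constant of the smooth part) handles all columns
    at once and decreases the objective at every step.
    """
    if penalty < 0:
        raise ValueError("lasso penalty must be nonnegative")
    X_t = np.asarray(X_t, dtype=float)
    Y = np.asarray(Y, dtype=float)
    d = X_t.shape[0]
    G = X_t @ X_t.T
    R = X_t @ Y
    L = 2.0 * max(scipy.linalg.eigh(G, eigvals_only=True,
                                    subset_by_index=[d - 1, d - 1])[0], 1e-12)
    step = 1.0 / L
    B = np.zeros((d, Y.shape[1]))
    for _ in range(solver_max_iter):
        grad = 2.0 * (G @ B - R)
        B_new = B - step * grad
        B_new = np.sign(B_new) * np.maximum(np.abs(B_new) - step * penalty, 0.0)
        delta = np.abs(B_new - B).max()
        B = B_new
        if delta <= solver_tol * max(1.0, np.abs(B).max()):
            break
    return B


def fit_trace_only(X: PhenotypeTensor, Y: GenotypeMatrix,
                   hp: ModelHyperparameters) -> solver.FitResult:
    """Joint fit with only the trace-norm penalty (``gamma1 = 0``)."""
    if hp.gamma2 <= 0:
        raise ValueError("trace-norm-only fit requires gamma2 > 0")
    hp0 = ModelHyperparameters(gamma1=0.0, gamma2=hp.gamma2, epsilon=hp.epsilon,
                               tol=hp.tol, max_iter=hp.max_iter)
    return solver.fit(X, Y, hp0)


def fit_baseline_tensor(spec: BaselineSpec, X: PhenotypeTensor,
                        Y: GenotypeMatrix) -> CoefficientTensor:
    """Fit the requested baseline on every visit and stack the results."""
    if spec.method is Method.TRACE_ONLY:
        hp = ModelHyperparameters(gamma1=0.0, gamma2=max(spec.penalty, 1e-12),
                                  tol=spec.solver_tol,
                                  max_iter=max(spec.solver_max_iter, 1))
        return fit_trace_only(X, Y, hp).coefficients
    mats = []
    for t in range(X.n_times):
        Xt = X.slice_at(t)
        if spec.method is Method.LR:
            mats.append(fit_linear_regression(Xt, Y.values))
        elif spec.method is Method.RR:
            mats.append(fit_ridge(Xt, Y.values, spec.penalty))
        elif spec.method is Method.LASSO:
            mats.append(fit_lasso(Xt, Y.values, spec.penalty,
                                  spec.solver_tol, spec.solver_max_iter))
        else:  # pragma: no cover
            raise ValueError(f"unknown method {spec.method}")
    return CoefficientTensor(np.stack(mats, axis=2))
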