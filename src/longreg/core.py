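"""Core data structures, tensor unfolding, regularizers and the model objective.

The model regresses per-subject SNP dosages on longitudinal imaging
features measured at T visits.  A coefficient matrix ``B_t`` (features x
SNPs) is learned per visit; the stack of these matrices is coupled across
visits by two penalties:

* a row-group penalty (the l2,1 norm of the mode-1 unfolding) that drives
  entire feature slabs -- all SNPs, all visits -- to zero jointly, and
* a trace norm on the mode-1 unfolding that favours a low-rank coefficient
  structure, tying together correlated SNP columns.

The full objective is::

    J(B) = sum_t ||X_t^T B_t - Y||_F^2
           + gamma1 * l21(unfold(B)) + gamma2 * tracenorm(unfold(B))

All functions here are pure; solvers live in :mod:`longreg.solver` and
file I/O in :mod:`longreg.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhenotypeTensor",
    "GenotypeMatrix",
    "CoefficientTensor",
    "ModelHyperparameters",
    "unfold_mode1",
    "fold_mode1",
    "tensor_l21_norm",
    "trace_norm",
    "longitudinal_loss",
    "objective_j2",
]


def _as_finite_array(values, name: str, ndim: int) -> np.ndarray:
    arr = np.array(values, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _default_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


def _check_ids(ids, expected: int, name: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(ids) != expected:
        raise ValueError(f"{name} has {len(ids)} entries, expected {expected}")
    if len(set(ids)) != len(ids):
        raise ValueError(f"{name} contains duplicates")
    return ids


@dataclass
class PhenotypeTensor:
    """Longitudinal imaging features.

    ``values`` has shape ``(d, n, T)``: feature k, subject i, visit t.
    All visits share the same feature and subject ordering; subjects with
    incomplete longitudinal coverage are excluded upstream, so no missing
    values are allowed.
    """

    values: np.ndarray
    feature_ids: list[str] = None
    subject_ids: list[str] = None
    time_labels: list[str] = None

    def __post_init__(self) -> None:
        self.values = _as_finite_array(self.values, "phenotype values", 3)
        d, n, T = self.values.shape
        if d < 1:
            raise ValueError("need at least one imaging feature (axis 'feature')")
        if n < 2:
            raise ValueError("need at least two subjects (axis 'subject')")
        if T < 1:
            raise ValueError("need at least one time point (axis 'time')")
        self.feature_ids = _check_ids(
            self.feature_ids if self.feature_ids is not None else _default_ids("feat", d),
            d, "feature_ids")
        self.subject_ids = _check_ids(
            self.subject_ids if self.subject_ids is not None else _default_ids("subj", n),
            n, "subject_ids")
        self.time_labels = _check_ids(
            self.time_labels if self.time_labels is not None else _default_ids("t", T),
            T, "time_labels")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    @property
    def n_times(self) -> int:
        return self.values.shape[2]

    def slice_at(self, t: int) -> np.ndarray:
        """The d x n feature matrix of visit ``t``."""
        return self.values[:, :, t]

    def restrict_times(self, times: Sequence[int]) -> "PhenotypeTensor":
        """Sub-tensor containing only the given visit indices, in order."""
        times = list(times)
        return PhenotypeTensor(
            self.values[:, :, times],
            feature_ids=list(self.feature_ids),
            subject_ids=list(self.subject_ids),
            time_labels=[self.time_labels[t] for t in times],
        )

    def restrict_subjects(self, idx: Sequence[int]) -> "PhenotypeTensor":
        idx = list(idx)
        return PhenotypeTensor(
            self.values[:, idx, :],
            feature_ids=list(self.feature_ids),
            subject_ids=[self.subject_ids[i] for i in idx],
            time_labels=list(self.time_labels),
        )

    @classmethod
    def from_matrices(cls, matrices: Sequence[np.ndarray], **kwargs) -> "PhenotypeTensor":
        """Stack per-visit d x n matrices into a tensor."""
        return cls(np.stack([np.asarray(m, dtype=float) for m in matrices], axis=2), **kwargs)


@dataclass
class GenotypeMatrix:
    """Subject x SNP dosage matrix (continuous additive coding, nominally [0, 2])."""

    values: np.ndarray
    snp_ids: list[str] = None
    subject_ids: list[str] = None

    def __post_init__(self) -> None:
        self.values = _as_finite_array(self.values, "genotype values", 2)
        n, c = self.values.shape
        if c < 1:
            raise ValueError("need at least one SNP (axis 'snp')")
        self.snp_ids = _check_ids(
            self.snp_ids if self.snp_ids is not None else _default_ids("snp", c),
            c, "snp_ids")
        self.subject_ids = _check_ids(
            self.subject_ids if self.subject_ids is not None else _default_ids("subj", n),
            n, "subject_ids")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def restrict_subjects(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            self.values[idx, :],
            snp_ids=list(self.snp_ids),
            subject_ids=[self.subject_ids[i] for i in idx],
        )


@dataclass
class CoefficientTensor:
    """Learned association weights, shape ``(d, c, T)``: feature x SNP x visit."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_finite_array(self.values, "coefficient values", 3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def slice_at(self, t: int) -> np.ndarray:
        return self.values[:, :, t]


@dataclass(frozen=True)
class ModelHyperparameters:
    """Regularization strengths and solver controls.

    ``gamma1`` weighs the row-group (l2,1) penalty, ``gamma2`` the trace
    norm.  ``epsilon`` smooths the reweighting so zero rows / rank-deficient
    unfoldings stay well-defined.
    """

    gamma1: float = 1.0
    gamma2: float = 1.0
    epsilon: float = 5e-5
    tol: float = 1e-6
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("gamma1 and gamma2 must be nonnegative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


def _coef_values(B) -> np.ndarray:
    if isinstance(B, CoefficientTensor):
        return B.values
    return _as_finite_array(B, "coefficient values", 3)


def unfold_mode1(B) -> np.ndarray:
    """Mode-1 unfolding ``[B_1 | B_2 | ... | B_T]`` of a (d, c, T) tensor.

    Column blocks are time-major: column ``t*c + j`` holds the weight of
    (SNP j, visit t).
    """
    v = _coef_values(B)
    d, c, T = v.shape
    return v.transpose(0, 2, 1).reshape(d, c * T)


def fold_mode1(M: np.ndarray, n_snps: int, n_times: int) -> CoefficientTensor:
    """Inverse of :func:`unfold_mode1`."""
    M = np.asarray(M, dtype=float)
    d, cT = M.shape
    if cT != n_snps * n_times:
        raise ValueError(f"cannot fold {M.shape} into ({d}, {n_snps}, {n_times})")
    return CoefficientTensor(M.reshape(d, n_times, n_snps).transpose(0, 2, 1))


def tensor_l21_norm(B) -> float:
    """Sum over features of the l2 norm of the feature's full (SNP, visit) slab.

    Equals the matrix l2,1 norm of the mode-1 unfolding.
    """
    v = _coef_values(B)
    return float(np.sqrt((v ** 2).sum(axis=(1, 2))).sum())


def trace_norm(M: np.ndarray) -> float:
    """Sum of singular values (nuclear norm)."""
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains non-finite values")
    return float(np.linalg.svd(M, compute_uv=False).sum())


def _check_aligned(X: PhenotypeTensor, B, Y: GenotypeMatrix) -> np.ndarray:
    Bv = _coef_values(B)
    d, n, T = X.values.shape
    if Bv.shape[0] != d:
        raise ValueError(
            f"feature axis mismatch: phenotypes have {d} features, "
            f"coefficients have {Bv.shape[0]}")
    if Bv.shape[2] != T:
        raise ValueError(
            f"time axis mismatch: phenotypes have {T} time points, "
            f"coefficients have {Bv.shape[2]}")
    if Y.values.shape[0] != n:
        raise ValueError(
            f"subject axis mismatch: phenotypes have {n} subjects, "
            f"genotypes have {Y.values.shape[0]}")
    if Bv.shape[1] != Y.values.shape[1]:
        raise ValueError(
            f"snp axis mismatch: genotypes have {Y.values.shape[1]} SNPs, "
            f"coefficients have {Bv.shape[1]}")
    return Bv


def longitudinal_loss(X: PhenotypeTensor, B, Y: GenotypeMatrix) -> float:
    """Sum over visits of the squared Frobenius residual ``||X_t^T B_t - Y||_F^2``."""
    Bv = _check_aligned(X, B, Y)
    total = 0.0
    for t in range(X.n_times):
        R = X.slice_at(t).T @ Bv[:, :, t] - Y.values
        total += float((R ** 2).sum())
    return total


def objective_j2(X: PhenotypeTensor, B, Y: GenotypeMatrix,
                 hp: ModelHyperparameters) -> float:
    """The full penalized objective J(B); see module docstring.

    With ``gamma1 = gamma2 = 0`` it reduces to the decoupled per-visit
    least-squares loss; with ``gamma2 = 0`` only the row-group penalty acts;
    with ``gamma1 = 0`` only the trace norm (the "trace-norm only" variant).
    """
    value = longitudinal_loss(X, B, Y)
    if hp.gamma1 > 0:
        value += hp.gamma1 * tensor_l21_norm(B)
    if hp.gamma2 > 0:
        value += hp.gamma2 * trace_norm(unfold_mode1(B))
    return value
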