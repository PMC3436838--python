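"""Cross-validated genotype prediction from longitudinal phenotypes.

Implements the evaluation protocol: seeded k-fold cross-validation in
which every method sees identical folds, per-SNP Pearson correlation and
pooled RMSE between predicted and observed dosages, and a time-point
ablation that re-runs the protocol on growing visit prefixes.

Conventions (fixed here because they matter for comparability):

* correlation is computed per SNP column over test subjects, then averaged
  over columns; zero-variance columns are dropped from the average with a
  logged warning;
* RMSE is pooled over all test entries;
* prediction averages the per-visit linear predictors over the visits the
  model was fitted on;
* features are z-scored and responses centered using training-fold
  statistics only (``standardize=True``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    CoefficientTensor,
    GenotypeMatrix,
    ModelHyperparameters,
    PhenotypeTensor,
)
from .baselines import BaselineSpec, fit_baseline_tensor
from . import solver

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "CVReport",
    "MethodSpec",
    "kfold_indices",
    "predict",
    "pearson_corr",
    "rmse",
    "fit_method",
    "cross_validate",
    "time_ablation",
]

# a method is either a joint-model hyperparameter setting, a baseline spec,
# or a sequence of either to be tuned on an inner split
MethodSpec = Union[ModelHyperparameters, BaselineSpec,
                   Sequence[Union[ModelHyperparameters, BaselineSpec]]]


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 5
    seed: int = 0
    standardize: bool = True
    time_subset: tuple[int, ...] | None = None  # None = all visits

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.time_subset is not None:
            ts = tuple(int(t) for t in self.time_subset)
            if not ts:
                raise ValueError("time_subset must be non-empty")
            if list(ts) != sorted(set(ts)):
                raise ValueError("time_subset must be sorted and duplicate-free")
            object.__setattr__(self, "time_subset", ts)


@dataclass
class CVReport:
    """Per-fold scores plus per-method means."""

    per_fold: pd.DataFrame  # columns: fold, method, corr, rmse
    mean_corr: dict[str, float]
    mean_rmse: dict[str, float]

    def summary(self) -> pd.DataFrame:
        rows = [{"method": m, "mean_corr": self.mean_corr[m],
                 "mean_rmse": self.mean_rmse[m]} for m in self.mean_corr]
        return pd.DataFrame(rows)

    def write(self, table_path, summary_path) -> None:
        self.per_fold.to_csv(table_path, sep="\t", index=False)
        with open(summary_path, "w") as fh:
            for m in self.mean_corr:
                fh.write(f"mean_corr.{m}\t{self.mean_corr[m]:.10g}\n")
                fh.write(f"mean_rmse.{m}\t{self.mean_rmse[m]:.10g}\n")


def kfold_indices(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition into folds with sizes differing by at most one."""
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds number of subjects n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def predict(X_test: PhenotypeTensor, B: CoefficientTensor) -> np.ndarray:
    """Average over visits of the per-visit linear predictor ``X_t^T B_t``."""
    if B.shape[2] != X_test.n_times:
        raise ValueError(
            f"time axis mismatch: phenotypes have {X_test.n_times} time points, "
            f"coefficients have {B.shape[2]}")
    if B.shape[0] != X_test.n_features:
        raise ValueError(
            f"feature axis mismatch: phenotypes have {X_test.n_features}, "
            f"coefficients have {B.shape[0]}")
    preds = [X_test.slice_at(t).T @ B.slice_at(t) for t in range(X_test.n_times)]
    return np.mean(preds, axis=0)


def pearson_corr(Yhat: np.ndarray, Y: np.ndarray) -> float:
    """Mean over SNP columns of the per-column Pearson correlation."""
    Yhat = np.asarray(Yhat, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Yhat.shape != Y.shape:
        raise ValueError(f"shape mismatch: {Yhat.shape} vs {Y.shape}")
    if Y.shape[0] < 2:
        raise ValueError("need at least two subjects for a correlation")
    a = Yhat - Yhat.mean(axis=0)
    b = Y - Y.mean(axis=0)
    sa = np.sqrt((a ** 2).sum(axis=0))
    sb = np.sqrt((b ** 2).sum(axis=0))
    ok = (sa > 0) & (sb > 0)
    if not np.any(ok):
        raise ValueError("all columns have zero variance; correlation undefined")
    if not np.all(ok):
        logger.warning("excluding %d zero-variance column(s) from the "
                       "correlation average", int((~ok).sum()))
    r = (a[:, ok] * b[:, ok]).sum(axis=0) / (sa[ok] * sb[ok])
    return float(np.clip(r, -1.0, 1.0).mean())


def rmse(Yhat: np.ndarray, Y: np.ndarray) -> float:
    """Root mean squared error pooled over all entries."""
    Yhat = np.asarray(Yhat, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Yhat.shape != Y.shape:
        raise ValueError(f"shape mismatch: {Yhat.shape} vs {Y.shape}")
    return float(np.sqrt(np.mean((Yhat - Y) ** 2)))


class _Standardizer:
    """Z-scores features per (feature, visit) and centers responses per SNP,
    with statistics from the training subjects only."""

    def __init__(self, X_train: PhenotypeTensor, Y_train: GenotypeMatrix):
        v = X_train.values
        self.x_mean = v.mean(axis=1, keepdims=True)            # (d, 1, T)
        sd = v.std(axis=1, keepdims=True)
        self.x_sd = np.where(sd > 1e-12, sd, 1.0)
        self.y_mean = Y_train.values.mean(axis=0, keepdims=True)  # (1, c)

    def transform_X(self, X: PhenotypeTensor) -> PhenotypeTensor:
        return PhenotypeTensor((X.values - self.x_mean) / self.x_sd,
                               feature_ids=list(X.feature_ids),
                               subject_ids=list(X.subject_ids),
                               time_labels=list(X.time_labels))

    def transform_Y(self, Y: GenotypeMatrix) -> GenotypeMatrix:
        return GenotypeMatrix(Y.values - self.y_mean,
                              snp_ids=list(Y.snp_ids),
                              subject_ids=list(Y.subject_ids))

    def add_y_mean(self, Yhat: np.ndarray) -> np.ndarray:
        return Yhat + self.y_mean


def fit_method(spec, X: PhenotypeTensor, Y: GenotypeMatrix) -> CoefficientTensor:
    """Fit one (non-tuned) method and return its coefficient stack."""
    if isinstance(spec, ModelHyperparameters):
        return solver.fit(X, Y, spec).coefficients
    if isinstance(spec, BaselineSpec):
        return fit_baseline_tensor(spec, X, Y)
    raise TypeError(f"unsupported method spec {type(spec).__name__}")


def _candidates(spec) -> list:
    if isinstance(spec, BaselineSpec) and spec.penalty_grid is not None:
        return [spec.with_penalty(p) for p in spec.penalty_grid]
    if isinstance(spec, (list, tuple)):
        return list(spec)
    return [spec]


def _tune(spec, X: PhenotypeTensor, Y: GenotypeMatrix, seed: int,
          standardize: bool, n_inner: int = 3):
    """Pick the candidate with the best inner-CV mean correlation."""
    cands = _candidates(spec)
    if len(cands) == 1:
        return cands[0]
    n = X.n_subjects
    folds = kfold_indices(n, min(n_inner, n), seed + 9173)
    best, best_key = None, None
    for cand in cands:
        corrs, errs = [], []
        for test_idx in folds:
            try:
                corr, err = _score_fold(cand, X, Y, test_idx, standardize)
            except ValueError:
                # degenerate candidate (e.g. a penalty so large every
                # prediction is constant): score it as worst possible
                corr, err = -np.inf, np.inf
            corrs.append(corr)
            errs.append(err)
        key = (-float(np.mean(corrs)), float(np.mean(errs)))
        if best_key is None or key < best_key:
            best, best_key = cand, key
    return best


def _score_fold(spec, X: PhenotypeTensor, Y: GenotypeMatrix,
                test_idx: np.ndarray, standardize: bool) -> tuple[float, float]:
    n = X.n_subjects
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    X_tr, Y_tr = X.restrict_subjects(train_idx), Y.restrict_subjects(train_idx)
    X_te, Y_te = X.restrict_subjects(test_idx), Y.restrict_subjects(test_idx)
    if standardize:
        std = _Standardizer(X_tr, Y_tr)
        B = fit_method(spec, std.transform_X(X_tr), std.transform_Y(Y_tr))
        Yhat = std.add_y_mean(predict(std.transform_X(X_te), B))
    else:
        B = fit_method(spec, X_tr, Y_tr)
        Yhat = predict(X_te, B)
    return pearson_corr(Yhat, Y_te.values), rmse(Yhat, Y_te.values)


def cross_validate(X: PhenotypeTensor, Y: GenotypeMatrix,
                   methods: Mapping[str, MethodSpec], cfg: CVConfig) -> CVReport:
    """Score every method on identical seeded folds.

    Methods given as candidate lists (or baseline specs carrying a
    ``penalty_grid``) are tuned per training fold on an inner 3-fold split.
    """
    if X.subject_ids != Y.subject_ids:
        raise ValueError("phenotype and genotype subject ids are not aligned")
    if cfg.time_subset is not None:
        X = X.restrict_times(cfg.time_subset)
    n = X.n_subjects
    folds = kfold_indices(n, cfg.n_folds, cfg.seed)
    rows = []
    for fold_no, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        X_tr = X.restrict_subjects(train_idx)
        Y_tr = Y.restrict_subjects(train_idx)
        for name, spec in methods.items():
            chosen = _tune(spec, X_tr, Y_tr, cfg.seed, cfg.standardize)
            corr, err = _score_fold(chosen, X, Y, test_idx, cfg.standardize)
            rows.append({"fold": fold_no, "method": name,
                         "corr": corr, "rmse": err})
    per_fold = pd.DataFrame(rows)
    grouped = per_fold.groupby("method", sort=False)
    return CVReport(
        per_fold=per_fold,
        mean_corr={m: float(g["corr"].mean()) for m, g in grouped},
        mean_rmse={m: float(g["rmse"].mean()) for m, g in grouped},
    )


def time_ablation(X: PhenotypeTensor, Y: GenotypeMatrix,
                  methods: Mapping[str, MethodSpec], cfg: CVConfig) -> pd.DataFrame:
    """Cross-validate on growing visit prefixes {1}, {1,2}, ..., {1..T}.

    The fold partition is identical across prefixes (same seed, same n), so
    rows are directly comparable.
    """
    rows = []
    for t_max in range(1, X.n_times + 1):
        sub = tuple(range(t_max))
        sub_cfg = CVConfig(n_folds=cfg.n_folds, seed=cfg.seed,
                           standardize=cfg.standardize, time_subset=sub)
        report = cross_validate(X, Y, methods, sub_cfg)
        for m in report.mean_corr:
            rows.append({
                "time_subset": "+".join(X.time_labels[t] for t in sub),
                "n_times": t_max,
                "method": m,
                "mean_corr": report.mean_corr[m],
                "mean_rmse": report.mean_rmse[m],
            })
    return pd.DataFrame(rows)
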