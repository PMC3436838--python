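"""Delimited-text readers and writers.

Interchange format: tab-separated tables with a header row.  Phenotype
files carry subjects in rows (first column ``subject_id``) and features in
columns, one file per visit; genotype files carry subjects in rows and
SNPs in columns.  Subjects are aligned strictly by id -- any mismatch is a
hard error, never a silent intersection.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CoefficientTensor, GenotypeMatrix, PhenotypeTensor

__all__ = [
    "load_phenotype_tensor",
    "write_phenotype_tensor",
    "load_genotype_matrix",
    "write_genotype_matrix",
    "write_coefficients",
    "load_coefficients",
]

SUBJECT_COL = "subject_id"


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus data columns")
    return df


def _numeric_block(df: pd.DataFrame, path) -> np.ndarray:
    data = df.iloc[:, 1:]
    out = np.empty(data.shape)
    for j, col in enumerate(data.columns):
        converted = pd.to_numeric(data[col], errors="coerce")
        bad = converted.isna() & data[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {data[col].iloc[row]!r} at row "
                f"{row + 2}, column {col!r}")
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise ValueError(f"{path}: missing value at row {row + 2}, column {col!r}")
        out[:, j] = converted.to_numpy()
    if not np.all(np.isfinite(out)):
        raise ValueError(f"{path}: non-finite values present")
    return out


def load_phenotype_tensor(paths: Sequence[str | os.PathLike],
                          time_labels: Sequence[str] | None = None) -> PhenotypeTensor:
    """Read one table per visit and stack them, features x subjects x visits.

    All files must list the same subjects and the same features in the same
    order; the first discrepancy is reported, not repaired.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("need at least one phenotype file")
    slabs, subjects, features = [], None, None
    for path in paths:
        df = _read_table(path)
        subj = [str(s) for s in df.iloc[:, 0]]
        feats = [str(f) for f in df.columns[1:]]
        if subjects is None:
            subjects, features = subj, feats
        else:
            if feats != features:
                diff = next(i for i, (a, b) in enumerate(
                    zip(feats + ["<missing>"] * len(features),
                        features + ["<missing>"] * len(feats))) if a != b)
                raise ValueError(
                    f"{path}: feature order differs from {paths[0]} at column "
                    f"{diff + 2} ({feats[diff] if diff < len(feats) else '<missing>'!r}"
                    f" vs {features[diff] if diff < len(features) else '<missing>'!r})")
            if subj != subjects:
                diff = next(i for i, (a, b) in enumerate(
                    zip(subj + ["<missing>"] * len(subjects),
                        subjects + ["<missing>"] * len(subj))) if a != b)
                raise ValueError(
                    f"{path}: subject order differs from {paths[0]} at row "
                    f"{diff + 2} ({subj[diff] if diff < len(subj) else '<missing>'!r}"
                    f" vs {subjects[diff] if diff < len(subjects) else '<missing>'!r})")
        slabs.append(_numeric_block(df, path).T)  # -> features x subjects
    labels = list(time_labels) if time_labels is not None else \
        [f"t{i}" for i in range(len(paths))]
    return PhenotypeTensor(np.stack(slabs, axis=2),
                           feature_ids=features, subject_ids=subjects,
                           time_labels=labels)


def write_phenotype_tensor(X: PhenotypeTensor,
                           paths: Sequence[str | os.PathLike]) -> None:
    if len(paths) != X.n_times:
        raise ValueError(f"need {X.n_times} paths, got {len(paths)}")
    for t, path in enumerate(paths):
        df = pd.DataFrame(X.slice_at(t).T, columns=X.feature_ids)
        df.insert(0, SUBJECT_COL, X.subject_ids)
        df.to_csv(path, sep="\t", index=False)


def load_genotype_matrix(path: str | os.PathLike,
                         subject_order: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read a subject x SNP dosage table.

    Handles the plain dialect (``subject_id`` first) and the dosage-export
    dialect whose first two columns are FID/IID-style ids (FID dropped, IID
    used as the subject id).  When ``subject_order`` is given the rows are
    reordered to match it; missing or extra subjects are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.upper() for c in df.columns[:2]]
    if len(df.columns) >= 3 and cols[0] in ("FID", "FAMID") and cols[1] in ("IID", "INDID"):
        df = df.drop(columns=df.columns[0])
    subjects = [str(s) for s in df.iloc[:, 0]]
    snps = [str(s) for s in df.columns[1:]]
    values = _numeric_block(df, path)
    G = GenotypeMatrix(values, snp_ids=snps, subject_ids=subjects)
    if subject_order is not None:
        wanted = [str(s) for s in subject_order]
        have = set(subjects)
        missing = [s for s in wanted if s not in have]
        if missing:
            raise ValueError(
                f"{path}: subjects missing from genotype file: {missing[:5]}")
        extra = [s for s in subjects if s not in set(wanted)]
        if extra:
            raise ValueError(
                f"{path}: genotype file has subjects absent from phenotypes: "
                f"{extra[:5]}")
        pos = {s: i for i, s in enumerate(subjects)}
        G = G.restrict_subjects([pos[s] for s in wanted])
    return G


def write_genotype_matrix(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(G.values, columns=G.snp_ids)
    df.insert(0, SUBJECT_COL, G.subject_ids)
    df.to_csv(path, sep="\t", index=False)


def write_coefficients(B: CoefficientTensor, feature_ids: Sequence[str],
                       snp_ids: Sequence[str], time_labels: Sequence[str],
                       out_dir: str | os.PathLike) -> list[str]:
    """One features x SNPs table per visit; returns the written paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for t, label in enumerate(time_labels):
        df = pd.DataFrame(B.slice_at(t), columns=list(snp_ids))
        df.insert(0, "feature_id", list(feature_ids))
        path = os.path.join(out_dir, f"coefficients_{label}.tsv")
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
        paths.append(path)
    return paths


def load_coefficients(paths: Sequence[str | os.PathLike]
                      ) -> tuple[CoefficientTensor, list[str], list[str]]:
    """Read per-visit coefficient tables back into a tensor.

    Returns ``(B, feature_ids, snp_ids)``; files must agree on both axes.
    """
    slabs, features, snps = [], None, None
    for path in paths:
        df = _read_table(path)
        feats = [str(f) for f in df.iloc[:, 0]]
        cols = [str(c) for c in df.columns[1:]]
        if features is None:
            features, snps = feats, cols
        elif feats != features or cols != snps:
            raise ValueError(f"{path}: axes differ from {paths[0]}")
        slabs.append(_numeric_block(df, path))
    return (CoefficientTensor(np.stack(slabs, axis=2)), features, snps)
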