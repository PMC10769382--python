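"""Typed matrix containers, delimited-file I/O, and kinship computation.

All downstream code works on three labelled numeric matrices: a trait
matrix (individuals x traits), a genotype dosage matrix (individuals x
markers, dosages in [0, 1]) and an optional kinship matrix (individuals x
individuals).  Files are plain CSV/TSV with a header row of labels and a
first column of row labels; missing values are rejected outright rather
than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitMatrix",
    "GenotypeMatrix",
    "KinshipMatrix",
    "CovariateMatrix",
    "read_matrix",
    "write_matrix",
    "compute_kinship",
    "align_by_ids",
]

SYMMETRY_TOL = 1e-10
PSD_TOL = 1e-8


class MatrixValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


def _check_no_missing(values: np.ndarray, rows: Sequence[str], cols: Sequence[str]) -> None:
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise MatrixValidationError(
            "no missing data supported: missing/non-finite value at "
            f"row {rows[i]!r}, column {cols[j]!r} "
            f"({bad.shape[0]} offending cell(s) total)"
        )


@dataclass
class TraitMatrix:
    """n x m matrix of quantitative traits (rows = individuals)."""

    values: np.ndarray
    trait_ids: list[str]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixValidationError("trait matrix must be 2-dimensional")
        n, m = self.values.shape
        if n < 3:
            raise MatrixValidationError(f"need at least 3 individuals, got {n}")
        if len(self.trait_ids) != m or len(self.individual_ids) != n:
            raise MatrixValidationError("label lengths do not match matrix shape")
        _check_no_missing(self.values, self.individual_ids, self.trait_ids)
        variances = self.values.var(axis=0)
        dead = np.flatnonzero(variances == 0.0)
        if dead.size:
            names = [self.trait_ids[k] for k in dead]
            raise MatrixValidationError(f"traits with zero variance: {names}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeMatrix:
    """n x p matrix of allele dosages in [0, 1] (rows = individuals).

    Zero-variance (monomorphic) markers are legal on input but flagged in
    ``zero_variance_markers``; kinship computation excludes them and scans
    assign them LOD 0.
    """

    values: np.ndarray
    marker_ids: list[str]
    individual_ids: list[str]
    zero_variance_markers: list[str] = field(default_factory=list, init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixValidationError("genotype matrix must be 2-dimensional")
        n, p = self.values.shape
        if len(self.marker_ids) != p or len(self.individual_ids) != n:
            raise MatrixValidationError("label lengths do not match matrix shape")
        _check_no_missing(self.values, self.individual_ids, self.marker_ids)
        if self.values.size and (self.values.min() < 0.0 or self.values.max() > 1.0):
            raise MatrixValidationError("allele dosages must lie in [0, 1]")
        variances = self.values.var(axis=0)
        self.zero_variance_markers = [
            self.marker_ids[k] for k in np.flatnonzero(variances == 0.0)
        ]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def polymorphic_mask(self) -> np.ndarray:
        """Boolean mask over markers: True where the marker varies."""
        return self.values.var(axis=0) > 0.0


@dataclass
class KinshipMatrix:
    """n x n symmetric positive semi-definite relatedness matrix."""

    values: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise MatrixValidationError(
                f"kinship must be square with matching labels, got {self.values.shape}"
            )
        _check_no_missing(self.values, self.individual_ids, self.individual_ids)
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            i, j = np.unravel_index(
                np.abs(self.values - self.values.T).argmax(), self.values.shape
            )
            raise MatrixValidationError(
                f"kinship matrix not symmetric: K[{i},{j}]={self.values[i, j]!r} vs "
                f"K[{j},{i}]={self.values[j, i]!r} (max asymmetry {asym:.3g})"
            )
        eigvals = np.linalg.eigvalsh(self.values)
        largest = max(eigvals[-1], 0.0)
        if eigvals[0] < -PSD_TOL * max(largest, 1.0):
            raise MatrixValidationError(
                f"kinship matrix is not positive semi-definite "
                f"(smallest eigenvalue {eigvals[0]:.3g})"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class CovariateMatrix:
    """n x q design of marker-independent covariates; first column = intercept."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise MatrixValidationError("covariates contain missing values")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise MatrixValidationError("covariate matrix is rank deficient")

    @classmethod
    def intercept_only(cls, n: int) -> "CovariateMatrix":
        return cls(np.ones((n, 1)))

    @property
    def q(self) -> int:
        return self.values.shape[1]


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0, header=0)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise MatrixValidationError(
                    f"non-numeric value in column {col!r}, row {bad[0]!r}"
                )
            df[col] = coerced
    if df.isna().any().any():
        col = df.columns[df.isna().any().to_numpy()][0]
        row = df.index[df[col].isna()][0]
        raise MatrixValidationError(
            f"no missing data supported: missing value at row {row!r}, column {col!r}"
        )
    return df


def read_matrix(
    path: str | Path,
    kind: str,
    rows_are_individuals: bool = True,
    delimiter: str | None = None,
) -> TraitMatrix | GenotypeMatrix | KinshipMatrix:
    """Read a labelled numeric table as a typed matrix.

    Parameters
    ----------
    path
        CSV (comma) or TSV (tab) file with a header row and a label column.
    kind
        One of ``"trait"``, ``"genotype"``, ``"kinship"``.
    rows_are_individuals
        If False the table is transposed after reading (trait tables are
        often shipped traits-by-individuals).  Ignored for kinship.
    """
    df = _read_table(path, delimiter)
    if kind != "kinship" and not rows_are_individuals:
        df = df.T
    values = df.to_numpy(dtype=float)
    row_ids = [str(r) for r in df.index]
    col_ids = [str(c) for c in df.columns]
    if kind == "trait":
        return TraitMatrix(values, trait_ids=col_ids, individual_ids=row_ids)
    if kind == "genotype":
        return GenotypeMatrix(values, marker_ids=col_ids, individual_ids=row_ids)
    if kind == "kinship":
        if row_ids != col_ids:
            raise MatrixValidationError("kinship row and column labels differ")
        return KinshipMatrix(values, individual_ids=row_ids)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(
    matrix: TraitMatrix | GenotypeMatrix | KinshipMatrix,
    path: str | Path,
    delimiter: str | None = None,
) -> None:
    """Write a typed matrix back to CSV/TSV (delimiter inferred from suffix)."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    if isinstance(matrix, TraitMatrix):
        cols, rows = matrix.trait_ids, matrix.individual_ids
    elif isinstance(matrix, GenotypeMatrix):
        cols, rows = matrix.marker_ids, matrix.individual_ids
    elif isinstance(matrix, KinshipMatrix):
        cols = rows = matrix.individual_ids
    else:
        raise TypeError(type(matrix))
    pd.DataFrame(matrix.values, index=rows, columns=cols).to_csv(path, sep=delimiter)


def compute_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Kinship from genotypes: K = Z Z^T / p' over polymorphic markers.

    Each included marker column is standardized to mean 0 and (population)
    variance 1, so the diagonal of K averages 1.  Zero-variance markers are
    excluded; an all-monomorphic panel is an error.  Any user-supplied
    kinship bypasses this estimator entirely.
    """
    mask = G.polymorphic_mask()
    if not mask.any():
        raise MatrixValidationError("all markers have zero variance; cannot compute kinship")
    X = G.values[:, mask]
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    K = (Z @ Z.T) / Z.shape[1]
    K = 0.5 * (K + K.T)  # exact symmetry against float drift
    return KinshipMatrix(K, individual_ids=list(G.individual_ids))


def align_by_ids(
    Y: TraitMatrix,
    G: GenotypeMatrix,
    K: KinshipMatrix | None = None,
) -> tuple[TraitMatrix, GenotypeMatrix, KinshipMatrix | None]:
    """Reorder genotype (and kinship) rows to match the trait individuals.

    Every input must carry the same set of individual IDs; reordering is by
    exact ID match and a mismatch is an error — silent misalignment is the
    classic mixed-model bug.
    """
    ref = Y.individual_ids
    if set(ref) != set(G.individual_ids) or len(set(ref)) != len(ref):
        missing = sorted(set(ref) ^ set(G.individual_ids))[:5]
        raise MatrixValidationError(
            f"individual IDs of traits and genotypes differ (examples: {missing})"
        )
    g_order = [G.individual_ids.index(i) for i in ref]
    G2 = GenotypeMatrix(
        G.values[g_order], marker_ids=list(G.marker_ids), individual_ids=list(ref)
    )
    K2 = None
    if K is not None:
        if set(ref) != set(K.individual_ids):
            raise MatrixValidationError("individual IDs of kinship differ from traits")
        k_order = [K.individual_ids.index(i) for i in ref]
        K2 = KinshipMatrix(K.values[np.ix_(k_order, k_order)], individual_ids=list(ref))
    return Y, G2, K2
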