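"""LOD scores for all trait x marker pairs from one matrix product.

For a one-degree-of-freedom test the LOD score is a function of the
Pearson correlation between trait and marker:

    LOD_ij = (n/2) log10(RSS0_i / RSS1_ij) = -(n/2) log10(1 - r_ij^2)

so after standardizing every trait and marker column to zero mean and unit
norm, the full m x p correlation matrix — and hence the full LOD matrix —
is a single matrix multiplication r = Ys^T Gs.  With unit-norm columns no
1/n factor appears; this is the only convention under which |r| <= 1 and
the regression-RSS identity holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StandardizedMatrix",
    "LodMatrix",
    "standardize_columns",
    "residualize_columns",
    "unit_normalize_columns",
    "pairwise_lod",
    "lod_from_correlation",
    "lod_to_loglik",
    "loglik_to_lod",
    "lod_to_neglog10p",
]

LOG10 = math.log(10.0)
# |r| clipped below 1 so perfectly collinear pairs give a large finite LOD
R_CLIP = 1.0 - 1e-12


@dataclass
class StandardizedMatrix:
    """Columns with zero mean and unit Euclidean norm."""

    values: np.ndarray
    scale_kind: str = "center-unit-norm"


@dataclass
class LodMatrix:
    """m x p LOD scores from 1-df tests."""

    lod: np.ndarray
    df: int = 1
    n_used: int = 0


def standardize_columns(M: np.ndarray, column_ids=None) -> StandardizedMatrix:
    """Center each column and scale it to unit norm; errors on constants."""
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    centered = M - M.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    dead = np.flatnonzero(norms == 0.0)
    if dead.size:
        labels = [column_ids[k] for k in dead] if column_ids is not None else dead.tolist()
        raise ValueError(f"zero-variance column(s): {labels}")
    return StandardizedMatrix(values=centered / norms)


def residualize_columns(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Project each column of M off the column span of X (QR-based)."""
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    Q, _ = np.linalg.qr(np.atleast_2d(np.asarray(X, dtype=float)))
    return M - Q @ (Q.T @ M)


def unit_normalize_columns(M: np.ndarray) -> np.ndarray:
    """Scale columns to unit norm without re-centering (post-residualization).

    Columns with zero norm (e.g. markers lying in the covariate span) are
    left at zero so they contribute r = 0 and LOD = 0.
    """
    M = np.asarray(M, dtype=float)
    norms = np.linalg.norm(M, axis=0)
    safe = np.where(norms == 0.0, 1.0, norms)
    return M / safe


def lod_from_correlation(r: np.ndarray, n: int) -> np.ndarray:
    """Map correlations to LOD scores: -(n/2) log10(1 - r^2), r clipped."""
    r = np.clip(np.asarray(r, dtype=float), -R_CLIP, R_CLIP)
    return -(n / 2.0) * np.log10(1.0 - r**2)


def pairwise_lod(
    Ys: StandardizedMatrix | np.ndarray,
    Gs: StandardizedMatrix | np.ndarray,
    n: int,
) -> LodMatrix:
    """LOD for every (trait, marker) pair via r = Ys^T Gs.

    Inputs must already have unit-norm columns (`standardize_columns` or
    residualize + `unit_normalize_columns`); ``n`` is the number of
    individuals entering the LOD exponent.
    """
    Yv = Ys.values if isinstance(Ys, StandardizedMatrix) else np.asarray(Ys, dtype=float)
    Gv = Gs.values if isinstance(Gs, StandardizedMatrix) else np.asarray(Gs, dtype=float)
    if Yv.ndim == 1:
        Yv = Yv[:, None]
    if Gv.ndim == 1:
        Gv = Gv[:, None]
    if Yv.shape[0] != Gv.shape[0]:
        raise ValueError(
            f"row-count mismatch: traits have {Yv.shape[0]} rows, markers {Gv.shape[0]}"
        )
    r = Yv.T @ Gv
    return LodMatrix(lod=lod_from_correlation(r, n), df=1, n_used=n)


def lod_to_loglik(lod, loglik_null):
    """Alternative-model log-likelihood: l1 = l0 + log(10) * LOD."""
    return np.asarray(loglik_null) + LOG10 * np.asarray(lod)


def loglik_to_lod(loglik_alt, loglik_null):
    """Inverse map: LOD = (l1 - l0) / log(10); exact round trip."""
    return (np.asarray(loglik_alt) - np.asarray(loglik_null)) / LOG10


def lod_to_neglog10p(lod: np.ndarray, df: int = 1) -> np.ndarray:
    """-log10 p from the chi-square(df) deviate 2 log(10) LOD.

    Reporting convenience only: treats the LOD as a likelihood-ratio
    statistic with the stated degrees of freedom.
    """
    chi2 = 2.0 * LOG10 * np.asarray(lod, dtype=float)
    logsf = stats.chi2.logsf(chi2, df)
    return -logsf / LOG10
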