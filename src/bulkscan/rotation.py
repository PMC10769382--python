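"""Spectral decomposition of the kinship matrix and data rotation.

With K = U diag(lambda) U^T, pre-multiplying traits, covariates and markers
by U^T turns the correlated LMM error N(0, sigma_g^2 K + sigma_e^2 I) into
independent heteroskedastic errors with variances sigma_e^2 (delta*lambda_i + 1).
The decomposition is computed once per dataset and shared by every scan —
the central efficiency premise of the whole approach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import KinshipMatrix

__all__ = ["KinshipSpectrum", "RotatedData", "eigen_kinship", "rotate"]

# eigenvalues more negative than this fraction of the largest mean K was not PSD
NEGATIVE_EIG_ERROR = 1e-6
# eigenvalues within this fraction of zero are clamped (floating-point drift)
NEGATIVE_EIG_CLAMP = 1e-8


@dataclass
class KinshipSpectrum:
    """Eigenvalues (descending, clamped >= 0) and orthonormal eigenvectors of K."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]


@dataclass
class RotatedData:
    """Traits and design rotated into the kinship eigenbasis (y* = U^T y)."""

    y_star: np.ndarray
    x_star: np.ndarray


def eigen_kinship(K: KinshipMatrix | np.ndarray) -> KinshipSpectrum:
    """Eigendecompose a kinship matrix, sorted by descending eigenvalue.

    Small negative eigenvalues (within ``-1e-8 * max``) are clamped to zero;
    anything more negative raises, since that indicates a genuinely invalid
    kinship rather than floating-point drift.
    """
    values = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    lam, U = np.linalg.eigh(values)
    lam = lam[::-1].copy()
    U = U[:, ::-1].copy()
    top = max(lam[0], 0.0)
    floor = -NEGATIVE_EIG_ERROR * max(top, 1.0)
    if lam[-1] < floor:
        raise ValueError(
            f"kinship matrix is not PSD: eigenvalue {lam[-1]:.6g} below tolerance"
        )
    np.clip(lam, 0.0, None, out=lam)
    return KinshipSpectrum(eigenvalues=lam, eigenvectors=U)


def rotate(M: np.ndarray, spectrum: KinshipSpectrum) -> np.ndarray:
    """Rotate columns of an n x k matrix into the kinship eigenbasis: U^T M."""
    M = np.asarray(M, dtype=float)
    was_1d = M.ndim == 1
    if was_1d:
        M = M[:, None]
    if M.shape[0] != spectrum.n:
        raise ValueError(
            f"row count {M.shape[0]} does not match spectrum size {spectrum.n}"
        )
    out = spectrum.eigenvectors.T @ M
    return out[:, 0] if was_1d else out
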