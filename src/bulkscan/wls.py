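"""Weighted least squares in the decorrelated basis.

After rotation, the LMM for a single trait is an independent-observation
regression with marginal variances sigma_e^2 * w_i, where

    w_i = delta * lambda_i + 1,    delta = h2 / (1 - h2).

Given h2 the fixed effects and residual variance have closed forms:

    beta_hat    = (X*^T W^-1 X*)^-1 X*^T W^-1 y*
    sigma_e2_ml = WRSS / n,     WRSS = (y* - X* beta)^T W^-1 (y* - X* beta)

and the profiled log-likelihood is a function of h2 alone.  Three objective
kinds are supported: plain maximum likelihood (``ml``), restricted maximum
likelihood (``reml``), and a maximum-a-posteriori variant (``map``) that
shrinks sigma_e^2 away from zero with a Scaled-Inverse-chi^2 prior — the
boundary-avoidance device that keeps h2 estimates off 1 when the kinship
matrix is rank deficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

__all__ = [
    "VarianceComponents",
    "PriorSpec",
    "WlsFit",
    "make_weights",
    "wls_fit",
    "map_sigma_e2",
    "profile_objective",
    "apply_observation_weights",
]

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class VarianceComponents:
    """(h2, sigma_e2, sigma_g2, delta) with the re-parameterization identities."""

    h2: float
    sigma_e2: float
    sigma_g2: float
    delta: float

    @classmethod
    def from_h2(cls, h2: float, sigma_e2: float) -> "VarianceComponents":
        if not 0.0 <= h2 < 1.0:
            raise ValueError(f"h2 must lie in [0, 1), got {h2}")
        if sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive")
        delta = h2 / (1.0 - h2)
        return cls(h2=h2, sigma_e2=sigma_e2, sigma_g2=delta * sigma_e2, delta=delta)

    @classmethod
    def from_sigmas(cls, sigma_g2: float, sigma_e2: float) -> "VarianceComponents":
        if sigma_g2 < 0 or sigma_e2 <= 0:
            raise ValueError("need sigma_g2 >= 0 and sigma_e2 > 0")
        total = sigma_g2 + sigma_e2
        return cls(
            h2=sigma_g2 / total,
            sigma_e2=sigma_e2,
            sigma_g2=sigma_g2,
            delta=sigma_g2 / sigma_e2,
        )


@dataclass(frozen=True)
class PriorSpec:
    """Scaled-Inverse-chi^2 prior on sigma_e^2 with dof nu0 and scale tau02.

    ``nu0 = 0`` switches the prior off: the MAP objective then reduces to
    plain maximum likelihood.
    """

    nu0: float
    tau02: float

    def __post_init__(self) -> None:
        if self.nu0 < 0:
            raise ValueError("nu0 must be >= 0")
        if self.tau02 <= 0:
            raise ValueError("tau02 must be > 0")

    def log_density(self, sigma2: float) -> float:
        """Log density of Scaled-Inv-chi^2(nu0, tau02) at sigma2 (nu0 > 0)."""
        nu, tau2 = self.nu0, self.tau02
        half = 0.5 * nu
        return (
            half * math.log(half * tau2)
            - math.lgamma(half)
            - (1.0 + half) * math.log(sigma2)
            - half * tau2 / sigma2
        )


@dataclass
class WlsFit:
    beta: np.ndarray
    sigma_e2_hat: float
    wrss: float
    loglik: float
    objective_kind: str


def make_weights(h2: float, lambdas: np.ndarray) -> np.ndarray:
    """Marginal variance multipliers w_i = delta*lambda_i + 1 at heritability h2."""
    if not 0.0 <= h2 < 1.0:
        raise ValueError(f"h2 must lie in [0, 1), got {h2}")
    lambdas = np.asarray(lambdas, dtype=float)
    delta = h2 / (1.0 - h2)
    return delta * lambdas + 1.0


def map_sigma_e2(wrss: float, n: int, prior: PriorSpec) -> float:
    """Posterior mode of sigma_e^2 under the conjugate Scaled-Inv-chi^2 prior.

    The Normal likelihood in sigma_e^2 combines with Scaled-Inv-chi^2(nu0,
    tau02) into Scaled-Inv-chi^2(nu0 + n, (nu0*tau02 + WRSS)/(nu0 + n)),
    whose mode is (nu0*tau02 + WRSS)/(nu0 + n + 2) — strictly positive
    whenever nu0 > 0, even at WRSS = 0.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if wrss < 0:
        raise ValueError("wrss must be nonnegative")
    return (prior.nu0 * prior.tau02 + wrss) / (prior.nu0 + n + 2.0)


def _loglik_ml(n: int, sigma2: float, sum_log_w: float, wrss: float) -> float:
    return -0.5 * (n * LOG_2PI + n * math.log(sigma2) + sum_log_w + wrss / sigma2)


def wls_fit(
    y_star: np.ndarray,
    x_star: np.ndarray,
    w: np.ndarray,
    objective_kind: str = "ml",
    prior: PriorSpec | None = None,
) -> WlsFit:
    """Closed-form weighted regression of one rotated trait on a rotated design.

    Rows are scaled by 1/sqrt(w_i) and the scaled system solved by a
    rank-revealing least-squares factorization (no explicit inverse).
    """
    y_star = np.asarray(y_star, dtype=float).ravel()
    x_star = np.atleast_2d(np.asarray(x_star, dtype=float))
    w = np.asarray(w, dtype=float)
    n, q = x_star.shape
    if y_star.shape[0] != n or w.shape[0] != n:
        raise ValueError("y_star, x_star and w must share the row count")

    sw = np.sqrt(w)
    Xw = x_star / sw[:, None]
    yw = y_star / sw
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < q:
        _, _, piv = sla.qr(Xw, mode="economic", pivoting=True)
        collinear = sorted(piv[rank:].tolist())
        raise ValueError(
            f"design is rank deficient (rank {rank} < {q}); "
            f"collinear column index(es): {collinear}"
        )
    resid = yw - Xw @ beta
    wrss = float(resid @ resid)
    sum_log_w = float(np.sum(np.log(w)))
    # perfect fit to float precision: no information left about sigma_e2
    degenerate = wrss <= 1e-12 * float(yw @ yw)

    kind = objective_kind.lower()
    if kind == "map" and (prior is None or prior.nu0 == 0.0):
        kind = "ml"  # nu0 = 0 recovers the no-prior objective
    if kind == "ml":
        if degenerate:
            raise ValueError("degenerate fit: weighted RSS is zero with no prior")
        sigma2 = wrss / n
        loglik = _loglik_ml(n, sigma2, sum_log_w, wrss)
    elif kind == "reml":
        if n <= q:
            raise ValueError("REML requires n > q")
        if degenerate:
            raise ValueError("degenerate fit: weighted RSS is zero with no prior")
        sigma2 = wrss / (n - q)
        _, logdet_xtx = np.linalg.slogdet(Xw.T @ Xw)
        loglik = -0.5 * (
            (n - q) * LOG_2PI
            + (n - q) * math.log(sigma2)
            + sum_log_w
            + logdet_xtx
            + wrss / sigma2
        )
    elif kind == "map":
        assert prior is not None
        sigma2 = map_sigma_e2(wrss, n, prior)
        loglik = _loglik_ml(n, sigma2, sum_log_w, wrss) + prior.log_density(sigma2)
    else:
        raise ValueError(f"unknown objective kind {objective_kind!r}")

    return WlsFit(
        beta=beta, sigma_e2_hat=sigma2, wrss=wrss, loglik=loglik, objective_kind=kind
    )


def profile_objective(
    h2: float,
    y_star: np.ndarray,
    x_star: np.ndarray,
    lambdas: np.ndarray,
    objective_kind: str = "ml",
    prior: PriorSpec | None = None,
) -> float:
    """Profiled objective at heritability h2 (beta and sigma_e^2 plugged in)."""
    w = make_weights(h2, lambdas)
    return wls_fit(y_star, x_star, w, objective_kind=objective_kind, prior=prior).loglik


def apply_observation_weights(
    weights: np.ndarray, *matrices: np.ndarray
) -> tuple[np.ndarray, ...]:
    """Pre-scale data by per-observation precision weights.

    For user-supplied residual weights v_i (variance of observation i
    proportional to 1/v_i), scaling y and X rows by sqrt(v_i) and K by
    sqrt(v_i v_j) reduces the weighted LMM to the standard one, after which
    the ordinary pipeline (eigendecomposition included) applies.  The last
    matrix passed is treated as the kinship (scaled on both sides) if it is
    square; pass matrices in order (y, X, ..., K).
    """
    v = np.asarray(weights, dtype=float)
    if np.any(v <= 0):
        raise ValueError("observation weights must be positive")
    s = np.sqrt(v)
    out = []
    for idx, M in enumerate(matrices):
        M = np.asarray(M, dtype=float)
        is_kinship = idx == len(matrices) - 1 and M.ndim == 2 and M.shape[0] == M.shape[1]
        if is_kinship and len(matrices) > 1:
            out.append(M * np.outer(s, s))
        elif M.ndim == 1:
            out.append(M * s)
        else:
            out.append(M * s[:, None])
    return tuple(out)
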