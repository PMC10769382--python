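"""Heritability estimation: Brent's method on [0, 1) and finite-grid search.

Two estimation styles feed the scan algorithms.  The exact style maximizes
the profiled objective with Brent's method, optionally restarted on each of
``s`` equal sub-intervals to dodge local maxima.  The grid style evaluates
the objective on a finite candidate set for every trait at once — one
multi-trait weighted regression per grid value — so that traits sharing a
winning grid value can later be scanned together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .wls import LOG_2PI, PriorSpec

__all__ = [
    "DEFAULT_H2_UPPER",
    "HeritabilityGrid",
    "GridLoglik",
    "optimize_h2_brent",
    "grid_loglik",
]

# h2 = 1 is excluded: the unprioritized objective can diverge there
DEFAULT_H2_UPPER = 1.0 - 1e-6
BRENT_XTOL = 1e-6


@dataclass(frozen=True)
class HeritabilityGrid:
    """Strictly increasing candidate h2 values in [0, 1)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("grid must be a non-empty 1-D array")
        if v.min() < 0.0 or v.max() >= 1.0:
            raise ValueError("grid values must lie in [0, 1)")
        if v.size > 1 and np.any(np.diff(v) <= 0):
            raise ValueError("grid values must be strictly increasing")
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls) -> "HeritabilityGrid":
        """The standard coarse grid: 0.0, 0.1, ..., 0.9."""
        return cls(np.round(np.arange(0.0, 1.0, 0.1), 10))

    @classmethod
    def from_step(cls, step: float, start: float = 0.0, stop: float = 1.0) -> "HeritabilityGrid":
        """Grid from ``start`` in increments of ``step``, excluding values >= stop."""
        k = int(math.floor((min(stop, 1.0) - start) / step - 1e-12)) + 1
        return cls(np.round(start + step * np.arange(k), 12))

    @classmethod
    def from_spec(cls, spec: str) -> "HeritabilityGrid":
        """Parse ``start:stop:step`` (stop-inclusive, values >= 1 dropped)."""
        start, stop, step = (float(t) for t in spec.split(":"))
        vals = np.round(np.arange(start, stop + step / 2, step), 12)
        return cls(vals[vals < 1.0])

    @property
    def size(self) -> int:
        return self.values.size


@dataclass
class GridLoglik:
    """Objective values (B x m) on the grid, plus the per-trait argmax."""

    grid: HeritabilityGrid
    values: np.ndarray
    argmax_h2: np.ndarray = field(init=False)
    argmax_index: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        # np.argmax returns the first maximizer: ties break toward smaller h2
        self.argmax_index = np.argmax(self.values, axis=0)
        self.argmax_h2 = self.grid.values[self.argmax_index]


def optimize_h2_brent(
    objective,
    interval: tuple[float, float] = (0.0, DEFAULT_H2_UPPER),
    n_subdivisions: int = 1,
    xtol: float = BRENT_XTOL,
) -> tuple[float, float]:
    """Maximize a scalar objective of h2 by Brent's method on sub-intervals.

    The interval is split into ``n_subdivisions`` equal pieces, bounded
    Brent run in each, and the best optimum across sub-intervals (also
    checking the sub-interval boundary points) returned as
    ``(h2_hat, objective_value)``.  More sub-intervals protect against
    multimodal objectives at proportional extra cost.
    """
    lo, hi = interval
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"invalid interval {interval}")
    if n_subdivisions < 1:
        raise ValueError("n_subdivisions must be >= 1")

    def safe(h2: float) -> float:
        val = objective(h2)
        if not np.isfinite(val):
            raise ValueError(f"objective returned non-finite value at h2={h2}")
        return float(val)

    edges = np.linspace(lo, hi, n_subdivisions + 1)
    candidates: list[tuple[float, float]] = [(h, safe(h)) for h in edges]
    for a, b in zip(edges[:-1], edges[1:]):
        res = optimize.minimize_scalar(
            lambda h: -safe(h),
            bounds=(a, b),
            method="bounded",
            options={"xatol": xtol},
        )
        candidates.append((float(res.x), -float(res.fun)))
    h2_hat, best = max(candidates, key=lambda t: t[1])
    return h2_hat, best


def _batched_objective(
    wrss: np.ndarray,
    n: int,
    q: int,
    sum_log_w: float,
    logdet_xtx: float,
    objective_kind: str,
    prior: PriorSpec | None,
) -> np.ndarray:
    """Vectorized profiled objective for a vector of per-trait WRSS values."""
    kind = objective_kind.lower()
    if kind == "map" and (prior is None or prior.nu0 == 0.0):
        kind = "ml"
    if kind == "ml":
        sigma2 = wrss / n
        return -0.5 * (n * LOG_2PI + n * np.log(sigma2) + sum_log_w + n)
    if kind == "reml":
        sigma2 = wrss / (n - q)
        return -0.5 * (
            (n - q) * LOG_2PI
            + (n - q) * np.log(sigma2)
            + sum_log_w
            + logdet_xtx
            + (n - q)
        )
    if kind == "map":
        assert prior is not None
        sigma2 = (prior.nu0 * prior.tau02 + wrss) / (prior.nu0 + n + 2.0)
        half = 0.5 * prior.nu0
        log_prior = (
            half * math.log(half * prior.tau02)
            - math.lgamma(half)
            - (1.0 + half) * np.log(sigma2)
            - half * prior.tau02 / sigma2
        )
        return (
            -0.5 * (n * LOG_2PI + n * np.log(sigma2) + sum_log_w + wrss / sigma2)
            + log_prior
        )
    raise ValueError(f"unknown objective kind {objective_kind!r}")


def grid_loglik(
    Y_star: np.ndarray,
    X_star: np.ndarray,
    grid: HeritabilityGrid,
    lambdas: np.ndarray,
    objective_kind: str = "ml",
    prior: PriorSpec | None = None,
) -> GridLoglik:
    """Profiled objective of every trait at every grid value, batched.

    For each candidate h2 the weights are fixed, so one multi-trait weighted
    regression (a single QR of the weighted design, projected against all
    trait columns at once) yields the m per-trait weighted RSS values and
    hence all m objective values for that grid row.
    """
    Y_star = np.asarray(Y_star, dtype=float)
    if Y_star.ndim == 1:
        Y_star = Y_star[:, None]
    X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
    lambdas = np.asarray(lambdas, dtype=float)
    n, q = X_star.shape
    values = np.empty((grid.size, Y_star.shape[1]))
    for b, h2 in enumerate(grid.values):
        delta = h2 / (1.0 - h2)
        w = delta * lambdas + 1.0
        sw = np.sqrt(w)
        Xw = X_star / sw[:, None]
        Yw = Y_star / sw[:, None]
        Q, _ = np.linalg.qr(Xw)
        resid = Yw - Q @ (Q.T @ Yw)
        wrss = np.einsum("ij,ij->j", resid, resid)
        sum_log_w = float(np.sum(np.log(w)))
        if objective_kind.lower() == "reml":
            _, logdet = np.linalg.slogdet(Xw.T @ Xw)
        else:
            logdet = 0.0
        values[b] = _batched_objective(
            wrss, n, q, sum_log_w, logdet, objective_kind, prior
        )
    return GridLoglik(grid=grid, values=values)
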