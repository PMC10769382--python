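"""Bulk genome-scan algorithms.

Four scans share one pipeline — rotate into the kinship eigenbasis,
reweight by the per-trait heritability, residualize against the covariates,
and convert correlations to LOD scores by a matrix product:

* ``scan_null_exact``: per-trait Brent optimization of the null-model h2,
  then one matrix product per trait (exact null heritability).
* ``scan_null_grid``: h2 restricted to a finite grid; traits sharing a
  winning grid value are batched into a single matrix product (fastest).
* ``scan_alt_grid``: re-optimizes h2 over the grid independently for every
  (trait, marker) pair by recovering alternative-model log-likelihoods from
  pseudo-LOD panels at each grid value (most accurate grid method).
* ``scan_lm``: plain linear model, no kinship adjustment — the comparison
  baseline that shows what relatedness correction changes.

A trait's null heritability estimate fixes the weight matrix for all its
markers, so the 1-df likelihood-ratio LOD reduces exactly to the
correlation form computed by `bulkscan.lod.pairwise_lod`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from joblib import Parallel, delayed

from .heritability import (
    DEFAULT_H2_UPPER,
    GridLoglik,
    HeritabilityGrid,
    grid_loglik,
    optimize_h2_brent,
)
from .io import CovariateMatrix, GenotypeMatrix, KinshipMatrix, TraitMatrix, compute_kinship
from .lod import (
    LOG10,
    LodMatrix,
    lod_from_correlation,
    residualize_columns,
    unit_normalize_columns,
)
from .rotation import KinshipSpectrum, eigen_kinship, rotate
from .wls import PriorSpec, make_weights, profile_objective

__all__ = [
    "ScanOptions",
    "ScanResult",
    "scan_null_exact",
    "scan_null_grid",
    "scan_alt_grid",
    "scan_lm",
]


@dataclass
class ScanOptions:
    """Settings shared by the scan algorithms.

    objective
        ``"reml"`` (default, matching common practice for variance
        components) or ``"ml"`` for the profiled likelihood used when
        estimating h2.  When ``prior`` is supplied with ``nu0 > 0`` the
        MAP objective (ML likelihood times Scaled-Inv-chi^2 prior on
        sigma_e^2) is used instead — the boundary-avoidance stabilizer.
    n_subdivisions
        Sub-intervals for Brent's method in the exact scan.
    n_workers
        Worker threads for per-trait / per-batch work; results are
        identical for any worker count (assembly order is fixed).
    marker_block_size
        Process markers in column blocks of this size to bound memory;
        None = one block.
    """

    objective: str = "reml"
    prior: PriorSpec | None = None
    n_subdivisions: int = 1
    h2_interval: tuple[float, float] = (0.0, DEFAULT_H2_UPPER)
    n_workers: int = 1
    marker_block_size: int | None = None

    @property
    def effective_objective(self) -> str:
        if self.prior is not None and self.prior.nu0 > 0:
            return "map"
        return self.objective

    def settings_record(self) -> dict[str, Any]:
        rec: dict[str, Any] = {
            "objective": self.effective_objective,
            "n_subdivisions": self.n_subdivisions,
            "h2_interval": list(self.h2_interval),
            "n_workers": self.n_workers,
        }
        if self.prior is not None:
            rec["prior"] = {"nu0": self.prior.nu0, "tau02": self.prior.tau02}
        return rec


@dataclass
class ScanResult:
    """LOD scores plus the heritability estimates that produced them."""

    lod: LodMatrix
    h2_null: np.ndarray
    method: str
    settings: dict[str, Any] = field(default_factory=dict)
    h2_panel: np.ndarray | None = None
    trait_ids: list[str] | None = None
    marker_ids: list[str] | None = None

    @property
    def lod_values(self) -> np.ndarray:
        return self.lod.lod

    def to_dataframe(self):
        import pandas as pd

        m, p = self.lod.lod.shape
        idx = self.marker_ids or [f"m{j}" for j in range(p)]
        cols = self.trait_ids or [f"t{i}" for i in range(m)]
        return pd.DataFrame(self.lod.lod.T, index=idx, columns=cols)


# ---------------------------------------------------------------------------
# input normalization


def _as_inputs(Y, G, K, X0):
    """Accept typed matrices or plain arrays; return aligned plain arrays."""
    if isinstance(Y, TraitMatrix):
        Yv, trait_ids = Y.values, list(Y.trait_ids)
    else:
        Yv = np.asarray(Y, dtype=float)
        if Yv.ndim == 1:
            Yv = Yv[:, None]
        trait_ids = [f"trait_{i}" for i in range(Yv.shape[1])]
    if isinstance(G, GenotypeMatrix):
        Gv, marker_ids = G.values, list(G.marker_ids)
    else:
        Gv = np.asarray(G, dtype=float)
        marker_ids = [f"marker_{j}" for j in range(Gv.shape[1])]
    if Yv.shape[0] != Gv.shape[0]:
        raise ValueError("traits and genotypes disagree on the number of individuals")
    n = Yv.shape[0]
    if X0 is None:
        X0v = np.ones((n, 1))
    elif isinstance(X0, CovariateMatrix):
        X0v = X0.values
    else:
        X0v = np.atleast_2d(np.asarray(X0, dtype=float))
    if K is None:
        Kv = None
    elif isinstance(K, KinshipMatrix):
        Kv = K.values
    else:
        Kv = np.asarray(K, dtype=float)
    poly = Gv.var(axis=0) > 0.0
    return Yv, Gv, Kv, X0v, trait_ids, marker_ids, poly


def _spectrum_for(Gv: np.ndarray, Kv: np.ndarray | None, poly: np.ndarray) -> KinshipSpectrum:
    if Kv is None:
        Kv = compute_kinship(
            GenotypeMatrix(
                Gv[:, poly],
                marker_ids=[str(j) for j in range(int(poly.sum()))],
                individual_ids=[str(i) for i in range(Gv.shape[0])],
            )
        ).values
    return eigen_kinship(Kv)


def _blocks(p: int, block: int | None):
    if block is None or block >= p:
        yield slice(0, p)
        return
    for start in range(0, p, block):
        yield slice(start, min(start + block, p))


def _lod_rows_for_weights(
    Y_dag: np.ndarray,
    G_dag: np.ndarray,
    X0_dag: np.ndarray,
    n: int,
    block: int | None,
) -> np.ndarray:
    """LOD panel for traits/markers already reweighted by a common W^{-1/2}.

    Both sides are residualized against the reweighted covariates so the
    correlation identity applies conditionally on X0, then unit-normalized
    (no re-centering — the intercept lives in X0).
    """
    Yr = unit_normalize_columns(residualize_columns(Y_dag, X0_dag))
    p = G_dag.shape[1]
    out = np.empty((Yr.shape[1], p))
    for sl in _blocks(p, block):
        Gr = unit_normalize_columns(residualize_columns(G_dag[:, sl], X0_dag))
        out[:, sl] = lod_from_correlation(Yr.T @ Gr, n)
    return out


def _assemble_full(lod_poly: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Re-insert zero LOD columns for monomorphic markers."""
    if poly.all():
        return lod_poly
    full = np.zeros((lod_poly.shape[0], poly.size))
    full[:, poly] = lod_poly
    return full


# ---------------------------------------------------------------------------
# scans


def scan_null_exact(Y, G, K=None, X0=None, options: ScanOptions | None = None) -> ScanResult:
    """Per-trait exact null-model heritability, then matrix-product LOD.

    For each trait: Brent-optimize the profiled objective of the null model
    to get h2_hat, reweight trait / covariates / markers by W(h2_hat)^{-1/2},
    and compute the LOD against every marker in one pass.  A single trait
    column gives the single-trait scan.
    """
    opts = options or ScanOptions()
    Yv, Gv, Kv, X0v, trait_ids, marker_ids, poly = _as_inputs(Y, G, K, X0)
    n, m = Yv.shape
    spec = _spectrum_for(Gv, Kv, poly)
    lam = spec.eigenvalues
    Y_star = rotate(Yv, spec)
    G_star = rotate(Gv[:, poly], spec)
    X0_star = rotate(X0v, spec)
    kind = opts.effective_objective

    def one_trait(i: int) -> tuple[float, np.ndarray]:
        y = Y_star[:, i]
        h2_hat, _ = optimize_h2_brent(
            lambda h2: profile_objective(h2, y, X0_star, lam, kind, opts.prior),
            interval=opts.h2_interval,
            n_subdivisions=opts.n_subdivisions,
        )
        sw = np.sqrt(make_weights(h2_hat, lam))
        row = _lod_rows_for_weights(
            (y / sw)[:, None], G_star / sw[:, None], X0_star / sw[:, None],
            n, opts.marker_block_size,
        )
        return h2_hat, row[0]

    if opts.n_workers > 1:
        results = Parallel(n_jobs=opts.n_workers, prefer="threads")(
            delayed(one_trait)(i) for i in range(m)
        )
    else:
        results = [one_trait(i) for i in range(m)]
    h2_null = np.array([r[0] for r in results])
    lod = np.vstack([r[1] for r in results]) if m else np.empty((0, int(poly.sum())))
    return ScanResult(
        lod=LodMatrix(lod=_assemble_full(lod, poly), df=1, n_used=n),
        h2_null=h2_null,
        method="null-exact",
        settings=opts.settings_record(),
        trait_ids=trait_ids,
        marker_ids=marker_ids,
    )


def scan_null_grid(
    Y, G, K=None, X0=None,
    grid: HeritabilityGrid | None = None,
    options: ScanOptions | None = None,
) -> ScanResult:
    """Grid-search null heritability, batching traits that share a grid value.

    One batched weighted regression per grid value scores every trait; each
    trait takes the best grid value; traits with the same winner form a
    batch scanned by a single matrix product.
    """
    opts = options or ScanOptions()
    grid = grid or HeritabilityGrid.default()
    Yv, Gv, Kv, X0v, trait_ids, marker_ids, poly = _as_inputs(Y, G, K, X0)
    n, m = Yv.shape
    spec = _spectrum_for(Gv, Kv, poly)
    lam = spec.eigenvalues
    Y_star = rotate(Yv, spec)
    G_star = rotate(Gv[:, poly], spec)
    X0_star = rotate(X0v, spec)

    gl = grid_loglik(Y_star, X0_star, grid, lam, opts.effective_objective, opts.prior)
    lod = np.empty((m, int(poly.sum())))

    def one_batch(b: int, members: np.ndarray) -> np.ndarray:
        sw = np.sqrt(make_weights(grid.values[b], lam))
        return _lod_rows_for_weights(
            Y_star[:, members] / sw[:, None],
            G_star / sw[:, None],
            X0_star / sw[:, None],
            n,
            opts.marker_block_size,
        )

    batches = [
        (b, np.flatnonzero(gl.argmax_index == b))
        for b in range(grid.size)
        if np.any(gl.argmax_index == b)
    ]
    if opts.n_workers > 1:
        panels = Parallel(n_jobs=opts.n_workers, prefer="threads")(
            delayed(one_batch)(b, members) for b, members in batches
        )
    else:
        panels = [one_batch(b, members) for b, members in batches]
    for (b, members), panel in zip(batches, panels):
        lod[members] = panel
    return ScanResult(
        lod=LodMatrix(lod=_assemble_full(lod, poly), df=1, n_used=n),
        h2_null=gl.argmax_h2.copy(),
        method="null-grid",
        settings={**opts.settings_record(), "grid": grid.values.tolist()},
        trait_ids=trait_ids,
        marker_ids=marker_ids,
    )


def scan_alt_grid(
    Y, G, K=None, X0=None,
    grid: HeritabilityGrid | None = None,
    options: ScanOptions | None = None,
) -> ScanResult:
    """Grid-search heritability independently for every (trait, marker) pair.

    At each grid value the pseudo-LOD panel L(h2) and the (marker-free)
    null log-likelihoods l0(i, h2) are cheap; the alternative-model
    log-likelihood is recovered as l1 = l0 + log(10) L.  Maximizing l0 per
    trait and l1 per pair over the grid gives the LOD at the per-pair
    optimal heritability:

        LOD_ij = [max_b l1(i,j,b) - max_b l0(i,b)] / log(10)

    The recovery identity holds exactly only for the ML profiled
    likelihood (the REML criterion carries a marker-dependent determinant
    term), so this scan always uses ML log-likelihood panels; the
    ``objective`` option is ignored here.
    """
    opts = options or ScanOptions()
    grid = grid or HeritabilityGrid.default()
    Yv, Gv, Kv, X0v, trait_ids, marker_ids, poly = _as_inputs(Y, G, K, X0)
    n, m = Yv.shape
    spec = _spectrum_for(Gv, Kv, poly)
    lam = spec.eigenvalues
    Y_star = rotate(Yv, spec)
    G_star = rotate(Gv[:, poly], spec)
    X0_star = rotate(X0v, spec)

    gl = grid_loglik(Y_star, X0_star, grid, lam, "ml", None)
    p_used = int(poly.sum())
    ell1_max = np.full((m, p_used), -np.inf)
    h2_panel = np.zeros((m, p_used))
    for b in range(grid.size):
        sw = np.sqrt(make_weights(grid.values[b], lam))
        pseudo = _lod_rows_for_weights(
            Y_star / sw[:, None],
            G_star / sw[:, None],
            X0_star / sw[:, None],
            n,
            opts.marker_block_size,
        )
        ell1 = gl.values[b][:, None] + LOG10 * pseudo
        better = ell1 > ell1_max
        ell1_max = np.where(better, ell1, ell1_max)
        h2_panel = np.where(better, grid.values[b], h2_panel)
    ell0_max = gl.values[gl.argmax_index, np.arange(m)]
    lod = (ell1_max - ell0_max[:, None]) / LOG10
    return ScanResult(
        lod=LodMatrix(lod=_assemble_full(lod, poly), df=1, n_used=n),
        h2_null=gl.argmax_h2.copy(),
        method="alt-grid",
        settings={**opts.settings_record(), "grid": grid.values.tolist()},
        h2_panel=_assemble_full(h2_panel, poly),
        trait_ids=trait_ids,
        marker_ids=marker_ids,
    )


def scan_lm(Y, G, X0=None, options: ScanOptions | None = None) -> ScanResult:
    """Plain linear-model scan: no kinship adjustment, unit weights."""
    opts = options or ScanOptions()
    Yv, Gv, _, X0v, trait_ids, marker_ids, poly = _as_inputs(Y, G, None, X0)
    n, m = Yv.shape
    lod = _lod_rows_for_weights(Yv, Gv[:, poly], X0v, n, opts.marker_block_size)
    return ScanResult(
        lod=LodMatrix(lod=_assemble_full(lod, poly), df=1, n_used=n),
        h2_null=np.zeros(m),
        method="lm",
        settings=opts.settings_record(),
        trait_ids=trait_ids,
        marker_ids=marker_ids,
    )
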