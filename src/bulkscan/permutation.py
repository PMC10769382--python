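"""Genome-wide permutation thresholds for a single trait under the LMM.

After decorrelating and reweighting at the null heritability estimate, the
null-model residuals r0 = y-dagger - X0-dagger beta0-hat are i.i.d.
N(0, sigma_e^2), so permuting them generates valid null copies of the
trait.  All permuted LOD curves are computed in one matrix-product pass;
the per-permutation genome-wide maxima give the empirical family-wise
threshold at each significance level.

The null heritability (and thus the weight matrix) is estimated once from
the observed trait and held fixed across permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .heritability import optimize_h2_brent
from .lod import lod_from_correlation, residualize_columns, unit_normalize_columns
from .scan import ScanOptions, _as_inputs, _spectrum_for
from .rotation import rotate
from .wls import make_weights, profile_objective, wls_fit

__all__ = ["PermutationThresholds", "permute_scan"]


@dataclass
class PermutationThresholds:
    """Empirical genome-wide max-LOD distribution and its quantiles."""

    max_lod: np.ndarray
    thresholds: dict[float, float]
    n_perm: int
    seed: int
    h2_null: float
    observed_max_lod: float
    identity_lod: np.ndarray | None = None

    def threshold(self, alpha: float) -> float:
        return self.thresholds[alpha]


def permute_scan(
    y,
    G,
    K=None,
    X0=None,
    n_perm: int = 1000,
    alphas: Sequence[float] = (0.05,),
    seed: int | None = None,
    include_identity: bool = False,
    options: ScanOptions | None = None,
) -> PermutationThresholds:
    """Permutation thresholds for one trait.

    Parameters
    ----------
    y
        Single trait (length-n vector or n x 1 TraitMatrix).
    n_perm
        Number of uniform random permutations (>= 1).
    alphas
        Significance levels; the threshold at alpha is the empirical
        (1 - alpha) quantile of the per-permutation genome-wide max LOD.
    include_identity
        If True the identity permutation is prepended as permutation #0
        (its LOD curve reproduces the observed scan).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    alphas = list(alphas)
    for a in alphas:
        if not 0.0 < a < 1.0:
            raise ValueError(f"invalid significance level {a}")
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    rng = np.random.default_rng(seed)

    opts = options or ScanOptions()
    yv = np.asarray(y.values if hasattr(y, "values") else y, dtype=float).reshape(-1, 1)
    Yv, Gv, Kv, X0v, _, _, poly = _as_inputs(yv, G, K, X0)
    n = Yv.shape[0]
    spec = _spectrum_for(Gv, Kv, poly)
    lam = spec.eigenvalues
    y_star = rotate(Yv[:, 0], spec)
    G_star = rotate(Gv[:, poly], spec)
    X0_star = rotate(X0v, spec)

    kind = opts.effective_objective
    h2_hat, _ = optimize_h2_brent(
        lambda h2: profile_objective(h2, y_star, X0_star, lam, kind, opts.prior),
        interval=opts.h2_interval,
        n_subdivisions=opts.n_subdivisions,
    )
    w = make_weights(h2_hat, lam)
    sw = np.sqrt(w)
    y_dag = y_star / sw
    X0_dag = X0_star / sw[:, None]
    G_dag = G_star / sw[:, None]

    fit0 = wls_fit(y_star, X0_star, w, objective_kind="ml")
    r0 = y_dag - X0_dag @ fit0.beta

    # permuted residuals, one column per permutation
    R = np.column_stack([r0[rng.permutation(n)] for _ in range(n_perm)])

    # permutation breaks orthogonality to X0-dagger, so residualize again
    Rr = unit_normalize_columns(residualize_columns(R, X0_dag))
    Gr = unit_normalize_columns(residualize_columns(G_dag, X0_dag))
    lod = lod_from_correlation(Rr.T @ Gr, n)  # n_perm x p
    max_lod = lod.max(axis=1)

    yr = unit_normalize_columns(residualize_columns(r0[:, None], X0_dag))
    observed_curve = lod_from_correlation(yr.T @ Gr, n)[0]
    observed = float(observed_curve.max())

    # linear-interpolation empirical quantile, the usual genome-scan convention
    thresholds = {a: float(np.quantile(max_lod, 1.0 - a)) for a in alphas}
    return PermutationThresholds(
        max_lod=max_lod,
        thresholds=thresholds,
        n_perm=n_perm,
        seed=seed,
        h2_null=h2_hat,
        observed_max_lod=observed,
        identity_lod=observed_curve if include_identity else None,
    )
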