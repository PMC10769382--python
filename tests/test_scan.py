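import numpy as np
import pytest

from bulkscan import (
    GenotypeMatrix,
    HeritabilityGrid,
    ScanOptions,
    eigen_kinship,
    make_weights,
    rotate,
    scan_alt_grid,
    scan_lm,
    scan_null_exact,
    scan_null_grid,
    wls_fit,
)

LOG10 = np.log(10.0)


def _explicit_lod_at_h2(Y, G, K, h2_vec, objective="ml"):
    """Oracle: per-(trait, marker) weighted likelihood-ratio fits at fixed h2."""
    spec = eigen_kinship(K)
    Ys = rotate(Y.values, spec)
    Gs = rotate(G.values, spec)
    X0s = rotate(np.ones((Y.n, 1)), spec)
    out = np.empty((Y.m, G.p))
    for i in range(Y.m):
        w = make_weights(h2_vec[i], spec.eigenvalues)
        l0 = wls_fit(Ys[:, i], X0s, w, "ml").loglik
        for j in range(G.p):
            l1 = wls_fit(Ys[:, i], np.column_stack([X0s, Gs[:, j]]), w, "ml").loglik
            out[i, j] = (l1 - l0) / LOG10
    return out


def test_null_exact_matches_explicit_per_marker_oracle(small_dataset):
    """Matrix-product LODs equal explicit WLS likelihood-ratio fits at the
    same per-trait null heritability (m=5, p=40, n=60)."""
    Y, G, K = small_dataset
    res = scan_null_exact(Y, G, K)
    oracle = _explicit_lod_at_h2(Y, G, K, res.h2_null)
    assert np.abs(res.lod_values - oracle).max() < 1e-8


def test_identity_kinship_reduces_to_lm(small_dataset):
    Y, G, _ = small_dataset
    K = np.eye(Y.n)
    lm = scan_lm(Y, G)
    for scan, kwargs in [
        (scan_null_exact, {}),
        (scan_null_grid, {"grid": HeritabilityGrid.default()}),
        (scan_alt_grid, {"grid": HeritabilityGrid.default()}),
    ]:
        res = scan(Y, G, K, **kwargs)
        assert np.abs(res.lod_values - lm.lod_values).max() < 1e-6


def test_lm_matches_regression_oracle(small_dataset):
    Y, G, _ = small_dataset
    res = scan_lm(Y, G)
    ones = np.ones((Y.n, 1))
    for i in range(Y.m):
        b0, *_ = np.linalg.lstsq(ones, Y.values[:, i], rcond=None)
        rss0 = np.sum((Y.values[:, i] - ones @ b0) ** 2)
        for j in range(G.p):
            X1 = np.column_stack([ones, G.values[:, j]])
            b1, *_ = np.linalg.lstsq(X1, Y.values[:, i], rcond=None)
            rss1 = np.sum((Y.values[:, i] - X1 @ b1) ** 2)
            expected = (Y.n / 2) * np.log10(rss0 / rss1)
            assert abs(res.lod_values[i, j] - expected) < 1e-8


def test_grid_degeneracy_reproduces_null_exact(small_dataset):
    """A grid consisting exactly of the per-trait exact optima reproduces
    the exact scan (all three bulk methods agree there)."""
    Y, G, K = small_dataset
    opts = ScanOptions(objective="ml")
    exact = scan_null_exact(Y, G, K, options=opts)
    grid = HeritabilityGrid(np.unique(np.round(exact.h2_null, 12)))
    grid_res = scan_null_grid(Y, G, K, grid=grid, options=opts)
    assert np.abs(grid_res.lod_values - exact.lod_values).max() < 1e-8


def test_null_grid_batching_equals_trait_loop(small_dataset):
    """Batched execution equals scanning each trait alone with the same grid."""
    Y, G, K = small_dataset
    grid = HeritabilityGrid.default()
    batched = scan_null_grid(Y, G, K, grid=grid)
    for i in range(Y.m):
        solo = scan_null_grid(Y.values[:, [i]], G, K, grid=grid)
        assert np.abs(solo.lod_values[0] - batched.lod_values[i]).max() < 1e-10


def test_alt_grid_matches_triple_loop_oracle(small_dataset):
    """Alt-grid equals a brute-force fit of every (trait, marker, grid value)
    alternative model followed by element-wise maximization."""
    Y, G, K = small_dataset
    grid = HeritabilityGrid.from_step(0.05)
    res = scan_alt_grid(Y, G, K, grid=grid)
    spec = eigen_kinship(K)
    Ys = rotate(Y.values, spec)
    Gs = rotate(G.values, spec)
    X0s = rotate(np.ones((Y.n, 1)), spec)
    m, p = Y.m, G.p
    for i in range(m):
        l0 = [
            wls_fit(Ys[:, i], X0s, make_weights(h, spec.eigenvalues), "ml").loglik
            for h in grid.values
        ]
        l0_max = max(l0)
        for j in range(0, p, 7):  # subsample markers to keep the loop short
            l1_max = max(
                wls_fit(
                    Ys[:, i],
                    np.column_stack([X0s, Gs[:, j]]),
                    make_weights(h, spec.eigenvalues),
                    "ml",
                ).loglik
                for h in grid.values
            )
            expected = (l1_max - l0_max) / LOG10
            assert abs(res.lod_values[i, j] - expected) < 1e-8


def test_alt_grid_single_point_equals_null_grid(small_dataset):
    Y, G, K = small_dataset
    grid = HeritabilityGrid(np.array([0.4]))
    a = scan_alt_grid(Y, G, K, grid=grid)
    b = scan_null_grid(Y, G, K, grid=grid, options=ScanOptions(objective="ml"))
    assert np.abs(a.lod_values - b.lod_values).max() < 1e-10


def test_alt_grid_dominates_null_grid(small_dataset):
    """Maximizing l1 over the grid can never lower the LOD below the
    null-grid value on the same grid (same ML objective)."""
    Y, G, K = small_dataset
    grid = HeritabilityGrid.default()
    alt = scan_alt_grid(Y, G, K, grid=grid)
    null = scan_null_grid(Y, G, K, grid=grid, options=ScanOptions(objective="ml"))
    assert np.all(alt.lod_values >= null.lod_values - 1e-8)
    assert np.all(alt.lod_values >= -1e-12)


def test_column_order_invariance(small_dataset, rng):
    Y, G, K = small_dataset
    res = scan_null_grid(Y, G, K)
    tperm = rng.permutation(Y.m)
    mperm = rng.permutation(G.p)
    from bulkscan import TraitMatrix

    Y2 = TraitMatrix(Y.values[:, tperm], trait_ids=[Y.trait_ids[i] for i in tperm],
                     individual_ids=list(Y.individual_ids))
    G2 = GenotypeMatrix(G.values[:, mperm], marker_ids=[G.marker_ids[j] for j in mperm],
                        individual_ids=list(G.individual_ids))
    res2 = scan_null_grid(Y2, G2, K)
    np.testing.assert_allclose(res2.lod_values, res.lod_values[np.ix_(tperm, mperm)],
                               atol=1e-10)


def test_thread_count_invariance(small_dataset):
    """Worker count never changes any LOD output."""
    Y, G, K = small_dataset
    for scan, kwargs in [
        (scan_null_exact, {}),
        (scan_null_grid, {"grid": HeritabilityGrid.default()}),
    ]:
        one = scan(Y, G, K, options=ScanOptions(n_workers=1), **kwargs)
        four = scan(Y, G, K, options=ScanOptions(n_workers=4), **kwargs)
        assert np.abs(one.lod_values - four.lod_values).max() < 1e-12


def test_marker_blocking_invariance(small_dataset):
    Y, G, K = small_dataset
    whole = scan_null_grid(Y, G, K)
    blocked = scan_null_grid(Y, G, K, options=ScanOptions(marker_block_size=7))
    assert np.abs(whole.lod_values - blocked.lod_values).max() < 1e-12


def test_monomorphic_marker_gets_zero_lod(small_dataset):
    Y, G, K = small_dataset
    vals = G.values.copy()
    vals[:, 5] = 1.0
    G2 = GenotypeMatrix(vals, marker_ids=list(G.marker_ids),
                        individual_ids=list(G.individual_ids))
    res = scan_null_grid(Y, G2, K)
    assert np.all(res.lod_values[:, 5] == 0.0)
    assert res.lod_values.shape == (Y.m, G.p)


def test_single_trait_scan_is_row_of_bulk(small_dataset):
    Y, G, K = small_dataset
    bulk = scan_null_exact(Y, G, K)
    solo = scan_null_exact(Y.values[:, [2]], G, K)
    assert np.abs(solo.lod_values[0] - bulk.lod_values[2]).max() < 1e-10


def test_qtl_detection_power():
    """A large-effect QTL (1.5 background SD, h2=0.4, n=200) is found at the
    causal marker in nearly all simulations."""
    from bulkscan import SimulationConfig, simulate_dataset

    hits = 0
    n_sim = 25
    for s in range(n_sim):
        cfg = SimulationConfig(n_strains=200, replicates_per_strain=1, n_markers=60,
                               n_traits=1, h2_true=0.4, qtl_positions=[30],
                               qtl_effects=[1.5], noise_seed=1000 + s)
        Y, G, K = simulate_dataset(cfg)
        res = scan_null_exact(Y, G, K)
        hits += int(res.lod_values[0].argmax()) == 30
    assert hits >= int(0.95 * n_sim) - 1


def test_lmm_shrinks_significance_on_structured_null():
    """On kinship-structured null traits the LMM -log10 p is typically no
    larger than the naive linear-model value (relatedness correction)."""
    from bulkscan import SimulationConfig, simulate_dataset
    from bulkscan.lod import lod_to_neglog10p

    cfg = SimulationConfig(n_strains=40, replicates_per_strain=3, n_markers=100,
                           n_traits=20, h2_true=0.6, noise_seed=77)
    Y, G, K = simulate_dataset(cfg)
    lmm = scan_null_grid(Y, G, K, grid=HeritabilityGrid.from_step(0.05))
    lm = scan_lm(Y, G)
    p_lmm = np.median(lod_to_neglog10p(lmm.lod_values))
    p_lm = np.median(lod_to_neglog10p(lm.lod_values))
    assert p_lmm <= p_lm
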