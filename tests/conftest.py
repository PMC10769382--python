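import numpy as np
import pytest

from bulkscan import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """n=60 (30 strains x 2 reps), m=5 traits, p=40 markers, one QTL.

    Strain replication makes the kinship rank deficient, so this fixture
    also exercises the boundary-avoidance regime.
    """
    cfg = SimulationConfig(
        n_strains=30,
        replicates_per_strain=2,
        n_markers=40,
        n_traits=5,
        h2_true=0.4,
        qtl_positions=[10],
        qtl_effects=[1.0],
        noise_seed=3,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def full_rank_dataset():
    """n=50 unrelated-strain individuals, full-rank kinship, m=4, p=30."""
    cfg = SimulationConfig(
        n_strains=50,
        replicates_per_strain=1,
        n_markers=30,
        n_traits=4,
        h2_true=0.3,
        noise_seed=9,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def boundary_dataset():
    """Duplicated-individual fixture where the ML objective diverges.

    One individual is genotyped (and phenotyped) twice — as when strain
    means are analysed with replicated genotype rows — so the kinship has a
    zero eigenvalue whose eigendirection carries no trait residual: the
    residual variance estimate collapses to zero as h2 -> 1 and the
    profiled ML objective blows up at the boundary.  Markers are dense and
    independent so the positive eigenvalues stay well away from zero.
    """
    from bulkscan import GenotypeMatrix, compute_kinship

    cfg = SimulationConfig(
        n_strains=60,
        replicates_per_strain=1,
        n_markers=300,
        n_traits=3,
        h2_true=0.5,
        markov_flip_prob=0.5,
        noise_seed=23,
    )
    Y, G, _ = simulate_dataset(cfg)
    gv = G.values.copy()
    gv[1] = gv[0]
    G2 = GenotypeMatrix(gv, marker_ids=list(G.marker_ids),
                        individual_ids=list(G.individual_ids))
    yv = Y.values.copy()
    yv[1] = yv[0]
    from bulkscan import TraitMatrix

    Y2 = TraitMatrix(yv, trait_ids=list(Y.trait_ids),
                     individual_ids=list(Y.individual_ids))
    return Y2, G2, compute_kinship(G2)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
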