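"""Synthetic structured-population fixtures with known ground truth.

Emulates a recombinant-inbred design: a modest number of inbred strains,
each replicated over several individuals, genotyped at biallelic markers
coded 0/1.  Strain haplotypes follow a Markov chain along the genome so
neighbouring markers are correlated (recombination-like LD), and strain
replication makes the genotype rows of replicates identical — which in
turn makes the kinship matrix low-rank, the regime where boundary
avoidance matters.

Traits are drawn from the generative LMM: fixed QTL effects (in trait-SD
units of the polygenic + noise background) plus a polygenic term
u ~ N(0, sigma_g^2 K) and noise e ~ N(0, sigma_e^2 I), with
sigma_g^2 / (sigma_g^2 + sigma_e^2) equal to the requested background
heritability.  All draws descend from one seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, KinshipMatrix, TraitMatrix, compute_kinship

__all__ = ["SimulationConfig", "simulate_genotypes", "simulate_traits", "simulate_dataset"]


@dataclass
class SimulationConfig:
    """Ground-truth settings for one simulated dataset.

    ``markov_flip_prob`` is the chance that a strain haplotype switches
    allele between adjacent markers (0.5 = independent markers); the
    default 0.1 gives block-like LD typical of an inbred panel.
    QTL effect sizes are in SD units of the polygenic + noise background.
    """

    n_strains: int = 50
    replicates_per_strain: int = 1
    n_markers: int = 200
    n_traits: int = 1
    h2_true: float = 0.5
    qtl_positions: list[int] = field(default_factory=list)
    qtl_effects: list[float] = field(default_factory=list)
    markov_flip_prob: float = 0.1
    total_variance: float = 1.0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_true < 1.0:
            raise ValueError("h2_true must lie in [0, 1)")
        if len(self.qtl_positions) != len(self.qtl_effects):
            raise ValueError("qtl_positions and qtl_effects must have equal length")
        if self.n_strains < 2 or self.replicates_per_strain < 1:
            raise ValueError("need at least 2 strains and 1 replicate")

    @property
    def n(self) -> int:
        return self.n_strains * self.replicates_per_strain


def _rng(cfg: SimulationConfig, stream: str) -> np.random.Generator:
    # sub-seeds derived deterministically from the single config seed
    # (crc32, not hash(): str hashing is salted per process)
    ss = np.random.SeedSequence(cfg.noise_seed, spawn_key=(zlib.crc32(stream.encode()),))
    return np.random.default_rng(ss)


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Strain-level 0/1 dosages with Markov LD, replicated within strain."""
    rng = _rng(cfg, "genotypes")
    s, p = cfg.n_strains, cfg.n_markers
    H = np.empty((s, p), dtype=float)
    H[:, 0] = rng.integers(0, 2, size=s)
    flips = rng.random((s, p - 1)) < cfg.markov_flip_prob
    for j in range(1, p):
        H[:, j] = np.where(flips[:, j - 1], 1.0 - H[:, j - 1], H[:, j - 1])
    G = np.repeat(H, cfg.replicates_per_strain, axis=0)
    ids = [
        f"strain{a:03d}_rep{b}"
        for a in range(s)
        for b in range(cfg.replicates_per_strain)
    ]
    return GenotypeMatrix(
        G, marker_ids=[f"mk{j:05d}" for j in range(p)], individual_ids=ids
    )


def simulate_traits(
    G: GenotypeMatrix, K: KinshipMatrix | None, cfg: SimulationConfig
) -> TraitMatrix:
    """Traits from the LMM generative model at the configured heritability.

    The polygenic + noise background has total variance ``total_variance``
    split so that sigma_g^2 / (sigma_g^2 + sigma_e^2) = h2_true; QTL
    effects are added on top of that background, so h2_true refers to the
    background decomposition (documented so recovery tests are well-posed).
    """
    if K is None:
        K = compute_kinship(G)
    n = G.n
    if K.n != n:
        raise ValueError("kinship size does not match genotypes")
    sigma_g2 = cfg.h2_true * cfg.total_variance
    sigma_e2 = (1.0 - cfg.h2_true) * cfg.total_variance
    if sigma_e2 <= 0:
        raise ValueError("h2_true = 1 leaves no residual variance")

    rng = _rng(cfg, "traits")
    m = cfg.n_traits
    Y = np.zeros((n, m))
    if sigma_g2 > 0:
        lam, U = np.linalg.eigh(K.values)
        lam = np.clip(lam, 0.0, None)
        Z = rng.standard_normal((n, m))
        Y += U @ (np.sqrt(sigma_g2 * lam)[:, None] * Z)
    Y += np.sqrt(sigma_e2) * rng.standard_normal((n, m))
    sd = np.sqrt(cfg.total_variance)
    for pos, eff in zip(cfg.qtl_positions, cfg.qtl_effects):
        Y += (eff * sd) * G.values[:, [pos]]
    return TraitMatrix(
        Y,
        trait_ids=[f"trait{i:04d}" for i in range(m)],
        individual_ids=list(G.individual_ids),
    )


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[TraitMatrix, GenotypeMatrix, KinshipMatrix]:
    """Genotypes, the kinship computed from them, and traits, in one call."""
    G = simulate_genotypes(cfg)
    K = compute_kinship(G)
    Y = simulate_traits(G, K, cfg)
    return Y, G, K
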