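"""Annotation-universe simulator with a planted GO-term-set overlap.

Builds a protein universe, three labeled protein sets (the bacterial
condensate set inside the universe, plus external P-body and stress-granule
reference sets), and a protein -> GO-term map in which the fraction of the
condensate term set shared with the reference term sets is planted at a
requested value.  Background universe proteins draw their terms mostly from
a non-shared vocabulary, so a planted overlap above the background rate is a
genuine enrichment detectable by the permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GoSimConfig", "GoGroundTruth", "simulate_go_universe"]


@dataclass
class GoSimConfig:
    """Study conditions for the annotation simulator."""

    seed: int
    universe_size: int = 2000
    n_terms: int = 600
    terms_per_protein_mean: float = 4.0
    set_sizes: tuple[int, int, int] = (80, 100, 120)   # condensate, P-body, SG
    planted_overlap: float = 0.35
    bg_shared_rate: float = 0.05   # background leakage into the shared pools
    n_perm: int = 1000

    def __post_init__(self):
        if not 0.0 <= self.planted_overlap <= 1.0:
            raise ValueError("planted_overlap must be in [0, 1]")
        if self.set_sizes[0] > self.universe_size:
            raise ValueError("condensate set larger than the universe")
        if self.n_terms < 6:
            raise ValueError("need at least 6 terms to partition the vocabulary")
        if self.terms_per_protein_mean < 1:
            raise ValueError("terms_per_protein_mean must be >= 1")


@dataclass
class GoGroundTruth:
    realized_overlap: float
    hp_terms: set
    pb_terms: set
    sg_terms: set
    shared_pool: list
    private_pool: list


def simulate_go_universe(
    config: GoSimConfig,
) -> tuple[dict, dict, GoGroundTruth]:
    """Build (annotation map, labeled protein sets, ground truth).

    The term vocabulary is partitioned into a P-body pool, a stress-granule
    pool, a condensate-private pool and a background pool.  The condensate
    term set takes ``round(planted_overlap * m)`` of its ``m`` terms from the
    reference pools and the rest from the private pool, then is dealt
    round-robin over the condensate proteins so the union realizes the set
    exactly.  Raises when the pools cannot supply the requested overlap.
    """
    rng = np.random.default_rng(config.seed)
    n_hp, n_pb, n_sg = config.set_sizes

    terms = [f"GO:{i:07d}" for i in range(config.n_terms)]
    quarter = config.n_terms // 4
    pb_pool = terms[:quarter]
    sg_pool = terms[quarter : 2 * quarter]
    hp_private_pool = terms[2 * quarter : 3 * quarter]
    bg_pool = terms[3 * quarter :]
    shared_pool = pb_pool + sg_pool

    # condensate term-set size: about half the per-protein mean times the set
    # size, bounded by what the pools can supply
    m = int(round(config.terms_per_protein_mean * n_hp / 2))
    p = config.planted_overlap
    if p > 0:
        m = min(m, int(np.floor(len(shared_pool) / p)))
    if p < 1:
        m = min(m, int(np.floor(len(hp_private_pool) / (1 - p))))
    if m < 2:
        raise ValueError(
            f"planted overlap {p} infeasible with n_terms={config.n_terms}: "
            "term pools cannot supply a condensate term set"
        )
    k_shared = int(round(p * m))

    hp_terms = list(rng.choice(shared_pool, size=k_shared, replace=False)) + list(
        rng.choice(hp_private_pool, size=m - k_shared, replace=False)
    )

    universe = [f"EC_{i:05d}" for i in range(config.universe_size)]
    hp_proteins = list(rng.choice(universe, size=n_hp, replace=False))
    pb_proteins = [f"PB_{i:04d}" for i in range(n_pb)]
    sg_proteins = [f"SG_{i:04d}" for i in range(n_sg)]

    annotation: dict[str, set] = {}

    # condensate proteins: deal the term set round-robin (union is exact),
    # then add extra draws from the same set for realistic multiplicity
    for protein in hp_proteins:
        annotation[protein] = set()
    for i, term in enumerate(hp_terms):
        annotation[hp_proteins[i % n_hp]].add(term)
    for protein in hp_proteins:
        extra = rng.poisson(max(config.terms_per_protein_mean - 1, 0))
        if extra:
            annotation[protein] |= set(
                rng.choice(hp_terms, size=min(extra, len(hp_terms)), replace=False)
            )

    # reference sets: full coverage of their pools plus random multiplicity
    for proteins, pool in ((pb_proteins, pb_pool), (sg_proteins, sg_pool)):
        for protein in proteins:
            annotation[protein] = set()
        for i, term in enumerate(pool):
            annotation[proteins[i % len(proteins)]].add(term)
        for protein in proteins:
            extra = rng.poisson(max(config.terms_per_protein_mean - 1, 0))
            if extra:
                annotation[protein] |= set(
                    rng.choice(pool, size=min(extra, len(pool)), replace=False)
                )

    # background universe proteins: mostly non-shared vocabulary
    non_shared = hp_private_pool + bg_pool
    hp_set = set(hp_proteins)
    for protein in universe:
        if protein in hp_set:
            continue
        n_p = max(int(rng.poisson(config.terms_per_protein_mean)), 1)
        picks = []
        for _ in range(n_p):
            if rng.uniform() < config.bg_shared_rate:
                picks.append(shared_pool[rng.integers(len(shared_pool))])
            else:
                picks.append(non_shared[rng.integers(len(non_shared))])
        annotation[protein] = set(picks)

    hp_term_set = set(hp_terms)
    pb_term_set = set(pb_pool)
    sg_term_set = set(sg_pool)
    realized = (
        len(hp_term_set & (pb_term_set | sg_term_set)) / len(hp_term_set)
        if hp_term_set else 0.0
    )
    protein_sets = {
        "HP_body": set(hp_proteins),
        "P_body": set(pb_proteins),
        "stress_granule": set(sg_proteins),
        "universe": set(universe),
    }
    truth = GoGroundTruth(
        realized_overlap=realized,
        hp_terms=hp_term_set,
        pb_terms=pb_term_set,
        sg_terms=sg_term_set,
        shared_pool=shared_pool,
        private_pool=hp_private_pool,
    )
    return annotation, protein_sets, truth
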