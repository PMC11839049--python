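"""GO-term-set overlap between condensate proteomes, with a permutation test.

The comparison is at the level of flat annotation term sets: each labeled
protein set (the bacterial condensate proteome and the eukaryotic P-body and
stress-granule reference sets) is mapped to the union of its members' GO
terms, and the two- and three-way intersections of those term sets are
computed.  Significance of the observed overlaps is assessed by re-drawing
the condensate protein set uniformly at random (same size, without
replacement) from a declared protein universe and recomputing the overlaps
for each permutation; the one-sided enrichment p-value uses the add-one
estimator ``(1 + #{null >= observed}) / (n_perm + 1)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OverlapResult",
    "PermutationResult",
    "build_term_set",
    "compute_term_overlap",
    "permutation_overlap_test",
]

logger = logging.getLogger(__name__)


def build_term_set(proteins, annotation: dict) -> set:
    """Union of GO terms annotated to the member proteins.

    Proteins absent from the annotation map are logged and skipped; an empty
    resulting term set triggers a warning but is returned as-is.
    """
    terms: set = set()
    missing = []
    for protein in proteins:
        if protein in annotation:
            terms |= set(annotation[protein])
        else:
            missing.append(protein)
    if missing:
        logger.info("%d proteins missing from annotation: %s ...",
                    len(missing), missing[:5])
    if not terms:
        warnings.warn("protein set maps to an empty term set", stacklevel=2)
    return terms


@dataclass
class OverlapResult:
    """Pairwise and three-way GO-term-set intersections and the shared fraction."""

    n_hp: int
    n_pb: int
    n_sg: int
    hp_pb: set
    hp_sg: set
    pb_sg: set
    three_way: set
    shared_fraction: float | None  # |hp & (pb | sg)| / |hp|; None if hp empty
    flags: list

    @property
    def joint(self) -> set:
        """Terms of the condensate set shared with P-bodies and/or stress granules."""
        return self.hp_pb | self.hp_sg


def compute_term_overlap(hp: set, pb: set, sg: set) -> OverlapResult:
    """All pairwise intersections, the three-way intersection, and the
    fraction of the condensate term set shared with either reference set."""
    flags = []
    if not hp:
        flags.append("empty condensate term set: shared fraction undefined")
    frac = len(hp & (pb | sg)) / len(hp) if hp else None
    return OverlapResult(
        n_hp=len(hp), n_pb=len(pb), n_sg=len(sg),
        hp_pb=hp & pb, hp_sg=hp & sg, pb_sg=pb & sg,
        three_way=hp & pb & sg,
        shared_fraction=frac,
        flags=flags,
    )


@dataclass
class PermutationResult:
    """Null distributions and p-values for the three overlap statistics."""

    n_perm: int
    seed: int
    observed: dict        # {'pb', 'sg', 'joint'} -> observed intersection size
    null: dict            # {'pb', 'sg', 'joint'} -> (n_perm,) int array
    p_values: dict        # {'pb', 'sg', 'joint'} -> add-one permutation p


def permutation_overlap_test(
    hp_proteins,
    universe,
    annotation: dict,
    pb_terms: set,
    sg_terms: set,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of condensate GO-term overlap with P-body/stress-granule sets.

    Each permutation draws ``|hp_proteins|`` proteins uniformly without
    replacement from ``universe``, rebuilds the term set, and recomputes the
    three overlap sizes (with the P-body terms, the stress-granule terms, and
    their union).  Proteins without annotations stay drawable and contribute
    empty term sets.  Deterministic given ``seed``.
    """
    hp_proteins = list(dict.fromkeys(hp_proteins))
    universe = list(dict.fromkeys(universe))
    if len(hp_proteins) > len(universe):
        raise ValueError("universe smaller than the condensate protein set")
    outside = set(hp_proteins) - set(universe)
    if outside:
        raise ValueError(
            f"condensate proteins outside the resampling universe: "
            f"{sorted(outside)[:5]} ..."
        )

    hp_terms = build_term_set(hp_proteins, annotation)
    observed = {
        "pb": len(hp_terms & pb_terms),
        "sg": len(hp_terms & sg_terms),
        "joint": len(hp_terms & (pb_terms | sg_terms)),
    }

    rng = np.random.default_rng(seed)
    universe_arr = np.asarray(universe, dtype=object)
    null = {key: np.empty(n_perm, dtype=int) for key in observed}
    for i in range(n_perm):
        draw = rng.choice(universe_arr, size=len(hp_proteins), replace=False)
        terms: set = set()
        for protein in draw:
            terms |= set(annotation.get(protein, ()))
        null["pb"][i] = len(terms & pb_terms)
        null["sg"][i] = len(terms & sg_terms)
        null["joint"][i] = len(terms & (pb_terms | sg_terms))

    p_values = {
        key: float((1 + int((null[key] >= observed[key]).sum())) / (n_perm + 1))
        for key in observed
    }
    return PermutationResult(
        n_perm=n_perm, seed=seed, observed=observed, null=null, p_values=p_values
    )
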