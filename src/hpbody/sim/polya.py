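"""3'-end read simulator with ZINB-distributed untemplated poly(A) tails.

Each simulated read belongs to a known gene: its tail length is drawn from
the gene's zero-inflated negative binomial (cell-specific mean mu_gc, shared
zero-inflation pi_g and overdispersion theta_g), the read sequence is that
many leading 'T' bases followed by a non-T-starting templated remainder, and
its alignment coordinates place the tail-anchoring end inside the gene's 3'
window with the antisense orientation the tail chemistry implies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..polya import (
    CELLS,
    AlignedRead,
    GeneModel,
    tail_window,
)

__all__ = ["PolyaSimConfig", "PolyaGroundTruth", "simulate_polya_reads",
           "sample_zinb"]

_TEMPLATE_FIRST = "ACG"   # first templated base is never T, keeping the
_TEMPLATE_ALL = "ACGT"    # terminal-T run equal to the drawn tail length


@dataclass
class PolyaSimConfig:
    """Study conditions for the poly(A)-tail read simulator."""

    seed: int
    gene_models: list            # of GeneModel
    cell_means: dict             # gene_id -> {(genotype, condition): mu >= 0}
    zero_inflation: dict         # gene_id -> pi in [0, 1]
    overdispersion: dict         # gene_id -> theta > 0
    reads_per_gene_per_sample: int = 100
    replicates_per_cell: int = 4
    read_length: int = 50

    def __post_init__(self):
        for g in self.gene_models:
            pi = self.zero_inflation[g.gene_id]
            theta = self.overdispersion[g.gene_id]
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"{g.gene_id}: pi must be in [0, 1]")
            if theta <= 0:
                raise ValueError(f"{g.gene_id}: theta must be > 0")
            if any(mu < 0 for mu in self.cell_means[g.gene_id].values()):
                raise ValueError(f"{g.gene_id}: cell means must be >= 0")
        if self.reads_per_gene_per_sample < 0:
            raise ValueError("reads_per_gene_per_sample must be >= 0")


@dataclass
class PolyaGroundTruth:
    cell_means: dict
    zero_inflation: dict
    overdispersion: dict
    design: dict                         # sample -> (genotype, condition)
    read_gene: dict = field(default_factory=dict)   # read_id -> gene_id
    read_tail: dict = field(default_factory=dict)   # read_id -> true tail length


def sample_zinb(rng, n, mu, theta, pi):
    """Draw n ZINB variates (NB2 parametrization, point mass at zero)."""
    if n == 0:
        return np.empty(0, dtype=int)
    zeros = rng.uniform(size=n) < pi
    if mu <= 0:
        nb = np.zeros(n, dtype=int)
    else:
        nb = rng.negative_binomial(theta, theta / (theta + mu), size=n)
    return np.where(zeros, 0, nb).astype(int)


def simulate_polya_reads(
    config: PolyaSimConfig,
) -> tuple[list[AlignedRead], PolyaGroundTruth]:
    """Simulate tail-bearing 3'-end reads for every gene and sample.

    Samples are named ``{genotype}_{condition}_r{replicate}`` across the four
    genotype x condition cells.  Anchors are uniform within each gene's 3'
    window; reads align antisense to their gene, so a plus-strand gene yields
    minus-strand alignments whose rightmost aligned base is the anchor.
    Overlapping same-strand windows are warned about (those reads become
    genuinely ambiguous downstream).
    """
    rng = np.random.default_rng(config.seed)
    design = {}
    for genotype, condition in CELLS:
        for rep in range(1, config.replicates_per_cell + 1):
            design[f"{genotype}_{condition}_r{rep}"] = (genotype, condition)

    by_strand: dict[tuple[str, str], list] = {}
    for gene in config.gene_models:
        w = tail_window(gene)
        for pw, pid in by_strand.get((gene.chrom, gene.strand), []):
            if w[0] < pw[1] and pw[0] < w[1]:
                warnings.warn(
                    f"3' windows of {pid} and {gene.gene_id} overlap; simulated "
                    "reads in the shared span are ambiguous",
                    stacklevel=2,
                )
        by_strand.setdefault((gene.chrom, gene.strand), []).append((w, gene.gene_id))

    reads: list[AlignedRead] = []
    truth = PolyaGroundTruth(
        cell_means=config.cell_means,
        zero_inflation=config.zero_inflation,
        overdispersion=config.overdispersion,
        design=design,
    )
    counter = 0
    for gene in config.gene_models:
        w_start, w_end = tail_window(gene)
        pi = config.zero_inflation[gene.gene_id]
        theta = config.overdispersion[gene.gene_id]
        for sample, cell in design.items():
            mu = config.cell_means[gene.gene_id][cell]
            tails = sample_zinb(rng, config.reads_per_gene_per_sample, mu, theta, pi)
            for k in tails:
                k = int(min(k, config.read_length - 1))
                n_template = config.read_length - k
                template = rng.choice(list(_TEMPLATE_FIRST)) + "".join(
                    rng.choice(list(_TEMPLATE_ALL), size=n_template - 1)
                )
                seq = "T" * k + template
                # anchor uniform in the window, clipped to valid coordinates
                anchor = int(rng.integers(max(w_start, 0), w_end))
                if gene.strand == "+":
                    aln_strand = "-"
                    pos0 = max(anchor - n_template + 1, 0)
                    aligned_length = anchor - pos0 + 1
                else:
                    aln_strand = "+"
                    pos0 = anchor
                    aligned_length = n_template
                read_id = f"read{counter:07d}"
                counter += 1
                reads.append(
                    AlignedRead(
                        read_id=read_id,
                        chrom=gene.chrom,
                        pos0=pos0,
                        strand=aln_strand,
                        sequence=seq,
                        sample=sample,
                        aligned_length=aligned_length,
                    )
                )
                truth.read_gene[read_id] = gene.gene_id
                truth.read_tail[read_id] = int(k)
    return reads, truth
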