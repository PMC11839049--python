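"""Rifampicin-chase count-table simulator with constant ERCC spike-ins.

Expected genomic counts decay as ``a_g * exp(-t / b_g)`` over the chase;
ERCC spike-in features stay constant in expectation (they are added per cell
equivalent, not transcribed).  Counts are Poisson-sampled unless noise is
disabled, in which case the expectations themselves are emitted so that
downstream decay fitting is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DecaySimConfig", "DecayGroundTruth", "simulate_decay_counts",
           "default_gene_params"]


@dataclass
class DecaySimConfig:
    """Study conditions for one genotype's transcription shut-off time course."""

    seed: int
    gene_params: pd.DataFrame          # index gene, columns a (baseline), b (min)
    timepoints: tuple = (0, 10, 30, 60)   # minutes after rifampicin
    # one decade of abundances, high enough that every spike-in stays above
    # the downstream relative-abundance threshold at all chase timepoints
    # (the passing set must not change as genomic reads decay, or the
    # passing-set median drifts and biases the fitted decay constants)
    spikein_abund: dict = field(default_factory=lambda: {
        f"ERCC-{i:05d}": a for i, a in enumerate(
            np.geomspace(500.0, 5000.0, 20), start=1)
    })
    depth: float = 1_000_000.0         # expected reads per sample at t=0
    poisson_noise: bool = True
    n_replicates: int = 2
    genotype: str = "WT"

    def __post_init__(self):
        gp = self.gene_params
        if (gp["a"] < 0).any() or (gp["b"] <= 0).any():
            raise ValueError("require a >= 0 and b > 0 for every gene")
        t = np.asarray(self.timepoints, dtype=float)
        if (t < 0).any() or not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be non-negative and increasing")
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if not self.spikein_abund:
            raise ValueError("need at least one spike-in feature")


@dataclass
class DecayGroundTruth:
    a: pd.Series
    b: pd.Series
    depth_scale: float     # reads per abundance unit at t=0
    genotype: str


def default_gene_params(
    n_genes: int, seed: int, b_range: tuple[float, float] = (5.0, 80.0)
) -> pd.DataFrame:
    """Realistic per-gene decay parameters: log-normal baselines, log-uniform taus."""
    rng = np.random.default_rng(seed)
    a = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n_genes)
    b = np.exp(rng.uniform(np.log(b_range[0]), np.log(b_range[1]), size=n_genes))
    return pd.DataFrame(
        {"a": a, "b": b}, index=[f"gene{i:04d}" for i in range(n_genes)]
    )


def simulate_decay_counts(
    config: DecaySimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, DecayGroundTruth]:
    """Simulate the count table; returns (counts, sample sheet, ground truth).

    The count table has genomic features plus ``ERCC-``-prefixed rows and one
    column per sample; the sample sheet has columns
    ``sample, genotype, timepoint_min, replicate, rifampicin``.  The global
    depth scale (reads per abundance unit, chosen so the expected total at
    t=0 equals ``depth``) is exported in the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    a = config.gene_params["a"].astype(float)
    b = config.gene_params["b"].astype(float)
    ercc = pd.Series(config.spikein_abund, dtype=float)
    scale = config.depth / (a.sum() + ercc.sum())

    columns = {}
    meta_rows = []
    for t in config.timepoints:
        gene_expect = scale * a * np.exp(-float(t) / b)
        expect = pd.concat([gene_expect, scale * ercc])
        for rep in range(1, config.n_replicates + 1):
            sample = f"{config.genotype}_t{int(t)}_r{rep}"
            if config.poisson_noise:
                columns[sample] = rng.poisson(expect.to_numpy())
            else:
                columns[sample] = expect.to_numpy()
            meta_rows.append((sample, config.genotype, float(t), rep, True))

    counts = pd.DataFrame(columns, index=expect.index)
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample", "genotype", "timepoint_min", "replicate", "rifampicin"],
    )
    truth = DecayGroundTruth(a=a, b=b, depth_scale=scale, genotype=config.genotype)
    return counts, meta, truth
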