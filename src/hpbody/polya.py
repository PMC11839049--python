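"""Untemplated poly(A)-tail calling and zero-inflated negative binomial modelling.

3'-end sequencing reads start with the reverse complement of the transcript's
poly(A) tail, so the untemplated tail appears as a run of 'T' at the 5' end of
the read as sequenced; under local alignment that run is soft-clipped and the
templated remainder anchors the read on the genome.  Reads whose tail-adjacent
aligned end falls in a gene's 3' window (50 bp upstream to 250 bp downstream of
the gene end, strand-aware) are assigned to that gene, and the per-gene tail
length distributions across genotype x condition cells are fitted with a
zero-inflated negative binomial (ZINB) regression: one log-link mean per cell
(four degrees of freedom), a single zero-inflation rate pi and a single
overdispersion theta per gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.special import expit, logit
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GENOTYPES",
    "CONDITIONS",
    "CELLS",
    "GeneModel",
    "AlignedRead",
    "TailDistribution",
    "ZinbFit",
    "TailSummary",
    "count_terminal_A",
    "tail_window",
    "assign_reads_to_tail_windows",
    "zinb_logpmf",
    "fit_zinb_tail_model",
    "summarize_tail_shifts",
]

GENOTYPES = ("WT", "ppk")
CONDITIONS = ("N+", "N24")
#: the four genotype x nitrogen-status cells of the design, in model order
CELLS = tuple((g, c) for g in GENOTYPES for c in CONDITIONS)

WINDOW_UPSTREAM = 50     # bases before the gene 3' end
WINDOW_DOWNSTREAM = 250  # bases after the gene 3' end


def count_terminal_A(sequence: str, mode: str = "terminal-run") -> int:
    """Number of untemplated 3' adenosines called from one read.

    In ``terminal-run`` mode (default) this is the length of the maximal run
    of 'T' at the 5' end of the read as sequenced — the tail reads out as
    leading T's given the adapter orientation.  ``total-t`` counts every T in
    the read and is provided for sensitivity analysis only.  Case-insensitive.
    """
    if not sequence:
        raise ValueError("empty read sequence")
    seq = sequence.upper()
    if mode == "total-t":
        return seq.count("T")
    if mode != "terminal-run":
        raise ValueError(f"unknown tail mode {mode!r}")
    n = 0
    for base in seq:
        if base != "T":
            break
        n += 1
    return n


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: 0-based half-open genomic interval with strand."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")


def tail_window(gene: GeneModel) -> tuple[int, int]:
    """3' window of a gene: 50 bp before to 250 bp after its 3' end, half-open.

    Plus strand: ``[end - 50, end + 250)``; minus strand:
    ``[start - 250, start + 50)``.  Always 300 bases wide (may extend below 0
    near a contig edge; membership tests handle that naturally).
    """
    if gene.strand == "+":
        return gene.end - WINDOW_UPSTREAM, gene.end + WINDOW_DOWNSTREAM
    return gene.start - WINDOW_DOWNSTREAM, gene.start + WINDOW_UPSTREAM


@dataclass(frozen=True)
class AlignedRead:
    """One aligned 3'-end read.

    ``sequence`` is the read as sequenced (tail T's leading).  ``pos0`` is the
    leftmost aligned reference position, ``strand`` the alignment strand.
    ``aligned_length`` is the reference span of the alignment; when absent it
    is inferred as the read length minus the soft-clipped leading T run.
    """

    read_id: str
    chrom: str
    pos0: int
    strand: str
    sequence: str
    sample: str
    aligned_length: int | None = None

    def __post_init__(self):
        if self.pos0 < 0:
            raise ValueError("position must be >= 0")
        if not self.sequence:
            raise ValueError("sequence non-empty")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def _aligned_span(self) -> int:
        if self.aligned_length is not None:
            return self.aligned_length
        return max(len(self.sequence) - count_terminal_A(self.sequence), 1)

    @property
    def tail_anchor(self) -> int:
        """Genomic coordinate of the aligned end adjacent to the terminal-T run.

        The tail is at the read's 5' end, so the anchor is the leftmost
        aligned base for a plus-strand alignment and the rightmost for a
        minus-strand alignment.
        """
        if self.strand == "+":
            return self.pos0
        return self.pos0 + self._aligned_span() - 1


@dataclass
class TailDistribution:
    """Per-gene, per-sample collections of terminal-A counts."""

    counts: dict = field(default_factory=dict)  # gene -> sample -> int ndarray
    n_unassigned: int = 0
    n_multi_assigned: int = 0

    def gene_observations(self, gene: str, design: dict) -> pd.DataFrame:
        """Long-format observations for one gene: tail count + cell labels."""
        rows = []
        for sample, vals in self.counts.get(gene, {}).items():
            genotype, condition = design[sample]
            for k in vals:
                rows.append((int(k), genotype, condition, sample))
        return pd.DataFrame(rows, columns=["tail", "genotype", "condition", "sample"])

    def histogram_frame(self) -> pd.DataFrame:
        """Tidy histogram: gene, sample, tail_length, n_reads."""
        rows = []
        for gene, per_sample in self.counts.items():
            for sample, vals in per_sample.items():
                lengths, n = np.unique(vals, return_counts=True)
                rows.extend((gene, sample, int(l), int(c)) for l, c in zip(lengths, n))
        return pd.DataFrame(rows, columns=["gene", "sample", "tail_length", "n_reads"])


def assign_reads_to_tail_windows(
    reads: list[AlignedRead],
    genes: list[GeneModel],
    orientation: str = "antisense",
    tail_mode: str = "terminal-run",
) -> TailDistribution:
    """Assign reads to gene 3' windows and collect terminal-A counts.

    A read is assigned to a gene when its tail-anchoring coordinate lies in
    the gene's 3' window and its alignment strand is consistent with the gene:
    ``antisense`` (default, matching the adapter chemistry that reads the tail
    as leading T's) requires the read to align opposite the gene's strand;
    ``sense`` requires the same strand.  Reads matching several windows are
    assigned to every matching gene (operon neighbours can share a poly(A)
    state); unassigned reads are counted, not dropped silently.
    """
    if orientation not in ("antisense", "sense"):
        raise ValueError(f"unknown orientation {orientation!r}")
    trees: dict[str, IntervalTree] = {}
    seen: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for gene in genes:
        w_start, w_end = tail_window(gene)
        for prev_start, prev_end, prev_id in seen.get((gene.chrom, gene.strand), []):
            if w_start < prev_end and prev_start < w_end:
                warnings.warn(
                    f"3' windows of {prev_id} and {gene.gene_id} overlap on "
                    f"{gene.chrom}{gene.strand}: reads there are ambiguous",
                    stacklevel=2,
                )
        seen.setdefault((gene.chrom, gene.strand), []).append(
            (w_start, w_end, gene.gene_id)
        )
        trees.setdefault(gene.chrom, IntervalTree()).addi(w_start, w_end, gene)

    acc: dict[str, dict[str, list[int]]] = {}
    n_unassigned = 0
    n_multi = 0
    for read in reads:
        tree = trees.get(read.chrom)
        hits = []
        if tree is not None:
            for iv in tree.at(read.tail_anchor):
                gene = iv.data
                same = read.strand == gene.strand
                if (orientation == "sense") == same:
                    hits.append(gene)
        if not hits:
            n_unassigned += 1
            continue
        if len(hits) > 1:
            n_multi += 1
        k = count_terminal_A(read.sequence, mode=tail_mode)
        for gene in hits:
            acc.setdefault(gene.gene_id, {}).setdefault(read.sample, []).append(k)

    counts = {
        g: {s: np.asarray(v, dtype=int) for s, v in per.items()}
        for g, per in acc.items()
    }
    return TailDistribution(counts, n_unassigned=n_unassigned, n_multi_assigned=n_multi)


def zinb_logpmf(k, mu, theta, pi):
    """Log pmf of the zero-inflated negative binomial.

    ``P(k) = pi * 1[k = 0] + (1 - pi) * NB(k; mu, theta)`` with the NB2
    parametrization (variance ``mu + mu^2 / theta``).  Vectorized over ``k``.
    """
    k = np.asarray(k)
    nb = stats.nbinom(theta, theta / (theta + mu))
    with np.errstate(divide="ignore"):
        log_nb = nb.logpmf(k)
        if pi <= 0.0:
            return log_nb
        if pi >= 1.0:
            return np.where(k == 0, 0.0, -np.inf)
        out = np.log1p(-pi) + log_nb
        return np.where(k == 0, np.logaddexp(np.log(pi), out), out)


@dataclass
class ZinbFit:
    """Per-gene ZINB fit: four cell means, shared pi and theta."""

    gene: object
    mu: dict                      # (genotype, condition) -> natural-scale mean
    beta: dict                    # (genotype, condition) -> log-link coefficient
    pi: float
    theta: float
    loglik: float
    converged: bool
    n_obs: int
    degenerate: bool = False      # all observations zero: pi -> 1, nothing fitted
    unfit: bool = False           # too few non-empty cells to fit
    cov_beta: pd.DataFrame | None = None
    reason: str = ""

    @property
    def usable(self) -> bool:
        return self.converged and not (self.degenerate or self.unfit)


def _cell_key(genotype: str, condition: str) -> str:
    return f"{genotype}|{condition}"


def fit_zinb_tail_model(
    dist: TailDistribution,
    gene: str,
    design: dict,
    max_iter: int = 500,
) -> ZinbFit:
    """Fit the per-gene ZINB regression across genotype x condition cells.

    The mean structure is one log-link coefficient per design cell (one-hot,
    no intercept); zero inflation and overdispersion are single shared
    parameters.  Genes with all-zero observations are flagged degenerate
    (pi -> 1) rather than fitted; genes observed in fewer than two cells are
    flagged unfit.
    """
    obs = dist.gene_observations(gene, design)
    n_obs = len(obs)
    if n_obs == 0:
        return ZinbFit(gene, {}, {}, np.nan, np.nan, np.nan, False, 0,
                       unfit=True, reason="no observations")
    cells_present = sorted(
        {(g, c) for g, c in zip(obs["genotype"], obs["condition"])},
        key=CELLS.index,
    )
    if len(cells_present) < 2:
        return ZinbFit(gene, {}, {}, np.nan, np.nan, np.nan, False, n_obs,
                       unfit=True, reason="observations in < 2 design cells")
    k = obs["tail"].to_numpy(dtype=float)
    if k.max() == 0:
        return ZinbFit(gene, {c: 0.0 for c in cells_present}, {}, 1.0, np.nan,
                       0.0, False, n_obs, degenerate=True,
                       reason="all observations zero")

    exog = pd.DataFrame(
        {
            _cell_key(g, c): ((obs["genotype"] == g) & (obs["condition"] == c)).astype(float)
            for g, c in cells_present
        }
    )
    exog_infl = np.ones((n_obs, 1))

    # moment-based starting values: log cell means, mild inflation, alpha=0.5
    start_beta = [
        np.log(k[exog[_cell_key(g, c)] == 1].mean() + 0.5) for g, c in cells_present
    ]
    zero_frac = float((k == 0).mean())
    start = np.concatenate(
        [[logit(np.clip(zero_frac / 2.0, 0.01, 0.9))], start_beta, [0.5]]
    )

    model = ZeroInflatedNegativeBinomialP(
        k, exog.to_numpy(), exog_infl=exog_infl, p=2
    )
    # L-BFGS is markedly more stable here than plain BFGS, which can diverge
    # from moment-based starts on heavily zero-inflated data
    res = None
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "nm"):
            try:
                cand = model.fit(
                    start_params=start, maxiter=max_iter, disp=0, method=method
                )
            except Exception:
                continue
            ok = bool(cand.mle_retvals.get("converged", False)) and np.isfinite(
                cand.llf
            )
            if res is None or (ok and not converged) or (
                ok == converged and np.isfinite(cand.llf)
                and (res is None or cand.llf > res.llf)
            ):
                res, converged = cand, ok
            if converged:
                break
    if res is None:
        return ZinbFit(gene, {}, {}, np.nan, np.nan, np.nan, False, n_obs,
                       reason="optimizer error in all methods")
    params = res.params
    pi = float(expit(params[0]))
    beta_vals = params[1 : 1 + len(cells_present)]
    alpha = float(params[-1])
    theta = 1.0 / alpha if alpha > 0 else np.inf
    beta = {cell: float(b) for cell, b in zip(cells_present, beta_vals)}
    mu = {cell: float(np.exp(b)) for cell, b in beta.items()}
    cov = None
    try:
        cov_full = np.asarray(res.cov_params())
        idx = list(range(1, 1 + len(cells_present)))
        cov = pd.DataFrame(
            cov_full[np.ix_(idx, idx)],
            index=[_cell_key(*c) for c in cells_present],
            columns=[_cell_key(*c) for c in cells_present],
        )
    except Exception:
        pass
    return ZinbFit(
        gene, mu, beta, pi, theta, float(res.llf), converged, n_obs,
        cov_beta=cov,
    )


@dataclass
class TailSummary:
    """Across-gene tail-length summary: per-cell means, shifts, significance."""

    means: pd.DataFrame        # gene x cell estimated mean tail ((1 - pi) mu)
    shifts: pd.DataFrame       # gene, condition, delta, p, padj
    cumulative: dict           # cell key -> DataFrame(mean_tail, cum_fraction)


def summarize_tail_shifts(fits: list[ZinbFit], fdr: float = 0.05) -> TailSummary:
    """Summarize fitted ZINB models into tail-length shifts between genotypes.

    The estimated mean tail length in a cell is ``(1 - pi) * mu_cell``.  For
    each condition the genotype shift is ``mean_ppk - mean_WT``, tested with a
    Wald test on the log-link coefficient contrast and Benjamini-Hochberg
    adjusted across genes within the condition.  Also emits per-cell
    cumulative distributions of the estimated means over genes.
    """
    usable = [f for f in fits if f.usable]
    if not usable:
        raise ValueError("no converged ZINB fits to summarize")

    mean_rows = {}
    for f in usable:
        mean_rows[f.gene] = {
            _cell_key(*cell): (1.0 - f.pi) * f.mu[cell]
            for cell in f.mu
        }
    means = pd.DataFrame.from_dict(mean_rows, orient="index").sort_index()

    shift_rows = []
    for f in usable:
        for cond in CONDITIONS:
            wt, pk = ("WT", cond), ("ppk", cond)
            if wt not in f.mu or pk not in f.mu:
                continue
            delta = (1.0 - f.pi) * (f.mu[pk] - f.mu[wt])
            p = np.nan
            if f.cov_beta is not None:
                kw, kp = _cell_key(*wt), _cell_key(*pk)
                var = (
                    f.cov_beta.loc[kp, kp]
                    + f.cov_beta.loc[kw, kw]
                    - 2.0 * f.cov_beta.loc[kp, kw]
                )
                if var > 0:
                    z = (f.beta[pk] - f.beta[wt]) / np.sqrt(var)
                    p = 2.0 * stats.norm.sf(abs(z))
            shift_rows.append((f.gene, cond, delta, p))
    shifts = pd.DataFrame(shift_rows, columns=["gene", "condition", "delta", "p"])
    shifts["padj"] = np.nan
    shifts["significant"] = False
    for cond in CONDITIONS:
        sel = (shifts["condition"] == cond) & shifts["p"].notna()
        if sel.any():
            rej, padj, _, _ = multipletests(
                shifts.loc[sel, "p"], alpha=fdr, method="fdr_bh"
            )
            shifts.loc[sel, "padj"] = padj
            shifts.loc[sel, "significant"] = rej

    cumulative = {}
    for col in means.columns:
        vals = np.sort(means[col].dropna().to_numpy())
        if vals.size:
            cumulative[col] = pd.DataFrame(
                {
                    "mean_tail": vals,
                    "cum_fraction": np.arange(1, vals.size + 1) / vals.size,
                }
            )
    return TailSummary(means=means, shifts=shifts, cumulative=cumulative)
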