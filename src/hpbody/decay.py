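"""Rifampicin-chase transcript half-life analysis with ERCC spike-in anchoring.

Raw gene-by-sample read counts are first turned into within-sample relative
abundances, then rescaled by the median relative abundance of the ERCC
spike-in features in that sample; because spike-ins are added per cell
equivalent before library prep, the result is a relative per-cell abundance
that can be compared across a transcription shut-off time course.  Per-gene
decay is modelled as ``y = a * exp(-t / b)`` with ``b`` the decay time
constant in minutes; decay constants between 5 and 65 minutes are considered
measurable (shorter decays are unresolvable before the first chase timepoint,
longer ones indistinguishable from stability over a 60-minute course).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DecayFit",
    "StabilityCall",
    "normalize_with_spikeins",
    "fit_exponential_decay",
    "fit_decay_table",
    "classify_stability_pair",
    "gene_set_halflife_shift",
    "MEASURABLE_MIN",
    "MEASURABLE_MAX",
]

ERCC_PREFIX = "ERCC-"
MEASURABLE_MIN = 5.0   # minutes
MEASURABLE_MAX = 65.0  # minutes
_STABLE_TAU = 65.0     # tau above this in one genotype ...
_UNSTABLE_TAU = 55.0   # ... and below this in the other => stable/unstable call
_SHIFT_TAU = 10.0      # minimum tau increase for a relative-stability call


def normalize_with_spikeins(
    counts: pd.DataFrame,
    ercc_min_rel_abund: float = 5e-4,
    ercc_prefix: str = ERCC_PREFIX,
) -> pd.DataFrame:
    """Two-step spike-in normalization of a feature x sample count table.

    Step 1 divides each count by its sample's total; step 2 divides the
    genomic features' relative abundances by the median relative abundance of
    the ERCC features exceeding ``ercc_min_rel_abund`` in that sample.
    Returns genomic features only.  Exactly scale-invariant per sample.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    is_ercc = counts.index.str.startswith(ercc_prefix)
    if not is_ercc.any():
        raise ValueError("count table contains no ERCC features")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    rel = counts / totals
    ercc_rel = rel.loc[is_ercc]
    scale = {}
    for sample in counts.columns:
        passing = ercc_rel[sample][ercc_rel[sample] > ercc_min_rel_abund]
        if passing.empty:
            raise ValueError(
                f"sample {sample!r}: no ERCC feature above relative abundance "
                f"{ercc_min_rel_abund}"
            )
        scale[sample] = passing.median()
    return rel.loc[~is_ercc] / pd.Series(scale)


@dataclass
class DecayFit:
    """Per-gene exponential decay fit ``y = a * exp(-t / b)``."""

    gene: object
    a: float            # baseline abundance at t=0
    b: float            # decay time constant, minutes
    residual: float     # sum of squared residuals
    converged: bool
    measurable: bool    # MEASURABLE_MIN <= b <= MEASURABLE_MAX


def _decay_model(t, a, b):
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        y = a * np.exp(-t / np.maximum(b, np.finfo(float).tiny))
    return np.nan_to_num(y, nan=0.0, posinf=np.finfo(float).max)


def fit_exponential_decay(
    timepoints: np.ndarray, abundances: np.ndarray, gene: object = None
) -> DecayFit:
    """Bounded least-squares fit of ``y = a * exp(-t / b)``.

    Both parameters are constrained non-negative and initialized at
    ``a = 0.001, b = 20`` (dogbox trust-region optimizer).  An all-zero series
    carries no decay information and is flagged unconverged.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if t.size < 3 or t.size != y.size:
        raise ValueError("need >= 3 matched (t, y) points")
    if (y < 0).any():
        raise ValueError("abundances must be non-negative")
    if y.max() == 0:
        return DecayFit(gene, 0.0, 0.0, 0.0, converged=False, measurable=False)
    best = None
    # second, data-scaled start rescues fits that fall into the degenerate
    # b -> 0 boundary minimum when the baseline start is far from the data
    for p0 in ((0.001, 20.0), (float(y.max()), 20.0)):
        try:
            popt, _ = optimize.curve_fit(
                _decay_model, t, y,
                p0=p0,
                bounds=(0.0, np.inf),
                method="dogbox",
                maxfev=10_000,
            )
        except Exception:
            continue
        sse = float(((y - _decay_model(t, *popt)) ** 2).sum())
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return DecayFit(gene, np.nan, np.nan, np.nan, converged=False, measurable=False)
    (a, b), resid = (float(v) for v in best[0]), best[1]
    measurable = MEASURABLE_MIN <= b <= MEASURABLE_MAX
    return DecayFit(gene, a, b, resid, converged=True, measurable=measurable)


def fit_decay_table(
    normalized: pd.DataFrame,
    meta: pd.DataFrame,
    genotype: str,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Fit decay for every gene in one genotype's rifampicin time course.

    ``meta`` needs columns ``sample, genotype, timepoint_min, replicate`` and
    optionally a boolean ``rifampicin`` column (untreated samples, if present,
    are excluded from the fit).  By default all replicate points enter one
    joint fit per gene; ``per_replicate=True`` instead fits each replicate
    separately and averages the fitted parameters of converged fits.
    """
    sel = meta[meta["genotype"] == genotype]
    if "rifampicin" in sel.columns:
        sel = sel[sel["rifampicin"].astype(bool)]
    if sel.empty:
        raise ValueError(f"no rifampicin samples for genotype {genotype!r}")
    samples = sel["sample"].tolist()
    missing = [s for s in samples if s not in normalized.columns]
    if missing:
        raise ValueError(f"samples absent from abundance table: {missing}")
    t_by_sample = sel.set_index("sample")["timepoint_min"].astype(float)

    rows = []
    for gene, row in normalized[samples].iterrows():
        if per_replicate:
            fits = []
            for _, rep in sel.groupby("replicate"):
                rs = rep["sample"].tolist()
                if len(rs) >= 3:
                    fits.append(
                        fit_exponential_decay(
                            t_by_sample[rs].to_numpy(), row[rs].to_numpy(), gene
                        )
                    )
            good = [f for f in fits if f.converged]
            if good:
                a = float(np.mean([f.a for f in good]))
                b = float(np.mean([f.b for f in good]))
                fit = DecayFit(
                    gene, a, b, float(np.sum([f.residual for f in good])),
                    converged=True,
                    measurable=MEASURABLE_MIN <= b <= MEASURABLE_MAX,
                )
            else:
                fit = DecayFit(gene, np.nan, np.nan, np.nan, False, False)
        else:
            fit = fit_exponential_decay(
                t_by_sample[samples].to_numpy(), row.to_numpy(), gene
            )
        rows.append((gene, fit.a, fit.b, fit.residual, fit.converged, fit.measurable))
    return pd.DataFrame(
        rows, columns=["gene", "a", "b", "residual", "converged", "measurable"]
    ).set_index("gene")


@dataclass
class StabilityCall:
    """Between-genotype stability category for one gene."""

    gene: object
    tau_WT: float
    tau_ppk: float
    category: str  # stable_WT_unstable_ppk | stable_ppk_unstable_WT |
    #              # WT_gt_ppk | ppk_gt_WT | no_call
    reason: str = ""


def classify_stability_pair(fit_WT: DecayFit, fit_ppk: DecayFit) -> StabilityCall:
    """Assign a gene to a stability-contrast category from its two decay fits.

    ``stable_X_unstable_Y``: tau above 65 min in genotype X and below 55 min
    in Y.  ``X_gt_Y``: both taus below 65 min but X's exceeds Y's by at least
    10 min.  Anything else (including the 55-65 min deadband) is ``no_call``.
    """
    if not (fit_WT.converged and fit_ppk.converged):
        return StabilityCall(
            fit_WT.gene, np.nan, np.nan, "no_call", reason="unconverged fit"
        )
    tw, tp = fit_WT.b, fit_ppk.b
    if tw > _STABLE_TAU and tp < _UNSTABLE_TAU:
        cat = "stable_WT_unstable_ppk"
    elif tp > _STABLE_TAU and tw < _UNSTABLE_TAU:
        cat = "stable_ppk_unstable_WT"
    elif tw < _STABLE_TAU and tp < _STABLE_TAU and tw >= tp + _SHIFT_TAU:
        cat = "WT_gt_ppk"
    elif tw < _STABLE_TAU and tp < _STABLE_TAU and tp >= tw + _SHIFT_TAU:
        cat = "ppk_gt_WT"
    else:
        cat = "no_call"
    return StabilityCall(fit_WT.gene, tw, tp, cat)


def gene_set_halflife_shift(
    tau_WT: pd.Series, tau_ppk: pd.Series, gene_set: set
) -> tuple[float, float]:
    """Compare half-life changes of a gene set against all other genes.

    Computes per-gene ``delta = tau_WT - tau_ppk`` (the stabilization
    attributable to the WT genotype), then returns
    ``(median delta in-set / median delta out-of-set - 1) * 100`` and the
    two-sided rank-sum p-value (normal approximation with tie correction)
    comparing the two delta samples.
    """
    common = tau_WT.index.intersection(tau_ppk.index)
    delta = (tau_WT[common] - tau_ppk[common]).dropna()
    in_set = delta.index.isin(gene_set)
    d_in, d_out = delta[in_set], delta[~in_set]
    if d_in.empty:
        raise ValueError("gene set has no fitted genes")
    if d_out.empty:
        raise ValueError("gene set covers all fitted genes: empty complement")
    shift_pct = (d_in.median() / d_out.median() - 1.0) * 100.0
    _, p = stats.mannwhitneyu(
        d_in.to_numpy(), d_out.to_numpy(), alternative="two-sided",
        method="asymptotic",
    )
    return float(shift_pct), float(p)
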