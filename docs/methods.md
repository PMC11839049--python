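# Methods

## Diffusion-state mixture model

Tracked molecules are assumed to occupy one of two or three diffusive states
for the lifetime of a trajectory; the mixture is across the population, not
within tracks. For a state with diffusion coefficient D (µm²/s) imaged at
frame interval τ (s) with exposure equal to τ, the observed per-step squared
displacement is exponentially distributed with mean (8/3)·D·τ: exposure
averaging ("motion blur") reduces the blur-free per-step MSD 4Dτ by a factor
2/3 per axis, giving 8/3 in two dimensions. The population CDF is the
weighted sum of these exponential CDFs. The `physical_blur` simulator mode
demonstrates this: it integrates Brownian substeps, averages positions over
the exposure, and its per-step r² converges to the same law the fitter
assumes (sample mean within 5 % at a few thousand steps).

Fitting minimizes the sum of squared deviations between the empirical CDF,
evaluated at the sorted unique r² values (thinned to at most 50 000 quantile
points for speed), and the model CDF. The objective is not convex in the
state parameters, so the fit runs ≥5 deterministic starts spanning two
decades around the data's characteristic D = mean(r²)/((8/3)τ) and keeps the
best solution; weights are bounded to [0,1] with a soft penalty on their sum
exceeding one, label switching is resolved by sorting D ascending afterwards.
Pools that are empty or have no spread cannot constrain the model and raise.

Partition fractions follow the formulas in the README. N_total counts the
pooled consecutive-frame steps from all classes (trajectories ≥4 frames);
the free-state identification is sanity-checked (D₃ > 1 µm²/s) and warned
about, not enforced, since it is an assumption about the data rather than a
constraint of the model. A negative nucleoid fraction (possible when the two
fits disagree strongly) is flagged, never clamped silently.

### Foci and classification

The composite image is min-max normalized to [0,1] before blob detection so
the LoG threshold of 0.1 is scale-free. A detected blob of scale σ becomes a
focus of radius √2·σ (the standard LoG blob-radius convention) with a disk
mask; trajectory-focus overlap is evaluated per localization against the
pixel mask. `In` requires literally complete overlap: fractions in (0.99, 1)
are still `InOut`. Displacements across missing frames are excluded —
"consecutive localizations" is read as consecutive frames. Trajectory files
carry coordinates in µm; pixel↔µm conversion is explicit via the required
`pixel_size` parameter.

### FRAP

One-phase association fitted by least squares; the half-time confidence
interval comes from 200 residual-bootstrap refits (percentile 2.5/97.5).
Traces with no net recovery (plateau ≤ baseline, or k at its floor) are
flagged unconverged rather than reported.

## Spike-in normalization and decay

Normalization is two exact divisions (sample total, then the median relative
abundance of ERCC features above 5·10⁻⁴ in that sample), which makes it
exactly invariant — bit-identical — under uniform rescaling of any single
sample's counts. A caveat the implementation surfaces rather than hides: the
set of spike-ins passing the relative-abundance filter must be stable across
the chase. If spike-in abundances straddle the threshold, the passing set
grows as genomic reads decay and the passing-set median drifts, biasing
every fitted decay constant upward. The simulator therefore defaults to one
decade of spike-in abundances comfortably above threshold at all timepoints,
which is also what the filter is for in practice: scaling should only ever
use robustly detected spike-ins.

Per-gene decay is fitted jointly across replicates (all (t, y) pairs in one
objective; a per-replicate mode that averages converged fits is available).
The fit keeps the conventional initialization (a=0.001, b=20, dogbox, both
parameters bounded below by zero) but adds a second, data-scaled start
(a₀ = max(y)): from the tiny-baseline start alone, fast-decaying genes at
realistic abundance scales can fall into a degenerate boundary minimum at
b→0 that matches only the t=0 points. The lower-SSE solution wins. Decay
constants in [5, 65] min are flagged measurable — faster decays are mostly
over before the first chase timepoint, slower ones are indistinguishable
from stability over a 60-minute course; values above 65 are reported as-is
with the flag false (clamping is a plotting concern). The stability
categories use τ > 65 vs τ < 55 for stable/unstable contrasts and a ≥10 min
shift for directional calls, leaving deliberate deadbands in which no call
is made. The gene-set comparison reports the percent difference of median
half-life changes and a two-sided rank-sum p-value (normal approximation
with tie correction).

## Poly(A) tail model

Tail calling defaults to the maximal terminal run of T at the 5′ end of the
read as sequenced: the untemplated tail cannot align and is soft-clipped
under local alignment, so the run length is the tail length. A `total-t`
mode (count every T) exists for sensitivity analysis only. The orientation
convention defaults to antisense — the adapter chemistry that produces
leading T's implies the read aligns opposite the gene — and is configurable.
The tail-anchoring coordinate is the aligned end nearest the terminal-T run
(leftmost base for plus-strand alignments, rightmost for minus-strand); all
intervals are 0-based half-open. Reads whose anchor falls in several genes'
3′ windows are assigned to every matching gene: operon neighbours genuinely
share a poly(A) state, and discarding such reads would bias against operons.

The per-gene ZINB has exactly four mean degrees of freedom (one log-link
coefficient per genotype × condition cell, one-hot, no intercept) and a
single zero-inflation rate and overdispersion; zero inflation applies at
k = 0 only. Fitting uses the standard maximum-likelihood count-model
machinery with moment-based starts (log cell means, half the observed zero
fraction through a logit, dispersion 0.5) and a 500-iteration cap. L-BFGS is
tried first — plain BFGS can diverge from these starts on heavily
zero-inflated data — with BFGS and Nelder–Mead as fallbacks; the first
converged result is kept. All-zero genes are flagged degenerate (π→1) and
genes observed in fewer than two cells unfit; neither enters downstream
summaries. The estimated mean tail in a cell is (1−π)·µ_cell; genotype
shifts per condition are Wald tests on the coefficient contrast,
Benjamini–Hochberg adjusted across genes within each condition (the
significance procedure is this package's choice of a standard default).

## GO overlap permutation test

Term sets are flat unions of member annotations — no ontology-graph
propagation. The null redraws the condensate protein set uniformly without
replacement from the declared universe; unannotated universe proteins stay
drawable with empty term sets. All three statistics (overlap with P-body
terms, with stress-granule terms, and with their union) are recomputed from
the same permutation stream. P-values use the add-one estimator
(1 + #{null ≥ observed})/(n_perm + 1), one-sided for enrichment, so they are
never zero and are bounded below by 1/(n_perm+1).

## What the generators emulate — and what they do not

* **Tracking** (`sim.spt`): one latent state per trajectory (matching the
  fitted model; switching would bias recovery tests), geometric trajectory
  lengths (mean 10 frames), uniform photoactivation over the movie, the
  slowest state confined to a circular condensate by resampling the step
  *direction* — never the drawn step length, so the per-step r² law remains
  exactly the model's law in `model_exact` mode. Defaults: 1500
  trajectories, τ = 20 ms, 0.1 µm pixels, D = (0.05, 0.3, 2.0) µm²/s,
  weights (0.45, 0.30, 0.25), condensate radius 0.4 µm in a 6.4 × 3.2 µm
  field. Rendered movies stamp unit Gaussian PSFs (σ = 1 px); there is no
  camera noise, drift, localization error in `model_exact` mode,
  state switching, or out-of-focus loss, so passing recovery tests shows the
  estimator chain is correct under its own model, not that real movies meet
  the model.
* **Decay** (`sim.decay`): expected genomic counts a·e^(−t/b) with Poisson
  sampling, constant spike-ins, a global depth scale exported in the ground
  truth. No library-composition bias, no overdispersion beyond Poisson, no
  rRNA contamination.
* **Poly(A)** (`sim.polya`): ZINB tail lengths per cell, 4 replicates per
  genotype × condition, tails written as literal leading T's with a non-T
  first template base so the terminal run equals the drawn length; anchors
  uniform in the 3′ window, antisense alignment. No sequencing errors, no
  adapter read-through, no isoform structure.
* **GO** (`sim.go`): a term vocabulary split into reference pools, a
  condensate-private pool and background; the condensate term set realizes
  the planted overlap exactly (round(p·m)/m) and background proteins leak
  only ~5 % of their terms into the reference pools, so a planted overlap
  above background is a genuine, detectable enrichment.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` use: 10⁵ displacements for
closed-form CDF checks (empirical CDF within ±0.01), 1500 trajectories for
full-pipeline fraction recovery (±0.05), 500 genes at depth 10⁶ for decay
recovery (≤15 % relative error; noise-free fits exact to 0.1 min), 2000
reads per design cell for ZINB recovery (π within ±0.05, cell means within
10 %; likelihood equal to a direct log-pmf summation to better than 10⁻⁸
relative), and a 6-protein universe for exhaustive enumeration of the
permutation null (agreement within 3 binomial standard errors at 1000
permutations). Sub-seeds for each stage derive from one user seed.

## Known limitations

Mixture-CDF fits are ill-conditioned when diffusion coefficients are closer
than ~3-fold; weights trade off against neighbouring states and recovered
αᵢ can drift several percent at 10⁴–10⁵ steps. The condensate estimator
counts slow-state weight among In/InOut trajectories, so nucleoid-bound
molecules that wander through a focus inflate F_condensate slightly. ZINB
zero inflation and NB dispersion are weakly identified when µ is small
(most NB mass already at zero). The GO test treats annotations as flat sets;
ontology-aware propagation would change both observed and null overlaps.
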