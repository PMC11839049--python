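"""Single-molecule condensate-partition analysis.

Workflow: sum a single-molecule movie into a composite image, detect
condensate foci with a Laplacian-of-Gaussian blob detector, filter foci by
trajectory content, classify trajectories by focus overlap, pool per-step
squared displacements, fit multi-state squared-displacement CDF models, and
combine the pieces into condensate / nucleoid / free partition fractions.
A one-phase-association FRAP fitter lives here too.

The diffusion model: for a molecule diffusing with coefficient ``D`` imaged
at frame interval ``tau`` with full-frame exposure, the per-step squared
displacement r^2 is exponentially distributed with mean ``(8/3) * D * tau``
(the 8/3 replaces the blur-free 4 because positions are exposure-averaged).
A population mixing ``m`` diffusive states therefore has

    P(r^2 <= x) = 1 - sum_i alpha_i * exp(-x / ((8/3) * D_i * tau))

with weights ``alpha_i`` summing to one.  Fits are nonlinear least squares
on the empirical CDF with deterministic multistart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from skimage.feature import blob_log

__all__ = [
    "CompositeImage",
    "Trajectory",
    "FocusRegion",
    "TrajectoryClass",
    "DisplacementPool",
    "DiffusionFit",
    "PartitionFractions",
    "FrapFit",
    "trajectories_from_table",
    "sum_frames",
    "detect_foci",
    "filter_foci",
    "classify_trajectories",
    "pool_squared_displacements",
    "displacement_cdf",
    "fit_displacement_cdf",
    "compute_partition_fractions",
    "class_step_counts",
    "partition_pipeline",
    "fit_frap_recovery",
]

#: exposure-averaged ("motion blurred") per-step MSD scale: <r^2> = (8/3) D tau
BLUR_MSD_FACTOR = 8.0 / 3.0


@dataclass(frozen=True)
class Trajectory:
    """One single-molecule track: frame indices and positions in micrometres."""

    trajectory_id: object
    frames: np.ndarray  # (n,) int, strictly increasing
    xy: np.ndarray      # (n, 2) float, micrometres

    def __post_init__(self):
        frames = np.asarray(self.frames)
        xy = np.asarray(self.xy, dtype=float)
        if frames.ndim != 1 or xy.shape != (frames.size, 2):
            raise ValueError("frames must be (n,) and xy (n, 2)")
        if frames.size == 0:
            raise ValueError("empty trajectory")
        if frames.size > 1 and not np.all(np.diff(frames) > 0):
            raise ValueError(
                f"frames not strictly increasing in trajectory {self.trajectory_id!r}"
            )
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "xy", xy)

    def __len__(self) -> int:
        return int(self.frames.size)


def trajectories_from_table(table: pd.DataFrame) -> list[Trajectory]:
    """Build :class:`Trajectory` objects from a long-format localization table.

    Expects columns ``trajectory_id, frame, x_um, y_um`` (the on-disk CSV
    layout).  Rows are sorted by frame within each trajectory.
    """
    required = {"trajectory_id", "frame", "x_um", "y_um"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"localization table missing columns: {sorted(missing)}")
    out = []
    for tid, grp in table.groupby("trajectory_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                trajectory_id=tid,
                frames=grp["frame"].to_numpy(dtype=int),
                xy=grp[["x_um", "y_um"]].to_numpy(dtype=float),
            )
        )
    return out


@dataclass(frozen=True)
class CompositeImage:
    """Pixelwise sum of all movie frames, with the pixel size in micrometres."""

    data: np.ndarray     # (H, W) non-negative
    pixel_size: float    # micrometres per pixel

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("composite image must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "data", data)


def sum_frames(movie: np.ndarray, pixel_size: float) -> CompositeImage:
    """Sum a (n_frames, H, W) stack pixelwise into a composite image."""
    movie = np.asarray(movie)
    if movie.ndim != 3 or movie.shape[0] == 0:
        raise ValueError("movie must be a non-empty (n_frames, H, W) stack")
    return CompositeImage(data=movie.sum(axis=0, dtype=float), pixel_size=pixel_size)


@dataclass
class FocusRegion:
    """A detected condensate focus: centroid/radius in micrometres plus pixel mask."""

    id: int
    centroid_um: tuple[float, float]  # (x, y)
    radius_um: float
    mask: np.ndarray                  # (H, W) bool
    pixel_size: float

    def contains(self, xy_um: np.ndarray) -> np.ndarray:
        """Boolean membership of (n, 2) micrometre points in the pixel mask."""
        xy_um = np.atleast_2d(np.asarray(xy_um, dtype=float))
        col = np.floor(xy_um[:, 0] / self.pixel_size).astype(int)
        row = np.floor(xy_um[:, 1] / self.pixel_size).astype(int)
        h, w = self.mask.shape
        ok = (row >= 0) & (row < h) & (col >= 0) & (col < w)
        out = np.zeros(len(xy_um), dtype=bool)
        out[ok] = self.mask[row[ok], col[ok]]
        return out


def detect_foci(
    image: CompositeImage,
    min_sigma: float = 3.0,
    max_sigma: float = 5.0,
    threshold: float = 0.1,
) -> list[FocusRegion]:
    """Detect candidate condensate foci in a composite image.

    The image is min-max normalized to [0, 1] so the LoG threshold is
    scale-free, then multiscale Laplacian-of-Gaussian blobs are found.  Each
    blob becomes a :class:`FocusRegion` whose radius is ``sqrt(2) * sigma``
    (the standard LoG blob-radius convention) and whose mask is the disk of
    that radius around the blob centre.
    """
    data = image.data
    lo, hi = float(data.min()), float(data.max())
    if hi > lo:
        norm = (data - lo) / (hi - lo)
    else:
        return []  # flat image: nothing to detect
    blobs = blob_log(norm, min_sigma=min_sigma, max_sigma=max_sigma, threshold=threshold)
    h, w = data.shape
    rows, cols = np.mgrid[0:h, 0:w]
    foci = []
    for i, (r, c, sigma) in enumerate(blobs):
        radius_px = np.sqrt(2.0) * sigma
        mask = (rows - r) ** 2 + (cols - c) ** 2 <= radius_px**2
        if not mask.any():
            continue
        foci.append(
            FocusRegion(
                id=i,
                centroid_um=((c + 0.5) * image.pixel_size, (r + 0.5) * image.pixel_size),
                radius_um=radius_px * image.pixel_size,
                mask=mask,
                pixel_size=image.pixel_size,
            )
        )
    return foci


def _focus_overlap_fraction(traj: Trajectory, foci: list[FocusRegion]) -> float:
    """Fraction of a trajectory's localizations inside any focus mask."""
    if not foci:
        return 0.0
    inside = np.zeros(len(traj), dtype=bool)
    for focus in foci:
        inside |= focus.contains(traj.xy)
    return float(inside.mean())


def filter_foci(
    foci: list[FocusRegion],
    trajectories: list[Trajectory],
    min_trajs: int = 10,
    min_len: int = 10,
    min_overlap: float = 0.7,
) -> list[FocusRegion]:
    """Keep foci supported by enough long, strongly overlapping trajectories.

    A focus is kept when at least ``min_trajs`` trajectories of at least
    ``min_len`` frames have at least ``min_overlap`` of their localizations
    inside the focus mask (all thresholds boundary-inclusive).
    """
    long_trajs = [t for t in trajectories if len(t) >= min_len]
    kept = []
    for focus in foci:
        n_support = 0
        for traj in long_trajs:
            frac = float(focus.contains(traj.xy).mean())
            if frac >= min_overlap:
                n_support += 1
                if n_support >= min_trajs:
                    break
        if n_support >= min_trajs:
            kept.append(focus)
    return kept


@dataclass(frozen=True)
class TrajectoryClass:
    trajectory_id: object
    overlap_fraction: float
    label: str  # "In" | "InOut" | "Out"


def classify_trajectories(
    trajectories: list[Trajectory], foci: list[FocusRegion]
) -> list[TrajectoryClass]:
    """Classify each trajectory by its overlap with the (filtered) foci.

    ``In``: every localization inside a focus; ``InOut``: overlap fraction in
    [0.25, 1); ``Out``: overlap fraction below 0.25.  Fractions above 0.99 but
    below 1 are still ``InOut`` — ``In`` demands complete overlap.
    """
    out = []
    for traj in trajectories:
        frac = _focus_overlap_fraction(traj, foci)
        if frac >= 1.0:
            label = "In"
        elif frac >= 0.25:
            label = "InOut"
        else:
            label = "Out"
        out.append(TrajectoryClass(traj.trajectory_id, frac, label))
    return out


@dataclass(frozen=True)
class DisplacementPool:
    """Pooled per-step squared displacements (micrometres squared) at lag tau."""

    r2_values: np.ndarray
    tau: float

    def __post_init__(self):
        r2 = np.asarray(self.r2_values, dtype=float)
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if np.any(r2 < 0):
            raise ValueError("squared displacements must be non-negative")
        object.__setattr__(self, "r2_values", r2)

    def __len__(self) -> int:
        return int(self.r2_values.size)


def pool_squared_displacements(
    trajectories: list[Trajectory], frame_interval: float, min_len: int = 4
) -> DisplacementPool:
    """Pool consecutive-frame squared displacements from long-enough tracks.

    Only trajectories of at least ``min_len`` frames contribute, and only
    pairs of localizations in consecutive frames; pairs that span a missing
    frame are excluded.
    """
    chunks = []
    for traj in trajectories:
        if len(traj) < min_len:
            continue
        consecutive = np.diff(traj.frames) == 1
        d = np.diff(traj.xy, axis=0)
        r2 = (d**2).sum(axis=1)[consecutive]
        if r2.size:
            chunks.append(r2)
    r2_all = np.concatenate(chunks) if chunks else np.empty(0)
    return DisplacementPool(r2_values=r2_all, tau=frame_interval)


def displacement_cdf(
    r2: np.ndarray, D: np.ndarray, weights: np.ndarray, tau: float
) -> np.ndarray:
    """Model CDF: ``1 - sum_i w_i exp(-r2 / ((8/3) D_i tau))``."""
    r2 = np.asarray(r2, dtype=float)[..., None]
    D = np.asarray(D, dtype=float)
    weights = np.asarray(weights, dtype=float)
    terms = weights * np.exp(-r2 / (BLUR_MSD_FACTOR * D * tau))
    return 1.0 - terms.sum(axis=-1)


@dataclass
class DiffusionFit:
    """Fitted multi-state squared-displacement CDF parameters.

    ``D`` is sorted ascending; ``alpha`` holds the weights of all but the
    fastest state (the last weight is one minus their sum).
    """

    n_states: int
    D: np.ndarray
    alpha: np.ndarray
    objective: float
    converged: bool
    tau: float
    n_points: int

    @property
    def weights(self) -> np.ndarray:
        """Full weight vector (sums to 1)."""
        return np.append(self.alpha, 1.0 - self.alpha.sum())

    def cdf(self, r2: np.ndarray) -> np.ndarray:
        return displacement_cdf(r2, self.D, self.weights, self.tau)


def _cdf_fit_starts(scale_D: float, n_states: int, n_starts: int) -> list[np.ndarray]:
    """Deterministic multistart parameter grid spanning the data's D scale."""
    starts = []
    ratios = [
        (0.05, 1.0, 10.0),
        (0.1, 0.5, 2.0),
        (0.02, 0.3, 5.0),
        (0.5, 1.0, 2.0),
        (0.01, 1.0, 100.0),
        (0.2, 2.0, 20.0),
    ][:n_starts]
    for ratio in ratios:
        D0 = scale_D * np.asarray(ratio[:n_states])
        w0 = np.full(n_states - 1, 1.0 / n_states)
        starts.append(np.concatenate([w0, D0]))
    return starts


def fit_displacement_cdf(
    pool: DisplacementPool,
    n_states: int,
    n_starts: int = 6,
    max_cdf_points: int = 50_000,
) -> DiffusionFit:
    """Fit the m-state mixture CDF to the empirical squared-displacement CDF.

    Objective: sum of squared deviations between the empirical CDF evaluated
    at the sorted unique r^2 values and the model CDF.  Deterministic
    multistart least squares; D relabelled ascending afterwards.  Pools with
    no displacement spread cannot constrain the model and raise.
    """
    if n_states not in (2, 3):
        raise ValueError("n_states must be 2 or 3")
    r2 = pool.r2_values
    if r2.size == 0:
        raise ValueError("empty displacement pool")
    x, counts = np.unique(r2, return_counts=True)
    if x.size < 2 or x.max() <= 0:
        raise ValueError("no displacement signal: pool has no spread")
    ecdf = np.cumsum(counts) / r2.size
    if x.size > max_cdf_points:  # thin on an even quantile grid for speed
        idx = np.linspace(0, x.size - 1, max_cdf_points).astype(int)
        x, ecdf = x[idx], ecdf[idx]

    tau = pool.tau
    scale_D = float(r2.mean()) / (BLUR_MSD_FACTOR * tau)

    def residuals(params):
        w = params[: n_states - 1]
        D = params[n_states - 1 :]
        wsum = w.sum()
        weights = np.append(w, max(1.0 - wsum, 0.0))
        res = displacement_cdf(x, D, weights, tau) - ecdf
        # soft feasibility penalty: weights of the named states cannot exceed 1
        return np.append(res, 10.0 * max(wsum - 1.0, 0.0) * np.sqrt(x.size))

    lower = np.concatenate([np.zeros(n_states - 1), np.full(n_states, 1e-8)])
    upper = np.concatenate([np.ones(n_states - 1), np.full(n_states, 1e4)])

    best = None
    for p0 in _cdf_fit_starts(scale_D, n_states, n_starts):
        p0 = np.clip(p0, lower + 1e-9, upper - 1e-9)
        try:
            sol = optimize.least_squares(
                residuals, p0, bounds=(lower, upper), method="trf", xtol=1e-12
            )
        except Exception:  # a diverging start is not fatal
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all CDF fit starts failed")

    w = best.x[: n_states - 1]
    D = best.x[n_states - 1 :]
    weights = np.append(w, max(1.0 - w.sum(), 0.0))
    weights = weights / weights.sum()
    order = np.argsort(D)
    D, weights = D[order], weights[order]
    objective = float(
        ((displacement_cdf(x, D, weights, tau) - ecdf) ** 2).sum()
    )
    return DiffusionFit(
        n_states=n_states,
        D=D,
        alpha=weights[:-1],
        objective=objective,
        converged=bool(best.success),
        tau=tau,
        n_points=int(r2.size),
    )


@dataclass
class PartitionFractions:
    """Condensate / nucleoid / free split of the tracked molecule population."""

    F_condensate: float
    F_nucleoid: float
    F_free: float
    N_in: int
    N_inout: int
    N_total_steps: int
    flags: list[str] = field(default_factory=list)


def class_step_counts(
    trajectories: list[Trajectory],
    classes: list[TrajectoryClass],
    min_len: int = 4,
) -> dict[str, int]:
    """Consecutive-frame step counts per class, from trajectories >= min_len frames."""
    by_id = {c.trajectory_id: c.label for c in classes}
    counts = {"In": 0, "InOut": 0, "Out": 0}
    for traj in trajectories:
        if len(traj) < min_len or traj.trajectory_id not in by_id:
            continue
        n_steps = int((np.diff(traj.frames) == 1).sum())
        counts[by_id[traj.trajectory_id]] += n_steps
    return counts


def compute_partition_fractions(
    full_fit: DiffusionFit,
    in_plus_inout_fit: DiffusionFit | None,
    n_in_steps: int,
    n_inout_steps: int,
    n_total_steps: int,
    free_D_floor: float = 1.0,
) -> PartitionFractions:
    """Combine the two CDF fits and class step counts into partition fractions.

    ``F_free`` is the fastest-state weight of the full-data fit (sanity check:
    its D should exceed ``free_D_floor`` um^2/s if that state is truly free
    diffusion).  ``F_condensate`` scales the slow-state weight of the
    In+InOut-subset fit by that subset's share of pooled steps.  ``F_nucleoid``
    is defined by subtraction; a negative value is flagged, never clamped
    silently.
    """
    if n_total_steps <= 0:
        raise ValueError("n_total_steps must be positive")
    flags: list[str] = []
    f_free = float(full_fit.weights[-1])
    if full_fit.D[-1] <= free_D_floor:
        flags.append(
            f"fastest state D={full_fit.D[-1]:.3g} um^2/s <= {free_D_floor}: "
            "'free' interpretation questionable"
        )
        warnings.warn(flags[-1], stacklevel=2)
    if in_plus_inout_fit is None or (n_in_steps + n_inout_steps) == 0:
        f_cond = 0.0
    else:
        slow_weight = float(in_plus_inout_fit.weights[:-1].sum())
        f_cond = (n_in_steps + n_inout_steps) / n_total_steps * slow_weight
    f_nuc = 1.0 - f_free - f_cond
    if f_nuc < 0:
        flags.append(f"F_nucleoid negative ({f_nuc:.4f})")
    return PartitionFractions(
        F_condensate=f_cond,
        F_nucleoid=f_nuc,
        F_free=f_free,
        N_in=int(n_in_steps),
        N_inout=int(n_inout_steps),
        N_total_steps=int(n_total_steps),
        flags=flags,
    )


def partition_pipeline(
    movie: np.ndarray,
    localization_table: pd.DataFrame,
    pixel_size: float,
    frame_interval: float,
    min_sigma: float = 3.0,
    max_sigma: float = 5.0,
    log_threshold: float = 0.1,
    min_trajs: int = 10,
    min_len_filter: int = 10,
    min_overlap: float = 0.7,
    min_len_pool: int = 4,
) -> dict:
    """Run the full condensate-partition analysis on one movie.

    detect foci -> filter by trajectory content -> classify trajectories ->
    pool squared displacements (all tracks, and the In+InOut subset) -> fit
    the three-state CDF models -> partition fractions.  Returns a dict with
    the composite image, foci, classes, fits and fractions.
    """
    trajectories = trajectories_from_table(localization_table)
    composite = sum_frames(movie, pixel_size)
    foci = detect_foci(composite, min_sigma, max_sigma, log_threshold)
    foci = filter_foci(foci, trajectories, min_trajs, min_len_filter, min_overlap)
    classes = classify_trajectories(trajectories, foci)

    pool_all = pool_squared_displacements(trajectories, frame_interval, min_len_pool)
    full_fit = fit_displacement_cdf(pool_all, n_states=3)

    labels = {c.trajectory_id: c.label for c in classes}
    subset = [
        t for t in trajectories if labels.get(t.trajectory_id) in ("In", "InOut")
    ]
    subset_fit = None
    pool_subset = pool_squared_displacements(subset, frame_interval, min_len_pool)
    if len(pool_subset) >= 100:
        subset_fit = fit_displacement_cdf(pool_subset, n_states=3)

    steps = class_step_counts(trajectories, classes, min_len_pool)
    fractions = compute_partition_fractions(
        full_fit, subset_fit, steps["In"], steps["InOut"], len(pool_all)
    )
    return {
        "composite": composite,
        "foci": foci,
        "classes": classes,
        "full_fit": full_fit,
        "subset_fit": subset_fit,
        "step_counts": steps,
        "fractions": fractions,
    }


@dataclass
class FrapFit:
    """One-phase association fit of a FRAP recovery trace."""

    y0: float
    plateau: float
    k: float            # 1/s
    t_half: float       # s
    t_half_ci: tuple[float, float] | None
    converged: bool


def _one_phase(t, y0, plateau, k):
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * t))


def fit_frap_recovery(
    timepoints: np.ndarray,
    intensities: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
) -> FrapFit:
    """Fit ``y(t) = y0 + (plateau - y0)(1 - exp(-k t))`` to a recovery trace.

    ``t_half = ln 2 / k``; its confidence interval comes from residual
    bootstrap refits.  Traces with no net recovery are flagged unconverged.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 4 or t.size != y.size:
        raise ValueError("need >= 4 matched (t, y) points")

    p0 = (float(y[0]), float(y[-1]), np.log(2) / max(t[-1] / 4.0, 1e-6))
    try:
        popt, _ = optimize.curve_fit(
            _one_phase, t, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except Exception:
        return FrapFit(np.nan, np.nan, np.nan, np.nan, None, converged=False)
    y0, plateau, k = (float(v) for v in popt)
    if plateau <= y0 or k <= 1e-8:
        return FrapFit(y0, plateau, k, np.nan, None, converged=False)
    t_half = float(np.log(2) / k)

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        resid = y - _one_phase(t, *popt)
        boot = []
        for _ in range(n_boot):
            yb = _one_phase(t, *popt) + rng.choice(resid, size=resid.size, replace=True)
            try:
                pb, _ = optimize.curve_fit(
                    _one_phase, t, yb, p0=popt,
                    bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                    maxfev=5_000,
                )
            except Exception:
                continue
            if pb[2] > 1e-8:
                boot.append(np.log(2) / pb[2])
        if len(boot) >= max(20, n_boot // 4):
            ci = tuple(float(v) for v in np.percentile(boot, [2.5, 97.5]))
    return FrapFit(y0, plateau, k, t_half, ci, converged=True)
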