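"""Mixture-of-diffusive-states single-particle-tracking simulator.

Emulates photoactivated single-molecule tracking of a condensate-forming
protein in a rod-shaped bacterium: each trajectory carries one latent
diffusive state for its whole life (the population-mixture model fitted
downstream assumes no within-track switching), the slowest state is confined
to a circular condensate, and per-step displacements follow the
motion-blurred law whose squared length is exponential with mean
``(8/3) * D * tau``.

Two displacement modes:

``model_exact``
    draws each step's squared displacement directly from the exponential law
    ``P(r^2 <= x) = 1 - exp(-x / ((8/3) D tau))`` with a uniform direction.
    This is the fitted model's own law, so recovery tests have a clean
    oracle.  Confinement and field containment resample the step direction
    (never the length), keeping the r^2 law exact.

``physical_blur``
    integrates fine-grained Brownian substeps and reports exposure-averaged
    positions (exposure = frame interval) plus localization noise,
    demonstrating where the 8/3 blur factor comes from; the per-step r^2 law
    converges to the same exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SptSimConfig", "SptGroundTruth", "simulate_spt", "render_spt_movie"]

_BLUR = 8.0 / 3.0


@dataclass
class SptSimConfig:
    """Study conditions for the tracking simulator.

    Defaults mirror the imaging setup the analyses assume: 20 ms frames at
    50 Hz, ~0.1 um pixels, about 1500 trajectories per replicate with a
    median length around ten frames, and three diffusive states (condensate,
    nucleoid-bound, free) with well separated diffusion coefficients.
    """

    seed: int
    n_trajectories: int = 1500
    frame_interval: float = 0.02          # s (50 Hz)
    pixel_size: float = 0.1               # um / pixel
    field: tuple[float, float] = (6.4, 3.2)          # um (width, height)
    condensate_center: tuple[float, float] = (1.6, 1.6)  # um
    condensate_radius: float = 0.4        # um
    diffusion_coefficients: tuple[float, float, float] = (0.05, 0.3, 2.0)  # um^2/s
    state_weights: tuple[float, float, float] = (0.45, 0.30, 0.25)
    traj_length_mean: float = 10.0        # frames, geometric law
    localization_noise: float = 0.02      # um std (physical_blur mode only)
    displacement_mode: str = "model_exact"
    n_movie_frames: int = 2000
    psf_sigma_px: float = 1.0
    n_blur_substeps: int = 20

    def __post_init__(self):
        w = np.asarray(self.state_weights, dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("state_weights must be non-negative and sum to 1")
        D = np.asarray(self.diffusion_coefficients, dtype=float)
        if (D < 0).any() or not np.all(np.diff(D) >= 0):
            raise ValueError("diffusion coefficients must be non-negative, non-decreasing")
        if self.condensate_radius >= min(self.field) / 2:
            raise ValueError("condensate radius must fit inside the field")
        if self.condensate_radius <= self.localization_noise:
            raise ValueError(
                "condensate radius <= localization noise: geometry unresolvable"
            )
        if self.displacement_mode not in ("model_exact", "physical_blur"):
            raise ValueError(f"unknown displacement_mode {self.displacement_mode!r}")
        if self.traj_length_mean < 1:
            raise ValueError("traj_length_mean must be >= 1")


@dataclass
class SptGroundTruth:
    """What the simulator actually did, for recovery tests."""

    states: np.ndarray            # (n_traj,) latent state per trajectory
    lengths: np.ndarray           # (n_traj,) frames
    in_condensate: np.ndarray     # (n_traj,) bool: confined to the condensate
    step_counts_by_state: np.ndarray   # (3,) consecutive-step counts, all tracks
    pooled_step_counts_by_state: np.ndarray  # (3,) only tracks >= 4 frames
    config: SptSimConfig = field(repr=False, default=None)

    @property
    def state_step_fractions(self) -> np.ndarray:
        """Step-weighted fractions of the three states among pooled steps."""
        total = self.pooled_step_counts_by_state.sum()
        return self.pooled_step_counts_by_state / total

    @property
    def fractions(self) -> dict:
        """Ground-truth condensate / nucleoid / free step fractions."""
        f = self.state_step_fractions
        return {"condensate": float(f[0]), "nucleoid": float(f[1]),
                "free": float(f[2])}


def _inside_field(pos: np.ndarray, field: tuple[float, float]) -> bool:
    return 0.0 <= pos[0] <= field[0] and 0.0 <= pos[1] <= field[1]


def _inside_disk(pos, center, radius) -> bool:
    return (pos[0] - center[0]) ** 2 + (pos[1] - center[1]) ** 2 <= radius**2


def _step_exact(rng, pos, step_len, accept, max_tries=200):
    """Advance by a fixed-length step in a uniform direction satisfying `accept`.

    Resampling the direction (never the length) preserves the per-step r^2
    law exactly under confinement.  If no admissible direction is found the
    particle stays put (vanishingly rare for step << geometry).
    """
    for _ in range(max_tries):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        new = pos + step_len * np.array([np.cos(theta), np.sin(theta)])
        if accept(new):
            return new
    return pos


def simulate_spt(config: SptSimConfig) -> tuple[pd.DataFrame, SptGroundTruth]:
    """Simulate trajectories; returns a localization table and the ground truth.

    The table has columns ``trajectory_id, frame, x_um, y_um`` (micrometres).
    State 0 (slowest) trajectories start uniformly inside the condensate and
    stay confined to it; states 1 and 2 start uniformly in the field and stay
    inside it.  Trajectory lengths are geometric with the configured mean;
    start frames are uniform over the movie so the rendered movie looks like
    a sparse photoactivation experiment.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trajectories
    D = np.asarray(config.diffusion_coefficients, dtype=float)
    tau = config.frame_interval
    center = np.asarray(config.condensate_center, dtype=float)
    radius = config.condensate_radius
    field_wh = config.field

    states = rng.choice(3, size=n, p=np.asarray(config.state_weights, dtype=float))
    lengths = rng.geometric(1.0 / config.traj_length_mean, size=n)

    rows_id, rows_frame, rows_x, rows_y = [], [], [], []
    step_counts = np.zeros(3, dtype=int)
    pooled_counts = np.zeros(3, dtype=int)
    in_condensate = states == 0

    for i in range(n):
        state = states[i]
        length = int(lengths[i])
        start_frame = int(rng.integers(0, max(config.n_movie_frames - length, 1)))
        if state == 0:
            # uniform in the condensate disk
            r = radius * np.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * np.pi)
            pos = center + r * np.array([np.cos(phi), np.sin(phi)])
            accept = lambda p: _inside_disk(p, center, radius)
        else:
            pos = np.array([rng.uniform(0.0, field_wh[0]),
                            rng.uniform(0.0, field_wh[1])])
            accept = lambda p: _inside_field(p, field_wh)

        if config.displacement_mode == "model_exact":
            traj = np.empty((length, 2))
            traj[0] = pos
            if length > 1:
                r2 = rng.exponential(scale=_BLUR * D[state] * tau, size=length - 1)
                for j, step_len in enumerate(np.sqrt(r2)):
                    pos = _step_exact(rng, pos, step_len, accept)
                    traj[j + 1] = pos
        else:
            traj = _blur_trajectory(
                rng, pos, length, D[state], tau, config.n_blur_substeps,
                accept, config.localization_noise,
            )

        rows_id.append(np.full(length, i))
        rows_frame.append(np.arange(start_frame, start_frame + length))
        rows_x.append(traj[:, 0])
        rows_y.append(traj[:, 1])
        step_counts[state] += length - 1
        if length >= 4:
            pooled_counts[state] += length - 1

    table = pd.DataFrame(
        {
            "trajectory_id": np.concatenate(rows_id),
            "frame": np.concatenate(rows_frame),
            "x_um": np.concatenate(rows_x),
            "y_um": np.concatenate(rows_y),
        }
    )
    truth = SptGroundTruth(
        states=states,
        lengths=lengths,
        in_condensate=in_condensate,
        step_counts_by_state=step_counts,
        pooled_step_counts_by_state=pooled_counts,
        config=config,
    )
    return table, truth


def _blur_trajectory(rng, pos, length, D, tau, n_sub, accept, loc_noise):
    """Exposure-averaged Brownian trajectory (physical_blur mode).

    Brownian substeps are integrated at ``tau / n_sub`` resolution; the
    reported position per frame is the mean of the substep positions during
    that frame's exposure, plus isotropic localization noise.  Containment is
    by rejection of the substep direction.
    """
    sub_sigma = np.sqrt(2.0 * D * tau / n_sub)  # per-axis substep std
    observed = np.empty((length, 2))
    current = np.asarray(pos, dtype=float)
    for f in range(length):
        positions = np.empty((n_sub, 2))
        for s in range(n_sub):
            step = rng.normal(0.0, sub_sigma, size=2)
            new = current + step
            tries = 0
            while not accept(new) and tries < 100:
                step_len = np.linalg.norm(step)
                theta = rng.uniform(0.0, 2.0 * np.pi)
                new = current + step_len * np.array([np.cos(theta), np.sin(theta)])
                tries += 1
            if accept(new):
                current = new
            positions[s] = current
        observed[f] = positions.mean(axis=0)
        if loc_noise > 0:
            observed[f] += rng.normal(0.0, loc_noise, size=2)
    return observed


def render_spt_movie(
    table: pd.DataFrame, config: SptSimConfig
) -> np.ndarray:
    """Render localizations into a (n_frames, H, W) movie of Gaussian spots.

    Each localization stamps a unit-amplitude Gaussian point-spread function
    of width ``psf_sigma_px`` at its position; summing the stack therefore
    produces a composite image whose condensate stands out as a bright blob.
    """
    px = config.pixel_size
    w_px = int(np.ceil(config.field[0] / px))
    h_px = int(np.ceil(config.field[1] / px))
    n_frames = int(table["frame"].max()) + 1
    movie = np.zeros((n_frames, h_px, w_px), dtype=np.float32)

    sigma = config.psf_sigma_px
    half = max(int(np.ceil(3 * sigma)), 1)
    offsets = np.arange(-half, half + 1)
    oy, ox = np.meshgrid(offsets, offsets, indexing="ij")

    frames = table["frame"].to_numpy(dtype=int)
    cx = table["x_um"].to_numpy() / px
    cy = table["y_um"].to_numpy() / px
    for f, x, y in zip(frames, cx, cy):
        col0, row0 = int(np.round(x)), int(np.round(y))
        kernel = np.exp(
            -(((row0 + oy) - y) ** 2 + ((col0 + ox) - x) ** 2) / (2.0 * sigma**2)
        )
        rows = row0 + offsets
        cols = col0 + offsets
        rsel = (rows >= 0) & (rows < h_px)
        csel = (cols >= 0) & (cols < w_px)
        movie[f][np.ix_(rows[rsel], cols[csel])] += kernel[np.ix_(rsel, csel)]
    return movie
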