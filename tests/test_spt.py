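"""Condensate-partition analysis: foci, classification, CDF fits, fractions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpbody.spt import (
    CompositeImage,
    DiffusionFit,
    DisplacementPool,
    FocusRegion,
    Trajectory,
    classify_trajectories,
    compute_partition_fractions,
    detect_foci,
    displacement_cdf,
    filter_foci,
    fit_displacement_cdf,
    fit_frap_recovery,
    pool_squared_displacements,
    sum_frames,
    trajectories_from_table,
)

PX = 0.1  # um per pixel used throughout these tests


def disk_focus(cx_px, cy_px, r_px, shape=(64, 64)):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = (rows - cy_px) ** 2 + (cols - cx_px) ** 2 <= r_px**2
    return FocusRegion(0, ((cx_px + 0.5) * PX, (cy_px + 0.5) * PX), r_px * PX, mask, PX)


def traj_at(points_um, tid=0, frames=None):
    points = np.asarray(points_um, dtype=float)
    if frames is None:
        frames = np.arange(len(points))
    return Trajectory(tid, np.asarray(frames), points)


# ---------------------------------------------------------------- sum_frames


class TestSumFrames:
    def test_constant_frames_sum_linearly(self):
        movie = np.full((3, 8, 8), 2.0)
        assert np.array_equal(sum_frames(movie, PX).data, np.full((8, 8), 6.0))

    def test_single_frame_is_identity(self, rng):
        frame = rng.uniform(size=(1, 5, 7))
        assert np.array_equal(sum_frames(frame, PX).data, frame[0])

    def test_matches_elementwise_sum_oracle(self, rng):
        movie = rng.uniform(size=(10, 6, 6))
        expected = np.zeros((6, 6))
        for f in movie:  # brute-force accumulation
            expected += f
        np.testing.assert_allclose(sum_frames(movie, PX).data, expected)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            sum_frames(np.empty((0, 4, 4)), PX)


# ---------------------------------------------------------------- detect_foci


class TestDetectFoci:
    @staticmethod
    def blob(cx, cy, sigma=4.0, shape=(64, 64)):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))

    def test_blank_image_yields_nothing(self):
        assert detect_foci(CompositeImage(np.zeros((32, 32)), PX)) == []

    def test_single_gaussian_blob_located(self):
        foci = detect_foci(CompositeImage(self.blob(20, 20), PX))
        assert len(foci) == 1
        cx, cy = foci[0].centroid_um
        assert abs(cx - 20 * PX) <= PX and abs(cy - 20 * PX) <= PX
        assert foci[0].mask.any()

    def test_two_blobs_found_separately(self):
        img = self.blob(20, 20) + self.blob(50, 20)
        assert len(detect_foci(CompositeImage(img, PX))) == 2

    def test_translation_equivariance(self):
        base = detect_foci(CompositeImage(self.blob(20, 20), PX))[0]
        shifted = detect_foci(CompositeImage(self.blob(27, 25), PX))[0]
        dx = shifted.centroid_um[0] - base.centroid_um[0]
        dy = shifted.centroid_um[1] - base.centroid_um[1]
        assert abs(dx - 7 * PX) <= PX and abs(dy - 5 * PX) <= PX


# ------------------------------------------------- filter_foci / classify


class TestFocusFiltering:
    def make_trajs(self, n, n_frames, inside_frac, focus_cx=2.0, focus_cy=2.0):
        """n trajectories of n_frames with the given fraction of points at the
        focus centre and the rest far away."""
        trajs = []
        n_in = int(round(inside_frac * n_frames))
        for i in range(n):
            pts = [(focus_cx, focus_cy)] * n_in + [(5.5, 5.5)] * (n_frames - n_in)
            trajs.append(traj_at(pts, tid=i))
        return trajs

    def test_focus_with_ten_fully_inside_trajectories_is_kept(self):
        focus = disk_focus(20, 20, 5)
        trajs = self.make_trajs(10, 10, 1.0)
        assert filter_foci([focus], trajs) == [focus]

    def test_nine_qualifying_trajectories_drop_the_focus(self):
        focus = disk_focus(20, 20, 5)
        trajs = self.make_trajs(9, 10, 1.0)
        assert filter_foci([focus], trajs) == []

    def test_seventy_percent_overlap_counts_at_threshold(self):
        focus = disk_focus(20, 20, 5)
        trajs = self.make_trajs(10, 10, 0.7)
        assert filter_foci([focus], trajs) == [focus]
        short = self.make_trajs(10, 10, 0.6)
        assert filter_foci([focus], short) == []

    def test_short_trajectories_do_not_count(self):
        focus = disk_focus(20, 20, 5)
        trajs = self.make_trajs(10, 9, 1.0)  # long enough overlap, too few frames
        assert filter_foci([focus], trajs) == []


class TestClassifyTrajectories:
    def classify_one(self, inside_frac, n_frames=20):
        focus = disk_focus(20, 20, 5)
        n_in = int(round(inside_frac * n_frames))
        pts = [(2.0, 2.0)] * n_in + [(5.5, 5.5)] * (n_frames - n_in)
        return classify_trajectories([traj_at(pts)], [focus])[0]

    @pytest.mark.parametrize(
        "frac,label",
        [(1.0, "In"), (0.5, "InOut"), (0.10, "Out"), (0.25, "InOut"), (0.95, "InOut")],
    )
    def test_label_thresholds(self, frac, label):
        assert self.classify_one(frac).label == label

    def test_agrees_with_brute_force_membership_count(self, rng):
        focus = disk_focus(20, 20, 8)
        trajs = [
            traj_at(rng.uniform(0.5, 5.5, size=(rng.integers(2, 15), 2)), tid=i)
            for i in range(50)
        ]
        classes = classify_trajectories(trajs, [focus])
        for traj, cls in zip(trajs, classes):
            inside = 0
            for x, y in traj.xy:  # brute force per-localization membership
                col, row = int(x / PX), int(y / PX)
                if focus.mask[row, col]:
                    inside += 1
            frac = inside / len(traj)
            assert cls.overlap_fraction == pytest.approx(frac)
            expected = "In" if frac == 1 else ("InOut" if frac >= 0.25 else "Out")
            assert cls.label == expected


# ------------------------------------------------------------- displacements


class TestPoolSquaredDisplacements:
    def test_three_frame_trajectory_contributes_nothing(self):
        t = traj_at([(0, 0), (0.1, 0), (0.2, 0)])
        assert len(pool_squared_displacements([t], 0.02)) == 0

    def test_four_frame_example_arithmetic(self):
        t = traj_at([(0, 0), (0.1, 0), (0.1, 0.1), (0.2, 0.1)])
        pool = pool_squared_displacements([t], 0.02)
        np.testing.assert_allclose(pool.r2_values, [0.01, 0.01, 0.01])

    def test_frame_gaps_are_excluded(self):
        t = traj_at([(0, 0), (0.1, 0), (0.3, 0), (0.4, 0)], frames=[0, 1, 3, 4])
        pool = pool_squared_displacements([t], 0.02)
        np.testing.assert_allclose(np.sort(pool.r2_values), [0.01, 0.01])

    def test_matches_brute_force_enumeration(self, rng):
        trajs = []
        for i in range(100):
            n = int(rng.integers(1, 12))
            trajs.append(traj_at(rng.normal(size=(n, 2)), tid=i))
        pool = pool_squared_displacements(trajs, 0.02)
        expected = []
        for t in trajs:
            if len(t) < 4:
                continue
            for j in range(len(t) - 1):
                d = t.xy[j + 1] - t.xy[j]
                expected.append(d @ d)
        np.testing.assert_allclose(np.sort(pool.r2_values), np.sort(expected))


class TestFitDisplacementCdf:
    TAU = 0.02

    def test_single_state_recovery(self, rng):
        r2 = rng.exponential(scale=(8 / 3) * 1.0 * self.TAU, size=30_000)
        fit = fit_displacement_cdf(DisplacementPool(r2, self.TAU), n_states=3)
        near = np.abs(fit.D - 1.0) <= 0.1
        assert fit.weights[near].sum() >= 0.95

    def test_three_state_recovery(self, rng):
        weights = np.array([0.3, 0.3, 0.4])
        D = np.array([0.05, 0.3, 2.0])
        states = rng.choice(3, size=60_000, p=weights)
        r2 = rng.exponential(scale=(8 / 3) * D[states] * self.TAU)
        fit = fit_displacement_cdf(DisplacementPool(r2, self.TAU), n_states=3)
        np.testing.assert_allclose(fit.weights, weights, atol=0.05)
        np.testing.assert_allclose(fit.D, D, rtol=0.15)

    def test_two_state_fit_on_two_state_data(self, rng):
        weights = np.array([0.4, 0.6])
        D = np.array([0.1, 2.0])
        states = rng.choice(2, size=40_000, p=weights)
        r2 = rng.exponential(scale=(8 / 3) * D[states] * self.TAU)
        fit = fit_displacement_cdf(DisplacementPool(r2, self.TAU), n_states=2)
        np.testing.assert_allclose(fit.weights, weights, atol=0.05)
        np.testing.assert_allclose(fit.D, D, rtol=0.15)

    def test_spurious_third_state_gets_negligible_weight(self, rng):
        # data truly from two states: the 3-state fit should not invent mass
        weights = np.array([0.4, 0.6])
        D = np.array([0.1, 2.0])
        states = rng.choice(2, size=100_000, p=weights)
        r2 = rng.exponential(scale=(8 / 3) * D[states] * self.TAU)
        fit = fit_displacement_cdf(DisplacementPool(r2, self.TAU), n_states=3)
        assert fit.weights.min() < 0.05

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            fit_displacement_cdf(DisplacementPool(np.empty(0), self.TAU), 3)

    def test_degenerate_pool_errors(self):
        with pytest.raises(ValueError, match="no displacement signal"):
            fit_displacement_cdf(DisplacementPool(np.full(500, 0.01), self.TAU), 3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        d_log=st.lists(st.floats(-3, 2), min_size=3, max_size=3),
        w_raw=st.lists(st.floats(0.01, 1), min_size=3, max_size=3),
    )
    def test_model_cdf_monotone_between_zero_and_one(self, d_log, w_raw):
        D = np.sort(10.0 ** np.asarray(d_log))
        w = np.asarray(w_raw) / np.sum(w_raw)
        x = np.linspace(0, 10, 500)
        cdf = displacement_cdf(x, D, w, self.TAU)
        assert cdf[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(cdf) >= -1e-12)
        assert np.all((cdf >= -1e-12) & (cdf <= 1.0 + 1e-12))
        big = displacement_cdf(np.array([1e9]), D, w, self.TAU)
        assert big[0] == pytest.approx(1.0)


# --------------------------------------------------------- partition fractions


def make_fit(D, weights, tau=0.02):
    D = np.asarray(D, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return DiffusionFit(
        n_states=len(D), D=D, alpha=weights[:-1], objective=0.0,
        converged=True, tau=tau, n_points=1000,
    )


class TestPartitionFractions:
    def test_stated_formula_arithmetic(self):
        full = make_fit([0.05, 0.3, 2.0], [0.35, 0.25, 0.40])
        subset = make_fit([0.05, 0.3, 2.0], [0.5, 0.3, 0.2])
        fr = compute_partition_fractions(full, subset, 300, 100, 1000)
        assert fr.F_condensate == pytest.approx(0.32)
        assert fr.F_free == pytest.approx(0.40)
        assert fr.F_nucleoid == pytest.approx(0.28)

    def test_empty_subset_gives_zero_condensate(self):
        full = make_fit([0.05, 0.3, 2.0], [0.35, 0.25, 0.40])
        fr = compute_partition_fractions(full, None, 0, 0, 1000)
        assert fr.F_condensate == 0.0
        assert fr.F_nucleoid == pytest.approx(1 - fr.F_free)

    def test_fractions_always_sum_to_one(self, rng):
        for _ in range(20):
            w_full = rng.dirichlet([1, 1, 1])
            w_sub = rng.dirichlet([1, 1, 1])
            n_in, n_inout = rng.integers(0, 500, size=2)
            full = make_fit([0.05, 0.3, 2.0], w_full)
            subset = make_fit([0.05, 0.3, 2.0], w_sub)
            fr = compute_partition_fractions(full, subset, n_in, n_inout, 1000)
            assert fr.F_condensate + fr.F_nucleoid + fr.F_free == pytest.approx(1.0)

    def test_slow_fast_state_warned(self):
        full = make_fit([0.05, 0.3, 0.8], [0.35, 0.25, 0.40])
        with pytest.warns(UserWarning, match="free"):
            fr = compute_partition_fractions(full, None, 0, 0, 100)
        assert fr.flags

    def test_zero_steps_error(self):
        full = make_fit([0.05, 0.3, 2.0], [0.3, 0.3, 0.4])
        with pytest.raises(ValueError):
            compute_partition_fractions(full, None, 0, 0, 0)


# ---------------------------------------------------------------------- FRAP


class TestFrapRecovery:
    def test_noise_free_closed_form(self):
        t = np.arange(0, 120, 5.0)
        y = 0.2 + 0.6 * (1 - np.exp(-0.1 * t))
        fit = fit_frap_recovery(t, y, n_boot=0)
        assert fit.converged
        assert fit.k == pytest.approx(0.1, rel=1e-6)
        assert fit.t_half == pytest.approx(np.log(2) / 0.1, rel=1e-6)

    def test_constant_signal_flagged(self):
        t = np.arange(0, 60, 5.0)
        fit = fit_frap_recovery(t, np.full_like(t, 0.5), n_boot=0)
        assert not fit.converged

    def test_noisy_recovery_within_fifteen_percent(self, rng):
        t = np.arange(0, 120, 5.0)  # imaging every 5 s over ~2 min
        y = 0.2 + 0.6 * (1 - np.exp(-0.1 * t)) + rng.normal(0, 0.02, size=t.size)
        fit = fit_frap_recovery(t, y, n_boot=100, seed=0)
        assert fit.converged
        assert fit.t_half == pytest.approx(np.log(2) / 0.1, rel=0.15)
        assert fit.t_half_ci is not None
        lo, hi = fit.t_half_ci
        assert lo <= fit.t_half <= hi


# ----------------------------------------------------------- table handling


class TestTrajectoryTable:
    def test_round_trip_grouping(self, rng):
        table = pd.DataFrame(
            {
                "trajectory_id": [0, 0, 1, 1, 1],
                "frame": [0, 1, 5, 6, 7],
                "x_um": rng.uniform(size=5),
                "y_um": rng.uniform(size=5),
            }
        )
        trajs = trajectories_from_table(table)
        assert [len(t) for t in trajs] == [2, 3]

    def test_non_monotone_frames_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(0, np.array([0, 0]), np.zeros((2, 2)))
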