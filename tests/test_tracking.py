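"""Linking, trajectory building, MSD and comigration."""

import numpy as np
import pytest

from conftest import brute_force_linking, linking_cost
from endoquant import synthgen
from endoquant.containers import Spot, Trajectory
from endoquant.tracking import (
    build_trajectories,
    estimate_diffusion,
    find_comigration,
    link_frames,
    mean_squared_displacement,
)


def _spots(points, channel="green", frame=None):
    return [Spot(x_um=x, y_um=y, photons=2000, channel=channel, frame=frame)
            for x, y in points]


class TestLinkFrames:
    def test_displacement_beyond_radius_never_links(self):
        a = _spots([(0.0, 0.0)])
        b = _spots([(3.0, 0.0)])
        assert link_frames(a, b, max_disp_um=2.5) == []

    def test_single_admissible_pair_links(self):
        a = _spots([(0.0, 0.0)])
        b = _spots([(1.0, 0.0)])
        assert link_frames(a, b, max_disp_um=2.5) == [(0, 0)]

    def test_empty_frames(self):
        assert link_frames([], _spots([(1, 1)])) == []
        assert link_frames(_spots([(1, 1)]), []) == []

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n, m = rng.integers(1, 6, 2)
            pa = rng.uniform(0, 6, (n, 2))
            pb = rng.uniform(0, 6, (m, 2))
            links = link_frames(_spots(pa), _spots(pb), 2.5)
            cost = linking_cost(pa, pb, links, 2.5)
            best_cost, best_links = brute_force_linking(pa, pb, 2.5)
            assert cost == pytest.approx(best_cost, abs=1e-9)
            assert sorted(links) == best_links

    def test_swapping_particles_keep_identity(self):
        # two distant particles exchange neighbourhoods between frames:
        # minimum total squared displacement keeps each with its own
        a = _spots([(0.0, 0.0), (10.0, 0.0)])
        b = _spots([(0.4, 0.0), (10.4, 0.0)])
        assert link_frames(a, b, 2.5) == [(0, 0), (1, 1)]

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        pa = rng.uniform(0, 8, (5, 2))
        pb = rng.uniform(0, 8, (5, 2))
        fwd = set(link_frames(_spots(pa), _spots(pb), 2.5))
        bwd = {(i, j) for j, i in link_frames(_spots(pb), _spots(pa), 2.5)}
        assert fwd == bwd


class TestBuildTrajectories:
    def test_static_particle_single_full_trajectory(self):
        frames = [_spots([(5.0, 5.0)], frame=t) for t in range(40)]
        trajs = build_trajectories(frames)
        assert len(trajs) == 1 and len(trajs[0]) == 40

    def test_no_step_exceeds_radius(self):
        rng = np.random.default_rng(2)
        frames = [_spots(rng.uniform(0, 10, (6, 2)), frame=t) for t in range(30)]
        for traj in build_trajectories(frames, 2.5, min_length=2):
            assert np.all(traj.step_lengths() < 2.5)

    def test_spot_conservation(self):
        rng = np.random.default_rng(3)
        frames = [_spots(rng.uniform(0, 6, (rng.integers(1, 5), 2)), frame=t)
                  for t in range(15)]
        trajs = build_trajectories(frames, 2.5, min_length=1)
        assert sum(len(t) for t in trajs) == sum(len(f) for f in frames)

    def test_ground_truth_links_recovered(self):
        # D small enough that P(step >= 2.5 um) is negligible and particles
        # stay well separated: nearly all truth links must be recovered
        truth = synthgen.simulate_brownian_paths(
            16, 150, 0.02, localization_sigma_um=0.0, fov_um=60.0, seed=4,
        )
        frames = []
        for t in range(150):
            pts = [(tr.x_um[t], tr.y_um[t]) for tr in truth.trajectories["green"]]
            frames.append(_spots(pts, frame=t))
        trajs = build_trajectories(frames, 2.5)
        # a perfect result is 16 trajectories spanning all 150 frames
        recovered_links = sum(len(t) - 1 for t in trajs)
        assert recovered_links >= 0.99 * 16 * 149
        assert len(trajs) <= 17


class TestMSD:
    def test_static_trajectory_noise_floor(self):
        rng = np.random.default_rng(5)
        jitter = rng.normal(0, 0.02, (200, 2))
        traj = Trajectory(0, "g", np.arange(200), 5 + jitter[:, 0],
                          5 + jitter[:, 1])
        msd = mean_squared_displacement(traj, 5)
        assert np.all(msd < 10 * 4 * 0.02**2)

    def test_lag_one_equals_mean_squared_step(self):
        rng = np.random.default_rng(6)
        xy = np.cumsum(rng.normal(0, 0.1, (50, 2)), axis=0)
        traj = Trajectory(0, "g", np.arange(50), xy[:, 0], xy[:, 1])
        msd = mean_squared_displacement(traj, 3)
        steps = np.diff(xy, axis=0)
        assert msd[0] == pytest.approx((steps**2).sum(axis=1).mean())

    def test_too_short_trajectory(self):
        traj = Trajectory(0, "g", [0], [1.0], [1.0])
        with pytest.raises(ValueError):
            mean_squared_displacement(traj, 1)

    def test_diffusion_recovery_from_ensemble(self):
        D, dt = 0.05, 0.05
        truth = synthgen.simulate_brownian_paths(60, 400, D, dt, fov_um=100.0,
                                                 seed=7)
        est = estimate_diffusion(truth.trajectories["green"], dt)
        assert est == pytest.approx(D, rel=0.10)


class TestComigration:
    def test_identical_paths_comigrate(self):
        frames = np.arange(50)
        xy = np.cumsum(np.random.default_rng(8).normal(0, 0.05, (50, 2)), axis=0)
        a = Trajectory(0, "green", frames, xy[:, 0], xy[:, 1])
        b = Trajectory(0, "red", frames, xy[:, 0], xy[:, 1])
        pairs = find_comigration([a], [b])
        assert len(pairs) == 1
        assert pairs[0].comigrating and pairs[0].mean_separation_um == 0.0

    def test_same_channel_rejected(self):
        t = Trajectory(0, "green", np.arange(30), np.zeros(30), np.zeros(30))
        with pytest.raises(ValueError):
            find_comigration([t], [t])

    def test_distant_independent_particles_do_not_comigrate(self):
        truth = synthgen.simulate_brownian_paths(10, 100, 0.05, fov_um=100.0,
                                                 seed=9)
        pairs = find_comigration(truth.trajectories["green"],
                                 truth.trajectories["red"])
        assert not any(p.comigrating for p in pairs)

    def test_designated_pairs_recovered_exactly(self):
        truth = synthgen.simulate_brownian_paths(
            20, 200, 0.05, n_comigrating_pairs=3,
            localization_sigma_um=0.02, fov_um=20.0, seed=10,
        )
        pairs = find_comigration(truth.trajectories["green"],
                                 truth.trajectories["red"],
                                 sep_threshold_um=0.3, min_overlap_frames=20)
        found = {(p.id_a, p.id_b) for p in pairs if p.comigrating}
        assert found == set(truth.comigrating_pairs)

    def test_short_overlap_excluded(self):
        a = Trajectory(0, "green", np.arange(10), np.zeros(10), np.zeros(10))
        b = Trajectory(0, "red", np.arange(10), np.zeros(10), np.zeros(10))
        assert find_comigration([a], [b], min_overlap_frames=20) == []
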