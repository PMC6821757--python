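"""Generator contracts: recorded truth, determinism, photon statistics."""

import numpy as np
import pytest

from endoquant import synthgen
from endoquant.synthgen import (
    make_brownian_movie,
    make_cell_image,
    make_expression_table,
    make_line_profile,
    make_phenotype_counts,
    make_zstack,
    simulate_brownian_paths,
)


class TestCellImage:
    def test_no_clusters_gives_pure_background(self):
        image, truth = make_cell_image(n_clusters=0, poisson_noise=False, seed=0)
        assert truth.cluster_positions == []
        np.testing.assert_allclose(image["clusters"], truth.background_level)

    def test_all_membrane_clusters_lie_on_mask(self):
        image, truth = make_cell_image(n_clusters=20, membrane_fraction=1.0, seed=1)
        px = image.pixel_size_um
        assert len(truth.cluster_positions) == 20
        for x, y in truth.cluster_positions:
            assert truth.membrane_mask[int(y / px), int(x / px)]

    def test_membrane_fraction_exact_by_construction(self):
        _, truth = make_cell_image(n_clusters=37, membrane_fraction=0.6, seed=2)
        n_mem = sum(truth.cluster_on_membrane)
        assert n_mem == round(37 * 0.6)
        assert truth.membrane_fraction == n_mem / 37

    def test_determinism(self):
        a, _ = make_cell_image(seed=42)
        b, _ = make_cell_image(seed=42)
        for ch in a.channel_names:
            np.testing.assert_array_equal(a[ch], b[ch])

    @pytest.mark.parametrize("kwargs", [
        {"width_px": 0}, {"membrane_fraction": 1.2},
        {"membrane_fraction": -0.1}, {"psf_sigma_um": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_cell_image(**kwargs)

    def test_positions_inside_bounds(self):
        image, truth = make_cell_image(n_clusters=60, membrane_fraction=0.5, seed=3)
        w, h = image.plane("clusters").extent_um
        for x, y in truth.cluster_positions:
            assert 0 <= x <= w and 0 <= y <= h

    def test_background_poisson_statistics(self):
        # variance/mean of a pure-background region ~ 1 (Poisson), >=1e4 px
        image, _ = make_cell_image(n_clusters=0, background=50.0, seed=4)
        corner = image["clusters"][:128, :128]
        assert corner.size >= 10_000
        assert corner.var() / corner.mean() == pytest.approx(1.0, rel=0.1)


class TestZStack:
    def test_degenerate_weights_put_every_spot_basal(self):
        w = [1.0] + [0.0] * 9
        _, truth = make_zstack(50, w, seed=0)
        assert all(rec[2] == 0 for rec in truth.spot_records)

    def test_uniform_weights_binomial_bound(self):
        w = [0.1] * 10
        _, truth = make_zstack(1000, w, width_px=700, height_px=700,
                               poisson_noise=False, seed=1)
        counts = np.bincount([r[2] for r in truth.spot_records], minlength=10)
        bound = 5 * np.sqrt(1000 * 0.1 * 0.9)
        assert np.all(np.abs(counts - 100) < bound)

    def test_empty_stack_is_background(self):
        stack, truth = make_zstack(0, [0.1] * 10, poisson_noise=False, seed=2)
        np.testing.assert_allclose(stack["spots"], 10.0)
        assert truth.spot_records == []

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            make_zstack(10, [0.5, 0.6])
        with pytest.raises(ValueError):
            make_zstack(10, [-0.1, 1.1])

    def test_determinism(self):
        a, _ = make_zstack(30, [0.1] * 10, seed=9)
        b, _ = make_zstack(30, [0.1] * 10, seed=9)
        np.testing.assert_array_equal(a["spots"], b["spots"])


class TestBrownian:
    def test_zero_diffusion_is_static_plus_jitter(self):
        truth = simulate_brownian_paths(5, 100, 0.0, localization_sigma_um=0.02,
                                        seed=0)
        for traj in truth.trajectories["green"]:
            assert traj.x_um.std() < 0.05
            assert traj.y_um.std() < 0.05
        for path in truth.paths["green"]:
            assert np.ptp(path, axis=0).max() == 0.0

    def test_trajectory_length_matches_acquisition_regime(self):
        truth = simulate_brownian_paths(3, 1500, 0.05, seed=1)
        for traj in truth.trajectories["green"]:
            assert 1000 <= len(traj) <= 2000

    def test_mean_squared_step_matches_diffusion_law(self):
        # law of large numbers on the generator's own steps: 4*D*dt
        D, dt = 0.05, 0.05
        truth = simulate_brownian_paths(100, 1001, D, dt, fov_um=200.0, seed=2)
        steps = np.diff(np.stack(truth.paths["green"]), axis=1)
        assert steps.shape[0] * steps.shape[1] >= 1e5
        msq = (steps**2).sum(axis=2).mean()
        assert msq == pytest.approx(4 * D * dt, rel=0.05)

    def test_comigrating_pairs_share_underlying_path(self):
        truth = simulate_brownian_paths(6, 50, 0.05, n_comigrating_pairs=2, seed=3)
        for i, j in truth.comigrating_pairs:
            np.testing.assert_array_equal(truth.paths["green"][i],
                                          truth.paths["red"][j])
        # observed positions differ by independent jitter only
        a = truth.trajectories["green"][0]
        b = truth.trajectories["red"][0]
        sep = np.hypot(a.x_um - b.x_um, a.y_um - b.y_um)
        assert 0 < sep.mean() < 5 * truth.localization_sigma_um

    def test_movie_determinism_and_shape(self):
        m1, _ = make_brownian_movie(3, 10, 0.05, fov_um=8.0, seed=4)
        m2, _ = make_brownian_movie(3, 10, 0.05, fov_um=8.0, seed=4)
        assert m1.n_frames == 10
        np.testing.assert_array_equal(m1["green"], m2["green"])
        np.testing.assert_array_equal(m1["red"], m2["red"])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_brownian_paths(2, 10, -0.1)
        with pytest.raises(ValueError):
            simulate_brownian_paths(2, 10, 0.05, n_comigrating_pairs=3)


class TestLineProfileGenerator:
    @pytest.mark.parametrize("ratio", [1.0, 1.5, 3.0])
    def test_noise_free_profile_encodes_exact_ratio(self, ratio):
        from endoquant.profiles import membrane_cytoplasm_ratio

        profile, true_ratio = make_line_profile(ratio)
        result = membrane_cytoplasm_ratio(profile)
        assert result.ratio == pytest.approx(true_ratio, abs=1e-9)

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            make_line_profile(0.5)


class TestExpressionTable:
    def test_null_table_has_unit_fold_changes(self):
        table, truth = make_expression_table(50, 0, noise_sd=0.0, seed=0)
        ctrl = table[[c for c in table if c.startswith("control")]].mean(axis=1)
        morph = table[[c for c in table if c.startswith("morphant")]].mean(axis=1)
        np.testing.assert_allclose(morph / ctrl, 1.0)
        assert truth.regulated_flags.sum() == 0

    def test_regulated_count_exceeds_screen_threshold(self):
        _, truth = make_expression_table(200, 12, fold_change=4.0, seed=1)
        above = np.abs(np.log2(truth.true_fold_changes)) > np.log2(3.8)
        assert above.sum() == 12
        assert truth.regulated_flags.sum() == 12

    def test_determinism(self):
        t1, _ = make_expression_table(100, 5, seed=7)
        t2, _ = make_expression_table(100, 5, seed=7)
        assert t1.equals(t2)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            make_expression_table(10, 0, n_replicates=1)


class TestPhenotypeCounts:
    def test_degenerate_probs(self):
        t = make_phenotype_counts(25, [1, 0, 0], seed=0)
        assert t.iloc[0].tolist() == [25, 0, 0]

    def test_zero_embryos(self):
        t = make_phenotype_counts(0, [0.6, 0.3, 0.1], seed=0)
        assert t.to_numpy().sum() == 0

    def test_multinomial_sampling_bound(self):
        n, probs = 10_000, np.array([0.6, 0.3, 0.1])
        t = make_phenotype_counts(n, probs, seed=1)
        frac = t.to_numpy()[0] / n
        bound = 3 * np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(frac - probs) < bound)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            make_phenotype_counts(10, [0.5, 0.5, 0.5])
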