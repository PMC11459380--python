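import numpy as np
import pytest
from scipy import stats

from trajdir import (Path, SyntheticSpec, analyse_trajectory,
                     make_bifurcation, make_branching, make_null_ensemble,
                     make_straight_path, path_to_spherical_data, sample_path,
                     select_arm)


class TestMakeBranching:
    def test_deterministic(self):
        a = make_branching(SyntheticSpec(n_cells_per_arm=50, seed=3))
        b = make_branching(SyntheticSpec(n_cells_per_arm=50, seed=3))
        np.testing.assert_array_equal(a.ensemble.attributes,
                                      b.ensemble.attributes)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_labels_and_backbone_positions(self):
        lab = make_branching(SyntheticSpec(n_cells_per_arm=40, seed=1))
        assert set(lab.labels) == {"default", "branch"}
        assert lab.backbone_positions.min() >= 0
        assert lab.backbone_positions.max() <= 1

    def test_noiseless_default_arm_is_perfectly_straight(self):
        lab = make_branching(SyntheticSpec(n_cells_per_arm=200,
                                           noise_sd=0.0, seed=2))
        res = analyse_trajectory(select_arm(lab, "default"), n_samples=5,
                                 n_null=4, seed=0)
        assert np.all(res.sampled_radii <= 1e-8)

    def test_noiseless_branch_path_minimax_radius_bound(self, rng):
        # Single decision point, no noise, orthogonal arms: seen from the
        # path start, a full-span branch path spans directions from u out
        # to atan(post_leg / dp_leg) > 45 degrees, so the minimax radius
        # is at least angle/4 (verified against the grid-search oracle).
        spec = SyntheticSpec(n_cells_per_arm=400, noise_sd=0.0,
                             branch_region_width=0.0, seed=5)
        lab = make_branching(spec)
        ens = select_arm(lab, "branch")
        path = sample_path(ens, 20, np.random.default_rng(8))
        sd = path_to_spherical_data(path, statistic="max")
        assert sd.radius >= spec.angle_between_arms / 4 - 0.02
        # whereas a sub-path entirely after the departure is straight
        post = ens.restricted(0.5)
        res = analyse_trajectory(post, n_samples=3, n_null=2, seed=0)
        assert np.all(res.sampled_radii <= 1e-8)

    def test_branch_region_departures_span_region(self):
        spec = SyntheticSpec(n_cells_per_arm=500, noise_sd=0.0,
                             branch_region_width=0.6, seed=9)
        lab = make_branching(spec)
        # Departures are drawn from a region, so at mid pseudotime some
        # branch cells are still on-axis while others have already left.
        branch = lab.ensemble.attributes[lab.labels == "branch"]
        u = np.ones(3) / np.sqrt(3)
        perp = np.linalg.norm(branch - np.outer(branch @ u, u), axis=1)
        pt = lab.ensemble.pseudotime[lab.labels == "branch"]
        mid = (pt > 0.25) & (pt < 0.4)
        assert perp[mid].min() < 1e-9 and perp[mid].max() > 0.1


class TestMakeBifurcation:
    def test_symmetric_arms_same_radius_distribution(self):
        lab = make_bifurcation(SyntheticSpec(n_cells_per_arm=300, seed=7))
        radii = {}
        for arm in ("arm1", "arm2"):
            res = analyse_trajectory(select_arm(lab, arm), n_samples=40,
                                     n_null=9, method="bySteps", seed=1)
            radii[arm] = res.sampled_radii
        p = stats.mannwhitneyu(radii["arm1"], radii["arm2"],
                               alternative="two-sided").pvalue
        assert p > 0.05

    def test_noiseless_post_dp_segments_are_straight(self):
        lab = make_bifurcation(SyntheticSpec(n_cells_per_arm=200,
                                             noise_sd=0.0, seed=3))
        for arm in ("arm1", "arm2"):
            ens = select_arm(lab, arm).restricted(0.55)
            res = analyse_trajectory(ens, n_samples=5, n_null=4, seed=0)
            assert np.all(res.sampled_radii <= 1e-8)

    def test_zero_angle_degenerates_to_straight_line(self):
        lab = make_bifurcation(SyntheticSpec(
            n_cells_per_arm=150, noise_sd=0.0, angle_between_arms=0.0,
            seed=2))
        res = analyse_trajectory(select_arm(lab, "arm1"), n_samples=5,
                                 n_null=4, seed=0)
        assert np.all(res.sampled_radii <= 1e-8)

    def test_labels(self):
        lab = make_bifurcation(SyntheticSpec(n_cells_per_arm=10, seed=0))
        assert set(lab.labels) == {"progenitor", "arm1", "arm2"}


class TestMakeNullEnsemble:
    def test_column_means_vanish_at_large_n(self):
        lab = make_null_ensemble(10_000, 3, seed=1)
        x = lab.ensemble.attributes
        se = x.std(axis=0, ddof=1) / np.sqrt(x.shape[0])
        assert np.all(np.abs(x.mean(axis=0)) < 3 * se)

    def test_deterministic_and_minimum_size(self):
        a = make_null_ensemble(20, 4, seed=5)
        b = make_null_ensemble(20, 4, seed=5)
        np.testing.assert_array_equal(a.ensemble.attributes,
                                      b.ensemble.attributes)
        with pytest.raises(ValueError):
            make_null_ensemble(5, 3)


class TestMakeStraightPath:
    def test_noiseless_is_exactly_collinear(self):
        path = make_straight_path(12, 4, step=0.5)
        assert path_to_spherical_data(path).radius <= 1e-12

    def test_radius_grows_with_noise(self):
        means = []
        for noise in (0.01, 0.1, 0.5):
            radii = [path_to_spherical_data(
                make_straight_path(10, 3, noise_sd=noise, seed=s)).radius
                for s in range(20)]
            means.append(np.mean(radii))
        assert means[0] < means[1] < means[2]

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            make_straight_path(5, 3, direction=[0, 0, 0])

    def test_custom_direction_normalized(self):
        path = make_straight_path(3, 2, direction=[0, 5], step=2.0)
        np.testing.assert_allclose(path.points[-1], [0, 4.0], atol=1e-12)


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_dims": 1}, {"dp_fraction": 0.0}, {"dp_fraction": 1.0},
        {"branch_region_width": -0.1}, {"noise_sd": -1.0},
        {"n_cells_per_arm": 0}, {"arm_length": 0.0},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticSpec(**kwargs)

    def test_unknown_arm_rejected(self):
        lab = make_branching(SyntheticSpec(n_cells_per_arm=10, seed=0))
        with pytest.raises(ValueError):
            select_arm(lab, "arm1")
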