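"""Generator contracts: geometry validation, determinism, the defocus
law, and the fusion-dominance property of generated stacks."""

import numpy as np
import pytest

from focusfuse.metrics import rmse
from focusfuse.synthetic import (
    SceneSpec,
    make_dataset,
    make_scene,
    random_scene,
    render_stack,
)

from conftest import gradient_energy


def footprint_energy(img, spec, i, exclusive=False):
    """Gradient energy inside cell i's footprint; ``exclusive`` removes
    pixels reachable by any other cell (including its blur spread)."""
    (cx, cy), r = spec.centers[i], spec.radii[i]
    ys, xs = np.mgrid[0 : spec.size, 0 : spec.size]
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 < (0.9 * r) ** 2
    if exclusive:
        for j in range(spec.n_cells):
            if j == i:
                continue
            (ox, oy), orr = spec.centers[j], spec.radii[j]
            mask &= (xs - ox) ** 2 + (ys - oy) ** 2 > (orr + 4) ** 2
        if mask.sum() < 30:
            return None
    gy, gx = np.gradient(img)
    return float(np.sum((gx**2 + gy**2)[mask]))


class TestSceneSpec:
    def test_margin_violation_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            SceneSpec(size=64, n_cells=1, centers=[[2.0, 32.0]], radii=[10.0],
                      depths=[0.5])

    def test_equal_depths_rejected_for_multi_cell(self):
        with pytest.raises(ValueError, match="distinct"):
            SceneSpec(size=64, n_cells=2, centers=[[20, 20], [44, 44]],
                      radii=[8, 8], depths=[0.3, 0.3])

    def test_cell_count_restricted_to_stages(self):
        with pytest.raises(ValueError):
            SceneSpec(size=64, n_cells=3, centers=[[20, 20]] * 3,
                      radii=[8] * 3, depths=[0.1, 0.5, 0.9])

    @pytest.mark.parametrize("n_cells", [1, 2, 4, 8])
    def test_random_scene_always_valid(self, n_cells):
        for seed in range(5):
            spec = random_scene(n_cells, size=64, seed=seed)
            assert spec.n_cells == n_cells  # __post_init__ validated


class TestRendering:
    def test_single_cell_structure(self):
        spec = SceneSpec(size=64, n_cells=1, centers=[[32, 32]], radii=[14],
                         depths=[0.5], texture_seed=1)
        scene = make_scene(spec)
        ss = render_stack(scene)
        gt = ss.ground_truth
        ys, xs = np.mgrid[0:64, 0:64]
        inside = gt[(xs - 32) ** 2 + (ys - 32) ** 2 < 14**2]
        corner = gt[:8, :8]
        # membrane ring and texture: far more structure than background
        assert inside.std() > 5 * corner.std()
        assert inside.max() > corner.max() + 0.1

    def test_same_seed_identical_scene(self):
        spec = random_scene(4, size=64, seed=7)
        a = render_stack(make_scene(spec))
        b = render_stack(make_scene(spec))
        assert np.array_equal(a.stack.planes, b.stack.planes)
        assert np.array_equal(a.ground_truth, b.ground_truth)

    def test_depth_map_values(self):
        spec = SceneSpec(size=64, n_cells=4,
                         centers=[[16, 16], [48, 16], [16, 48], [48, 48]],
                         radii=[9, 9, 9, 9], depths=[0.2, 0.2, 0.8, 0.8],
                         texture_seed=3)
        ss = render_stack(make_scene(spec))
        vals = set(np.unique(ss.depth_map))
        assert vals == {0.2, 0.5, 0.8}  # two depth groups + background

    @pytest.mark.parametrize("depth,expected_plane", [(0.0, 0), (0.5, 3), (1.0, 6)])
    def test_cell_sharpest_in_nearest_plane(self, depth, expected_plane):
        spec = SceneSpec(size=64, n_cells=1, centers=[[32, 32]], radii=[14],
                         depths=[depth], texture_seed=5, noise_sigma=0.0)
        ss = render_stack(make_scene(spec))
        energies = [footprint_energy(p, spec, 0) for p in ss.stack.planes]
        assert int(np.argmax(energies)) == expected_plane

    def test_depth_sharpness_correspondence_ensemble(self):
        # over seeded scenes, each cell's exclusive footprint (pixels not
        # reachable by any overlapping neighbor) is sharpest in the plane
        # nearest its depth
        focus = np.linspace(0, 1, 7)
        checked = 0
        for seed in range(20):
            spec = random_scene(2, size=64, seed=seed, noise_sigma=0.0)
            ss = render_stack(make_scene(spec))
            for i in range(spec.n_cells):
                energies = [footprint_energy(p, spec, i, exclusive=True)
                            for p in ss.stack.planes]
                if energies[0] is None:  # fully overlapped cell
                    continue
                best = int(np.argmax(energies))
                dist = np.abs(focus - spec.depths[i])
                # nearest plane wins; a depth sitting at the midpoint
                # between two planes may resolve to either of them
                assert dist[best] <= dist.min() + 0.02
                checked += 1
        assert checked >= 25  # most cells have an exclusive footprint

    def test_rim_blur_matches_sigma_law(self):
        # the defocused rim profile of an isolated cell is the in-focus
        # profile convolved with a Gaussian whose width is
        # sigma_max * |depth - focus|; fit that width per plane
        from scipy import ndimage as ndi
        from scipy.optimize import minimize_scalar

        spec = SceneSpec(size=96, n_cells=1, centers=[[48, 48]], radii=[30],
                         depths=[0.0], texture_seed=2, noise_sigma=0.0)
        ss = render_stack(make_scene(spec), sigma_max=6.0)
        sharp = ss.stack.planes[0][48, :]  # in-focus row through the rim

        for plane_idx in (2, 4, 6):
            profile = ss.stack.planes[plane_idx][48, :]

            def loss(s):
                diff = ndi.gaussian_filter1d(sharp, s) - profile
                return float(np.sum(diff[55:96] ** 2))

            fitted = minimize_scalar(loss, bounds=(0.1, 12), method="bounded").x
            expected = 6.0 * plane_idx / 6.0
            assert fitted == pytest.approx(expected, rel=0.10)


class TestDataset:
    def test_80_20_split_counts(self):
        train, test = make_dataset(10, size=64, seed=3)
        assert len(train) == 8 and len(test) == 2

    def test_seed_reproducible_bytes(self):
        a_train, a_test = make_dataset(6, size=64, seed=9)
        b_train, b_test = make_dataset(6, size=64, seed=9)
        for (sa, ta), (sb, tb) in zip(a_train + a_test, b_train + b_test):
            assert np.array_equal(sa.stack.planes, sb.stack.planes)
            assert np.array_equal(ta, tb)
            assert sa.stack.stack_id == sb.stack.stack_id

    def test_split_disjoint_and_exhaustive(self):
        train, test = make_dataset(10, size=64, seed=1)
        ids = [s.stack.stack_id for s, _ in train + test]
        assert len(set(ids)) == 10

    def test_cell_counts_cycle_in_fixed_proportion(self):
        train, test = make_dataset(8, size=64, seed=2)
        counts = sorted(s.spec.n_cells for s, _ in train + test)
        assert counts == [1, 1, 2, 2, 4, 4, 8, 8]

    def test_lp_target_beats_worst_plane(self):
        train, test = make_dataset(8, size=64, seed=4)
        for ss, target in train + test:
            worst = max(rmse(p, ss.ground_truth) for p in ss.stack.planes)
            assert rmse(target, ss.ground_truth) < worst

    def test_ground_truth_closer_to_target_than_average_plane(self):
        train, test = make_dataset(6, size=64, seed=5)
        for ss, target in train + test:
            mean_plane = np.mean([rmse(p, target) for p in ss.stack.planes])
            assert rmse(ss.ground_truth, target) < mean_plane

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            make_dataset(3, size=64, seed=0)
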