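import itertools
import warnings

import numpy as np
import pytest

import fibroquant as fq
from fibroquant.mri_seg import SegmentationParams


def exhaustive_quantizer_mse(values, weights, k=4):
    """Independent oracle: minimum quantization MSE over every contiguous
    partition of the sorted distinct values into k non-empty classes."""
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    order = np.argsort(v)
    v, w = v[order], w[order]
    W = np.concatenate(([0.0], np.cumsum(w)))
    S = np.concatenate(([0.0], np.cumsum(w * v)))
    Q = np.concatenate(([0.0], np.cumsum(w * v * v)))

    def sse(a, b):
        ww = W[b] - W[a]
        return (Q[b] - Q[a]) - (S[b] - S[a]) ** 2 / ww

    n = len(v)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        idx = (0, *cuts, n)
        total = sum(sse(a, b) for a, b in zip(idx[:-1], idx[1:]))
        best = min(best, total)
    return best / W[-1]


class TestGaussianLowpass:
    def test_sigma_zero_is_identity(self, small_stack):
        out = fq.gaussian_lowpass(small_stack, 0.0)
        np.testing.assert_array_equal(out.voxels, small_stack.voxels)

    def test_constant_stack_invariant(self, small_geometry):
        stack = fq.LungStack(voxels=np.full(small_geometry.shape, 37.0),
                             geometry=small_geometry)
        out = fq.gaussian_lowpass(stack, 2.5)
        np.testing.assert_allclose(out.voxels, 37.0, rtol=1e-12)

    def test_impulse_response_matches_kernel_oracle(self, small_geometry):
        # independent oracle: direct construction of the truncated,
        # normalized discrete Gaussian kernel used for 2D convolution
        sigma = 1.0
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1d = np.exp(-x ** 2 / (2 * sigma ** 2))
        k1d /= k1d.sum()
        vox = np.zeros(small_geometry.shape)
        vox[1, 32, 32] = 200.0
        out = fq.gaussian_lowpass(
            fq.LungStack(voxels=vox, geometry=small_geometry), sigma)
        assert out.voxels[1, 32, 32] == pytest.approx(200.0 * k1d[radius] ** 2)
        # per-slice filtering: other slices untouched
        assert out.voxels[0].max() == 0.0

    def test_negative_sigma_rejected(self, small_stack):
        with pytest.raises(ValueError):
            fq.gaussian_lowpass(small_stack, -1.0)


class TestLloydMaxFit:
    def test_two_point_masses(self):
        m = fq.fit_lloyd_max(np.array([0.0, 0.0, 10.0, 10.0]), k=2)
        assert m.levels == (0.0, 10.0)
        assert m.thresholds == (5.0,)
        assert m.mse == 0.0

    def test_four_distinct_values_exact(self):
        m = fq.fit_lloyd_max(np.array([1.0, 2.0, 3.0, 4.0] * 5), k=4)
        assert m.levels == (1.0, 2.0, 3.0, 4.0)
        assert m.mse == 0.0
        assert m.converged

    def test_uniform_eight_values_matches_exhaustive_oracle(self):
        vals = np.arange(8, dtype=float)
        m = fq.fit_lloyd_max(vals, k=4)
        oracle = exhaustive_quantizer_mse(vals, np.ones(8), k=4)
        assert m.mse == pytest.approx(oracle, abs=1e-12)

    def test_quantile_init_supported(self):
        m = fq.fit_lloyd_max(np.array([1.0, 2.0, 3.0, 4.0] * 5), k=4,
                             init="quantile")
        assert m.levels == (1.0, 2.0, 3.0, 4.0)

    def test_weighted_histogram_input_equivalent_to_sample(self):
        sample = np.array([0.0] * 3 + [5.0] * 2 + [7.0] * 4 + [9.0])
        mw = fq.fit_lloyd_max(np.array([0.0, 5.0, 7.0, 9.0]), k=2,
                              weights=np.array([3.0, 2.0, 4.0, 1.0]))
        ms = fq.fit_lloyd_max(sample, k=2)
        assert mw.levels == ms.levels and mw.mse == pytest.approx(ms.mse)

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(ValueError, match="degenerate histogram"):
            fq.fit_lloyd_max(np.array([1.0, 2.0, 3.0] * 10), k=4)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            fq.fit_lloyd_max(np.array([1.0, np.nan, 3.0, 4.0]), k=4)

    def test_midpoint_and_centroid_conditions_at_convergence(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(mu, 2, 500) for mu in (0, 20, 50, 90)])
        x -= x.min()
        m = fq.fit_lloyd_max(x, k=4)
        assert m.converged
        lv = np.array(m.levels)
        th = np.array(m.thresholds)
        np.testing.assert_allclose(th, 0.5 * (lv[:-1] + lv[1:]), atol=1e-6)
        lab = m.assign(x)
        for i in range(1, 5):
            np.testing.assert_allclose(x[lab == i].mean(), lv[i - 1],
                                       atol=1e-4)

    def test_fitted_mse_beats_equal_width_quantizer(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.gamma(2.0, 10.0, size=2000)
            m = fq.fit_lloyd_max(x, k=4)
            edges = np.linspace(x.min(), x.max(), 5)
            idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, 3)
            sse = sum(((x[idx == i] - x[idx == i].mean()) ** 2).sum()
                      for i in range(4) if (idx == i).any())
            assert m.mse <= sse / len(x) + 1e-12


class TestQuantize:
    @pytest.fixture
    def model(self):
        return fq.fit_lloyd_max(np.array([0.0, 10.0, 20.0, 30.0] * 4), k=4)

    def test_top_level_maps_to_top_class(self, model):
        assert model.assign(np.array([model.levels[-1]]))[0] == 4

    def test_value_exactly_at_threshold_goes_to_lower_class(self, model):
        t1 = model.thresholds[0]
        assert model.assign(np.array([t1]))[0] == 1
        assert model.assign(np.array([np.nextafter(t1, np.inf)]))[0] == 2

    def test_labels_match_nearest_level_oracle(self, model, small_geometry):
        rng = np.random.default_rng(2)
        vox = rng.uniform(0, 30, size=small_geometry.shape)
        labels = fq.quantize(
            fq.LungStack(voxels=vox, geometry=small_geometry), model).labels
        oracle = np.argmin(
            np.abs(vox[..., None] - np.array(model.levels)), axis=-1) + 1
        np.testing.assert_array_equal(labels, oracle)

    def test_monotone_in_intensity(self, model):
        v = np.sort(np.random.default_rng(3).uniform(-5, 40, 1000))
        lab = model.assign(v)
        assert np.all(np.diff(lab) >= 0)


class TestExtractHighestClass:
    def _classmap(self, plane):
        return fq.ClassMap(labels=np.asarray(plane)[None], k=4)

    def test_all_top_class_returns_border(self):
        cm = self._classmap(np.full((8, 8), 4))
        border = np.zeros((1, 8, 8), bool)
        border[0, 2:6, 2:6] = True
        out = fq.extract_highest_class(cm, fq.BorderMask(mask=border))
        np.testing.assert_array_equal(out, border)

    def test_no_candidates_gives_empty(self):
        cm = self._classmap(np.full((8, 8), 2))
        border = np.ones((1, 8, 8), bool)
        out = fq.extract_highest_class(cm, fq.BorderMask(mask=border))
        assert not out.any()

    def test_batch_mode_matches_flood_fill_oracle(self):
        plane = np.ones((8, 8), int)
        plane[1:3, 1:3] = 4      # component fully inside the border
        plane[5:8, 5:8] = 4      # component crossing the border
        border = np.zeros((8, 8), bool)
        border[0:7, 0:7] = True
        cm = self._classmap(plane)
        out = fq.extract_highest_class(cm, fq.BorderMask(mask=border[None]))

        # oracle: hand flood-fill over top-class pixels, then clip to border
        visited = np.zeros_like(border)
        stack = [(r, c) for r in range(8) for c in range(8)
                 if plane[r, c] == 4 and border[r, c]]
        expect = np.zeros_like(border)
        while stack:
            r, c = stack.pop()
            if visited[r, c]:
                continue
            visited[r, c] = True
            if plane[r, c] == 4 and border[r, c]:
                expect[r, c] = True
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < 8 and 0 <= cc < 8 and not visited[rr, cc]:
                            stack.append((rr, cc))
        np.testing.assert_array_equal(out[0], expect)

    def test_seeded_mode_keeps_only_seeded_component(self):
        plane = np.ones((8, 8), int)
        plane[0:2, 0:2] = 4
        plane[6:8, 6:8] = 4
        cm = self._classmap(plane)
        border = fq.BorderMask(mask=np.ones((1, 8, 8), bool))
        out = fq.extract_highest_class(cm, border, seeds=[(0, 0, 0)])
        assert out[0, 0:2, 0:2].all() and not out[0, 6:8, 6:8].any()

    def test_seed_outside_border_rejected(self):
        cm = self._classmap(np.full((8, 8), 4))
        border = np.zeros((1, 8, 8), bool)
        border[0, 0:4, 0:4] = True
        with pytest.raises(ValueError, match="outside the border"):
            fq.extract_highest_class(cm, fq.BorderMask(mask=border),
                                     seeds=[(0, 6, 6)])

    def test_seed_not_top_class_warned_and_ignored(self):
        plane = np.ones((8, 8), int)
        plane[4, 4] = 4
        cm = self._classmap(plane)
        border = fq.BorderMask(mask=np.ones((1, 8, 8), bool))
        with pytest.warns(UserWarning, match="not in the highest class"):
            out = fq.extract_highest_class(cm, border, seeds=[(0, 0, 0)])
        assert not out.any()

    def test_four_vs_eight_connectivity(self):
        plane = np.ones((8, 8), int)
        plane[2, 2] = plane[3, 3] = 4  # diagonal touch
        cm = self._classmap(plane)
        border = fq.BorderMask(mask=np.ones((1, 8, 8), bool))
        out8 = fq.extract_highest_class(cm, border, seeds=[(0, 2, 2)],
                                        connectivity=8)
        out4 = fq.extract_highest_class(cm, border, seeds=[(0, 2, 2)],
                                        connectivity=4)
        assert out8.sum() == 2 and out4.sum() == 1


class TestComputeVolume:
    def test_empty_mask_zero_volume(self, mouse):
        res = fq.compute_volume(np.zeros(mouse.shape, bool), mouse)
        assert res.total_volume_ul == 0.0

    def test_single_pixel_mouse_voxel_volume(self, mouse):
        m = np.zeros(mouse.shape, bool)
        m[0, 0, 0] = True
        assert fq.compute_volume(m, mouse).total_volume_ul == 0.0341796875

    def test_full_slice_mouse(self, mouse):
        m = np.zeros(mouse.shape, bool)
        m[3] = True
        res = fq.compute_volume(m, mouse)
        assert res.total_volume_ul == pytest.approx(30.0 * 30.0 * 1.4)
        assert res.per_slice_area_mm2[3] == pytest.approx(900.0)

    def test_total_is_area_sum_times_thickness(self, mouse):
        rng = np.random.default_rng(0)
        m = rng.random(mouse.shape) > 0.8
        res = fq.compute_volume(m, mouse)
        assert res.total_volume_ul == pytest.approx(
            sum(res.per_slice_area_mm2) * mouse.slice_thickness_mm)

    def test_geometry_mismatch_rejected(self, mouse):
        with pytest.raises(ValueError):
            fq.compute_volume(np.zeros((2, 2, 2), bool), mouse)


class TestSegmentLungInjury:
    def test_noise_free_cubic_lesion_exact(self, mouse):
        spec = fq.PhantomSpec(
            geometry=mouse,
            lesions=(fq.LesionSpec(center=(5, 95, 95), radius_px=1,
                                   intensity=100, shape="box"),))
        stack, border, truth = fq.generate_lung_phantom(spec)
        res = fq.segment_lung_injury(
            stack, border,
            SegmentationParams(sigma_px=0.0, fit_within_border=False))
        assert res.total_volume_ul == truth.lesion_volume_ul == 0.3076171875

    def test_noise_free_baseline_recovers_vessel_volume(self, mouse):
        spec = fq.PhantomSpec(geometry=mouse,
                              vessels=fq.default_vessels(mouse))
        stack, border, truth = fq.generate_lung_phantom(spec)
        res = fq.segment_lung_injury(
            stack, border,
            SegmentationParams(sigma_px=0.0, fit_within_border=False))
        assert res.total_volume_ul == truth.vessel_volume_ul

    def test_noisy_phantom_recovery_within_tolerance(self):
        from conftest import mouse_phantom
        stack, border, truth = mouse_phantom(60.0, seed=21)
        res = fq.segment_lung_injury(stack, border)
        target = truth.lesion_volume_ul + truth.vessel_volume_ul
        assert abs(res.total_volume_ul - target) / target <= 0.15

    def test_segmentation_contained_in_border(self):
        from conftest import mouse_phantom
        stack, border, _ = mouse_phantom(40.0, seed=2)
        res = fq.segment_lung_injury(stack, border)
        assert not (res.segmentation_mask & ~border.mask).any()

    def test_doubling_fov_quadruples_volume(self, mouse):
        big = fq.ImageGeometry(mouse.matrix_size, mouse.field_of_view_mm * 2,
                               mouse.slice_thickness_mm, mouse.n_slices)
        rng = np.random.default_rng(1)
        m = rng.random(mouse.shape) > 0.7
        v1 = fq.compute_volume(m, mouse).total_volume_ul
        v2 = fq.compute_volume(m, big).total_volume_ul
        assert v2 == pytest.approx(4 * v1)

    def test_slice_permutation_leaves_volume_unchanged(self):
        from conftest import mouse_phantom
        stack, border, _ = mouse_phantom(30.0, seed=4)
        res = fq.segment_lung_injury(stack, border)
        perm = np.random.default_rng(0).permutation(stack.shape[0])
        stack_p = fq.LungStack(voxels=stack.voxels[perm],
                               geometry=stack.geometry)
        border_p = fq.BorderMask(mask=border.mask[perm])
        res_p = fq.segment_lung_injury(stack_p, border_p)
        assert res_p.total_volume_ul == pytest.approx(res.total_volume_ul,
                                                      rel=1e-12)

    def test_result_json_round_trip_idempotent(self):
        from conftest import mouse_phantom
        stack, border, _ = mouse_phantom(20.0, seed=6)
        res = fq.segment_lung_injury(stack, border)
        back = fq.SegmentationResult.from_json(res.to_json())
        assert back.per_slice_area_mm2 == res.per_slice_area_mm2
        assert back.total_volume_ul == res.total_volume_ul
        assert back.to_json() == res.to_json()

    def test_rerun_is_bit_identical(self):
        from conftest import mouse_phantom
        stack, border, _ = mouse_phantom(25.0, seed=8)
        j1 = fq.segment_lung_injury(stack, border).to_json()
        j2 = fq.segment_lung_injury(stack, border).to_json()
        assert j1 == j2
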