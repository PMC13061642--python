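"""Coefficient estimation, rendering, coherent merging, centroid refinement."""

import numpy as np
import pytest

from lsom import (
    Dot,
    FilterMatrix,
    IlluminationConfig,
    NoiseModel,
    PointSource,
    RasterGrid,
    RepetitionPlan,
    estimate_coefficients,
    measure_vector,
    merge_directions,
    object_band_field,
    preset,
    refine_centroid_pixel,
    render_image,
)
from lsom.metrics import psf_fwhm

from conftest import in_span_band_field


class TestEstimateCoefficients:
    def test_ideal_diagonal_noiseless_roundtrip(self, basis_1d):
        c_o = np.array([1.0, 0.5 - 0.2j, 0.3j, 0.1, 0.05, 0.02])
        field = in_span_band_field(basis_1d, c_o)
        c_m, _ = measure_vector(
            field, basis_1d, 6, 0, RepetitionPlan.uniform(6), NoiseModel(poisson=False)
        )
        W = FilterMatrix(np.diag(1.0 / basis_1d.gammas), np.eye(6), np.zeros((6, 6)))
        assert np.max(np.abs(estimate_coefficients(c_m, W) - c_o)) < 1e-10

    def test_zero_filter_gives_zero(self, basis_1d):
        W = FilterMatrix(np.zeros((6, 6)), np.eye(6), np.zeros((6, 6)))
        out = estimate_coefficients(np.ones(6, dtype=complex), W)
        assert np.all(out == 0)

    def test_dimension_mismatch(self, basis_1d):
        W = FilterMatrix(np.zeros((6, 6)), np.eye(6), np.zeros((6, 6)))
        with pytest.raises(ValueError, match="does not match"):
            estimate_coefficients(np.ones(5, dtype=complex), W)

    def test_monte_carlo_unbiased_with_allocated_plan(self, basis_1d, pipeline_1d_noisy):
        c_o = np.array([1.0, 0.5 - 0.2j, 0.3j, 0.1, 0.05, 0.02])
        field = in_span_band_field(basis_1d, c_o)
        Winv = np.linalg.pinv(pipeline_1d_noisy.transfer.matrix)
        rng = np.random.default_rng(4)
        noise = NoiseModel(photons_per_submeasurement=1e4, poisson=True, seed=0)
        n = 400
        vals = []
        for _ in range(n):
            c_m, _ = measure_vector(
                field, basis_1d, 6, 0, pipeline_1d_noisy.plan, noise, rng=rng
            )
            vals.append(Winv @ c_m)
        vals = np.array(vals)
        se = vals.std(axis=0) / np.sqrt(n)
        # small systematic from the fitted-T residual is allowed on top of SE
        assert np.all(np.abs(vals.mean(axis=0) - c_o) < 3 * se + 0.02 * np.abs(c_o).max())


class TestRenderImage:
    def test_basis_vector_renders_mode(self, basis_1d):
        e0 = np.zeros(6)
        e0[0] = 1.0
        img = render_image(e0, basis_1d)
        assert np.allclose(img.field.samples, basis_1d.modes[:, 0])

    def test_parseval_on_quadrature_grid(self, basis_2d):
        rng = np.random.default_rng(6)
        c = rng.normal(size=13) + 1j * rng.normal(size=13)
        img = render_image(c, basis_2d)
        assert abs(img.field.energy() - np.sum(np.abs(c) ** 2)) < 1e-10

    def test_point_source_peak_near_source(self, basis_2d):
        pos = (0.1, -0.08)
        c = basis_2d.evaluate(np.array([pos]))[0]
        grid = RasterGrid.centered(0.8, 121, 2)
        img = render_image(c, basis_2d, grid)
        inten = img.intensity.copy()
        inten[~img.fov_mask] = 0.0
        i, j = np.unravel_index(np.argmax(inten), inten.shape)
        peak = np.array([grid.axes[0][i], grid.axes[1][j]])
        # truncated 13-mode projection biases the peak toward the center;
        # it stays within a PSF radius of the true position
        assert np.linalg.norm(peak - np.array(pos)) < 0.09

    def test_raster_masked_outside_fov(self, basis_2d):
        c = np.zeros(13)
        c[0] = 1.0
        grid = RasterGrid.centered(0.8, 61, 2)
        img = render_image(c, basis_2d, grid)
        corners = img.field.samples[0, 0], img.field.samples[-1, -1]
        assert corners[0] == 0 and corners[1] == 0


class TestMergeDirections:
    def test_single_direction_equals_compensated_input(self, basis_1d):
        ill = IlluminationConfig(azimuth_deg=0.0)
        rng = np.random.default_rng(7)
        c = rng.normal(size=6) + 1j * rng.normal(size=6)
        img = render_image(c, basis_1d)
        merged = merge_directions([img], [ill])
        kv = ill.k_vector(1)[0]
        expect = img.field.samples * np.exp(-1j * kv * basis_1d.grid.points)
        assert np.allclose(merged.field.samples, expect)

    def test_four_directions_on_centered_dot_give_real_image(self, pipeline_2d):
        # noiseless chain, centrosymmetric real object: after ramp removal
        # and global phase alignment the merged image is real up to a
        # global phase
        dot = Dot(diameter=0.125, dim=2)
        img = pipeline_2d.reconstruct(dot)
        s = img.field.samples.ravel()
        phase = np.vdot(s, np.abs(s))
        phase /= abs(phase)
        rotated = s * phase
        assert np.max(np.abs(rotated.imag)) < 1e-6 * np.max(np.abs(rotated.real))

    def test_merged_psf_not_wider_than_single_direction(self, pipeline_1d, basis_1d):
        grid = RasterGrid.centered(0.8, 801, 1)
        src = PointSource(position=(0.05,), dim=1)
        per_dir = [
            pipeline_1d.reconstruct_direction(src, ill, grid)
            for ill in pipeline_1d.illuminations
        ]
        merged = merge_directions(per_dir, pipeline_1d.illuminations)
        fw_m, _ = psf_fwhm(np.abs(merged.field.samples) ** 2, grid, (0.05,))
        fw_single = []
        for img, ill in zip(per_dir, pipeline_1d.illuminations):
            one = merge_directions([img], [ill])
            fw, _ = psf_fwhm(np.abs(one.field.samples) ** 2, grid, (0.05,))
            fw_single.append(fw)
        assert fw_m <= min(fw_single) + 1e-9

    def test_inconsistent_grids_rejected(self, basis_1d):
        c = np.zeros(6)
        c[0] = 1.0
        a = render_image(c, basis_1d, RasterGrid.centered(0.8, 101, 1))
        b = render_image(c, basis_1d, RasterGrid.centered(0.8, 51, 1))
        ills = [IlluminationConfig(azimuth_deg=0.0)] * 2
        with pytest.raises(ValueError, match="grid"):
            merge_directions([a, b], ills)


class TestRefineCentroidPixel:
    def _reconstructor(self, pipeline, obj, grid, rng=None):
        def rec(offset):
            shifted = obj.shifted(-np.atleast_1d(np.asarray(offset, float)))
            return pipeline.reconstruct(shifted, grid, rng=rng)

        return rec

    def test_true_offset_selected_noiseless(self, pipeline_1d):
        grid = RasterGrid.centered(0.8, 201, 1)
        obj = Dot(diameter=0.1, position=(0.08,), dim=1)
        candidates = [(-0.08,), (0.0,), (0.08,), (0.16,)]
        best = refine_centroid_pixel(candidates, self._reconstructor(pipeline_1d, obj, grid))
        assert best == (0.08,)

    def test_tie_broken_by_smaller_offset(self, basis_1d):
        from lsom.reconstruction import ReconstructedImage
        from lsom import ComplexField

        def rec(offset):
            # symmetric centroids: |offset| determines nothing, force a tie
            samples = basis_1d.modes[:, 0]
            return ReconstructedImage(
                field=ComplexField(samples, basis_1d.grid, "object")
            )

        best = refine_centroid_pixel([(0.2,), (0.1,), (-0.1,)], rec)
        assert best == (0.1,) or best == (-0.1,)

    def test_empty_reconstructions_error(self, basis_1d):
        from lsom.reconstruction import ReconstructedImage
        from lsom import ComplexField

        def rec(offset):
            return ReconstructedImage(
                field=ComplexField(np.zeros(basis_1d.grid.n_points), basis_1d.grid, "object")
            )

        with pytest.raises(ValueError, match="empty"):
            refine_centroid_pixel([(0.0,)], rec)

    def test_noisy_selection_close_to_truth(self, basis_1d, pipeline_1d_noisy):
        grid = RasterGrid.centered(0.8, 101, 1)
        obj = Dot(diameter=0.1, position=(0.06,), dim=1)
        candidates = [(0.0,), (0.03,), (0.06,), (0.09,), (0.12,)]
        rng = np.random.default_rng(10)
        hits = 0
        n_runs = 40
        for _ in range(n_runs):
            best = refine_centroid_pixel(
                candidates, self._reconstructor(pipeline_1d_noisy, obj, grid, rng=rng)
            )
            if abs(best[0] - 0.06) <= 0.03 + 1e-12:
                hits += 1
        assert hits >= int(0.95 * n_runs)


class TestEndToEnd:
    def test_in_span_object_reproduced_to_1e8(self, pipeline_2d, basis_2d):
        rng = np.random.default_rng(9)
        c = rng.normal(size=13) + 1j * rng.normal(size=13)
        field = in_span_band_field(basis_2d, c)
        c_m, _ = measure_vector(
            field, basis_2d, 13, 0, pipeline_2d.plan, NoiseModel(poisson=False)
        )
        c_e = estimate_coefficients(c_m, pipeline_2d.filter)
        img = render_image(c_e, basis_2d)
        truth = render_image(c, basis_2d)
        num = np.sqrt(basis_2d.grid.norm2(img.field.samples - truth.field.samples))
        den = np.sqrt(basis_2d.grid.norm2(truth.field.samples))
        assert num / den < 1e-8

    def test_noiseless_chain_linear_in_object_amplitude(self, pipeline_1d, basis_1d):
        grid = RasterGrid.centered(0.8, 101, 1)
        obj1 = Dot(diameter=0.1, position=(0.05,), dim=1, scale=1.0)
        obj2 = Dot(diameter=0.1, position=(0.05,), dim=1, scale=2.5 - 1.0j)
        a = pipeline_1d.reconstruct_direction(obj1, pipeline_1d.illuminations[0], grid)
        b = pipeline_1d.reconstruct_direction(obj2, pipeline_1d.illuminations[0], grid)
        assert np.allclose(b.field.samples, (2.5 - 1.0j) * a.field.samples, atol=1e-10)
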