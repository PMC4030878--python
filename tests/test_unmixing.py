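import numpy as np
import pytest

import spectramix as sm
from spectramix.errors import (
    CollinearityError,
    DegenerateSpectrumError,
    GridMismatchError,
)

from conftest import (
    dye_library,
    gaussian_spectrum,
    grid_search_nnls,
    single_disk_scene,
)


class TestBackground:
    def test_constant_cube_background(self, grid):
        cube = sm.SpectralCube(grid, np.full((4, 4, grid.n_bands), 3.0))
        roi = sm.ROI("bg", np.array([[0, 0], [1, 1]]))
        bg = sm.estimate_background(cube, roi)
        assert np.allclose(bg.values, 3.0)

    def test_singleton_roi_returns_that_pixel(self, grid):
        vals = np.random.default_rng(0).uniform(0, 10, (3, 3, grid.n_bands))
        cube = sm.SpectralCube(grid, vals)
        bg = sm.estimate_background(cube, sm.ROI("p", np.array([[2, 1]])))
        assert np.allclose(bg.values, vals[2, 1])

    def test_two_pixel_roi_is_mean(self, grid):
        vals = np.random.default_rng(1).uniform(0, 10, (2, 2, grid.n_bands))
        cube = sm.SpectralCube(grid, vals)
        bg = sm.estimate_background(cube, sm.ROI("p", np.array([[0, 0], [1, 1]])))
        assert np.allclose(bg.values, (vals[0, 0] + vals[1, 1]) / 2)

    def test_subtraction_cancels_own_background(self, grid):
        cube = sm.SpectralCube(grid, np.full((3, 3, grid.n_bands), 5.0))
        out = sm.subtract_background(cube, sm.Spectrum(grid, np.full(grid.n_bands, 5.0)))
        assert np.all(out.values == 0)

    def test_zero_background_is_identity(self, grid):
        vals = np.random.default_rng(2).uniform(0, 9, (3, 3, grid.n_bands))
        cube = sm.SpectralCube(grid, vals)
        out = sm.subtract_background(cube, sm.Spectrum(grid, np.zeros(grid.n_bands)))
        assert np.array_equal(out.values, vals)

    def test_subtraction_clamps_at_zero(self, grid):
        cube = sm.SpectralCube(grid, np.full((2, 2, grid.n_bands), 1.0))
        big = sm.Spectrum(grid, np.full(grid.n_bands, 2.0))
        out = sm.subtract_background(cube, big)
        assert np.all(out.values == 0)

    def test_grid_mismatch_rejected(self, grid, small_grid):
        cube = sm.SpectralCube(grid, np.ones((2, 2, grid.n_bands)))
        with pytest.raises(GridMismatchError):
            sm.subtract_background(
                cube, sm.Spectrum(small_grid, np.zeros(small_grid.n_bands))
            )


class TestBuildReference:
    def test_recovers_true_emission_from_single_dye_scene(self, grid):
        cube, truth = single_disk_scene(
            grid, dye="FITC", brightness=3000.0, background=36.0
        )
        obj = truth.objects[0]
        mask = obj.roi.mask(cube.height, cube.width)
        bg_px = np.column_stack(np.nonzero(~mask))
        name, ref = sm.build_reference(
            cube, obj.roi, sm.ROI("bg", bg_px), "FITC"
        )
        true_ref = sm.emission_spectrum(sm.CATALOG["FITC"], grid)
        assert np.linalg.norm(ref.values - true_ref.values) < 0.02

    def test_blank_field_raises_degenerate(self, grid):
        cube = sm.SpectralCube(grid, np.full((8, 8, grid.n_bands), 2.0))
        sig = sm.ROI("sig", np.array([[1, 1], [1, 2]]))
        bg = sm.ROI("bg", np.array([[5, 5], [5, 6]]))
        with pytest.raises(DegenerateSpectrumError):
            sm.build_reference(cube, sig, bg, "blank")

    def test_reference_invariant_to_scene_brightness(self, grid):
        refs = []
        for scale in (1.0, 10.0):
            cube, truth = single_disk_scene(grid, dye="Cy5", brightness=500.0 * scale)
            obj = truth.objects[0]
            mask = obj.roi.mask(cube.height, cube.width)
            bg_px = np.column_stack(np.nonzero(~mask))
            refs.append(
                sm.build_reference(cube, obj.roi, sm.ROI("bg", bg_px), "Cy5")[1].values
            )
        assert np.allclose(refs[0], refs[1], atol=1e-12)

    def test_overlapping_rois_rejected(self, grid):
        cube = sm.SpectralCube(grid, np.ones((4, 4, grid.n_bands)))
        roi = sm.ROI("a", np.array([[0, 0], [0, 1]]))
        with pytest.raises(ValueError, match="disjoint"):
            sm.build_reference(cube, roi, roi, "x")


class TestUnmixPixel:
    @pytest.mark.parametrize("mode", ["clamp", "nnls"])
    def test_pure_pixel(self, six_dye_library, mode):
        name, ref = six_dye_library.entries[2]
        spec = sm.Spectrum(ref.grid, 3.0 * ref.values)
        coef, resid = sm.unmix_pixel(spec, six_dye_library, mode=mode)
        assert coef[name] == pytest.approx(3.0, abs=1e-9)
        assert resid <= 1e-9
        for other, value in coef.items():
            if other != name:
                assert value == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("mode", ["clamp", "nnls"])
    def test_exact_mixture_in_span(self, grid, mode):
        lib = dye_library(grid, ["FITC", "Cy5"])
        mix = sm.Spectrum(
            grid,
            0.5 * lib.entries[0][1].values + 0.5 * lib.entries[1][1].values,
        )
        coef, _ = sm.unmix_pixel(mix, lib, mode=mode)
        assert coef["FITC"] == pytest.approx(0.5, abs=1e-9)
        assert coef["Cy5"] == pytest.approx(0.5, abs=1e-9)

    def test_partially_negative_mixture_clamp_vs_nnls(self, grid):
        # broad reference R1 covering a narrow R2 so that R1 - 0.1 R2 >= 0
        r1 = gaussian_spectrum(grid, 600.0, fwhm_nm=120.0)
        r2 = gaussian_spectrum(grid, 600.0, fwhm_nm=25.0)
        lib = sm.SpectralLibrary([("broad", r1), ("narrow", r2)])
        target = r1.values - 0.1 * r2.values
        assert np.all(target >= 0)
        spec = sm.Spectrum(grid, target)
        coef_c, _ = sm.unmix_pixel(spec, lib, mode="clamp")
        # unconstrained fit is exactly (1, -0.1); clamp zeroes the second
        assert coef_c["broad"] == pytest.approx(1.0, abs=1e-9)
        assert coef_c["narrow"] == 0.0
        coef_n, _ = sm.unmix_pixel(spec, lib, mode="nnls")
        A = lib.matrix()
        oracle = grid_search_nnls(A, target, scale=1.0)
        assert coef_n["broad"] == pytest.approx(oracle[0], abs=0.005)
        assert coef_n["narrow"] == pytest.approx(oracle[1], abs=0.005)

    def test_identical_references_raise_collinearity(self, grid):
        r = gaussian_spectrum(grid, 550.0)
        lib = sm.SpectralLibrary([("a", r), ("b", sm.Spectrum(grid, r.values.copy()))])
        with pytest.raises(CollinearityError, match="'a' and 'b'"):
            sm.unmix_pixel(r, lib)

    @pytest.mark.parametrize("mode", ["clamp", "nnls"])
    def test_scale_equivariance(self, six_dye_library, mode):
        grid = six_dye_library.grid
        rng = np.random.default_rng(11)
        weights = rng.uniform(0.1, 2.0, len(six_dye_library.names))
        spec_vals = six_dye_library.matrix() @ weights
        for c in (0.5, 7.0):
            base, _ = sm.unmix_pixel(sm.Spectrum(grid, spec_vals), six_dye_library, mode)
            scaled, _ = sm.unmix_pixel(
                sm.Spectrum(grid, c * spec_vals), six_dye_library, mode
            )
            for name in six_dye_library.names:
                assert scaled[name] == pytest.approx(c * base[name], rel=1e-9)

    def test_permutation_equivariance(self, grid):
        names = ["FITC", "Cy3", "Cy5"]
        lib = dye_library(grid, names)
        spec_vals = lib.matrix() @ np.array([1.0, 2.0, 3.0])
        spec = sm.Spectrum(grid, spec_vals)
        coef, _ = sm.unmix_pixel(spec, lib)
        lib_perm = sm.SpectralLibrary([lib.entries[i] for i in (2, 0, 1)])
        coef_perm, _ = sm.unmix_pixel(spec, lib_perm)
        assert coef == pytest.approx(coef_perm)


class TestUnmixCube:
    def test_zero_cube_gives_zero_abundances(self, grid, six_dye_library):
        cube = sm.SpectralCube(grid, np.zeros((3, 3, grid.n_bands)))
        ab = sm.unmix_cube(cube, six_dye_library)
        assert np.all(ab.coefficients == 0)
        assert np.all(ab.residual == 0)

    def test_five_dye_scene_per_pixel_recovery(self, grid):
        panel = sm.DYE_PANEL_FIVE
        lib = dye_library(grid, panel)
        rng = np.random.default_rng(3)
        bright = {d: float(b) for d, b in zip(panel, rng.uniform(500, 3000, 5))}
        spec = sm.SceneSpec(
            height=24, width=24,
            objects=[sm.SceneObject("disk", (12.0, 12.0), 8.0, bright)],
            grid=grid,
        )
        cube, truth = sm.render_scene(spec)
        ab = sm.unmix_cube(cube, lib)
        obj = truth.objects[0]
        for i, dye in enumerate(panel):
            in_disk = ab.coefficients[obj.pixels[:, 0], obj.pixels[:, 1], i]
            assert np.allclose(in_disk, bright[dye], rtol=0.01)

    def test_six_dye_overlapping_cells_conserve_totals(self, grid):
        panel = sm.DYE_PANEL_SIX
        lib = dye_library(grid, panel)
        rng = np.random.default_rng(4)
        objects = []
        expected = dict.fromkeys(panel, 0.0)
        for k in range(3):
            bright = {d: float(b) for d, b in zip(panel, rng.uniform(300, 2500, 6))}
            # overlapping disks
            objects.append(sm.SceneObject("disk", (16.0, 12.0 + 6 * k), 7.0, bright))
        spec = sm.SceneSpec(height=32, width=40, objects=objects, grid=grid)
        cube, truth = sm.render_scene(spec)
        for obj in truth.objects:
            for d, t in obj.totals.items():
                expected[d] += t
        ab = sm.unmix_cube(cube, lib)
        for i, dye in enumerate(panel):
            recovered = ab.coefficients[:, :, i].sum()
            assert recovered == pytest.approx(expected[dye], rel=0.02)

    def test_background_component_fitted_separately(self, grid):
        panel = ["FITC", "Cy5"]
        bg_spec = sm.Spectrum(grid, np.full(grid.n_bands, 1.0 / grid.n_bands))
        lib = sm.SpectralLibrary(
            [(n, sm.emission_spectrum(sm.CATALOG[n], grid)) for n in panel],
            background=bg_spec,
        )
        vals = np.zeros((2, 2, grid.n_bands))
        vals[:] = 36.0 * bg_spec.values + 100.0 * lib.entries[0][1].values
        ab = sm.unmix_cube(sm.SpectralCube(grid, vals), lib)
        assert ab.names == panel
        assert np.allclose(ab.plane("FITC"), 100.0, rtol=1e-6)
        assert np.allclose(ab.background_coefficients, 36.0, rtol=1e-6)


class TestNoiseRobustness:
    def test_roi_totals_within_5_percent_under_shot_noise(self, grid, bead_library):
        """With shot noise at ~5000 peak counts, per-ROI total abundances
        stay within 5% of truth at least 95% of the time over 50 seeds."""
        ok = 0
        trials = 0
        for seed in range(50):
            reps = sm.make_bead_panel(
                1, sm.NoiseModel("shot"), seed=seed, jitter_px=0
            )
            cube, truth = reps[0]
            ab = sm.unmix_cube(cube, bead_library)
            for obj, dye in zip(truth.objects, sm.BEAD_PANEL):
                rep = sm.roi_report(ab, obj.roi)
                trials += 1
                ok += abs(rep.total[dye] - obj.totals[dye]) / obj.totals[dye] < 0.05
        assert ok / trials >= 0.95


class TestRenderRGB:
    def test_fitc_scene_dominates_blue_channel(self, grid):
        cube, truth = single_disk_scene(grid, dye="FITC", brightness=2000.0)
        rgb = sm.render_rgb(cube)
        obj = truth.objects[0]
        px = rgb[obj.pixels[:, 0], obj.pixels[:, 1], :]
        assert np.all(px[:, 2] >= px[:, 0])
        assert np.all(px[:, 2] >= px[:, 1])

    def test_deep_red_bead_dominates_red_channel(self, grid):
        cube, truth = single_disk_scene(grid, dye="bead_deep_red", brightness=2000.0)
        rgb = sm.render_rgb(cube)
        obj = truth.objects[0]
        px = rgb[obj.pixels[:, 0], obj.pixels[:, 1], :]
        assert np.all(px[:, 0] >= px[:, 1])
        assert np.all(px[:, 0] >= px[:, 2])

    def test_zero_cube_renders_black(self, grid):
        cube = sm.SpectralCube(grid, np.zeros((4, 4, grid.n_bands)))
        assert np.all(sm.render_rgb(cube) == 0)

    def test_empty_interval_rejected(self, grid):
        cube = sm.SpectralCube(grid, np.ones((2, 2, grid.n_bands)))
        with pytest.raises(ValueError, match="no grid bands"):
            sm.render_rgb(cube, bands=((900.0, 950.0), (561.0, 635.0), (475.0, 557.0)))


class TestOracleEquivalence:
    def test_nnls_matches_grid_search_on_small_instances(self):
        """NNLS solutions agree with an exhaustive nonnegative grid search
        (0.001 resolution) on random small libraries."""
        rng = np.random.default_rng(42)
        for trial in range(20):
            n_bands = int(rng.integers(6, 13))
            k = int(rng.integers(1, 4))
            g = sm.WavelengthGrid(500.0, 700.0, n_bands)
            peaks = rng.uniform(510, 690, k)
            while k > 1 and np.min(np.diff(np.sort(peaks))) < 30:
                peaks = rng.uniform(510, 690, k)
            entries = [
                (f"d{i}", gaussian_spectrum(g, p, fwhm_nm=40.0)) for i, p in enumerate(peaks)
            ]
            lib = sm.SpectralLibrary(entries)
            true = rng.uniform(0.0, 1.0, k)
            spec_vals = lib.matrix() @ true + rng.normal(0, 0.002, n_bands)
            spec_vals = np.clip(spec_vals, 0.0, None)
            coef, _ = sm.unmix_pixel(sm.Spectrum(g, spec_vals), lib, mode="nnls")
            oracle = grid_search_nnls(lib.matrix(), spec_vals, scale=1.0)
            for i, name in enumerate(lib.names):
                assert coef[name] == pytest.approx(oracle[i], abs=0.005)
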