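import itertools

import numpy as np
import pytest

import spectramix as sm


def grid_search_nnls(A, b, scale, step=0.001):
    """Independent oracle: exhaustive nonnegative grid search, refined.

    Starts on a coarse grid over [0, 2*scale] per coefficient and refines
    the bracket around the best point down to ``step`` resolution; sound
    for this convex least-squares objective.
    """
    k = A.shape[1]
    lo = np.zeros(k)
    hi = np.full(k, 2.0 * scale)
    spacing = (hi - lo) / 20.0
    while True:
        axes = [np.arange(lo[i], hi[i] + spacing[i] / 2, spacing[i]) for i in range(k)]
        pts = np.array(list(itertools.product(*axes)))
        pts = np.clip(pts, 0.0, None)
        resid = np.linalg.norm(pts @ A.T - b, axis=1)
        best = pts[np.argmin(resid)]
        if spacing.max() <= step:
            return best
        lo = np.maximum(best - 1.5 * spacing, 0.0)
        hi = best + 1.5 * spacing
        spacing = np.maximum((hi - lo) / 20.0, step / 2)


@pytest.fixture
def grid():
    return sm.default_grid()


@pytest.fixture
def small_grid():
    return sm.WavelengthGrid(500.0, 700.0, 11)


def gaussian_spectrum(grid, peak_nm, fwhm_nm=30.0, normalized=True):
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vals = np.exp(-0.5 * ((grid.centers - peak_nm) / sigma) ** 2)
    if normalized:
        vals = vals / vals.sum()
    return sm.Spectrum(grid, vals)


def dye_library(grid, names):
    return sm.SpectralLibrary(
        [(n, sm.emission_spectrum(sm.CATALOG[n], grid)) for n in names]
    )


@pytest.fixture
def bead_library(grid):
    return dye_library(grid, sm.BEAD_PANEL)


@pytest.fixture
def six_dye_library(grid):
    return dye_library(grid, sm.DYE_PANEL_SIX)


def single_disk_scene(grid, dye="bead_green", brightness=1000.0, noise=None,
                      background=0.0, center=(16.0, 16.0), radius=5.0, size=32):
    spec = sm.SceneSpec(
        height=size,
        width=size,
        objects=[
            sm.SceneObject("disk", center, radius, {dye: brightness})
        ],
        background_level=background,
        noise=noise or sm.NoiseModel(),
        grid=grid,
    )
    return sm.render_scene(spec)
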