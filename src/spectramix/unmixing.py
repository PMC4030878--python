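"""Linear spectral unmixing against a reference library.

Each pixel's measured spectrum is modelled as a nonnegative combination of
the library's normalized reference spectra (plus, optionally, a background
spectrum fitted as an extra component). Two fitting modes are provided:

``clamp``
    Unconstrained least squares, with negative coefficients reported as
    zero afterwards — the behaviour of the original analysis software,
    which noted occasional negative contributions and zeroes them.
``nnls``
    True nonnegative least squares (the statistically preferable option).

The residual reported per pixel is the L2 norm of the misfit computed with
the *reported* (post-clamp) coefficients, so downstream QC can flag pixels
with unmodelled autofluorescence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .core import ROI, Spectrum, SpectralCube, SpectralLibrary, normalize
from .errors import CollinearityError, DegenerateSpectrumError, GridMismatchError

__all__ = [
    "AbundanceMap",
    "estimate_background",
    "subtract_background",
    "build_reference",
    "unmix_pixel",
    "unmix_cube",
    "render_rgb",
]

logger = logging.getLogger(__name__)

#: Condition number of the reference matrix above which the library is
#: treated as collinear.
COLLINEARITY_CONDITION_LIMIT = 1e6


@dataclass
class AbundanceMap:
    """Per-pixel, per-reference unmixing coefficients.

    ``coefficients`` is dimensioned (height, width, n_entries); entries
    follow ``names``. ``residual`` is the per-pixel L2 misfit norm. The
    background component, when fitted, is kept separately in
    ``background_coefficients`` and excluded from the named entries.
    """

    names: list[str]
    coefficients: np.ndarray
    residual: np.ndarray
    background_coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.residual = np.asarray(self.residual, dtype=float)
        if self.coefficients.ndim != 3 or self.coefficients.shape[2] != len(self.names):
            raise ValueError(
                f"coefficients must be (H, W, {len(self.names)}), "
                f"got {self.coefficients.shape}"
            )
        if self.residual.shape != self.coefficients.shape[:2]:
            raise ValueError("residual shape must match image shape")
        if np.any(self.coefficients < 0) or np.any(self.residual < 0):
            raise ValueError("coefficients and residuals must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.coefficients.shape[:2]

    def plane(self, name: str) -> np.ndarray:
        return self.coefficients[:, :, self.names.index(name)]


def estimate_background(cube: SpectralCube, roi: ROI) -> Spectrum:
    """Mean spectrum over a background ROI (not normalized)."""
    roi.check_bounds(cube.height, cube.width)
    vals = cube.values[roi.rows, roi.cols, :].mean(axis=0)
    return Spectrum(cube.grid, np.clip(vals, 0.0, None))


def subtract_background(cube: SpectralCube, background: Spectrum) -> SpectralCube:
    """Subtract a background spectrum from every pixel, clamping at zero."""
    if background.grid != cube.grid:
        raise GridMismatchError("background grid does not match cube grid")
    return SpectralCube(cube.grid, np.clip(cube.values - background.values, 0.0, None))


def build_reference(
    single_dye_cube: SpectralCube,
    signal_roi: ROI,
    background_roi: ROI,
    name: str,
) -> tuple[str, Spectrum]:
    """Build a normalized reference spectrum from a single-dye image.

    The mean spectrum over ``signal_roi``, background-corrected by the mean
    over ``background_roi``, is normalized to sum one.

    Raises
    ------
    DegenerateSpectrumError
        If the corrected spectrum carries no signal (e.g. a blank field).
    """
    for roi in (signal_roi, background_roi):
        roi.check_bounds(single_dye_cube.height, single_dye_cube.width)
    sig_px = {tuple(p) for p in signal_roi.pixels}
    if sig_px & {tuple(p) for p in background_roi.pixels}:
        raise ValueError("signal and background ROIs must be disjoint")
    signal = single_dye_cube.values[signal_roi.rows, signal_roi.cols, :].mean(axis=0)
    background = single_dye_cube.values[
        background_roi.rows, background_roi.cols, :
    ].mean(axis=0)
    corrected = np.clip(signal - background, 0.0, None)
    if corrected.sum() <= 0:
        raise DegenerateSpectrumError(
            f"reference {name!r}: no signal above background"
        )
    return name, normalize(Spectrum(single_dye_cube.grid, corrected))


def _check_collinearity(matrix: np.ndarray, names: list[str]) -> None:
    if np.linalg.cond(matrix) <= COLLINEARITY_CONDITION_LIMIT:
        return
    # identify the most similar pair to make the diagnostic actionable
    norms = np.linalg.norm(matrix, axis=0)
    unit = matrix / np.where(norms > 0, norms, 1.0)
    gram = np.abs(unit.T @ unit)
    np.fill_diagonal(gram, -1.0)
    i, j = np.unravel_index(np.argmax(gram), gram.shape)
    raise CollinearityError(
        f"library is numerically collinear; most similar pair: "
        f"{names[i]!r} and {names[j]!r} (|cos| = {gram[i, j]:.6f})"
    )


def _design_matrix(
    library: SpectralLibrary, fit_background: bool
) -> tuple[np.ndarray, list[str]]:
    use_bg = fit_background and library.background is not None
    A = library.matrix(include_background=use_bg)
    names = library.names + (["<background>"] if use_bg else [])
    _check_collinearity(A, names)
    return A, names


def _solve(A: np.ndarray, B: np.ndarray, mode: str) -> np.ndarray:
    """Solve min ||A x - b|| for each column b of B; returns (k, n) array."""
    if mode == "clamp":
        coef, *_ = np.linalg.lstsq(A, B, rcond=None)
        return np.clip(coef, 0.0, None)
    if mode == "nnls":
        return np.column_stack(
            [scipy.optimize.nnls(A, B[:, i])[0] for i in range(B.shape[1])]
        )
    raise ValueError(f"unknown unmixing mode {mode!r}")


def unmix_pixel(
    spectrum: Spectrum,
    library: SpectralLibrary,
    mode: str = "clamp",
) -> tuple[dict[str, float], float]:
    """Decompose one spectrum into per-reference coefficients plus residual.

    Returns the named coefficients (background excluded) and the L2 norm of
    the misfit computed with the reported (post-clamp) coefficients.
    """
    if spectrum.grid != library.grid:
        raise GridMismatchError("spectrum grid does not match library grid")
    A, _ = _design_matrix(library, fit_background=True)
    coef = _solve(A, spectrum.values[:, None], mode)[:, 0]
    residual = float(np.linalg.norm(spectrum.values - A @ coef))
    named = dict(zip(library.names, coef[: len(library.names)]))
    return named, residual


def unmix_cube(
    cube: SpectralCube,
    library: SpectralLibrary,
    mode: str = "clamp",
) -> AbundanceMap:
    """Unmix every pixel of a cube against a library.

    If the library carries a background spectrum it is fitted as an extra
    component whose coefficients are reported separately and excluded from
    the named abundance entries.
    """
    if cube.grid != library.grid:
        raise GridMismatchError("cube grid does not match library grid")
    A, _ = _design_matrix(library, fit_background=True)
    h, w = cube.shape
    B = cube.values.reshape(-1, cube.grid.n_bands).T  # (bands, pixels)
    coef = _solve(A, B, mode)  # (k, pixels)
    resid = np.linalg.norm(B - A @ coef, axis=0)
    k_named = len(library.names)
    n_clamped = int(np.sum(coef == 0.0)) if mode == "clamp" else 0
    if n_clamped:
        logger.info("unmix_cube: %d coefficients clamped to zero", n_clamped)
    background = None
    if coef.shape[0] > k_named:
        background = coef[k_named].reshape(h, w)
    return AbundanceMap(
        names=list(library.names),
        coefficients=coef[:k_named].T.reshape(h, w, k_named),
        residual=resid.reshape(h, w),
        background_coefficients=background,
    )


def render_rgb(
    cube: SpectralCube,
    bands: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] = (
        (635.0, 752.0),  # red
        (561.0, 635.0),  # green
        (475.0, 557.0),  # blue
    ),
) -> np.ndarray:
    """Pseudo-color display: sum three wavelength intervals into 8-bit RGB.

    ``bands`` gives the (red, green, blue) intervals in nm; the default is
    the conventional display choice blue = 475-557, green = 561-635 and
    red = 635-752 nm. Channels are scaled jointly by the global maximum.
    """
    centers = cube.grid.centers
    channels = []
    for lo, hi in bands:
        sel = (centers >= lo) & (centers <= hi)
        if not np.any(sel):
            raise ValueError(f"band {lo}-{hi} nm contains no grid bands")
        channels.append(cube.values[:, :, sel].sum(axis=2))
    rgb = np.stack(channels, axis=-1)
    peak = rgb.max()
    if peak > 0:
        rgb = rgb / peak * 255.0
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)
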