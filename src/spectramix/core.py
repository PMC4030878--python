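"""Domain types shared across the pipeline.

The central objects are a :class:`WavelengthGrid` of evenly spaced emission
bands, per-band :class:`Spectrum` vectors, image-shaped :class:`SpectralCube`
stacks (one grayscale plane per band), a :class:`SpectralLibrary` of named
reference spectra used for unmixing, and pixel-set :class:`ROI` regions.

Conventions
-----------
* pixel coordinates are 0-based ``(row, col)``, row-major;
* band index 0 is the shortest wavelength;
* intensities are nonnegative reals in arbitrary "counts" units;
* two grids are interchangeable only if ``start_nm``, ``stop_nm`` and
  ``n_bands`` are identical — otherwise an explicit :func:`resample` is
  required, which prevents silent band misalignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSpectrumError, GridMismatchError

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SpectralCube",
    "SpectralLibrary",
    "ROI",
    "default_grid",
    "normalize",
    "resample",
]

#: Maximum number of reference entries a library may hold (the analysis
#: software this emulates accepts up to nine references plus a background).
MAX_LIBRARY_ENTRIES = 9


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced emission-wavelength bands, in nanometres.

    Band centers run from ``start_nm`` to ``stop_nm`` inclusive, strictly
    increasing. The default acquisition grid spans 450-800 nm in 36 bands
    (10 nm spacing).
    """

    start_nm: float
    stop_nm: float
    n_bands: int

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValueError(
                f"start_nm ({self.start_nm}) must be < stop_nm ({self.stop_nm})"
            )
        if self.n_bands < 2:
            raise ValueError(f"n_bands must be >= 2, got {self.n_bands}")

    @property
    def centers(self) -> np.ndarray:
        """Band-center wavelengths (nm), shape ``(n_bands,)``."""
        return np.linspace(self.start_nm, self.stop_nm, self.n_bands)

    @property
    def spacing_nm(self) -> float:
        return (self.stop_nm - self.start_nm) / (self.n_bands - 1)

    def nearest_band(self, wavelength_nm: float) -> int:
        """Index of the band whose center is closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.centers - wavelength_nm)))


def default_grid() -> WavelengthGrid:
    """The 450-800 nm, 36-band (10 nm) acquisition grid."""
    return WavelengthGrid(450.0, 800.0, 36)


@dataclass
class Spectrum:
    """Per-band nonnegative intensity on a :class:`WavelengthGrid`."""

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bands,):
            raise ValueError(
                f"spectrum has {self.values.shape} values for a "
                f"{self.grid.n_bands}-band grid"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")
        if np.any(self.values < 0):
            raise ValueError("spectrum values must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def normalized(self) -> "Spectrum":
        return normalize(self)

    def __eq__(self, other: object) -> bool:  # value semantics, used in tests
        if not isinstance(other, Spectrum):
            return NotImplemented
        return self.grid == other.grid and np.array_equal(self.values, other.values)


@dataclass
class SpectralCube:
    """An H x W image with one intensity per pixel per band."""

    grid: WavelengthGrid
    values: np.ndarray  # (height, width, n_bands)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"cube values must be (H, W, {self.grid.n_bands}), "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube values must be finite")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.grid, np.clip(self.values[row, col], 0.0, None))


@dataclass
class SpectralLibrary:
    """Named, normalized reference spectra plus an optional background.

    At most :data:`MAX_LIBRARY_ENTRIES` references are allowed; names must be
    unique and all spectra (background included) must share one grid.
    Entries are area-normalized (sum to one) so that unmixing coefficients
    carry total-signal meaning.
    """

    entries: list[tuple[str, Spectrum]]
    background: Spectrum | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.entries) <= MAX_LIBRARY_ENTRIES:
            raise ValueError(
                f"library must hold 1..{MAX_LIBRARY_ENTRIES} entries, "
                f"got {len(self.entries)}"
            )
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate entry names: {names}")
        grid = self.entries[0][1].grid
        for name, spec in self.entries:
            if spec.grid != grid:
                raise GridMismatchError(f"entry {name!r} is on a different grid")
            if abs(spec.total - 1.0) > 1e-6:
                raise ValueError(f"entry {name!r} is not normalized (sum={spec.total})")
        if self.background is not None and self.background.grid != grid:
            raise GridMismatchError("background spectrum is on a different grid")

    @property
    def grid(self) -> WavelengthGrid:
        return self.entries[0][1].grid

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    def matrix(self, include_background: bool = False) -> np.ndarray:
        """Reference spectra as columns, shape ``(n_bands, n_components)``."""
        cols = [spec.values for _, spec in self.entries]
        if include_background and self.background is not None:
            cols.append(self.background.values)
        return np.column_stack(cols)


@dataclass
class ROI:
    """A labelled set of pixel coordinates.

    ``pixels`` is stored as a unique, lexicographically sorted ``(N, 2)``
    integer array of (row, col) coordinates.
    """

    label: str
    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[1] != 2 or px.shape[0] == 0:
            raise ValueError("ROI pixels must be a non-empty (N, 2) array")
        px = np.unique(px.astype(np.intp), axis=0)
        if np.any(px < 0):
            raise ValueError("ROI pixel coordinates must be nonnegative")
        self.pixels = px

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])

    def check_bounds(self, height: int, width: int) -> None:
        if (
            self.pixels[:, 0].max() >= height
            or self.pixels[:, 1].max() >= width
        ):
            raise ValueError(
                f"ROI {self.label!r} exceeds image bounds ({height}, {width})"
            )

    @property
    def rows(self) -> np.ndarray:
        return self.pixels[:, 0]

    @property
    def cols(self) -> np.ndarray:
        return self.pixels[:, 1]

    def mask(self, height: int, width: int) -> np.ndarray:
        self.check_bounds(height, width)
        m = np.zeros((height, width), dtype=bool)
        m[self.rows, self.cols] = True
        return m


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale a spectrum so its band intensities sum to one.

    Raises
    ------
    DegenerateSpectrumError
        If the spectrum is all zero.
    """
    total = spectrum.values.sum()
    if total <= 0:
        raise DegenerateSpectrumError("cannot normalize an all-zero spectrum")
    return Spectrum(spectrum.grid, spectrum.values / total)


def resample(spectrum: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto another grid.

    Values outside the source grid's support are zero. Source and target
    grids must overlap.

    Raises
    ------
    GridMismatchError
        If the grids are disjoint.
    """
    if spectrum.grid == target:
        return Spectrum(target, spectrum.values.copy())
    src = spectrum.grid
    if src.stop_nm < target.start_nm or target.stop_nm < src.start_nm:
        raise GridMismatchError(
            f"grids do not overlap: source {src.start_nm}-{src.stop_nm} nm, "
            f"target {target.start_nm}-{target.stop_nm} nm"
        )
    vals = np.interp(
        target.centers, src.centers, spectrum.values, left=0.0, right=0.0
    )
    return Spectrum(target, np.clip(vals, 0.0, None))
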