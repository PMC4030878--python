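"""Synthetic spectral scenes with known ground truth.

This module emulates the two kinds of specimens used to validate the
pipeline: fields of multi-color fluorescent calibration beads, and mixtures
of two cell populations expressing a handful of transcripts at
population-specific levels (a thyroid-cancer-like rare population carrying
an elevated RET-analogue signal inside a breast-cancer-like majority).

A scene is rendered band by band: each object contributes
``brightness x emission_spectrum`` to every pixel it covers, on top of a
flat background and optional broad autofluorescence. Optional band-sequential
photobleaching then attenuates band ``b`` by ``(1 - rate)**b``, and finally
shot (Poisson) and read (Gaussian) noise are applied. Ground truth records
each object's pixel set and exact noiseless per-dye totals.

Emission spectra are modelled as single Gaussians (default FWHM 30 nm)
centered on the catalogued emission peaks; the catalog carries the dye and
bead panels used throughout (FITC, Cy3, Cy3.5, Texas Red, Cy5, Cy5.5, DAPI,
and the green/orange/red/deep-red plus crimson/scarlet/ultra-red beads).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ROI, Spectrum, SpectralCube, WavelengthGrid, default_grid
from .errors import SceneSpecError

__all__ = [
    "FluorophoreModel",
    "NoiseModel",
    "SceneObject",
    "SceneSpec",
    "ObjectTruth",
    "GroundTruth",
    "CATALOG",
    "DYE_PANEL_FIVE",
    "DYE_PANEL_SIX",
    "BEAD_PANEL",
    "RED_BEAD_PANEL",
    "emission_spectrum",
    "render_scene",
    "make_bead_panel",
    "make_cell_mixture",
]

#: Default emission full width at half maximum (nm) for the Gaussian model.
DEFAULT_FWHM_NM = 30.0

#: Default per-cell biological variability (coefficient of variation).
DEFAULT_CELL_CV = 0.20

#: Default peak-band signal level, in counts, for bright objects.
DEFAULT_PEAK_COUNTS = 5000.0


@dataclass(frozen=True)
class FluorophoreModel:
    """A fluorochrome with a Gaussian emission profile.

    ``excitation_peak_nm`` is carried as metadata only; excitation and filter
    physics are collapsed into per-object brightness scalars.
    """

    name: str
    emission_peak_nm: float
    fwhm_nm: float = DEFAULT_FWHM_NM
    excitation_peak_nm: float | None = None

    def __post_init__(self) -> None:
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be positive")


def _cat(name: str, exc: float, em: float) -> FluorophoreModel:
    return FluorophoreModel(name, emission_peak_nm=em, excitation_peak_nm=exc)


#: Built-in fluorochrome and bead catalog (excitation/emission peaks in nm).
CATALOG: dict[str, FluorophoreModel] = {
    m.name: m
    for m in [
        _cat("FITC", 495, 528),
        _cat("Cy3", 552, 565),
        _cat("Cy3.5", 581, 596),
        _cat("TexasRed", 596, 620),
        _cat("Cy5", 650, 667),
        _cat("Cy5.5", 678, 703),
        _cat("DAPI", 363, 461),
        _cat("bead_green", 505, 515),
        _cat("bead_orange", 540, 560),
        _cat("bead_red", 580, 605),
        _cat("bead_deep_red", 633, 660),
        _cat("bead_crimson", 625, 645),
        _cat("bead_scarlet", 645, 680),
        _cat("bead_ultra_red", 665, 695),
    ]
}

#: Five-reporter transcript panel (MAP3K11/PTK6/EFNA2/LCK/CLK3 labelling).
DYE_PANEL_FIVE = ["FITC", "Cy3", "TexasRed", "Cy5", "Cy5.5"]

#: Six-reporter transcript panel (RET/EFNA1/ABL/EFNA4/RON/PTK6 labelling).
DYE_PANEL_SIX = ["FITC", "Cy3", "Cy3.5", "TexasRed", "Cy5", "Cy5.5"]

#: Four-color calibration bead panel (2.5 um beads).
BEAD_PANEL = ["bead_green", "bead_orange", "bead_red", "bead_deep_red"]

#: Red-to-infrared calibration panel (emissions 605, 645, 660, 680 nm).
RED_BEAD_PANEL = ["bead_red", "bead_crimson", "bead_deep_red", "bead_scarlet"]


@dataclass(frozen=True)
class NoiseModel:
    """Detection noise: ``none``, ``shot`` (Poisson), or ``shot+read``."""

    kind: str = "none"
    read_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "shot", "shot+read"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.read_sd < 0:
            raise ValueError("read_sd must be >= 0")

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return signal
        out = rng.poisson(np.clip(signal, 0.0, None)).astype(float)
        if self.kind == "shot+read" and self.read_sd > 0:
            out = out + rng.normal(0.0, self.read_sd, size=out.shape)
        return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class SceneObject:
    """A disk-shaped object (bead, or cell = nucleus disk inside a larger
    cytoplasm disk) with per-fluorophore brightness in counts/pixel."""

    shape: str  # "disk" | "cell"
    center: tuple[float, float]  # (row, col)
    radius_px: float
    brightness: dict[str, float]  # fluorophore name -> total counts per pixel
    nucleus_radius_px: float = 0.0  # cells only
    dapi_brightness: float = 0.0  # cells only, counts/pixel in the DAPI image
    population: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "cell"):
            raise ValueError(f"unknown object shape {self.shape!r}")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if any(v < 0 for v in self.brightness.values()):
            raise ValueError("brightness values must be >= 0")


@dataclass
class SceneSpec:
    """Full description of a synthetic scene."""

    height: int
    width: int
    objects: list[SceneObject] = field(default_factory=list)
    background_level: float = 0.0  # total counts per pixel, flat spectrum
    autofluorescence: Spectrum | None = None  # added to every pixel
    noise: NoiseModel = field(default_factory=NoiseModel)
    bleach_rate: float = 0.0  # per-band geometric fading, band-sequential
    seed: int = 0
    grid: WavelengthGrid = field(default_factory=default_grid)
    fluorophores: dict[str, FluorophoreModel] = field(default_factory=lambda: dict(CATALOG))

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise SceneSpecError("scene must be at least 1x1 pixels")
        if self.background_level < 0:
            raise SceneSpecError("background_level must be >= 0")
        if not 0.0 <= self.bleach_rate < 1.0:
            raise SceneSpecError("bleach_rate must be in [0, 1)")


@dataclass
class ObjectTruth:
    """Ground truth for one rendered object."""

    label: str
    population: str
    pixels: np.ndarray  # (N, 2) in-bounds pixel coordinates
    totals: dict[str, float]  # per-dye noiseless total counts over pixels
    center: tuple[float, float]

    @property
    def roi(self) -> ROI:
        return ROI(self.label, self.pixels)


@dataclass
class GroundTruth:
    """Ground truth for a rendered scene."""

    objects: list[ObjectTruth]
    background_level: float
    dapi: np.ndarray | None = None  # 2-D DAPI reference image, cells only

    def totals_frame(self) -> dict[str, dict[str, float]]:
        return {o.label: dict(o.totals) for o in self.objects}


def emission_spectrum(model: FluorophoreModel, grid: WavelengthGrid) -> Spectrum:
    """Gaussian emission profile sampled at band centers, normalized to sum 1.

    If the peak lies more than three FWHM outside the grid a warning is
    emitted and the (possibly all-zero) unnormalized spectrum is returned.
    """
    sigma = model.fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vals = np.exp(-0.5 * ((grid.centers - model.emission_peak_nm) / sigma) ** 2)
    out_left = grid.start_nm - model.emission_peak_nm
    out_right = model.emission_peak_nm - grid.stop_nm
    if max(out_left, out_right) > 3.0 * model.fwhm_nm:
        warnings.warn(
            f"emission peak of {model.name!r} ({model.emission_peak_nm} nm) lies "
            f"more than 3 FWHM outside the {grid.start_nm}-{grid.stop_nm} nm grid",
            stacklevel=2,
        )
        if vals.sum() == 0:
            return Spectrum(grid, vals)
    return Spectrum(grid, vals / vals.sum())


def _disk_pixels(
    center: tuple[float, float], radius: float, height: int, width: int
) -> np.ndarray:
    r0 = max(int(np.floor(center[0] - radius)), 0)
    r1 = min(int(np.ceil(center[0] + radius)), height - 1)
    c0 = max(int(np.floor(center[1] - radius)), 0)
    c1 = min(int(np.ceil(center[1] + radius)), width - 1)
    if r1 < r0 or c1 < c0:
        return np.empty((0, 2), dtype=np.intp)
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return np.column_stack([rr[inside], cc[inside]]).astype(np.intp)


def render_scene(spec: SceneSpec) -> tuple[SpectralCube, GroundTruth]:
    """Render a scene to a spectral cube plus exact ground truth.

    The noiseless signal at pixel ``p`` is
    ``background + autofluorescence + sum_objects sum_dyes brightness * emission``;
    photobleaching and noise are applied afterwards, so recorded ground-truth
    totals are the noiseless per-object sums.
    """
    grid = spec.grid
    nb = grid.n_bands
    cube = np.zeros((spec.height, spec.width, nb), dtype=float)
    cube += spec.background_level / nb
    if spec.autofluorescence is not None:
        if spec.autofluorescence.grid != grid:
            raise SceneSpecError("autofluorescence spectrum is on a different grid")
        cube += spec.autofluorescence.values

    emissions = {
        name: emission_spectrum(model, grid).values
        for name, model in spec.fluorophores.items()
    }

    objects: list[ObjectTruth] = []
    dapi = None
    has_cells = any(o.shape == "cell" for o in spec.objects)
    if has_cells:
        dapi = np.zeros((spec.height, spec.width), dtype=float)

    for i, obj in enumerate(spec.objects):
        px = _disk_pixels(obj.center, obj.radius_px, spec.height, spec.width)
        if px.shape[0] == 0:
            raise SceneSpecError(
                f"object {i} at {obj.center} lies fully outside the image"
            )
        pixel_spectrum = np.zeros(nb)
        for dye, bright in obj.brightness.items():
            if dye not in emissions:
                raise SceneSpecError(f"object {i} references unknown dye {dye!r}")
            pixel_spectrum += bright * emissions[dye]
        cube[px[:, 0], px[:, 1], :] += pixel_spectrum
        if obj.shape == "cell" and obj.nucleus_radius_px > 0:
            npx = _disk_pixels(obj.center, obj.nucleus_radius_px, spec.height, spec.width)
            if npx.shape[0]:
                dapi[npx[:, 0], npx[:, 1]] += obj.dapi_brightness
        objects.append(
            ObjectTruth(
                label=f"obj{i:03d}",
                population=obj.population,
                pixels=px,
                totals={d: float(b * px.shape[0]) for d, b in obj.brightness.items()},
                center=obj.center,
            )
        )

    if spec.bleach_rate > 0:
        cube *= (1.0 - spec.bleach_rate) ** np.arange(nb)

    rng = np.random.default_rng(spec.seed)
    cube = spec.noise.apply(cube, rng)
    if dapi is not None:
        dapi = spec.noise.apply(dapi, rng)

    truth = GroundTruth(objects=objects, background_level=spec.background_level, dapi=dapi)
    return SpectralCube(grid, cube), truth


def _bead_brightness(panel: list[str], grid: WavelengthGrid, peak_counts: float) -> dict[str, float]:
    """Per-dye brightness such that the peak band reads ``peak_counts``."""
    out = {}
    for name in panel:
        em = emission_spectrum(CATALOG[name], grid).values
        out[name] = peak_counts / em.max()
    return out


def make_bead_panel(
    n_replicates: int,
    noise: NoiseModel | None = None,
    seed: int = 0,
    panel: list[str] | None = None,
    peak_counts: float = DEFAULT_PEAK_COUNTS,
    background_level: float = 0.0,
    jitter_px: int = 2,
    grid: WavelengthGrid | None = None,
) -> list[tuple[SpectralCube, GroundTruth]]:
    """Replicate renderings of one four-bead calibration layout.

    Each replicate shares the same bead layout (2.5 um scale, ~8 px diameter
    disks, one dye per bead) but gets an independent noise realization and a
    small integer stage-repositioning translation of at most ``jitter_px``
    pixels per axis.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    noise = noise or NoiseModel()
    panel = panel or BEAD_PANEL
    grid = grid or default_grid()
    bright = _bead_brightness(panel, grid, peak_counts)
    size = 64
    centers = [(20.0, 20.0), (20.0, 44.0), (44.0, 20.0), (44.0, 44.0)]
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(n_replicates):
        shift = rng.integers(-jitter_px, jitter_px + 1, size=2) if jitter_px else (0, 0)
        objects = [
            SceneObject(
                shape="disk",
                center=(c[0] + shift[0], c[1] + shift[1]),
                radius_px=4.0,
                brightness={dye: bright[dye]},
            )
            for c, dye in zip(centers, panel)
        ]
        spec = SceneSpec(
            height=size,
            width=size,
            objects=objects,
            background_level=background_level,
            noise=noise,
            seed=int(rng.integers(0, 2**31 - 1)),
            grid=grid,
        )
        out.append(render_scene(spec))
    return out


#: Default per-dye mean per-pixel brightness profiles for the two cell
#: populations, in counts/pixel, chosen so the summed peak-band signal of a
#: typical cell is on the order of DEFAULT_PEAK_COUNTS. The majority
#: population is the breast-cancer analogue (ABL/PTK6-analogues high, RET
#: analogue low); the rare population is the thyroid-cancer analogue (RET
#: analogue high, ABL analogue low).
MAJORITY_PROFILE = {
    "FITC": 800.0,     # RET analogue: low in the majority
    "Cy3": 1600.0,
    "Cy3.5": 2400.0,   # ABL analogue: high in the majority
    "TexasRed": 1600.0,
    "Cy5": 1600.0,
    "Cy5.5": 2400.0,   # PTK6 analogue: high in the majority
}

RARE_PROFILE = {
    "FITC": 2400.0,    # RET analogue: high in the rare population
    "Cy3": 1600.0,
    "Cy3.5": 800.0,    # ABL analogue: low in the rare population
    "TexasRed": 1600.0,
    "Cy5": 1600.0,
    "Cy5.5": 1200.0,
}


def make_cell_mixture(
    n_cells: int,
    rare_fraction: float,
    rare_elevation: float,
    panel: list[FluorophoreModel] | list[str] | None = None,
    seed: int = 0,
    target_dye: str = "FITC",
    cell_cv: float = DEFAULT_CELL_CV,
    noise: NoiseModel | None = None,
    majority_profile: dict[str, float] | None = None,
    rare_profile: dict[str, float] | None = None,
    background_level: float = 0.0,
    cell_radius_px: float = 5.0,
    nucleus_radius_px: float = 3.0,
    grid: WavelengthGrid | None = None,
) -> tuple[SpectralCube, GroundTruth]:
    """Render a two-population cell mixture with exactly
    ``round(rare_fraction * n_cells)`` rare cells.

    Rare cells take ``rare_profile`` (by default a copy of the majority
    profile) with the ``target_dye`` mean multiplied by
    ``1 + rare_elevation / 100``. Per-cell, per-dye brightness is drawn
    log-normally (mean-one factors with coefficient of variation
    ``cell_cv``) around the population means. Cells are disks laid out on a
    jittered grid; nuclei carry a DAPI signal rendered into a separate
    reference image (``GroundTruth.dapi``).
    """
    if n_cells < 1:
        raise SceneSpecError("empty scene: n_cells must be >= 1")
    if not 0.0 <= rare_fraction <= 1.0:
        raise ValueError("rare_fraction must be in [0, 1]")
    if rare_elevation < 0:
        raise ValueError("rare_elevation must be >= 0")
    grid = grid or default_grid()
    noise = noise or NoiseModel()
    if panel is None:
        panel_names = DYE_PANEL_SIX
    else:
        panel_names = [p.name if isinstance(p, FluorophoreModel) else p for p in panel]
    fluorophores = dict(CATALOG)
    if panel is not None:
        for p in panel:
            if isinstance(p, FluorophoreModel):
                fluorophores[p.name] = p
    if target_dye not in panel_names:
        raise ValueError(f"target dye {target_dye!r} not in panel {panel_names}")

    maj = dict(majority_profile or {d: MAJORITY_PROFILE.get(d, 1600.0) for d in panel_names})
    if rare_profile is None:
        rare = dict(maj)
    else:
        rare = dict(rare_profile)
    rare[target_dye] = rare.get(target_dye, maj[target_dye]) * (1.0 + rare_elevation / 100.0)

    n_rare = int(round(rare_fraction * n_cells))
    rng = np.random.default_rng(seed)
    rare_idx = set(rng.choice(n_cells, size=n_rare, replace=False).tolist())

    # jittered-grid layout with enough clearance that cells never touch
    n_side = int(np.ceil(np.sqrt(n_cells)))
    pitch = int(2 * cell_radius_px + 5)
    margin = int(cell_radius_px + 3)
    size_h = margin * 2 + pitch * (int(np.ceil(n_cells / n_side)) - 1) + 1
    size_w = margin * 2 + pitch * (n_side - 1) + 1

    sigma = np.sqrt(np.log(1.0 + cell_cv**2))
    objects = []
    for i in range(n_cells):
        r = margin + (i // n_side) * pitch + rng.integers(-1, 2)
        c = margin + (i % n_side) * pitch + rng.integers(-1, 2)
        profile = rare if i in rare_idx else maj
        factors = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=len(panel_names)))
        brightness = {d: profile[d] * f for d, f in zip(panel_names, factors)}
        objects.append(
            SceneObject(
                shape="cell",
                center=(float(r), float(c)),
                radius_px=cell_radius_px,
                brightness=brightness,
                nucleus_radius_px=nucleus_radius_px,
                dapi_brightness=1000.0,
                population="rare" if i in rare_idx else "majority",
            )
        )

    spec = SceneSpec(
        height=size_h,
        width=size_w,
        objects=objects,
        background_level=background_level,
        noise=noise,
        seed=int(rng.integers(0, 2**31 - 1)),
        grid=grid,
        fluorophores=fluorophores,
    )
    return render_scene(spec)
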