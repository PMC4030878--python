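"""File formats: spectral cubes as multi-page TIFF, libraries and ROIs as
JSON, label images, and run manifests.

A spectral cube is stored as a multi-page grayscale 32-bit float TIFF, one
page per band ordered short to long wavelength. The wavelength grid rides
in the TIFF description tag as JSON and, redundantly, in a ``.json``
sidecar next to the file; either source suffices on read. Writing then
reading a cube is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import ROI, Spectrum, SpectralCube, SpectralLibrary, WavelengthGrid
from .errors import FormatError

__all__ = [
    "read_cube",
    "write_cube",
    "read_library",
    "write_library",
    "read_rois",
    "write_rois",
    "read_image",
    "write_image",
    "write_manifest",
]


def _grid_to_dict(grid: WavelengthGrid) -> dict:
    return {
        "start_nm": grid.start_nm,
        "stop_nm": grid.stop_nm,
        "n_bands": grid.n_bands,
    }


def _grid_from_dict(d: dict) -> WavelengthGrid:
    try:
        return WavelengthGrid(float(d["start_nm"]), float(d["stop_nm"]), int(d["n_bands"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"invalid grid metadata: {d!r}") from exc


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_cube(cube: SpectralCube, path: str | Path) -> None:
    """Write a cube as a band-per-page float32 TIFF plus JSON sidecar."""
    path = Path(path)
    meta = {"grid": _grid_to_dict(cube.grid)}
    pages = np.moveaxis(cube.values.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack", description=json.dumps(meta))
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_cube(path: str | Path) -> SpectralCube:
    """Read a cube written by :func:`write_cube`.

    The grid is taken from the TIFF description tag, falling back to the
    sidecar file.

    Raises
    ------
    FormatError
        If no grid metadata is found or the page count does not match it.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    meta = None
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = None
    if not isinstance(meta, dict) or "grid" not in meta:
        sidecar = _sidecar(path)
        if not sidecar.exists():
            raise FormatError(
                f"{path}: no grid metadata in TIFF description and no sidecar "
                f"{sidecar.name}"
            )
        meta = json.loads(sidecar.read_text())
    grid = _grid_from_dict(meta.get("grid", {}))
    if pages.ndim == 2:
        pages = pages[None, :, :]
    if pages.shape[0] != grid.n_bands:
        raise FormatError(
            f"{path}: {pages.shape[0]} TIFF pages but grid declares "
            f"{grid.n_bands} bands"
        )
    return SpectralCube(grid, np.moveaxis(pages.astype(float), 0, 2))


def write_library(library: SpectralLibrary, path: str | Path) -> None:
    """Write a reference library as structured JSON."""
    doc = {
        "grid": _grid_to_dict(library.grid),
        "entries": [
            {"name": name, "values": spec.values.tolist()}
            for name, spec in library.entries
        ],
    }
    if library.background is not None:
        doc["background"] = library.background.values.tolist()
    Path(path).write_text(json.dumps(doc, indent=2))


def read_library(path: str | Path) -> SpectralLibrary:
    try:
        doc = json.loads(Path(path).read_text())
        grid = _grid_from_dict(doc["grid"])
        entries = [
            (e["name"], Spectrum(grid, np.asarray(e["values"], dtype=float)))
            for e in doc["entries"]
        ]
        background = (
            Spectrum(grid, np.asarray(doc["background"], dtype=float))
            if "background" in doc
            else None
        )
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: malformed library file ({exc})") from exc
    try:
        return SpectralLibrary(entries, background)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _roi_to_runs(roi: ROI) -> list[list[int]]:
    """Encode an ROI as [row, col_start, col_stop] runs (stop inclusive)."""
    runs = []
    for row in np.unique(roi.rows):
        cols = np.sort(roi.cols[roi.rows == row])
        breaks = np.flatnonzero(np.diff(cols) > 1)
        starts = np.concatenate([[0], breaks + 1])
        stops = np.concatenate([breaks, [cols.size - 1]])
        for s, e in zip(starts, stops):
            runs.append([int(row), int(cols[s]), int(cols[e])])
    return runs


def write_rois(rois: list[ROI], path: str | Path) -> None:
    """Write ROIs as a JSON list of pixel-run records."""
    doc = [{"label": r.label, "runs": _roi_to_runs(r)} for r in rois]
    Path(path).write_text(json.dumps(doc, indent=2))


def read_rois(path: str | Path) -> list[ROI]:
    try:
        doc = json.loads(Path(path).read_text())
        rois = []
        for rec in doc:
            pixels = [
                (row, col)
                for row, c0, c1 in rec["runs"]
                for col in range(c0, c1 + 1)
            ]
            rois.append(ROI(rec["label"], np.array(pixels, dtype=np.intp)))
        return rois
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: malformed ROI file ({exc})") from exc


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a 2-D image; label images as uint16, others as float32."""
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        tifffile.imwrite(Path(path), image.astype(np.uint16))
    else:
        tifffile.imwrite(Path(path), image.astype(np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_manifest(out_dir: str | Path, config: dict, seed: int | None = None) -> None:
    """Record the exact configuration, seed and versions of a run."""
    from . import __version__

    doc = {
        "config": config,
        "seed": seed,
        "versions": {"spectramix": __version__, "numpy": np.__version__},
    }
    Path(out_dir, "manifest.json").write_text(json.dumps(doc, indent=2, default=str))
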