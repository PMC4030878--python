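"""Region-of-interest definition.

Two routes are provided, mirroring interactive spectral-analysis practice:
seeded region growing on joint intensity / spectral-composition similarity,
and DAPI-guided cell segmentation (nuclei found by Otsu thresholding of the
DAPI reference image, then expanded to cell territories by nearest-nucleus
assignment). Both are fully deterministic.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import expand_labels

from .core import ROI, SpectralCube
from .errors import EmptySeedError
from .unmixing import AbundanceMap

__all__ = ["GrowParams", "grow_roi", "segment_cells", "label_image_to_rois"]


@dataclass(frozen=True)
class GrowParams:
    """Admission rules for seeded region growing.

    ``intensity_tol`` is a fraction of the seed pixel's total intensity;
    ``spectral_tol`` is the maximum spectral angle (radians) between a
    candidate pixel's spectrum and the seed spectrum. Spectral angle is
    brightness-invariant, so the two tolerances control complementary
    aspects of similarity.
    """

    intensity_tol: float = 0.3
    spectral_tol: float = 0.15
    max_area: int = 10_000
    connectivity: int = 4

    def __post_init__(self) -> None:
        if self.intensity_tol <= 0 or self.spectral_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_area < 1:
            raise ValueError("max_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


_OFFSETS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS8 = _OFFSETS4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def grow_roi(
    cube: SpectralCube,
    seed: tuple[int, int],
    params: GrowParams | None = None,
    label: str = "seed",
) -> ROI:
    """Grow a connected ROI from a seed pixel.

    A candidate pixel is admitted when its total intensity is within
    ``intensity_tol`` (relative) of the seed's and the spectral angle to the
    seed spectrum is at most ``spectral_tol``. Admission is breadth-first
    (row-major neighbour order) and stops once ``max_area`` pixels have been
    admitted.

    Raises
    ------
    EmptySeedError
        If the seed pixel has zero total intensity.
    """
    params = params or GrowParams()
    h, w = cube.shape
    r0, c0 = int(seed[0]), int(seed[1])
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError(f"seed {seed} outside image ({h}, {w})")
    totals = cube.values.sum(axis=2)
    seed_total = totals[r0, c0]
    if seed_total <= 0:
        raise EmptySeedError(f"seed pixel {seed} has no signal")
    seed_spec = cube.values[r0, c0]
    seed_norm = np.linalg.norm(seed_spec)

    def admissible(r: int, c: int) -> bool:
        t = totals[r, c]
        if abs(t - seed_total) > params.intensity_tol * seed_total:
            return False
        v = cube.values[r, c]
        nv = np.linalg.norm(v)
        if nv == 0 or seed_norm == 0:
            return False
        cosang = np.clip(v @ seed_spec / (nv * seed_norm), -1.0, 1.0)
        return np.arccos(cosang) <= params.spectral_tol

    offsets = _OFFSETS4 if params.connectivity == 4 else _OFFSETS8
    visited = np.zeros((h, w), dtype=bool)
    visited[r0, c0] = True
    admitted = [(r0, c0)]
    queue = deque([(r0, c0)])
    while queue and len(admitted) < params.max_area:
        r, c = queue.popleft()
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not visited[rr, cc]:
                visited[rr, cc] = True
                if admissible(rr, cc):
                    admitted.append((rr, cc))
                    queue.append((rr, cc))
                    if len(admitted) >= params.max_area:
                        break
    return ROI(label, np.array(admitted, dtype=np.intp))


def segment_cells(
    dapi_image: np.ndarray,
    abundance: AbundanceMap | None = None,
    dilation_px: int = 6,
    min_nucleus_area: int = 20,
) -> list[ROI]:
    """Segment cells from a DAPI nuclear reference image.

    Nuclei are the connected components of the image above its Otsu
    threshold, filtered by ``min_nucleus_area``. Each cell ROI is its
    nucleus expanded by ``dilation_px`` pixels, with contested pixels going
    to the nearest nucleus (ties resolved deterministically toward the lower
    label index). Labels follow the raster order of nucleus centroids. A
    blank image yields an empty list.
    """
    dapi = np.asarray(dapi_image, dtype=float)
    if dapi.ndim != 2:
        raise ValueError("dapi_image must be 2-D")
    if abundance is not None and abundance.shape != dapi.shape:
        raise ValueError(
            f"DAPI image {dapi.shape} does not match abundance {abundance.shape}"
        )
    if np.all(dapi == dapi.flat[0]):
        return []  # blank (constant) image: nothing to segment
    mask = dapi > threshold_otsu(dapi)
    if not mask.any():
        return []
    labels = cc_label(mask, connectivity=1)
    # drop specks, then relabel by raster order of centroids for stability
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_nucleus_area)
    keep = keep[keep != 0]
    if keep.size == 0:
        return []
    centroids = ndimage.center_of_mass(mask, labels, keep)
    order = np.lexsort(
        (np.array([c[1] for c in centroids]), np.array([c[0] for c in centroids]))
    )
    relabel = np.zeros(labels.max() + 1, dtype=np.int32)
    for new, idx in enumerate(order, start=1):
        relabel[keep[idx]] = new
    nuclei = relabel[labels]
    cells = expand_labels(nuclei, distance=dilation_px)
    rois = []
    for lab in range(1, len(order) + 1):
        rows, cols = np.nonzero(cells == lab)
        rois.append(ROI(f"cell{lab:03d}", np.column_stack([rows, cols])))
    return rois


def label_image_to_rois(labels: np.ndarray, prefix: str = "roi") -> list[ROI]:
    """Convert a label image (0 = background) into ROIs, one per label."""
    labels = np.asarray(labels)
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        out.append(ROI(f"{prefix}{int(lab):03d}", np.column_stack([rows, cols])))
    return out
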