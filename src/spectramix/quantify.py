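"""Per-ROI quantification, replicate statistics, classification and
rare-cell detection.

The reporting conventions follow standard fluorescence-integration
practice: an ROI is summarized by its area, the average per-pixel
intensity of each dye, the total (= area x average) and the relative
contribution of each dye as a percent of the ROI's summed dye signal.
Reproducibility across replicate images is expressed as the coefficient of
variation (CV, percent, sample standard deviation over mean) of per-object
per-dye totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ROI
from .errors import InsufficientCellsError, MatchingError
from .unmixing import AbundanceMap

__all__ = [
    "ROIReport",
    "ReplicateStats",
    "CellProfile",
    "roi_report",
    "replicate_stats",
    "match_objects",
    "classify_cells",
    "detect_rare",
    "profiles_from_reports",
    "reports_to_frame",
]


@dataclass
class ROIReport:
    """Quantification of one ROI.

    ``total[d] == area * average[d]`` exactly, and relative contributions
    sum to 100% whenever the ROI has any dye signal. ``degenerate`` marks
    ROIs whose summed dye signal is zero (relative contributions are then
    reported as 0). ``residual_fraction`` is the share of unmodelled signal:
    ``sum(residual) / (sum(residual) + sum(totals))``.
    """

    label: str
    area: int
    average: dict[str, float]
    total: dict[str, float]
    relative_pct: dict[str, float]
    residual_fraction: float
    degenerate: bool = False

    @property
    def dyes(self) -> list[str]:
        return list(self.total)


@dataclass
class ReplicateStats:
    """Cross-replicate reproducibility of per-object per-dye totals.

    CV is 100 x sample standard deviation (ddof=1) / mean, defined only for
    positive means (NaN otherwise). ``per_object`` is indexed by (object
    label, dye).
    """

    per_object: pd.DataFrame  # columns: mean, sd, cv_pct
    cv_min: float
    cv_max: float
    cv_mean: float


@dataclass
class CellProfile:
    """Per-cell dye totals and relative percentages, plus assignment."""

    label: str
    total: dict[str, float]
    relative_pct: dict[str, float]
    population: str = "unassigned"
    rare: bool = False
    true_population: str = ""  # carried from ground truth when known


def roi_report(abundance: AbundanceMap, roi: ROI) -> ROIReport:
    """Integrate an abundance map over one ROI."""
    h, w = abundance.shape
    roi.check_bounds(h, w)
    area = roi.area
    averages = {}
    for k, name in enumerate(abundance.names):
        pixel_sum = float(abundance.coefficients[roi.rows, roi.cols, k].sum())
        averages[name] = pixel_sum / area
    # report total as area x average so the identity holds exactly
    totals = {d: area * a for d, a in averages.items()}
    grand = sum(totals.values())
    resid = float(abundance.residual[roi.rows, roi.cols].sum())
    if grand > 0:
        relative = {d: 100.0 * t / grand for d, t in totals.items()}
        degenerate = False
    else:
        relative = {d: 0.0 for d in totals}
        degenerate = True
    denom = resid + grand
    return ROIReport(
        label=roi.label,
        area=area,
        average=averages,
        total=totals,
        relative_pct=relative,
        residual_fraction=resid / denom if denom > 0 else 0.0,
        degenerate=degenerate,
    )


def match_objects(
    reference: list[tuple[float, float]],
    candidates: list[tuple[float, float]],
    radius_px: float = 10.0,
) -> list[int]:
    """Match reference object centroids to candidate centroids.

    The optimal global translation (difference of centroid means) is removed
    first, then each reference maps to its nearest candidate within
    ``radius_px``. Returns candidate indices, one per reference.

    Raises
    ------
    MatchingError
        If any reference has no candidate within the radius, or two
        references map to the same candidate.
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidates, dtype=float)
    if cand.size == 0:
        raise MatchingError("no candidate objects to match against")
    shift = cand.mean(axis=0) - ref.mean(axis=0)
    out: list[int] = []
    for i, r in enumerate(ref):
        d = np.linalg.norm(cand - (r + shift), axis=1)
        j = int(np.argmin(d))
        if d[j] > radius_px:
            raise MatchingError(
                f"object {i} has no match within {radius_px} px (nearest "
                f"{d[j]:.1f} px)"
            )
        if j in out:
            raise MatchingError(f"objects {out.index(j)} and {i} both match candidate {j}")
        out.append(j)
    return out


def replicate_stats(
    reports: list[list[ROIReport]],
    matching: list[list[int]] | None = None,
) -> ReplicateStats:
    """Cross-replicate CVs of per-object per-dye totals.

    ``reports`` holds one list of ROI reports per replicate; ``matching``
    gives, for each replicate, the report index of each tracked object
    (identity matching by list position when omitted). Requires at least two
    replicates with every object present in each.

    Raises
    ------
    MatchingError
        If an object is missing from a replicate.
    """
    if len(reports) < 2:
        raise ValueError("need at least two replicates")
    n_objects = len(matching[0]) if matching is not None else len(reports[0])
    dyes = reports[0][0].dyes
    rows = []
    for obj in range(n_objects):
        for dye in dyes:
            totals = []
            for rep, rep_reports in enumerate(reports):
                idx = matching[rep][obj] if matching is not None else obj
                if idx >= len(rep_reports):
                    raise MatchingError(f"object {obj} missing in replicate {rep}")
                totals.append(rep_reports[idx].total[dye])
            totals = np.asarray(totals)
            mean = totals.mean()
            sd = totals.std(ddof=1)
            cv = 100.0 * sd / mean if mean > 0 else np.nan
            rows.append(
                {"object": f"obj{obj:03d}", "dye": dye, "mean": mean, "sd": sd, "cv_pct": cv}
            )
    frame = pd.DataFrame(rows).set_index(["object", "dye"])
    cvs = frame["cv_pct"].dropna()
    return ReplicateStats(
        per_object=frame,
        cv_min=float(cvs.min()),
        cv_max=float(cvs.max()),
        cv_mean=float(cvs.mean()),
    )


def profiles_from_reports(
    reports: list[ROIReport], true_populations: dict[str, str] | None = None
) -> list[CellProfile]:
    """Wrap ROI reports as cell profiles (one cell per ROI)."""
    true_populations = true_populations or {}
    return [
        CellProfile(
            label=r.label,
            total=dict(r.total),
            relative_pct=dict(r.relative_pct),
            true_population=true_populations.get(r.label, ""),
        )
        for r in reports
    ]


def classify_cells(
    profiles: list[CellProfile],
    centroids: dict[str, dict[str, float]] | None = None,
    marker: str | None = None,
    marker_threshold_pct: float | None = None,
) -> list[CellProfile]:
    """Assign each cell to a population.

    Centroid rule: nearest population centroid in relative-percent space
    (Euclidean over the dyes named in the centroids); exact ties give
    ``"unassigned"``. Threshold rule: population ``"positive"`` when the
    marker dye's relative percent is at least the threshold, else
    ``"negative"``. Exactly one rule must be supplied. Returns new profiles;
    an empty input yields an empty list.
    """
    if (centroids is None) == (marker is None):
        raise ValueError("supply either centroids or a marker threshold rule")
    out = []
    for p in profiles:
        if centroids is not None:
            dists = {}
            for pop, cent in centroids.items():
                missing = [d for d in cent if d not in p.relative_pct]
                if missing:
                    raise ValueError(f"profile {p.label} lacks dye(s) {missing}")
                dists[pop] = float(
                    np.sqrt(sum((p.relative_pct[d] - v) ** 2 for d, v in cent.items()))
                )
            best = min(dists.values())
            winners = sorted(pop for pop, d in dists.items() if d == best)
            assigned = winners[0] if len(winners) == 1 else "unassigned"
        else:
            if marker not in p.relative_pct:
                raise ValueError(f"profile {p.label} lacks marker dye {marker!r}")
            assigned = (
                "positive"
                if p.relative_pct[marker] >= (marker_threshold_pct or 0.0)
                else "negative"
            )
        out.append(
            CellProfile(
                label=p.label,
                total=dict(p.total),
                relative_pct=dict(p.relative_pct),
                population=assigned,
                rare=p.rare,
                true_population=p.true_population,
            )
        )
    return out


def detect_rare(
    profiles: list[CellProfile],
    target_dye: str,
    elevation_threshold: float = 50.0,
) -> list[str]:
    """Flag cells whose target-dye total exceeds the cohort baseline.

    The baseline is the median of the target dye's totals across all cells
    (robust to the rare cells themselves); a cell is flagged when its total
    is at least ``baseline * (1 + elevation_threshold / 100)``. Requires at
    least five cells.

    Raises
    ------
    InsufficientCellsError
        If fewer than five profiles are supplied.
    """
    if len(profiles) < 5:
        raise InsufficientCellsError(
            f"rare-cell detection needs >= 5 cells, got {len(profiles)}"
        )
    totals = np.array([p.total[target_dye] for p in profiles])
    baseline = float(np.median(totals))
    cut = baseline * (1.0 + elevation_threshold / 100.0)
    return [p.label for p, t in zip(profiles, totals) if t >= cut]


def reports_to_frame(reports: list[ROIReport]) -> pd.DataFrame:
    """Long-format table: one row per (ROI, dye).

    Columns ``area``, ``int`` (average intensity per pixel), ``total`` and
    ``relative_pct`` mirror the conventional ROI report layout.
    """
    rows = []
    for r in reports:
        for dye in r.dyes:
            rows.append(
                {
                    "roi": r.label,
                    "dye": dye,
                    "area": r.area,
                    "int": r.average[dye],
                    "total": r.total[dye],
                    "relative_pct": r.relative_pct[dye],
                    "residual_fraction": r.residual_fraction,
                }
            )
    return pd.DataFrame(rows)
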