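"""Quantification of p16-positive fibroblastic foci on annotated whole-slide images.

A pathologist annotates, on a digitised lung biopsy slide, (a) the lung
parenchyma as one or more polygons (optionally with holes, e.g. around large
airways) and (b) the location of each p16-positive fibroblastic focus as a
point mark.  Given the scanner's microns-per-pixel calibration, this module
turns those annotations into a tissue area in mm², a focus count, a focus
density per 100 mm² of lung tissue, and a dichotomous p16-low / p16-high
class (default cutoff: 2.1 foci per 100 mm²).

Coordinates are 0-based pixel units, x to the right and y down (origin at the
top-left corner), matching common whole-slide annotation exports.  Calibration
is isotropic: a single µm/px value applies to both axes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .errors import InvalidGeometryError, QuantificationError

log = logging.getLogger(__name__)

#: Default density cutoff (foci per 100 mm²) separating p16-low from p16-high.
#: A configuration value, not a constant: `cohort_stats.roc_curve` can re-derive
#: it from outcome data.
DEFAULT_CUTOFF = 2.1

Ring = Sequence[tuple[float, float]]


def ring_area(ring: Ring) -> float:
    """Area in px² of a simple polygon ring by the shoelace formula.

    The ring is implicitly closed (the first vertex need not be repeated) and
    the result is orientation-independent.
    """
    pts = np.asarray(ring, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InvalidGeometryError(
            f"a ring needs at least 3 (x, y) vertices, got shape {pts.shape}"
        )
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2.0)


@dataclass
class FocusMark:
    """A point annotation marking one p16-positive fibroblastic focus."""

    focus_id: str
    location: tuple[float, float]
    note: str | None = None


@dataclass
class TissueRegion:
    """One annotated lung-parenchyma polygon, optionally with holes."""

    outer_ring: Ring
    holes: list[Ring] = field(default_factory=list)

    def __post_init__(self) -> None:
        outer = ring_area(self.outer_ring)
        for hole in self.holes:
            if ring_area(hole) >= outer:
                raise InvalidGeometryError(
                    "hole area must be smaller than its outer ring area"
                )

    def area_px2(self) -> float:
        """Net area in px²: outer ring minus all holes."""
        return ring_area(self.outer_ring) - sum(ring_area(h) for h in self.holes)

    def polygon(self) -> Polygon:
        return Polygon(self.outer_ring, self.holes)

    def bounds(self) -> tuple[float, float, float, float]:
        pts = np.asarray(self.outer_ring, dtype=float)
        return (
            float(pts[:, 0].min()),
            float(pts[:, 1].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].max()),
        )


@dataclass
class CalibratedSlide:
    """Annotation geometry plus µm/px calibration: the unit of quantification."""

    slide_id: str
    microns_per_pixel: float
    tissue_regions: list[TissueRegion] = field(default_factory=list)
    focus_marks: list[FocusMark] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.slide_id:
            raise InvalidGeometryError("slide_id must be non-empty")
        if not self.microns_per_pixel > 0:
            raise InvalidGeometryError(
                f"microns_per_pixel must be > 0, got {self.microns_per_pixel}"
            )
        ids = [m.focus_id for m in self.focus_marks]
        if len(ids) != len(set(ids)):
            raise InvalidGeometryError(f"duplicate focus_id on slide {self.slide_id}")


@dataclass
class SlideQuantification:
    """Per-slide result: count, area, density per 100 mm² and p16 class."""

    slide_id: str
    n_foci: int
    tissue_area_mm2: float
    density: float
    p16_class: str
    n_foci_excluded: int


def _bboxes_overlap(a, b) -> bool:
    return not (a[2] < b[0] or b[2] < a[0] or a[3] < b[1] or b[3] < a[1])


def tissue_area_mm2(slide: CalibratedSlide) -> float:
    """Total annotated tissue area in mm².

    Region areas are summed without polygon union; the input contract forbids
    overlapping tissue annotations, and a warning is emitted when region
    bounding boxes overlap.
    """
    regions = slide.tissue_regions
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            if _bboxes_overlap(regions[i].bounds(), regions[j].bounds()):
                warnings.warn(
                    f"slide {slide.slide_id}: tissue regions {i} and {j} have "
                    "overlapping bounding boxes; areas are summed without union",
                    stacklevel=2,
                )
    area_px2 = sum(r.area_px2() for r in regions)
    return area_px2 * slide.microns_per_pixel**2 / 1e6


def point_in_region(point: tuple[float, float], region: TissueRegion) -> bool:
    """True iff the point lies inside the region (even–odd rule).

    Boundary points count as inside, so marginal subpleural foci sitting
    exactly on the annotation outline are retained.
    """
    return bool(region.polygon().covers(Point(point)))


def classify_density(density: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Dichotomise a focus density: 'low' iff density <= cutoff, else 'high'."""
    if density < 0:
        raise ValueError(f"density must be non-negative, got {density}")
    return "low" if density <= cutoff else "high"


def quantify_slide(
    slide: CalibratedSlide, cutoff: float = DEFAULT_CUTOFF
) -> SlideQuantification:
    """Count in-tissue foci and normalise to foci per 100 mm² of lung tissue.

    Marks falling outside every tissue region are excluded from the count
    (tallied in ``n_foci_excluded`` and logged).  A slide with foci but zero
    annotated tissue area cannot be quantified and raises; a fully empty slide
    quantifies to density 0 with a warning.
    """
    area = tissue_area_mm2(slide)
    inside = 0
    excluded = 0
    for mark in slide.focus_marks:
        if any(point_in_region(mark.location, r) for r in slide.tissue_regions):
            inside += 1
        else:
            excluded += 1
            log.warning(
                "slide %s: focus %s at %s lies outside all tissue regions; excluded",
                slide.slide_id,
                mark.focus_id,
                mark.location,
            )
    if area <= 0:
        if slide.focus_marks:
            raise QuantificationError(
                f"slide {slide.slide_id}: {len(slide.focus_marks)} focus marks "
                "but zero tissue area"
            )
        warnings.warn(
            f"slide {slide.slide_id}: zero tissue area and no foci; density set to 0",
            stacklevel=2,
        )
        density = 0.0
    else:
        density = 100.0 * inside / area
    return SlideQuantification(
        slide_id=slide.slide_id,
        n_foci=inside,
        tissue_area_mm2=area,
        density=density,
        p16_class=classify_density(density, cutoff),
        n_foci_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# GeoJSON I/O
#
# Tissue regions are Polygon features with properties.classification.name ==
# "Tissue"; foci are Point features with classification.name == "Focus".
# Polygonal focus annotations are reduced to their centroid before containment
# testing (a density only needs a count; the centroid rule is deterministic).
# Calibration comes from a top-level "microns_per_pixel" property or the
# `mpp` argument.
# ---------------------------------------------------------------------------


def _classification_name(props: dict) -> str | None:
    cls = props.get("classification")
    if isinstance(cls, dict):
        return cls.get("name")
    if isinstance(cls, str):
        return cls
    return None


def read_geojson(path, mpp: float | None = None, slide_id: str | None = None) -> CalibratedSlide:
    """Read a slide annotation FeatureCollection from a GeoJSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise InvalidGeometryError(f"{path}: not a GeoJSON FeatureCollection")
    mpp = mpp if mpp is not None else doc.get("microns_per_pixel")
    if mpp is None:
        raise InvalidGeometryError(
            f"{path}: no microns_per_pixel property and no --mpp override"
        )
    slide_id = slide_id or doc.get("slide_id") or str(path)
    regions: list[TissueRegion] = []
    marks: list[FocusMark] = []
    n_anon = 0
    for feat in doc.get("features", []):
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        name = _classification_name(props)
        gtype = geom.get("type")
        if name == "Tissue":
            if gtype != "Polygon":
                raise InvalidGeometryError(
                    f"{path}: Tissue feature with geometry type {gtype!r}"
                )
            rings = geom["coordinates"]
            regions.append(
                TissueRegion(
                    outer_ring=[tuple(p) for p in rings[0]],
                    holes=[[tuple(p) for p in hole] for hole in rings[1:]],
                )
            )
        elif name == "Focus":
            if gtype == "Point":
                loc = tuple(geom["coordinates"])
            elif gtype == "Polygon":
                loc = tuple(Polygon(geom["coordinates"][0]).centroid.coords[0])
            else:
                raise InvalidGeometryError(
                    f"{path}: Focus feature with geometry type {gtype!r}"
                )
            n_anon += 1
            marks.append(
                FocusMark(
                    focus_id=props.get("name", f"focus_{n_anon}"),
                    location=loc,
                    note=props.get("note"),
                )
            )
    return CalibratedSlide(
        slide_id=slide_id,
        microns_per_pixel=float(mpp),
        tissue_regions=regions,
        focus_marks=marks,
    )


def write_geojson(slide: CalibratedSlide, path) -> None:
    """Write a slide's annotations back out as a GeoJSON FeatureCollection."""
    features = []
    for region in slide.tissue_regions:
        coords = [[list(p) for p in region.outer_ring]]
        coords += [[list(p) for p in hole] for hole in region.holes]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": coords},
                "properties": {"classification": {"name": "Tissue"}},
            }
        )
    for mark in slide.focus_marks:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(mark.location)},
                "properties": {
                    "classification": {"name": "Focus"},
                    "name": mark.focus_id,
                    **({"note": mark.note} if mark.note else {}),
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "slide_id": slide.slide_id,
        "microns_per_pixel": slide.microns_per_pixel,
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def quantification_table(
    slides: Iterable[CalibratedSlide], cutoff: float = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Quantify each slide and assemble one row per slide."""
    rows = []
    for slide in slides:
        q = quantify_slide(slide, cutoff=cutoff)
        rows.append(
            {
                "slide_id": q.slide_id,
                "n_foci": q.n_foci,
                "n_foci_excluded": q.n_foci_excluded,
                "tissue_area_mm2": q.tissue_area_mm2,
                "density_per_100mm2": q.density,
                "p16_class": q.p16_class,
            }
        )
    return pd.DataFrame(rows)
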