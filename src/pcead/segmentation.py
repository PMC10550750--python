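"""Inference: anomalous pixels to slide-coordinate tumor polygons.

Per test patch the frozen reconstructor, the NERD and the cut-off
threshold produce a boolean anomaly mask; 4-connected components of the
mask are traced to pixel-boundary polygons (vertices on the integer
lattice, half-open pixel convention), shifted to level-0 slide
coordinates, merged across patches by geometric union, and written as a
QuPath-compatible GeoJSON FeatureCollection.

Pixel-boundary tracing (rather than marching-squares midpoints) keeps
polygon area equal to the member-pixel count exactly, which in turn
makes the downstream confusion matrix an integer computation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import shapely.affinity
from scipy import ndimage
from shapely.geometry import Polygon, box, mapping, shape
from shapely.ops import unary_union
from skimage.morphology import closing as _binary_closing, disk

from .anomaly_model import (NERD, CutoffThreshold, binarize, mahalanobis_map,
                            reconstruction_error)
from .wsi_tiling import (Patch, SlideSource, TissueMask, build_resolution_pyramid,
                         compute_tissue_mask, extract_patches)

__all__ = [
    "AnomalyMask", "PolygonSet", "TilingConfig", "mask_to_polygons",
    "merge_patch_polygons", "segment_slide", "write_polygons", "read_polygons",
]

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class AnomalyMask:
    """Boolean anomaly grid for one patch, with its level-0 origin."""

    mask: np.ndarray
    origin: tuple[int, int] = (0, 0)
    slide: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class PolygonSet:
    """Tumor regions as simple polygons in level-0 pixel coordinates."""

    polygons: list[Polygon] = field(default_factory=list)
    slide: str = ""
    role: str = "predicted"            # or "annotated"

    def __post_init__(self):
        cleaned = []
        for p in self.polygons:
            if p.is_empty:
                continue
            if not p.is_valid:
                p = shapely.make_valid(p)
            cleaned.extend(_as_polygons(p))
        self.polygons = cleaned

    @property
    def total_area(self) -> float:
        return float(sum(p.area for p in self.polygons))

    def union(self):
        return unary_union(self.polygons) if self.polygons else Polygon()

    def __len__(self) -> int:
        return len(self.polygons)


def _as_polygons(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    return [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]


@dataclass
class TilingConfig:
    """Inference tiling knobs; sizes and areas are level-0 pixels."""

    patch_size: int = 1024
    min_tissue_fraction: float = 0.5
    thumbnail_downsample: int = 32
    min_area: float = 256.0
    closing_radius: int = 0


def _runs_to_rectangles(mask: np.ndarray) -> list[Polygon]:
    """Row runs of True pixels as unit-height rectangles on the lattice."""
    rects = []
    for y in range(mask.shape[0]):
        row = mask[y]
        if not row.any():
            continue
        padded = np.concatenate([[False], row, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for x0, x1 in zip(starts, ends):
            rects.append(box(float(x0), float(y), float(x1), float(y + 1)))
    return rects


def mask_to_polygons(mask: AnomalyMask | np.ndarray, min_area: float = 0.0,
                     closing_radius: int = 0) -> PolygonSet:
    """Trace 4-connected mask components to pixel-boundary polygons.

    Components smaller than ``min_area`` pixels are dropped; with
    ``closing_radius`` > 0 a morphological closing with a disk of that
    radius is applied first.  Polygons are shifted by the mask's level-0
    origin.  With no closing, each polygon's area equals its component's
    pixel count exactly.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    am = mask if isinstance(mask, AnomalyMask) else AnomalyMask(mask=mask)
    grid = am.mask
    if closing_radius > 0:
        grid = _binary_closing(grid, disk(closing_radius)).astype(bool)
    labels, n = ndimage.label(grid, structure=FOUR_CONNECTED)
    polys = []
    for slc, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        comp = labels[slc] == lab
        if comp.sum() < min_area:
            continue
        geom = unary_union(_runs_to_rectangles(comp))
        dy, dx = slc[0].start, slc[1].start
        geom = shapely.affinity.translate(
            geom, xoff=float(dx + am.origin[0]), yoff=float(dy + am.origin[1]))
        polys.extend(_as_polygons(geom))
    return PolygonSet(polygons=polys, slide=am.slide, role="predicted")


def merge_patch_polygons(parts: list[PolygonSet]) -> PolygonSet:
    """Union per-patch polygon sets into one slide-level set.

    Touching polygons from adjacent patches fuse; duplicates collapse, so
    the merged area never exceeds the sum of the parts.
    """
    parts = [p for p in parts if len(p)]
    if not parts:
        return PolygonSet(polygons=[], slide=parts[0].slide if parts else "")
    slides = {p.slide for p in parts}
    if len(slides) > 1:
        raise ValueError(f"cannot merge polygons from different slides: {slides}")
    merged = unary_union([g for p in parts for g in p.polygons])
    return PolygonSet(polygons=_as_polygons(merged), slide=parts[0].slide,
                      role=parts[0].role)


def segment_slide(slide: SlideSource, model, nerd: NERD,
                  threshold: CutoffThreshold,
                  tiling: TilingConfig | None = None,
                  tissue_mask: TissueMask | None = None) -> PolygonSet:
    """End-to-end inference on one slide.

    Composes tissue masking, patch extraction, reconstruction, per-pixel
    Mahalanobis distances, thresholding, polygonization and cross-patch
    merging.  ``model`` is any reconstructor exposing ``resolution``
    (None = native) and ``reconstruct(Patch) -> Patch``.  Pixels outside
    tissue patches are never predicted anomalous.  When the model works
    below the tiling patch size, masks are computed at model resolution
    and the polygons scaled back to level-0 by the size ratio.
    """
    tiling = tiling or TilingConfig()
    if tissue_mask is None:
        try:
            tissue_mask = compute_tissue_mask(slide, tiling.thumbnail_downsample)
        except Exception as exc:
            raise RuntimeError(
                f"[tissue-mask] slide {slide.identifier}: {exc}") from exc
    parts = []
    for patch in extract_patches(slide, tissue_mask, tiling.patch_size,
                                 tiling.min_tissue_fraction):
        try:
            work = patch
            if model.resolution is not None and model.resolution < patch.level_size:
                work = build_resolution_pyramid(patch, min_size=model.resolution)[-1]
            recon = model.reconstruct(work)
            err = reconstruction_error(work, recon)
            dmap = mahalanobis_map(err, nerd)
            amask = binarize(dmap, threshold)
        except Exception as exc:
            raise RuntimeError(
                f"[reconstruct] slide {slide.identifier} patch {patch.origin}: {exc}"
            ) from exc
        scale = patch.level_size / work.level_size
        local = mask_to_polygons(
            AnomalyMask(mask=amask, origin=(0, 0), slide=slide.identifier),
            min_area=tiling.min_area / (scale * scale),
            closing_radius=tiling.closing_radius)
        polys = [shapely.affinity.affine_transform(
            g, [scale, 0, 0, scale, patch.origin[0], patch.origin[1]])
            for g in local.polygons]
        parts.append(PolygonSet(polygons=polys, slide=slide.identifier))
    merged = merge_patch_polygons(parts) if parts else PolygonSet(
        polygons=[], slide=slide.identifier)
    merged.slide = slide.identifier
    return merged


def write_polygons(pset: PolygonSet, path) -> None:
    """GeoJSON FeatureCollection, one Feature per polygon.

    Coordinates are level-0 (x, y) pixel units per the QuPath convention;
    vertices are written as exact binary64 reprs so a round trip
    preserves them bit-for-bit.
    """
    features = []
    for p in pset.polygons:
        features.append({
            "type": "Feature",
            "geometry": mapping(p),
            "properties": {"slide": pset.slide, "role": pset.role,
                           "area_px": p.area},
        })
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))


def read_polygons(path) -> PolygonSet:
    """Read a (QuPath-compatible) GeoJSON FeatureCollection of polygons."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed GeoJSON in {path}: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a FeatureCollection")
    polys, slide, role = [], "", "annotated"
    for i, feat in enumerate(doc.get("features", [])):
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise ValueError(f"{path}: malformed feature {i}: {exc}") from exc
        got = _as_polygons(geom)
        if not got and not geom.is_empty:
            warnings.warn(f"{path}: feature {i} is not polygonal; skipped",
                          stacklevel=2)
        polys.extend(got)
        props = feat.get("properties") or {}
        slide = props.get("slide", slide)
        role = props.get("role", role)
    # bypass __post_init__ cleaning so vertices survive exactly
    pset = PolygonSet.__new__(PolygonSet)
    pset.polygons = polys
    pset.slide = slide
    pset.role = role
    return pset
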