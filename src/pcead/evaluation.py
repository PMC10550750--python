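"""Pixel-level, polygon-based evaluation of tumor predictions.

Predicted and annotated polygon sets are rasterized over an evaluation
region at a raster downsample, every raster pixel is labeled
independently by pixel-center inclusion, and the four counts follow:
TP inside both polygon sets, FP inside predicted only, FN inside
annotated only, TN inside neither.  Sensitivity TP/(TP+FN),
specificity TN/(TN+FP) and F1 2TP/(2TP+FP+FN) are per-slide; the cohort
report gives their mean and (n-1)-denominator SD over slides where the
metric is defined (0/0 cases carry an explicit undefined marker and are
excluded with a warning).

The TN universe matters: evaluating the whole slide inflates
specificity through the vast whitespace, so the default region is the
tissue bounding box; both conventions are available and recorded.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.prepared import prep

from .segmentation import PolygonSet
from .wsi_tiling import TissueMask

__all__ = [
    "ConfusionCounts", "SlideMetrics", "pixel_confusion", "metrics",
    "slide_level_call", "summarize_cohort", "tissue_bbox", "write_report",
]

# nudge for the half-open convention: a pixel center lying exactly on a
# polygon edge belongs to the polygon on its lower-left side
_EDGE_EPS = 1e-9


@dataclass
class ConfusionCounts:
    """Pixel counts over an evaluation region at a raster downsample."""

    tp: int
    fp: int
    tn: int
    fn: int
    region: tuple[int, int, int, int]   # (x0, y0, x1, y1), half-open
    downsample: int = 1

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class SlideMetrics:
    """Per-slide metrics; None marks an undefined (0/0) value."""

    slide: str
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    positive_call: bool = False


def _raster_membership(pset: PolygonSet, region, downsample):
    x0, y0, x1, y1 = region
    d = downsample
    nx = -(-(x1 - x0) // d)
    ny = -(-(y1 - y0) // d)
    cx = x0 + (np.arange(nx) + 0.5) * d + _EDGE_EPS
    cy = y0 + (np.arange(ny) + 0.5) * d + _EDGE_EPS
    gx, gy = np.meshgrid(cx, cy)
    geom = pset.union()
    if geom.is_empty:
        return np.zeros((ny, nx), dtype=bool)
    return shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(ny, nx)


def pixel_confusion(pred: PolygonSet, truth: PolygonSet,
                    region: tuple[int, int, int, int],
                    downsample: int = 1) -> ConfusionCounts:
    """Rasterize both polygon sets over ``region`` and count TP/FP/TN/FN.

    ``region`` is a half-open level-0 rectangle (x0, y0, x1, y1); a
    raster pixel belongs to a set when its center falls inside the set's
    polygon union.  TP+FP+TN+FN always equals the raster pixel count.
    """
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    x0, y0, x1, y1 = region
    if x1 <= x0 or y1 <= y0:
        raise ValueError("empty evaluation region")
    if pred.slide and truth.slide and pred.slide != truth.slide:
        raise ValueError(f"slide mismatch: {pred.slide!r} vs {truth.slide!r}")
    in_pred = _raster_membership(pred, region, downsample)
    in_truth = _raster_membership(truth, region, downsample)
    return ConfusionCounts(
        tp=int(np.sum(in_pred & in_truth)),
        fp=int(np.sum(in_pred & ~in_truth)),
        fn=int(np.sum(~in_pred & in_truth)),
        tn=int(np.sum(~in_pred & ~in_truth)),
        region=tuple(region),
        downsample=downsample,
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts, slide: str = "") -> SlideMetrics:
    """Sensitivity, specificity and F1 from the pixel counts.

    A 0/0 ratio (e.g. sensitivity on a slide with no annotated tumor)
    yields None rather than a fake number.
    """
    return SlideMetrics(
        slide=slide,
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def slide_level_call(pred: PolygonSet, min_area: float = 0.0) -> bool:
    """Slide-level tumor presence: total predicted area >= min_area.

    With the default min_area the call is positive for any nonempty
    prediction — the slide-level accuracy statistic of the pipeline.
    """
    if not len(pred):
        return False
    return pred.total_area >= min_area


def tissue_bbox(mask: TissueMask) -> tuple[int, int, int, int]:
    """Level-0 bounding box of the tissue mask (half-open)."""
    rows = np.flatnonzero(mask.mask.any(axis=1))
    cols = np.flatnonzero(mask.mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("tissue mask is empty; no bounding box")
    d = mask.downsample
    return (int(cols[0] * d), int(rows[0] * d),
            int((cols[-1] + 1) * d), int((rows[-1] + 1) * d))


def summarize_cohort(per_slide: list[SlideMetrics]) -> dict:
    """Cohort mean +/- SD per metric over slides where it is defined.

    SD uses the n-1 denominator and is None for a single slide; raises
    if a metric is undefined on every slide.
    """
    if not per_slide:
        raise ValueError("no slides to summarize")
    report: dict = {"n_slides": len(per_slide), "metrics": {}, "per_slide": []}
    for name in ("sensitivity", "specificity", "f1"):
        vals = [getattr(m, name) for m in per_slide]
        defined = sorted(v for v in vals if v is not None)
        n_undef = len(vals) - len(defined)
        if not defined:
            raise ValueError(f"{name} undefined on every slide")
        if n_undef:
            warnings.warn(
                f"{name} undefined on {n_undef} slide(s); excluded from the "
                "cohort mean", stacklevel=2)
        arr = np.array(defined)
        report["metrics"][name] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else None,
            "n_defined": int(arr.size),
        }
    for m in sorted(per_slide, key=lambda m: m.slide):
        report["per_slide"].append({
            "slide": m.slide, "sensitivity": m.sensitivity,
            "specificity": m.specificity, "f1": m.f1,
            "positive_call": m.positive_call,
        })
    calls = [m.positive_call for m in per_slide]
    report["n_positive_calls"] = int(sum(calls))
    return report


def write_report(report: dict, out_dir) -> None:
    """Cohort JSON plus a per-slide CSV table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "cohort_report.json").write_text(json.dumps(report, indent=1))
    with open(out / "per_slide_metrics.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["slide", "sensitivity",
                                           "specificity", "f1", "positive_call"])
        w.writeheader()
        for row in report["per_slide"]:
            w.writerow(row)
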