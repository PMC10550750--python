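"""Synthetic pseudo-histology slides with known truth.

Real H&E whole-slide cohorts are proprietary, so every stage of the
pipeline is exercised on generated slides: bright whitespace background,
"normal tissue" as a spatially correlated random color field around an
H&E-like base color, planted anomalous regions whose color/texture
statistics differ by a stated shift, optional on-slide ink strokes, and
paired ground-truth polygons.

The module also provides an oracle reconstructor: a deterministic stand
in for the frozen GAN that reconstructs the normal texture well (it
shrinks the deviation from the assumed base color) and anomalous texture
poorly, isolating Phases 2-3 and inference from GPU-scale training.
Anomalies here are texture/color shifts, not tumor morphology — the
anomaly math downstream is texture-agnostic, so a green end-to-end test
establishes the pipeline's statistics, not histological realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon

from .segmentation import PolygonSet, write_polygons
from .wsi_tiling import ArraySlide, Patch

__all__ = [
    "AnomalySpec", "InkSpec", "SyntheticSlideSpec", "OracleReconstructor",
    "generate_slide", "oracle_reconstruct", "make_cohort",
    "DEFAULT_BASE_COLOR", "DEFAULT_SHIFT_DIRECTION",
]

# H&E-like stroma pink and a shift direction toward a blue-purple tone
DEFAULT_BASE_COLOR = (0.80, 0.58, 0.72)
DEFAULT_SHIFT_DIRECTION = (0.39, -0.84, 0.39)   # unit L2 norm
BACKGROUND_LUMINANCE = 245


def disc_polygon(cx: float, cy: float, r: float, n_vertices: int = 64) -> Polygon:
    """Regular n-gon approximation of a disc (area within 0.2% of pi r^2)."""
    ang = 2 * np.pi * np.arange(n_vertices) / n_vertices
    return Polygon(np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)]))


@dataclass
class AnomalySpec:
    """A planted anomalous region: geometry plus color/texture shift.

    ``color_shift`` is the L2 magnitude of the RGB mean shift applied
    inside the region along ``direction``; ``texture_scale`` multiplies
    the local noise amplitude.
    """

    geometry: Polygon
    color_shift: float = 0.3
    direction: tuple[float, float, float] = DEFAULT_SHIFT_DIRECTION
    texture_scale: float = 1.5


@dataclass
class InkSpec:
    """An on-slide ink stroke (the classic false-positive artifact)."""

    start: tuple[float, float]
    end: tuple[float, float]
    width: float = 8.0
    color: tuple[float, float, float] = (0.10, 0.45, 0.20)   # marker green


@dataclass
class SyntheticSlideSpec:
    """Everything needed to render one pseudo-slide deterministically."""

    size: int = 512
    seed: int = 0
    background_luminance: int = BACKGROUND_LUMINANCE
    base_color: tuple[float, float, float] = DEFAULT_BASE_COLOR
    correlation_length: float = 4.0
    noise_sd: float = 0.03
    tissue_radii: tuple[float, float] = (0.44, 0.41)   # ellipse, fraction of size
    anomalies: list[AnomalySpec] = field(default_factory=list)
    inks: list[InkSpec] = field(default_factory=list)
    identifier: str = "synthetic"

    def __post_init__(self):
        for a in self.anomalies:
            x0, y0, x1, y1 = a.geometry.bounds
            if x0 < 0 or y0 < 0 or x1 > self.size or y1 > self.size:
                raise ValueError(
                    f"anomaly {a.geometry.bounds} outside slide bounds "
                    f"[0, {self.size})^2")


def _correlated_field(rng, size, corr_len):
    raw = rng.standard_normal((size, size))
    f = gaussian_filter(raw, sigma=corr_len, mode="reflect")
    return f / max(f.std(), 1e-12)


def _polygon_mask(poly: Polygon, size: int) -> np.ndarray:
    from shapely import contains_xy

    yy, xx = np.mgrid[0:size, 0:size]
    return contains_xy(poly, xx.ravel() + 0.5, yy.ravel() + 0.5).reshape(size, size)


def render_slide(spec: SyntheticSlideSpec) -> tuple[ArraySlide, PolygonSet]:
    """Render the spec to an in-memory slide and its truth polygons."""
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    bg = spec.background_luminance / 255.0
    img = np.full((s, s, 3), bg, dtype=np.float64)

    # elliptical tissue blob
    yy, xx = np.mgrid[0:s, 0:s]
    cx = cy = (s - 1) / 2.0
    rx, ry = spec.tissue_radii[0] * s, spec.tissue_radii[1] * s
    tissue = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0

    # correlated color noise: one shared field plus per-channel fields
    shared = _correlated_field(rng, s, spec.correlation_length)
    base = np.array(spec.base_color)
    noise = np.empty((s, s, 3))
    for c in range(3):
        own = _correlated_field(rng, s, spec.correlation_length)
        noise[..., c] = spec.noise_sd * (0.7 * shared + 0.714 * own)
    img[tissue] = (base + noise)[tissue]

    truth_polys = []
    for a in spec.anomalies:
        amask = _polygon_mask(a.geometry, s) & tissue
        shift = a.color_shift * np.array(a.direction)
        img[amask] = (base + shift + a.texture_scale * noise)[amask]
        truth_polys.append(a.geometry)

    for ink in spec.inks:
        p0, p1 = np.array(ink.start), np.array(ink.end)
        seg = p1 - p0
        L2 = float(seg @ seg)
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
        t = np.clip(((pts - p0) @ seg) / max(L2, 1e-9), 0, 1)
        d = np.linalg.norm(pts - (p0 + t[:, None] * seg), axis=1).reshape(s, s)
        stroke = d <= ink.width / 2.0
        img[stroke] = ink.color

    img = np.clip(img, 0.0, 1.0)
    pixels = np.round(img * 255.0).astype(np.uint8)
    slide = ArraySlide(identifier=spec.identifier, pixels=pixels)
    truth = PolygonSet(polygons=truth_polys, slide=spec.identifier, role="annotated")
    return slide, truth


def generate_slide(spec: SyntheticSlideSpec, out_dir=None,
                   image_format: str = "tiff") -> tuple[ArraySlide, PolygonSet]:
    """Render a slide and, if ``out_dir`` is given, write image + truth.

    The image is a tiled TIFF (or PNG fallback) named
    ``<identifier>.<ext>``; truth is ``<identifier>.truth.geojson``.
    Output is byte-identical for a fixed spec/seed.
    """
    slide, truth = render_slide(spec)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if image_format == "tiff":
            tile = min(256, spec.size)
            tifffile.imwrite(out / f"{spec.identifier}.tif", slide.pixels,
                             tile=(tile, tile), photometric="rgb")
        elif image_format == "png":
            from PIL import Image

            Image.fromarray(slide.pixels).save(out / f"{spec.identifier}.png")
        else:
            raise ValueError(f"unknown image format {image_format!r}")
        write_polygons(truth, out / f"{spec.identifier}.truth.geojson")
    return slide, truth


@dataclass
class OracleReconstructor:
    """Deterministic stand-in for the frozen GAN.

    Reconstruction model: bright (whitespace) pixels pass through
    unchanged; tissue pixels are reconstructed as the assumed base color
    plus ``shrink`` times a Gaussian-smoothed deviation field, so normal
    texture (small deviations) reconstructs with near-zero error while a
    color-shifted anomaly keeps roughly (1 - shrink) of its shift as
    error.  Interface-compatible with FrozenModel.reconstruct.
    """

    base_color: tuple[float, float, float] = DEFAULT_BASE_COLOR
    bandwidth: float = 2.0
    shrink: float = 0.3
    whitespace_luminance: float = 0.88   # [0, 1] scale
    resolution: int | None = None        # works at native patch size

    def reconstruct(self, patch: Patch) -> Patch:
        img = patch.image
        lum = img @ np.array([0.299, 0.587, 0.114])
        bright = lum >= self.whitespace_luminance
        diff = img - np.array(self.base_color)
        diff[bright] = 0.0
        smooth = np.stack(
            [gaussian_filter(diff[..., c], sigma=self.bandwidth, mode="nearest")
             for c in range(3)], axis=-1)
        recon = np.array(self.base_color) + self.shrink * smooth
        recon[bright] = img[bright]
        recon = np.clip(recon, 0.0, 1.0)
        return Patch(image=recon, slide=patch.slide, origin=patch.origin)


def oracle_reconstruct(patch: Patch, oracle: OracleReconstructor) -> Patch:
    """Functional form of :meth:`OracleReconstructor.reconstruct`."""
    return oracle.reconstruct(patch)


def _largest_remainder(n: int, ratios) -> list[int]:
    r = np.asarray(ratios, dtype=np.float64)
    r = r / r.sum()
    quota = r * n
    base = np.floor(quota).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    # tiny cohorts: every phase with a positive ratio gets at least one slide
    while n >= np.count_nonzero(r) and any(
            b == 0 for b, q in zip(base, r) if q > 0):
        i = int(np.argmax(base))
        j = next(k for k, (b, q) in enumerate(zip(base, r)) if b == 0 and q > 0)
        base[i] -= 1
        base[j] += 1
    return base.tolist()


def make_cohort(n_slides: int, tumor_fraction_range=(0.05, 0.15), seed: int = 0,
                out_dir=None, n_tumor: int | None = None,
                n_normal_inference: int = 0, split=(0.71, 0.14, 0.14),
                slide_size: int = 512, noise_sd: float = 0.03,
                color_shift: float = 0.3, with_ink: bool = False) -> dict:
    """Generate a reproducible cohort of slides with a phase manifest.

    Normal slides are assigned to the three training phases by
    largest-remainder apportionment of ``split`` (the real cohort's
    100/20/20 of 140 normals corresponds to ratios 0.71/0.14/0.14);
    ``n_normal_inference`` normals and every tumor slide go to the
    inference split.  Tumor area fraction (relative to the tissue
    ellipse) is drawn uniformly from ``tumor_fraction_range``; a range of
    (0, 0) — or ``n_tumor`` = 0 — yields an all-normal cohort.  Returns
    the manifest (and writes slides + truth + ``manifest.json`` under
    ``out_dir`` when given).
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    lo, hi = tumor_fraction_range
    if n_tumor is None:
        n_tumor = 0 if hi <= 0 else max(1, int(round(n_slides * 0.5)))
    if n_tumor + n_normal_inference > n_slides:
        raise ValueError("n_tumor + n_normal_inference exceeds n_slides")
    n_normal = n_slides - n_tumor
    n_train_normals = n_normal - n_normal_inference
    phase_counts = _largest_remainder(n_train_normals, split)
    phases = (["phase1"] * phase_counts[0] + ["phase2"] * phase_counts[1]
              + ["phase3"] * phase_counts[2] + ["inference"] * n_normal_inference)

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_slides)
    entries = []
    slides = {}
    for i in range(n_slides):
        rng = np.random.default_rng(children[i])
        slide_seed = int(rng.integers(0, 2**31 - 1))
        is_tumor = i >= n_normal
        ident = f"{'tumor' if is_tumor else 'normal'}_{i:03d}"
        anomalies, frac = [], 0.0
        if is_tumor:
            frac = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            s = slide_size
            rx, ry = 0.44 * s, 0.41 * s
            tissue_area = math.pi * rx * ry
            r = math.sqrt(frac * tissue_area / math.pi)
            # center placed so the disc stays well inside the tissue ellipse
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0, 0.55)
            cx = (s - 1) / 2 + rad * (rx - r) * math.cos(ang)
            cy = (s - 1) / 2 + rad * (ry - r) * math.sin(ang)
            anomalies.append(AnomalySpec(geometry=disc_polygon(cx, cy, r),
                                         color_shift=color_shift))
        inks = []
        if with_ink and is_tumor and i % 2 == 0:
            s = slide_size
            inks.append(InkSpec(start=(0.2 * s, 0.25 * s), end=(0.5 * s, 0.3 * s)))
        spec = SyntheticSlideSpec(size=slide_size, seed=slide_seed,
                                  noise_sd=noise_sd, anomalies=anomalies,
                                  inks=inks, identifier=ident)
        phase = "inference" if is_tumor else phases[i]
        entry = {"slide": ident, "type": "tumor" if is_tumor else "normal",
                 "phase": phase, "tumor_fraction": frac, "seed": slide_seed}
        if out_dir is not None:
            generate_slide(spec, out_dir)
            entry["image"] = f"{ident}.tif"
            entry["truth"] = f"{ident}.truth.geojson"
        else:
            slides[ident] = render_slide(spec)
        entries.append(entry)

    manifest = {"seed": seed, "n_slides": n_slides, "slide_size": slide_size,
                "split": list(split), "slides": entries}
    if out_dir is not None:
        Path(out_dir, "manifest.json").write_text(json.dumps(manifest, indent=1))
    else:
        manifest["rendered"] = slides
    return manifest
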