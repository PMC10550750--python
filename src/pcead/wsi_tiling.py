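"""Tissue detection, patch extraction and the sharded training-record store.

Whole-slide images are mostly bright whitespace; only tissue regions are
worth training on.  This module finds tissue with Otsu's histogram
threshold on a downsampled luminance thumbnail, tiles the tissue into
fixed-size square patches on a non-overlapping grid, builds the
power-of-two resolution pyramid each patch contributes to progressive
training, and persists patches in a sharded, length-delimited binary
record store (image bytes + file name, height, width, channels).

Coordinates are level-0 pixels, 0-based, x = column, y = row; patch
extents are half-open ``[x, x+s) x [y, y+s)``.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "SlideSource",
    "ArraySlide",
    "TissueMask",
    "Patch",
    "DegenerateHistogramError",
    "RecordParseError",
    "otsu_threshold",
    "compute_tissue_mask",
    "extract_patches",
    "build_resolution_pyramid",
    "write_record_shards",
    "read_record_shards",
    "open_slide",
]

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class DegenerateHistogramError(ValueError):
    """All histogram mass sits in one bin: no threshold separates two classes."""


class RecordParseError(ValueError):
    """A record shard is corrupted; carries shard path and record index."""

    def __init__(self, path, index, reason):
        self.path = str(path)
        self.index = index
        super().__init__(f"corrupt record {index} in shard {path}: {reason}")


@dataclass
class ArraySlide:
    """In-memory slide backed by an H x W x 3 uint8 array."""

    identifier: str
    pixels: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.pixels)
        if a.ndim != 3 or a.shape[2] != 3:
            raise ValueError("slide pixels must be H x W x 3 RGB")
        self.pixels = a.astype(np.uint8, copy=False)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def read_region(self, x: int, y: int, w: int, h: int) -> np.ndarray:
        """RGB uint8 values of the level-0 rectangle [x, x+w) x [y, y+h)."""
        if x < 0 or y < 0 or x + w > self.width or y + h > self.height:
            raise ValueError("region outside slide bounds")
        return self.pixels[y : y + h, x : x + w]


# any object with identifier/width/height/read_region works as a slide source
SlideSource = ArraySlide


@dataclass
class TissueMask:
    """Binary tissue grid at a thumbnail downsample factor.

    ``tissue_darker`` is the polarity flag: True means tissue is the class
    below the Otsu threshold (H&E background is bright whitespace).
    """

    mask: np.ndarray
    downsample: int
    threshold: int
    tissue_darker: bool = True

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (0 <= self.threshold <= 255):
            raise ValueError("threshold must be in [0, 255]")


@dataclass
class Patch:
    """Square RGB tile with its slide-coordinate provenance.

    ``image`` holds intensities in [0, 1]; ``size`` is the side length at
    this resolution level (a power of two); ``origin`` is the level-0
    (x, y) of the patch's top-left corner.
    """

    image: np.ndarray
    slide: str
    origin: tuple[int, int]
    size: int = field(default=0)

    def __post_init__(self):
        img = np.asarray(self.image, dtype=np.float64)
        if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] != img.shape[1]:
            raise ValueError("patch image must be square H x H x 3")
        if img.min() < 0 or img.max() > 1:
            raise ValueError("patch intensities must lie in [0, 1]")
        self.image = img
        if not self.size:
            self.size = img.shape[0]

    @property
    def level_size(self) -> int:
        return self.image.shape[0]

    def to_uint8(self) -> np.ndarray:
        return np.round(self.image * 255.0).astype(np.uint8)

    @property
    def file_name(self) -> str:
        x, y = self.origin
        return f"{self.slide}_x{x}_y{y}_s{self.level_size}.png"


def otsu_threshold(histogram: Sequence[int]) -> int:
    """Otsu threshold of a 256-bin intensity histogram.

    Returns the threshold T maximizing the between-class variance of the
    split {v < T} vs {v >= T}; ties are broken by the smallest maximizing
    T so results are deterministic.  T is the lower edge of the upper
    class, so the strict test ``value < T`` selects exactly the lower
    (dark, tissue) class.
    """
    h = np.asarray(histogram, dtype=np.float64)
    if h.shape != (256,) or (h < 0).any():
        raise ValueError("histogram must be 256 non-negative counts")
    total = h.sum()
    if total <= 0:
        raise DegenerateHistogramError("empty histogram")
    if np.count_nonzero(h) < 2:
        raise DegenerateHistogramError("all mass in a single bin")
    bins = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(h)[:-1]            # mass of {v < T} for T = 1..255
    w1 = total - w0
    m0 = np.cumsum(h * bins)[:-1]
    mu_total = (h * bins).sum()
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m0 / w0
        mu1 = (mu_total - m0) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[~valid] = -np.inf
    return int(np.argmax(var_between)) + 1


def luminance(rgb: np.ndarray) -> np.ndarray:
    """8-bit Rec.601 luminance of an H x W x 3 uint8 (or [0,1] float) image."""
    a = np.asarray(rgb, dtype=np.float64)
    if a.max() <= 1.0:
        a = a * 255.0
    return np.round(a @ LUMA_WEIGHTS).clip(0, 255).astype(np.uint8)


def _thumbnail(slide: SlideSource, downsample: int) -> np.ndarray:
    """Block-averaged thumbnail; edge blocks average their partial footprint."""
    px = slide.read_region(0, 0, slide.width, slide.height).astype(np.float64)
    h, w = px.shape[:2]
    d = downsample
    th, tw = -(-h // d), -(-w // d)
    pad_h, pad_w = th * d - h, tw * d - w
    if pad_h or pad_w:
        px = np.pad(px, ((0, pad_h), (0, pad_w), (0, 0)), mode="edge")
    return px.reshape(th, d, tw, d, 3).mean(axis=(1, 3))


def compute_tissue_mask(slide: SlideSource, downsample: int = 32,
                        tissue_darker: bool = True) -> TissueMask:
    """Otsu tissue mask on a luminance thumbnail.

    Tissue is marked where thumbnail luminance is strictly below the Otsu
    threshold (histology background is bright); pass
    ``tissue_darker=False`` for the complementary polarity.
    """
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    lum = luminance(_thumbnail(slide, downsample))
    hist = np.bincount(lum.ravel(), minlength=256)
    t = otsu_threshold(hist)
    mask = lum < t if tissue_darker else lum >= t
    return TissueMask(mask=mask, downsample=downsample, threshold=t,
                      tissue_darker=tissue_darker)


def tissue_fractions(mask: TissueMask, patch_size: int,
                     width: int, height: int) -> np.ndarray:
    """Exact per-grid-cell tissue fraction implied by the thumbnail mask.

    A level-0 pixel (px, py) counts as tissue iff its thumbnail cell
    (px // d, py // d) is true; the fraction is the tissue pixel count of
    the cell divided by patch_size**2.  Computed by accumulating the
    level-0 footprint overlap of every thumbnail cell with every grid
    cell, so it matches a brute-force per-pixel count exactly.
    """
    d = mask.downsample
    ny, nx = height // patch_size, width // patch_size
    frac = np.zeros((ny, nx), dtype=np.float64)
    m = mask.mask
    for gy in range(ny):
        y0, y1 = gy * patch_size, (gy + 1) * patch_size
        r0, r1 = y0 // d, (y1 - 1) // d + 1
        oh = np.minimum((np.arange(r0, r1) + 1) * d, y1) - np.maximum(
            np.arange(r0, r1) * d, y0)
        for gx in range(nx):
            x0, x1 = gx * patch_size, (gx + 1) * patch_size
            c0, c1 = x0 // d, (x1 - 1) // d + 1
            ow = np.minimum((np.arange(c0, c1) + 1) * d, x1) - np.maximum(
                np.arange(c0, c1) * d, x0)
            sub = m[r0:r1, c0:c1]
            frac[gy, gx] = (oh[:, None] * ow[None, :] * sub).sum()
    return frac / float(patch_size * patch_size)


def extract_patches(slide: SlideSource, mask: TissueMask, patch_size: int,
                    min_tissue_fraction: float = 0.5) -> Iterator[Patch]:
    """Yield grid-aligned tissue patches in row-major order.

    The grid is non-overlapping and anchored at (0, 0); a patch is
    emitted when its tissue coverage under ``mask`` is at least
    ``min_tissue_fraction``.
    """
    if not 0 <= min_tissue_fraction <= 1:
        raise ValueError("min_tissue_fraction must be in [0, 1]")
    if patch_size > slide.width or patch_size > slide.height:
        warnings.warn(
            f"patch_size {patch_size} exceeds slide {slide.identifier} "
            f"bounds {slide.width}x{slide.height}; no patches emitted",
            stacklevel=2,
        )
        return
    frac = tissue_fractions(mask, patch_size, slide.width, slide.height)
    ny, nx = frac.shape
    for gy in range(ny):
        for gx in range(nx):
            if frac[gy, gx] >= min_tissue_fraction:
                x, y = gx * patch_size, gy * patch_size
                img = slide.read_region(x, y, patch_size, patch_size)
                yield Patch(image=img.astype(np.float64) / 255.0,
                            slide=slide.identifier, origin=(x, y))


def downsample2(image: np.ndarray, mode: str = "area") -> np.ndarray:
    """Halve a square image by 2x2 area averaging (or nearest-neighbor)."""
    s = image.shape[0]
    if mode == "area":
        return image.reshape(s // 2, 2, s // 2, 2, -1).mean(axis=(1, 3))
    if mode == "nearest":
        return image[::2, ::2]
    raise ValueError(f"unknown downsample mode {mode!r}")


def build_resolution_pyramid(patch: Patch, min_size: int = 4,
                             mode: str = "area") -> list[Patch]:
    """Full power-of-two ladder from the patch's size down to ``min_size``.

    Each level halves the previous one by 2x2 area averaging (matching the
    discriminator's average-pooling convention); slide id and level-0
    origin are carried through unchanged.  Ordered largest to smallest.
    """
    s = patch.level_size
    if s < 4 or (s & (s - 1)) != 0:
        raise ValueError(f"patch size {s} is not a power of two >= 4")
    levels = [patch]
    img = patch.image
    while img.shape[0] > min_size:
        img = downsample2(img, mode=mode)
        levels.append(Patch(image=img, slide=patch.slide, origin=patch.origin))
    return levels


# ---------------------------------------------------------------------------
# Record store: length-delimited binary records, sharded.
#
# record := MAGIC(4) | u32 header_len | header JSON | u64 image_len | bytes
# The header carries the four named fields (file_name, height, width,
# channels) plus level/slide/origin so reads can filter by resolution.
# ---------------------------------------------------------------------------

RECORD_MAGIC = b"PCRD"


def _encode_record(patch: Patch) -> bytes:
    img = patch.to_uint8()
    header = {
        "file_name": patch.file_name,
        "height": int(img.shape[0]),
        "width": int(img.shape[1]),
        "channels": int(img.shape[2]),
        "level": int(patch.level_size),
        "slide": patch.slide,
        "x": int(patch.origin[0]),
        "y": int(patch.origin[1]),
    }
    hb = json.dumps(header, sort_keys=True).encode()
    ib = img.tobytes()
    return RECORD_MAGIC + struct.pack("<I", len(hb)) + hb + struct.pack("<Q", len(ib)) + ib


def write_record_shards(patches: Iterable[Patch], out_dir, shard_size: int = 256) -> list[Path]:
    """Write patches into shards of at most ``shard_size`` records each.

    Shards are grouped by (slide, level) and named
    ``<slide>-<level>-NNNNN.rec``.  Returns the shard paths written.
    """
    if shard_size < 1:
        raise ValueError("shard_size must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    open_shards: dict[tuple[str, int], tuple[Path, list[bytes], int]] = {}
    paths: list[Path] = []

    def _flush(key):
        path, buf, _ = open_shards.pop(key)
        path.write_bytes(b"".join(buf))
        paths.append(path)

    counters: dict[tuple[str, int], int] = {}
    for patch in patches:
        key = (patch.slide, patch.level_size)
        if key not in open_shards:
            idx = counters.get(key, 0)
            counters[key] = idx + 1
            name = f"{patch.slide}-{patch.level_size}-{idx:05d}.rec"
            open_shards[key] = (out_dir / name, [], 0)
        path, buf, n = open_shards[key]
        buf.append(_encode_record(patch))
        open_shards[key] = (path, buf, n + 1)
        if n + 1 >= shard_size:
            _flush(key)
    for key in list(open_shards):
        _flush(key)
    return sorted(paths)


def read_record_shards(paths: Iterable, level: int | None = None) -> Iterator[Patch]:
    """Stream patches back from shards, optionally filtered by level.

    Raises :class:`RecordParseError` naming the shard and record index on
    any framing or payload corruption.
    """
    for path in paths:
        data = Path(path).read_bytes()
        pos, idx = 0, 0
        while pos < len(data):
            try:
                if data[pos : pos + 4] != RECORD_MAGIC:
                    raise ValueError("bad magic")
                pos += 4
                (hlen,) = struct.unpack_from("<I", data, pos)
                pos += 4
                header = json.loads(data[pos : pos + hlen])
                pos += hlen
                (ilen,) = struct.unpack_from("<Q", data, pos)
                pos += 8
                raw = data[pos : pos + ilen]
                pos += ilen
                h, w, c = header["height"], header["width"], header["channels"]
                if len(raw) != h * w * c:
                    raise ValueError("image byte length mismatch")
                img = np.frombuffer(raw, dtype=np.uint8).reshape(h, w, c)
            except RecordParseError:
                raise
            except Exception as exc:
                raise RecordParseError(path, idx, exc) from exc
            if level is None or header["level"] == level:
                yield Patch(image=img.astype(np.float64) / 255.0,
                            slide=header["slide"],
                            origin=(header["x"], header["y"]))
            idx += 1


def open_slide(path) -> ArraySlide:
    """Load a TIFF/PNG slide, or a PNG tile directory with a manifest.

    A tile directory must contain ``manifest.json`` with keys ``width``,
    ``height``, ``tile_size`` and tiles named ``<x>_<y>.png`` (level-0
    pixel origin of each tile).
    """
    path = Path(path)
    if path.is_dir():
        manifest = json.loads((path / "manifest.json").read_text())
        w, h, ts = manifest["width"], manifest["height"], manifest["tile_size"]
        canvas = np.full((h, w, 3), 255, dtype=np.uint8)
        for tile in path.glob("*.png"):
            x, y = (int(v) for v in tile.stem.split("_"))
            arr = np.asarray(Image.open(tile).convert("RGB"))
            canvas[y : y + arr.shape[0], x : x + arr.shape[1]] = arr
        return ArraySlide(identifier=path.name, pixels=canvas)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return ArraySlide(identifier=path.stem, pixels=arr[..., :3])
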