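"""Image / annotation I/O, polygon rasterisation, denoising and splitting.

The polygon fill convention is explicit because annotation tools differ:
a pixel belongs to the mask iff its centre (integer coordinates, origin
top-left) lies strictly inside the polygon by the even-odd rule *or* on its
boundary.  Rasterisation is a vectorised ray cast, so it agrees with a
brute-force point-in-polygon scan by construction.

Non-local-means denoising wraps ``skimage.restoration.denoise_nl_means``;
``h`` is in the intensity units of the image passed in (8-bit counts for
uint8 input, fractional intensity for [0, 1] floats), and the choice is
recorded on the returned parameters object.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.restoration import denoise_nl_means

__all__ = [
    "AnnotatedImage", "NlmParams", "SplitSpec", "labelme_to_mask",
    "polygon_to_mask", "nlm_denoise", "split_dataset", "load_image",
    "save_mask", "load_mask", "load_labelme", "load_annotated",
    "pad_to_multiple", "tile_image", "stitch_tiles",
]

log = logging.getLogger(__name__)


@dataclass
class AnnotatedImage:
    image: np.ndarray
    mask: np.ndarray
    image_path: str | None = None
    annotation_path: str | None = None
    provenance: str = "real"          # "real" | "synthetic"

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask must share spatial shape")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")


@dataclass
class NlmParams:
    """Non-local-means settings; defaults follow common 8-bit practice."""

    h: float = 10.0
    patch_size: int = 7
    search_window: int = 21
    intensity_scale: str | None = None   # recorded by nlm_denoise

    def __post_init__(self):
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 1")
        if self.search_window < self.patch_size or self.search_window % 2 == 0:
            raise ValueError("search_window must be odd and >= patch_size")


@dataclass(frozen=True)
class SplitSpec:
    ratio: tuple[int, int, int] = (14, 3, 3)
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.ratio):
            raise ValueError("ratio components must be positive")


# ---------------------------------------------------------------------------
# rasterisation

def polygon_to_mask(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise one polygon (vertices as (x, y)) to a {0,1} mask.

    Pixel centres strictly inside (even-odd rule) or on the boundary are
    foreground.  Vertices are clipped to the canvas.
    """
    H, W = shape
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    pts[:, 0] = np.clip(pts[:, 0], 0, W - 1e-9)
    pts[:, 1] = np.clip(pts[:, 1], 0, H - 1e-9)
    x0, x1 = int(np.floor(pts[:, 0].min())), min(int(np.ceil(pts[:, 0].max())), W - 1)
    y0, y1 = int(np.floor(pts[:, 1].min())), min(int(np.ceil(pts[:, 1].max())), H - 1)
    x0, y0 = max(x0, 0), max(y0, 0)
    X, Y = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = np.zeros(X.shape, dtype=bool)
    on_edge = np.zeros(X.shape, dtype=bool)
    n = len(pts)
    for i in range(n):
        xa, ya = pts[i]
        xb, yb = pts[(i + 1) % n]
        crosses = (ya > Y) != (yb > Y)
        if crosses.any():
            xint = xa + (Y - ya) * (xb - xa) / (yb - ya)
            inside ^= crosses & (X < xint)
        ex, ey = xb - xa, yb - ya
        elen = np.hypot(ex, ey)
        if elen == 0:
            on_edge |= (X == xa) & (Y == ya)
            continue
        cross = ex * (Y - ya) - ey * (X - xa)
        within = ((X >= min(xa, xb) - 1e-9) & (X <= max(xa, xb) + 1e-9) &
                  (Y >= min(ya, yb) - 1e-9) & (Y <= max(ya, yb) + 1e-9))
        on_edge |= (np.abs(cross) <= 1e-9 * elen) & within
    mask = np.zeros((H, W), dtype=np.uint8)
    mask[y0:y1 + 1, x0:x1 + 1] = (inside | on_edge).astype(np.uint8)
    return mask


def labelme_to_mask(annotation, shape: tuple[int, int]) -> np.ndarray:
    """Union of all polygon shapes in a LabelMe document (dict, JSON string
    or path); degenerate polygons (< 3 vertices) are skipped with a warning."""
    doc = load_labelme(annotation)
    mask = np.zeros(shape, dtype=np.uint8)
    for k, shp in enumerate(doc.get("shapes", [])):
        if shp.get("shape_type", "polygon") != "polygon":
            continue
        pts = shp.get("points", [])
        if len(pts) < 3:
            msg = f"skipping degenerate polygon #{k} with {len(pts)} points"
            warnings.warn(msg, stacklevel=2)
            log.warning(msg)
            continue
        mask |= polygon_to_mask(np.asarray(pts, dtype=float), shape)
    return mask


def load_labelme(annotation) -> dict:
    if isinstance(annotation, dict):
        return annotation
    if isinstance(annotation, (str, Path)) and Path(str(annotation)).exists():
        text = Path(annotation).read_text()
    else:
        text = str(annotation)
    try:
        return json.loads(text)
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed LabelMe JSON: {e}") from e


# ---------------------------------------------------------------------------
# denoising

def nlm_denoise(image: np.ndarray, params: NlmParams | None = None) -> np.ndarray:
    """Non-local-means denoising; output has the input's shape and scale."""
    params = params or NlmParams()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite pixels")
    was_int = img.dtype.kind in "iu"
    work = img.astype(np.float64)
    params.intensity_scale = "8bit" if was_int or work.max() > 1.5 else "normalized"
    out = denoise_nl_means(
        work, h=params.h, patch_size=params.patch_size,
        patch_distance=(params.search_window - 1) // 2,
        fast_mode=True, preserve_range=True)
    if was_int:
        return np.clip(np.round(out), 0, np.iinfo(img.dtype).max).astype(img.dtype)
    return out


# ---------------------------------------------------------------------------
# splitting

def _largest_remainder(n: int, ratio: tuple[int, ...]) -> list[int]:
    total = sum(ratio)
    exact = [n * r / total for r in ratio]
    sizes = [int(np.floor(e)) for e in exact]
    rem = n - sum(sizes)
    order = sorted(range(len(ratio)), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def split_dataset(items: list, spec: SplitSpec | None = None):
    """Seeded shuffle + largest-remainder apportionment into train/val/test."""
    spec = spec or SplitSpec()
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty item list")
    perm = np.random.default_rng(spec.seed).permutation(len(items))
    shuffled = [items[i] for i in perm]
    n_train, n_val, n_test = _largest_remainder(len(items), spec.ratio)
    return (shuffled[:n_train],
            shuffled[n_train:n_train + n_val],
            shuffled[n_train + n_val:])


# ---------------------------------------------------------------------------
# image / mask files

def load_image(path) -> np.ndarray:
    """Read an image as float64 in [0, 1], averaging channels if RGB."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    img = img.astype(np.float64)
    if img.max() > 1.5:
        img = img / 255.0
    return img


def save_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def load_mask(path) -> np.ndarray:
    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[..., 0]
    return (raw > 127).astype(np.uint8)


def load_annotated(image_path, annotation_path, provenance="real") -> AnnotatedImage:
    img = load_image(image_path)
    mask = labelme_to_mask(annotation_path, img.shape)
    return AnnotatedImage(image=img, mask=mask, image_path=str(image_path),
                          annotation_path=str(annotation_path),
                          provenance=provenance)


# ---------------------------------------------------------------------------
# tiling for large images

def pad_to_multiple(image: np.ndarray, divisor: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Edge-pad bottom/right so both spatial dims divide ``divisor``."""
    H, W = image.shape[:2]
    ph = (-H) % divisor
    pw = (-W) % divisor
    if ph == 0 and pw == 0:
        return image, (H, W)
    return np.pad(image, ((0, ph), (0, pw)), mode="edge"), (H, W)


def tile_image(image: np.ndarray, tile: int = 512,
               overlap: int = 64) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Cut overlapping tiles covering the image; each entry is ((y, x), tile)."""
    H, W = image.shape[:2]
    step = tile - overlap
    ys = list(range(0, max(H - tile, 0) + 1, step))
    xs = list(range(0, max(W - tile, 0) + 1, step))
    if not ys or ys[-1] + tile < H:
        ys.append(max(H - tile, 0))
    if not xs or xs[-1] + tile < W:
        xs.append(max(W - tile, 0))
    out = []
    for y in sorted(set(ys)):
        for x in sorted(set(xs)):
            out.append(((y, x), image[y:y + tile, x:x + tile]))
    return out


def stitch_tiles(tiles: list[tuple[tuple[int, int], np.ndarray]],
                 shape: tuple[int, int], overlap: int = 64) -> np.ndarray:
    """Reassemble tile predictions; in overlaps, the tile whose centre is
    closer to the pixel wins (each tile keeps its central region)."""
    out = np.zeros(shape, dtype=float)
    dist = np.full(shape, np.inf)
    for (y, x), t in tiles:
        th, tw = t.shape[:2]
        yy, xx = np.mgrid[0:th, 0:tw]
        d = np.maximum(np.abs(yy - (th - 1) / 2), np.abs(xx - (tw - 1) / 2))
        region = (slice(y, y + th), slice(x, x + tw))
        take = d < dist[region]
        out[region][take] = t[take]
        dist[region][take] = d[take]
    return out
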