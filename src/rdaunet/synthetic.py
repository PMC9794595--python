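"""Synthetic brightfield organoid scenes with exact ground truth.

Real organoid brightfield images show quasi-elliptical bodies with a bright
interior and a dark rim, uneven illumination, blurred boundaries, mutual
adhesion of neighbouring organoids and a busy background of out-of-focus
"ghost" organoids and bubbles.  The generator renders a minimal model of
each of these confounders on a flat canvas:

* organoids are random ellipses (equivalent radius ~ N(mean, sd), bounded
  eccentricity, uniform orientation) with a bright interior and dark rim;
* with probability ``adhesion_prob`` a new organoid is placed touching an
  existing one, so their masks merge into one connected component while the
  catalogue keeps them as separate entries;
* ghosts are low-contrast, heavily blurred rings and bubbles thin
  high-contrast rings -- both rendered into the image but never into the
  ground-truth mask;
* illumination is a smooth low-order polynomial field with a configurable
  peak-to-trough relative amplitude, boundaries are softened with a
  Gaussian blur, and i.i.d. Gaussian noise is added last.

The ground-truth mask is computed by an exact point-in-ellipse test on
pixel centres (row-major, origin top-left, integer pixel centres); pixels
claimed by an earlier organoid are not re-counted, so the catalogued areas
always sum to the mask's foreground count.  Everything is driven by one
integer seed: identical specs give bit-identical scenes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneSpec", "SceneTruth", "OrganoidTruth", "ArtifactTruth",
    "GrowthSeriesSpec", "PlacementError", "make_scene", "make_growth_series",
    "make_dataset", "ellipse_polygon",
]

BACKGROUND = 0.55
INTERIOR_DELTA = 0.18
RIM_DELTA = -0.22
RIM_START = 0.75          # rim occupies normalised radius [RIM_START, 1]
GHOST_DELTA = -0.06
BUBBLE_DELTA = -0.45


class PlacementError(RuntimeError):
    """Raised when organoids cannot be placed within the retry budget."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; the seed makes it reproducible."""

    width: int = 512
    height: int = 512
    n_organoids: int = 40
    radius_mean: float = 9.0
    radius_sd: float = 2.0
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    adhesion_prob: float = 0.15
    n_ghosts: int = 8
    n_bubbles: int = 4
    illumination_gradient: float = 0.15
    noise_sd: float = 0.02
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_organoids, self.n_ghosts, self.n_bubbles) < 0:
            raise ValueError("counts must be >= 0")
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be > 0")
        if not 0.0 <= self.adhesion_prob <= 1.0:
            raise ValueError("adhesion_prob must be in [0, 1]")
        lo, hi = self.eccentricity_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("eccentricity_range must be within [0, 1)")


@dataclass(frozen=True)
class OrganoidTruth:
    id: int
    center: tuple[float, float]       # (x, y) = (col, row)
    axes: tuple[float, float]         # semi-axes (a, b)
    orientation: float                # radians
    area_px: int


@dataclass(frozen=True)
class ArtifactTruth:
    kind: str                         # "ghost" | "bubble"
    center: tuple[float, float]
    radius: float


@dataclass
class SceneTruth:
    mask: np.ndarray                  # uint8 {0,1}, (H, W)
    organoids: list[OrganoidTruth]
    artifacts: list[ArtifactTruth]


@dataclass(frozen=True)
class GrowthSeriesSpec:
    """A group's imaging series across culture days.

    ``growth_rate_per_day`` multiplies the expected organoid *area* per day
    of culture, so the equivalent radius grows by its square root.  Counts
    per image default to the 70-160 range typical of a full-size well image.
    """

    group_label: str = "CTR"
    days: tuple[int, ...] = (1, 3, 5, 7)
    images_per_day: int = 4
    organoids_per_image: tuple[int, int] = (70, 160)
    growth_rate_per_day: float = 1.3
    seed: int = 0
    scene: SceneSpec = field(default_factory=lambda: SceneSpec(
        width=1024, height=768, radius_mean=6.0, radius_sd=1.5))

    def __post_init__(self):
        if not self.days:
            raise ValueError("days must be a nonempty ascending list")
        if list(self.days) != sorted(self.days):
            raise ValueError("days must be sorted ascending")
        if self.growth_rate_per_day <= 0:
            raise ValueError("growth_rate_per_day must be > 0")
        if self.images_per_day < 1:
            raise ValueError("images_per_day must be >= 1")


# ---------------------------------------------------------------------------

def _ellipse_pixels(center, a, b, theta, shape):
    """Boolean bbox patch + offset for pixels whose centres lie in the ellipse."""
    H, W = shape
    cx, cy = center
    rmax = max(a, b)
    x0, x1 = int(np.floor(cx - rmax)), int(np.ceil(cx + rmax)) + 1
    y0, y1 = int(np.floor(cy - rmax)), int(np.ceil(cy + rmax)) + 1
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, W), min(y1, H)
    if x1 <= x0 or y1 <= y0:
        return np.zeros((0, 0), bool), np.zeros((0, 0)), (0, 0)
    X, Y = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    dx, dy = X - cx, Y - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    rho2 = u * u + v * v
    return rho2 <= 1.0, rho2, (y0, x0)


def _sample_axes(rng, spec: SceneSpec, radius_mean=None, radius_sd=None):
    rm = spec.radius_mean if radius_mean is None else radius_mean
    rs = spec.radius_sd if radius_sd is None else radius_sd
    r = max(rng.normal(rm, rs), 2.0)
    lo, hi = spec.eccentricity_range
    e = rng.uniform(lo, hi)
    stretch = (1.0 - e * e) ** 0.25
    return r / stretch, r * stretch, rng.uniform(0.0, np.pi), r


def _illumination(rng, spec: SceneSpec):
    H, W = spec.height, spec.width
    if spec.illumination_gradient == 0:
        return np.ones((H, W))
    Y, X = np.mgrid[0:H, 0:W]
    xn = X / max(W - 1, 1) - 0.5
    yn = Y / max(H - 1, 1) - 0.5
    c = rng.normal(size=5)
    f = c[0] * xn + c[1] * yn + c[2] * xn * yn + c[3] * xn ** 2 + c[4] * yn ** 2
    span = f.max() - f.min()
    if span < 1e-12:
        return np.ones((H, W))
    f = (f - f.min()) / span - 0.5   # in [-0.5, 0.5]
    return 1.0 + spec.illumination_gradient * f


def make_scene(spec: SceneSpec, *, max_tries: int = 200,
               radius_mean: float | None = None,
               radius_sd: float | None = None,
               n_organoids: int | None = None):
    """Render one scene; returns ``(image, truth)`` with image in [0, 1].

    ``radius_mean``/``radius_sd``/``n_organoids`` optionally override the
    spec (used by the growth series without rebuilding specs per day).
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    n_org = spec.n_organoids if n_organoids is None else n_organoids

    placed: list[tuple[float, float, float]] = []   # (cx, cy, r)
    params = []
    for _ in range(n_org):
        a, b, theta, r = _sample_axes(rng, spec, radius_mean, radius_sd)
        for attempt in range(max_tries):
            adhere = placed and rng.random() < spec.adhesion_prob
            if adhere:
                ox, oy, orad = placed[rng.integers(len(placed))]
                ang = rng.uniform(0, 2 * np.pi)
                d = (r + orad) * rng.uniform(0.7, 0.95)
                cx, cy = ox + d * np.cos(ang), oy + d * np.sin(ang)
                if not (0 <= cx < W and 0 <= cy < H):
                    continue
            else:
                cx = rng.uniform(r, max(W - r, r + 1e-9))
                cy = rng.uniform(r, max(H - r, r + 1e-9))
                clear = all((cx - ox) ** 2 + (cy - oy) ** 2 > (1.05 * (r + orad)) ** 2
                            for ox, oy, orad in placed)
                if not clear:
                    continue
            placed.append((cx, cy, r))
            params.append((cx, cy, a, b, theta))
            break
        else:
            raise PlacementError(
                f"could not place organoid {len(placed) + 1}/{n_org} on a "
                f"{W}x{H} canvas after {max_tries} tries; reduce n_organoids "
                "or radius_mean")

    claimed = np.full((H, W), -1, dtype=np.int32)
    image = BACKGROUND * np.ones((H, W))
    organoids = []
    for k, (cx, cy, a, b, theta) in enumerate(params):
        inside, rho2, (y0, x0) = _ellipse_pixels((cx, cy), a, b, theta, (H, W))
        sub = claimed[y0:y0 + inside.shape[0], x0:x0 + inside.shape[1]]
        new = inside & (sub == -1)
        sub[new] = k
        rho = np.sqrt(rho2)
        patch = image[y0:y0 + inside.shape[0], x0:x0 + inside.shape[1]]
        patch[inside & (rho < RIM_START)] = BACKGROUND + INTERIOR_DELTA
        patch[inside & (rho >= RIM_START)] = BACKGROUND + RIM_DELTA
        organoids.append(OrganoidTruth(
            id=k, center=(float(cx), float(cy)), axes=(float(a), float(b)),
            orientation=float(theta), area_px=int(new.sum())))
    mask = (claimed >= 0).astype(np.uint8)

    if spec.blur_sigma > 0:
        image = gaussian_filter(image, spec.blur_sigma)

    artifacts = []
    ghost_layer = np.zeros((H, W))
    for _ in range(spec.n_ghosts):
        r = spec.radius_mean * rng.uniform(0.8, 1.6)
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        inside, rho2, (y0, x0) = _ellipse_pixels((cx, cy), r, r, 0.0, (H, W))
        rho = np.sqrt(rho2)
        band = inside & (rho >= 0.7)
        ghost_layer[y0:y0 + band.shape[0], x0:x0 + band.shape[1]][band] = GHOST_DELTA
        artifacts.append(ArtifactTruth("ghost", (float(cx), float(cy)), float(r)))
    if spec.n_ghosts:
        image = image + gaussian_filter(ghost_layer, 3.0 * spec.blur_sigma + 1.0)

    for _ in range(spec.n_bubbles):
        r = spec.radius_mean * rng.uniform(0.4, 0.9)
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        inside, rho2, (y0, x0) = _ellipse_pixels((cx, cy), r, r, 0.0, (H, W))
        rho = np.sqrt(rho2)
        ring = inside & (rho >= 0.8)
        image[y0:y0 + ring.shape[0], x0:x0 + ring.shape[1]][ring] = (
            BACKGROUND + BUBBLE_DELTA)
        artifacts.append(ArtifactTruth("bubble", (float(cx), float(cy)), float(r)))

    image = image * _illumination(rng, spec)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=(H, W))
    image = np.clip(image, 0.0, 1.0)
    return image, SceneTruth(mask=mask, organoids=organoids, artifacts=artifacts)


def make_growth_series(spec: GrowthSeriesSpec) -> list[tuple[int, np.ndarray, SceneTruth]]:
    """Scenes for every (day, replicate); per-day expected area follows
    ``growth_rate_per_day ** (day - days[0])``."""
    out = []
    d0 = spec.days[0]
    for day in spec.days:
        area_factor = spec.growth_rate_per_day ** (day - d0)
        rfac = float(area_factor ** 0.5)  # radius scales with sqrt(area)
        for i in range(spec.images_per_day):
            scene_seed = int(np.random.SeedSequence(
                [spec.seed, int(day), i]).generate_state(1)[0] % (2 ** 31))
            sub = replace(spec.scene, seed=scene_seed)
            rng = np.random.default_rng(scene_seed + 1)
            n = int(rng.integers(spec.organoids_per_image[0],
                                 spec.organoids_per_image[1] + 1))
            image, truth = make_scene(
                sub,
                radius_mean=spec.scene.radius_mean * rfac,
                radius_sd=spec.scene.radius_sd * rfac,
                n_organoids=n)
            out.append((day, image, truth))
    return out


# ---------------------------------------------------------------------------
# dataset export (images + LabelMe-style polygon JSON + masks + manifest)

def ellipse_polygon(org: OrganoidTruth, n_points: int = 72) -> np.ndarray:
    """(x, y) vertices tracing the organoid's boundary."""
    t = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    a, b = org.axes
    ct, st = np.cos(org.orientation), np.sin(org.orientation)
    x = org.center[0] + a * np.cos(t) * ct - b * np.sin(t) * st
    y = org.center[1] + a * np.cos(t) * st + b * np.sin(t) * ct
    return np.stack([x, y], axis=1)


def _labelme_document(truth: SceneTruth, shape: tuple[int, int],
                      image_path: str) -> dict:
    H, W = shape
    shapes = []
    for org in truth.organoids:
        pts = ellipse_polygon(org)
        pts[:, 0] = np.clip(pts[:, 0], 0, W - 1e-3)
        pts[:, 1] = np.clip(pts[:, 1], 0, H - 1e-3)
        shapes.append({
            "label": "organoid",
            "points": [[float(x), float(y)] for x, y in pts],
            "group_id": org.id,
            "shape_type": "polygon",
            "flags": {},
        })
    return {"version": "5.2.1", "flags": {}, "shapes": shapes,
            "imagePath": image_path, "imageData": None,
            "imageHeight": H, "imageWidth": W}


def make_dataset(n_images: int, template: SceneSpec, out_dir,
                 seed: int = 0) -> pd.DataFrame:
    """Write ``n_images`` scenes as 8-bit PNGs with LabelMe-style JSON
    annotations and {0,255} mask PNGs; returns (and writes) the manifest."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_images):
        scene_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                         % (2 ** 31))
        spec = replace(template, seed=scene_seed)
        image, truth = make_scene(spec)
        stem = f"scene_{i:04d}"
        img_path = out_dir / f"{stem}.png"
        ann_path = out_dir / f"{stem}.json"
        mask_path = out_dir / f"{stem}_mask.png"
        iio.imwrite(img_path, np.round(image * 255).astype(np.uint8))
        iio.imwrite(mask_path, (truth.mask * 255).astype(np.uint8))
        doc = _labelme_document(truth, truth.mask.shape, img_path.name)
        ann_path.write_text(json.dumps(doc))
        rows.append({"image": img_path.name, "annotation": ann_path.name,
                     "mask": mask_path.name, "seed": scene_seed,
                     "n_organoids": len(truth.organoids)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
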