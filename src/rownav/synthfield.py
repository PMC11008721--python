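"""Synthetic maize-field scene generation with exact ground truth.

Real crop-row imagery of the kind this toolkit targets — forward-facing
views of two converging seedling rows on soil, shot under daylight or
artificial night lighting — is emulated here by a parametric generator:
green Gaussian-profile blobs placed at fixed spacing along two known row
lines over a textured soil background, with optional missing-plant gaps,
off-row weed blobs, centre jitter, and a multiplicative axial illumination
falloff that mimics distance from a floodlight.  Every scene carries its
ground truth (boxes, row lines, navigation line, gap positions), so the
enhancement, fitting and evaluation stages can be tested end to end without
any field data.

The module also provides the six single-image augmentation operations
(colour, brightness, contrast, noise, rotation, mirroring) used to expand a
dataset sevenfold, the 2x2 mosaic composite, and an 8:1:1 train/val/test
splitter.  All operations are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .rowfit import Detection, FittedLine, NavigationLine, navigation_line

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "AugmentOp",
    "generate_scene",
    "perturb_detections",
    "augment_image",
    "mosaic_composite",
    "default_augment_ops",
    "expand_dataset",
    "split_dataset",
]

SOIL_RGB = (0.30, 0.22, 0.15)
PLANT_RGB = (0.10, 0.45, 0.12)
WEED_RGB = (0.08, 0.30, 0.10)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and photometry of a synthetic two-row field scene.

    Row lines are given by their x-position at the top (y=0) and bottom
    (y=height) image edges; rows converge toward the top as in a forward
    camera view.  ``spacing`` is the vertical plant separation along a row
    (must exceed the blob diameter), ``gap_*`` list plant indices omitted to
    create missing-plant gaps, ``jitter_sigma`` perturbs true plant centres,
    ``illum_min`` is the top-edge illumination multiplier (1 = flat light).
    """

    width: int = 640
    height: int = 640
    n_plants: int = 20
    spacing: float = 28.0
    plant_radius: float = 10.0
    y_start: float = 48.0
    left_top_x: float = 269.0
    left_bottom_x: float = 205.0
    right_top_x: float = 371.0
    right_bottom_x: float = 435.0
    gap_left: tuple[int, ...] = ()
    gap_right: tuple[int, ...] = ()
    weed_count: int = 0
    jitter_sigma: float = 0.0
    illum_min: float = 1.0
    soil_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 2 * self.plant_radius:
            raise ValueError("spacing must exceed the plant diameter (blobs would overlap)")
        if not 0 < self.illum_min <= 1:
            raise ValueError("illum_min must lie in (0, 1]")

    def row_line(self, side: str) -> FittedLine:
        """True row line in y = mx + b form."""
        top = self.left_top_x if side == "left" else self.right_top_x
        bot = self.left_bottom_x if side == "left" else self.right_bottom_x
        if top == bot:
            raise ValueError("exactly vertical ground-truth rows are not representable")
        m = self.height / (bot - top)
        return FittedLine(m=m, b=-m * top, form="y_of_x", n_points=self.n_plants)


@dataclass
class SyntheticScene:
    image: np.ndarray
    gt_boxes: list[Detection]
    gt_left: FittedLine
    gt_right: FittedLine
    gt_nav: NavigationLine
    gap_truth: dict[str, tuple[int, ...]]
    config: SceneConfig


def _splat_blob(img: np.ndarray, cx: float, cy: float, radius: float,
                rgb: tuple[float, float, float]) -> None:
    """Additively draw a Gaussian-profile blob (sigma = radius/2) in place."""
    H, W, _ = img.shape
    r = int(math.ceil(3 * radius))
    y0, y1 = max(0, int(cy) - r), min(H, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(W, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    profile = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * (radius / 2.0) ** 2))
    for c in range(3):
        img[y0:y1, x0:x1, c] += rgb[c] * profile


def _row_x_of_y(cfg: SceneConfig, side: str, y: float) -> float:
    top = cfg.left_top_x if side == "left" else cfg.right_top_x
    bot = cfg.left_bottom_x if side == "left" else cfg.right_bottom_x
    return top + (bot - top) * y / cfg.height


def generate_scene(cfg: SceneConfig | None = None) -> SyntheticScene:
    """Render a two-row scene and its ground truth, deterministically per seed."""
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.height, cfg.width
    img = np.empty((H, W, 3))
    for c, v in enumerate(SOIL_RGB):
        img[:, :, c] = v
    img += rng.normal(0.0, cfg.soil_noise, (H, W, 1))

    boxes: list[Detection] = []
    side_r = cfg.plant_radius
    for side, gaps in (("left", cfg.gap_left), ("right", cfg.gap_right)):
        for i in range(cfg.n_plants):
            if i in gaps:
                continue
            y = cfg.y_start + i * cfg.spacing
            x = _row_x_of_y(cfg, side, y)
            if cfg.jitter_sigma > 0:
                x += rng.normal(0.0, cfg.jitter_sigma)
                y += rng.normal(0.0, cfg.jitter_sigma)
            _splat_blob(img, x, y, side_r, PLANT_RGB)
            boxes.append(Detection(x - side_r, y - side_r, x + side_r, y + side_r))

    line_l, line_r = cfg.row_line("left"), cfg.row_line("right")
    for _ in range(cfg.weed_count):
        # off-row clutter: rejection-sample a spot > 3 radii from both rows
        for _attempt in range(100):
            wy = rng.uniform(0.08 * H, 0.92 * H)
            wx = rng.uniform(0.08 * W, 0.92 * W)
            if (abs(wx - _row_x_of_y(cfg, "left", wy)) > 3 * side_r
                    and abs(wx - _row_x_of_y(cfg, "right", wy)) > 3 * side_r):
                break
        _splat_blob(img, wx, wy, 0.5 * side_r, WEED_RGB)

    if cfg.illum_min < 1.0:
        mult = cfg.illum_min + (1.0 - cfg.illum_min) * (np.arange(H) / (H - 1))
        img *= mult[:, None, None]
    np.clip(img, 0.0, 1.0, out=img)

    return SyntheticScene(
        image=img, gt_boxes=boxes, gt_left=line_l, gt_right=line_r,
        gt_nav=navigation_line(line_l, line_r),
        gap_truth={"left": cfg.gap_left, "right": cfg.gap_right},
        config=cfg,
    )


def perturb_detections(
    scene: SyntheticScene,
    sigma_center: float = 0.0,
    p_miss: float = 0.0,
    n_false: int = 0,
    seed: int = 0,
) -> list[Detection]:
    """Turn ground-truth boxes into imperfect detector output.

    Each box centre is jittered by an isotropic Gaussian, each box is dropped
    independently with probability ``p_miss``, and ``n_false`` clutter boxes
    are placed uniformly in the central corridor of the image.  Confidences
    are drawn uniformly in (0.3, 1.0).
    """
    if not 0 <= p_miss <= 1:
        raise ValueError("p_miss must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cfg = scene.config
    out: list[Detection] = []
    for b in scene.gt_boxes:
        if rng.random() < p_miss:
            continue
        dx = rng.normal(0.0, sigma_center) if sigma_center > 0 else 0.0
        dy = rng.normal(0.0, sigma_center) if sigma_center > 0 else 0.0
        out.append(Detection(b.x1 + dx, b.y1 + dy, b.x2 + dx, b.y2 + dy,
                             confidence=float(rng.uniform(0.3, 1.0))))
    r = cfg.plant_radius
    for _ in range(n_false):
        fx = rng.uniform(0.06 * cfg.width, 0.94 * cfg.width)
        fy = rng.uniform(0.06 * cfg.height, 0.94 * cfg.height)
        out.append(Detection(fx - r, fy - r, fx + r, fy + r,
                             confidence=float(rng.uniform(0.3, 1.0))))
    return out


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

SINGLE_IMAGE_OPS = ("color", "brightness", "contrast", "noise", "rotation", "mirror")


@dataclass(frozen=True)
class AugmentOp:
    """One augmentation operation; parameters not given are drawn from seed."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SINGLE_IMAGE_OPS + ("mosaic",):
            raise ValueError(f"unknown augmentation kind {self.kind!r}")


def _op_rng(op: AugmentOp) -> np.random.Generator:
    return np.random.default_rng(op.seed)


def augment_image(img, op: AugmentOp) -> np.ndarray:
    """Apply one augmentation; result clamped to [0, 1], deterministic per seed.

    color      : per-channel additive shift (default drawn in ±10/255)
    brightness : global additive offset (default drawn in ±0.15)
    contrast   : gain about the image mean (default 0.8 or 1.2)
    noise      : additive Gaussian, sigma 0.02
    rotation   : fixed-angle rotation (default drawn in ±10°), border fill
    mirror     : horizontal flip
    mosaic     : 2x2 composite of exactly four images (pass a list)
    """
    if op.kind == "mosaic":
        return mosaic_composite(img, size=op.params.get("size", (640, 640)))
    img = np.asarray(img, dtype=float)
    rng = _op_rng(op)
    if op.kind == "color":
        shift = op.params.get("shift")
        if shift is None:
            shift = rng.uniform(-10 / 255, 10 / 255, 3)
        out = img + np.asarray(shift)[None, None, :]
    elif op.kind == "brightness":
        off = op.params.get("offset")
        if off is None:
            off = float(rng.uniform(-0.15, 0.15))
        out = img + off
    elif op.kind == "contrast":
        gain = op.params.get("gain")
        if gain is None:
            gain = float(rng.choice([0.8, 1.2]))
        out = img.mean() + gain * (img - img.mean())
    elif op.kind == "noise":
        sigma = op.params.get("sigma", 0.02)
        out = img + rng.normal(0.0, sigma, img.shape)
    elif op.kind == "rotation":
        angle = op.params.get("angle_deg")
        if angle is None:
            angle = float(rng.uniform(-10.0, 10.0))
        if angle == 0.0:
            return img.copy()
        out = ndimage.rotate(img, angle, axes=(1, 0), reshape=False,
                             order=1, mode="nearest")
    elif op.kind == "mirror":
        out = img[:, ::-1, :].copy()
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(op.kind)
    return np.clip(out, 0.0, 1.0)


def _resize(img: np.ndarray, h: int, w: int) -> np.ndarray:
    zoom = (h / img.shape[0], w / img.shape[1], 1.0)
    return ndimage.zoom(img, zoom, order=1)


def mosaic_composite(imgs, size: tuple[int, int] = (640, 640)) -> np.ndarray:
    """2x2 mosaic of four images, each resized to a quadrant of ``size``."""
    if len(imgs) != 4:
        raise ValueError(f"mosaic requires exactly 4 input images, got {len(imgs)}")
    W, H = size
    hh, ww = H // 2, W // 2
    tiles = [_resize(np.asarray(im, dtype=float), hh, ww) for im in imgs]
    top = np.concatenate(tiles[:2], axis=1)
    bottom = np.concatenate(tiles[2:], axis=1)
    return np.clip(np.concatenate([top, bottom], axis=0), 0.0, 1.0)


def default_augment_ops(seed: int = 0) -> list[AugmentOp]:
    """The six single-image operations, each with its own derived seed."""
    return [AugmentOp(kind=k, seed=seed * 6 + i)
            for i, k in enumerate(SINGLE_IMAGE_OPS)]


def expand_dataset(images: list, ops: list[AugmentOp] | None = None,
                   seed: int = 0) -> list[np.ndarray]:
    """Sevenfold expansion: originals plus one variant per operation per image."""
    if not images:
        raise ValueError("cannot expand an empty dataset")
    if ops is None:
        ops = default_augment_ops(seed)
    kinds = sorted(op.kind for op in ops)
    if kinds != sorted(SINGLE_IMAGE_OPS):
        raise ValueError("expansion requires exactly the six single-image operations")
    out = [np.asarray(im, dtype=float) for im in images]
    for op in ops:
        for i, im in enumerate(images):
            out.append(augment_image(im, replace(op, seed=op.seed + 7919 * i)))
    return out


def split_dataset(items: list, ratios: tuple[int, int, int] = (8, 1, 1),
                  seed: int = 0) -> tuple[list, list, list]:
    """Shuffled train/val/test split by largest-remainder apportionment."""
    if min(ratios) <= 0:
        raise ValueError("ratios must be positive")
    n = len(items)
    if n < 3:
        raise ValueError("need at least 3 items to split three ways")
    total = sum(ratios)
    quota = [n * r / total for r in ratios]
    sizes = [int(q) for q in quota]
    rema = [q - s for q, s in zip(quota, sizes)]
    for i in sorted(range(3), key=lambda i: -rema[i])[: n - sum(sizes)]:
        sizes[i] += 1
    idx = np.random.default_rng(seed).permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    return ([items[i] for i in idx[:a]],
            [items[i] for i in idx[a:b]],
            [items[i] for i in idx[b:]])
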