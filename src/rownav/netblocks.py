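"""Training-free reference implementations of detection-network building blocks.

Deterministic tensor operations (numpy, channels-first C×H×W) covering the
blocks a lightweight single-stage crop detector composes — efficient channel
attention (ECA), coordinate attention (CA), fast spatial pyramid pooling
(SPPF), the Focus space-to-depth stem — plus the CIoU bounding-box
regression loss and the composite detection loss.  No training happens here:
parameters of the attention forwards are drawn deterministically from a seed
so that structural properties (shapes, monotonicity, attenuation) can be
verified exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BoxCWH",
    "CIoUTerms",
    "LossBatch",
    "eca_kernel_size",
    "eca_forward",
    "make_ca_params",
    "ca_forward",
    "sppf_forward",
    "focus_slice",
    "ciou_loss",
    "composite_loss",
]

_EPS = 1e-12


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _validate_tensor(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 3:
        raise ValueError(f"expected a CxHxW tensor, got shape {t.shape}")
    if not np.all(np.isfinite(t)):
        raise ValueError("tensor contains non-finite values")
    return t


# ---------------------------------------------------------------------------
# Efficient channel attention
# ---------------------------------------------------------------------------

def eca_kernel_size(c_in: int) -> int:
    """Adaptive 1D kernel size k = |(log2(C_in) + 1) / 2|_odd.

    Nearest odd integer; an exact midpoint between two odd numbers rounds to
    the larger.  Minimum kernel size is 1.
    """
    if c_in < 1:
        raise ValueError("channel count must be >= 1")
    t = (math.log2(c_in) + 1.0) / 2.0
    lo = 2 * math.floor((t - 1.0) / 2.0) + 1   # largest odd <= t (or t itself)
    hi = lo + 2
    k = lo if (t - lo) < (hi - t) else hi
    return max(1, k)


def eca_forward(t: np.ndarray, kernel: np.ndarray | None = None) -> np.ndarray:
    """Efficient channel attention: recalibrate channels from their means.

    Global average pooling gives one statistic per channel; a circularly
    padded 1D convolution of length k mixes each channel with its k-1
    neighbours; a sigmoid maps the result to a scale in (0, 1) that
    multiplies the channel.
    """
    t = _validate_tensor(t)
    C = t.shape[0]
    if kernel is None:
        k = eca_kernel_size(C)
        kernel = np.full(k, 1.0 / k)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or kernel.size % 2 == 0:
        raise ValueError("kernel must be a 1D array of odd length")
    means = t.mean(axis=(1, 2))
    half = kernel.size // 2
    padded = np.concatenate([means[-half:], means, means[:half]]) if half else means
    mixed = np.convolve(padded, kernel[::-1], mode="valid")
    scales = _sigmoid(mixed)
    return t * scales[:, None, None]


# ---------------------------------------------------------------------------
# Coordinate attention
# ---------------------------------------------------------------------------

@dataclass
class CAParams:
    """Weights of the coordinate-attention 1x1 convolutions.

    w_mix : (C_r, C) shared mixing conv applied to the concatenated pooled
            descriptors; w_h / w_w : (C, C_r) per-branch convs producing the
            height and width attention maps.
    """

    w_mix: np.ndarray
    w_h: np.ndarray
    w_w: np.ndarray


def make_ca_params(channels: int, reduction: int = 4, seed: int = 0,
                   zero: bool = False) -> CAParams:
    """Deterministic (seeded) parameters for the CA reference forward.

    ``zero=True`` yields pass-through convs (all-zero weights), under which
    both attention maps are sigmoid(0) = 0.5 everywhere and the block scales
    its input by exactly 0.25.
    """
    if reduction < 1:
        raise ValueError("reduction must be >= 1")
    if reduction > channels:
        raise ValueError("reduction ratio exceeds channel count")
    c_r = max(1, math.ceil(channels / reduction))
    if zero:
        return CAParams(np.zeros((c_r, channels)), np.zeros((channels, c_r)),
                        np.zeros((channels, c_r)))
    rng = np.random.default_rng(seed)
    scale = 1.0 / math.sqrt(channels)
    return CAParams(
        w_mix=rng.normal(0.0, scale, (c_r, channels)),
        w_h=rng.normal(0.0, scale, (channels, c_r)),
        w_w=rng.normal(0.0, scale, (channels, c_r)),
    )


def ca_forward(t: np.ndarray, params: CAParams) -> np.ndarray:
    """Coordinate attention: factorised spatial attention with positional cues.

    Average pooling along the width (kernel 1xW) and along the height (Hx1)
    yields per-row and per-column channel descriptors; they are concatenated
    along the spatial axis, mixed by a shared 1x1 conv to C/r channels (ReLU),
    split back, expanded by per-branch 1x1 convs, and squashed by sigmoids
    into attention factors a_h(y), a_w(x) in (0, 1) that multiply the input:

        out[c, y, x] = in[c, y, x] * a_h[c, y] * a_w[c, x]
    """
    t = _validate_tensor(t)
    C, H, W = t.shape
    if params.w_mix.shape[1] != C:
        raise ValueError("parameter shape does not match channel count")
    pool_h = t.mean(axis=2)            # (C, H): pooled over width
    pool_w = t.mean(axis=1)            # (C, W): pooled over height
    cat = np.concatenate([pool_h, pool_w], axis=1)   # (C, H+W)
    mixed = np.maximum(params.w_mix @ cat, 0.0)      # (C_r, H+W)
    a_h = _sigmoid(params.w_h @ mixed[:, :H])        # (C, H)
    a_w = _sigmoid(params.w_w @ mixed[:, H:])        # (C, W)
    return t * a_h[:, :, None] * a_w[:, None, :]


# ---------------------------------------------------------------------------
# SPPF and Focus
# ---------------------------------------------------------------------------

def _maxpool_same(t: np.ndarray, k: int) -> np.ndarray:
    """Stride-1 kxk max pooling with same-size output (pad value -inf)."""
    return ndimage.maximum_filter(t, size=(1, k, k), mode="constant", cval=-np.inf)


def sppf_forward(t: np.ndarray, proj: np.ndarray | None = None) -> np.ndarray:
    """Fast spatial pyramid pooling: 5/9/13 receptive fields by repeated 5x5.

    Stride-1 max pools of kernel 5, 9 and 13 are realised as one, two and
    three sequential 5x5 pools (exactly equivalent), concatenated with the
    input along channels (4C) and projected back to C by a 1x1 conv.  With
    ``proj=None`` the raw 4C concatenation is returned, exposing the pyramid
    for testing.
    """
    t = _validate_tensor(t)
    p5 = _maxpool_same(t, 5)
    p9 = _maxpool_same(p5, 5)
    p13 = _maxpool_same(p9, 5)
    cat = np.concatenate([t, p5, p9, p13], axis=0)
    if proj is None:
        return cat
    proj = np.asarray(proj, dtype=float)
    if proj.shape != (t.shape[0], 4 * t.shape[0]):
        raise ValueError(f"projection must have shape (C, 4C), got {proj.shape}")
    return np.einsum("oc,chw->ohw", proj, cat)


def focus_slice(t: np.ndarray) -> np.ndarray:
    """Space-to-depth 2x2 slicing: CxHxW -> 4C x H/2 x W/2.

    Sub-grids are stacked in fixed order top-left, top-right, bottom-left,
    bottom-right; every input value appears exactly once in the output.
    """
    t = _validate_tensor(t)
    _, H, W = t.shape
    if H % 2 or W % 2:
        raise ValueError(f"spatial dims must be even, got {H}x{W}")
    return np.concatenate(
        [t[:, 0::2, 0::2], t[:, 0::2, 1::2], t[:, 1::2, 0::2], t[:, 1::2, 1::2]],
        axis=0,
    )


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxCWH:
    """Box as centre, width, height (pixels or any consistent unit)."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box extents must be positive")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)


@dataclass
class CIoUTerms:
    iou: float
    rho: float          # centre distance
    c_diag: float       # enclosing-box diagonal
    v: float            # aspect-consistency term
    alpha: float
    loss: float


def _iou_cwh(a: BoxCWH, b: BoxCWH) -> float:
    ax1, ay1, ax2, ay2 = a.corners
    bx1, by1, bx2, by2 = b.corners
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = a.w * a.h + b.w * b.h - inter
    return inter / union if union > 0 else 0.0


def ciou_loss(pred: BoxCWH, gt: BoxCWH) -> CIoUTerms:
    """Complete-IoU regression loss between a predicted and a ground-truth box.

        L = 1 - IoU + rho^2 / c^2 + alpha * v

    with rho the centre distance, c the diagonal of the tightest box
    enclosing both, v = (4/pi^2)(arctan(w_gt/h_gt) - arctan(w/h))^2 the
    aspect-ratio consistency term and alpha = v / ((1 - IoU) + v) its
    trade-off weight (0 when both v = 0 and IoU = 1, guarding 0/0).
    Identical boxes give L = 0.
    """
    iou = _iou_cwh(pred, gt)
    rho = math.hypot(pred.cx - gt.cx, pred.cy - gt.cy)
    px1, py1, px2, py2 = pred.corners
    gx1, gy1, gx2, gy2 = gt.corners
    cw = max(px2, gx2) - min(px1, gx1)
    ch = max(py2, gy2) - min(py1, gy1)
    c_diag = math.hypot(cw, ch)
    v = (4.0 / math.pi**2) * (math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)) ** 2
    denom = (1.0 - iou) + v
    alpha = 0.0 if denom <= _EPS else v / denom
    loss = 1.0 - iou + (rho**2) / (c_diag**2) + alpha * v
    return CIoUTerms(iou=iou, rho=rho, c_diag=c_diag, v=v, alpha=alpha, loss=loss)


@dataclass
class LossBatch:
    """Per-anchor predictions and targets for the composite detection loss.

    cls_pred/cls_true : (N, K) class probabilities and one-hot targets
                        (K = 1 in the single-class maize-seedling setting);
    obj_pred/obj_true : (N,) IoU-aware objectness probabilities and targets;
    boxes_pred/boxes_true : per-positive BoxCWH pairs;
    reg_pred/reg_true : (N, 4) localization offsets (L1 term);
    pos_mask          : (N,) booleans marking positive anchors — all others
                        are treated as negatives for the objectness term.
    """

    cls_pred: np.ndarray
    cls_true: np.ndarray
    obj_pred: np.ndarray
    obj_true: np.ndarray
    boxes_pred: list[BoxCWH]
    boxes_true: list[BoxCWH]
    reg_pred: np.ndarray
    reg_true: np.ndarray
    pos_mask: np.ndarray


def _cross_entropy(p: np.ndarray, g: np.ndarray) -> float:
    """Summed cross-entropy -sum g log p over rows of class probabilities."""
    p = np.clip(p, _EPS, 1.0)
    return float(-(g * np.log(p)).sum())


def _binary_cross_entropy(p: np.ndarray, g: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)).sum())


def composite_loss(
    batch: LossBatch,
    lambda1: float = 1.0,
    lambda2: float = 5.0,
    lambda3: float = 1.0,
    l1_enabled: bool = False,
) -> tuple[float, dict[str, float]]:
    """Composite detection loss, normalised by the positive count.

        L = (1/N_pos) [ CE(cls | pos) + l1*CE(obj | pos+neg)
                        + l2*sum CIoU(box | pos) + l3*sum L1(reg | pos) ]

    Classification uses categorical cross-entropy over positives, objectness
    binary cross-entropy over every anchor, box regression the CIoU loss and
    (late-training only, ``l1_enabled``) an L1 offset penalty.  Returns the
    total and a per-term breakdown that sums to it.
    """
    pos = np.asarray(batch.pos_mask, dtype=bool)
    n_pos = int(pos.sum())
    if n_pos < 1:
        raise ValueError("composite loss requires at least one positive sample")
    cls_term = _cross_entropy(batch.cls_pred[pos], batch.cls_true[pos])
    obj_term = _binary_cross_entropy(batch.obj_pred, batch.obj_true)
    if len(batch.boxes_pred) != n_pos or len(batch.boxes_true) != n_pos:
        raise ValueError("box lists must carry one entry per positive")
    box_term = sum(ciou_loss(p, g).loss for p, g in zip(batch.boxes_pred, batch.boxes_true))
    reg_term = float(np.abs(batch.reg_pred[pos] - batch.reg_true[pos]).sum()) if l1_enabled else 0.0
    breakdown = {
        "cls": cls_term / n_pos,
        "obj": lambda1 * obj_term / n_pos,
        "box": lambda2 * box_term / n_pos,
        "reg": lambda3 * reg_term / n_pos,
    }
    return sum(breakdown.values()), breakdown
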