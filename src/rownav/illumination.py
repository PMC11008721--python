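"""Retinex-based adaptive gamma enhancement for low-light field imagery.

The enhancement pipeline models an RGB image as the pixel-wise product of a
smooth illumination (luminance) field ``L`` and a per-channel reflectance
``R_c``:

    I_c(x, y) = R_c(x, y) * L(x, y),    c in {r, g, b}

Only the luminance is modified.  A per-level gamma exponent is derived from
the luminance histogram's weighted cumulative distribution,

    gamma(l) = 1 - CDF_w(l),    CDF_w(l) = sum_{v<=l} P_w(v) / sp,

where ``P_w`` is the min-max-normalised probability of each luminance level
and ``sp`` normalises the weighted CDF to 1 at the top level.  Because
``gamma`` lies in [0, 1] and luminance lies in [0, 1], the correction
``L_en = L ** gamma`` can only brighten; dark levels (small weighted CDF,
gamma near 1) are lifted gently while mid levels receive the strongest
stretch, evening out the axial falloff of an artificial light source.

Recomposing ``R_c * L_en`` restores colour and detail at the new brightness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "EnhanceConfig",
    "GammaTable",
    "estimate_illumination",
    "decompose_retinex",
    "build_gamma_table",
    "apply_gamma",
    "recompose",
    "enhance",
]


@dataclass(frozen=True)
class EnhanceConfig:
    """Parameters of the enhancement transform.

    blur_sigma : Gaussian low-pass scale (pixels) for illumination estimation.
    bins       : number of luminance histogram levels B (256 matches 8-bit
                 imagery).
    eps_floor  : lower clamp for the luminance map so the reflectance division
                 is always defined.
    clamp_output : clip the recomposed image to [0, 1] (reflectance can exceed
                 1 wherever I_c > L).
    """

    blur_sigma: float = 15.0
    bins: int = 256
    eps_floor: float = 1e-6
    clamp_output: bool = True

    def __post_init__(self) -> None:
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be positive")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if not 0 < self.eps_floor < 1:
            raise ValueError("eps_floor must lie in (0, 1)")


@dataclass
class GammaTable:
    """Per-luminance-level statistics driving the adaptive gamma correction."""

    bins: int
    counts: np.ndarray        # n_l, shape (B,)
    n_pixels: int             # n_p = sum(counts)
    pdf: np.ndarray           # P(l) = n_l / n_p
    weights: np.ndarray       # P_w(l) = (P - P_min) / (P_max - P_min)
    sp: float                 # sum of P_w over all levels
    gamma: np.ndarray         # gamma(l) = 1 - cumsum(P_w)(l) / sp
    degenerate: bool = field(default=False)


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    return img


def quantize_levels(L: np.ndarray, bins: int) -> np.ndarray:
    """Map luminance values in [0, 1] to integer levels 0..bins-1.

    level(x) = floor(min(x, 1 - ulp) * bins), so x == 1 lands in the top bin.
    """
    capped = np.minimum(L, np.nextafter(1.0, 0.0))
    return np.floor(capped * bins).astype(np.intp)


def estimate_illumination(img: np.ndarray, cfg: EnhanceConfig | None = None) -> np.ndarray:
    """Estimate the smooth luminance field of an RGB image.

    Single-scale-Retinex convention: Gaussian low-pass (reflected borders) of
    the per-pixel channel maximum, clamped to [eps_floor, 1].  Max-channel
    avoids biasing the hue of strongly green vegetation pixels.
    """
    cfg = cfg or EnhanceConfig()
    img = _validate_image(img)
    lum = img.max(axis=2)
    smooth = ndimage.gaussian_filter(lum, sigma=cfg.blur_sigma, mode="reflect")
    return np.clip(smooth, cfg.eps_floor, 1.0)


def decompose_retinex(img: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Per-channel reflectance R_c = I_c / L.

    The product R_c * L reconstructs the input exactly (up to rounding), which
    is what makes luminance-only editing colour-preserving.
    """
    img = _validate_image(img)
    L = np.asarray(L, dtype=float)
    if L.shape != img.shape[:2]:
        raise ValueError(f"luminance shape {L.shape} does not match image {img.shape[:2]}")
    if L.min() <= 0:
        raise ValueError("luminance must be strictly positive (>= eps_floor)")
    return img / L[:, :, None]


def build_gamma_table(L: np.ndarray, cfg: EnhanceConfig | None = None) -> GammaTable:
    """Derive per-level gamma exponents from the luminance histogram.

    With level probabilities P(l) = n_l / n_p, min-max weights
    P_w(l) = (P(l) - P_min) / (P_max - P_min) and global normaliser
    sp = sum_l P_w(l), the exponent is gamma(l) = 1 - cumsum(P_w)(l) / sp.
    A flat histogram (P_max == P_min) leaves no brightness ordering to
    exploit; the table is then the identity (gamma == 1).
    """
    cfg = cfg or EnhanceConfig()
    L = np.asarray(L, dtype=float)
    if L.size == 0:
        raise ValueError("empty luminance map")
    B = cfg.bins
    levels = quantize_levels(L, B)
    counts = np.bincount(levels.ravel(), minlength=B).astype(np.intp)
    n_pixels = int(counts.sum())
    pdf = counts / n_pixels
    p_min, p_max = pdf.min(), pdf.max()
    # No exploitable brightness ordering: flat histogram, or a single occupied
    # level (whose weighted CDF would be a step to 1, whitening the image).
    if p_max == p_min or int((counts > 0).sum()) <= 1:
        return GammaTable(
            bins=B, counts=counts, n_pixels=n_pixels, pdf=pdf,
            weights=np.zeros(B), sp=0.0, gamma=np.ones(B), degenerate=True,
        )
    weights = (pdf - p_min) / (p_max - p_min)
    sp = float(weights.sum())
    gamma = 1.0 - np.cumsum(weights) / sp
    # cumsum rounding can leave the top level at ~1e-16 instead of 0
    gamma = np.clip(gamma, 0.0, 1.0)
    return GammaTable(
        bins=B, counts=counts, n_pixels=n_pixels, pdf=pdf,
        weights=weights, sp=sp, gamma=gamma, degenerate=False,
    )


def apply_gamma(L: np.ndarray, tab: GammaTable) -> np.ndarray:
    """Per-pixel correction L_en = L ** gamma(level(L)).

    gamma in [0, 1] and L in [0, 1] make this brightening-only; a degenerate
    table returns L unchanged.
    """
    L = np.asarray(L, dtype=float)
    if tab.degenerate:
        return L.copy()
    exponents = tab.gamma[quantize_levels(L, tab.bins)]
    return np.power(L, exponents)


def recompose(R: np.ndarray, L_en: np.ndarray, cfg: EnhanceConfig | None = None) -> np.ndarray:
    """Fuse reflectance with corrected luminance: out_c = R_c * L_en."""
    cfg = cfg or EnhanceConfig()
    R = np.asarray(R, dtype=float)
    L_en = np.asarray(L_en, dtype=float)
    if R.shape[:2] != L_en.shape:
        raise ValueError(f"reflectance shape {R.shape} does not match luminance {L_en.shape}")
    out = R * L_en[:, :, None]
    if cfg.clamp_output:
        out = np.clip(out, 0.0, 1.0)
    return out


def enhance(img: np.ndarray, cfg: EnhanceConfig | None = None) -> np.ndarray:
    """Full enhancement: decompose, gamma-correct the luminance, recompose.

    Deterministic; a uniform image comes back unchanged (degenerate
    histogram).
    """
    cfg = cfg or EnhanceConfig()
    L = estimate_illumination(img, cfg)
    R = decompose_retinex(img, L)
    tab = build_gamma_table(L, cfg)
    L_en = apply_gamma(L, tab)
    return recompose(R, L_en, cfg)
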