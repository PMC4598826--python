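"""Data normalization and stain-deconvolution feature extraction.

Normalization is a per-channel percentile saturation stretch; the feature
image fed to both coarse matching and elastic refinement is either the
normalized grayscale section or the eosin-assigned stain-concentration
channel obtained by optical-density deconvolution of an RGB section.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateStainError, EmptyHistogramError

__all__ = [
    "SaturationBounds",
    "StainMatrix",
    "FeatureImage",
    "channel_histogram",
    "saturation_bounds",
    "stretch_channel",
    "normalize_image",
    "rgb_to_od",
    "od_to_rgb",
    "build_stain_matrix",
    "default_he_matrix",
    "deconvolve",
    "extract_feature_image",
    "HEMATOXYLIN_OD",
    "EOSIN_OD",
]

log = logging.getLogger(__name__)

# Widely published H&E optical-density vectors (configurable at run level).
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
EOSIN_OD = (0.072, 0.990, 0.105)


@dataclass(frozen=True)
class SaturationBounds:
    x_low: int
    x_high: int
    p_low: float
    p_high: float


@dataclass(frozen=True)
class StainMatrix:
    """Row-normalized 3x3 optical-density color system.

    Rows are unit stain vectors (OD per RGB channel); the forward model is
    OD = M^T @ C for stain amounts C, so deconvolution is C = (M^T)^-1 @ OD.
    """

    rows: np.ndarray  # (3, 3)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rows", np.asarray(self.rows, dtype=np.float64).reshape(3, 3)
        )

    @property
    def inverse_t(self) -> np.ndarray:
        try:
            inv = np.linalg.inv(self.rows.T)
        except np.linalg.LinAlgError as exc:
            raise DegenerateStainError("degenerate stain system") from exc
        if not np.all(np.isfinite(inv)):
            raise DegenerateStainError("degenerate stain system")
        return inv


@dataclass
class FeatureImage:
    """8-bit single-channel registration feature image."""

    pixels: np.ndarray
    provenance: str  # gray_normalized | eosin_channel | hematoxylin_channel | luminance


def channel_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of a single uint8 channel."""
    return np.bincount(np.asarray(img, dtype=np.uint8).ravel(), minlength=256)


def saturation_bounds(
    hist: np.ndarray, p_low: float, p_high: float
) -> SaturationBounds:
    """Lower/upper intensity bounds saturating fixed tail fractions.

    x_low is the smallest level whose cumulative count (from 0, inclusive)
    strictly exceeds p_low * total; x_high the largest level whose upward
    cumulative count strictly exceeds p_high * total.
    """
    hist = np.asarray(hist, dtype=np.int64)
    total = int(hist.sum())
    if total == 0:
        raise EmptyHistogramError("empty histogram")
    csum = np.cumsum(hist)
    x_low = int(np.argmax(csum > p_low * total))
    rsum = np.cumsum(hist[::-1])[::-1]  # cumulative from level upward
    x_high = 255 - int(np.argmax(rsum[::-1] > p_high * total))
    x_high = max(x_high, x_low)
    return SaturationBounds(x_low, x_high, p_low, p_high)


def stretch_channel(img: np.ndarray, b: SaturationBounds) -> np.ndarray:
    """Linear remap of [x_low, x_high] onto [0, 255] with clamping.

    A constant channel (x_low == x_high) maps to all zeros: it carries no
    registration signal and is kept in background.
    """
    x = np.asarray(img, dtype=np.float64)
    if b.x_high == b.x_low:
        return np.zeros_like(img, dtype=np.uint8)
    out = 255.0 * (x - b.x_low) / (b.x_high - b.x_low)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def normalize_image(img: np.ndarray, p_low: float = 0.01, p_high: float = 0.01):
    """Saturation contrast stretch, each channel from its own histogram."""
    img = np.asarray(img)
    if img.ndim == 2:
        return stretch_channel(img, saturation_bounds(channel_histogram(img), p_low, p_high))
    chans = [
        stretch_channel(
            img[:, :, c],
            saturation_bounds(channel_histogram(img[:, :, c]), p_low, p_high),
        )
        for c in range(img.shape[2])
    ]
    return np.stack(chans, axis=-1)


def rgb_to_od(img: np.ndarray) -> np.ndarray:
    """Per-channel optical density -log10(I/255), zeros clamped to 1."""
    x = np.maximum(np.asarray(img, dtype=np.float64), 1.0)
    return -np.log10(x / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of rgb_to_od (forward transmission model), uint8 output."""
    return np.clip(np.rint(255.0 * 10.0 ** (-np.asarray(od, dtype=np.float64))), 0, 255).astype(np.uint8)


def build_stain_matrix(stain1_od, stain2_od) -> StainMatrix:
    """Two measured stain OD vectors plus an orthogonal residual row.

    Rows are unit-normalized; the residual is the cross product of the first
    two with negative components zeroed, renormalized.
    """
    v1 = np.asarray(stain1_od, dtype=np.float64)
    v2 = np.asarray(stain2_od, dtype=np.float64)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DegenerateStainError("degenerate stain system: zero stain vector")
    r1, r2 = v1 / n1, v2 / n2
    cross = np.cross(r1, r2)
    if np.linalg.norm(cross) < 1e-9:
        raise DegenerateStainError("degenerate stain system: parallel stain vectors")
    r3 = np.where(cross < 0, 0.0, cross)
    if np.linalg.norm(r3) < 1e-12:
        r3 = -cross  # cross entirely negative: flip instead of zeroing out
    r3 = r3 / np.linalg.norm(r3)
    m = StainMatrix(np.stack([r1, r2, r3]))
    m.inverse_t  # raises if singular
    return m


def default_he_matrix() -> StainMatrix:
    return build_stain_matrix(HEMATOXYLIN_OD, EOSIN_OD)


def deconvolve(img: np.ndarray, m: StainMatrix):
    """Separate an RGB image into per-stain concentration channels.

    Returns (channels_uint8, concentrations) where ``concentrations`` is the
    raw float (H, W, 3) stain-amount array and ``channels_uint8`` its
    per-channel min-max rescale to 8 bits.
    """
    od = rgb_to_od(img)
    conc = od @ m.inverse_t.T  # per pixel: (M^T)^-1 @ od
    chans = []
    for c in range(3):
        ch = conc[:, :, c]
        lo, hi = float(ch.min()), float(ch.max())
        if hi > lo:
            ch8 = np.clip(np.rint(255.0 * (ch - lo) / (hi - lo)), 0, 255).astype(np.uint8)
        else:
            ch8 = np.zeros(ch.shape, dtype=np.uint8)
        chans.append(ch8)
    return chans, conc


def extract_feature_image(
    img: np.ndarray,
    m: StainMatrix | None = None,
    channel: str = "eosin",
) -> FeatureImage:
    """Feature image for matching: normalized gray, or a stain channel.

    Grayscale input passes through unchanged (deconvolution is skipped).
    RGB input without a stain matrix falls back to luminance with a warning.
    ``channel`` selects which stain row feeds the feature image; by
    convention row 0 is hematoxylin and row 1 is eosin.
    """
    img = np.asarray(img)
    if img.ndim == 2:
        return FeatureImage(img.copy(), "gray_normalized")
    if m is None or channel == "luminance":
        if m is None and channel != "luminance":
            log.warning("RGB input without a stain matrix: falling back to luminance")
        lum = np.clip(
            np.rint(
                0.2126 * img[:, :, 0] + 0.7152 * img[:, :, 1] + 0.0722 * img[:, :, 2]
            ),
            0,
            255,
        ).astype(np.uint8)
        return FeatureImage(lum, "luminance")
    idx = {"hematoxylin": 0, "eosin": 1}.get(channel)
    if idx is None:
        raise ValueError(f"unknown feature channel {channel!r}")
    chans, _ = deconvolve(img, m)
    return FeatureImage(chans[idx], f"{channel}_channel")
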