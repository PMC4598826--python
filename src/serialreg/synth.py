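"""Synthetic deformed-sequence generator for quantitative evaluation.

Builds the standard quantitative test construction: one textured base
section duplicated n times, each copy (except the first) independently
perturbed by a random smooth B-spline deformation on a black background.
Ground-truth fields are kept so recovery can also be judged by endpoint
error.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .bspline import BSplineField, warp_image
from .imaging_io import SectionStack

__all__ = [
    "SyntheticSpec",
    "SyntheticSequence",
    "generate_base_texture",
    "random_field",
    "generate_sequence",
]


@dataclass(frozen=True)
class SyntheticSpec:
    n: int = 10
    size: tuple[int, int] = (512, 512)  # (H, W)
    magnitude: float = 8.0  # target mean displacement, px
    smoothness: float = 48.0  # control-point spacing, px
    seed: int = 0
    base: str | None = None  # optional path to a user-supplied base image

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


@dataclass
class SyntheticSequence:
    stack: SectionStack
    truth_fields: list[BSplineField] = dc_field(default_factory=list)
    spec: SyntheticSpec | None = None


def generate_base_texture(size: tuple[int, int], seed: int = 0) -> np.ndarray:
    """Deterministic tissue-like texture: bright blobs and ridges inside a
    roughly elliptical foreground on black, with a >= 8 px black frame.

    Bright structure (intensity >= 200) covers 10-30% of the foreground.
    """
    h, w = size
    if h < 128 or w < 128:
        raise ValueError("base texture requires size >= 128x128")
    rng = np.random.default_rng(seed)

    # band-passed random field: smooth blobs minus a broader trend
    noise = rng.standard_normal((h, w))
    fine = ndimage.gaussian_filter(noise, 6.0)
    coarse = ndimage.gaussian_filter(noise, 24.0)
    band = fine - coarse
    band = (band - band.mean()) / (band.std() + 1e-12)

    # wavy elliptical foreground, kept >= 8 px off the border
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = h / 2.0 - 16.0, w / 2.0 - 16.0
    theta = np.arctan2(ys - cy, xs - cx)
    wobble = 1.0 + 0.06 * np.sin(5 * theta + rng.uniform(0, 2 * np.pi))
    rad = np.sqrt(((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2)
    fg = rad < wobble * 0.92

    # mid-gray tissue with bright eosinophilic-style structure
    tissue = 90.0 + 35.0 * band
    bright_q = np.quantile(band[fg], 0.80)  # top 20% of texture becomes bright
    bright = fg & (band >= bright_q)
    out = np.zeros((h, w))
    out[fg] = np.clip(tissue[fg], 30.0, 180.0)
    out[bright] = np.clip(215.0 + 35.0 * band[bright], 200.0, 255.0)
    return out.astype(np.uint8)


def random_field(
    size: tuple[int, int],
    magnitude: float,
    smoothness: float,
    seed: int = 0,
) -> BSplineField:
    """Random smooth B-spline field with an exact mean displacement.

    Coefficient displacements are drawn from a zero-mean Gaussian and then
    rescaled so the field's mean deformation equals ``magnitude`` (the mean
    of ||s * d|| is linear in s, so the rescale is exact up to rounding).
    """
    h, w = size
    field = BSplineField.identity((h, w), (smoothness, smoothness))
    if magnitude == 0:
        return field
    rng = np.random.default_rng(seed)
    disp = rng.standard_normal(field.coeffs.shape)
    trial = BSplineField(field.coeffs + disp, field.spacing, field.shape)
    base_mag = trial.mean_displacement()
    if base_mag == 0:
        return field
    scale = magnitude / base_mag
    return BSplineField(field.coeffs + scale * disp, field.spacing, field.shape)


def generate_sequence(spec: SyntheticSpec) -> SyntheticSequence:
    """n copies of one base section, each independently deformed.

    Section 0 is the undeformed base (identity truth field); sections
    1..n-1 are warps of the base by independent seeded random fields.
    """
    if spec.base is not None:
        from .imaging_io import read_stack

        base = read_stack(spec.base)[0] if str(spec.base).endswith((".tif", ".tiff")) else None
        if base is None:
            from PIL import Image

            base = np.asarray(Image.open(spec.base).convert("L"))
    else:
        base = generate_base_texture(spec.size, spec.seed)
    size = base.shape[:2]
    sections = [base.copy()]
    fields = [BSplineField.identity(size, (spec.smoothness, spec.smoothness))]
    for i in range(1, spec.n):
        f = random_field(size, spec.magnitude, spec.smoothness, seed=spec.seed * 10007 + i)
        fields.append(f)
        sections.append(warp_image(base, f))
    return SyntheticSequence(SectionStack(sections), fields, spec)
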