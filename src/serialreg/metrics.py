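"""Registration-accuracy metric on section stacks.

Per consecutive pair, the score r_i is the fraction of "white" pixels
(intensity >= t, default t = 200) of section i, inside the common
foreground mask of the pair, that are also white in section i + 1.  The
stack score R is the mean of the pairwise scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ShapeError
from .imaging_io import SectionStack

__all__ = [
    "EvaluationMask",
    "foreground_mask",
    "build_evaluation_mask",
    "pair_accuracy",
    "stack_accuracy",
    "DEFAULT_WHITE_THRESHOLD",
]

DEFAULT_WHITE_THRESHOLD = 200


@dataclass
class EvaluationMask:
    foreground_i: np.ndarray
    foreground_j: np.ndarray
    common: np.ndarray
    white_i: np.ndarray
    white_j: np.ndarray
    t: int


def _intensity(img: np.ndarray) -> np.ndarray:
    """Per-pixel brightness; RGB reduced to the max channel."""
    img = np.asarray(img)
    return img.max(axis=2) if img.ndim == 3 else img


def foreground_mask(img: np.ndarray, bg_tol: int = 0) -> np.ndarray:
    """Non-background support: intensity > bg_tol, interior holes filled."""
    mask = _intensity(img) > bg_tol
    return ndimage.binary_fill_holes(mask)


def build_evaluation_mask(
    img_i: np.ndarray,
    img_j: np.ndarray,
    t: int = DEFAULT_WHITE_THRESHOLD,
    bg_tol: int = 0,
) -> EvaluationMask:
    if img_i.shape[:2] != img_j.shape[:2]:
        raise ShapeError(f"shape error: {img_i.shape} vs {img_j.shape}")
    fg_i = foreground_mask(img_i, bg_tol)
    fg_j = foreground_mask(img_j, bg_tol)
    common = fg_i & fg_j
    white_i = common & (_intensity(img_i) >= t)
    white_j = common & (_intensity(img_j) >= t)
    return EvaluationMask(fg_i, fg_j, common, white_i, white_j, t)


def pair_accuracy(
    img_i: np.ndarray,
    img_j: np.ndarray,
    t: int = DEFAULT_WHITE_THRESHOLD,
    bg_tol: int = 0,
    symmetric: bool = False,
) -> float:
    """Similar-intensity overlap score r in [0, 1] for one section pair.

    Directed form (default): |W_i & W_j| / |W_i|.  Both white sets empty
    scores 1; W_i empty with W_j nonempty scores 0.  The symmetric variant
    normalizes by |W_i | W_j| instead.
    """
    m = build_evaluation_mask(img_i, img_j, t, bg_tol)
    inter = int(np.count_nonzero(m.white_i & m.white_j))
    n_i = int(np.count_nonzero(m.white_i))
    n_j = int(np.count_nonzero(m.white_j))
    if symmetric:
        union = int(np.count_nonzero(m.white_i | m.white_j))
        return 1.0 if union == 0 else inter / union
    if n_i == 0:
        return 1.0 if n_j == 0 else 0.0
    return inter / n_i


def stack_accuracy(
    stack: SectionStack,
    t: int = DEFAULT_WHITE_THRESHOLD,
    bg_tol: int = 0,
    symmetric: bool = False,
) -> tuple[float, list[float]]:
    """Overall accuracy R = mean of r_i over the N - 1 consecutive pairs."""
    rs = [
        pair_accuracy(stack[i], stack[i + 1], t, bg_tol, symmetric)
        for i in range(len(stack) - 1)
    ]
    return float(np.mean(rs)), rs
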