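"""Feature-based coarse global alignment of a section pair.

Difference-of-Gaussian interest points with local-gradient descriptors are
detected on the feature images, matched with a ratio test and cross check,
and a global transform is estimated by seeded RANSAC with a least-squares
refit on the consensus set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import SIFT
from skimage.feature import match_descriptors as _sk_match

from .errors import CoarseRegistrationError, InsufficientExtentError, NoFeaturesError
from .preprocess import FeatureImage

__all__ = [
    "Keypoint",
    "CorrespondenceSet",
    "GlobalTransform2D",
    "detect_keypoints",
    "match_descriptors",
    "ransac_transform",
    "apply_global",
    "identity_transform",
    "MIN_SAMPLES",
]

MIN_SAMPLES = {"translation": 1, "rigid": 2, "similarity": 2, "affine": 3}


@dataclass(frozen=True)
class Keypoint:
    x: float
    y: float
    scale: float
    orientation: float
    descriptor: np.ndarray  # unit-norm


@dataclass
class CorrespondenceSet:
    """Candidate point matches between two images, (x, y) coordinate rows."""

    src: np.ndarray  # (P, 2) points in image 1
    dst: np.ndarray  # (P, 2) points in image 2
    distances: np.ndarray  # (P,) descriptor distances
    inlier_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return int(self.src.shape[0])


@dataclass
class GlobalTransform2D:
    """2x3 matrix mapping source (x, y, 1) -> target (x, y)."""

    model_class: str
    matrix: np.ndarray
    mean_residual: float = 0.0
    n_inliers: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 3)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2][None, :]

    def inverse(self) -> "GlobalTransform2D":
        m = np.vstack([self.matrix, [0.0, 0.0, 1.0]])
        inv = np.linalg.inv(m)[:2]
        return GlobalTransform2D(self.model_class, inv)

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.matrix, identity_transform().matrix))


def identity_transform(model_class: str = "identity") -> GlobalTransform2D:
    return GlobalTransform2D(model_class, np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))


def detect_keypoints(f: FeatureImage | np.ndarray, params: dict | None = None):
    """DoG scale-space keypoints with descriptors on a feature image.

    Deterministic for fixed input and parameters; an empty list is a valid
    result (e.g. constant images).
    """
    img = f.pixels if isinstance(f, FeatureImage) else np.asarray(f)
    if img.shape[0] < 32 or img.shape[1] < 32:
        raise InsufficientExtentError(
            f"insufficient extent: {img.shape[1]}x{img.shape[0]} < 32x32"
        )
    params = dict(params or {})
    detector = SIFT(
        upsampling=params.get("upsampling", 1),
        n_octaves=params.get("n_octaves", 8),
        n_scales=params.get("n_scales", 3),
        sigma_min=params.get("sigma_min", 1.6),
        c_dog=params.get("c_dog", 0.009),
        c_edge=params.get("c_edge", 10.0),
    )
    try:
        detector.detect_and_extract(img)
    except RuntimeError:  # scikit-image raises when nothing is found
        return []
    desc = detector.descriptors.astype(np.float64)
    norms = np.linalg.norm(desc, axis=1)
    norms[norms == 0] = 1.0
    desc = desc / norms[:, None]
    kps = []
    for i in range(desc.shape[0]):
        y, x = detector.keypoints[i]
        kps.append(
            Keypoint(
                x=float(detector.positions[i][1]) if hasattr(detector, "positions") else float(x),
                y=float(detector.positions[i][0]) if hasattr(detector, "positions") else float(y),
                scale=float(detector.scales[i]),
                orientation=float(detector.orientations[i]),
                descriptor=desc[i],
            )
        )
    return kps


def match_descriptors(
    k1: list[Keypoint], k2: list[Keypoint], ratio: float = 0.8
) -> CorrespondenceSet:
    """Nearest-neighbour matches passing a Lowe ratio test, cross-checked."""
    if not k1 or not k2:
        raise NoFeaturesError("no features to match")
    d1 = np.stack([k.descriptor for k in k1])
    d2 = np.stack([k.descriptor for k in k2])
    pairs = _sk_match(d1, d2, cross_check=True, max_ratio=ratio)
    src = np.array([[k1[i].x, k1[i].y] for i in pairs[:, 0]], dtype=np.float64).reshape(-1, 2)
    dst = np.array([[k2[j].x, k2[j].y] for j in pairs[:, 1]], dtype=np.float64).reshape(-1, 2)
    dists = (
        np.linalg.norm(d1[pairs[:, 0]] - d2[pairs[:, 1]], axis=1)
        if len(pairs)
        else np.empty(0)
    )
    return CorrespondenceSet(src, dst, dists)


# ------------------------------------------------------------------ #
# model estimators: least squares on (src, dst) point sets
def _estimate_translation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    t = (dst - src).mean(axis=0)
    return np.array([[1.0, 0.0, t[0]], [0.0, 1.0, t[1]]])


def _estimate_umeyama(src: np.ndarray, dst: np.ndarray, scale: bool) -> np.ndarray | None:
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / src.shape[0]
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, d])
    rot = u @ diag @ vt
    if scale:
        var_s = (xs**2).sum() / src.shape[0]
        if var_s == 0:
            return None
        rot = rot * (np.trace(np.diag(s) @ diag) / var_s)
    t = mu_d - rot @ mu_s
    return np.hstack([rot, t[:, None]])


def _estimate_affine(src: np.ndarray, dst: np.ndarray) -> np.ndarray | None:
    a = np.hstack([src, np.ones((src.shape[0], 1))])
    sol, *_ = np.linalg.lstsq(a, dst, rcond=None)
    m = sol.T  # (2, 3)
    if not np.all(np.isfinite(m)):
        return None
    return m


def _estimate(model_class: str, src: np.ndarray, dst: np.ndarray) -> np.ndarray | None:
    if model_class == "translation":
        return _estimate_translation(src, dst)
    if model_class == "rigid":
        return _estimate_umeyama(src, dst, scale=False)
    if model_class == "similarity":
        return _estimate_umeyama(src, dst, scale=True)
    if model_class == "affine":
        return _estimate_affine(src, dst)
    raise ValueError(f"unknown model class {model_class!r}")


def ransac_transform(
    c: CorrespondenceSet,
    model_class: str = "similarity",
    inlier_tol: float = 3.0,
    max_iters: int = 2000,
    seed: int = 0,
) -> GlobalTransform2D:
    """Seeded RANSAC consensus transform with least-squares refit on inliers.

    Fails ("coarse registration failed") below the minimal sample size for
    the model class or when the best consensus has fewer than 3 inliers.
    """
    k = MIN_SAMPLES[model_class]
    n = len(c)
    if n < k:
        raise CoarseRegistrationError(
            f"coarse registration failed: {n} correspondences < minimal sample {k}"
        )
    rng = np.random.default_rng(seed)
    best_mask: np.ndarray | None = None
    best_count = 0
    best_sse = np.inf
    for _ in range(max_iters):
        idx = rng.choice(n, size=k, replace=False)
        m = _estimate(model_class, c.src[idx], c.dst[idx])
        if m is None:
            continue
        res = np.linalg.norm(c.src @ m[:, :2].T + m[:, 2] - c.dst, axis=1)
        mask = res < inlier_tol
        count = int(mask.sum())
        sse = float((res[mask] ** 2).sum())
        if count > best_count or (count == best_count and sse < best_sse):
            best_count, best_mask, best_sse = count, mask, sse
    if best_mask is None or best_count < 3:
        raise CoarseRegistrationError(
            f"coarse registration failed: best consensus {best_count} < 3 inliers"
        )
    m = _estimate(model_class, c.src[best_mask], c.dst[best_mask])
    if m is None:
        raise CoarseRegistrationError("coarse registration failed: degenerate refit")
    res = np.linalg.norm(c.src @ m[:, :2].T + m[:, 2] - c.dst, axis=1)
    mask = res < inlier_tol
    if int(mask.sum()) < 3:
        mask = best_mask
    c.inlier_mask = mask
    mean_res = float(res[mask].mean()) if mask.any() else float("inf")
    return GlobalTransform2D(model_class, m, mean_res, int(mask.sum()))


def apply_global(img: np.ndarray, t: GlobalTransform2D) -> np.ndarray:
    """Backward-warp resampling of an image by a global transform.

    Output pixel x takes the value of the source at T^-1(x); bilinear
    interpolation, out-of-domain black.
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    inv = t.inverse().matrix
    ys, xs = np.mgrid[0:h, 0:w]
    gx = inv[0, 0] * xs + inv[0, 1] * ys + inv[0, 2]
    gy = inv[1, 0] * xs + inv[1, 1] * ys + inv[1, 2]
    coords = np.stack([gy, gx])

    def _one(ch):
        return ndimage.map_coordinates(
            ch.astype(np.float64), coords, order=1, mode="constant", cval=0.0
        )

    out = (
        _one(img)
        if img.ndim == 2
        else np.stack([_one(img[:, :, ci]) for ci in range(img.shape[2])], axis=-1)
    )
    if img.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out
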