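"""Tensor-product cubic B-spline deformation fields.

A field stores absolute target positions: evaluating the field at pixel
(x, y) yields the position g(x, y) = sum_kl C_kl * b3(x/s_x - k) * b3(y/s_y - l)
that the pixel maps to.  With coefficients placed on their own grid
positions (C_kl = (k*s_x, l*s_y)) the field is exactly the identity map,
because the cardinal cubic B-spline reproduces linear functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DomainError, ShapeError

__all__ = [
    "BSplineField",
    "cubic_bspline",
    "cubic_bspline_deriv",
    "basis_matrix",
    "n_coeffs",
    "fit_field",
    "warp_image",
    "sample_bilinear",
]


def cubic_bspline(t: np.ndarray) -> np.ndarray:
    """Cardinal cubic B-spline b3(t), supported on |t| < 2."""
    t = np.abs(np.asarray(t, dtype=np.float64))
    out = np.zeros_like(t)
    inner = t < 1.0
    outer = (t >= 1.0) & (t < 2.0)
    ti = t[inner]
    out[inner] = 2.0 / 3.0 - ti * ti + 0.5 * ti * ti * ti
    to = t[outer]
    out[outer] = ((2.0 - to) ** 3) / 6.0
    return out


def cubic_bspline_deriv(t: np.ndarray) -> np.ndarray:
    """First derivative of the cardinal cubic B-spline."""
    t = np.asarray(t, dtype=np.float64)
    s = np.sign(t)
    a = np.abs(t)
    out = np.zeros_like(a)
    inner = a < 1.0
    outer = (a >= 1.0) & (a < 2.0)
    ai = a[inner]
    out[inner] = s[inner] * (-2.0 * ai + 1.5 * ai * ai)
    ao = a[outer]
    out[outer] = s[outer] * (-0.5 * (2.0 - ao) ** 2)
    return out


def n_coeffs(extent: int, spacing: float) -> int:
    """Number of coefficients needed to cover coordinates [0, extent-1].

    Basis index k runs from -1 to floor((extent-1)/spacing) + 2; the array
    index is k + 1.
    """
    return int(np.floor((extent - 1) / spacing)) + 4


def basis_matrix(
    coords: np.ndarray, spacing: float, ncoeff: int, deriv: bool = False
) -> np.ndarray:
    """Dense basis matrix B with B[i, j] = b3(coords[i]/spacing - (j - 1)).

    With ``deriv`` the entries are d/dcoord of the same basis, i.e.
    b3'(t)/spacing.
    """
    t = np.asarray(coords, dtype=np.float64)[:, None] / spacing - (
        np.arange(ncoeff, dtype=np.float64)[None, :] - 1.0
    )
    if deriv:
        return cubic_bspline_deriv(t) / spacing
    return cubic_bspline(t)


def _local_weights(t: np.ndarray, ncoeff: int, deriv: bool = False):
    """4-tap local basis weights and array indices for scattered evaluation.

    Returns (idx, w, valid) where idx, w are (P, 4) and valid flags points
    whose support lies fully inside the coefficient array.
    """
    base = np.floor(t).astype(np.int64)
    offs = np.arange(-1, 3, dtype=np.int64)
    idx = base[:, None] + offs[None, :] + 1  # +1: array index = k + 1
    frac = t[:, None] - (base[:, None] + offs[None, :]).astype(np.float64)
    w = cubic_bspline_deriv(frac) if deriv else cubic_bspline(frac)
    valid = (idx[:, 0] >= 0) & (idx[:, -1] <= ncoeff - 1)
    np.clip(idx, 0, ncoeff - 1, out=idx)
    return idx, w, valid


@dataclass
class BSplineField:
    """Cubic B-spline 2D deformation field over an H x W pixel domain.

    coeffs:  (nL, nK, 2) array of absolute target positions, last axis (x, y).
    spacing: (s_x, s_y) control-point spacings in pixels.
    shape:   (H, W) image domain.
    """

    coeffs: np.ndarray
    spacing: tuple[float, float]
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        h, w = self.shape
        nk = n_coeffs(w, self.spacing[0])
        nl = n_coeffs(h, self.spacing[1])
        if self.coeffs.shape != (nl, nk, 2):
            raise ShapeError(
                f"coefficient grid {self.coeffs.shape} does not match domain "
                f"{self.shape} at spacing {self.spacing}: expected ({nl}, {nk}, 2)"
            )

    # ------------------------------------------------------------------ #
    @classmethod
    def identity(cls, shape: tuple[int, int], spacing: tuple[float, float]):
        h, w = shape
        sx, sy = spacing
        nk = n_coeffs(w, sx)
        nl = n_coeffs(h, sy)
        kx = (np.arange(nk, dtype=np.float64) - 1.0) * sx
        ly = (np.arange(nl, dtype=np.float64) - 1.0) * sy
        coeffs = np.empty((nl, nk, 2))
        coeffs[:, :, 0] = kx[None, :]
        coeffs[:, :, 1] = ly[:, None]
        return cls(coeffs, (sx, sy), (h, w))

    @classmethod
    def from_affine(
        cls,
        matrix: np.ndarray,
        shape: tuple[int, int],
        spacing: tuple[float, float],
    ):
        """Field that reproduces an affine map exactly (linear precision).

        ``matrix`` is 2x3 acting on column vectors (x, y, 1).
        """
        ident = cls.identity(shape, spacing)
        m = np.asarray(matrix, dtype=np.float64)
        pts = ident.coeffs.reshape(-1, 2)
        out = pts @ m[:, :2].T + m[:, 2][None, :]
        return cls(out.reshape(ident.coeffs.shape), ident.spacing, shape)

    # ------------------------------------------------------------------ #
    @property
    def identity_coeffs(self) -> np.ndarray:
        return BSplineField.identity(self.shape, self.spacing).coeffs

    def _grid_bases(self, deriv_x: bool = False, deriv_y: bool = False):
        h, w = self.shape
        sx, sy = self.spacing
        bx = basis_matrix(np.arange(w), sx, self.coeffs.shape[1], deriv=deriv_x)
        by = basis_matrix(np.arange(h), sy, self.coeffs.shape[0], deriv=deriv_y)
        return bx, by

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate on the full pixel grid; returns (gx, gy) each (H, W)."""
        bx, by = self._grid_bases()
        gx = by @ self.coeffs[:, :, 0] @ bx.T
        gy = by @ self.coeffs[:, :, 1] @ bx.T
        return gx, gy

    def displacement_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) = g(x, y) - (x, y) on the full pixel grid.

        Evaluated from the coefficient deviation against the identity
        placement so an exactly-identity field yields exactly zero.
        """
        bx, by = self._grid_bases()
        d = self.coeffs - self.identity_coeffs
        return by @ d[:, :, 0] @ bx.T, by @ d[:, :, 1] @ bx.T

    def mean_displacement(self) -> float:
        u, v = self.displacement_grid()
        return float(np.mean(np.hypot(u, v)))

    def derivative_grids(self):
        """(dgx/dx, dgx/dy, dgy/dx, dgy/dy) on the full pixel grid."""
        bx, by = self._grid_bases()
        bxd, byd = self._grid_bases(deriv_x=True, deriv_y=True)
        cx, cy = self.coeffs[:, :, 0], self.coeffs[:, :, 1]
        return (
            by @ cx @ bxd.T,
            byd @ cx @ bx.T,
            by @ cy @ bxd.T,
            byd @ cy @ bx.T,
        )

    # ------------------------------------------------------------------ #
    def evaluate(self, points: np.ndarray, check_domain: bool = True) -> np.ndarray:
        """Evaluate at scattered (x, y) points, shape (P, 2).

        With ``check_domain`` points outside [0, W-1] x [0, H-1] raise
        DomainError; otherwise the spline is evaluated wherever its support
        is covered and NaN is returned elsewhere.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        h, w = self.shape
        sx, sy = self.spacing
        if check_domain:
            bad = (
                (pts[:, 0] < 0)
                | (pts[:, 0] > w - 1)
                | (pts[:, 1] < 0)
                | (pts[:, 1] > h - 1)
            )
            if np.any(bad):
                raise DomainError(
                    f"{int(bad.sum())} point(s) outside domain {w - 1} x {h - 1}"
                )
        nl, nk = self.coeffs.shape[:2]
        ix, wx, vx = _local_weights(pts[:, 0] / sx, nk)
        iy, wy, vy = _local_weights(pts[:, 1] / sy, nl)
        out = np.zeros((pts.shape[0], 2))
        for a in range(4):
            for b in range(4):
                out += self.coeffs[iy[:, a], ix[:, b]] * (
                    wy[:, a] * wx[:, b]
                )[:, None]
        invalid = ~(vx & vy)
        if np.any(invalid):
            out[invalid] = np.nan
        return out

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.evaluate(points, check_domain=True)

    def jacobian(self, points: np.ndarray) -> np.ndarray:
        """Jacobian d(gx, gy)/d(x, y) at scattered points; (P, 2, 2)."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        sx, sy = self.spacing
        nl, nk = self.coeffs.shape[:2]
        ix, wx, _ = _local_weights(pts[:, 0] / sx, nk)
        iy, wy, _ = _local_weights(pts[:, 1] / sy, nl)
        _, wxd, _ = _local_weights(pts[:, 0] / sx, nk, deriv=True)
        _, wyd, _ = _local_weights(pts[:, 1] / sy, nl, deriv=True)
        wxd = wxd / sx
        wyd = wyd / sy
        jac = np.zeros((pts.shape[0], 2, 2))
        for a in range(4):
            for b in range(4):
                c = self.coeffs[iy[:, a], ix[:, b]]
                jac[:, :, 0] += c * (wy[:, a] * wxd[:, b])[:, None]
                jac[:, :, 1] += c * (wyd[:, a] * wx[:, b])[:, None]
        return jac

    def copy(self) -> "BSplineField":
        return BSplineField(self.coeffs.copy(), self.spacing, self.shape)


# ---------------------------------------------------------------------- #
def fit_field(
    gx: np.ndarray,
    gy: np.ndarray,
    spacing: tuple[float, float],
    shape: tuple[int, int] | None = None,
) -> BSplineField:
    """Least-squares fit of a B-spline field to full-grid target maps."""
    if shape is None:
        shape = gx.shape
    h, w = shape
    sx, sy = spacing
    bx = basis_matrix(np.arange(w), sx, n_coeffs(w, sx))
    by = basis_matrix(np.arange(h), sy, n_coeffs(h, sy))
    coeffs = np.empty((by.shape[1], bx.shape[1], 2))
    for comp, g in enumerate((gx, gy)):
        a, *_ = np.linalg.lstsq(by, np.asarray(g, dtype=np.float64), rcond=None)
        c, *_ = np.linalg.lstsq(bx, a.T, rcond=None)
        coeffs[:, :, comp] = c.T
    return BSplineField(coeffs, (sx, sy), (h, w))


def warp_image(img: np.ndarray, field: BSplineField) -> np.ndarray:
    """Backward-warp an image by a field: out(x) = img(g(x)).

    Bilinear sampling, out-of-domain pixels 0.  uint8 in, uint8 out;
    float input stays float.
    """
    img = np.asarray(img)
    if img.shape[:2] != field.shape:
        raise DomainError(
            f"image shape {img.shape[:2]} does not match field domain {field.shape}"
        )
    gx, gy = field.grid()
    coords = np.stack([gy, gx])

    def _one(channel: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            channel.astype(np.float64), coords, order=1, mode="constant", cval=0.0
        )

    if img.ndim == 2:
        out = _one(img)
    else:
        out = np.stack([_one(img[:, :, c]) for c in range(img.shape[2])], axis=-1)
    if img.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out


def sample_bilinear(img: np.ndarray, xs: np.ndarray, ys: np.ndarray):
    """Bilinear sample with exact spatial gradient of the interpolant.

    Returns (value, d/dx, d/dy, in_domain_mask); out-of-domain entries are 0.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    mask = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    x = np.clip(xs, 0, w - 1)
    y = np.clip(ys, 0, h - 1)
    x0 = np.clip(np.floor(x).astype(np.int64), 0, w - 2)
    y0 = np.clip(np.floor(y).astype(np.int64), 0, h - 2)
    fx = x - x0
    fy = y - y0
    flat = img.ravel()
    base = y0 * w + x0
    i00 = flat[base]
    i01 = flat[base + 1]
    i10 = flat[base + w]
    i11 = flat[base + w + 1]
    gy = 1.0 - fy
    gx = 1.0 - fx
    val = gy * (gx * i00 + fx * i01) + fy * (gx * i10 + fx * i11)
    dvdx = gy * (i01 - i00) + fy * (i11 - i10)
    dvdy = gx * (i10 - i00) + fx * (i11 - i01)
    fmask = mask.astype(np.float64)
    return val * fmask, dvdx * fmask, dvdy * fmask, mask
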