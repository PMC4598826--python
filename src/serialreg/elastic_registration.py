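"""Area-based bidirectional elastic refinement.

Both deformation directions (source->target and target->source) are cubic
B-spline fields optimized jointly, coarse-to-fine over a control-grid
pyramid, by minimizing

    E = w_img (E_img_st + E_img_ts) + w_div (E_div_st + E_div_ts)
      + w_rot (E_rot_st + E_rot_ts) + w_cons E_cons

with analytic gradients for every term.  E_img is the mean squared
intensity difference after backward warping; E_div / E_rot penalize the
squared divergence and curl of the displacement; E_cons penalizes the two
fields failing to be mutual inverses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import minimize
from skimage.transform import resize

from .bspline import (
    BSplineField,
    basis_matrix,
    fit_field,
    sample_bilinear,
    warp_image,
)
from .coarse_registration import GlobalTransform2D, identity_transform
from .errors import DomainError, OptimizationDivergedError, ShapeError
from .preprocess import FeatureImage

__all__ = [
    "EnergyWeights",
    "ElasticParams",
    "PairElasticResult",
    "eval_field",
    "warp_image",
    "energy_image",
    "energy_regularization",
    "energy_consistency",
    "register_elastic",
    "compose_with_global",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnergyWeights:
    w_img: float = 1.0
    w_div: float = 0.1
    w_rot: float = 0.1
    w_cons: float = 1.0

    def __post_init__(self) -> None:
        if self.w_img <= 0:
            raise ValueError("w_img must be positive")
        if min(self.w_div, self.w_rot, self.w_cons) < 0:
            raise ValueError("energy weights must be nonnegative")


@dataclass(frozen=True)
class ElasticParams:
    spacing_px: float = 16.0
    pyramid_levels: int = 3
    max_iters: int = 200
    tol: float = 1e-5
    cons_stride: int = 4
    # pixel stride for the optimizer's sampled image/regularization sums; the
    # public energy operations always use the full grid
    img_stride: int = 2


@dataclass
class PairElasticResult:
    warped_source: np.ndarray
    field_fwd: BSplineField  # source -> target (samples source at target pixels)
    field_bwd: BSplineField  # target -> source
    final_energy: float
    energy_trace: list[float] = dc_field(default_factory=list)


def eval_field(f: BSplineField, points: np.ndarray) -> np.ndarray:
    """Evaluate g at (x, y) points; raises DomainError outside the domain."""
    return f(points)


def energy_image(src: np.ndarray, tgt: np.ndarray, f_st: BSplineField) -> float:
    """Mean squared intensity difference of warp(src, f_st) against tgt.

    Averaged over pixels whose warped sample stays inside the source domain.
    """
    src = np.asarray(src, dtype=np.float64)
    tgt = np.asarray(tgt, dtype=np.float64)
    if src.shape != tgt.shape:
        raise ShapeError(f"shape mismatch: {src.shape} vs {tgt.shape}")
    gx, gy = f_st.grid()
    val, _, _, mask = sample_bilinear(src, gx, gy)
    m = int(mask.sum())
    if m == 0:
        raise DomainError("no overlap between warped source and target")
    diff = (val - tgt)[mask]
    return float(np.mean(diff * diff))


def energy_regularization(f: BSplineField) -> tuple[float, float]:
    """(E_div, E_rot): mean squared divergence and curl of the displacement."""
    dgxdx, dgxdy, dgydx, dgydy = f.derivative_grids()
    div = (dgxdx - 1.0) + (dgydy - 1.0)
    rot = dgydx - dgxdy
    return float(np.mean(div * div)), float(np.mean(rot * rot))


def energy_consistency(
    f_st: BSplineField, f_ts: BSplineField, stride: int = 1
) -> float:
    """Mean squared round-trip error of the two fields, both directions."""
    if f_st.shape != f_ts.shape:
        raise ShapeError("consistency requires fields on the same domain")
    h, w = f_st.shape

    def _one_way(fa: BSplineField, fb: BSplineField) -> float:
        ys, xs = np.mgrid[0:h:stride, 0:w:stride]
        pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(np.float64)
        p = fa.evaluate(pts, check_domain=False)
        keep = (
            np.isfinite(p).all(axis=1)
            & (p[:, 0] >= 0)
            & (p[:, 0] <= w - 1)
            & (p[:, 1] >= 0)
            & (p[:, 1] <= h - 1)
        )
        if not keep.any():
            return 0.0
        q = fb.evaluate(p[keep], check_domain=False)
        ok = np.isfinite(q).all(axis=1)
        r = q[ok] - pts[keep][ok]
        if r.size == 0:
            return 0.0
        return float(np.mean(np.sum(r * r, axis=1)))

    return 0.5 * (_one_way(f_st, f_ts) + _one_way(f_ts, f_st))


# ------------------------------------------------------------------ #
class _LevelModel:
    """Energy + analytic gradient for one pyramid level.

    Parameter vector is the concatenated coefficient deviation of both
    fields from their initialization.
    """

    def __init__(
        self, src, tgt, shape, spacing, init_st, init_ts, weights, stride, img_stride=1
    ):
        self.src = np.asarray(src, dtype=np.float64)
        self.tgt = np.asarray(tgt, dtype=np.float64)
        self.h, self.w = shape
        self.spacing = spacing
        self.c0_st = init_st
        self.c0_ts = init_ts
        self.wt = weights
        self.nl, self.nk = init_st.shape[:2]
        sx = sy = spacing
        xs = np.arange(0, self.w, img_stride, dtype=np.float64)
        ys = np.arange(0, self.h, img_stride, dtype=np.float64)
        self.src_sub = self.src[::img_stride, ::img_stride]
        self.tgt_sub = self.tgt[::img_stride, ::img_stride]
        self.bx = basis_matrix(xs, sx, self.nk)
        self.by = basis_matrix(ys, sy, self.nl)
        self.bxd = basis_matrix(xs, sx, self.nk, deriv=True)
        self.byd = basis_matrix(ys, sy, self.nl, deriv=True)
        self.n_samples = xs.size * ys.size
        # consistency subgrid
        self.cons_x = np.arange(0, self.w, stride, dtype=np.float64)
        self.cons_y = np.arange(0, self.h, stride, dtype=np.float64)
        self.bxc = basis_matrix(self.cons_x, sx, self.nk)
        self.byc = basis_matrix(self.cons_y, sy, self.nl)
        self.npar = self.nl * self.nk * 2
        self._last_x: np.ndarray | None = None
        self._last_f: float = np.inf

    def cached_energy(self, theta: np.ndarray) -> float:
        """Energy at theta, reusing the most recent objective evaluation."""
        if self._last_x is not None and np.array_equal(theta, self._last_x):
            return self._last_f
        return self.energy(theta, want_grad=False)

    # -- helpers ---------------------------------------------------- #
    def _split(self, theta):
        d_st = theta[: self.npar].reshape(self.nl, self.nk, 2)
        d_ts = theta[self.npar :].reshape(self.nl, self.nk, 2)
        return self.c0_st + d_st, self.c0_ts + d_ts

    def _image_term(self, moving, fixed, c, want_grad):
        """moving: full-resolution image; fixed: image on the sample subgrid."""
        gx = self.by @ c[:, :, 0] @ self.bx.T
        gy = self.by @ c[:, :, 1] @ self.bx.T
        val, dvx, dvy, mask = sample_bilinear(moving, gx, gy)
        m = max(int(mask.sum()), 1)
        r = np.where(mask, val - fixed, 0.0)
        e = float(np.sum(r * r) / m)
        if not want_grad:
            return e, None
        gcx = (2.0 / m) * (self.by.T @ (r * dvx) @ self.bx)
        gcy = (2.0 / m) * (self.by.T @ (r * dvy) @ self.bx)
        return e, np.stack([gcx, gcy], axis=-1)

    def _reg_term(self, c, want_grad):
        dgxdx = self.by @ c[:, :, 0] @ self.bxd.T
        dgxdy = self.byd @ c[:, :, 0] @ self.bx.T
        dgydx = self.by @ c[:, :, 1] @ self.bxd.T
        dgydy = self.byd @ c[:, :, 1] @ self.bx.T
        div = dgxdx + dgydy - 2.0
        rot = dgydx - dgxdy
        n = self.n_samples
        e_div = float(np.sum(div * div) / n)
        e_rot = float(np.sum(rot * rot) / n)
        if not want_grad:
            return e_div, e_rot, None, None
        g_div = np.stack(
            [
                (2.0 / n) * (self.by.T @ div @ self.bxd),
                (2.0 / n) * (self.byd.T @ div @ self.bx),
            ],
            axis=-1,
        )
        g_rot = np.stack(
            [
                (-2.0 / n) * (self.byd.T @ rot @ self.bx),
                (2.0 / n) * (self.by.T @ rot @ self.bxd),
            ],
            axis=-1,
        )
        return e_div, e_rot, g_div, g_rot

    def _cons_term(self, c_in, c_out, want_grad):
        """One direction: f_out(f_in(x)) vs x on the consistency subgrid."""
        from .bspline import _local_weights

        px = self.byc @ c_in[:, :, 0] @ self.bxc.T
        py = self.byc @ c_in[:, :, 1] @ self.bxc.T
        hs, ws = px.shape
        keep = (px >= 0) & (px <= self.w - 1) & (py >= 0) & (py <= self.h - 1)
        pts_x = px.ravel()
        pts_y = py.ravel()
        ix, wx, vx = _local_weights(pts_x / self.spacing, self.nk)
        iy, wy, vy = _local_weights(pts_y / self.spacing, self.nl)
        valid = keep.ravel() & vx & vy
        n_valid = max(int(valid.sum()), 1)
        qx = np.zeros_like(pts_x)
        qy = np.zeros_like(pts_y)
        for a in range(4):
            for b in range(4):
                wgt = wy[:, a] * wx[:, b]
                qx += c_out[iy[:, a], ix[:, b], 0] * wgt
                qy += c_out[iy[:, a], ix[:, b], 1] * wgt
        rx = np.where(valid, qx - np.tile(self.cons_x, hs), 0.0)
        ry = np.where(valid, qy - np.repeat(self.cons_y, ws), 0.0)
        e = float((np.sum(rx * rx) + np.sum(ry * ry)) / n_valid)
        if not want_grad:
            return e, None, None
        # gradient wrt the outer field: scatter basis-weighted residuals
        scale = 2.0 / n_valid
        ncoef = self.nl * self.nk
        flat_idx = np.concatenate(
            [iy[:, a] * self.nk + ix[:, b] for a in range(4) for b in range(4)]
        )
        wflat = np.concatenate([wy[:, a] * wx[:, b] for a in range(4) for b in range(4)])
        gx_out = np.bincount(flat_idx, weights=wflat * np.tile(rx, 16), minlength=ncoef)
        gy_out = np.bincount(flat_idx, weights=wflat * np.tile(ry, 16), minlength=ncoef)
        g_out = scale * np.stack(
            [gx_out.reshape(self.nl, self.nk), gy_out.reshape(self.nl, self.nk)],
            axis=-1,
        )
        # gradient wrt the inner field: chain through the outer Jacobian
        _, wxd, _ = _local_weights(pts_x / self.spacing, self.nk, deriv=True)
        _, wyd, _ = _local_weights(pts_y / self.spacing, self.nl, deriv=True)
        wxd = wxd / self.spacing
        wyd = wyd / self.spacing
        j = np.zeros((pts_x.size, 2, 2))  # d(qx,qy)/d(px,py)
        for a in range(4):
            for b in range(4):
                cvals = c_out[iy[:, a], ix[:, b]]
                j[:, :, 0] += cvals * (wy[:, a] * wxd[:, b])[:, None]
                j[:, :, 1] += cvals * (wyd[:, a] * wx[:, b])[:, None]
        sx = np.where(valid, j[:, 0, 0] * rx + j[:, 1, 0] * ry, 0.0).reshape(hs, ws)
        sy = np.where(valid, j[:, 0, 1] * rx + j[:, 1, 1] * ry, 0.0).reshape(hs, ws)
        g_in = np.stack(
            [
                scale * (self.byc.T @ sx @ self.bxc),
                scale * (self.byc.T @ sy @ self.bxc),
            ],
            axis=-1,
        )
        return e, g_in, g_out

    # -- objective -------------------------------------------------- #
    def energy(self, theta, want_grad=True):
        c_st, c_ts = self._split(theta)
        w = self.wt
        e_img_st, g_img_st = self._image_term(self.src, self.tgt_sub, c_st, want_grad)
        e_img_ts, g_img_ts = self._image_term(self.tgt, self.src_sub, c_ts, want_grad)
        e_div_st, e_rot_st, gd_st, gr_st = self._reg_term(c_st, want_grad)
        e_div_ts, e_rot_ts, gd_ts, gr_ts = self._reg_term(c_ts, want_grad)
        e_c1, gc1_in, gc1_out = self._cons_term(c_st, c_ts, want_grad)
        e_c2, gc2_in, gc2_out = self._cons_term(c_ts, c_st, want_grad)
        e = (
            w.w_img * (e_img_st + e_img_ts)
            + w.w_div * (e_div_st + e_div_ts)
            + w.w_rot * (e_rot_st + e_rot_ts)
            + w.w_cons * 0.5 * (e_c1 + e_c2)
        )
        if not np.isfinite(e):
            raise OptimizationDivergedError("optimization diverged: non-finite energy")
        self._last_x = np.array(theta, copy=True)
        self._last_f = e
        if not want_grad:
            return e
        g_st = (
            w.w_img * g_img_st
            + w.w_div * gd_st
            + w.w_rot * gr_st
            + w.w_cons * 0.5 * (gc1_in + gc2_out)
        )
        g_ts = (
            w.w_img * g_img_ts
            + w.w_div * gd_ts
            + w.w_rot * gr_ts
            + w.w_cons * 0.5 * (gc1_out + gc2_in)
        )
        return e, np.concatenate([g_st.ravel(), g_ts.ravel()])


def _resize_level(img: np.ndarray, shape) -> np.ndarray:
    if img.shape == tuple(shape):
        return np.asarray(img, dtype=np.float64)
    return resize(
        np.asarray(img, dtype=np.float64),
        shape,
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )


def _scale_transform(t: GlobalTransform2D, factor: float) -> GlobalTransform2D:
    """Transform acting on coordinates divided by ``factor``."""
    m = t.matrix.copy()
    m[:, 2] /= factor
    return GlobalTransform2D(t.model_class, m)


def register_elastic(
    src: FeatureImage | np.ndarray,
    tgt: FeatureImage | np.ndarray,
    init: GlobalTransform2D | None = None,
    weights: EnergyWeights | None = None,
    params: ElasticParams | None = None,
) -> PairElasticResult:
    """Jointly optimize forward and backward fields over a grid pyramid.

    The forward field is initialized from the inverse of ``init`` (it samples
    the source at target-frame pixels) and therefore already contains the
    coarse global component; the returned forward field is the total
    deformation of the source.
    """
    src_img = src.pixels if isinstance(src, FeatureImage) else np.asarray(src)
    tgt_img = tgt.pixels if isinstance(tgt, FeatureImage) else np.asarray(tgt)
    if src_img.shape != tgt_img.shape:
        raise ShapeError(f"shape mismatch: {src_img.shape} vs {tgt_img.shape}")
    weights = weights or EnergyWeights()
    params = params or ElasticParams()
    init = init or identity_transform()
    h, w = src_img.shape
    s0 = float(params.spacing_px)
    factors = [2 ** (params.pyramid_levels - 1 - i) for i in range(params.pyramid_levels)]

    f_st: BSplineField | None = None
    f_ts: BSplineField | None = None
    trace: list[float] = []
    final_e = np.inf
    for factor in factors:
        lvl_shape = (int(np.ceil(h / factor)), int(np.ceil(w / factor)))
        if min(lvl_shape) < 4 * s0 and factor != factors[-1]:
            continue  # level too coarse for the control grid; skip
        lsrc = _resize_level(src_img, lvl_shape)
        ltgt = _resize_level(tgt_img, lvl_shape)
        if f_st is None:
            t_lvl = _scale_transform(init, factor)
            f_st = BSplineField.from_affine(t_lvl.inverse().matrix, lvl_shape, (s0, s0))
            f_ts = BSplineField.from_affine(t_lvl.matrix, lvl_shape, (s0, s0))
        else:
            f_st = _transfer_field(f_st, lvl_shape, s0)
            f_ts = _transfer_field(f_ts, lvl_shape, s0)
        model = _LevelModel(
            lsrc,
            ltgt,
            lvl_shape,
            s0,
            f_st.coeffs.copy(),
            f_ts.coeffs.copy(),
            weights,
            params.cons_stride,
            params.img_stride,
        )
        trace = [model.energy(np.zeros(2 * model.npar), want_grad=False)]

        def _cb(xk, model=model, trace=trace):
            trace.append(model.cached_energy(xk))

        res = minimize(
            model.energy,
            np.zeros(2 * model.npar),
            jac=True,
            method="L-BFGS-B",
            callback=_cb,
            options={"maxiter": params.max_iters, "ftol": params.tol, "maxcor": 20},
        )
        c_st, c_ts = model._split(res.x)
        f_st = BSplineField(c_st, (s0, s0), lvl_shape)
        f_ts = BSplineField(c_ts, (s0, s0), lvl_shape)
        final_e = float(res.fun)
    warped = warp_image(src_img, f_st)
    return PairElasticResult(warped, f_st, f_ts, final_e, trace)


def _transfer_field(f: BSplineField, new_shape, spacing: float) -> BSplineField:
    """Resample a field onto a finer-level domain: g'(x) = rho * g(x / rho)."""
    oh, ow = f.shape
    nh, nw = new_shape
    rho_x = nw / ow
    rho_y = nh / oh
    bx = basis_matrix(np.arange(nw) / rho_x, f.spacing[0], f.coeffs.shape[1])
    by = basis_matrix(np.arange(nh) / rho_y, f.spacing[1], f.coeffs.shape[0])
    gx = rho_x * (by @ f.coeffs[:, :, 0] @ bx.T)
    gy = rho_y * (by @ f.coeffs[:, :, 1] @ bx.T)
    return fit_field(gx, gy, (spacing, spacing), (nh, nw))


def compose_with_global(t: GlobalTransform2D, f: BSplineField) -> BSplineField:
    """Field whose evaluation equals f(T(x)), refit on the same control grid.

    Points T(x) outside the field domain are linearly extended from the
    nearest in-domain point before the refit.
    """
    h, w = f.shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(np.float64)
    tp = t.apply(pts)
    clipped = np.clip(tp, [0, 0], [w - 1, h - 1])
    vals = f.evaluate(clipped, check_domain=False)
    off = tp - clipped
    outside = np.any(off != 0, axis=1)
    if outside.any():
        jac = f.jacobian(clipped[outside])
        vals[outside] += np.einsum("pij,pj->pi", jac, off[outside])
    gx = vals[:, 0].reshape(h, w)
    gy = vals[:, 1].reshape(h, w)
    return fit_field(gx, gy, f.spacing, (h, w))
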