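import numpy as np
import pytest

from serialreg.bspline import BSplineField, warp_image
from serialreg.coarse_registration import GlobalTransform2D, identity_transform
from serialreg.elastic_registration import (
    ElasticParams,
    EnergyWeights,
    compose_with_global,
    energy_consistency,
    energy_image,
    energy_regularization,
    register_elastic,
)
from serialreg.errors import ShapeError
from serialreg.synth import random_field

SHAPE = (128, 128)
SPACING = (16.0, 16.0)


def identity(shape=SHAPE, spacing=SPACING):
    return BSplineField.identity(shape, spacing)


def translation(tx, ty, shape=SHAPE, spacing=SPACING):
    f = identity(shape, spacing)
    return BSplineField(f.coeffs + np.array([tx, ty]), spacing, shape)


class TestEnergyImage:
    def test_self_zero(self, texture128):
        assert energy_image(texture128, texture128, identity()) == pytest.approx(0.0, abs=1e-18)

    def test_constant_offset(self, texture128):
        src = np.clip(texture128.astype(int), 0, 245).astype(np.uint8)
        tgt = (src + 10).astype(np.uint8)
        assert energy_image(src, tgt, identity()) == pytest.approx(100.0)

    def test_per_pixel_oracle(self, rng):
        src = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        tgt = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        f = translation(1.0, 0.0, (32, 32), (8.0, 8.0))
        got = energy_image(src, tgt, f)
        # brute force: warped(x) = src(x+1); in-domain for x <= 30
        acc = []
        for y in range(32):
            for x in range(31):
                acc.append((float(src[y, x + 1]) - float(tgt[y, x])) ** 2)
        assert got == pytest.approx(np.mean(acc))

    def test_shape_mismatch(self, rng):
        with pytest.raises(ShapeError):
            energy_image(np.zeros((16, 16)), np.zeros((16, 17)), identity((16, 16), (8, 8)))


class TestEnergyRegularization:
    def test_identity_zero(self):
        e_div, e_rot = energy_regularization(identity())
        assert e_div == pytest.approx(0.0, abs=1e-18)
        assert e_rot == pytest.approx(0.0, abs=1e-18)

    def test_translation_zero(self):
        e_div, e_rot = energy_regularization(translation(4.0, -7.0))
        assert e_div == pytest.approx(0.0, abs=1e-16)
        assert e_rot == pytest.approx(0.0, abs=1e-16)

    def test_uniform_scaling_closed_form(self):
        # u = eps*x, v = eps*y  ->  div = 2 eps, rot = 0
        eps = 0.01
        m = np.array([[1 + eps, 0.0, 0.0], [0.0, 1 + eps, 0.0]])
        f = BSplineField.from_affine(m, SHAPE, SPACING)
        e_div, e_rot = energy_regularization(f)
        assert e_div == pytest.approx((2 * eps) ** 2, rel=1e-6)
        assert e_rot == pytest.approx(0.0, abs=1e-12)

    def test_analytic_vs_central_differences(self, rng):
        f = random_field(SHAPE, 3.0, 24.0, seed=7)
        dgxdx, dgxdy, dgydx, dgydy = f.derivative_grids()
        h = 0.5
        ys, xs = np.mgrid[2 : SHAPE[0] - 2, 2 : SHAPE[1] - 2]
        pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        for axis, (anx, any_) in enumerate(
            [(dgxdx, dgydx), (dgxdy, dgydy)]
        ):
            dp = np.zeros(2)
            dp[axis] = h
            num = (f(pts + dp) - f(pts - dp)) / (2 * h)
            got_x = anx[2 : SHAPE[0] - 2, 2 : SHAPE[1] - 2].ravel()
            got_y = any_[2 : SHAPE[0] - 2, 2 : SHAPE[1] - 2].ravel()
            np.testing.assert_allclose(num[:, 0], got_x, atol=2e-3)
            np.testing.assert_allclose(num[:, 1], got_y, atol=2e-3)


class TestEnergyConsistency:
    def test_both_identity(self):
        assert energy_consistency(identity(), identity(), stride=4) == pytest.approx(0.0, abs=1e-18)

    def test_exact_inverses(self):
        f = translation(6.0, 0.0)
        g = translation(-6.0, 0.0)
        assert energy_consistency(f, g, stride=4) == pytest.approx(0.0, abs=1e-16)

    def test_one_sided_translation_closed_form(self):
        d = 5.0
        e = energy_consistency(translation(d, 0.0), identity(), stride=4)
        assert e == pytest.approx(d * d, rel=1e-9)


class TestRegisterElastic:
    def test_self_registration_fixed_point(self, texture128):
        res = register_elastic(texture128, texture128, None, None, ElasticParams(pyramid_levels=2))
        assert res.field_fwd.mean_displacement() <= 0.25
        assert res.field_bwd.mean_displacement() <= 0.25

    def test_planted_field_recovery(self, texture256):
        truth = random_field((256, 256), 4.0, 48.0, seed=1)
        src = warp_image(texture256, truth)
        res = register_elastic(src, texture256)
        # f_bwd warps target into the source frame, so it should match truth
        gx, gy = res.field_bwd.grid()
        tx, ty = truth.grid()
        epe = np.hypot(gx - tx, gy - ty)[32:-32, 32:-32]
        assert epe.mean() <= 1.0

    def test_energy_trace_non_increasing(self, texture128):
        truth = random_field(SHAPE, 3.0, 48.0, seed=2)
        src = warp_image(texture128, truth)
        res = register_elastic(src, texture128, None, None, ElasticParams(pyramid_levels=2))
        diffs = np.diff(res.energy_trace)
        assert np.all(diffs <= 1e-9)

    def test_consistency_dominant_limit(self, texture128):
        truth = translation(4.0, 0.0)
        src = warp_image(texture128, truth)
        w = EnergyWeights(w_img=1.0, w_div=0.1, w_rot=0.1, w_cons=500.0)
        res = register_elastic(src, texture128, None, w, ElasticParams(pyramid_levels=2))
        e = energy_consistency(res.field_fwd, res.field_bwd, stride=2)
        assert np.sqrt(e) < 0.5

    def test_deterministic(self, texture128):
        truth = random_field(SHAPE, 3.0, 48.0, seed=3)
        src = warp_image(texture128, truth)
        p = ElasticParams(pyramid_levels=2, max_iters=30)
        r1 = register_elastic(src, texture128, None, None, p)
        r2 = register_elastic(src, texture128, None, None, p)
        np.testing.assert_array_equal(r1.field_fwd.coeffs, r2.field_fwd.coeffs)
        assert r1.energy_trace == r2.energy_trace


class TestOptimizerGradient:
    def test_analytic_gradient_matches_finite_difference(self, rng):
        from serialreg.elastic_registration import _LevelModel

        shape = (48, 48)
        src = rng.integers(0, 256, shape).astype(np.float64)
        tgt = rng.integers(0, 256, shape).astype(np.float64)
        ident = BSplineField.identity(shape, (16.0, 16.0))
        model = _LevelModel(
            src, tgt, shape, 16.0, ident.coeffs, ident.coeffs,
            EnergyWeights(1.0, 0.1, 0.1, 1.0), stride=2, img_stride=1,
        )
        theta = rng.normal(0, 0.5, 2 * model.npar)
        _, grad = model.energy(theta)
        h = 1e-5
        idxs = rng.choice(theta.size, 25, replace=False)
        for i in idxs:
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            num = (model.energy(tp, want_grad=False) - model.energy(tm, want_grad=False)) / (2 * h)
            assert grad[i] == pytest.approx(num, rel=2e-3, abs=1e-7)


class TestComposeWithGlobal:
    def test_identity_transform_unchanged(self):
        f = random_field(SHAPE, 3.0, 32.0, seed=4)
        comp = compose_with_global(identity_transform(), f)
        gx0, gy0 = f.grid()
        gx1, gy1 = comp.grid()
        assert np.abs(gx1 - gx0).mean() < 0.1
        assert np.abs(gy1 - gy0).mean() < 0.1

    def test_translation_of_identity(self):
        t = GlobalTransform2D("translation", np.array([[1.0, 0, 4.0], [0, 1.0, -3.0]]))
        comp = compose_with_global(t, identity())
        u, v = comp.displacement_grid()
        np.testing.assert_allclose(u, 4.0, atol=1e-6)
        np.testing.assert_allclose(v, -3.0, atol=1e-6)

    def test_pointwise_composition_oracle(self, rng):
        t = GlobalTransform2D(
            "affine", np.array([[0.98, 0.03, 2.0], [-0.02, 1.01, -1.0]])
        )
        f = random_field(SHAPE, 3.0, 32.0, seed=5)
        comp = compose_with_global(t, f)
        pts = np.column_stack([rng.uniform(5, 120, 200), rng.uniform(5, 120, 200)])
        want = f.evaluate(np.clip(t.apply(pts), 0, 127), check_domain=False)
        got = comp(pts)
        err = np.linalg.norm(got - want, axis=1)
        assert err.mean() < 0.1
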