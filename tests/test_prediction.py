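import numpy as np
import pandas as pd
import pytest

from ogdex import prediction as pr
from ogdex import synthetic_data as sd
from ogdex.climate_terrain import COVARIATE_NAMES
from ogdex.hierarchical_model import ModelParameters
from ogdex.raster import RasterGrid


def simple_params(beta0=-3.0, beta1=0.02, lin=None, quad=None):
    return ModelParameters(
        beta0=beta0,
        beta1=beta1,
        beta_lin=np.zeros(6) if lin is None else np.asarray(lin, float),
        beta_quad=np.zeros(6) if quad is None else np.asarray(quad, float),
        period_eff=np.zeros(2),
        sigma_plot=0.1,
        sigma_resid=0.3,
    )


Z0 = np.zeros(6)


class TestDevelopmentRate:
    def test_centered_covariates_give_intercept(self):
        assert pr.development_rate(simple_params(), Z0) == pytest.approx(0.02)

    def test_linear_when_no_quadratic(self):
        p = simple_params(lin=[0.01, 0, 0, 0, 0, 0])
        z = np.zeros(6)
        z[0] = 2.0
        assert pr.development_rate(p, z) == pytest.approx(0.02 + 0.02)

    def test_vectorised_equals_loop(self):
        rng = np.random.default_rng(0)
        p = simple_params(lin=rng.normal(0, 0.01, 6), quad=rng.normal(0, 0.01, 6))
        Z = rng.standard_normal((50, 6))
        vec = pr.development_rate(p, Z)
        loop = [
            p.beta1 + sum(p.beta_lin[k] * z[k] + p.beta_quad[k] * z[k] ** 2
                          for k in range(6))
            for z in Z
        ]
        np.testing.assert_allclose(vec, loop, atol=1e-12)

    def test_missing_covariate_error(self):
        with pytest.raises(ValueError):
            pr.development_rate(simple_params(), np.zeros(5))
        bad = np.zeros(6)
        bad[2] = np.nan
        with pytest.raises(ValueError):
            pr.development_rate(simple_params(), bad)


class TestPredictIndex:
    def test_linear_predictor_zero_gives_half(self):
        assert pr.predict_index(simple_params(), Z0, 150.0) == pytest.approx(0.5)

    def test_age_zero(self):
        assert pr.predict_index(simple_params(), Z0, 0.0) == pytest.approx(
            0.04743, abs=1e-5
        )

    def test_zero_rate_constant(self):
        p = simple_params(beta1=0.0)
        ages = np.array([0.0, 100.0, 500.0])
        out = pr.predict_index(p, Z0, ages)
        np.testing.assert_allclose(out, out[0])


class TestAgeAtIndex:
    def test_closed_form(self):
        res = pr.age_at_index(simple_params(), Z0, 0.5)
        assert res.reachable and res.t == pytest.approx(150.0, abs=1e-6)

    def test_negative_rate_unreachable(self):
        res = pr.age_at_index(simple_params(beta1=-0.01), Z0, 0.5)
        assert not res.reachable

    def test_beyond_age_max_unreachable(self):
        res = pr.age_at_index(simple_params(beta1=0.001), Z0, 0.9, age_max=1000.0)
        assert not res.reachable

    def test_target_validation(self):
        with pytest.raises(ValueError):
            pr.age_at_index(simple_params(), Z0, 1.0)

    @pytest.mark.parametrize("q", [0.2, 0.5, 0.8])
    def test_inverse_consistency(self, q):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = simple_params(beta0=rng.uniform(-6, -1), beta1=rng.uniform(0.01, 0.1))
            res = pr.age_at_index(p, Z0, q)
            if res.reachable:
                assert pr.predict_index(p, Z0, res.t) == pytest.approx(q, abs=1e-6)

    def test_monotone_in_rate(self):
        t = [pr.age_at_index(simple_params(beta1=c), Z0, 0.5).t
             for c in (0.02, 0.03, 0.05)]
        assert t[0] > t[1] > t[2]


class TestClamp:
    def _rule(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({n: rng.normal(0, 1, 500) for n in COVARIATE_NAMES})
        return pr.ClampRule.from_training(frame), frame

    def test_clamps_only_outside_band(self):
        rule, frame = self._rule()
        name = COVARIATE_NAMES[0]
        out = pr.clamp_covariates(
            pd.DataFrame({n: [0.0, 99.0] for n in COVARIATE_NAMES}), rule
        )
        assert out[name][0] == 0.0  # inside band untouched
        assert out[name][1] == rule.q_high[name]

    def test_idempotent(self):
        rule, frame = self._rule()
        once = pr.clamp_covariates(frame, rule)
        pd.testing.assert_frame_equal(pr.clamp_covariates(once, rule), once)


def uniform_stack(values: dict[str, float], shape=(6, 6), cell=20.0):
    return {
        n: RasterGrid(np.full(shape, values.get(n, 0.0)), cell)
        for n in COVARIATE_NAMES
    }


def identity_scaler():
    from ogdex.hierarchical_model import StandardScaler
    return StandardScaler(
        {n: 0.0 for n in COVARIATE_NAMES}, {n: 1.0 for n in COVARIATE_NAMES}
    )


class TestMaps:
    def test_uniform_stack_matches_scalar(self):
        p = simple_params()
        stack = uniform_stack({})
        t_map = pr.map_t_target(stack, p, identity_scaler(), target=0.5)
        assert t_map.values == pytest.approx(150.0)

    def test_nodata_propagates(self):
        p = simple_params()
        stack = uniform_stack({})
        stack[COVARIATE_NAMES[0]].values[2, 3] = np.nan
        t_map = pr.map_t_target(stack, p, identity_scaler())
        assert np.isnan(t_map.values[2, 3])
        assert np.isnan(t_map.values).sum() == 1

    def test_unreachable_sentinel(self):
        p = simple_params(beta1=-0.01)
        t_map = pr.map_t_target(uniform_stack({}), p, identity_scaler())
        assert np.all(t_map.values == pr.UNREACHABLE)

    def test_geometry_mismatch_error(self):
        stack = uniform_stack({})
        stack[COVARIATE_NAMES[1]] = RasterGrid(np.zeros((5, 5)), 20.0)
        with pytest.raises(ValueError, match="geometry"):
            pr.map_t_target(stack, simple_params(), identity_scaler())

    def test_index_map_inverts_t_map(self):
        p = simple_params(lin=[0.005, 0, 0, -0.002, 0, 0])
        rng = np.random.default_rng(3)
        stack = {
            n: RasterGrid(rng.normal(0, 1, (8, 8)), 20.0) for n in COVARIATE_NAMES
        }
        t_map = pr.map_t_target(stack, p, identity_scaler(), target=0.5)
        age = t_map.like(np.where(t_map.values == pr.UNREACHABLE, np.nan,
                                  t_map.values))
        idx = pr.map_index(stack, age, None, p, identity_scaler())
        reach = np.isfinite(age.values)
        np.testing.assert_allclose(idx.values[reach], 0.5, atol=1e-6)

    def test_mask_all_gives_all_nodata(self):
        stack = uniform_stack({})
        age = RasterGrid(np.full((6, 6), 100.0), 20.0)
        mask = RasterGrid(np.zeros((6, 6)), 20.0)
        idx = pr.map_index(stack, age, mask, simple_params(), identity_scaler())
        assert np.all(np.isnan(idx.values))

    def test_age_monotonicity(self):
        stack = uniform_stack({})
        p = simple_params()
        a1 = RasterGrid(np.full((6, 6), 80.0), 20.0)
        a2 = RasterGrid(np.full((6, 6), 160.0), 20.0)
        i1 = pr.map_index(stack, a1, None, p, identity_scaler())
        i2 = pr.map_index(stack, a2, None, p, identity_scaler())
        assert np.all(i2.values > i1.values)
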