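import numpy as np
import pytest
from scipy.special import expit

import funcfdr as F
from funcfdr.errors import InsufficientDataError, InvalidTuningError
from funcfdr.pi0 import EPS_PI0


def _fully_powered_dataset(pi0_fn, m=20000, seed=5):
    """Alternative p-values all zero: E[xi | z] / (1 - lambda) equals pi0(z)
    exactly, so the thresholding estimators become unbiased for pi0(z)."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(size=m)
    h = (rng.uniform(size=m) < 1.0 - pi0_fn(z)).astype(int)
    p = rng.uniform(size=m)
    p[h == 1] = 0.0
    return F.Dataset.from_arrays(p=p, z_raw=z, h=h)


class TestXiIndicator:
    @pytest.mark.parametrize(
        "p, lam, expected", [(0.7, 0.5, 1), (0.5, 0.5, 0), (0.0, 0.0, 0)]
    )
    def test_strict_threshold(self, p, lam, expected):
        assert F.xi_indicator(p, lam) == expected

    def test_lambda_one_rejected(self):
        with pytest.raises(InvalidTuningError):
            F.xi_indicator(0.5, 1.0)


class TestGlm:
    def test_all_indicators_one_gives_pi0_of_one(self):
        rng = np.random.default_rng(0)
        ds = F.Dataset.from_arrays(
            p=rng.uniform(0.6, 1.0, size=500), z_raw=rng.normal(size=500)
        )
        est = F.estimate_pi0_glm(ds, lam=0.5)
        assert np.all(est(np.linspace(0, 1, 11)) > 0.999)

    def test_uniform_null_estimates_one_everywhere(self):
        rng = np.random.default_rng(2)
        m = 10000
        ds = F.Dataset.from_arrays(
            p=rng.uniform(size=m), z_raw=rng.uniform(size=m)
        )
        est = F.estimate_pi0_glm(ds, lam=0.5)
        # binomial SE of the mean of xi, on the pi0 scale
        se = np.sqrt(0.5 * 0.5 / m) / 0.5
        assert np.all(est(np.array([0.1, 0.5, 0.9])) >= 1.0 - 3 * se)

    def test_recovers_logit_linear_pi0_with_full_power(self):
        pi0_fn = lambda z: expit(-1.0 + 2.0 * z)
        ds = _fully_powered_dataset(pi0_fn)
        est = F.estimate_pi0_glm(ds, lam=0.5)
        for z0 in (0.25, 0.75):
            # binomial SE of the conditional mean, locally ~ m/10 points
            se = np.sqrt(pi0_fn(z0) * (1 - pi0_fn(z0)) / (ds.m / 10)) / 0.5
            assert abs(est(np.array(z0)) - pi0_fn(z0)) < 3 * se

    def test_monotone_in_z(self):
        rng = np.random.default_rng(4)
        m = 3000
        z = rng.uniform(size=m)
        p = rng.uniform(size=m) ** (1 + 2 * z)  # smaller p at large z
        ds = F.Dataset.from_arrays(p=p, z_raw=z)
        vals = F.estimate_pi0_glm(ds, lam=0.5)(np.linspace(0, 1, 101))
        diffs = np.diff(vals)
        assert np.all(diffs <= 1e-12) or np.all(diffs >= -1e-12)


class TestGam:
    def test_df_one_reproduces_glm(self):
        rng = np.random.default_rng(6)
        m = 2000
        ds = F.Dataset.from_arrays(
            p=rng.uniform(size=m) ** 1.5, z_raw=rng.uniform(size=m)
        )
        zg = np.linspace(0, 1, 51)
        glm = F.estimate_pi0_glm(ds, lam=0.5)(zg)
        gam = F.estimate_pi0_gam(ds, lam=0.5, df_grid=[1])(zg)
        np.testing.assert_allclose(gam, glm, atol=1e-6)

    def test_recovers_cosine_pi0_with_full_power(self):
        pi0_fn = lambda z: np.clip(0.6 + 0.3 * np.cos(2 * np.pi * z), 0, 1)
        ds = _fully_powered_dataset(pi0_fn, seed=7)
        est = F.estimate_pi0_gam(ds, lam=0.5)
        for z0, truth in ((0.0, 0.9), (0.5, 0.3), (1.0, 0.9)):
            se = np.sqrt(truth * (1 - truth) / (ds.m / 10)) / 0.5
            assert abs(est(np.array(z0)) - truth) < 3 * se

    def test_all_indicators_one_capped_at_one(self):
        rng = np.random.default_rng(8)
        ds = F.Dataset.from_arrays(
            p=rng.uniform(0.7, 1.0, size=400), z_raw=rng.normal(size=400)
        )
        assert np.all(F.estimate_pi0_gam(ds, lam=0.5)(np.linspace(0, 1, 7)) > 0.999)

    def test_empty_df_grid_rejected(self):
        rng = np.random.default_rng(9)
        ds = F.Dataset.from_arrays(p=rng.uniform(size=100), z_raw=rng.normal(size=100))
        with pytest.raises(InvalidTuningError):
            F.estimate_pi0_gam(ds, lam=0.5, df_grid=[])


class TestKernel:
    def test_storey_scalar_arithmetic(self):
        p = np.array([0.9, 0.8, 0.7, 0.6, 0.1, 0.2, 0.3, 0.4, 0.45, 0.05])
        assert F.storey_pi0(p, 0.5) == pytest.approx(4 / (10 * 0.5))

    def test_uniform_z_estimates_storey_constant(self):
        rng = np.random.default_rng(10)
        m = 10000
        ds = F.Dataset.from_arrays(p=rng.uniform(size=m), z_raw=rng.uniform(size=m))
        est = F.estimate_pi0_kernel(ds, lam=0.5)
        pi0_s = min(1.0, est.params["pi0_storey"])
        zg = np.linspace(0.1, 0.9, 33)
        assert np.max(np.abs(est(zg) - pi0_s)) < 0.05

    def test_conditional_density_integrates_to_one(self):
        rng = np.random.default_rng(11)
        ds = F.Dataset.from_arrays(
            p=rng.uniform(size=5000), z_raw=rng.normal(size=5000)
        )
        est = F.estimate_pi0_kernel(ds, lam=0.5)
        zg = np.linspace(1e-6, 1 - 1e-6, 1024)
        mass = np.trapezoid(est.params["h_lambda"](zg), zg)
        assert abs(mass - 1.0) < 1e-3

    def test_too_few_retained_records(self):
        rng = np.random.default_rng(12)
        ds = F.Dataset.from_arrays(
            p=rng.uniform(0, 0.2, size=100), z_raw=rng.normal(size=100)
        )
        with pytest.raises(InsufficientDataError):
            F.estimate_pi0_kernel(ds, lam=0.9)


class TestInvariants:
    @pytest.mark.parametrize("method", ["glm", "gam", "kernel"])
    def test_range_inside_unit_interval_with_floor(self, method):
        rng = np.random.default_rng(13)
        m = 4000
        ds = F.Dataset.from_arrays(
            p=rng.uniform(size=m) ** 3, z_raw=rng.uniform(size=m)
        )
        vals = F.estimate_pi0(ds, method=method, lam=0.5)(np.linspace(0, 1, 101))
        assert np.all(vals >= EPS_PI0) and np.all(vals <= 1.0)

    def test_kernel_factorization_integral(self):
        """Integral of the kernel pi0(z) over z ~ Storey scalar (h integrates
        to 1), up to the [0,1]-clipping of the product."""
        rng = np.random.default_rng(14)
        m = 8000
        ds = F.Dataset.from_arrays(p=rng.uniform(size=m), z_raw=rng.uniform(size=m))
        est = F.estimate_pi0_kernel(ds, lam=0.5)
        zg = np.linspace(1e-6, 1 - 1e-6, 1024)
        integral = np.trapezoid(
            np.clip(est.params["h_lambda"](zg) * est.params["pi0_storey"], 0, None),
            zg,
        )
        assert abs(integral - est.params["pi0_storey"]) < 2e-3


class TestSelectLambda:
    def test_single_element_grid(self):
        rng = np.random.default_rng(15)
        ds = F.Dataset.from_arrays(p=rng.uniform(size=500), z_raw=rng.uniform(size=500))
        assert F.select_lambda(ds, lambda_grid=[0.4]) == 0.4

    def test_null_only_ties_break_to_smallest(self):
        rng = np.random.default_rng(16)
        ds = F.Dataset.from_arrays(
            p=rng.uniform(size=2000), z_raw=rng.uniform(size=2000)
        )
        lam = F.select_lambda(
            ds, method="glm", lambda_grid=[0.0, 0.2, 0.4, 0.6, 0.8],
            n_bootstrap=30, seed=4,
        )
        assert lam == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(17)
        ds = F.Dataset.from_arrays(
            p=rng.uniform(size=1500) ** 2, z_raw=rng.uniform(size=1500)
        )
        grid = [0.1, 0.3, 0.5]
        a = F.select_lambda(ds, method="glm", lambda_grid=grid, n_bootstrap=20, seed=9)
        b = F.select_lambda(ds, method="glm", lambda_grid=grid, n_bootstrap=20, seed=9)
        assert a == b

    def test_empty_grid_rejected(self):
        rng = np.random.default_rng(18)
        ds = F.Dataset.from_arrays(p=rng.uniform(size=100), z_raw=rng.normal(size=100))
        with pytest.raises(InvalidTuningError):
            F.select_lambda(ds, lambda_grid=[])
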