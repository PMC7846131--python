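import numpy as np
import pytest
from scipy.stats import kstest

import funcfdr as F
from funcfdr.errors import ConfigurationError
from funcfdr.simulate import (
    bayes_error,
    matched_p_threshold,
    oracle_pfdr_pfnr,
    p_threshold_bayes_error,
)


class TestGenerateDataset:
    def test_pure_null_pvalues_are_uniform(self):
        cfg = F.SimulationConfig(m=10000, pi0_spec="constant:c=1", seed=40)
        ds = F.generate_dataset(cfg)
        assert np.all(ds.h == 0)
        assert kstest(ds.p, "uniform").pvalue > 0.001

    def test_all_alternative_beta_mean(self):
        # Beta(0.5, 1) has mean a/(a+1) = 1/3
        cfg = F.SimulationConfig(
            m=10000, pi0_spec="constant:c=0", alt_spec="beta:a=0.5", seed=41
        )
        ds = F.generate_dataset(cfg)
        assert np.all(ds.h == 1)
        se = np.std(ds.p) / np.sqrt(ds.m)
        assert abs(ds.p.mean() - 1 / 3) < 3 * se

    def test_same_seed_bitwise_identical(self):
        cfg = F.SimulationConfig(m=5000, seed=42)
        a, b = F.generate_dataset(cfg), F.generate_dataset(cfg)
        assert np.array_equal(a.p, b.p) and np.array_equal(a.z, b.z)
        assert np.array_equal(a.h, b.h)

    def test_conditional_null_fraction_matches_pi0(self):
        """Pr(H=0 | z in bin) tracks pi0 at bin centres, 20 bins, m=50000."""
        cfg = F.SimulationConfig(
            m=50000, pi0_spec="linear-logit:b0=0.4,b1=1.2", seed=43
        )
        ds = F.generate_dataset(cfg)
        pi0 = cfg.pi0()
        edges = np.linspace(0, 1, 21)
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (ds.z_raw >= lo) & (ds.z_raw < hi)
            n = sel.sum()
            centre = pi0(np.array((lo + hi) / 2))
            se = np.sqrt(centre * (1 - centre) / n)
            assert abs((ds.h[sel] == 0).mean() - centre) < 3 * se + 0.01

    def test_unknown_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            F.generate_dataset(F.SimulationConfig(m=10, pi0_spec="sigmoid:x=1"))
        with pytest.raises(ConfigurationError):
            F.generate_dataset(F.SimulationConfig(m=10, alt_spec="gamma:a=2"))


class TestOracleR:
    def test_pure_null_posterior_is_one(self):
        cfg = F.SimulationConfig(m=10, pi0_spec="constant:c=1")
        assert F.oracle_r(cfg, 0.3, 0.5) == 1.0

    def test_arithmetic_at_p_one(self):
        cfg = F.SimulationConfig(
            m=10, pi0_spec="constant:c=0.5", alt_spec="beta:a=0.5"
        )
        assert F.oracle_r(cfg, 1.0, 0.5) == pytest.approx(2 / 3)

    def test_limit_at_p_zero(self):
        cfg = F.SimulationConfig(
            m=10, pi0_spec="constant:c=0.5", alt_spec="beta:a=0.5"
        )
        assert F.oracle_r(cfg, 0.0, 0.5) == 0.0
        assert F.oracle_r(cfg, 1e-12, 0.5) < 1e-5


class TestOraclePfdrPfnr:
    def test_full_region_pfdr_is_marginal_null_probability(self):
        cfg = F.SimulationConfig(m=10, pi0_spec="constant:c=0.7")
        res = oracle_pfdr_pfnr(cfg, 1.0)
        assert res.pfdr == pytest.approx(0.7, abs=1e-3)
        assert res.pfnr == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("tau", [0.1, 0.3, 0.5, 0.8])
    def test_pfdr_bounded_by_tau(self, tau):
        cfg = F.SimulationConfig(
            m=10, pi0_spec="linear:c0=0.6,c1=0.3", alt_spec="beta:a=0.3"
        )
        res = oracle_pfdr_pfnr(cfg, tau)
        assert res.pfdr <= tau + 1e-9

    def test_empty_region_flagged(self):
        cfg = F.SimulationConfig(
            m=10, pi0_spec="constant:c=0.9", alt_spec="beta:a=0.9"
        )
        # r is bounded well away from 0 here; tau below its infimum
        res = oracle_pfdr_pfnr(cfg, 1e-6)
        assert res.empty and np.isnan(res.pfdr)

    def test_monte_carlo_agreement(self):
        """FDP among draws with r <= tau matches the quadrature pFDR."""
        cfg = F.SimulationConfig(
            m=10, pi0_spec="linear:c0=0.6,c1=0.3", alt_spec="beta:a=0.3"
        )
        rng = np.random.default_rng(44)
        n = 10**6
        z = rng.uniform(size=n)
        pi0 = cfg.pi0()(z)
        a = cfg.alt_shape()(z)
        h = (rng.uniform(size=n) < 1 - pi0).astype(int)
        p = rng.uniform(size=n)
        p[h == 1] = p[h == 1] ** (1 / a[h == 1])
        r = F.oracle_r(cfg, p, z)
        sel = r <= 0.2
        mc = (h[sel] == 0).mean()
        se = np.sqrt(mc * (1 - mc) / sel.sum())
        assert abs(mc - oracle_pfdr_pfnr(cfg, 0.2).pfdr) < 3 * se + 1e-3


class TestBayesError:
    def test_boundary_taus_give_zero(self):
        cfg = F.SimulationConfig(
            m=10, pi0_spec="linear:c0=0.6,c1=0.3", alt_spec="beta:a=0.3"
        )
        assert bayes_error(cfg, 0.0) == pytest.approx(0.0, abs=1e-6)
        assert bayes_error(cfg, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_r_threshold_beats_matched_p_threshold(self):
        """Thresholding r(p,z) is Bayes-optimal: no p-only cutoff with the
        same rejection mass achieves lower risk."""
        cfg = F.SimulationConfig(
            m=10, pi0_spec="linear:c0=0.6,c1=0.3", alt_spec="beta:a=0.3"
        )
        for tau in np.linspace(0.05, 0.95, 20):
            mass = oracle_pfdr_pfnr(cfg, tau).mass_rejected
            t = matched_p_threshold(cfg, mass)
            assert bayes_error(cfg, tau) <= p_threshold_bayes_error(cfg, t, tau) + 1e-4


class TestEndToEnd:
    def test_rhat_close_to_oracle_r(self):
        """RMS difference between the plug-in r_hat and the true posterior
        below 0.10 at m = 20000 (logit-linear pi0, constant Beta shape)."""
        cfg = F.SimulationConfig(
            m=20000, pi0_spec="linear-logit:b0=0.4,b1=1.2",
            alt_spec="beta:a=0.25", seed=45,
        )
        ds = F.generate_dataset(cfg)
        pi0 = F.estimate_pi0_glm(ds, lam=0.5)
        dens = F.estimate_joint_density(ds, seed=45)
        r_hat = F.compute_local_fdr(pi0, dens, ds)
        r_true = F.oracle_r(cfg, ds.p, ds.z)
        assert np.sqrt(np.mean((r_hat - r_true) ** 2)) <= 0.10

    def test_study_records_failures_and_summary_shape(self):
        cfg = F.SimulationConfig(m=600, pi0_spec="linear:c0=0.6,c1=0.3", seed=46)
        res = F.run_simulation_study(cfg, replicates=3, alpha=0.05, lam=0.5)
        assert set(res.summary["metric"]) == {
            "fdp_ffdr", "tp_ffdr", "fdp_standard", "tp_standard"
        }
        assert len(res.per_replicate) == 3
        assert res.n_failures == 0

    def test_ranking_differs_from_p_only_order(self):
        """The functional q-values re-rank tests relative to the p-value
        order when Z is informative (Kendall tau strictly below 1)."""
        from scipy.stats import kendalltau

        cfg = F.SimulationConfig(
            m=3000, pi0_spec="linear:c0=0.6,c1=0.3", alt_spec="beta:a=0.25",
            seed=47,
        )
        ds = F.generate_dataset(cfg)
        res = F.ffdr_pipeline(ds, pi0_method="glm", lam=0.5, seed=47)
        tau = kendalltau(ds.p, res.q).statistic
        assert tau < 1.0 - 1e-6
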