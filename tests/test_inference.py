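"""Priors, HPDI, adaptive delayed-acceptance sampler, chain summaries."""

import numpy as np
import pytest
from scipy import integrate, stats

from dlnafilter import default_priors, hpdi, posterior_summaries
from dlnafilter.inference import (
    ChainResult,
    Prior,
    PriorSpec,
    delayed_acceptance_sampler,
    split_rhat,
)


class TestPriors:
    def test_uniform_support_bounds(self):
        priors = default_priors(sigma_eps_center=0.1)
        assert priors.priors["delay_mean"].logpdf_natural(24.0) == -np.inf
        assert np.isfinite(priors.priors["delay_mean"].logpdf_natural(10.0))
        assert priors.priors["delay_sd"].logpdf_natural(20.5) == -np.inf

    def test_hill_coefficient_prior_center(self):
        pr = default_priors(0.1).priors["n"]
        # mode of the log-scale density sits at log 1.5
        assert pr.a == pytest.approx(np.log(1.5))
        assert pr.b == 5.0

    @pytest.mark.parametrize("name", ["mu", "delay_mean", "kappa", "n"])
    def test_density_integrates_to_one(self, name):
        pr = default_priors(0.1).priors[name]
        if pr.kind == "uniform":
            val, _ = integrate.quad(
                lambda x: np.exp(pr.logpdf_natural(x)), pr.a, pr.b
            )
        else:
            # substitute x = e^t: the Jacobian in logpdf_natural must make
            # the integrand a proper density over the log scale
            val, _ = integrate.quad(
                lambda t: np.exp(pr.logpdf_natural(np.exp(t)) + t),
                pr.a - 8 * pr.b, pr.a + 8 * pr.b, limit=200,
            )
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_transform_roundtrip_and_jacobian(self):
        priors = PriorSpec({
            "mu": Prior("lognormal", np.log(0.58), 0.5),
            "delay_mean": Prior("uniform", 0.0, 23.0),
        })
        values = {"mu": 0.8, "delay_mean": 9.0}
        theta = priors.to_transformed(values)
        back = priors.to_natural(theta)
        assert back["mu"] == pytest.approx(0.8)
        assert back["delay_mean"] == pytest.approx(9.0)
        # transformed-scale density = natural density * |dx/dtheta|
        lp_t = priors.logprior_transformed(theta)
        jac_mu = values["mu"]
        frac = values["delay_mean"] / 23.0
        jac_dm = 23.0 * frac * (1 - frac)
        lp_nat = (
            priors.priors["mu"].logpdf_natural(0.8)
            + priors.priors["delay_mean"].logpdf_natural(9.0)
        )
        assert lp_t == pytest.approx(lp_nat + np.log(jac_mu) + np.log(jac_dm))


class TestHPDI:
    def test_standard_normal(self):
        rng = np.random.default_rng(1)
        lo, hi = hpdi(rng.normal(size=200_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_uniform_width(self):
        rng = np.random.default_rng(2)
        lo, hi = hpdi(rng.uniform(size=100_000), 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_constant_draws_zero_width(self):
        lo, hi = hpdi(np.full(500, 3.3), 0.95)
        assert lo == hi == 3.3

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="100"):
            hpdi(np.arange(50), 0.95)

    def test_skewed_narrower_than_central(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(size=100_000)
        lo, hi = hpdi(x, 0.9)
        central = np.quantile(x, [0.05, 0.95])
        assert (hi - lo) < (central[1] - central[0])
        assert lo == pytest.approx(0.0, abs=0.01)


def _gauss_logpost(theta):
    # standard bivariate normal target
    return -0.5 * float(theta @ theta)


class TestSampler:
    def test_equal_likelihoods_reduce_to_plain_mh(self):
        rng = np.random.default_rng(7)
        samples, _, a1, a2 = delayed_acceptance_sampler(
            _gauss_logpost, _gauss_logpost, np.zeros(2), 4000, rng
        )
        # stage-2 ratio is identically 1: every stage-1 survivor is kept
        assert a1 == a2
        assert 0.1 < a1 < 0.7

    def test_stage1_rate_bounds_overall_rate(self):
        rng = np.random.default_rng(8)
        coarse = lambda th: _gauss_logpost(th * 1.1)  # biased surrogate
        _, _, a1, a2 = delayed_acceptance_sampler(
            coarse, _gauss_logpost, np.zeros(2), 4000, rng
        )
        assert a2 <= a1

    def test_prior_recovery_with_flat_likelihood(self):
        # target = prior alone: sample quantiles must match prior quantiles
        priors = PriorSpec({
            "mu": Prior("lognormal", np.log(0.58), 0.5),
            "delay_mean": Prior("uniform", 0.0, 23.0),
        })
        logpost = priors.logprior_transformed
        rng = np.random.default_rng(9)
        samples, _, _, _ = delayed_acceptance_sampler(
            logpost, logpost, priors.to_transformed(
                {"mu": 0.58, "delay_mean": 11.0}
            ), 30_000, rng,
        )
        natural = np.array(
            [list(priors.to_natural(s).values()) for s in samples[5000:]]
        )
        # mu ~ lognormal(log .58, .5); delay_mean ~ U(0,23)
        q = np.quantile(natural[:, 0], [0.25, 0.5, 0.75])
        ref = np.exp(np.log(0.58) + 0.5 * stats.norm.ppf([0.25, 0.5, 0.75]))
        assert np.allclose(q, ref, rtol=0.12)
        assert np.mean(natural[:, 1]) == pytest.approx(11.5, abs=1.2)

    def test_nonfinite_start_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError, match="non-finite"):
            delayed_acceptance_sampler(
                lambda th: -np.inf, _gauss_logpost, np.zeros(2), 10, rng
            )


def _chain_from(samples, names=("a", "b"), log_posterior=None):
    samples = np.asarray(samples, dtype=float)
    if log_posterior is None:
        # stationary-looking log-posterior trace
        log_posterior = np.random.default_rng(0).normal(size=len(samples))
    return ChainResult(
        names=list(names),
        samples=samples,
        log_posterior=np.asarray(log_posterior, dtype=float),
        accept_stage1=0.5,
        accept_overall=0.3,
        seed=0,
        dt_coarse=0.5,
        dt_fine=0.1,
    )


class TestSummaries:
    def _stationary_chains(self, n_chains=3, n=2000, offset=0.0):
        rng = np.random.default_rng(11)
        out = []
        for c in range(n_chains):
            x = rng.normal(size=(n, 2))
            if c == n_chains - 1 and offset:
                x += offset
            out.append(_chain_from(x))
        return out

    def test_identical_chains_none_excluded(self):
        chains = self._stationary_chains()
        table, excluded = posterior_summaries(chains, burn_in=0.5)
        assert excluded == []
        assert set(table.index) == {"a", "b"}
        assert table.loc["a", "mean"] == pytest.approx(0.0, abs=0.1)

    def test_offset_chain_flagged(self):
        chains = self._stationary_chains(offset=10.0)
        _, excluded = posterior_summaries(chains, burn_in=0.5)
        assert excluded == [2]

    def test_drifting_chain_flagged(self):
        # a chain still climbing towards the mode: drifting samples and
        # drifting log-posterior
        rng = np.random.default_rng(12)
        ramp = np.linspace(0, 20, 2000)
        drift = ramp[:, None] + rng.normal(size=(2000, 2))
        good = self._stationary_chains(n_chains=1)
        _, excluded = posterior_summaries(
            good + [_chain_from(drift, log_posterior=-ramp)], burn_in=0.0
        )
        assert 1 in excluded

    def test_all_flagged_raises(self):
        rng = np.random.default_rng(13)
        ramp = np.linspace(0, 50, 2000)
        drift = ramp[:, None] + rng.normal(size=(2000, 2))
        with pytest.raises(ValueError, match="non-convergent"):
            posterior_summaries(
                [_chain_from(drift, log_posterior=-ramp)], burn_in=0.0
            )

    def test_split_rhat_near_one_for_white_noise(self):
        rng = np.random.default_rng(14)
        r = split_rhat([rng.normal(size=5000) for _ in range(4)])
        assert r == pytest.approx(1.0, abs=0.01)
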