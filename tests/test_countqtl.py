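"""Count-QTL model: likelihood oracles, decision rules, sampler behaviour."""

import numpy as np
import pytest
from scipy.stats import betabinom, nbinom, norm

import trimodalqtl as tq
from trimodalqtl.countqtl import QTLFit, _fast_loglik_factory
from trimodalqtl.simulate import FeatureCounts


def nb_p(mu, phi):
    return phi / (phi + mu)


class TestAllelicFraction:
    @pytest.mark.parametrize(
        "alpha0,beta,het,expect",
        [
            (0.0, 0.0, True, 0.5),
            (0.0, np.log(2.0), True, 2.0 / 3.0),
            (float(np.log(0.4 / 0.6)), 0.0, True, 0.4),
            (float(np.log(0.4 / 0.6)), 5.0, False, 0.4),
        ],
    )
    def test_examples(self, alpha0, beta, het, expect):
        assert tq.allelic_fraction(alpha0, beta, het) == pytest.approx(expect, abs=1e-12)

    def test_refbias_identity(self):
        assert tq.RefBias(0.5).alpha0 == pytest.approx(0.0, abs=1e-15)
        assert tq.RefBias(0.3).alpha0 != 0.0
        with pytest.raises(ValueError):
            tq.RefBias(0.0)


class TestLogLikelihood:
    def test_homozygote_donor_is_pure_nb(self):
        counts = FeatureCounts("f", np.array([12]), np.array([np.nan]), np.array([1.5]))
        geno = tq.GenotypePosterior("v", np.array([[1.0, 0.0, 0.0]]))
        phi, g0 = 4.0, 1.1
        got = tq.log_likelihood(0.7, np.array([g0]), phi, 9.0, counts, geno, tq.RefBias())
        mu = np.exp(g0) * 1.5
        assert got == pytest.approx(nbinom.logpmf(12, phi, nb_p(mu, phi)), abs=1e-10)

    def test_heterozygote_term_by_term(self):
        counts = FeatureCounts("f", np.array([10]), np.array([5.0]), np.array([1.0]))
        geno = tq.GenotypePosterior("v", np.array([[0.0, 1.0, 0.0]]))
        phi, theta, g0 = 3.0, 8.0, 2.0
        got = tq.log_likelihood(0.0, np.array([g0]), phi, theta, counts, geno, tq.RefBias(0.5))
        mu = np.exp(g0)  # genotype factor is 1 at beta=0
        expect = nbinom.logpmf(10, phi, nb_p(mu, phi)) + betabinom.logpmf(
            5, 10, 0.5 * theta, 0.5 * theta)
        assert got == pytest.approx(expect, abs=1e-10)

    def test_uniform_genotype_probabilities_are_equal_mixture(self):
        counts = FeatureCounts("f", np.array([20]), np.array([8.0]), np.array([1.0]))
        geno = tq.GenotypePosterior("v", np.array([[1 / 3, 1 / 3, 1 / 3]]))
        beta, phi, theta, g0, ai0 = 0.4, 5.0, 12.0, 2.5, 0.45
        bias = tq.RefBias(ai0)
        got = tq.log_likelihood(beta, np.array([g0]), phi, theta, counts, geno, bias)
        terms = []
        for g, fac in ((0, 1.0), (1, (1 + np.exp(beta)) / 2), (2, np.exp(beta))):
            mu = np.exp(g0) * fac
            t = nbinom.pmf(20, phi, nb_p(mu, phi)) / 3
            if g == 1:
                pi = tq.allelic_fraction(bias.alpha0, beta, True)
                t *= betabinom.pmf(8, 20, pi * theta, (1 - pi) * theta)
            terms.append(t)
        assert got == pytest.approx(np.log(sum(terms)), abs=1e-10)

    def test_enumeration_oracle_five_donors(self, rng):
        """Mixture likelihood equals the brute-force genotype enumeration."""
        n = 5
        probs = rng.dirichlet(np.ones(3), size=n)
        total = rng.integers(5, 60, size=n)
        alt = np.where(rng.random(n) < 0.6, rng.binomial(total, 0.5).astype(float), np.nan)
        lib = rng.uniform(0.5, 2.0, size=n)
        counts = FeatureCounts("f", total, alt, lib)
        geno = tq.GenotypePosterior("v", probs)
        beta, phi, theta, g0 = 0.3, 6.0, 15.0, 2.2
        bias = tq.RefBias(0.42)
        got = tq.log_likelihood(beta, np.array([g0]), phi, theta, counts, geno, bias)
        expect = 0.0
        for i in range(n):
            acc = 0.0
            for g, fac in ((0, 1.0), (1, (1 + np.exp(beta)) / 2), (2, np.exp(beta))):
                mu = np.exp(g0) * lib[i] * fac
                t = probs[i, g] * nbinom.pmf(total[i], phi, nb_p(mu, phi))
                if g == 1 and not np.isnan(alt[i]):
                    pi = tq.allelic_fraction(bias.alpha0, beta, True)
                    t *= betabinom.pmf(alt[i], total[i], pi * theta, (1 - pi) * theta)
                acc += t
            expect += np.log(acc)
        assert got == pytest.approx(expect, abs=1e-10)

    def test_fast_factory_matches_reference(self, rng):
        cfg = tq.SimulationConfig(seed=30, n_donors=40, log_afc=0.3)
        panel = tq.simulate_genotypes(cfg, n_variants=1)
        feat = tq.simulate_count_feature(panel, cfg)
        geno = tq.GenotypePosterior.from_panel(panel)
        bias = tq.RefBias(0.47)
        x = np.ones((40, 1))
        fast = _fast_loglik_factory(feat, geno, bias, x)
        for _ in range(5):
            v = np.array([rng.normal(0, 0.5), rng.normal(4.5, 0.5),
                          rng.normal(1.5, 0.5), rng.normal(2.5, 0.5)])
            ref = tq.log_likelihood(v[0], v[1:2], np.exp(v[2]), np.exp(v[3]),
                                    feat, geno, bias, covariates=x)
            assert fast(v) == pytest.approx(ref, rel=1e-12)

    def test_data_errors(self):
        geno = tq.GenotypePosterior("v", np.array([[0.0, 1.0, 0.0]]))
        bad = FeatureCounts("f", np.array([0]), np.array([3.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="zero total"):
            tq.log_likelihood(0.0, np.zeros(1), 1.0, 1.0, bad, geno, tq.RefBias())
        misaligned = FeatureCounts("f", np.array([5, 6]), np.array([np.nan, np.nan]),
                                   np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="misaligned"):
            tq.log_likelihood(0.0, np.zeros(1), 1.0, 1.0, misaligned, geno, tq.RefBias())


class TestDecisions:
    def _fit(self, ci, rhat=1.0, ai=0.5):
        return QTLFit("f", (ci[0] + ci[1]) / 2, 0.1, ci, rhat, ai, 10)

    def test_significant(self):
        assert tq.classify_qtl(self._fit((0.1, 0.5))) == "significant"

    def test_ci_containing_zero(self):
        assert tq.classify_qtl(self._fit((-0.1, 0.5))) == "not_significant"

    def test_reference_bias_discard(self):
        assert tq.classify_qtl(self._fit((0.1, 0.5), ai=0.35)) == "discarded_bias"

    def test_one_sided_bias_filter_keeps_alt_ward(self):
        # only reference-ward bias (AI0 < 0.4) discards; AI0 = 0.7 passes
        assert tq.classify_qtl(self._fit((0.1, 0.5), ai=0.7)) == "significant"

    def test_convergence_discard(self):
        assert tq.classify_qtl(self._fit((0.1, 0.5), rhat=1.02)) == "discarded_convergence"


class TestApproxPP:
    def test_zero_mean(self):
        fit = QTLFit("f", 0.0, 1.0, (-1, 1), 1.0, 0.5, 5)
        assert tq.approx_posterior_probability(fit) == pytest.approx(0.0)

    def test_ninety_nine_percent_quantile(self):
        z = norm.ppf(0.995)  # 2.5758...
        fit = QTLFit("f", z, 1.0, (0, 1), 1.0, 0.5, 5)
        assert tq.approx_posterior_probability(fit) == pytest.approx(0.99, abs=1e-9)

    def test_limit_and_monotonicity(self):
        fits = [QTLFit("f", m, 1.0, (0, 1), 1.0, 0.5, 5) for m in (0.5, 1.0, 2.0, 50.0)]
        pps = [tq.approx_posterior_probability(f) for f in fits]
        assert all(a < b for a, b in zip(pps, pps[1:]))
        assert pps[-1] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            tq.approx_posterior_probability(QTLFit("f", 1.0, 0.0, (0, 1), 1.0, 0.5, 5))


class TestSampler:
    def test_few_heterozygotes_skipped_with_reason(self):
        probs = np.tile([[0.98, 0.01, 0.01]], (20, 1))
        geno = tq.GenotypePosterior("v", probs / probs.sum(axis=1, keepdims=True))
        counts = FeatureCounts("f", np.full(20, 30), np.full(20, np.nan), np.ones(20))
        model = tq.CountQTLModel(n_warmup=50, n_draws=50).fit(counts, geno)
        assert model.decision_ == "skipped_few_hets"
        assert np.isnan(model.fit_.post_mean)

    def test_fit_detects_strong_effect(self, small_cohort):
        cfg, panel = small_cohort
        feat = tq.simulate_count_feature(panel, cfg, 0)
        geno = tq.GenotypePosterior.from_panel(panel, 0)
        model = tq.CountQTLModel(n_warmup=800, n_draws=800, thin=4, seed=1).fit(feat, geno)
        assert model.fit_.rhat < 1.05
        assert abs(model.fit_.post_mean - np.log(1.5)) < 0.3

    def test_allele_flip_negates_posterior_mean(self, small_cohort):
        """Relabeling alleles (n1 -> c-n1, G -> 2-G, AI0 -> 1-AI0) flips the
        sign of the posterior mean within Monte-Carlo error."""
        cfg, panel = small_cohort
        feat = tq.simulate_count_feature(panel, cfg, 1)
        geno = tq.GenotypePosterior.from_panel(panel, 1)
        bias = tq.RefBias(0.45)
        flipped_counts = FeatureCounts(feat.feature_id + "_flip", feat.total,
                                       feat.total - feat.alt, feat.libsize)
        flipped_geno = tq.GenotypePosterior("v_flip", geno.probs[:, ::-1].copy())
        flipped_bias = tq.RefBias(1 - 0.45)
        kw = dict(n_warmup=800, n_draws=800, thin=4)
        m1 = tq.CountQTLModel(seed=5, **kw).fit(feat, geno, bias)
        m2 = tq.CountQTLModel(seed=6, **kw).fit(flipped_counts, flipped_geno, flipped_bias)
        mc_se = np.hypot(m1.fit_.post_sd, m2.fit_.post_sd) / np.sqrt(200)
        assert abs(m1.fit_.post_mean + m2.fit_.post_mean) < 3 * max(mc_se, 0.02)

    def test_same_seed_reproducible(self, small_cohort):
        cfg, panel = small_cohort
        feat = tq.simulate_count_feature(panel, cfg, 0)
        geno = tq.GenotypePosterior.from_panel(panel, 0)
        a = tq.CountQTLModel(n_warmup=100, n_draws=100, seed=3).fit(feat, geno)
        b = tq.CountQTLModel(n_warmup=100, n_draws=100, seed=3).fit(feat, geno)
        assert np.array_equal(a.draws_, b.draws_)
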