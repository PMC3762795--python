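"""Fixed/random pooling, heterogeneity, and the model-selection rule."""

import math

import numpy as np
import pytest

from snpmeta import (
    Contrast,
    EffectEstimate,
    SimulationConfig,
    StudyCorpus,
    heterogeneity,
    meta_analyse,
    pool_fixed,
    pool_random,
    select_model,
    simulate_corpus,
    study_effects,
)
from snpmeta.contrasts import included_tables

from test_corpus import make_record


def eff(log_or, se, sid="s"):
    return EffectEstimate(study_id=sid, log_or=log_or, se=se)


class TestHeterogeneityClosedForm:
    def test_identical_studies_have_no_dispersion(self):
        effects = [eff(0.3, 0.2, "a"), eff(0.3, 0.2, "b")]
        het = heterogeneity(effects)
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0
        assert het.tau2 == 0.0

    def test_two_effect_hand_computation(self):
        """(0, 0.1) and (1, 0.1): w=100 each, centre 0.5, so
        Q = 100·0.25·2 = 50, C = 200 − 20000/200 = 100,
        τ² = (50−1)/100 = 0.49, and the DL pooled SE is 0.5."""
        effects = [eff(0.0, 0.1, "a"), eff(1.0, 0.1, "b")]
        het = heterogeneity(effects)
        assert het.q == pytest.approx(50.0)
        assert het.tau2 == pytest.approx(0.49)
        pooled = pool_random(effects, het.tau2)
        assert math.log(pooled.or_) == pytest.approx(0.5)
        assert (math.log(pooled.ci_high) - math.log(pooled.or_)) / 1.96 == pytest.approx(0.5)

    def test_single_study_definitions(self):
        het = heterogeneity([eff(0.2, 0.1)])
        assert (het.q, het.p, het.i2, het.tau2) == (0.0, 1.0, 0.0, 0.0)


class TestModelSelection:
    @pytest.mark.parametrize("p_q,expected", [
        (0.54, "fixed"),      # clearly homogeneous
        (0.0005, "random"),   # clearly heterogeneous
        (0.10, "random"),     # the boundary belongs to random (strict >)
        (0.101, "fixed"),
    ])
    def test_threshold_rule(self, p_q, expected):
        assert select_model(p_q) == expected

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            select_model(1.5)


class TestPooling:
    def test_single_study_pool_equals_the_study(self):
        rec = make_record(case_cc=30, case_ct=20, case_tt=10,
                          ctrl_cc=25, ctrl_ct=25, ctrl_tt=10)
        corpus = StudyCorpus(records=[rec])
        for contrast in Contrast:
            result = meta_analyse(corpus, contrast)
            [e] = study_effects(corpus, contrast)
            assert result.k == 1
            assert result.q == 0.0
            assert math.log(result.or_) == pytest.approx(e.log_or, rel=1e-9)

    def test_symmetric_arms_give_unit_or(self):
        rec = make_record(case_cc=10, case_ct=10, case_tt=10,
                          ctrl_cc=10, ctrl_ct=10, ctrl_tt=10)
        corpus = StudyCorpus(records=[rec])
        for contrast in Contrast:
            assert meta_analyse(corpus, contrast).or_ == pytest.approx(1.0)

    def test_random_with_zero_tau2_equals_iv_fixed(self):
        effects = [eff(0.1, 0.2, "a"), eff(0.3, 0.15, "b"), eff(-0.1, 0.3, "c")]
        fixed = pool_fixed(effects, method="IV")
        random = pool_random(effects, 0.0)
        assert random.or_ == pytest.approx(fixed.or_, rel=1e-12)
        assert random.ci_low == pytest.approx(fixed.ci_low, rel=1e-12)

    def test_empty_effect_list_rejected(self):
        with pytest.raises(ValueError):
            pool_fixed([], method="IV")

    def test_pooled_log_or_within_study_hull(self, corpus):
        for contrast in Contrast:
            effects = study_effects(corpus, contrast)
            thetas = [e.log_or for e in effects]
            tables = included_tables(corpus, contrast)
            het = heterogeneity(effects)
            for result in (
                pool_fixed(effects, tables, method="IV"),
                pool_fixed(effects, tables, method="MH"),
                pool_random(effects, het.tau2),
            ):
                assert min(thetas) <= math.log(result.or_) <= max(thetas)

    def test_random_ci_no_narrower_than_iv_fixed(self, corpus):
        for contrast in Contrast:
            effects = study_effects(corpus, contrast)
            het = heterogeneity(effects)
            fixed = pool_fixed(effects, method="IV")
            random = pool_random(effects, het.tau2)
            width_f = math.log(fixed.ci_high) - math.log(fixed.ci_low)
            width_r = math.log(random.ci_high) - math.log(random.ci_low)
            assert width_r >= width_f - 1e-12
            if het.tau2 == 0:
                assert width_r == pytest.approx(width_f, rel=1e-12)

    def test_statistic_ranges(self, corpus):
        for contrast in Contrast:
            r = meta_analyse(corpus, contrast)
            assert 0 <= r.i2 <= 100
            assert 0 < r.p_z <= 1
            assert 0 < r.p_q <= 1
            assert r.tau2 >= 0
            assert r.ci_low <= r.or_ <= r.ci_high


class TestAgainstIndependentOracle:
    """DL pooling for k ≤ 3 checked against a from-scratch evaluation of
    the closed-form expressions, sharing no code with the library path."""

    @staticmethod
    def _oracle_dl(thetas, ses):
        w = [1.0 / s**2 for s in ses]
        sw = sum(w)
        centre = sum(wi * t for wi, t in zip(w, thetas)) / sw
        q = sum(wi * (t - centre) ** 2 for wi, t in zip(w, thetas))
        df = len(thetas) - 1
        c = sw - sum(wi**2 for wi in w) / sw
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        wstar = [1.0 / (s**2 + tau2) for s in ses]
        mu = sum(wi * t for wi, t in zip(wstar, thetas)) / sum(wstar)
        se = (1.0 / sum(wstar)) ** 0.5
        return q, tau2, mu, se

    @pytest.mark.parametrize("k", [2, 3])
    def test_dl_matches_brute_force(self, k):
        rng = np.random.default_rng(12345 + k)
        for _ in range(50):
            thetas = rng.normal(0, 1, size=k).tolist()
            ses = rng.uniform(0.05, 0.8, size=k).tolist()
            effects = [eff(t, s, f"s{i}") for i, (t, s) in enumerate(zip(thetas, ses))]
            q_o, tau2_o, mu_o, se_o = self._oracle_dl(thetas, ses)
            het = heterogeneity(effects)
            pooled = pool_random(effects, het.tau2)
            assert het.q == pytest.approx(q_o, rel=1e-10)
            assert het.tau2 == pytest.approx(tau2_o, rel=1e-10, abs=1e-12)
            assert math.log(pooled.or_) == pytest.approx(mu_o, rel=1e-10, abs=1e-12)
            assert (math.log(pooled.ci_high) - math.log(pooled.or_)) / 1.96 == pytest.approx(se_o, rel=1e-10)


def test_mh_and_iv_agree_on_large_homogeneous_corpora():
    """With no heterogeneity and big arms, the two fixed-effect
    estimators must agree to well under 0.1% relative difference."""
    config = SimulationConfig(k=12, n_case_range=(3000, 4000),
                              n_ctrl_range=(3000, 4000),
                              true_log_or=0.25, tau=0.0, seed=77)
    corpus = simulate_corpus(config)
    mh = meta_analyse(corpus, Contrast.ALLELE, fixed_method="MH", model_threshold=1e-12)
    iv = meta_analyse(corpus, Contrast.ALLELE, fixed_method="IV", model_threshold=1e-12)
    assert abs(mh.or_ - iv.or_) / iv.or_ < 1e-3


def test_fixture_overall_results_match_reported_summaries(corpus):
    """Overall pooled ORs agree with the published summary estimates and
    the exclusion rule yields the published degrees of freedom."""
    allele = meta_analyse(corpus, Contrast.ALLELE)
    assert allele.model == "random_DL"
    assert allele.or_ == pytest.approx(0.905, abs=0.005)
    recessive = meta_analyse(corpus, Contrast.RECESSIVE)
    assert recessive.model == "fixed_MH"
    assert recessive.df == 37
    assert recessive.or_ == pytest.approx(1.15, abs=0.005)
    assert (recessive.ci_low, recessive.ci_high) == pytest.approx((1.03, 1.29), abs=0.005)
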