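"""Liability-model arithmetic, orthant probabilities, ML fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import multivariate_normal

from famcoagg.liability import (
    COUSIN,
    SIBLING,
    ParameterDomainError,
    STUDY_COMPONENTS,
    VarianceComponents,
    decompose_correlation,
    pair_correlation_matrix,
    threshold_from_prevalence,
)
from famcoagg.quantgen import (
    PATTERNS,
    BivariateLiabilityACE,
    PatternCounts,
    RectangleEngine,
    _pattern_rectangles,
    counts_from_outcomes,
    default_specs,
    fit_bivariate_ace,
    pair_loglikelihood,
    pattern_probabilities,
    pattern_probability,
    select_model,
    simulate_pattern_counts,
)

T1 = threshold_from_prevalence(0.0230)
T2 = threshold_from_prevalence(0.0414)


class TestPairCorrelationMatrix:
    def test_study_values_cousin_entries(self):
        """Entries derived from the fitted study parameters: within-person
        0.13*sqrt(.84*.23)+0.02*sqrt(.16*.68); cousin same-trait-1
        0.125*0.84; cousin cross 0.125*0.13*sqrt(.84*.23)."""
        R = pair_correlation_matrix(STUDY_COMPONENTS, COUSIN)
        assert R[0, 1] == pytest.approx(0.0637378, abs=1e-6)
        assert R[0, 2] == pytest.approx(0.105, abs=1e-12)
        assert R[1, 3] == pytest.approx(0.125 * 0.23 + 0.0 * 0.09, abs=1e-12)
        assert R[0, 3] == pytest.approx(0.0071426, abs=1e-6)
        assert np.allclose(R, R.T) and np.allclose(np.diag(R), 1.0)

    def test_sibling_pure_additive_sharing(self):
        vc = VarianceComponents(
            a2=(1.0, 0.0), c2=(0.0, 0.0), e2=(0.0, 1.0), rA=None, rC=None, rE=0.0
        )
        R = pair_correlation_matrix(vc, SIBLING)
        assert R[0, 2] == pytest.approx(0.5)
        assert R[0, 1] == 0.0 and R[0, 3] == 0.0

    def test_all_zero_correlations_give_block_identity(self):
        vc = VarianceComponents(
            a2=(0.3, 0.3), c2=(0.1, 0.1), e2=(0.6, 0.6), rA=0.0, rC=0.0, rE=0.0
        )
        R = pair_correlation_matrix(vc, COUSIN)
        assert R[0, 1] == 0.0 and R[0, 3] == 0.0 and R[1, 2] == 0.0
        assert R[0, 2] == pytest.approx(0.125 * 0.3)


class TestPatternProbability:
    def test_independence_is_product_of_tails(self):
        """Identity correlation: all-below probability equals the product
        of univariate non-case probabilities."""
        p = pattern_probability(np.eye(4), [T1, T2, T1, T2], [0, 0, 0, 0], tol=1e-7)
        expected = ((1 - 0.023) * (1 - 0.0414)) ** 2
        assert p == pytest.approx(expected, abs=5e-7)

    def test_sixteen_patterns_sum_to_one(self):
        R = pair_correlation_matrix(STUDY_COMPONENTS, SIBLING)
        probs = pattern_probabilities(R, [T1, T2, T1, T2])
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_engine_agrees_with_scipy_reference(self):
        """Dual route: the QMC engine against scipy's MVN CDF (Genz) on
        every pattern of a study-parameter matrix."""
        R = pair_correlation_matrix(STUDY_COMPONENTS, COUSIN)
        t = np.array([T1, T2, T1, T2])
        probs = pattern_probabilities(R, t, RectangleEngine(n_points=8192, n_shifts=4))
        Rb, ub = _pattern_rectangles(R, t, PATTERNS)
        for i in range(16):
            ref = multivariate_normal(mean=np.zeros(4), cov=Rb[i], allow_singular=True).cdf(ub[i])
            assert probs[i] == pytest.approx(ref, abs=2e-6)

    def test_non_psd_correlation_rejected(self):
        bad = np.eye(4)
        for i in range(3):
            bad[i, i + 1] = bad[i + 1, i] = 0.9
        assert np.linalg.eigvalsh(bad)[0] < -1e-6
        with pytest.raises(ParameterDomainError):
            pattern_probability(bad, [1, 1, 1, 1], [0, 0, 0, 0])

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ParameterDomainError):
            pattern_probability(np.eye(4), [np.inf, 1, 1, 1], [0, 0, 0, 0])


class TestLikelihood:
    def test_single_pair_independence_factorizes(self):
        vc = VarianceComponents(
            a2=(0.0, 0.0), c2=(0.0, 0.0), e2=(1.0, 1.0), rA=None, rC=None, rE=0.0,
            thresholds=(T1, T2),
        )
        counts = np.zeros(16)
        counts[0b1010] = 1  # member1 both traits affected? bits (m1t1,m1t2,m2t1,m2t2)
        data = PatternCounts(counts={"full_sibling": counts}, specs={"full_sibling": SIBLING})
        ll = pair_loglikelihood(data, vc)
        expected = np.log(0.023) + np.log(1 - 0.0414) + np.log(0.023) + np.log(1 - 0.0414)
        assert ll == pytest.approx(expected, abs=1e-5)

    def test_member_swap_invariance(self):
        rng = np.random.default_rng(8)
        counts = {
            "full_sibling": simulate_pattern_counts(STUDY_COMPONENTS, SIBLING, 30000, rng),
            "cousin": simulate_pattern_counts(STUDY_COMPONENTS, COUSIN, 10000, rng),
        }
        swapped = {
            label: np.array([c[((i & 0b0011) << 2) | ((i & 0b1100) >> 2)] for i in range(16)])
            for label, c in counts.items()
        }
        d1 = PatternCounts(counts=counts, specs=default_specs())
        d2 = PatternCounts(counts=swapped, specs=default_specs())
        eng = RectangleEngine(8192, n_shifts=2)
        assert pair_loglikelihood(d1, STUDY_COMPONENTS, eng) == pytest.approx(
            pair_loglikelihood(d2, STUDY_COMPONENTS, eng), rel=1e-6
        )

    def test_collapsed_equals_per_pair_without_covariates(self):
        rng = np.random.default_rng(9)
        counts = {"full_sibling": simulate_pattern_counts(STUDY_COMPONENTS, SIBLING, 400, rng)}
        rows = []
        for pat in range(16):
            rows += [("full_sibling", pat, 0.0, 0.0, 0.0, 0.0)] * int(counts["full_sibling"][pat])
        per_pair = pd.DataFrame(
            rows, columns=["class_label", "pattern", "female1", "female2", "z1", "z2"]
        )
        data = PatternCounts(
            counts=counts, specs={"full_sibling": SIBLING}, per_pair=per_pair
        )
        vc = STUDY_COMPONENTS.replace(threshold_covariates=((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)))
        eng = RectangleEngine(2048)
        a = pair_loglikelihood(data, vc, eng, mode="collapsed")
        b = pair_loglikelihood(data, vc, eng, mode="per_pair")
        assert a == pytest.approx(b, abs=1e-9)

    def test_truth_beats_perturbations_on_large_counts(self):
        rng = np.random.default_rng(10)
        counts = {
            "full_sibling": simulate_pattern_counts(STUDY_COMPONENTS, SIBLING, 300000, rng),
            "cousin": simulate_pattern_counts(STUDY_COMPONENTS, COUSIN, 80000, rng),
        }
        data = PatternCounts(counts=counts, specs=default_specs())
        eng = RectangleEngine(4096)
        ll_truth = pair_loglikelihood(data, STUDY_COMPONENTS, eng)
        for perturbed in (
            STUDY_COMPONENTS.replace(a2=(0.7, 0.23), e2=(0.3, 0.68)),
            STUDY_COMPONENTS.replace(rA=0.5),
            STUDY_COMPONENTS.replace(thresholds=(T1 + 0.15, T2)),
        ):
            assert ll_truth > pair_loglikelihood(data, perturbed, eng)


class TestFitting:
    def test_identifiability_guard(self):
        counts = {"full_sibling": np.ones(16)}
        with pytest.raises(ParameterDomainError, match="unidentified"):
            BivariateLiabilityACE("ACE", "ACE").fit(
                counts, specs={"full_sibling": SIBLING}
            )

    def test_e_only_model_needs_no_second_class(self):
        rng = np.random.default_rng(11)
        vc = VarianceComponents(
            a2=(0.0, 0.0), c2=(0.0, 0.0), e2=(1.0, 1.0), rA=None, rC=None, rE=0.1,
            thresholds=(T1, T2),
        )
        counts = {"full_sibling": simulate_pattern_counts(vc, SIBLING, 20000, rng)}
        res = fit_bivariate_ace(
            counts, ("E", "E"), specs={"full_sibling": SIBLING},
            n_starts=1, qmc_points=1024, ci_method="none",
        )
        assert res.estimates.a2 == (0.0, 0.0)
        assert abs(res.estimates.rE - 0.1) < 0.1

    def test_recovery_of_well_identified_quantities(self):
        """Single scaled fit: trait-1 heritability, the sibling-identified
        combination a2/2 + c2 for trait 2, and both thresholds."""
        rng = np.random.default_rng(12)
        counts = {
            "full_sibling": simulate_pattern_counts(STUDY_COMPONENTS, SIBLING, 150000, rng),
            "cousin": simulate_pattern_counts(STUDY_COMPONENTS, COUSIN, 40000, rng),
        }
        est = BivariateLiabilityACE("AE", "ACE", n_starts=2, ci_method="none").fit(counts)
        vc = est.vc_
        assert vc.a2[0] == pytest.approx(0.84, abs=0.06)
        assert 0.5 * vc.a2[1] + vc.c2[1] == pytest.approx(0.5 * 0.23 + 0.09, abs=0.03)
        assert vc.thresholds[0] == pytest.approx(T1, abs=0.02)
        assert vc.thresholds[1] == pytest.approx(T2, abs=0.02)
        assert est.converged_

    def test_null_genetic_correlation_recovery(self):
        """Data generated with rA = 0: the estimate stays near zero and
        the delta interval covers zero."""
        vc_null = VarianceComponents(
            a2=(0.6, 0.6), c2=(0.0, 0.2), e2=(0.4, 0.2), rA=0.0, rC=None, rE=0.1,
            thresholds=(threshold_from_prevalence(0.05), threshold_from_prevalence(0.08)),
        )
        rng = np.random.default_rng(13)
        counts = {
            "full_sibling": simulate_pattern_counts(vc_null, SIBLING, 120000, rng),
            "cousin": simulate_pattern_counts(vc_null, COUSIN, 30000, rng),
        }
        est = BivariateLiabilityACE(
            "AE", "ACE", n_starts=2, ci_method="delta", ci_params=["rA"]
        ).fit(counts)
        lo, hi = est.ci_["rA"]
        assert abs(est.vc_.rA) < 0.15
        assert lo <= 0.0 <= hi

    def test_aic_definition_and_nesting(self):
        rng = np.random.default_rng(14)
        counts = {
            "full_sibling": simulate_pattern_counts(STUDY_COMPONENTS, SIBLING, 40000, rng),
            "cousin": simulate_pattern_counts(STUDY_COMPONENTS, COUSIN, 10000, rng),
        }
        kw = dict(n_starts=1, qmc_points=1024, ci_method="none")
        ae = fit_bivariate_ace(counts, ("AE", "ACE"), **kw)
        ace = fit_bivariate_ace(counts, ("ACE", "ACE"), **kw)
        for r in (ae, ace):
            assert r.aic == pytest.approx(2 * r.n_params - 2 * r.log_likelihood, abs=1e-9)
        assert ace.n_params - ae.n_params == 2  # c2_1 and rC
        d_aic = ace.aic - ae.aic
        assert d_aic == pytest.approx(
            2 * (ace.n_params - ae.n_params) - 2 * (ace.log_likelihood - ae.log_likelihood),
            abs=1e-9,
        )

    def test_e_only_ranks_last_on_familial_data(self):
        rng = np.random.default_rng(15)
        counts = {
            "full_sibling": simulate_pattern_counts(STUDY_COMPONENTS, SIBLING, 60000, rng),
            "cousin": simulate_pattern_counts(STUDY_COMPONENTS, COUSIN, 15000, rng),
        }
        results = select_model(
            counts,
            candidates=(("AE", "ACE"), ("AE", "AE"), ("E", "E")),
            n_starts=1, qmc_points=1024, ci_method="none",
        )
        assert results[-1].model_label == "E-E"

    def test_profile_interval_brackets_estimate(self):
        rng = np.random.default_rng(16)
        counts = {
            "full_sibling": simulate_pattern_counts(STUDY_COMPONENTS, SIBLING, 50000, rng),
            "cousin": simulate_pattern_counts(STUDY_COMPONENTS, COUSIN, 12000, rng),
        }
        est = BivariateLiabilityACE(
            "AE", "ACE", n_starts=1, qmc_points=1024,
            ci_method="profile", ci_params=["a2_1"],
        ).fit(counts)
        lo, hi = est.ci_["a2_1"]
        assert lo < est.vc_.a2[0] < hi
        assert hi - lo < 0.2  # informative at this n


class TestDecomposition:
    def test_pure_genetic_share(self):
        vc = VarianceComponents(
            a2=(0.5, 0.5), c2=(0.0, 0.0), e2=(0.5, 0.5), rA=0.4, rC=None, rE=0.0
        )
        shares = decompose_correlation(vc)
        assert shares["A"] == pytest.approx(1.0)
        assert shares["C"] is None
        assert shares["E"] == pytest.approx(0.0)

    def test_study_point_values(self):
        """A-share = 0.13*sqrt(.84*.23) / (that + 0.02*sqrt(.16*.68))."""
        shares = decompose_correlation(STUDY_COMPONENTS)
        a_part = 0.13 * np.sqrt(0.84 * 0.23)
        e_part = 0.02 * np.sqrt(0.16 * 0.68)
        assert shares["A"] == pytest.approx(a_part / (a_part + e_part), abs=1e-9)
        assert shares["A"] == pytest.approx(0.8965, abs=0.001)
        assert shares["A"] + shares["E"] == pytest.approx(1.0, abs=1e-12)
        assert shares["C"] is None

    def test_zero_total_covariance_is_undefined(self):
        vc = VarianceComponents(
            a2=(0.5, 0.5), c2=(0.0, 0.0), e2=(0.5, 0.5), rA=0.0, rC=None, rE=0.0
        )
        assert all(v is None for v in decompose_correlation(vc).values())


class TestPatternEncoding:
    def test_counts_from_outcomes_round_trip(self):
        rng = np.random.default_rng(17)
        outcomes = rng.random((5000, 4)) < 0.2
        counts = counts_from_outcomes(outcomes)
        assert counts.sum() == 5000
        idx = outcomes @ np.array([8, 4, 2, 1])
        for i in range(16):
            assert counts[i] == (idx == i).sum()
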