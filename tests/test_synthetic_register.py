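"""Generator: pedigree structure, liabilities, phenotypes, event emission."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest
from scipy.special import ndtr

from famcoagg.liability import COUSIN, SIBLING, ParameterDomainError, threshold_from_prevalence
from famcoagg.register_model import DEFAULT_ERA_MAP, validate_registers
from famcoagg.synthetic_register import (
    CrossTraitCorrelations,
    SimulationParams,
    TraitParams,
    generate_register,
    liabilities_to_phenotypes,
    simulate_liabilities,
    simulate_pair_outcomes,
    simulate_pedigree_structure,
)


def bisect_threshold(p, lo=-10.0, hi=10.0):
    """Independent oracle: invert the standard-normal upper tail by bisection."""
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if 1.0 - ndtr(mid) > p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestThresholds:
    @pytest.mark.parametrize("p,expected", [(0.5, 0.0), (0.023, 1.9953933102), (0.0414, 1.7346658976)])
    def test_matches_bisection_oracle(self, p, expected):
        t = threshold_from_prevalence(p)
        assert t == pytest.approx(expected, abs=1e-9)
        assert t == pytest.approx(bisect_threshold(p), abs=1e-8)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_domain_error(self, p):
        with pytest.raises(ParameterDomainError):
            threshold_from_prevalence(p)


def _uniform_trait(**kw):
    base = dict(a2=0.5, c2=0.2, e2=0.3, prevalence=0.1)
    base.update(kw)
    return base


class TestPedigreeStructure:
    def test_all_singleton_sibships_degenerate(self):
        params = SimulationParams(n_families=1, sibship_size_distribution={1: 1.0}, seed=1)
        ped = simulate_pedigree_structure(params)
        roles = ped.structure["role"].value_counts().to_dict()
        assert roles.get("aunt_uncle", 0) == 0
        assert roles.get("cousin", 0) == 0
        assert roles["child"] == 1
        child = ped.structure.loc[ped.structure["role"] == "child", "person_id"].iloc[0]
        link = ped.links[ped.links["child_id"] == child]
        assert link["mother_id"].notna().all() and link["father_id"].notna().all()

    def test_sibship_two_gives_cousins(self):
        params = SimulationParams(n_families=1, sibship_size_distribution={2: 1.0}, seed=2)
        ped = simulate_pedigree_structure(params)
        assert (ped.structure["role"] == "cousin").sum() >= 1

    def test_parent_child_gap_at_least_15(self, small_pedigree):
        years = small_pedigree.persons.set_index("person_id")["birth_year"]
        for child, mother, father in small_pedigree.links.itertuples(index=False):
            assert years[child] - years[mother] >= 15
            assert years[child] - years[father] >= 15

    def test_pair_counts_match_branching_expectation(self):
        """Sibling pairs per family: E[C(s,2)] = 4/3 for s ~ U{1,2,3};
        index-cousin pairs: E[s_index] * 2 * E[s-1] * E[s] = 8."""
        n_fam = 4000
        params = SimulationParams(n_families=n_fam, seed=5)
        ped = simulate_pedigree_structure(params)
        struct = ped.structure
        per_fam_children = struct[struct["role"] == "child"].groupby("family").size()
        per_fam_children = per_fam_children.reindex(range(n_fam), fill_value=0)
        sib_pairs = per_fam_children * (per_fam_children - 1) / 2
        se = sib_pairs.std() / np.sqrt(n_fam)
        assert abs(sib_pairs.mean() - 4 / 3) < 3 * se
        per_fam_cousins = struct[struct["role"] == "cousin"].groupby("family").size()
        per_fam_cousins = per_fam_cousins.reindex(range(n_fam), fill_value=0)
        cousin_pairs = per_fam_children * per_fam_cousins
        se = cousin_pairs.std() / np.sqrt(n_fam)
        assert abs(cousin_pairs.mean() - 8.0) < 3 * se

    def test_censoring_rate(self):
        params = SimulationParams(n_families=1200, censor_before_10_prob=0.2, seed=7)
        ped = simulate_pedigree_structure(params)
        kids = ped.structure[ped.structure["generation"] == 2]["person_id"]
        p = ped.persons.set_index("person_id").loc[kids]
        censored = (
            (p["death_year"] - p["birth_year"] <= 9).fillna(False)
            | (p["emigration_year"] - p["birth_year"] <= 9).fillna(False)
        )
        se = np.sqrt(0.2 * 0.8 / len(kids))
        assert abs(censored.mean() - 0.2) < 3 * se


class TestLiabilities:
    def _pairs_of(self, ped, role_pair):
        """Full-sibling index pairs (same mother+father) or cousin pairs."""
        links = ped.links
        both = links.merge(links, on=["mother_id", "father_id"])
        sibs = both[both["child_id_x"] < both["child_id_y"]]
        return sibs[["child_id_x", "child_id_y"]].to_numpy()

    def test_zero_a2_gives_zero_sibling_A_correlation(self):
        params = SimulationParams(
            n_families=300,
            traits=(
                TraitParams("t1", a2=0.0, c2=0.0, e2=1.0, prevalence=0.1),
                TraitParams("t2", a2=0.0, c2=0.0, e2=1.0, prevalence=0.1),
            ),
            cross=CrossTraitCorrelations(0, 0, 0),
            seed=3,
        )
        ped = simulate_pedigree_structure(params)
        liab = simulate_liabilities(ped, params)
        assert np.allclose(liab[["A1", "A2"]].to_numpy(), 0.0)

    def test_pure_additive_sharing_fractions(self):
        """a2=1: sibling liability correlation 0.5, cousin 0.125."""
        params = SimulationParams(
            n_families=4000,
            traits=(
                TraitParams("t1", a2=1.0, c2=0.0, e2=0.0, prevalence=0.1),
                TraitParams("t2", a2=0.0, c2=0.0, e2=1.0, prevalence=0.1),
            ),
            cross=CrossTraitCorrelations(0, 0, 0),
            seed=11,
        )
        ped = simulate_pedigree_structure(params)
        liab = simulate_liabilities(ped, params).set_index("person_id")
        struct = ped.structure.set_index("person_id")
        links = ped.links
        both = links.merge(links, on=["mother_id", "father_id"])
        sibs = both[both["child_id_x"] < both["child_id_y"]]
        # one pair per sibship so pairs are independent across families
        sibs = sibs.drop_duplicates(["mother_id", "father_id"])
        x = liab.loc[sibs["child_id_x"], "L1"].to_numpy()
        y = liab.loc[sibs["child_id_y"], "L1"].to_numpy()
        r_sib = np.corrcoef(x, y)[0, 1]
        n = len(x)
        assert n > 1000
        assert abs(r_sib - 0.5) < 3 * (1 - 0.25) / np.sqrt(n)
        # cousins: one (index child, cousin) pair per family
        kids = struct[struct["role"] == "child"].groupby("family").groups
        cuz = struct[struct["role"] == "cousin"].groupby("family").groups
        xs, ys = [], []
        for fam in kids:
            if fam in cuz:
                xs.append(liab.loc[kids[fam][0], "L1"])
                ys.append(liab.loc[cuz[fam][0], "L1"])
        r_cuz = np.corrcoef(xs, ys)[0, 1]
        assert abs(r_cuz - 0.125) < 3 / np.sqrt(len(xs))

    def test_within_person_cross_trait_correlation(self):
        """Default (study) parameters imply within-person cross-trait
        liability correlation rA*sqrt(a2_1 a2_2) + rE*sqrt(e2_1 e2_2)."""
        params = SimulationParams(n_families=3000, seed=13)
        ped = simulate_pedigree_structure(params)
        liab = simulate_liabilities(ped, params)
        expected = 0.13 * np.sqrt(0.84 * 0.23) + 0.02 * np.sqrt(0.16 * 0.68)
        r = np.corrcoef(liab["L1"], liab["L2"])[0, 1]
        assert abs(r - expected) < 3 / np.sqrt(len(liab))

    def test_total_liability_is_standardized(self):
        params = SimulationParams(n_families=3000, seed=17)
        ped = simulate_pedigree_structure(params)
        liab = simulate_liabilities(ped, params)
        n = len(liab)
        for col in ("L1", "L2"):
            assert abs(liab[col].mean()) < 4 / np.sqrt(n)
            assert abs(liab[col].var() - 1.0) < 5 / np.sqrt(n)


class TestPhenotypes:
    def test_prevalence_matches_target(self):
        params = SimulationParams(n_families=3000, seed=19)
        ped = simulate_pedigree_structure(params)
        liab = simulate_liabilities(ped, params)
        phen = liabilities_to_phenotypes(ped, liab, params)
        # restrict to the grandchild generation (inside the birth-year range)
        gen2 = set(ped.structure.loc[ped.structure["generation"] == 2, "person_id"])
        sub = phen[phen["person_id"].isin(gen2)]
        for trait, target in (("ADHD", 0.023), ("anyAD", 0.0414)):
            rate = sub.loc[sub["trait"] == trait, "is_case"].mean()
            n = (sub["trait"] == trait).sum()
            assert abs(rate - target) < 3 * np.sqrt(target * (1 - target) / n) + 0.003

    def test_sex_shift_monotonicity(self):
        params = SimulationParams(n_families=4000, seed=23)
        ped = simulate_pedigree_structure(params)
        liab = simulate_liabilities(ped, params)
        phen = liabilities_to_phenotypes(ped, liab, params)
        sex = ped.persons.set_index("person_id")["sex"]
        sub = phen[phen["trait"] == "ADHD"].set_index("person_id")
        female_rate = sub.loc[sex == "female", "is_case"].mean()
        male_rate = sub.loc[sex == "male", "is_case"].mean()
        assert female_rate < male_rate  # positive female threshold shift

    def test_censored_case_retains_truth_but_has_no_event_year(self):
        params = SimulationParams(n_families=300, censor_before_10_prob=0.9, seed=29)
        ped = simulate_pedigree_structure(params)
        liab = simulate_liabilities(ped, params)
        phen = liabilities_to_phenotypes(ped, liab, params)
        persons = ped.persons.set_index("person_id")
        end = pd.concat([persons["death_year"], persons["emigration_year"]], axis=1).min(axis=1)
        cases = phen[phen["is_case"]].set_index("person_id")
        early = cases[end.reindex(cases.index) < cases.index.map(persons["birth_year"]) + 3]
        assert len(early) > 0
        assert early["diagnosis_year"].isna().all()
        assert early["is_case"].all()


class TestEmission:
    def test_era_coding_of_events(self, small_bundle):
        era = DEFAULT_ERA_MAP
        for row in small_bundle.diagnoses.itertuples():
            assert era.system_for_year(row.event_year) == row.code_system

    def test_dispensations_within_drug_era(self, small_bundle):
        assert (small_bundle.dispensations["event_year"] >= 2005).all()

    def test_generator_output_validates(self, small_bundle):
        assert validate_registers(small_bundle).ok

    def test_bit_reproducible_under_fixed_seed(self):
        params = SimulationParams(n_families=40, seed=77)
        b1, t1, _ = generate_register(params)
        b2, t2, _ = generate_register(params)
        for name in ("persons", "links", "diagnoses", "dispensations"):
            pdt.assert_frame_equal(b1.table(name), b2.table(name))
        pdt.assert_frame_equal(t1, t2)

    def test_observed_sex_distribution_mirrors_configuration(self, small_bundle, small_truth, small_pedigree):
        """The female threshold shifts push trait 1 male-ward and trait 2
        female-ward among cases."""
        sex = small_pedigree.persons.set_index("person_id")["sex"]
        cases1 = small_truth[(small_truth["trait"] == "ADHD") & small_truth["is_case"]]
        cases2 = small_truth[(small_truth["trait"] == "anyAD") & small_truth["is_case"]]
        f1 = (sex.loc[cases1["person_id"]] == "female").mean()
        f2 = (sex.loc[cases2["person_id"]] == "female").mean()
        assert f1 < f2


class TestPairOutcomeSimulator:
    def test_sibling_concordance_matches_liability_correlation(self):
        """Tetrachoric-scale same-trait sibling concordance for trait 1 is
        consistent with liability correlation 0.5 * a2_1 at study values."""
        from scipy import optimize
        from scipy.stats import multivariate_normal

        params = SimulationParams(n_families=1, seed=31)
        out = simulate_pair_outcomes(params, SIBLING, 200_000, sex_structure=False)
        a, b = out[:, 0], out[:, 2]
        p11 = (a & b).mean()
        t = threshold_from_prevalence(0.023)

        def f(r):
            return multivariate_normal(mean=[0, 0], cov=[[1, r], [r, 1]]).cdf([-t, -t]) - p11

        r_hat = optimize.brentq(f, -0.5, 0.9, xtol=1e-5)
        # MC standard error propagated through the tetrachoric inversion
        dens = 0.0106  # bivariate normal density at (t, t, r=0.42)
        se = np.sqrt(p11 * (1 - p11) / len(a)) / dens
        assert abs(r_hat - 0.5 * 0.84) < 3 * se
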