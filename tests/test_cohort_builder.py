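"""Cohort construction vs an independent brute-force pedigree walker."""

import numpy as np
import pandas as pd
import pytest

from famcoagg.cohort_builder import (
    ConfigurationError,
    apply_cohort_filter,
    build_index_cohort,
    build_relative_pairs,
    family_clusters,
    select_quantgen_pairs,
)
from famcoagg.synthetic_register import SimulationParams, generate_register

from conftest import make_bundle


# ---------------------------------------------------------------------------
# independent oracle: plain-dict pedigree walker


class Walker:
    """Brute-force relative enumeration from the link table alone."""

    def __init__(self, bundle):
        self.mother = {}
        self.father = {}
        for child, m, f in bundle.links.itertuples(index=False):
            if m is not None:
                self.mother[child] = m
            if f is not None:
                self.father[child] = f
        self.children = {}
        for child in set(self.mother) | set(self.father):
            for p in (self.mother.get(child), self.father.get(child)):
                if p is not None:
                    self.children.setdefault(p, set()).add(child)
        self.sex = dict(zip(bundle.persons["person_id"], bundle.persons["sex"]))

    def full_siblings(self, pid):
        m, f = self.mother.get(pid), self.father.get(pid)
        if m is None or f is None:
            return set()
        return {
            s
            for s in self.children.get(m, set()) & self.children.get(f, set())
            if s != pid and self.mother.get(s) == m and self.father.get(s) == f
        }

    def aunts_uncles(self, pid, want_sex):
        out = set()
        for side, parent in (("maternal", self.mother.get(pid)), ("paternal", self.father.get(pid))):
            if parent is None:
                continue
            for sib in self.full_siblings(parent):
                if self.sex.get(sib) == want_sex:
                    out.add((sib, side))
        return out

    def cousins(self, pid):
        out = set()
        for side, parent in (("maternal", self.mother.get(pid)), ("paternal", self.father.get(pid))):
            if parent is None:
                continue
            for sib in self.full_siblings(parent):
                for kid in self.children.get(sib, set()):
                    if kid != pid:
                        out.add((kid, side))
        return out


@pytest.fixture(scope="module")
def oracle_register():
    return generate_register(SimulationParams(n_families=400, seed=4))


class TestIndexCohort:
    def _tiny(self):
        return make_bundle(
            [
                ("m", "female", 1940, None, None),
                ("f", "male", 1938, None, None),
                ("early", "female", 1959, None, None),
                ("ok", "male", 1960, None, None),
                ("died9", "female", 1980, 1989, None),
                ("died10", "male", 1980, 1990, None),
                ("nomother", "female", 1990, None, None),
            ],
            links=[
                ("early", "m", "f"),
                ("ok", "m", "f"),
                ("died9", "m", "f"),
                ("died10", "m", "f"),
                ("nomother", None, "f"),
            ],
        )

    def test_exclusion_cascade_boundaries(self):
        cohort = build_index_cohort(self._tiny(), (1960, 2010), 10)
        members = set(cohort.ids)
        assert "early" not in members  # born before the window
        assert "nomother" not in members  # unknown mother
        assert "died9" not in members  # died at age 9 ("before age 10")
        assert "died10" in members  # age exactly 10 is retained
        assert "ok" in members
        assert cohort.exclusions["excluded_unknown_mother"] == 1
        assert cohort.exclusions["excluded_died_or_emigrated"] == 1

    def test_late_window_restricts_parent_cohorts(self):
        bundle = self._tiny()
        cohort = build_index_cohort(bundle, (1960, 2010), 10)
        pairs = build_relative_pairs(bundle, cohort, "mother", late_window=(1980, 2010))
        assert set(pairs.pairs["index_id"]) == {"died10"}  # only member born >= 1980

    def test_parent_relation_requires_late_window(self, small_bundle):
        cohort = build_index_cohort(small_bundle)
        with pytest.raises(ConfigurationError, match="late birth window"):
            build_relative_pairs(small_bundle, cohort, "father")

    def test_unknown_relation_rejected(self, small_bundle):
        cohort = build_index_cohort(small_bundle)
        with pytest.raises(ConfigurationError, match="unknown relation"):
            build_relative_pairs(small_bundle, cohort, "grandparent")


class TestPairOracle:
    def test_pairs_equal_brute_force_enumeration(self, oracle_register):
        bundle, _, _ = oracle_register
        walker = Walker(bundle)
        index = build_index_cohort(bundle, (1960, 2010), 10)
        survived = {}
        p = bundle.persons
        alive = ~(
            ((p["death_year"] - p["birth_year"]) <= 9).fillna(False)
            | ((p["emigration_year"] - p["birth_year"]) <= 9).fillna(False)
        )
        survived = dict(zip(p["person_id"], alive))
        late = set(
            index.members.loc[index.members["birth_year"].between(1980, 2010), "person_id"]
        )
        members = set(index.ids)

        def expected(relation):
            out = set()
            for pid in members:
                if relation in ("mother", "father", "aunt", "uncle") and pid not in late:
                    continue
                if relation == "mother":
                    m = walker.mother.get(pid)
                    if m is not None:
                        out.add((pid, m, "not_applicable"))
                elif relation == "father":
                    f = walker.father.get(pid)
                    if f is not None:
                        out.add((pid, f, "not_applicable"))
                elif relation == "full_sibling":
                    for s in walker.full_siblings(pid):
                        if survived.get(s, True):
                            out.add((min(pid, s), max(pid, s), "not_applicable"))
                elif relation in ("aunt", "uncle"):
                    want = "female" if relation == "aunt" else "male"
                    for rel, side in walker.aunts_uncles(pid, want):
                        if survived.get(rel, True):
                            out.add((pid, rel, side))
                elif relation == "cousin":
                    # handled separately below (side depends on perspective)
                    pass
            return out

        def expected_cousins():
            """Unique unordered cousin pairs; the side label follows the
            perspective of the smaller eligible index id (the retention
            rule for symmetric relations)."""
            seen = {}
            for pid in members:
                for rel, side in walker.cousins(pid):
                    if not survived.get(rel, True):
                        continue
                    key = (min(pid, rel), max(pid, rel))
                    if key not in seen or pid < seen[key][0]:
                        seen[key] = (pid, side)
            return {(k[0], k[1], v[1]) for k, v in seen.items()}

        for relation in ("mother", "father", "full_sibling", "aunt", "uncle", "cousin"):
            lw = (1980, 2010) if relation in ("mother", "father", "aunt", "uncle") else None
            cohort = build_relative_pairs(bundle, index, relation, lw)
            got = set()
            for r in cohort.pairs.itertuples():
                a, b = r.index_id, r.relative_id
                if relation in ("full_sibling", "cousin"):
                    a, b = min(a, b), max(a, b)
                got.add((a, b, r.side))
            want = expected_cousins() if relation == "cousin" else expected(relation)
            assert got == want, relation

    def test_clusters_are_consistent_within_pairs(self, oracle_register):
        bundle, _, _ = oracle_register
        clusters = family_clusters(bundle)
        index = build_index_cohort(bundle)
        cohort = build_relative_pairs(bundle, index, "cousin")
        pairs = cohort.pairs
        assert (pairs["index_id"].map(clusters) == pairs["family_cluster_id"]).all()
        assert (pairs["relative_id"].map(clusters) == pairs["family_cluster_id"]).all()


class TestQuantgenPairs:
    def _three_sib_bundle(self):
        return make_bundle(
            [
                ("m", "female", 1950, None, None),
                ("f", "male", 1950, None, None),
                ("a", "female", 1980, None, None),
                ("b", "male", 1982, None, None),
                ("c", "female", 1984, None, None),
            ],
            links=[("a", "m", "f"), ("b", "m", "f"), ("c", "m", "f")],
        )

    def test_single_pair_family_selected_with_certainty(self):
        bundle = make_bundle(
            [
                ("m", "female", 1950, None, None),
                ("f", "male", 1950, None, None),
                ("a", "female", 1980, None, None),
                ("b", "male", 1982, None, None),
            ],
            links=[("a", "m", "f"), ("b", "m", "f")],
        )
        sel = select_quantgen_pairs(bundle, "full_sibling", seed=0)
        assert len(sel) == 1
        assert {sel.loc[0, "member1_id"], sel.loc[0, "member2_id"]} == {"a", "b"}

    def test_uniform_pair_sampling(self):
        bundle = self._three_sib_bundle()
        counts = {}
        n = 3000
        for seed in range(n):
            sel = select_quantgen_pairs(bundle, "full_sibling", seed=seed)
            key = frozenset((sel.loc[0, "member1_id"], sel.loc[0, "member2_id"]))
            counts[key] = counts.get(key, 0) + 1
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for key, c in counts.items():
            assert abs(c / n - 1 / 3) < 3 * se, (key, c / n)

    def test_disjoint_families_give_disjoint_pairs(self, oracle_register):
        bundle, _, _ = oracle_register
        for relation in ("full_sibling", "cousin"):
            sel = select_quantgen_pairs(bundle, relation, seed=1)
            people = pd.concat([sel["member1_id"], sel["member2_id"]])
            assert people.is_unique
            assert len(sel) > 50

    def test_selected_cousins_are_cousins(self, oracle_register):
        bundle, _, _ = oracle_register
        walker = Walker(bundle)
        sel = select_quantgen_pairs(bundle, "cousin", seed=2)
        for r in sel.itertuples():
            assert r.member2_id in {c for c, _ in walker.cousins(r.member1_id)}


class TestCohortFilter:
    def test_identity_arithmetic_and_commutativity(self, small_bundle):
        cohort = build_index_cohort(small_bundle)
        same, report = apply_cohort_filter(cohort, [("all", "birth_year >= 0")])
        assert len(same) == len(cohort) and report["all"] == 0

        clauses = [("late", "birth_year >= 1990"), ("male", "sex == 'male'")]
        filtered, report = apply_cohort_filter(cohort, clauses)
        assert len(filtered) == (
            (cohort.members["birth_year"] >= 1990) & (cohort.members["sex"] == "male")
        ).sum()
        swapped, _ = apply_cohort_filter(cohort, clauses[::-1])
        assert set(swapped.ids) == set(filtered.ids)

    def test_unknown_attribute_is_configuration_error(self, small_bundle):
        cohort = build_index_cohort(small_bundle)
        with pytest.raises(ConfigurationError, match="nope"):
            apply_cohort_filter(cohort, [("nope", "no_such_column > 1")])

    def test_phenotype_flag_filter(self, small_bundle, small_case_matrix):
        cohort = build_index_cohort(small_bundle)
        attrs = small_case_matrix[["ADHD"]]
        filtered, report = apply_cohort_filter(cohort, [("drop_adhd", "~ADHD")], attributes=attrs)
        carriers = set(small_case_matrix.index[small_case_matrix["ADHD"]])
        assert set(filtered.ids) == set(cohort.ids) - carriers
        assert report["drop_adhd"] == len(set(cohort.ids) & carriers)
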