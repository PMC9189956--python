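"""Cohort construction: index cohort, relative-pair cohorts, pair sampling.

Reproduces the emulated study's cohort logic on a validated register
bundle: the index birth cohort with its exclusion cascade (birth window,
known mother, survival to age 10), the six index–relative pair cohorts
(mother, father, full sibling, aunt, uncle, cousin) with maternal/paternal
side labels, family cluster identifiers for robust-variance estimation,
and the one-pair-per-family sampling used by the quantitative genetic
model.

Year-granularity reading of "died or emigrated before age 10": an event
year at most 9 years after the birth year excludes the person; age
exactly 10 is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .register_model import RegisterBundle

RELATIONS = ("mother", "father", "full_sibling", "aunt", "uncle", "cousin")
#: relations whose pair cohorts are restricted to a late index birth window
PARENT_GENERATION_RELATIONS = ("mother", "father", "aunt", "uncle")
#: relations with a defined maternal/paternal side
SIDED_RELATIONS = ("aunt", "uncle", "cousin")
#: symmetric relations where (a, b) and (b, a) describe the same pair
SYMMETRIC_RELATIONS = ("full_sibling", "cousin")


class ConfigurationError(ValueError):
    pass


@dataclass
class IndexCohort:
    """Index birth cohort with eligibility metadata and exclusion counts."""

    members: pd.DataFrame  # person_id, sex, birth_year
    birth_window: tuple[int, int]
    min_survival_age: int
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def ids(self) -> pd.Series:
        return self.members["person_id"]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class RelativePairCohort:
    relation: str
    pairs: pd.DataFrame  # index_id, relative_id, relation, side, family_cluster_id
    restriction: tuple[int, int]
    dropped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


def _survived(persons: pd.DataFrame, min_survival_age: int) -> pd.Series:
    """True when the person neither died nor emigrated before the cutoff age."""
    ok = pd.Series(True, index=persons.index)
    for col in ("death_year", "emigration_year"):
        age = persons[col] - persons["birth_year"]
        ok &= ~(age.notna() & (age <= min_survival_age - 1))
    return ok


def build_index_cohort(
    bundle: RegisterBundle,
    birth_window: tuple[int, int] = (1960, 2010),
    min_survival_age: int = 10,
) -> IndexCohort:
    """Apply the study's exclusion cascade to define the index cohort.

    Members are persons born within ``birth_window`` (inclusive) whose
    biological mother is known and who did not die or emigrate before
    ``min_survival_age``.  The exclusion counts mirror a study-flowchart
    accounting.
    """
    persons = bundle.persons
    in_window = persons["birth_year"].between(*birth_window)
    candidates = persons[in_window]

    with_mother = bundle.links.loc[bundle.links["mother_id"].notna(), "child_id"]
    known_mother = candidates["person_id"].isin(with_mother)
    after_mother = candidates[known_mother]

    survived = _survived(after_mother, min_survival_age)
    members = after_mother[survived]

    exclusions = {
        "born_in_window": int(in_window.sum()),
        "excluded_unknown_mother": int((~known_mother).sum()),
        "excluded_died_or_emigrated": int((~survived).sum()),
        "final": int(len(members)),
    }
    return IndexCohort(
        members=members[["person_id", "sex", "birth_year"]].reset_index(drop=True),
        birth_window=birth_window,
        min_survival_age=min_survival_age,
        exclusions=exclusions,
    )


# ---------------------------------------------------------------------------
# family clusters


def family_clusters(bundle: RegisterBundle) -> pd.Series:
    """Cluster id per person: connected components of the parent-child graph.

    Any two pairs sharing a person necessarily share a cluster, which makes
    this the most conservative clustering unit for robust variance.
    """
    persons = bundle.persons["person_id"]
    pos = pd.Series(np.arange(len(persons)), index=persons)
    rows, cols = [], []
    links = bundle.links
    for col in ("mother_id", "father_id"):
        sub = links[links[col].notna() & links[col].isin(pos.index)]
        rows.extend(pos[sub["child_id"]].to_numpy())
        cols.extend(pos[sub[col]].to_numpy())
    n = len(persons)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return pd.Series([f"fam{c}" for c in labels], index=persons.to_numpy(), name="family_cluster_id")


# ---------------------------------------------------------------------------
# relative pairs


def _full_sibling_frame(links: pd.DataFrame) -> pd.DataFrame:
    """All ordered full-sibling pairs (share both known parents)."""
    both = links[links["mother_id"].notna() & links["father_id"].notna()]
    merged = both.merge(both, on=["mother_id", "father_id"], suffixes=("_a", "_b"))
    merged = merged[merged["child_id_a"] != merged["child_id_b"]]
    return merged.rename(columns={"child_id_a": "a", "child_id_b": "b"})[["a", "b"]]


def build_relative_pairs(
    bundle: RegisterBundle,
    index: IndexCohort,
    relation: str,
    late_window: Optional[tuple[int, int]] = None,
    *,
    clusters: Optional[pd.Series] = None,
) -> RelativePairCohort:
    """Construct the index–relative pair cohort for one relation.

    Mothers/fathers come from direct links; full siblings share both
    parents; aunts/uncles are full siblings of the linking parent (side =
    which parent); cousins are children of the index's parents' full
    siblings (side = linking parent).  Relatives failing the
    survival-to-age-10 rule are dropped for sibling/aunt/uncle/cousin
    cohorts; parent-generation cohorts require ``late_window`` on the
    index birth year.  Symmetric relations are de-duplicated to unique
    unordered pairs.
    """
    if relation not in RELATIONS:
        raise ConfigurationError(
            f"unknown relation '{relation}'; expected one of {RELATIONS}"
        )
    if relation in PARENT_GENERATION_RELATIONS and late_window is None:
        raise ConfigurationError(f"relation '{relation}' requires a late birth window")

    members = index.members
    restriction = index.birth_window
    if late_window is not None:
        members = members[members["birth_year"].between(*late_window)]
        restriction = tuple(late_window)
    index_ids = set(members["person_id"])

    persons = bundle.persons
    links = bundle.links
    dropped: dict[str, int] = {}

    parent_col = {"mother": "mother_id", "father": "father_id"}
    if relation in parent_col:
        sub = links[links["child_id"].isin(index_ids) & links[parent_col[relation]].notna()]
        pairs = pd.DataFrame(
            {"index_id": sub["child_id"], "relative_id": sub[parent_col[relation]]}
        )
        side = "not_applicable"
    elif relation == "full_sibling":
        sib = _full_sibling_frame(links)
        sib = sib[sib["a"].isin(index_ids)]
        pairs = sib.rename(columns={"a": "index_id", "b": "relative_id"})
        side = "not_applicable"
    elif relation in ("aunt", "uncle"):
        want_sex = "female" if relation == "aunt" else "male"
        sib = _full_sibling_frame(links)  # parent -> parent's full siblings
        rel_frames = []
        for side_label, col in (("maternal", "mother_id"), ("paternal", "father_id")):
            pl = links[links["child_id"].isin(index_ids) & links[col].notna()]
            pl = pl.rename(columns={"child_id": "index_id"})[["index_id", col]]
            j = pl.merge(sib, left_on=col, right_on="a")
            j = j.rename(columns={"b": "relative_id"})[["index_id", "relative_id"]]
            j["side"] = side_label
            rel_frames.append(j)
        pairs = pd.concat(rel_frames, ignore_index=True)
        sex = persons.set_index("person_id")["sex"]
        pairs = pairs[pairs["relative_id"].map(sex) == want_sex]
        side = None  # already a column
    elif relation == "cousin":
        sib = _full_sibling_frame(links)
        frames = []
        for side_label, col in (("maternal", "mother_id"), ("paternal", "father_id")):
            pl = links[links["child_id"].isin(index_ids) & links[col].notna()]
            pl = pl.rename(columns={"child_id": "index_id"})[["index_id", col]]
            au = pl.merge(sib, left_on=col, right_on="a").rename(columns={"b": "au_id"})
            # children of the aunt/uncle, through either parental role
            kids = []
            for kcol in ("mother_id", "father_id"):
                k = au.merge(links, left_on="au_id", right_on=kcol)
                kids.append(k.rename(columns={"child_id": "relative_id"})[["index_id", "relative_id"]])
            j = pd.concat(kids, ignore_index=True)
            j["side"] = side_label
            frames.append(j)
        pairs = pd.concat(frames, ignore_index=True)
        pairs = pairs[pairs["index_id"] != pairs["relative_id"]]
        side = None

    if side is not None:
        pairs = pairs.assign(side=side)
    pairs = pairs.drop_duplicates(["index_id", "relative_id", "side"])

    # survival rule on the relative (not applied to parents, who were by
    # construction alive at the index birth)
    if relation not in ("mother", "father"):
        alive = _survived(persons.set_index("person_id"), index.min_survival_age)
        keep = pairs["relative_id"].map(alive).fillna(False).astype(bool)
        dropped["relative_died_or_emigrated"] = int((~keep).sum())
        pairs = pairs[keep]

    if relation in SYMMETRIC_RELATIONS:
        # unique unordered pairs: when both orderings are eligible keep the
        # lexicographically smaller index_id
        lo = pairs[["index_id", "relative_id"]].min(axis=1)
        hi = pairs[["index_id", "relative_id"]].max(axis=1)
        pairs = pairs.assign(_lo=lo, _hi=hi).sort_values(
            ["_lo", "_hi", "index_id"], kind="mergesort"
        )
        before = len(pairs)
        pairs = pairs.drop_duplicates(["_lo", "_hi"]).drop(columns=["_lo", "_hi"])
        dropped["duplicate_unordered"] = before - len(pairs)

    if clusters is None:
        clusters = family_clusters(bundle)
    pairs = pairs.assign(
        relation=relation, family_cluster_id=pairs["index_id"].map(clusters).to_numpy()
    )
    pairs = pairs[["index_id", "relative_id", "relation", "side", "family_cluster_id"]]
    return RelativePairCohort(
        relation=relation,
        pairs=pairs.reset_index(drop=True),
        restriction=tuple(restriction),
        dropped=dropped,
    )


def build_all_relative_pairs(
    bundle: RegisterBundle,
    index: IndexCohort,
    late_window: tuple[int, int] = (1980, 2010),
    relations: Iterable[str] = RELATIONS,
) -> dict[str, RelativePairCohort]:
    clusters = family_clusters(bundle)
    out = {}
    for rel in relations:
        lw = late_window if rel in PARENT_GENERATION_RELATIONS else None
        out[rel] = build_relative_pairs(bundle, index, rel, lw, clusters=clusters)
    return out


# ---------------------------------------------------------------------------
# quantitative-genetics pair sampling


def select_quantgen_pairs(
    bundle: RegisterBundle,
    relation: str,
    seed: int,
    *,
    birth_window: tuple[int, int] = (1960, 2010),
    min_survival_age: int = 10,
) -> pd.DataFrame:
    """Sample one sibling or cousin pair per family, uniformly and seeded.

    Eligible persons are born within ``birth_window`` and survived to
    ``min_survival_age``.  The family unit is the nuclear sibship (both
    shared parents) for siblings and the grandparental lineage for
    cousins.  Because a person belongs to two grandparental lineages,
    cousin pairs sampled from different lineages may collide; collisions
    are resolved greedily in deterministic lineage order, so the returned
    pairs are disjoint in persons.

    Returns a frame: member1_id, member2_id, family_key, relation.
    """
    if relation not in ("full_sibling", "cousin"):
        raise ConfigurationError("quantgen pairs are defined for full_sibling or cousin")
    rng = np.random.default_rng(seed)
    persons = bundle.persons
    eligible = persons[
        persons["birth_year"].between(*birth_window)
        & _survived(persons, min_survival_age)
    ]["person_id"]
    eligible = set(eligible)
    links = bundle.links
    both = links[links["mother_id"].notna() & links["father_id"].notna()]
    both = both[both["child_id"].isin(eligible)]

    rows: list[tuple] = []
    if relation == "full_sibling":
        for (m, f), grp in sorted(
            both.groupby(["mother_id", "father_id"]), key=lambda kv: kv[0]
        ):
            kids = sorted(grp["child_id"])
            if len(kids) < 2:
                continue
            n = len(kids)
            i, j = _random_unordered_pair(rng, n)
            rows.append((kids[i], kids[j], f"{m}|{f}"))
    else:
        sib = _full_sibling_frame(links)
        parent_couple = both.set_index("child_id")[["mother_id", "father_id"]]
        # lineage key = the shared grandparental couple of the two linking
        # parents; enumerate cousin pairs per lineage
        parents = links[links["mother_id"].notna() & links["father_id"].notna()]
        children_of = parents.groupby(["mother_id", "father_id"])["child_id"].apply(list)
        by_parent: dict[str, list[str]] = {}
        for (m, f), kids in children_of.items():
            for p in (m, f):
                by_parent.setdefault(p, []).extend(k for k in kids if k in eligible)
        # grandparental couples and their (full-sib) children
        grand = parents.groupby(["mother_id", "father_id"])["child_id"].apply(sorted)
        used: set[str] = set()
        for (gm, gf), sibship in sorted(grand.items(), key=lambda kv: kv[0]):
            if len(sibship) < 2:
                continue
            cousin_pairs: list[tuple[str, str]] = []
            for ai in range(len(sibship)):
                for bi in range(ai + 1, len(sibship)):
                    for x in by_parent.get(sibship[ai], []):
                        for y in by_parent.get(sibship[bi], []):
                            if x != y:
                                cousin_pairs.append((min(x, y), max(x, y)))
            cousin_pairs = sorted(set(cousin_pairs))
            if not cousin_pairs:
                continue
            x, y = cousin_pairs[int(rng.integers(len(cousin_pairs)))]
            if x in used or y in used:
                continue
            used.update((x, y))
            rows.append((x, y, f"{gm}|{gf}"))

    out = pd.DataFrame(rows, columns=["member1_id", "member2_id", "family_key"])
    out["relation"] = relation
    return out


def _random_unordered_pair(rng, n: int) -> tuple[int, int]:
    """Uniform unordered pair of distinct indices in range(n)."""
    i = int(rng.integers(n))
    j = int(rng.integers(n - 1))
    if j >= i:
        j += 1
    return (i, j) if i < j else (j, i)


# ---------------------------------------------------------------------------
# generic cohort filtering (sensitivity-analysis hook)


def filter_frame(
    df: pd.DataFrame, clauses: Iterable[tuple[str, str]]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply named pandas-query clauses conjunctively; count removals.

    Each clause is ``(label, query)``; a query referencing an unknown
    column raises :class:`ConfigurationError`.
    """
    report: dict[str, int] = {}
    out = df
    for label, query in clauses:
        try:
            kept = out.query(query)
        except Exception as exc:  # noqa: BLE001 - surface as config error
            raise ConfigurationError(f"predicate '{label}' failed: {exc}") from exc
        report[label] = len(out) - len(kept)
        out = kept
    return out, report


def apply_cohort_filter(cohort, clauses, attributes: Optional[pd.DataFrame] = None):
    """Filter an :class:`IndexCohort` or :class:`RelativePairCohort`.

    ``attributes`` (indexed by person_id) is joined onto the cohort frame
    first, so predicates can reference person attributes and phenotype
    flags.  Returns a filtered cohort of the same type plus a removal
    report.
    """
    if isinstance(cohort, IndexCohort):
        frame = cohort.members
        if attributes is not None:
            frame = frame.join(attributes, on="person_id")
        kept, report = filter_frame(frame, clauses)
        new = IndexCohort(
            members=kept[cohort.members.columns].reset_index(drop=True),
            birth_window=cohort.birth_window,
            min_survival_age=cohort.min_survival_age,
            exclusions=dict(cohort.exclusions),
        )
        return new, report
    if isinstance(cohort, RelativePairCohort):
        frame = cohort.pairs
        if attributes is not None:
            frame = frame.join(attributes.add_prefix("index_"), on="index_id")
            frame = frame.join(attributes.add_prefix("relative_"), on="relative_id")
        kept, report = filter_frame(frame, clauses)
        new = RelativePairCohort(
            relation=cohort.relation,
            pairs=kept[cohort.pairs.columns].reset_index(drop=True),
            restriction=cohort.restriction,
            dropped=dict(cohort.dropped),
        )
        return new, report
    raise ConfigurationError(f"cannot filter object of type {type(cohort).__name__}")
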