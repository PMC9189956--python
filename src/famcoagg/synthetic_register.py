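"""Synthetic multi-generation register generator.

Families are simulated as three-generation pedigrees — two grandparental
couples, a maternal and a paternal parental sibship (supplying the mother,
father, aunts and uncles), and a grandchild generation (index individuals,
their full siblings, and cousins through the aunts/uncles) — with bivariate
liabilities from the ACE model in :mod:`famcoagg.liability`.  Dichotomizing
the liabilities at prevalence-calibrated, sex- and birth-year-shifted
thresholds yields lifetime phenotypes, which are then emitted as
era-coded diagnosis and dispensation events in a
:class:`~famcoagg.register_model.RegisterBundle`.

The generative truth (per-person liabilities and case status) is retained
alongside the bundle so that every downstream stage can be tested against
known parameter values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .liability import (
    ParameterDomainError,
    RelativeClassSpec,
    VarianceComponents,
    pair_correlation_matrix,
    threshold_from_prevalence,
)
from .register_model import (
    DEFAULT_ERA_MAP,
    DRUG_REGISTER_START,
    REGISTER_END,
    EraMap,
    RegisterBundle,
    config_hash,
)

GENERATOR_VERSION = "0.1.0"


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class TraitParams:
    """One trait's generative parameters.

    ``sex_threshold_shift`` is the female-minus-male additive threshold
    offset in liability SD units (positive = lower female prevalence);
    ``birth_year_linear``/``birth_year_cubic`` act on the birth year
    standardized to [-1, 1] over the configured range.
    """

    name: str
    a2: float
    c2: float
    e2: float
    prevalence: float
    sex_threshold_shift: float = 0.0
    birth_year_linear: float = 0.0
    birth_year_cubic: float = 0.0

    def __post_init__(self):
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-12:
            raise ParameterDomainError(
                f"{self.name}: a2+c2+e2 = {self.a2 + self.c2 + self.e2}, expected 1"
            )
        if not 0.0 < self.prevalence < 1.0:
            raise ParameterDomainError(f"{self.name}: prevalence outside (0, 1)")


@dataclass(frozen=True)
class CrossTraitCorrelations:
    rA: float = 0.0
    rC: float = 0.0
    rE: float = 0.0

    def __post_init__(self):
        for name in ("rA", "rC", "rE"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ParameterDomainError(f"{name} outside [-1, 1]: {v}")


# Default study conditions.  Variance components and cross-trait
# correlations are the fitted values of the emulated study's best model;
# the sex threshold shifts reproduce the printed case sex distributions
# (trait 1: 36.0% female; trait 2: 56.3% female; cohort 48.6% female).
DEFAULT_TRAIT1 = TraitParams(
    name="ADHD", a2=0.84, c2=0.0, e2=0.16, prevalence=0.0230, sex_threshold_shift=0.218
)
DEFAULT_TRAIT2 = TraitParams(
    name="anyAD", a2=0.23, c2=0.09, e2=0.68, prevalence=0.0414, sex_threshold_shift=-0.144
)
DEFAULT_CROSS = CrossTraitCorrelations(rA=0.13, rC=0.0, rE=0.02)


@dataclass
class SimulationParams:
    n_families: int = 1000
    sibship_size_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 1 / 3, 2: 1 / 3, 3: 1 / 3}
    )
    traits: tuple[TraitParams, TraitParams] = (DEFAULT_TRAIT1, DEFAULT_TRAIT2)
    cross: CrossTraitCorrelations = DEFAULT_CROSS
    birth_year_range: tuple[int, int] = (1960, 2010)
    censor_before_10_prob: float = 0.039  # fraction who die/emigrate before age 10
    female_fraction: float = 0.486
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 0:
            raise ParameterDomainError("n_families must be >= 0")
        sizes = sorted(self.sibship_size_distribution)
        probs = np.array([self.sibship_size_distribution[s] for s in sizes], float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9 or min(sizes) < 1:
            raise ParameterDomainError("sibship_size_distribution must be a pmf over sizes >= 1")
        if self.birth_year_range[0] >= self.birth_year_range[1]:
            raise ParameterDomainError("birth_year_range must be an increasing pair")
        # implied pair correlation matrices must be PSD for both classes
        vc = self.components(calibrate=False)
        for spec in (RelativeClassSpec("full_sibling", 0.5, 1.0), RelativeClassSpec("cousin", 0.125, 0.0)):
            pair_correlation_matrix(vc, spec)

    def components(self, calibrate: bool = True) -> VarianceComponents:
        """Express the generator's parameters as :class:`VarianceComponents`.

        With ``calibrate`` the baseline (male, mid-birth-year) thresholds
        are solved so that the population prevalence, averaged over the
        configured sex mix and a uniform birth-year distribution, equals
        each trait's target prevalence.
        """
        t1, t2 = self.traits
        rC = self.cross.rC if t1.c2 * t2.c2 > 0 else None
        rA = self.cross.rA if t1.a2 * t2.a2 > 0 else None
        if calibrate:
            thresholds = tuple(self.calibrated_threshold(k) for k in range(2))
        else:
            thresholds = (
                threshold_from_prevalence(t1.prevalence),
                threshold_from_prevalence(t2.prevalence),
            )
        return VarianceComponents(
            a2=(t1.a2, t2.a2),
            c2=(t1.c2, t2.c2),
            e2=(t1.e2, t2.e2),
            rA=rA,
            rC=rC,
            rE=self.cross.rE,
            thresholds=thresholds,
            threshold_covariates=tuple(
                (t.sex_threshold_shift, t.birth_year_linear, t.birth_year_cubic)
                for t in self.traits
            ),
        )

    def calibrated_threshold(self, k: int) -> float:
        """Baseline threshold for trait ``k`` matching its target prevalence.

        Averages the upper-tail probability over sex (Bernoulli
        ``female_fraction``) and standardized birth year (uniform on
        [-1, 1], 21-point midpoint rule), then solves for the baseline.
        """
        t = self.traits[k]
        z = np.linspace(-1, 1, 21)
        shift_grid = t.birth_year_linear * z + t.birth_year_cubic * z**3

        def mean_prev(base: float) -> float:
            male = norm.sf(base + shift_grid).mean()
            female = norm.sf(base + t.sex_threshold_shift + shift_grid).mean()
            return self.female_fraction * female + (1 - self.female_fraction) * male

        lo, hi = -10.0, 10.0
        return float(brentq(lambda b: mean_prev(b) - t.prevalence, lo, hi, xtol=1e-12))

    def standardized_birth_year(self, years: np.ndarray) -> np.ndarray:
        first, last = self.birth_year_range
        mid = 0.5 * (first + last)
        half = 0.5 * (last - first)
        return (np.asarray(years, float) - mid) / half

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["sibship_size_distribution"] = {
            str(k): v for k, v in self.sibship_size_distribution.items()
        }
        return d


# ---------------------------------------------------------------------------
# pedigree structure


@dataclass
class Pedigree:
    """Register persons/links plus generator-internal structure.

    ``structure`` columns: ``person_id``, ``family``, ``generation``
    (0 = founders, 1 = parental, 2 = grandchild), ``role`` (grandparent,
    parent, aunt_uncle, au_spouse, child, cousin), ``branch`` (maternal /
    paternal / none) and ``nuclear_id`` — the sibship of origin, the unit
    over which shared-environment (C) liability is drawn.
    """

    persons: pd.DataFrame
    links: pd.DataFrame
    structure: pd.DataFrame


def _draw_sizes(rng, dist: dict[int, float], n: int) -> np.ndarray:
    sizes = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[s] for s in sizes], float)
    probs = probs / probs.sum()
    return rng.choice(sizes, size=n, p=probs)


def simulate_pedigree_structure(params: SimulationParams, rng=None) -> Pedigree:
    """Simulate family structures (persons + parent links, no phenotypes).

    Parent–child birth-year gaps are at least 18 years; sibling spacing is
    1–4 years; grandchild-generation firstborn years fall around the
    configured ``birth_year_range`` so that the downstream birth-window
    restriction behaves as in real register data.  Death/emigration before
    age 10 is applied, at rate ``censor_before_10_prob``, to everyone except
    founders and the two linking parents.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    first, last = params.birth_year_range
    persons: list[tuple] = []
    links: list[tuple] = []
    structure: list[tuple] = []

    def sex_draw() -> str:
        return "female" if rng.random() < params.female_fraction else "male"

    for f in range(params.n_families):
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"F{f:06d}P{counter:03d}"

        def add_person(sex, birth, gen, role, branch, nuclear, censorable):
            pid = new_id()
            death = emig = None
            if censorable and rng.random() < params.censor_before_10_prob:
                year = int(birth + rng.integers(0, 10))
                if rng.random() < 0.5:
                    death = year
                else:
                    emig = year
            persons.append((pid, sex, int(birth), death, emig))
            structure.append((pid, f, gen, role, branch, nuclear))
            return pid

        parent_of_branch = {}
        parent_year = {}
        aunts_uncles = []  # (pid, birth_year, branch)
        for branch in ("maternal", "paternal"):
            size = int(_draw_sizes(rng, params.sibship_size_distribution, 1)[0])
            firstborn = int(rng.integers(first - 28, last - 22))
            gp_year = firstborn - int(rng.integers(20, 36))
            gm = add_person("female", gp_year, 0, "grandparent", branch, f"F{f:06d}self{branch}GM", False)
            gf = add_person(
                "male", gp_year + int(rng.integers(-4, 5)), 0, "grandparent", branch,
                f"F{f:06d}self{branch}GF", False,
            )
            nuclear = f"F{f:06d}N{branch}"
            years = firstborn + np.concatenate([[0], np.cumsum(rng.integers(1, 5, size - 1))])
            parent_idx = int(rng.integers(size))
            want_sex = "female" if branch == "maternal" else "male"
            for i in range(size):
                is_parent = i == parent_idx
                sex = want_sex if is_parent else sex_draw()
                pid = add_person(sex, years[i], 1, "parent" if is_parent else "aunt_uncle",
                                 branch, nuclear, not is_parent)
                links.append((pid, gm, gf))
                if is_parent:
                    parent_of_branch[branch] = pid
                    parent_year[branch] = int(years[i])
                else:
                    aunts_uncles.append((pid, int(years[i]), sex, branch))

        mother = parent_of_branch["maternal"]
        father = parent_of_branch["paternal"]

        # grandchild generation: the index sibship
        size = int(_draw_sizes(rng, params.sibship_size_distribution, 1)[0])
        firstborn = max(parent_year["maternal"], parent_year["paternal"]) + int(rng.integers(18, 33))
        years = firstborn + np.concatenate([[0], np.cumsum(rng.integers(1, 5, size - 1))])
        nuclear = f"F{f:06d}Nindex"
        for i in range(size):
            pid = add_person(sex_draw(), years[i], 2, "child", "none", nuclear, True)
            links.append((pid, mother, father))

        # cousins through each aunt/uncle
        for au, au_year, au_sex, branch in aunts_uncles:
            spouse_sex = "male" if au_sex == "female" else "female"
            spouse_year = au_year + int(rng.integers(-4, 5))
            spouse = add_person(
                spouse_sex, spouse_year, 1, "au_spouse", branch,
                f"F{f:06d}self{au}", False,
            )
            n_child = int(_draw_sizes(rng, params.sibship_size_distribution, 1)[0])
            firstborn = max(au_year, spouse_year) + int(rng.integers(18, 33))
            years = firstborn + np.concatenate([[0], np.cumsum(rng.integers(1, 5, n_child - 1))])
            nuclear = f"F{f:06d}N{au}"
            cmother, cfather = (au, spouse) if au_sex == "female" else (spouse, au)
            for i in range(n_child):
                pid = add_person(sex_draw(), years[i], 2, "cousin", branch, nuclear, True)
                links.append((pid, cmother, cfather))

    persons_df = pd.DataFrame(persons, columns=["person_id", "sex", "birth_year", "death_year", "emigration_year"])
    persons_df["death_year"] = persons_df["death_year"].astype("Int64")
    persons_df["emigration_year"] = persons_df["emigration_year"].astype("Int64")
    links_df = pd.DataFrame(links, columns=["child_id", "mother_id", "father_id"]).astype("object")
    structure_df = pd.DataFrame(
        structure, columns=["person_id", "family", "generation", "role", "branch", "nuclear_id"]
    )
    return Pedigree(persons_df, links_df, structure_df)


# ---------------------------------------------------------------------------
# liabilities


def _component_cov(v1: float, v2: float, r: float) -> np.ndarray:
    c = r * np.sqrt(v1 * v2)
    return np.array([[v1, c], [c, v2]])


def _mvn_factor(cov: np.ndarray) -> np.ndarray:
    """Square root of a (possibly singular) PSD 2x2 covariance."""
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def simulate_liabilities(
    pedigree: Pedigree, params: SimulationParams, rng=None
) -> pd.DataFrame:
    """Draw bivariate A/C/E liabilities over the pedigree.

    Founders draw additive-genetic values from N(0, Sigma_A); each child's
    additive value is the parental midvalue plus a segregation deviate with
    covariance Sigma_A/2.  Shared environment is drawn once per nuclear
    sibship (founders form singleton sibships); unique environment is
    independent per person.  Returned columns: A1, A2, C1, C2, E1, E2,
    L1, L2 indexed by person_id.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    t1, t2 = params.traits
    sig_a = _component_cov(t1.a2, t2.a2, params.cross.rA)
    sig_c = _component_cov(t1.c2, t2.c2, params.cross.rC)
    sig_e = _component_cov(t1.e2, t2.e2, params.cross.rE)
    fa = _mvn_factor(sig_a)
    fa_seg = _mvn_factor(sig_a / 2.0)
    fc = _mvn_factor(sig_c)
    fe = _mvn_factor(sig_e)

    struct = pedigree.structure
    ids = struct["person_id"].to_numpy()
    n = len(ids)
    pos = {pid: i for i, pid in enumerate(ids)}
    A = np.zeros((n, 2))

    links = pedigree.links
    child_pos = np.array([pos[c] for c in links["child_id"]], dtype=int) if len(links) else np.array([], int)
    mother_pos = np.array([pos[m] for m in links["mother_id"]], dtype=int) if len(links) else np.array([], int)
    father_pos = np.array([pos[p] for p in links["father_id"]], dtype=int) if len(links) else np.array([], int)

    has_parents = np.zeros(n, bool)
    has_parents[child_pos] = True
    founders = ~has_parents
    A[founders] = rng.standard_normal((founders.sum(), 2)) @ fa.T

    gen = struct["generation"].to_numpy()
    child_gen = gen[child_pos] if len(links) else np.array([], int)
    for g in sorted(set(child_gen.tolist())):
        sel = child_gen == g
        mid = 0.5 * (A[mother_pos[sel]] + A[father_pos[sel]])
        A[child_pos[sel]] = mid + rng.standard_normal((sel.sum(), 2)) @ fa_seg.T

    nuclear = struct["nuclear_id"].to_numpy()
    uniq, inverse = np.unique(nuclear, return_inverse=True)
    C_units = rng.standard_normal((len(uniq), 2)) @ fc.T
    C = C_units[inverse]
    E = rng.standard_normal((n, 2)) @ fe.T

    out = pd.DataFrame(
        {
            "person_id": ids,
            "A1": A[:, 0], "A2": A[:, 1],
            "C1": C[:, 0], "C2": C[:, 1],
            "E1": E[:, 0], "E2": E[:, 1],
        }
    )
    out["L1"] = out["A1"] + out["C1"] + out["E1"]
    out["L2"] = out["A2"] + out["C2"] + out["E2"]
    return out


# ---------------------------------------------------------------------------
# phenotypes


def liabilities_to_phenotypes(
    pedigree: Pedigree,
    liabilities: pd.DataFrame,
    params: SimulationParams,
    rng=None,
    *,
    last_register_year: int = REGISTER_END,
    calibrate: bool = True,
) -> pd.DataFrame:
    """Dichotomize liabilities into lifetime phenotypes with event years.

    A person is a case for trait *k* when the total liability exceeds
    ``threshold_k + sex_shift_k * 1[female] + linear_k * z + cubic_k * z^3``
    with ``z`` the standardized birth year.  Cases draw a first-diagnosis
    year uniformly between age 3 and the earliest of death, emigration and
    the register end; when that window is empty the case keeps
    ``diagnosis_year`` missing (true case, never observable) — truth and
    observation are kept separate.

    Returns a long table: person_id, trait, liability, is_case,
    diagnosis_year.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    persons = pedigree.persons.set_index("person_id")
    df = liabilities.set_index("person_id").join(
        persons[["sex", "birth_year", "death_year", "emigration_year"]]
    )
    z = params.standardized_birth_year(df["birth_year"].to_numpy())
    female = (df["sex"] == "female").to_numpy()
    birth = df["birth_year"].to_numpy()
    end = np.full(len(df), last_register_year, dtype=float)
    for col in ("death_year", "emigration_year"):
        vals = df[col].to_numpy(dtype="float64", na_value=np.inf)
        end = np.minimum(end, vals)

    frames = []
    for k, trait in enumerate(params.traits):
        base = params.calibrated_threshold(k) if calibrate else threshold_from_prevalence(trait.prevalence)
        thr = (
            base
            + trait.sex_threshold_shift * female
            + trait.birth_year_linear * z
            + trait.birth_year_cubic * z**3
        )
        liab = df[f"L{k + 1}"].to_numpy()
        is_case = liab > thr
        lo = birth + 3
        hi = np.minimum(end, last_register_year)
        valid = is_case & (hi >= lo)
        year = np.full(len(df), np.nan)
        if valid.any():
            year[valid] = rng.integers(lo[valid], hi[valid].astype(int) + 1)
        frames.append(
            pd.DataFrame(
                {
                    "person_id": df.index,
                    "trait": trait.name,
                    "liability": liab,
                    "is_case": is_case,
                    "diagnosis_year": pd.array(year, dtype="Int64"),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# event emission


@dataclass(frozen=True)
class DiseaseChannel:
    """One diagnosable disease with era-specific codes and optional drugs."""

    name: str
    weight: float
    codes: dict  # code_system -> code prefix emitted
    atc: tuple[str, ...] = ()


@dataclass(frozen=True)
class TraitCoding:
    channels: tuple[DiseaseChannel, ...]
    drug_fraction: float = 0.0  # cases additionally dispensing a drug
    drug_only_fraction: float = 0.0  # cases visible only through dispensations


@dataclass(frozen=True)
class CodingConfig:
    traits: dict  # trait name -> TraitCoding
    era_map: EraMap = DEFAULT_ERA_MAP

    def to_jsonable(self) -> dict:
        return {
            name: {
                "drug_fraction": tc.drug_fraction,
                "drug_only_fraction": tc.drug_only_fraction,
                "channels": [
                    {"name": ch.name, "weight": ch.weight, "codes": dict(ch.codes), "atc": list(ch.atc)}
                    for ch in tc.channels
                ],
            }
            for name, tc in self.traits.items()
        }


def _ad(name, weight, icd10, icd9, icd8=None, icd7=None, atc=()):
    codes = {"ICD10": icd10, "ICD9": icd9}
    if icd8:
        codes["ICD8"] = icd8
    if icd7:
        codes["ICD7"] = icd7
    return DiseaseChannel(name, weight, codes, tuple(atc))


#: Illustrative case-coding configuration.  Code prefixes follow the
#: conventional ICD chapters for each disease but are NOT the study's
#: (unpublished) supplementary lists; channel weights are proportional to
#: the printed index-cohort case counts.  Early-era (ICD-7/8) codes are
#: deliberately sparse, as in real historical registers.
DEFAULT_CODING = CodingConfig(
    traits={
        "ADHD": TraitCoding(
            channels=(
                DiseaseChannel("ADHD", 1.0, {"ICD10": "F90", "ICD9": "314"}, ("N06BA",)),
            ),
            drug_fraction=0.55,
            drug_only_fraction=0.10,
        ),
        "anyAD": TraitCoding(
            channels=(
                _ad("ankylosing_spondylitis", 7196, "M45", "720", "712"),
                _ad("celiac_disease", 37872, "K90", "579", "269"),
                _ad("crohns_disease", 21971, "K50", "555", "563"),
                _ad("graves_disease", 14111, "E05", "242", "242"),
                _ad("hashimotos_disease", 7548, "E063", "245", "245"),
                _ad("multiple_sclerosis", 8900, "G35", "340", "340"),
                _ad("psoriasis", 45954, "L40", "696", "696"),
                _ad("rheumatoid_arthritis", 15090, "M05", "714", "712"),
                _ad("sarcoidosis", 6960, "D86", "135", "135"),
                _ad("sjogrens_syndrome", 2858, "M350", "7102"),
                _ad("systemic_lupus_erythematosus", 3452, "M32", "7100", "734"),
                _ad("type1_diabetes", 34653, "E10", "250", "250", "260", atc=("A10A",)),
                _ad("ulcerative_colitis", 30414, "K51", "556", "563"),
            ),
            drug_fraction=0.15,
            drug_only_fraction=0.0,
        ),
    }
)


def emit_register(
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    params: SimulationParams,
    coding: CodingConfig = DEFAULT_CODING,
    rng=None,
    *,
    last_register_year: int = REGISTER_END,
) -> RegisterBundle:
    """Turn lifetime phenotypes into register events.

    Each observable case emits one diagnosis event whose ``code_system``
    matches its diagnosis year under the era map, unless it is selected as
    drug-only, in which case (as for the configured extra ``drug_fraction``)
    a dispensation in the drug-register era is emitted instead.  Cases
    whose diagnosis year precedes the first configured era, or whose
    channel has no code for that era, leave no trace (register-era
    censoring); a year falling in an internal gap of the era map raises
    :class:`GenerationError` (misconfiguration).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 3]))
    era_map = coding.era_map
    persons = pedigree.persons.set_index("person_id")
    birth = persons["birth_year"]
    end_obs = pd.concat(
        [persons["death_year"], persons["emigration_year"]], axis=1
    ).min(axis=1).fillna(last_register_year).clip(upper=last_register_year)

    diag_rows: list[tuple] = []
    disp_rows: list[tuple] = []
    counts: dict[str, dict[str, int]] = {}

    era_start = era_map.start
    for trait in params.traits:
        tc = coding.traits.get(trait.name)
        sub = phenotypes[(phenotypes["trait"] == trait.name) & phenotypes["is_case"]]
        c = counts[trait.name] = {
            "cases": int(sub.shape[0]),
            "diagnosis_events": 0,
            "dispensation_events": 0,
            "invisible": 0,
        }
        if tc is None or sub.empty:
            c["invisible"] = int(sub.shape[0])
            continue
        weights = np.array([ch.weight for ch in tc.channels], float)
        weights /= weights.sum()
        chan_idx = rng.choice(len(tc.channels), size=len(sub), p=weights)
        drug_only = rng.random(len(sub)) < tc.drug_only_fraction
        extra_drug = rng.random(len(sub)) < tc.drug_fraction

        pids = sub["person_id"].to_numpy()
        years = sub["diagnosis_year"].to_numpy(dtype="float64", na_value=np.nan)
        for i, pid in enumerate(pids):
            ch = tc.channels[chan_idx[i]]
            visible = False
            year = years[i]
            wants_drug = (drug_only[i] or extra_drug[i]) and ch.atc
            if not drug_only[i] and not np.isnan(year):
                year = int(year)
                system = era_map.system_for_year(year)
                if system is None:
                    if year >= era_start:
                        raise GenerationError(
                            f"diagnosis year {year} falls in a gap of the era map"
                        )
                    # pre-register year: event never recorded
                else:
                    code = ch.codes.get(system)
                    if code is not None:
                        diag_rows.append((pid, code, system, year))
                        c["diagnosis_events"] += 1
                        visible = True
            if wants_drug:
                lo = max(DRUG_REGISTER_START, int(birth[pid]) + 3)
                hi = int(min(end_obs[pid], last_register_year))
                if hi >= lo:
                    dy = int(rng.integers(lo, hi + 1))
                    atc = ch.atc[int(rng.integers(len(ch.atc)))]
                    disp_rows.append((pid, atc, dy))
                    c["dispensation_events"] += 1
                    visible = True
            if not visible:
                c["invisible"] += 1

    diagnoses = pd.DataFrame(diag_rows, columns=["person_id", "code", "code_system", "event_year"])
    dispensations = pd.DataFrame(disp_rows, columns=["person_id", "atc_code", "event_year"])
    if diagnoses.empty:
        diagnoses = diagnoses.astype({"event_year": "int64"})
    if dispensations.empty:
        dispensations = dispensations.astype({"event_year": "int64"})

    params_json = params.to_jsonable()
    metadata = {
        "seed": params.seed,
        "generator_version": GENERATOR_VERSION,
        "config_hash": config_hash({"params": params_json, "coding": coding.to_jsonable()}),
        "params": json.dumps(params_json, sort_keys=True),
        "emission_counts": json.dumps(counts, sort_keys=True),
    }
    return RegisterBundle(
        persons=pedigree.persons.copy(),
        links=pedigree.links.copy(),
        diagnoses=diagnoses,
        dispensations=dispensations,
        metadata=metadata,
    )


def generate_register(
    params: SimulationParams, coding: CodingConfig = DEFAULT_CODING
) -> tuple[RegisterBundle, pd.DataFrame, Pedigree]:
    """Full generator pipeline: structure -> liabilities -> phenotypes -> bundle.

    Bit-reproducible for a fixed seed.  Returns the register bundle, the
    truth phenotype table and the pedigree (with generator-internal
    structure).
    """
    ss = np.random.SeedSequence(params.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(4)]
    pedigree = simulate_pedigree_structure(params, streams[0])
    liab = simulate_liabilities(pedigree, params, streams[1])
    phen = liabilities_to_phenotypes(pedigree, liab, params, streams[2])
    bundle = emit_register(pedigree, phen, params, coding, streams[3])
    return bundle, phen, pedigree


def write_truth(phenotypes: pd.DataFrame, path) -> None:
    cols = ["person_id", "trait", "liability", "is_case", "diagnosis_year"]
    phenotypes.loc[:, cols].sort_values(["trait", "person_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# direct (pedigree-free) simulators of model-implied quantities


def _threshold_matrix(params: SimulationParams, female: np.ndarray) -> np.ndarray:
    """(n, 2) per-person thresholds under the sex mix, at mid birth year."""
    out = np.empty((len(female), 2))
    for k, t in enumerate(params.traits):
        out[:, k] = params.calibrated_threshold(k) + t.sex_threshold_shift * female
    return out


def simulate_individual_outcomes(
    params: SimulationParams, n: int, rng=None
) -> pd.DataFrame:
    """Simulate ``n`` unrelated individuals' case status for both traits.

    Liabilities are bivariate normal with the model-implied within-person
    cross-trait correlation; thresholds carry the configured sex structure
    (birth-year effects are held at the range midpoint).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    vc = params.components(calibrate=False)
    w = vc.within_person_cross
    L = rng.standard_normal((n, 2)) @ np.linalg.cholesky(np.array([[1.0, w], [w, 1.0]])).T
    female = rng.random(n) < params.female_fraction
    thr = _threshold_matrix(params, female)
    cases = L > thr
    return pd.DataFrame({"female": female, "case1": cases[:, 0], "case2": cases[:, 1]})


def simulate_pair_outcomes(
    params: SimulationParams,
    spec: RelativeClassSpec,
    n_pairs: int,
    rng=None,
    *,
    sex_structure: bool = True,
) -> np.ndarray:
    """Simulate pair case-status patterns directly from the 4x4 model.

    Returns a boolean array of shape (n_pairs, 4) ordered (m1 t1, m1 t2,
    m2 t1, m2 t2).  With ``sex_structure`` each member independently draws
    a sex and the thresholds shift accordingly; without it both members
    use the prevalence-implied thresholds directly (the collapsed-count
    study condition).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    vc = params.components(calibrate=sex_structure)
    R = pair_correlation_matrix(vc, spec)
    w, v = np.linalg.eigh(R)
    factor = v * np.sqrt(np.clip(w, 0, None))
    L = rng.standard_normal((n_pairs, 4)) @ factor.T
    if sex_structure:
        thr = np.empty((n_pairs, 4))
        for member in range(2):
            female = rng.random(n_pairs) < params.female_fraction
            thr[:, 2 * member : 2 * member + 2] = _threshold_matrix(params, female)
    else:
        t = vc.thresholds
        thr = np.tile(np.array([t[0], t[1], t[0], t[1]]), (n_pairs, 1))
    return L > thr
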