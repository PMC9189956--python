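"""Lifetime phenotyping from diagnosis and dispensation events.

A :class:`CaseDefinition` lists code-system-qualified diagnosis code
prefixes and/or ATC code prefixes; a person is a lifetime case when any
single event matches any rule (any-of logic), with the first matching
year recorded.  Prefix matching mirrors how ICD hierarchies are
conventionally queried: a three-character stem matches all its subcodes.

Also provides the any-of-N composite (union of member phenotypes, first
event year = earliest across members) and the minimum-case inclusion
filter (a phenotype is analysed only when strictly more than ``min_cases``
index-cohort members carry it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_builder import ConfigurationError, IndexCohort
from .register_model import CODE_SYSTEMS, DRUG_REGISTER_START, RegisterBundle


@dataclass(frozen=True)
class CaseDefinition:
    """One lifetime phenotype: any matching event makes a case."""

    name: str
    diagnosis_rules: tuple[tuple[str, str], ...] = ()  # (code_system, prefix)
    drug_rules: tuple[str, ...] = ()  # ATC prefixes

    def __post_init__(self):
        if not self.diagnosis_rules and not self.drug_rules:
            raise ConfigurationError(f"case definition '{self.name}' has no rules")
        for system, prefix in self.diagnosis_rules:
            if system not in CODE_SYSTEMS:
                raise ConfigurationError(
                    f"'{self.name}': unknown code system '{system}'"
                )
            if not prefix:
                raise ConfigurationError(f"'{self.name}': empty diagnosis prefix")
        if any(not p for p in self.drug_rules):
            raise ConfigurationError(f"'{self.name}': empty ATC prefix")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CaseDefinition":
        diag = []
        for system, prefixes in dict(d.get("diagnosis", {})).items():
            if isinstance(prefixes, str):
                prefixes = [prefixes]
            diag.extend((system, p) for p in prefixes)
        drugs = d.get("atc", [])
        if isinstance(drugs, str):
            drugs = [drugs]
        return cls(name=d["name"], diagnosis_rules=tuple(diag), drug_rules=tuple(drugs))


def _first_match_years(
    events: pd.DataFrame, code_col: str, prefixes: Sequence[str], year_col: str = "event_year"
) -> pd.Series:
    """Earliest event year per person over events matching any prefix."""
    if events.empty or not prefixes:
        return pd.Series(dtype="float64")
    codes = events[code_col].astype(str)
    mask = np.zeros(len(events), dtype=bool)
    for p in prefixes:
        mask |= codes.str.startswith(p).to_numpy()
    hit = events[mask]
    if hit.empty:
        return pd.Series(dtype="float64")
    return hit.groupby("person_id")[year_col].min().astype("float64")


def apply_case_definition(
    bundle: RegisterBundle,
    definition: CaseDefinition,
    *,
    drug_register_start: int = DRUG_REGISTER_START,
) -> pd.DataFrame:
    """Evaluate one case definition over every person in the bundle.

    Returns a frame (person_id, phenotype, is_case, first_event_year);
    ``is_case`` iff ``first_event_year`` is present.  Dispensations dated
    before the drug-register era never contribute.
    """
    firsts = []
    by_system: dict[str, list[str]] = {}
    for system, prefix in definition.diagnosis_rules:
        by_system.setdefault(system, []).append(prefix)
    for system, prefixes in by_system.items():
        ev = bundle.diagnoses[bundle.diagnoses["code_system"] == system]
        firsts.append(_first_match_years(ev, "code", prefixes))
    if definition.drug_rules:
        disp = bundle.dispensations
        disp = disp[disp["event_year"] >= drug_register_start]
        firsts.append(_first_match_years(disp, "atc_code", definition.drug_rules))

    if firsts:
        first_year = pd.concat(firsts, axis=1).min(axis=1)
    else:
        first_year = pd.Series(dtype="float64")
    out = pd.DataFrame({"person_id": bundle.persons["person_id"]})
    out["phenotype"] = definition.name
    mapped = out["person_id"].map(first_year)
    out["first_event_year"] = pd.array(mapped, dtype="Int64")
    out["is_case"] = out["first_event_year"].notna()
    return out[["person_id", "phenotype", "is_case", "first_event_year"]]


def build_phenotype_table(
    bundle: RegisterBundle, definitions: Iterable[CaseDefinition]
) -> pd.DataFrame:
    """Long phenotype table over all definitions (one row per person x phenotype)."""
    frames = [apply_case_definition(bundle, d) for d in definitions]
    if not frames:
        raise ConfigurationError("no case definitions given")
    return pd.concat(frames, ignore_index=True)


def build_any_ad(
    phenotypes: pd.DataFrame, ad_names: Sequence[str], name: str = "anyAD"
) -> pd.DataFrame:
    """Composite 'any of the listed diseases' phenotype (idempotent union).

    Case iff case for at least one member phenotype; first event year is
    the earliest across members.
    """
    present = set(phenotypes["phenotype"])
    unknown = [n for n in ad_names if n not in present]
    if unknown:
        raise ConfigurationError(f"unknown phenotype name(s) in composite: {unknown}")
    sub = phenotypes[phenotypes["phenotype"].isin(ad_names)]
    agg = sub.groupby("person_id").agg(
        is_case=("is_case", "any"), first_event_year=("first_event_year", "min")
    )
    out = agg.reset_index()
    out["phenotype"] = name
    out["first_event_year"] = out["first_event_year"].astype("Int64")
    out.loc[~out["is_case"], "first_event_year"] = pd.NA
    return out[["person_id", "phenotype", "is_case", "first_event_year"]]


def case_counts(
    phenotypes: pd.DataFrame, index: IndexCohort
) -> pd.Series:
    """Index-cohort case count per phenotype."""
    sub = phenotypes[phenotypes["person_id"].isin(set(index.ids))]
    return sub[sub["is_case"]].groupby("phenotype").size().reindex(
        sorted(set(phenotypes["phenotype"])), fill_value=0
    )


def apply_min_case_filter(
    phenotypes: pd.DataFrame, index: IndexCohort, min_cases: int = 2000
) -> tuple[list[str], pd.Series]:
    """Retain phenotypes with strictly more than ``min_cases`` index cases.

    Returns (retained names, full count report).  The inequality is
    strict: a phenotype with exactly ``min_cases`` cases is dropped.
    """
    counts = case_counts(phenotypes, index)
    retained = [name for name, c in counts.items() if c > min_cases]
    return retained, counts


def wide_case_matrix(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """person_id x phenotype boolean case matrix."""
    return (
        phenotypes.pivot(index="person_id", columns="phenotype", values="is_case")
        .fillna(False)
        .astype(bool)
    )


# ---------------------------------------------------------------------------
# default illustrative definitions (matched to the synthetic generator's
# default coding configuration; real-study supplementary code lists are
# not public)

DEFAULT_AD_NAMES = (
    "ankylosing_spondylitis",
    "celiac_disease",
    "crohns_disease",
    "graves_disease",
    "hashimotos_disease",
    "multiple_sclerosis",
    "psoriasis",
    "rheumatoid_arthritis",
    "sarcoidosis",
    "sjogrens_syndrome",
    "systemic_lupus_erythematosus",
    "type1_diabetes",
    "ulcerative_colitis",
)


def default_case_definitions() -> list[CaseDefinition]:
    """ADHD plus the 13 illustrative autoimmune-disease definitions."""
    from .synthetic_register import DEFAULT_CODING  # local: avoids import cycle

    defs = [
        CaseDefinition(
            "ADHD",
            diagnosis_rules=(("ICD10", "F90"), ("ICD9", "314")),
            drug_rules=("N06BA",),
        )
    ]
    for ch in DEFAULT_CODING.traits["anyAD"].channels:
        defs.append(
            CaseDefinition(
                ch.name,
                diagnosis_rules=tuple((s, p) for s, p in ch.codes.items()),
                drug_rules=tuple(ch.atc),
            )
        )
    return defs
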