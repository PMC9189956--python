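"""Shared fixtures: small synthetic register bundles with known truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from famcoagg.phenotyping import DEFAULT_AD_NAMES, build_any_ad, build_phenotype_table, default_case_definitions, wide_case_matrix
from famcoagg.synthetic_register import (
    CodingConfig,
    DiseaseChannel,
    SimulationParams,
    TraitCoding,
    generate_register,
)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SimulationParams(n_families=250, seed=42)


@pytest.fixture(scope="session")
def small_register(small_params):
    """(bundle, truth, pedigree) for ~250 families (~4,000 persons)."""
    return generate_register(small_params)


@pytest.fixture(scope="session")
def small_bundle(small_register):
    return small_register[0]


@pytest.fixture(scope="session")
def small_truth(small_register):
    return small_register[1]


@pytest.fixture(scope="session")
def small_pedigree(small_register):
    return small_register[2]


@pytest.fixture(scope="session")
def small_case_matrix(small_bundle):
    phen = build_phenotype_table(small_bundle, default_case_definitions())
    phen = pd.concat([phen, build_any_ad(phen, DEFAULT_AD_NAMES)], ignore_index=True)
    return wide_case_matrix(phen)


@pytest.fixture(scope="session")
def complete_coding() -> CodingConfig:
    """Coding config with a code in every era and no drug-only cases, so
    every case with an in-era diagnosis year is observable."""
    return CodingConfig(
        traits={
            "ADHD": TraitCoding(
                channels=(
                    DiseaseChannel(
                        "ADHD", 1.0,
                        {"ICD10": "F90", "ICD9": "314", "ICD8": "308", "ICD7": "301"},
                        ("N06BA",),
                    ),
                ),
                drug_fraction=0.3,
                drug_only_fraction=0.0,
            ),
            "anyAD": TraitCoding(
                channels=(
                    DiseaseChannel(
                        "psoriasis", 2.0,
                        {"ICD10": "L40", "ICD9": "696", "ICD8": "696", "ICD7": "706"},
                    ),
                    DiseaseChannel(
                        "type1_diabetes", 1.0,
                        {"ICD10": "E10", "ICD9": "250", "ICD8": "250", "ICD7": "260"},
                        ("A10A",),
                    ),
                ),
                drug_fraction=0.2,
                drug_only_fraction=0.0,
            ),
        }
    )


def make_person_frame(rows):
    df = pd.DataFrame(rows, columns=["person_id", "sex", "birth_year", "death_year", "emigration_year"])
    df["death_year"] = df["death_year"].astype("Int64")
    df["emigration_year"] = df["emigration_year"].astype("Int64")
    return df


def make_bundle(persons, links=(), diagnoses=(), dispensations=()):
    from famcoagg.register_model import RegisterBundle

    links_df = pd.DataFrame(list(links), columns=["child_id", "mother_id", "father_id"]).astype("object")
    diag_df = pd.DataFrame(list(diagnoses), columns=["person_id", "code", "code_system", "event_year"])
    if diag_df.empty:
        diag_df = diag_df.astype({"event_year": "int64"}) if "event_year" in diag_df else diag_df
    disp_df = pd.DataFrame(list(dispensations), columns=["person_id", "atc_code", "event_year"])
    for df in (diag_df, disp_df):
        if df.empty:
            df["event_year"] = df.get("event_year", pd.Series(dtype="int64")).astype("int64")
    return RegisterBundle(
        persons=make_person_frame(persons),
        links=links_df,
        diagnoses=diag_df,
        dispensations=disp_df,
        metadata={},
    )
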