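"""Pipeline configuration: one structured YAML file, schema-checked.

Per-stage random seeds are derived from the single master seed through a
documented counter scheme (``numpy.random.SeedSequence(master, spawn_key=
(stage_index,))``), so every stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .cohort_builder import RELATIONS, ConfigurationError

#: Stage order for seed derivation; append only.
STAGES = ("simulate", "quantgen_pairs", "bootstrap", "quantgen_fit")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage 31-bit seed derived from the master seed."""
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage '{stage}' for seed derivation")
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SimulateConfig:
    n_families: int = 20000
    sibship_size_distribution: dict = field(default_factory=lambda: {1: 1 / 3, 2: 1 / 3, 3: 1 / 3})
    birth_year_range: tuple[int, int] = (1960, 2010)
    censor_before_10_prob: float = 0.039


@dataclass
class CohortConfig:
    birth_window: tuple[int, int] = (1960, 2010)
    late_window: tuple[int, int] = (1980, 2010)
    min_survival_age: int = 10


@dataclass
class PhenotypeConfig:
    min_cases: int = 50  # scaled-down analogue of the study's 2000-case rule
    composite_name: str = "anyAD"


@dataclass
class AnalysisConfig:
    exposure: str = "ADHD"
    outcomes: tuple[str, ...] = ("anyAD",)
    relations: tuple[str, ...] = RELATIONS
    n_knots: int = 5
    n_boot: int = 200
    standardize: bool = True
    ror_contrasts: tuple[str, ...] = (
        "mother_vs_father",
        "aunt_vs_uncle",
        "maternal_side_vs_paternal_side",
    )


@dataclass
class QuantgenConfig:
    enabled: bool = True
    candidates: tuple[tuple[str, str], ...] = (("AE", "ACE"), ("ACE", "ACE"), ("AE", "AE"))
    n_starts: int = 2
    qmc_points: int = 2048
    ci_method: str = "delta"


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "results"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    cohorts: CohortConfig = field(default_factory=CohortConfig)
    phenotypes: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    quantgen: QuantgenConfig = field(default_factory=QuantgenConfig)

    def validate(self) -> "PipelineConfig":
        for rel in self.analysis.relations:
            if rel not in RELATIONS:
                raise ConfigurationError(f"unknown relation in roster: '{rel}'")
        for c in self.analysis.ror_contrasts:
            if c not in ("mother_vs_father", "aunt_vs_uncle", "maternal_side_vs_paternal_side"):
                raise ConfigurationError(f"unknown ROR contrast: '{c}'")
        if self.simulate.n_families < 0:
            raise ConfigurationError("n_families must be >= 0")
        if self.quantgen.ci_method not in ("profile", "delta", "none"):
            raise ConfigurationError(f"unknown ci_method: {self.quantgen.ci_method}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc, data):
            if data is None:
                return dc()
            fields = {f: t for f, t in dc.__dataclass_fields__.items()}
            unknown = set(data) - set(fields)
            if unknown:
                raise ConfigurationError(f"unknown config key(s) for {dc.__name__}: {sorted(unknown)}")
            kwargs = {}
            for k, v in data.items():
                if isinstance(v, list):
                    v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
                if k == "sibship_size_distribution" and isinstance(v, dict):
                    v = {int(s): float(p) for s, p in v.items()}
                kwargs[k] = v
            return dc(**kwargs)

        cfg = cls(
            seed=int(raw.get("seed", 1)),
            outdir=str(raw.get("outdir", "results")),
            simulate=build(SimulateConfig, raw.get("simulate")),
            cohorts=build(CohortConfig, raw.get("cohorts")),
            phenotypes=build(PhenotypeConfig, raw.get("phenotypes")),
            analysis=build(AnalysisConfig, raw.get("analysis")),
            quantgen=build(QuantgenConfig, raw.get("quantgen")),
        )
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
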