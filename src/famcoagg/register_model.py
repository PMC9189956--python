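"""Register-shaped data model: tables, IO and validation.

The package operates on four logical tables mirroring the structure of
Nordic-style population registers:

``persons``
    one row per individual: ``person_id``, ``sex`` (``female``/``male``),
    ``birth_year``, optional ``death_year`` and ``emigration_year``.
``links``
    one row per child: ``child_id``, optional ``mother_id``/``father_id``
    (multi-generation register analogue).
``diagnoses``
    diagnosis events: ``person_id``, ``code``, ``code_system``
    (ICD7/ICD8/ICD9/ICD10), ``event_year`` (patient register analogue).
``dispensations``
    dispensed-drug events: ``person_id``, ``atc_code``, ``event_year``
    (prescribed-drug register analogue; the register era starts 2005).

All dates are stored at year granularity: every rule in scope
(survival-to-age-10 exclusion, birth-window restrictions, coding eras)
resolves at the year level.  Tables are persisted as tab-separated UTF-8
with a single header row; absent optional values are empty strings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

SEX_VALUES = ("female", "male")
CODE_SYSTEMS = ("ICD7", "ICD8", "ICD9", "ICD10")

#: First year of the prescribed-drug register (established July 2005; the
#: year is the finest granularity this model keeps).
DRUG_REGISTER_START = 2005
#: Last year with register coverage in the emulated study (drug data ran
#: through December 2013).
REGISTER_END = 2013

PERSON_COLUMNS = ("person_id", "sex", "birth_year", "death_year", "emigration_year")
LINK_COLUMNS = ("child_id", "mother_id", "father_id")
DIAGNOSIS_COLUMNS = ("person_id", "code", "code_system", "event_year")
DISPENSATION_COLUMNS = ("person_id", "atc_code", "event_year")

TABLE_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "persons": PERSON_COLUMNS,
    "links": LINK_COLUMNS,
    "diagnoses": DIAGNOSIS_COLUMNS,
    "dispensations": DISPENSATION_COLUMNS,
}

TABLE_KEYS: Mapping[str, tuple[str, ...]] = {
    "persons": ("person_id",),
    "links": ("child_id",),
    "diagnoses": ("person_id", "code_system", "code", "event_year"),
    "dispensations": ("person_id", "atc_code", "event_year"),
}

_OPTIONAL_INT_COLUMNS = {"death_year", "emigration_year"}
_OPTIONAL_STR_COLUMNS = {"mother_id", "father_id"}


class RegisterFormatError(ValueError):
    """A register file violates the expected schema."""


@dataclass(frozen=True)
class EraInterval:
    start: int
    end: int | None  # inclusive; None = open-ended
    code_system: str

    def contains(self, year: int) -> bool:
        return year >= self.start and (self.end is None or year <= self.end)


@dataclass(frozen=True)
class EraMap:
    """Mapping from calendar year to the diagnosis coding system in force."""

    intervals: tuple[EraInterval, ...]

    def system_for_year(self, year: int) -> str | None:
        for iv in self.intervals:
            if iv.contains(year):
                return iv.code_system
        return None

    @property
    def start(self) -> int:
        return min(iv.start for iv in self.intervals)


#: Swedish patient-register coding eras.
DEFAULT_ERA_MAP = EraMap(
    (
        EraInterval(1964, 1967, "ICD7"),
        EraInterval(1968, 1986, "ICD8"),
        EraInterval(1987, 1996, "ICD9"),
        EraInterval(1997, None, "ICD10"),
    )
)


@dataclass
class RegisterBundle:
    persons: pd.DataFrame
    links: pd.DataFrame
    diagnoses: pd.DataFrame
    dispensations: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def copy(self) -> "RegisterBundle":
        return RegisterBundle(
            persons=self.persons.copy(),
            links=self.links.copy(),
            diagnoses=self.diagnoses.copy(),
            dispensations=self.dispensations.copy(),
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class Finding:
    """One validation finding: a kind, the offending table/keys, a message."""

    kind: str
    table: str
    key: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def kinds(self) -> set[str]:
        return {f.kind for f in self.findings}

    def by_kind(self, kind: str) -> list[Finding]:
        return [f for f in self.findings if f.kind == kind]

    def __len__(self) -> int:
        return len(self.findings)

    def summary(self) -> str:
        if self.ok:
            return "valid: no findings"
        counts = pd.Series([f.kind for f in self.findings]).value_counts()
        return "; ".join(f"{k}: {v}" for k, v in counts.items())


def empty_bundle(metadata: dict | None = None) -> RegisterBundle:
    tables = {
        name: pd.DataFrame({c: pd.Series(dtype=_dtype_for(c)) for c in cols})
        for name, cols in TABLE_COLUMNS.items()
    }
    return RegisterBundle(metadata=dict(metadata or {}), **tables)


def _dtype_for(column: str) -> str:
    if column in ("birth_year", "event_year"):
        return "int64"
    if column in _OPTIONAL_INT_COLUMNS:
        return "Int64"
    return "object"


def _normalise_table(name: str, df: pd.DataFrame, path: str | None = None) -> pd.DataFrame:
    cols = TABLE_COLUMNS[name]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        where = f" in {path}" if path else ""
        raise RegisterFormatError(f"{name} table{where} lacks column(s) {missing}")
    df = df.loc[:, list(cols)].copy()
    for c in cols:
        if c in ("birth_year", "event_year"):
            coerced = pd.to_numeric(df[c], errors="coerce")
            if coerced.isna().any() and len(df):
                row = int(coerced.index[coerced.isna()][0])
                where = f"{path or name}, line {row + 2}, column {c}"
                raise RegisterFormatError(f"malformed integer value at {where}")
            df[c] = coerced.astype("int64")
        elif c in _OPTIONAL_INT_COLUMNS:
            # unparseable optional fields become absent values
            df[c] = pd.to_numeric(df[c], errors="coerce").astype("Int64")
        else:
            df[c] = df[c].astype("object")
            df.loc[df[c].isin(["", None]) | df[c].isna(), c] = None
    return df


def load_registers(
    paths: Mapping[str, str | Path],
    *,
    metadata_path: str | Path | None = None,
    validate: bool = True,
) -> RegisterBundle:
    """Read the four register tables from tab-separated files.

    ``paths`` maps table names (``persons``, ``links``, ``diagnoses``,
    ``dispensations``) to file paths.  Raises :class:`FileNotFoundError` for
    missing files, :class:`RegisterFormatError` for malformed content, and
    (when ``validate``) :class:`RegisterValidationError` if the loaded bundle
    violates register invariants.
    """
    tables = {}
    for name in TABLE_COLUMNS:
        if name not in paths:
            raise RegisterFormatError(f"no path given for table '{name}'")
        p = Path(paths[name])
        if not p.exists():
            raise FileNotFoundError(f"register table file not found: {p}")
        raw = pd.read_csv(p, sep="\t", dtype="object", keep_default_na=False)
        raw = raw.replace({"": None})
        tables[name] = _normalise_table(name, raw, str(p))
    metadata: dict = {}
    if metadata_path is not None and Path(metadata_path).exists():
        metadata = json.loads(Path(metadata_path).read_text())
    bundle = RegisterBundle(metadata=metadata, **tables)
    if validate:
        report = validate_registers(bundle)
        if not report.ok:
            raise RegisterValidationError(report)
    return bundle


class RegisterValidationError(ValueError):
    def __init__(self, report: ValidationReport):
        self.report = report
        first = report.findings[:5]
        msg = f"register bundle invalid ({len(report)} finding(s)): " + "; ".join(
            f"[{f.kind}] {f.message}" for f in first
        )
        super().__init__(msg)


def write_registers(bundle: RegisterBundle, directory: str | Path) -> dict[str, str]:
    """Write the bundle as one TSV per table plus ``metadata.json``.

    Deterministic: fixed column order, rows sorted by the table's primary
    key.  Returns a manifest mapping table name to file path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, cols in TABLE_COLUMNS.items():
        df = bundle.table(name).loc[:, list(cols)]
        df = df.sort_values(list(TABLE_KEYS[name]), kind="mergesort").reset_index(drop=True)
        path = directory / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, na_rep="")
        manifest[name] = str(path)
    meta_path = directory / "metadata.json"
    meta_path.write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True) + "\n")
    manifest["metadata"] = str(meta_path)
    return manifest


def bundle_paths(directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    return {name: directory / f"{name}.tsv" for name in TABLE_COLUMNS}


def load_bundle_dir(directory: str | Path, validate: bool = True) -> RegisterBundle:
    directory = Path(directory)
    return load_registers(
        bundle_paths(directory), metadata_path=directory / "metadata.json", validate=validate
    )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# validation


def _find_pedigree_cycles(links: pd.DataFrame) -> list[str]:
    """Return ids of children involved in an ancestry cycle (iterative DFS)."""
    parents: dict[str, list[str]] = {}
    for child, mother, father in links[["child_id", "mother_id", "father_id"]].itertuples(
        index=False
    ):
        parents[child] = [p for p in (mother, father) if p is not None]
    WHITE, GREY, BLACK = 0, 1, 2
    colour: dict[str, int] = {}
    in_cycle: list[str] = []
    for start in parents:
        if colour.get(start, WHITE) != WHITE:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        colour[start] = GREY
        while stack:
            node, i = stack[-1]
            kids = parents.get(node, [])
            if i < len(kids):
                stack[-1] = (node, i + 1)
                nxt = kids[i]
                c = colour.get(nxt, WHITE)
                if c == GREY:
                    in_cycle.append(nxt)
                elif c == WHITE:
                    colour[nxt] = GREY
                    stack.append((nxt, 0))
            else:
                colour[node] = BLACK
                stack.pop()
    return in_cycle


def validate_registers(
    bundle: RegisterBundle,
    *,
    era_map: EraMap = DEFAULT_ERA_MAP,
    drug_register_start: int = DRUG_REGISTER_START,
) -> ValidationReport:
    """Check every register invariant; violations are findings, not errors."""
    findings: list[Finding] = []

    def add(kind: str, table: str, keys: Iterable, message: str) -> None:
        for k in keys:
            findings.append(Finding(kind, table, str(k), message.format(key=k)))

    persons = bundle.persons
    links = bundle.links

    dup = persons.loc[persons["person_id"].duplicated(), "person_id"].unique()
    add("duplicate_person_id", "persons", dup, "person_id '{key}' occurs more than once")
    dup = links.loc[links["child_id"].duplicated(), "child_id"].unique()
    add("duplicate_child_id", "links", dup, "child_id '{key}' occurs more than once")

    for col in ("death_year", "emigration_year"):
        bad = persons.loc[
            persons[col].notna() & (persons[col] < persons["birth_year"]), "person_id"
        ]
        add("event_before_birth", "persons", bad, f"{col} precedes birth_year for '{{key}}'")

    bad_sex = persons.loc[~persons["sex"].isin(SEX_VALUES), "person_id"]
    add("invalid_sex", "persons", bad_sex, "sex value invalid for '{key}'")

    known = set(persons["person_id"])
    for col in ("child_id", "mother_id", "father_id"):
        ids = links[col].dropna()
        missing = ids[~ids.isin(known)].unique()
        add(
            "unresolved_reference",
            "links",
            missing,
            f"{col} '{{key}}' not present in persons table",
        )
    for name in ("diagnoses", "dispensations"):
        ids = bundle.table(name)["person_id"]
        missing = ids[~ids.isin(known)].unique()
        add(
            "unresolved_reference",
            name,
            missing,
            "person_id '{key}' not present in persons table",
        )

    self_parent = links.loc[
        (links["child_id"] == links["mother_id"]) | (links["child_id"] == links["father_id"]),
        "child_id",
    ]
    add("pedigree_cycle", "links", self_parent, "'{key}' is its own parent")
    cyc = _find_pedigree_cycles(links)
    add("pedigree_cycle", "links", sorted(set(cyc)), "'{key}' participates in an ancestry cycle")

    diags = bundle.diagnoses
    empty_code = diags.loc[diags["code"].isna() | (diags["code"] == ""), "person_id"]
    add("empty_code", "diagnoses", empty_code, "empty diagnosis code for '{key}'")
    bad_system = diags.loc[~diags["code_system"].isin(CODE_SYSTEMS), "person_id"]
    add("invalid_code_system", "diagnoses", bad_system, "unknown code_system for '{key}'")

    ok_system = diags["code_system"].isin(CODE_SYSTEMS)
    if ok_system.any():
        expected = diags.loc[ok_system, "event_year"].map(era_map.system_for_year)
        mism = diags.loc[ok_system].loc[
            expected.isna() | (expected != diags.loc[ok_system, "code_system"])
        ]
        add(
            "era_mismatch",
            "diagnoses",
            (f"{r.person_id}/{r.event_year}" for r in mism.itertuples()),
            "code_system inconsistent with event_year for '{key}'",
        )

    disp = bundle.dispensations
    empty_atc = disp.loc[disp["atc_code"].isna() | (disp["atc_code"] == ""), "person_id"]
    add("empty_code", "dispensations", empty_atc, "empty ATC code for '{key}'")
    pre_era = disp.loc[disp["event_year"] < drug_register_start, "person_id"]
    add(
        "pre_register_era_event",
        "dispensations",
        pre_era,
        "dispensation before the drug-register era for '{key}'",
    )

    # events relative to the person's own life span (data errors, surfaced)
    life = persons.set_index("person_id")[["birth_year", "death_year"]]
    for name in ("diagnoses", "dispensations"):
        ev = bundle.table(name)
        ev = ev[ev["person_id"].isin(known)]
        merged = ev.join(life, on="person_id")
        before = merged.loc[merged["event_year"] < merged["birth_year"], "person_id"]
        add("event_before_birth", name, before, "event precedes birth for '{key}'")
        after = merged.loc[
            merged["death_year"].notna() & (merged["event_year"] > merged["death_year"]),
            "person_id",
        ]
        add("event_after_death", name, after, "event after death for '{key}'")

    return ValidationReport(findings)
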