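"""End-to-end pipeline: simulate -> cohorts -> phenotypes -> association ->
standardization -> ROR contrasts -> quantitative genetics, with tabular
outputs mirroring a register study's result structures (pair-count table,
case-count table, OR forest table, ROR table, variance-component report).

Every stage logs input/output row counts (the cohort-flowchart as a log
artifact) and derives its randomness from the master seed via
:func:`famcoagg.config.stage_seed`, so identical config + seed yields
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .association import run_pair_association, run_within_individual
from .cohort_builder import (
    PARENT_GENERATION_RELATIONS,
    build_all_relative_pairs,
    build_index_cohort,
    family_clusters,
    select_quantgen_pairs,
)
from .config import PipelineConfig, stage_seed
from .liability import SIBLING, COUSIN
from .marginal_effects import merge_cohorts, ror_contrast, side_split, standardized_risks_for_pairs
from .phenotyping import (
    DEFAULT_AD_NAMES,
    build_any_ad,
    build_phenotype_table,
    case_counts,
    default_case_definitions,
    apply_min_case_filter,
    wide_case_matrix,
)
from .quantgen import PatternCounts, counts_from_outcomes, select_model
from .register_model import RegisterBundle, load_bundle_dir, validate_registers, write_registers
from .synthetic_register import SimulationParams, generate_register, write_truth

log = logging.getLogger("famcoagg")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def simulation_params(config: PipelineConfig) -> SimulationParams:
    sim = config.simulate
    return SimulationParams(
        n_families=sim.n_families,
        sibship_size_distribution=dict(sim.sibship_size_distribution),
        birth_year_range=tuple(sim.birth_year_range),
        censor_before_10_prob=sim.censor_before_10_prob,
        seed=stage_seed(config.seed, "simulate"),
    )


def cmd_simulate(config: PipelineConfig, outdir: str | Path) -> Path:
    """Generate a register bundle plus truth table on disk."""
    outdir = Path(outdir)
    params = simulation_params(config)
    bundle, truth, _ = generate_register(params)
    report = validate_registers(bundle)
    if not report.ok:
        raise StageError("simulate", f"generator output failed validation: {report.summary()}")
    bundle_dir = outdir / "bundle"
    write_registers(bundle, bundle_dir)
    write_truth(truth, bundle_dir / "truth_phenotypes.tsv")
    log.info(
        "simulate: %d families -> %d persons, %d diagnoses, %d dispensations",
        params.n_families, len(bundle.persons), len(bundle.diagnoses), len(bundle.dispensations),
    )
    return bundle_dir


def _load_bundle(outdir: Path) -> RegisterBundle:
    bundle_dir = outdir / "bundle"
    if not bundle_dir.exists():
        raise StageError("cohorts", f"no bundle at {bundle_dir}; run simulate first")
    return load_bundle_dir(bundle_dir)


def cmd_run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns a manifest of written files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    bundle_dir = outdir / "bundle"
    if not bundle_dir.exists():
        cmd_simulate(config, outdir)
    bundle = _load_bundle(outdir)

    # --- cohorts ----------------------------------------------------------
    cc = config.cohorts
    index = build_index_cohort(bundle, tuple(cc.birth_window), cc.min_survival_age)
    if len(index) == 0:
        raise StageError("cohorts", "index cohort is empty")
    pairs = build_all_relative_pairs(
        bundle, index, tuple(cc.late_window), config.analysis.relations
    )
    (outdir / "exclusions.json").write_text(json.dumps(index.exclusions, indent=2))
    manifest["exclusions"] = "exclusions.json"
    table1 = pd.DataFrame(
        [
            {
                "cohort": rel,
                "n_unique_index": p.pairs["index_id"].nunique(),
                "n_unique_relatives": p.pairs["relative_id"].nunique(),
                "n_pairs": len(p),
                "restriction": f"{p.restriction[0]}-{p.restriction[1]}",
            }
            for rel, p in pairs.items()
        ]
    )
    _write(table1, outdir / "table1_pairs.tsv", manifest, "table1")
    for rel, p in pairs.items():
        _write(p.pairs, outdir / f"pairs_{rel}.tsv", manifest, f"pairs_{rel}")
        log.info("cohorts: %s -> %d pairs (dropped %s)", rel, len(p), p.dropped)

    # --- phenotypes -------------------------------------------------------
    definitions = default_case_definitions()
    phen = build_phenotype_table(bundle, definitions)
    composite = build_any_ad(phen, DEFAULT_AD_NAMES, config.phenotypes.composite_name)
    phen = pd.concat([phen, composite], ignore_index=True)
    retained, counts = apply_min_case_filter(phen, index, config.phenotypes.min_cases)
    _write(phen, outdir / "phenotypes.tsv", manifest, "phenotypes")
    case_matrix = wide_case_matrix(phen)

    sex = bundle.persons.set_index("person_id")["sex"]
    idx_ids = set(index.ids)
    exposure = config.analysis.exposure
    t2rows = []
    for name in sorted(set(phen["phenotype"])):
        carriers = set(phen.loc[(phen["phenotype"] == name) & phen["is_case"], "person_id"]) & idx_ids
        both = carriers & set(
            phen.loc[(phen["phenotype"] == exposure) & phen["is_case"], "person_id"]
        )
        t2rows.append(
            {
                "phenotype": name,
                "n_index_cases": len(carriers),
                "prevalence_per_10000": round(1e4 * len(carriers) / max(len(index), 1), 1),
                "female_pct": round(
                    100 * float((sex.loc[sorted(carriers)] == "female").mean()) if carriers else float("nan"), 1
                ),
                "n_with_exposure": len(both),
                "retained": name in retained or name == exposure,
            }
        )
    _write(pd.DataFrame(t2rows), outdir / "table2_cases.tsv", manifest, "table2")

    outcomes = [o for o in config.analysis.outcomes if o in retained or o in case_matrix.columns]
    if not outcomes:
        raise StageError("phenotypes", "no analysis outcome survives the minimum-case filter")

    # --- associations -----------------------------------------------------
    clusters = family_clusters(bundle)
    or_rows = []
    for outcome in outcomes:
        res = run_within_individual(
            index.members, case_matrix, exposure, outcome,
            clusters=index.members["person_id"].map(clusters),
            n_knots=config.analysis.n_knots,
        )
        or_rows.append({"analysis": "within_individual", "relation": "self", "outcome": outcome, **res.to_dict()})
        for rel, cohort in pairs.items():
            res = run_pair_association(
                cohort, case_matrix, bundle.persons, exposure, outcome,
                n_knots=config.analysis.n_knots,
            )
            or_rows.append({"analysis": "co_aggregation", "relation": rel, "outcome": outcome, **res.to_dict()})
    or_table = pd.DataFrame(or_rows)
    _write(or_table, outdir / "or_results.tsv", manifest, "or_results")

    # --- standardized risks ----------------------------------------------
    if config.analysis.standardize:
        sr_rows = []
        boot_seed = stage_seed(config.seed, "bootstrap")
        for outcome in outcomes:
            for rel, cohort in pairs.items():
                sr = standardized_risks_for_pairs(
                    cohort, case_matrix, bundle.persons, exposure, outcome,
                    n_knots=config.analysis.n_knots,
                    n_boot=config.analysis.n_boot,
                    seed=boot_seed,
                )
                sr_rows.append({"analysis": rel, "outcome": outcome, **sr.to_dict()})
        _write(pd.DataFrame(sr_rows), outdir / "standardized_risks.tsv", manifest, "standardized_risks")

    # --- ROR contrasts ----------------------------------------------------
    ror_rows = []
    for outcome in outcomes:
        for contrast in config.analysis.ror_contrasts:
            try:
                a, b = _contrast_cohorts(contrast, pairs)
            except KeyError as exc:
                log.warning("ror: skipping %s (missing cohort %s)", contrast, exc)
                continue
            res = ror_contrast(
                a, b, case_matrix, bundle.persons, exposure, outcome,
                contrast=contrast, n_knots=config.analysis.n_knots,
            )
            ror_rows.append({"outcome": outcome, **res.to_dict()})
    if ror_rows:
        _write(pd.DataFrame(ror_rows), outdir / "ror_results.tsv", manifest, "ror_results")

    # --- quantitative genetic modelling ----------------------------------
    if config.quantgen.enabled:
        qg, pattern_table = _run_quantgen(config, bundle, case_matrix, exposure, outcomes[0])
        (outdir / "quantgen_fit.json").write_text(json.dumps(qg, indent=2))
        manifest["quantgen"] = "quantgen_fit.json"
        _write(pattern_table, outdir / "pattern_counts.tsv", manifest, "pattern_counts")

    (outdir / "config_echo.json").write_text(json.dumps(config.to_dict(), indent=2, default=str))
    manifest["config"] = "config_echo.json"
    return manifest


def _contrast_cohorts(contrast: str, pairs: dict):
    if contrast == "mother_vs_father":
        return pairs["mother"], pairs["father"]
    if contrast == "aunt_vs_uncle":
        return pairs["aunt"], pairs["uncle"]
    if contrast == "maternal_side_vs_paternal_side":
        maternal = merge_cohorts(
            "maternal_aunt_uncle", side_split(pairs["aunt"], "maternal"), side_split(pairs["uncle"], "maternal")
        )
        paternal = merge_cohorts(
            "paternal_aunt_uncle", side_split(pairs["aunt"], "paternal"), side_split(pairs["uncle"], "paternal")
        )
        return maternal, paternal
    raise KeyError(contrast)


def _run_quantgen(config, bundle, case_matrix, exposure, outcome):
    seed = stage_seed(config.seed, "quantgen_pairs")
    counts = {}
    for relation, spec in (("full_sibling", SIBLING), ("cousin", COUSIN)):
        sel = select_quantgen_pairs(
            bundle, relation, seed,
            birth_window=tuple(config.cohorts.birth_window),
            min_survival_age=config.cohorts.min_survival_age,
        )
        if len(sel) < 50:
            raise StageError("quantgen", f"too few {relation} pairs ({len(sel)}) for model fitting")
        outc = np.zeros((len(sel), 4), dtype=bool)
        for j, (col, pheno) in enumerate(
            (("member1_id", exposure), ("member1_id", outcome), ("member2_id", exposure), ("member2_id", outcome))
        ):
            outc[:, j] = sel[col].map(case_matrix[pheno]).fillna(False).to_numpy(dtype=bool)
        counts[relation] = counts_from_outcomes(outc)
    data = PatternCounts(counts=counts, specs={"full_sibling": SIBLING, "cousin": COUSIN})
    results = select_model(
        data,
        candidates=tuple(config.quantgen.candidates),
        n_starts=config.quantgen.n_starts,
        qmc_points=config.quantgen.qmc_points,
        ci_method=config.quantgen.ci_method,
        random_state=stage_seed(config.seed, "quantgen_fit"),
    )
    from .quantgen import PATTERNS

    pattern_table = pd.DataFrame(
        [
            {
                "relative_class": label,
                "m1_t1": PATTERNS[i, 0], "m1_t2": PATTERNS[i, 1],
                "m2_t1": PATTERNS[i, 2], "m2_t2": PATTERNS[i, 3],
                "count": int(c[i]),
            }
            for label, c in counts.items()
            for i in range(16)
        ]
    )
    best = results[0]
    vc = best.estimates
    return {
        "selected_model": best.model_label,
        "aic_table": [
            {"model": r.model_label, "aic": r.aic, "loglik": r.log_likelihood, "n_params": r.n_params}
            for r in results
        ],
        "estimates": {
            "a2": list(vc.a2), "c2": list(vc.c2), "e2": list(vc.e2),
            "rA": vc.rA, "rC": vc.rC, "rE": vc.rE,
            "thresholds": list(vc.thresholds),
        },
        "ci": {k: list(v) for k, v in best.ci.items()},
        "covariance_shares": best.covariance_shares,
        "n_pairs": {k: int(v.sum()) for k, v in counts.items()},
        "converged": best.converged,
    }, pattern_table


def _write(df: pd.DataFrame, path: Path, manifest: dict, key: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    manifest[key] = path.name


# ---------------------------------------------------------------------------
# report rendering (no recomputation: every number comes from a results file)

EXPECTED_TABLES = ("table1_pairs.tsv", "or_results.tsv")


def cmd_report(results_dir: str | Path) -> str:
    results_dir = Path(results_dir)
    missing = [f for f in EXPECTED_TABLES if not (results_dir / f).exists()]
    if missing:
        raise StageError("report", f"missing result tables in {results_dir}: {missing}")
    lines = []

    t1 = pd.read_csv(results_dir / "table1_pairs.tsv", sep="\t")
    lines.append("Pair cohorts")
    lines.append(t1.to_string(index=False))

    ors = pd.read_csv(results_dir / "or_results.tsv", sep="\t")
    bad = ors[ors["ci_low"] > ors["ci_high"]]
    if not bad.empty:
        raise StageError("report", f"corrupted OR rows (ci_low > ci_high): {bad['relation'].tolist()}")
    lines.append("\nOdds ratios (95% CI)")
    for _, r in ors.iterrows():
        bar = _forest_bar(r["or"], r["ci_low"], r["ci_high"])
        lines.append(
            f"  {r['relation']:>18} {r['outcome']:<10} OR {r['or']:6.3f} "
            f"({r['ci_low']:.3f}-{r['ci_high']:.3f})  {bar}"
        )

    ror_path = results_dir / "ror_results.tsv"
    if ror_path.exists():
        rors = pd.read_csv(ror_path, sep="\t")
        lines.append("\nRatio-of-odds-ratio contrasts")
        for _, r in rors.iterrows():
            lines.append(
                f"  {r['contrast']:>32} ROR {r['ror']:6.3f} ({r['ci_low']:.3f}-{r['ci_high']:.3f}) p={r['p']:.3g}"
            )

    qg_path = results_dir / "quantgen_fit.json"
    if qg_path.exists():
        qg = json.loads(qg_path.read_text())
        e = qg["estimates"]
        lines.append("\nVariance components (selected model: %s)" % qg["selected_model"])
        lines.append(
            f"  trait1 a2={e['a2'][0]:.3f} c2={e['c2'][0]:.3f} e2={e['e2'][0]:.3f}"
        )
        lines.append(
            f"  trait2 a2={e['a2'][1]:.3f} c2={e['c2'][1]:.3f} e2={e['e2'][1]:.3f}"
        )
        lines.append(
            f"  rA={_fmt(e['rA'])} rC={_fmt(e['rC'])} rE={_fmt(e['rE'])}  "
            f"covariance shares: {qg['covariance_shares']}"
        )
    return "\n".join(lines)


def _fmt(v) -> str:
    return "NA" if v is None else f"{v:.3f}"


def _forest_bar(mid, lo, hi, lo_axis=0.5, hi_axis=2.0, width=40) -> str:
    def pos(v):
        v = min(max(v, lo_axis), hi_axis)
        return int(round((np.log(v) - np.log(lo_axis)) / (np.log(hi_axis) - np.log(lo_axis)) * (width - 1)))

    chars = [" "] * width
    for i in range(pos(lo), pos(hi) + 1):
        chars[i] = "-"
    chars[pos(1.0)] = "|"
    chars[pos(mid)] = "*"
    return "".join(chars)
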