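"""Regression-standardized absolute risks and ratio-of-odds-ratio contrasts.

Standardization averages a fitted logistic model's predicted outcome
probability over the whole analysis population with the exposure forced
to each level, yielding marginal absolute risks (AR), their difference
(RD), and cluster-bootstrap percentile intervals.

The ratio-of-odds-ratio (ROR) contrasts probe maternal effects: two
relative-pair cohorts (e.g. mothers vs fathers) are merged and the
exposure x group interaction is estimated with cluster-robust Wald
inference; the exponentiated interaction is the ratio of the two groups'
exposure odds ratios.  Only the group main effect and the single
exposure x group interaction enter beyond the shared covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import (
    ClusterLogisticOR,
    InteractionOR,
    ORResult,
    _irls_logit,
    birth_year_spline_columns,
    pair_analysis_frame,
    run_pair_association,
)
from .cohort_builder import ConfigurationError, RelativePairCohort

CONTRAST_LABELS = ("mother_vs_father", "aunt_vs_uncle", "maternal_side_vs_paternal_side")


@dataclass
class StandardizedRisk:
    ar_exposed: float
    ar_unexposed: float
    rd: float
    ar_exposed_ci: tuple[float, float]
    ar_unexposed_ci: tuple[float, float]
    rd_ci: tuple[float, float]
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "ar_exposed": self.ar_exposed,
            "ar_exposed_lo": self.ar_exposed_ci[0],
            "ar_exposed_hi": self.ar_exposed_ci[1],
            "ar_unexposed": self.ar_unexposed,
            "ar_unexposed_lo": self.ar_unexposed_ci[0],
            "ar_unexposed_hi": self.ar_unexposed_ci[1],
            "rd": self.rd,
            "rd_lo": self.rd_ci[0],
            "rd_hi": self.rd_ci[1],
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


@dataclass
class RORResult:
    contrast: str
    ror: float
    ci_low: float
    ci_high: float
    p_value: float
    component_ors: dict  # group label -> ORResult
    n_obs: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "contrast": self.contrast,
            "ror": self.ror,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
            "n_pairs": self.n_obs,
        }
        for label, orr in self.component_ors.items():
            d[f"or_{label}"] = orr.estimate
            d[f"or_{label}_lo"] = orr.ci_low
            d[f"or_{label}_hi"] = orr.ci_high
        return d


def _standardize(design: np.ndarray, params: np.ndarray, exposure_col: int, design_fn=None) -> tuple[float, float]:
    """Mean inverse-logit prediction with the exposure forced to 1/0.

    ``design_fn(level)`` rebuilds the whole design at a forced exposure
    level (needed when covariates involve the exposure, e.g. interaction
    columns); the default simply overwrites the exposure column.
    """
    out = []
    for level in (1.0, 0.0):
        if design_fn is not None:
            d = np.asarray(design_fn(level), dtype=float)
        else:
            d = design.copy()
            d[:, exposure_col] = level
        eta = d @ params
        out.append(float(np.mean(1.0 / (1.0 + np.exp(-eta)))))
    return out[0], out[1]


def standardized_risks(
    fitted: ClusterLogisticOR,
    n_boot: int = 500,
    seed: int = 0,
    *,
    exposure_col: int = 1,
    design_fn=None,
) -> StandardizedRisk:
    """Standardized absolute risks from a fitted logistic exposure model.

    The standardization population is every row of the analysis data
    ("total population" standard).  Percentile intervals come from
    ``n_boot`` nonparametric bootstrap resamples drawn at cluster level
    (row level when the model was fitted without clusters); the resampled
    models are refitted by plain ML (robust covariances are irrelevant to
    the point predictions the bootstrap averages).
    """
    if not hasattr(fitted, "_design"):
        raise ConfigurationError("standardized_risks requires a fitted ClusterLogisticOR")
    design, y = fitted._design, fitted._y
    params = fitted.params_.to_numpy()
    ar1, ar0 = _standardize(design, params, exposure_col, design_fn)

    rng = np.random.default_rng(seed)
    clusters = fitted._clusters
    if clusters is None:
        groups = np.arange(len(y))
    else:
        groups = pd.Categorical(clusters).codes
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    boundaries = np.searchsorted(sorted_groups, np.arange(sorted_groups.max() + 2))
    member_rows = [order[boundaries[g] : boundaries[g + 1]] for g in range(sorted_groups.max() + 1)]

    boot = np.empty((n_boot, 3))
    n_groups = len(member_rows)
    for b in range(n_boot):
        take = rng.integers(0, n_groups, n_groups)
        rows = np.concatenate([member_rows[g] for g in take])
        d, yy = design[rows], y[rows]
        try:
            beta = _irls_logit(d, yy)
            b1, b0 = _standardize(design, beta, exposure_col, design_fn)
        except Exception:  # degenerate resample (e.g. no cases)
            b1, b0 = np.nan, np.nan
        boot[b] = (b1, b0, b1 - b0)

    def pct(col):
        vals = boot[:, col]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            return (float("nan"), float("nan"))
        return tuple(np.percentile(vals, [2.5, 97.5]).tolist())

    return StandardizedRisk(
        ar_exposed=ar1,
        ar_unexposed=ar0,
        rd=ar1 - ar0,
        ar_exposed_ci=pct(0),
        ar_unexposed_ci=pct(1),
        rd_ci=pct(2),
        n_boot=n_boot,
        seed=seed,
    )


def standardized_risks_for_pairs(
    pairs: RelativePairCohort,
    case_matrix: pd.DataFrame,
    persons: pd.DataFrame,
    exposure_phenotype: str,
    outcome_phenotype: str,
    *,
    n_knots: int = 5,
    n_boot: int = 500,
    seed: int = 0,
) -> StandardizedRisk:
    """Convenience driver: fit the pair association model, then standardize."""
    df = pair_analysis_frame(pairs, case_matrix, persons, exposure_phenotype, outcome_phenotype)
    cov = pd.concat(
        [
            birth_year_spline_columns(df["index_birth_year"], "iby", n_knots),
            birth_year_spline_columns(df["relative_birth_year"], "rby", n_knots),
        ],
        axis=1,
    ).to_numpy()
    est = ClusterLogisticOR().fit(
        cov,
        df["outcome"].to_numpy(),
        exposure=df["exposure"].to_numpy(),
        clusters=df["family_cluster_id"].to_numpy(),
    )
    return standardized_risks(est, n_boot=n_boot, seed=seed)


def ror_contrast(
    pairs_a: RelativePairCohort,
    pairs_b: RelativePairCohort,
    case_matrix: pd.DataFrame,
    persons: pd.DataFrame,
    exposure_phenotype: str,
    outcome_phenotype: str,
    *,
    contrast: str = "",
    n_knots: int = 5,
    adjust_birth_year: bool = True,
) -> RORResult:
    """Ratio of the exposure ORs between two relative-pair groups.

    Group A is coded 1, so ``ror = OR_A / OR_B``.  The merged model holds
    exposure, group, exposure x group, and the birth-year splines of both
    members; inference is cluster-robust on the family cluster id, which
    the two cohorts share when built from one bundle.
    """
    frames = []
    for label, cohort in (("b", pairs_b), ("a", pairs_a)):
        if len(cohort) == 0:
            raise ValueError(f"empty group in ROR contrast: {label} ({cohort.relation})")
        df = pair_analysis_frame(cohort, case_matrix, persons, exposure_phenotype, outcome_phenotype)
        df["group"] = 1.0 if label == "a" else 0.0
        df["group_label"] = cohort.relation
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)

    cov = None
    if adjust_birth_year:
        cov = pd.concat(
            [
                birth_year_spline_columns(merged["index_birth_year"], "iby", n_knots),
                birth_year_spline_columns(merged["relative_birth_year"], "rby", n_knots),
            ],
            axis=1,
        ).to_numpy()

    est = InteractionOR().fit(
        cov,
        merged["outcome"].to_numpy(),
        exposure=merged["exposure"].to_numpy(),
        modifier=merged["group"].to_numpy(),
        clusters=merged["family_cluster_id"].to_numpy(),
        model_spec=f"ROR {contrast or pairs_a.relation + '_vs_' + pairs_b.relation}",
    )
    components = {}
    for cohort in (pairs_a, pairs_b):
        key = cohort.relation if pairs_a.relation != pairs_b.relation else f"group_{cohort is pairs_a}"
        components[key] = run_pair_association(
            cohort, case_matrix, persons, exposure_phenotype, outcome_phenotype,
            n_knots=n_knots, adjust_birth_year=adjust_birth_year,
        )
    return RORResult(
        contrast=contrast or f"{pairs_a.relation}_vs_{pairs_b.relation}",
        ror=est.ratio_,
        ci_low=est.ci_[0],
        ci_high=est.ci_[1],
        p_value=est.p_value_,
        component_ors=components,
        n_obs=len(merged),
        flags=est.result_.flags,
    )


def side_split(cohort: RelativePairCohort, side: str) -> RelativePairCohort:
    """Restrict a sided pair cohort (aunt/uncle/cousin) to one side."""
    sub = cohort.pairs[cohort.pairs["side"] == side]
    return RelativePairCohort(
        relation=f"{cohort.relation}_{side}",
        pairs=sub.reset_index(drop=True),
        restriction=cohort.restriction,
        dropped=dict(cohort.dropped),
    )


def merge_cohorts(label: str, *cohorts: RelativePairCohort) -> RelativePairCohort:
    """Concatenate pair cohorts (e.g. aunts + uncles of one side)."""
    pairs = pd.concat([c.pairs for c in cohorts], ignore_index=True)
    return RelativePairCohort(
        relation=label, pairs=pairs, restriction=cohorts[0].restriction, dropped={}
    )
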