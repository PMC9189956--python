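"""Odds-ratio estimation with cluster-robust inference.

Associations between two lifetime binary phenotypes — within individuals
or across index–relative pairs — are estimated by maximum-likelihood
logistic regression with natural-cubic-spline adjustment for birth year,
cluster-robust (sandwich) standard errors aggregated over family
clusters, and Wald 95% confidence intervals (multiplier 1.96, two-sided
p-values).  No multiple-testing adjustment is applied.

The logistic fits are performed by statsmodels' binomial GLM (IRLS,
coefficient-change tolerance 1e-8, at most 100 iterations) with its
cluster sandwich covariance; this module owns the design construction,
diagnostics and result contracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._estimator import ParamsMixin
from .cohort_builder import ConfigurationError, RelativePairCohort, family_clusters
from .register_model import RegisterBundle

Z95 = 1.96  # Wald multiplier, fixed by convention


def _irls_logit(design: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Plain logistic IRLS returning coefficients only.

    Used in resampling loops (e.g. the standardization bootstrap) where
    only point predictions are needed; agrees with the GLM fit to
    numerical precision and avoids per-fit model-object overhead.
    """
    from scipy.special import expit

    beta = np.zeros(design.shape[1])
    p0 = min(max(float(y.mean()), 1e-8), 1 - 1e-8)
    beta[0] = np.log(p0 / (1 - p0))
    for _ in range(max_iter):
        eta = design @ beta
        mu = expit(eta)
        w = mu * (1 - mu) + 1e-12
        wx = design * w[:, None]
        new = np.linalg.solve(design.T @ wx, wx.T @ (eta + (y - mu) / w))
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta

DEFAULT_KNOT_PERCENTILES = (5.0, 27.5, 50.0, 72.5, 95.0)


# ---------------------------------------------------------------------------
# natural cubic splines


@dataclass(frozen=True)
class SplineBasis:
    """Natural cubic spline basis (linear beyond the boundary knots).

    With K knots the basis has K-1 columns (intercept excluded): the
    identity plus K-2 truncated-cubic combinations whose second and third
    derivatives vanish outside the boundary knots.
    """

    knots: np.ndarray

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        k = self.knots
        K = len(k)

        def d(j):  # (x - k_j)+^3 - (x - k_K)+^3, scaled
            return (
                np.clip(x - k[j], 0, None) ** 3 - np.clip(x - k[-1], 0, None) ** 3
            ) / (k[-1] - k[j])

        cols = [x]
        dK1 = d(K - 2)
        for j in range(K - 2):
            cols.append(d(j) - dK1)
        return np.column_stack(cols)

    @property
    def n_columns(self) -> int:
        return len(self.knots) - 1

    def column_names(self, prefix: str) -> list[str]:
        return [f"{prefix}_ns{i}" for i in range(self.n_columns)]


def natural_cubic_spline_basis(
    values,
    n_knots: int = 5,
    knots: Optional[Sequence[float]] = None,
    percentiles: Sequence[float] = DEFAULT_KNOT_PERCENTILES,
) -> SplineBasis:
    """Place knots (by default at the 5/27.5/50/72.5/95 percentiles) and
    return the natural cubic spline basis over ``values``.

    Raises :class:`ConfigurationError` for coincident knots or inputs with
    fewer than two distinct values.
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ConfigurationError("spline input has fewer than 2 distinct values")
    if knots is None:
        if n_knots != len(percentiles):
            percentiles = np.linspace(2.5, 97.5, n_knots)
        knots = np.percentile(values, list(percentiles))
    knots = np.asarray(sorted(knots), dtype=float)
    if np.unique(knots).size != knots.size:
        raise ConfigurationError(f"coincident spline knots: {knots.tolist()}")
    if knots.size < 3:
        raise ConfigurationError("need at least 3 knots for a natural cubic spline")
    return SplineBasis(knots=knots)


# ---------------------------------------------------------------------------
# results


@dataclass
class ORResult:
    estimate: float
    log_se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_obs: int
    n_clusters: int
    model_spec: str
    flags: list[str] = field(default_factory=list)
    params: Optional[pd.Series] = None

    def to_dict(self) -> dict:
        return {
            "or": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
            "log_se": self.log_se,
            "n_pairs": self.n_obs,
            "n_clusters": self.n_clusters,
            "model_spec": self.model_spec,
            "flags": ";".join(self.flags),
        }


@dataclass
class InteractionResult:
    ratio: float  # exponentiated interaction coefficient
    log_se: float
    ci_low: float
    ci_high: float
    p_value: float
    stratum_ors: dict  # modifier level -> ORResult
    n_obs: int
    n_clusters: int
    model_spec: str
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# estimators


def _as_2d(covariates) -> np.ndarray:
    if covariates is None:
        return np.empty((0, 0))
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


class ClusterLogisticOR(ParamsMixin):
    """Logistic odds ratio for a binary exposure with sandwich inference.

    Fits ``logit P(y=1) = b0 + b1*exposure + covariates`` by IRLS and
    reports ``exp(b1)`` with a cluster-robust Wald interval.  With a
    single cluster (or no cluster ids) the estimator falls back to the
    heteroscedasticity-robust sandwich with a warning flag.

    Parameters
    ----------
    max_iter, tol : IRLS controls.
    use_correction : apply the small-sample cluster correction factor
        G/(G-1); disabling it makes the one-observation-per-cluster
        sandwich coincide with the classical HC0 estimator.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-8, use_correction: bool = True):
        self.max_iter = max_iter
        self.tol = tol
        self.use_correction = use_correction

    # sklearn-style: fit(X, y) with exposure as the first design column
    def fit(self, X, y, *, exposure=None, clusters=None, model_spec: str = ""):
        y = np.asarray(y, dtype=float)
        if exposure is None:
            X = _as_2d(X)
            exposure, covariates = X[:, 0], X[:, 1:]
        else:
            exposure = np.asarray(exposure, dtype=float)
            covariates = _as_2d(X) if X is not None else np.empty((len(y), 0))
        if y.min() == y.max():
            raise ValueError("outcome has no variation (need >=1 case and >=1 non-case)")
        if covariates.size == 0:
            covariates = np.empty((len(y), 0))
        design = np.column_stack([np.ones(len(y)), exposure, covariates])

        flags: list[str] = []
        cov_type, cov_kwds = self._cov_spec(clusters, len(y), flags)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = sm.GLM(y, design, family=sm.families.Binomial())
            res = model.fit(
                maxiter=self.max_iter, tol=self.tol, cov_type=cov_type, cov_kwds=cov_kwds
            )
        for w in caught:
            if "erfect" in str(w.message) or "onverge" in str(w.message):
                flags.append("possible_separation_or_nonconvergence")
                break
        beta = res.params[1]
        var = float(res.cov_params()[1, 1])
        if var < 0:
            flags.append("nonpsd_covariance")
            var = 0.0
        se = float(np.sqrt(var))
        if abs(beta) > 15 or se > 50:
            flags.append("diverged_estimate")

        from scipy.stats import norm as _norm

        self.params_ = pd.Series(res.params)
        self.or_ = float(np.exp(beta))
        self.log_se_ = se
        self.ci_ = (float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se)))
        self.p_value_ = float(2 * _norm.sf(abs(beta / se))) if se > 0 else float("nan")
        self.n_obs_ = int(len(y))
        self.n_clusters_ = int(pd.Series(clusters).nunique()) if clusters is not None else len(y)
        self.flags_ = flags
        self._glm_result = res
        self._design = design
        self._y = y
        self._clusters = None if clusters is None else np.asarray(clusters)
        self.result_ = ORResult(
            estimate=self.or_,
            log_se=se,
            ci_low=self.ci_[0],
            ci_high=self.ci_[1],
            p_value=self.p_value_,
            n_obs=self.n_obs_,
            n_clusters=self.n_clusters_,
            model_spec=model_spec or f"exposure + {covariates.shape[1]} covariate(s)",
            flags=flags,
            params=self.params_,
        )
        # statsmodels results hold reference cycles; collect promptly so
        # replicate loops do not accumulate memory
        import gc

        gc.collect()
        return self

    def predict_proba(self, X=None) -> np.ndarray:
        res = self._glm_result
        design = self._design if X is None else X
        return np.asarray(res.predict(design))

    def _cov_spec(self, clusters, n, flags):
        if clusters is None:
            flags.append("no_clusters_hc_fallback")
            return "HC0", {}
        codes = pd.Categorical(pd.Series(clusters)).codes
        if len(np.unique(codes)) < 2:
            warnings.warn("single cluster: falling back to heteroscedasticity-robust SEs")
            flags.append("single_cluster_hc_fallback")
            return "HC0", {}
        return "cluster", {"groups": codes, "use_correction": self.use_correction}


def fit_logistic_or(
    outcome,
    exposure,
    covariates=None,
    cluster_ids=None,
    *,
    use_correction: bool = True,
    model_spec: str = "",
) -> ORResult:
    """Functional wrapper over :class:`ClusterLogisticOR`."""
    est = ClusterLogisticOR(use_correction=use_correction)
    est.fit(covariates, outcome, exposure=exposure, clusters=cluster_ids, model_spec=model_spec)
    return est.result_


class InteractionOR(ParamsMixin):
    """Exposure x modifier interaction on the log-odds scale.

    The exponentiated interaction coefficient is the ratio of the
    exposure odds ratios between the two modifier strata; stratum ORs are
    additionally estimated by stratified fits.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-8, use_correction: bool = True):
        self.max_iter = max_iter
        self.tol = tol
        self.use_correction = use_correction

    def fit(self, covariates, y, *, exposure, modifier, clusters=None, model_spec: str = "",
            stratum_fits: bool = True):
        y = np.asarray(y, dtype=float)
        exposure = np.asarray(exposure, dtype=float)
        modifier = np.asarray(modifier, dtype=float)
        for level in (0.0, 1.0):
            if not (modifier == level).any():
                raise ValueError(f"empty modifier stratum: {level:g}")
        cov = _as_2d(covariates) if covariates is not None else np.empty((len(y), 0))
        design = np.column_stack(
            [np.ones(len(y)), exposure, modifier, exposure * modifier, cov]
        )
        flags: list[str] = []
        helper = ClusterLogisticOR(self.max_iter, self.tol, self.use_correction)
        cov_type, cov_kwds = helper._cov_spec(clusters, len(y), flags)
        res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
            maxiter=self.max_iter, tol=self.tol, cov_type=cov_type, cov_kwds=cov_kwds
        )
        beta = res.params[3]
        var = float(res.cov_params()[3, 3])
        if var < 0:  # degenerate cluster covariance on tiny strata
            flags.append("nonpsd_covariance")
            var = 0.0
        se = float(np.sqrt(var))
        from scipy.stats import norm as _norm

        strata = {}
        for level in (0, 1) if stratum_fits else ():
            mask = modifier == level
            sub_clusters = None if clusters is None else np.asarray(clusters)[mask]
            strata[level] = fit_logistic_or(
                y[mask],
                exposure[mask],
                cov[mask] if cov.size else None,
                sub_clusters,
                use_correction=self.use_correction,
                model_spec=f"stratum modifier={level}",
            )
        self.ratio_ = float(np.exp(beta))
        self.log_se_ = se
        self.ci_ = (float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se)))
        self.p_value_ = float(2 * _norm.sf(abs(beta / se))) if se > 0 else float("nan")
        self.stratum_ors_ = strata
        self.params_ = pd.Series(res.params)
        self.result_ = InteractionResult(
            ratio=self.ratio_,
            log_se=se,
            ci_low=self.ci_[0],
            ci_high=self.ci_[1],
            p_value=self.p_value_,
            stratum_ors=strata,
            n_obs=int(len(y)),
            n_clusters=int(pd.Series(clusters).nunique()) if clusters is not None else len(y),
            model_spec=model_spec or "exposure * modifier",
            flags=flags,
        )
        return self


def fit_or_with_interaction(
    outcome, exposure, modifier, covariates=None, cluster_ids=None, **kw
) -> InteractionResult:
    est = InteractionOR(**{k: v for k, v in kw.items() if k in ("max_iter", "tol", "use_correction")})
    est.fit(
        covariates,
        outcome,
        exposure=exposure,
        modifier=modifier,
        clusters=cluster_ids,
        model_spec=kw.get("model_spec", ""),
        stratum_fits=kw.get("stratum_fits", True),
    )
    return est.result_


# ---------------------------------------------------------------------------
# analysis drivers


def birth_year_spline_columns(
    years: pd.Series, prefix: str, n_knots: int = 5
) -> pd.DataFrame:
    basis = natural_cubic_spline_basis(years.to_numpy(), n_knots=n_knots)
    mat = basis.transform(years.to_numpy())
    return pd.DataFrame(mat, columns=basis.column_names(prefix), index=years.index)


def pair_analysis_frame(
    pairs: RelativePairCohort,
    case_matrix: pd.DataFrame,
    persons: pd.DataFrame,
    exposure_phenotype: str,
    outcome_phenotype: str,
) -> pd.DataFrame:
    """Assemble the pair-level analysis dataset.

    One row per pair: relative's outcome, index's exposure, both birth
    years, the family cluster.  Persons missing a phenotype row count as
    non-cases.
    """
    df = pairs.pairs.copy()
    info = persons.set_index("person_id")
    exp = case_matrix[exposure_phenotype] if exposure_phenotype in case_matrix else pd.Series(False, index=case_matrix.index)
    out = case_matrix[outcome_phenotype] if outcome_phenotype in case_matrix else pd.Series(False, index=case_matrix.index)
    df["exposure"] = df["index_id"].map(exp).fillna(False).astype(int)
    df["outcome"] = df["relative_id"].map(out).fillna(False).astype(int)
    df["index_birth_year"] = df["index_id"].map(info["birth_year"])
    df["relative_birth_year"] = df["relative_id"].map(info["birth_year"])
    return df


def run_pair_association(
    pairs: RelativePairCohort,
    case_matrix: pd.DataFrame,
    persons: pd.DataFrame,
    exposure_phenotype: str,
    outcome_phenotype: str,
    *,
    n_knots: int = 5,
    adjust_birth_year: bool = True,
) -> ORResult:
    """Index-exposure vs relative-outcome OR for one relative class.

    Adjusted for natural cubic splines of both members' birth years;
    clustered on the family cluster id.
    """
    df = pair_analysis_frame(pairs, case_matrix, persons, exposure_phenotype, outcome_phenotype)
    cov_frames = []
    if adjust_birth_year:
        for col, prefix in (("index_birth_year", "iby"), ("relative_birth_year", "rby")):
            cov_frames.append(birth_year_spline_columns(df[col], prefix, n_knots))
    cov = pd.concat(cov_frames, axis=1).to_numpy() if cov_frames else None
    spec = (
        f"{pairs.relation}: {outcome_phenotype}(relative) ~ {exposure_phenotype}(index)"
        + (" + ns(index by) + ns(relative by)" if adjust_birth_year else "")
    )
    return fit_logistic_or(
        df["outcome"].to_numpy(),
        df["exposure"].to_numpy(),
        cov,
        df["family_cluster_id"].to_numpy(),
        model_spec=spec,
    )


def run_within_individual(
    index_members: pd.DataFrame,
    case_matrix: pd.DataFrame,
    exposure_phenotype: str,
    outcome_phenotype: str,
    *,
    clusters: Optional[pd.Series] = None,
    bundle: Optional[RegisterBundle] = None,
    n_knots: int = 5,
    sex_adjustment: str = "covariate",
) -> ORResult:
    """Within-individual OR, adjusted for sex and birth-year splines.

    ``sex_adjustment`` is ``"covariate"`` (default) or ``"none"``;
    stratified analyses go through :func:`fit_or_with_interaction`.
    """
    df = index_members.set_index("person_id")
    y = df.index.map(case_matrix.get(outcome_phenotype, pd.Series(dtype=bool))).fillna(False).astype(int)
    x = df.index.map(case_matrix.get(exposure_phenotype, pd.Series(dtype=bool))).fillna(False).astype(int)
    cov_frames = [birth_year_spline_columns(df["birth_year"], "by", n_knots)]
    if sex_adjustment == "covariate":
        cov_frames.append(pd.DataFrame({"female": (df["sex"] == "female").astype(float)}, index=df.index))
    cov = pd.concat(cov_frames, axis=1).to_numpy()
    if clusters is None and bundle is not None:
        clusters = df.index.map(family_clusters(bundle))
    spec = f"within: {outcome_phenotype} ~ {exposure_phenotype} + ns(by)" + (
        " + sex" if sex_adjustment == "covariate" else ""
    )
    return fit_logistic_or(
        np.asarray(y), np.asarray(x), cov,
        None if clusters is None else np.asarray(clusters),
        model_spec=spec,
    )
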