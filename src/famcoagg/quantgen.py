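"""Bivariate liability-threshold ACE model fitting on relative-pair data.

The data unit is a relative pair with two binary traits per member, i.e.
a 16-cell contingency pattern per relative class (full siblings, full
cousins).  Under the liability model each pattern's probability is a
rectangle probability of a 4-variate standard normal whose correlation
matrix is built from the variance components and the class's kinship
sharing coefficients (:func:`famcoagg.liability.pair_correlation_matrix`).

Fitting maximizes the multinomial likelihood over an unconstrained
reparameterization (additive log-ratios on each trait's variance simplex,
inverse hyperbolic tangents for the factor correlations), with multiple
seeded starts, and selects among ACE/AE/CE/E sub-models by AIC.
Confidence intervals are profile-likelihood based by default, with
delta-method Wald intervals as a fallback.

Identifiability requires at least two relative classes with distinct
(a_share, c_share) whenever both A and C are free for some trait; the
sibling (0.5, 1.0) vs cousin (0.125, 0.0) contrast makes each trait's
(a2, c2) the solution of a full-rank 2x2 linear system, which the fitter
verifies before optimizing.

Rectangle probabilities: the public :func:`pattern_probability` uses
randomized quasi-Monte Carlo separation-of-variables (Genz) with an error
estimate tightened until the requested accuracy; the likelihood loop uses
the same algorithm on a fixed deterministic point set, vectorized over
all class-pattern rectangles.  ``scipy.stats.multivariate_normal.cdf``
serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri
from scipy.stats import chi2, qmc

from ._estimator import ParamsMixin
from .liability import (
    COUSIN,
    SIBLING,
    ParameterDomainError,
    RelativeClassSpec,
    VarianceComponents,
    decompose_correlation,
    pair_correlation_matrix,
    threshold_from_prevalence,
)

#: The 16 joint outcome patterns in bit order (m1t1, m1t2, m2t1, m2t2);
#: bit value 1 = affected (liability above threshold).
PATTERNS = np.array([[(i >> 3) & 1, (i >> 2) & 1, (i >> 1) & 1, i & 1] for i in range(16)])

PROB_FLOOR = 1e-300
_CHI2_95 = float(chi2.ppf(0.95, 1))


def counts_from_outcomes(outcomes: np.ndarray) -> np.ndarray:
    """Collapse an (n, 4) boolean outcome array to 16 pattern counts."""
    outcomes = np.asarray(outcomes).astype(int)
    idx = outcomes @ np.array([8, 4, 2, 1])
    return np.bincount(idx, minlength=16)


@dataclass
class PatternCounts:
    """16-cell contingency data per relative class.

    ``counts`` maps a class label to its length-16 count vector (pattern
    order as in :data:`PATTERNS`); ``specs`` maps the same labels to
    kinship sharing coefficients.  ``per_pair`` optionally holds one row
    per pair (columns: ``class_label``, ``pattern``, ``female1``,
    ``female2``, ``z1``, ``z2``) for the covariate-threshold likelihood
    mode.
    """

    counts: Dict[str, np.ndarray]
    specs: Dict[str, RelativeClassSpec]
    per_pair: Optional[pd.DataFrame] = None

    def __post_init__(self):
        for label, c in list(self.counts.items()):
            c = np.asarray(c, dtype=float)
            if c.shape != (16,) or (c < 0).any():
                raise ValueError(f"class '{label}': counts must be 16 non-negative cells")
            self.counts[label] = c
            if label not in self.specs:
                raise ValueError(f"class '{label}' lacks a RelativeClassSpec")

    @property
    def n_pairs(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def default_specs() -> Dict[str, RelativeClassSpec]:
    return {"full_sibling": SIBLING, "cousin": COUSIN}


# ---------------------------------------------------------------------------
# rectangle probabilities


class RectangleEngine:
    """Vectorized Genz separation-of-variables CDF for batches of 4-D
    normal rectangles (lower limits all -inf).

    Uses a fixed scrambled-Sobol point set so repeated evaluations are
    deterministic; with ``n_shifts`` independent scrambles the spread of
    the per-scramble means yields an error estimate.
    """

    def __init__(self, n_points: int = 2048, seed: int = 1234, n_shifts: int = 1):
        self.n_points = n_points
        self.n_shifts = n_shifts
        seeds = np.random.SeedSequence(seed).spawn(n_shifts)
        self._w = np.stack(
            [
                qmc.Sobol(d=3, scramble=True, seed=np.random.default_rng(s)).random(n_points)
                for s in seeds
            ]
        )  # (n_shifts, n_points, 3)

    def cdf(self, corr: np.ndarray, upper: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """P(X <= upper[i]) under N(0, corr[i]); returns (prob, stderr)."""
        corr = np.asarray(corr, float)
        upper = np.asarray(upper, float)
        m = corr.shape[0]
        # variable ordering: increasing limit (improves accuracy)
        order = np.argsort(upper, axis=1)
        b = np.take_along_axis(upper, order, axis=1)
        R = np.empty_like(corr)
        for i in range(m):
            R[i] = corr[i][np.ix_(order[i], order[i])]
        try:
            L = np.linalg.cholesky(R + 1e-12 * np.eye(4))
        except np.linalg.LinAlgError:
            # project to the nearest correlation-like PSD matrix
            w, v = np.linalg.eigh(R)
            w = np.clip(w, 1e-10, None)
            R = v @ (w[..., None] * np.swapaxes(v, -1, -2))
            d = np.sqrt(np.diagonal(R, axis1=-2, axis2=-1))
            R = R / d[:, :, None] / d[:, None, :]
            L = np.linalg.cholesky(R + 1e-12 * np.eye(4))

        K, N = self.n_shifts, self.n_points
        tiny = 1e-15
        probs = np.empty((K, m))
        for k in range(K):
            wk = self._w[k]  # (N, 3)
            e = np.broadcast_to(
                ndtr(b[:, 0, None] / L[:, 0, 0, None]), (m, N)
            ).copy()  # conditional prob at layer 1
            prod = e.copy()
            ys = np.empty((m, N, 3))
            for j in range(1, 4):
                ys[:, :, j - 1] = ndtri(np.clip(wk[None, :, j - 1] * e, tiny, 1 - tiny))
                num = b[:, j, None] - np.einsum("mp,mnp->mn", L[:, j, :j], ys[:, :, :j])
                e = ndtr(num / L[:, j, j, None])
                prod = prod * e
            probs[k] = prod.mean(axis=1)
        prob = probs.mean(axis=0)
        err = probs.std(axis=0, ddof=1) / np.sqrt(K) if K > 1 else np.zeros(m)
        return prob, err


def _pattern_rectangles(
    corr: np.ndarray, thresholds: np.ndarray, patterns: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map patterns to equivalent all-below rectangles via sign flips.

    For pattern bit 1 (affected, X_i > t_i) the variable is negated:
    P(X_i > t_i) = P(-X_i <= -t_i).  Correlations flip accordingly.
    """
    signs = 1.0 - 2.0 * patterns  # 1 for below, -1 for above
    m = len(patterns)
    R = np.empty((m, 4, 4))
    for i in range(m):
        s = signs[i]
        R[i] = corr * np.outer(s, s)
    upper = signs * thresholds
    return R, upper


def pattern_probabilities(
    corr: np.ndarray,
    thresholds: Sequence[float],
    engine: Optional[RectangleEngine] = None,
) -> np.ndarray:
    """Probabilities of all 16 patterns for one correlation/threshold set."""
    if engine is None:
        engine = RectangleEngine(n_points=8192, n_shifts=2)
    thresholds = np.asarray(thresholds, float)
    R, upper = _pattern_rectangles(np.asarray(corr, float), thresholds, PATTERNS)
    probs, _ = engine.cdf(R, upper)
    return probs


def pattern_probability(
    corr: np.ndarray,
    thresholds: Sequence[float],
    pattern: Sequence[int],
    tol: float = 1e-7,
    max_points: int = 1 << 17,
    seed: int = 99,
) -> float:
    """Rectangle probability of one joint outcome pattern.

    ``pattern`` holds four 0/1 indicators (1 = liability above its
    threshold) in the order (m1 t1, m1 t2, m2 t1, m2 t2).  The randomized
    QMC point set is doubled until the estimated standard error is below
    ``tol`` (or ``max_points`` is reached).
    """
    corr = np.asarray(corr, float)
    if corr.shape != (4, 4):
        raise ParameterDomainError("corr must be 4x4")
    if np.linalg.eigvalsh(corr)[0] < -1e-10:
        raise ParameterDomainError("corr must be positive semi-definite")
    thresholds = np.asarray(thresholds, float)
    if not np.isfinite(thresholds).all():
        raise ParameterDomainError("thresholds must be finite")
    pattern = np.asarray(pattern, int).reshape(1, 4)
    R, upper = _pattern_rectangles(corr, thresholds, pattern)
    n = 4096
    while True:
        engine = RectangleEngine(n_points=n, seed=seed, n_shifts=8)
        prob, err = engine.cdf(R, upper)
        if err[0] <= tol or n >= max_points:
            return float(prob[0])
        n *= 2


# ---------------------------------------------------------------------------
# likelihood


def _class_probabilities(
    vc: VarianceComponents,
    specs: Dict[str, RelativeClassSpec],
    engine: RectangleEngine,
) -> Dict[str, np.ndarray]:
    """16 pattern probabilities per relative class, one batched engine call."""
    all_R, all_u, labels = [], [], []
    t = np.array([vc.thresholds[0], vc.thresholds[1], vc.thresholds[0], vc.thresholds[1]])
    for label, spec in specs.items():
        corr = pair_correlation_matrix(vc, spec)
        R, u = _pattern_rectangles(corr, t, PATTERNS)
        all_R.append(R)
        all_u.append(u)
        labels.append(label)
    probs, _ = engine.cdf(np.concatenate(all_R), np.concatenate(all_u))
    return {label: probs[16 * i : 16 * (i + 1)] for i, label in enumerate(labels)}


def pair_loglikelihood(
    data: PatternCounts,
    vc: VarianceComponents,
    engine: Optional[RectangleEngine] = None,
    *,
    mode: str = "auto",
) -> float:
    """Multinomial log-likelihood of the pattern data under ``vc``.

    ``mode='collapsed'`` uses the 16-cell counts per class;
    ``mode='per_pair'`` evaluates per-pair thresholds shifted by the
    covariate coefficients in ``vc.threshold_covariates`` (grouping
    identical covariate rows); ``'auto'`` picks per-pair when per-pair
    rows are present and covariate coefficients are non-zero.  The two
    modes agree exactly when all covariate coefficients are zero.
    """
    if engine is None:
        engine = RectangleEngine(n_points=4096)
    covs = vc.threshold_covariates
    has_cov = covs is not None and any(any(c != 0 for c in row) for row in covs)
    if mode == "auto":
        mode = "per_pair" if (data.per_pair is not None and has_cov) else "collapsed"
    if mode == "collapsed":
        probs = _class_probabilities(vc, data.specs, engine)
        ll = 0.0
        for label, counts in data.counts.items():
            p = np.maximum(probs[label], PROB_FLOOR)
            ll += float(counts @ np.log(p))
        return ll
    if data.per_pair is None:
        raise ValueError("per-pair likelihood mode requires per_pair rows")
    if covs is None:
        covs = ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
    df = data.per_pair
    grouped = df.groupby(
        ["class_label", "pattern", "female1", "female2", "z1", "z2"]
    ).size()
    ll = 0.0
    all_R, all_u, weights = [], [], []
    for (label, pattern, f1, f2, z1, z2), n in grouped.items():
        spec = data.specs[label]
        corr = pair_correlation_matrix(vc, spec)
        thr = np.empty(4)
        for member, (f, z) in enumerate(((f1, z1), (f2, z2))):
            for k in range(2):
                s, lin, cub = covs[k]
                thr[2 * member + k] = vc.thresholds[k] + s * f + lin * z + cub * z**3
        R, u = _pattern_rectangles(corr, thr, PATTERNS[int(pattern)].reshape(1, 4))
        all_R.append(R)
        all_u.append(u)
        weights.append(n)
    probs, _ = engine.cdf(np.concatenate(all_R), np.concatenate(all_u))
    probs = np.maximum(probs, PROB_FLOOR)
    return float(np.asarray(weights) @ np.log(probs))


# ---------------------------------------------------------------------------
# parameter mapping


def _parse_components(spec: str) -> frozenset:
    comps = frozenset(spec.upper())
    if not comps <= {"A", "C", "E"} or "E" not in comps:
        raise ParameterDomainError(
            f"component set '{spec}' invalid: must be a subset of ACE containing E"
        )
    return comps


class _ParamMap:
    """Bijection between named free coordinates and VarianceComponents.

    Coordinates: per-trait additive log-ratios ``la_k = log(a2/e2)`` and
    ``lc_k = log(c2/e2)`` (only for included components), ``zA/zC/zE``
    (atanh of the defined correlations), thresholds ``t1``/``t2``, and
    optionally the six threshold covariate coefficients.  A single natural
    parameter may be held fixed (for profile likelihood): proportions are
    then profiled through a logit coordinate on the remaining simplex mass.
    """

    CORR_FOR = {"rA": "a2", "rC": "c2", "rE": "e2"}

    def __init__(
        self,
        comps: tuple[frozenset, frozenset],
        fixed: Optional[dict] = None,
        estimate_covariates: bool = False,
    ):
        self.comps = comps
        self.fixed = dict(fixed or {})
        self.estimate_covariates = estimate_covariates
        self.names: list[str] = []
        for k in (0, 1):
            fixed_here = [p for p in (f"a2_{k+1}", f"c2_{k+1}") if p in self.fixed]
            if len(fixed_here) > 1:
                raise ParameterDomainError("at most one fixed proportion per trait")
            if fixed_here:
                other = "C" if fixed_here[0].startswith("a2") else "A"
                if other in comps[k]:
                    self.names.append(f"q_{k+1}")  # logit of other / (other + e2)
            else:
                if "A" in comps[k]:
                    self.names.append(f"la_{k+1}")
                if "C" in comps[k]:
                    self.names.append(f"lc_{k+1}")
        for rname in ("rA", "rC", "rE"):
            comp = {"rA": "A", "rC": "C", "rE": "E"}[rname]
            if comp in comps[0] and comp in comps[1] and rname not in self.fixed:
                self.names.append(f"z{rname[1]}")
        self.names += ["t1", "t2"]
        if estimate_covariates:
            self.names += [f"tc_{k+1}_{c}" for k in (0, 1) for c in ("sex", "lin", "cub")]

    @property
    def n_free(self) -> int:
        return len(self.names)

    def to_components(self, x: np.ndarray) -> VarianceComponents:
        vals = dict(zip(self.names, x))
        a2, c2, e2 = [0.0, 0.0], [0.0, 0.0], [1.0, 1.0]
        for k in (0, 1):
            kk = k + 1
            fixed_a = self.fixed.get(f"a2_{kk}")
            fixed_c = self.fixed.get(f"c2_{kk}")
            if fixed_a is not None or fixed_c is not None:
                fval = fixed_a if fixed_a is not None else fixed_c
                rest = 1.0 - fval
                qname = f"q_{kk}"
                if qname in vals:
                    frac = 1.0 / (1.0 + np.exp(-vals[qname]))
                    other_val = rest * frac
                else:
                    other_val = 0.0
                if fixed_a is not None:
                    a2[k], c2[k] = fval, other_val
                else:
                    c2[k], a2[k] = fval, other_val
                e2[k] = rest - other_val
            else:
                wa = np.exp(vals.get(f"la_{kk}", -np.inf)) if "A" in self.comps[k] else 0.0
                wc = np.exp(vals.get(f"lc_{kk}", -np.inf)) if "C" in self.comps[k] else 0.0
                tot = 1.0 + wa + wc
                a2[k], c2[k], e2[k] = wa / tot, wc / tot, 1.0 / tot
        rs = {}
        for rname in ("rA", "rC", "rE"):
            comp = {"rA": "A", "rC": "C", "rE": "E"}[rname]
            if comp in self.comps[0] and comp in self.comps[1]:
                if rname in self.fixed:
                    rs[rname] = float(self.fixed[rname])
                else:
                    rs[rname] = float(np.tanh(vals[f"z{rname[1]}"]))
            else:
                rs[rname] = None
        covs = None
        if self.estimate_covariates:
            covs = tuple(
                (vals[f"tc_{k+1}_sex"], vals[f"tc_{k+1}_lin"], vals[f"tc_{k+1}_cub"])
                for k in (0, 1)
            )
        return VarianceComponents(
            a2=tuple(a2),
            c2=tuple(c2),
            e2=tuple(e2),
            rA=rs["rA"],
            rC=rs["rC"],
            rE=rs["rE"],
            thresholds=(float(vals["t1"]), float(vals["t2"])),
            threshold_covariates=covs,
        )

    def from_components(self, vc: VarianceComponents) -> np.ndarray:
        def logratio(num, den):
            return float(np.log(max(num, 1e-8) / max(den, 1e-8)))

        vals = {}
        for k in (0, 1):
            kk = k + 1
            if f"q_{kk}" in self.names:
                fixed_a = self.fixed.get(f"a2_{kk}")
                other = vc.c2[k] if fixed_a is not None else vc.a2[k]
                rest = 1.0 - (fixed_a if fixed_a is not None else self.fixed[f"c2_{kk}"])
                frac = np.clip(other / max(rest, 1e-10), 1e-6, 1 - 1e-6)
                vals[f"q_{kk}"] = float(np.log(frac / (1 - frac)))
            if f"la_{kk}" in self.names:
                vals[f"la_{kk}"] = logratio(vc.a2[k], vc.e2[k])
            if f"lc_{kk}" in self.names:
                vals[f"lc_{kk}"] = logratio(vc.c2[k], vc.e2[k])
        for rname in ("rA", "rC", "rE"):
            zname = f"z{rname[1]}"
            if zname in self.names:
                r = getattr(vc, rname) or 0.0
                vals[zname] = float(np.arctanh(np.clip(r, -0.999, 0.999)))
        vals["t1"], vals["t2"] = vc.thresholds
        if self.estimate_covariates:
            covs = vc.threshold_covariates or ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
            for k in (0, 1):
                for c, v in zip(("sex", "lin", "cub"), covs[k]):
                    vals[f"tc_{k+1}_{c}"] = float(v)
        return np.array([vals[n] for n in self.names])


# ---------------------------------------------------------------------------
# fit result


@dataclass
class FitResult:
    estimates: VarianceComponents
    log_likelihood: float
    aic: float
    n_params: int
    model_label: str
    ci: Dict[str, tuple] = field(default_factory=dict)
    covariance_shares: Dict[str, Optional[float]] = field(default_factory=dict)
    converged: bool = True
    grad_norm: float = float("nan")
    n_starts_used: int = 1
    ci_method: str = "none"

    def summary_frame(self) -> pd.DataFrame:
        vc = self.estimates
        rows = []
        for name, value in [
            ("a2_1", vc.a2[0]), ("c2_1", vc.c2[0]), ("e2_1", vc.e2[0]),
            ("a2_2", vc.a2[1]), ("c2_2", vc.c2[1]), ("e2_2", vc.e2[1]),
            ("rA", vc.rA), ("rC", vc.rC), ("rE", vc.rE),
            ("t1", vc.thresholds[0]), ("t2", vc.thresholds[1]),
        ]:
            lo, hi = self.ci.get(name, (np.nan, np.nan))
            rows.append((name, value, lo, hi))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "ci_low", "ci_high"])


# ---------------------------------------------------------------------------
# estimator


class BivariateLiabilityACE(ParamsMixin):
    """Maximum-likelihood bivariate liability-threshold ACE estimator.

    Parameters
    ----------
    trait1_components, trait2_components : str
        Sub-model per trait: "ACE", "AE", "CE" or "E" (E is mandatory).
    n_starts : int
        Multi-start count; the first start is a method-of-moments
        (tetrachoric) estimate, the rest are seeded perturbations.
    qmc_points : int
        QMC points per likelihood evaluation.
    gtol : float
        Projected-gradient norm at convergence.
    ci_method : "profile", "delta" or "none".
    ci_params : which natural parameters receive intervals (default: all
        free variance proportions and correlations).

    Fitted attributes: ``vc_`` (estimates), ``loglik_``, ``aic_``,
    ``ci_``, ``result_`` (:class:`FitResult`), ``converged_``.
    """

    def __init__(
        self,
        trait1_components: str = "ACE",
        trait2_components: str = "ACE",
        n_starts: int = 5,
        qmc_points: int = 2048,
        gtol: float = 1e-6,
        max_iter: int = 300,
        ci_method: str = "profile",
        ci_params: Optional[Sequence[str]] = None,
        estimate_covariates: bool = False,
        random_state: int = 0,
    ):
        self.trait1_components = trait1_components
        self.trait2_components = trait2_components
        self.n_starts = n_starts
        self.qmc_points = qmc_points
        self.gtol = gtol
        self.max_iter = max_iter
        self.ci_method = ci_method
        self.ci_params = ci_params
        self.estimate_covariates = estimate_covariates
        self.random_state = random_state

    # -- public API --------------------------------------------------------

    def fit(self, data: PatternCounts | Dict[str, np.ndarray], specs=None):
        if not isinstance(data, PatternCounts):
            data = PatternCounts(counts=dict(data), specs=dict(specs or default_specs()))
        comps = (_parse_components(self.trait1_components), _parse_components(self.trait2_components))
        self._check_identifiability(comps, data.specs)
        engine = RectangleEngine(n_points=self.qmc_points)
        pmap = _ParamMap(comps, estimate_covariates=self.estimate_covariates)
        negll = self._make_objective(pmap, data, engine)

        starts = self._starting_points(pmap, data, comps)
        best = None
        n_used = 0
        for x0 in starts:
            n_used += 1
            res = optimize.minimize(
                negll,
                x0,
                method="L-BFGS-B",
                options={"maxiter": self.max_iter, "gtol": self.gtol, "ftol": 1e-12},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("bivariate ACE fit failed to produce a finite likelihood")
        grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else float("nan")
        converged = bool(best.success) or grad_norm < 1e-3

        vc = pmap.to_components(best.x)
        loglik = -float(best.fun)
        k = pmap.n_free
        aic = 2.0 * k - 2.0 * loglik

        ci: Dict[str, tuple] = {}
        method = self.ci_method
        if method in ("profile", "delta"):
            ci = self._confidence_intervals(method, pmap, best.x, loglik, data, engine, comps)

        self.vc_ = vc
        self.loglik_ = loglik
        self.aic_ = aic
        self.ci_ = ci
        self.converged_ = converged
        self.n_params_ = k
        self._pmap = pmap
        self._data = data
        self._engine = engine
        self._x = best.x
        self.result_ = FitResult(
            estimates=vc,
            log_likelihood=loglik,
            aic=aic,
            n_params=k,
            model_label=f"{self.trait1_components}-{self.trait2_components}",
            ci=ci,
            covariance_shares=decompose_correlation(vc),
            converged=converged,
            grad_norm=grad_norm,
            n_starts_used=n_used,
            ci_method=method,
        )
        return self

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _check_identifiability(comps, specs: Dict[str, RelativeClassSpec]) -> None:
        needs_ac = any({"A", "C"} <= c for c in comps)
        if not needs_ac:
            if len(specs) < 1:
                raise ParameterDomainError("at least one relative class required")
            return
        shares = np.array([[s.a_share, s.c_share] for s in specs.values()])
        if len(specs) < 2 or np.linalg.matrix_rank(shares) < 2:
            raise ParameterDomainError(
                "A and C are jointly unidentified: need >=2 relative classes with "
                "linearly independent (a_share, c_share) rows; got "
                + ", ".join(f"{k}({s.a_share},{s.c_share})" for k, s in specs.items())
            )

    def _make_objective(self, pmap: _ParamMap, data: PatternCounts, engine: RectangleEngine):
        mode = "per_pair" if (self.estimate_covariates and data.per_pair is not None) else "collapsed"

        def negll(x: np.ndarray) -> float:
            try:
                vc = pmap.to_components(x)
                return -pair_loglikelihood(data, vc, engine, mode=mode)
            except ParameterDomainError:
                return 1e10
            except FloatingPointError:
                return 1e10

        return negll

    def _moment_start(self, data: PatternCounts, comps) -> VarianceComponents:
        """Method-of-moments start: thresholds from pooled margins,
        correlations tetrachoric, components by solving the sharing
        equations (least squares, clipped into the simplex interior)."""
        margins = np.zeros(2)
        total = 0.0
        per_class: Dict[str, dict] = {}
        for label, counts in data.counts.items():
            n = counts.sum()
            if n == 0:
                continue
            total += 2 * n
            p = counts / n
            marg = {v: float(p @ PATTERNS[:, v]) for v in range(4)}
            margins[0] += n * (marg[0] + marg[2])
            margins[1] += n * (marg[1] + marg[3])
            per_class[label] = {"p": p, "marg": marg, "n": n}
        prev = np.clip(margins / max(total, 1.0), 1e-6, 1 - 1e-6)
        t = np.array([threshold_from_prevalence(prev[0]), threshold_from_prevalence(prev[1])])

        def joint(p, v1, v2):
            return float(p @ (PATTERNS[:, v1] * PATTERNS[:, v2]))

        def tetrachoric(p11, t1, t2):
            from scipy.stats import multivariate_normal as mvn

            def f(r):
                return mvn(mean=[0, 0], cov=[[1, r], [r, 1]]).cdf([-t1, -t2]) - p11

            lo, hi = -0.99, 0.99
            try:
                if f(lo) * f(hi) > 0:
                    return 0.0
                return float(optimize.brentq(f, lo, hi, xtol=1e-6))
            except Exception:
                return 0.0

        within, same1, same2, crossp = [], {}, {}, {}
        for label, d in per_class.items():
            p, n = d["p"], d["n"]
            w1 = tetrachoric(joint(p, 0, 1), t[0], t[1])
            w2 = tetrachoric(joint(p, 2, 3), t[0], t[1])
            within.extend([w1, w2])
            same1[label] = tetrachoric(joint(p, 0, 2), t[0], t[0])
            same2[label] = tetrachoric(joint(p, 1, 3), t[1], t[1])
            x1 = tetrachoric(joint(p, 0, 3), t[0], t[1])
            x2 = tetrachoric(joint(p, 1, 2), t[1], t[0])
            crossp[label] = 0.5 * (x1 + x2)
        w = float(np.mean(within)) if within else 0.0

        a2, c2, e2 = [0.3, 0.3], [0.1, 0.1], [0.6, 0.6]
        for k, same in enumerate((same1, same2)):
            rows, rhs = [], []
            for label, r in same.items():
                s = data.specs[label]
                cols = []
                if "A" in comps[k]:
                    cols.append(s.a_share)
                if "C" in comps[k]:
                    cols.append(s.c_share)
                rows.append(cols)
                rhs.append(r)
            if rows and rows[0]:
                sol, *_ = np.linalg.lstsq(np.array(rows, float), np.array(rhs), rcond=None)
                vals = list(np.clip(sol, 0.01, 0.9))
                ia = 0
                a2[k] = vals[ia] if "A" in comps[k] else 0.0
                if "A" in comps[k]:
                    ia += 1
                c2[k] = vals[ia] if "C" in comps[k] and ia < len(vals) else 0.0
            else:
                a2[k] = 0.0 if "A" not in comps[k] else a2[k]
                c2[k] = 0.0 if "C" not in comps[k] else c2[k]
            if a2[k] + c2[k] > 0.95:
                scale = 0.95 / (a2[k] + c2[k])
                a2[k] *= scale
                c2[k] *= scale
            e2[k] = 1.0 - a2[k] - c2[k]

        hasA = "A" in comps[0] and "A" in comps[1]
        hasC = "C" in comps[0] and "C" in comps[1]
        rows, rhs = [], []
        for label, r in crossp.items():
            s = data.specs[label]
            cols = []
            if hasA:
                cols.append(s.a_share * np.sqrt(max(a2[0] * a2[1], 1e-12)))
            if hasC:
                cols.append(s.c_share * np.sqrt(max(c2[0] * c2[1], 1e-12)))
            rows.append(cols)
            rhs.append(r)
        rA = rC = None
        if rows and rows[0]:
            sol, *_ = np.linalg.lstsq(np.array(rows, float), np.array(rhs), rcond=None)
            i = 0
            if hasA:
                rA = float(np.clip(sol[i], -0.9, 0.9))
                i += 1
            if hasC:
                rC = float(np.clip(sol[i], -0.9, 0.9)) if i < len(sol) else 0.0
        used = (rA or 0.0) * np.sqrt(a2[0] * a2[1]) + (rC or 0.0) * np.sqrt(c2[0] * c2[1])
        denom = np.sqrt(max(e2[0] * e2[1], 1e-12))
        rE = float(np.clip((w - used) / denom, -0.9, 0.9))
        return VarianceComponents(
            a2=tuple(a2), c2=tuple(c2), e2=tuple(e2),
            rA=rA if hasA else None, rC=rC if hasC else None, rE=rE,
            thresholds=(float(t[0]), float(t[1])),
        )

    def _starting_points(self, pmap: _ParamMap, data: PatternCounts, comps):
        vc0 = self._moment_start(data, comps)
        x0 = pmap.from_components(vc0)
        starts = [x0]
        rng = np.random.default_rng(self.random_state)
        for _ in range(max(0, self.n_starts - 1)):
            starts.append(x0 + rng.normal(0, 0.4, size=len(x0)))
        return starts

    # -- confidence intervals ---------------------------------------------

    def _free_natural_params(self, comps) -> list[str]:
        names = []
        for k in (0, 1):
            if "A" in comps[k]:
                names.append(f"a2_{k+1}")
            if "C" in comps[k]:
                names.append(f"c2_{k+1}")
        if "A" in comps[0] and "A" in comps[1]:
            names.append("rA")
        if "C" in comps[0] and "C" in comps[1]:
            names.append("rC")
        names.append("rE")
        return names

    def _natural_value(self, vc: VarianceComponents, name: str) -> float:
        if name.startswith(("a2", "c2", "e2")):
            which, k = name.split("_")
            return getattr(vc, which)[int(k) - 1]
        return getattr(vc, name)

    def _confidence_intervals(self, method, pmap, x_hat, loglik_hat, data, engine, comps):
        names = list(self.ci_params) if self.ci_params else self._free_natural_params(comps)
        vc_hat = pmap.to_components(x_hat)
        ses = self._delta_ses(pmap, x_hat, data, engine, names)
        ci: Dict[str, tuple] = {}
        for name in names:
            est = self._natural_value(vc_hat, name)
            se = ses.get(name, 0.1)
            if method == "delta":
                lo, hi = est - 1.96 * se, est + 1.96 * se
            else:
                lo = self._profile_bound(name, est, se, -1, pmap, data, engine, loglik_hat, vc_hat, comps)
                hi = self._profile_bound(name, est, se, +1, pmap, data, engine, loglik_hat, vc_hat, comps)
            if name.startswith(("a2", "c2", "e2")):
                lo, hi = max(lo, 0.0), min(hi, 1.0)
            else:
                lo, hi = max(lo, -1.0), min(hi, 1.0)
            ci[name] = (float(lo), float(hi))
        return ci

    def _delta_ses(self, pmap, x_hat, data, engine, names) -> Dict[str, float]:
        """Delta-method SEs via numerical Hessian in free coordinates."""
        negll = self._make_objective(pmap, data, engine)
        n = len(x_hat)
        h = 1e-4
        H = np.empty((n, n))
        f0 = negll(x_hat)
        for i in range(n):
            for j in range(i, n):
                xpp = x_hat.copy(); xpp[i] += h; xpp[j] += h
                xpm = x_hat.copy(); xpm[i] += h; xpm[j] -= h
                xmp = x_hat.copy(); xmp[i] -= h; xmp[j] += h
                xmm = x_hat.copy(); xmm[i] -= h; xmm[j] -= h
                H[i, j] = H[j, i] = (negll(xpp) - negll(xpm) - negll(xmp) + negll(xmm)) / (4 * h * h)
        try:
            cov = np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            return {}
        # jacobian of each requested natural parameter wrt coordinates
        out = {}
        for name in names:
            g = np.empty(n)
            for i in range(n):
                xp = x_hat.copy(); xp[i] += h
                xm = x_hat.copy(); xm[i] -= h
                g[i] = (
                    self._natural_value(pmap.to_components(xp), name)
                    - self._natural_value(pmap.to_components(xm), name)
                ) / (2 * h)
            var = float(g @ cov @ g)
            out[name] = float(np.sqrt(max(var, 1e-12)))
        _ = f0
        return out

    def _profile_deviance(self, name, value, pmap, data, engine, vc_hat, comps) -> float:
        fixed = {name: value}
        try:
            pm = _ParamMap(comps, fixed=fixed, estimate_covariates=self.estimate_covariates)
            x0 = pm.from_components(vc_hat)
        except (ParameterDomainError, ValueError, KeyError):
            return np.inf
        negll = self._make_objective(pm, data, engine)
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B",
            options={"maxiter": 120, "gtol": max(self.gtol, 1e-5), "ftol": 1e-11},
        )
        return float(res.fun)

    def _profile_bound(self, name, est, se, direction, pmap, data, engine, loglik_hat, vc_hat, comps):
        """Find the 95% profile bound by bracketing + bisection on the
        profile deviance crossing chi2(1, 0.95)."""
        if name.startswith(("a2", "c2")):
            hard = (1e-6, 1 - 1e-6)
        else:
            hard = (-0.999, 0.999)

        def dev(v):
            return 2.0 * (self._profile_deviance(name, v, pmap, data, engine, vc_hat, comps) + loglik_hat)

        target = _CHI2_95
        step = max(se, 1e-3)
        v_in = est
        v_out = None
        for mult in (1.0, 2.0, 4.0, 8.0, 16.0):
            cand = est + direction * mult * step
            cand = np.clip(cand, hard[0], hard[1])
            if dev(cand) > target:
                v_out = cand
                break
            v_in = cand
            if cand in hard:
                break
        if v_out is None:
            return hard[0] if direction < 0 else hard[1]
        for _ in range(20):
            mid = 0.5 * (v_in + v_out)
            if abs(v_out - v_in) < 1e-4:
                break
            if dev(mid) > target:
                v_out = mid
            else:
                v_in = mid
        return 0.5 * (v_in + v_out)


def fit_bivariate_ace(
    data: PatternCounts | Dict[str, np.ndarray],
    model_spec: tuple[str, str] = ("ACE", "ACE"),
    specs=None,
    **options,
) -> FitResult:
    """Functional wrapper over :class:`BivariateLiabilityACE`."""
    est = BivariateLiabilityACE(
        trait1_components=model_spec[0], trait2_components=model_spec[1], **options
    )
    est.fit(data, specs=specs)
    return est.result_


DEFAULT_CANDIDATES = (
    ("ACE", "ACE"),
    ("AE", "ACE"),
    ("ACE", "AE"),
    ("AE", "AE"),
    ("CE", "ACE"),
    ("E", "ACE"),
)


def select_model(
    data: PatternCounts | Dict[str, np.ndarray],
    candidates: Sequence[tuple[str, str]] = DEFAULT_CANDIDATES,
    specs=None,
    **options,
) -> list[FitResult]:
    """Fit candidate sub-models and rank by AIC (ties: fewer parameters).

    Failed fits are excluded with a warning.  The first element is the
    selected (best-fitting, most parsimonious) model; each result carries
    its AIC so ΔAIC is directly computable.
    """
    if len(candidates) < 2:
        raise ValueError("model selection needs at least two candidates")
    results = []
    for cand in candidates:
        try:
            results.append(fit_bivariate_ace(data, cand, specs=specs, **options))
        except (ParameterDomainError, RuntimeError) as exc:
            warnings.warn(f"candidate {cand} failed: {exc}")
    if not results:
        raise RuntimeError("every candidate model failed")
    results.sort(key=lambda r: (r.aic, r.n_params))
    return results


# ---------------------------------------------------------------------------
# simulation of pattern counts (generator at pair level)


def simulate_pattern_counts(
    vc: VarianceComponents,
    spec: RelativeClassSpec,
    n_pairs: int,
    rng=None,
) -> np.ndarray:
    """Draw ``n_pairs`` relative pairs from the liability model and
    collapse to 16 pattern counts (thresholds as in ``vc``, no covariate
    structure — the collapsed-count study condition)."""
    if rng is None:
        rng = np.random.default_rng(0)
    R = pair_correlation_matrix(vc, spec)
    w, v = np.linalg.eigh(R)
    factor = v * np.sqrt(np.clip(w, 0, None))
    L = rng.standard_normal((n_pairs, 4)) @ factor.T
    t = np.array([vc.thresholds[0], vc.thresholds[1], vc.thresholds[0], vc.thresholds[1]])
    return counts_from_outcomes(L > t)
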