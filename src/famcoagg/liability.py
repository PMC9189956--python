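"""Core bivariate liability-threshold ACE model arithmetic.

Two binary traits are modelled through latent standard-normal liabilities.
Each trait's liability variance is partitioned into additive-genetic (A),
shared-environment (C) and unique-environment (E) proportions
(``a2 + c2 + e2 = 1``), and the traits are coupled through component-wise
correlations ``rA``, ``rC``, ``rE``.  A person is affected when the
liability exceeds a threshold fixed by the trait's lifetime prevalence.

For a pair of relatives the four liabilities (member 1 trait 1, member 1
trait 2, member 2 trait 1, member 2 trait 2) are jointly normal with a
4x4 correlation matrix determined by the variance components and by the
relative class's kinship sharing coefficients: full siblings share half
the additive-genetic variance and all of the shared environment, full
cousins share one eighth of the additive-genetic variance and none of the
shared environment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.stats import norm


class ParameterDomainError(ValueError):
    """Parameter combination outside the model's admissible domain."""


def threshold_from_prevalence(p: float) -> float:
    """Liability threshold with upper-tail standard-normal mass ``p``.

    >>> threshold_from_prevalence(0.5)
    0.0
    """
    if not 0.0 < p < 1.0:
        raise ParameterDomainError(f"prevalence must lie in (0, 1), got {p}")
    return float(norm.isf(p))


def prevalence_from_threshold(t: float) -> float:
    return float(norm.sf(t))


@dataclass(frozen=True)
class RelativeClassSpec:
    """Kinship sharing coefficients of one relative class."""

    label: str
    a_share: float  # fraction of additive-genetic variance shared
    c_share: float  # fraction of shared-environment variance shared

    def __post_init__(self):
        if not 0.0 <= self.a_share <= 1.0:
            raise ParameterDomainError(f"a_share outside [0, 1]: {self.a_share}")
        if self.c_share not in (0.0, 1.0):
            raise ParameterDomainError(f"c_share must be 0 or 1: {self.c_share}")


SIBLING = RelativeClassSpec("full_sibling", 0.5, 1.0)
COUSIN = RelativeClassSpec("cousin", 0.125, 0.0)


@dataclass
class VarianceComponents:
    """Standardized bivariate ACE parameters.

    ``a2``, ``c2``, ``e2`` are per-trait variance proportions (2-tuples,
    trait order fixed by the caller).  ``rA``/``rC``/``rE`` are the
    cross-trait correlations of the corresponding latent factors; a
    correlation is ``None`` exactly when the component is absent (variance
    proportion zero) for at least one trait, in which case it contributes
    nothing and is structurally removed from any fitted model.
    ``thresholds`` are baseline liability thresholds; optional
    ``threshold_covariates`` hold per-trait (sex, birth-year linear,
    birth-year cubic) additive threshold-shift coefficients.
    """

    a2: tuple[float, float]
    c2: tuple[float, float]
    e2: tuple[float, float]
    rA: Optional[float]
    rC: Optional[float]
    rE: Optional[float]
    thresholds: tuple[float, float] = (0.0, 0.0)
    threshold_covariates: Optional[tuple[tuple[float, float, float], tuple[float, float, float]]] = None

    def __post_init__(self):
        for k in range(2):
            s = self.a2[k] + self.c2[k] + self.e2[k]
            if abs(s - 1.0) > 1e-12:
                raise ParameterDomainError(
                    f"variance proportions for trait {k + 1} sum to {s}, not 1"
                )
            for name in ("a2", "c2", "e2"):
                v = getattr(self, name)[k]
                if not 0.0 <= v <= 1.0:
                    raise ParameterDomainError(f"{name}[{k}] outside [0, 1]: {v}")
        for name, comp in (("rA", "a2"), ("rC", "c2"), ("rE", "e2")):
            r = getattr(self, name)
            prod = getattr(self, comp)[0] * getattr(self, comp)[1]
            if r is None:
                if prod > 0 and name == "rE":
                    raise ParameterDomainError("rE must be given when both traits have E > 0")
            elif not -1.0 <= r <= 1.0:
                raise ParameterDomainError(f"{name} outside [-1, 1]: {r}")

    # -- component-wise cross-trait covariance contributions ---------------
    def cross_cov(self, component: str) -> float:
        comp = {"A": ("rA", "a2"), "C": ("rC", "c2"), "E": ("rE", "e2")}[component]
        r = getattr(self, comp[0])
        v = getattr(self, comp[1])
        if r is None or v[0] * v[1] == 0.0:
            return 0.0
        return r * float(np.sqrt(v[0] * v[1]))

    @property
    def within_person_cross(self) -> float:
        """Within-individual cross-trait liability correlation."""
        return self.cross_cov("A") + self.cross_cov("C") + self.cross_cov("E")

    def replace(self, **kw) -> "VarianceComponents":
        return replace(self, **kw)


#: Point estimates reported by the source study's best model (AE for the
#: neurodevelopmental trait, ACE for the autoimmune composite), with
#: thresholds at lifetime prevalences 2.30% and 4.14%.
STUDY_COMPONENTS = VarianceComponents(
    a2=(0.84, 0.23),
    c2=(0.0, 0.09),
    e2=(0.16, 0.68),
    rA=0.13,
    rC=None,
    rE=0.02,
    thresholds=(threshold_from_prevalence(0.0230), threshold_from_prevalence(0.0414)),
)


def pair_correlation_matrix(vc: VarianceComponents, spec: RelativeClassSpec) -> np.ndarray:
    """4x4 liability correlation matrix for one relative class.

    Variable order: (member1 trait1, member1 trait2, member2 trait1,
    member2 trait2).  Raises :class:`ParameterDomainError` if the implied
    matrix is not positive semi-definite, signalling an inadmissible
    parameter combination to callers such as the ML optimizer.
    """
    w = vc.within_person_cross
    same = [spec.a_share * vc.a2[k] + spec.c_share * vc.c2[k] for k in range(2)]
    cross = spec.a_share * vc.cross_cov("A") + spec.c_share * vc.cross_cov("C")
    R = np.array(
        [
            [1.0, w, same[0], cross],
            [w, 1.0, cross, same[1]],
            [same[0], cross, 1.0, w],
            [cross, same[1], w, 1.0],
        ]
    )
    if np.linalg.eigvalsh(R)[0] < -1e-10:
        raise ParameterDomainError(
            f"pair correlation matrix for {spec.label} is not positive semi-definite"
        )
    return R


def decompose_correlation(vc: VarianceComponents) -> dict[str, Optional[float]]:
    """Split the cross-trait liability covariance into A/C/E shares.

    Shares sum to 1 when defined; a structurally absent component is
    reported as ``None`` and a near-zero total covariance makes all shares
    undefined.
    """
    parts = {comp: vc.cross_cov(comp) for comp in "ACE"}
    absent = {
        "A": vc.rA is None or vc.a2[0] * vc.a2[1] == 0.0,
        "C": vc.rC is None or vc.c2[0] * vc.c2[1] == 0.0,
        "E": vc.rE is None or vc.e2[0] * vc.e2[1] == 0.0,
    }
    total = sum(parts.values())
    if abs(total) < 1e-12:
        return {comp: None for comp in "ACE"}
    return {comp: (None if absent[comp] else parts[comp] / total) for comp in "ACE"}
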