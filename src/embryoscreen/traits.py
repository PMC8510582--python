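"""Risk reduction for diseases defined by thresholding a quantitative trait.

A "dichotomized" trait (e.g. cognitive impairment as IQ below 70, or high
cholesterol as LDL-C above a clinical cutoff) is mathematically the same
threshold character as a disease liability: the trait plays the role of
the liability, the cutoff implies a prevalence, and selecting the embryo
with the most favorable trait PRS is exactly lowest-risk prioritization on
the implied disease.  No separate integration machinery is needed — this
module converts trait-scale specifications and delegates to
:mod:`.analytic`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from scipy import stats

from .analytic import risk_lrp
from .core import RiskResult, ScreeningScenario, Strategy, risk_metrics

_NORM = stats.norm


@dataclass(frozen=True)
class TraitThresholdSpec:
    """A normally distributed trait plus the cutoff defining 'affected'.

    ``tail`` says which side of the threshold counts as affected; the
    implied prevalence is the normal tail mass beyond the threshold.
    ``r2_trait`` is the fraction of trait variance the PRS explains.
    """

    trait_mean: float
    trait_sd: float
    threshold: float
    tail: Literal["lower", "upper"] = "lower"
    r2_trait: float = 0.0

    def __post_init__(self) -> None:
        if self.trait_sd <= 0:
            raise ValueError("trait_sd must be positive")
        if self.tail not in ("lower", "upper"):
            raise ValueError(f"tail must be 'lower' or 'upper'; got {self.tail}")
        if not 0.0 <= self.r2_trait < 1.0:
            raise ValueError("r2_trait must lie in [0, 1)")


def implied_prevalence(spec: TraitThresholdSpec) -> float:
    """Tail mass of ``N(mean, sd^2)`` beyond the threshold."""
    z = (spec.threshold - spec.trait_mean) / spec.trait_sd
    return float(_NORM.cdf(z) if spec.tail == "lower" else _NORM.sf(z))


def tail_retention_fraction(spec: TraitThresholdSpec, gain: float) -> float:
    """Fraction of affected individuals within ``gain`` of the threshold.

    These are the individuals a uniform favorable shift of size ``gain``
    would carry across the cutoff — the intuition for why a small trait
    shift yields a large relative reduction in the affected fraction.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    z_thr = (spec.threshold - spec.trait_mean) / spec.trait_sd
    dz = gain / spec.trait_sd
    if spec.tail == "lower":
        tail_mass = _NORM.cdf(z_thr)
        inside = _NORM.cdf(z_thr) - _NORM.cdf(z_thr - dz)
    else:
        tail_mass = _NORM.sf(z_thr)
        inside = _NORM.sf(z_thr) - _NORM.sf(z_thr + dz)
    if tail_mass <= 0.0:
        raise ValueError("threshold implies zero prevalence")
    return float(inside / tail_mass)


def rrr_dichotomized(spec: TraitThresholdSpec, n: int) -> RiskResult:
    """Risk reduction for the dichotomized trait under LRP with n embryos.

    Selecting the embryo with the most favorable trait PRS (lowest for a
    lower-tail disease, highest for an upper-tail one) is, by the
    reflection symmetry of the normal model, identical to lowest-risk
    prioritization on a disease with prevalence
    :func:`implied_prevalence` and PRS variance ``r2_trait``.
    """
    K = implied_prevalence(spec)
    scenario = ScreeningScenario(K=K, r2_ps=spec.r2_trait, n=n, strategy=Strategy.LRP)
    return risk_metrics(K, risk_lrp(scenario))
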