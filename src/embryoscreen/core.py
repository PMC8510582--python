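"""Core domain types and liability-scale arithmetic.

The framework models disease risk with the classical liability threshold
model: every individual carries a latent liability ``y ~ N(0, 1)`` and is
affected iff ``y > z_K``, where ``z_K`` is the upper ``K``-quantile of the
standard normal and ``K`` is the population prevalence.  A polygenic risk
score (PRS) explains a fraction ``r2_ps`` of the liability variance.  For a
batch of ``n`` IVF embryos of one couple, scores decompose as
``s_i = c + x_i`` with the shared (mid-parental) component
``c ~ N(0, r2_ps/2)`` and embryo-specific components
``x_i ~ N(0, r2_ps/2)``; the liability of each embryo is ``y_i = s_i + e_i``
with residual ``e_i ~ N(0, 1 - r2_ps)``.

Everything downstream (analytic quadrature, Monte Carlo, the genome-level
simulator) consumes the small value types defined here.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats


class Strategy(str, enum.Enum):
    """Embryo selection strategy.

    LRP
        Lowest-risk prioritization: implant the embryo with the minimum PRS.
    HRE
        High-risk exclusion: implant a random embryo whose PRS lies below
        the population top-``q`` cutoff; if every embryo is high-risk,
        implant a random embryo.
    HRE_FALLBACK_LOWEST
        As HRE, but when every embryo is high-risk the lowest-PRS embryo is
        implanted.  At ``q = 1`` this variant coincides with LRP.
    """

    LRP = "LRP"
    HRE = "HRE"
    HRE_FALLBACK_LOWEST = "HRE_FALLBACK_LOWEST"


class ParentalStatus(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


def liability_threshold(K: float) -> float:
    """Return ``z_K``, the liability threshold for prevalence ``K``.

    ``z_K`` is the ``(1-K)``-quantile of the standard normal: the upper-tail
    mass above it equals ``K``.

    Raises
    ------
    ValueError
        If ``K`` is not strictly inside ``(0, 1)``.
    """
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence K must lie in (0, 1); got {K}")
    return float(stats.norm.isf(K))


@dataclass(frozen=True)
class ScreeningScenario:
    """Parameter bundle driving every risk calculator.

    Parameters
    ----------
    K : float
        Disease prevalence, in (0, 1).
    r2_ps : float
        Fraction of liability variance explained by the PRS, in [0, 1).
    n : int
        Number of viable embryos in the batch, >= 1.
    strategy : Strategy
        Selection strategy.
    q : float, optional
        High-risk fraction: embryos in the population top-``q`` of the PRS
        distribution are flagged.  Required for the HRE strategies and
        ignored under LRP.
    """

    K: float
    r2_ps: float
    n: int
    strategy: Strategy = Strategy.LRP
    q: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"K must lie in (0, 1); got {self.K}")
        if not 0.0 <= self.r2_ps < 1.0:
            raise ValueError(f"r2_ps must lie in [0, 1); got {self.r2_ps}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be an integer >= 1; got {self.n}")
        object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "strategy", Strategy(self.strategy))
        if self.strategy is Strategy.LRP:
            object.__setattr__(self, "q", None)
        else:
            if self.q is None:
                raise ValueError(f"strategy {self.strategy.value} requires q")
            if not 0.0 <= self.q <= 1.0:
                raise ValueError(f"q must lie in [0, 1]; got {self.q}")

    @property
    def z_K(self) -> float:
        return liability_threshold(self.K)

    @property
    def sigma_shared(self) -> float:
        """SD of the shared (mid-parental) score component c."""
        return math.sqrt(self.r2_ps / 2.0)

    @property
    def sigma_specific(self) -> float:
        """SD of the embryo-specific score component x_i."""
        return math.sqrt(self.r2_ps / 2.0)

    @property
    def sigma_residual(self) -> float:
        """SD of the non-score liability residual e."""
        return math.sqrt(1.0 - self.r2_ps)

    @property
    def score_threshold(self) -> float:
        """Population PRS value at the top-``q`` cutoff, ``z_q * sqrt(r2_ps)``.

        Only meaningful for the HRE strategies.
        """
        if self.q is None:
            raise ValueError("score_threshold is defined only when q is set")
        if self.q <= 0.0:
            return math.inf
        if self.q >= 1.0:
            return -math.inf
        return float(stats.norm.isf(self.q)) * math.sqrt(self.r2_ps)


@dataclass(frozen=True)
class CoupleContext:
    """Parental conditioning information.

    ``c`` is the mean parental PRS on the liability scale (population mean
    zero).  ``h2`` is the narrow-sense liability heritability, needed only
    when conditioning on parental disease status.
    """

    c: Optional[float] = None
    h2: Optional[float] = None
    status_parent1: ParentalStatus = ParentalStatus.UNKNOWN
    status_parent2: ParentalStatus = ParentalStatus.UNKNOWN

    def __post_init__(self) -> None:
        if self.h2 is not None and not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must lie in [0, 1]; got {self.h2}")
        object.__setattr__(
            self, "status_parent1", ParentalStatus(self.status_parent1)
        )
        object.__setattr__(
            self, "status_parent2", ParentalStatus(self.status_parent2)
        )

    def validate_against(self, scenario: ScreeningScenario) -> None:
        if self.h2 is not None and self.h2 < scenario.r2_ps:
            raise ValueError(
                "h2 must be >= r2_ps (the score variance cannot exceed the "
                f"total genetic variance); got h2={self.h2}, "
                f"r2_ps={scenario.r2_ps}"
            )


def percentile_to_c(
    percentile_parent1: float, percentile_parent2: float, r2_ps: float
) -> float:
    """Convert parental PRS population percentiles to the shared component c.

    Each parent's PRS is read off as the given lower-tail quantile of the
    population score distribution ``N(0, r2_ps)``; ``c`` is the mean of the
    two parental scores.
    """
    for p in (percentile_parent1, percentile_parent2):
        if not 0.0 < p < 1.0:
            raise ValueError(f"percentiles must lie in (0, 1); got {p}")
    if r2_ps < 0:
        raise ValueError("r2_ps must be non-negative")
    if r2_ps == 0.0:
        warnings.warn(
            "r2_ps = 0: the PRS distribution is degenerate, c = 0",
            stacklevel=2,
        )
        return 0.0
    sd = math.sqrt(r2_ps)
    prs1 = sd * stats.norm.ppf(percentile_parent1)
    prs2 = sd * stats.norm.ppf(percentile_parent2)
    return float((prs1 + prs2) / 2.0)


@dataclass(frozen=True)
class RiskResult:
    """Disease probability of the implanted embryo plus reduction metrics.

    ``rrr = 1 - p_disease / p_baseline`` (relative risk reduction) and
    ``arr = p_baseline - p_disease`` (absolute risk reduction), where the
    baseline is the risk of a randomly selected embryo under the same
    conditioning.  ``mc_se``/``mc_se_baseline`` carry binomial standard
    errors for Monte-Carlo estimates and are ``None`` for analytic results.
    """

    p_disease: float
    p_baseline: float
    rrr: float
    arr: float
    mc_se: Optional[float] = None
    mc_se_baseline: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "p_disease": self.p_disease,
            "p_baseline": self.p_baseline,
            "rrr": self.rrr,
            "arr": self.arr,
            "mc_se": self.mc_se,
            "mc_se_baseline": self.mc_se_baseline,
        }


def risk_metrics(
    p_baseline: float,
    p_disease: float,
    mc_se: Optional[float] = None,
    mc_se_baseline: Optional[float] = None,
) -> RiskResult:
    """Build a :class:`RiskResult` from baseline and selected-embryo risks."""
    for p in (p_baseline, p_disease):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probabilities must lie in [0, 1]; got {p}")
    if p_baseline == 0.0:
        raise ZeroDivisionError(
            "relative risk reduction is undefined for a zero baseline risk"
        )
    rrr = 1.0 - p_disease / p_baseline
    arr = p_baseline - p_disease
    return RiskResult(
        p_disease=float(p_disease),
        p_baseline=float(p_baseline),
        rrr=float(rrr),
        arr=float(arr),
        mc_se=mc_se,
        mc_se_baseline=mc_se_baseline,
    )


@dataclass
class EmbryoBatch:
    """One couple's simulated embryos (a Monte-Carlo record).

    Invariants: ``s = x + c`` and ``y = s + e`` elementwise; ``affected_i``
    iff ``y_i > z_K``; ``selected`` indexes the implanted embryo.
    """

    c: float
    x: np.ndarray
    s: np.ndarray = field(repr=False)
    e: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    affected: np.ndarray = field(repr=False)
    selected: int = 0
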