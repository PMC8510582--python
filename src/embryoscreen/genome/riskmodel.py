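"""Score-to-risk models with case-control ascertainment correction."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError


@dataclass(frozen=True)
class LogisticRiskModel:
    """Logistic model of disease status on PRS, adjusted to the population.

    ``intercept_sample`` is the maximum-likelihood intercept in the
    ascertained sample; ``intercept_adjusted`` subtracts the log-odds of
    the sampling distortion,
    ``log[(P/(1-P)) * ((1-K)/K)]`` with ``P`` the sample case fraction,
    so that predictions are on the population scale.
    """

    slope: float
    intercept_sample: float
    intercept_adjusted: float
    K: float
    sample_case_fraction: float

    def predict(self, scores) -> np.ndarray:
        """Population-scale disease probability for each score."""
        eta = self.intercept_adjusted + self.slope * np.asarray(scores, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_sample_scale(self, scores) -> np.ndarray:
        eta = self.intercept_sample + self.slope * np.asarray(scores, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic_risk(scores, statuses, K: float) -> LogisticRiskModel:
    """Maximum-likelihood logistic regression of status on score.

    No covariates beyond the score.  Raises on perfect separation, which
    would send the slope to infinity.
    """
    scores = np.asarray(scores, dtype=float)
    statuses = np.asarray(statuses).astype(int)
    if not 0.0 < K < 1.0:
        raise ValueError("K must lie in (0, 1)")
    if statuses.min() == statuses.max():
        raise ValueError("both cases and controls are required")
    if scores[statuses == 1].min() > scores[statuses == 0].max() or (
        scores[statuses == 1].max() < scores[statuses == 0].min()
    ):
        raise ValueError("perfect separation: scores fully split the classes")
    X = sm.add_constant(scores)
    try:
        fit = sm.Logit(statuses, X).fit(disp=0)
    except PerfectSeparationError as err:  # pragma: no cover - guarded above
        raise ValueError("perfect separation in logistic fit") from err
    intercept, slope = fit.params
    P = statuses.mean()
    adjustment = math.log((P / (1.0 - P)) * ((1.0 - K) / K))
    return LogisticRiskModel(
        slope=float(slope),
        intercept_sample=float(intercept),
        intercept_adjusted=float(intercept - adjustment),
        K=K,
        sample_case_fraction=float(P),
    )


def calibrate_score_percentiles(scores, statuses, K: float) -> Tuple[float, float]:
    """Prevalence-weighted normal approximation of the population PRS.

    Cases receive total weight ``K`` and controls ``1 - K``, undoing the
    case oversampling; returns the weighted mean and weighted variance of
    the reference normal used for population score percentiles.
    """
    scores = np.asarray(scores, dtype=float)
    statuses = np.asarray(statuses).astype(bool)
    n_case = int(statuses.sum())
    n_ctrl = int((~statuses).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both cases and controls are required")
    w = np.where(statuses, K / n_case, (1.0 - K) / n_ctrl)
    mean = float(np.sum(w * scores))
    var = float(np.sum(w * (scores - mean) ** 2))
    if var <= 1e-14 * (1.0 + mean**2):
        raise ValueError("zero-variance scores cannot define percentiles")
    return mean, var


def score_percentile_threshold(mean: float, variance: float, q: float) -> float:
    """Score value at the population top-``q`` cutoff of the reference normal."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    return float(mean + math.sqrt(variance) * stats.norm.isf(q))


def observed_to_liability_r2(
    r2_observed: float, K: float, sample_case_fraction: float
) -> float:
    """Convert case-control observed-scale R2 to the liability scale.

    Uses the ascertainment-corrected transformation for a 0/1 status
    regressed on a score in a sample with case fraction ``P`` when the
    population prevalence is ``K``:

    ``R2_liab = R2_obs * C / (1 + R2_obs * theta * C)``

    with ``C = K^2 (1-K)^2 / (z^2 P (1-P))``,
    ``theta = m (P-K)/(1-K) * (m (P-K)/(1-K) - t)``, where ``t`` is the
    liability threshold, ``z`` the standard normal density at ``t`` and
    ``m = z/K`` the mean liability of cases.  With no ascertainment
    (``P = K``) this reduces to the classical ``R2_obs * K(1-K)/z^2``.
    """
    if not 0.0 <= r2_observed < 1.0:
        raise ValueError("r2_observed must lie in [0, 1)")
    if not 0.0 < K < 1.0 or not 0.0 < sample_case_fraction < 1.0:
        raise ValueError("K and sample_case_fraction must lie in (0, 1)")
    if r2_observed == 0.0:
        return 0.0
    P = sample_case_fraction
    t = stats.norm.isf(K)
    z = stats.norm.pdf(t)
    m = z / K
    C = (K * (1.0 - K)) ** 2 / (z**2 * P * (1.0 - P))
    theta = m * (P - K) / (1.0 - K) * (m * (P - K) / (1.0 - K) - t)
    out = r2_observed * C / (1.0 + r2_observed * theta * C)
    if not 0.0 < out < 1.0:
        raise ValueError(
            f"liability-scale r2 {out:.4g} outside (0, 1); "
            "check the inputs for misuse"
        )
    return float(out)
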