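"""Deterministic risk calculators for embryo selection strategies.

All quantities are derived from the generative model in :mod:`.core`:
conditional on the shared component ``c``, embryo scores are
``s_i = c + x_i`` with ``x_i ~ N(0, r2/2)`` iid, and the selected embryo's
liability adds an independent residual ``e ~ N(0, 1 - r2)``.  Disease means
liability above ``z_K``.

Two reductions keep every computation a one- or two-dimensional quadrature:

* Integrating a normal upper-tail ``P(x + E > a)`` over ``E ~ N(0, v)``
  collapses into a single normal tail with variance inflated by ``v``.
  In particular, averaging the conditional-on-``c`` LRP risk over
  ``c ~ N(0, r2/2)`` simply replaces the residual variance ``1 - r2`` by
  ``1 - r2/2``, so the unconditional LRP risk is a single integral over the
  minimum-score order statistic.
* The high-risk-exclusion mixture is written without dividing by truncation
  masses: with ``p = P(x < tau)`` the chance a single embryo is unflagged,

  ``P_HRE(disease | c) = a(p) * I_low + (1-p)^(n-1) * I_high``,

  where ``a(p) = [1 - (1-p)^n] / p`` (the expected inverse inclusion
  weight, evaluated stably), ``I_low``/``I_high`` are plain integrals of
  ``phi(x) * P(disease | x, c)`` below/above the truncation point ``tau``,
  and the fallback-to-lowest variant replaces the second term by the
  minimum over the all-flagged batch,
  ``n * Int_{tau}^{inf} phi(x) [1 - Phi(x/sd)]^{n-1} P(disease|x,c) dx``.

Gauss-Legendre quadrature with a doubled-resolution consistency check is
used throughout; integrands are smooth with Gaussian decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .core import (
    CoupleContext,
    ParentalStatus,
    RiskResult,
    ScreeningScenario,
    Strategy,
    liability_threshold,
    risk_metrics,
)

_NORM = stats.norm
# half-width of integration ranges, in SDs of the integrated variable
_RANGE_SD = 8.5


class NumericalIntegrationError(RuntimeError):
    """Raised when the quadrature consistency check fails."""


@lru_cache(maxsize=32)
def _leggauss(m: int) -> Tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(m)
    return x, w


def _segment_nodes(lo: np.ndarray, hi: np.ndarray, m: int):
    """Affinely map m-point Gauss-Legendre nodes onto [lo, hi] (broadcast).

    Returns nodes and weights with a trailing quadrature axis.
    """
    x, w = _leggauss(m)
    lo = np.asarray(lo, dtype=float)[..., None]
    hi = np.asarray(hi, dtype=float)[..., None]
    half = (hi - lo) / 2.0
    nodes = (hi + lo) / 2.0 + half * x
    weights = half * w
    return nodes, weights


def _inclusion_factor(p: np.ndarray, n: int) -> np.ndarray:
    """a(p) = [1 - (1-p)^n] / p, stable as p -> 0 (limit n)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, float(n))
    mask = p > 1e-12
    pm = p[mask]
    with np.errstate(divide="ignore"):  # p = 1 -> log1p(-1) = -inf, a(1) = 1
        out[mask] = -np.expm1(n * np.log1p(-pm)) / pm
    return out


def _lrp_min_tail(
    n: int, sigma_x: float, shift: np.ndarray, sigma_out: float, m: int = 200
) -> np.ndarray:
    """E over the minimum of n iid N(0, sigma_x^2) of the residual tail.

    Computes ``Int n phi(x/sx)/sx [1-Phi(x/sx)]^(n-1)
    * Phibar((shift - x)/sigma_out) dx`` vectorized over ``shift``.
    """
    shift = np.asarray(shift, dtype=float)
    if sigma_x == 0.0:
        return _NORM.sf(shift / sigma_out)
    lo = np.full(shift.shape, -_RANGE_SD * sigma_x)
    hi = np.full(shift.shape, _RANGE_SD * sigma_x)
    x, w = _segment_nodes(lo, hi, m)
    z = x / sigma_x
    dens = n * _NORM.pdf(z) / sigma_x * _NORM.sf(z) ** (n - 1)
    tail = _NORM.sf((shift[..., None] - x) / sigma_out)
    return np.einsum("...k,...k->...", w, dens * tail)


def _hre_selected_tail(
    n: int,
    sigma_x: float,
    tau: np.ndarray,
    shift: np.ndarray,
    sigma_out: float,
    fallback_lowest: bool,
    m: int = 200,
) -> np.ndarray:
    """Disease probability of the HRE-selected embryo, given tau and shift.

    ``tau`` is the embryo-specific-score cutoff (score threshold minus c);
    ``shift`` is the liability threshold minus all conditioned-on liability
    components; ``sigma_out`` is the SD of the remaining independent
    liability noise.  Broadcasts over tau/shift.
    """
    tau, shift = np.broadcast_arrays(
        np.asarray(tau, dtype=float), np.asarray(shift, dtype=float)
    )
    if sigma_x == 0.0:
        # selection is uninformative: every embryo has x = 0
        return _NORM.sf(shift / sigma_out)
    lo = -_RANGE_SD * sigma_x
    hi = _RANGE_SD * sigma_x
    tau_c = np.clip(tau, lo, hi)
    p_low = _NORM.cdf(tau / sigma_x)

    def _integral(a, b, min_of_truncated: bool):
        x, w = _segment_nodes(a, b, m)
        z = x / sigma_x
        dens = _NORM.pdf(z) / sigma_x
        if min_of_truncated:
            dens = n * dens * _NORM.sf(z) ** (n - 1)
        tail = _NORM.sf((shift[..., None] - x) / sigma_out)
        return np.einsum("...k,...k->...", w, dens * tail)

    i_low = _integral(np.full_like(tau_c, lo), tau_c, False)
    term_low = _inclusion_factor(p_low, n) * i_low
    if fallback_lowest:
        term_high = _integral(tau_c, np.full_like(tau_c, hi), True)
    else:
        i_high = _integral(tau_c, np.full_like(tau_c, hi), False)
        term_high = (1.0 - p_low) ** (n - 1) * i_high
    return term_low + term_high


def risk_random_given_c(scenario: ScreeningScenario, c) -> np.ndarray | float:
    """Disease probability of a randomly selected embryo given ``c``.

    Closed form: score given c is ``N(c, r2/2)`` and the residual is
    ``N(0, 1-r2)``, so the liability is ``N(c, 1 - r2/2)``.
    """
    scale = math.sqrt(1.0 - scenario.r2_ps / 2.0)
    out = _NORM.sf((scenario.z_K - np.asarray(c, dtype=float)) / scale)
    return float(out) if np.isscalar(c) else out


def _selected_risk_given_c(
    scenario: ScreeningScenario, c: np.ndarray, m: int = 200
) -> np.ndarray:
    """P(disease | c) of the strategy-selected embryo (vectorized over c)."""
    c = np.asarray(c, dtype=float)
    shift = scenario.z_K - c
    sx = scenario.sigma_specific
    se = scenario.sigma_residual
    if scenario.strategy is Strategy.LRP:
        return _lrp_min_tail(scenario.n, sx, shift, se, m=m)
    tau = scenario.score_threshold - c
    return _hre_selected_tail(
        scenario.n,
        sx,
        tau,
        shift,
        se,
        fallback_lowest=scenario.strategy is Strategy.HRE_FALLBACK_LOWEST,
        m=m,
    )


def risk_given_c(scenario: ScreeningScenario, c: float) -> RiskResult:
    """Risk of the strategy-selected embryo conditional on the couple's c.

    The baseline is the risk of a randomly selected embryo of the same
    couple (:func:`risk_random_given_c`).
    """
    p_sel = float(_selected_risk_given_c(scenario, np.asarray([c]))[0])
    p_base = float(risk_random_given_c(scenario, c))
    return risk_metrics(p_base, p_sel)


def _integrate_over_c(scenario: ScreeningScenario, m: int) -> float:
    """Average the conditional selected-embryo risk over c ~ N(0, r2/2)."""
    sc = scenario.sigma_shared
    if sc == 0.0:
        return float(_selected_risk_given_c(scenario, np.zeros(1), m=m)[0])
    nodes, w = _segment_nodes(-_RANGE_SD * sc, _RANGE_SD * sc, m)
    dens = _NORM.pdf(nodes / sc) / sc
    vals = _selected_risk_given_c(scenario, nodes, m=m)
    return float(np.sum(w * dens * vals))


def _checked(coarse: float, fine: float, what: str, tol: float = 1e-8) -> float:
    if not math.isfinite(fine) or abs(fine - coarse) > tol:
        raise NumericalIntegrationError(
            f"quadrature for {what} did not converge "
            f"(estimates {coarse!r} vs {fine!r})"
        )
    return fine


def risk_lrp(scenario: ScreeningScenario) -> float:
    """Unconditional disease probability under lowest-risk prioritization.

    Averaging over ``c`` collapses analytically: the selected score is
    ``c + min_i x_i`` and ``c`` simply joins the residual, giving a single
    integral over the order statistic with outer SD ``sqrt(1 - r2/2)``.
    """
    scn = ScreeningScenario(scenario.K, scenario.r2_ps, scenario.n, Strategy.LRP)
    sigma_out = math.sqrt(1.0 - scn.r2_ps / 2.0)
    shift = np.asarray([scn.z_K])

    def _eval(m):
        return float(
            _lrp_min_tail(scn.n, scn.sigma_specific, shift, sigma_out, m=m)[0]
        )

    return _checked(_eval(200), _eval(400), "risk_lrp")


def risk_lrp_via_c_integration(scenario: ScreeningScenario, m: int = 200) -> float:
    """LRP risk by explicit two-level quadrature over c then x.

    Kept as an independent route for cross-validating :func:`risk_lrp`.
    """
    scn = ScreeningScenario(scenario.K, scenario.r2_ps, scenario.n, Strategy.LRP)
    return _integrate_over_c(scn, m)


def risk_hre(scenario: ScreeningScenario) -> float:
    """Unconditional disease probability under high-risk exclusion."""
    if scenario.q is None:
        raise ValueError("HRE requires the exclusion fraction q")
    scn = ScreeningScenario(
        scenario.K, scenario.r2_ps, scenario.n, Strategy.HRE, scenario.q
    )
    return _checked(
        _integrate_over_c(scn, 200), _integrate_over_c(scn, 400), "risk_hre"
    )


def risk_hre_fallback_lowest(scenario: ScreeningScenario) -> float:
    """HRE risk when an all-high-risk batch falls back to the lowest score."""
    if scenario.q is None:
        raise ValueError("HRE_FALLBACK_LOWEST requires the exclusion fraction q")
    scn = ScreeningScenario(
        scenario.K,
        scenario.r2_ps,
        scenario.n,
        Strategy.HRE_FALLBACK_LOWEST,
        scenario.q,
    )
    return _checked(
        _integrate_over_c(scn, 200),
        _integrate_over_c(scn, 400),
        "risk_hre_fallback_lowest",
    )


def risk_selected(scenario: ScreeningScenario) -> float:
    """Unconditional selected-embryo risk for the scenario's strategy."""
    if scenario.strategy is Strategy.LRP:
        return risk_lrp(scenario)
    if scenario.strategy is Strategy.HRE:
        return risk_hre(scenario)
    return risk_hre_fallback_lowest(scenario)


def risk_reduction(scenario: ScreeningScenario) -> RiskResult:
    """Population-level risk reduction (baseline = prevalence K)."""
    return risk_metrics(scenario.K, risk_selected(scenario))


# ---------------------------------------------------------------------------
# per-couple RRR distribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerCoupleCurve:
    """Per-couple RRR evaluated on an equal-mass grid of c quantiles."""

    c_grid: np.ndarray
    pcrrr: np.ndarray
    weights: np.ndarray
    p_selected: np.ndarray
    p_random: np.ndarray

    def mean(self) -> float:
        return float(np.sum(self.weights * self.pcrrr))

    def quantile(self, q) -> np.ndarray:
        order = np.argsort(self.pcrrr)
        cdf = np.cumsum(self.weights[order])
        return np.interp(np.asarray(q, dtype=float), cdf, self.pcrrr[order])


def pcrrr_distribution(
    scenario: ScreeningScenario, n_quantiles: int = 10_000
) -> PerCoupleCurve:
    """Distribution of the per-couple RRR over all couples.

    The grid holds the mid-quantile values ``(i - 0.5)/m`` of the shared
    component ``c ~ N(0, r2/2)``, so every grid point carries equal
    probability mass and the weighted conditional risks reproduce the
    unconditional ones.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    probs = (np.arange(n_quantiles) + 0.5) / n_quantiles
    c_grid = scenario.sigma_shared * _NORM.ppf(probs)
    p_sel = _selected_risk_given_c(scenario, c_grid)
    p_rand = np.asarray(risk_random_given_c(scenario, c_grid))
    pcrrr = 1.0 - p_sel / p_rand
    weights = np.full(n_quantiles, 1.0 / n_quantiles)
    return PerCoupleCurve(c_grid, pcrrr, weights, p_sel, p_rand)


# ---------------------------------------------------------------------------
# conditioning on parental disease status
# ---------------------------------------------------------------------------


def _parental_posterior_nodes(
    status: ParentalStatus, h2: float, z_K: float, m: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes/weights for a parent's genetic liability u ~ N(0, h2).

    The parent is affected iff ``u + env > z_K`` with
    ``env ~ N(0, 1 - h2)``, so the posterior density of u is the prior
    times the matching environmental tail mass, renormalized.
    """
    h = math.sqrt(h2)
    nodes, w = _segment_nodes(-_RANGE_SD * h, _RANGE_SD * h, m)
    prior = _NORM.pdf(nodes / h) / h
    se = math.sqrt(1.0 - h2)
    if status is ParentalStatus.AFFECTED:
        like = _NORM.sf((z_K - nodes) / se) if se > 0 else (nodes > z_K) * 1.0
    elif status is ParentalStatus.UNAFFECTED:
        like = _NORM.cdf((z_K - nodes) / se) if se > 0 else (nodes <= z_K) * 1.0
    else:  # unknown: marginalize
        like = np.ones_like(nodes)
    weights = w * prior * like
    total = weights.sum()
    if total <= 0:
        raise NumericalIntegrationError(
            "parental posterior has vanishing mass; check h2 and status"
        )
    return nodes, weights / total


def risk_given_parental_status(
    scenario: ScreeningScenario,
    couple: CoupleContext,
    m_parent: int = 96,
    m_c: int = 48,
    m_x: int = 160,
) -> RiskResult:
    """Risk of the selected embryo conditional on parental disease status.

    Each parent's liability splits into score ``s ~ N(0, r2)``, non-score
    genetic ``g ~ N(0, h2 - r2)`` and environment ``~ N(0, 1 - h2)``; only
    the genetic part ``u = s + g`` is transmitted.  The offspring receives
    the mid-parental score ``c`` and mid-parental non-score component, plus
    segregation noise with half the parental variances, and an independent
    environment.  The computation integrates the conditional embryo risk
    over the posterior of ``(u_1, u_2)`` given the statuses; for the HRE
    strategies (whose selection cutoff depends on ``c`` rather than on the
    total transmitted component) an inner integral over ``c`` given
    ``t = (u_1 + u_2)/2`` is added, using the jointly-normal conditional
    ``c | t ~ N(t r2/h2, r2 (h2-r2) / (2 h2))``.
    """
    if couple.h2 is None:
        raise ValueError("parental-status conditioning requires h2")
    couple.validate_against(scenario)
    h2 = couple.h2
    r2 = scenario.r2_ps
    z_K = scenario.z_K
    n = scenario.n

    if h2 == 0.0:
        # no heritable signal: status is uninformative
        res = risk_reduction(scenario)
        return res

    u1, w1 = _parental_posterior_nodes(couple.status_parent1, h2, z_K, m_parent)
    u2, w2 = _parental_posterior_nodes(couple.status_parent2, h2, z_K, m_parent)
    t = (u1[:, None] + u2[None, :]) / 2.0  # transmitted mid-parental component
    w = w1[:, None] * w2[None, :]

    # segregation + environment variance left after conditioning on t
    # (score seg r2/2 enters selection; non-score seg (h2-r2)/2 + env 1-h2)
    var_rand = 1.0 - h2 / 2.0
    p_base = float(np.sum(w * _NORM.sf((z_K - t) / math.sqrt(var_rand))))

    sigma_rem = math.sqrt(1.0 - (h2 + r2) / 2.0)
    sx = scenario.sigma_specific

    if scenario.strategy is Strategy.LRP:
        # selection acts on within-batch x only; independent of (c, t)
        p_sel_grid = _lrp_min_tail(n, sx, z_K - t, sigma_rem, m=m_x)
        p_sel = float(np.sum(w * p_sel_grid))
    else:
        if r2 == 0.0:
            p_sel = p_base
        else:
            s_thr = scenario.score_threshold
            mu_c = t * (r2 / h2)
            var_c = r2 * (h2 - r2) / (2.0 * h2)
            fallback = scenario.strategy is Strategy.HRE_FALLBACK_LOWEST
            if var_c == 0.0:
                p_sel_grid = _hre_selected_tail(
                    n, sx, s_thr - mu_c, z_K - t, sigma_rem, fallback, m=m_x
                )
                p_sel = float(np.sum(w * p_sel_grid))
            else:
                sd_c = math.sqrt(var_c)
                # row-wise over the u1 grid to bound the broadcast size
                p_sel = 0.0
                for i in range(t.shape[0]):
                    mu_i = mu_c[i]
                    c_nodes, c_w = _segment_nodes(
                        mu_i - _RANGE_SD * sd_c, mu_i + _RANGE_SD * sd_c, m_c
                    )
                    c_dens = _NORM.pdf((c_nodes - mu_i[..., None]) / sd_c) / sd_c
                    p_grid = _hre_selected_tail(
                        n,
                        sx,
                        s_thr - c_nodes,
                        (z_K - t[i])[..., None],
                        sigma_rem,
                        fallback,
                        m=m_x,
                    )
                    p_row = np.sum(c_w * c_dens * p_grid, axis=-1)
                    p_sel += float(np.sum(w[i] * p_row))

    return risk_metrics(p_base, p_sel)
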