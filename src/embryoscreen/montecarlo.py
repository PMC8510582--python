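"""Vectorized stochastic simulation of embryo batches and selection.

This module is the stochastic counterpart (and independent oracle) of
:mod:`.analytic`.  Batches are simulated exactly as the generative model
states: shared component ``c ~ N(0, r2/2)``, embryo-specific
``x_i ~ N(0, r2/2)``, scores ``s_i = c + x_i``, liabilities
``y_i = s_i + e_i`` with ``e_i ~ N(0, 1 - r2)``, affected iff
``y_i > z_K``.  All randomness flows from a single ``numpy`` Generator
seeded explicitly; fixed seed means bit-identical output.

Simulations are chunked so that no more than ~10^7 scalar draws are alive
at once, keeping memory flat for millions of batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import (
    CoupleContext,
    ParentalStatus,
    RiskResult,
    ScreeningScenario,
    Strategy,
    liability_threshold,
    risk_metrics,
)

_CHUNK_SCALARS = 10_000_000


def _select_indices(
    rng: np.random.Generator,
    s: np.ndarray,
    strategy: Strategy,
    score_threshold: float,
) -> np.ndarray:
    """Return the index of the implanted embryo for each batch (rows of s)."""
    n_batches, n = s.shape
    if strategy is Strategy.LRP:
        return np.argmin(s, axis=1)
    low = s < score_threshold
    # random uniform keys; unflagged embryos get an offset so that the
    # minimum key is a uniformly random unflagged embryo when any exists,
    # and a uniformly random embryo otherwise
    keys = rng.random((n_batches, n)) - 10.0 * low
    sel = np.argmin(keys, axis=1)
    if strategy is Strategy.HRE_FALLBACK_LOWEST:
        none_low = ~low.any(axis=1)
        if none_low.any():
            sel[none_low] = np.argmin(s[none_low], axis=1)
    return sel


def _binomial_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1.0 - p), 0.0) / n)


def _sample_couples_by_status(
    rng: np.random.Generator,
    n_needed: int,
    scenario: ScreeningScenario,
    couple: CoupleContext,
    max_attempts: int = 2000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Rejection-sample (c, d) pairs matching the parental statuses.

    Each parent draws score ``s ~ N(0, r2)``, non-score genetic
    ``g ~ N(0, h2 - r2)`` and environment ``~ N(0, 1 - h2)``; the parent is
    affected iff the sum exceeds ``z_K``.  Returns the mid-parental score
    ``c`` and mid-parental non-score genetic component ``d`` of accepted
    couples.
    """
    if couple.h2 is None:
        raise ValueError("status conditioning requires h2")
    couple.validate_against(scenario)
    h2, r2, z_K = couple.h2, scenario.r2_ps, scenario.z_K
    targets = (couple.status_parent1, couple.status_parent2)
    if any(t is ParentalStatus.UNKNOWN for t in targets):
        raise ValueError(
            "rejection sampling requires definite statuses; use the "
            "analytic route to marginalize an unknown parent"
        )
    want_aff = np.array([t is ParentalStatus.AFFECTED for t in targets])
    acc_rate_floor = 1e-5

    out_c = np.empty(n_needed)
    out_d = np.empty(n_needed)
    filled = 0
    drawn = 0
    batch = max(10_000, min(n_needed * 4, 2_000_000))
    for _ in range(max_attempts):
        s = rng.normal(0.0, math.sqrt(r2), (batch, 2)) if r2 > 0 else np.zeros((batch, 2))
        g = (
            rng.normal(0.0, math.sqrt(h2 - r2), (batch, 2))
            if h2 > r2
            else np.zeros((batch, 2))
        )
        env = (
            rng.normal(0.0, math.sqrt(1.0 - h2), (batch, 2))
            if h2 < 1
            else np.zeros((batch, 2))
        )
        affected = (s + g + env) > z_K
        ok = (affected == want_aff).all(axis=1)
        drawn += batch
        idx = np.nonzero(ok)[0]
        take = min(idx.size, n_needed - filled)
        if take:
            out_c[filled : filled + take] = s[idx[:take]].mean(axis=1)
            out_d[filled : filled + take] = g[idx[:take]].mean(axis=1)
            filled += take
        if filled >= n_needed:
            return out_c, out_d
        if drawn >= 10 * batch and filled / drawn < acc_rate_floor:
            raise RuntimeError(
                f"acceptance rate {filled / drawn:.2e} below {acc_rate_floor}; "
                "use the analytic parental-status route instead"
            )
    raise RuntimeError("failed to sample enough couples matching the statuses")


def sample_batches(
    scenario: ScreeningScenario, n_batches: int, seed: int
) -> "BatchArrays":
    """Draw full embryo batches as arrays (one row per couple).

    Exposes every intermediate of the generative model — shared component,
    embryo-specific components, scores, residuals, liabilities, affection
    flags and the selected index — for inspection and diagnostics.
    """
    rng = np.random.default_rng(seed)
    n = scenario.n
    c = rng.normal(0.0, scenario.sigma_shared, n_batches)
    x = rng.normal(0.0, scenario.sigma_specific, (n_batches, n))
    s = x + c[:, None]
    e = rng.normal(0.0, scenario.sigma_residual, (n_batches, n))
    y = s + e
    affected = y > scenario.z_K
    thr = (
        scenario.score_threshold
        if scenario.strategy is not Strategy.LRP
        else math.nan
    )
    selected = _select_indices(rng, s, scenario.strategy, thr)
    return BatchArrays(c=c, x=x, s=s, e=e, y=y, affected=affected, selected=selected)


@dataclass(frozen=True)
class BatchArrays:
    """Column-oriented stack of :class:`~embryoscreen.core.EmbryoBatch`."""

    c: np.ndarray
    x: np.ndarray
    s: np.ndarray
    e: np.ndarray
    y: np.ndarray
    affected: np.ndarray
    selected: np.ndarray

    def __len__(self) -> int:
        return self.c.shape[0]

    def batch(self, i: int):
        from .core import EmbryoBatch

        return EmbryoBatch(
            c=float(self.c[i]),
            x=self.x[i],
            s=self.s[i],
            e=self.e[i],
            y=self.y[i],
            affected=self.affected[i],
            selected=int(self.selected[i]),
        )


def simulate_selection(
    scenario: ScreeningScenario,
    n_batches: int,
    seed: int,
    condition_c: Optional[float] = None,
    condition_status: Optional[CoupleContext] = None,
) -> RiskResult:
    """Simulate embryo batches and return the selected-embryo risk.

    The baseline arm selects the first embryo of every batch (identical in
    distribution to a uniformly random embryo) and receives its own
    independent residual draw.  Standard errors are binomial.

    ``condition_c`` fixes the shared component; ``condition_status``
    rejection-samples couples by parental disease status (which also makes
    the embryo inherit a mid-parental non-score genetic component).
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if condition_c is not None and condition_status is not None:
        raise ValueError("condition on either c or parental status, not both")
    rng = np.random.default_rng(seed)
    n = scenario.n
    z_K = scenario.z_K
    sig_x = scenario.sigma_specific
    thr = (
        scenario.score_threshold
        if scenario.strategy is not Strategy.LRP
        else math.nan
    )

    if condition_status is not None:
        h2 = condition_status.h2
        c_all, d_all = _sample_couples_by_status(
            rng, n_batches, scenario, condition_status
        )
        sig_seg = math.sqrt((h2 - scenario.r2_ps) / 2.0)  # non-score segregation
        sig_env = math.sqrt(1.0 - h2)
    else:
        c_all = d_all = None
        sig_seg = 0.0
        sig_env = scenario.sigma_residual

    chunk = max(1, _CHUNK_SCALARS // max(n, 1))
    aff_sel = 0
    aff_base = 0
    done = 0
    while done < n_batches:
        m = min(chunk, n_batches - done)
        if condition_status is not None:
            c = c_all[done : done + m]
            extra = d_all[done : done + m]
        elif condition_c is not None:
            c = np.full(m, float(condition_c))
            extra = 0.0
        else:
            c = rng.normal(0.0, scenario.sigma_shared, m)
            extra = 0.0
        x = rng.normal(0.0, sig_x, (m, n)) if sig_x > 0 else np.zeros((m, n))
        s = x + c[:, None]
        sel = _select_indices(rng, s, scenario.strategy, thr)
        rows = np.arange(m)

        def _liability(idx):
            g_seg = rng.normal(0.0, sig_seg, m) if sig_seg > 0 else 0.0
            env = rng.normal(0.0, sig_env, m) if sig_env > 0 else 0.0
            return s[rows, idx] + extra + g_seg + env

        aff_sel += int(np.sum(_liability(sel) > z_K))
        aff_base += int(np.sum(_liability(np.zeros(m, dtype=int)) > z_K))
        done += m

    p_sel = aff_sel / n_batches
    p_base = aff_base / n_batches
    return risk_metrics(
        p_base,
        p_sel,
        mc_se=_binomial_se(p_sel, n_batches),
        mc_se_baseline=_binomial_se(p_base, n_batches),
    )


# ---------------------------------------------------------------------------
# two-disease pleiotropy experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PleiotropyScenario:
    """Two diseases whose polygenic scores are genetically correlated.

    ``rho`` is the correlation between the two scores; the covariance
    ``rho * sqrt(r2_1 * r2_2)`` is split equally between the shared and
    embryo-specific components, mirroring the single-disease variance
    split.  Residual (environmental) liability components are independent
    across diseases: genetic correlation is the only coupling.
    """

    rho: float
    K1: float
    K2: float
    r2_1: float
    r2_2: float
    n: int
    n_couples: int
    seed: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1]; got {self.rho}")
        for K in (self.K1, self.K2):
            if not 0.0 < K < 1.0:
                raise ValueError(f"prevalence must lie in (0, 1); got {K}")
        for r2 in (self.r2_1, self.r2_2):
            if not 0.0 <= r2 < 1.0:
                raise ValueError(f"r2 must lie in [0, 1); got {r2}")
        if self.n < 1 or self.n_couples < 1:
            raise ValueError("n and n_couples must be >= 1")
        cov = self.rho * math.sqrt(self.r2_1 * self.r2_2)
        if cov**2 > self.r2_1 * self.r2_2 + 1e-12:
            raise ValueError("score covariance matrix is not PSD")

    @property
    def cholesky_half(self) -> np.ndarray:
        """Cholesky factor of the half-variance score covariance.

        Lower-triangular, so the target disease's draws do not depend on
        rho: with the same seed, the target-disease results are identical
        across rho values.
        """
        cov = 0.5 * np.array(
            [
                [self.r2_1, self.rho * math.sqrt(self.r2_1 * self.r2_2)],
                [self.rho * math.sqrt(self.r2_1 * self.r2_2), self.r2_2],
            ]
        )
        return np.linalg.cholesky(cov + 1e-300 * np.eye(2))


@dataclass(frozen=True)
class PleiotropyResult:
    rrr_target: float
    rri_correlated: float
    se_rrr_target: float
    se_rri_correlated: float
    p_target_selected: float
    p_target_random: float
    p_correlated_selected: float
    p_correlated_random: float


def simulate_pleiotropy(p: PleiotropyScenario) -> PleiotropyResult:
    """Risk change for a correlated disease under lowest-risk selection.

    Per couple, the embryo with the lowest *target-disease* PRS is
    implanted (LRP); the comparison arm implants the first (random)
    embryo of the same batch.  Returns the target-disease RRR and the
    correlated disease's relative risk *increase*
    (``P_selected / P_random - 1``), with delta-method standard errors.
    """
    rng = np.random.default_rng(p.seed)
    L = p.cholesky_half
    zK = np.array([liability_threshold(p.K1), liability_threshold(p.K2)])
    sig_e = np.sqrt([1.0 - p.r2_1, 1.0 - p.r2_2])

    chunk = max(1, _CHUNK_SCALARS // (4 * p.n))
    counts = np.zeros((2, 2), dtype=np.int64)  # [arm(sel,rand), disease]
    done = 0
    while done < p.n_couples:
        m = min(chunk, p.n_couples - done)
        c = rng.standard_normal((m, 2)) @ L.T
        x = rng.standard_normal((m, p.n, 2)) @ L.T
        s = x + c[:, None, :]
        sel = np.argmin(s[:, :, 0], axis=1)  # lowest target-disease PRS
        rows = np.arange(m)
        for arm, idx in enumerate((sel, np.zeros(m, dtype=int))):
            for d in range(2):
                e = rng.normal(0.0, sig_e[d], m)
                y = s[rows, idx, d] + e
                counts[arm, d] += int(np.sum(y > zK[d]))
        done += m

    probs = counts / p.n_couples
    (p1_sel, p2_sel), (p1_rand, p2_rand) = probs
    se = np.sqrt(probs * (1.0 - probs) / p.n_couples)
    rrr_target = 1.0 - p1_sel / p1_rand
    rri_correlated = p2_sel / p2_rand - 1.0
    # independent-arm delta method on the ratio
    se_ratio1 = (p1_sel / p1_rand) * math.sqrt(
        (se[0, 0] / p1_sel) ** 2 + (se[1, 0] / p1_rand) ** 2
    )
    se_ratio2 = (p2_sel / p2_rand) * math.sqrt(
        (se[0, 1] / p2_sel) ** 2 + (se[1, 1] / p2_rand) ** 2
    )
    return PleiotropyResult(
        rrr_target=float(rrr_target),
        rri_correlated=float(rri_correlated),
        se_rrr_target=float(se_ratio1),
        se_rri_correlated=float(se_ratio2),
        p_target_selected=float(p1_sel),
        p_target_random=float(p1_rand),
        p_correlated_selected=float(p2_sel),
        p_correlated_random=float(p2_rand),
    )
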