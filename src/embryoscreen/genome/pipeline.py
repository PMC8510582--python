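"""Virtual couples, empirical risk reduction, and model diagnostics."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from ..core import RiskResult, Strategy, risk_metrics
from .cohort import PhasedCohort
from .gmap import GeneticMap
from .meiosis import simulate_offspring
from .riskmodel import (
    LogisticRiskModel,
    calibrate_score_percentiles,
    fit_logistic_risk,
    observed_to_liability_r2,
    score_percentile_threshold,
)
from .scoring import ScoreModel, compute_prs


def _rounded_composition(n_couples: int, K: float) -> Tuple[int, int, int]:
    """Largest-remainder rounding of the couple status mix.

    Returns (both-control, mixed, both-case) counts with fractions
    (1-K)^2, 2K(1-K), K^2.
    """
    fracs = np.array([(1.0 - K) ** 2, 2.0 * K * (1.0 - K), K**2])
    raw = fracs * n_couples
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n_couples - counts.sum()]:
        counts[i] += 1
    return int(counts[0]), int(counts[1]), int(counts[2])


def mate_virtual_couples(
    cohort: PhasedCohort, n_couples: int, K: float, seed: int
) -> List[Tuple[int, int]]:
    """Randomly pair individuals into couples matching the prevalence mix.

    A fraction ``(1-K)^2`` of couples are control-control, ``K^2``
    case-case and ``2K(1-K)`` mixed (largest-remainder rounding).  No
    individual is paired with itself and no couple is repeated;
    individuals may appear in several couples when the cohort is small
    (with a warning).
    """
    if not 0.0 <= K < 1.0:
        raise ValueError("K must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    cases = np.nonzero(cohort.is_case)[0]
    controls = np.nonzero(~cohort.is_case)[0]
    n_cc, n_mixed, n_aa = _rounded_composition(n_couples, K)
    requirements = [
        (n_cc, controls, controls, "controls"),
        (n_mixed, cases, controls, "cases and controls"),
        (n_aa, cases, cases, "cases"),
    ]
    if (n_cc > 0 and controls.size < 2) or (n_aa > 0 and cases.size < 2) or (
        n_mixed > 0 and (cases.size < 1 or controls.size < 1)
    ):
        raise ValueError(
            f"cohort too small for the requested composition: needs "
            f">=2 controls for {n_cc} control couples, >=2 cases for "
            f"{n_aa} case couples and >=1 of each for {n_mixed} mixed "
            f"couples (have {cases.size} cases, {controls.size} controls)"
        )
    if 2 * n_couples > cohort.n_samples:
        warnings.warn(
            "cohort smaller than 2 x n_couples: individuals will be reused "
            "across couples",
            stacklevel=2,
        )
    couples: List[Tuple[int, int]] = []
    seen = set()
    for count, pool_a, pool_b, _label in requirements:
        for _ in range(count):
            for _attempt in range(10_000):
                a = int(rng.choice(pool_a))
                b = int(rng.choice(pool_b))
                if a == b:
                    continue
                key = (min(a, b), max(a, b))
                if key in seen:
                    continue
                seen.add(key)
                couples.append((a, b))
                break
            else:
                raise RuntimeError("could not form enough unique couples")
    return couples


def empirical_rrr(
    couple_embryo_scores: np.ndarray,
    risk_model: LogisticRiskModel,
    strategy: Strategy,
    n_embryos_used: int,
    percentile_ref: Optional[Tuple[float, float]] = None,
    q: Optional[float] = None,
    seed: int = 0,
) -> RiskResult:
    """Empirical risk reduction over simulated couples.

    ``couple_embryo_scores`` has shape ``(n_couples, n_embryos)``; only
    the first ``n_embryos_used`` embryos of each couple are considered.
    Per couple one embryo is chosen by the strategy and one uniformly at
    random, their population-scale predicted risks are averaged over
    couples, and the relative reduction of the strategy arm against the
    random arm is returned.
    """
    scores = np.asarray(couple_embryo_scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("couple_embryo_scores must be 2-D")
    n_couples, n_avail = scores.shape
    if n_embryos_used < 1 or n_embryos_used > n_avail:
        raise ValueError(
            f"n_embryos_used must lie in [1, {n_avail}]; got {n_embryos_used}"
        )
    strategy = Strategy(strategy)
    scores = scores[:, :n_embryos_used]
    rng = np.random.default_rng(seed)
    rows = np.arange(n_couples)
    if strategy is Strategy.LRP:
        sel = np.argmin(scores, axis=1)
    else:
        if percentile_ref is None or q is None:
            raise ValueError("HRE strategies require percentile_ref and q")
        mean, variance = percentile_ref
        thr = score_percentile_threshold(mean, variance, q)
        low = scores < thr
        keys = rng.random(scores.shape) - 10.0 * low
        sel = np.argmin(keys, axis=1)
        if strategy is Strategy.HRE_FALLBACK_LOWEST:
            none_low = ~low.any(axis=1)
            sel[none_low] = np.argmin(scores[none_low], axis=1)
    random_pick = rng.integers(0, n_embryos_used, n_couples)
    p_sel = float(np.mean(risk_model.predict(scores[rows, sel])))
    p_rand = float(np.mean(risk_model.predict(scores[rows, random_pick])))
    return risk_metrics(p_rand, p_sel)


@dataclass
class VarianceDiagnostics:
    """Within-couple embryo score variance checks.

    Under Mendelian segregation the pooled within-couple variance should
    be half the parental population score variance and independent of the
    mean parental score.
    """

    table: pd.DataFrame  # columns: mean_parental_score, embryo_variance
    pooled_embryo_variance: float
    parental_variance: float
    variance_ratio: float
    slope: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"pooled embryo variance {self.pooled_embryo_variance:.4g} "
            f"({self.variance_ratio:.3f} x parental), "
            f"slope vs mid-parental score {self.slope:.3g}"
        )


def embryo_variance_diagnostics(
    mean_parental_scores: np.ndarray,
    couple_embryo_scores: np.ndarray,
    parental_variance: float,
) -> VarianceDiagnostics:
    """Per-couple embryo score variance and its regression on parental PRS."""
    mean_parental_scores = np.asarray(mean_parental_scores, dtype=float)
    scores = np.asarray(couple_embryo_scores, dtype=float)
    if scores.shape[1] < 2:
        raise ValueError("need >= 2 embryos per couple for a variance")
    per_couple = scores.var(axis=1, ddof=1)
    pooled = float(per_couple.mean())
    if len(per_couple) >= 2 and np.ptp(mean_parental_scores) > 0:
        slope = float(np.polyfit(mean_parental_scores, per_couple, 1)[0])
    else:
        slope = float("nan")
    table = pd.DataFrame(
        {
            "mean_parental_score": mean_parental_scores,
            "embryo_variance": per_couple,
        }
    )
    return VarianceDiagnostics(
        table=table,
        pooled_embryo_variance=pooled,
        parental_variance=float(parental_variance),
        variance_ratio=pooled / float(parental_variance),
        slope=slope,
    )


@dataclass
class GenomePipelineResult:
    """End-to-end outputs of the synthetic-cohort validation pipeline."""

    rrr_lrp: RiskResult
    rrr_hre: RiskResult
    r2_liability: float
    r2_observed: float
    risk_model: LogisticRiskModel
    percentile_ref: Tuple[float, float]
    diagnostics: VarianceDiagnostics
    theory_rrr_lrp: float
    n_couples: int
    n_embryos: int
    per_couple: pd.DataFrame = field(repr=False)

    def summary(self) -> dict:
        return {
            "rrr_lrp": self.rrr_lrp.rrr,
            "rrr_hre": self.rrr_hre.rrr,
            "theory_rrr_lrp": self.theory_rrr_lrp,
            "r2_liability": self.r2_liability,
            "r2_observed": self.r2_observed,
            "variance_ratio": self.diagnostics.variance_ratio,
            "variance_slope": self.diagnostics.slope,
            "n_couples": self.n_couples,
            "n_embryos": self.n_embryos,
        }


def run_genome_pipeline(
    cohort: PhasedCohort,
    gmap: GeneticMap,
    model: ScoreModel,
    K: float,
    n_couples: int,
    n_embryos: int = 5,
    q: float = 0.02,
    seed: int = 0,
    dialect: str = "sum",
) -> GenomePipelineResult:
    """Couples -> embryos -> scores -> risks -> empirical risk reduction.

    Mirrors the case-control validation design: fit the
    ascertainment-adjusted logistic risk model and the weighted-normal
    percentile reference on the parental cohort, simulate ``n_embryos``
    per virtual couple by Mendelian segregation, score them, and compare
    PRS-based selection against random selection.  The liability-scale r2
    implied by the parental fit (via the observed-to-liability
    conversion) feeds the analytic theory value reported alongside.
    """
    from .. import analytic
    from ..core import ScreeningScenario

    rng = np.random.default_rng(seed)
    parent_scores = compute_prs(cohort.haplotypes, cohort.variants, model, dialect)
    statuses = cohort.is_case
    risk_model = fit_logistic_risk(parent_scores, statuses, K)
    percentile_ref = calibrate_score_percentiles(parent_scores, statuses, K)
    r2_obs = float(np.corrcoef(parent_scores, statuses.astype(float))[0, 1] ** 2)
    r2_liab = observed_to_liability_r2(r2_obs, K, float(statuses.mean()))

    couples = mate_virtual_couples(cohort, n_couples, K, seed=int(rng.integers(2**31)))
    embryo_scores = np.empty((len(couples), n_embryos))
    mean_parent = np.empty(len(couples))
    for ci, (a, b) in enumerate(couples):
        embryos = simulate_offspring(
            cohort.sample_haplotypes(a),
            cohort.sample_haplotypes(b),
            cohort.variants,
            gmap,
            n_embryos,
            rng=rng,
        )
        embryo_scores[ci] = compute_prs(embryos, cohort.variants, model, dialect)
        mean_parent[ci] = (parent_scores[a] + parent_scores[b]) / 2.0

    sel_seed = int(rng.integers(2**31))
    rrr_lrp = empirical_rrr(
        embryo_scores, risk_model, Strategy.LRP, n_embryos, seed=sel_seed
    )
    rrr_hre = empirical_rrr(
        embryo_scores,
        risk_model,
        Strategy.HRE,
        n_embryos,
        percentile_ref=percentile_ref,
        q=q,
        seed=sel_seed,
    )
    diagnostics = embryo_variance_diagnostics(
        mean_parent, embryo_scores, parental_variance=float(np.var(parent_scores, ddof=1))
    )
    theory = analytic.risk_reduction(
        ScreeningScenario(K=K, r2_ps=r2_liab, n=n_embryos, strategy=Strategy.LRP)
    ).rrr
    per_couple = pd.DataFrame(
        {
            "parent1": [a for a, _ in couples],
            "parent2": [b for _, b in couples],
            "mean_parental_score": mean_parent,
            **{f"embryo_{i + 1}": embryo_scores[:, i] for i in range(n_embryos)},
        }
    )
    return GenomePipelineResult(
        rrr_lrp=rrr_lrp,
        rrr_hre=rrr_hre,
        r2_liability=r2_liab,
        r2_observed=r2_obs,
        risk_model=risk_model,
        percentile_ref=percentile_ref,
        diagnostics=diagnostics,
        theory_rrr_lrp=theory,
        n_couples=len(couples),
        n_embryos=n_embryos,
        per_couple=per_couple,
    )
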