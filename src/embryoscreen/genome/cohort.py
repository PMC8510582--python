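"""Phased case-control cohorts and the synthetic cohort generator."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from ..core import liability_threshold
from .gmap import GeneticMap
from .scoring import ScoreModel

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class PhasedCohort:
    """Phased haplotypes plus case/control labels.

    ``haplotypes`` has shape ``(n_samples, 2, n_variants)`` with alleles
    coded 0 (ref) / 1 (alt); ``variants`` is a DataFrame with columns
    chrom, pos (1-based), id, ref, alt, positions strictly increasing
    within each chromosome.  ``is_case`` is a boolean vector per sample.
    """

    samples: list
    is_case: np.ndarray
    variants: pd.DataFrame
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.is_case = np.asarray(self.is_case, dtype=bool)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        n_samples = len(self.samples)
        n_variants = len(self.variants)
        if self.is_case.shape != (n_samples,):
            raise ValueError("is_case must have one entry per sample")
        if self.haplotypes.shape != (n_samples, 2, n_variants):
            raise ValueError(
                "haplotypes must have shape (n_samples, 2, n_variants); got "
                f"{self.haplotypes.shape}"
            )
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError(
                    f"variant positions must strictly increase within {chrom}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosages(self) -> np.ndarray:
        """Alt-allele dosage matrix, shape (n_samples, n_variants)."""
        return self.haplotypes.sum(axis=1)

    def sample_haplotypes(self, index: int) -> np.ndarray:
        return self.haplotypes[index]


def generate_synthetic_cohort(
    n_cases: int,
    n_controls: int,
    n_variants: int = 1000,
    n_chromosomes: int = 10,
    maf_range: Tuple[float, float] = (0.05, 0.5),
    target_r2_liab: float = 0.1,
    K: float = 0.01,
    seed: int = 0,
    variant_spacing_bp: int = 1_000_000,
    cm_per_mb: float = 1.0,
    max_population: int = 2_000_000,
) -> Tuple[PhasedCohort, GeneticMap, ScoreModel]:
    """Simulate a liability-threshold case-control cohort.

    Variants are independent (linkage equilibrium) with allele frequencies
    uniform in ``maf_range`` and additive effects drawn ``N(0, 1)`` then
    rescaled so the population score variance ``sum 2 p (1-p) w^2`` equals
    ``target_r2_liab`` on the liability scale.  Liability is the centred
    score plus an independent ``N(0, 1 - target_r2_liab)`` residual; cases
    exceed the prevalence threshold.  Individuals are simulated until the
    requested numbers of cases and controls are collected, which emulates
    case-control ascertainment.

    Returns the cohort together with a constant-rate genetic map
    (``cm_per_mb``, default 1 cM/Mb) and the generating score model.
    """
    rng = np.random.default_rng(seed)
    if n_cases < 1 or n_controls < 1 or n_variants < 1 or n_chromosomes < 1:
        raise ValueError("all counts must be >= 1")
    lo_maf, hi_maf = maf_range
    if not (0.0 < lo_maf <= hi_maf <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if not 0.0 <= target_r2_liab < 1.0:
        raise ValueError("target_r2_liab must lie in [0, 1)")

    # variant table: evenly split across chromosomes, fixed spacing
    per_chrom = [
        n_variants // n_chromosomes + (1 if i < n_variants % n_chromosomes else 0)
        for i in range(n_chromosomes)
    ]
    records = []
    for ci, count in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        for vi in range(count):
            pos = (vi + 1) * variant_spacing_bp
            records.append((chrom, pos, f"{chrom}:{pos}", "A", "G"))
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)

    maf = rng.uniform(lo_maf, hi_maf, n_variants)
    raw_w = rng.standard_normal(n_variants)
    var_unit = np.sum(2.0 * maf * (1.0 - maf) * raw_w**2)
    if target_r2_liab > 0:
        if var_unit <= 0:
            raise ValueError(
                "cannot reach the target r2 with the drawn weights/MAFs"
            )
        weights = raw_w * math.sqrt(target_r2_liab / var_unit)
    else:
        weights = np.zeros(n_variants)
    effect_allele = np.where(rng.random(n_variants) < 0.5, "G", "A")
    # weights are stored per effect allele; flipping the effect allele to
    # ref only shifts the score by a constant, which the centring absorbs
    alt_weight = np.where(effect_allele == "G", weights, -weights)
    score_mean = float(np.sum(alt_weight * 2.0 * maf))  # E of the alt-dosage score
    model = ScoreModel(
        pd.DataFrame(
            {
                "id": variants["id"],
                "effect_allele": effect_allele,
                "weight": weights,
            }
        )
    )

    sigma_e = math.sqrt(1.0 - target_r2_liab)
    z_K = liability_threshold(K)
    need = {True: n_cases, False: n_controls}
    got = {True: [], False: []}
    have = {True: 0, False: 0}
    simulated = 0
    batch = max(2000, int(1.5 * (n_cases / max(K, 1e-6) + n_controls)))
    batch = min(batch, 200_000)
    while have[True] < need[True] or have[False] < need[False]:
        if simulated >= max_population:
            raise RuntimeError(
                f"exhausted {max_population} simulated individuals before "
                f"collecting {n_cases} cases and {n_controls} controls"
            )
        m = min(batch, max_population - simulated)
        hap = (rng.random((m, 2, n_variants)) < maf).astype(np.uint8)
        score = hap.sum(axis=1) @ alt_weight
        liab = (score - score_mean) + rng.normal(0.0, sigma_e, m)
        case = liab > z_K
        simulated += m
        for status in (True, False):
            short = need[status] - have[status]
            if short > 0:
                idx = np.nonzero(case == status)[0][:short]
                if idx.size:
                    got[status].append(hap[idx])
                    have[status] += idx.size

    hap_cases = np.concatenate(got[True], axis=0)
    hap_controls = np.concatenate(got[False], axis=0)
    haplotypes = np.concatenate([hap_cases, hap_controls], axis=0)
    samples = [f"case{i + 1}" for i in range(n_cases)] + [
        f"ctrl{i + 1}" for i in range(n_controls)
    ]
    is_case = np.array([True] * n_cases + [False] * n_controls)
    cohort = PhasedCohort(samples, is_case, variants, haplotypes)

    spans = {}
    for chrom, grp in variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        spans[chrom] = (max(1, pos[0] - variant_spacing_bp), pos[-1] + variant_spacing_bp)
    gmap = GeneticMap.linear(spans, cm_per_mb=cm_per_mb)
    return cohort, gmap, model
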