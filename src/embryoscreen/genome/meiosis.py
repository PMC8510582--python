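"""Mendelian gamete formation with map-based Poisson recombination.

Crossovers per chromosome are Poisson with mean equal to the chromosome's
genetic length in Morgan; crossover positions are uniform in genetic
distance.  A gamete starts on a random parental strand and switches
strand at every crossover; the transmitted allele at each variant follows
from the number of crossovers genetically to its left (a crossover
landing exactly on a variant's position — a probability-zero tie — leaves
that variant with the left-hand segment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gmap import GeneticMap


def _chrom_blocks(variants: pd.DataFrame):
    for chrom, grp in variants.groupby("chrom", sort=False):
        yield chrom, grp.index.to_numpy(), grp["pos"].to_numpy()


def _gametes_for_parent(
    parent_hap: np.ndarray,
    variants: pd.DataFrame,
    gmap: GeneticMap,
    n_gametes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n_variants = parent_hap.shape[1]
    out = np.empty((n_gametes, n_variants), dtype=np.uint8)
    for chrom, cols, pos in _chrom_blocks(variants):
        var_cm = gmap.bp_to_cm(chrom, pos)
        lo_cm, hi_cm = gmap.span_cm(chrom)
        length_m = (hi_cm - lo_cm) / 100.0
        n_xo = rng.poisson(length_m, n_gametes)
        starts = rng.integers(0, 2, n_gametes)
        for g in range(n_gametes):
            if n_xo[g] == 0:
                strand = np.full(cols.size, starts[g])
            else:
                xo_cm = np.sort(rng.uniform(lo_cm, hi_cm, n_xo[g]))
                crossings = np.searchsorted(xo_cm, var_cm, side="left")
                strand = (starts[g] + crossings) % 2
            out[g, cols] = parent_hap[strand, cols]
    return out


def simulate_offspring(
    parent1_hap: np.ndarray,
    parent2_hap: np.ndarray,
    variants: pd.DataFrame,
    gmap: GeneticMap,
    n_embryos: int,
    seed=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate diploid embryos of two phased parents.

    Returns haplotypes of shape ``(n_embryos, 2, n_variants)``: one
    recombinant gamete per parent.  Every variant position must fall
    inside the genetic map's range (no extrapolation).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    parent1_hap = np.asarray(parent1_hap, dtype=np.uint8)
    parent2_hap = np.asarray(parent2_hap, dtype=np.uint8)
    if parent1_hap.shape != parent2_hap.shape or parent1_hap.ndim != 2:
        raise ValueError("parents must share an identical (2, n_variants) shape")
    if parent1_hap.shape[1] != len(variants):
        raise ValueError("haplotype length must equal the variant count")
    g1 = _gametes_for_parent(parent1_hap, variants, gmap, n_embryos, rng)
    g2 = _gametes_for_parent(parent2_hap, variants, gmap, n_embryos, rng)
    return np.stack([g1, g2], axis=1)
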