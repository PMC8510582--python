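"""Additive polygenic score models and dosage scoring."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ScoreModel:
    """PLINK-score-style table of (variant id, effect allele, weight)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "effect_allele", "weight"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"score model table lacks columns {sorted(missing)}")
        if self.table["id"].duplicated().any():
            raise ValueError("duplicate variant ids in score model")

    def __len__(self) -> int:
        return len(self.table)


def compute_prs(
    haplotypes: np.ndarray,
    variants: pd.DataFrame,
    model: ScoreModel,
    dialect: str = "sum",
) -> np.ndarray:
    """Additive PRS per individual: sum of weight x effect-allele dosage.

    ``haplotypes`` is ``(n_individuals, 2, n_variants)`` (0 = ref,
    1 = alt), aligned with ``variants``.  Score variants whose id is not
    present are reported with a warning; variants whose effect allele
    matches neither ref nor alt raise.  ``dialect='sum'`` (default)
    returns the raw weighted dosage sum; ``dialect='average'`` divides by
    twice the number of matched variants (the per-allele average a
    standard scoring tool applies by default).  Risk-reduction results are
    invariant to this affine choice.
    """
    if dialect not in ("sum", "average"):
        raise ValueError(f"unknown scoring dialect {dialect!r}")
    haplotypes = np.asarray(haplotypes)
    if haplotypes.ndim == 2:
        haplotypes = haplotypes[None, :, :]
    idx_of = {vid: i for i, vid in enumerate(variants["id"])}
    matched_cols = []
    signs_ref = []  # True when the effect allele is the ref allele
    weights = []
    n_unmatched = 0
    ref = variants["ref"].to_numpy()
    alt = variants["alt"].to_numpy()
    for vid, ea, w in model.table[["id", "effect_allele", "weight"]].itertuples(
        index=False
    ):
        i = idx_of.get(vid)
        if i is None:
            n_unmatched += 1
            continue
        if ea == alt[i]:
            signs_ref.append(False)
        elif ea == ref[i]:
            signs_ref.append(True)
        else:
            raise ValueError(
                f"effect allele {ea!r} of {vid} matches neither ref nor alt"
            )
        matched_cols.append(i)
        weights.append(w)
    if n_unmatched and not matched_cols:
        raise ValueError("no score variants could be matched to the genotypes")
    if n_unmatched:
        warnings.warn(
            f"{n_unmatched} score variant(s) not found in the genotypes",
            stacklevel=2,
        )
    cols = np.asarray(matched_cols, dtype=int)
    w = np.asarray(weights, dtype=float)
    flip = np.asarray(signs_ref, dtype=bool)
    alt_dosage = haplotypes[:, :, cols].sum(axis=1).astype(float)
    dosage = np.where(flip, 2.0 - alt_dosage, alt_dosage)
    score = dosage @ w
    if dialect == "average":
        score = score / (2.0 * len(cols))
    return score
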