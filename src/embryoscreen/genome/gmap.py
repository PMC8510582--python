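"""Genetic maps: monotone bp <-> cM interpolation per chromosome."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np


@dataclass
class GeneticMap:
    """Per-chromosome monotone tables of (bp position, cM position).

    Interpolation is piecewise linear and defined only over the spanned
    range: positions outside it raise instead of extrapolating.
    """

    tables: Dict[str, Tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (bp, cm) in self.tables.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise ValueError(f"map for {chrom} needs >= 2 anchor points")
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"bp positions must strictly increase ({chrom})")
            if not np.all(np.diff(cm) >= 0):
                raise ValueError(f"cM positions must be non-decreasing ({chrom})")
            clean[chrom] = (bp, cm)
        self.tables = clean

    @property
    def chromosomes(self):
        return list(self.tables)

    def _check_range(self, chrom: str, bp: np.ndarray) -> None:
        table_bp = self.tables[chrom][0]
        if np.any(bp < table_bp[0]) or np.any(bp > table_bp[-1]):
            raise ValueError(
                f"position outside the genetic map range for {chrom} "
                f"[{table_bp[0]:.0f}, {table_bp[-1]:.0f}]; no extrapolation"
            )

    def bp_to_cm(self, chrom: str, bp) -> np.ndarray:
        bp = np.asarray(bp, dtype=float)
        self._check_range(chrom, bp)
        table_bp, table_cm = self.tables[chrom]
        return np.interp(bp, table_bp, table_cm)

    def cm_to_bp(self, chrom: str, cm) -> np.ndarray:
        """Inverse interpolation (left-most bp on flat cM segments)."""
        cm = np.asarray(cm, dtype=float)
        table_bp, table_cm = self.tables[chrom]
        return np.interp(cm, table_cm, table_bp)

    def span_cm(self, chrom: str) -> Tuple[float, float]:
        table_cm = self.tables[chrom][1]
        return float(table_cm[0]), float(table_cm[-1])

    def length_morgan(self, chrom: str) -> float:
        lo, hi = self.span_cm(chrom)
        return (hi - lo) / 100.0

    @classmethod
    def linear(
        cls, chrom_spans_bp: Dict[str, Tuple[float, float]], cm_per_mb: float = 1.0
    ) -> "GeneticMap":
        """Constant-rate map (default 1 cM/Mb) over the given bp spans."""
        tables = {}
        for chrom, (lo, hi) in chrom_spans_bp.items():
            bp = np.array([float(lo), float(hi)])
            cm = (bp - bp[0]) * cm_per_mb / 1e6
            tables[chrom] = (bp, cm)
        return cls(tables)
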