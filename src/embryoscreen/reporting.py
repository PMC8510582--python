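"""Result records, CSV/JSON writers, and run configuration round-trip."""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional

import pandas as pd
import yaml


@dataclass
class RunConfig:
    """Resolved parameters of one CLI run; written beside the results."""

    command: str
    params: Dict[str, Any]
    outdir: str
    seed: Optional[int] = None

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class RunReport:
    """A tidy result table plus provenance, exportable as CSV and JSON."""

    config: RunConfig
    rows: List[Dict[str, Any]] = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def add(self, **row: Any) -> None:
        self.rows.append(row)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write(self, stem: str = "results") -> Dict[str, str]:
        os.makedirs(self.config.outdir, exist_ok=True)
        paths = {
            "csv": os.path.join(self.config.outdir, f"{stem}.csv"),
            "json": os.path.join(self.config.outdir, f"{stem}.json"),
            "config": os.path.join(self.config.outdir, "config.yaml"),
        }
        self.frame().to_csv(paths["csv"], index=False, float_format="%.10g")
        payload = {
            "command": self.config.command,
            "params": self.config.params,
            "seed": self.config.seed,
            "runtime_s": round(time.time() - self.started, 3),
            "results": self.rows,
        }
        with open(paths["json"], "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
            fh.write("\n")
        self.config.to_yaml(paths["config"])
        return paths


def format_percent(x: float) -> str:
    """Human-readable percentage at one decimal place."""
    return f"{100.0 * x:.1f}%"
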