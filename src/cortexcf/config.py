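"""Serializable analysis configuration and provenance hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Resolved parameters of one end-to-end analysis.

    Preprocessing defaults follow the protocol the package implements:
    third-order Savitzky-Golay high-pass over a 210 s window, percent
    signal change, 103 s run tails held out as the test set.
    """

    seed: int = 0
    # simulation
    runs: int = 4
    samples_per_run: int = 250
    snr: float = 1.0
    correlation_length_mm: float = 5.0
    n_targets: int = 50
    cf_sigma_mm: float = 6.0
    sources: List[Dict] = field(default_factory=lambda: [
        {"name": "somato", "kind": "patch", "width_mm": 40.0,
         "height_mm": 20.0, "spacing_mm": 1.25,
         "gradient": "edge_geodesic", "n_modes": 40},
    ])
    # preprocessing
    savgol_order: int = 3
    savgol_window_s: float = 210.0
    tail_s: float = 103.0
    apply_preprocessing: bool = False
    # model
    lambda_points: int = 10
    lambda_min_exp: float = -2.0
    lambda_max_exp: float = 6.0
    rectify: bool = True
    # outputs
    out_dir: Optional[str] = None

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def lambda_grid(self):
        import numpy as np
        return np.logspace(self.lambda_min_exp, self.lambda_max_exp,
                           self.lambda_points)
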