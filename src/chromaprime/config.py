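"""Analysis configuration: every numeric threshold of the pipeline in one place.

Defaults follow the study conventions: ±200 bp summit windows for tag
counting, correction factors from the median of the top 25,000 peaks,
2-fold replicate-consistent specific-DHS calls, 3-fold inducibility,
gene groups at 2-fold with a minimum read count of 50 over a universe of
loci with mean expression ≥ 3, a 10-fold high-variation set, 50/100 kb
proximity distances, ±100 bp motif-scan windows, and 2,000 bp / 10 bp
density profiles.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass
class AnalysisConfig:
    window_halfwidth: int = 200
    top_n_for_norm: int = 25000
    specific_fc: float = 2.0
    inducible_fc: float = 3.0
    expr_min_count: float = 50.0
    expr_universe_min_mean: float = 3.0
    high_var_fc: float = 10.0
    proximity_dist: int = 50000
    closest_gene_max_dist: int = 100000
    motif_scan_halfwidth: int = 100
    density_window: int = 2000
    density_bin: int = 10
    pseudocount: float = 1.0
    significance_count_cutoff: float = 10.0
    fdr_alpha: float = 0.05
    # footprint caller
    footprint_min_width: int = 11
    footprint_max_width: int = 25
    footprint_flank: int = 35
    footprint_min_cuts: int = 30
    footprint_min_imbalance: float = 0.6
    rng_seed: int = 0

    _POSITIVE = (
        "window_halfwidth", "top_n_for_norm", "specific_fc", "inducible_fc",
        "expr_min_count", "expr_universe_min_mean", "high_var_fc",
        "proximity_dist", "closest_gene_max_dist", "motif_scan_halfwidth",
        "density_window", "density_bin", "significance_count_cutoff",
        "fdr_alpha", "footprint_min_width", "footprint_max_width",
        "footprint_flank", "footprint_min_cuts",
    )

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.footprint_min_width > self.footprint_max_width:
            raise ValueError("footprint_min_width > footprint_max_width")
        if not (0.0 <= self.footprint_min_imbalance <= 1.0):
            raise ValueError("footprint_min_imbalance must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        """Stable hash of the configuration, recorded in every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
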