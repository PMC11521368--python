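"""YAML analysis configuration.

A configuration file declares the column schema (continuous columns,
categorical level sets and reference levels), the log10 transform list, the
candidate predictor pool, the correlation structures to compete, and the
estimator.  Example::

    species_column: species
    continuous: [whole_brain, body_mass, daily_traveled_distance]
    categorical:
      tool_use: {levels: [no, yes], reference: no}
    log10: [whole_brain, body_mass]
    pool:
      variables: [log10_body_mass, daily_traveled_distance, population_density]
      mandatory: [log10_body_mass]
      max_size: 4
    structures: [brownian, pagel, ou]
    estimator: ml
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .selection import CandidatePool

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    species_column: str = "species"
    continuous: list[str] = field(default_factory=list)
    categorical: dict[str, dict] = field(default_factory=dict)
    log10: list[str] = field(default_factory=list)
    pool: CandidatePool | None = None
    structures: tuple[str, ...] = ("brownian", "pagel", "ou")
    estimator: str = "ml"
    collinearity_threshold: float = 0.7

    @property
    def method(self) -> str:
        return self.estimator.upper()

    @property
    def reference_levels(self) -> dict[str, str]:
        return {col: spec["reference"] for col, spec in self.categorical.items() if "reference" in spec}

    @property
    def level_sets(self) -> dict[str, list[str]]:
        return {col: list(spec["levels"]) for col, spec in self.categorical.items() if "levels" in spec}


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pool = None
    if "pool" in raw:
        p = raw.pop("pool")
        pool = CandidatePool(
            variables=tuple(p["variables"]),
            mandatory=tuple(p.get("mandatory", ())),
            max_size=p.get("max_size"),
        )
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = AnalysisConfig(**{k: v for k, v in raw.items() if k != "pool"}, pool=pool)
    if isinstance(cfg.structures, list):
        cfg.structures = tuple(cfg.structures)
    if cfg.estimator.lower() not in ("ml", "reml"):
        raise ValueError(f"estimator must be 'ml' or 'reml', got {cfg.estimator!r}")
    cfg.estimator = cfg.estimator.lower()
    return cfg
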