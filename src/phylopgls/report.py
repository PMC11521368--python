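"""Descriptive outputs and run provenance.

Covers the descriptive statistics the analysis reports alongside the model
fits — pairwise Pearson correlations among region volumes and the stacked
region-volume decomposition (frontal pole + dorso-lateral prefrontal cortex
+ rest of brain = whole brain) — plus a small run manifest that ties every
written table back to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = ["region_correlations", "stacked_volume_table", "RunManifest"]


def region_correlations(
    data: pd.DataFrame, regions: list[str], display_decimals: int = 2
) -> pd.DataFrame:
    """Pairwise Pearson r among (log-scale) region volumes.

    Highly correlated region volumes (r near 1) are the expected outcome for
    allometrically scaling brain regions.  Needs >= 3 complete rows; a
    zero-variance region yields NaN.
    """
    sub = data[regions].dropna()
    if len(sub) < 3:
        raise ValueError(f"need >= 3 complete rows, have {len(sub)}")
    corr = sub.astype(float).corr(method="pearson")
    return corr.round(display_decimals)


def stacked_volume_table(
    data: pd.DataFrame,
    whole: str = "whole_brain",
    fp: str = "fp",
    dlpfc: str = "dlpfc",
) -> pd.DataFrame:
    """Decompose the whole-brain volume per species: FP, DLPFC and the rest
    of the brain (ROB = whole - FP - DLPFC); the three parts sum back to the
    whole-brain volume exactly."""
    for col in (whole, fp, dlpfc):
        if col not in data.columns:
            raise ValueError(f"column {col!r} absent")
    bad = data.index[data[fp] + data[dlpfc] > data[whole]].tolist()
    if bad:
        raise ValueError(f"FP + DLPFC exceeds whole-brain volume for species {bad}")
    fp_v = data[fp].astype(float)
    dlpfc_v = data[dlpfc].astype(float)
    rob = data[whole].astype(float) - fp_v - dlpfc_v
    # report the total as the recomputed sum so the conservation identity
    # fp + dlpfc + rob == whole_brain holds exactly (<= 1 ulp from input)
    return pd.DataFrame(
        {"fp": fp_v, "dlpfc": dlpfc_v, "rob": rob, "whole_brain": fp_v + dlpfc_v + rob},
        index=data.index,
    )


def _hash_bytes(payload: bytes) -> str:
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance attached to every written output table."""

    command: str
    config_hash: str
    tree_hash: str
    data_hash: str
    seed: int | None
    package_version: str
    timestamp: str

    @classmethod
    def create(
        cls,
        tree_text: str = "",
        data_text: str = "",
        config_text: str = "",
        seed: int | None = None,
    ) -> "RunManifest":
        from . import __version__

        return cls(
            command=" ".join(sys.argv),
            config_hash=_hash_bytes(config_text.encode()),
            tree_hash=_hash_bytes(tree_text.encode()),
            data_hash=_hash_bytes(data_text.encode()),
            seed=seed,
            package_version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @property
    def hash(self) -> str:
        body = json.dumps([self.config_hash, self.tree_hash, self.data_hash, self.seed])
        return _hash_bytes(body.encode())


def write_table(df: pd.DataFrame, path, manifest: RunManifest | None = None) -> None:
    """TSV writer with a provenance comment header."""
    with open(path, "w") as fh:
        if manifest is not None:
            fh.write(f"# manifest: {manifest.hash}\n")
        df.to_csv(fh, sep="\t")
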