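"""Species-level trait tables: loading, derived variables, tree alignment.

The analyses operate on a table with exactly one row per species holding
brain-region volumes (whole brain, frontal pole, dorso-lateral prefrontal
cortex), body mass, and socio-ecological predictors (dietary quality index,
tool use, daily traveled distance in km, group size, population density in
individuals/km^2, social system, mating system, mate guarding, seasonal
breeding, weaning age as % of maximum lifespan).  Volumes and body mass are
log10-transformed before modeling; daily traveled distance and population
density stay on their raw scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Phylogeny, normalize_label

__all__ = [
    "DietComposition",
    "dqi",
    "load_trait_table",
    "aggregate_species_means",
    "transform_for_analysis",
    "encode_categoricals",
    "align_to_tree",
    "collinearity_check",
]

log = logging.getLogger(__name__)


class TraitTableError(ValueError):
    """Raised for malformed or inconsistent trait tables."""


@dataclass(frozen=True)
class DietComposition:
    """Percentages of diet items: plant structural parts (s), plant
    reproductive parts (r), animal prey (a)."""

    s: float
    r: float
    a: float

    def __post_init__(self) -> None:
        for name, v in (("s", self.s), ("r", self.r), ("a", self.a)):
            if v < 0:
                raise ValueError(f"diet component {name} must be >= 0, got {v}")
        if self.s + self.r + self.a > 100 + 1e-6:
            raise ValueError("diet components exceed 100%")


def dqi(d: DietComposition | None = None, *, s: float = None, r: float = None, a: float = None) -> float:
    """Dietary quality index, DQI = 1*s + 2*r + 3.5*a.

    Low values (around 100) characterize folivorous diets; high values
    (around 200) more diversified diets including fruit and animal prey.
    Accepts either a :class:`DietComposition` or keyword components.
    """
    if d is None:
        d = DietComposition(s=s, r=r, a=a)
    return 1.0 * d.s + 2.0 * d.r + 3.5 * d.a


def load_trait_table(
    path,
    species_column: str = "species",
    continuous: list[str] | None = None,
    categorical: dict[str, list[str]] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited trait table into a species-indexed DataFrame.

    The delimiter is sniffed (comma vs tab) unless given.  Species labels are
    normalized so that ``Pan troglodytes`` matches the tree tip
    ``Pan_troglodytes``.  Missing values stay as NaN.

    Parameters
    ----------
    continuous
        Columns that must be numeric; a non-numeric entry raises an error
        naming the offending row and column.
    categorical
        Mapping of column name to its allowed level set; unseen levels raise.
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    if species_column not in df.columns:
        raise TraitTableError(
            f"no {species_column!r} column; found {list(df.columns)}"
        )
    df[species_column] = df[species_column].map(normalize_label)
    dup = df[species_column][df[species_column].duplicated()].tolist()
    if dup:
        raise TraitTableError(f"duplicate species rows: {sorted(set(dup))}")
    df = df.set_index(species_column)
    for col in continuous or []:
        if col not in df.columns:
            raise TraitTableError(f"declared continuous column {col!r} absent")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad:
            raise TraitTableError(
                f"non-numeric value in continuous column {col!r} for species {bad}"
            )
        df[col] = coerced
    for col, levels in (categorical or {}).items():
        seen = set(df[col].dropna().unique())
        unknown = seen - set(levels)
        if unknown:
            raise TraitTableError(
                f"column {col!r} has levels {sorted(unknown)} outside declared set {levels}"
            )
    return df


def aggregate_species_means(
    df: pd.DataFrame, species_column: str = "species", columns: list[str] | None = None
) -> pd.DataFrame:
    """Collapse multiple specimens per species to species means.

    Averaging happens on the raw measurement scale (e.g. mm^3), *before* any
    log transform; non-averaged columns must be constant within species.
    """
    if species_column in df.columns:
        df = df.set_index(species_column)
    groups = df.groupby(level=0, sort=False)
    columns = columns or [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    out = groups.first()
    for col in columns:
        out[col] = groups[col].mean()
    return out


def transform_for_analysis(
    df: pd.DataFrame, log10_columns: tuple[str, ...] | list[str] = (),
) -> pd.DataFrame:
    """Add ``log10_<col>`` columns for volumes and body mass.

    Every transformed value must be strictly positive; violations raise an
    error naming the species.  Other predictors (daily traveled distance,
    population density, ...) are left on their raw scales.
    """
    out = df.copy()
    for col in log10_columns:
        if col not in df.columns:
            raise TraitTableError(f"cannot log-transform absent column {col!r}")
        vals = df[col].astype(float)
        bad = df.index[(vals <= 0) & vals.notna()].tolist()
        if bad:
            raise TraitTableError(
                f"non-positive values in {col!r} for species {bad}; cannot log10"
            )
        out[f"log10_{col}"] = np.log10(vals)
    return out


def encode_categoricals(
    df: pd.DataFrame, reference_levels: dict[str, str]
) -> pd.DataFrame:
    """Treatment-code categorical columns against configured reference levels.

    A k-level factor becomes k-1 dummy columns named ``<col>[<level>]``;
    binary yes/no factors therefore become a single 0/1 column.
    """
    out = df.copy()
    for col, ref in reference_levels.items():
        if col not in df.columns:
            raise TraitTableError(f"categorical column {col!r} absent")
        levels = df[col].dropna().unique().tolist()
        if ref not in levels and df[col].notna().any():
            raise TraitTableError(
                f"reference level {ref!r} not observed in {col!r} (levels: {sorted(map(str, levels))})"
            )
        for level in sorted(str(l) for l in levels if str(l) != str(ref)):
            out[f"{col}[{level}]"] = (df[col].astype(str) == level).astype(float)
            out.loc[df[col].isna(), f"{col}[{level}]"] = np.nan
        out = out.drop(columns=[col])
    return out


def align_to_tree(
    df: pd.DataFrame, tree: Phylogeny, policy: str = "intersect"
) -> tuple[pd.DataFrame, Phylogeny]:
    """Match trait rows to tree tips; return both in tip order.

    ``strict`` errors when the species sets differ; ``intersect`` prunes both
    sides to the shared species (logged).  Fewer than 3 shared species is an
    error either way.
    """
    if policy not in ("intersect", "strict"):
        raise ValueError(f"unknown policy {policy!r}")
    table_species = set(df.index)
    tip_species = set(tree.tips)
    shared = table_species & tip_species
    if len(shared) < 3:
        raise TraitTableError(
            f"only {len(shared)} species shared between table and tree; need >= 3"
        )
    if policy == "strict" and table_species != tip_species:
        raise TraitTableError(
            f"species sets differ: table-only {sorted(table_species - tip_species)}, "
            f"tree-only {sorted(tip_species - table_species)}"
        )
    drop_tips = sorted(tip_species - shared)
    if drop_tips:
        log.info("align_to_tree: pruning %d tips absent from table: %s", len(drop_tips), drop_tips)
        tree = tree.prune(drop_tips)
    drop_rows = sorted(table_species - shared)
    if drop_rows:
        log.info("align_to_tree: dropping %d rows absent from tree: %s", len(drop_rows), drop_rows)
    aligned = df.loc[tree.tips]
    return aligned, tree


def collinearity_check(
    df: pd.DataFrame, variables: list[str], threshold: float = 0.7
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations among candidate predictors.

    Returns the correlation table (complete cases per pair) and the list of
    pairs whose |r| exceeds ``threshold``; zero-variance columns yield NaN
    and are flagged with r recorded as NaN.
    """
    sub = df[variables].astype(float)
    corr = sub.corr(method="pearson")
    flagged: list[tuple[str, str, float]] = []
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r) or abs(r) > threshold:
                flagged.append((a, b, float(r)))
    return corr, flagged
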