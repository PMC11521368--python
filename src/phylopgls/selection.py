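"""Candidate-model enumeration and AIC-based selection.

Every predictor subset (mandatory variables always included, optional ones
up to a size cap) is fitted under every requested correlation structure;
fits are ranked by ascending AIC, with ties broken by fewer predictors and
then lexicographic predictor list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .pgls import ModelSpec, PGLSFit, fit_pgls
from .phylo import Phylogeny

__all__ = ["CandidatePool", "ModelComparison", "enumerate_models", "compare_models", "comparison_report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidatePool:
    """The predictor universe for a model sweep.

    variables
        All candidate predictors (socio-ecological variables + body mass).
    mandatory
        Predictors present in every candidate model (default: none beyond
        what the caller lists; the study keeps body mass mandatory).
    max_size
        Cap on total predictors per model, mandatory included.
    """

    variables: tuple[str, ...]
    mandatory: tuple[str, ...] = ()
    max_size: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "mandatory", tuple(self.mandatory))
        if not self.variables:
            raise ValueError("candidate pool is empty")
        if not set(self.mandatory) <= set(self.variables):
            raise ValueError("mandatory predictors must be among the pool variables")
        cap = self.max_size if self.max_size is not None else len(self.variables)
        if not len(self.mandatory) <= cap <= len(self.variables):
            raise ValueError(
                f"max_size must lie in [{len(self.mandatory)}, {len(self.variables)}]"
            )


def enumerate_models(pool: CandidatePool, response: str) -> list[ModelSpec]:
    """All subsets of optional variables (size-capped) unioned with the
    mandatory set, in deterministic lexicographic order."""
    optional = sorted(set(pool.variables) - set(pool.mandatory))
    cap = (pool.max_size if pool.max_size is not None else len(pool.variables)) - len(
        pool.mandatory
    )
    specs: list[ModelSpec] = []
    for size in range(cap + 1):
        for extra in combinations(optional, size):
            specs.append(ModelSpec(response, tuple(pool.mandatory) + extra))
    return specs


@dataclass
class ModelComparison:
    """Fits across spec x structure, ranked by AIC (smaller is better)."""

    fits: list[PGLSFit]
    failures: list[tuple[ModelSpec, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fits:
            causes = "; ".join(f"{s}/{k}: {msg}" for s, k, msg in self.failures)
            raise ValueError(f"every candidate fit failed ({causes})")
        self.fits = sorted(
            self.fits,
            key=lambda f: (f.aic, len(f.spec.predictors), f.spec.predictors),
        )

    @property
    def best(self) -> PGLSFit:
        return self.fits[0]

    @property
    def delta_aic(self) -> np.ndarray:
        aics = np.array([f.aic for f in self.fits])
        return aics - aics.min()


def compare_models(
    data: pd.DataFrame,
    tree: Phylogeny,
    response: str,
    pool: CandidatePool,
    structures: tuple[str, ...] = ("brownian", "pagel", "ou"),
    method: str = "ML",
) -> ModelComparison:
    """Fit every candidate spec under every structure and rank by AIC.

    Infeasible fits (too few complete cases, degenerate likelihoods) are
    logged and excluded rather than aborting the sweep.
    """
    specs = enumerate_models(pool, response)
    fits: list[PGLSFit] = []
    failures: list[tuple[ModelSpec, str, str]] = []
    for spec in specs:
        k_coef = len(spec.terms)
        n_complete = int(data[[response, *spec.predictors]].dropna().shape[0])
        for kind in structures:
            if n_complete < k_coef + 2:
                failures.append((spec, kind, f"only {n_complete} complete cases"))
                continue
            try:
                fits.append(fit_pgls(data, spec, tree, kind=kind, method=method))
            except Exception as exc:
                log.warning("compare_models: %s under %s failed: %s", spec, kind, exc)
                failures.append((spec, kind, str(exc)))
    return ModelComparison(fits, failures)


def comparison_report(mc: ModelComparison) -> pd.DataFrame:
    """One row per fit: spec, structure, logLik, k, AIC, dAIC, Akaike weight."""
    delta = mc.delta_aic
    weights = np.exp(-delta / 2.0)
    weights = weights / weights.sum()
    rows = []
    for fit, d, w in zip(mc.fits, delta, weights):
        rows.append(
            {
                "model": str(fit.spec),
                "predictors": " + ".join(fit.spec.predictors),
                "structure": fit.structure.kind,
                "parameter": fit.structure.parameter,
                "n": fit.n,
                "k": fit.k,
                "logLik": fit.loglik,
                "AIC": fit.aic,
                "dAIC": d,
                "akaike_weight": w,
            }
        )
    return pd.DataFrame(rows)
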