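"""Species-level leave-one-out robustness for a selected PGLS model.

Each species is removed from both the trait table and the tree, the selected
model is refitted (structure parameter re-estimated by default), and the
procedure reports which removals flip a predictor's significance at the
chosen threshold or its coefficient sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pgls import ModelSpec, PGLSFit, fit_pgls
from .phylo import Phylogeny

__all__ = ["JackknifeResult", "leave_one_out", "jackknife_summary"]

log = logging.getLogger(__name__)


@dataclass
class JackknifeResult:
    """The full fit plus one replicate fit per removed species."""

    full_fit: PGLSFit
    removed_species: list[str]
    fits: dict[str, PGLSFit]
    failed: dict[str, str]
    alpha: float
    # per predictor: removals where p crossed alpha relative to the full fit
    losses: dict[str, list[str]] = field(default_factory=dict)
    gains: dict[str, list[str]] = field(default_factory=dict)
    sign_changes: dict[str, list[str]] = field(default_factory=dict)


def leave_one_out(
    data: pd.DataFrame,
    tree: Phylogeny,
    spec: ModelSpec,
    kind: str = "brownian",
    alpha: float = 0.05,
    method: str = "ML",
    freeze_parameter: bool = False,
) -> JackknifeResult:
    """Refit ``spec`` with each species removed from table and tree.

    A "loss" for a predictor is a removal under which p <= alpha in the
    all-species fit but p > alpha in the replicate; a "gain" is the reverse.
    ``freeze_parameter`` pins the replicate structure parameter at the
    full-fit estimate instead of re-estimating it.
    """
    full_fit = fit_pgls(data, spec, tree, kind=kind, method=method)
    fixed = full_fit.structure.parameter if freeze_parameter else None
    fits: dict[str, PGLSFit] = {}
    failed: dict[str, str] = {}
    for species in tree.tips:
        sub_tree = tree.prune(species)
        sub_data = data.drop(index=species).loc[sub_tree.tips]
        try:
            fits[species] = fit_pgls(
                sub_data, spec, sub_tree, kind=kind, method=method, fixed_parameter=fixed
            )
        except Exception as exc:
            log.warning("leave_one_out: removal of %s failed: %s", species, exc)
            failed[species] = str(exc)
    losses: dict[str, list[str]] = {p: [] for p in spec.predictors}
    gains: dict[str, list[str]] = {p: [] for p in spec.predictors}
    sign_changes: dict[str, list[str]] = {p: [] for p in spec.predictors}
    for predictor in spec.predictors:
        full_sig = full_fit.p[predictor] <= alpha
        for species, fit in fits.items():
            rep_sig = fit.p[predictor] <= alpha
            if full_sig and not rep_sig:
                losses[predictor].append(species)
            elif rep_sig and not full_sig:
                gains[predictor].append(species)
            if np.sign(fit.beta[predictor]) != np.sign(full_fit.beta[predictor]):
                sign_changes[predictor].append(species)
    return JackknifeResult(
        full_fit=full_fit,
        removed_species=list(tree.tips),
        fits=fits,
        failed=failed,
        alpha=alpha,
        losses=losses,
        gains=gains,
        sign_changes=sign_changes,
    )


def jackknife_summary(j: JackknifeResult) -> pd.DataFrame:
    """Per predictor: beta range across removals, counts of significance
    losses/gains and sign changes, and the offending species."""
    rows = []
    for predictor in j.full_fit.spec.predictors:
        betas = [fit.beta[predictor] for fit in j.fits.values()]
        rows.append(
            {
                "predictor": predictor,
                "beta_full": j.full_fit.beta[predictor],
                "beta_min": float(np.min(betas)),
                "beta_max": float(np.max(betas)),
                "n_loss": len(j.losses[predictor]),
                "n_gain": len(j.gains[predictor]),
                "n_sign_change": len(j.sign_changes[predictor]),
                "loss_species": ";".join(j.losses[predictor]),
                "sign_change_species": ";".join(j.sign_changes[predictor]),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")
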