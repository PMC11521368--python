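"""Phylogenetic generalized least squares: the estimation core.

The model is y = X beta + eps with eps ~ MVN(0, sigma^2 V), where V is
derived from the phylogeny under one of three correlation structures
(Brownian, Pagel's lambda, Ornstein-Uhlenbeck).  Estimation whitens the data
through a Cholesky factor of V and runs ordinary least squares on the
transformed problem; the structure parameter (lambda or alpha) is profiled
by maximum likelihood over a grid followed by bounded scalar refinement.

Conventions
-----------
* sigma^2 is the ML estimate r' V^-1 r / n; standard errors apply the
  finite-sample correction n/(n - k_coef).
* t statistics use df = n - (number of regression coefficients); p-values
  are two-sided Student-t.
* AIC counts k = regression coefficients + 1 (sigma^2) + 1 if a structure
  parameter was estimated.
* REML is available through ``method="REML"`` for probing software
  differences; AIC comparisons across fixed-effect sets should use ML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import CovarianceModel, CovMatrix, Phylogeny, apply_structure

__all__ = [
    "ModelSpec",
    "PGLSFit",
    "gls_estimate",
    "fit_pgls",
    "standardized_betas",
    "likelihood_ratio_test",
    "coefficient_table",
    "DegenerateFitError",
]

log = logging.getLogger(__name__)

_LAMBDA_GRID = np.linspace(0.0, 1.0, 41)


class PGLSError(ValueError):
    pass


class DegenerateFitError(PGLSError):
    """Perfect fit (sigma^2 = 0): t-values would be infinite."""


@dataclass(frozen=True)
class ModelSpec:
    """A response, an ordered predictor list, and an intercept flag."""

    response: str
    predictors: tuple[str, ...]
    include_intercept: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("predictors must be distinct")
        if self.response in self.predictors:
            raise ValueError("response cannot appear among predictors")

    @property
    def terms(self) -> tuple[str, ...]:
        return (("(Intercept)",) if self.include_intercept else ()) + self.predictors

    def __str__(self) -> str:
        rhs = " + ".join(self.predictors) or "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class GLSResult:
    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    loglik: float
    loglik_reml: float
    cov_unscaled: np.ndarray  # (X' V^-1 X)^-1
    n: int
    k_coef: int


@dataclass
class PGLSFit:
    """A fitted PGLS model with the full coefficient-table statistics."""

    spec: ModelSpec
    structure: CovarianceModel
    species: list[str]
    beta: pd.Series
    se: pd.Series
    std_beta: pd.Series
    t: pd.Series
    p: pd.Series
    sigma2: float
    loglik: float
    aic: float
    n: int
    k: int
    df_resid: int
    method: str = "ML"
    boundary: bool = False
    cov_unscaled: np.ndarray | None = field(default=None, repr=False)

    def __str__(self) -> str:
        param = "" if self.structure.parameter is None else f"({self.structure.parameter:.3g})"
        return (
            f"PGLSFit[{self.spec}; {self.structure.kind}{param}; "
            f"n={self.n}, logLik={self.loglik:.3f}, AIC={self.aic:.2f}]"
        )


def _chol(V: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor with a small-jitter fallback for near-singular V."""
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-10 * float(np.mean(np.diag(V)))
        try:
            return linalg.cholesky(V + jitter * np.eye(V.shape[0]), lower=True)
        except linalg.LinAlgError as exc:
            raise PGLSError(
                "covariance matrix is not positive definite; "
                "check structure-parameter bounds"
            ) from exc


def gls_estimate(
    y: np.ndarray,
    X: np.ndarray,
    V: np.ndarray | CovMatrix,
    term_names: list[str] | None = None,
) -> GLSResult:
    """Generalized least squares by Cholesky whitening.

    Solves beta = (X'V^-1 X)^-1 X'V^-1 y by factorizing V = LL', whitening
    (z = L^-1 y, W = L^-1 X) and running OLS on (z, W).  Returns the ML
    sigma^2 (RSS/n), the maximized Gaussian log-likelihood, the REML
    log-likelihood, and standard errors with the n/(n-k) small-sample
    correction on sigma^2.
    """
    if isinstance(V, CovMatrix):
        V = V.values
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if V.shape != (n, n) or y.shape[0] != n:
        raise PGLSError(f"dimension mismatch: y {y.shape}, X {X.shape}, V {V.shape}")
    if n < k + 2:
        raise PGLSError(f"need n >= k+2 observations (n={n}, k={k})")
    L = _chol(V)
    z = linalg.solve_triangular(L, y, lower=True)
    W = linalg.solve_triangular(L, X, lower=True)
    rank = np.linalg.matrix_rank(W)
    if rank < k:
        names = term_names or [f"x{j}" for j in range(k)]
        raise PGLSError(
            f"design matrix is rank deficient (rank {rank} < {k}); "
            f"check for collinear columns among {names}"
        )
    beta, _, _, _ = linalg.lstsq(W, z)
    resid = z - W @ beta
    rss = float(resid @ resid)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if rss <= 1e-12 * max(1.0, float(z @ z)):
        raise DegenerateFitError(
            "residual variance is zero (perfect fit); standard errors undefined"
        )
    sigma2 = rss / n
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdetV + n)
    # REML: restricted likelihood of the error contrasts
    sigma2_r = rss / (n - k)
    _, logdet_WtW = np.linalg.slogdet(W.T @ W)
    loglik_reml = -0.5 * (
        (n - k) * np.log(2.0 * np.pi * sigma2_r) + logdetV + logdet_WtW + (n - k)
    )
    cov_unscaled = linalg.inv(W.T @ W)
    se = np.sqrt(np.diag(cov_unscaled) * sigma2 * n / (n - k))
    return GLSResult(beta, se, sigma2, loglik, loglik_reml, cov_unscaled, n, k)


def _build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Complete-case response/design extraction in the data's row order."""
    cols = [spec.response, *spec.predictors]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise PGLSError(f"columns absent from data: {missing}")
    sub = data[cols].astype(float).dropna()
    dropped = data.index.difference(sub.index).tolist()
    if dropped:
        log.info("fit_pgls: dropping %d incomplete species: %s", len(dropped), dropped)
    y = sub[spec.response].to_numpy()
    Xcols = [sub[p].to_numpy() for p in spec.predictors]
    if spec.include_intercept:
        X = np.column_stack([np.ones(len(sub)), *Xcols]) if Xcols else np.ones((len(sub), 1))
    else:
        X = np.column_stack(Xcols)
    return y, X, list(spec.terms), sub.index.tolist()


def _ou_grid(tree_depth: float) -> np.ndarray:
    # alpha spans [1e-4/T, 1e2/T] on a log scale; robust to multimodality
    return np.geomspace(1e-4 / tree_depth, 1e2 / tree_depth, 41)


def fit_pgls(
    data: pd.DataFrame,
    spec: ModelSpec,
    tree: Phylogeny,
    kind: str = "brownian",
    method: str = "ML",
    fixed_parameter: float | None = None,
) -> PGLSFit:
    """Fit a PGLS model, profiling the structure parameter by ML.

    ``data`` must be aligned to ``tree`` (row order = tip order); rows with
    missing values in the model's columns are dropped (the tree is pruned to
    match).  For ``pagel``/``ou`` the parameter is maximized over a grid with
    bounded refinement unless ``fixed_parameter`` pins it.
    """
    if method not in ("ML", "REML"):
        raise ValueError(f"method must be 'ML' or 'REML', got {method!r}")
    if list(data.index) != tree.tips:
        raise PGLSError("data is not aligned to tree (row order must equal tip order)")
    y, X, terms, species = _build_design(data, spec)
    sub_tree = tree if species == tree.tips else tree.prune(
        [t for t in tree.tips if t not in set(species)]
    )
    # after pruning, tip order is preserved as a subsequence of the original
    order = sub_tree.tips
    reorder = [species.index(s) for s in order]
    y, X = y[reorder], X[reorder]
    species = order

    def result_for(model: CovarianceModel) -> GLSResult:
        V = apply_structure(sub_tree, model).values
        return gls_estimate(y, X, V, term_names=terms)

    objective = (lambda r: r.loglik) if method == "ML" else (lambda r: r.loglik_reml)
    boundary = False
    estimated_param = False
    if kind == "brownian":
        model = CovarianceModel("brownian")
        res = result_for(model)
    elif kind in ("pagel", "ou"):
        if fixed_parameter is not None:
            model = CovarianceModel(kind, fixed_parameter)
            res = result_for(model)
        else:
            estimated_param = True
            grid = _LAMBDA_GRID if kind == "pagel" else _ou_grid(sub_tree.depth)
            lls = []
            for par in grid:
                try:
                    lls.append(objective(result_for(CovarianceModel(kind, float(par)))))
                except (PGLSError, DegenerateFitError):
                    lls.append(-np.inf)
            if not np.isfinite(lls).any():
                raise PGLSError(
                    f"profile likelihood failed at every {kind} grid point; trace: {lls}"
                )
            best = int(np.argmax(lls))
            lo = grid[max(best - 1, 0)]
            hi = grid[min(best + 1, len(grid) - 1)]
            if kind == "ou":
                lo, hi = np.log(lo), np.log(hi)

            def neg(par_t: float) -> float:
                par = float(np.exp(par_t)) if kind == "ou" else float(par_t)
                try:
                    return -objective(result_for(CovarianceModel(kind, par)))
                except (PGLSError, DegenerateFitError):
                    return np.inf

            if lo < hi:
                opt = optimize.minimize_scalar(
                    neg, bounds=(lo, hi), method="bounded",
                    options={"xatol": 1e-8},
                )
                par_hat = float(np.exp(opt.x)) if kind == "ou" else float(opt.x)
                if -opt.fun < lls[best]:  # refinement never worse than grid
                    par_hat = float(grid[best])
            else:
                par_hat = float(grid[best])
            bounds = (0.0, 1.0) if kind == "pagel" else (grid[0], grid[-1])
            boundary = (
                abs(par_hat - bounds[0]) <= 1e-6 * max(1.0, abs(bounds[0]))
                or abs(par_hat - bounds[1]) <= 1e-6 * max(1.0, abs(bounds[1]))
            )
            model = CovarianceModel(kind, par_hat)
            res = result_for(model)
    else:
        raise ValueError(f"unknown structure kind {kind!r}")

    n, k_coef = res.n, res.k_coef
    df_resid = n - k_coef
    t_vals = res.beta / res.se
    p_vals = 2.0 * stats.t.sf(np.abs(t_vals), df_resid)
    k = k_coef + 1 + (1 if estimated_param else 0)
    loglik = res.loglik if method == "ML" else res.loglik_reml
    aic = -2.0 * loglik + 2.0 * k

    beta = pd.Series(res.beta, index=terms, name="beta")
    sub = data.loc[species]
    sd_y = float(sub[spec.response].std(ddof=1))
    std_beta = pd.Series(np.nan, index=terms, name="std_beta")
    for term in spec.predictors:
        sd_x = float(sub[term].std(ddof=1))
        std_beta[term] = np.nan if sd_x == 0 or sd_y == 0 else beta[term] * sd_x / sd_y

    return PGLSFit(
        spec=spec,
        structure=model,
        species=species,
        beta=beta,
        se=pd.Series(res.se, index=terms, name="se"),
        std_beta=std_beta,
        t=pd.Series(t_vals, index=terms, name="t"),
        p=pd.Series(p_vals, index=terms, name="p"),
        sigma2=res.sigma2,
        loglik=loglik,
        aic=aic,
        n=n,
        k=k,
        df_resid=df_resid,
        method=method,
        boundary=boundary,
    )


def standardized_betas(fit: PGLSFit, data: pd.DataFrame) -> pd.Series:
    """std_beta_j = beta_j * sd(x_j) / sd(y) over the fitted species set.

    Sample standard deviations; the intercept is excluded (NaN).  A
    zero-variance predictor yields NaN.
    """
    sub = data.loc[fit.species]
    sd_y = float(sub[fit.spec.response].std(ddof=1))
    out = pd.Series(np.nan, index=list(fit.beta.index), name="std_beta")
    for term in fit.spec.predictors:
        sd_x = float(sub[term].std(ddof=1))
        if sd_x == 0 or sd_y == 0:
            log.warning("standardized_betas: zero variance for %r; undefined", term)
            continue
        out[term] = fit.beta[term] * sd_x / sd_y
    return out


def likelihood_ratio_test(full: PGLSFit, reduced: PGLSFit) -> tuple[float, int, float]:
    """2*(logLik_full - logLik_reduced) against chi-squared.

    The specs must be nested (reduced predictors a subset of the full set),
    share response, species set and structure kind, and both be ML fits.
    Returns (statistic, df, p).
    """
    if full.method != "ML" or reduced.method != "ML":
        raise PGLSError("likelihood-ratio tests require ML fits")
    if full.spec.response != reduced.spec.response:
        raise PGLSError("fits have different responses")
    if not set(reduced.spec.predictors) <= set(full.spec.predictors):
        raise PGLSError("models are not nested")
    if set(full.species) != set(reduced.species):
        raise PGLSError("fits use different species sets")
    if full.structure.kind != reduced.structure.kind:
        raise PGLSError("fits use different correlation structures")
    df = len(full.spec.terms) - len(reduced.spec.terms)
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


def coefficient_table(fit: PGLSFit, display_precision: int | None = None) -> pd.DataFrame:
    """The five-column coefficient table: estimate, SE, standardized beta,
    t, p — one row per term, intercept first (its standardized beta empty).

    With ``display_precision`` set, estimates are rounded for display and p
    is shown to 3 decimals (0 meaning < 5e-4); full precision otherwise.
    """
    tab = pd.DataFrame(
        {
            "Beta (estimate)": fit.beta,
            "Beta (std. error)": fit.se,
            "Standardized beta": fit.std_beta,
            "t-Value": fit.t,
            "p-Value": fit.p,
        }
    )
    tab.index.name = "Predictor"
    if display_precision is not None:
        for col in ("Beta (estimate)", "Beta (std. error)", "Standardized beta", "t-Value"):
            tab[col] = tab[col].map(
                lambda v: np.nan if pd.isna(v) else float(f"%.{display_precision}g" % v)
            )
        tab["p-Value"] = fit.p.map(lambda v: 0.0 if v < 5e-4 else round(v, 3))
    return tab
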