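"""Firth penalized logistic regression for differential expression.

Each gene is modelled separately: disease status (case = 1) is regressed
on the gene's standardized normalized abundance plus optional covariates.
The Firth penalty adds half the log-determinant of the Fisher information
to the log-likelihood, which keeps coefficient estimates finite even under
complete separation — the failure mode that rules out classical logistic
regression for genes with near-perfect case/control count differences.

The reported statistic per gene is the standardized log odds ratio (LOR):
the log-odds change per one standard deviation of abundance, positive when
the gene is more abundant in cases. P-values come from the penalized
likelihood-ratio test by default (Wald available), adjusted across genes
by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve
from scipy.special import expit
from scipy.stats import chi2, spearmanr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contrast:
    """A case/control comparison over sample conditions."""

    name: str
    case: frozenset[str]
    control: frozenset[str]

    def __post_init__(self) -> None:
        if self.case & self.control:
            raise ValueError(
                f"contrast {self.name!r}: case and control conditions overlap"
            )


#: The three standard contrasts: each disease against control, and the
#: pooled neurodegenerative-disease (ND) group against control.
DEFAULT_CONTRASTS = (
    Contrast("HD_vs_C", frozenset({"HD"}), frozenset({"C"})),
    Contrast("PD_vs_C", frozenset({"PD"}), frozenset({"C"})),
    Contrast("ND_vs_C", frozenset({"HD", "PD"}), frozenset({"C"})),
)


@dataclass
class FirthFit:
    """Result of one penalized-likelihood fit."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float  # penalized log-likelihood at the optimum
    converged: bool
    n_iter: int


def standardize_gene(values: np.ndarray | pd.Series) -> np.ndarray:
    """Scale to mean 0 and sample standard deviation 1 (denominator n-1)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-d vector of at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector cannot be standardized")
    return (x - x.mean()) / sd


def _penalized_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    p = expit(eta)
    w = p * (1.0 - p)
    xtwx = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_fit(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-6,
    fixed: tuple[int, ...] = (),
) -> FirthFit:
    """Maximize the Firth-penalized logistic log-likelihood.

    Newton-Raphson on the modified score
    ``U*(beta) = X' (y - p + h (1/2 - p))`` with ``h`` the hat-matrix
    diagonal, with step-halving whenever a full step would decrease the
    penalized log-likelihood. Convergence when the sup-norm of the (free
    components of the) modified score drops below ``tol``; iteration then
    continues briefly to polish the coefficients well past that
    tolerance. The fit is returned with ``converged=False`` after
    ``max_iter`` iterations otherwise.

    ``fixed`` holds design-column indices whose coefficients are pinned
    at zero: the restricted fit used by the penalized likelihood-ratio
    test, in which the penalty keeps the *full* design's information
    matrix.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary (0/1)")
    if y.min() == y.max():
        raise ValueError("y contains a single class")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    n, k = X.shape
    free = np.array([j for j in range(k) if j not in set(fixed)])
    if len(free) == 0:
        raise ValueError("no free coefficients")
    beta = np.zeros(k)
    ll = _penalized_loglik(beta, X, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        w = p * (1.0 - p)
        xtwx = (X * w[:, None]).T @ X
        xtwx_inv = np.linalg.inv(xtwx)
        # hat diagonal of W^(1/2) X (X'WX)^-1 X' W^(1/2)
        h = w * np.einsum("ij,jk,ik->i", X, xtwx_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        supnorm = np.abs(score[free]).max()
        if supnorm < tol:
            converged = True
        if supnorm < tol * 1e-4:  # polished: stop refining
            break
        delta = np.zeros(k)
        delta[free] = np.linalg.solve(xtwx[np.ix_(free, free)], score[free])
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new = _penalized_loglik(cand, X, y)
            if ll_new >= ll - 1e-12:
                beta, ll = cand, ll_new
                break
            step /= 2.0
        else:  # no improving step found: stuck at the current point
            break

    p = expit(X @ beta)
    w = p * (1.0 - p)
    xtwx = (X * w[:, None]).T @ X
    se = np.sqrt(np.diag(np.linalg.inv(xtwx)))
    return FirthFit(beta=beta, se=se, loglik=ll, converged=converged, n_iter=it)


def firth_test(
    y: np.ndarray,
    X: np.ndarray,
    term_index: int,
    reduced_loglik: float | None = None,
    method: str = "plrt",
) -> float:
    """Raw p-value for one design column of a Firth logistic model.

    ``plrt`` (default): penalized likelihood-ratio statistic
    ``2 (l*_full - l*_restricted)`` against chi-square with 1 df, where
    the restricted model pins the tested coefficient at zero while the
    penalty retains the full design's information matrix. ``wald``:
    squared z of the coefficient. Returns NaN when a fit fails to
    converge. A precomputed ``reduced_loglik`` may be supplied when the
    restricted model is shared across many tests.
    """
    full = firth_fit(y, X)
    if not full.converged:
        return float("nan")
    if method == "wald":
        stat = (full.beta[term_index] / full.se[term_index]) ** 2
    elif method == "plrt":
        if reduced_loglik is None:
            reduced = firth_fit(y, X, fixed=(term_index,))
            if not reduced.converged:
                return float("nan")
            reduced_loglik = reduced.loglik
        stat = max(0.0, 2.0 * (full.loglik - reduced_loglik))
    else:
        raise ValueError(f"unknown test method {method!r}")
    return float(chi2.sf(stat, df=1))


def bh_adjust(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries propagate as NaN and do not count toward the number of
    tests. Values outside [0, 1] raise.
    """
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum() > 0:
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _covariate_matrix(
    samples: pd.DataFrame, covariates: tuple[str, ...] | list[str]
) -> np.ndarray:
    """Continuous covariates standardized; categoricals dummy-coded with
    the first level as reference."""
    cols = []
    for cov in covariates:
        if cov not in samples.columns:
            raise KeyError(f"covariate {cov!r} missing from sample metadata")
        col = samples[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(standardize_gene(col.to_numpy()))
        else:
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            cols.extend(dummies[c].to_numpy() for c in dummies.columns)
    if not cols:
        return np.empty((len(samples), 0))
    return np.column_stack(cols)


def de_contrast(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: Contrast,
    covariates: tuple[str, ...] | list[str] = (),
    q_threshold: float = 0.01,
    method: str = "plrt",
) -> pd.DataFrame:
    """Per-gene Firth DE for one contrast.

    Fits ``status ~ intercept + standardized abundance [+ covariates]``
    for every gene and returns a DataFrame indexed by gene id with columns
    ``lor`` (standardized log odds ratio, positive = more abundant in
    case), ``se``, ``p`` (penalized LRT by default), ``q`` (BH across the
    genes tested in this contrast), ``converged``, ``de`` (q below
    ``q_threshold``) and ``contrast``. Genes whose fit fails are reported
    with NaN p/q and excluded from the BH denominator.
    """
    cond = samples.loc[norm.columns, "condition"]
    keep = cond.isin(contrast.case | contrast.control)
    ids = cond.index[keep]
    y = cond.loc[ids].isin(contrast.case).to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"contrast {contrast.name!r} has an empty group")

    sub = samples.loc[ids]
    covar = _covariate_matrix(sub, covariates)
    intercept = np.ones((len(ids), 1))

    # Without covariates the restricted model (count coefficient pinned at
    # zero) is identical for every gene: its weights are constant across
    # samples and the standardized count column always contributes the
    # same X'X block, so the restricted penalized likelihood is shared.
    share_restricted = method == "plrt" and covar.shape[1] == 0
    shared_restricted_loglik = None

    mat = norm[ids].to_numpy(dtype=float)
    n_genes = mat.shape[0]
    lor = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    p = np.full(n_genes, np.nan)
    converged = np.zeros(n_genes, dtype=bool)
    for g in range(n_genes):
        row = mat[g]
        if row.std(ddof=1) == 0:
            continue
        x = standardize_gene(row)
        design = np.hstack([intercept, x[:, None], covar])
        fit = firth_fit(y, design)
        lor[g] = fit.beta[1]
        se[g] = fit.se[1]
        converged[g] = fit.converged
        if not fit.converged:
            continue
        if method == "wald":
            p[g] = chi2.sf((fit.beta[1] / fit.se[1]) ** 2, df=1)
        else:
            if share_restricted:
                if shared_restricted_loglik is None:
                    shared_restricted_loglik = firth_fit(
                        y, design, fixed=(1,)
                    ).loglik
                restricted_loglik = shared_restricted_loglik
            else:
                restricted_loglik = firth_fit(y, design, fixed=(1,)).loglik
            stat = max(0.0, 2.0 * (fit.loglik - restricted_loglik))
            p[g] = chi2.sf(stat, df=1)

    q = bh_adjust(p)
    n_failed = int((~converged).sum())
    if n_failed:
        logger.warning(
            "%s: %d gene fits did not converge", contrast.name, n_failed
        )
    return pd.DataFrame(
        {
            "lor": lor,
            "se": se,
            "p": p,
            "q": q,
            "converged": converged,
            "de": (q < q_threshold) & ~np.isnan(q),
            "contrast": contrast.name,
        },
        index=norm.index,
    )


@dataclass
class BatchConcordance:
    """Spearman agreement of per-gene LORs with vs without a batch term."""

    contrast: str
    rho: float
    pvalue: float


def batch_concordance(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: Contrast,
    covariates: tuple[str, ...] | list[str] = (),
    batch_column: str = "batch",
) -> BatchConcordance:
    """Diagnostic for batch confounding.

    Runs the per-gene Firth models with and without the categorical batch
    covariate and reports the Spearman correlation of the count
    coefficients between the two model families. A high rho indicates the
    batch structure does not reorder the evidence for differential
    expression.
    """
    cond = samples.loc[norm.columns, "condition"]
    keep = cond.isin(contrast.case | contrast.control)
    sub = samples.loc[cond.index[keep]]
    batches = sub[batch_column]
    if batches.nunique() < 2:
        raise ValueError("batch concordance requires at least two batches")
    y_part = sub["condition"].isin(contrast.case)
    if batches.groupby(y_part).nunique().max() == 1 and batches.nunique() == 2:
        raise ValueError(
            "batch is perfectly confounded with the case/control split"
        )
    without = de_contrast(norm, samples, contrast, covariates)
    with_batch = de_contrast(
        norm, samples, contrast, tuple(covariates) + (batch_column,)
    )
    ok = without["converged"] & with_batch["converged"]
    rho, pval = spearmanr(without.loc[ok, "lor"], with_batch.loc[ok, "lor"])
    return BatchConcordance(contrast.name, float(rho), float(pval))
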