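"""Unpenalized binary logistic regression with AIC and Wald significance.

This is the decision engine for clade expansion: at every candidate node two
nested models are fitted — the clade as a single predictor versus its
children as separate predictors — and compared by AIC = 2k - 2 ln L. Because
the children sum to the parent, the collapsed model is a linear restriction
of the expanded one, so the expanded maximized likelihood can never be lower;
AIC's 2-per-parameter penalty is what stops indiscriminate splitting.

Estimation is straight Newton-Raphson (IRLS) with step halving. The normal
equations are solved by least squares, so exactly collinear designs (e.g.
two children that are each half the parent) converge to a maximum-likelihood
point rather than erroring; their standard errors come out infinite and the
affected coefficients are treated as non-significant. Complete or
quasi-complete separation is flagged when coefficients diverge on the
standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "LogisticFit",
    "ModelComparison",
    "fit_logistic",
    "aic",
    "wald_pvalues",
    "compare_models",
]

# |coefficient| on standardized predictors beyond which we call separation:
# at scale 30 a one-SD change moves the log-odds by 30, far past any
# plausible finite-MLE fit.
_SEPARATION_SCALE = 30.0


@dataclass
class LogisticFit:
    """Result of one maximum-likelihood logistic fit (intercept first)."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    n_parameters: int
    converged: bool
    separation_detected: bool
    n_samples: int


@dataclass
class ModelComparison:
    """Verdict of the collapsed-vs-expanded comparison at one node."""

    aic_collapsed: float
    aic_expanded: float
    expand: bool
    significant_children: np.ndarray
    fallback_reason: str | None = None
    n_fits: int = 2
    child_pvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # ll = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def _irls(design: np.ndarray, y: np.ndarray, max_iter: int, tol: float):
    """Newton-Raphson on an explicit design matrix (intercept included).

    Returns (beta, cov, ll, converged). ``cov`` is the inverse observed
    information via pseudo-inverse; rank-deficient directions get inf SEs
    downstream.
    """
    n, k = design.shape
    beta = np.zeros(k)
    eta = design @ beta
    ll = _log_likelihood(eta, y)
    converged = False
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = design.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = p * (1.0 - p)
        # fisher information; lstsq tolerates exact collinearity
        wx = design * w[:, None]
        hess = design.T @ wx
        step, *_ = np.linalg.lstsq(hess, grad, rcond=None)
        # step halving keeps the likelihood monotone
        new_ll = -np.inf
        for _half in range(30):
            cand = beta + step
            cand_eta = design @ cand
            new_ll = _log_likelihood(cand_eta, y)
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        if new_ll < ll - 1e-12:
            break  # no ascent direction left
        beta, eta, ll = beta + step, design @ (beta + step), new_ll
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    hess = design.T @ (design * w[:, None])
    cov = np.linalg.pinv(hess)
    return beta, cov, ll, converged


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression with intercept.

    Parameters
    ----------
    X:
        ``(n, p)`` predictor matrix, ``p >= 1``, no intercept column and no
        all-constant column (drop constants upstream).
    y:
        Binary outcome containing both classes.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if X.size == 0 or X.shape[1] == 0:
        raise ValueError("empty predictor matrix")
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size}")
    classes = np.unique(y)
    if classes.size != 2 or not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("y must contain both classes, coded 0/1")
    col_sd = X.std(axis=0)
    if np.any(col_sd == 0):
        bad = np.flatnonzero(col_sd == 0).tolist()
        raise ValueError(f"constant predictor column(s) at index {bad}")
    return _fit_design(np.column_stack([np.ones(y.size), X]), y, col_sd,
                       max_iter, tol)


def _fit_design(design, y, col_sd, max_iter=100, tol=1e-8) -> LogisticFit:
    beta, cov, ll, converged = _irls(design, y, max_iter, tol)
    var = np.diag(cov).copy()
    var[var <= 0] = np.inf
    se = np.sqrt(var)
    # flag separation on the standardized scale (slopes only)
    scaled = np.abs(beta[1:]) * np.asarray(col_sd)
    separation = bool(np.any(scaled > _SEPARATION_SCALE)) or (
        not converged and ll > -1e-6 * y.size
    )
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        log_likelihood=ll,
        n_parameters=design.shape[1],
        converged=converged,
        separation_detected=separation,
        n_samples=int(y.size),
    )


def aic(fit: LogisticFit) -> float:
    """Akaike information criterion, 2k - 2 ln L (lower is better)."""
    return 2.0 * fit.n_parameters - 2.0 * fit.log_likelihood


def wald_pvalues(fit: LogisticFit) -> np.ndarray:
    """Two-sided normal-approximation p-values for the non-intercept
    coefficients. An infinite standard error (collinearity, separation)
    yields p = 1, so the affected child is pruned rather than kept on an
    unstable estimate."""
    beta = fit.coefficients[1:]
    se = fit.standard_errors[1:]
    p = np.ones_like(beta)
    ok = np.isfinite(se) & (se > 0)
    z = np.zeros_like(beta)
    z[ok] = beta[ok] / se[ok]
    p[ok] = 2.0 * sps.norm.sf(np.abs(z[ok]))
    return p


def compare_models(
    node_abund: np.ndarray,
    child_abunds: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    use_log: bool = False,
    use_aicc: bool = False,
    child_p_adjust: str = "none",
) -> ModelComparison:
    """Decide whether splitting a clade into its children improves label
    prediction.

    ``child_abunds`` is ``(n_samples, n_children)`` and must sum per sample
    to ``node_abund`` (the clade abundance is the sum of its parts). The
    collapsed model uses the clade total as the single predictor; the
    expanded model uses the children. Expansion requires a strictly lower
    AIC — a tie keeps the clade collapsed (parsimony). If the expanded fit
    separates or fails to converge, the clade is kept collapsed and the
    reason recorded.

    ``significant_children[i]`` marks children whose expanded-model Wald
    p-value is below ``alpha``; constant (e.g. all-zero) children are
    excluded from the design and marked non-significant.
    """
    node_abund = np.asarray(node_abund, dtype=float).ravel()
    child_abunds = np.atleast_2d(np.asarray(child_abunds, dtype=float))
    if child_abunds.shape[0] != node_abund.size:
        child_abunds = child_abunds.T
    y = np.asarray(y, dtype=float).ravel()
    n, c = child_abunds.shape
    if not np.allclose(child_abunds.sum(axis=1), node_abund, atol=1e-9):
        raise ValueError("children abundances do not sum to the node abundance")

    xs_node = np.log(node_abund) if use_log else node_abund
    xs_child = np.log(child_abunds) if use_log else child_abunds

    n_fits = 0
    # collapsed model: intercept + clade total (intercept-only if constant)
    if np.std(xs_node) == 0:
        fit_col = _fit_design(np.ones((n, 1)), y, col_sd=np.empty(0))
    else:
        fit_col = fit_logistic(xs_node[:, None], y)
    n_fits += 1

    def _ic(fit: LogisticFit) -> float:
        val = aic(fit)
        if use_aicc:
            k = fit.n_parameters
            if fit.n_samples - k - 1 > 0:
                val += 2.0 * k * (k + 1) / (fit.n_samples - k - 1)
            else:
                val = np.inf
        return val

    aic_col = _ic(fit_col)
    significant = np.zeros(c, dtype=bool)
    pvals = np.ones(c)
    keep = np.flatnonzero(xs_child.std(axis=0) > 0)

    if keep.size == 0:
        return ModelComparison(
            aic_collapsed=aic_col, aic_expanded=np.nan, expand=False,
            significant_children=significant, child_pvalues=pvals,
            fallback_reason="all_children_constant", n_fits=n_fits,
        )

    fit_exp = fit_logistic(xs_child[:, keep], y)
    n_fits += 1
    aic_exp = _ic(fit_exp)

    if fit_exp.separation_detected or not fit_exp.converged:
        return ModelComparison(
            aic_collapsed=aic_col, aic_expanded=aic_exp, expand=False,
            significant_children=significant, child_pvalues=pvals,
            fallback_reason="expanded_fit_unstable", n_fits=n_fits,
        )

    p_keep = wald_pvalues(fit_exp)
    if child_p_adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        p_keep = multipletests(p_keep, method="fdr_bh")[1]
    elif child_p_adjust != "none":
        raise ValueError(f"unknown child_p_adjust {child_p_adjust!r}")
    pvals[keep] = p_keep
    significant[keep] = p_keep < alpha

    return ModelComparison(
        aic_collapsed=aic_col,
        aic_expanded=aic_exp,
        expand=bool(aic_exp < aic_col),
        significant_children=significant,
        child_pvalues=pvals,
        n_fits=n_fits,
    )
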