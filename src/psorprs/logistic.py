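"""Logistic regression by iteratively reweighted least squares.

A small, well-tested Newton/IRLS fitter with the exact semantics the risk
models need: Wald standard errors from the observed information, a
closed-form intercept-only null log-likelihood, explicit detection of
rank-deficient designs and of complete separation (where the MLE does not
exist), and a likelihood-ratio test helper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, xlogy
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from ._exceptions import (
    ConvergenceError,
    SeparationError,
    SingularDesignError,
    ValidationError,
)

INTERCEPT = "intercept"


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""

    params: pd.Series
    cov: pd.DataFrame
    llf: float
    llnull: float
    nobs: int
    niter: int
    converged: bool

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.values)),
                         index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * norm.sf(np.abs(self.zvalues)),
                         index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        half = norm.ppf(1 - alpha / 2) * self.bse
        return pd.DataFrame(
            {"low": self.params - half, "high": self.params + half}
        )

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "or": np.exp(self.params),
                "ci_low": np.exp(ci["low"]),
                "ci_high": np.exp(ci["high"]),
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        lines = [
            "Logistic regression (IRLS)",
            f"  n = {self.nobs}, log-likelihood = {self.llf:.4f}, "
            f"null = {self.llnull:.4f}, iterations = {self.niter}",
            f"  {'term':<20}{'coef':>10}{'se':>10}{'z':>9}{'p':>12}"
            f"{'OR':>10}",
        ]
        ors = np.exp(self.params)
        for name in self.params.index:
            lines.append(
                f"  {name:<20}{self.params[name]:>10.4f}"
                f"{self.bse[name]:>10.4f}{self.zvalues[name]:>9.3f}"
                f"{self.pvalues[name]:>12.3e}{ors[name]:>10.4f}"
            )
        return "\n".join(lines)


def _as_design(design, add_intercept: bool) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        names = [str(c) for c in design.columns]
        matrix = design.to_numpy(dtype=float)
    elif isinstance(design, dict):
        names = list(design)
        matrix = np.column_stack([np.asarray(design[k], float) for k in names])
    else:
        matrix = np.asarray(design, dtype=float)
        if matrix.ndim == 1:
            matrix = matrix[:, None]
        names = [f"x{i}" for i in range(matrix.shape[1])]
    if add_intercept:
        matrix = np.column_stack([np.ones(matrix.shape[0]), matrix])
        names = [INTERCEPT] + names
    return matrix, names


def fit_logistic(
    response,
    design,
    add_intercept: bool = True,
    tol: float = 1e-8,
    maxiter: int = 50,
) -> LogisticFit:
    """Fit a logistic model by IRLS.

    ``design`` may be a DataFrame, a dict of named columns, or an array
    (an intercept is prepended unless ``add_intercept=False``).
    Convergence requires the max absolute score (gradient) below ``tol``
    within ``maxiter`` Newton steps (with step-halving).  A rank-deficient
    design raises :class:`SingularDesignError`; diverging coefficients
    raise :class:`SeparationError` naming the worst term.
    """
    y = np.asarray(response, dtype=float)
    matrix, names = _as_design(design, add_intercept)
    n, p = matrix.shape
    if y.shape != (n,):
        raise ValidationError("response length does not match design rows")
    if not np.isfinite(matrix).all() or not np.isfinite(y).all():
        raise ValidationError("design/response contain non-finite values")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("response must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("response is constant; logistic fit undefined")
    if n <= p:
        raise ValidationError(f"need more observations ({n}) than terms ({p})")
    if np.linalg.matrix_rank(matrix) < p:
        raise SingularDesignError(
            "design matrix is rank deficient (collinear or duplicated terms)"
        )

    def loglik(beta):
        eta = matrix @ beta
        return float(np.sum(xlogy(y, expit(eta)) + xlogy(1 - y, expit(-eta))))

    beta = np.zeros(p)
    ll = loglik(beta)
    converged = False
    info = None
    niter = 0
    for niter in range(1, maxiter + 1):
        mu = expit(matrix @ beta)
        weights = np.clip(mu * (1 - mu), 1e-12, None)
        score = matrix.T @ (y - mu)
        info = matrix.T @ (matrix * weights[:, None])
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "information matrix singular during IRLS (separation or "
                "degenerate design)"
            ) from None
        # step-halving keeps the likelihood monotone
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll_new = loglik(candidate)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = candidate
        ll = ll_new
    else:
        niter = maxiter

    if not converged:
        worst = int(np.argmax(np.abs(beta)))
        if np.max(np.abs(beta)) > 12.0:
            raise SeparationError(
                f"coefficients diverge (|beta| max at term {names[worst]!r}); "
                "data are completely or quasi-completely separated"
            )
        raise ConvergenceError(
            f"IRLS did not converge in {maxiter} iterations"
        )

    # with separated data the score also vanishes (all weights collapse to
    # zero), so "convergence" at an absurd coefficient still means no MLE
    if np.max(np.abs(beta)) > 12.0:
        worst = int(np.argmax(np.abs(beta)))
        raise SeparationError(
            f"coefficient for term {names[worst]!r} diverges "
            f"({beta[worst]:.1f}); data are completely or quasi-completely "
            "separated"
        )
    mu = expit(matrix @ beta)
    weights = np.clip(mu * (1 - mu), 1e-12, None)
    info = matrix.T @ (matrix * weights[:, None])
    cov = np.linalg.inv(info)
    pbar = y.mean()
    llnull = float(n * (xlogy(pbar, pbar) + xlogy(1 - pbar, 1 - pbar)))
    return LogisticFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        llf=loglik(beta),
        llnull=llnull,
        nobs=n,
        niter=niter,
        converged=True,
    )


def lr_test(full: LogisticFit, reduced: LogisticFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested logistic fits: (statistic, df, p)."""
    df = len(full.params) - len(reduced.params)
    if df <= 0:
        raise ValidationError("full model must have more terms than reduced")
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    return stat, df, float(chi2_dist.sf(stat, df))
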