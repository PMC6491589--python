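"""Per-protein linear models and empirical-Bayes moderated testing.

Each protein g is fitted by ordinary least squares against the shared design
matrix X, giving coefficients beta_g, residual variance s_g^2 on d_g degrees
of freedom, and average log2 intensity A_g.  The residual variances are then
shrunk toward a common prior via the hierarchical model

    s_g^2 | sigma_g^2  ~  sigma_g^2 * chi^2_{d_g} / d_g
    1 / sigma_g^2      ~  chi^2_{d_0} / (d_0 * s_0^2(A_g))

i.e. a scaled-inverse-chi-square prior on sigma_g^2 whose scale may depend
smoothly on A_g (the intensity "trend").  The hyperparameters are estimated
by the method of moments on z_g = log s_g^2, using the digamma/trigamma
moments of log-chi-square variables: a lowess curve of z on A locates
log s_0^2(A), and the excess dispersion of the residuals over the chi-square
sampling floor is inverted through the trigamma function to give d_0.

The posterior (squeezed) variance

    s~_g^2 = (d_0 * s_0^2(A_g) + d_g * s_g^2) / (d_0 + d_g)

replaces s_g^2 in the t-statistic, which is referred to a t distribution on
d_0 + d_g degrees of freedom (standard normal when d_0 is infinite).
p-values are Benjamini–Hochberg adjusted per coefficient across proteins,
and calls use strict comparison adjusted p < alpha (default 0.01).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .design import DesignMatrix, validate_design

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Per-protein OLS output against a shared design."""

    coefficients: np.ndarray        # proteins × coefficients, log2 units
    residual_variance: np.ndarray   # s_g^2
    residual_df: int                # d_g = n_obs - rank(X), shared
    unscaled_variances: np.ndarray  # diag (X'X)^-1, per coefficient
    mean_log_intensity: np.ndarray  # A_g
    design: DesignMatrix
    protein_ids: list[str]

    @property
    def n_proteins(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class VariancePrior:
    """Estimated prior: degrees of freedom d0 (may be +inf) and per-protein
    prior variance s0^2(A_g) (constant when trend is off)."""

    prior_df: float
    prior_variance: np.ndarray
    trend: bool


@dataclass
class ModeratedStats:
    """Moderated test of one coefficient across proteins."""

    coefficient: str
    effect: np.ndarray
    posterior_variance: np.ndarray
    t: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    prior_df: float
    residual_df: int
    alpha: float
    protein_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": self.effect,
                "t": self.t,
                "p_raw": self.p_raw,
                "p_adjusted": self.p_adjusted,
                "significant": self.significant,
            },
            index=pd.Index(self.protein_ids, name="protein"),
        )


def _align_to_design(Y, design: DesignMatrix) -> np.ndarray:
    """Return Y's columns in design row order (by key for DataFrames with a
    (replicate, channel) MultiIndex; positional otherwise)."""
    if isinstance(Y, pd.DataFrame):
        missing = [k for k in design.row_keys if k not in Y.columns]
        if missing:
            raise ValueError(f"Y lacks observations required by the design: {missing}")
        return Y[design.row_keys].to_numpy(float)
    arr = np.asarray(Y, float)
    if arr.shape[1] != design.n_observations:
        raise ValueError(
            f"Y has {arr.shape[1]} observations but design has {design.n_observations}"
        )
    return arr


def fit_linear_models(Y, design: DesignMatrix, protein_ids: list[str] | None = None) -> FitResult:
    """OLS per protein: beta from the normal equations, s_g^2 from the
    residual sum of squares on n - p degrees of freedom."""
    validate_design(design)
    arr = _align_to_design(Y, design)
    x = design.matrix
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than coefficients ({p})")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = arr @ x @ xtx_inv
    resid = arr - beta @ x.T
    df = n - p
    s2 = np.einsum("ij,ij->i", resid, resid) / df

    if protein_ids is None:
        protein_ids = (
            list(Y.index) if isinstance(Y, pd.DataFrame) else [str(i) for i in range(arr.shape[0])]
        )
    return FitResult(
        coefficients=beta,
        residual_variance=s2,
        residual_df=df,
        unscaled_variances=np.diag(xtx_inv).copy(),
        mean_log_intensity=arr.mean(axis=1),
        design=design,
        protein_ids=list(protein_ids),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def estimate_variance_prior(
    fit: FitResult,
    trend: bool = True,
    span: float = 0.5,
) -> VariancePrior:
    """Method-of-moments fit of (d0, s0^2(A)) from the observed log residual
    variances.

    ``z_g = log s_g^2`` has expectation ``log sigma_g^2 + digamma(d_g/2) -
    log(d_g/2)`` and excess variance ``trigamma(d0/2)`` beyond the chi-square
    sampling variance ``trigamma(d_g/2)``.  With ``trend`` a lowess curve of
    z on A_g supplies the location; otherwise the location is the mean.
    Non-positive excess dispersion yields d0 = +inf (no moderation needed).
    """
    if fit.residual_df <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    n = fit.n_proteins
    if n < 50:
        logger.warning("variance prior estimated from only %d proteins; unstable", n)

    s2 = fit.residual_variance.copy()
    floor = np.finfo(float).eps * max(float(np.mean(s2)), np.finfo(float).tiny)
    s2 = np.maximum(s2, floor)  # perfect fits participate at the floor

    dg = float(fit.residual_df)
    z = np.log(s2)
    e = z - special.digamma(dg / 2.0) + math.log(dg / 2.0)

    if trend:
        location = lowess(
            e, fit.mean_log_intensity, frac=span, it=3, return_sorted=False
        )
    else:
        location = np.full(n, e.mean())

    resid = e - location
    evar = float(np.sum(resid**2) / (n - 1)) - float(special.polygamma(1, dg / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(location + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        logger.warning("log-variance dispersion at or below chi-square floor; d0 = +inf")
        d0 = math.inf
        s0 = np.exp(location)
    return VariancePrior(prior_df=float(d0), prior_variance=s0, trend=trend)


def squeeze_variances(fit: FitResult, prior: VariancePrior) -> np.ndarray:
    """Posterior variances: convex combination of prior and observed."""
    d0, dg = prior.prior_df, float(fit.residual_df)
    if math.isinf(d0):
        return prior.prior_variance.copy()
    return (d0 * prior.prior_variance + dg * fit.residual_variance) / (d0 + dg)


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, mapped back to input order."""
    p = np.asarray(p, float)
    if not np.all(np.isfinite(p)) or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significance(p_adjusted, alpha: float = 0.01) -> np.ndarray:
    """Strictly-below-alpha significance calls on adjusted p-values."""
    return np.asarray(p_adjusted, float) < alpha


def moderated_t_test(
    fit: FitResult,
    prior: VariancePrior,
    coefficient: str,
    alpha: float = 0.01,
) -> ModeratedStats:
    """Moderated t-test of one coefficient being zero, with BH adjustment
    across proteins and strict alpha calls.

    ``coefficient`` is a design column name, or a role when unambiguous.
    """
    j = fit.design.column_index(coefficient)
    beta = fit.coefficients[:, j]
    s2_post = squeeze_variances(fit, prior)

    vj = fit.unscaled_variances[j]
    se = np.sqrt(s2_post * vj)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    exploded = (se == 0) & (beta != 0)
    if exploded.any():
        logger.warning("%d proteins with zero posterior variance: t = ±inf, p = 0", exploded.sum())
    t = np.where(se == 0, np.where(exploded, np.sign(beta) * np.inf, 0.0), t)

    d0 = prior.prior_df
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=d0 + fit.residual_df)
    p = np.where(exploded, 0.0, p)

    p_adj = adjust_bh(p)
    return ModeratedStats(
        coefficient=fit.design.names[j],
        effect=beta,
        posterior_variance=s2_post,
        t=t,
        p_raw=p,
        p_adjusted=p_adj,
        significant=call_significance(p_adj, alpha),
        prior_df=d0,
        residual_df=fit.residual_df,
        alpha=alpha,
        protein_ids=fit.protein_ids,
    )
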