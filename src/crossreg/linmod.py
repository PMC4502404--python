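"""Moderated per-feature linear models.

Fits one ordinary least-squares model per feature (gene or methylation
probe) on a shared design matrix and shrinks the residual variances toward
a common prior by empirical-Bayes moderation: a scaled inverse-chi-square
prior is fitted to the observed variance distribution by the method of
moments on the log residual variances, and each feature's variance is
replaced by the posterior mean.  The resulting moderated t-statistic has
``df_residual + prior_df`` degrees of freedom, which stabilises inference
with few samples per group.

This is the shared machinery behind both differential-expression and
differential-methylation testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ValidationError

#: Upper bound on the estimated prior degrees of freedom.  Very large
#: estimates arise when residual variances are nearly constant; capping
#: keeps the posterior df finite and the t reference distribution proper.
MAX_PRIOR_DF = 50.0


def _trigamma(x):
    return special.polygamma(1, x)


def _trigamma_inverse(y: float, iterations: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    # trigamma(x) ~ 1/x + 1/(2x^2) for large x, ~ 1/x^2 for small x
    x = 0.5 + 1.0 / y
    for _ in range(iterations):
        f = _trigamma(x) - y
        df = special.polygamma(2, x)
        step = f / df
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * abs(x):
            x = x_new
            break
        x = x_new
    return float(x)


def estimate_prior(s2: np.ndarray, df_residual: float) -> tuple[float, float]:
    """Fit a scaled inverse-chi-square prior to observed residual variances.

    Moment matching on ``log(s2)``: if s2 ~ s0^2 * F(df, d0) then the mean
    and variance of log(s2) are closed-form in digamma/trigamma, which we
    invert for the prior df ``d0`` and prior scale ``s0^2``.

    Returns ``(prior_df, prior_var)``.  ``prior_df`` is capped at
    :data:`MAX_PRIOR_DF`.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return MAX_PRIOR_DF, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df_residual / 2.0) + np.log(df_residual / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - _trigamma(df_residual / 2.0)
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
    else:
        d0 = np.inf
    d0 = min(d0, MAX_PRIOR_DF)
    if np.isfinite(d0):
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:  # pragma: no cover - d0 is capped above
        s0_sq = np.exp(e_mean)
    return float(d0), float(s0_sq)


def design_from_factor(factor: pd.Series, contrast: tuple[str, str]):
    """Cell-means design matrix for a categorical factor.

    Returns ``(X, c, levels)`` where ``X`` is samples x levels one-hot and
    ``c`` picks ``contrast[0] - contrast[1]``.
    """
    factor = pd.Series(factor)
    levels = sorted(map(str, factor.unique()))
    for lv in contrast:
        if str(lv) not in levels:
            raise ValidationError(f"contrast level {lv!r} not present in factor")
    X = np.column_stack([(factor.astype(str) == lv).to_numpy(float) for lv in levels])
    c = np.zeros(len(levels))
    c[levels.index(str(contrast[0]))] = 1.0
    c[levels.index(str(contrast[1]))] = -1.0
    return X, c, levels


@dataclass
class ModeratedFit:
    """Result of a moderated linear-model fit across features.

    Attributes
    ----------
    coef : effect estimate per feature for the requested contrast
    t : moderated t-statistic
    p : two-sided p-value from the t distribution with ``df_total`` df
    df_residual : residual degrees of freedom of the OLS fit
    prior_df : estimated (or supplied) prior degrees of freedom
    prior_var : prior variance scale
    s2_post : posterior residual variances
    """

    coef: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_residual: float
    prior_df: float
    prior_var: float
    s2_post: np.ndarray


def fit_moderated(
    y: np.ndarray,
    design: np.ndarray,
    contrast: np.ndarray,
    prior_df: float | None = None,
) -> ModeratedFit:
    """Fit per-feature OLS with empirical-Bayes variance moderation.

    Parameters
    ----------
    y : (n_features, n_samples) response matrix
    design : (n_samples, p) design matrix; must be full column rank
    contrast : length-p vector defining the tested linear combination
    prior_df : if given, use this prior df instead of estimating it.
        ``prior_df=0`` disables moderation: the statistic is then the
        classical t on the OLS fit.
    """
    y = np.asarray(y, float)
    X = np.asarray(design, float)
    c = np.asarray(contrast, float)
    n, p = X.shape
    if y.shape[1] != n:
        raise ValidationError(
            f"response has {y.shape[1]} samples but design has {n} rows"
        )
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        raise ValidationError("singular design matrix")
    df_resid = n - p
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom (n <= p)")
    xtx_inv = np.linalg.inv(xtx)
    beta = y @ (X @ xtx_inv)  # features x p
    resid = y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df_resid
    coef = beta @ c
    se_unit = float(np.sqrt(c @ xtx_inv @ c))

    if prior_df is None:
        d0, s0_sq = estimate_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 0.0
    if d0 > 0:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
    else:
        s2_post = s2
    df_total = df_resid + d0

    se = np.sqrt(s2_post) * se_unit
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    # degenerate features: zero effect and zero variance -> no evidence
    flat = (se == 0) & (coef == 0)
    t[flat] = 0.0
    p_val = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_val[np.isinf(t)] = 0.0
    return ModeratedFit(
        coef=coef,
        t=t,
        p=p_val,
        df_residual=float(df_resid),
        prior_df=float(d0),
        prior_var=float(s0_sq),
        s2_post=s2_post,
    )
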