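"""Inferential layer: regressions, ANOVA, mixed models and AICc comparison.

The question asked of the data is whether a species' relative abundance
(ln-transformed mean or maximum percent) predicts its stratigraphic
longevity.  The battery comprises:

* ordinary least squares of longevity on one ln-abundance metric, with
  residual diagnostics (normality, heteroscedasticity, sign-runs) reported
  as advisory only;
* one-way fixed-effects ANOVA of longevity across taxonomic orders or
  biogeographic categories;
* a linear mixed model with ln mean abundance as fixed effect and a random
  intercept on biogeographic category, fitted by maximum likelihood so its
  AIC is comparable with the fixed-effects regression;
* small-sample AICc and pairwise model comparison (positive delta favours
  the simpler model).

All p-values are two-sided and no multiple-testing correction is applied;
results are reported together so users can correct as they see fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.sandbox.stats.runs import runstest_1samp

logger = logging.getLogger(__name__)

__all__ = [
    "ModelResult",
    "AnovaResult",
    "ols_longevity",
    "residual_diagnostics",
    "one_way_anova",
    "mixed_model",
    "ancova_fixed",
    "aicc",
    "compare_models",
]


@dataclass
class ModelResult:
    """Summary of a fitted model, sufficient for reporting and AICc
    comparison."""

    model_label: str
    n: int
    k: int                      # estimated parameters incl. variance terms
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    r_squared: Optional[float]
    f_stat: Optional[float]
    p_value: Optional[float]    # slope test (OLS) / fixed-slope test (mixed)
    loglik: float
    aic: float
    aicc: float
    residuals: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    converged: bool = True
    notes: str = ""


@dataclass
class AnovaResult:
    groups: dict[str, dict]     # label -> {"n": int, "mean": float}
    f_stat: float
    p_value: float
    df_between: int
    df_within: int


# ----------------------------------------------------------------------
def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion:
    AIC + 2k(k+1)/(n-k-1) with AIC = 2k - 2 loglik."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return 2 * k - 2 * loglik + 2 * k * (k + 1) / (n - k - 1)


def ols_longevity(
    x: Sequence[float],
    y: Sequence[float],
    label: str = "ols",
) -> ModelResult:
    """OLS regression of longevity (my) on one ln-abundance metric.

    Returns slope/intercept with standard errors, R-squared, overall F, the
    two-sided slope-test p-value, log-likelihood and AIC/AICc (k = 3:
    intercept, slope, residual variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not np.isfinite(x).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in regression inputs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    n = int(fit.nobs)
    k = 3  # beta0, beta1, sigma^2
    return ModelResult(
        model_label=label,
        n=n,
        k=k,
        coefficients={"intercept": float(fit.params[0]), "slope": float(fit.params[1])},
        std_errors={"intercept": float(fit.bse[0]), "slope": float(fit.bse[1])},
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        p_value=float(fit.pvalues[1]),
        loglik=float(fit.llf),
        aic=2 * k - 2 * float(fit.llf),
        aicc=aicc(float(fit.llf), k, n),
        residuals=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
    )


def residual_diagnostics(m: ModelResult) -> dict:
    """Advisory residual diagnostics for a fitted regression.

    Reports Shapiro-Wilk normality, Breusch-Pagan heteroscedasticity and a
    runs test on residual signs (sensitive to unmodelled curvature), plus the
    residual-vs-fitted table.  These never gate anything downstream."""
    resid = m.residuals
    out: dict = {
        "model_label": m.model_label,
        "table": pd.DataFrame({"fitted": m.fitted, "residual": resid}),
    }
    if np.allclose(resid, 0):
        out.update(
            shapiro_w=np.nan, shapiro_p=np.nan,
            bp_lm=np.nan, bp_p=np.nan, runs_z=np.nan, runs_p=np.nan,
            degenerate=True,
        )
        return out
    sw = scipy.stats.shapiro(resid)
    exog = sm.add_constant(m.fitted)
    bp_lm, bp_p, _, _ = het_breuschpagan(resid, exog)
    order = np.argsort(m.fitted, kind="stable")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        runs_z, runs_p = runstest_1samp(resid[order], cutoff=0, correction=False)
    out.update(
        shapiro_w=float(sw.statistic), shapiro_p=float(sw.pvalue),
        bp_lm=float(bp_lm), bp_p=float(bp_p),
        runs_z=float(runs_z), runs_p=float(runs_p),
        degenerate=False,
    )
    return out


def one_way_anova(values: Sequence[float], labels: Sequence[str]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA of longevity across groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size != labels.size:
        raise ValueError("values and labels lengths differ")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("ANOVA needs at least two groups")
    groups = {}
    arrays = []
    for lab in uniq:
        vals = values[labels == lab]
        if len(vals) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 members")
        groups[str(lab)] = {"n": int(len(vals)), "mean": float(np.mean(vals))}
        arrays.append(vals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = scipy.stats.f_oneway(*arrays)
    if not np.isfinite(f_stat):
        # zero within-group variance: 0/0 when the means agree too
        means = np.array([np.mean(a) for a in arrays])
        if np.ptp(means) == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    return AnovaResult(
        groups=groups,
        f_stat=float(f_stat),
        p_value=float(p),
        df_between=len(uniq) - 1,
        df_within=int(values.size - len(uniq)),
    )


def mixed_model(
    y: Sequence[float],
    x: Sequence[float],
    g: Sequence[str],
    label: str = "mixed",
) -> ModelResult:
    """Longevity ~ ln mean abundance with a random intercept on
    biogeographic category, fitted by maximum likelihood (not REML) so that
    AIC comparison against the fixed-effects regression is valid.

    A random intercept on a two-level factor is weakly identified; a singular
    fit (variance component at zero) is reported with a warning, not an
    error.  k = 4: intercept, slope, group variance, residual variance.
    """
    df = pd.DataFrame({
        "y": np.asarray(y, dtype=float),
        "x": np.asarray(x, dtype=float),
        "g": np.asarray(g).astype(str),
    })
    if df["g"].nunique() < 2:
        raise ValueError("need at least two biogeographic categories")
    if len(df) < 10:
        raise ValueError("need at least 10 observations")

    model = smf.mixedlm("y ~ x", df, groups=df["g"])
    # gradient methods that land exactly on the zero-variance boundary can
    # report a degenerate likelihood or a singular Hessian; Powell stays
    # just off the boundary and always returns a usable fit
    fit = None
    last_err: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "nm"):
            try:
                cand = model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
                continue
            if np.isfinite(cand.llf):
                fit = cand
                break
    if fit is None:
        raise RuntimeError(f"mixed model failed to fit: {last_err}")

    re_var = float(fit.cov_re.iloc[0, 0])
    notes = ""
    if re_var < 1e-8:
        notes = "singular fit: random-intercept variance estimated at 0"
        logger.warning(notes)

    n = int(fit.nobs)
    k = 4
    ll = float(fit.llf)
    # marginal (fixed-effects) fitted values: defined even for singular fits
    fitted = (
        float(fit.params["Intercept"]) + float(fit.params["x"]) * df["x"].to_numpy()
    )
    return ModelResult(
        model_label=label,
        n=n,
        k=k,
        coefficients={
            "intercept": float(fit.params["Intercept"]),
            "slope": float(fit.params["x"]),
            "group_var": re_var,
            "resid_var": float(fit.scale),
        },
        std_errors={
            "intercept": float(fit.bse["Intercept"]),
            "slope": float(fit.bse["x"]),
        },
        r_squared=None,
        f_stat=None,
        p_value=float(fit.pvalues["x"]),
        loglik=ll,
        aic=2 * k - 2 * ll,
        aicc=aicc(ll, k, n),
        residuals=df["y"].to_numpy() - fitted,
        fitted=fitted,
        converged=bool(fit.converged),
        notes=notes,
    )


def ancova_fixed(
    y: Sequence[float],
    x: Sequence[float],
    g: Sequence[str],
    label: str = "ancova",
) -> ModelResult:
    """Fixed-effects sensitivity variant: longevity ~ ln abundance + category
    as a fixed factor (for when the 2-level random intercept is too fragile)."""
    df = pd.DataFrame({
        "y": np.asarray(y, dtype=float),
        "x": np.asarray(x, dtype=float),
        "g": np.asarray(g).astype(str),
    })
    fit = smf.ols("y ~ x + C(g)", df).fit()
    n = int(fit.nobs)
    k = int(fit.df_model) + 2  # coefficients + residual variance
    ll = float(fit.llf)
    coefs = {name: float(v) for name, v in fit.params.items()}
    return ModelResult(
        model_label=label,
        n=n,
        k=k,
        coefficients=coefs,
        std_errors={name: float(v) for name, v in fit.bse.items()},
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        p_value=float(fit.pvalues["x"]),
        loglik=ll,
        aic=2 * k - 2 * ll,
        aicc=aicc(ll, k, n),
        residuals=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
    )


def compare_models(complex_model: ModelResult, simple_model: ModelResult) -> dict:
    """Delta AICc = AICc(complex) - AICc(simple); positive delta means the
    simpler model is preferred.  Both models must be fitted to the same
    response vector."""
    if complex_model.n != simple_model.n:
        raise ValueError(
            f"models fitted to different n ({complex_model.n} vs {simple_model.n})"
        )
    delta = complex_model.aicc - simple_model.aicc
    preferred = simple_model.model_label if delta >= 0 else complex_model.model_label
    return {
        "delta_aicc": float(delta),
        "preferred": preferred,
        "complex": complex_model.model_label,
        "simple": simple_model.model_label,
    }
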