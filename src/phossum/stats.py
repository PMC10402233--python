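"""Regression battery for phosphene-shape analysis.

Models follow the statsmodels idiom: a model object is built from data and
``fit()`` returns a results object carrying estimates, uncertainties and
diagnostics, with a ``summary()`` table.

- :class:`StandardizedOLS`: multiple linear regression on z-scored response
  and predictors, reporting standardized coefficients (beta) and partial
  correlations (residualization convention) per predictor.
- :class:`SummationRegression`: no-intercept simple regression of a
  paired-electrode descriptor on the sum of the two single-electrode
  descriptors; a slope in (0.5, 1) means paired percepts are larger than the
  average of their single-electrode counterparts but smaller than their sum.
- :class:`MixedShapeModel`: linear mixed-effects model with a participant
  random intercept (REML by default; ML for information criteria).

Information criteria use the Gaussian log-likelihood with the ML variance
estimate; the parameter count includes the intercept (when present) and the
residual variance, so AIC/BIC differences between models fitted to the same
response are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "StandardizedOLS",
    "SummationRegression",
    "MixedShapeModel",
    "RegressionResult",
    "ModelComparison",
    "bonferroni",
    "vif",
    "welch_t_from_summary",
    "compare_models",
    "qq_normality",
]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def bonferroni(p, m: int):
    """Bonferroni-adjusted p-values: min(1, p * m)."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    out = np.minimum(1.0, p * m)
    return float(out) if out.ndim == 0 else out


def vif(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Variance inflation factor per predictor: 1 / (1 - R^2_j).

    R^2_j is from regressing predictor j (with intercept) on the others.
    Perfect collinearity raises.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one column")
    n, p = X.shape
    if p == 1:
        return np.array([1.0])
    out = np.empty(p)
    for j in range(p):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        if r2 > 1 - 1e-12:
            raise ValueError(f"predictor {j} is perfectly collinear")
        out[j] = 1.0 / (1.0 - r2)
    return out


def welch_t_from_summary(m1: float, sem1: float, m2: float, sem2: float) -> float:
    """Welch's t from group means and standard errors of the mean.

    t = (m1 - m2) / sqrt(sem1^2 + sem2^2).  Only the t value is computed;
    printed degrees of freedom in source tables are not reproduced.
    """
    if sem1 < 0 or sem2 < 0:
        raise ValueError("standard errors must be non-negative")
    denom = np.hypot(sem1, sem2)
    if denom == 0:
        raise ValueError("both standard errors are zero")
    return float((m1 - m2) / denom)


def qq_normality(residuals, plot_ax=None) -> float:
    """Correlation of sample vs theoretical normal quantiles.

    The quantile-quantile correlation of the residuals against the standard
    normal (Blom plotting positions); values near 1 indicate normality.
    Optionally draws the Q-Q plot onto ``plot_ax``.
    """
    r = np.sort(np.asarray(residuals, dtype=float))
    n = r.size
    if n < 10:
        raise ValueError("need at least 10 residuals")
    if r.std(ddof=0) == 0:
        raise ValueError("residuals are constant")
    q = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    corr = float(np.corrcoef(q, r)[0, 1])
    if plot_ax is not None:
        plot_ax.plot(q, r, "o", ms=3)
        plot_ax.set_xlabel("theoretical normal quantiles")
        plot_ax.set_ylabel("sample quantiles")
        plot_ax.set_title(f"Q-Q (r = {corr:.4f})")
    return corr


def _gaussian_ic(resid: np.ndarray, k_mean: int) -> tuple[float, float, float]:
    """(llf, aic, bic) from residuals with the ML variance estimate.

    ``k_mean`` counts mean-structure parameters; the residual variance adds
    one more to the penalty.
    """
    n = resid.size
    ssr = float(resid @ resid)
    sigma2 = max(ssr / n, 1e-300)
    llf = -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0)
    k = k_mean + 1
    return llf, -2 * llf + 2 * k, -2 * llf + k * np.log(n)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Estimates and diagnostics of one fitted regression."""

    model_name: str
    predictor_names: list[str]
    beta: np.ndarray                 # standardized coefficients
    partial_r: np.ndarray            # partial correlation per predictor
    pvalues: np.ndarray              # raw two-sided
    pvalues_bonferroni: np.ndarray
    n: int
    aic: float
    bic: float
    llf: float
    vif: np.ndarray | None
    resid: np.ndarray
    intercept: float | None = None
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"{self.model_name}  (n = {self.n})",
            f"AIC = {self.aic:.3f}   BIC = {self.bic:.3f}",
            f"{'predictor':<22}{'beta':>10}{'r':>10}{'p':>12}{'p(bonf)':>12}"
            + ("" if self.vif is None else f"{'VIF':>8}"),
        ]
        for i, name in enumerate(self.predictor_names):
            row = (
                f"{name:<22}{self.beta[i]:>10.4f}{self.partial_r[i]:>10.4f}"
                f"{self.pvalues[i]:>12.4g}{self.pvalues_bonferroni[i]:>12.4g}"
            )
            if self.vif is not None:
                row += f"{self.vif[i]:>8.2f}"
            lines.append(row)
        if "interpretation" in self.extra:
            lines.append(self.extra["interpretation"])
        return "\n".join(lines)

    def qq_normality(self) -> float:
        return qq_normality(self.resid)


@dataclass
class ModelComparison:
    """AIC/BIC comparison of two fits of the same response."""

    delta_aic: float            # AIC(A) - AIC(B); positive favors B
    delta_bic: float
    aic_band: str
    bic_band: str
    winner: str                 # 'A', 'B' or 'tie'
    aic_a: float
    aic_b: float
    bic_a: float
    bic_b: float

    #: Qualitative evidence bands on |delta|: below the first edge both
    #: models are supported; past the second there is strong evidence
    #: against the model with the higher criterion.
    AIC_EDGES = (2.0, 7.0)
    BIC_EDGES = (2.0, 6.0)

    def summary(self) -> str:
        return (
            f"AIC: A = {self.aic_a:.3f}, B = {self.aic_b:.3f}, "
            f"dAIC = {self.delta_aic:.3f} ({self.aic_band})\n"
            f"BIC: A = {self.bic_a:.3f}, B = {self.bic_b:.3f}, "
            f"dBIC = {self.delta_bic:.3f} ({self.bic_band})\n"
            f"preferred model: {self.winner}"
        )


def _band(delta: float, edges: tuple[float, float]) -> str:
    d = abs(delta)
    if d < edges[0]:
        return "both supported"
    if d < edges[1]:
        return "some evidence"
    return "strong evidence"


def compare_models(fit_a: RegressionResult, fit_b: RegressionResult) -> ModelComparison:
    """Compare two fits of the same response via AIC/BIC."""
    if fit_a.n != fit_b.n:
        raise ValueError("models were fitted to different numbers of points")
    d_aic = fit_a.aic - fit_b.aic
    d_bic = fit_a.bic - fit_b.bic
    if abs(d_aic) < ModelComparison.AIC_EDGES[0]:
        winner = "tie"
    else:
        winner = "B" if d_aic > 0 else "A"
    return ModelComparison(
        delta_aic=d_aic,
        delta_bic=d_bic,
        aic_band=_band(d_aic, ModelComparison.AIC_EDGES),
        bic_band=_band(d_bic, ModelComparison.BIC_EDGES),
        winner=winner,
        aic_a=fit_a.aic,
        aic_b=fit_b.aic,
        bic_a=fit_a.bic,
        bic_b=fit_b.bic,
    )


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance column cannot be standardized")
    return (a - a.mean()) / sd


class StandardizedOLS:
    """Multiple regression on z-scored response and predictors.

    Reports the standardized coefficient beta and, per predictor, the
    partial correlation computed by the residualization convention:
    the Pearson correlation between the residuals of y and of X_j after
    each is regressed (with intercept) on the remaining predictors.
    """

    def __init__(self, y, X, predictor_names: list[str] | None = None,
                 intercept: bool = True, name: str = "StandardizedOLS"):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if y.shape[0] != X.shape[0]:
            raise ValueError("y and X must have the same number of rows")
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
        if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
            raise ValueError("predictor matrix is rank deficient")
        self.y = y
        self.X = X
        self.intercept = intercept
        self.name = name
        self.predictor_names = (
            predictor_names
            if predictor_names is not None
            else [f"x{j}" for j in range(p)]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       predictors: list[str], **kw) -> "StandardizedOLS":
        sub = df[[response] + predictors].dropna()
        return cls(sub[response].to_numpy(), sub[predictors].to_numpy(),
                   predictor_names=list(predictors), name=f"{response} ~ "
                   + " + ".join(predictors), **kw)

    def fit(self) -> RegressionResult:
        yz = _zscore(self.y)
        Xz = np.column_stack([_zscore(c) for c in self.X.T])
        design = sm.add_constant(Xz) if self.intercept else Xz
        res = sm.OLS(yz, design).fit()
        off = 1 if self.intercept else 0
        beta = res.params[off:]
        pvals = res.pvalues[off:]
        p = Xz.shape[1]
        partial = np.empty(p)
        for j in range(p):
            others = np.delete(Xz, j, axis=1)
            base = sm.add_constant(others) if others.size else \
                np.ones((len(yz), 1))
            ry = yz - base @ np.linalg.lstsq(base, yz, rcond=None)[0]
            rx = Xz[:, j] - base @ np.linalg.lstsq(base, Xz[:, j], rcond=None)[0]
            partial[j] = np.corrcoef(ry, rx)[0, 1]
        llf, aic, bic = _gaussian_ic(res.resid, design.shape[1])
        return RegressionResult(
            model_name=self.name,
            predictor_names=self.predictor_names,
            beta=np.asarray(beta),
            partial_r=partial,
            pvalues=np.asarray(pvals),
            pvalues_bonferroni=bonferroni(np.asarray(pvals), max(p, 1)),
            n=len(yz),
            aic=aic,
            bic=bic,
            llf=llf,
            vif=vif(Xz) if p > 1 else np.array([1.0]),
            resid=np.asarray(res.resid),
            intercept=float(res.params[0]) if self.intercept else None,
        )


class SummationRegression:
    """No-intercept regression of paired descriptors on summed singles.

    The intercept is omitted because a zero predictor (no single-electrode
    percept) must imply a zero paired percept.  The slope is the closed-form
    sum(x*y)/sum(x^2); the reported r is the Pearson correlation.
    """

    def __init__(self, paired, sum_of_singles, name: str = "paired ~ 0 + sum(singles)"):
        y = np.asarray(paired, dtype=float)
        x = np.asarray(sum_of_singles, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("paired and sum_of_singles must be 1-D, same length")
        if y.size < 3:
            raise ValueError("need at least 3 pairs")
        if (y < 0).any() or (x < 0).any():
            raise ValueError("descriptor totals must be non-negative")
        if not (x > 0).any():
            raise ValueError("all-zero predictor")
        self.y = y
        self.x = x
        self.name = name

    def fit(self) -> RegressionResult:
        res = sm.OLS(self.y, self.x[:, None]).fit()
        slope = float(res.params[0])
        pval = float(res.pvalues[0])
        r = float(np.corrcoef(self.x, self.y)[0, 1])
        llf, aic, bic = _gaussian_ic(res.resid, 1)
        interp = (
            "paired percepts larger than the single-electrode average but "
            "smaller than their sum (0.5 < slope < 1)"
            if 0.5 < slope < 1.0
            else "slope outside (0.5, 1): no sub-additive summation flag"
        )
        return RegressionResult(
            model_name=self.name,
            predictor_names=["sum_of_singles"],
            beta=np.array([slope]),
            partial_r=np.array([r]),
            pvalues=np.array([pval]),
            pvalues_bonferroni=np.array([pval]),
            n=self.y.size,
            aic=aic,
            bic=bic,
            llf=llf,
            vif=None,
            resid=np.asarray(res.resid),
            intercept=None,
            extra={"interpretation": interp},
        )


class MixedShapeModel:
    """Linear mixed-effects model with a per-group random intercept.

    Fixed effects are the z-scored predictors (plus intercept); the grouping
    factor is the participant.  REML by default; information criteria are
    always computed from an ML fit of the same model so they are comparable
    across fixed-effect structures.  Partial correlations are approximated
    from the fixed-effect t statistics, r = t / sqrt(t^2 + df).
    """

    def __init__(self, y, X, groups, predictor_names: list[str] | None = None,
                 standardize: bool = True, name: str = "MixedShapeModel"):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        groups = np.asarray(groups)
        if not (len(y) == len(X) == len(groups)):
            raise ValueError("y, X and groups must have the same length")
        if len(np.unique(groups)) < 2:
            raise ValueError("need at least 2 groups for a random intercept")
        self.y = y
        self.X = X
        self.groups = groups
        self.standardize = standardize
        self.name = name
        self.predictor_names = (
            predictor_names
            if predictor_names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       predictors: list[str], groups: str = "participant",
                       **kw) -> "MixedShapeModel":
        sub = df[[response] + predictors + [groups]].dropna()
        return cls(sub[response].to_numpy(), sub[predictors].to_numpy(),
                   sub[groups].to_numpy(), predictor_names=list(predictors),
                   name=f"{response} ~ " + " + ".join(predictors)
                   + f" + (1|{groups})", **kw)

    def fit(self, reml: bool = True) -> RegressionResult:
        X = self.X
        if self.standardize:
            X = np.column_stack([_zscore(c) for c in X.T])
            y = _zscore(self.y)
        else:
            y = self.y
        exog = sm.add_constant(X)
        model = sm.MixedLM(y, exog, groups=self.groups)
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = model.fit(reml=reml, method=["powell", "lbfgs"])
        if not res.converged:
            raise RuntimeError(
                f"mixed model did not converge: {self.name}; "
                f"gradient norm unavailable, try rescaling predictors"
            )
        # ML fit of the same model for comparable information criteria
        if reml:
            with np.errstate(all="ignore"), _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                res_ml = model.fit(reml=False, method=["powell", "lbfgs"])
        else:
            res_ml = res
        beta = np.asarray(res.fe_params)[1:]
        pvals = np.asarray(res.pvalues)[1 : 1 + X.shape[1]]
        tvals = np.asarray(res.tvalues)[1 : 1 + X.shape[1]]
        df_resid = len(y) - exog.shape[1]
        partial = tvals / np.sqrt(tvals**2 + df_resid)
        try:
            resid = np.asarray(res.resid)
        except (ValueError, np.linalg.LinAlgError):
            # singular random-effects covariance: fall back to marginal resid
            resid = y - exog @ np.asarray(res.fe_params)
        k = exog.shape[1] + 2  # fixed effects + random-intercept var + resid var
        llf = float(res_ml.llf)
        aic = -2 * llf + 2 * k
        bic = -2 * llf + k * np.log(len(y))
        p = X.shape[1]
        return RegressionResult(
            model_name=self.name,
            predictor_names=self.predictor_names,
            beta=beta,
            partial_r=partial,
            pvalues=pvals,
            pvalues_bonferroni=bonferroni(pvals, max(p, 1)),
            n=len(y),
            aic=aic,
            bic=bic,
            llf=llf,
            vif=vif(X) if p > 1 else np.array([1.0]),
            resid=resid,
            converged=bool(res.converged),
            extra={"random_intercept_var": float(np.asarray(res.cov_re)[0, 0]),
                   "reml": reml},
        )
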