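"""Random-effects meta-analysis of cohort prevalences.

Per-cohort prevalences are pooled on the logit scale (boundedness; the
standard choice for proportions) with inverse-variance weights and the
DerSimonian-Laird moment estimator of the between-cohort variance tau2.
Heterogeneity is summarised by Cochran's Q and I2 = max(0, (Q-df)/Q)*100
with a test-based (Higgins-Thompson) confidence interval.  Subgroup
analyses pool each stratum separately (its own tau2) and compare stratum
means with a random-effects between-group Q statistic; meta-regression
uses study-level moderators with a method-of-moments residual tau2 and the
omnibus Wald statistic QM on the moderator coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PrevalenceEstimate",
    "MetaResult",
    "SubgroupResult",
    "MetaRegressionResult",
    "cohort_prevalence",
    "pool_random_effects",
    "RandomEffectsMeta",
    "subgroup_analysis",
    "meta_regress",
    "leave_one_out",
    "bonferroni_threshold",
    "forest_table",
]


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _logit(p):
    return np.log(p / (1.0 - p))


@dataclass
class PrevalenceEstimate:
    """One cohort's prevalence with its logit-scale effect and variance."""

    cohort_id: object
    cases: int
    n: int
    p_hat: float
    transformed_effect: float
    se_transformed: float
    ci_low: float
    ci_high: float


def cohort_prevalence(cases: int, n: int, alpha: float = 0.05,
                      cohort_id=None) -> PrevalenceEstimate:
    """Prevalence with a normal-interval CI on the logit scale.

    The logit effect has se = sqrt(1/cases + 1/(n-cases)); zero or full
    cells get a 0.5 continuity correction so the logit stays finite.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= cases <= n:
        raise ValueError(f"cases={cases} outside [0, {n}]")
    p_hat = cases / n
    a, b = float(cases), float(n - cases)
    if a == 0.0 or b == 0.0:
        a, b = a + 0.5, b + 0.5
    eff = np.log(a / b)
    se = np.sqrt(1.0 / a + 1.0 / b)
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    lo, hi = _expit(eff - zq * se), _expit(eff + zq * se)
    if cases == 0:
        lo = 0.0
    if cases == n:
        hi = 1.0
    return PrevalenceEstimate(cohort_id, cases, n, p_hat, eff, se,
                              float(lo), float(hi))


@dataclass
class MetaResult:
    """Pooled random-effects result on the proportion scale."""

    k: int
    pooled_p: float
    ci_low: float
    ci_high: float
    pooled_logit: float
    se_pooled_logit: float
    tau2: float
    Q: float
    df: int
    I2: float
    I2_ci: tuple = (np.nan, np.nan)

    def summary(self) -> str:
        return (
            f"Random-effects pooled prevalence (k={self.k}): "
            f"{100 * self.pooled_p:.1f}% "
            f"(95% CI {100 * self.ci_low:.1f}-{100 * self.ci_high:.1f}%)\n"
            f"  tau2={self.tau2:.4f}  Q={self.Q:.2f} (df={self.df})  "
            f"I2={self.I2:.0f}% "
            f"(95% CI {self.I2_ci[0]:.0f}-{self.I2_ci[1]:.0f}%)"
        )

    def to_dict(self) -> dict:
        return {
            "k": self.k, "pooled_p": self.pooled_p,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "tau2": self.tau2, "Q": self.Q, "df": self.df,
            "I2": self.I2, "I2_ci": list(self.I2_ci),
        }


def _dl_tau2(y, v):
    """DerSimonian-Laird moment estimator on effects y with variances v."""
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    df = len(y) - 1
    c = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
    return tau2, Q, df


def _i2_ci(Q, df, alpha=0.05):
    """Test-based Higgins-Thompson confidence interval for I2 (percent)."""
    if df < 1:
        return (np.nan, np.nan)
    if Q > df + 1:
        se_ln_h = 0.5 * (np.log(Q) - np.log(df)) / (
            np.sqrt(2.0 * Q) - np.sqrt(2.0 * df - 1.0))
    else:
        if df < 2:
            return (np.nan, np.nan)
        se_ln_h = np.sqrt(1.0 / (2.0 * (df - 1.0))
                          * (1.0 - 1.0 / (3.0 * (df - 1.0) ** 2)))
    ln_h = 0.5 * np.log(max(Q / df, 1.0))
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    lo_h = max(np.exp(ln_h - zq * se_ln_h), 1.0)
    hi_h = max(np.exp(ln_h + zq * se_ln_h), 1.0)
    to_i2 = lambda h: 100.0 * (h ** 2 - 1.0) / h ** 2
    return (to_i2(lo_h), to_i2(hi_h))


class RandomEffectsMeta:
    """DerSimonian-Laird random-effects pooling of logit prevalences.

    Parameters
    ----------
    estimates : sequence of PrevalenceEstimate
    """

    def __init__(self, estimates):
        estimates = list(estimates)
        if len(estimates) < 2:
            raise ValueError("need at least two studies")
        if any(e.se_transformed <= 0 for e in estimates):
            raise ValueError("every study needs a positive standard error")
        self.estimates = estimates
        self.y = np.array([e.transformed_effect for e in estimates])
        self.v = np.array([e.se_transformed ** 2 for e in estimates])

    def fit(self, alpha: float = 0.05) -> MetaResult:
        tau2, Q, df = _dl_tau2(self.y, self.v)
        w = 1.0 / (self.v + tau2)
        mu = float(np.sum(w * self.y) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        zq = stats.norm.ppf(1.0 - alpha / 2.0)
        I2 = max(0.0, 100.0 * (Q - df) / Q) if Q > 0 else 0.0
        return MetaResult(
            k=len(self.y), pooled_p=float(_expit(mu)),
            ci_low=float(_expit(mu - zq * se)),
            ci_high=float(_expit(mu + zq * se)),
            pooled_logit=mu, se_pooled_logit=se,
            tau2=tau2, Q=Q, df=df, I2=I2, I2_ci=_i2_ci(Q, df, alpha))


def pool_random_effects(estimates, alpha: float = 0.05) -> MetaResult:
    """Functional form of :class:`RandomEffectsMeta` + ``fit``."""
    return RandomEffectsMeta(estimates).fit(alpha=alpha)


@dataclass
class SubgroupResult:
    strata: dict  # label -> MetaResult
    Q_between: float
    df_between: int
    p_between: float

    def to_dict(self) -> dict:
        return {
            "strata": {k: v.to_dict() for k, v in self.strata.items()},
            "Q_between": self.Q_between,
            "df_between": self.df_between,
            "p_between": self.p_between,
        }


def subgroup_analysis(estimates, stratum_labels, alpha=0.05) -> SubgroupResult:
    """Independent random-effects pooling per stratum plus a between-group
    heterogeneity test.

    Q_between = sum_g w_g (theta_g - theta_bar)^2 with w_g the inverse
    variance of each stratum's pooled logit, referred to chi2 with
    (#strata - 1) degrees of freedom.
    """
    labels = list(stratum_labels)
    if len(labels) != len(list(estimates)):
        raise ValueError("every estimate needs a stratum label")
    groups: dict = {}
    for e, lab in zip(estimates, labels):
        groups.setdefault(lab, []).append(e)
    if len(groups) < 2:
        raise ValueError("need at least two strata")
    strata = {}
    thetas, variances = [], []
    for lab in sorted(groups, key=str):
        es = groups[lab]
        if len(es) == 1:
            e = es[0]
            r = MetaResult(k=1, pooled_p=e.p_hat, ci_low=e.ci_low,
                           ci_high=e.ci_high,
                           pooled_logit=e.transformed_effect,
                           se_pooled_logit=e.se_transformed,
                           tau2=0.0, Q=0.0, df=0, I2=0.0)
        else:
            r = pool_random_effects(es, alpha=alpha)
        if r.se_pooled_logit <= 0:
            raise ValueError(f"stratum {lab!r} has zero pooled variance")
        strata[lab] = r
        thetas.append(r.pooled_logit)
        variances.append(r.se_pooled_logit ** 2)
    thetas = np.array(thetas)
    wg = 1.0 / np.array(variances)
    theta_bar = np.sum(wg * thetas) / np.sum(wg)
    Qb = float(np.sum(wg * (thetas - theta_bar) ** 2))
    dfb = len(strata) - 1
    p = float(stats.chi2.sf(Qb, dfb))
    return SubgroupResult(strata=strata, Q_between=Qb, df_between=dfb,
                          p_between=p)


@dataclass
class MetaRegressionResult:
    coef: pd.Series
    se: pd.Series
    QM: float
    df: int
    p: float
    tau2_residual: float
    tau2_base: float
    het_explained: float

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.to_dict(), "se": self.se.to_dict(),
            "QM": self.QM, "df": self.df, "p": self.p,
            "tau2_residual": self.tau2_residual,
            "tau2_base": self.tau2_base,
            "het_explained": self.het_explained,
        }


class MetaRegression:
    """Mixed-effects meta-regression with study-level moderators.

    ``design`` is a DataFrame (or 2-d array) of moderator columns; an
    intercept is prepended.  Categorical moderators should arrive
    dummy-coded against the alphabetically first level.  tau2 is the
    method-of-moments (DerSimonian-Laird-type) estimator generalised to a
    design matrix; QM is the Wald chi-square statistic on all moderator
    coefficients jointly.
    """

    def __init__(self, estimates, design):
        estimates = list(estimates)
        self.y = np.array([e.transformed_effect for e in estimates])
        self.v = np.array([e.se_transformed ** 2 for e in estimates])
        if isinstance(design, pd.DataFrame):
            self.names = ["intercept"] + list(design.columns)
            Z = design.to_numpy(dtype=float)
        else:
            Z = np.asarray(design, dtype=float)
            if Z.ndim == 1:
                Z = Z[:, None]
            self.names = ["intercept"] + [f"mod{j}" for j in range(Z.shape[1])]
        # constant moderators carry no contrast (they alias the intercept):
        # drop them rather than fail, so a no-op moderator yields QM = 0
        keep = [j for j in range(Z.shape[1]) if np.ptp(Z[:, j]) > 0]
        self.names = ["intercept"] + [self.names[1 + j] for j in keep]
        Z = Z[:, keep] if keep else np.empty((len(self.y), 0))
        self.X = np.column_stack([np.ones(len(self.y)), Z])
        k, p = self.X.shape
        if k <= p:
            raise ValueError("need more studies than design columns")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("rank-deficient moderator design")

    @staticmethod
    def _mom_tau2(y, v, X):
        """Moment estimator of residual tau2 given a design matrix."""
        W = np.diag(1.0 / v)
        XtW = X.T @ W
        H = W - XtW.T @ np.linalg.solve(XtW @ X, XtW)
        QE = float(y @ H @ y)
        k, p = X.shape
        denom = float(np.trace(H))
        return max(0.0, (QE - (k - p)) / denom) if denom > 0 else 0.0, QE

    def fit(self) -> MetaRegressionResult:
        y, v, X = self.y, self.v, self.X
        tau2_base, _ = self._mom_tau2(y, v, np.ones((len(y), 1)))
        tau2_res, _ = self._mom_tau2(y, v, X)
        w = 1.0 / (v + tau2_res)
        XtWX = X.T @ (w[:, None] * X)
        cov = np.linalg.inv(XtWX)
        beta = cov @ (X.T @ (w * y))
        p_mod = X.shape[1] - 1
        if p_mod == 0:
            QM, pval = 0.0, 1.0
        else:
            b_mod = beta[1:]
            cov_mod = cov[1:, 1:]
            QM = float(b_mod @ np.linalg.solve(cov_mod, b_mod))
            pval = float(stats.chi2.sf(QM, p_mod))
        het = 100.0 * max(0.0, 1.0 - tau2_res / tau2_base) \
            if tau2_base > 0 else 0.0
        return MetaRegressionResult(
            coef=pd.Series(beta, index=self.names),
            se=pd.Series(np.sqrt(np.diag(cov)), index=self.names),
            QM=QM, df=p_mod, p=pval,
            tau2_residual=tau2_res, tau2_base=tau2_base,
            het_explained=het)


def meta_regress(estimates, covariate_design) -> MetaRegressionResult:
    """Functional form of :class:`MetaRegression` + ``fit``."""
    return MetaRegression(estimates, covariate_design).fit()


def leave_one_out(estimates, alpha=0.05):
    """Re-pool k times, omitting one study each; input order preserved."""
    estimates = list(estimates)
    if len(estimates) < 3:
        raise ValueError("leave-one-out needs at least three studies")
    out = []
    for i, e in enumerate(estimates):
        rest = estimates[:i] + estimates[i + 1:]
        out.append((e.cohort_id, pool_random_effects(rest, alpha=alpha)))
    return out


def bonferroni_threshold(alpha: float, n_phenotypes: int,
                         n_tests_per_phenotype: int) -> float:
    """alpha / (phenotypes x tests per phenotype)."""
    if n_phenotypes < 1 or n_tests_per_phenotype < 1:
        raise ValueError("counts must be positive integers")
    return alpha / (n_phenotypes * n_tests_per_phenotype)


def forest_table(estimates, result: MetaResult) -> pd.DataFrame:
    """Forest-plot table: per-study proportion, CI and pooled weight (%)."""
    w = 1.0 / (np.array([e.se_transformed ** 2 for e in estimates])
               + result.tau2)
    w = 100.0 * w / w.sum()
    return pd.DataFrame({
        "study": [e.cohort_id for e in estimates],
        "p": [e.p_hat for e in estimates],
        "ci_low": [e.ci_low for e in estimates],
        "ci_high": [e.ci_high for e in estimates],
        "weight": w,
    })
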