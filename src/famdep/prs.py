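"""Polygenic-score computation and family-clustered prediction of MDD.

A polygenic risk score is the weighted sum of effect-allele dosages over a
weight table (variant id, effect allele, other allele, per-allele weight).
Dosage columns are labelled ``variant:allele`` with the allele the dosage
counts; scoring flips the dose (2 - dose) when the counted allele is the
weight table's other allele, and drops (with a warning count) variants
matching neither orientation.

Case-control prediction uses logistic GEE with an exchangeable working
correlation within families and robust sandwich standard errors, reporting
the odds ratio per standard deviation of the score.  Explained variance is
the Nagelkerke pseudo-R2 difference between the full and covariates-only
independence logistic models, with the Lee et al. ascertainment-corrected
conversion to the liability scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .varcomp import LiabilityScale

__all__ = [
    "read_weight_table",
    "compute_prs",
    "PrsGeeModel",
    "GeeFit",
    "gee_logistic",
    "decile_case_proportions",
    "plot_decile_proportions",
    "nagelkerke_r2",
    "pseudo_r2",
    "LiabilityConversion",
    "liability_r2",
]


def read_weight_table(path) -> pd.DataFrame:
    """Read a tab-delimited scoring file (variant_id, effect_allele,
    other_allele, weight)."""
    w = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    required = {"variant_id", "effect_allele", "other_allele", "weight"}
    missing = required - set(w.columns)
    if missing:
        raise ValueError(f"weight table missing columns {sorted(missing)}")
    if w["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in weight table")
    if not np.isfinite(w["weight"]).all():
        raise ValueError("non-finite weight")
    return w


def compute_prs(dosages: pd.DataFrame, weight_table: pd.DataFrame,
                standardize=True) -> pd.DataFrame:
    """Score individuals: raw_i = sum_m w_m * dose_im on the effect allele.

    ``dosages`` holds an ``individual_id`` column plus one column per
    variant named ``variantid:allele`` (the allele the dosage counts,
    entries in [0, 2]).  Doses whose counted allele is the weight table's
    other allele are flipped to ``2 - dose``; variants matching no weight
    row or neither allele are dropped and counted.  Returns a frame with
    ``individual_id, raw_score, z_score, n_variants_used``.
    """
    wt = weight_table.set_index("variant_id")
    cols, weights, flips = [], [], []
    n_dropped = 0
    for col in dosages.columns:
        if col == "individual_id" or ":" not in col:
            continue
        vid, allele = col.rsplit(":", 1)
        if vid not in wt.index:
            n_dropped += 1
            continue
        row = wt.loc[vid]
        if allele == row["effect_allele"]:
            flips.append(False)
        elif allele == row["other_allele"]:
            flips.append(True)
        else:
            warnings.warn(f"variant {vid}: dosage allele {allele!r} matches "
                          f"neither orientation; dropped")
            n_dropped += 1
            continue
        cols.append(col)
        weights.append(float(row["weight"]))
    if not cols:
        raise ValueError("no variants matched the weight table")
    D = dosages[cols].to_numpy(dtype=float)
    if D.min() < 0 or D.max() > 2:
        raise ValueError("dosages must lie in [0, 2]")
    flips = np.asarray(flips)
    D = np.where(flips[None, :], 2.0 - D, D)
    raw = D @ np.asarray(weights)
    out = pd.DataFrame({
        "individual_id": dosages["individual_id"].to_numpy()
        if "individual_id" in dosages else np.arange(len(dosages)),
        "raw_score": raw,
        "n_variants_used": len(cols),
    })
    if standardize:
        sd = raw.std(ddof=0)
        out["z_score"] = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
    return out


@dataclass
class GeeFit:
    """Family-clustered logistic GEE fit for a standardized score."""

    params: pd.Series
    bse: pd.Series  # robust (sandwich)
    or_per_sd: float
    or_ci: tuple
    alpha_working: float
    n_clusters: int
    n_obs: int
    results: object  # statsmodels GEEResults

    def summary(self) -> str:
        return (
            f"GEE logistic (exchangeable, {self.n_clusters} families, "
            f"n={self.n_obs})\n"
            f"  OR per SD of PRS: {self.or_per_sd:.3f} "
            f"(95% CI {self.or_ci[0]:.3f}-{self.or_ci[1]:.3f})\n"
            f"  working correlation alpha: {self.alpha_working:.4f}"
        )


class PrsGeeModel:
    """Logistic GEE of case status on a standardized PRS plus covariates.

    Thin model wrapper around statsmodels GEE with an exchangeable working
    correlation (families as clusters) and robust sandwich covariance.
    """

    def __init__(self, y, X, cluster_ids, exog_names=None, score_col=1):
        y = np.asarray(y, dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        X = np.asarray(X, dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular design matrix")
        # monotone-likelihood (separation) guard on the score column
        s = X[:, score_col]
        if s[y == 1].size and s[y == 0].size and \
                (s[y == 1].min() > s[y == 0].max()
                 or s[y == 1].max() < s[y == 0].min()):
            raise ValueError("separation detected on the score column")
        self.y, self.X = y, X
        self.groups = np.asarray(cluster_ids)
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(X.shape[1])])
        self.score_col = score_col

    def fit(self, alpha=0.05, maxiter=60) -> GeeFit:
        model = sm.GEE(self.y, self.X, groups=self.groups,
                       family=sm.families.Binomial(),
                       cov_struct=sm.cov_struct.Exchangeable())
        res = model.fit(maxiter=maxiter)
        params = pd.Series(res.params, index=self.exog_names)
        bse = pd.Series(res.bse, index=self.exog_names)
        b = params.iloc[self.score_col]
        se = bse.iloc[self.score_col]
        zq = norm.ppf(1 - alpha / 2)
        return GeeFit(
            params=params, bse=bse,
            or_per_sd=float(np.exp(b)),
            or_ci=(float(np.exp(b - zq * se)), float(np.exp(b + zq * se))),
            alpha_working=float(model.cov_struct.dep_params),
            n_clusters=len(np.unique(self.groups)),
            n_obs=len(self.y), results=res)


def gee_logistic(y, X, cluster_ids, exog_names=None, score_col=1) -> GeeFit:
    """Functional form of :class:`PrsGeeModel` + ``fit``."""
    return PrsGeeModel(y, X, cluster_ids, exog_names=exog_names,
                       score_col=score_col).fit()


def decile_case_proportions(z_scores, y, ids=None):
    """Case proportion per decile of the score, with a linear trend.

    Ties are broken by a stable sort on (z_score, individual id); decile g
    covers ranks [g*n/10, (g+1)*n/10).  Returns ``(table, trend)`` where
    the table has one row per decile (n, cases, proportion) and ``trend``
    holds the OLS slope of proportion on decile index with a 95% CI.
    """
    z = np.asarray(z_scores, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(z)
    if n < 10:
        raise ValueError("need at least 10 observations")
    ids = np.arange(n) if ids is None else np.asarray(ids)
    order = np.lexsort((ids, z))
    bounds = [round(g * n / 10) for g in range(11)]
    rows = []
    for g in range(10):
        sel = order[bounds[g]:bounds[g + 1]]
        rows.append({"decile": g + 1, "n": len(sel),
                     "cases": int(y[sel].sum()),
                     "proportion": float(y[sel].mean())})
    table = pd.DataFrame(rows)
    X = sm.add_constant(table["decile"].to_numpy(dtype=float))
    ols = sm.OLS(table["proportion"].to_numpy(), X).fit()
    ci = ols.conf_int()[1]
    trend = {"slope": float(ols.params[1]), "slope_se": float(ols.bse[1]),
             "ci_low": float(ci[0]), "ci_high": float(ci[1])}
    return table, trend


def plot_decile_proportions(table, trend=None, ax=None):
    """Decile-of-PRS case-proportion plot with the fitted trend band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = table["decile"].to_numpy(dtype=float)
    ax.scatter(x, table["proportion"], zorder=3)
    X = sm.add_constant(x)
    ols = sm.OLS(table["proportion"].to_numpy(), X).fit()
    pred = ols.get_prediction(X)
    band = pred.conf_int()
    ax.plot(x, pred.predicted_mean, color="C1")
    ax.fill_between(x, band[:, 0], band[:, 1], alpha=0.25, color="C1")
    ax.set_xlabel("PRS decile")
    ax.set_ylabel("proportion of cases")
    return ax


# ----------------------------------------------------------------------
# explained variance


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R2 from model and intercept-only log-likelihoods."""
    cs = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    return float(cs / (1.0 - np.exp(2.0 * ll_null / n)))


def pseudo_r2(y, X_full, X_null) -> float:
    """Nagelkerke pseudo-R2 attributable to the score.

    Both designs are fitted as plain (independence) logistic regressions on
    the same sample; the result is R2_N(full) - R2_N(covariates-only),
    each against the intercept-only likelihood.
    """
    y = np.asarray(y, dtype=float)
    X_full = np.asarray(X_full, dtype=float)
    X_null = np.asarray(X_null, dtype=float)
    if len(y) != len(X_full) or len(y) != len(X_null):
        raise ValueError("mismatched samples")
    n = len(y)
    ll_full = sm.Logit(y, X_full).fit(disp=False).llf
    ll_cov = sm.Logit(y, X_null).fit(disp=False).llf
    ll0 = sm.Logit(y, np.ones((n, 1))).fit(disp=False).llf
    return nagelkerke_r2(ll_full, ll0, n) - nagelkerke_r2(ll_cov, ll0, n)


@dataclass
class LiabilityConversion:
    """Lee et al. observed-to-liability R2 conversion with ascertainment."""

    K: float
    P: float
    t: float
    z: float
    c_factor: float
    theta: float
    r2_liability: float


def liability_r2(r2_observed: float, K: float, P: float
                 ) -> LiabilityConversion:
    """Ascertainment-corrected liability-scale R2 (Lee et al. 2012).

    c = [K(1-K)/z^2] * [K(1-K)/(P(1-P))]; a = (z/K)(P-K)/(1-K);
    theta = a(a - t); r2_liab = c*r2 / (1 + c*theta*r2).  With K = P the
    ascertainment term vanishes and only the scale factor remains.
    """
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("K and P must lie in (0, 1)")
    ls = LiabilityScale.from_prevalence(K)
    c = (K * (1 - K) / ls.z ** 2) * (K * (1 - K) / (P * (1 - P)))
    a = (ls.z / K) * (P - K) / (1 - K)
    theta = a * (a - ls.t)
    r2l = c * r2_observed / (1.0 + c * theta * r2_observed)
    return LiabilityConversion(K=K, P=P, t=ls.t, z=ls.z, c_factor=c,
                               theta=theta, r2_liability=float(r2l))
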