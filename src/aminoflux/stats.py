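"""Cohort endpoint comparison: normality gate, ln-transform policy, ROUT
outlier removal, one-way ANCOVA with age and BMI, and Benjamini-Hochberg
FDR within endpoint families.

The procedure mirrors standard covariate-adjusted group comparison practice
in clinical metabolic studies: each endpoint is tested for normality
(D'Agostino-Pearson omnibus K^2), ln-transformed when non-normal, screened
for outliers with the ROUT method (robust fit + FDR on residual t
p-values) on the scale where normality was confirmed, and compared between
groups with a linear model adjusting for age and BMI.  Group means are
reported as arithmetic mean [95% CI], or geometric mean [95% CI] when the
endpoint was analyzed on the ln scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .config import StatsConfig
from .errors import InputError, ModelError

__all__ = [
    "NormalityResult", "AncovaResult", "dagostino_pearson",
    "transform_policy", "rout_outliers", "ancova", "bh_fdr",
    "categorical_compare", "percent_difference", "percent_difference_ci",
    "group_mean_ci", "compare_endpoints",
]

_MIN_NORMALITY_N = 8
_MIN_ROUT_N = 10


@dataclass
class NormalityResult:
    k2: float
    p: float
    testable: bool

    @property
    def normal_at(self):
        return lambda alpha: (not self.testable) or self.p >= alpha


def dagostino_pearson(values) -> NormalityResult:
    """D'Agostino-Pearson omnibus test: K^2 = Z(skew)^2 + Z(kurt)^2 ~ chi2(2).

    Samples smaller than 8 are reported untestable (the kurtosis Z-score is
    undefined below that size) rather than given a p-value.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InputError("values must be finite")
    if x.size < _MIN_NORMALITY_N:
        return NormalityResult(k2=np.nan, p=np.nan, testable=False)
    k2, p = sps.normaltest(x)
    return NormalityResult(k2=float(k2), p=float(p), testable=True)


def transform_policy(values, config: StatsConfig):
    """Apply the study's ln-transform policy to one endpoint.

    Returns ``(values_out, transformed, status)`` where status is one of
    ``normal`` (no transform needed), ``untestable`` (sample too small to
    gate), ``transformed`` (ln applied, retest passed),
    ``transformed_nonnormal`` (ln applied, still non-normal; analysis
    proceeds on the ln scale with a warning), or ``non_transformable``
    (non-normal but contains non-positive values; analyzed untransformed).
    """
    x = np.asarray(values, dtype=float)
    res = dagostino_pearson(x)
    if not res.testable:
        return x, False, "untestable"
    if res.p >= config.normality_alpha:
        return x, False, "normal"
    if np.any(x <= 0):
        return x, False, "non_transformable"
    lx = np.log(x)
    res2 = dagostino_pearson(lx)
    status = ("transformed" if res2.p >= config.normality_alpha
              else "transformed_nonnormal")
    return lx, True, status


def _robust_constant_fit(x: np.ndarray, n_iter: int = 50):
    """Robust location via IRLS on the Lorentzian merit, with the robust
    residual SD taken from the 68.27th percentile of |residuals| and a
    small-sample correction n/(n - K), K = 1 fitted parameter."""
    m = float(np.median(x))
    n = x.size
    for _ in range(n_iter):
        r = x - m
        rsdr = float(np.percentile(np.abs(r), 68.27)) * n / (n - 1)
        rsdr = max(rsdr, 1e-300)
        w = 1.0 / (1.0 + (r / rsdr) ** 2)
        m_new = float(np.sum(w * x) / np.sum(w))
        if abs(m_new - m) <= 1e-12 * max(1.0, abs(m)):
            m = m_new
            break
        m = m_new
    r = x - m
    rsdr = float(np.percentile(np.abs(r), 68.27)) * n / (n - 1)
    return m, max(rsdr, 1e-300)


def rout_outliers(values, q: float = 0.05):
    """ROUT outlier detection for a single sample (constant model).

    Fits a robust location (Lorentzian-weighted IRLS), scales residuals by
    the robust SD (68.27th-percentile rule with small-sample correction),
    converts each scaled residual to a two-tailed t p-value (df = n - 1),
    and flags outliers by Benjamini-Hochberg at rate ``q``.  Samples with
    fewer than 10 points are returned untouched.

    Returns ``(kept_values, outlier_indices)``.
    """
    if not 0 < q < 1:
        raise InputError("q must be in (0, 1)")
    x = np.asarray(values, dtype=float)
    if x.size < _MIN_ROUT_N:
        return x.copy(), np.array([], dtype=int)
    m, rsdr = _robust_constant_fit(x)
    tstat = np.abs(x - m) / rsdr
    p = 2.0 * sps.t.sf(tstat, df=x.size - 1)
    reject = multipletests(p, alpha=q, method="fdr_bh")[0]
    out_idx = np.flatnonzero(reject)
    keep = np.delete(x, out_idx)
    return keep, out_idx


@dataclass
class AncovaResult:
    estimate: float            # adjusted CD - CN difference
    ci: tuple
    p: float
    n_per_group: dict = field(default_factory=dict)


def ancova(values, groups, covariates: pd.DataFrame,
           config: StatsConfig | None = None) -> AncovaResult:
    """One-way ANCOVA: endpoint ~ group + covariates (default age, BMI).

    ``groups`` must contain exactly the labels CN and CD; the reported
    estimate is the adjusted CD - CN difference with its two-sided CI and
    p-value.  Subjects with missing covariates are dropped listwise.
    """
    config = (config or StatsConfig()).validate()
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    cov = covariates.loc[:, list(config.covariates)].to_numpy(dtype=float)
    if y.size != g.size or cov.shape[0] != y.size:
        raise InputError("values, groups and covariates must align")
    keep = np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    y, g, cov = y[keep], g[keep], cov[keep]
    labels = set(g)
    if labels != {"CN", "CD"}:
        raise ModelError(f"need both CN and CD groups, got {sorted(labels)}")
    n_cn, n_cd = int(np.sum(g == "CN")), int(np.sum(g == "CD"))
    if min(n_cn, n_cd) < 3:
        raise InputError("need >= 3 subjects per group")
    X = np.column_stack([np.ones(y.size), (g == "CD").astype(float), cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("singular design (constant covariate or "
                         "collinear columns)")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=1 - config.ci_level)[1]
    return AncovaResult(estimate=float(fit.params[1]),
                        ci=(float(ci[0]), float(ci[1])),
                        p=float(fit.pvalues[1]),
                        n_per_group={"CN": n_cn, "CD": n_cd})


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforced:
    q_(i) = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def categorical_compare(table, method: str = "exact") -> float:
    """Two-sided test of association for a 2x2 contingency table.

    Default is Fisher's exact test; ``method='chi2'`` uses the chi-squared
    test with continuity correction.  An empty row or column margin makes
    the comparison undefined and returns NaN.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(
            t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
            raise InputError("table must be 2x2 nonnegative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return float("nan")
    if method == "exact":
        return float(sps.fisher_exact(t, alternative="two-sided")[1])
    if method == "chi2":
        return float(sps.chi2_contingency(t, correction=True)[1])
    raise InputError(f"unknown method {method!r}")


def percent_difference(cn_mean: float, cd_mean: float) -> float:
    """Percent difference of CD relative to CN: (CD - CN)/CN * 100."""
    if cn_mean == 0:
        raise InputError("CN reference mean must be non-zero")
    return (cd_mean - cn_mean) / cn_mean * 100.0


def percent_difference_ci(cn_values, cd_values, method: str = "bootstrap",
                          n_boot: int = 2000, ci_level: float = 0.95,
                          rng: np.random.Generator | None = None):
    """Percent difference with CI by nonparametric bootstrap (default) or
    the delta method."""
    x = np.asarray(cn_values, dtype=float)
    y = np.asarray(cd_values, dtype=float)
    est = percent_difference(x.mean(), y.mean())
    alpha = 1 - ci_level
    if method == "delta":
        # var of g = (my/mx - 1)*100 by first-order expansion
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        var = (100.0 / mx) ** 2 * vy + (100.0 * my / mx ** 2) ** 2 * vx
        z = sps.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        return est, (est - half, est + half)
    if method != "bootstrap":
        raise InputError(f"unknown method {method!r}")
    rng = rng or np.random.default_rng(0)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        xb = x[rng.integers(0, x.size, x.size)]
        yb = y[rng.integers(0, y.size, y.size)]
        reps[b] = percent_difference(xb.mean(), yb.mean())
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return est, (float(lo), float(hi))


def group_mean_ci(values, ci_level: float = 0.95, geometric: bool = False):
    """Mean [CI] of one group; with ``geometric=True`` the values are on
    the ln scale and the back-transformed geometric mean [CI] is
    returned."""
    x = np.asarray(values, dtype=float)
    n = x.size
    m = x.mean()
    if n > 1:
        half = sps.t.ppf(1 - (1 - ci_level) / 2, n - 1) * x.std(ddof=1) \
            / np.sqrt(n)
    else:
        half = np.nan
    lo, hi = m - half, m + half
    if geometric:
        return float(np.exp(m)), (float(np.exp(lo)), float(np.exp(hi)))
    return float(m), (float(lo), float(hi))


def _family_of(endpoint: str, config: StatsConfig) -> str:
    for fam, prefixes in config.families.items():
        if any(endpoint.startswith(p) for p in prefixes):
            return fam
    return "other"


def compare_endpoints(endpoint_long: pd.DataFrame, subjects: pd.DataFrame,
                      config: StatsConfig | None = None,
                      apply_rout: bool = True) -> pd.DataFrame:
    """Run the full endpoint-comparison procedure over a long table.

    Parameters
    ----------
    endpoint_long : DataFrame with columns subject_id, endpoint, value.
    subjects : DataFrame with columns subject_id, group and the configured
        covariates (default age, bmi).
    config : StatsConfig
    apply_rout : bool
        Disable to compare against the no-outlier-removal path.

    Returns
    -------
    DataFrame with one row per endpoint: group means with CIs (geometric
    when ln-transformed), the unadjusted t-test difference with CI, the
    covariate-adjusted difference with CI, ANCOVA p, BH q within the
    endpoint's family, and bookkeeping columns.
    """
    config = (config or StatsConfig()).validate()
    meta = subjects.set_index("subject_id")
    rows = []
    for endpoint, grp in endpoint_long.groupby("endpoint", sort=True):
        grp = grp.dropna(subset=["value"])
        sids = grp["subject_id"].to_numpy()
        vals = grp["value"].to_numpy(dtype=float)
        groups = meta.loc[sids, "group"].to_numpy()

        tvals, transformed, status = transform_policy(vals, config)

        # ROUT runs per group on the scale where normality was confirmed
        removed = 0
        if apply_rout and status in ("normal", "transformed"):
            keep_mask = np.ones(tvals.size, dtype=bool)
            for glab in ("CN", "CD"):
                idx = np.flatnonzero(groups == glab)
                _, out = rout_outliers(tvals[idx], q=config.rout_q)
                keep_mask[idx[out]] = False
                removed += out.size
            sids, vals, tvals, groups = (sids[keep_mask], vals[keep_mask],
                                         tvals[keep_mask],
                                         groups[keep_mask])

        cn_raw, cd_raw = vals[groups == "CN"], vals[groups == "CD"]
        cn_t, cd_t = tvals[groups == "CN"], tvals[groups == "CD"]
        mean_cn, ci_cn = group_mean_ci(cn_t, config.ci_level,
                                       geometric=transformed)
        mean_cd, ci_cd = group_mean_ci(cd_t, config.ci_level,
                                       geometric=transformed)

        # unadjusted "estimated difference" column: classic unpaired t-test
        # on the raw scale
        tt = sps.ttest_ind(cd_raw, cn_raw, equal_var=True)
        diff = float(cd_raw.mean() - cn_raw.mean())
        tdf = cn_raw.size + cd_raw.size - 2
        se = abs(diff / tt.statistic) if tt.statistic != 0 else np.nan
        tcrit = sps.t.ppf(1 - (1 - config.ci_level) / 2, tdf)
        d_lo, d_hi = diff - tcrit * se, diff + tcrit * se

        try:
            res = ancova(tvals, groups, meta.loc[sids], config)
            p, adj, adj_ci = res.p, res.estimate, res.ci
        except (InputError, ModelError):
            p, adj, adj_ci = np.nan, np.nan, (np.nan, np.nan)

        rows.append({
            "endpoint": endpoint, "family": _family_of(endpoint, config),
            "mean_cn": mean_cn, "ci_cn_low": ci_cn[0], "ci_cn_high": ci_cn[1],
            "mean_cd": mean_cd, "ci_cd_low": ci_cd[0], "ci_cd_high": ci_cd[1],
            "estimated_difference": diff, "ci_low": d_lo, "ci_high": d_hi,
            "adjusted_difference": adj, "adj_ci_low": adj_ci[0],
            "adj_ci_high": adj_ci[1], "p": p, "q": np.nan,
            "transformed": transformed, "normality_status": status,
            "n_cn": int(cn_raw.size), "n_cd": int(cd_raw.size),
            "outliers_removed": removed,
        })

    out = pd.DataFrame(rows)
    if out.empty:
        return out
    for fam, fgrp in out.groupby("family"):
        ok = fgrp.index[np.isfinite(fgrp["p"])]
        if len(ok):
            out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out
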