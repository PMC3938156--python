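"""Group comparison and correlation analyses on per-subject pathway metrics.

The group analysis mirrors the classical neuroimaging design: for each
diffusion parameter, per-pathway linear models ``value ~ group + age +
motion`` give the covariate-adjusted group effect (the per-pathway p-values
are the primary output), and a Wilks-lambda multivariate test across the
four pathways is reported as an omnibus.  Raw per-group mean and SD
accompany every test.  No multiple-comparison correction is applied to the
primary p-values; a Benjamini-Hochberg column is emitted alongside, clearly
labelled as an extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import log
from .pathways import flag_single_subject

__all__ = [
    "GroupResult",
    "PATHWAYS",
    "records_frame",
    "glm_group_test",
    "partial_correlation",
    "empirical_cdf",
    "flag_table",
    "age_regression",
]

PATHWAYS = ("L_DDN", "L_VDN", "R_DDN", "R_VDN")


@dataclass
class GroupResult:
    metric: str
    pathway: str
    estimate: float  # adjusted group effect (B - A)
    p_value: float
    mean_sd_A: tuple
    mean_sd_B: tuple
    p_bh: float | None = None  # Benjamini-Hochberg adjusted (extension)
    wilks_lambda: float | None = None
    wilks_p: float | None = None


def records_frame(records) -> pd.DataFrame:
    df = pd.DataFrame(records)
    if "group" not in df:
        raise ValueError("records need a 'group' column")
    return df


def _usable_covariates(df: pd.DataFrame, covariates) -> list:
    keep = []
    for c in covariates:
        if c not in df:
            continue
        if np.isclose(df[c].std(ddof=0), 0.0):
            log(f"covariate {c!r} is constant; dropped from the design")
            continue
        keep.append(c)
    return keep


def glm_group_test(records, metric: str, covariates=("age", "motion"),
                   pathways=PATHWAYS) -> list:
    """Covariate-adjusted group tests of one metric, one model per pathway.

    Fits ``value ~ group + age + motion`` per pathway by OLS and reports the
    group-effect estimate and its F-test p-value (t squared), plus the raw
    per-group mean and SD, a Benjamini-Hochberg column across the four
    pathways, and a Wilks-lambda omnibus across them.
    """
    import statsmodels.api as sm

    df = records_frame(records)
    cols = [f"{metric}_{p}" for p in pathways]
    missing = [c for c in cols if c not in df]
    if missing:
        raise ValueError(f"records lack columns {missing}")
    df = df.dropna(subset=cols)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    if (df["group"].value_counts() < 3).any():
        raise ValueError("need at least 3 subjects per group")
    covs = _usable_covariates(df, covariates)
    gind = (df["group"] == groups[1]).astype(float).to_numpy()

    results = []
    pvals = []
    for pw in pathways:
        y = df[f"{metric}_{pw}"].to_numpy(dtype=float)
        X = np.c_[np.ones(len(y)), gind] if not covs else np.c_[
            np.ones(len(y)), gind, df[covs].to_numpy(dtype=float)
        ]
        fit = sm.OLS(y, X).fit()
        est = float(fit.params[1])
        p = float(fit.pvalues[1])
        a = y[gind == 0]
        b = y[gind == 1]
        results.append(
            GroupResult(
                metric=metric,
                pathway=pw,
                estimate=est,
                p_value=p,
                mean_sd_A=(float(a.mean()), float(a.std(ddof=1))),
                mean_sd_B=(float(b.mean()), float(b.std(ddof=1))),
            )
        )
        pvals.append(p)
    # Benjamini-Hochberg across the four pathway tests (reporting extension)
    from statsmodels.stats.multitest import multipletests

    _, p_bh, *_ = multipletests(pvals, method="fdr_bh")
    for r, pb in zip(results, p_bh):
        r.p_bh = float(pb)

    # Wilks-lambda omnibus on covariate-residualized responses
    lam, wp = _wilks_lambda(df, metric, pathways, covs, gind)
    for r in results:
        r.wilks_lambda, r.wilks_p = lam, wp
    return results


def _wilks_lambda(df, metric, pathways, covs, gind):
    Y = df[[f"{metric}_{p}" for p in pathways]].to_numpy(dtype=float)
    n, q = Y.shape
    Z = np.c_[np.ones(n)] if not covs else np.c_[
        np.ones(n), df[covs].to_numpy(dtype=float)
    ]
    Xf = np.c_[Z, gind]
    # residual cross-product matrices under full and reduced models
    def resid_ss(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ beta
        return R.T @ R

    Ef = resid_ss(Xf)
    Er = resid_ss(Z)
    try:
        lam = float(np.linalg.det(Ef) / np.linalg.det(Er))
    except np.linalg.LinAlgError:
        return None, None
    if not np.isfinite(lam) or lam <= 0:
        return None, None
    # Rao's F approximation, one-df hypothesis: exact F(q, n - rank(Xf) - q + 1)
    df_err = n - Xf.shape[1]
    df2 = df_err - q + 1
    if df2 <= 0:
        return lam, None
    F = (1.0 - lam) / lam * df2 / q
    p = float(sps.f.sf(F, q, df2))
    return lam, p


def partial_correlation(records, metric: str, behavior: str,
                        covariates=("age", "motion")) -> tuple:
    """Partial Pearson correlation controlling for age and motion.

    Correlates the residuals of both variables after OLS regression on the
    covariates; the p-value uses a t reference with n - 4 degrees of freedom
    (two covariates plus the intercept and the correlation itself).
    """
    df = records_frame(records).dropna(subset=[metric, behavior])
    if len(df) < 5:
        raise ValueError("need at least 5 complete records")
    covs = _usable_covariates(df, covariates)
    Z = np.c_[np.ones(len(df))] if not covs else np.c_[
        np.ones(len(df)), df[covs].to_numpy(dtype=float)
    ]
    def residual(col):
        y = df[col].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        return y - Z @ beta

    rx, ry = residual(metric), residual(behavior)
    if np.allclose(rx.std(), 0) or np.allclose(ry.std(), 0):
        raise ValueError("zero-variance residuals; correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = len(df) - 2 - len(covs)
    r_clamped = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clamped * np.sqrt(dof / (1.0 - r_clamped**2))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return r, p


def empirical_cdf(values) -> pd.DataFrame:
    """Step-function table P(parameter <= X) at each observed value."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("empirical CDF of an empty sample")
    p = np.arange(1, len(v) + 1) / len(v)
    return pd.DataFrame({"value": v, "cdf": p})


def flag_table(records, metrics, pathways=PATHWAYS,
               criteria=("lower_decile", "three_se"),
               leave_one_out: bool = False) -> pd.DataFrame:
    """Percentage of group-B subjects flagged per pathway x metric x criterion.

    With ``leave_one_out`` the table instead scores each group-A subject
    against the rest of group A (a self-calibration check).  Percentages are
    rounded to whole percent.
    """
    df = records_frame(records)
    a = df[df["group"] == "A"]
    b = df[df["group"] == "B"]
    rows = []
    for pw in pathways:
        for metric in metrics:
            col = f"{metric}_{pw}"
            if col not in df:
                continue
            ref_all = a[col].dropna().to_numpy(dtype=float)
            if len(ref_all) < 2:
                log(f"flag table: reference group too small for {col}; skipped")
                continue
            row = {"pathway": pw, "metric": metric}
            for crit in criteria:
                if leave_one_out:
                    flags = [
                        flag_single_subject(v, np.delete(ref_all, i), crit)
                        for i, v in enumerate(ref_all)
                    ]
                else:
                    vals = b[col].dropna().to_numpy(dtype=float)
                    flags = [flag_single_subject(v, ref_all, crit) for v in vals]
                row[crit] = int(round(100.0 * np.mean(flags))) if flags else 0
            rows.append(row)
    return pd.DataFrame(rows)


def age_regression(records, response: str, group: str | None = None) -> tuple:
    """OLS of a response on age within one group: returns (R^2, p, slope)."""
    df = records_frame(records)
    if group is not None:
        df = df[df["group"] == group]
    df = df.dropna(subset=[response, "age"])
    if len(df) < 3:
        raise ValueError("need at least 3 records")
    age = df["age"].to_numpy(dtype=float)
    if np.isclose(age.std(), 0.0):
        raise ValueError("constant age; regression undefined")
    y = df[response].to_numpy(dtype=float)
    res = sps.linregress(age, y)
    return float(res.rvalue**2), float(res.pvalue), float(res.slope)
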