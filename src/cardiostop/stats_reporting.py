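"""Statistical layer: paired comparisons with mean-difference CIs, OLS
regressions, the 10-variable Pearson correlation matrix with
Benjamini-Hochberg FDR adjustment, and report-table assembly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VARIABLES",
    "PairedTestResult",
    "CorrelationTable",
    "paired_t",
    "linear_regression",
    "fdr_adjust",
    "correlation_matrix_fdr",
    "build_reports",
    "ReportBundle",
]


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up with cumulative
    minimum, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]

logger = logging.getLogger(__name__)

#: correlation-table variables (column names of the cohort results frame)
VARIABLES = ("ssrt_systole", "ssrt_diastole", "ssd_systole", "ssd_diastole",
             "hrv", "bpm", "barratt", "accuracy", "awareness", "sensibility")

#: display labels for report tables
VARIABLE_LABELS = {
    "ssrt_systole": "SSRT-s", "ssrt_diastole": "SSRT-d",
    "ssd_systole": "SSD-s", "ssd_diastole": "SSD-d",
    "hrv": "HRV", "bpm": "bpm", "barratt": "Barratt",
    "accuracy": "Interoceptive accuracy",
    "awareness": "Interoceptive awareness",
    "sensibility": "Interoceptive sensibility",
}


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    ci95: tuple[float, float]
    eta_squared: float       # t^2 / (t^2 + df)


def paired_t(x, y) -> PairedTestResult:
    """Classical paired t-test with a 95% CI of the mean difference and an
    eta-squared effect size derived as t^2/(t^2 + df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("paired_t needs two equal-length 1-d samples, n >= 3")
    d = x - y
    if np.var(d, ddof=1) == 0.0:
        raise ValueError("degenerate pairing: zero variance of differences")
    n = d.size
    df = n - 1
    res = stats.ttest_rel(x, y)
    se = d.std(ddof=1) / math.sqrt(n)
    tcrit = stats.t.ppf(0.975, df)
    mean_diff = float(d.mean())
    t = float(res.statistic)
    return PairedTestResult(
        t=t, df=df, p=float(res.pvalue), mean_diff=mean_diff,
        ci95=(mean_diff - tcrit * se, mean_diff + tcrit * se),
        eta_squared=t * t / (t * t + df),
    )


@dataclass(frozen=True)
class RegressionResult:
    f: float
    df_model: int
    df_resid: int
    p: float
    r_squared: float
    params: pd.Series        # intercept + coefficients
    pvalues: pd.Series


def linear_regression(y, X, names: list[str] | None = None) -> RegressionResult:
    """OLS with intercept: overall F on (k, n-k-1) df plus per-coefficient
    two-sided p-values. Raises on rank deficiency, naming collinear columns."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} rows for {k} predictors")
    Xc = sm.add_constant(pd.DataFrame(X, columns=list(names)))
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        # identify columns that do not raise the rank
        bad = []
        base = np.ones((n, 1))
        for j, name in enumerate(["const"] + list(names)):
            col = Xc.to_numpy()[:, j:j + 1]
            if np.linalg.matrix_rank(np.hstack([base, col])) == np.linalg.matrix_rank(base):
                bad.append(name)
            else:
                base = np.hstack([base, col])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y, Xc).fit()
    return RegressionResult(
        f=float(fit.fvalue), df_model=int(fit.df_model),
        df_resid=int(fit.df_resid), p=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
        params=fit.params, pvalues=fit.pvalues,
    )


@dataclass(frozen=True)
class CorrelationTable:
    variables: tuple[str, ...]
    r: pd.DataFrame          # full symmetric matrices; diagonal NaN
    p: pd.DataFrame
    p_fdr: pd.DataFrame
    n: pd.DataFrame          # pairwise complete cases

    def pairs(self) -> pd.DataFrame:
        """Long-format lower triangle: one row per variable pair."""
        rows = []
        v = self.variables
        for i in range(1, len(v)):
            for j in range(i):
                rows.append({
                    "var_a": v[i], "var_b": v[j],
                    "r": self.r.iloc[i, j], "p": self.p.iloc[i, j],
                    "p_fdr": self.p_fdr.iloc[i, j],
                    "n": self.n.iloc[i, j],
                    "sig_uncorrected": bool(self.p.iloc[i, j] < 0.05),
                    "sig_fdr": bool(self.p_fdr.iloc[i, j] < 0.05),
                })
        return pd.DataFrame(rows)


def correlation_matrix_fdr(data: pd.DataFrame,
                           variables: tuple[str, ...] = VARIABLES,
                           min_n: int = 4) -> CorrelationTable:
    """Pairwise Pearson correlations (pairwise deletion) with two-sided p
    values, Benjamini-Hochberg adjusted across all pairs jointly.

    Pairs with fewer than ``min_n`` complete cases or a constant variable are
    left NaN (and excluded from the FDR family).
    """
    m = len(variables)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    nmat = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i):
            xy = data[[variables[i], variables[j]]].dropna()
            nmat[i, j] = nmat[j, i] = len(xy)
            if len(xy) < min_n:
                logger.warning("correlation %s~%s: only %d complete cases",
                               variables[i], variables[j], len(xy))
                continue
            x, y = xy.iloc[:, 0], xy.iloc[:, 1]
            if x.std() == 0 or y.std() == 0:
                logger.warning("correlation %s~%s: constant variable",
                               variables[i], variables[j])
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    il, jl = np.tril_indices(m, -1)
    raw = p[il, jl]
    ok = ~np.isnan(raw)
    adj = np.full_like(raw, np.nan)
    if ok.any():
        adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
    p_fdr = np.full((m, m), np.nan)
    p_fdr[il, jl] = adj
    p_fdr[jl, il] = adj
    idx = list(variables)
    return CorrelationTable(
        variables=tuple(variables),
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        p_fdr=pd.DataFrame(p_fdr, index=idx, columns=idx),
        n=pd.DataFrame(nmat, index=idx, columns=idx),
    )


@dataclass(frozen=True)
class ReportBundle:
    table1: pd.DataFrame         # long-format correlation table with sig flags
    fig2_means: pd.DataFrame     # condition means +/- SEM (go RT/SSRT/SSD x phase)
    fig1d_hist: pd.DataFrame | None  # achieved-offset histograms per trial type
    exclusion_flow: dict
    paired_tests: dict           # measure -> PairedTestResult


_FIG2_MEASURES = (("go_rt", "go_rt_systole", "go_rt_diastole"),
                  ("ssrt", "ssrt_systole", "ssrt_diastole"),
                  ("ssd", "ssd_systole", "ssd_diastole"))


def build_reports(cohort: pd.DataFrame, events=None, true_r=None,
                  exclusion_flow: dict | None = None) -> ReportBundle:
    """Assemble the analysis report tables from a retained-cohort results
    frame (one row per participant, columns as in :data:`VARIABLES` plus
    go_rt_systole/go_rt_diastole).

    Emits the correlation table (r / p / p_FDR with significance flags),
    condition means with standard errors, timing histograms when scheduled
    events and the true RR series are supplied, and the exclusion flow.
    Missing upstream columns yield missing cells, not failures.
    """
    for col in VARIABLES:
        if col not in cohort.columns:
            logger.warning("build_reports: column %r missing; cells will be NaN", col)
            cohort = cohort.assign(**{col: np.nan})
    table = correlation_matrix_fdr(cohort)
    table1 = table.pairs()
    table1.insert(0, "label_a", table1["var_a"].map(VARIABLE_LABELS))
    table1.insert(1, "label_b", table1["var_b"].map(VARIABLE_LABELS))

    rows = []
    for measure, col_s, col_d in _FIG2_MEASURES:
        for phase, col in (("systole", col_s), ("diastole", col_d)):
            vals = cohort[col].dropna() if col in cohort.columns else pd.Series(dtype=float)
            rows.append({
                "measure": measure, "phase": phase, "n": len(vals),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sem": float(vals.sem()) if len(vals) > 1 else np.nan,
            })
    fig2 = pd.DataFrame(rows)

    paired = {}
    for measure, col_s, col_d in _FIG2_MEASURES:
        if col_s in cohort.columns and col_d in cohort.columns:
            xy = cohort[[col_s, col_d]].dropna()
            if len(xy) >= 3 and np.var(xy[col_s] - xy[col_d], ddof=1) > 0:
                paired[measure] = paired_t(xy[col_s], xy[col_d])

    fig1d = None
    if events and true_r is not None:
        from .cardiac_gating import timing_precision
        tp = timing_precision(events, true_r)
        recs = []
        centers = (tp.bin_edges[:-1] + tp.bin_edges[1:]) / 2.0
        for ttype, counts in tp.histograms.items():
            for c, cnt in zip(centers, counts):
                recs.append({"trial_type": ttype, "bin_center_ms": float(c),
                             "count": int(cnt)})
        fig1d = pd.DataFrame(recs)

    return ReportBundle(table1=table1, fig2_means=fig2, fig1d_hist=fig1d,
                        exclusion_flow=exclusion_flow or {},
                        paired_tests=paired)


def render_report_md(bundle: ReportBundle) -> str:
    """Human-readable markdown report."""
    lines = ["# Cardiac stop-signal analysis report", ""]
    if bundle.exclusion_flow:
        f = bundle.exclusion_flow
        lines += ["## Exclusion flow",
                  f"{f.get('entrants', '?')} entrants -> "
                  f"{f.get('after_pass1', '?')} after waiting filter -> "
                  f"{f.get('retained', '?')} retained", ""]
    lines.append("## Condition means (mean +/- SEM)")
    for _, row in bundle.fig2_means.iterrows():
        lines.append(f"- {row['measure']} {row['phase']}: "
                     f"{row['mean']:.1f} +/- {row['sem']:.1f} (n={row['n']})")
    lines.append("")
    lines.append("## Paired systole vs diastole contrasts")
    for m, res in bundle.paired_tests.items():
        lines.append(
            f"- {m}: t({res.df}) = {res.t:.2f}, p = {res.p:.3f}, "
            f"mean diff = {res.mean_diff:.2f} "
            f"[{res.ci95[0]:.2f}, {res.ci95[1]:.2f}], eta^2 = {res.eta_squared:.3f}")
    lines.append("")
    lines.append("## Correlations (r / p / p_FDR; * p<0.05, ** p_FDR<0.05)")
    for _, row in bundle.table1.iterrows():
        star = "**" if row["sig_fdr"] else ("*" if row["sig_uncorrected"] else "")
        if np.isnan(row["r"]):
            lines.append(f"- {row['label_a']} ~ {row['label_b']}: missing")
        else:
            lines.append(f"- {row['label_a']} ~ {row['label_b']}: "
                         f"r = {row['r']:.3f}, p = {row['p']:.3f}, "
                         f"p_FDR = {row['p_fdr']:.3f} {star}")
    return "\n".join(lines) + "\n"
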