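"""Statistical comparison of the sign-handling pipelines.

Three complementary views, all two-tailed at the 0.05 level:

* per-site Welch (unequal-variance) t-tests on the trial-level,
  threshold-averaged metrics, Holm–Šidák corrected within each metric;
* threshold-matched Welch tests (site × threshold p-value matrices per
  pipeline pair per metric, the heatmap view);
* paired t-tests across sites on site-mean metrics per pipeline pair.

Plus the site-level AUC-vs-age-mean polynomial regression used to probe
why model performance varies so much between sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from signedfc.evaluation import METRICS

__all__ = [
    "WelchResult",
    "RegressionFit",
    "welch_test",
    "holm_sidak",
    "pipeline_comparison_suite",
    "auc_age_regression",
]


@dataclass(frozen=True)
class WelchResult:
    """Unequal-variance t-test outcome (two-tailed)."""

    t_statistic: float
    dof: float
    p_value: float


@dataclass(frozen=True)
class RegressionFit:
    """Polynomial least-squares fit of AUC on site mean age."""

    coefficients: tuple[float, ...]  # intercept first, ascending degree
    r_squared: float
    f_p_value: float
    degree: int


def welch_test(sample_a, sample_b) -> WelchResult:
    """Welch's t-test with Welch–Satterthwaite degrees of freedom.

    Two identical constant samples are a defined no-difference case and
    return t = 0, p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        return WelchResult(np.inf if a.mean() > b.mean() else -np.inf,
                           float(a.size + b.size - 2), 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    dof = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return WelchResult(float(t), float(dof), float(p))


def holm_sidak(p_values) -> np.ndarray:
    """Holm–Šidák step-down adjustment, returned in the input order.

    Sorted ascending, the i-th smallest p becomes 1 − (1 − p)^(m − i + 1)
    with a running maximum enforcing step-down monotonicity; adjusted
    values dominate the raw ones elementwise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def _trial_means(results: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Threshold-averaged metric per (pipeline, site, repetition) — the
    trial-level unit for the per-site Welch comparisons."""
    return (
        results.groupby(["pipeline", "site", "repetition"])[metric]
        .mean()
        .reset_index()
    )


def pipeline_comparison_suite(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """All pipeline-vs-pipeline comparison tables from a results frame.

    Returns ``welch_site`` (per-site tests on threshold-averaged trials),
    ``welch_thresholdwise`` (threshold-matched tests on repetitions), and
    ``paired_t`` (across-site paired tests on site means).  Holm–Šidák
    families are delimited per metric within each comparison type.
    """
    pipelines = sorted(results["pipeline"].unique())
    if len(pipelines) < 2:
        raise ValueError("need at least 2 pipelines to compare")
    pairs = list(itertools.combinations(pipelines, 2))
    sites = sorted(results["site"].unique())
    thresholds = sorted(results["threshold"].unique())

    cells = results.groupby(["pipeline", "site", "threshold"]).size()
    expected = {
        (p, s, t) for p in pipelines for s in sites for t in thresholds
    }
    missing = sorted(expected - set(cells.index))
    if missing:
        raise ValueError(f"results grid is incomplete; missing cells: {missing[:10]}")

    site_rows = []
    for metric in METRICS:
        tm = _trial_means(results, metric)
        for pa, pb in pairs:
            for site in sites:
                a = tm.query("pipeline == @pa and site == @site")[metric].to_numpy()
                b = tm.query("pipeline == @pb and site == @site")[metric].to_numpy()
                if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
                    continue  # undefined AUC at a one-class site
                if a.size < 2 or b.size < 2:
                    continue  # a single trial cannot support a variance estimate
                r = welch_test(a, b)
                site_rows.append(
                    {"pair": f"{pa}-{pb}", "metric": metric, "site": site,
                     "t": r.t_statistic, "dof": r.dof, "p": r.p_value}
                )
    welch_site = pd.DataFrame(
        site_rows, columns=["pair", "metric", "site", "t", "dof", "p"]
    )
    welch_site["adjusted_p"] = np.nan
    for metric in METRICS:
        sel = welch_site["metric"] == metric
        if sel.any():
            welch_site.loc[sel, "adjusted_p"] = holm_sidak(
                welch_site.loc[sel, "p"].to_numpy()
            )

    thr_rows = []
    for metric in METRICS:
        for pa, pb in pairs:
            for site in sites:
                for thr in thresholds:
                    a = results.query(
                        "pipeline == @pa and site == @site and threshold == @thr"
                    )[metric].to_numpy()
                    b = results.query(
                        "pipeline == @pb and site == @site and threshold == @thr"
                    )[metric].to_numpy()
                    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
                        continue
                    if a.size < 2 or b.size < 2:
                        continue
                    r = welch_test(a, b)
                    thr_rows.append(
                        {"pair": f"{pa}-{pb}", "metric": metric, "site": site,
                         "threshold": thr, "t": r.t_statistic, "p": r.p_value}
                    )
    welch_thr = pd.DataFrame(
        thr_rows, columns=["pair", "metric", "site", "threshold", "t", "p"]
    )
    welch_thr["adjusted_p"] = np.nan
    for metric in METRICS:
        sel = welch_thr["metric"] == metric
        if sel.any():
            welch_thr.loc[sel, "adjusted_p"] = holm_sidak(
                welch_thr.loc[sel, "p"].to_numpy()
            )

    paired_rows = []
    site_means = (
        results.groupby(["pipeline", "site"])[list(METRICS)].mean().reset_index()
    )
    for metric in METRICS:
        for pa, pb in pairs:
            a = site_means.query("pipeline == @pa").set_index("site")[metric]
            b = site_means.query("pipeline == @pb").set_index("site")[metric]
            common = a.index.intersection(b.index)
            av, bv = a[common].to_numpy(), b[common].to_numpy()
            ok = np.isfinite(av) & np.isfinite(bv)
            av, bv = av[ok], bv[ok]
            diff = av - bv
            if diff.std(ddof=1) == 0:
                # zero-variance differences: no evidence of a difference if
                # all-zero, otherwise a degenerate certain difference
                t, p = (0.0, 1.0) if np.all(diff == 0) else (np.inf, 0.0)
            else:
                t, p = sps.ttest_rel(av, bv)
            paired_rows.append(
                {"pair": f"{pa}-{pb}", "metric": metric, "n_sites": int(ok.sum()),
                 "t": float(t), "p": float(p)}
            )
    paired = pd.DataFrame(paired_rows)
    paired["adjusted_p"] = np.nan
    for metric in METRICS:
        sel = paired["metric"] == metric
        paired.loc[sel, "adjusted_p"] = holm_sidak(paired.loc[sel, "p"].to_numpy())

    return {
        "welch_site": welch_site,
        "welch_thresholdwise": welch_thr,
        "paired_t": paired,
    }


def auc_age_regression(
    site_auc_means, site_age_means, degree: int = 2
) -> RegressionFit:
    """OLS fit of site AUC on a polynomial in site mean age (default
    quadratic), with R² and the overall F-test p-value against the
    intercept-only model.  A cubic fit is available via ``degree=3``."""
    import statsmodels.api as sm

    y = np.asarray(site_auc_means, dtype=float)
    age = np.asarray(site_age_means, dtype=float)
    if y.size != age.size:
        raise ValueError("AUC and age vectors are misaligned")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if y.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} sites for degree {degree}")
    if len(np.unique(age)) <= degree:
        raise ValueError(
            f"need more than {degree} distinct age values for a degree-{degree} fit"
        )
    x = np.vander(age, degree + 1, increasing=True)  # 1, age, age^2, ...
    fit = sm.OLS(y, x).fit()
    return RegressionFit(
        coefficients=tuple(float(c) for c in fit.params),
        r_squared=float(fit.rsquared),
        f_p_value=float(fit.f_pvalue),
        degree=degree,
    )
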