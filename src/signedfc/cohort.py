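"""Synthetic multi-site cohort generator.

Emulates per-subject ROI time series (regional BOLD averages) with a
modular block covariance, group-dependent between-module coupling, per-site
noise scaling, and optional global-signal regression (GSR).  GSR — removal
of the brain-wide mean signal from every region — mathematically forces
some pairwise correlations negative, which is exactly the regime the
sign-handling pipelines are designed to probe.

The default site templates mirror the demographic structure of the 17-site
ABIDE I cohort (per-site ASD/HC counts, sex tallies, and age means/SDs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SiteTemplate",
    "CohortSpec",
    "RoiTimeSeries",
    "default_site_templates",
    "build_block_correlation",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: label convention used throughout: healthy controls are 1, ASD is 0.
HC_LABEL = 1
ASD_LABEL = 0

# Per-site demographics: (site, group, sex, age_mean, age_sd, count).
# 17 acquisition sites; undefined SDs for n=1 cells are recorded as 0.
_SITE_DEMOGRAPHICS = [
    ("CALTECH", "ASD", "F", 24.35, 6.91, 4), ("CALTECH", "ASD", "M", 28.27, 11.08, 15),
    ("CALTECH", "HC", "F", 22.77, 4.31, 4), ("CALTECH", "HC", "M", 29.51, 11.83, 14),
    ("CMU", "ASD", "F", 27.00, 6.93, 3), ("CMU", "ASD", "M", 26.18, 5.88, 11),
    ("CMU", "HC", "F", 26.00, 5.29, 3), ("CMU", "HC", "M", 27.10, 6.12, 10),
    ("KKI", "ASD", "F", 9.61, 1.85, 4), ("KKI", "ASD", "M", 10.12, 1.38, 16),
    ("KKI", "HC", "F", 9.49, 0.81, 8), ("KKI", "HC", "M", 10.22, 1.23, 20),
    ("LEUVEN", "ASD", "F", 14.00, 1.41, 3), ("LEUVEN", "ASD", "M", 18.18, 5.09, 26),
    ("LEUVEN", "HC", "F", 13.56, 0.75, 5), ("LEUVEN", "HC", "M", 19.01, 5.05, 29),
    ("MAX_MUN", "ASD", "F", 35.33, 8.50, 3), ("MAX_MUN", "ASD", "M", 24.76, 15.27, 21),
    ("MAX_MUN", "HC", "F", 32.00, 0.0, 1), ("MAX_MUN", "HC", "M", 24.37, 8.81, 27),
    ("NYU", "ASD", "F", 18.62, 9.14, 10), ("NYU", "ASD", "M", 14.14, 6.59, 65),
    ("NYU", "HC", "F", 15.37, 6.45, 26), ("NYU", "HC", "M", 15.76, 6.10, 74),
    ("OHSU", "ASD", "M", 11.43, 2.18, 12), ("OHSU", "HC", "M", 10.09, 1.12, 14),
    ("OLIN", "ASD", "F", 19.00, 5.00, 3), ("OLIN", "ASD", "M", 16.06, 3.04, 16),
    ("OLIN", "HC", "F", 17.50, 3.54, 2), ("OLIN", "HC", "M", 16.54, 3.78, 13),
    ("PITT", "ASD", "F", 12.60, 0.95, 4), ("PITT", "ASD", "M", 20.03, 7.38, 25),
    ("PITT", "HC", "F", 16.07, 3.60, 4), ("PITT", "HC", "M", 19.36, 6.97, 23),
    ("SBL", "ASD", "M", 35.00, 10.43, 15), ("SBL", "HC", "M", 33.73, 6.61, 15),
    ("SDSU", "ASD", "F", 12.44, 0.0, 1), ("SDSU", "ASD", "M", 14.89, 1.70, 13),
    ("SDSU", "HC", "F", 13.26, 2.69, 6), ("SDSU", "HC", "M", 14.58, 1.46, 16),
    ("STANFORD", "ASD", "F", 10.02, 1.63, 4), ("STANFORD", "ASD", "M", 9.99, 1.68, 15),
    ("STANFORD", "HC", "F", 9.01, 1.01, 4), ("STANFORD", "HC", "M", 10.19, 1.66, 16),
    ("TRINITY", "ASD", "M", 16.81, 3.17, 22), ("TRINITY", "HC", "M", 17.08, 3.77, 25),
    ("UCLA", "ASD", "F", 12.46, 3.42, 6), ("UCLA", "ASD", "M", 13.08, 2.34, 48),
    ("UCLA", "HC", "F", 12.82, 0.89, 6), ("UCLA", "HC", "M", 13.03, 2.04, 38),
    ("UM", "ASD", "F", 13.53, 3.12, 9), ("UM", "ASD", "M", 13.11, 2.30, 57),
    ("UM", "HC", "F", 14.78, 2.82, 18), ("UM", "HC", "M", 14.82, 3.85, 56),
    ("USM", "ASD", "M", 23.46, 8.33, 46), ("USM", "HC", "M", 21.29, 8.35, 25),
    ("YALE", "ASD", "F", 12.88, 3.00, 8), ("YALE", "ASD", "M", 12.70, 3.14, 20),
    ("YALE", "HC", "F", 13.52, 2.64, 8), ("YALE", "HC", "M", 12.34, 2.79, 20),
]


@dataclass(frozen=True)
class SiteTemplate:
    """Demographic template for one acquisition site.

    ``noise_scale`` multiplies the generated signal amplitude and is the only
    scanner/protocol effect modelled; ``n_timepoints`` is the run length T.
    """

    site_name: str
    n_asd: int
    n_hc: int
    age_mean_asd: float
    age_mean_hc: float
    age_sd_asd: float
    age_sd_hc: float
    noise_scale: float = 1.0
    n_timepoints: int = 150
    n_asd_female: int = 0
    n_hc_female: int = 0

    def __post_init__(self) -> None:
        if self.n_asd < 0 or self.n_hc < 0:
            raise ValueError("group counts must be non-negative")
        if self.n_asd == 0 and self.n_hc == 0:
            raise ValueError(f"site {self.site_name!r} has no subjects")
        if self.age_sd_asd < 0 or self.age_sd_hc < 0:
            raise ValueError("age SDs must be non-negative")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")
        if self.n_asd_female > self.n_asd or self.n_hc_female > self.n_hc:
            raise ValueError("female count exceeds group count")


def _pool(cells: list[tuple[float, float, int]]) -> tuple[float, float, int]:
    """Pool sex-stratified (mean, sd, n) cells into one group summary."""
    n = sum(c[2] for c in cells)
    mean = sum(c[0] * c[2] for c in cells) / n
    # second moment combination; table SDs are treated as population-like
    var = sum(c[2] * (c[1] ** 2 + c[0] ** 2) for c in cells) / n - mean**2
    return mean, math.sqrt(max(var, 0.0)), n


def default_site_templates(n_timepoints: int = 150) -> list[SiteTemplate]:
    """The 17 default site templates (ABIDE-I-shaped demographics)."""
    sites: dict[str, dict] = {}
    for site, group, sex, mean, sd, count in _SITE_DEMOGRAPHICS:
        d = sites.setdefault(site, {"ASD": [], "HC": [], "ASD_F": 0, "HC_F": 0})
        d[group].append((mean, sd, count))
        if sex == "F":
            d[group + "_F"] += count
    templates = []
    for site, d in sites.items():
        m_asd, s_asd, n_asd = _pool(d["ASD"])
        m_hc, s_hc, n_hc = _pool(d["HC"])
        templates.append(
            SiteTemplate(
                site_name=site,
                n_asd=n_asd,
                n_hc=n_hc,
                age_mean_asd=m_asd,
                age_mean_hc=m_hc,
                age_sd_asd=s_asd,
                age_sd_hc=s_hc,
                n_timepoints=n_timepoints,
                n_asd_female=d["ASD_F"],
                n_hc_female=d["HC_F"],
            )
        )
    return templates


RoiTimeSeries = np.ndarray  # shape (n_regions, n_timepoints)


@dataclass
class CohortSpec:
    """Population model for the synthetic cohort.

    Regions are grouped into ``n_modules`` communities; regional activity is
    drawn from a zero-mean multivariate normal whose correlation is
    ``within_module_corr`` inside a module and a group-dependent
    ``between_module_corr_*`` across modules.  A between-module difference
    between the ASD and HC values is the planted, topology-level group
    effect the classifier is asked to recover.
    """

    n_regions: int = 200
    n_modules: int = 5
    within_module_corr: float = 0.4
    between_module_corr_hc: float = 0.10
    between_module_corr_asd: float = 0.20
    apply_gsr: bool = True
    gsr_regression: bool = False
    min_age: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.within_module_corr < 1:
            raise ValueError("within_module_corr must lie in (0, 1)")
        for name in ("between_module_corr_hc", "between_module_corr_asd"):
            if not -1 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (-1, 1)")
        if self.n_modules < 1 or self.n_regions < self.n_modules:
            raise ValueError("need 1 <= n_modules <= n_regions")
        # fail fast if either group covariance is invalid
        for group in ("ASD", "HC"):
            self.group_covariance(group)

    def module_assignment(self) -> np.ndarray:
        """Deterministic region→module map (round-robin by region index)."""
        return np.arange(self.n_regions) % self.n_modules

    def group_covariance(self, group: str) -> np.ndarray:
        between = (
            self.between_module_corr_asd if group == "ASD" else self.between_module_corr_hc
        )
        cov = build_block_correlation(
            self.n_regions, self.module_assignment(), self.within_module_corr, between
        )
        return cov


def build_block_correlation(
    n_regions: int,
    modules: np.ndarray,
    within: float,
    between: float,
    *,
    psd_tol: float = 1e-10,
    repair_tol: float = 1e-6,
) -> np.ndarray:
    """Block correlation matrix: ``within`` inside modules, ``between`` across.

    Unit variances, so the matrix doubles as the population covariance.
    Validity is checked by the smallest eigenvalue: tiny negative drift
    (within ``repair_tol``) is repaired by eigenvalue clipping, anything
    worse is rejected — silently fixing a grossly non-PSD request would
    hide a user error.
    """
    same = modules[:, None] == modules[None, :]
    cov = np.where(same, within, between)
    np.fill_diagonal(cov, 1.0)
    min_eig = float(np.linalg.eigvalsh(cov)[0])
    if min_eig < -repair_tol:
        raise ValueError(
            "requested correlation structure is not positive semi-definite "
            f"(min eigenvalue {min_eig:.3g}; within={within}, between={between}, "
            f"n_regions={n_regions})"
        )
    if min_eig < -psd_tol:
        eigval, eigvec = np.linalg.eigh(cov)
        cov = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
    return cov


def _gsr(ts: np.ndarray, regression: bool) -> np.ndarray:
    """Remove the global (cross-region mean) signal.

    Default is per-time-point mean subtraction; ``regression=True`` instead
    regresses each region's series on the global series and keeps residuals.
    Both leave the cross-region mean at (numerically) zero for every time
    point in the subtraction case, and guarantee anti-correlations whenever
    any positive coupling exists.
    """
    g = ts.mean(axis=0)
    if not regression:
        return ts - g[None, :]
    gc = g - g.mean()
    denom = float(gc @ gc)
    if denom == 0.0:
        return ts - g[None, :]
    beta = (ts - ts.mean(axis=1, keepdims=True)) @ gc / denom
    return ts - beta[:, None] * g[None, :]


def generate_subject(
    spec: CohortSpec,
    group: str,
    site: SiteTemplate,
    rng: np.random.Generator,
) -> RoiTimeSeries:
    """Draw one subject's N×T regional time-series matrix.

    Zero-mean multivariate normal with the group's block covariance, scaled
    by the site's ``noise_scale``; GSR applied afterwards if requested.
    """
    if group not in ("ASD", "HC"):
        raise ValueError(f"unknown diagnosis group {group!r}")
    cov = spec.group_covariance(group)
    # eigendecomposition square root: stable for the (possibly singular)
    # clipped covariance
    eigval, eigvec = np.linalg.eigh(cov)
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    z = rng.standard_normal((spec.n_regions, site.n_timepoints))
    ts = site.noise_scale * (root @ z)
    if spec.apply_gsr:
        ts = _gsr(ts, spec.gsr_regression)
    return ts


def generate_cohort(
    spec: CohortSpec,
    sites: list[SiteTemplate] | None = None,
    seed: int | None = None,
) -> tuple[list[RoiTimeSeries], pd.DataFrame]:
    """Generate a full multi-site cohort.

    Returns the per-subject time-series list and an aligned phenotype table
    with columns ``SUB_ID, SITE_ID, DX_GROUP, SEX, AGE_AT_SCAN``.
    Deterministic given ``seed`` (defaults to ``spec.seed``).
    """
    if sites is None:
        sites = default_site_templates()
    if len(sites) < 2:
        raise ValueError("need at least 2 sites for leave-one-site-out analysis")
    names = [s.site_name for s in sites]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate site names: {dupes}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    series: list[RoiTimeSeries] = []
    rows = []
    for site in sites:
        for group, n, n_f, age_mu, age_sd in (
            ("ASD", site.n_asd, site.n_asd_female, site.age_mean_asd, site.age_sd_asd),
            ("HC", site.n_hc, site.n_hc_female, site.age_mean_hc, site.age_sd_hc),
        ):
            ages = np.maximum(rng.normal(age_mu, age_sd, size=n), spec.min_age)
            for i in range(n):
                sub_id = f"{site.site_name}_{group}_{i:04d}"
                series.append(generate_subject(spec, group, site, rng))
                rows.append(
                    {
                        "SUB_ID": sub_id,
                        "SITE_ID": site.site_name,
                        "DX_GROUP": group,
                        "SEX": "F" if i < n_f else "M",
                        "AGE_AT_SCAN": float(ages[i]),
                    }
                )
    phenotype = pd.DataFrame(rows)
    if phenotype["SUB_ID"].duplicated().any():
        raise RuntimeError("subject ids are not unique")  # pragma: no cover
    return series, phenotype


def labels_from_phenotype(phenotype: pd.DataFrame) -> np.ndarray:
    """Diagnosis labels with the HC=1 / ASD=0 convention."""
    return (phenotype["DX_GROUP"].to_numpy() == "HC").astype(int)


def write_cohort(
    out_dir: str | Path,
    series: list[RoiTimeSeries],
    phenotype: pd.DataFrame,
) -> None:
    """Persist a cohort: one tab-delimited file per subject (rows = time
    points, columns = ROIs, ROI-label header) plus ``phenotype.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ts, sub_id in zip(series, phenotype["SUB_ID"], strict=True):
        labels = "\t".join(f"ROI_{i:03d}" for i in range(ts.shape[0]))
        np.savetxt(
            out / f"{sub_id}_rois.1D",
            ts.T,
            delimiter="\t",
            header=labels,
            comments="",
        )
    phenotype.to_csv(out / "phenotype.csv", index=False)


def read_cohort(in_dir: str | Path) -> tuple[list[RoiTimeSeries], pd.DataFrame]:
    """Load a cohort written by :func:`write_cohort`."""
    src = Path(in_dir)
    phenotype = pd.read_csv(src / "phenotype.csv")
    series = []
    for sub_id in phenotype["SUB_ID"]:
        ts = np.loadtxt(src / f"{sub_id}_rois.1D", skiprows=1, delimiter="\t")
        series.append(np.atleast_2d(ts).T)
    return series, phenotype
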