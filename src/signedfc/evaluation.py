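"""Leave-one-site-out cross-validation, metrics, and aggregation.

Each acquisition site in turn is the held-out test set; everything fitted
— feature standardization, optional PCA of raw correlations, the MLP —
sees training sites only.  Each (site, pipeline, threshold) cell is
repeated ``n_repeats`` times with distinct seeds to average out weight
initialization and validation-split randomness.

Metric conventions (HC = 1, ASD = 0): sensitivity is the fraction of
healthy controls predicted 1, specificity the fraction of ASD subjects
predicted 0, and AUC is the Mann–Whitney rank statistic with ties counted
half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from signedfc import features as feat
from signedfc import mlp as mlp_mod
from signedfc.cohort import labels_from_phenotype
from signedfc.connectivity import (
    PipelineMode,
    ThresholdGrid,
    apply_pipeline,
    pearson_connectivity,
    proportional_threshold,
)

__all__ = [
    "LosoFold",
    "loso_split",
    "compute_metrics",
    "run_experiment",
    "aggregate",
]

METRICS = ("accuracy", "auc", "sensitivity", "specificity")


@dataclass(frozen=True)
class LosoFold:
    """One leave-one-site-out split."""

    test_site: str
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]


def loso_split(phenotype: pd.DataFrame) -> list[LosoFold]:
    """One fold per distinct site, ordered by site label."""
    sites = sorted(phenotype["SITE_ID"].unique())
    if len(sites) < 2:
        raise ValueError("leave-one-site-out needs at least 2 sites")
    folds = []
    for site in sites:
        is_test = phenotype["SITE_ID"] == site
        folds.append(
            LosoFold(
                test_site=site,
                train_subjects=tuple(phenotype.loc[~is_test, "SUB_ID"]),
                test_subjects=tuple(phenotype.loc[is_test, "SUB_ID"]),
            )
        )
    return folds


def _auc_mann_whitney(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the probability a random positive outranks a random negative,
    ties counted half (the Mann–Whitney U / (n1 n0) statistic)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def compute_metrics(
    labels, probabilities
) -> tuple[float, float, float, float]:
    """(accuracy, sensitivity, specificity, auc) at the 0.5 threshold.

    With only one class present the AUC is undefined and comes back NaN;
    the other metrics are still computed (the absent class's rate is NaN).
    """
    y = np.asarray(labels, dtype=int).ravel()
    p = np.asarray(probabilities, dtype=float).ravel()
    if y.shape != p.shape:
        raise ValueError("labels and probabilities are misaligned")
    pred = (p >= 0.5).astype(int)
    accuracy = float((pred == y).mean())
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    sensitivity = float((pred[y == 1] == 1).mean()) if n_pos else float("nan")
    specificity = float((pred[y == 0] == 0).mean()) if n_neg else float("nan")
    auc = _auc_mann_whitney(y, p) if n_pos and n_neg else float("nan")
    return accuracy, sensitivity, specificity, auc


def extract_feature_table(
    connectivities,
    subject_ids,
    mode: PipelineMode,
    threshold: float,
    threshold_index: int,
    base_seed: int = 0,
) -> feat.FeatureMatrix:
    """Graph features for every subject under one (pipeline, threshold) cell.

    The community-detection seed is derived from the subject index and the
    threshold index so extraction is reproducible subject by subject.
    """
    rows = []
    n_nodes = connectivities[0].n_regions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for s_idx, conn in enumerate(connectivities):
            w = apply_pipeline(conn, mode)
            g = proportional_threshold(w, threshold)
            seed = (base_seed + 100_003 * s_idx + threshold_index) % (2**31)
            rows.append(feat.assemble_graph_features(g, seed=seed))
    return feat.FeatureMatrix(
        values=np.array(rows),
        feature_names=feat.graph_feature_names(n_nodes),
        subject_ids=tuple(subject_ids),
    )


def run_experiment(
    cohort,
    pipelines=(PipelineMode.POS, PipelineMode.NEG, PipelineMode.ABS),
    grid: ThresholdGrid | None = None,
    cfg: mlp_mod.MlpConfig | None = None,
    n_repeats: int = 5,
    base_seed: int = 0,
    use_pca: bool = False,
    pca_components: int = 600,
) -> pd.DataFrame:
    """Full pipeline comparison: one row per (site, pipeline, threshold,
    repetition) with the four test-set metrics.

    ``cohort`` is a ``(list of N×T arrays, phenotype DataFrame)`` pair.
    Per-threshold models are trained independently; repetition ``r`` uses
    MLP seed ``base_seed + r``.  Standardization (and PCA when enabled) is
    fitted inside each training fold only.
    """
    series, phenotype = cohort
    grid = grid or ThresholdGrid()
    cfg = cfg or mlp_mod.MlpConfig()
    subject_ids = tuple(phenotype["SUB_ID"])
    labels = labels_from_phenotype(phenotype)
    label_of = dict(zip(subject_ids, labels))

    connectivities = [pearson_connectivity(ts) for ts in series]
    conn_of = dict(zip(subject_ids, connectivities))
    folds = loso_split(phenotype)

    records = []
    for mode in pipelines:
        for t_idx, p in enumerate(grid):
            table = extract_feature_table(
                connectivities, subject_ids, mode, p, t_idx, base_seed
            )
            row_of = {sid: i for i, sid in enumerate(table.subject_ids)}
            for fold in folds:
                tr_rows = [row_of[s] for s in fold.train_subjects]
                te_rows = [row_of[s] for s in fold.test_subjects]
                train_fm = feat.FeatureMatrix(
                    table.values[tr_rows],
                    table.feature_names,
                    fold.train_subjects,
                )
                test_fm = feat.FeatureMatrix(
                    table.values[te_rows],
                    table.feature_names,
                    fold.test_subjects,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    if use_pca:
                        pca = feat.fit_pca(
                            [conn_of[s] for s in fold.train_subjects],
                            pca_components,
                        )
                        names = tuple(
                            f"pca_{i:03d}" for i in range(pca.n_components)
                        )
                        tr_p = np.array(
                            [transform for transform in (
                                feat.transform_pca(pca, conn_of[s])
                                for s in fold.train_subjects
                            )]
                        )
                        te_p = np.array(
                            [feat.transform_pca(pca, conn_of[s])
                             for s in fold.test_subjects]
                        )
                        train_fm = feat.FeatureMatrix(
                            np.hstack([train_fm.values, tr_p]),
                            train_fm.feature_names + names,
                            train_fm.subject_ids,
                        )
                        test_fm = feat.FeatureMatrix(
                            np.hstack([test_fm.values, te_p]),
                            test_fm.feature_names + names,
                            test_fm.subject_ids,
                        )
                    train_std, test_std = feat.standardize(train_fm, test_fm)
                y_train = np.array([label_of[s] for s in fold.train_subjects])
                y_test = np.array([label_of[s] for s in fold.test_subjects])
                for rep in range(n_repeats):
                    rep_cfg = mlp_mod.MlpConfig(
                        **{**cfg.__dict__, "seed": base_seed + rep}
                    )
                    model = mlp_mod.train(train_std, y_train, rep_cfg)
                    probs = mlp_mod.predict_proba(model, test_std)
                    acc, sens, spec, auc = compute_metrics(y_test, probs)
                    records.append(
                        {
                            "site": fold.test_site,
                            "pipeline": mode.value,
                            "threshold": p,
                            "repetition": rep,
                            "accuracy": acc,
                            "sensitivity": sens,
                            "specificity": spec,
                            "auc": auc,
                            "n_test": len(te_rows),
                        }
                    )
    return pd.DataFrame(records)


def aggregate(results: pd.DataFrame) -> pd.DataFrame:
    """Per-site mean and SD across thresholds, plus overall summary rows.

    For each (pipeline, site, metric): repetitions are averaged within each
    threshold first, then the mean and SD are taken across thresholds.
    Summary rows: ``Mean`` is the unweighted mean of site means,
    ``Weighted Mean`` weights each site by its test-set size; their SD
    columns carry the corresponding mean of site SDs.  Undefined (NaN) AUC
    cells are excluded, with the exclusion count reported.
    """
    if results.empty:
        raise ValueError("no results to aggregate")
    rows = []
    for (pipeline, site), df in results.groupby(["pipeline", "site"]):
        rec: dict = {"pipeline": pipeline, "site": site, "n_test": int(df["n_test"].iloc[0])}
        for metric in METRICS:
            per_threshold = df.groupby("threshold")[metric].mean()
            rec[f"{metric}_mean"] = float(per_threshold.mean())
            rec[f"{metric}_sd"] = float(per_threshold.std(ddof=0))
        rec["n_undefined_auc"] = int(df["auc"].isna().sum())
        rows.append(rec)
    table = pd.DataFrame(rows)

    summaries = []
    for pipeline, df in table.groupby("pipeline"):
        w = df["n_test"].to_numpy(dtype=float)
        for name, weights in (("Mean", np.ones_like(w)), ("Weighted Mean", w)):
            rec = {"pipeline": pipeline, "site": name, "n_test": int(w.sum())}
            for metric in METRICS:
                means = df[f"{metric}_mean"].to_numpy()
                sds = df[f"{metric}_sd"].to_numpy()
                ok = np.isfinite(means)
                rec[f"{metric}_mean"] = float(
                    np.average(means[ok], weights=weights[ok])
                )
                rec[f"{metric}_sd"] = float(
                    np.average(sds[ok], weights=weights[ok])
                )
            rec["n_undefined_auc"] = int(df["n_undefined_auc"].sum())
            summaries.append(rec)
    return pd.concat([table, pd.DataFrame(summaries)], ignore_index=True)
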