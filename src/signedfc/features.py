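"""Per-subject feature assembly, PCA of raw correlations, standardization.

The graph feature vector concatenates, in a fixed registry order, seven
node-level metrics (each of length N) and four global metrics, giving
7N + 4 features — 1,404 for a 200-region parcellation.  PCA components of
the vectorized raw correlation matrix can be appended as non-graph
features.  Standardization statistics are always estimated on the training
fold only and applied unchanged to held-out subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from signedfc import graph_features as gf
from signedfc.connectivity import BinaryGraph, ConnectivityMatrix

__all__ = [
    "FeatureMatrix",
    "PcaModel",
    "NODE_METRICS",
    "GLOBAL_METRICS",
    "graph_feature_names",
    "assemble_graph_features",
    "fit_pca",
    "transform_pca",
    "standardize",
]

#: node-level metric registry, in feature-vector order
NODE_METRICS: tuple[str, ...] = (
    "degree",
    "clustering",
    "local_efficiency",
    "betweenness",
    "eigenvector",
    "participation",
    "within_module_z",
)

#: global metric registry, appended after the node blocks
GLOBAL_METRICS: tuple[str, ...] = (
    "char_path_length",
    "global_efficiency",
    "transitivity",
    "assortativity",
)


@dataclass
class FeatureMatrix:
    """Subjects × features table with aligned ids and unique feature names."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains non-finite entries")
        if v.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("shape does not match ids / names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        self.values = v
        self.feature_names = tuple(self.feature_names)
        self.subject_ids = tuple(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def graph_feature_names(n_nodes: int) -> tuple[str, ...]:
    """Fixed feature-name registry for an ``n_nodes``-region graph."""
    names = [
        f"{metric}_{i:03d}" for metric in NODE_METRICS for i in range(n_nodes)
    ]
    names.extend(GLOBAL_METRICS)
    return tuple(names)


def assemble_graph_features(graph: BinaryGraph, seed: int = 0) -> np.ndarray:
    """Concatenate the full graph-metric feature vector for one subject.

    Length is exactly ``7 * n_nodes + 4``.  The community partition feeding
    the participation coefficient and within-module z-score is recomputed
    per graph with the given seed so extraction is reproducible.
    """
    partition = gf.detect_communities(graph, seed=seed)
    with warnings.catch_warnings():
        # degenerate sentinels (documented) may fire on sparse graphs
        warnings.simplefilter("ignore", UserWarning)
        cpl, eff = gf.shortest_path_metrics(graph)
        node_blocks = [
            gf.degree(graph),
            gf.clustering_coefficient(graph),
            gf.local_efficiency(graph),
            gf.betweenness_centrality(graph),
            gf.eigenvector_centrality(graph),
            gf.participation_coefficient(graph, partition),
            gf.within_module_zscore(graph, partition),
        ]
        assort = gf.assortativity(graph) if graph.n_edges else 0.0
    globals_block = np.array([cpl, eff, gf.transitivity(graph), assort])
    return np.concatenate(node_blocks + [globals_block])


@dataclass
class PcaModel:
    """PCA of vectorized (strict upper triangle) training correlations."""

    component_loadings: np.ndarray  # D x K
    training_means: np.ndarray  # length D
    n_components: int

    @property
    def input_dim(self) -> int:
        return self.component_loadings.shape[0]


def _vectorize(conn: ConnectivityMatrix) -> np.ndarray:
    n = conn.n_regions
    iu, ju = np.triu_indices(n, k=1)
    return conn.values[iu, ju]


def fit_pca(
    training_connectivities: list[ConnectivityMatrix], n_components: int = 600
) -> PcaModel:
    """Fit PCA on the training fold's vectorized correlation matrices.

    The requested component count is truncated to the feasible rank
    ``min(n_train - 1, D)`` with a warning; 600 components is the default
    for non-graph features.
    """
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    if len(training_connectivities) < 2:
        raise ValueError("PCA needs at least 2 training subjects")
    x = np.array([_vectorize(c) for c in training_connectivities])
    feasible = min(len(training_connectivities) - 1, x.shape[1])
    if n_components > feasible:
        warnings.warn(
            f"requested {n_components} components exceeds feasible rank "
            f"{feasible}; truncating",
            stacklevel=2,
        )
        n_components = feasible
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x)
    return PcaModel(
        component_loadings=pca.components_.T.copy(),
        training_means=pca.mean_.copy(),
        n_components=n_components,
    )


def transform_pca(model: PcaModel, conn: ConnectivityMatrix) -> np.ndarray:
    """Project one subject's correlation matrix onto the fitted components."""
    x = _vectorize(conn)
    if x.shape[0] != model.input_dim:
        raise ValueError(
            f"connectivity dimension {x.shape[0]} does not match the "
            f"fitted model ({model.input_dim})"
        )
    return (x - model.training_means) @ model.component_loadings


def standardize(
    train: FeatureMatrix, *others: FeatureMatrix
) -> tuple[FeatureMatrix, ...]:
    """Remove the training mean and scale to unit training variance.

    Statistics use the population convention and come from ``train`` only;
    zero-variance features map to 0 everywhere (with a warning) so no
    division blows up.
    """
    if train.n_subjects == 0:
        raise ValueError("empty training feature matrix")
    mu = train.values.mean(axis=0)
    sd = train.values.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance feature(s) mapped to 0",
            stacklevel=2,
        )
    safe_sd = np.where(constant, 1.0, sd)

    def _apply(fm: FeatureMatrix) -> FeatureMatrix:
        z = (fm.values - mu) / safe_sd
        z[:, constant] = 0.0
        return FeatureMatrix(z, fm.feature_names, fm.subject_ids)

    return tuple(_apply(fm) for fm in (train, *others))
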