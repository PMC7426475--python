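"""Connectivity matrices, sign-handling pipelines, proportional thresholding.

The three pipelines decide what "connection strength" means when a
correlation matrix contains anti-correlations:

* ``POS`` — keep only positive correlations (the common default);
* ``NEG`` — flip the sign and keep only what was negative, so the graph is
  built from the anti-correlation network;
* ``ABS`` — rank connections by magnitude regardless of sign.

Proportional thresholding then keeps the top fraction ``p`` of the
N(N-1)/2 possible connections, yielding a sparse binary graph at matched
density across pipelines.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "PipelineMode",
    "ThresholdGrid",
    "BinaryGraph",
    "pearson_connectivity",
    "apply_pipeline",
    "proportional_threshold",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N×N Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    roi_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal must be 1")
        object.__setattr__(self, "values", v)
        labels = self.roi_labels or tuple(f"ROI_{i:03d}" for i in range(v.shape[0]))
        if len(labels) != v.shape[0]:
            raise ValueError("roi_labels length must match matrix size")
        object.__setattr__(self, "roi_labels", tuple(labels))

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


class PipelineMode(enum.Enum):
    """Sign-handling convention applied before thresholding."""

    POS = "pos"
    NEG = "neg"
    ABS = "abs"


@dataclass(frozen=True)
class ThresholdGrid:
    """Ordered grid of proportional-threshold fractions.

    Default: 20% to 50% of the strongest connections in 2% increments
    (16 values).
    """

    fractions: tuple[float, ...] = tuple(np.round(np.arange(0.20, 0.501, 0.02), 2))

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.fractions)
        if not f:
            raise ValueError("empty threshold grid")
        if any(not 0 < x <= 1 for x in f):
            raise ValueError("threshold fractions must lie in (0, 1]")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("threshold fractions must be strictly increasing")
        object.__setattr__(self, "fractions", f)

    def __iter__(self):
        return iter(self.fractions)

    def __len__(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected simple graph from thresholding a connectivity matrix."""

    n_nodes: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"invalid edge ({i}, {j}) for {self.n_nodes} nodes")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "BinaryGraph":
        edges = frozenset(tuple(sorted(e)) for e in g.edges())
        return cls(n_nodes=g.number_of_nodes(), edges=edges)


def pearson_connectivity(ts: np.ndarray, roi_labels=None) -> ConnectivityMatrix:
    """Pearson correlation of every region pair of an N×T time-series matrix."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise ValueError("need an N x T matrix with T >= 2")
    labels = tuple(roi_labels) if roi_labels else tuple(
        f"ROI_{i:03d}" for i in range(ts.shape[0])
    )
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance ROI(s): {bad}")
    c = np.corrcoef(ts)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(values=c, roi_labels=labels)


def apply_pipeline(conn: ConnectivityMatrix, mode: PipelineMode) -> np.ndarray:
    """Transform a correlation matrix into nonnegative connection strengths.

    Entries that the mode discards (and exact zeros, which carry no
    strength) come back as 0; all retained weights are strictly positive.
    The diagonal is always 0.
    """
    c = conn.values
    if mode is PipelineMode.POS:
        w = np.where(c > 0, c, 0.0)
    elif mode is PipelineMode.NEG:
        w = np.where(c < 0, -c, 0.0)
    elif mode is PipelineMode.ABS:
        w = np.abs(c)
    else:  # pragma: no cover
        raise ValueError(f"unknown pipeline mode {mode!r}")
    np.fill_diagonal(w, 0.0)
    return w


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def proportional_threshold(weights: np.ndarray, p: float) -> BinaryGraph:
    """Keep the top ``p`` fraction of the strongest connections as edges.

    The edge budget ``k = round(p * N(N-1)/2)`` counts against *all* node
    pairs, not just the sign-retained ones, so a given ``p`` means the same
    graph density in every pipeline whenever enough connections survive the
    sign filter.  If fewer than ``k`` positive weights remain, all of them
    become edges and a warning is emitted.  Ties at the cut are broken by
    lexicographic (i, j) order.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not 0 < p <= 1:
        raise ValueError(f"threshold fraction must lie in (0, 1], got {p}")
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    keep = vals > 0
    iu, ju, vals = iu[keep], ju[keep], vals[keep]
    k = _round_half_away(p * n * (n - 1) / 2)
    if len(vals) < k:
        warnings.warn(
            f"only {len(vals)} retained connections for a budget of {k}; "
            "graph will be sparser than the requested density",
            stacklevel=2,
        )
        k = len(vals)
    # sort by decreasing weight, ties by (i, j)
    order = np.lexsort((ju, iu, -vals))
    edges = frozenset(
        (int(iu[t]), int(ju[t])) for t in order[:k]
    )
    return BinaryGraph(n_nodes=n, edges=edges)
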