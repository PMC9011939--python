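"""Construction of spatial views from a sample.

A *view* is a derived feature matrix, aligned row-wise to the sample, that
represents one spatial context in which marker relationships may act:

* the **intraview** — the expression of all other markers measured in the
  same unit (the target marker's own column is dropped at modeling time);
* the **juxtaview** — the summed expression (or cell-type counts) over a
  unit's direct neighbors in a pruned Delaunay cell graph;
* the **paraview** — a distance-weighted aggregate of the expression of all
  other units in the sample, with a weight family (gaussian / exponential /
  linear / constant) of scale ``l`` and an inner "zone of indifference"
  ``z`` inside which units contribute nothing, so that juxta and para
  information do not overlap when ``z`` equals the juxta cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError, distance_matrix

from .sample_io import SpatialSample

logger = logging.getLogger("polyview")

WEIGHT_FAMILIES = ("gaussian", "exponential", "linear", "constant")

#: pairwise weights smaller than this are treated as exactly zero
WEIGHT_TRUNCATION = 1e-12


@dataclass
class View:
    """A named derived feature matrix aligned to a sample."""

    name: str
    features: np.ndarray
    feature_names: list[str]
    #: base marker behind each column ("" when the column is not marker-derived);
    #: names importance-matrix rows and locates a target's own column.
    base_markers: list[str] = field(default_factory=list)
    #: whether the target's own column is dropped at modeling time (the
    #: Y-tilde convention); neighbor-count views keep it, since counting a
    #: unit's own type among its neighbors is exactly how self-preference
    #: is detected.
    drop_target: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("view features must be 2D")
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature name count mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names within a view")
        if not np.isfinite(self.features).all():
            raise ValueError("non-finite values in view features")
        if not self.base_markers:
            self.base_markers = [""] * self.features.shape[1]
        if len(self.base_markers) != self.features.shape[1]:
            raise ValueError("base marker count mismatch")

    @property
    def n_units(self) -> int:
        return self.features.shape[0]


@dataclass
class NeighborGraph:
    """Symmetric neighbor relation over unit indices, without self-edges."""

    edges: set[tuple[int, int]]
    n_units: int
    cutoff: float

    def __post_init__(self) -> None:
        canonical = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edges are not allowed")
            if not (0 <= i < self.n_units and 0 <= j < self.n_units):
                raise ValueError("edge index out of range")
            canonical.add((min(i, j), max(i, j)))
        self.edges = canonical

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_units)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj


def build_intraview(sample: SpatialSample) -> View:
    """Expression matrix verbatim; the target column is dropped downstream."""
    return View(
        name="intra",
        features=sample.expression.copy(),
        feature_names=list(sample.markers),
        base_markers=list(sample.markers),
        meta={"kind": "intra"},
    )


def delaunay_neighbors(positions: np.ndarray, cutoff: float = np.inf) -> NeighborGraph:
    """2D Delaunay triangulation pruned to edges not longer than ``cutoff``.

    Degenerate input (fewer than 3 points, or collinear points for which
    qhull fails) falls back to a plain distance-threshold graph with a
    logged warning, so tiny fixtures remain usable.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    edges: set[tuple[int, int]] = set()

    def _distance_graph() -> set[tuple[int, int]]:
        out = set()
        d = distance_matrix(positions, positions)
        for i in range(n):
            for j in range(i + 1, n):
                if d[i, j] <= cutoff:
                    out.add((i, j))
        return out

    if n < 3:
        logger.warning(
            "fewer than 3 units: falling back to distance-threshold graph"
        )
        return NeighborGraph(_distance_graph(), n, cutoff)
    try:
        tri = Delaunay(positions[:, :2])
    except QhullError:
        logger.warning(
            "degenerate (collinear?) input: falling back to distance-threshold graph"
        )
        return NeighborGraph(_distance_graph(), n, cutoff)

    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(simplex[a]), int(simplex[b])
                if np.linalg.norm(positions[i] - positions[j]) <= cutoff:
                    edges.add((min(i, j), max(i, j)))
    return NeighborGraph(edges, n, cutoff)


def juxta_cutoff(
    samples: Iterable[SpatialSample],
    rule: str = "pairwise_quantile",
    q: float = 0.25,
) -> float:
    """Edge-pruning length for the juxtaview cell graph, pooled across samples.

    ``pairwise_quantile``: the q-quantile of all inter-unit Euclidean
    distances (the IMC default is q=0.25). ``neighbor_quantile``: the
    q-quantile of Delaunay first-neighbor edge lengths (the structural
    in-silico workflows use q=0.75).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("at least one sample is required")
    pooled: list[np.ndarray] = []
    for sample in samples:
        pos = sample.positions
        if rule == "pairwise_quantile":
            d = distance_matrix(pos, pos)
            iu = np.triu_indices(pos.shape[0], k=1)
            pooled.append(d[iu])
        elif rule == "neighbor_quantile":
            graph = delaunay_neighbors(pos, cutoff=np.inf)
            lengths = [
                float(np.linalg.norm(pos[i] - pos[j])) for i, j in graph.edges
            ]
            pooled.append(np.asarray(lengths))
        else:
            raise ValueError(f"unknown cutoff rule {rule!r}")
    all_d = np.concatenate(pooled)
    if all_d.size == 0:
        raise ValueError("no distances available to compute a cutoff")
    return float(np.quantile(all_d, q))


def build_juxtaview(
    sample: SpatialSample,
    graph: NeighborGraph,
    suffix: str = ".juxta",
) -> View:
    """Sum of expression over each unit's direct neighbors.

    Isolated units get an all-zero row. Feature names are the marker names
    with ``suffix`` appended to distinguish them from intraview features.
    """
    if graph.n_units != sample.n_units:
        raise ValueError("graph and sample disagree on the number of units")
    features = np.zeros_like(sample.expression)
    for i, j in graph.edges:
        features[i] += sample.expression[j]
        features[j] += sample.expression[i]
    return View(
        name="juxta",
        features=features,
        feature_names=[m + suffix for m in sample.markers],
        base_markers=list(sample.markers),
        meta={"kind": "juxta", "cutoff": graph.cutoff},
    )


def paraview_weight(
    d: float | np.ndarray,
    family: str = "gaussian",
    l: float = 1.0,
    z: float = 0.0,
) -> float | np.ndarray:
    """Distance weight 1(d >= z) * w_family(d, l).

    Families: gaussian ``exp(-d^2/l^2)``, exponential ``exp(-d/l)``,
    linear ``max(1 - d/l, 0)`` and constant ``1(d <= l)``. The linear
    family is clamped at zero (the raw form goes negative past ``l``).
    The zone boundary itself contributes (``d >= z``).
    """
    if l <= 0:
        raise ValueError("l must be positive")
    if z < 0:
        raise ValueError("z must be non-negative")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if family == "gaussian":
        w = np.exp(-(d**2) / l**2)
    elif family == "exponential":
        w = np.exp(-d / l)
    elif family == "linear":
        w = np.clip(1.0 - d / l, 0.0, None)
    elif family == "constant":
        w = (d <= l).astype(float)
    else:
        raise ValueError(f"unknown weight family {family!r}")
    w = np.where(d >= z, w, 0.0)
    w = np.where(w < WEIGHT_TRUNCATION, 0.0, w)
    if w.ndim == 0:
        return float(w)
    return w


def build_paraview(
    sample: SpatialSample,
    family: str = "gaussian",
    l: float = 1.0,
    z: float = 0.0,
    suffix: str = ".para",
) -> View:
    """Distance-weighted aggregate of the expression of all *other* units.

    Row c is ``sum_{j != c} w(d_cj) Y_j``. The unit's own row (d = 0) is
    always excluded, even when z = 0: the intraview already carries the
    unit's own expression.
    """
    d = distance_matrix(sample.positions, sample.positions)
    w = paraview_weight(d, family=family, l=l, z=z)
    w = np.asarray(w, dtype=float)
    np.fill_diagonal(w, 0.0)
    features = w @ sample.expression
    return View(
        name="para",
        features=features,
        feature_names=[m + suffix for m in sample.markers],
        base_markers=list(sample.markers),
        meta={"kind": "para", "family": family, "l": l, "z": z},
    )


def build_celltype_views(
    sample: SpatialSample,
    graph: NeighborGraph,
    types: Sequence[str] | None = None,
) -> tuple[View, View]:
    """One-hot identity intraview and neighbor-count juxtaview for cell types.

    The intra view one-hot encodes each unit's type; the juxta view counts,
    per type, how many direct neighbors a unit has of that type.
    """
    if sample.celltype is None:
        raise ValueError("sample has no cell-type labels")
    if types is None:
        types = sorted(set(sample.celltype))
    types = list(types)
    type_index = {t: i for i, t in enumerate(types)}
    onehot = np.zeros((sample.n_units, len(types)))
    for row, label in enumerate(sample.celltype):
        onehot[row, type_index[label]] = 1.0
    counts = np.zeros_like(onehot)
    for i, j in graph.edges:
        counts[i] += onehot[j]
        counts[j] += onehot[i]
    intra = View(
        name="intra",
        features=onehot,
        feature_names=list(types),
        base_markers=list(types),
        meta={"kind": "intra", "encoding": "onehot"},
    )
    juxta = View(
        name="juxta",
        features=counts,
        feature_names=[t + ".juxta" for t in types],
        base_markers=list(types),
        drop_target=False,
        meta={"kind": "juxta", "encoding": "counts", "cutoff": graph.cutoff},
    )
    return intra, juxta
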