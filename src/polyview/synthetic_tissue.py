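"""Structural in-silico tissues: spatial cell-type patterns + marker expression.

Three canonical layouts over four approximately equally abundant cell
types serve as ground truth for structural-relationship recovery:

* ``random`` — no type prefers any neighbor (negative control);
* ``self`` — one type (ct1) co-localizes with itself;
* ``mutual`` — two types (ct1, ct3) co-localize with each other.

Positions are a jittered grid; labels start balanced and random and are
refined by seeded greedy label swaps that increase the configured
neighbor affinity among Delaunay neighbors until the affinity reaches a
target enrichment over the permutation-null expectation (the ``strength``
parameter). This directly controls the quantity the downstream
neighborhood view must detect, while leaving the non-focal types close
to randomly arranged.

Expression is multivariate normal per cell type with diagonal covariance
(common spread 1): *informative* markers get per-type means arranged on a
ladder with rung size drawn uniformly from [4, 8] spread units, so any
two types are separated by at least 4 standard deviations; *uninformative*
markers share one mean across types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sample_io import RunConfig, SpatialSample
from .views import (
    NeighborGraph,
    build_celltype_views,
    build_intraview,
    build_juxtaview,
    delaunay_neighbors,
    juxta_cutoff,
)
from .modeling import TargetResult, run_multiview, stable_seed

DEFAULT_TYPES = ("ct0", "ct1", "ct2", "ct3")


@dataclass
class TissueLayout:
    positions: np.ndarray
    celltype: list[str]
    pattern: str  # "random" | "self" | "mutual"
    focal_types: tuple[str, ...] = ()
    types: tuple[str, ...] = DEFAULT_TYPES

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        counts = {t: self.celltype.count(t) for t in self.types}
        expected = len(self.celltype) / len(self.types)
        for t, c in counts.items():
            if abs(c - expected) > 0.1 * expected:
                raise ValueError(f"cell-type abundances unbalanced: {counts}")

    @property
    def n_units(self) -> int:
        return self.positions.shape[0]


@dataclass
class ExpressionModel:
    """Multivariate-normal marker model driven by cell type."""

    n_markers: int = 100
    n_informative: int = 75
    spread: float = 1.0
    shift_range: tuple[float, float] = (4.0, 8.0)
    base_range: tuple[float, float] = (2.0, 10.0)
    types: tuple[str, ...] = DEFAULT_TYPES
    means: np.ndarray | None = None  # (n_types, n_markers), filled by sampling

    def sample_means(self, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        n_types = len(self.types)
        means = np.empty((n_types, self.n_markers))
        base = rng.uniform(*self.base_range, size=self.n_markers)
        means[:] = base
        for m in range(self.n_informative):
            rung = rng.uniform(*self.shift_range)
            order = rng.permutation(n_types)
            sign = rng.choice([-1.0, 1.0])
            means[:, m] = base[m] + sign * rung * order
        self.means = means
        return means


def _affinity(labels: np.ndarray, edges: np.ndarray, focal: np.ndarray) -> int:
    """Number of focal neighbor pairs: (a, a) for self, {a, b} for mutual."""
    la, lb = labels[edges[:, 0]], labels[edges[:, 1]]
    if focal.size == 1:
        return int(np.sum((la == focal[0]) & (lb == focal[0])))
    a, b = focal
    return int(np.sum(((la == a) & (lb == b)) | ((la == b) & (lb == a))))


def generate_layout(
    L: int = 2000,
    n_types: int = 4,
    pattern: str = "random",
    strength: float = 2.0,
    seed: int = 0,
    spacing: float = 1.0,
    jitter: float = 0.25,
    max_sweeps: int = 200,
) -> TissueLayout:
    """Jittered-grid positions with a planted neighbor-preference pattern.

    ``strength`` is the target enrichment of the focal neighbor-pair count
    over its expectation under random labels; refinement stops once it is
    reached (or after ``max_sweeps`` label-swap sweeps). ``random`` skips
    refinement entirely.
    """
    if L < 50:
        raise ValueError("need at least 50 cells")
    if pattern not in ("random", "self", "mutual"):
        raise ValueError(f"unknown pattern {pattern!r}")
    types = DEFAULT_TYPES[:n_types]
    rng = np.random.default_rng(seed)

    side = int(np.ceil(np.sqrt(L)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    grid = np.column_stack([gx.ravel(), gy.ravel()]).astype(float) * spacing
    chosen = rng.choice(grid.shape[0], size=L, replace=False)
    positions = grid[chosen] + rng.uniform(
        -jitter * spacing, jitter * spacing, size=(L, 2)
    )

    labels = np.repeat(np.arange(n_types), int(np.ceil(L / n_types)))[:L]
    rng.shuffle(labels)

    focal_types: tuple[str, ...] = ()
    if pattern != "random":
        graph = delaunay_neighbors(positions, cutoff=np.inf)
        edges = np.asarray(sorted(graph.edges), dtype=int)
        adjacency: list[list[int]] = [[] for _ in range(L)]
        for i, j in edges:
            adjacency[i].append(j)
            adjacency[j].append(i)
        if pattern == "self":
            focal = np.array([1])  # ct1
            focal_types = (types[1],)
            null_pairs = len(edges) / n_types**2
        else:
            focal = np.array([1, 3])  # ct1 <-> ct3
            focal_types = (types[1], types[3])
            null_pairs = 2 * len(edges) / n_types**2
        target = strength * null_pairs

        if focal.size == 1:
            f0 = int(focal[0])

            def pair(a: int, b: int) -> int:
                return int(a == f0 and b == f0)
        else:
            fa, fb = int(focal[0]), int(focal[1])

            def pair(a: int, b: int) -> int:
                return int((a == fa and b == fb) or (a == fb and b == fa))

        focal_set = set(int(f) for f in focal)

        def objective(a: int, b: int) -> int:
            # reward focal adjacency; mildly penalize adjacency that the
            # planted preference would otherwise induce as a side effect —
            # same-type clumps for the self pattern, any bystander-bystander
            # adjacency (which complement-crowding inflates) for the mutual
            # pattern — so non-focal pairs stay near their null rates
            if pair(a, b):
                return 2
            if focal_set == {a} == {b}:
                return 0
            if len(focal_set) == 1:
                return -1 if a == b else 0
            return -1 if (a not in focal_set and b not in focal_set) else 0

        def local_score(u: int, w: int) -> tuple[int, int]:
            # (objective, focal-pair count) on edges incident to u or w
            h = f = 0
            for v in adjacency[u]:
                h += objective(labels[u], labels[v])
                f += pair(labels[u], labels[v])
            for v in adjacency[w]:
                if v != u:  # count a shared edge once
                    h += objective(labels[w], labels[v])
                    f += pair(labels[w], labels[v])
            return h, f

        focal_count = _affinity(labels, edges, focal)
        for _ in range(max_sweeps):
            if focal_count >= target:
                break
            order = rng.permutation(L)
            partners = rng.integers(0, L, size=L)
            for u, w in zip(order, partners):
                if focal_count >= target:
                    break
                u, w = int(u), int(w)
                if u == w or labels[u] == labels[w]:
                    continue
                h_before, f_before = local_score(u, w)
                labels[u], labels[w] = labels[w], labels[u]
                h_after, f_after = local_score(u, w)
                # a swap must gain focal pairs; the penalty term only vetoes
                # gains that crowd the bystander types together
                if f_after > f_before and h_after > h_before:
                    focal_count += f_after - f_before
                else:
                    labels[u], labels[w] = labels[w], labels[u]

    return TissueLayout(
        positions=positions,
        celltype=[types[i] for i in labels],
        pattern=pattern,
        focal_types=focal_types,
        types=types,
    )


def neighbor_enrichment(
    layout: TissueLayout,
    type_a: str,
    type_b: str,
    n_perm: int = 200,
    seed: int = 0,
) -> float:
    """Observed / permutation-expected count of (a, b) neighbor pairs.

    The null pools >= ``n_perm`` seeded label permutations over the same
    Delaunay graph.
    """
    graph = delaunay_neighbors(layout.positions, cutoff=np.inf)
    edges = np.asarray(sorted(graph.edges), dtype=int)
    labels = np.asarray(layout.celltype)

    def count(lab: np.ndarray) -> int:
        la, lb = lab[edges[:, 0]], lab[edges[:, 1]]
        if type_a == type_b:
            return int(np.sum((la == type_a) & (lb == type_a)))
        return int(
            np.sum(((la == type_a) & (lb == type_b)) | ((la == type_b) & (lb == type_a)))
        )

    observed = count(labels)
    rng = np.random.default_rng(seed)
    null = np.mean([count(rng.permutation(labels)) for _ in range(n_perm)])
    return observed / null if null > 0 else np.inf


def simulate_expression(
    layout: TissueLayout, model: ExpressionModel | None = None, seed: int = 0
) -> SpatialSample:
    """Draw per-cell expression from the cell type's multivariate normal."""
    model = model or ExpressionModel()
    rng = np.random.default_rng(seed)
    if model.means is None:
        model.sample_means(stable_seed(seed, "means"))
    type_index = {t: i for i, t in enumerate(model.types)}
    rows = np.array([type_index[t] for t in layout.celltype])
    expr = model.means[rows] + rng.normal(
        scale=model.spread, size=(layout.n_units, model.n_markers)
    )
    return SpatialSample(
        positions=layout.positions.copy(),
        expression=expr,
        markers=[f"gene_{m}" for m in range(model.n_markers)],
        celltype=list(layout.celltype),
    )


def top_differential_markers(
    sample: SpatialSample, celltype: str, n: int = 10
) -> list[str]:
    """Markers ranked by |mean(type) - mean(all other types)|, top n."""
    labels = np.asarray(sample.celltype)
    inside = labels == celltype
    if not inside.any() or inside.all():
        raise ValueError(f"no contrast possible for type {celltype!r}")
    diff = np.abs(
        sample.expression[inside].mean(axis=0)
        - sample.expression[~inside].mean(axis=0)
    )
    order = np.argsort(-diff)[:n]
    return [sample.markers[i] for i in order]


def _structural_graph(sample: SpatialSample) -> NeighborGraph:
    """Juxta graph at the 75th percentile of first-neighbor distances.

    The deliberately loose threshold emulates the error of picking the
    cutoff on real data.
    """
    cutoff = juxta_cutoff([sample], rule="neighbor_quantile", q=0.75)
    return delaunay_neighbors(sample.positions, cutoff=cutoff)


def celltype_workflow(
    sample: SpatialSample,
    config: RunConfig | None = None,
    sample_id: str = "",
) -> list[TargetResult]:
    """Cell-type identity workflow: one-hot targets, neighbor-count juxtaview.

    The intraview (one-hot identity) would trivially predict identity by
    exclusion, so it is bypassed: the meta-model baseline is an
    intercept-only model and the gain equals the multiview R^2.
    """
    base = config or RunConfig()
    config = RunConfig(
        n_trees=base.n_trees,
        cv_folds=base.cv_folds,
        seed=base.seed,
        gain_threshold=base.gain_threshold,
        importance_cutoff=base.importance_cutoff,
        bypass_intra=True,
        eq3_denominator=base.eq3_denominator,
    )
    graph = _structural_graph(sample)
    intra, juxta = build_celltype_views(sample, graph)
    types = intra.feature_names
    return run_multiview(
        sample, [intra, juxta], config, targets=list(types), sample_id=sample_id
    )


def expression_workflow(
    sample: SpatialSample,
    config: RunConfig | None = None,
    targets: list[str] | None = None,
    sample_id: str = "",
) -> list[TargetResult]:
    """Marker-expression workflow: expression targets, summed-expression juxtaview.

    As in the identity workflow the intraview is bypassed; predictors are
    the juxtaview over all markers. ``targets`` restricts the modeled
    targets (e.g. to representative differential markers) while keeping
    the full predictor set.
    """
    base = config or RunConfig()
    config = RunConfig(
        n_trees=base.n_trees,
        cv_folds=base.cv_folds,
        seed=base.seed,
        gain_threshold=base.gain_threshold,
        importance_cutoff=base.importance_cutoff,
        bypass_intra=True,
        eq3_denominator=base.eq3_denominator,
    )
    graph = _structural_graph(sample)
    intra = build_intraview(sample)
    juxta = build_juxtaview(sample, graph)
    return run_multiview(
        sample, [intra, juxta], config, targets=targets, sample_id=sample_id
    )


def generate_structural_suite(
    L: int = 2000,
    n_markers: int = 100,
    n_informative: int = 75,
    strength: float = 2.0,
    seed: int = 0,
) -> dict[str, SpatialSample]:
    """The three canonical tissues (random / self / mutual) with expression."""
    model = ExpressionModel(n_markers=n_markers, n_informative=n_informative)
    model.sample_means(stable_seed(seed, "suite-means"))
    out = {}
    for pattern in ("random", "self", "mutual"):
        layout = generate_layout(
            L=L, pattern=pattern, strength=strength,
            seed=stable_seed(seed, "layout", pattern),
        )
        out[pattern] = simulate_expression(
            layout, model, seed=stable_seed(seed, "expr", pattern)
        )
    return out


def structural_workflows(
    samples: dict[str, SpatialSample],
    config: RunConfig | None = None,
    expression_tissues: tuple[str, ...] = ("mutual",),
    n_representative: int = 10,
) -> dict:
    """Run both structural workflows over the canonical tissue suite.

    Returns per-tissue identity-workflow results, expression-workflow
    results for the requested tissues (targets restricted to each type's
    top ``n_representative`` differential markers), and the representative
    marker lists per type.
    """
    config = config or RunConfig()
    bundle: dict = {"celltype": {}, "expression": {}, "representative": {}}
    for name, sample in samples.items():
        bundle["celltype"][name] = celltype_workflow(
            sample, config, sample_id=name
        )
    for name in expression_tissues:
        sample = samples[name]
        types = sorted(set(sample.celltype))
        reps = {
            t: top_differential_markers(sample, t, n=n_representative)
            for t in types
        }
        bundle["representative"][name] = reps
        targets = [m for t in types for m in reps[t]]
        # a marker can represent two types; deduplicate, keep order
        targets = list(dict.fromkeys(targets))
        bundle["expression"][name] = expression_workflow(
            sample, config, targets=targets, sample_id=name
        )
    return bundle
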