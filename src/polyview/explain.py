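"""From raw forest importances to interpretable interaction estimates.

The raw impurity-reduction importances of a view model live on an
arbitrary scale. They are turned into comparable *weighted importances*

    M_kj = (I_kj - mean_j I_kj) / spread * (1 - p_k)

i.e. standardized over the predictors of each target and damped by the
significance of the view's fusion coefficient: a view that contributes
nothing to the meta-model (p ~ 1) yields near-zero weighted importances
regardless of how its forest ranked the predictors. Being standardized,
weighted importances from multiple samples can be aggregated by simple
averaging; aggregation accentuates consistently inferred interactions.

Downstream summaries: per-sample R^2 and importance signature vectors for
cohort-level comparison, interaction counting and view/group contrasts at
an importance cutoff, and Louvain communities of the interaction network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .modeling import TargetResult


@dataclass
class ImportanceMatrix:
    """Weighted importances of one view: predictors (rows) x targets (cols)."""

    view: str
    matrix: pd.DataFrame
    sample_id: str = ""

    @property
    def predictors(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def targets(self) -> list[str]:
        return list(self.matrix.columns)


def weight_importances(
    raw: np.ndarray, p: float, denominator: str = "sd"
) -> np.ndarray:
    """Standardize a raw importance vector and damp it by (1 - p).

    ``denominator`` selects the spread: ``"sd"`` (true standardization,
    the default) or ``"var"`` (the printed form of the weighting formula).
    Zero-spread (constant) vectors map to all-zeros.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("standardization needs at least 2 predictors")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if denominator not in ("sd", "var"):
        raise ValueError("denominator must be 'sd' or 'var'")
    sd = raw.std(ddof=1)  # sample sd: raw (2,4,6) standardizes to (-1,0,1)
    if sd == 0.0:
        return np.zeros_like(raw)
    spread = sd if denominator == "sd" else sd**2
    return (raw - raw.mean()) / spread * (1.0 - p)


def sample_importances(
    results: Sequence[TargetResult],
    predictors: Sequence[str] | None = None,
    denominator: str = "sd",
    sample_id: str = "",
) -> dict[str, ImportanceMatrix]:
    """Weighted importance matrices of one sample, one per view.

    Rows are the union of predictor (base-marker) names across targets
    unless ``predictors`` fixes the universe; cells a predictor never
    competes for (e.g. a target's own intraview column) are NaN.
    """
    view_names: list[str] = []
    for res in results:
        for v in res.view_names:
            if v not in view_names:
                view_names.append(v)
    if predictors is None:
        seen: list[str] = []
        for res in results:
            for bases in res.predictor_bases:
                for b in bases:
                    if b not in seen:
                        seen.append(b)
        predictors = seen
    predictors = list(predictors)
    targets = [res.target for res in results]

    out: dict[str, ImportanceMatrix] = {}
    for view in view_names:
        matrix = pd.DataFrame(
            np.nan, index=predictors, columns=targets, dtype=float
        )
        for res in results:
            if view not in res.view_names:
                continue
            vi = res.view_names.index(view)
            raw = res.raw_importances[vi]
            if raw.size < 2:
                weighted = np.zeros_like(raw)  # spread undefined
            else:
                weighted = weight_importances(
                    raw, float(res.pvalues[vi]), denominator
                )
            for base, value in zip(res.predictor_bases[vi], weighted):
                if base in matrix.index:
                    matrix.loc[base, res.target] = value
        out[view] = ImportanceMatrix(view=view, matrix=matrix, sample_id=sample_id)
    return out


def aggregate(
    matrices: Sequence[ImportanceMatrix],
    subset: Iterable[str] | None = None,
) -> ImportanceMatrix:
    """Element-wise mean of per-sample matrices of the same view.

    ``subset`` restricts to the given sample ids. Entries missing (NaN) in
    some samples are averaged over the samples where they are present.
    """
    matrices = list(matrices)
    if subset is not None:
        wanted = set(subset)
        matrices = [m for m in matrices if m.sample_id in wanted]
    if not matrices:
        raise ValueError("no matrices to aggregate")
    views = {m.view for m in matrices}
    if len(views) > 1:
        raise ValueError(f"cannot aggregate across views: {sorted(views)}")
    frames = [m.matrix for m in matrices]
    stacked = pd.concat(frames, keys=range(len(frames)))
    mean = stacked.groupby(level=1, sort=False).mean()
    mean = mean.reindex(frames[0].index)
    return ImportanceMatrix(view=matrices[0].view, matrix=mean, sample_id="")


def _retained_targets(
    cohort: Mapping[str, Sequence[TargetResult]], gain_threshold: float
) -> list[str]:
    """Targets whose cohort-mean gain reaches the threshold (pp).

    Filtering on the cohort mean (not per sample) keeps signature vectors
    of every sample at identical length and ordering.
    """
    order: list[str] = []
    gains: dict[str, list[float]] = {}
    for results in cohort.values():
        for res in results:
            if res.target not in gains:
                gains[res.target] = []
                order.append(res.target)
            gains[res.target].append(res.gain)
    return [t for t in order if np.mean(gains[t]) >= gain_threshold]


def r2_signature(
    cohort: Mapping[str, Sequence[TargetResult]],
    gain_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-sample concatenation of (intra R^2, multi R^2, gain) per marker.

    Markers with cohort-mean gain below ``gain_threshold`` percentage
    points are removed, so the vector length is 3 x (retained markers).
    R^2 values are expressed in percent so all entries share units.
    """
    retained = _retained_targets(cohort, gain_threshold)
    if not retained:
        import logging

        logging.getLogger("polyview").warning(
            "no marker passes the gain filter: empty signatures"
        )
    columns = []
    for t in retained:
        columns += [f"{t}_intra.R2", f"{t}_multi.R2", f"{t}_gain.R2"]
    rows = {}
    for sample_id, results in cohort.items():
        lookup = {res.target: res for res in results}
        vec: list[float] = []
        for t in retained:
            res = lookup[t]
            vec += [100.0 * res.intra_r2, 100.0 * res.multi_r2, res.gain]
        rows[sample_id] = vec
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def importance_signature(
    cohort: Mapping[str, Sequence[TargetResult]],
    gain_threshold: float = 2.0,
    predictors: Sequence[str] | None = None,
    denominator: str = "sd",
) -> pd.DataFrame:
    """Per-sample concatenation of weighted importances over all views.

    The vector covers (retained targets) x (all predictors) x (views); its
    entries are named ``view_predictor_target``. Cells without a defined
    importance (a target's own intraview column) contribute 0.
    """
    retained = _retained_targets(cohort, gain_threshold)
    per_sample = {
        sample_id: sample_importances(
            results, predictors=predictors, denominator=denominator,
            sample_id=sample_id,
        )
        for sample_id, results in cohort.items()
    }
    # shared universe: view and predictor order from the first sample
    first = next(iter(per_sample.values()))
    view_names = list(first.keys())
    predictor_names = first[view_names[0]].predictors

    columns = [
        f"{view}_{pred}_{t}"
        for view in view_names
        for t in retained
        for pred in predictor_names
    ]
    rows = {}
    for sample_id, mats in per_sample.items():
        vec: list[float] = []
        for view in view_names:
            block = mats[view].matrix.reindex(
                index=predictor_names, columns=retained
            )
            vec += list(np.nan_to_num(block.to_numpy().T.ravel()))
        rows[sample_id] = vec
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def count_interactions(agg: ImportanceMatrix, cutoff: float = 0.5) -> int:
    """Number of (predictor, target) entries with importance >= cutoff."""
    values = agg.matrix.to_numpy()
    return int(np.sum(values >= cutoff))


def _important_pairs(agg: ImportanceMatrix, cutoff: float) -> set[tuple[str, str]]:
    mask = agg.matrix >= cutoff
    rows, cols = np.nonzero(mask.to_numpy())
    return {
        (agg.predictors[i], agg.targets[j]) for i, j in zip(rows, cols)
    }


def contrast_views(
    agg_a: ImportanceMatrix,
    agg_b: ImportanceMatrix,
    cutoff: float = 0.5,
) -> set[tuple[str, str]]:
    """Pairs important in view a but not in view b.

    A pair missing (NaN) in b counts as "not important" there.
    """
    if set(agg_a.targets) != set(agg_b.targets):
        raise ValueError("views disagree on the target universe")
    return _important_pairs(agg_a, cutoff) - _important_pairs(agg_b, cutoff)


def contrast_groups(
    agg_group1: ImportanceMatrix,
    agg_group2: ImportanceMatrix,
    cutoff: float = 0.5,
) -> set[tuple[str, str]]:
    """Pairs important in group 1 and not in group 2, for the same view."""
    if agg_group1.view != agg_group2.view:
        raise ValueError("group contrast requires the same view")
    if set(agg_group1.targets) != set(agg_group2.targets) or set(
        agg_group1.predictors
    ) != set(agg_group2.predictors):
        raise ValueError("groups disagree on the marker universe")
    return _important_pairs(agg_group1, cutoff) - _important_pairs(agg_group2, cutoff)


def communities(agg: ImportanceMatrix, seed: int = 42) -> list[set[str]]:
    """Louvain communities of the undirected interaction network.

    The square predictor-target matrix A is symmetrized to A + A^T,
    negative weights clamped to zero, zero-degree nodes dropped, and the
    modularity-maximizing partition extracted with a fixed seed.
    """
    A = agg.matrix
    if list(A.index) != list(A.columns):
        raise ValueError("communities need identical predictor and target sets")
    sym = np.nan_to_num(A.to_numpy()) + np.nan_to_num(A.to_numpy()).T
    np.fill_diagonal(sym, 0.0)
    sym = np.clip(sym, 0.0, None)
    graph = nx.Graph()
    names = list(A.index)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            if sym[i, j] > 0:
                graph.add_edge(a, names[j], weight=float(sym[i, j]))
    if graph.number_of_edges() == 0:
        raise ValueError("empty graph after clamping")
    parts = nx.community.louvain_communities(graph, weight="weight", seed=seed)
    return [set(part) for part in parts]
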