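"""Multi-sample orchestration: cohort runs, aggregation, permutation nulls.

Every sample is processed independently (the per-sample RNG streams are
keyed by the master seed and the sample id, so results do not depend on
processing order), with one cohort-wide juxtaview cutoff. Aggregated
weighted-importance matrices, signatures and grouped contrasts are then
computed over the per-sample results.

The permutation null re-runs the identical pipeline on replicates whose
unit coordinates are shuffled within each sample; comparing gains and
view contributions between original and permuted layouts quantifies how
much of the model's performance genuinely comes from tissue structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sample_io import RunConfig, SpatialSample, ViewSpec
from .views import (
    build_intraview,
    build_juxtaview,
    build_paraview,
    delaunay_neighbors,
    juxta_cutoff,
)
from .modeling import TargetResult, permute_coordinates, run_multiview, stable_seed
from .explain import ImportanceMatrix, aggregate, sample_importances


DEFAULT_VIEWS = [
    ViewSpec(name="intra"),
    ViewSpec(name="juxta", cutoff_rule="pairwise_quantile", cutoff_q=0.25),
    ViewSpec(name="para", family="gaussian", l_grid=(100.0,), zone="auto"),
]


@dataclass
class CohortResult:
    per_sample: dict[str, list[TargetResult]]
    aggregated: dict[str, ImportanceMatrix]
    juxta_cutoff: float
    config: RunConfig

    def mean_gain(self) -> float:
        gains = [
            r.gain for results in self.per_sample.values() for r in results
        ]
        return float(np.mean(gains))

    def contributions(self, view: str) -> np.ndarray:
        values = []
        for results in self.per_sample.values():
            for r in results:
                if view in r.view_names:
                    values.append(r.contributions[r.view_names.index(view)])
        return np.asarray(values)

    def gains(self) -> np.ndarray:
        return np.asarray(
            [r.gain for results in self.per_sample.values() for r in results]
        )


def _build_views(
    sample: SpatialSample,
    specs: list[ViewSpec],
    cutoff: float,
):
    views = []
    for spec in specs:
        if spec.name == "intra":
            views.append(build_intraview(sample))
        elif spec.name == "juxta":
            graph = delaunay_neighbors(sample.positions, cutoff=cutoff)
            views.append(build_juxtaview(sample, graph))
        elif spec.name == "para":
            z = cutoff if spec.zone == "auto" else float(spec.zone)
            views.append(
                build_paraview(
                    sample, family=spec.family, l=float(spec.l_grid[0]), z=z
                )
            )
        else:
            raise ValueError(f"unknown view spec {spec.name!r}")
    return views


def run_cohort(
    samples: dict[str, SpatialSample],
    config: RunConfig | None = None,
) -> CohortResult:
    """Independent per-sample multiview runs plus cohort-level aggregation.

    The juxtaview pruning length is computed once from all samples pooled
    (the cohort is assumed to share units of measurement); paraview zones
    set to ``"auto"`` reuse it so juxta- and para-information do not
    overlap. All samples must share the marker universe.
    """
    if not samples:
        raise ValueError("empty cohort")
    config = config or RunConfig()
    specs = config.views or DEFAULT_VIEWS
    marker_sets = {tuple(s.markers) for s in samples.values()}
    if len(marker_sets) > 1:
        raise ValueError("samples disagree on the marker universe")

    juxta_specs = [s for s in specs if s.name == "juxta"]
    if juxta_specs:
        rule = juxta_specs[0].cutoff_rule
        q = juxta_specs[0].cutoff_q
    else:
        rule, q = "pairwise_quantile", 0.25
    cutoff = juxta_cutoff(samples.values(), rule=rule, q=q)

    per_sample: dict[str, list[TargetResult]] = {}
    matrices: dict[str, list[ImportanceMatrix]] = {}
    markers = next(iter(samples.values())).markers
    for sample_id in sorted(samples):
        sample = samples[sample_id]
        views = _build_views(sample, specs, cutoff)
        results = run_multiview(sample, views, config, sample_id=sample_id)
        per_sample[sample_id] = results
        for view, mat in sample_importances(
            results,
            predictors=markers,
            denominator=config.eq3_denominator,
            sample_id=sample_id,
        ).items():
            matrices.setdefault(view, []).append(mat)

    aggregated = {view: aggregate(mats) for view, mats in matrices.items()}
    return CohortResult(
        per_sample=per_sample,
        aggregated=aggregated,
        juxta_cutoff=cutoff,
        config=config,
    )


@dataclass
class PermutationNullResult:
    original: CohortResult
    permuted: list[CohortResult]
    gain_pvalue: float  # H1: original gains > permuted gains
    contribution_pvalues: dict[str, float] = field(default_factory=dict)

    def permuted_gains(self) -> np.ndarray:
        return np.concatenate([c.gains() for c in self.permuted])

    def fraction_nonpositive_permuted_gain(self) -> float:
        gains = self.permuted_gains()
        return float(np.mean(gains <= 0.0))


def permutation_null(
    samples: dict[str, SpatialSample],
    n_perm: int = 10,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> PermutationNullResult:
    """Full cohort re-runs on coordinate-permuted replicates.

    For each of ``n_perm`` replicates, every sample's positions are
    row-permuted (expression untouched) and the identical pipeline is
    re-run. Reports one-sided Wilcoxon rank-sum (Mann-Whitney) tests of
    (a) original gains exceeding permuted gains and (b) each view's
    contribution being *higher under permutation* for the intraview and
    *lower under permutation* for the spatial views.
    """
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    original = run_cohort(samples, config)
    permuted: list[CohortResult] = []
    for p in range(n_perm):
        shuffled = {
            sid: permute_coordinates(s, 1, seed=stable_seed(seed, "perm", p, sid))[0]
            for sid, s in samples.items()
        }
        permuted.append(run_cohort(shuffled, config))

    orig_gains = original.gains()
    perm_gains = np.concatenate([c.gains() for c in permuted])
    gain_p = float(
        stats.mannwhitneyu(orig_gains, perm_gains, alternative="greater").pvalue
    )
    contribution_pvalues: dict[str, float] = {}
    view_names = sorted(original.aggregated)
    for view in view_names:
        orig_c = original.contributions(view)
        perm_c = np.concatenate([c.contributions(view) for c in permuted])
        alternative = "greater" if view == "intra" else "less"
        contribution_pvalues[view] = float(
            stats.mannwhitneyu(perm_c, orig_c, alternative=alternative).pvalue
        )
    return PermutationNullResult(
        original=original,
        permuted=permuted,
        gain_pvalue=gain_p,
        contribution_pvalues=contribution_pvalues,
    )
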