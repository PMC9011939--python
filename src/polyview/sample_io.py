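"""Reading and writing spatial samples and modeling results.

A *spatial sample* is a table with one row per spatial unit (a segmented
cell or a capture spot): two or three coordinate columns plus one column
per measured marker, optionally a categorical cell-type column. Files are
plain delimited text (comma or tab, auto-detected by extension) with a
mandatory header, matching common IMC / spatial-transcriptomics exports.

Results are serialized as long-format tables (one row per predictor-target
pair per view) so that cross-sample aggregation is a plain concatenation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("polyview")

PERFORMANCE_FILE = "performance.csv"
IMPORTANCE_FILE_TEMPLATE = "importances_{view}.csv"
CONFIG_ECHO_FILE = "config.yaml"


@dataclass
class SpatialSample:
    """Spatial coordinates paired with marker expression.

    Attributes
    ----------
    positions : (L, s) float array, s in {2, 3}
        Spatial coordinates of each unit. Units (pixels, microns) are
        arbitrary but must be consistent within a cohort.
    expression : (L, k) float array
        Measured expression, one column per marker.
    markers : list of k unique marker names.
    unit_ids : list of L identifiers (row order is meaningful and is never
        permuted by I/O).
    celltype : optional list of L categorical labels.
    """

    positions: np.ndarray
    expression: np.ndarray
    markers: list[str]
    unit_ids: list[str] = field(default_factory=list)
    celltype: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] not in (2, 3):
            raise ValueError("positions must be L x s with s in {2, 3}")
        if self.expression.ndim != 2:
            raise ValueError("expression must be a 2D matrix")
        if self.positions.shape[0] != self.expression.shape[0]:
            raise ValueError(
                "positions and expression disagree on the number of units"
            )
        if self.n_units < 1:
            raise ValueError("a sample needs at least one spatial unit")
        if self.n_markers < 2:
            raise ValueError("a sample needs at least two markers")
        if len(self.markers) != self.n_markers:
            raise ValueError("marker names do not match expression columns")
        if len(set(self.markers)) != len(self.markers):
            dupes = sorted({m for m in self.markers if self.markers.count(m) > 1})
            raise ValueError(f"duplicate marker names: {dupes}")
        if np.isnan(self.positions).any() or np.isnan(self.expression).any():
            raise ValueError("missing value (NaN) in sample")
        if not (np.isfinite(self.positions).all() and np.isfinite(self.expression).all()):
            raise ValueError("non-finite value in sample")
        if not self.unit_ids:
            self.unit_ids = [str(i) for i in range(self.n_units)]
        if len(self.unit_ids) != self.n_units:
            raise ValueError("unit_ids length does not match number of units")
        if self.celltype is not None and len(self.celltype) != self.n_units:
            raise ValueError("celltype length does not match number of units")

    @property
    def n_units(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.expression.shape[1]

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"unknown marker {marker!r}") from None


@dataclass
class ViewSpec:
    """Configuration of one spatially contextualized view."""

    name: str
    family: str = "gaussian"
    l_grid: tuple[float, ...] = (25.0, 50.0, 100.0, 200.0, 400.0)
    zone: float | str = "auto"  # "auto" -> juxta cutoff
    cutoff_rule: str = "pairwise_quantile"
    cutoff_q: float = 0.25


@dataclass
class RunConfig:
    """Tunable parameters of the multiview pipeline.

    Defaults follow the reference workflow: 100-tree forests, 10-fold CV
    for the meta-model, a 2-percentage-point gain filter for signatures and
    an importance cutoff of 0.5 for interaction counting.
    """

    n_trees: int = 100
    cv_folds: int = 10
    seed: int = 42
    gain_threshold: float = 2.0  # percentage points
    importance_cutoff: float = 0.5
    bypass_intra: bool = False
    eq3_denominator: str = "sd"  # {"sd", "var"}
    views: list[ViewSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("ensemble size must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv folds must be >= 2")
        for value in (self.gain_threshold, self.importance_cutoff):
            if not np.isfinite(value):
                raise ValueError("thresholds must be finite")
        if self.eq3_denominator not in ("sd", "var"):
            raise ValueError("eq3_denominator must be 'sd' or 'var'")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate column names in header: {dupes}")
    return pd.read_csv(path, sep=sep, header=0)


def read_sample(
    path: str | Path,
    coord_columns: Sequence[str] = ("x", "y"),
    marker_columns: Sequence[str] | str = "rest",
    celltype_column: str | None = None,
    id_column: str | None = None,
) -> SpatialSample:
    """Read a delimited sample table into a validated :class:`SpatialSample`.

    ``marker_columns="rest"`` treats every column that is not a coordinate,
    id or cell-type column as a marker. Row order is preserved.
    """
    df = _read_table(path)
    missing = [c for c in coord_columns if c not in df.columns]
    if missing:
        raise ValueError(f"missing coordinate columns: {missing}")
    if marker_columns == "rest":
        reserved = set(coord_columns) | {celltype_column, id_column}
        marker_columns = [c for c in df.columns if c not in reserved]
    else:
        marker_columns = list(marker_columns)
        missing = [c for c in marker_columns if c not in df.columns]
        if missing:
            raise ValueError(f"missing marker columns: {missing}")
    if len(set(marker_columns)) != len(marker_columns):
        raise ValueError("duplicate marker names in header")

    def _numeric(block: pd.DataFrame, what: str) -> np.ndarray:
        arr = block.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        if np.isnan(arr).any():
            rows, cols = np.nonzero(np.isnan(arr))
            col = block.columns[cols[0]]
            raise ValueError(
                f"missing value or non-numeric cell in {what} column "
                f"{col!r} (row {rows[0]})"
            )
        return arr

    positions = _numeric(df[list(coord_columns)], "coordinate")
    expression = _numeric(df[marker_columns], "marker")
    celltype = None
    if celltype_column is not None:
        if celltype_column not in df.columns:
            raise ValueError(f"missing cell-type column {celltype_column!r}")
        celltype = df[celltype_column].astype(str).tolist()
    unit_ids = (
        df[id_column].astype(str).tolist()
        if id_column is not None
        else [str(i) for i in range(len(df))]
    )
    return SpatialSample(
        positions=positions,
        expression=expression,
        markers=list(marker_columns),
        unit_ids=unit_ids,
        celltype=celltype,
    )


def write_sample(sample: SpatialSample, path: str | Path) -> None:
    """Write a sample back to delimited text (inverse of :func:`read_sample`)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    coord_names = ["x", "y", "z"][: sample.positions.shape[1]]
    df = pd.DataFrame(sample.positions, columns=coord_names)
    df["unit_id"] = sample.unit_ids
    if sample.celltype is not None:
        df["celltype"] = sample.celltype
    for j, m in enumerate(sample.markers):
        df[m] = sample.expression[:, j]
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def performance_table(results: Sequence["TargetResult"]) -> pd.DataFrame:  # noqa: F821
    """Long-format per-target performance summary.

    One row per target with intra/multiview R2, gain (percentage points),
    and one contribution and p-value column per view.
    """
    view_names: list[str] = []
    for res in results:
        for v in res.view_names:
            if v not in view_names:
                view_names.append(v)
    rows = []
    for res in results:
        row: dict[str, object] = {
            "target": res.target,
            "intra_r2": res.intra_r2,
            "multi_r2": res.multi_r2,
            "gain": res.gain,
        }
        for v in view_names:
            idx = res.view_names.index(v) if v in res.view_names else None
            row[f"contribution_{v}"] = (
                res.contributions[idx] if idx is not None else np.nan
            )
            row[f"pvalue_{v}"] = res.pvalues[idx] if idx is not None else np.nan
        rows.append(row)
    columns = ["target", "intra_r2", "multi_r2", "gain"]
    for v in view_names:
        columns += [f"contribution_{v}", f"pvalue_{v}"]
    return pd.DataFrame(rows, columns=columns)


def importance_tables(
    results: Sequence["TargetResult"],  # noqa: F821
) -> dict[str, pd.DataFrame]:
    """One long-format (predictor, target, importance) table per view."""
    tables: dict[str, list[dict[str, object]]] = {}
    for res in results:
        for v, names, imps in zip(
            res.view_names, res.predictor_names, res.raw_importances
        ):
            rows = tables.setdefault(v, [])
            for name, imp in zip(names, imps):
                rows.append(
                    {"predictor": name, "target": res.target, "importance": imp}
                )
    return {
        v: pd.DataFrame(rows, columns=["predictor", "target", "importance"])
        for v, rows in tables.items()
    }


def write_results(
    results: Sequence["TargetResult"],  # noqa: F821
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> list[Path]:
    """Write performance and per-view importance tables under ``out_dir``.

    Values are printed with 12 significant digits so that a write/read
    round trip is the identity at that precision. Returns written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    perf = performance_table(results)
    perf_path = out_dir / PERFORMANCE_FILE
    perf.to_csv(perf_path, index=False, float_format="%.12g")
    written.append(perf_path)

    for view, table in importance_tables(results).items():
        path = out_dir / IMPORTANCE_FILE_TEMPLATE.format(view=view)
        table.to_csv(path, index=False, float_format="%.12g")
        written.append(path)

    if config is not None:
        echo = {
            "n_trees": config.n_trees,
            "cv_folds": config.cv_folds,
            "seed": config.seed,
            "gain_threshold": config.gain_threshold,
            "importance_cutoff": config.importance_cutoff,
            "bypass_intra": config.bypass_intra,
            "eq3_denominator": config.eq3_denominator,
            "views": [
                {
                    "name": v.name,
                    "family": v.family,
                    "l_grid": list(v.l_grid),
                    "zone": v.zone,
                    "cutoff_rule": v.cutoff_rule,
                    "cutoff_q": v.cutoff_q,
                }
                for v in config.views
            ],
        }
        cfg_path = out_dir / CONFIG_ECHO_FILE
        cfg_path.write_text(yaml.safe_dump(echo, sort_keys=False))
        written.append(cfg_path)
    return written


def read_results(out_dir: str | Path) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Read back a results directory written by :func:`write_results`."""
    out_dir = Path(out_dir)
    perf = pd.read_csv(out_dir / PERFORMANCE_FILE)
    importances = {}
    for path in sorted(out_dir.glob("importances_*.csv")):
        view = path.stem[len("importances_"):]
        importances[view] = pd.read_csv(path)
    return perf, importances
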