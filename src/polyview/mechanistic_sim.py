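"""Mechanistic reaction-diffusion tissue simulator with known ground truth.

A 2D cellular-automata model of 29 molecular species — 5 diffusing
ligands L1-L5, 5 receptors R1-R5 and 19 intracellular proteins X10-X28 —
on a square grid whose sites are empty or occupied by one of four cell
types. Each cell type expresses a distinct receptor subset and carries a
distinct intracellular wiring. Per species s the concentration field
obeys

    dc_s/dt = d_s * Lap(c_s) + P_s - gamma_s * c_s

with zero-flux boundaries, explicit 5-point finite differences and the
stability bound dt <= h^2 / (4 max d_s). Only ligands diffuse. Production
is linear: a ligand is produced at rate alpha * (activity of its producer
node) in cell types that produce it; a receptor is activated at rate
beta * (local ligand concentration) in cell types expressing it; an
intracellular node is activated at rate beta * (upstream activity).
Degradation is proportional to concentration. Root nodes (no upstream
edge anywhere) do not degrade, so their randomized initial per-cell
activity persists and drives spatial heterogeneity — the signal all
downstream inference feeds on.

The wiring defines directed ground-truth matrices over the 24 *measured*
species (ligands are excluded as hard to measure in practice): an
intracellular edge is any direct receptor->protein or protein->protein
link; an intercellular edge links a ligand's producer node to the
receptor that ligand activates. Matrices are compared to inferred
importances on their undirected projection sgn(A + A^T).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .sample_io import RunConfig, SpatialSample
from .modeling import run_multiview, stable_seed
from .views import View, build_intraview, build_paraview
from .explain import ImportanceMatrix, aggregate, sample_importances

LIGANDS = [f"L{i}" for i in range(1, 6)]
RECEPTORS = [f"R{i}" for i in range(1, 6)]
PROTEINS = [f"X{i}" for i in range(10, 29)]
SPECIES = LIGANDS + RECEPTORS + PROTEINS
MEASURED = RECEPTORS + PROTEINS  # 24 species -> 552 ordered candidate pairs

CELL_TYPES = ["CT1", "CT2", "CT3", "CT4"]

#: receptor subsets expressed per cell type (distinct by construction)
RECEPTOR_EXPRESSION: dict[str, tuple[str, ...]] = {
    "CT1": ("R3", "R4", "R5"),
    "CT2": ("R1", "R2", "R4"),
    "CT3": ("R1", "R3", "R5"),
    "CT4": ("R1", "R2", "R5"),
}

#: ligand i is specific: it activates only receptor i
LIGAND_RECEPTOR = dict(zip(LIGANDS, RECEPTORS))


@dataclass
class Wiring:
    """Directed wiring of one cell type."""

    celltype: str
    intra_edges: list[tuple[str, str]]  # among measured species
    produces: dict[str, tuple[str, ...]]  # ligand -> producer node(s)


def default_networks() -> dict[str, Wiring]:
    """The four cell-type wirings.

    Each expressed receptor drives a signaling cascade of depth >= 3
    whose deeper tiers secrete the matching ligand (e.g. X14 produces L1).
    X10-X12 and X28 are reserved as root nodes (never a child in any
    type); every tier also mixes in a basal root input, staggered per cell
    type, so (a) inverting a receptor's activity from its downstream nodes
    alone is an ill-conditioned subtraction, as in real convergent
    signaling, and (b) the ligand fields of different cascades stay
    largely decorrelated. Cascades never feed each other, keeping every
    ligand's production a clean function of its own relay. Every ligand
    has exactly two producer nodes, and the truth sizes fall in the
    intended regime (34-40 ordered intracellular pairs and 10-16 ordered
    intercellular pairs per cell type).
    """
    # each receptor owns one cascade, shared by every cell type expressing
    # it, so a node's biological meaning is consistent across types
    chain = {
        "R1": ("X13", "X14", "X15"),
        "R2": ("X16", "X17", "X18"),
        "R3": ("X19", "X20", "X21"),
        "R4": ("X22", "X23", "X24"),
        "R5": ("X25", "X26", "X27"),
    }
    roots = ("X10", "X11", "X12", "X28")
    wirings = {}
    for t, ct in enumerate(CELL_TYPES):
        edges: list[tuple[str, str]] = []
        produces: dict[str, tuple[str, ...]] = {}
        for i, receptor in enumerate(RECEPTOR_EXPRESSION[ct]):
            a, b, c = chain[receptor]
            r1 = roots[(i + t) % 4]
            r2 = roots[(i + t + 1) % 4]
            edges += [(receptor, a), (r1, a), (a, b), (r2, b), (b, c)]
            if i < 2:  # two cascades get a third basal input at the leaf
                edges.append((roots[(i + t + 2) % 4], c))
            # the cascade's deeper tiers secrete the matching ligand: an
            # autocrine/paracrine relay (e.g. X14 produces L1)
            ligand = LIGANDS[RECEPTORS.index(receptor)]
            produces[ligand] = (b, c)
        wirings[ct] = Wiring(ct, intra_edges=edges, produces=produces)
    return wirings


@dataclass
class GroundTruthNetwork:
    """Directed truth matrices over the 24 measured species for one model."""

    intra: pd.DataFrame
    inter: pd.DataFrame

    def undirected(self, which: str = "intra") -> pd.DataFrame:
        A = (self.intra if which == "intra" else self.inter).to_numpy()
        U = np.sign(A + A.T)
        np.fill_diagonal(U, 0)
        return pd.DataFrame(U, index=MEASURED, columns=MEASURED)


def ground_truth(
    wirings: dict[str, Wiring] | None = None,
    celltypes: list[str] | None = None,
) -> GroundTruthNetwork:
    """Truth matrices for one cell type or the union over several.

    Intracellular truth: direct wiring edges of the given type(s).
    Intercellular truth: producer-node -> receptor links through a shared
    ligand, for receptors expressed in the given type(s); producers are
    pooled over *all* cell types, since any neighboring cell may secrete.
    """
    wirings = wirings or default_networks()
    celltypes = celltypes or CELL_TYPES
    intra = pd.DataFrame(0, index=MEASURED, columns=MEASURED, dtype=int)
    inter = pd.DataFrame(0, index=MEASURED, columns=MEASURED, dtype=int)
    producers: dict[str, set[str]] = {lig: set() for lig in LIGANDS}
    for w in wirings.values():
        for lig, nodes in w.produces.items():
            producers[lig].update(nodes)
    for ct in celltypes:
        w = wirings[ct]
        for src, dst in w.intra_edges:
            intra.loc[src, dst] = 1
        for receptor in RECEPTOR_EXPRESSION[ct]:
            ligand = LIGANDS[RECEPTORS.index(receptor)]
            for node in producers[ligand]:
                inter.loc[node, receptor] = 1
    return GroundTruthNetwork(intra=intra, inter=inter)


@dataclass
class MechanisticParams:
    """Rates, grid and integration settings of the simulator.

    Defaults put the ligand decay length sqrt(d/gamma) near 3 grid units,
    inside the paraview radius of significance of 10 used downstream.
    """

    grid: int = 100
    occupancy: float = 0.5
    d_ligand: float = 1.0
    gamma_ligand: float = 0.1
    gamma_protein: float = 0.5
    #: root nodes decay slowly: their randomized initial activity is the
    #: persistent heterogeneity the whole tissue rides on, and the finite
    #: horizon leaves the system in a transient regime where instantaneous
    #: measurements do not satisfy exact steady-state relations
    gamma_root: float = 0.05
    alpha: float = 0.002  # ligand production scale
    beta_scale: float = 1.0  # interaction strength scale
    mix_boost: float = 4.0  # amplification of root-driven basal inputs
    dt: float = 0.2
    horizon: float = 25.0
    tol: float = 1e-6
    init_high: float = 0.1
    init_mode: str = "random"  # or "constant" (init_high everywhere)
    #: measurement detection floor: concentrations below this read as 0, so
    #: species a cell type's wiring never touches yield exactly-constant
    #: (and downstream-ignorable) measurements instead of round-off noise
    measurement_floor: float = 1e-4
    wirings: dict[str, Wiring] = field(default_factory=default_networks)

    def __post_init__(self) -> None:
        if self.d_ligand > 0 and self.dt > 1.0 / (4.0 * self.d_ligand):
            raise ValueError(
                "dt violates the explicit-diffusion stability bound h^2/(4 d)"
            )
        for rate in (self.gamma_ligand, self.gamma_protein, self.alpha,
                     self.beta_scale):
            if rate < 0:
                raise ValueError("rates must be non-negative")

    def root_nodes(self) -> set[str]:
        children = {dst for w in self.wirings.values() for _, dst in w.intra_edges}
        parents = {src for w in self.wirings.values() for src, _ in w.intra_edges}
        return {p for p in parents if p not in children and p not in RECEPTORS}

    def beta(self, ct: str, src: str, dst: str) -> float:
        """Per-edge interaction strength, deterministic in the edge identity.

        Edges leaving root nodes are boosted by ``mix_boost``: the shared
        basal drive then dominates first-tier cascade nodes, so recovering
        a receptor's activity from its downstream nodes alone is an
        ill-conditioned subtraction of two large correlated signals.
        """
        u = stable_seed("beta", ct, src, dst) / (2**31 - 1)
        b = self.beta_scale * (0.6 + 0.9 * u)
        if src in self.root_nodes():
            b *= self.mix_boost
        return b


@dataclass
class SimulationResult:
    fields: dict[str, np.ndarray]  # species -> (grid, grid) final field
    layout: np.ndarray  # (grid, grid) int: -1 empty, 0..3 cell types
    sample: SpatialSample
    n_steps: int
    converged: bool
    mass_history: dict[str, list[float]] | None = None


def random_layout(grid: int, occupancy: float, seed: int) -> np.ndarray:
    """Random assignment of grid sites to {empty, CT1..CT4}."""
    rng = np.random.default_rng(seed)
    layout = np.full((grid, grid), -1, dtype=int)
    occupied = rng.random((grid, grid)) < occupancy
    layout[occupied] = rng.integers(0, len(CELL_TYPES), size=int(occupied.sum()))
    return layout


def _laplacian(c: np.ndarray) -> np.ndarray:
    """5-point Laplacian with zero-flux (reflecting) boundaries; h = 1."""
    p = np.pad(c, 1, mode="edge")
    return p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * c


def simulate(
    params: MechanisticParams | None = None,
    seed: int = 0,
    layout: np.ndarray | None = None,
    track_mass: bool = False,
) -> SimulationResult:
    """Integrate the model to its horizon (or convergence) and measure cells.

    Integration stops early once the maximum relative field change per
    step falls below ``params.tol``. The measurement table contains the
    24 non-ligand species at every occupied site. NaN or overflow aborts
    with a diagnostic (instability).
    """
    params = params or MechanisticParams()
    g = params.grid
    if layout is None:
        layout = random_layout(g, params.occupancy, stable_seed(seed, "layout"))
    rng = np.random.default_rng(stable_seed(seed, "init"))

    if params.init_mode == "random":
        c = {s: rng.uniform(0.0, params.init_high, size=(g, g)) for s in SPECIES}
    else:
        c = {s: np.full((g, g), params.init_high) for s in SPECIES}

    roots = params.root_nodes()
    gamma = {}
    for s in SPECIES:
        if s in LIGANDS:
            gamma[s] = params.gamma_ligand
        elif s in roots:
            gamma[s] = params.gamma_root
        else:
            gamma[s] = params.gamma_protein

    type_masks = {
        ct: (layout == i).astype(float) for i, ct in enumerate(CELL_TYPES)
    }

    # precompute (species, source species, rate, mask) production terms
    terms: list[tuple[str, str, float, np.ndarray]] = []
    for i, ct in enumerate(CELL_TYPES):
        w = params.wirings[ct]
        mask = type_masks[ct]
        for lig, nodes in w.produces.items():
            for node in nodes:
                terms.append((lig, node, params.alpha, mask))
        for receptor in RECEPTOR_EXPRESSION[ct]:
            ligand = LIGANDS[RECEPTORS.index(receptor)]
            terms.append((receptor, ligand, params.beta(ct, ligand, receptor), mask))
        for src, dst in w.intra_edges:
            terms.append((dst, src, params.beta(ct, src, dst), mask))

    n_steps = max(1, int(round(params.horizon / params.dt)))
    mass_history: dict[str, list[float]] | None = None
    if track_mass:
        mass_history = {s: [float(c[s].sum())] for s in LIGANDS}
    converged = False
    for step in range(n_steps):
        production: dict[str, np.ndarray] = {}
        for dst, src, rate, mask in terms:
            inc = rate * c[src] * mask
            if dst in production:
                production[dst] += inc
            else:
                production[dst] = inc
        max_rel = 0.0
        for s in SPECIES:
            dc = production.get(s, 0.0) - gamma[s] * c[s]
            if s in LIGANDS and params.d_ligand > 0:
                dc = dc + params.d_ligand * _laplacian(c[s])
            dc = params.dt * np.asarray(dc)
            if np.size(dc) > 1 or dc != 0.0:
                scale = np.abs(c[s]).max()
                if scale > 0:
                    max_rel = max(max_rel, float(np.abs(dc).max()) / scale)
                c[s] = c[s] + dc
            if not np.isfinite(c[s]).all():
                raise FloatingPointError(
                    f"instability: non-finite values in species {s} at step {step}"
                )
        if track_mass:
            for s in LIGANDS:
                mass_history[s].append(float(c[s].sum()))
        if max_rel < params.tol:
            converged = True
            break

    ys, xs = np.nonzero(layout >= 0)
    positions = np.column_stack([xs, ys]).astype(float)
    expression = np.column_stack([c[s][ys, xs] for s in MEASURED])
    expression[np.abs(expression) < params.measurement_floor] = 0.0
    celltype = [CELL_TYPES[layout[y, x]] for y, x in zip(ys, xs)]
    sample = SpatialSample(
        positions=positions,
        expression=expression,
        markers=list(MEASURED),
        celltype=celltype,
    )
    return SimulationResult(
        fields=c,
        layout=layout,
        sample=sample,
        n_steps=step + 1,
        converged=converged,
        mass_history=mass_history,
    )


# ---------------------------------------------------------------------------
# benchmarking
# ---------------------------------------------------------------------------


def candidate_pairs(n_species: int = len(MEASURED)) -> int:
    """Ordered off-diagonal pairs among the measured species (24 -> 552)."""
    return n_species * (n_species - 1)


def evaluate(
    importances: ImportanceMatrix,
    truth_undirected: pd.DataFrame,
) -> tuple[float, float]:
    """AUROC and AUPRC of an importance matrix against undirected truth.

    Candidates are all ordered off-diagonal pairs of the shared species
    universe; scores are the (possibly negative) weighted importances with
    absent entries at 0; labels come from the symmetric truth projection.
    AUROC is the tie-aware rank statistic (Mann-Whitney), AUPRC the
    step-wise area under the precision-recall curve.
    """
    species = list(truth_undirected.index)
    M = importances.matrix.reindex(index=species, columns=species)
    scores = np.nan_to_num(M.to_numpy())
    labels = truth_undirected.to_numpy()
    off = ~np.eye(len(species), dtype=bool)
    y_true = labels[off].astype(int)
    y_score = scores[off]
    if y_true.min() == y_true.max():
        raise ValueError("degenerate truth: all labels equal")
    return (
        float(roc_auc_score(y_true, y_score)),
        float(average_precision_score(y_true, y_score)),
    )


def subset_sample(sample: SpatialSample, mask: np.ndarray) -> SpatialSample:
    mask = np.asarray(mask, dtype=bool)
    return SpatialSample(
        positions=sample.positions[mask],
        expression=sample.expression[mask],
        markers=list(sample.markers),
        unit_ids=[u for u, m in zip(sample.unit_ids, mask) if m],
        celltype=(
            [ctype for ctype, m in zip(sample.celltype, mask) if m]
            if sample.celltype
            else None
        ),
    )


def functional_benchmark(
    n_samples: int = 2,
    grid: int = 50,
    para_l: float = 10.0,
    seed: int = 0,
    config: RunConfig | None = None,
    params: MechanisticParams | None = None,
) -> dict:
    """Recover the planted interaction networks from simulated tissues.

    Simulates ``n_samples`` random layouts, runs the intraview+paraview
    pipeline twice — once per cell type (cell-type information available)
    and once on all cells pooled (no cell-type information) — aggregates
    weighted importances across samples and scores each view against the
    matching ground truth. Returns AUROC/AUPRC per (scenario, cell type,
    view) plus per-target gains per cell type for the first sample.
    """
    config = config or RunConfig()
    params = params or MechanisticParams(grid=grid)
    wirings = params.wirings

    per_ct_mats: dict[str, dict[str, list[ImportanceMatrix]]] = {
        ct: {} for ct in CELL_TYPES
    }
    global_mats: dict[str, list[ImportanceMatrix]] = {}
    gains: dict[str, dict[str, float]] = {ct: {} for ct in CELL_TYPES}

    for i in range(n_samples):
        sim = simulate(params, seed=stable_seed(seed, "sim", i))
        sample = sim.sample
        # views are built once over the whole tissue: the paraview
        # aggregates over every cell, whatever its type
        intra_full = build_intraview(sample)
        para_full = build_paraview(sample, family="gaussian", l=para_l, z=0.0)
        for ct in CELL_TYPES:
            mask = np.asarray(sample.celltype) == ct
            sub = subset_sample(sample, mask)
            views = []
            for v in (intra_full, para_full):
                views.append(
                    View(
                        name=v.name,
                        features=v.features[mask],
                        feature_names=list(v.feature_names),
                        base_markers=list(v.base_markers),
                        drop_target=v.drop_target,
                        meta=dict(v.meta),
                    )
                )
            results = run_multiview(
                sub, views, config, sample_id=f"s{i}-{ct}"
            )
            if i == 0:
                gains[ct] = {r.target: r.gain for r in results}
            mats = sample_importances(
                results, predictors=MEASURED, sample_id=f"s{i}",
                denominator=config.eq3_denominator,
            )
            for view, mat in mats.items():
                per_ct_mats[ct].setdefault(view, []).append(mat)
        results = run_multiview(
            sample, [intra_full, para_full], config, sample_id=f"s{i}-all"
        )
        mats = sample_importances(
            results, predictors=MEASURED, sample_id=f"s{i}",
            denominator=config.eq3_denominator,
        )
        for view, mat in mats.items():
            global_mats.setdefault(view, []).append(mat)

    report: dict = {"with_celltypes": {}, "without_celltypes": {}, "gains": gains}
    for ct in CELL_TYPES:
        truth = ground_truth(wirings, [ct])
        report["with_celltypes"][ct] = {}
        for view, mats in per_ct_mats[ct].items():
            agg = aggregate(mats)
            which = "intra" if view == "intra" else "inter"
            auroc, auprc = evaluate(agg, truth.undirected(which))
            report["with_celltypes"][ct][view] = {
                "auroc": auroc, "auprc": auprc,
            }
    truth_all = ground_truth(wirings, CELL_TYPES)
    for view, mats in global_mats.items():
        agg = aggregate(mats)
        which = "intra" if view == "intra" else "inter"
        auroc, auprc = evaluate(agg, truth_all.undirected(which))
        report["without_celltypes"][view] = {"auroc": auroc, "auprc": auprc}
    return report
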