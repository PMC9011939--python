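"""Per-view ensemble models and the late-fusion meta-model.

For each target marker the expression is modeled as

    Y_i = a_I + a_0 F_0(intra) + sum_v a_v F_v(view_v),

a two-step procedure: (1) each view-specific model F_v is a bagged forest
of 100 full, unpruned regression trees (round(sqrt(m)) candidate features
per split) trained independently; (2) the fusion coefficients ``a`` are
estimated by ridge regression of the target on the views' *out-of-bag*
predictions, with the penalty chosen automatically by leave-one-out
generalized cross-validation. Using OOB predictions keeps the meta-model
honest: every unit's view prediction comes from trees that never saw it.

Performance is summarized as cross-validated variance explained (R^2) of
the full meta-model versus the intraview-only meta-model; their difference
in percentage points is the *gain*, the central quantity of the framework.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Ridge, RidgeCV
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .sample_io import RunConfig, SpatialSample
from .views import View

logger = logging.getLogger("polyview")

#: lambda grid for the ridge meta-model: 50 log-spaced points
RIDGE_ALPHAS = np.logspace(-6, 3, 50)


def stable_seed(*parts: int | str) -> int:
    """Deterministic sub-seed (< 2**31) from a master seed and string keys.

    Keyed hashing makes per-(sample, target, view) RNG streams independent
    of scheduling order, so cohort results do not depend on execution order.
    """
    h = 0
    for part in parts:
        h = zlib.crc32(str(part).encode("utf8"), h)
    return h % (2**31 - 1)


# ---------------------------------------------------------------------------
# view-specific forests
# ---------------------------------------------------------------------------


@dataclass
class ViewModel:
    """A bagged forest for one (view, target) pair."""

    view_name: str
    target: str
    n_trees: int
    oob_predictions: np.ndarray
    raw_importances: np.ndarray
    feature_names: list[str]
    oob_r2: float
    degenerate: bool = False


def fit_view_model(
    target: str,
    features: np.ndarray,
    feature_names: list[str],
    y: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
    view_name: str = "",
) -> ViewModel:
    """Train a bagged forest and collect OOB predictions and importances.

    Each of the ``n_trees`` full, unpruned trees is grown on a bootstrap
    bag; ``round(sqrt(m))`` candidate features are examined per split. The
    OOB prediction of a unit is the mean over trees whose bag excluded it
    (with 100 trees a unit is in every bag with probability ~1e-40; if it
    happens the full-ensemble mean is used and a debug line logged).
    Importances are the total impurity (variance) reduction per feature
    summed over all trees.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    L, m = X.shape
    if L < 2 or m < 1:
        raise ValueError("need at least 2 units and 1 feature")
    if np.ptp(y) == 0.0:
        logger.warning("constant target %r: degenerate mean model", target)
        return ViewModel(
            view_name=view_name,
            target=target,
            n_trees=n_trees,
            oob_predictions=np.full(L, y[0], dtype=float),
            raw_importances=np.zeros(m),
            feature_names=list(feature_names),
            oob_r2=0.0,
            degenerate=True,
        )
    max_features = max(1, round(np.sqrt(m)))
    rng = np.random.default_rng(seed)

    oob_sum = np.zeros(L)
    oob_count = np.zeros(L)
    full_sum = np.zeros(L)
    importances = np.zeros(m)
    for _ in range(n_trees):
        bag = rng.integers(0, L, size=L)
        in_bag = np.zeros(L, dtype=bool)
        in_bag[bag] = True
        tree = DecisionTreeRegressor(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[bag], y[bag])
        pred = tree.predict(X)
        full_sum += pred
        oob = ~in_bag
        oob_sum[oob] += pred[oob]
        oob_count[oob] += 1
        importances += tree.tree_.compute_feature_importances(normalize=False)

    oob_pred = np.empty(L)
    covered = oob_count > 0
    oob_pred[covered] = oob_sum[covered] / oob_count[covered]
    if not covered.all():
        logger.debug(
            "%d unit(s) were in every bag; using full-ensemble prediction",
            int((~covered).sum()),
        )
        oob_pred[~covered] = full_sum[~covered] / n_trees

    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - oob_pred) ** 2))
    oob_r2 = 1.0 - sse / sst
    return ViewModel(
        view_name=view_name,
        target=target,
        n_trees=n_trees,
        oob_predictions=oob_pred,
        raw_importances=importances,
        feature_names=list(feature_names),
        oob_r2=oob_r2,
    )


# ---------------------------------------------------------------------------
# meta-model
# ---------------------------------------------------------------------------


def _cv_r2(
    y: np.ndarray, Z: np.ndarray, folds: int, seed: int, alphas: np.ndarray
) -> float:
    """Pooled cross-validated fraction of variance explained of a ridge fit.

    Within each fold, predictors are standardized on the training part and
    the penalty re-selected by GCV; the baseline of the pooled SST is the
    training-fold mean (an intercept-only model). The value may be negative
    on uninformative predictors and is reported unclipped.
    """
    L = len(y)
    folds = min(folds, L)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = 0.0
    sst = 0.0
    for train, test in kf.split(Z):
        mu = Z[train].mean(axis=0)
        sd = Z[train].std(axis=0)
        sd[sd == 0] = 1.0
        Zs_train = (Z[train] - mu) / sd
        Zs_test = (Z[test] - mu) / sd
        model = RidgeCV(alphas=alphas, fit_intercept=True)
        model.fit(Zs_train, y[train])
        pred = model.predict(Zs_test)
        sse += float(np.sum((y[test] - pred) ** 2))
        sst += float(np.sum((y[test] - y[train].mean()) ** 2))
    if sst == 0.0:
        raise ValueError("constant target: SST is zero")
    return 1.0 - sse / sst


def fit_meta_model(
    y: np.ndarray,
    view_oob: np.ndarray,
    view_names: list[str],
    folds: int = 10,
    seed: int = 0,
    intra_view: str | None = "intra",
) -> dict:
    """Late fusion of view OOB predictions by ridge regression.

    Returns a dict with the raw fusion coefficients (``alpha``, plus
    ``intercept``), per-view p-values from a t-test on an unpenalized
    least-squares refit, non-negative ``contributions`` normalized to sum
    to one over the views, and cross-validated ``multi_r2`` / ``intra_r2``
    (the latter from a meta-model restricted to the intraview prediction,
    or 0 when no intraview is present).
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(view_oob, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 1:
        raise ValueError("need at least one view prediction column")
    if Z.shape[1] != len(view_names):
        raise ValueError("view name count mismatch")
    L, V = Z.shape
    if np.ptp(y) == 0.0:
        raise ValueError("constant target: SST is zero")

    # ridge fit on standardized predictions; coefficients mapped back to the
    # raw prediction scale for interpretation
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    Zs = (Z - mu) / safe_sd
    ridge = RidgeCV(alphas=RIDGE_ALPHAS, fit_intercept=True)
    ridge.fit(Zs, y)
    alpha = ridge.coef_ / safe_sd
    alpha[sd == 0] = 0.0
    intercept = float(ridge.intercept_ - np.sum(alpha * mu))

    # per-view significance from an unpenalized OLS refit (ridge coefficients
    # lack a finite-sample t distribution)
    pvalues = _ols_pvalues(y, Z)

    # non-negative normalized contributions over the views
    clamped = np.clip(alpha, 0.0, None)
    total = clamped.sum()
    if total > 0:
        contributions = clamped / total
    else:
        contributions = np.full(V, 1.0 / V)

    multi_r2 = _cv_r2(y, Z, folds, seed, RIDGE_ALPHAS)
    if intra_view is not None and intra_view in view_names:
        intra_col = Z[:, [view_names.index(intra_view)]]
        intra_r2 = _cv_r2(y, intra_col, folds, seed, RIDGE_ALPHAS)
    else:
        intra_r2 = 0.0

    return {
        "alpha": alpha,
        "intercept": intercept,
        "pvalues": pvalues,
        "contributions": contributions,
        "multi_r2": multi_r2,
        "intra_r2": intra_r2,
        "ridge_lambda": float(ridge.alpha_),
    }


def _ols_pvalues(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values of an unpenalized linear refit."""
    L, V = Z.shape
    X = np.column_stack([np.ones(L), Z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = L - X.shape[1]
    if df <= 0:
        return np.ones(V)
    sigma2 = float(resid @ resid) / df
    try:
        cov = sigma2 * np.linalg.pinv(X.T @ X)
    except np.linalg.LinAlgError:
        return np.ones(V)
    se = np.sqrt(np.clip(np.diag(cov)[1:], 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1:] / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(p), p, 1.0)
    return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# per-target pipeline
# ---------------------------------------------------------------------------


@dataclass
class TargetResult:
    """Everything the framework estimates for one target marker."""

    target: str
    view_names: list[str]
    alpha: np.ndarray
    intercept: float
    pvalues: np.ndarray
    contributions: np.ndarray
    intra_r2: float
    multi_r2: float
    gain: float  # percentage points
    raw_importances: list[np.ndarray]
    predictor_names: list[list[str]]
    predictor_bases: list[list[str]] = field(default_factory=list)
    view_oob_r2: dict[str, float] = field(default_factory=dict)
    chosen_l: float | None = None


def _target_vector(
    sample: SpatialSample, views: list[View], target: str
) -> np.ndarray:
    """Resolve a target name to its observation vector.

    Marker targets come from the expression matrix; otherwise the intraview
    is searched for a feature of that name (e.g. one-hot cell-type targets).
    """
    if target in sample.markers:
        return sample.expression[:, sample.marker_index(target)]
    for view in views:
        if view.name == "intra" and target in view.feature_names:
            return view.features[:, view.feature_names.index(target)]
    raise KeyError(f"unknown target {target!r}")


def _predictor_block(
    view: View, target: str
) -> tuple[np.ndarray, list[str], list[str]]:
    """Predictor matrix of a view for one target, plus feature/base names.

    Views with ``drop_target`` exclude the target's own column (Y-tilde);
    neighbor-count views keep every column.
    """
    if view.drop_target:
        keep = [i for i, b in enumerate(view.base_markers) if b != target]
    else:
        keep = list(range(len(view.feature_names)))
    if not keep:
        raise ValueError(f"view {view.name!r} has no predictors for {target!r}")
    names = [view.feature_names[i] for i in keep]
    bases = [view.base_markers[i] or view.feature_names[i] for i in keep]
    return view.features[:, keep], names, bases


def _degenerate_result(
    target: str, views: list[View], config: RunConfig
) -> TargetResult:
    names, importances, predictor_names, predictor_bases = [], [], [], []
    for view in views:
        if config.bypass_intra and view.name == "intra":
            continue
        _, feat_names, bases = _predictor_block(view, target)
        names.append(view.name)
        importances.append(np.zeros(len(feat_names)))
        predictor_names.append(feat_names)
        predictor_bases.append(bases)
    n = len(names)
    return TargetResult(
        target=target,
        view_names=names,
        alpha=np.zeros(n),
        intercept=0.0,
        pvalues=np.ones(n),
        contributions=np.full(n, 1.0 / n) if n else np.empty(0),
        intra_r2=0.0,
        multi_r2=0.0,
        gain=0.0,
        raw_importances=importances,
        predictor_names=predictor_names,
        predictor_bases=predictor_bases,
    )


def run_multiview(
    sample: SpatialSample,
    views: list[View],
    config: RunConfig | None = None,
    targets: list[str] | None = None,
    sample_id: str = "",
) -> list[TargetResult]:
    """Train view models and the meta-model for every target.

    With ``config.bypass_intra`` the intraview model is skipped entirely,
    its prediction excluded from the meta-model, and ``intra_r2`` set to 0
    so the baseline is an intercept-only model. Seeds for each (target,
    view) forest are derived from ``config.seed`` and the names involved,
    so results are reproducible and order-independent.
    """
    config = config or RunConfig()
    if targets is None:
        targets = list(sample.markers)
    view_names_all = [v.name for v in views]
    if len(set(view_names_all)) != len(view_names_all):
        raise ValueError("duplicate view names")
    if not config.bypass_intra and len(views) < 2 and "intra" in view_names_all:
        logger.warning("only the intraview is present: gain will be 0")

    results: list[TargetResult] = []
    for target in targets:
        y = _target_vector(sample, views, target)
        if np.ptp(y) == 0.0:
            # constant target (e.g. below the detection floor everywhere):
            # nothing to model; emit an all-zero degenerate result
            logger.warning("constant target %r: degenerate result", target)
            results.append(_degenerate_result(target, views, config))
            continue
        used_views: list[View] = []
        models: list[ViewModel] = []
        bases_per_view: list[list[str]] = []
        for view in views:
            if config.bypass_intra and view.name == "intra":
                continue
            X, names, bases = _predictor_block(view, target)
            bases_per_view.append(bases)
            model = fit_view_model(
                target,
                X,
                names,
                y,
                n_trees=config.n_trees,
                seed=stable_seed(config.seed, sample_id, target, view.name),
                view_name=view.name,
            )
            used_views.append(view)
            models.append(model)
        if not models:
            raise ValueError("no views left to model (bypass_intra with intra only)")
        Z = np.column_stack([m.oob_predictions for m in models])
        names = [v.name for v in used_views]
        meta = fit_meta_model(
            y,
            Z,
            names,
            folds=config.cv_folds,
            seed=stable_seed(config.seed, sample_id, target, "meta"),
            intra_view=None if config.bypass_intra else "intra",
        )
        gain = 100.0 * (meta["multi_r2"] - meta["intra_r2"])
        results.append(
            TargetResult(
                target=target,
                view_names=names,
                alpha=meta["alpha"],
                intercept=meta["intercept"],
                pvalues=meta["pvalues"],
                contributions=meta["contributions"],
                intra_r2=meta["intra_r2"],
                multi_r2=meta["multi_r2"],
                gain=gain,
                raw_importances=[m.raw_importances for m in models],
                predictor_names=[m.feature_names for m in models],
                predictor_bases=bases_per_view,
                view_oob_r2={m.view_name: m.oob_r2 for m in models},
            )
        )
    return results


def optimize_l(
    sample: SpatialSample,
    marker: str,
    l_grid: list[float],
    family: str = "gaussian",
    z: float = 0.0,
    config: RunConfig | None = None,
    extra_views: list[View] | None = None,
    sample_id: str = "",
) -> tuple[float, dict[float, float]]:
    """Choose the paraview scale ``l`` maximizing the gain for one marker.

    For every candidate ``l`` the pipeline (intraview + optional extra
    views + paraview at ``l``) is run for the marker and the gain in
    variance explained recorded; the argmax is returned, ties broken
    toward smaller ``l`` to prefer local explanations.
    """
    from .views import build_intraview, build_paraview

    if not l_grid:
        raise ValueError("empty l grid")
    config = config or RunConfig()
    gains: dict[float, float] = {}
    for l in sorted(l_grid):
        views = [build_intraview(sample)]
        views += list(extra_views or [])
        views.append(build_paraview(sample, family=family, l=l, z=z))
        res = run_multiview(
            sample, views, config, targets=[marker], sample_id=sample_id
        )[0]
        gains[l] = res.gain
    chosen = max(sorted(gains), key=lambda l: (gains[l], -l))
    return chosen, gains


def permute_coordinates(
    sample: SpatialSample, n_perm: int = 10, seed: int = 0
) -> list[SpatialSample]:
    """Replicates with row-permuted positions and untouched expression.

    Per-marker expression marginals are exactly preserved; only the link
    between a unit's expression and its location is destroyed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_perm):
        perm = rng.permutation(sample.n_units)
        out.append(
            SpatialSample(
                positions=sample.positions[perm],
                expression=sample.expression.copy(),
                markers=list(sample.markers),
                unit_ids=list(sample.unit_ids),
                celltype=list(sample.celltype) if sample.celltype else None,
            )
        )
    return out
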