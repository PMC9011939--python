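import numpy as np
import pytest
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from polyview import (
    RunConfig,
    SpatialSample,
    build_intraview,
    build_paraview,
    fit_meta_model,
    fit_view_model,
    optimize_l,
    permute_coordinates,
    run_multiview,
    stable_seed,
)

from conftest import make_sample


# --- view-specific forests -------------------------------------------------


def test_constant_target_yields_degenerate_mean_model(rng):
    X = rng.normal(size=(30, 4))
    model = fit_view_model("t", X, list("abcd"), np.zeros(30), n_trees=20, seed=0)
    assert model.degenerate
    np.testing.assert_array_equal(model.oob_predictions, 0.0)
    np.testing.assert_array_equal(model.raw_importances, 0.0)


def test_feature_equal_to_target_dominates_importances(rng):
    # 200-unit sample where y is exactly one feature: that feature must
    # collect the maximum importance in a 100-tree forest
    X = rng.normal(size=(200, 5))
    y = X[:, 2].copy()
    model = fit_view_model("t", X, list("abcde"), y, n_trees=100, seed=1)
    assert np.argmax(model.raw_importances) == 2
    assert model.oob_r2 > 0.8


def test_oob_r2_agrees_with_cross_validated_forest(rng):
    # independent estimator: sklearn's RandomForestRegressor under 10-fold
    # CV should agree with our bagged-forest OOB estimate on a smooth target
    X = rng.uniform(-2, 2, size=(500, 3))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + 0.1 * rng.normal(size=500)
    model = fit_view_model("t", X, list("abc"), y, n_trees=100, seed=2)

    sse = sst = 0.0
    for train, test in KFold(10, shuffle=True, random_state=0).split(X):
        rf = RandomForestRegressor(
            n_estimators=100, max_features=2, random_state=0
        ).fit(X[train], y[train])
        pred = rf.predict(X[test])
        sse += np.sum((y[test] - pred) ** 2)
        sst += np.sum((y[test] - y[train].mean()) ** 2)
    cv_r2 = 1 - sse / sst
    assert abs(model.oob_r2 - cv_r2) < 0.1


def test_forest_importances_nonnegative_and_reproducible(rng):
    X = rng.normal(size=(60, 4))
    y = X @ np.array([1.0, -2.0, 0.0, 0.5]) + 0.1 * rng.normal(size=60)
    m1 = fit_view_model("t", X, list("abcd"), y, n_trees=50, seed=7)
    m2 = fit_view_model("t", X, list("abcd"), y, n_trees=50, seed=7)
    assert (m1.raw_importances >= 0).all()
    np.testing.assert_array_equal(m1.oob_predictions, m2.oob_predictions)
    np.testing.assert_array_equal(m1.raw_importances, m2.raw_importances)


# --- meta-model ------------------------------------------------------------


def test_perfect_view_takes_full_contribution(rng):
    y = rng.normal(size=100)
    noise = rng.normal(size=100)
    meta = fit_meta_model(
        y, np.column_stack([y, noise]), ["intra", "para"], folds=10, seed=0
    )
    assert meta["contributions"][0] > 0.99
    assert meta["multi_r2"] > 0.99
    assert meta["intra_r2"] > 0.99


def test_identical_views_split_contribution(rng):
    y = rng.normal(size=80)
    pred = y + 0.2 * rng.normal(size=80)
    meta = fit_meta_model(
        y, np.column_stack([pred, pred]), ["juxta", "para"],
        folds=10, seed=0, intra_view=None,
    )
    np.testing.assert_allclose(meta["contributions"], [0.5, 0.5], atol=0.02)


def test_noise_views_do_not_beat_intraview(rng):
    y = rng.normal(size=150)
    intra_pred = y + 0.5 * rng.normal(size=150)
    noise_pred = rng.normal(size=150)
    meta = fit_meta_model(
        y, np.column_stack([intra_pred, noise_pred]), ["intra", "juxta"],
        folds=10, seed=1,
    )
    assert meta["multi_r2"] <= meta["intra_r2"] + 0.05
    assert meta["pvalues"][1] > 0.05  # noise view not significant


def test_constant_target_raises(rng):
    with pytest.raises(ValueError, match="constant target"):
        fit_meta_model(np.ones(20), rng.normal(size=(20, 2)), ["a", "b"])


def test_contributions_nonnegative_and_normalized(rng):
    y = rng.normal(size=60)
    Z = rng.normal(size=(60, 3))
    meta = fit_meta_model(y, Z, ["intra", "juxta", "para"], folds=5, seed=3)
    assert (meta["contributions"] >= 0).all()
    assert meta["contributions"].sum() == pytest.approx(1.0)
    assert ((meta["pvalues"] >= 0) & (meta["pvalues"] <= 1)).all()


# --- full pipeline ---------------------------------------------------------


def _tiny_run(seed=0, **config_kwargs):
    sample = make_sample(n_units=60, n_markers=3, seed=4)
    views = [
        build_intraview(sample),
        build_paraview(sample, family="gaussian", l=3.0),
    ]
    config = RunConfig(n_trees=20, cv_folds=5, seed=seed, **config_kwargs)
    return run_multiview(sample, views, config)


def test_run_multiview_contributions_sum_to_one():
    for res in _tiny_run():
        assert res.contributions.sum() == pytest.approx(1.0)
        assert res.gain == pytest.approx(
            100 * (res.multi_r2 - res.intra_r2)
        )


def test_run_multiview_is_reproducible():
    r1, r2 = _tiny_run(seed=9), _tiny_run(seed=9)
    for a, b in zip(r1, r2):
        assert a.multi_r2 == b.multi_r2
        for ia, ib in zip(a.raw_importances, b.raw_importances):
            np.testing.assert_array_equal(ia, ib)


def test_bypass_intra_uses_intercept_baseline():
    results = _tiny_run(bypass_intra=True)
    for res in results:
        assert "intra" not in res.view_names
        assert res.intra_r2 == 0.0


def test_intraview_drops_target_column():
    sample = make_sample(n_units=40, n_markers=3, seed=2)
    views = [build_intraview(sample)]
    res = run_multiview(
        sample, views, RunConfig(n_trees=10, cv_folds=5), targets=["m1"]
    )[0]
    assert res.predictor_names[0] == ["m0", "m2"]  # k-1 predictors


def test_contributions_invariant_to_view_feature_rescaling():
    # tree ensembles are scale invariant and the meta-model refit absorbs
    # scale, so rescaling one view's features changes nothing
    sample = make_sample(n_units=60, n_markers=3, seed=4)
    para = build_paraview(sample, family="gaussian", l=3.0)
    res1 = run_multiview(
        sample, [build_intraview(sample), para], RunConfig(n_trees=20, cv_folds=5)
    )
    para.features = para.features * 37.0
    res2 = run_multiview(
        sample, [build_intraview(sample), para], RunConfig(n_trees=20, cv_folds=5)
    )
    for a, b in zip(res1, res2):
        np.testing.assert_allclose(a.contributions, b.contributions, atol=1e-8)
        np.testing.assert_allclose(a.multi_r2, b.multi_r2, atol=1e-8)


# --- paraview scale optimization -------------------------------------------


def test_optimize_l_single_grid_point():
    sample = make_sample(n_units=50, n_markers=3, seed=6)
    chosen, gains = optimize_l(
        sample, "m0", [7.0], config=RunConfig(n_trees=10, cv_folds=5)
    )
    assert chosen == 7.0 and set(gains) == {7.0}


def test_optimize_l_rejects_empty_grid(small_sample):
    with pytest.raises(ValueError, match="empty"):
        optimize_l(small_sample, "m0", [])


def _planted_radius_sample(seed, l_true=50.0, n=220):
    """Marker m1 equals the paraview of marker m0 at scale l_true + noise."""
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0, 400, size=(n, 2))
    m0 = rng.normal(size=n)
    base = SpatialSample(positions, np.column_stack([m0, m0]), ["m0", "m1"])
    para = build_paraview(base, family="gaussian", l=l_true)
    m1 = para.features[:, 0]
    m1 = (m1 - m1.mean()) / m1.std() + 0.2 * rng.normal(size=n)
    return SpatialSample(
        positions, np.column_stack([m0, m1]), ["m0", "m1"]
    )


def test_optimize_l_recovers_planted_interaction_radius():
    grid = [25.0, 50.0, 100.0, 200.0, 400.0]
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        sample = _planted_radius_sample(seed=100 + rep)
        chosen, _ = optimize_l(
            sample, "m1", grid,
            config=RunConfig(n_trees=30, cv_folds=5, seed=rep),
        )
        hits += chosen in (25.0, 50.0, 100.0)
    assert hits >= 0.8 * n_rep


def test_optimize_l_gain_consistent_with_fresh_run():
    sample = _planted_radius_sample(seed=5)
    config = RunConfig(n_trees=30, cv_folds=5, seed=3)
    chosen, gains = optimize_l(sample, "m1", [25.0, 50.0], config=config)
    views = [
        build_intraview(sample),
        build_paraview(sample, family="gaussian", l=chosen),
    ]
    fresh = run_multiview(sample, views, config, targets=["m1"])[0]
    assert fresh.gain == pytest.approx(gains[chosen], abs=1e-9)


# --- coordinate permutation ------------------------------------------------


def test_permute_preserves_expression_and_marginals():
    sample = make_sample(n_units=30, n_markers=3, seed=8)
    perms = permute_coordinates(sample, n_perm=5, seed=1)
    assert len(perms) == 5
    for p in perms:
        np.testing.assert_array_equal(p.expression, sample.expression)
        assert sorted(map(tuple, p.positions)) == sorted(
            map(tuple, sample.positions)
        )


def test_permute_single_unit_is_identity():
    s = SpatialSample([[0.0, 0.0]], [[1.0, 2.0]], ["a", "b"])
    (p,) = permute_coordinates(s, 1, seed=0)
    np.testing.assert_array_equal(p.positions, s.positions)


def test_stable_seed_is_order_keyed_and_bounded():
    assert stable_seed(1, "a", "b") != stable_seed(1, "b", "a")
    assert stable_seed(42, "s") == stable_seed(42, "s")
    assert 0 <= stable_seed(2**62, "x") < 2**31
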