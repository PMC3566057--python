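"""Presence-background model: geometry, fitting, evaluation, binary maps."""

import warnings

import numpy as np
import pytest
from scipy.stats import chisquare

import phyloniche as pn
from phyloniche.enm import (
    BackgroundSample,
    MaxEnt,
    binarize_mtp,
    build_background,
    build_features,
    crossvalidate,
    evaluate_auc,
    fit_maxent,
    minimum_convex_polygon,
    select_top_variables,
    split_train_test,
    stack_richness,
    variable_contribution,
    EvaluationReport,
    BinarySurface,
)
from phyloniche.occurrences import OccurrenceSet
from phyloniche.rasters import GridSpec, Raster, RasterStack
from phyloniche.simulate import (
    NicheSpec,
    sample_occurrences,
    suitability_from_niche,
)
from phyloniche.surfaces import SuitabilitySurface

from conftest import make_climate_stack


# -- minimum convex polygon -------------------------------------------------

def test_unit_square_hull_area_one():
    hull = minimum_convex_polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
    assert hull.area == pytest.approx(1.0)  # shoelace by hand: 1


def test_interior_points_do_not_change_hull():
    tri = minimum_convex_polygon([(0, 0), (4, 0), (0, 4)])
    tri2 = minimum_convex_polygon([(0, 0), (4, 0), (0, 4), (1, 1)])
    assert tri.equals(tri2)


def test_collinear_points_rejected():
    with pytest.raises(ValueError, match="collinear"):
        minimum_convex_polygon([(0, 0), (1, 1), (2, 2)])
    with pytest.raises(ValueError, match="at least 3"):
        minimum_convex_polygon([(0, 0), (1, 1)])


# -- background sampling ----------------------------------------------------

def test_single_cell_polygon_yields_that_cell(flat_stack):
    poly = minimum_convex_polygon([(0.2, 0.2), (0.8, 0.2), (0.5, 0.8)])
    bg = build_background(poly, flat_stack, 1, seed=0)
    assert bg.cells.tolist() == [[4, 0]]


def test_background_uniform_over_eligible_cells(flat_stack):
    poly = minimum_convex_polygon([(0, 0), (4, 0), (4, 5), (0, 5)])
    counts = np.zeros(20)
    rng = np.random.default_rng(0)
    for _ in range(3000):
        bg = build_background(poly, flat_stack, 1, rng)
        r, c = bg.cells[0]
        counts[r * 4 + c] += 1
    _, p = chisquare(counts)
    assert p > 0.01


def test_background_seed_reproducible_and_capped(flat_stack, caplog):
    poly = minimum_convex_polygon([(0, 0), (4, 0), (4, 5), (0, 5)])
    a = build_background(poly, flat_stack, 10, seed=7)
    b = build_background(poly, flat_stack, 10, seed=7)
    np.testing.assert_array_equal(a.cells, b.cells)
    with caplog.at_level("WARNING"):
        full = build_background(poly, flat_stack, 10_000, seed=7)
    assert len(full) == 20
    assert "using all" in caplog.text


# -- train/test split -------------------------------------------------------

@pytest.mark.parametrize("n, frac, expected", [(10, 0.8, (8, 2)), (2, 0.8, (1, 1))])
def test_split_sizes(n, frac, expected):
    occ = OccurrenceSet("sp", [(i + 0.5, 0.5) for i in range(n)])
    train, test = split_train_test(occ, frac, seed=0)
    assert (len(train), len(test)) == expected
    assert set(train.points) | set(test.points) == set(occ.points)
    assert not set(train.points) & set(test.points)


def test_split_rejects_tiny_or_bad_fraction():
    occ = OccurrenceSet("sp", [(0.5, 0.5)])
    with pytest.raises(ValueError):
        split_train_test(occ, 0.8)
    with pytest.raises(ValueError):
        split_train_test(OccurrenceSet("sp", [(0.5, 0.5), (1.5, 0.5)]), 1.2)


# -- fitting ----------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_niche():
    """One informative and one pure-noise variable, presences from a known
    Gaussian response to the first."""
    stack = make_climate_stack(n_rows=60, n_cols=60, n_layers=2, seed=8)
    mu, tau = 60.0, 12.75
    truth = suitability_from_niche(
        NicheSpec("sp", ("bio01",), [mu], [tau]), stack
    )
    occ = sample_occurrences(truth, 250, seed=1)
    poly = minimum_convex_polygon(occ.points)
    bg = build_background(poly, stack, 2500, seed=2)
    feats = build_features(stack, bg)
    res = MaxEnt(occ, bg, feats).fit(beta=0.1)
    return stack, mu, tau, occ, bg, feats, res


def test_no_signal_fit_stays_near_uniform(flat_stack):
    """Presences drawn uniformly from background leave all weights tiny and
    the predicted surface near-uniform."""
    stack = make_climate_stack(n_rows=20, n_cols=20, n_layers=1, seed=4)
    poly = minimum_convex_polygon([(0.0, 0.0), (0.99, 0.0), (0.99, 0.99), (0.0, 0.99)])
    bg = build_background(poly, stack, 400, seed=0)
    rng = np.random.default_rng(3)
    pres_cells = bg.cells[rng.choice(len(bg), 200, replace=False)]
    feats = build_features(stack, bg)
    res = fit_maxent(pres_cells, bg, feats)
    assert np.all(np.abs(res.params) <= 0.05)
    surf = res.predict_raw()
    n_cells = feats.valid_mask.sum()
    assert np.max(np.abs(surf.weights[feats.valid_mask] - 1 / n_cells)) < 2 / n_cells


def test_top_decile_presences_give_positive_linear_weight():
    stack = make_climate_stack(n_rows=30, n_cols=30, n_layers=1, seed=6)
    vals = stack["bio01"].values
    thresh = np.quantile(vals, 0.9)
    cells = np.argwhere(vals >= thresh)[:30]
    poly = minimum_convex_polygon([(0, 0), (1.49, 0), (1.49, 1.49), (0, 1.49)])
    bg = build_background(poly, stack, 800, seed=0)
    feats = build_features(stack, bg)
    res = fit_maxent(cells, bg, feats)
    assert res.params[0] > 0


def test_objective_is_non_decreasing(fitted_niche):
    *_, res = fitted_niche
    diffs = np.diff(res.objective_path)
    assert (diffs >= -1e-12).all()


def test_quadratic_optimum_recovers_niche_mean(fitted_niche):
    _, mu, tau, occ, bg, feats, _ = fitted_niche
    res = MaxEnt(occ, bg, feats).fit(beta=0.1, relax=True)
    assert abs(res.quadratic_optimum("bio01") - mu) < 0.5 * tau


def test_summary_mentions_species_and_features(fitted_niche):
    *_, res = fitted_niche
    text = res.summary()
    assert "bio01" in text and "bio02^2" in text and "presences" in text


def test_degenerate_feature_dropped_with_warning(flat_stack):
    spec = flat_stack.spec
    vals = np.arange(20, dtype=float).reshape(5, 4)
    stack = RasterStack(
        [Raster(spec, vals, "grad"), Raster(spec, np.full((5, 4), 7.0), "const")]
    )
    poly = minimum_convex_polygon([(0, 0), (3.9, 0), (3.9, 4.9), (0, 4.9)])
    bg = build_background(poly, stack, 20, seed=0)
    feats = build_features(stack, bg)
    assert feats.degenerate[2] and feats.degenerate[3]
    with pytest.warns(UserWarning, match="zero-variance"):
        res = fit_maxent(np.array([[0, 0], [1, 1]]), bg, feats)
    assert res.params[2] == res.params[3] == 0.0


# -- prediction -------------------------------------------------------------

def test_zero_weights_predict_uniform(flat_stack):
    bg = BackgroundSample(np.argwhere(flat_stack.valid_mask))
    feats = build_features(flat_stack, bg)
    surf = pn.enm.predict_raw_from_params(np.zeros(2), feats)
    np.testing.assert_allclose(surf.weights, 1 / 20)
    assert surf.weights.sum() == pytest.approx(1.0)


def test_prediction_ranking_matches_scores(fitted_niche, rng):
    *_, feats, res = fitted_niche
    surf = res.predict_raw()
    scores = feats.matrix @ res.params
    flat = surf.weights.ravel()[np.flatnonzero(feats.valid_mask.ravel())]
    pick = rng.choice(len(scores), 20, replace=False)
    order_a = np.argsort(scores[pick])
    order_b = np.argsort(flat[pick])
    np.testing.assert_array_equal(order_a, order_b)


# -- AUC --------------------------------------------------------------------

def _surface_from_weights(w):
    w = np.asarray(w, dtype=float)
    return SuitabilitySurface(
        GridSpec(w.shape[0], w.shape[1], 1.0, 0.0, 0.0),
        w / w.sum(),
        np.ones_like(w, dtype=bool),
    )


def test_auc_is_one_when_presences_dominate():
    surf = _surface_from_weights([[1, 2, 3, 10, 20]])
    bg = BackgroundSample([[0, 0], [0, 1], [0, 2]])
    assert evaluate_auc(surf, np.array([[0, 3], [0, 4]]), bg) == 1.0


def test_auc_is_half_under_ties():
    surf = _surface_from_weights([[1, 1, 1, 1]])
    bg = BackgroundSample([[0, 0], [0, 1]])
    assert evaluate_auc(surf, np.array([[0, 2], [0, 3]]), bg) == 0.5


def test_auc_near_half_for_background_subsamples():
    stack = make_climate_stack(n_rows=20, n_cols=20, seed=9)
    rng = np.random.default_rng(0)
    surf = suitability_from_niche(
        NicheSpec("sp", ("bio01",), [50.0], [20.0]), stack
    )
    bg = BackgroundSample(np.argwhere(stack.valid_mask))
    aucs = []
    for _ in range(200):
        pres = bg.cells[rng.choice(len(bg), 10, replace=False)]
        aucs.append(evaluate_auc(surf, pres, bg))
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


# -- cross-validation -------------------------------------------------------

def test_loo_crossvalidation_runs_n_folds():
    stack = make_climate_stack(n_rows=30, n_cols=30, seed=10)
    truth = suitability_from_niche(
        NicheSpec("sp", ("bio01",), [55.0], [20.0]), stack
    )
    occ = sample_occurrences(truth, 10, seed=0)
    poly = minimum_convex_polygon([(0, 0), (1.49, 0), (1.49, 1.49), (0, 1.49)])
    bg = build_background(poly, stack, 500, seed=0)
    feats = build_features(stack, bg)
    surf, report = crossvalidate(occ, bg, feats, seed=3)
    assert report.replicates == 10  # leave-one-out for n <= 12
    assert surf.weights.sum() == pytest.approx(1.0)
    surf2, report2 = crossvalidate(occ, bg, feats, seed=3)
    np.testing.assert_array_equal(surf.weights, surf2.weights)
    assert report.auc == report2.auc
    with pytest.raises(ValueError):
        crossvalidate(occ, bg, feats, k=11)


# -- variable contributions -------------------------------------------------

def test_contributions_sum_100_and_zero_for_absent_variable(fitted_niche):
    _, mu, tau, occ, bg, feats, res = fitted_niche
    contrib = variable_contribution(res, occ, n_permutations=5, seed=0)
    assert sum(contrib.values()) == pytest.approx(100.0)
    lam = res.params.copy()
    lam[2:] = 0.0  # remove bio02 from the model entirely
    res2 = pn.MaxEntResults(
        model=res.model, params=lam, beta=res.beta, converged=True,
        n_iter=res.n_iter, objective_path=res.objective_path,
    )
    contrib2 = variable_contribution(res2, occ, n_permutations=5, seed=0)
    assert contrib2["bio02"] == 0.0
    assert contrib2["bio01"] == pytest.approx(100.0)


def test_informative_variable_dominates_contributions(fitted_niche):
    _, mu, tau, occ, bg, feats, res = fitted_niche
    contrib = variable_contribution(res, occ, n_permutations=20, seed=1)
    assert contrib["bio01"] > 90.0


def test_select_top_variables_ranking_and_ties():
    def rep(sp, contribs):
        return EvaluationReport(
            species=sp, n_points=10, n_train=8, n_test=2, auc=0.9,
            contributions=contribs,
        )

    reports = [
        rep("a", {"x": 50.0, "y": 30.0, "z": 20.0}),
        rep("b", {"x": 10.0, "y": 70.0, "z": 20.0}),
        rep("c", {"x": 30.0, "y": 20.0, "z": 50.0}),
    ]
    # column means: x=30, y=40, z=30 -> y first, then x before z alphabetically
    assert select_top_variables(reports, 3) == ["y", "x", "z"]
    equal = [rep("a", {"b": 25.0, "a": 25.0, "d": 25.0, "c": 25.0})]
    assert select_top_variables(equal, 2) == ["a", "b"]
    with pytest.raises(ValueError):
        select_top_variables(reports, 4)


# -- binary maps ------------------------------------------------------------

def test_mtp_threshold_is_min_over_presences():
    surf = _surface_from_weights([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    cells = np.array([[1, 1], [2, 2]])  # weights 5/45 and 9/45
    b = binarize_mtp(surf, cells)
    assert b.threshold == pytest.approx(5 / 45)
    expected = np.array(
        [[False, False, False], [False, True, True], [True, True, True]]
    )
    np.testing.assert_array_equal(b.mask, expected)


def test_presences_at_max_cell_select_argmax_only():
    surf = _surface_from_weights([[1, 1, 5]])
    b = binarize_mtp(surf, np.array([[0, 2]]))
    np.testing.assert_array_equal(b.mask, [[False, False, True]])


def test_richness_counts_species_per_cell(rng):
    spec = GridSpec(4, 4, 1.0, 0.0, 0.0)
    masks = [rng.random((4, 4)) > 0.5 for _ in range(5)]
    binaries = [BinarySurface(spec, m, 0.1) for m in masks]
    richness = stack_richness(binaries)
    np.testing.assert_array_equal(richness.values, np.sum(masks, axis=0))
    same = [BinarySurface(spec, masks[0], 0.1)] * 2
    assert set(np.unique(stack_richness(same).values)) <= {0.0, 2.0}
    disjoint = [
        BinarySurface(spec, np.eye(4, dtype=bool), 0.1),
        BinarySurface(spec, ~np.eye(4, dtype=bool), 0.1),
    ]
    assert stack_richness(disjoint).values.max() == 1
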