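"""Split/fit/predict/evaluate contracts of the SVR intensity model."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.svm import SVR

import odormix as om
from odormix.intensity_model import _fold_indices


def _dataset(seed=1, **overrides):
    return om.generate_panel_dataset(
        om.GeneratorConfig.for_pair("EA", "BA", seed=seed, **overrides)
    )


# ---------------------------------------------------------------- splitting

@pytest.mark.parametrize("n, expected", [(30, (21, 9)), (31, (22, 9))])
def test_split_sizes(n, expected):
    ds = _dataset(n_samples=n)
    train, test = om.split_dataset(ds, 0.7, seed=0)
    assert (len(train), len(test)) == expected


def test_split_is_deterministic_and_disjoint():
    ds = _dataset()
    t1, s1 = om.split_dataset(ds, 0.7, seed=5)
    t2, s2 = om.split_dataset(ds, 0.7, seed=5)
    assert t1.to_dataframe().equals(t2.to_dataframe())
    assert s1.to_dataframe().equals(s2.to_dataframe())
    seen = [(a.conc_a, a.conc_b, a.oi) for a in t1.samples + s1.samples]
    assert len(seen) == len(ds) == len(set(seen))
    with pytest.raises(om.ConfigurationError):
        om.split_dataset(ds, 1.0, seed=0)


def test_fold_assignment_sizes():
    folds = _fold_indices(21, 10, seed=3)
    sizes = sorted(len(f) for f in folds)
    assert len(folds) == 10
    assert max(sizes) - min(sizes) <= 1
    assert sorted(np.concatenate(folds)) == list(range(21))


# ------------------------------------------------------------------ metrics

def test_metric_reference_points():
    assert om.r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    obs = np.array([1.0, 2.0, 3.0])
    assert om.r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)
    assert om.r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)
    assert om.mae([1, 2], [1, 2]) == 0.0
    assert om.mae([1, 2], [2, 2]) == pytest.approx(0.5)
    assert om.mae([1, 5], [2, 2]) == om.mae([2, 2], [1, 5])


def test_metrics_match_sklearn_on_random_vectors():
    rng = np.random.default_rng(12)
    for _ in range(25):
        n = int(rng.integers(2, 40))
        obs = rng.normal(size=n)
        pred = obs + rng.normal(scale=0.5, size=n)
        assert om.r_squared(obs, pred) == pytest.approx(r2_score(obs, pred), abs=1e-10)
        assert om.mae(obs, pred) == pytest.approx(
            mean_absolute_error(obs, pred), abs=1e-10
        )


def test_metric_error_conditions():
    with pytest.raises(om.SizeError):
        om.mae([], [])
    with pytest.raises(om.SizeError):
        om.r_squared([1.0], [1.0])
    with pytest.raises(om.DataError):
        om.r_squared([2.0, 2.0], [1.0, 3.0])
    with pytest.raises(om.SizeError):
        om.mae([1.0, 2.0], [1.0])


# -------------------------------------------------------------- grid search

def test_single_cell_grid_is_selected():
    ds = _dataset()
    train, _ = om.split_dataset(ds, 0.7, seed=0)
    grid = om.HyperparameterGrid(c_values=(10.0,), gamma_values=(0.1,))
    model = om.fit_intensity_model(train, grid, cv_folds=5, seed=0)
    assert (model.selected_c, model.selected_gamma) == (10.0, 0.1)
    assert len(model.cv_table) == 1


def test_grid_selection_matches_naive_reimplementation():
    """Independent oracle: a plain double loop over the grid with the same
    seeded folds must pick the same (C, gamma)."""
    ds = _dataset(seed=21)
    train, _ = om.split_dataset(ds, 0.7, seed=2)
    c_values = (0.5, 8.0, 128.0)
    gamma_values = (0.01, 0.1, 1.0)
    grid = om.HyperparameterGrid(c_values=c_values, gamma_values=gamma_values)
    model = om.fit_intensity_model(train, grid, cv_folds=10, seed=13)

    x = np.log(np.column_stack([train.conc_a, train.conc_b]))
    xs = (x - x.mean(axis=0)) / x.std(axis=0)
    y = train.oi
    folds = _fold_indices(len(train), 10, seed=13)
    results = {}
    for c, g in itertools.product(c_values, gamma_values):
        errs = []
        for val in folds:
            fit = np.array([i for i in range(len(train)) if i not in set(val)])
            reg = SVR(kernel="rbf", C=c, gamma=g, epsilon=grid.epsilon)
            reg.fit(xs[fit], y[fit])
            errs.append(np.mean(np.abs(y[val] - reg.predict(xs[val]))))
        results[(c, g)] = np.mean(errs)
    naive_choice = min(sorted(results), key=lambda k: results[k])
    assert (model.selected_c, model.selected_gamma) == naive_choice
    # the retained cv table agrees with the oracle's error estimates
    for (c, g), err in results.items():
        row = model.cv_table[(model.cv_table.C == c) & (model.cv_table.gamma == g)]
        assert float(row.cv_mae.iloc[0]) == pytest.approx(err, abs=1e-10)


def test_noiseless_additive_target_is_learnable():
    ds = _dataset(seed=5, rho_max=0.0, noise_sigma=0.0, n_samples=60)
    train, _ = om.split_dataset(ds, 0.7, seed=6)
    model = om.fit_intensity_model(train, cv_folds=10, seed=7)
    report = om.evaluate_model(model, train, train)
    # residuals concentrate inside the epsilon tube; a small tail escapes it
    assert report.mae_train <= model.epsilon
    assert report.r2_train >= 0.99
    resid = np.abs(model.predict_intensity(train.conc_a, train.conc_b) - train.oi)
    assert resid.max() <= 0.45


def test_fit_error_conditions():
    ds = _dataset()
    train, _ = om.split_dataset(ds, 0.7, seed=0)
    with pytest.raises(om.SizeError):
        om.fit_intensity_model(train, cv_folds=len(train) + 1, seed=0)
    with pytest.raises(om.ConfigurationError):
        om.fit_intensity_model(train, feature_scaling="minmax")
    flat = om.PanelDataset(
        ds.odorant_a,
        ds.odorant_b,
        [om.BinaryMixtureSample(1.0, float(b), float(o)) for b, o in
         zip([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])],
    )
    with pytest.raises(om.DataError, match="degenerate"):
        om.fit_intensity_model(flat, cv_folds=2, seed=0)


# --------------------------------------------------- prediction/persistence

def test_prediction_contracts(ester_pipeline, tmp_path):
    model = ester_pipeline.model
    a = float(ester_pipeline.dataset.conc_a[0])
    b = float(ester_pipeline.dataset.conc_b[0])
    assert model.predict_intensity(a, b) == model.predict_intensity(a, b)
    lo, hi = model.oi_range
    grid_a = np.geomspace(a / 10, a * 10, 10)
    grid_b = np.geomspace(b / 10, b * 10, 10)
    ga, gb = np.meshgrid(grid_a, grid_b)
    preds = model.predict_intensity(ga, gb)
    assert preds.shape == (10, 10)
    assert np.all((preds >= lo) & (preds <= hi))
    with pytest.raises(om.DomainError):
        model.predict_intensity(-1.0, b)

    path = tmp_path / "model.joblib"
    om.save_model(model, path)
    reloaded = om.load_model(path)
    probe = reloaded.predict_intensity(ga, gb)
    assert np.array_equal(probe, preds)  # bit-for-bit
    assert reloaded.selected_c == model.selected_c
    assert reloaded.cv_table.equals(model.cv_table)


def test_unfitted_model_raises_state_error(ester_pipeline):
    import dataclasses

    broken = dataclasses.replace(ester_pipeline.model, svr=None)
    with pytest.raises(om.StateError):
        broken.predict_intensity(1.0, 1.0)


def test_evaluate_on_same_split_twice_is_symmetric(ester_pipeline):
    model, train = ester_pipeline.model, ester_pipeline.train
    rep = om.evaluate_model(model, train, train)
    assert rep.r2_train == rep.r2_test
    assert rep.mae_train == rep.mae_test
    assert rep.n_train == rep.n_test == len(train)


def test_overfitting_guard_across_seeds(recovery_runs):
    """Train and test accuracy stay comparable over repeated default runs."""
    gaps = [p.report.r2_train - p.report.r2_test for p in recovery_runs]
    assert sum(g <= 0.2 for g in gaps) >= 18  # >= 90% of 20 runs
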