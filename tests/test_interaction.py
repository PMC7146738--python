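"""Interaction statistics, surface construction, scatter and summary."""

import numpy as np
import pandas as pd
import pytest

import odormix as om
from odormix.interaction import AdditiveIntensityOracle

EST = om.OdorFamily.ESTER
ARO = om.OdorFamily.AROMATIC
ALD = om.OdorFamily.ALDEHYDE


def test_oi_sum_reference_points():
    assert om.oi_sum(3, 3, EST, EST) == pytest.approx(3.00)
    assert om.oi_sum(1, 2, ARO, ARO) == pytest.approx(3.21)
    root = 1.82 / 1.76
    assert om.oi_sum(root, root, ALD, ALD) == pytest.approx(0.0, abs=1e-12)


def test_reduction_and_ratio_reference_points():
    assert om.oi_reduction(3.0, 3.0) == 0.0
    assert om.oi_reduction(4.0, 3.0) == 1.0
    assert om.oi_reduction(2.0, 2.5) == -0.5  # synergism sign convention
    assert om.oi_reduction_ratio(4.0, 3.0) == pytest.approx(0.25)
    assert om.oi_reduction_ratio(5.0, 5.0) == 0.0
    assert om.oi_reduction_ratio(2.0, 0.0) == 1.0
    with pytest.raises(om.DomainError):
        om.oi_reduction_ratio(0.0, 1.0)


def test_mixing_ratio_reference_points():
    assert om.mixing_ratio(2, 2) == 0.5
    assert om.mixing_ratio(3, 1) == 0.75
    assert om.mixing_ratio(0, 5) == 0.0
    assert om.mixing_ratio(1, 3) + om.mixing_ratio(3, 1) == pytest.approx(1.0)
    with pytest.raises(om.DomainError):
        om.mixing_ratio(-3, 1)


@pytest.fixture(scope="module")
def additive_products():
    """Noiseless additive dataset scored by the exact additive oracle."""
    cfg = om.GeneratorConfig.for_pair("EA", "BA", seed=17, rho_max=0.0,
                                      noise_sigma=0.0, oi_clip=None)
    ds = om.generate_panel_dataset(cfg)
    oracle = AdditiveIntensityOracle(ds.odorant_a, ds.odorant_b)
    surf = om.simulate_interaction_surface(oracle, ds, resolution=40)
    return ds, surf


def test_surface_shape_and_grid_bounds(ester_pipeline):
    surf = ester_pipeline.surface
    assert surf.oi_mix.shape == surf.oi_sum.shape == (50, 50)
    assert surf.oi_reduction.shape == surf.mask.shape == (50, 50)
    ds = ester_pipeline.dataset
    assert surf.axis_a.min() == pytest.approx(ds.lnoav_a().min())
    assert surf.axis_a.max() == pytest.approx(ds.lnoav_a().max())
    assert surf.axis_b.min() == pytest.approx(ds.lnoav_b().min())
    assert surf.axis_b.max() == pytest.approx(ds.lnoav_b().max())
    with pytest.raises(om.SizeError):
        om.simulate_interaction_surface(ester_pipeline.model, ds, resolution=1)


def test_surface_identities_and_mask(ester_pipeline):
    surf = ester_pipeline.surface
    assert np.array_equal(surf.oi_reduction, surf.oi_sum - surf.oi_mix)
    assert np.array_equal(surf.mask, surf.oi_sum < surf.min_oi_sum)
    # Eq consistency: ratio * oi_sum == reduction wherever both defined
    ok = surf.oi_sum != 0
    ratio = (surf.oi_sum[ok] - surf.oi_mix[ok]) / surf.oi_sum[ok]
    assert np.allclose(ratio * surf.oi_sum[ok], surf.oi_reduction[ok], atol=1e-12)


def test_additive_oracle_gives_zero_interaction(additive_products):
    ds, surf = additive_products
    unmasked = ~surf.mask
    assert np.allclose(surf.oi_reduction[unmasked], 0.0, atol=1e-9)
    sc = om.ratio_scatter(ds, surf)
    assert np.allclose(sc.table["oi_reduction_ratio"], 0.0, atol=1e-9)
    summary = om.summarize_surface(sc)
    assert abs(summary.peak_ratio) <= 1e-9
    assert summary.intensity_ratio_correlation == 0.0


def test_scatter_bookkeeping_and_row_validity(ester_pipeline):
    ds, surf, sc = (ester_pipeline.dataset, ester_pipeline.surface,
                    ester_pipeline.scatter)
    n_unmasked = int((~surf.mask).sum())
    assert len(sc.table) == len(ds) + n_unmasked - sc.n_dropped
    assert sc.n_dropped >= 0
    x = sc.table["x_a"].to_numpy()
    assert np.all((x > 0) & (x < 1))
    assert set(sc.table["source"]) <= {"measured", "predicted"}
    with pytest.raises(om.DataError):
        other = om.generate_panel_dataset(om.GeneratorConfig.for_pair("B", "T", seed=1))
        om.ratio_scatter(other, surf)


def test_scatter_ratio_is_intensity_independent(ester_pipeline):
    pred = ester_pipeline.scatter.table.query("source == 'predicted'")
    from scipy import stats

    rho = stats.spearmanr(pred["oi_reduction_ratio"], pred["oi_mix"]).statistic
    assert abs(rho) <= 0.3


def test_surface_argmax_near_equal_mixing(ester_pipeline):
    surf = ester_pipeline.surface
    la, lb = surf.grid()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(surf.oi_sum != 0, surf.oi_reduction / surf.oi_sum, -np.inf)
    ratio[surf.mask] = -np.inf
    i, j = np.unravel_index(np.argmax(ratio), ratio.shape)
    x_at_peak = la[i, j] / (la[i, j] + lb[i, j])
    assert abs(x_at_peak - 0.5) <= 0.1


def test_noiseless_ground_truth_recovery():
    cfg = om.GeneratorConfig.for_pair("EA", "BA", seed=8, rho_max=0.35,
                                      noise_sigma=0.0, n_samples=60)
    ds = om.generate_panel_dataset(cfg)
    train, _ = om.split_dataset(ds, 0.7, seed=9)
    model = om.fit_intensity_model(train, cv_folds=10, seed=10)
    surf = om.simulate_interaction_surface(model, ds, 50, 2.0)
    summary = om.summarize_surface(om.ratio_scatter(ds, surf))
    assert summary.peak_ratio == pytest.approx(0.35, abs=0.02)
    assert summary.peak_x_a == pytest.approx(0.5, abs=0.05)


def test_summary_duplication_invariance(ester_pipeline):
    sc = ester_pipeline.scatter
    doubled = om.RatioScatter(
        pair=sc.pair,
        table=pd.concat([sc.table, sc.table], ignore_index=True),
        n_dropped=sc.n_dropped,
    )
    s1, s2 = om.summarize_surface(sc), om.summarize_surface(doubled)
    assert s1.peak_ratio == s2.peak_ratio
    assert s1.peak_x_a == s2.peak_x_a
    assert s2.n_points == 2 * s1.n_points


def test_summary_requires_enough_rows(ester_pipeline):
    tiny = om.RatioScatter(
        pair=ester_pipeline.scatter.pair,
        table=ester_pipeline.scatter.table.head(5),
        n_dropped=0,
    )
    with pytest.raises(om.SizeError):
        om.summarize_surface(tiny)


def test_surface_export_schema(ester_pipeline):
    df = ester_pipeline.surface.to_dataframe()
    assert list(df.columns) == [
        "lnoav_a", "lnoav_b", "conc_a_mg_m3", "conc_b_mg_m3",
        "oi_mix", "oi_sum", "oi_reduction", "masked",
    ]
    assert len(df) == 50 * 50
    assert df["masked"].dtype == bool
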