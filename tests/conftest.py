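"""Shared fixtures: default end-to-end products and the multi-seed study."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import odormix as om

settings.register_profile(
    "odormix",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("odormix")


@dataclasses.dataclass
class PipelineProducts:
    """Everything one end-to-end run produces, kept in memory for tests."""

    dataset: om.PanelDataset
    train: om.PanelDataset
    test: om.PanelDataset
    model: om.TrainedIntensityModel
    report: om.EvaluationReport
    surface: om.InteractionSurface
    scatter: om.RatioScatter
    summary: om.SurfaceSummary


def run_default_pipeline(pair=("EA", "BA"), gen_seed=42, split_seed=7, cv_seed=11,
                         **generator_overrides) -> PipelineProducts:
    config = om.GeneratorConfig.for_pair(*pair, seed=gen_seed, **generator_overrides)
    dataset = om.generate_panel_dataset(config)
    train, test = om.split_dataset(dataset, 0.7, split_seed)
    model = om.fit_intensity_model(train, cv_folds=10, seed=cv_seed)
    report = om.evaluate_model(model, train, test)
    surface = om.simulate_interaction_surface(model, dataset, 50, 2.0)
    scatter = om.ratio_scatter(dataset, surface)
    summary = om.summarize_surface(scatter)
    return PipelineProducts(dataset, train, test, model, report,
                            surface, scatter, summary)


@pytest.fixture(scope="session")
def ester_pipeline() -> PipelineProducts:
    """Default ester (EA+BA) pipeline at the benchmark seed combination."""
    return run_default_pipeline()


@pytest.fixture(scope="session")
def recovery_runs() -> list[PipelineProducts]:
    """Twenty seeded default ester runs for the parameter-recovery study."""
    return [
        run_default_pipeline(gen_seed=100 + i, split_seed=200 + i, cv_seed=300 + i)
        for i in range(20)
    ]
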