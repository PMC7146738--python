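"""Run configuration, dataset file I/O and the end-to-end pipeline.

The pipeline executes the full per-pair workflow — generate (or read) panel
data, split 70/30, grid-search and fit the SVR, evaluate, densify the
composition space, build the ratio scatter and summary, and write every
artifact (CSV/JSON/figures) plus a log from which the run is fully
reconstructible.  All randomness flows from three named seeds (generator,
split, cv); identical configuration reproduces every numeric artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    ParseError,
    PipelineError,
    SizeError,
)
from .intensity_model import (
    EvaluationReport,
    HyperparameterGrid,
    evaluate_model,
    fit_intensity_model,
    save_model,
    split_dataset,
)
from .interaction import ratio_scatter, simulate_interaction_surface, summarize_surface
from .psychophysics import Odorant, default_registry
from .synthetic_panel import (
    BinaryMixtureSample,
    GeneratorConfig,
    PanelDataset,
    generate_panel_dataset,
)

__all__ = [
    "SplitConfig",
    "ModelConfig",
    "SurfaceConfig",
    "RunConfig",
    "write_dataset",
    "read_dataset",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

DATASET_COLUMNS = ["odorant_a", "odorant_b", "conc_a_mg_m3", "conc_b_mg_m3", "oi", "source"]


def _fresh_seed() -> int:
    # Auto-fill for omitted seeds; echoed in the resolved config so the run
    # stays reconstructible.
    return int(np.random.SeedSequence().entropy % (2**31))


@dataclass
class SplitConfig:
    train_fraction: float = 0.7
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction!r}"
            )


@dataclass
class ModelConfig:
    c_values: tuple[float, ...] | None = None  # None -> default log2 lattice
    gamma_values: tuple[float, ...] | None = None
    epsilon: float = 0.1
    cv_folds: int = 10
    seed: int | None = None
    feature_scaling: str = "log-standard"

    def grid(self) -> HyperparameterGrid:
        default = HyperparameterGrid.default()
        return HyperparameterGrid(
            c_values=tuple(self.c_values) if self.c_values else default.c_values,
            gamma_values=tuple(self.gamma_values) if self.gamma_values else default.gamma_values,
            epsilon=self.epsilon,
        )


@dataclass
class SurfaceConfig:
    resolution: int = 50
    min_oi_sum: float = 2.0

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ConfigurationError(
                f"surface resolution must be >= 2, got {self.resolution!r}"
            )


@dataclass
class RunConfig:
    """Full parameterization of one end-to-end run."""

    generator: GeneratorConfig
    output_dir: Path
    split: SplitConfig = field(default_factory=SplitConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)
    dataset_path: Path | None = None  # read instead of generate when set

    def resolved(self) -> "RunConfig":
        """Copy with every omitted seed auto-filled (and later echoed)."""
        cfg = dataclasses.replace(self)
        if cfg.split.seed is None:
            cfg.split = dataclasses.replace(cfg.split, seed=_fresh_seed())
        if cfg.model.seed is None:
            cfg.model = dataclasses.replace(cfg.model, seed=_fresh_seed())
        return cfg

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "split": dataclasses.asdict(self.split),
            "model": dataclasses.asdict(self.model),
            "surface": dataclasses.asdict(self.surface),
            "output_dir": str(self.output_dir),
            "dataset_path": str(self.dataset_path) if self.dataset_path else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            gen = GeneratorConfig.from_dict(d["generator"])
        except KeyError:
            raise ConfigurationError("run config must carry a 'generator' section")
        model_d = dict(d.get("model", {}))
        for key in ("c_values", "gamma_values"):
            if model_d.get(key) is not None:
                model_d[key] = tuple(model_d[key])
        return cls(
            generator=gen,
            output_dir=Path(d.get("output_dir", ".")),
            split=SplitConfig(**d.get("split", {})),
            model=ModelConfig(**model_d),
            surface=SurfaceConfig(**d.get("surface", {})),
            dataset_path=Path(d["dataset_path"]) if d.get("dataset_path") else None,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load YAML or JSON config, auto-detected by extension."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParseError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)


def write_dataset(dataset: PanelDataset, path) -> None:
    """Write a panel dataset as CSV (documented header, full float precision)."""
    dataset.to_dataframe().to_csv(path, index=False)


def read_dataset(path, registry: dict[str, Odorant] | None = None) -> PanelDataset:
    """Read and validate a panel dataset CSV.

    Malformed rows are rejected with their file line number (header = line 1).
    """
    path = Path(path)
    registry = registry if registry is not None else default_registry()
    try:
        table = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SizeError(f"{path}: file is empty")
    missing = [c for c in DATASET_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if len(table) == 0:
        raise SizeError(f"{path}: no data rows below the header")

    samples: list[BinaryMixtureSample] = []
    pair: tuple[str, str] | None = None
    for i, row in enumerate(table.itertuples(index=False)):
        line = i + 2
        ab_a, ab_b = str(row.odorant_a).strip(), str(row.odorant_b).strip()
        for ab in (ab_a, ab_b):
            if ab not in registry:
                raise ParseError(
                    f"{path}: line {line}: unknown odorant abbreviation {ab!r}"
                )
        if pair is None:
            pair = (ab_a, ab_b)
        elif (ab_a, ab_b) != pair:
            raise ParseError(
                f"{path}: line {line}: pair ({ab_a}, {ab_b}) differs from "
                f"first row's pair {pair}; one file per pair"
            )
        values = {}
        for col in ("conc_a_mg_m3", "conc_b_mg_m3", "oi"):
            raw = getattr(row, col)
            try:
                values[col] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: line {line}: column {col!r} is not numeric: {raw!r}"
                )
            if not np.isfinite(values[col]):
                raise ParseError(
                    f"{path}: line {line}: column {col!r} is not finite: {raw!r}"
                )
        for col in ("conc_a_mg_m3", "conc_b_mg_m3"):
            if values[col] <= 0:
                raise ParseError(
                    f"{path}: line {line}: column {col!r} must be > 0, "
                    f"got {values[col]!r}"
                )
        source = str(row.source).strip()
        if source not in ("measured", "predicted"):
            raise ParseError(
                f"{path}: line {line}: source must be measured|predicted, got {source!r}"
            )
        samples.append(
            BinaryMixtureSample(
                conc_a=values["conc_a_mg_m3"],
                conc_b=values["conc_b_mg_m3"],
                oi=values["oi"],
                source=source,
            )
        )
    return PanelDataset(
        registry[pair[0]], registry[pair[1]], samples, provenance=str(path)
    )


def _json_dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute generate -> split -> fit -> evaluate -> surface -> scatter ->
    summarize and write all artifacts under ``config.output_dir``.

    Returns a mapping of artifact names to paths.  Any stage failure raises
    :class:`PipelineError` carrying the stage name.  Rerunning with an
    identical (fully seeded) config reproduces every numeric artifact.
    """
    config = config.resolved()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dataset": out / "dataset.csv",
        "model": out / "model.joblib",
        "evaluation": out / "evaluation.json",
        "surface": out / "surface.csv",
        "scatter": out / "scatter.csv",
        "summary": out / "summary.json",
        "figure_surface": out / "surface.png",
        "figure_scatter": out / "scatter.png",
        "log": out / "run.log",
    }

    handler = logging.FileHandler(paths["log"], mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("odormix")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineError(name, str(exc)) from exc
        return wrap

    try:
        logger.info("resolved run config: %s", json.dumps(config.to_dict(), sort_keys=True))

        if config.dataset_path is not None:
            dataset = stage("read")(read_dataset, config.dataset_path)
        else:
            dataset = stage("generate")(generate_panel_dataset, config.generator)
        write_dataset(dataset, paths["dataset"])
        logger.info("dataset: %d samples for pair %s (%s)",
                    len(dataset), dataset.pair, dataset.provenance)

        train, test = stage("split")(
            split_dataset, dataset, config.split.train_fraction, config.split.seed
        )
        logger.info("split: %d train / %d test (seed=%d)",
                    len(train), len(test), config.split.seed)

        model = stage("fit")(
            fit_intensity_model, train, config.model.grid(),
            config.model.cv_folds, config.model.seed,
            config.model.feature_scaling,
        )
        logger.info("fit: selected C=%g gamma=%g epsilon=%g (cv seed=%d)",
                    model.selected_c, model.selected_gamma, model.epsilon,
                    config.model.seed)
        save_model(model, paths["model"])

        report: EvaluationReport = stage("evaluate")(evaluate_model, model, train, test)
        _json_dump(report.to_dict(), paths["evaluation"])
        logger.info("evaluate: %s", report.to_dict())

        surface = stage("surface")(
            simulate_interaction_surface, model, dataset,
            config.surface.resolution, config.surface.min_oi_sum,
        )
        surface.to_dataframe().to_csv(paths["surface"], index=False)

        scatter = stage("scatter")(ratio_scatter, dataset, surface)
        scatter.table.to_csv(paths["scatter"], index=False)

        summary = stage("summarize")(summarize_surface, scatter)
        _json_dump(summary.to_dict(), paths["summary"])
        logger.info("summary: %s", summary.to_dict())

        from .plotting import plot_interaction_surface, plot_ratio_scatter

        stage("figures")(plot_interaction_surface, surface, paths["figure_surface"])
        stage("figures")(plot_ratio_scatter, scatter, paths["figure_scatter"])
    finally:
        handler.close()
        root.removeHandler(handler)

    return paths
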