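"""Per-pair odor-intensity regression: RBF-SVR with grid-searched C and gamma.

The model maps the two raw component concentrations (mg/m^3) of a binary
mixture directly to the mixture's odor intensity on the OIRS scale.
Protocol: random 70/30 train/test split; features scaled on training-set
statistics (RBF kernels are scale sensitive); hyperparameters C and gamma
selected on a log2 lattice by k-fold (default 10) cross-validated mean
absolute error with seeded fold assignment; ties broken toward smaller C,
then smaller gamma (flatter models); the winning cell refit on the full
training set.  The epsilon-insensitive tube half-width is fixed (default
0.1 OIRS) and not searched.

Feature scaling defaults to z-scored *log* concentration ("log-standard"):
odor intensity is linear in log concentration (the lnOAV laws), and panel
designs span several concentration decades, so z-scoring raw concentrations
collapses most samples into a tiny cluster that a single global RBF length
scale cannot resolve.  Plain z-scoring of raw concentrations remains
available as ``feature_scaling="standard"``.

Accuracy is reported as the coefficient of determination R^2 and the mean
absolute error, computed separately on the training and test splits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .errors import ConfigurationError, DataError, DomainError, SizeError, StateError
from .synthetic_panel import PanelDataset

__all__ = [
    "HyperparameterGrid",
    "TrainedIntensityModel",
    "EvaluationReport",
    "split_dataset",
    "fit_intensity_model",
    "predict_oi",
    "r_squared",
    "mae",
    "evaluate_model",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class HyperparameterGrid:
    """Candidate C/gamma values for the RBF-SVR grid search.

    The default is the canonical log2 lattice C in {2^-5, 2^-3, ..., 2^15},
    gamma in {2^-15, 2^-13, ..., 2^3}; epsilon is a fixed tube width, not a
    search dimension.
    """

    c_values: tuple[float, ...]
    gamma_values: tuple[float, ...]
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if not self.c_values or not self.gamma_values:
            raise ConfigurationError("hyperparameter grids must be non-empty")
        if any(c <= 0 for c in self.c_values) or any(g <= 0 for g in self.gamma_values):
            raise ConfigurationError("all C and gamma values must be > 0")
        if not self.epsilon > 0:
            raise ConfigurationError(f"epsilon must be > 0, got {self.epsilon!r}")

    @classmethod
    def default(cls) -> "HyperparameterGrid":
        return cls(
            c_values=tuple(2.0 ** np.arange(-5, 16, 2)),
            gamma_values=tuple(2.0 ** np.arange(-15, 4, 2)),
            epsilon=0.1,
        )


@dataclass
class TrainedIntensityModel:
    """Fitted RBF-SVR predictor for one mixture pair.

    Carries the training-set feature scaling statistics, the selected
    hyperparameters, the full cross-validation table and a digest of the
    training conditions, so a persisted model is fully self-describing.
    """

    pair: tuple[str, str]
    feature_mean: np.ndarray  # shape (2,): per-feature means (scaled space)
    feature_std: np.ndarray  # shape (2,)
    selected_c: float
    selected_gamma: float
    epsilon: float
    cv_table: pd.DataFrame  # columns: C, gamma, cv_mae
    train_digest: str
    feature_scaling: str = "log-standard"  # "log-standard" | "standard"
    #: Codomain of the predictor: panel targets live on the OIRS span [0, 8],
    #: so raw SVR outputs are clipped to it (None disables).
    oi_range: tuple[float, float] | None = (0.0, 8.0)
    svr: SVR | None = None

    def _scale(self, x: np.ndarray) -> np.ndarray:
        if self.feature_scaling == "log-standard":
            x = np.log(x)
        return (x - self.feature_mean) / self.feature_std

    def predict_intensity(self, conc_a, conc_b):
        """Predicted mixture OI (OIRS units) at the given concentrations.

        Accepts scalars or broadcastable arrays; deterministic for a fixed
        model.
        """
        if self.svr is None:
            raise StateError("model has no fitted predictor; fit or load it first")
        a = np.asarray(conc_a, dtype=float)
        b = np.asarray(conc_b, dtype=float)
        scalar = a.ndim == 0 and b.ndim == 0
        if np.any(a <= 0) or np.any(b <= 0):
            raise DomainError("concentrations must be > 0 mg/m^3")
        a2, b2 = np.broadcast_arrays(np.atleast_1d(a), np.atleast_1d(b))
        xs = self._scale(np.column_stack([a2.ravel(), b2.ravel()]))
        y = self.svr.predict(xs).reshape(a2.shape)
        if self.oi_range is not None:
            y = np.clip(y, *self.oi_range)
        return float(y.ravel()[0]) if scalar else y


@dataclass(frozen=True)
class EvaluationReport:
    """R^2 and MAE on the training and test splits."""

    r2_train: float
    r2_test: float
    mae_train: float
    mae_test: float
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def split_dataset(dataset: PanelDataset, train_fraction: float = 0.7,
                  seed: int = 0) -> tuple[PanelDataset, PanelDataset]:
    """Seeded random train/test partition without replacement.

    The training size is round(train_fraction * n) with ties-to-even; row
    order within each part follows the original dataset.
    """
    if not 0 < train_fraction < 1:
        raise ConfigurationError(
            f"train_fraction must lie in (0, 1), got {train_fraction!r}"
        )
    n = len(dataset)
    if n < 4:
        raise SizeError(f"dataset must hold >= 4 samples to split, got {n}")
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise SizeError(
            f"split of {n} samples at fraction {train_fraction} leaves an empty part"
        )
    perm = np.random.default_rng(seed).permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    tag = f"{dataset.provenance}|split(fraction={train_fraction},seed={seed})"
    return (
        dataset.subset(train_idx, provenance=tag + "|train"),
        dataset.subset(test_idx, provenance=tag + "|test"),
    )


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle, then contiguous blocks; fold sizes differ by <= 1."""
    order = np.random.default_rng(seed).permutation(n)
    return [np.sort(block) for block in np.array_split(order, folds)]


def fit_intensity_model(train: PanelDataset,
                        grid: HyperparameterGrid | None = None,
                        cv_folds: int = 10, seed: int = 0,
                        feature_scaling: str = "log-standard"
                        ) -> TrainedIntensityModel:
    """Grid-search an RBF-SVR on the training split and refit the winner.

    For every (C, gamma) cell the mean absolute error is estimated by
    ``cv_folds``-fold cross-validation with seeded fold assignment; the cell
    with minimal mean CV MAE wins (ties: smaller C, then smaller gamma).
    """
    if grid is None:
        grid = HyperparameterGrid.default()
    if feature_scaling not in ("log-standard", "standard"):
        raise ConfigurationError(
            f"feature_scaling must be 'log-standard' or 'standard', "
            f"got {feature_scaling!r}"
        )
    n = len(train)
    if n < 4:
        raise SizeError(f"training set must hold >= 4 samples, got {n}")
    if cv_folds < 2 or cv_folds > n:
        raise SizeError(
            f"cv_folds must lie in [2, n_train={n}], got {cv_folds}"
        )

    x = np.column_stack([train.conc_a, train.conc_b])
    if feature_scaling == "log-standard":
        x = np.log(x)
    y = train.oi
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    if np.any(std == 0):
        raise DataError(
            "degenerate feature: a concentration column has zero variance"
        )
    xs = (x - mean) / std

    folds = _fold_indices(n, cv_folds, seed)
    all_idx = np.arange(n)
    rows = []
    best: tuple[float, float, float] | None = None  # (cv_mae, C, gamma)
    for c in sorted(grid.c_values):
        for g in sorted(grid.gamma_values):
            fold_errors = []
            for val_idx in folds:
                fit_idx = np.setdiff1d(all_idx, val_idx)
                reg = SVR(kernel="rbf", C=c, gamma=g, epsilon=grid.epsilon)
                reg.fit(xs[fit_idx], y[fit_idx])
                pred = reg.predict(xs[val_idx])
                fold_errors.append(float(np.mean(np.abs(y[val_idx] - pred))))
            cv_mae = float(np.mean(fold_errors))
            rows.append({"C": c, "gamma": g, "cv_mae": cv_mae})
            if best is None or cv_mae < best[0]:
                best = (cv_mae, c, g)

    _, sel_c, sel_g = best
    final = SVR(kernel="rbf", C=sel_c, gamma=sel_g, epsilon=grid.epsilon)
    final.fit(xs, y)
    pair = (train.odorant_a.abbreviation, train.odorant_b.abbreviation)
    return TrainedIntensityModel(
        pair=pair,
        feature_mean=mean,
        feature_std=std,
        selected_c=float(sel_c),
        selected_gamma=float(sel_g),
        epsilon=grid.epsilon,
        cv_table=pd.DataFrame(rows),
        train_digest=f"n={n},cv_folds={cv_folds},cv_seed={seed}",
        feature_scaling=feature_scaling,
        svr=final,
    )


def predict_oi(model: TrainedIntensityModel, conc_a, conc_b):
    """Predicted mixture OI at the given concentrations (see the method)."""
    return model.predict_intensity(conc_a, conc_b)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise SizeError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 2:
        raise SizeError(f"need >= 2 observations for R^2, got {obs.size}")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise DataError("R^2 undefined: observed values are all equal")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def mae(observed, predicted) -> float:
    """Mean absolute error; zero iff the sequences are identical."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise SizeError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise SizeError("MAE undefined on empty input")
    return float(np.mean(np.abs(obs - pred)))


def evaluate_model(model: TrainedIntensityModel, train: PanelDataset,
                   test: PanelDataset) -> EvaluationReport:
    """R^2 and MAE on both splits; never refits the model."""
    if len(train) == 0 or len(test) == 0:
        raise SizeError("both splits must be non-empty for evaluation")
    pred_train = model.predict_intensity(train.conc_a, train.conc_b)
    pred_test = model.predict_intensity(test.conc_a, test.conc_b)
    return EvaluationReport(
        r2_train=r_squared(train.oi, pred_train),
        r2_test=r_squared(test.oi, pred_test),
        mae_train=mae(train.oi, pred_train),
        mae_test=mae(test.oi, pred_test),
        n_train=len(train),
        n_test=len(test),
    )


_PERSIST_VERSION = 1


def save_model(model: TrainedIntensityModel, path) -> None:
    """Persist a fitted model; reload reproduces predictions bit-for-bit."""
    payload = {
        "version": _PERSIST_VERSION,
        "pair": model.pair,
        "feature_mean": model.feature_mean,
        "feature_std": model.feature_std,
        "selected_c": model.selected_c,
        "selected_gamma": model.selected_gamma,
        "epsilon": model.epsilon,
        "cv_table": model.cv_table,
        "train_digest": model.train_digest,
        "feature_scaling": model.feature_scaling,
        "oi_range": model.oi_range,
        "svr": model.svr,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedIntensityModel:
    payload = joblib.load(path)
    if payload.get("version") != _PERSIST_VERSION:
        raise StateError(f"unsupported model file version {payload.get('version')!r}")
    return TrainedIntensityModel(
        pair=tuple(payload["pair"]),
        feature_mean=np.asarray(payload["feature_mean"], dtype=float),
        feature_std=np.asarray(payload["feature_std"], dtype=float),
        selected_c=payload["selected_c"],
        selected_gamma=payload["selected_gamma"],
        epsilon=payload["epsilon"],
        cv_table=payload["cv_table"],
        train_digest=payload["train_digest"],
        feature_scaling=payload["feature_scaling"],
        oi_range=payload["oi_range"],
        svr=payload["svr"],
    )
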