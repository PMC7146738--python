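"""Odor-interaction statistics and model-densified interaction surfaces.

For a binary mixture the additive expectation is OI_sum = OI_a + OI_b, each
component's intensity coming from its family law at the component's lnOAV.
The interaction degree is quantified as

    OI reduction       = OI_sum - OI_mix
    OI reduction ratio = (OI_sum - OI_mix) / OI_sum

(positive => antagonism, negative => synergism), and is analysed against
the composition coordinate x_a = lnOAV_a / (lnOAV_a + lnOAV_b).

Because measured panels are sparse, the fitted intensity model densifies
composition space: a rectangular lnOAV grid spanning the observed per-
component ranges is scored by the model, cells whose additive intensity
falls below a cut-off (default 2.0 OIRS, where panel error dominates) are
masked out, and the result feeds a contour surface, a ratio-vs-mixing-ratio
scatter and a compact summary (peak ratio and its location, plus a rank
correlation checking that the interaction degree does not depend on the
mixture's intensity level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DomainError, SizeError
from .psychophysics import OdorFamily, Odorant, conc_from_lnoav, ln_oav, oi_from_lnoav
from .synthetic_panel import PanelDataset

__all__ = [
    "InteractionSurface",
    "RatioScatter",
    "SurfaceSummary",
    "AdditiveIntensityOracle",
    "oi_sum",
    "oi_reduction",
    "oi_reduction_ratio",
    "mixing_ratio",
    "simulate_interaction_surface",
    "ratio_scatter",
    "summarize_surface",
]

logger = logging.getLogger(__name__)


def oi_sum(lnoav_a, lnoav_b, family_a: OdorFamily, family_b: OdorFamily):
    """Additive (no-interaction) mixture intensity OI_a + OI_b, unclamped."""
    return oi_from_lnoav(lnoav_a, family_a) + oi_from_lnoav(lnoav_b, family_b)


def oi_reduction(oi_sum_val, oi_mix_val):
    """OI_sum - OI_mix; positive means antagonism, negative synergism."""
    s = np.asarray(oi_sum_val, dtype=float)
    m = np.asarray(oi_mix_val, dtype=float)
    out = s - m
    return float(out) if out.ndim == 0 else out


def oi_reduction_ratio(oi_sum_val, oi_mix_val):
    """(OI_sum - OI_mix) / OI_sum; 0 when additive, 1 at full suppression."""
    s = np.asarray(oi_sum_val, dtype=float)
    m = np.asarray(oi_mix_val, dtype=float)
    if np.any(s == 0):
        raise DomainError("OI reduction ratio undefined where OI_sum = 0")
    out = (s - m) / s
    return float(out) if out.ndim == 0 else out


def mixing_ratio(lnoav_a, lnoav_b):
    """Composition coordinate x_a = lnOAV_a / (lnOAV_a + lnOAV_b)."""
    la = np.asarray(lnoav_a, dtype=float)
    lb = np.asarray(lnoav_b, dtype=float)
    total = la + lb
    if np.any(total <= 0):
        raise DomainError(
            "mixing ratio undefined: lnOAV_a + lnOAV_b must be > 0"
        )
    out = la / total
    return float(out) if out.ndim == 0 else out


class AdditiveIntensityOracle:
    """Exact no-interaction reference predictor for a mixture pair.

    Implements the same ``predict_intensity`` contract as a trained model
    but returns the closed-form additive intensity.  Useful as a null
    model: feeding it to the surface builder must yield OI reduction
    identically zero.
    """

    def __init__(self, odorant_a: Odorant, odorant_b: Odorant):
        self.odorant_a = odorant_a
        self.odorant_b = odorant_b
        self.pair = (odorant_a.abbreviation, odorant_b.abbreviation)

    def predict_intensity(self, conc_a, conc_b):
        return oi_sum(
            ln_oav(conc_a, self.odorant_a),
            ln_oav(conc_b, self.odorant_b),
            self.odorant_a.family,
            self.odorant_b.family,
        )


@dataclass
class InteractionSurface:
    """Model predictions on a rectangular lnOAV grid for one pair.

    ``oi_mix[i, j]`` corresponds to (axis_a[i], axis_b[j]); ``mask`` is True
    exactly where OI_sum < min_oi_sum (excluded weak-stimulus cells).
    ``anchors`` holds the overlay points for plotting: the measured samples
    and the unmasked grid predictions.
    """

    pair: tuple[str, str]
    axis_a: np.ndarray
    axis_b: np.ndarray
    oi_mix: np.ndarray
    oi_sum: np.ndarray
    oi_reduction: np.ndarray
    mask: np.ndarray
    anchors: pd.DataFrame
    min_oi_sum: float
    odorant_a: Odorant
    odorant_b: Odorant

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (indexing='ij') of the two lnOAV axes."""
        return np.meshgrid(self.axis_a, self.axis_b, indexing="ij")

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export (one row per cell) with concentration columns."""
        la, lb = self.grid()
        return pd.DataFrame(
            {
                "lnoav_a": la.ravel(),
                "lnoav_b": lb.ravel(),
                "conc_a_mg_m3": conc_from_lnoav(la.ravel(), self.odorant_a),
                "conc_b_mg_m3": conc_from_lnoav(lb.ravel(), self.odorant_b),
                "oi_mix": self.oi_mix.ravel(),
                "oi_sum": self.oi_sum.ravel(),
                "oi_reduction": self.oi_reduction.ravel(),
                "masked": self.mask.ravel(),
            }
        )


@dataclass
class RatioScatter:
    """Ratio-vs-mixing-ratio rows from measured samples and grid predictions.

    ``table`` columns: x_a, oi_reduction_ratio, oi_mix, source.  Rows whose
    ratio is undefined (OI_sum <= 0, x_a outside (0, 1)) or that fall outside
    the measured total-stimulus range (extrapolation guard on predicted
    cells) are dropped; ``n_dropped`` counts them so that
    rows = n_measured + n_unmasked_cells - n_dropped.
    """

    pair: tuple[str, str]
    table: pd.DataFrame
    n_dropped: int


@dataclass(frozen=True)
class SurfaceSummary:
    """Headline interaction pattern read off the densified scatter.

    Peak statistics are taken over the model-predicted rows: the dense grid
    is the analysis product, and a maximum over individual noisy panel
    readings would be biased upward by measurement error.
    """

    peak_ratio: float
    peak_x_a: float
    intensity_ratio_correlation: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "peak_ratio": self.peak_ratio,
            "peak_x_a": self.peak_x_a,
            "intensity_ratio_correlation": self.intensity_ratio_correlation,
            "n_points": self.n_points,
        }


def simulate_interaction_surface(model, dataset: PanelDataset,
                                 resolution: int = 50,
                                 min_oi_sum: float = 2.0) -> InteractionSurface:
    """Score a rectangular lnOAV grid with the fitted model.

    The axes span each component's observed lnOAV range in ``dataset`` with
    ``resolution`` evenly spaced points.  Cells with OI_sum < ``min_oi_sum``
    are masked (the weak-stimulus exclusion); extrapolation into sparsely
    sampled parts of the rectangle is NOT masked here and must be judged by
    the reader of the contour map, exactly as with the measured overlays.
    """
    if resolution < 2:
        raise SizeError(f"resolution must be >= 2, got {resolution}")
    if not hasattr(model, "predict_intensity"):
        raise DataError("model must expose predict_intensity(conc_a, conc_b)")
    if len(dataset) == 0:
        raise SizeError("dataset must hold samples to define the grid bounds")

    la_obs = dataset.lnoav_a()
    lb_obs = dataset.lnoav_b()
    axis_a = np.linspace(la_obs.min(), la_obs.max(), resolution)
    axis_b = np.linspace(lb_obs.min(), lb_obs.max(), resolution)
    la, lb = np.meshgrid(axis_a, axis_b, indexing="ij")

    fam_a = dataset.odorant_a.family
    fam_b = dataset.odorant_b.family
    ca = conc_from_lnoav(la, dataset.odorant_a)
    cb = conc_from_lnoav(lb, dataset.odorant_b)
    oi_mix_grid = model.predict_intensity(ca, cb)
    oi_sum_grid = oi_sum(la, lb, fam_a, fam_b)
    reduction = oi_sum_grid - oi_mix_grid
    mask = oi_sum_grid < min_oi_sum

    measured = pd.DataFrame(
        {
            "lnoav_a": la_obs,
            "lnoav_b": lb_obs,
            "oi_mix": dataset.oi,
            "source": "measured",
        }
    )
    keep = ~mask
    predicted = pd.DataFrame(
        {
            "lnoav_a": la[keep],
            "lnoav_b": lb[keep],
            "oi_mix": np.asarray(oi_mix_grid)[keep],
            "source": "predicted",
        }
    )
    anchors = pd.concat([measured, predicted], ignore_index=True)

    return InteractionSurface(
        pair=dataset.pair,
        axis_a=axis_a,
        axis_b=axis_b,
        oi_mix=np.asarray(oi_mix_grid),
        oi_sum=np.asarray(oi_sum_grid),
        oi_reduction=np.asarray(reduction),
        mask=mask,
        anchors=anchors,
        min_oi_sum=min_oi_sum,
        odorant_a=dataset.odorant_a,
        odorant_b=dataset.odorant_b,
    )


def ratio_scatter(dataset: PanelDataset, surface: InteractionSurface) -> RatioScatter:
    """One scatter row per measured sample and per usable unmasked cell.

    Measured rows use the panel OI; predicted rows use the model's grid
    predictions.  Rows with OI_sum <= 0 or x_a outside (0, 1) are dropped,
    as are rows whose odor intensity OI_mix falls below the surface's
    weak-stimulus cut-off: at faint stimuli the relative error of either a
    panel reading or a model prediction dominates the reduction ratio, so
    only mixtures with distinct olfactory stimulation enter the ratio
    analysis.  Predicted cells whose total stimulus T = lnOAV_a + lnOAV_b
    falls outside the measured T-range are also dropped: there the RBF model
    is extrapolating far from any training sample and its reduction ratio is
    an artefact, not an interaction estimate.  All drops are counted.
    """
    if tuple(dataset.pair) != tuple(surface.pair):
        raise DataError(
            f"dataset pair {dataset.pair} does not match surface pair {surface.pair}"
        )
    fam_a = dataset.odorant_a.family
    fam_b = dataset.odorant_b.family

    # measured rows
    la_m = dataset.lnoav_a()
    lb_m = dataset.lnoav_b()
    t_m = la_m + lb_m
    s_m = oi_sum(la_m, lb_m, fam_a, fam_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_m = np.where(t_m != 0, la_m / t_m, np.nan)
        r_m = np.where(s_m != 0, (s_m - dataset.oi) / s_m, np.nan)
    keep_m = (s_m > 0) & (t_m > 0) & (x_m > 0) & (x_m < 1)
    keep_m &= dataset.oi >= surface.min_oi_sum
    n_measured = len(dataset)

    # predicted rows from unmasked grid cells
    la_g, lb_g = surface.grid()
    t_g = la_g + lb_g
    s_g = surface.oi_sum
    unmasked = ~surface.mask
    n_unmasked = int(unmasked.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        x_g = np.where(t_g != 0, la_g / t_g, np.nan)
        r_g = np.where(s_g != 0, (s_g - surface.oi_mix) / s_g, np.nan)
    t_lo, t_hi = (float(t_m.min()), float(t_m.max())) if n_measured else (-np.inf, np.inf)
    keep_g = unmasked & (s_g > 0) & (t_g > 0) & (x_g > 0) & (x_g < 1)
    keep_g &= surface.oi_mix >= surface.min_oi_sum
    keep_g &= (t_g >= t_lo) & (t_g <= t_hi)

    table = pd.concat(
        [
            pd.DataFrame(
                {
                    "x_a": x_m[keep_m],
                    "oi_reduction_ratio": r_m[keep_m],
                    "oi_mix": dataset.oi[keep_m],
                    "source": "measured",
                }
            ),
            pd.DataFrame(
                {
                    "x_a": x_g[keep_g],
                    "oi_reduction_ratio": r_g[keep_g],
                    "oi_mix": surface.oi_mix[keep_g],
                    "source": "predicted",
                }
            ),
        ],
        ignore_index=True,
    )
    n_dropped = (n_measured + n_unmasked) - len(table)
    if n_dropped:
        logger.info(
            "ratio_scatter(%s+%s): dropped %d of %d candidate rows "
            "(undefined ratio or outside the measured total-stimulus range)",
            *surface.pair, n_dropped, n_measured + n_unmasked,
        )
    return RatioScatter(pair=tuple(surface.pair), table=table, n_dropped=n_dropped)


def summarize_surface(scatter: RatioScatter) -> SurfaceSummary:
    """Peak interaction degree, its location, and the intensity-independence
    rank correlation.

    Peak and correlation are computed over predicted rows (falling back to
    all rows if the scatter carries none); a constant input yields a
    correlation of 0.0 by convention.
    """
    table = scatter.table
    if len(table) < 10:
        raise SizeError(f"need >= 10 scatter rows to summarize, got {len(table)}")
    pred = table[table["source"] == "predicted"]
    basis = pred if len(pred) else table
    i_peak = basis["oi_reduction_ratio"].idxmax()
    ratio = basis["oi_reduction_ratio"].to_numpy()
    intensity = basis["oi_mix"].to_numpy()
    if len(basis) < 2 or np.all(ratio == ratio[0]) or np.all(intensity == intensity[0]):
        corr = 0.0
    else:
        corr = float(stats.spearmanr(ratio, intensity).statistic)
        if not np.isfinite(corr):
            corr = 0.0
    return SurfaceSummary(
        peak_ratio=float(basis.loc[i_peak, "oi_reduction_ratio"]),
        peak_x_a=float(basis.loc[i_peak, "x_a"]),
        intensity_ratio_correlation=corr,
        n_points=int(len(table)),
    )
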