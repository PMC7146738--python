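"""Synthetic sensory-panel datasets for binary odorant mixtures.

Real olfactometry panels for binary mixtures (20-35 samples per pair, OIRS
intensities roughly 2-7, panel error around 0.3-0.4 OIRS units) are expensive
and rarely deposited.  This module generates datasets with the statistical
structure such panels exhibit, so the whole modelling pipeline is testable
end to end:

* ratio-dependent antagonism — the mixture's intensity falls short of the
  additive expectation OI_sum, most strongly when the two components'
  lnOAV mixing ratio is close to 1:1, vanishing for near-pure stimuli;
* weaker interaction for aromatic hydrocarbons than for esters/aldehydes;
* additive Gaussian panel noise, clipped to the physical OIRS range [0, 8].

The ground-truth interaction is a symmetric kernel on the mixing ratio
x_a = lnOAV_a / (lnOAV_a + lnOAV_b):

    rho(x_a) = rho_max * (4 x_a (1 - x_a))**shape_p
    OI_mix_true = OI_sum * (1 - rho(x_a))

which peaks at x_a = 0.5 (value rho_max) and is zero at the pure-component
boundaries.  rho_max < 0 yields synergism instead of antagonism.  Two
contrast strategies ship alongside: ``additive`` (no interaction) and
``strongest_component`` (mixture smells like its strongest part).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError
from .psychophysics import (
    Odorant,
    OdorFamily,
    conc_from_lnoav,
    get_odorant,
    ln_oav,
    oi_from_lnoav,
)

__all__ = [
    "BinaryMixtureSample",
    "PanelDataset",
    "GeneratorConfig",
    "INTERACTION_STRATEGIES",
    "default_rho_max",
    "true_reduction_ratio",
    "true_mixture_oi",
    "generate_panel_dataset",
]

INTERACTION_STRATEGIES = ("ratio_kernel", "additive", "strongest_component")

#: Default peak reduction ratio per family: esters/aldehydes interact strongly,
#: aromatic hydrocarbons only weakly.
_FAMILY_RHO_MAX = {
    OdorFamily.ESTER: 0.35,
    OdorFamily.ALDEHYDE: 0.35,
    OdorFamily.AROMATIC: 0.15,
}


def default_rho_max(family: OdorFamily) -> float:
    """Default ground-truth peak reduction ratio for a chemical family."""
    return _FAMILY_RHO_MAX[OdorFamily(family)]


@dataclass(frozen=True)
class BinaryMixtureSample:
    """One observation of a binary mixture: two concentrations and an OI."""

    conc_a: float  # mg/m^3
    conc_b: float  # mg/m^3
    oi: float  # OIRS units
    source: str = "measured"  # "measured" | "predicted"

    def __post_init__(self) -> None:
        if not (self.conc_a > 0 and self.conc_b > 0):
            raise DomainError(
                f"mixture concentrations must be > 0 mg/m^3, got "
                f"({self.conc_a!r}, {self.conc_b!r})"
            )
        if self.source not in ("measured", "predicted"):
            raise ConfigurationError(f"unknown sample source {self.source!r}")


@dataclass
class PanelDataset:
    """A per-pair collection of binary-mixture samples.

    Both odorants must belong to the same chemical family (mixtures are
    studied within families, where a single OI-lnOAV law applies to each
    component).
    """

    odorant_a: Odorant
    odorant_b: Odorant
    samples: list[BinaryMixtureSample] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.odorant_a.family != self.odorant_b.family:
            raise DataError(
                f"odorants {self.odorant_a.abbreviation} and "
                f"{self.odorant_b.abbreviation} belong to different families "
                f"({self.odorant_a.family.value} vs {self.odorant_b.family.value})"
            )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.odorant_a.abbreviation, self.odorant_b.abbreviation)

    @property
    def conc_a(self) -> np.ndarray:
        return np.array([s.conc_a for s in self.samples], dtype=float)

    @property
    def conc_b(self) -> np.ndarray:
        return np.array([s.conc_b for s in self.samples], dtype=float)

    @property
    def oi(self) -> np.ndarray:
        return np.array([s.oi for s in self.samples], dtype=float)

    def lnoav_a(self) -> np.ndarray:
        return ln_oav(self.conc_a, self.odorant_a) if self.samples else np.array([])

    def lnoav_b(self) -> np.ndarray:
        return ln_oav(self.conc_b, self.odorant_b) if self.samples else np.array([])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "odorant_a": self.odorant_a.abbreviation,
                "odorant_b": self.odorant_b.abbreviation,
                "conc_a_mg_m3": self.conc_a,
                "conc_b_mg_m3": self.conc_b,
                "oi": self.oi,
                "source": [s.source for s in self.samples],
            }
        )

    def subset(self, indices, provenance: str | None = None) -> "PanelDataset":
        """New dataset holding the samples at ``indices`` (row order kept)."""
        return PanelDataset(
            self.odorant_a,
            self.odorant_b,
            [self.samples[i] for i in np.asarray(indices, dtype=int)],
            provenance if provenance is not None else self.provenance,
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic panel generator.

    Design points are drawn as (mixing ratio x_a, total stimulus
    T = lnOAV_a + lnOAV_b): x_a from the discrete ``x_levels``, T uniform on
    ``total_lnoav_range``.  Points whose additive intensity OI_sum falls
    below ``min_oi_sum`` (default 2.0 OIRS — the weak-stimulus exclusion
    level, where panel error dominates) are rejected and redrawn.  The panel
    reading is the ground-truth mixture OI plus N(0, noise_sigma) noise,
    clipped to ``oi_clip`` (the physical OIRS span).

    ``seed`` is mandatory; identical config => bit-identical dataset.
    """

    pair: tuple[str, str]
    seed: int
    rho_max: float = 0.35
    shape_p: float = 1.0
    noise_sigma: float = 0.3
    n_samples: int = 30
    x_levels: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    total_lnoav_range: tuple[float, float] = (3.0, 10.0)
    min_oi_sum: float = 2.0
    oi_clip: tuple[float, float] | None = (0.0, 8.0)
    interaction: str = "ratio_kernel"

    def __post_init__(self) -> None:
        if len(self.pair) != 2:
            raise ConfigurationError(f"pair must name two odorants, got {self.pair!r}")
        if not -1.0 < self.rho_max < 1.0:
            raise ConfigurationError(
                f"rho_max must lie in (-1, 1), got {self.rho_max!r}"
            )
        if not self.shape_p >= 0:
            raise ConfigurationError(f"shape_p must be >= 0, got {self.shape_p!r}")
        if not self.noise_sigma >= 0:
            raise ConfigurationError(
                f"noise_sigma must be >= 0, got {self.noise_sigma!r}"
            )
        if not self.n_samples >= 4:
            raise ConfigurationError(
                f"n_samples must be >= 4, got {self.n_samples!r}"
            )
        if not self.x_levels or not all(0 < x < 1 for x in self.x_levels):
            raise ConfigurationError(
                f"x_levels must be non-empty with values in (0, 1), got {self.x_levels!r}"
            )
        lo, hi = self.total_lnoav_range
        if not lo < hi:
            raise ConfigurationError(
                f"total_lnoav_range must satisfy low < high, got {self.total_lnoav_range!r}"
            )
        if self.oi_clip is not None and not self.oi_clip[0] < self.oi_clip[1]:
            raise ConfigurationError(f"invalid oi_clip {self.oi_clip!r}")
        if self.interaction not in INTERACTION_STRATEGIES:
            raise ConfigurationError(
                f"unknown interaction strategy {self.interaction!r}; "
                f"choose from {INTERACTION_STRATEGIES}"
            )

    @classmethod
    def for_pair(cls, abbrev_a: str, abbrev_b: str, seed: int, **overrides
                 ) -> "GeneratorConfig":
        """Config for a registry pair with the family-default rho_max."""
        od_a = get_odorant(abbrev_a)
        get_odorant(abbrev_b)  # validate early
        overrides.setdefault("rho_max", default_rho_max(od_a.family))
        return cls(pair=(abbrev_a, abbrev_b), seed=seed, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pair"] = list(self.pair)
        d["x_levels"] = list(self.x_levels)
        d["total_lnoav_range"] = list(self.total_lnoav_range)
        d["oi_clip"] = list(self.oi_clip) if self.oi_clip is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "seed" not in d or d["seed"] is None:
            raise ConfigurationError("serialized GeneratorConfig must carry a seed")
        d["pair"] = tuple(d["pair"])
        if "x_levels" in d:
            d["x_levels"] = tuple(d["x_levels"])
        if "total_lnoav_range" in d:
            d["total_lnoav_range"] = tuple(d["total_lnoav_range"])
        if d.get("oi_clip") is not None:
            d["oi_clip"] = tuple(d["oi_clip"])
        return cls(**d)

    def digest(self) -> str:
        """Short stable hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def true_reduction_ratio(x_a, rho_max: float, shape_p: float):
    """Ground-truth OI reduction ratio at mixing ratio ``x_a``.

    rho(x) = rho_max * (4 x (1-x))**shape_p: symmetric about 0.5, equal to
    rho_max at x = 0.5 and 0 at the pure components.  Negative rho_max
    models synergism.
    """
    if not -1.0 < rho_max < 1.0:
        raise ConfigurationError(f"rho_max must lie in (-1, 1), got {rho_max!r}")
    if not shape_p >= 0:
        raise ConfigurationError(f"shape_p must be >= 0, got {shape_p!r}")
    x = np.asarray(x_a, dtype=float)
    scalar = x.ndim == 0
    if np.any((x < 0) | (x > 1)):
        raise DomainError(f"mixing ratio must lie in [0, 1], got {x_a!r}")
    kernel = (4.0 * x * (1.0 - x)) ** shape_p
    out = rho_max * kernel
    return float(out) if scalar else out


def true_mixture_oi(lnoav_a, lnoav_b, family_a: OdorFamily, family_b: OdorFamily,
                    rho_max: float = 0.35, shape_p: float = 1.0,
                    interaction: str = "ratio_kernel"):
    """Ground-truth mixture intensity at a design point.

    Computes OI_sum from the two lnOAVs through the family laws and applies
    the chosen interaction strategy.  The mixing ratio is undefined when
    lnOAV_a + lnOAV_b <= 0.
    """
    la = np.asarray(lnoav_a, dtype=float)
    lb = np.asarray(lnoav_b, dtype=float)
    scalar = la.ndim == 0 and lb.ndim == 0
    total = la + lb
    if np.any(total <= 0):
        raise DomainError(
            "mixing ratio undefined: lnOAV_a + lnOAV_b must be > 0, got "
            f"{float(np.min(total))!r}"
        )
    oi_a = oi_from_lnoav(la, family_a)
    oi_b = oi_from_lnoav(lb, family_b)
    s = oi_a + oi_b
    if interaction == "additive":
        out = s
    elif interaction == "strongest_component":
        out = np.maximum(oi_a, oi_b)
    elif interaction == "ratio_kernel":
        x = la / total
        out = s * (1.0 - true_reduction_ratio(np.clip(x, 0.0, 1.0), rho_max, shape_p))
    else:
        raise ConfigurationError(f"unknown interaction strategy {interaction!r}")
    return float(out) if scalar else np.asarray(out)


def generate_panel_dataset(config: GeneratorConfig,
                           registry: dict[str, Odorant] | None = None
                           ) -> PanelDataset:
    """Draw a seeded synthetic panel dataset for one mixture pair.

    Design points violating the OI_sum >= min_oi_sum constraint are rejected
    and redrawn (up to 1000 * n_samples attempts).  Identical config (seed
    included) yields a bit-identical dataset.
    """
    if registry is None:
        od_a, od_b = get_odorant(config.pair[0]), get_odorant(config.pair[1])
    else:
        try:
            od_a, od_b = registry[config.pair[0]], registry[config.pair[1]]
        except KeyError as exc:
            raise ConfigurationError(f"unknown odorant abbreviation {exc.args[0]!r}")

    rng = np.random.default_rng(config.seed)
    lo, hi = config.total_lnoav_range
    samples: list[BinaryMixtureSample] = []
    max_draws = 1000 * config.n_samples
    draws = 0
    while len(samples) < config.n_samples and draws < max_draws:
        draws += 1
        x = float(rng.choice(config.x_levels))
        t = float(rng.uniform(lo, hi))
        la, lb = x * t, (1.0 - x) * t
        oi_sum_val = float(
            oi_from_lnoav(la, od_a.family) + oi_from_lnoav(lb, od_b.family)
        )
        if oi_sum_val < config.min_oi_sum:
            continue
        oi_true = true_mixture_oi(
            la, lb, od_a.family, od_b.family,
            rho_max=config.rho_max, shape_p=config.shape_p,
            interaction=config.interaction,
        )
        oi = oi_true + float(rng.normal(0.0, config.noise_sigma))
        if config.oi_clip is not None:
            oi = float(np.clip(oi, *config.oi_clip))
        samples.append(
            BinaryMixtureSample(
                conc_a=conc_from_lnoav(la, od_a),
                conc_b=conc_from_lnoav(lb, od_b),
                oi=oi,
                source="measured",
            )
        )
    if len(samples) < config.n_samples:
        raise ConfigurationError(
            f"design region empty: only {len(samples)}/{config.n_samples} samples "
            f"satisfy OI_sum >= {config.min_oi_sum} after {max_draws} draws"
        )
    return PanelDataset(od_a, od_b, samples, provenance=f"synthetic:{config.digest()}")
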