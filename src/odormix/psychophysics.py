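"""Psychophysics of single odorants: concentration, lnOAV and odor intensity.

The perceived intensity of a single odorant, expressed on the 1-butanol odor
intensity referencing scale (OIRS, levels 1-8), is well described by a linear
function of the natural logarithm of its odor activity value,

    lnOAV = ln(C / C_thr),        OI = slope * lnOAV + intercept,

where ``C`` is the gas-phase concentration (mg/m^3) and ``C_thr`` the panel
detection threshold of the substance.  The slope/intercept pair is specific to
the chemical family: esters (1.40, -2.70), aldehydes (1.76, -1.82) and
aromatic hydrocarbons (1.07, 0.00).  The laws are affine and unbounded here;
clipping to the physical OIRS range is a measurement-model decision that
belongs to the synthetic panel generator, not to the law itself.

The default odorant registry covers nine common odor pollutants (three per
family) with their detection thresholds in mg/m^3, shipped as a package data
file (``data/odorants.csv``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = [
    "OdorFamily",
    "PsychophysicalLaw",
    "Odorant",
    "DEFAULT_LAWS",
    "default_registry",
    "get_odorant",
    "ln_oav",
    "oi_from_lnoav",
    "lnoav_from_oi",
    "conc_from_lnoav",
]


class OdorFamily(str, enum.Enum):
    """Chemical family of an odorant; selects the OI-lnOAV law."""

    ESTER = "ester"
    ALDEHYDE = "aldehyde"
    AROMATIC = "aromatic"


@dataclass(frozen=True)
class PsychophysicalLaw:
    """Affine OI-lnOAV relationship for one chemical family.

    Parameters
    ----------
    family : OdorFamily
    slope : float
        OIRS units per lnOAV unit; must be positive (intensity grows with
        concentration).
    intercept : float
        OIRS units at lnOAV = 0, i.e. at the detection threshold.
    """

    family: OdorFamily
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ConfigurationError(
                f"psychophysical slope must be > 0, got {self.slope!r}"
            )


#: Family-specific OI-lnOAV coefficients.  The aromatic intercept is stored
#: explicitly as 0.0 so all three families share the same affine law type.
DEFAULT_LAWS: dict[OdorFamily, PsychophysicalLaw] = {
    OdorFamily.ESTER: PsychophysicalLaw(OdorFamily.ESTER, 1.40, -2.70),
    OdorFamily.ALDEHYDE: PsychophysicalLaw(OdorFamily.ALDEHYDE, 1.76, -1.82),
    OdorFamily.AROMATIC: PsychophysicalLaw(OdorFamily.AROMATIC, 1.07, 0.00),
}


@dataclass(frozen=True)
class Odorant:
    """A single odorous substance with its panel detection threshold.

    Notes
    -----
    CAS numbers are stored as opaque identifier strings and are not
    checksum-validated.  The registry lists 117-71-7 for n-heptaldehyde,
    as printed in the source table; the CAS commonly found in reference
    databases is 111-71-1 (heptanal).  The discrepancy is preserved rather
    than silently corrected.
    """

    abbreviation: str
    name: str
    cas: str
    family: OdorFamily
    threshold: float  # mg/m^3

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ConfigurationError(
                f"odor threshold must be > 0 mg/m^3, got {self.threshold!r} "
                f"for {self.abbreviation!r}"
            )


_REGISTRY_CACHE: dict[str, Odorant] | None = None


def default_registry() -> dict[str, Odorant]:
    """Load the nine-odorant default registry, keyed by abbreviation.

    The registry is read once from the packaged ``data/odorants.csv``
    (header ``abbreviation,name,cas,family,threshold_mg_m3``) and cached.
    """
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        with resources.files("odormix").joinpath("data/odorants.csv").open("r") as fh:
            table = pd.read_csv(fh, dtype={"cas": str})
        registry: dict[str, Odorant] = {}
        for row in table.itertuples(index=False):
            od = Odorant(
                abbreviation=row.abbreviation,
                name=row.name,
                cas=row.cas,
                family=OdorFamily(row.family),
                threshold=float(row.threshold_mg_m3),
            )
            if od.abbreviation in registry:
                raise ConfigurationError(
                    f"duplicate abbreviation {od.abbreviation!r} in registry"
                )
            registry[od.abbreviation] = od
        _REGISTRY_CACHE = registry
    return dict(_REGISTRY_CACHE)


def get_odorant(abbreviation: str) -> Odorant:
    """Look up one odorant in the default registry by abbreviation."""
    registry = default_registry()
    try:
        return registry[abbreviation]
    except KeyError:
        raise ConfigurationError(
            f"unknown odorant abbreviation {abbreviation!r}; "
            f"known: {sorted(registry)}"
        ) from None


def _law_for(family: OdorFamily,
             laws: dict[OdorFamily, PsychophysicalLaw] | None) -> PsychophysicalLaw:
    table = DEFAULT_LAWS if laws is None else laws
    try:
        return table[OdorFamily(family)]
    except (KeyError, ValueError):
        raise ConfigurationError(f"no psychophysical law registered for {family!r}")


def _maybe_scalar(values: np.ndarray, scalar: bool) -> float | np.ndarray:
    return float(values) if scalar else values


def ln_oav(concentration, odorant: Odorant):
    """Natural log of the odor activity value, ln(C / C_thr).

    Parameters
    ----------
    concentration : float or array-like
        Gas-phase concentration in mg/m^3; strictly positive.
    odorant : Odorant
        Supplies the detection threshold C_thr.

    Returns
    -------
    float or ndarray
        Dimensionless lnOAV; 0 exactly at the detection threshold and
        strictly increasing in concentration.
    """
    c = np.asarray(concentration, dtype=float)
    scalar = c.ndim == 0
    if np.any(~np.isfinite(c)) or np.any(c <= 0):
        bad = c if scalar else c[(~np.isfinite(c)) | (c <= 0)].ravel()[0]
        raise DomainError(
            f"concentration must be finite and > 0 mg/m^3, got {float(bad)!r}"
        )
    return _maybe_scalar(np.log(c / odorant.threshold), scalar)


def oi_from_lnoav(lnoav, family: OdorFamily,
                  laws: dict[OdorFamily, PsychophysicalLaw] | None = None):
    """Odor intensity (OIRS units) from lnOAV via the family's affine law.

    No clamping is applied: values below the law's root are negative and
    represent sub-threshold stimuli; downstream stages decide their fate.
    """
    law = _law_for(family, laws)
    x = np.asarray(lnoav, dtype=float)
    return _maybe_scalar(law.slope * x + law.intercept, x.ndim == 0)


def lnoav_from_oi(oi, family: OdorFamily,
                  laws: dict[OdorFamily, PsychophysicalLaw] | None = None):
    """Exact inverse of :func:`oi_from_lnoav`: (OI - intercept) / slope."""
    law = _law_for(family, laws)
    if law.slope == 0:
        raise ConfigurationError("psychophysical law with zero slope is not invertible")
    y = np.asarray(oi, dtype=float)
    return _maybe_scalar((y - law.intercept) / law.slope, y.ndim == 0)


def conc_from_lnoav(lnoav, odorant: Odorant):
    """Concentration in mg/m^3 from lnOAV: C_thr * exp(lnOAV).

    Exact inverse of :func:`ln_oav`.
    """
    x = np.asarray(lnoav, dtype=float)
    return _maybe_scalar(odorant.threshold * np.exp(x), x.ndim == 0)
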