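"""Per-animal consumption dosimetry.

Grams of gelatin eaten (cup mass pre - post), the THC dose that implies in
mg/kg, time-binned consumption rates around a fixed changepoint, and the
fraction of animals that refused the gelatin entirely.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError

#: small mass losses indistinguishable from drying are clamped to zero;
#: gains beyond this are a weighing error
EVAPORATION_TOLERANCE_G = 0.05

#: scale resolution; "did not consume" means grams <= this default
NONCONSUMER_THRESHOLD_G = 0.0

GELATIN_DENSITY_G_PER_ML = 1.0  # aqueous / Ensure gels


@dataclass(frozen=True)
class GelatinSpec:
    """Gelatin identity: formulation label, treatment, and THC
    concentration expressed as X mg THC per 15 ml gelatin."""

    label: str  # {"CTR", "E"}
    treatment: str  # {"VEH", "THC"}
    concentration: float  # mg THC / 15 ml

    def __post_init__(self) -> None:
        if self.label not in ("CTR", "E"):
            raise ConfigurationError(f"unknown gelatin label {self.label!r}")
        if self.treatment not in ("VEH", "THC"):
            raise ConfigurationError(f"unknown treatment {self.treatment!r}")
        if self.concentration < 0:
            raise ConfigurationError("concentration must be >= 0")
        if self.treatment == "VEH" and self.concentration != 0:
            raise ConfigurationError("vehicle gelatin must have concentration 0")


@dataclass(frozen=True)
class RatePair:
    """Early/late consumption rates (mg gelatin/min) around a changepoint."""

    early_rate: float
    late_rate: float
    percent_reduction: float  # NaN when undefined (early rate 0)
    undefined_reduction: bool = False


def grams_consumed(pre_mass: float, post_mass: float,
                   tolerance: float = EVAPORATION_TOLERANCE_G) -> float:
    """Gelatin eaten in grams, ``pre_mass - post_mass``.

    Apparent gains within ``tolerance`` (evaporation-scale noise) clamp to
    zero; larger gains are a data error (the cup cannot gain mass).
    """
    if pre_mass <= 0 or post_mass <= 0:
        raise DataError("cup masses must be > 0")
    diff = pre_mass - post_mass
    if diff < -tolerance:
        raise DataError(
            f"cup gained {-diff:.3f} g (> tolerance {tolerance} g): weighing error")
    return max(diff, 0.0)


def dose_mg_per_kg(grams: float, spec: GelatinSpec, body_mass_g: float) -> float:
    """THC dose consumed, in mg per kg body mass.

    With gelatin density 1 g/ml, ``grams`` of gelatin carry
    ``grams * concentration / 15`` mg THC.
    """
    if body_mass_g <= 0:
        raise DataError("body mass must be > 0")
    if grams < 0:
        raise DataError("grams consumed must be >= 0")
    ml = grams / GELATIN_DENSITY_G_PER_ML
    mg_thc = ml * spec.concentration / 15.0
    return mg_thc / (body_mass_g / 1000.0)


def piecewise_rates(minutes, cumulative_mg, changepoint: float = 40.0) -> RatePair:
    """Early and late consumption rates from a cumulative intake series.

    ``early_rate`` is the mean rate from 0 to ``changepoint``; ``late_rate``
    from ``changepoint`` to the end of the series (linear interpolation at
    the changepoint).  ``percent_reduction`` is 100*(r1-r2)/r1, flagged
    undefined (NaN) when the early rate is zero.
    """
    t = np.asarray(minutes, dtype=float)
    c = np.asarray(cumulative_mg, dtype=float)
    if t.shape != c.shape or t.size < 2:
        raise DataError("need aligned minute/cumulative arrays with >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise DataError("minute marks must be strictly increasing")
    if np.any(np.diff(c) < -1e-9):
        raise DataError("cumulative series must be nondecreasing")
    end = float(t[-1])
    if not t[0] <= changepoint < end or changepoint <= 0:
        raise DataError("changepoint must lie strictly inside the window")
    c0 = float(np.interp(0.0, t, c)) if t[0] > 0 else float(c[0])
    c_cp = float(np.interp(changepoint, t, c))
    r1 = (c_cp - c0) / changepoint
    r2 = (float(c[-1]) - c_cp) / (end - changepoint)
    if r1 > 0:
        return RatePair(r1, r2, 100.0 * (r1 - r2) / r1)
    return RatePair(r1, r2, math.nan, undefined_reduction=r2 > 0)


def nonconsumer_fraction(grams_list, threshold: float = NONCONSUMER_THRESHOLD_G) -> float:
    """Fraction of animals whose consumption is at or below ``threshold``
    grams (an unbroken gelatin surface at scale resolution)."""
    g = np.asarray(grams_list, dtype=float)
    if g.size == 0:
        raise DataError("empty consumption list")
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    return float(np.mean(g <= threshold))
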