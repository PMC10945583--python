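"""Cross-route dose equivalence: the inverse-prediction model.

An oral-consumption group's mean triad response is mapped onto the fitted
i.p. dose-response curve of the same assay to obtain the i.p. dose that
would produce it ("predicted i.p. dose"); the per-behavior predictions are
aggregated (mean +/- SEM across behaviors), compared between access
conditions as a fold ratio, propagated through the sex-specific 120 dB
startle quadratic, and validated against the measured startle response.
Equivalence is purely response-surface matching: no oral bioavailability
or pharmacokinetic conversion is attempted.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (DataError, DegenerateDesignError, NotConvergedError,
                     OutOfRangeError)
from .triad import DoseResponseFit
from .startle import StartlePolynomial
from . import stats

__all__ = ["invert_emax", "aggregate_predicted", "fold_ratio",
           "predict_startle", "validate_within_sem", "bootstrap_predicted_dose",
           "EquivalenceReport"]


def invert_emax(fit: DoseResponseFit, observed: float,
                allow_extrapolation: bool = False) -> float:
    """Dose (mg/kg) on the fitted Emax curve producing ``observed``.

    Closed form: d = ED50 * (observed - B) / (T - observed).  The observed
    response must lie between Bottom and Top (direction-aware); responses
    at or beyond the asymptote have no finite dose.  By default the
    predicted dose may not exceed the largest dose the curve was fitted
    on; ``allow_extrapolation`` relaxes that cap to twice the largest
    tested dose (the curve's upper reaches are an extrapolated asymptote
    when the response did not plateau).
    """
    if not fit.converged:
        raise NotConvergedError(f"fit for assay {fit.assay!r} is flagged")
    b, t, e = fit.bottom, fit.top, fit.ed50
    sign = 1.0 if t > b else -1.0
    effect = sign * (float(observed) - b)
    span = sign * (t - b)
    if effect < 0:
        raise OutOfRangeError(
            f"observed {observed} is outside the dynamic range "
            f"(beyond Bottom {b}) for assay {fit.assay!r}")
    if effect >= span:
        raise OutOfRangeError(
            f"observed {observed} is at or beyond the asymptote Top {t} "
            f"for assay {fit.assay!r}: no finite dose")
    dose = e * effect / (span - effect)
    if fit.max_dose is not None:
        cap = fit.max_dose * (2.0 if allow_extrapolation else 1.0)
        if dose > cap * (1 + 1e-12):
            raise OutOfRangeError(
                f"predicted dose {dose:.3g} mg/kg exceeds the "
                f"{'extrapolation cap' if allow_extrapolation else 'tested range'} "
                f"({cap:.3g} mg/kg) for assay {fit.assay!r}")
    return float(dose)


def aggregate_predicted(per_behavior_doses) -> tuple[float, float]:
    """Mean and SEM of the per-behavior predicted doses.

    The SEM is the across-behavior spread, sample SD / sqrt(k) over the
    k behaviors; with a single behavior it is not available (NaN).
    """
    d = np.asarray(per_behavior_doses, dtype=float)
    if d.size == 0:
        raise DataError("no predicted doses to aggregate")
    return float(d.mean()), stats.sem(d)


def fold_ratio(a: float, b: float) -> float:
    """Ratio a/b of two predicted doses (unitless)."""
    if b == 0:
        raise DataError("fold ratio undefined for zero reference dose")
    return float(a) / float(b)


def predict_startle(poly: StartlePolynomial, dose: float) -> float:
    """Startle V_max (cm/min) the polynomial predicts at ``dose`` mg/kg.

    Negative polynomial values are unphysical and floored at 0 with a
    warning.
    """
    if dose < 0:
        raise DataError("dose must be >= 0")
    v = poly.predict(float(dose))
    if v < 0:
        warnings.warn(
            f"predicted startle {v:.1f} cm/min at {dose} mg/kg is negative; "
            "floored at 0", stacklevel=2)
        return 0.0
    return float(v)


def validate_within_sem(predicted: float, measured_mean: float,
                        measured_sem: float) -> str:
    """Verdict on a prediction against a measured group response:
    ``within_sem`` iff |predicted - measured_mean| <= measured_sem."""
    if measured_sem < 0 or math.isnan(measured_sem):
        raise DataError("measured SEM must be a nonnegative number")
    return ("within_sem"
            if abs(predicted - measured_mean) <= measured_sem
            else "outside_sem")


def bootstrap_predicted_dose(doses, responses, observed, *, assay: str = "",
                             n_boot: int = 1000, seed: int = 0,
                             allow_extrapolation: bool = False):
    """Nonparametric bootstrap CI for a single behavior's predicted dose.

    Animals (dose, response pairs) are resampled with replacement, the
    Emax curve refitted, and the inversion repeated; returns the vector of
    bootstrap predicted doses (replicates whose refit fails or whose
    inversion leaves the dynamic range are dropped).  This per-behavior
    uncertainty is distinct from the across-behavior SEM reported by
    :func:`aggregate_predicted`.
    """
    from .triad import fit_emax

    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_boot):
        idx = rng.integers(0, d.size, d.size)
        try:
            fit = fit_emax(d[idx], y[idx], assay=assay)
            out.append(invert_emax(fit, observed,
                                   allow_extrapolation=allow_extrapolation))
        except (NotConvergedError, OutOfRangeError, DegenerateDesignError,
                DataError):
            continue
    return np.asarray(out)


@dataclass(frozen=True)
class EquivalenceReport:
    """Predicted i.p. equivalents for one oral-access condition."""

    condition: str
    per_behavior_dose: dict[str, float]  # assay -> mg/kg
    aggregate_mean: float  # mg/kg
    aggregate_sem: float  # mg/kg (NaN if a single behavior)
    predicted_startle: dict[str, float] = field(default_factory=dict)  # sex -> cm/min
    startle_verdict: dict[str, str] = field(default_factory=dict)  # sex -> verdict
    fold_vs: dict[str, float] = field(default_factory=dict)  # other condition -> ratio

    def display(self) -> dict:
        """Paper-precision rounding: doses and folds at 1 decimal,
        startle at integer cm/min."""
        return {
            "condition": self.condition,
            "per_behavior_dose": {k: round(v, 1)
                                  for k, v in self.per_behavior_dose.items()},
            "aggregate": f"{self.aggregate_mean:.1f} ± "
                         f"{self.aggregate_sem:.1f} mg/kg",
            "predicted_startle": {k: round(v)
                                  for k, v in self.predicted_startle.items()},
            "startle_verdict": dict(self.startle_verdict),
            "fold_vs": {k: round(v, 1) for k, v in self.fold_vs.items()},
        }
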