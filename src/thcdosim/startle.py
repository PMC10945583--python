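"""Acoustic startle analysis.

Group summaries of peak startle velocity (V_max, cm/min) across the
escalating tone series, and the second-order polynomial fitted to the
120 dB dose-response used for cross-route prediction.  Startle effects
are sex-dependent, so sexes are always fitted separately.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import STARTLE_TONES
from .errors import DataError, DegenerateDesignError
from . import stats

__all__ = ["startle_curve", "fit_startle_polynomial", "StartlePolynomial"]


@dataclass(frozen=True)
class StartlePolynomial:
    """V_max(dose) = a0 + a1*dose + a2*dose^2 at 120 dB, per sex."""

    sex: str
    a0: float  # cm/min
    a1: float  # cm/min per mg/kg
    a2: float  # cm/min per (mg/kg)^2
    rss: float

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        out = self.a0 + self.a1 * d + self.a2 * d * d
        return float(out) if out.ndim == 0 else out

    @property
    def vertex_dose(self) -> float:
        """Dose at the extremum (the inverted-U peak when a2 < 0)."""
        if self.a2 == 0:
            raise DataError("linear polynomial has no vertex")
        return -self.a1 / (2.0 * self.a2)


def startle_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM V_max per (sex, route, dose/access, tone).

    ``records`` follows the startle schema (columns sex, route,
    dose_mg_per_kg, access_hr, tone_db, vmax_cm_per_min).  Tones outside
    the fixed presentation set are rejected.
    """
    required = {"sex", "route", "dose_mg_per_kg", "access_hr",
                "tone_db", "vmax_cm_per_min"}
    missing = required - set(records.columns)
    if missing:
        raise DataError(f"startle table missing columns {sorted(missing)}")
    tones = records["tone_db"].astype(str)
    bad = set(tones) - set(STARTLE_TONES)
    if bad:
        raise DataError(f"unknown tone level(s) {sorted(bad)}")
    df = records.assign(tone_db=tones)
    grouped = df.groupby(["sex", "route", "dose_mg_per_kg", "access_hr", "tone_db"],
                         dropna=False)["vmax_cm_per_min"]
    out = grouped.agg(n="count", mean_vmax="mean",
                      sem_vmax=lambda v: stats.sem(v)).reset_index()
    return out


def fit_startle_polynomial(doses, vmax_means, sex: str) -> StartlePolynomial:
    """Least-squares quadratic through the 120 dB dose-response.

    Fitted to per-dose group means (vehicle included as dose 0); needs at
    least three distinct doses.  Three points give exact interpolation
    (RSS 0).
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(vmax_means, dtype=float)
    if d.shape != y.shape:
        raise DataError("doses and means must align")
    if np.unique(d).size < 3:
        raise DegenerateDesignError("need >= 3 distinct doses for a quadratic")
    X = np.column_stack([np.ones_like(d), d, d * d])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return StartlePolynomial(sex=sex, a0=float(coef[0]), a1=float(coef[1]),
                             a2=float(coef[2]), rss=float(resid @ resid))
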