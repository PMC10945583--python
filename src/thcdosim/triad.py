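"""Cannabimimetic triad analysis.

Difference scores (post - pre, or post - vehicle-post when no pre-test was
collected), three-parameter Emax dose-response fits with ED50 extraction,
and the consumption-vs-response linear regression used both for the main
dose-response relationship and for the CB1R-blockade (SR1) contrast.

The dose-response model is the Hill-slope-1 three-parameter form on a
linear dose axis,

    y(d) = B + (T - B) * d / (d + ED50),

which is defined at d = 0 (vehicle), with Bottom B the vehicle response
and Top T the asymptote.  Depressant effects (hypolocomotion, hypothermia)
are fitted on signed difference scores with T < B; no magnitude transform
is applied.  Responses that do not plateau within the tested dose range
are fitted anyway and flagged (``plateau_reached`` False when the largest
tested dose is below 2*ED50), so inversion treats T as an extrapolated
asymptote.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DataError, DegenerateDesignError, NotConvergedError
from . import stats

__all__ = ["difference_score", "fit_emax", "ed50", "predict",
           "consumption_response_regression", "DoseResponseFit"]


def difference_score(pre, post, mode: str = "post_pre",
                     veh_post_mean: float | None = None):
    """Gelatin/injection-dependent change in an assay value.

    ``post_pre`` is post - pre.  ``post_minus_veh`` substitutes the
    vehicle-group post-test mean for the missing pre-test (post - VEH).
    """
    if mode == "post_pre":
        return np.asarray(post, dtype=float) - np.asarray(pre, dtype=float) \
            if np.ndim(post) else float(post) - float(pre)
    if mode == "post_minus_veh":
        if veh_post_mean is None:
            raise DataError("post_minus_veh mode requires veh_post_mean")
        out = np.asarray(post, dtype=float) - float(veh_post_mean)
        return float(out) if out.ndim == 0 else out
    raise DataError(f"unknown difference-score mode {mode!r}")


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted Emax curve for one behavioral assay."""

    assay: str
    bottom: float
    top: float
    ed50: float
    rss: float
    covariance: np.ndarray | None  # 3x3 over (bottom, top, ed50); None if singular
    n_points: int
    converged: bool
    #: False when the largest tested dose < 2*ED50 (response did not
    #: approach its asymptote within the design)
    plateau_reached: bool = True
    max_dose: float | None = None

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        out = self.bottom + (self.top - self.bottom) * d / (d + self.ed50)
        return float(out) if out.ndim == 0 else out


def predict(fit: DoseResponseFit, dose):
    """Mean response of a fitted curve at ``dose`` (mg/kg)."""
    return fit.predict(dose)


def _linear_bt(doses, responses, ed50_val):
    """Profile out (B, T) for fixed ED50: the model is linear in them."""
    w = doses / (doses + ed50_val)
    X = np.column_stack([1.0 - w, w])
    coef, *_ = np.linalg.lstsq(X, responses, rcond=None)
    resid = responses - X @ coef
    return coef, float(resid @ resid)


def fit_emax(doses, responses, assay: str = "",
             n_grid: int = 60) -> DoseResponseFit:
    """Least-squares fit of the three-parameter Emax model.

    The ED50 is profiled on a log grid spanning [min positive dose / 10,
    max dose * 10] with (B, T) solved linearly at each grid point, then
    the best candidate is polished with a bounded trust-region refinement.
    Ties in residual sum of squares go to the smaller ED50.  A fit with an
    unidentifiable span (|T - B| indistinguishable from zero) or a
    non-converged refinement is returned flagged (``converged`` False) and
    refused by downstream operations.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape:
        raise DataError("doses and responses must align")
    if np.any(d < 0):
        raise DataError("doses must be >= 0")
    levels = np.unique(d)
    if levels.size < 3:
        raise DegenerateDesignError(
            f"need >= 3 distinct dose levels, got {levels.size}")
    if d.size < 4:
        raise DegenerateDesignError("need >= 4 points")

    pos = levels[levels > 0]
    lo, hi = pos.min() / 10.0, levels.max() * 10.0
    grid = np.geomspace(lo, hi, n_grid)
    rss_grid = np.empty(n_grid)
    for i, e in enumerate(grid):
        _, rss_grid[i] = _linear_bt(d, y, e)
    # best RSS; ties (within floating noise) to the smaller ED50
    best = int(np.argmin(np.where(rss_grid <= rss_grid.min() * (1 + 1e-12),
                                  rss_grid, np.inf)))
    (b0, t0), _ = _linear_bt(d, y, grid[best])

    def resid(theta):
        b, t, log_e = theta
        e = math.exp(log_e)
        return b + (t - b) * d / (d + e) - y

    sol = least_squares(resid, x0=[b0, t0, math.log(grid[best])],
                        method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    b, t, log_e = sol.x
    e = math.exp(log_e)
    rss = float(sol.fun @ sol.fun)

    scale = max(np.ptp(y), np.abs(y).max(), 1e-12)
    identifiable = abs(t - b) > 1e-6 * scale and lo / 2 < e < hi * 2
    converged = bool(sol.success) and identifiable

    cov = None
    if converged and d.size > 3:
        # delta-method back-transform of log(ED50) to ED50
        J = sol.jac.copy()
        J[:, 2] /= e  # d/d(ed50) = d/d(log ed50) / ed50
        JtJ = J.T @ J
        try:
            sigma2 = rss / (d.size - 3)
            cov = sigma2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            cov = None

    return DoseResponseFit(
        assay=assay, bottom=float(b), top=float(t), ed50=float(e), rss=rss,
        covariance=cov, n_points=int(d.size), converged=converged,
        plateau_reached=bool(levels.max() >= 2 * e),
        max_dose=float(levels.max()))


def ed50(fit: DoseResponseFit) -> float:
    """Median effective dose of a converged fit (mg/kg)."""
    if not fit.converged:
        raise NotConvergedError(
            f"fit for assay {fit.assay!r} is flagged; ED50 unavailable")
    return fit.ed50


def consumption_response_regression(consumed_doses, diffs) -> stats.RegressionResult:
    """OLS of individual difference scores on individually consumed dose
    (mg/kg), with the F test of zero slope.

    The same machinery serves the CB1R-blockade contrast, where a flat
    regression (no dose-response relationship) is the expected outcome.
    """
    return stats.linreg_ftest(consumed_doses, diffs)
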