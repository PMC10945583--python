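"""Summary statistics and tests reported by the pipeline.

Implemented directly from sums of squares (SEM, one-/two-way ANOVA with
optional subject blocking, Sidak adjustment, regression F test); the only
external numeric is the F-distribution tail probability from scipy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import ConfigurationError, DataError, DegenerateDesignError

__all__ = [
    "sem", "one_way_anova", "two_way_anova", "sidak_adjust", "linreg_ftest",
    "AnovaResult", "EffectTest", "RegressionResult", "format_p",
]

#: p-values below this are reported as "<1e-15" in display strings
_P_FLOOR = 1e-15


def format_p(p: float) -> str:
    """Prism-style display: thresholded at 0.001 and floored at 1e-15."""
    if p < _P_FLOOR:
        return "<1e-15"
    if p < 0.001:
        return "p<0.001"
    return f"p={p:.3f}"


def sem(values) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n).

    Returns NaN (not available) for a single observation.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DataError("sem of empty sample")
    if x.size == 1:
        return math.nan
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


@dataclass(frozen=True)
class EffectTest:
    name: str
    ss: float
    df_num: int
    df_den: int
    f: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    effects: tuple[EffectTest, ...]
    ss_residual: float
    df_residual: int
    ss_total: float

    def __getitem__(self, name: str) -> EffectTest:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def _f_test(ss_num, df_num, ss_den, df_den, name) -> EffectTest:
    if ss_num <= 0 or df_num == 0:
        # a literally-zero effect sum of squares: F = 0, p = 1
        return EffectTest(name, max(ss_num, 0.0), df_num, df_den, 0.0, 1.0)
    if ss_den <= 0 or df_den == 0:
        # zero error term with a nonzero effect: infinitely significant
        return EffectTest(name, ss_num, df_num, df_den, math.inf, 0.0)
    f = (ss_num / df_num) / (ss_den / df_den)
    p = float(_sps.f.sf(f, df_num, df_den))
    return EffectTest(name, ss_num, df_num, df_den, f, p)


def one_way_anova(groups) -> AnovaResult:
    """Fixed-effects one-way ANOVA from the between/within decomposition.

    ``groups`` is a sequence of samples (one per treatment level), each of
    size >= 2.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise DegenerateDesignError("one-way ANOVA needs >= 2 groups")
    if any(g.size < 2 for g in gs):
        raise DegenerateDesignError("every group needs n >= 2")
    allx = np.concatenate(gs)
    gm = allx.mean()
    ssb = sum(g.size * (g.mean() - gm) ** 2 for g in gs)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in gs)
    dfb = len(gs) - 1
    dfw = allx.size - len(gs)
    eff = _f_test(ssb, dfb, ssw, dfw, "group")
    return AnovaResult((eff,), ss_residual=ssw, df_residual=dfw,
                       ss_total=float(((allx - gm) ** 2).sum()))


def two_way_anova(values, factor_a, factor_b, subject=None) -> AnovaResult:
    """Balanced two-way ANOVA with interaction.

    ``values`` are observations with parallel level arrays ``factor_a``
    and ``factor_b``.  When ``subject`` is given the design is treated as
    repeated measures: subjects are nested in factor A (between) and
    crossed with factor B (within); A is tested against the
    subject-within-A mean square, B and A x B against the residual.
    The design must be complete and balanced.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.shape == fa.shape == fb.shape):
        raise DataError("values and factor arrays must align")
    a_levels = sorted(set(fa.tolist()))
    b_levels = sorted(set(fb.tolist()))
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise DegenerateDesignError("both factors need >= 2 levels")

    cells = {}
    for ai in a_levels:
        for bj in b_levels:
            cell = y[(fa == ai) & (fb == bj)]
            if cell.size == 0:
                raise DataError(f"incomplete design: empty cell ({ai!r}, {bj!r})")
            cells[ai, bj] = cell
    sizes = {c.size for c in cells.values()}
    if len(sizes) != 1:
        raise DataError("unbalanced design is out of scope")
    r = sizes.pop()

    gm = y.mean()
    ss_total = float(((y - gm) ** 2).sum())
    mean_a = {ai: y[fa == ai].mean() for ai in a_levels}
    mean_b = {bj: y[fb == bj].mean() for bj in b_levels}
    ss_a = r * b * sum((mean_a[ai] - gm) ** 2 for ai in a_levels)
    ss_b = r * a * sum((mean_b[bj] - gm) ** 2 for bj in b_levels)
    ss_ab = r * sum(
        (cells[ai, bj].mean() - mean_a[ai] - mean_b[bj] + gm) ** 2
        for ai in a_levels for bj in b_levels)

    if subject is None:
        if r < 2:
            raise DegenerateDesignError(
                "one observation per cell: no within-cell error term")
        ss_err = ss_total - ss_a - ss_b - ss_ab
        df_err = a * b * (r - 1)
        effects = (
            _f_test(ss_a, a - 1, ss_err, df_err, "A"),
            _f_test(ss_b, b - 1, ss_err, df_err, "B"),
            _f_test(ss_ab, (a - 1) * (b - 1), ss_err, df_err, "A:B"),
        )
        return AnovaResult(effects, ss_err, df_err, ss_total)

    # repeated measures: subject blocked, nested in A, crossed with B
    subj = np.asarray(subject)
    if subj.shape != y.shape:
        raise DataError("subject array must align with values")
    subj_ids = sorted(set(subj.tolist()))
    for sid in subj_ids:
        mask = subj == sid
        if len(set(fa[mask].tolist())) != 1:
            raise DataError(f"subject {sid!r} appears in multiple A levels")
        if sorted(fb[mask].tolist()) != b_levels:
            raise DataError(f"subject {sid!r} does not cover every B level once")
    n_s = len(subj_ids) // a
    if len(subj_ids) != a * n_s or n_s < 2:
        raise DataError("need an equal number (>= 2) of subjects per A level")

    ss_subj = b * sum(
        (y[subj == sid].mean() - mean_a[fa[subj == sid][0]]) ** 2
        for sid in subj_ids)
    df_subj = a * (n_s - 1)
    ss_err = ss_total - ss_a - ss_b - ss_ab - ss_subj
    df_err = a * (n_s - 1) * (b - 1)
    effects = (
        _f_test(ss_a, a - 1, ss_subj, df_subj, "A"),
        _f_test(ss_b, b - 1, ss_err, df_err, "B"),
        _f_test(ss_ab, (a - 1) * (b - 1), ss_err, df_err, "A:B"),
    )
    return AnovaResult(effects, ss_err, df_err, ss_total)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiplicity adjustment 1 - (1-p)^m, capped at 1."""
    if not 0 <= p <= 1:
        raise ConfigurationError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ConfigurationError(f"m must be >= 1, got {m}")
    # -expm1(m*log1p(-p)) is the numerically stable form for small p
    if p == 1.0:
        return 1.0
    return min(1.0, -math.expm1(m * math.log1p(-p)))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    f: float
    df: tuple[int, int]
    p: float
    r_squared: float
    n: int


def linreg_ftest(x, y) -> RegressionResult:
    """Simple OLS with the F test of zero slope (df 1, n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("x and y must align")
    n = x.size
    if n < 3:
        raise DegenerateDesignError("regression needs >= 3 points")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise DegenerateDesignError("constant predictor")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_reg = slope * sxy
    ss_res = max(ss_total - ss_reg, 0.0)
    r2 = 0.0 if ss_total == 0 else ss_reg / ss_total
    eff = _f_test(ss_reg, 1, ss_res, n - 2, "slope")
    return RegressionResult(slope, intercept, eff.f, (1, n - 2), eff.p, r2, n)
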