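"""Descriptive pharmacokinetic summaries.

Group-mean peaks (Cmax/Tmax), normalization to a reference collection
time, and the PK-behavior correlation check for concentration tables of
THC, 11-OH-THC and 11-COOH-THC in brain and plasma.  The reference 1 hr
samples come from a shorter access condition than the later time points;
normalization uses them anyway (the report carries a provenance note).
"""
from __future__ import annotations

import pandas as pd

from .errors import DataError
from . import stats

ANALYTES = ("THC", "11-OH-THC", "11-COOH-THC")
TISSUES = ("brain", "plasma")

#: carried into the report wherever 1 hr-normalized ratios appear
REFERENCE_PROVENANCE_NOTE = (
    "1 hr reference samples come from a reduced-access condition (1 hr "
    "total access) and are normalized against as collected")

_PK_COLS = {"animal_id", "tissue", "analyte", "time_hr", "conc_pmol_per_g"}


def _check(df: pd.DataFrame) -> pd.DataFrame:
    missing = _PK_COLS - set(df.columns)
    if missing:
        raise DataError(f"pk table missing columns {sorted(missing)}")
    if df.empty:
        raise DataError("empty pk table")
    if (df["conc_pmol_per_g"] < 0).any():
        raise DataError("concentrations must be >= 0")
    return df


def group_means(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM concentration per (tissue, analyte, time_hr)."""
    df = _check(df)
    out = (df.groupby(["tissue", "analyte", "time_hr"])["conc_pmol_per_g"]
             .agg(n="count", mean_conc="mean", sem_conc=lambda v: stats.sem(v))
             .reset_index())
    return out


def peak_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Cmax (pmol/g) and Tmax (hr) of the group-mean curve per
    tissue x analyte; ties go to the earliest time."""
    means = group_means(df).sort_values("time_hr", kind="stable")
    rows = []
    for (tissue, analyte), sub in means.groupby(["tissue", "analyte"]):
        i = sub["mean_conc"].to_numpy().argmax()
        rows.append({"tissue": tissue, "analyte": analyte,
                     "cmax_pmol_per_g": float(sub["mean_conc"].iloc[i]),
                     "tmax_hr": float(sub["time_hr"].iloc[i])})
    return pd.DataFrame(rows)


def normalize_to_reference(df: pd.DataFrame, reference_time: float = 1.0) -> pd.DataFrame:
    """Group-mean concentrations divided by the reference-time group mean
    of the same tissue x analyte (the reference time maps to 1.0)."""
    means = group_means(df)
    rows = []
    for (tissue, analyte), sub in means.groupby(["tissue", "analyte"]):
        ref = sub.loc[sub["time_hr"] == reference_time, "mean_conc"]
        if ref.empty:
            raise DataError(
                f"reference time {reference_time} hr absent for "
                f"({tissue}, {analyte})")
        ref_mean = float(ref.iloc[0])
        if ref_mean == 0:
            raise DataError(
                f"zero reference mean for ({tissue}, {analyte})")
        for _, r in sub.iterrows():
            rows.append({"tissue": tissue, "analyte": analyte,
                         "time_hr": float(r["time_hr"]),
                         "ratio_to_reference": float(r["mean_conc"]) / ref_mean})
    return pd.DataFrame(rows)


def correlate_pk_behavior(pk_values: pd.Series, triad_diffs: pd.Series) -> stats.RegressionResult:
    """Per-animal regression of a triad difference score on a PK
    concentration; both series must be indexed by animal id."""
    joined = pd.concat({"pk": pk_values, "diff": triad_diffs}, axis=1, join="inner")
    if len(joined) < len(pk_values) or len(joined) < len(triad_diffs):
        unmatched = set(pk_values.index).symmetric_difference(triad_diffs.index)
        raise DataError(f"unpaired animals: {sorted(map(str, unmatched))[:5]}")
    return stats.linreg_ftest(joined["pk"].to_numpy(), joined["diff"].to_numpy())
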