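"""Table schemas, validated IO, and the end-to-end pipeline.

All tables are comma-delimited UTF-8 CSV with fixed lower-snake headers;
times are minutes (consumption series) or hours (PK), doses mg/kg, masses
grams.  ``run_pipeline`` ties the stages together and emits a JSON report
with full-precision numbers plus display fields rounded to reporting
precision.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, consumption as cons, equivalence as eq
from . import pk as pkmod
from . import startle as st
from . import stats, triad as tri
from .config import TRIAD_ASSAYS, SimulationConfig
from .errors import ConfigurationError, DataError
from .simulate import generate_cohort

log = logging.getLogger("thcdosim")

SCHEMAS: dict[str, list[str]] = {
    "consumption": ["animal_id", "sex", "day", "condition", "gel_label", "treatment",
                    "conc_mg_per_15ml", "pre_mass_g", "post_mass_g",
                    "body_mass_g"],
    "timeseries": ["animal_id", "day", "treatment", "minute", "cumulative_mg"],
    "triad": ["animal_id", "sex", "route", "condition",
              "nominal_dose_or_conc", "consumed_mg_per_kg", "assay", "pre",
              "post"],
    "startle": ["animal_id", "sex", "route", "condition", "dose_mg_per_kg",
                "access_hr", "tone_db", "vmax_cm_per_min"],
    "pk": ["animal_id", "sex", "tissue", "analyte", "time_hr",
           "conc_pmol_per_g"],
}


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: either a simulation block or input CSV paths."""

    simulation: SimulationConfig | None = None
    input_paths: dict[str, str] | None = None
    changepoint_min: float = 40.0
    nonconsumer_threshold_g: float = cons.NONCONSUMER_THRESHOLD_G
    evaporation_tolerance_g: float = cons.EVAPORATION_TOLERANCE_G
    allow_extrapolation: bool = False
    bootstrap_reps: int = 0
    out_dir: str = "results"
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_paths is None):
            raise ConfigurationError(
                "exactly one of a simulation block or input paths is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "simulation" in d and d["simulation"] is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)


def _validate_rows(name: str, df: pd.DataFrame,
                   tolerance: float) -> list[str]:
    """Row-level invariant checks; returns human-readable error strings
    with 1-based data line numbers (header is line 1)."""
    errors = []
    if name == "consumption":
        for i, row in df.iterrows():
            line = i + 2
            if row.pre_mass_g <= 0 or row.post_mass_g <= 0:
                errors.append(f"line {line}: non-positive cup mass")
            elif row.post_mass_g - row.pre_mass_g > tolerance:
                errors.append(
                    f"line {line}: cup gained "
                    f"{row.post_mass_g - row.pre_mass_g:.3f} g (> tolerance)")
            if row.body_mass_g <= 0:
                errors.append(f"line {line}: non-positive body mass")
    elif name == "pk":
        bad = df.index[df["conc_pmol_per_g"] < 0]
        errors += [f"line {i + 2}: negative concentration" for i in bad]
    elif name == "timeseries":
        for aid, sub in df.groupby("animal_id"):
            if sub.sort_values("minute")["cumulative_mg"].diff().min() < -1e-9:
                errors.append(f"animal {aid}: cumulative series decreases")
    return errors


def read_tables(paths: dict[str, str],
                tolerance: float = cons.EVAPORATION_TOLERANCE_G) -> dict[str, pd.DataFrame]:
    """Read and validate cohort CSVs keyed by table name.

    Header mismatches are a hard error naming the offending columns;
    invariant violations are collected into a per-row error report.
    """
    out = {}
    for name, path in paths.items():
        if name not in SCHEMAS:
            raise ConfigurationError(f"unknown table {name!r}")
        if not Path(path).exists():
            raise DataError(f"{name} table not found: {path}")
        df = pd.read_csv(path)
        if name == "startle" and "tone_db" in df.columns:
            # "null" is the silent QC trial, not a missing value, and tone
            # labels are strings ("80" not 80.0)
            df["tone_db"] = [
                "null" if (isinstance(t, float) and math.isnan(t)) else
                str(int(t)) if isinstance(t, (int, float)) else str(t)
                for t in df["tone_db"]]
        missing = set(SCHEMAS[name]) - set(df.columns)
        if missing:
            raise DataError(
                f"{name} table {path}: missing columns {sorted(missing)}")
        if df.empty:
            log.warning("%s table %s is empty", name, path)
        row_errors = _validate_rows(name, df, tolerance)
        if row_errors:
            raise DataError(f"{name} table {path}: "
                            + "; ".join(row_errors[:20]))
        out[name] = df
    return out


def write_tables(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, str]:
    out = {}
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        path = d / f"{name}.csv"
        df.to_csv(path, index=False)
        out[name] = str(path)
    return out


# ---------------------------------------------------------------------------
# pipeline stages

def _round(x, nd):
    return None if x is None or (isinstance(x, float) and math.isnan(x)) \
        else round(float(x), nd)


def consumption_summary(df: pd.DataFrame, threshold: float,
                        tolerance: float) -> dict:
    rows = []
    grams_groups = []
    for (label, treatment, conc), sub in df.groupby(
            ["gel_label", "treatment", "conc_mg_per_15ml"]):
        spec = cons.GelatinSpec(label, treatment, conc)
        grams = np.array([cons.grams_consumed(r.pre_mass_g, r.post_mass_g,
                                              tolerance)
                          for r in sub.itertuples()])
        doses = np.array([cons.dose_mg_per_kg(g, spec, m)
                          for g, m in zip(grams, sub["body_mass_g"])])
        rows.append({
            "gel_label": label, "treatment": treatment,
            "conc_mg_per_15ml": conc, "n": int(len(sub)),
            "mean_grams": float(grams.mean()), "sem_grams": stats.sem(grams),
            "mean_dose_mg_per_kg": float(doses.mean()),
            "sem_dose_mg_per_kg": stats.sem(doses),
            "nonconsumer_fraction": cons.nonconsumer_fraction(grams, threshold),
        })
        if len(grams) >= 2:
            grams_groups.append(grams)
    summary = {"groups": rows}
    if len(grams_groups) >= 2:
        a = stats.one_way_anova(grams_groups)["group"]
        summary["grams_anova"] = {
            "f": a.f, "df": [a.df_num, a.df_den], "p": a.p,
            "display": f"F_{a.df_num},{a.df_den} = {a.f:.2f}, {stats.format_p(a.p)}"}
    return summary


def rate_summary(ts: pd.DataFrame, changepoint: float) -> dict:
    out = {}
    for treatment, sub in ts.groupby("treatment"):
        pairs = []
        for _, ser in sub.groupby("animal_id"):
            ser = ser.sort_values("minute")
            pairs.append(cons.piecewise_rates(ser["minute"].to_numpy(),
                                              ser["cumulative_mg"].to_numpy(),
                                              changepoint))
        r1 = float(np.mean([p.early_rate for p in pairs]))
        r2 = float(np.mean([p.late_rate for p in pairs]))
        reduction = 100.0 * (r1 - r2) / r1 if r1 > 0 else math.nan
        out[str(treatment)] = {
            "n": len(pairs), "early_rate_mg_per_min": r1,
            "late_rate_mg_per_min": r2, "percent_reduction": reduction,
            "changepoint_min": changepoint,
            "display": f"{r1:.1f} -> {r2:.1f} mg/min "
                       f"({reduction:.1f}% reduction)"}
    return out


def triad_stage(triad_df: pd.DataFrame) -> tuple[dict, dict]:
    """Fit the i.p. reference Emax curve per assay and regress oral
    responses on individually consumed dose; returns (report, fits)."""
    fits = {}
    report = {"fits": {}, "consumption_regression": {}}
    ip = triad_df[triad_df["route"] == "ip"]
    for assay in TRIAD_ASSAYS:
        sub = ip[ip["assay"] == assay]
        diffs = tri.difference_score(sub["pre"].to_numpy(), sub["post"].to_numpy())
        fit = tri.fit_emax(sub["nominal_dose_or_conc"].to_numpy(), diffs,
                           assay=assay)
        fits[assay] = fit
        report["fits"][assay] = {
            "bottom": fit.bottom, "top": fit.top, "ed50_mg_per_kg": fit.ed50,
            "rss": fit.rss, "n": fit.n_points, "converged": fit.converged,
            "plateau_reached": fit.plateau_reached,
            "display": {"ed50": _round(fit.ed50, 1)}}
    oral = triad_df[(triad_df["route"] != "ip")
                    & triad_df["consumed_mg_per_kg"].notna()]
    for assay in TRIAD_ASSAYS:
        sub = oral[oral["assay"] == assay]
        if sub["consumed_mg_per_kg"].nunique() < 3:
            continue
        diffs = tri.difference_score(sub["pre"].to_numpy(), sub["post"].to_numpy())
        reg = tri.consumption_response_regression(
            sub["consumed_mg_per_kg"].to_numpy(), diffs)
        report["consumption_regression"][assay] = {
            "slope": reg.slope, "intercept": reg.intercept, "f": reg.f,
            "df": list(reg.df), "p": reg.p, "r_squared": reg.r_squared,
            "display": f"F_{reg.df[0]},{reg.df[1]} = {reg.f:.2f}, "
                       f"{stats.format_p(reg.p)}"}
    return report, fits


def startle_stage(startle_df: pd.DataFrame) -> tuple[dict, dict]:
    """Tone curves plus the per-sex 120 dB quadratic on the i.p. arm."""
    curve = st.startle_curve(startle_df)
    polys = {}
    report = {"polynomials": {}}
    ip120 = curve[(curve["route"] == "ip") & (curve["tone_db"] == "120")]
    for sex, sub in ip120.groupby("sex"):
        if sub["dose_mg_per_kg"].nunique() < 3:
            continue
        poly = st.fit_startle_polynomial(sub["dose_mg_per_kg"].to_numpy(),
                                         sub["mean_vmax"].to_numpy(), sex)
        polys[sex] = poly
        report["polynomials"][sex] = {
            "a0": poly.a0, "a1": poly.a1, "a2": poly.a2, "rss": poly.rss}
    return report, polys


def equivalence_stage(triad_df, fits, polys, startle_df,
                      allow_extrapolation=False) -> dict:
    """Invert the i.p. curves at the oral group-mean responses, aggregate,
    and validate predicted startle against the measured oral startle."""
    report = {}
    oral = triad_df[triad_df["route"] != "ip"]
    per_condition_mean = {}
    for condition, sub in oral.groupby("condition"):
        per_behavior = {}
        for assay in TRIAD_ASSAYS:
            asub = sub[sub["assay"] == assay]
            if asub.empty or assay not in fits:
                continue
            mean_diff = float(tri.difference_score(
                asub["pre"].to_numpy(), asub["post"].to_numpy()).mean())
            try:
                per_behavior[assay] = eq.invert_emax(
                    fits[assay], mean_diff,
                    allow_extrapolation=allow_extrapolation)
            except (eq.OutOfRangeError, eq.NotConvergedError) as exc:
                # out of range / flagged fit: report, don't fail the run
                per_behavior[assay] = None
                log.warning("inversion failed for %s %s: %s",
                            condition, assay, exc)
        doses = [v for v in per_behavior.values() if v is not None]
        if not doses:
            continue
        mean, semv = eq.aggregate_predicted(doses)
        per_condition_mean[condition] = mean
        report[condition] = {
            "per_behavior_dose_mg_per_kg": per_behavior,
            "aggregate_mean_mg_per_kg": mean,
            "aggregate_sem_mg_per_kg": semv,
            "display": f"{mean:.1f} \u00b1 "
                       f"{(semv if not math.isnan(semv) else 0):.1f} mg/kg",
        }
    keys = sorted(per_condition_mean)
    folds = {}
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            if per_condition_mean[kb] > 0:
                folds[f"{ka}_vs_{kb}"] = eq.fold_ratio(
                    per_condition_mean[ka], per_condition_mean[kb])
    if folds:
        report["fold_ratios"] = {k: {"value": v, "display": round(v, 1)}
                                 for k, v in folds.items()}

    # propagate through the startle quadratic and validate against the
    # measured oral startle at 120 dB for the same condition
    if polys and startle_df is not None:
        oral120 = startle_df[(startle_df["route"] != "ip")
                             & (startle_df["tone_db"].astype(str) == "120")]
        validation = {}
        for condition, mean_dose in per_condition_mean.items():
            for sex, poly in polys.items():
                pred = eq.predict_startle(poly, mean_dose)
                entry = {"predicted_vmax_cm_per_min": pred,
                         "display": round(pred)}
                meas = oral120[(oral120["sex"] == sex)
                               & (oral120["condition"] == condition)]
                if not meas.empty:
                    v = meas["vmax_cm_per_min"].to_numpy()
                    m = float(v.mean())
                    s = stats.sem(v)
                    entry["measured_mean"] = m
                    entry["measured_sem"] = s
                    entry["verdict"] = eq.validate_within_sem(pred, m, s)
                validation[f"{condition}_{sex}"] = entry
        report["startle_validation"] = validation
    elif not polys:
        report["startle_validation"] = "absent"
    return report


def pk_stage(pk_df: pd.DataFrame) -> dict:
    peaks = pkmod.peak_summary(pk_df)
    ratios = pkmod.normalize_to_reference(pk_df, reference_time=1.0)
    return {
        "peaks": peaks.to_dict(orient="records"),
        "normalized_to_1hr": ratios.to_dict(orient="records"),
        "note": pkmod.REFERENCE_PROVENANCE_NOTE,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write ``report.json`` plus per-stage CSVs.

    Deterministic given the seed.  Missing optional tables (startle, pk,
    timeseries) downgrade their stages to an "absent" marker with a
    warning rather than failing the run.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        seed = config.seed if config.seed is not None else config.simulation.seed
        cohort = generate_cohort(config.simulation, seed)
        tables = cohort.tables()
        write_tables(tables, out_dir / "tables")
    else:
        seed = config.seed
        tables = read_tables(config.input_paths,
                             tolerance=config.evaporation_tolerance_g)

    report: dict = {"provenance": {
        "version": __version__, "seed": seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(_config_dict(config), sort_keys=True).encode()
        ).hexdigest(),
    }}

    stage = "consumption"
    try:
        if "consumption" in tables:
            report["consumption"] = consumption_summary(
                tables["consumption"], config.nonconsumer_threshold_g,
                config.evaporation_tolerance_g)
        if "timeseries" in tables:
            stage = "rates"
            report["rates"] = rate_summary(tables["timeseries"],
                                           config.changepoint_min)
        stage = "triad"
        fits = {}
        if "triad" in tables:
            report["triad"], fits = triad_stage(tables["triad"])
        stage = "startle"
        polys = {}
        if "startle" in tables:
            report["startle"], polys = startle_stage(tables["startle"])
        else:
            log.warning("startle table absent; validation will be skipped")
        stage = "equivalence"
        if fits:
            report["equivalence"] = equivalence_stage(
                tables.get("triad"), fits, polys, tables.get("startle"),
                allow_extrapolation=config.allow_extrapolation)
        stage = "pk"
        if "pk" in tables:
            report["pk"] = pk_stage(tables["pk"])
    except (DataError, ConfigurationError) as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc

    with open(out_dir / "report.json", "w") as fh:
        json.dump(_sanitize(report), fh, indent=2)
    return report


def _sanitize(o):
    """NaN -> null and numpy scalars -> native for strict-JSON output."""
    if isinstance(o, dict):
        return {k: _sanitize(v) for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_sanitize(v) for v in o]
    if isinstance(o, (np.floating, np.integer, np.bool_)):
        o = o.item()
    if isinstance(o, float) and math.isnan(o):
        return None
    return o


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulation is not None:
        d["simulation"] = config.simulation.to_dict()
    return d


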