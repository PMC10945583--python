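"""Synthetic cohort generation.

Draws animal-level data with the statistical structure the downstream
analyses assume: triad difference scores following Emax dose-response
curves with additive Gaussian noise, cumulative gelatin intake with a
piecewise-linear rate profile and a lognormal per-animal rate multiplier,
sex-specific quadratic 120 dB startle dose-responses with scaled-down
lower tones, and one-compartment oral-absorption pharmacokinetics with a
sequential metabolite chain.  The behavioral and PK streams are generated
independently (the analyses assume no pharmacodynamic linkage), and all
randomness flows from a single seed.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .config import (STARTLE_TONES, TRIAD_ASSAYS, ConsumptionProfile,
                     PkParams, SimulationConfig)
from .errors import ConfigurationError

__all__ = ["generate_cohort", "simulate_consumption", "simulate_startle",
           "simulate_pk", "CohortTables"]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _lognormal_mean_cv(rng, mean, cv, size=None):
    """Lognormal draws with the requested arithmetic mean and CV."""
    if mean == 0:
        return np.zeros(size) if size else 0.0
    if cv == 0:
        return np.full(size, float(mean)) if size else float(mean)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2), size)


def simulate_consumption(profile: ConsumptionProfile, bin_minutes: float,
                         seed=None) -> pd.DataFrame:
    """One animal's cumulative intake (mg) recorded every ``bin_minutes``.

    The series is the profile's piecewise-linear mean scaled by a single
    lognormal rate multiplier (mean 1, CV ``animal_rate_cv``), so it is
    nonnegative and nondecreasing and starts at 0.
    """
    if bin_minutes <= 0:
        raise ConfigurationError("bin width must be > 0")
    n_bins = profile.duration / bin_minutes
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ConfigurationError("bin width must divide the access duration")
    rng = _rng(seed)
    mult = float(_lognormal_mean_cv(rng, 1.0, profile.animal_rate_cv))
    minutes = np.arange(0, int(round(n_bins)) + 1) * bin_minutes
    cum = mult * profile.mean_cumulative(minutes)
    return pd.DataFrame({"minute": minutes, "cumulative_mg": cum})


def simulate_startle(dose: float, sex: str, params: dict, n: int,
                     seed=None, *, tone_scale=None, noise_sd: float = 150.0,
                     access_hr: float = float("nan"),
                     route: str = "ip") -> pd.DataFrame:
    """Startle records for ``n`` animals of one sex at one dose.

    The 120 dB mean follows the sex-specific quadratic a0 + a1*d + a2*d^2;
    lower tones are scaled-down versions of it; noise is additive Gaussian
    (scaled with the tone amplitude) and responses clip at 0.
    """
    if dose < 0:
        raise ConfigurationError("dose must be >= 0")
    if sex not in params:
        raise ConfigurationError(f"no startle parameters for sex {sex!r}")
    if tone_scale is None:
        tone_scale = SimulationConfig().tone_scale
    a0, a1, a2 = params[sex]
    mean120 = a0 + a1 * dose + a2 * dose * dose
    rng = _rng(seed)
    rows = []
    for i in range(n):
        for tone in STARTLE_TONES:
            s = tone_scale[tone]
            v = mean120 * s + rng.normal(0.0, noise_sd * s)
            rows.append({"animal_id": i, "sex": sex, "route": route,
                         "dose_mg_per_kg": dose, "access_hr": access_hr,
                         "tone_db": tone,
                         "vmax_cm_per_min": max(v, 0.0)})
    return pd.DataFrame(rows)


# state order: gut, THC, 11-OH-THC, 11-COOH-THC
def _pk_matrix(p: PkParams) -> np.ndarray:
    return np.array([
        [-p.ka, 0.0, 0.0, 0.0],
        [p.ka, -(p.ke_thc + p.k_form_oh), 0.0, 0.0],
        [0.0, p.k_form_oh, -(p.ke_oh + p.k_form_cooh), 0.0],
        [0.0, 0.0, p.k_form_cooh, -p.ke_cooh],
    ])


def simulate_pk(dose: float, times, params: PkParams | None = None) -> pd.DataFrame:
    """Noise-free concentration curves (pmol/g) per analyte and tissue.

    Linear first-order chain solved exactly with the matrix exponential;
    concentrations are zero at t = 0, rise to a single interior maximum,
    and metabolite peaks trail the parent peak.
    """
    if dose < 0:
        raise ConfigurationError("dose must be >= 0")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ConfigurationError("times must be >= 0")
    p = params or PkParams()
    A = _pk_matrix(p)
    x0 = np.array([dose, 0.0, 0.0, 0.0])
    amounts = np.stack([expm(A * ti) @ x0 for ti in np.atleast_1d(t)])
    mults = {"THC": 1.0, "11-OH-THC": p.oh_level_mult,
             "11-COOH-THC": p.cooh_level_mult}
    rows = []
    for j, (analyte, mult) in enumerate(mults.items(), start=1):
        brain = amounts[:, j] * p.brain_scale * mult
        for tissue, conc in (("brain", brain),
                             ("plasma", brain / p.brain_plasma_ratio)):
            for ti, ci in zip(np.atleast_1d(t), conc):
                rows.append({"analyte": analyte, "tissue": tissue,
                             "time_hr": float(ti),
                             "conc_pmol_per_g": float(ci)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortTables:
    """The generated cohort in the pipeline's CSV schemas."""

    consumption: pd.DataFrame
    timeseries: pd.DataFrame
    triad: pd.DataFrame
    startle: pd.DataFrame
    pk: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"consumption": self.consumption, "timeseries": self.timeseries,
                "triad": self.triad, "startle": self.startle, "pk": self.pk}


def _body_mass(rng, cfg: SimulationConfig, size: int) -> np.ndarray:
    """Normal body masses truncated (by redraw) at the lower bound."""
    m = rng.normal(cfg.body_mass_mean, cfg.body_mass_sd, size)
    while np.any(m < cfg.body_mass_min):
        bad = m < cfg.body_mass_min
        m[bad] = rng.normal(cfg.body_mass_mean, cfg.body_mass_sd, bad.sum())
    return m


def generate_cohort(config: SimulationConfig, seed=None) -> CohortTables:
    """Generate a full synthetic cohort.

    Deterministic given (config, seed); ``seed`` defaults to the config
    seed.  Animals are independent across tables (consumption-dose,
    rate-time-course, triad, startle and PK animals are separate groups,
    mirroring terminal or once-only assays).
    """
    rng = _rng(config.seed if seed is None else seed)
    ids = (f"A{i:05d}" for i in itertools.count(1))
    sexes = list(config.sexes)

    def draw_sexes(n):
        return [sexes[i % len(sexes)] for i in range(n)]

    # ---- consumption (total-mass dosimetry cohort) --------------------
    cons_rows = []
    for cond in config.oral_conditions:
        n = config.n_per_group
        mass = _body_mass(rng, config, n)
        for i, sex in enumerate(draw_sexes(n)):
            if cond.treatment == "THC" and cond.concentration > 0:
                dose = float(_lognormal_mean_cv(
                    rng, cond.mean_consumed_dose, config.consumed_dose_cv))
                grams = dose * (mass[i] / 1000.0) * 15.0 / cond.concentration
            else:
                grams = float(_lognormal_mean_cv(
                    rng, cond.mean_consumed_grams, config.consumed_dose_cv))
            pre = 4.0
            cons_rows.append({
                "animal_id": next(ids), "sex": sex, "day": 2,
                "condition": cond.label,
                "gel_label": cond.gel_label, "treatment": cond.treatment,
                "conc_mg_per_15ml": cond.concentration,
                "pre_mass_g": pre, "post_mass_g": pre - grams,
                "body_mass_g": mass[i]})
    consumption = pd.DataFrame(cons_rows)

    # ---- 10-min cumulative intake (rate cohort) -----------------------
    ts_rows = []
    for treatment, profile in config.consumption_profiles.items():
        for _ in range(config.n_per_group):
            aid = next(ids)
            ser = simulate_consumption(profile, 10.0, rng)
            ser.insert(0, "animal_id", aid)
            ser.insert(1, "day", 2)
            ser.insert(2, "treatment", treatment)
            ts_rows.append(ser)
    timeseries = pd.concat(ts_rows, ignore_index=True)

    # ---- triad ---------------------------------------------------------
    triad_rows = []

    def triad_group(route, nominal, effect_dose, n, consumed=None,
                    condition="ip"):
        group_sexes = draw_sexes(n)
        group_ids = [next(ids) for _ in range(n)]
        for assay in TRIAD_ASSAYS:
            base_mean, base_sd = config.baselines[assay]
            pre = rng.normal(base_mean, base_sd, n)
            diff = (config.assay_params[assay].response(effect_dose)
                    + rng.normal(0.0, config.noise_sd[assay], n))
            for k in range(n):
                triad_rows.append({
                    "animal_id": group_ids[k], "sex": group_sexes[k],
                    "route": route, "condition": condition,
                    "nominal_dose_or_conc": nominal,
                    "consumed_mg_per_kg": (np.nan if consumed is None
                                           else consumed[k]),
                    "assay": assay, "pre": pre[k], "post": pre[k] + diff[k]})

    for dose in config.ip_doses:
        triad_group("ip", dose, dose, config.n_per_group)
    for cond in config.oral_conditions:
        equiv = cond.equivalent_ip_dose or 0.0
        n = config.n_per_group
        consumed = _lognormal_mean_cv(rng, cond.mean_consumed_dose,
                                      config.consumed_dose_cv, n)
        consumed = np.atleast_1d(consumed)
        route = "e_gel" if cond.gel_label == "E" else "ctr_gel"
        triad_group(route, cond.concentration, equiv, n, consumed=consumed,
                    condition=cond.label)
    triad = pd.DataFrame(triad_rows)

    # ---- startle --------------------------------------------------------
    st_frames = []
    for sex in config.sexes:
        for dose in config.startle_ip_doses:
            df = simulate_startle(dose, sex, config.startle_params,
                                  config.n_per_group, rng,
                                  tone_scale=config.tone_scale,
                                  noise_sd=config.noise_sd["startle"])
            df["condition"] = "ip"
            df["animal_id"] = [next(ids) for _ in range(config.n_per_group)
                               for _ in STARTLE_TONES]
            st_frames.append(df)
        for cond in config.oral_conditions:
            if cond.treatment != "THC":
                continue
            equiv = cond.equivalent_ip_dose or 0.0
            df = simulate_startle(equiv, sex, config.startle_params,
                                  config.n_per_group, rng,
                                  tone_scale=config.tone_scale,
                                  noise_sd=config.noise_sd["startle"],
                                  access_hr=cond.access_hr, route="e_gel")
            df["condition"] = cond.label
            df["dose_mg_per_kg"] = np.nan  # oral route: dose is consumed, not injected
            df["animal_id"] = [next(ids) for _ in range(config.n_per_group)
                               for _ in STARTLE_TONES]
            st_frames.append(df)
    startle = pd.concat(st_frames, ignore_index=True)

    # ---- pharmacokinetics ----------------------------------------------
    pk_cond = next((c for c in config.oral_conditions
                    if c.treatment == "THC" and c.access_hr == 2.0), None)
    pk_dose = pk_cond.mean_consumed_dose if pk_cond else 0.0
    times = (1.0, 2.0, 2.5, 26.0)
    mean_curves = simulate_pk(pk_dose, times, config.pk_params)
    pk_rows = []
    for t in times:
        at_t = mean_curves[mean_curves["time_hr"] == t]
        for sex in draw_sexes(config.n_per_group):
            aid = next(ids)
            mult = float(_lognormal_mean_cv(rng, 1.0, config.pk_animal_cv))
            for _, r in at_t.iterrows():
                pk_rows.append({"animal_id": aid, "sex": sex,
                                "tissue": r["tissue"], "analyte": r["analyte"],
                                "time_hr": t,
                                "conc_pmol_per_g": r["conc_pmol_per_g"] * mult})
    pk = pd.DataFrame(pk_rows)

    return CohortTables(consumption=consumption, timeseries=timeseries,
                        triad=triad, startle=startle, pk=pk)
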