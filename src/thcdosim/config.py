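"""Simulation configuration for synthetic behavioral-pharmacology cohorts.

The generator emulates a voluntary oral THC consumption study in adult
C57BL/6J mice: mice eat a THC-containing gelatin (chocolate-Ensure "E-gel"
or sugar-water "CTR-gel") or receive THC i.p., and the cannabimimetic triad
(open-field locomotion, tail-flick analgesia, core temperature), acoustic
startle, 10-min cumulative consumption and brain/plasma pharmacokinetics
are recorded.

Default parameter values are the study conditions the analyses assume:
triad ED50s of 1.3 / 3.9 / 14.4 mg/kg i.p. for hypolocomotion, analgesia
and hypothermia; a consumption-rate changepoint at 40 min
(13.0 -> 4.2 mg gelatin/min for THC E-gel, 16.3 -> 9.9 for vehicle);
sex-specific inverted-U startle quadratics at 120 dB; and brain THC
peaking at ~550 pmol/g after consumption of the 10 mg/15 ml gel.
Dispersion parameters (noise SDs, rate CVs, body-mass spread) are
calibration choices, not reported values; see docs/methods.md.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError

TRIAD_ASSAYS = ("locomotion", "tail_flick", "temperature")
#: Tone labels in presentation order; "null" is a no-stimulus QC trial.
STARTLE_TONES = ("null", "80", "90", "100", "105", "110", "120")
SEXES = ("male", "female")


@dataclass(frozen=True)
class EmaxParams:
    """Three-parameter dose-response curve y = B + (T-B)*d/(d+ED50).

    ``bottom`` is the vehicle (d=0) response, ``top`` the asymptotic
    response (below ``bottom`` for depressant effects such as
    hypolocomotion or hypothermia) and ``ed50`` the dose in mg/kg giving
    the half-maximal effect.
    """

    bottom: float
    top: float
    ed50: float

    def __post_init__(self) -> None:
        if not self.ed50 > 0:
            raise ConfigurationError(f"ed50 must be > 0, got {self.ed50}")
        if self.bottom == self.top:
            raise ConfigurationError("bottom and top must differ")

    def response(self, dose):
        """Mean response at ``dose`` (mg/kg, scalar or array)."""
        import numpy as np

        d = np.asarray(dose, dtype=float)
        out = self.bottom + (self.top - self.bottom) * d / (d + self.ed50)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ConsumptionProfile:
    """Piecewise-linear mean intake: ``early_rate`` mg gelatin/min up to
    ``changepoint`` minutes, then ``late_rate`` until ``duration``.

    ``animal_rate_cv`` is the coefficient of variation of a per-animal
    lognormal rate multiplier (one draw per animal, scaling both rates),
    which keeps series nonnegative and nondecreasing.
    """

    early_rate: float
    late_rate: float
    changepoint: float = 40.0
    duration: float = 120.0
    onset_delay: float = 0.0
    animal_rate_cv: float = 0.25

    def __post_init__(self) -> None:
        if self.early_rate < 0 or self.late_rate < 0:
            raise ConfigurationError("rates must be >= 0")
        if not 0 < self.changepoint < self.duration:
            raise ConfigurationError("changepoint must lie strictly inside (0, duration)")
        if self.animal_rate_cv < 0 or self.onset_delay < 0:
            raise ConfigurationError("onset_delay and animal_rate_cv must be >= 0")

    def mean_cumulative(self, minute):
        """Noise-free cumulative intake (mg) at ``minute``."""
        import numpy as np

        t = np.maximum(np.asarray(minute, dtype=float) - self.onset_delay, 0.0)
        cp = self.changepoint - self.onset_delay
        early = self.early_rate * np.minimum(t, cp)
        late = self.late_rate * np.maximum(t - cp, 0.0)
        out = early + late
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PkParams:
    """One-compartment oral absorption with a sequential metabolite chain.

    gut --ka--> THC --k_form_oh--> 11-OH-THC --k_form_cooh--> 11-COOH-THC,
    with first-order elimination of each central species.  The chain is a
    calibration device that reproduces the observed concentration ranges
    and ordering of peaks (metabolite peaks at or after the parent peak);
    no kinetic model is fitted to data.

    ``brain_scale`` maps model amounts (mg/kg dose units) to brain
    concentrations in pmol/g for the parent; per-metabolite multipliers
    adjust the metabolite levels; ``brain_plasma_ratio`` is the brain:plasma
    partition applied uniformly.
    """

    ka: float = 1.5  # 1/hr
    ke_thc: float = 0.05  # 1/hr, non-metabolic clearance of THC
    k_form_oh: float = 0.10  # 1/hr, THC -> 11-OH-THC
    ke_oh: float = 0.70  # 1/hr
    k_form_cooh: float = 0.25  # 1/hr, 11-OH -> 11-COOH
    ke_cooh: float = 0.35  # 1/hr
    brain_scale: float = 24.3  # pmol/g per mg/kg (parent, at unit amount)
    # level multipliers lift the metabolites into their observed ranges
    # (extensive first-pass metabolism after oral dosing)
    oh_level_mult: float = 8.9
    cooh_level_mult: float = 17.5
    brain_plasma_ratio: float = 1.4

    def __post_init__(self) -> None:
        for name in ("ka", "ke_thc", "k_form_oh", "ke_oh", "k_form_cooh", "ke_cooh"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.brain_scale <= 0 or self.brain_plasma_ratio <= 0:
            raise ConfigurationError("scales must be > 0")


@dataclass(frozen=True)
class OralCondition:
    """One voluntary-access arm: gel identity, access window, and the
    calibrated group-level consumption / potency anchors."""

    label: str  # e.g. "e_gel_10_2hr"
    gel_label: str  # {"CTR", "E"}
    treatment: str  # {"VEH", "THC"}
    concentration: float  # mg THC per 15 ml gelatin
    access_hr: float
    mean_consumed_dose: float  # mg/kg group mean (THC) or n/a for VEH
    mean_consumed_grams: float  # g gelatin group mean
    equivalent_ip_dose: float | None = None  # mg/kg i.p. giving the same triad response


def _default_assay_params() -> dict[str, EmaxParams]:
    # ED50s 1.3 / 3.9 / 14.4 mg/kg; hypothermia Top chosen so the curve
    # passes through -5.84 degC at 30 mg/kg i.p.
    return {
        "locomotion": EmaxParams(bottom=0.0, top=-4000.0, ed50=1.3),
        "tail_flick": EmaxParams(bottom=0.0, top=6.0, ed50=3.9),
        "temperature": EmaxParams(bottom=0.0, top=-8.64, ed50=14.4),
    }


def _default_consumption_profiles() -> dict[str, ConsumptionProfile]:
    return {
        "THC": ConsumptionProfile(early_rate=13.0, late_rate=4.2),
        "VEH": ConsumptionProfile(early_rate=16.3, late_rate=9.9),
    }


def _default_startle_params() -> dict[str, tuple[float, float, float]]:
    # (a0, a1, a2) in cm/min, cm/min per mg/kg, cm/min per (mg/kg)^2 at
    # 120 dB.  Calibrated through the oral-equivalent anchor responses
    # 1733/558 cm/min (males) and 688/310 cm/min (females) at 3.7 and
    # 8.8 mg/kg, plus a small positive response at 10 mg/kg so the curve
    # stays physical over the tested range; males show an inverted U
    # (vertex ~2.5 mg/kg), females a monotone decline.
    return {
        "male": (1588.282, 152.4276, -30.6256),
        "female": (871.5375, -39.2982, -2.7856),
    }


def _default_oral_conditions() -> list[OralCondition]:
    return [
        OralCondition("e_gel_10_2hr", "E", "THC", 10.0, 2.0,
                      mean_consumed_dose=29.2, mean_consumed_grams=1.0,
                      equivalent_ip_dose=3.7),
        OralCondition("e_gel_10_1hr", "E", "THC", 10.0, 1.0,
                      mean_consumed_dose=20.0, mean_consumed_grams=0.7,
                      equivalent_ip_dose=8.8),
        OralCondition("veh_e_gel_2hr", "E", "VEH", 0.0, 2.0,
                      mean_consumed_dose=0.0, mean_consumed_grams=1.9),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Complete parameterization of the synthetic cohort generator."""

    n_per_group: int = 10
    sexes: tuple[str, ...] = SEXES
    ip_doses: tuple[float, ...] = (0.0, 0.1, 0.3, 1.0, 3.0, 5.0, 10.0, 30.0)
    #: startle arm uses a reduced i.p. design (startle is a once-only assay)
    startle_ip_doses: tuple[float, ...] = (0.0, 0.1, 1.0, 5.0, 10.0)
    gel_concentrations: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0)
    assay_params: dict[str, EmaxParams] = field(default_factory=_default_assay_params)
    consumption_profiles: dict[str, ConsumptionProfile] = field(
        default_factory=_default_consumption_profiles)
    startle_params: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_startle_params)
    pk_params: PkParams = field(default_factory=PkParams)
    oral_conditions: tuple[OralCondition, ...] = field(
        default_factory=lambda: tuple(_default_oral_conditions()))
    #: additive Gaussian SD on the difference-score scale, per assay
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "locomotion": 800.0, "tail_flick": 1.2, "temperature": 1.7,
        "startle": 150.0})
    #: pre-test baselines: assay -> (mean, SD)
    baselines: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "locomotion": (4000.0, 300.0), "tail_flick": (2.0, 0.3),
        "temperature": (37.0, 0.3)})
    #: relative V_max amplitude per tone (120 dB defines the scale)
    tone_scale: dict[str, float] = field(default_factory=lambda: {
        "null": 0.02, "80": 0.05, "90": 0.12, "100": 0.25,
        "105": 0.40, "110": 0.60, "120": 1.00})
    consumed_dose_cv: float = 0.30
    pk_animal_cv: float = 0.20
    body_mass_mean: float = 25.0  # g, adult C57BL/6J
    body_mass_sd: float = 2.0
    body_mass_min: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if not self.sexes:
            raise ConfigurationError("at least one sex required")
        for s in self.sexes:
            if s not in SEXES:
                raise ConfigurationError(f"unknown sex {s!r}")
            if s not in self.startle_params:
                raise ConfigurationError(f"missing startle params for sex {s!r}")
        if not self.ip_doses:
            raise ConfigurationError("at least one i.p. dose required")
        if any(d < 0 for d in self.ip_doses):
            raise ConfigurationError("doses must be >= 0")
        for assay in TRIAD_ASSAYS:
            if assay not in self.assay_params:
                raise ConfigurationError(f"missing Emax params for assay {assay!r}")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ConfigurationError("noise SDs must be >= 0")

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["assay_params"] = {k: dataclasses.asdict(v) for k, v in self.assay_params.items()}
        d["consumption_profiles"] = {
            k: dataclasses.asdict(v) for k, v in self.consumption_profiles.items()}
        d["pk_params"] = dataclasses.asdict(self.pk_params)
        d["oral_conditions"] = [dataclasses.asdict(c) for c in self.oral_conditions]
        d["startle_params"] = {k: list(v) for k, v in self.startle_params.items()}
        for key in ("sexes", "ip_doses", "startle_ip_doses", "gel_concentrations"):
            d[key] = list(d[key])
        d["baselines"] = {k: list(v) for k, v in self.baselines.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "assay_params" in d:
            d["assay_params"] = {k: EmaxParams(**v) for k, v in d["assay_params"].items()}
        if "consumption_profiles" in d:
            d["consumption_profiles"] = {
                k: ConsumptionProfile(**v) for k, v in d["consumption_profiles"].items()}
        if "pk_params" in d:
            d["pk_params"] = PkParams(**d["pk_params"])
        if "oral_conditions" in d:
            d["oral_conditions"] = tuple(OralCondition(**c) for c in d["oral_conditions"])
        if "startle_params" in d:
            d["startle_params"] = {k: tuple(v) for k, v in d["startle_params"].items()}
        for key in ("sexes", "ip_doses", "startle_ip_doses", "gel_concentrations"):
            if key in d:
                d[key] = tuple(d[key])
        if "baselines" in d:
            d["baselines"] = {k: tuple(v) for k, v in d["baselines"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
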