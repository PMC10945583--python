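"""Synthetic cohort generator: determinism, calibration anchors and
structural invariants."""
import numpy as np
import pytest

from thcdosim import (ConsumptionProfile, SimulationConfig,
                      generate_cohort, simulate_consumption, simulate_pk,
                      simulate_startle)
from thcdosim.config import TRIAD_ASSAYS
from thcdosim.errors import ConfigurationError


class TestDeterminism:
    def test_identical_seed_gives_identical_tables(self, small_config):
        t1 = generate_cohort(small_config, seed=11).tables()
        t2 = generate_cohort(small_config, seed=11).tables()
        for name in t1:
            assert t1[name].to_csv() == t2[name].to_csv()

    def test_different_seed_differs(self, small_config):
        a = generate_cohort(small_config, seed=1).triad
        b = generate_cohort(small_config, seed=2).triad
        assert not a["post"].equals(b["post"])


class TestConsumptionSimulation:
    def test_zero_rates_give_zero_series(self):
        prof = ConsumptionProfile(0.0, 0.0, animal_rate_cv=0.0)
        ser = simulate_consumption(prof, 10.0, seed=0)
        assert (ser["cumulative_mg"] == 0).all()

    def test_noiseless_piecewise_values(self):
        prof = ConsumptionProfile(13.0, 4.2, changepoint=40.0,
                                  duration=120.0, animal_rate_cv=0.0)
        ser = simulate_consumption(prof, 10.0, seed=0).set_index("minute")
        assert ser.loc[40, "cumulative_mg"] == pytest.approx(520.0)
        assert ser.loc[120, "cumulative_mg"] == pytest.approx(856.0)

    def test_series_nondecreasing_with_noise(self, rng):
        prof = ConsumptionProfile(13.0, 4.2, animal_rate_cv=0.4)
        for _ in range(20):
            ser = simulate_consumption(prof, 10.0, rng)
            assert (np.diff(ser["cumulative_mg"]) >= 0).all()
            assert ser["cumulative_mg"].iloc[0] == 0.0

    def test_bad_bin_rejected(self):
        prof = ConsumptionProfile(13.0, 4.2)
        with pytest.raises(ConfigurationError):
            simulate_consumption(prof, 0.0, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_consumption(prof, 7.0, seed=0)


class TestStartleSimulation:
    PARAMS = SimulationConfig().startle_params

    def test_flat_polynomial_gives_dose_independent_mean(self):
        flat = {"male": (500.0, 0.0, 0.0)}
        means = []
        for dose in (0.0, 2.0, 8.0):
            df = simulate_startle(dose, "male", flat, n=200, seed=3)
            means.append(df[df.tone_db == "120"]["vmax_cm_per_min"].mean())
        assert np.ptp(means) < 40.0

    def test_inverted_u_has_interior_maximum(self):
        doses = [0.1, 1.0, 5.0, 10.0]
        means = []
        for dose in doses:
            df = simulate_startle(dose, "male", self.PARAMS, n=4, seed=5,
                                  noise_sd=0.0)
            means.append(df[df.tone_db == "120"]["vmax_cm_per_min"].mean())
        peak = int(np.argmax(means))
        assert 0 < peak < len(doses) - 1

    def test_lower_tones_are_scaled_down(self):
        df = simulate_startle(1.0, "female", self.PARAMS, n=4, seed=6,
                              noise_sd=0.0)
        mean_by_tone = df.groupby("tone_db")["vmax_cm_per_min"].mean()
        assert mean_by_tone["80"] < mean_by_tone["110"] < mean_by_tone["120"]

    def test_unknown_sex_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_startle(1.0, "unknown", self.PARAMS, n=2, seed=0)


class TestPkSimulation:
    TIMES = np.array([0.0, 1.0, 2.0, 2.5, 26.0])

    def test_zero_dose_gives_zero_everywhere(self):
        df = simulate_pk(0.0, self.TIMES)
        assert (df["conc_pmol_per_g"] == 0).all()

    def test_zero_at_time_zero(self):
        df = simulate_pk(29.2, self.TIMES)
        assert (df[df.time_hr == 0.0]["conc_pmol_per_g"] == 0).all()

    def test_brain_thc_calibration_window(self):
        """Default calibration: brain THC in 500-600 pmol/g at the end of
        the 2 hr access, below 50 pmol/g 24 hr later."""
        df = simulate_pk(29.2, self.TIMES)
        brain = df[(df.analyte == "THC") & (df.tissue == "brain")]
        at2 = brain[brain.time_hr == 2.0]["conc_pmol_per_g"].iloc[0]
        at26 = brain[brain.time_hr == 26.0]["conc_pmol_per_g"].iloc[0]
        assert 500.0 <= at2 <= 600.0
        assert at26 < 50.0

    def test_single_interior_maximum_per_analyte(self):
        t = np.linspace(0, 30, 400)
        df = simulate_pk(29.2, t)
        for (analyte, tissue), sub in df.groupby(["analyte", "tissue"]):
            c = sub.sort_values("time_hr")["conc_pmol_per_g"].to_numpy()
            assert (c >= 0).all()
            peak = int(np.argmax(c))
            assert 0 < peak < c.size - 1
            assert (np.diff(c[:peak + 1]) >= -1e-9).all()
            assert (np.diff(c[peak:]) <= 1e-9).all()

    def test_metabolite_peaks_trail_parent(self):
        t = np.linspace(0, 30, 600)
        df = simulate_pk(29.2, t)
        brain = df[df.tissue == "brain"]
        tmax = {a: brain[brain.analyte == a].sort_values("time_hr")
                .pipe(lambda s: s["time_hr"].iloc[s["conc_pmol_per_g"].to_numpy().argmax()])
                for a in ("THC", "11-OH-THC", "11-COOH-THC")}
        assert tmax["THC"] <= tmax["11-OH-THC"] <= tmax["11-COOH-THC"]

    def test_negative_dose_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_pk(-1.0, [1.0])


class TestGenerateCohort:
    def test_noiseless_triad_scores_follow_emax_exactly(self, noiseless_config):
        cohort = generate_cohort(noiseless_config, seed=0)
        ip = cohort.triad[cohort.triad.route == "ip"]
        for assay in TRIAD_ASSAYS:
            params = noiseless_config.assay_params[assay]
            sub = ip[ip.assay == assay]
            diff = (sub["post"] - sub["pre"]).to_numpy()
            expected = params.response(sub["nominal_dose_or_conc"].to_numpy())
            assert diff == pytest.approx(expected, abs=1e-9)

    def test_group_mean_consumed_dose_anchor(self):
        """The 10 mg/15 ml gel with 2 hr access is calibrated to a mean
        consumed dose of 29.2 mg/kg."""
        cfg = SimulationConfig.from_dict({**SimulationConfig().to_dict(),
                                          "n_per_group": 100})
        cohort = generate_cohort(cfg, seed=123)
        df = cohort.consumption
        grp = df[df.condition == "e_gel_10_2hr"]
        grams = grp["pre_mass_g"] - grp["post_mass_g"]
        doses = grams * (10.0 / 15.0) / (grp["body_mass_g"] / 1000.0)
        semv = doses.std(ddof=1) / np.sqrt(len(doses))
        assert abs(doses.mean() - 29.2) < 2 * semv

    def test_empty_sexes_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig.from_dict({**SimulationConfig().to_dict(),
                                        "sexes": []})

    def test_tables_conform_to_schemas(self, small_config):
        from thcdosim.io import SCHEMAS
        tables = generate_cohort(small_config, seed=4).tables()
        for name, df in tables.items():
            assert set(SCHEMAS[name]) <= set(df.columns), name
            assert len(df) > 0
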