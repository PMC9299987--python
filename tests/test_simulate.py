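"""Integrator correctness: closed forms, oracle equivalence, invariants."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from oatimpact.model import (
    N_COMPARTMENTS,
    ON_OAT_MASK,
    IncarcerationStratum,
    hazard_factors,
    index_of,
    transition_matrix,
)
from oatimpact.simulate import (
    ConfigError,
    EntrySchedule,
    mean_episode_stats,
    person_years,
    run_model,
    summarize_for_calibration,
)


def test_zero_inputs_give_zero_output(inert_params):
    years = np.arange(2001, 2021)
    sched = EntrySchedule(
        years=years,
        entries=np.zeros(years.size),
        stratum_fracs=np.tile([1.0, 0, 0, 0], (years.size, 1)),
        initial_population=np.zeros(N_COMPARTMENTS),
    )
    out = run_model(inert_params, sched, t_end=2020.0)
    assert np.all(out.occupancy == 0.0)
    assert np.all(out.cum_od == 0.0) and np.all(out.cum_oth == 0.0)


def test_closed_compartment_exponential_survival(inert_params, off_rest_comm, single_mass_schedule):
    """Dead fraction in an isolated compartment is 1 - exp(-h T)."""
    p = inert_params.replace_flat({"mu_od_2001": 0.02, "mu_oth_2001": 0.03})
    sched = single_mass_schedule(off_rest_comm, amount=1000.0)
    out = run_model(p, sched, t_end=2011.0)
    T = 10.0
    h = 0.05
    dead_frac = out.total_deaths()[-1] / 1000.0
    assert dead_frac == pytest.approx(1.0 - math.exp(-h * T), abs=1e-9)
    # cause split proportional to cause-specific hazards
    assert out.total_deaths("od")[-1] / out.total_deaths()[-1] == pytest.approx(
        0.02 / 0.05, rel=1e-9
    )


def test_matrix_exponential_oracle(ref_params, nsw_schedule):
    """With constant hazards and no entries, RK4 matches expm to 1e-8."""
    p = ref_params.replace_flat({"slope_od": 0.0, "slope_oth": 0.0})
    pop = nsw_schedule.initial_population
    years = np.arange(2001, 2021)
    sched = EntrySchedule(
        years=years,
        entries=np.zeros(years.size),
        stratum_fracs=np.tile([1.0, 0, 0, 0], (years.size, 1)),
        initial_population=pop,
    )
    out = run_model(p, sched, t_end=2011.0)

    T = transition_matrix(p)
    f_od, f_oth = hazard_factors(p)
    haz = p.trend.mu_od_2001 * f_od + p.trend.mu_oth_2001 * f_oth
    A = T.T - np.diag(T.sum(axis=1) + haz)
    expected = expm(A * 10.0) @ pop
    scale = pop.sum()
    assert np.max(np.abs(out.occupancy[-1] - expected)) < 1e-8 * scale


def test_mass_conservation_default_run(ref_params, nsw_schedule):
    out = run_model(ref_params, nsw_schedule, t_end=2020.0)
    scale = out.initial_total + nsw_schedule.entries.sum()
    assert out.mass_balance_error() < 1e-8 * scale
    assert np.all(out.occupancy >= -1e-9 * scale)
    # cumulative deaths never decrease
    assert np.all(np.diff(out.total_deaths()) >= -1e-9)


def test_step_halving_robustness(ref_params, nsw_schedule):
    """Halving the integrator step moves cumulative deaths by < 0.1%."""
    coarse = run_model(ref_params, nsw_schedule, t_end=2020.0, steps_per_year=36)
    fine = run_model(ref_params, nsw_schedule, t_end=2020.0, steps_per_year=72)
    d0, d1 = coarse.total_deaths()[-1], fine.total_deaths()[-1]
    assert abs(d0 - d1) / d1 < 1e-3


def test_null_oat_effects_make_engagement_rates_irrelevant(ref_params, nsw_schedule):
    """With all RRs = 1 (and no cessation path), OAT churn cannot affect deaths."""
    neutral = {
        k: 1.0
        for k in ref_params.to_flat()
        if k.startswith("rr_") or k.startswith("prison_mort")
    }
    neutral.update({"cease_rate": 0.0, "relapse_rate": 0.0})
    p1 = ref_params.replace_flat(neutral)
    p2 = p1.replace_flat(
        {
            "discont_oat_m1_rapid": p1.rates.discont_oat_m1_stable,
            "discont_oat_m1_stable": p1.rates.discont_oat_m1_rapid,
            "discont_oat_9p_rapid": 0.31,
            "discont_oat_9p_stable": 2.2,
            "enrol_comm": 1.9,
            "enrol_prison": 0.2,
        }
    )
    out1 = run_model(p1, nsw_schedule, t_end=2016.0)
    out2 = run_model(p2, nsw_schedule, t_end=2016.0)
    assert out1.total_deaths()[-1] == pytest.approx(
        out2.total_deaths()[-1], rel=1e-9
    )
    assert out1.total_deaths("od")[-1] == pytest.approx(
        out2.total_deaths("od")[-1], rel=1e-9
    )


class TestPersonYears:
    def test_constant_occupancy(self, inert_params, off_rest_comm, single_mass_schedule):
        sched = single_mass_schedule(off_rest_comm, amount=100.0)
        out = run_model(inert_params, sched, t_end=2010.0)
        mask = np.zeros(N_COMPARTMENTS, dtype=bool)
        mask[index_of(off_rest_comm)] = True
        assert person_years(out, mask, (2003.0, 2004.0)) == pytest.approx(100.0)
        # predicate selector form
        assert person_years(
            out, lambda c: c == off_rest_comm, (2003.0, 2004.0)
        ) == pytest.approx(100.0)

    def test_additivity_over_windows_and_masks(self, ref_params, nsw_schedule):
        out = run_model(ref_params, nsw_schedule, t_end=2018.0)
        whole = person_years(out, ON_OAT_MASK, (2001.0, 2018.0))
        split = person_years(out, ON_OAT_MASK, (2001.0, 2009.0)) + person_years(
            out, ON_OAT_MASK, (2009.0, 2018.0)
        )
        assert whole == pytest.approx(split, rel=1e-12)
        by_parts = sum(
            person_years(
                out, lambda c, s=s: c.on_oat and c.incarceration is s, (2001.0, 2018.0)
            )
            for s in IncarcerationStratum
        )
        assert whole == pytest.approx(by_parts, rel=1e-12)

    def test_empty_window(self, ref_params, nsw_schedule):
        out = run_model(ref_params, nsw_schedule, t_end=2018.0)
        assert person_years(out, ON_OAT_MASK, (2005.0, 2005.0)) == 0.0


class TestCalibrationSummaries:
    def test_proportions_bounded(self, ref_params, nsw_schedule):
        out = run_model(ref_params, nsw_schedule, t_end=2018.0)
        s = summarize_for_calibration(out)
        props = s[s.series_name.str.startswith("prop_")]["value"]
        assert ((props >= 0) & (props <= 1)).all()

    def test_all_overdose_when_other_cause_off(self, ref_params, nsw_schedule):
        p = ref_params.replace_flat({"mu_oth_2001": 0.0, "slope_oth": 0.0})
        out = run_model(p, nsw_schedule, t_end=2018.0)
        s = summarize_for_calibration(out)
        prop_od = s[s.series_name == "prop_od_deaths"]["value"]
        assert np.allclose(prop_od, 1.0)

    def test_pastyear_definition(self, ref_params, nsw_schedule):
        """Past-year incarceration = prison + months 1-12 post-release."""
        out = run_model(ref_params, nsw_schedule, t_end=2018.0)
        s = summarize_for_calibration(out).set_index(["series_name", "year"])
        i = out.snapshot_index(2010.0)
        from oatimpact.model import STRATUM_MASK

        expected = (
            out.occupancy[
                i,
                STRATUM_MASK[IncarcerationStratum.PRISON]
                | STRATUM_MASK[IncarcerationStratum.REL_2_12],
            ].sum()
            / out.alive[i]
        )
        assert s.loc[("prop_pastyear", 2010), "value"] == pytest.approx(expected)

    def test_window_too_short_raises(self, ref_params, nsw_schedule):
        out = run_model(ref_params, nsw_schedule, t_end=2010.0)
        with pytest.raises(ValueError):
            summarize_for_calibration(out)


class TestScheduleValidation:
    def test_year_gap_rejected(self):
        with pytest.raises(ConfigError):
            EntrySchedule(
                years=np.array([2001, 2003]),
                entries=np.array([1.0, 1.0]),
                stratum_fracs=np.tile([1.0, 0, 0, 0], (2, 1)),
                initial_population=np.zeros(N_COMPARTMENTS),
            ).validate()

    def test_bad_stratum_fracs_rejected(self):
        with pytest.raises(ConfigError):
            EntrySchedule(
                years=np.array([2001]),
                entries=np.array([1.0]),
                stratum_fracs=np.array([[0.5, 0.1, 0.1, 0.1]]),
                initial_population=np.zeros(N_COMPARTMENTS),
            ).validate()

    def test_horizon_not_covered(self, ref_params):
        years = np.arange(2001, 2010)
        sched = EntrySchedule(
            years=years,
            entries=np.ones(years.size),
            stratum_fracs=np.tile([1.0, 0, 0, 0], (years.size, 1)),
            initial_population=np.zeros(N_COMPARTMENTS),
        )
        with pytest.raises(ConfigError):
            run_model(ref_params, sched, t_end=2020.0)


class TestEpisodeStats:
    def test_single_rate_episode_duration(self, inert_params):
        """Uniform discontinuation rate r with no death gives duration 1/r."""
        r = 0.5
        p = inert_params.replace_flat(
            {
                "exit_oat_m1": 12.0,
                "exit_oat_1_9": 1.5,
                "discont_oat_m1_rapid": r,
                "discont_oat_1_9_rapid": r,
                "discont_oat_9p_rapid": r,
                "discont_oat_m1_stable": r,
                "discont_oat_1_9_stable": r,
                "discont_oat_9p_stable": r,
            }
        )
        episodes, duration = mean_episode_stats(p)
        assert episodes == pytest.approx(1.0, abs=1e-9)
        assert duration == pytest.approx(1.0 / r, rel=1e-6)

    def test_absorbing_oat_flagged_infinite(self, inert_params):
        p = inert_params.replace_flat(
            {"exit_oat_m1": 12.0, "exit_oat_1_9": 1.5}
        )  # no discontinuation, no cessation, no death
        episodes, duration = mean_episode_stats(p)
        assert math.isinf(duration)

    def test_reference_duration_plausible(self, ref_params):
        """Flux-weighted episode duration sits near the observed ~1.7 years."""
        episodes, duration = mean_episode_stats(ref_params, horizon_years=13)
        assert 1.0 < duration < 2.5
        assert 2.5 < episodes < 6.0


def test_output_series_tidy_export(ref_params, nsw_schedule, tmp_path):
    out = run_model(ref_params, nsw_schedule, t_end=2018.0)
    df = out.to_tidy_frame()
    assert set(df.columns) == {
        "time",
        "use_stage",
        "engagement",
        "stratum",
        "occupancy",
        "cum_od_deaths",
        "cum_other_deaths",
    }
    assert len(df) == out.times.size * N_COMPARTMENTS
    path = tmp_path / "traj.csv"
    out.to_csv(path)
    assert path.exists()


def test_entry_schedule_csv_round_trip(nsw_schedule, tmp_path):
    path = tmp_path / "entries.csv"
    nsw_schedule.to_csv(path)
    back = EntrySchedule.from_csv(path)
    assert np.array_equal(back.years, nsw_schedule.years)
    assert np.allclose(back.entries, nsw_schedule.entries)
    assert np.allclose(back.initial_population, nsw_schedule.initial_population)
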