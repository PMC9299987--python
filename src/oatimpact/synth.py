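"""NSW-like synthetic cohort data for calibration and testing.

No public release of the linked OAT registry cohort exists, so this
module emulates its calibration series from the published aggregate
summaries: 49,359 people ever on OAT over 2001-18, a mean of 16,886 on
OAT at any one time (range 13,889-20,048), ~52% OAT coverage, 7.3%
currently incarcerated, 23.1% incarcerated in the past year, and 5,045
total / 1,508 overdose deaths over 2001-16.

The generator builds a front-loaded yearly entry schedule and an initial
2001 population, runs the forward model at a reference parameter set
(posterior-style relative risks plus structural rates chosen to
reproduce the aggregates above) and perturbs the resulting seven series
with truncated multiplicative observation noise.  Because the targets
come from the model itself at a known parameter set, the generator also
doubles as a ground-truth harness for calibration-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .calibrate import CalibrationTargets
from .model import (
    COMPARTMENTS,
    N_COMPARTMENTS,
    Compartment,
    EngagementClass,
    IncarcerationStratum,
    MortalityTrend,
    ParameterSet,
    RateSet,
    RelativeRisks,
    UseStage,
    index_of,
)
from .simulate import EntrySchedule, run_model, summarize_for_calibration

__all__ = [
    "SyntheticCohortConfig",
    "reference_parameters",
    "nsw_entry_schedule",
    "generate_targets",
    "generate_truth",
    "retention_curve",
]


@dataclass
class SyntheticCohortConfig:
    """Targets for the synthetic cohort, defaulting to the NSW summaries."""

    ever_oat: float = 49_359.0
    mean_oat_census: float = 16_886.0
    oat_census_range: tuple = (13_889.0, 20_048.0)
    coverage: float = 0.52
    pct_incarcerated: float = 0.073
    pct_pastyear_incarcerated: float = 0.231
    total_deaths_2001_16: float = 5_045.0
    od_deaths_2001_16: float = 1_508.0
    trend_form: str = "linear"
    noise: float = 0.02  # relative sd of multiplicative observation noise
    seed: int = 0
    # entry-schedule shape: initial cohort size and yearly geometric decay
    initial_population: float = 22_500.0
    entry_decay: float = 0.98
    initial_coverage: float = 0.63
    entry_stratum_fracs: tuple = (0.70, 0.12, 0.06, 0.12)

    def validate(self) -> None:
        if not 0 < self.coverage <= 1 or not 0 < self.initial_coverage <= 1:
            raise ValueError("OAT coverage must lie in (0, 1]")
        if self.pct_incarcerated + self.pct_pastyear_incarcerated > 1:
            raise ValueError("incarceration fractions exceed the cohort")
        for v in (
            self.ever_oat,
            self.mean_oat_census,
            self.total_deaths_2001_16,
            self.od_deaths_2001_16,
            self.initial_population,
        ):
            if v <= 0:
                raise ValueError("cohort summary targets must be positive")
        if self.od_deaths_2001_16 > self.total_deaths_2001_16:
            raise ValueError("overdose deaths cannot exceed total deaths")
        if self.initial_population >= self.ever_oat:
            raise ValueError("initial population must be below the ever-OAT total")
        if not 0 < self.entry_decay <= 1:
            raise ValueError("entry_decay must lie in (0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")


def reference_parameters() -> ParameterSet:
    """The NSW-like reference parameter set.

    Relative risks and 2001 mortality anchors sit at posterior-style
    values from the mortality literature; structural rates (engagement,
    incarceration, cessation) are chosen so the forward model reproduces
    the published cohort aggregates (coverage, census, incarceration
    fractions, death counts, episode statistics).
    """
    return ParameterSet(
        trend=MortalityTrend(
            mu_od_2001=0.003,
            mu_oth_2001=0.009,
            slope_od=0.00025,
            slope_oth=0.00005,
        ),
        rr=RelativeRisks(),
        rates=RateSet(),
        p_stable=0.5,
    )


def _episode_stage_occupancy(rates: RateSet, eng: EngagementClass) -> np.ndarray:
    """Relative time spent in the three on-OAT stages within one episode."""
    d1 = rates.discont(eng, UseStage.OAT_M1)
    d2 = rates.discont(eng, UseStage.OAT_1_9)
    d3 = rates.discont(eng, UseStage.OAT_9P)
    t1 = 1.0 / (rates.exit_oat_m1 + d1)
    p1 = rates.exit_oat_m1 * t1
    t2 = 1.0 / (rates.exit_oat_1_9 + d2)
    p2 = rates.exit_oat_1_9 * t2
    t3 = 1.0 / max(d3 + rates.cease_rate, 1e-9)
    occ = np.array([t1, p1 * t2, p1 * p2 * t3])
    return occ / occ.sum()


def _initial_population(cfg: SyntheticCohortConfig, p: ParameterSet) -> np.ndarray:
    """Initial 2001 occupancy consistent with the configured aggregates."""
    strata = {
        IncarcerationStratum.COMM: 1.0
        - cfg.pct_incarcerated
        - (cfg.pct_pastyear_incarcerated - cfg.pct_incarcerated)
        - 0.012,
        IncarcerationStratum.PRISON: cfg.pct_incarcerated,
        IncarcerationStratum.REL_M1: 0.012,
        IncarcerationStratum.REL_2_12: cfg.pct_pastyear_incarcerated
        - cfg.pct_incarcerated,
    }
    pop = np.zeros(N_COMPARTMENTS)
    off_m1_frac = 0.05  # share of off-OAT opioid users in their first month off
    no_use_frac = 0.02  # share of the cohort already in stable cessation
    for strat, s_frac in strata.items():
        n_strat = cfg.initial_population * s_frac
        pop[
            index_of(Compartment(UseStage.NO_USE, EngagementClass.STABLE, strat))
        ] += n_strat * no_use_frac
        using = n_strat * (1.0 - no_use_frac)
        on = using * cfg.initial_coverage
        off = using - on
        for eng, e_frac in (
            (EngagementClass.STABLE, p.p_stable),
            (EngagementClass.RAPID, 1.0 - p.p_stable),
        ):
            stage_occ = _episode_stage_occupancy(p.rates, eng)
            for stage, f in zip(
                (UseStage.OAT_M1, UseStage.OAT_1_9, UseStage.OAT_9P), stage_occ
            ):
                pop[index_of(Compartment(stage, eng, strat))] += on * e_frac * f
            pop[
                index_of(Compartment(UseStage.OFF_M1, eng, strat))
            ] += off * e_frac * off_m1_frac
            pop[
                index_of(Compartment(UseStage.OFF_REST, eng, strat))
            ] += off * e_frac * (1.0 - off_m1_frac)
    return pop


def nsw_entry_schedule(
    cfg: SyntheticCohortConfig | None = None,
    p: ParameterSet | None = None,
    calibrate_census: bool = True,
) -> EntrySchedule:
    """Yearly entry schedule shaped to reproduce the cohort aggregates.

    Entries run 2001-2017 with mild geometric decay (slightly larger
    early-year intake); 2018-2020 have zero intake so the impact window
    can be simulated without new entrants.  Because the model is linear
    in population mass, one forward run yields an exact multiplicative
    correction of the intake (entries plus initial population) so the
    mean on-OAT census matches ``cfg.mean_oat_census`` exactly
    (``calibrate_census=False`` skips the forward run and keeps the raw
    ever-OAT total).
    """
    cfg = cfg or SyntheticCohortConfig()
    cfg.validate()
    p = p or reference_parameters()
    years = np.arange(2001, 2021)
    entries = np.zeros(years.size)
    n_entry_years = 17  # 2001..2017
    weights = cfg.entry_decay ** np.arange(n_entry_years)
    total_entries = cfg.ever_oat - cfg.initial_population
    entries[:n_entry_years] = total_entries * weights / weights.sum()
    fracs = np.tile(np.asarray(cfg.entry_stratum_fracs, dtype=float), (years.size, 1))
    schedule = EntrySchedule(
        years=years,
        entries=entries,
        stratum_fracs=fracs,
        initial_population=_initial_population(cfg, p),
    )
    if calibrate_census:
        out = run_model(p, schedule, t_end=2018.0)
        frame = summarize_for_calibration(out)
        census = (
            frame[frame["series_name"].isin(["n_oat_prison", "n_oat_comm"])]
            .groupby("year")["value"]
            .sum()
        )
        scale = cfg.mean_oat_census / float(census.mean())
        schedule = EntrySchedule(
            years=years,
            entries=entries * scale,
            stratum_fracs=fracs,
            initial_population=schedule.initial_population * scale,
        )
    return schedule


def generate_targets(
    cfg: SyntheticCohortConfig | None = None,
) -> tuple[CalibrationTargets, EntrySchedule]:
    """Synthetic calibration targets plus the entry schedule that made them.

    Runs the forward model at the reference parameters over 2001-18,
    extracts the seven calibration series and applies truncated
    multiplicative Gaussian noise (seeded, reproducible).
    """
    cfg = cfg or SyntheticCohortConfig()
    cfg.validate()
    p = reference_parameters()
    if cfg.trend_form != "linear":
        p = p.replace_flat({"trend_form": cfg.trend_form, "exp_rate": 0.11})
    schedule = nsw_entry_schedule(cfg, p)
    targets = generate_truth(p, schedule, noise=cfg.noise, seed=cfg.seed)
    return targets, schedule


def generate_truth(
    p: ParameterSet,
    schedule: EntrySchedule,
    noise: float = 0.0,
    seed: int = 0,
) -> CalibrationTargets:
    """Forward-model calibration series with observation noise.

    With ``noise=0`` the returned targets are exactly the model's own
    summaries, so the calibration distance at ``p`` is zero -- the oracle
    for parameter-recovery tests.
    """
    out = run_model(p, schedule, t_end=2018.0)
    frame = summarize_for_calibration(out).copy()
    if noise > 0:
        rng = np.random.default_rng(seed)
        factors = 1.0 + noise * rng.standard_normal(len(frame))
        factors = np.clip(factors, 0.25, 4.0)
        frame["value"] = frame["value"] * factors
        is_prop = frame["series_name"].str.startswith("prop_")
        frame.loc[is_prop, "value"] = frame.loc[is_prop, "value"].clip(0.0, 1.0)
        frame["value"] = frame["value"].clip(lower=0.0)
    return CalibrationTargets(frame=frame)


def retention_curve(p_stable: float, discont: dict, t) -> np.ndarray:
    """Fraction still on OAT ``t`` years after initiation.

    ``discont`` maps engagement class name ("STABLE"/"RAPID") to the
    stage-specific discontinuation rates ``(d_m1, d_1_9, d_9p)``.  Each
    class's retention is the survival function of the three-stage
    phase-type chain (structural progression 12/yr then 1.5/yr, exit by
    discontinuation); the curve is the class mixture.  Used to translate
    medication-level retention data into class-specific rates and to
    check the implied mean episode duration.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    mix = {"STABLE": p_stable, "RAPID": 1.0 - p_stable}
    total = np.zeros_like(t)
    for cls, (d1, d2, d3) in discont.items():
        A = np.array(
            [
                [-(12.0 + d1), 0.0, 0.0],
                [12.0, -(1.5 + d2), 0.0],
                [0.0, 1.5, -d3],
            ]
        )
        surv = np.array(
            [expm(A * ti)[:, 0].sum() for ti in t]
        )  # start in stage 1
        total += mix[cls] * surv
    return total
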