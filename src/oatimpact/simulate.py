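"""Deterministic integration of the cohort model over calendar time.

The model is a linear, time-inhomogeneous ODE system over the 44
compartments, with yearly cohort entries treated as a constant inflow rate
within each calendar year and cause-specific death hazards that follow
calendar-time trends.  Alongside occupancy the integrator accumulates, per
compartment, cumulative overdose deaths, cumulative other-cause deaths and
person-years, so that every death is attributed to the compartment and
time of its occurrence.

Integration is classical fixed-step RK4 on the augmented state, with the
number of sub-steps chosen from the stiffest total outflow rate present
(scenario structures can inject rates of order 100/year).  Output is
recorded on a monthly grid; cohort snapshots used for calibration are the
1 January states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .model import (
    COMPARTMENTS,
    N_COMPARTMENTS,
    ON_OAT_MASK,
    STRATUM_MASK,
    Compartment,
    EngagementClass,
    IncarcerationStratum,
    ParameterSet,
    UseStage,
    hazard_factors,
    index_of,
    transition_matrix,
)

__all__ = [
    "EntrySchedule",
    "OutputSeries",
    "ConfigError",
    "SimulationError",
    "run_model",
    "person_years",
    "summarize_for_calibration",
    "mean_episode_stats",
    "CALIBRATION_SERIES",
]

STRATA_ORDER = (
    IncarcerationStratum.COMM,
    IncarcerationStratum.PRISON,
    IncarcerationStratum.REL_M1,
    IncarcerationStratum.REL_2_12,
)


class ConfigError(ValueError):
    """Invalid run configuration (e.g. a gap in the entry schedule)."""


class SimulationError(RuntimeError):
    """Numerical failure during integration, with diagnostics."""


@dataclass
class EntrySchedule:
    """Yearly cohort entries and the initial 2001 population.

    ``years`` are calendar years; ``entries[i]`` people enter during year
    ``years[i]``, spread uniformly through the year, all into the first
    month on OAT, split across incarceration strata by
    ``stratum_fracs[i]`` (order COMM, PRISON, REL_M1, REL_2_12) and across
    engagement classes by the run's ``p_stable``.
    ``initial_population`` is the occupancy vector on 1 January of the
    first year.
    """

    years: np.ndarray
    entries: np.ndarray
    stratum_fracs: np.ndarray  # shape (n_years, 4)
    initial_population: np.ndarray  # shape (44,)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.entries = np.asarray(self.entries, dtype=float)
        self.stratum_fracs = np.asarray(self.stratum_fracs, dtype=float)
        self.initial_population = np.asarray(self.initial_population, dtype=float)

    def validate(self) -> None:
        if self.years.size == 0:
            raise ConfigError("empty entry schedule")
        if np.any(np.diff(self.years) != 1):
            raise ConfigError("entry schedule years must be consecutive")
        if self.entries.shape != self.years.shape:
            raise ConfigError("entries and years must align")
        if self.stratum_fracs.shape != (self.years.size, 4):
            raise ConfigError("stratum_fracs must be (n_years, 4)")
        if np.any(self.entries < 0):
            raise ConfigError("entry counts must be non-negative")
        if np.any(self.stratum_fracs < 0) or not np.allclose(
            self.stratum_fracs.sum(axis=1), 1.0, atol=1e-8
        ):
            raise ConfigError("stratum fractions must be non-negative and sum to 1")
        if self.initial_population.shape != (N_COMPARTMENTS,):
            raise ConfigError("initial_population must have one value per compartment")
        if np.any(self.initial_population < 0):
            raise ConfigError("initial population must be non-negative")

    def covers(self, y0: int, y1: int) -> bool:
        return self.years[0] <= y0 and self.years[-1] >= y1 - 1

    def inflow_vector(
        self, year: int, p_stable: float, prison_entries_off_oat: bool = False
    ) -> np.ndarray:
        """Inflow rate vector (people per year) during calendar ``year``."""
        idx = np.searchsorted(self.years, year)
        if idx >= self.years.size or self.years[idx] != year:
            raise ConfigError(f"entry schedule does not cover year {year}")
        b = np.zeros(N_COMPARTMENTS)
        total = self.entries[idx]
        for s_i, strat in enumerate(STRATA_ORDER):
            amount = total * self.stratum_fracs[idx, s_i]
            if amount == 0.0:
                continue
            if prison_entries_off_oat and strat is IncarcerationStratum.PRISON:
                stage = UseStage.OFF_M1
            else:
                stage = UseStage.OAT_M1
            for eng, frac in (
                (EngagementClass.STABLE, p_stable),
                (EngagementClass.RAPID, 1.0 - p_stable),
            ):
                if frac:
                    b[index_of(Compartment(stage, eng, strat))] += amount * frac
        return b

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "entries": self.entries,
                "frac_comm": self.stratum_fracs[:, 0],
                "frac_prison": self.stratum_fracs[:, 1],
                "frac_rel_m1": self.stratum_fracs[:, 2],
                "frac_rel_2_12": self.stratum_fracs[:, 3],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
        init = pd.DataFrame(
            {
                "compartment": [c.label for c in COMPARTMENTS],
                "initial_population": self.initial_population,
            }
        )
        init.to_csv(str(path).replace(".csv", "_initial.csv"), index=False)

    @classmethod
    def from_csv(cls, path, initial_path=None) -> "EntrySchedule":
        df = pd.read_csv(path)
        if initial_path is None:
            initial_path = str(path).replace(".csv", "_initial.csv")
        init = pd.read_csv(initial_path)
        pop = np.zeros(N_COMPARTMENTS)
        from .model import compartment_from_label

        for _, row in init.iterrows():
            pop[index_of(compartment_from_label(row["compartment"]))] = row[
                "initial_population"
            ]
        return cls(
            years=df["year"].to_numpy(),
            entries=df["entries"].to_numpy(),
            stratum_fracs=df[
                ["frac_comm", "frac_prison", "frac_rel_m1", "frac_rel_2_12"]
            ].to_numpy(),
            initial_population=pop,
        )


@dataclass
class OutputSeries:
    """Monthly trajectories of one model run.

    All arrays share the leading time axis of ``times`` (calendar years on
    a monthly grid).  ``cum_od`` / ``cum_oth`` are cumulative deaths by
    compartment of occurrence; ``py`` is cumulative person-years per
    compartment; ``cum_entries`` is cumulative cohort inflow.
    """

    times: np.ndarray
    occupancy: np.ndarray  # (T, 44)
    cum_od: np.ndarray  # (T, 44)
    cum_oth: np.ndarray  # (T, 44)
    py: np.ndarray  # (T, 44)
    cum_entries: np.ndarray  # (T,)
    initial_total: float
    params: ParameterSet | None = None

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy.sum(axis=1)

    def total_deaths(self, cause: str = "total") -> np.ndarray:
        if cause == "od":
            return self.cum_od.sum(axis=1)
        if cause == "other":
            return self.cum_oth.sum(axis=1)
        return (self.cum_od + self.cum_oth).sum(axis=1)

    def mass_balance_error(self) -> float:
        lhs = self.initial_total + self.cum_entries
        rhs = self.alive + self.total_deaths()
        return float(np.max(np.abs(lhs - rhs)))

    def snapshot_index(self, t: float) -> int:
        i = int(round((t - self.times[0]) * 12))
        if not 0 <= i < self.times.size or abs(self.times[i] - t) > 1e-9:
            raise ValueError(f"time {t} not on the monthly output grid")
        return i

    def deaths_between(
        self, t0: float, t1: float, cause: str = "total", mask: np.ndarray | None = None
    ) -> float:
        i0, i1 = self.snapshot_index(t0), self.snapshot_index(t1)
        if cause == "od":
            cum = self.cum_od
        elif cause == "other":
            cum = self.cum_oth
        else:
            cum = self.cum_od + self.cum_oth
        if mask is not None:
            cum = cum[:, mask]
        return float(cum[i1].sum() - cum[i0].sum())

    def to_tidy_frame(self) -> pd.DataFrame:
        rows = []
        for j, c in enumerate(COMPARTMENTS):
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "use_stage": c.use_stage.value,
                        "engagement": c.engagement.value,
                        "stratum": c.incarceration.value,
                        "occupancy": self.occupancy[:, j],
                        "cum_od_deaths": self.cum_od[:, j],
                        "cum_other_deaths": self.cum_oth[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_tidy_frame().to_csv(path, index=False)


def _steps_per_year(p: ParameterSet, requested: int | None) -> int:
    """Sub-steps per year: multiple of 12, resolving the stiffest outflow."""
    T = transition_matrix(p)
    max_out = float(T.sum(axis=1).max())
    # RK4 stability needs h < ~2.78/rate; 1.1x the fastest outflow keeps a
    # comfortable margin while letting the caller trade accuracy for speed
    stability_floor = int(math.ceil(1.1 * max_out))
    needed = max(requested if requested is not None else 48, stability_floor, 12)
    return 12 * int(math.ceil(needed / 12))


def run_model(
    p: ParameterSet,
    schedule: EntrySchedule,
    t_end: float = 2020.0,
    scenario=None,
    steps_per_year: int | None = None,
    mass_tol: float = 1e-6,
) -> OutputSeries:
    """Integrate the model from the schedule's first year to ``t_end``.

    ``scenario`` may be a :class:`~oatimpact.scenarios.ScenarioSpec`; its
    parameter and rate overrides are applied to a copy of ``p`` and its
    entry-reassignment flag redirects prison entrants to the first month
    off OAT.  Deterministic given inputs.
    """
    prison_entries_off_oat = False
    if scenario is not None:
        p = scenario.apply(p)
        prison_entries_off_oat = bool(
            getattr(scenario, "prison_entries_off_oat", False)
        )
    p.validate()
    schedule.validate()
    t0 = float(schedule.years[0])
    if t_end <= t0:
        raise ConfigError(f"t_end={t_end} must exceed start year {t0}")
    n_years = int(round(t_end - t0))
    if abs(t_end - t0 - n_years) > 1e-9:
        raise ConfigError("t_end must be a whole number of years after start")
    if not schedule.covers(int(t0), int(t_end)):
        raise ConfigError(
            f"entry schedule ({schedule.years[0]}-{schedule.years[-1]}) does not "
            f"cover horizon [{t0}, {t_end}]"
        )

    spy = _steps_per_year(p, steps_per_year)
    sub = spy // 12  # sub-steps per month
    h = 1.0 / spy

    T = transition_matrix(p)
    TT = T.T - np.diag(T.sum(axis=1))  # inflows minus transition outflow
    f_od, f_oth = hazard_factors(p)
    trend = p.trend

    n_months = n_years * 12
    times = t0 + np.arange(n_months + 1) / 12.0
    occ = np.empty((n_months + 1, N_COMPARTMENTS))
    cum_od = np.empty_like(occ)
    cum_oth = np.empty_like(occ)
    py = np.empty_like(occ)
    cum_entries = np.empty(n_months + 1)

    n = schedule.initial_population.astype(float).copy()
    D_od = np.zeros(N_COMPARTMENTS)
    D_oth = np.zeros(N_COMPARTMENTS)
    PY = np.zeros(N_COMPARTMENTS)
    E = 0.0
    initial_total = float(n.sum())
    scale = max(1.0, initial_total + float(schedule.entries.sum()))

    occ[0], cum_od[0], cum_oth[0], py[0], cum_entries[0] = n, D_od, D_oth, PY, E

    def mu(t: float) -> tuple[float, float]:
        return trend.mu_od(t), trend.mu_oth(t)

    m = 0
    for year_i in range(n_years):
        year = int(t0) + year_i
        b = schedule.inflow_vector(year, p.p_stable, prison_entries_off_oat)
        b_total = float(b.sum())
        for month in range(12):
            t_month = t0 + year_i + month / 12.0
            for k in range(sub):
                t = t_month + k * h
                # RK4 on (n, D_od, D_oth, PY, E)
                m1od, m1ot = mu(t)
                m2od, m2ot = mu(t + 0.5 * h)
                m4od, m4ot = mu(t + h)

                def f(nv, mod, mot):
                    haz = mod * f_od + mot * f_oth
                    return TT @ nv - haz * nv + b

                k1 = f(n, m1od, m1ot)
                k2 = f(n + 0.5 * h * k1, m2od, m2ot)
                k3 = f(n + 0.5 * h * k2, m2od, m2ot)
                k4 = f(n + h * k3, m4od, m4ot)
                # death/person-year accumulators use the same RK4 stages
                for acc, fac, mods in (
                    (D_od, f_od, (m1od, m2od, m4od)),
                    (D_oth, f_oth, (m1ot, m2ot, m4ot)),
                ):
                    g1 = mods[0] * fac * n
                    g2 = mods[1] * fac * (n + 0.5 * h * k1)
                    g3 = mods[1] * fac * (n + 0.5 * h * k2)
                    g4 = mods[2] * fac * (n + h * k3)
                    acc += (h / 6.0) * (g1 + 2 * g2 + 2 * g3 + g4)
                PY += (h / 6.0) * (
                    n
                    + 2 * (n + 0.5 * h * k1)
                    + 2 * (n + 0.5 * h * k2)
                    + (n + h * k3)
                )
                n = n + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                E += h * b_total
            m += 1
            if not np.all(np.isfinite(n)):
                raise SimulationError(
                    f"non-finite occupancy at t={times[m]:.3f}; "
                    "check parameter magnitudes"
                )
            if n.min() < -1e-6 * scale:
                raise SimulationError(
                    f"negative occupancy {n.min():.3e} at t={times[m]:.3f}"
                )
            occ[m], cum_od[m], cum_oth[m], py[m], cum_entries[m] = (
                n,
                D_od.copy(),
                D_oth.copy(),
                PY.copy(),
                E,
            )

    out = OutputSeries(
        times=times,
        occupancy=occ,
        cum_od=cum_od,
        cum_oth=cum_oth,
        py=py,
        cum_entries=cum_entries,
        initial_total=initial_total,
        params=p,
    )
    err = out.mass_balance_error()
    if err > mass_tol * scale:
        raise SimulationError(
            f"mass balance violated: max error {err:.3e} vs tolerance "
            f"{mass_tol * scale:.3e}"
        )
    return out


def _as_mask(selector) -> np.ndarray:
    if isinstance(selector, np.ndarray):
        return selector.astype(bool)
    return np.array([bool(selector(c)) for c in COMPARTMENTS])


def person_years(o: OutputSeries, selector, window: tuple[float, float]) -> float:
    """Person-years in the selected compartments over ``[t0, t1]``.

    ``selector`` is either a boolean mask over compartments or a predicate
    ``Compartment -> bool``.  Additive over disjoint selectors and
    windows; an empty window yields 0.
    """
    t0, t1 = window
    if t1 <= t0:
        return 0.0
    mask = _as_mask(selector)
    series = o.py[:, mask].sum(axis=1)
    v0 = float(np.interp(t0, o.times, series))
    v1 = float(np.interp(t1, o.times, series))
    return v1 - v0


# The seven calibration series (the on-OAT census is split into its prison
# and community components, so eight named rows in the tidy layout).
CALIBRATION_SERIES = (
    "cohort_alive",
    "deaths",
    "prop_od_deaths",
    "prop_od_on_oat",
    "n_oat_prison",
    "n_oat_comm",
    "prop_incarc",
    "prop_pastyear",
)

_SERIES_LAST_YEAR = {
    "cohort_alive": 2018,
    "deaths": 2017,
    "prop_od_deaths": 2016,
    "prop_od_on_oat": 2016,
    "n_oat_prison": 2018,
    "n_oat_comm": 2018,
    "prop_incarc": 2018,
    "prop_pastyear": 2018,
}

_PRISON_OAT_MASK = ON_OAT_MASK & STRATUM_MASK[IncarcerationStratum.PRISON]
_COMM_OAT_MASK = ON_OAT_MASK & ~STRATUM_MASK[IncarcerationStratum.PRISON]
_PASTYEAR_MASK = (
    STRATUM_MASK[IncarcerationStratum.PRISON]
    | STRATUM_MASK[IncarcerationStratum.REL_2_12]
)


def summarize_for_calibration(o: OutputSeries) -> pd.DataFrame:
    """Annual summaries matching the calibration targets.

    Returns a tidy frame (series_name, year, value) with, per year:
    cohort size alive on 1 January; annual deaths; proportion of deaths
    from overdose; proportion of overdose deaths occurring on OAT; numbers
    on OAT in and out of prison on 1 January; proportion currently
    incarcerated; and proportion incarcerated in the past year excluding
    those released under one month ago (prison + months 1-12 post-release).
    """
    y0 = int(round(o.times[0]))
    y_last = int(round(o.times[-1]))
    if y_last < 2018:
        raise ValueError(
            f"output ends {y_last}; calibration summaries need the run to "
            "reach 1 January 2018"
        )
    rows = []
    for name in CALIBRATION_SERIES:
        for year in range(y0, _SERIES_LAST_YEAR[name] + 1):
            i = o.snapshot_index(float(year))
            if name == "cohort_alive":
                v = o.alive[i]
            elif name == "deaths":
                v = o.deaths_between(year, year + 1.0)
            elif name == "prop_od_deaths":
                tot = o.deaths_between(year, year + 1.0)
                v = o.deaths_between(year, year + 1.0, "od") / tot if tot > 0 else 0.0
            elif name == "prop_od_on_oat":
                od = o.deaths_between(year, year + 1.0, "od")
                on = o.deaths_between(year, year + 1.0, "od", ON_OAT_MASK)
                v = on / od if od > 0 else 0.0
            elif name == "n_oat_prison":
                v = o.occupancy[i, _PRISON_OAT_MASK].sum()
            elif name == "n_oat_comm":
                v = o.occupancy[i, _COMM_OAT_MASK].sum()
            elif name == "prop_incarc":
                v = (
                    o.occupancy[i, STRATUM_MASK[IncarcerationStratum.PRISON]].sum()
                    / o.alive[i]
                )
            else:  # prop_pastyear
                v = o.occupancy[i, _PASTYEAR_MASK].sum() / o.alive[i]
            rows.append((name, year, float(v)))
    return pd.DataFrame(rows, columns=["series_name", "year", "value"])


def mean_episode_stats(
    p: ParameterSet, ref_year: float = 2010.0, horizon_years: int = 400
) -> tuple[float, float]:
    """Expected OAT episodes per person and mean episode duration (years).

    Computed by propagating one entry cohort (unit mass entering the first
    month on OAT in the community) through the model with hazards frozen
    at ``ref_year``, accumulating on-OAT person-years and the re-enrolment
    flux exactly via the matrix exponential of an augmented generator.
    Episodes = 1 + expected re-enrolments; duration = on-OAT person-years
    per episode.  If long-stay OAT has no exit at all the duration is
    unbounded and reported as ``inf``.
    """
    from scipy.linalg import expm

    p.validate()
    r = p.rates
    # absorbing pathology: no way out of the 9+ month stage
    if r.discont_oat_9p_rapid == 0 and r.discont_oat_9p_stable == 0 and (
        r.cease_rate == 0
    ):
        haz = hazard_factors(p)[0] + hazard_factors(p)[1]
        if p.trend.mu_od(ref_year) + p.trend.mu_oth(ref_year) == 0 or np.all(
            haz[ON_OAT_MASK] == 0
        ):
            return (1.0, math.inf)

    T_mat = transition_matrix(p)
    f_od, f_oth = hazard_factors(p)
    haz = p.trend.mu_od(ref_year) * f_od + p.trend.mu_oth(ref_year) * f_oth
    A = T_mat.T - np.diag(T_mat.sum(axis=1) + haz)

    # accumulator rows: on-OAT person-years; flux into OAT_M1 (re-enrolment).
    # Only flows from non-OAT_M1 sources count as episode starts (stratum
    # moves within the first month are not new episodes).
    py_row = ON_OAT_MASK.astype(float)
    enrol_row = np.zeros(N_COMPARTMENTS)
    oat_m1_mask = STAGE_MASK_OAT_M1
    T_full = transition_matrix(p)
    for j in np.where(oat_m1_mask)[0]:
        col = T_full[:, j].copy()
        col[oat_m1_mask] = 0.0
        enrol_row += col

    M = np.zeros((N_COMPARTMENTS + 2, N_COMPARTMENTS + 2))
    M[:N_COMPARTMENTS, :N_COMPARTMENTS] = A
    M[N_COMPARTMENTS, :N_COMPARTMENTS] = py_row
    M[N_COMPARTMENTS + 1, :N_COMPARTMENTS] = enrol_row

    n0 = np.zeros(N_COMPARTMENTS + 2)
    for eng, frac in (
        (EngagementClass.STABLE, p.p_stable),
        (EngagementClass.RAPID, 1.0 - p.p_stable),
    ):
        n0[
            index_of(
                Compartment(UseStage.OAT_M1, eng, IncarcerationStratum.COMM)
            )
        ] = frac

    P = expm(M)  # one-year propagator of the augmented linear system
    y = n0
    for _ in range(horizon_years):
        y = P @ y
        if y[:N_COMPARTMENTS].sum() < 1e-10:
            break
    py_oat = float(y[N_COMPARTMENTS])
    episodes = 1.0 + float(y[N_COMPARTMENTS + 1])
    return episodes, py_oat / episodes


STAGE_MASK_OAT_M1 = _as_mask(lambda c: c.use_stage is UseStage.OAT_M1)
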