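"""Counterfactual scenarios, impact metrics and uncertainty analyses.

Five counterfactuals quantify program impact and high-risk periods:

* ``no_oat`` — every protective (and first-month adverse) OAT effect on
  mortality, and the OAT effect on incarceration, removed.
* ``no_prison_oat`` — no OAT provision in prison: enrolment in prison
  stops, incarceration interrupts treatment (on -> off at 100/year inside
  prison) and prison entrants join the cohort off OAT.
* ``no_rel_m1_risk`` / ``no_oat_m1_risk`` / ``no_off_m1_risk`` — the
  excess mortality of the first month post-release, on OAT, or off OAT
  removed (population-attributable-fraction scenarios).

Each calibrated particle is run under baseline and counterfactual with
identical inputs; deaths averted, percentage reductions, life-years
gained and per-100-person-year rates are aggregated across particles as
weighted means with 2.5/97.5-percentile credible intervals.  Percentage
averted uses the counterfactual deaths as denominator for OAT-removal
scenarios, and baseline deaths (the PAF convention) for risk-removal
scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import (
    ABCSMCConfig,
    CalibrationTargets,
    ParticleSet,
    calibrate_model,
    weighted_quantile,
)
from .model import (
    ON_OAT_MASK,
    STRATUM_MASK,
    IncarcerationStratum,
    ParameterSet,
)
from .simulate import EntrySchedule, person_years, run_model

__all__ = [
    "ScenarioSpec",
    "SCENARIO_NAMES",
    "make_scenario",
    "baseline_scenario",
    "ImpactSummary",
    "impact",
    "scenario_battery",
    "paf",
    "sensitivity_run",
    "variance_decomposition",
]

SCENARIO_NAMES = (
    "no_oat",
    "no_prison_oat",
    "no_rel_m1_risk",
    "no_oat_m1_risk",
    "no_off_m1_risk",
)

_REL_M1_MASK = STRATUM_MASK[IncarcerationStratum.REL_M1]
_REL_YEAR_MASK = _REL_M1_MASK | STRATUM_MASK[IncarcerationStratum.REL_2_12]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named set of parameter/rate overrides defining a counterfactual."""

    name: str
    param_overrides: tuple = ()  # ((flat_name, value), ...)
    prison_entries_off_oat: bool = False
    denominator: str = "counterfactual"  # or "baseline" (PAF convention)

    def apply(self, p: ParameterSet) -> ParameterSet:
        """Parameter set with this scenario's overrides applied."""
        if not self.param_overrides:
            return p
        return p.replace_flat(dict(self.param_overrides))

    @property
    def is_baseline(self) -> bool:
        return not self.param_overrides and not self.prison_entries_off_oat


def baseline_scenario() -> ScenarioSpec:
    return ScenarioSpec(name="baseline")


def make_scenario(name: str) -> ScenarioSpec:
    """Build one of the five counterfactual scenario specifications."""
    if name == "no_oat":
        rr_one = (
            "rr_od_oat_comm",
            "rr_oth_oat_comm",
            "rr_od_oat_prison",
            "rr_oth_oat_prison",
            "rr_m1_on",
            "rr_m1_off",
            "rr_incarc_oat",
        )
        return ScenarioSpec(
            name=name,
            param_overrides=tuple((k, 1.0) for k in rr_one),
            denominator="counterfactual",
        )
    if name == "no_prison_oat":
        return ScenarioSpec(
            name=name,
            param_overrides=(("enrol_prison", 0.0), ("prison_oat_exit", 100.0)),
            prison_entries_off_oat=True,
            denominator="counterfactual",
        )
    if name == "no_rel_m1_risk":
        return ScenarioSpec(
            name=name,
            param_overrides=(("rr_od_rel_m1", 1.0), ("rr_oth_rel_m1", 1.0)),
            denominator="baseline",
        )
    if name == "no_oat_m1_risk":
        return ScenarioSpec(
            name=name, param_overrides=(("rr_m1_on", 1.0),), denominator="baseline"
        )
    if name == "no_off_m1_risk":
        return ScenarioSpec(
            name=name, param_overrides=(("rr_m1_off", 1.0),), denominator="baseline"
        )
    if name == "baseline":
        return baseline_scenario()
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")


@dataclass
class ImpactSummary:
    """Posterior summaries (mean, 2.5%, 97.5%) of scenario impact metrics."""

    scenario: str
    metrics: dict = field(default_factory=dict)  # name -> (mean, lo, hi)
    per_particle: pd.DataFrame | None = None

    def mean(self, name: str) -> float:
        return self.metrics[name][0]

    def interval(self, name: str) -> tuple[float, float]:
        return self.metrics[name][1], self.metrics[name][2]

    def frame(self) -> pd.DataFrame:
        rows = [
            {"scenario": self.scenario, "metric": k, "mean": v[0], "lo": v[1], "hi": v[2]}
            for k, v in self.metrics.items()
        ]
        return pd.DataFrame(rows)


def _particle_metrics(
    scenario: ScenarioSpec,
    base_run,
    cf_run,
    window: tuple[float, float],
) -> dict:
    """All impact metrics for one particle (baseline vs counterfactual runs)."""
    w0, w1 = window
    m: dict[str, float] = {}
    for cause, key in (("od", "od"), ("other", "oth"), ("total", "total")):
        b = base_run.deaths_between(w0, w1, cause)
        c = cf_run.deaths_between(w0, w1, cause)
        m[f"{key}_deaths_base"] = b
        m[f"{key}_deaths_cf"] = c
        m[f"{key}_averted"] = c - b  # signed change relative to baseline
        if scenario.denominator == "counterfactual":
            m[f"pct_{key}_averted"] = 100.0 * (c - b) / c if c > 0 else np.nan
        else:
            m[f"pct_{key}_averted"] = 100.0 * (b - c) / b if b > 0 else np.nan
        if b > 0:
            m[f"paf_{key}"] = (b - c) / b
        else:
            m[f"paf_{key}"] = np.nan
    alive_all = np.ones(base_run.occupancy.shape[1], dtype=bool)
    m["lyg"] = person_years(base_run, alive_all, window) - person_years(
        cf_run, alive_all, window
    )
    m["py_oat_base"] = person_years(base_run, ON_OAT_MASK, window)
    m["py_oat_cf"] = person_years(cf_run, ON_OAT_MASK, window)
    if m["py_oat_base"] > 0:
        m["averted_per_100py_oat"] = 100.0 * m["total_averted"] / m["py_oat_base"]
        m["lyg_per_100py_oat"] = 100.0 * m["lyg"] / m["py_oat_base"]
    else:
        m["averted_per_100py_oat"] = np.nan
        m["lyg_per_100py_oat"] = np.nan
    # post-release metrics: extra deaths in the release strata per missed
    # on-OAT person-year there (meaningful for the prison-OAT scenario)
    for label, mask in (("rel_m1", _REL_M1_MASK), ("rel_year", _REL_YEAR_MASK)):
        extra = cf_run.deaths_between(w0, w1, "total", mask) - base_run.deaths_between(
            w0, w1, "total", mask
        )
        missed_py = person_years(base_run, ON_OAT_MASK & mask, window) - person_years(
            cf_run, ON_OAT_MASK & mask, window
        )
        m[f"{label}_missed_py_oat"] = missed_py
        m[f"{label}_averted_per_100py_oat"] = (
            100.0 * extra / missed_py if missed_py > 0 else np.nan
        )
    return m


def _summarize(
    scenario_name: str, table: pd.DataFrame, weights: np.ndarray
) -> ImpactSummary:
    metrics = {}
    for col in table.columns:
        vals = table[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if not ok.any():
            metrics[col] = (np.nan, np.nan, np.nan)
            continue
        v, w = vals[ok], weights[ok]
        mean = float(np.average(v, weights=w))
        lo, hi = weighted_quantile(v, [0.025, 0.975], w)
        metrics[col] = (mean, float(lo), float(hi))
    return ImpactSummary(scenario=scenario_name, metrics=metrics, per_particle=table)


def _select_particles(particles: ParticleSet, max_particles: int | None):
    if max_particles is None or max_particles >= len(particles):
        idx = np.arange(len(particles))
        return idx, particles.weights.copy()
    # systematic resampling: deterministic, equal output weights
    positions = (np.arange(max_particles) + 0.5) / max_particles
    cum = np.cumsum(particles.weights)
    idx = np.searchsorted(cum, positions)
    return idx, np.full(max_particles, 1.0 / max_particles)


def scenario_battery(
    particles: ParticleSet,
    schedule: EntrySchedule,
    base: ParameterSet,
    scenarios,
    window: tuple[float, float] = (2001.0, 2021.0),
    t_end: float = 2021.0,
    steps_per_year: int | None = None,
    max_particles: int | None = None,
) -> dict:
    """Run baseline + each scenario for every particle; summarize per scenario.

    The baseline run is shared across scenarios per particle.  When both
    ``no_oat`` and ``no_prison_oat`` are requested, the prison program's
    share of total program impact (deaths averted by prison OAT divided by
    deaths averted by the whole program, per particle) is added to the
    ``no_prison_oat`` summary as ``share_of_program_impact_pct``.
    """
    specs = [make_scenario(s) if isinstance(s, str) else s for s in scenarios]
    idx, weights = _select_particles(particles, max_particles)
    rows: dict[str, list[dict]] = {s.name: [] for s in specs}
    for i in idx:
        p = base.replace_flat(particles.param_dict(int(i)))
        base_run = run_model(p, schedule, t_end=t_end, steps_per_year=steps_per_year)
        for spec in specs:
            cf_run = run_model(
                p, schedule, t_end=t_end, scenario=spec, steps_per_year=steps_per_year
            )
            rows[spec.name].append(_particle_metrics(spec, base_run, cf_run, window))
    tables = {name: pd.DataFrame(r) for name, r in rows.items()}
    if "no_oat" in tables and "no_prison_oat" in tables:
        prog = tables["no_oat"]["total_averted"].to_numpy()
        prison = tables["no_prison_oat"]["total_averted"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            tables["no_prison_oat"]["share_of_program_impact_pct"] = np.where(
                prog > 0, 100.0 * prison / prog, np.nan
            )
    return {name: _summarize(name, tbl, weights) for name, tbl in tables.items()}


def impact(
    particles: ParticleSet,
    schedule: EntrySchedule,
    scenario: ScenarioSpec | str,
    base: ParameterSet,
    window: tuple[float, float] = (2001.0, 2021.0),
    **kwargs,
) -> ImpactSummary:
    """Impact of one counterfactual vs baseline across the particle set."""
    spec = make_scenario(scenario) if isinstance(scenario, str) else scenario
    return scenario_battery(
        particles, schedule, base, [spec], window=window, **kwargs
    )[spec.name]


def paf(
    particles: ParticleSet,
    schedule: EntrySchedule,
    scenario: ScenarioSpec | str,
    base: ParameterSet,
    cause: str = "total",
    **kwargs,
) -> tuple[float, float, float]:
    """Population-attributable fraction of a removed risk, with 95% CrI.

    PAF = (baseline deaths - counterfactual deaths) / baseline deaths for
    the given cause ("od", "other" or "total").
    """
    spec = make_scenario(scenario) if isinstance(scenario, str) else scenario
    if spec.denominator != "baseline":
        raise ValueError(
            f"scenario {spec.name!r} is not a risk-removal (PAF) scenario"
        )
    summary = impact(particles, schedule, spec, base, **kwargs)
    key = {"od": "paf_od", "other": "paf_oth", "total": "paf_total"}[cause]
    mean, lo, hi = summary.metrics[key]
    if not np.isfinite(mean):
        warnings.warn("PAF undefined: zero baseline deaths for some particles")
    return mean, lo, hi


SENSITIVITY_VARIANTS = ("exp_od_trend", "no_relapse")


def sensitivity_run(
    variant: str,
    targets: CalibrationTargets,
    schedule: EntrySchedule,
    base: ParameterSet,
    priors: dict,
    config: ABCSMCConfig,
    recalibrate: bool = True,
    particles: ParticleSet | None = None,
    scenario: str = "no_oat",
    **impact_kwargs,
) -> tuple[ImpactSummary, ParticleSet]:
    """Impact under an alternative model structure.

    ``exp_od_trend`` replaces the linear overdose mortality trend with an
    exponential one at 0.11/year; ``no_relapse`` removes relapse from the
    no-use state.  By default the altered structure is recalibrated with
    ABC-SMC before the impact comparison; pass ``recalibrate=False`` with
    an existing particle set to re-use baseline posteriors instead.
    """
    if variant not in SENSITIVITY_VARIANTS:
        raise ValueError(f"unknown sensitivity variant {variant!r}")
    priors = dict(priors)
    if variant == "exp_od_trend":
        alt = base.replace_flat(
            {"slope_od": 0.0, "exp_rate": 0.11, "trend_form": "exponential"}
        )
        priors.pop("slope_od", None)
    else:  # no_relapse
        alt = base.replace_flat({"relapse_rate": 0.0})
        priors.pop("relapse_rate", None)
    if recalibrate:
        particles = calibrate_model(
            priors,
            targets,
            schedule,
            alt,
            config,
            steps_per_year=impact_kwargs.get("steps_per_year"),
        )
    elif particles is None:
        raise ValueError("recalibrate=False requires an existing particle set")
    summary = impact(particles, schedule, scenario, alt, **impact_kwargs)
    return summary, particles


def variance_decomposition(
    particles: ParticleSet, outcome: np.ndarray
) -> pd.Series:
    """Share of outcome variance explained per parameter (linear ANCOVA).

    Fits an ordinary least-squares linear model of the per-particle
    outcome on all calibrated parameters and attributes explained variance
    by each parameter's partial (type II) sum of squares as a percentage
    of the total outcome variance.  Shares lie in [0, 100] and sum to at
    most ~100 (up to sampling correlation between parameters).
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    if len(particles) < 50:
        raise ValueError("variance decomposition needs at least 50 particles")
    if y.shape[0] != len(particles):
        raise ValueError("outcome length must match the particle count")

    X = particles.values.copy()
    names = list(particles.names)
    sd = X.std(axis=0)
    keep = sd > 1e-12
    dropped = [n for n, k in zip(names, keep) if not k]
    X, names = X[:, keep], [n for n, k in zip(names, keep) if k]
    # drop collinear columns via pivoted QR on the standardized design
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    q, r = np.linalg.qr(Xs)
    diag = np.abs(np.diag(r))
    collinear = diag < 1e-8 * diag.max()
    if collinear.any():
        dropped += [n for n, c in zip(names, collinear) if c]
        X = X[:, ~collinear]
        names = [n for n, c in zip(names, collinear) if not c]
    if dropped:
        warnings.warn(f"dropped degenerate/collinear parameters: {dropped}")

    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0:
        return pd.Series(0.0, index=names)

    design = sm.add_constant(X)
    full = sm.OLS(y, design).fit()
    ss_res_full = float(full.ssr)
    shares = {}
    for j, name in enumerate(names):
        sub = np.delete(design, j + 1, axis=1)  # +1 for the constant column
        reduced = sm.OLS(y, sub).fit()
        shares[name] = 100.0 * max(0.0, float(reduced.ssr) - ss_res_full) / ss_total
    return pd.Series(shares).sort_values(ascending=False)
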