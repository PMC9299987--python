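"""Core state space and hazard structure for the OAT mortality model.

The model tracks a cohort of people who ever received opioid agonist
treatment (OAT) through a cross-product of

* five opioid-use stages (first month on OAT, months 1-9 on OAT, 9+ months
  on OAT, first month off OAT, rest of time off OAT) plus a ``NO_USE``
  stage for people who have ceased both OAT and illicit opioid use,
* two latent engagement classes (rapid turnover vs. stable treatment),
  which differ only in their OAT discontinuation rates, and
* four incarceration strata (community, currently incarcerated, released
  under one month ago, released 1-12 months ago).

``NO_USE`` carries incarceration strata but no engagement distinction
(canonicalized to ``STABLE``), giving (5 x 2 + 1) x 4 = 44 compartments.

Mortality has two competing causes, fatal overdose and all other causes,
with calendar-time trends in the baseline rates and multiplicative
relative risks by OAT stage and incarceration stratum.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from enum import Enum
import numpy as np

__all__ = [
    "UseStage",
    "EngagementClass",
    "IncarcerationStratum",
    "Compartment",
    "COMPARTMENTS",
    "N_COMPARTMENTS",
    "index_of",
    "compartment_from_label",
    "MortalityTrend",
    "RelativeRisks",
    "RateSet",
    "ParameterSet",
    "ModelError",
    "hazards",
    "hazard_factors",
    "transition_matrix",
    "build_generator",
    "YEAR_START",
    "YEAR_END",
]

YEAR_START = 2001.0
YEAR_END = 2021.0  # end of calendar 2020: the 20-year impact window is [2001, 2021)


class ModelError(ValueError):
    """Inconsistent model structure (e.g. a negative constructed rate)."""


class UseStage(Enum):
    OAT_M1 = "OAT_M1"  # first month on OAT
    OAT_1_9 = "OAT_1_9"  # months 1-9 on OAT
    OAT_9P = "OAT_9P"  # 9+ months on OAT
    OFF_M1 = "OFF_M1"  # first month after OAT discontinuation
    OFF_REST = "OFF_REST"  # rest of time off OAT, still using opioids
    NO_USE = "NO_USE"  # ceased OAT and illicit opioid use


OAT_STAGES = frozenset({UseStage.OAT_M1, UseStage.OAT_1_9, UseStage.OAT_9P})
OFF_USE_STAGES = frozenset({UseStage.OFF_M1, UseStage.OFF_REST})


class EngagementClass(Enum):
    RAPID = "RAPID"
    STABLE = "STABLE"


class IncarcerationStratum(Enum):
    COMM = "COMM"  # never / not incarcerated in the past year
    PRISON = "PRISON"  # currently incarcerated
    REL_M1 = "REL_M1"  # released < 1 month ago
    REL_2_12 = "REL_2_12"  # released 1-12 months ago


@dataclass(frozen=True)
class Compartment:
    """One cell of the use-stage x engagement x incarceration cross-product."""

    use_stage: UseStage
    engagement: EngagementClass
    incarceration: IncarcerationStratum

    def __post_init__(self) -> None:
        if (
            self.use_stage is UseStage.NO_USE
            and self.engagement is not EngagementClass.STABLE
        ):
            raise ModelError("NO_USE compartments are canonicalized to STABLE")

    @property
    def on_oat(self) -> bool:
        return self.use_stage in OAT_STAGES

    @property
    def label(self) -> str:
        return (
            f"{self.use_stage.value}|{self.engagement.value}|"
            f"{self.incarceration.value}"
        )


def _enumerate_compartments() -> tuple[Compartment, ...]:
    comps = []
    for stage in (
        UseStage.OAT_M1,
        UseStage.OAT_1_9,
        UseStage.OAT_9P,
        UseStage.OFF_M1,
        UseStage.OFF_REST,
    ):
        for eng in (EngagementClass.RAPID, EngagementClass.STABLE):
            for strat in IncarcerationStratum:
                comps.append(Compartment(stage, eng, strat))
    for strat in IncarcerationStratum:
        comps.append(Compartment(UseStage.NO_USE, EngagementClass.STABLE, strat))
    return tuple(comps)


COMPARTMENTS: tuple[Compartment, ...] = _enumerate_compartments()
N_COMPARTMENTS = len(COMPARTMENTS)
_INDEX = {c: i for i, c in enumerate(COMPARTMENTS)}
_LABEL_INDEX = {c.label: c for c in COMPARTMENTS}

assert N_COMPARTMENTS == 44


def index_of(c: Compartment) -> int:
    """Position of ``c`` in the canonical compartment ordering."""
    try:
        return _INDEX[c]
    except KeyError:
        raise KeyError(f"unknown compartment {c!r}") from None


def compartment_from_label(label: str) -> Compartment:
    try:
        return _LABEL_INDEX[label]
    except KeyError:
        raise KeyError(f"unknown compartment label {label!r}") from None


def _mask(pred) -> np.ndarray:
    return np.array([bool(pred(c)) for c in COMPARTMENTS])


ON_OAT_MASK = _mask(lambda c: c.on_oat)
OFF_USE_MASK = _mask(lambda c: c.use_stage in OFF_USE_STAGES)
NO_USE_MASK = _mask(lambda c: c.use_stage is UseStage.NO_USE)
STRATUM_MASK = {
    s: _mask(lambda c, s=s: c.incarceration is s) for s in IncarcerationStratum
}
STAGE_MASK = {s: _mask(lambda c, s=s: c.use_stage is s) for s in UseStage}


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class MortalityTrend:
    """Baseline cause-specific mortality rates and their calendar trends.

    Rates are per person-year at the 2001 anchor; the linear form adds an
    absolute yearly increment (floored at zero), while the exponential form
    (a sensitivity structure for overdose only) multiplies the 2001 rate by
    ``exp(exp_rate * (t - t_start))``.
    """

    mu_od_2001: float = 0.003
    mu_oth_2001: float = 0.009
    slope_od: float = 0.0
    slope_oth: float = 0.0
    form: str = "linear"  # overdose trend form: "linear" | "exponential"
    exp_rate: float = 0.11
    t_start: float = 2001.0

    def mu_od(self, t: float) -> float:
        dt = t - self.t_start
        if self.form == "exponential":
            return self.mu_od_2001 * math.exp(self.exp_rate * dt)
        return max(0.0, self.mu_od_2001 + self.slope_od * dt)

    def mu_oth(self, t: float) -> float:
        return max(0.0, self.mu_oth_2001 + self.slope_oth * (t - self.t_start))

    def validate(self) -> None:
        if self.form not in ("linear", "exponential"):
            raise ModelError(f"unknown trend form {self.form!r}")
        if self.mu_od_2001 < 0 or self.mu_oth_2001 < 0:
            raise ModelError("2001 mortality rates must be non-negative")


@dataclass
class RelativeRisks:
    """Multiplicative relative risks on the baseline mortality hazards.

    On-vs-off-OAT effects are stratum specific (community vs prison);
    first-month factors apply to both causes jointly; post-release factors
    are relative to the community stratum, with the months 2-12 residual
    elevation applying to overdose only.  The in-prison multipliers scale
    off-OAT mortality inside prison relative to the community (both < 1:
    mortality during incarceration is lower than outside).
    """

    rr_od_oat_comm: float = 0.174
    rr_oth_oat_comm: float = 0.374
    rr_m1_on: float = 2.294
    rr_m1_off: float = 1.782
    rr_od_oat_prison: float = 0.173
    rr_oth_oat_prison: float = 0.466
    rr_od_rel_m1: float = 4.032
    rr_oth_rel_m1: float = 1.657
    rr_od_rel_2_12: float = 1.161
    rr_incarc_oat: float = 0.818
    prison_mort_mult_od: float = 0.5
    prison_mort_mult_oth: float = 0.5

    def validate(self) -> None:
        for name, v in dataclasses.asdict(self).items():
            if not v > 0:
                raise ModelError(f"relative risk {name} must be > 0, got {v}")


# Structural dwell-time exit rates (per year): "first month" compartments
# empty at 12/yr, months 1-9 on OAT at 1.5/yr (mean 8 further months), the
# 1-12 month post-release stratum at 12/11 so mean tracked post-release
# time totals 12 months.
EXIT_OAT_M1 = 12.0
EXIT_OAT_1_9 = 1.5
EXIT_OFF_M1 = 12.0
REL_M1_TO_2_12 = 12.0
REL_2_12_TO_COMM = 12.0 / 11.0


@dataclass
class RateSet:
    """Transition rates (per person-year) between compartments."""

    exit_oat_m1: float = EXIT_OAT_M1
    exit_oat_1_9: float = EXIT_OAT_1_9
    exit_off_m1: float = EXIT_OFF_M1
    rel_m1_to_2_12: float = REL_M1_TO_2_12
    rel_2_12_to_comm: float = REL_2_12_TO_COMM
    # OAT discontinuation (stage -> first month off OAT), engagement-specific
    discont_oat_m1_rapid: float = 4.0
    discont_oat_1_9_rapid: float = 2.5
    discont_oat_9p_rapid: float = 0.78
    discont_oat_m1_stable: float = 0.8
    discont_oat_1_9_stable: float = 0.45
    discont_oat_9p_stable: float = 0.13
    # re-enrolment onto OAT (off-OAT stages -> first month on OAT)
    enrol_comm: float = 0.58
    enrol_prison: float = 1.4
    # long-term cessation of OAT and opioid use, and relapse back to use
    cease_rate: float = 0.02
    relapse_rate: float = 0.05
    # incarceration dynamics
    incarc_rate_comm: float = 0.24
    incarc_rate_postrel: float = 0.60
    release_rate: float = 3.6
    # extra on->off OAT rate inside prison (scenario hook; 0 at baseline,
    # i.e. OAT continues uninterrupted across incarceration transitions)
    prison_oat_exit: float = 0.0

    def validate(self) -> None:
        for name, v in dataclasses.asdict(self).items():
            if v < 0:
                raise ModelError(f"rate {name} must be >= 0, got {v}")

    def discont(self, engagement: EngagementClass, stage: UseStage) -> float:
        key = {
            UseStage.OAT_M1: "m1",
            UseStage.OAT_1_9: "1_9",
            UseStage.OAT_9P: "9p",
        }[stage]
        return getattr(self, f"discont_oat_{key}_{engagement.value.lower()}")


@dataclass
class ParameterSet:
    """Everything driving one deterministic model realization."""

    trend: MortalityTrend = field(default_factory=MortalityTrend)
    rr: RelativeRisks = field(default_factory=RelativeRisks)
    rates: RateSet = field(default_factory=RateSet)
    p_stable: float = 0.5

    def validate(self) -> None:
        self.trend.validate()
        self.rr.validate()
        self.rates.validate()
        if not 0.0 <= self.p_stable <= 1.0:
            raise ModelError(f"p_stable must lie in [0,1], got {self.p_stable}")

    # -- flat named-value record round-trip --------------------------------

    def to_flat(self) -> dict:
        flat: dict = {}
        for group in (self.trend, self.rr, self.rates):
            for k, v in dataclasses.asdict(group).items():
                if k == "form":
                    flat["trend_form"] = v
                else:
                    flat[k] = float(v)
        flat["p_stable"] = float(self.p_stable)
        return flat

    @classmethod
    def from_flat(cls, flat: dict) -> "ParameterSet":
        trend_fields = {f.name for f in dataclasses.fields(MortalityTrend)}
        rr_fields = {f.name for f in dataclasses.fields(RelativeRisks)}
        rate_fields = {f.name for f in dataclasses.fields(RateSet)}
        trend_kw, rr_kw, rate_kw = {}, {}, {}
        p_stable = 0.5
        for k, v in flat.items():
            if k == "trend_form":
                trend_kw["form"] = v
            elif k == "p_stable":
                p_stable = float(v)
            elif k in trend_fields:
                trend_kw[k] = float(v)
            elif k in rr_fields:
                rr_kw[k] = float(v)
            elif k in rate_fields:
                rate_kw[k] = float(v)
            else:
                raise KeyError(f"unknown parameter {k!r}")
        return cls(
            trend=MortalityTrend(**trend_kw),
            rr=RelativeRisks(**rr_kw),
            rates=RateSet(**rate_kw),
            p_stable=p_stable,
        )

    def replace_flat(self, overrides: dict) -> "ParameterSet":
        """Copy with a subset of flat parameter names replaced."""
        flat = self.to_flat()
        for k, v in overrides.items():
            if k not in flat:
                raise KeyError(f"unknown parameter {k!r}")
            flat[k] = v
        return ParameterSet.from_flat(flat)


# ---------------------------------------------------------------------------
# Hazards
# ---------------------------------------------------------------------------


def hazard_factors(p: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    """Time-independent multiplicative factors (f_od, f_oth) per compartment.

    The cause-specific hazard of compartment ``c`` at time ``t`` is
    ``mu_od(t) * f_od[c]`` and ``mu_oth(t) * f_oth[c]``.  Factors combine
    multiplicatively: OAT-status RR (community or prison variant), the
    joint first-month-on / first-month-off elevations, and the
    incarceration-stratum factor.  ``NO_USE`` compartments have zero
    overdose hazard and plain other-cause hazard.
    """
    rr = p.rr
    f_od = np.empty(N_COMPARTMENTS)
    f_oth = np.empty(N_COMPARTMENTS)
    for i, c in enumerate(COMPARTMENTS):
        if c.use_stage is UseStage.NO_USE:
            f_od[i] = 0.0
            f_oth[i] = 1.0
            continue
        od = 1.0
        oth = 1.0
        in_prison = c.incarceration is IncarcerationStratum.PRISON
        if c.on_oat:
            od *= rr.rr_od_oat_prison if in_prison else rr.rr_od_oat_comm
            oth *= rr.rr_oth_oat_prison if in_prison else rr.rr_oth_oat_comm
        if c.use_stage is UseStage.OAT_M1:
            od *= rr.rr_m1_on
            oth *= rr.rr_m1_on
        elif c.use_stage is UseStage.OFF_M1:
            od *= rr.rr_m1_off
            oth *= rr.rr_m1_off
        if in_prison:
            od *= rr.prison_mort_mult_od
            oth *= rr.prison_mort_mult_oth
        elif c.incarceration is IncarcerationStratum.REL_M1:
            od *= rr.rr_od_rel_m1
            oth *= rr.rr_oth_rel_m1
        elif c.incarceration is IncarcerationStratum.REL_2_12:
            od *= rr.rr_od_rel_2_12  # overdose only; other-cause factor stays 1
        f_od[i] = od
        f_oth[i] = oth
    return f_od, f_oth


def hazards(
    c: Compartment, t: float, p: ParameterSet
) -> tuple[float, float]:
    """Instantaneous (overdose, other-cause) mortality rates per person-year."""
    if not (YEAR_START <= t <= YEAR_END):
        raise ValueError(f"t={t} outside model horizon [{YEAR_START}, {YEAR_END}]")
    i = index_of(c)
    f_od, f_oth = hazard_factors(p)
    return p.trend.mu_od(t) * f_od[i], p.trend.mu_oth(t) * f_oth[i]


# ---------------------------------------------------------------------------
# Transition structure
# ---------------------------------------------------------------------------


def transition_matrix(p: ParameterSet) -> np.ndarray:
    """Time-independent transition-rate matrix ``T`` over compartments.

    ``T[i, j]`` is the flow rate (per person-year) from compartment ``i``
    to ``j``; the diagonal is zero (total outflow is assembled in
    :func:`build_generator` together with the death hazards).
    """
    r = p.rates
    rr = p.rr
    T = np.zeros((N_COMPARTMENTS, N_COMPARTMENTS))

    def add(src: Compartment, dst: Compartment, rate: float) -> None:
        if rate < 0:
            raise ModelError(
                f"negative rate {rate} for {src.label} -> {dst.label}"
            )
        if rate:
            T[index_of(src), index_of(dst)] += rate

    for c in COMPARTMENTS:
        stage, eng, strat = c.use_stage, c.engagement, c.incarceration
        here = lambda s: Compartment(s, eng, strat)  # noqa: E731
        in_prison = strat is IncarcerationStratum.PRISON
        enrol = r.enrol_prison if in_prison else r.enrol_comm

        # --- opioid-use stage progression (stratum preserved) ---
        if stage is UseStage.OAT_M1:
            add(c, here(UseStage.OAT_1_9), r.exit_oat_m1)
            add(c, here(UseStage.OFF_M1), r.discont(eng, stage))
        elif stage is UseStage.OAT_1_9:
            add(c, here(UseStage.OAT_9P), r.exit_oat_1_9)
            add(c, here(UseStage.OFF_M1), r.discont(eng, stage))
        elif stage is UseStage.OAT_9P:
            add(c, here(UseStage.OFF_M1), r.discont(eng, stage))
            add(
                c,
                Compartment(UseStage.NO_USE, EngagementClass.STABLE, strat),
                r.cease_rate,
            )
        elif stage is UseStage.OFF_M1:
            add(c, here(UseStage.OFF_REST), r.exit_off_m1)
            add(c, here(UseStage.OAT_M1), enrol)
        elif stage is UseStage.OFF_REST:
            add(c, here(UseStage.OAT_M1), enrol)
            add(
                c,
                Compartment(UseStage.NO_USE, EngagementClass.STABLE, strat),
                r.cease_rate,
            )
        else:  # NO_USE: relapse back into off-OAT opioid use
            add(c, Compartment(UseStage.OFF_REST, eng, strat), r.relapse_rate)

        # scenario hook: forced OAT interruption inside prison
        if in_prison and c.on_oat and r.prison_oat_exit:
            add(c, here(UseStage.OFF_M1), r.prison_oat_exit)

        # --- incarceration stratum transitions (use stage preserved) ---
        incarc_mult = rr.rr_incarc_oat if c.on_oat else 1.0
        move = lambda s: Compartment(stage, eng, s)  # noqa: E731
        if strat is IncarcerationStratum.COMM:
            add(c, move(IncarcerationStratum.PRISON), r.incarc_rate_comm * incarc_mult)
        elif strat is IncarcerationStratum.PRISON:
            add(c, move(IncarcerationStratum.REL_M1), r.release_rate)
        elif strat is IncarcerationStratum.REL_M1:
            add(c, move(IncarcerationStratum.REL_2_12), r.rel_m1_to_2_12)
            add(
                c,
                move(IncarcerationStratum.PRISON),
                r.incarc_rate_postrel * incarc_mult,
            )
        else:  # REL_2_12
            add(c, move(IncarcerationStratum.COMM), r.rel_2_12_to_comm)
            add(
                c,
                move(IncarcerationStratum.PRISON),
                r.incarc_rate_postrel * incarc_mult,
            )
    return T


def build_generator(
    t: float, p: ParameterSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full generator at time ``t``: (Q, overdose deaths, other deaths).

    ``Q`` is the 44 x 44 rate matrix with non-negative off-diagonal
    transition rates and diagonal equal to minus the total outflow
    (transitions plus both death hazards), so that mass is conserved in
    the continuous-time sense.  The two returned vectors are the
    per-compartment cause-specific death-outflow rates at ``t``.
    """
    p.validate()
    T = transition_matrix(p)
    f_od, f_oth = hazard_factors(p)
    d_od = p.trend.mu_od(t) * f_od
    d_oth = p.trend.mu_oth(t) * f_oth
    Q = T.copy()
    np.fill_diagonal(Q, -(T.sum(axis=1) + d_od + d_oth))
    return Q, d_od, d_oth
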