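"""Approximate Bayesian computation (sequential Monte Carlo) calibration.

The model is calibrated to seven annual cohort series by minimising a
normalised sum of squared deviations.  A population of parameter
particles is drawn from the priors, then evolved over generations: each
generation resamples ancestors by weight, perturbs them with an
independent Gaussian kernel (reflected at the prior bounds) and accepts
proposals whose distance falls under a shrinking threshold (the 75th
percentile of the previous generation's accepted distances).  Iteration
stops when the median distance no longer improves appreciably.  The
weighted particle population approximates the posterior; 95% credible
intervals are its 2.5th/97.5th weighted percentiles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ParameterSet

__all__ = [
    "UniformPrior",
    "LognormalCIPrior",
    "lognormal_from_ci",
    "default_priors",
    "CalibrationTargets",
    "distance",
    "ABCSMCConfig",
    "ParticleSet",
    "abc_smc",
    "calibrate_model",
    "weighted_quantile",
    "credible_interval",
    "CalibrationError",
]

log = logging.getLogger("oatimpact.calibrate")

Z975 = float(stats.norm.ppf(0.975))


class CalibrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


def lognormal_from_ci(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Log-scale (location, scale) whose 2.5/97.5% quantiles are (lo, hi).

    Quantile matching: location is the midpoint of the log bounds and the
    scale spans the log CI over 2 x z_0.975.  Published means are often
    not exactly lognormal-consistent with their CIs; the CI wins, and the
    implied mean ``exp(location + scale^2/2)`` is generally within ~10% of
    the stated one.
    """
    if not (0 < lo < hi) or mean <= 0:
        raise ValueError(f"need 0 < lo < hi and mean > 0, got ({mean}, {lo}, {hi})")
    if not (lo < mean < hi):
        raise ValueError(f"mean {mean} must lie inside the CI ({lo}, {hi})")
    location = 0.5 * (math.log(lo) + math.log(hi))
    scale = (math.log(hi) - math.log(lo)) / (2.0 * Z975)
    return location, scale


@dataclass(frozen=True)
class UniformPrior:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"uniform prior needs lo < hi, got ({self.lo}, {self.hi})")

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lo, self.hi)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.uniform(self.lo, self.hi, size=size)

    def pdf(self, x: float) -> float:
        return 1.0 / (self.hi - self.lo) if self.lo <= x <= self.hi else 0.0

    def interval95(self) -> tuple[float, float]:
        w = self.hi - self.lo
        return (self.lo + 0.025 * w, self.hi - 0.025 * w)


@dataclass(frozen=True)
class LognormalCIPrior:
    """Lognormal prior stated as mean + 95% CI, truncated to [lo, hi]."""

    mean: float
    lo: float
    hi: float

    @property
    def log_params(self) -> tuple[float, float]:
        return lognormal_from_ci(self.mean, self.lo, self.hi)

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lo, self.hi)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        mu, sigma = self.log_params
        a = (math.log(self.lo) - mu) / sigma
        b = (math.log(self.hi) - mu) / sigma
        draw = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)
        return np.exp(draw)

    def pdf(self, x: float) -> float:
        if not self.lo <= x <= self.hi:
            return 0.0
        mu, sigma = self.log_params
        a = (math.log(self.lo) - mu) / sigma
        b = (math.log(self.hi) - mu) / sigma
        z = (math.log(x) - mu) / sigma
        norm_mass = stats.norm.cdf(b) - stats.norm.cdf(a)
        return stats.norm.pdf(z) / (sigma * x * norm_mass)

    def interval95(self) -> tuple[float, float]:
        return (self.lo, self.hi)


Prior = UniformPrior | LognormalCIPrior


def default_priors(base: ParameterSet, structural_width: float = 0.2) -> dict:
    """Default calibration priors.

    Mortality anchors get wide uniform priors; the relative-risk block
    gets literature-derived lognormal mean/CI priors truncated to their
    bounds; structural transition rates get +/-20% uniform priors around
    the reference rates in ``base`` (the convention used to turn point
    estimates of calibrated transition rates into prior distributions).
    """
    flat = base.to_flat()

    def around(name: str) -> UniformPrior:
        v = flat[name]
        return UniformPrior(v * (1 - structural_width), v * (1 + structural_width))

    priors: dict[str, Prior] = {
        "mu_od_2001": UniformPrior(0.001, 0.05),
        "mu_oth_2001": UniformPrior(0.001, 0.05),
        "slope_od": UniformPrior(0.0, 0.001),
        "slope_oth": UniformPrior(0.0, 0.001),
        "rr_od_oat_comm": LognormalCIPrior(0.22, 0.13, 0.35),
        "rr_oth_oat_comm": LognormalCIPrior(0.57, 0.34, 0.80),
        "rr_m1_on": LognormalCIPrior(1.97, 0.93, 4.00),
        "rr_m1_off": LognormalCIPrior(2.38, 1.53, 3.75),
        "rr_od_oat_prison": LognormalCIPrior(0.12, 0.06, 0.26),
        "rr_oth_oat_prison": LognormalCIPrior(0.32, 0.15, 0.63),
        "rr_od_rel_m1": LognormalCIPrior(3.70, 2.22, 5.18),
        "rr_od_rel_2_12": LognormalCIPrior(1.70, 1.02, 2.38),
        "rr_oth_rel_m1": LognormalCIPrior(1.40, 0.84, 1.96),
        "rr_incarc_oat": LognormalCIPrior(0.80, 0.71, 0.90),
    }
    for name in (
        "prison_mort_mult_od",
        "prison_mort_mult_oth",
        "discont_oat_m1_rapid",
        "discont_oat_1_9_rapid",
        "discont_oat_9p_rapid",
        "discont_oat_m1_stable",
        "discont_oat_1_9_stable",
        "discont_oat_9p_stable",
        "enrol_comm",
        "enrol_prison",
        "cease_rate",
        "relapse_rate",
        "incarc_rate_comm",
        "incarc_rate_postrel",
        "release_rate",
        "p_stable",
    ):
        priors[name] = around(name)
    return priors


# ---------------------------------------------------------------------------
# Targets and distance
# ---------------------------------------------------------------------------


@dataclass
class CalibrationTargets:
    """Observed annual series plus per-series normalisation constants.

    ``frame`` is tidy (series_name, year, value).  By default each series
    is normalised by the maximum of its observed values, putting all
    series on a comparable [0, 1] scale in the distance.
    """

    frame: pd.DataFrame
    norms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"series_name", "year", "value"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"targets frame needs columns {sorted(required)}")
        if not self.norms:
            self.norms = {
                name: float(np.abs(g["value"]).max()) or 1.0
                for name, g in self.frame.groupby("series_name")
            }

    def validate(self) -> None:
        years = self.frame["year"]
        if years.min() < 2001 or years.max() > 2018:
            raise ValueError("target years must lie within 2001-2018")
        for name, g in self.frame.groupby("series_name"):
            if str(name).startswith("prop_"):
                v = g["value"]
                if (v < 0).any() or (v > 1).any():
                    raise ValueError(f"proportion series {name} outside [0,1]")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationTargets":
        return cls(frame=pd.read_csv(path))


def distance(sim: pd.DataFrame, obs: CalibrationTargets) -> float:
    """Normalised sum-of-squares distance between simulated and observed series.

    Sums ``((sim - obs) / norm)**2`` over every (series, year) pair present
    in the observations; years missing from either side are skipped.
    Zero iff the simulation matches the observations exactly.
    """
    merged = obs.frame.merge(
        sim, on=["series_name", "year"], suffixes=("_obs", "_sim")
    )
    if merged.empty:
        raise ValueError("no overlapping (series, year) pairs between sim and obs")
    norms = merged["series_name"].map(obs.norms).astype(float)
    resid = (merged["value_sim"] - merged["value_obs"]) / norms
    return float((resid**2).sum())


# ---------------------------------------------------------------------------
# ABC-SMC
# ---------------------------------------------------------------------------


@dataclass
class ABCSMCConfig:
    n_particles: int = 1000
    max_generations: int = 8
    improvement_tol: float = 0.01  # relative median-distance improvement
    seed: int = 0
    accept_quantile: float = 0.75  # next threshold = this quantile of distances
    kernel_scale: float = 1.5  # kernel sd = scale x weighted sd of prev gen
    max_attempts_factor: int = 50


@dataclass
class ParticleSet:
    """Weighted posterior parameter draws from ABC-SMC."""

    names: list
    values: np.ndarray  # (n_particles, n_params)
    weights: np.ndarray  # sums to 1
    distances: np.ndarray
    generation: int
    seed: int
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("particle weights must be non-negative")
        s = self.weights.sum()
        if not math.isclose(s, 1.0, rel_tol=1e-9):
            self.weights = self.weights / s

    def __len__(self) -> int:
        return self.values.shape[0]

    def param_dict(self, i: int) -> dict:
        return dict(zip(self.names, self.values[i]))

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def posterior_mean(self, name: str) -> float:
        return float(np.average(self.column(name), weights=self.weights))

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            header = {
                "kind": "particle_set",
                "names": list(self.names),
                "generation": self.generation,
                "seed": self.seed,
                "history": self.history,
            }
            fh.write(json.dumps(header, sort_keys=True) + "\n")
            for i in range(len(self)):
                rec = {
                    "generation": self.generation,
                    "weight": float(self.weights[i]),
                    "distance": float(self.distances[i]),
                    "params": {k: float(v) for k, v in self.param_dict(i).items()},
                }
                fh.write(json.dumps(rec, sort_keys=True) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "ParticleSet":
        with open(path) as fh:
            header = json.loads(fh.readline())
            names = header["names"]
            values, weights, distances = [], [], []
            for line in fh:
                rec = json.loads(line)
                values.append([rec["params"][k] for k in names])
                weights.append(rec["weight"])
                distances.append(rec["distance"])
        return cls(
            names=names,
            values=np.array(values),
            weights=np.array(weights),
            distances=np.array(distances),
            generation=header["generation"],
            seed=header["seed"],
            history=header.get("history", []),
        )


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a proposal back into [lo, hi]."""
    if lo == hi:
        return lo
    width = hi - lo
    # fold onto a 2*width sawtooth, then mirror
    y = (x - lo) % (2.0 * width)
    return lo + (y if y <= width else 2.0 * width - y)


def abc_smc(
    priors: Mapping[str, Prior],
    targets: CalibrationTargets,
    simulator: Callable[[dict], pd.DataFrame],
    config: ABCSMCConfig,
) -> ParticleSet:
    """Run ABC-SMC and return the final weighted particle generation.

    ``simulator`` maps a flat {parameter: value} record (for the
    calibrated parameters only) to a tidy summary frame comparable with
    ``targets``.  Generation 0 samples the priors directly; later
    generations resample by weight, perturb with a reflected Gaussian
    kernel and accept under the shrinking threshold.  Fully reproducible
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    names = sorted(priors)
    n_params = len(names)
    n = config.n_particles
    bounds = np.array([priors[k].bounds for k in names])

    def prior_pdf(theta: np.ndarray) -> float:
        out = 1.0
        for k, x in zip(names, theta):
            out *= priors[k].pdf(float(x))
        return out

    # generation 0: straight prior sample
    values = np.column_stack([np.asarray(priors[k].sample(rng, n)) for k in names])
    distances = np.array(
        [distance(simulator(dict(zip(names, row))), targets) for row in values]
    )
    weights = np.full(n, 1.0 / n)
    history = [
        {
            "generation": 0,
            "epsilon": None,
            "acceptance_rate": 1.0,
            "median_distance": float(np.median(distances)),
        }
    ]
    log.info("gen 0: median distance %.4g", history[0]["median_distance"])

    generation = 0
    for gen in range(1, config.max_generations + 1):
        eps = float(np.percentile(distances, 100.0 * config.accept_quantile))
        mean = np.average(values, axis=0, weights=weights)
        var = np.average((values - mean) ** 2, axis=0, weights=weights)
        kernel_sd = config.kernel_scale * np.sqrt(var)
        kernel_sd = np.maximum(kernel_sd, 1e-9 * (bounds[:, 1] - bounds[:, 0]) + 1e-15)

        new_values = np.empty_like(values)
        new_distances = np.empty(n)
        accepted = 0
        attempts = 0
        max_attempts = config.max_attempts_factor * n
        while accepted < n and attempts < max_attempts:
            attempts += 1
            j = rng.choice(n, p=weights)
            prop = values[j] + rng.normal(0.0, kernel_sd)
            prop = np.array(
                [_reflect(x, lo, hi) for x, (lo, hi) in zip(prop, bounds)]
            )
            d = distance(simulator(dict(zip(names, prop))), targets)
            if d <= eps:
                new_values[accepted] = prop
                new_distances[accepted] = d
                accepted += 1
        if accepted < n:
            log.warning(
                "gen %d: only %d/%d accepted after %d attempts; stopping",
                gen,
                accepted,
                n,
                attempts,
            )
            break

        # importance weights: prior / kernel mixture density of ancestors
        log_w = np.empty(n)
        inv_sd = 1.0 / kernel_sd
        log_wprev = np.log(weights)
        norm_const = np.sum(np.log(inv_sd)) - 0.5 * n_params * math.log(2 * math.pi)
        for i in range(n):
            z = (new_values[i] - values) * inv_sd  # (n_prev, n_params)
            log_k = log_wprev + norm_const - 0.5 * np.sum(z * z, axis=1)
            mix = float(np.logaddexp.reduce(log_k))
            pr = prior_pdf(new_values[i])
            log_w[i] = (math.log(pr) if pr > 0 else -np.inf) - mix
        log_w -= log_w.max()
        w = np.exp(log_w)
        w_sum = w.sum()
        if not np.isfinite(w_sum) or w_sum <= 0:
            raise CalibrationError("degenerate importance weights in ABC-SMC")
        w /= w_sum
        ess = 1.0 / float(np.sum(w**2))
        if ess < 2.0:
            raise CalibrationError(
                f"effective sample size collapsed (ESS={ess:.2f}) at generation {gen}"
            )

        prev_median = float(np.median(distances))
        values, weights, distances = new_values, w, new_distances
        generation = gen
        med = float(np.median(distances))
        history.append(
            {
                "generation": gen,
                "epsilon": eps,
                "acceptance_rate": accepted / attempts,
                "median_distance": med,
                "ess": ess,
            }
        )
        log.info(
            "gen %d: eps %.4g, acc %.2f, median %.4g, ESS %.1f",
            gen,
            eps,
            accepted / attempts,
            med,
            ess,
        )
        if prev_median > 0 and (prev_median - med) / prev_median < config.improvement_tol:
            break

    return ParticleSet(
        names=names,
        values=values,
        weights=weights,
        distances=distances,
        generation=generation,
        seed=config.seed,
        history=history,
    )


def calibrate_model(
    priors: Mapping[str, Prior],
    targets: CalibrationTargets,
    schedule,
    base: ParameterSet,
    config: ABCSMCConfig,
    t_end: float = 2018.0,
    steps_per_year: int | None = None,
) -> ParticleSet:
    """ABC-SMC over the cohort model (calibration window ends 1 Jan 2018)."""
    from .simulate import run_model, summarize_for_calibration

    def simulator(overrides: dict) -> pd.DataFrame:
        p = base.replace_flat(overrides)
        out = run_model(p, schedule, t_end=t_end, steps_per_year=steps_per_year)
        return summarize_for_calibration(out)

    targets.validate()
    return abc_smc(priors, targets, simulator, config)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


def weighted_quantile(
    values: Sequence[float], q, weights: Sequence[float] | None = None
) -> np.ndarray:
    """Weighted quantiles with linear interpolation.

    With equal weights this reproduces ``numpy.quantile``'s default
    (linear) convention exactly.
    """
    v = np.asarray(values, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantiles must lie in [0, 1]")
    if weights is None:
        w = np.full(v.size, 1.0 / v.size)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    t = np.cumsum(w) - 0.5 * w
    t = (t - t[0]) / (t[-1] - t[0]) if t[-1] > t[0] else np.zeros_like(t)
    return np.interp(q, t, v)


def credible_interval(
    particles: ParticleSet, f: Callable[[dict], float] | str
) -> tuple[float, float, float]:
    """(weighted mean, 2.5th, 97.5th percentile) of a particle functional.

    ``f`` is either a calibrated parameter name or a callable evaluated on
    each particle's flat parameter record.
    """
    if len(particles) == 0:
        raise ValueError("empty particle set")
    if isinstance(f, str):
        vals = particles.column(f)
    else:
        vals = np.array([f(particles.param_dict(i)) for i in range(len(particles))])
    mean = float(np.average(vals, weights=particles.weights))
    lo, hi = weighted_quantile(vals, [0.025, 0.975], particles.weights)
    return mean, float(lo), float(hi)
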