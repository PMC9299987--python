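"""Counterfactual specifications, impact metrics, PAF and ANCOVA."""

import numpy as np
import pytest

from oatimpact.calibrate import ParticleSet
from oatimpact.scenarios import (
    ScenarioSpec,
    baseline_scenario,
    impact,
    make_scenario,
    paf,
    scenario_battery,
    sensitivity_run,
    variance_decomposition,
)
from oatimpact.simulate import person_years, run_model


def _particles_from_flats(flats: list[dict]) -> ParticleSet:
    names = sorted(flats[0])
    values = np.array([[f[k] for k in names] for f in flats])
    n = len(flats)
    return ParticleSet(
        names=names,
        values=values,
        weights=np.full(n, 1.0 / n),
        distances=np.zeros(n),
        generation=0,
        seed=0,
    )


@pytest.fixture(scope="module")
def small_particles(request):
    """A hand-made posterior-style particle set over the key RRs."""
    rng = np.random.default_rng(21)
    flats = []
    for _ in range(5):
        flats.append(
            {
                "rr_od_oat_comm": float(rng.uniform(0.15, 0.20)),
                "rr_oth_oat_comm": float(rng.uniform(0.34, 0.42)),
                "rr_m1_on": float(rng.uniform(1.9, 2.7)),
                "rr_m1_off": float(rng.uniform(1.5, 2.4)),
            }
        )
    return _particles_from_flats(flats)


class TestMakeScenario:
    def test_no_oat_overrides(self):
        spec = make_scenario("no_oat")
        overrides = dict(spec.param_overrides)
        for key in (
            "rr_od_oat_comm",
            "rr_oth_oat_comm",
            "rr_od_oat_prison",
            "rr_oth_oat_prison",
            "rr_m1_on",
            "rr_m1_off",
            "rr_incarc_oat",
        ):
            assert overrides[key] == 1.0
        # mortality trends untouched
        assert not any(k.startswith(("mu_", "slope_")) for k in overrides)
        assert spec.denominator == "counterfactual"

    def test_no_prison_oat_implementation(self, ref_params):
        spec = make_scenario("no_prison_oat")
        p = spec.apply(ref_params)
        assert p.rates.enrol_prison == 0.0
        assert p.rates.prison_oat_exit == 100.0
        assert spec.prison_entries_off_oat

    def test_paf_scenarios_use_baseline_denominator(self):
        for name in ("no_rel_m1_risk", "no_oat_m1_risk", "no_off_m1_risk"):
            assert make_scenario(name).denominator == "baseline"

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            make_scenario("no_such_scenario")

    def test_empty_spec_equals_baseline_run(self, ref_params, nsw_schedule):
        base = run_model(ref_params, nsw_schedule, t_end=2010.0)
        via_spec = run_model(
            ref_params, nsw_schedule, t_end=2010.0, scenario=baseline_scenario()
        )
        assert np.array_equal(base.occupancy, via_spec.occupancy)
        assert np.array_equal(base.cum_od, via_spec.cum_od)


class TestImpact:
    def test_baseline_scenario_zero_impact(
        self, small_particles, nsw_schedule, ref_params
    ):
        summary = impact(
            small_particles, nsw_schedule, baseline_scenario(), ref_params
        )
        assert summary.mean("total_averted") == pytest.approx(0.0, abs=1e-6)
        assert summary.mean("lyg") == pytest.approx(0.0, abs=1e-4)

    def test_no_oat_counterfactual_antisymmetry(
        self, small_particles, nsw_schedule, ref_params
    ):
        """Removing protective RRs (< 1) increases deaths for every particle."""
        summary = impact(small_particles, nsw_schedule, "no_oat", ref_params)
        table = summary.per_particle
        assert (table["total_deaths_cf"] >= table["total_deaths_base"]).all()
        assert (table["od_averted"] > 0).all()
        assert (table["lyg"] > 0).all()

    def test_per_100py_arithmetic_identity(
        self, small_particles, nsw_schedule, ref_params
    ):
        summary = impact(small_particles, nsw_schedule, "no_oat", ref_params)
        t = summary.per_particle
        recon = t["averted_per_100py_oat"] * t["py_oat_base"] / 100.0
        assert np.allclose(recon, t["total_averted"], rtol=1e-9)

    def test_pct_denominator_conventions(
        self, small_particles, nsw_schedule, ref_params
    ):
        no_oat = impact(small_particles, nsw_schedule, "no_oat", ref_params)
        t = no_oat.per_particle
        assert np.allclose(
            t["pct_od_averted"],
            100 * t["od_averted"] / t["od_deaths_cf"],
        )
        rel = impact(small_particles, nsw_schedule, "no_off_m1_risk", ref_params)
        t = rel.per_particle
        assert np.allclose(
            t["pct_od_averted"],
            100 * (t["od_deaths_base"] - t["od_deaths_cf"]) / t["od_deaths_base"],
        )


class TestPAF:
    def test_removed_rr_already_one_gives_zero(self, nsw_schedule, ref_params):
        neutral = ref_params.replace_flat(
            {"rr_od_rel_m1": 1.0, "rr_oth_rel_m1": 1.0}
        )
        particles = _particles_from_flats(
            [{"rr_od_oat_comm": 0.174}, {"rr_od_oat_comm": 0.19}]
        )
        mean, lo, hi = paf(
            particles, nsw_schedule, "no_rel_m1_risk", neutral, cause="total"
        )
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_single_paf_below_joint_paf(self, nsw_schedule, ref_params):
        """Removing one first-month risk averts less than removing both."""
        particles = _particles_from_flats(
            [{"rr_m1_on": 2.3, "rr_m1_off": 1.8}, {"rr_m1_on": 2.0, "rr_m1_off": 2.2}]
        )
        joint = ScenarioSpec(
            name="no_both_m1",
            param_overrides=(("rr_m1_on", 1.0), ("rr_m1_off", 1.0)),
            denominator="baseline",
        )
        res = scenario_battery(
            particles,
            nsw_schedule,
            ref_params,
            ["no_oat_m1_risk", "no_off_m1_risk", joint],
        )
        for single in ("no_oat_m1_risk", "no_off_m1_risk"):
            s = res[single].per_particle["paf_total"].to_numpy()
            j = res["no_both_m1"].per_particle["paf_total"].to_numpy()
            assert np.all(s <= j + 1e-12)

    def test_paf_requires_risk_removal_scenario(
        self, small_particles, nsw_schedule, ref_params
    ):
        with pytest.raises(ValueError):
            paf(small_particles, nsw_schedule, "no_oat", ref_params)


def test_prison_share_metric(small_particles, nsw_schedule, ref_params):
    res = scenario_battery(
        small_particles, nsw_schedule, ref_params, ["no_oat", "no_prison_oat"]
    )
    share = res["no_prison_oat"].metrics["share_of_program_impact_pct"]
    assert 0.0 < share[0] < 100.0
    t_prog = res["no_oat"].per_particle["total_averted"].to_numpy()
    t_pris = res["no_prison_oat"].per_particle["total_averted"].to_numpy()
    expected = np.mean(100 * t_pris / t_prog)
    assert share[0] == pytest.approx(expected)


def test_sensitivity_identity_when_structure_unchanged(nsw_schedule, ref_params):
    """No-relapse sensitivity with relapse already absent equals baseline."""
    base = ref_params.replace_flat({"relapse_rate": 0.0})
    particles = _particles_from_flats(
        [{"rr_od_oat_comm": 0.174}, {"rr_od_oat_comm": 0.19}]
    )
    direct = impact(particles, nsw_schedule, "no_oat", base)
    via_sens, _ = sensitivity_run(
        "no_relapse",
        targets=None,
        schedule=nsw_schedule,
        base=base,
        priors={},
        config=None,
        recalibrate=False,
        particles=particles,
    )
    for key in ("pct_od_averted", "total_averted", "lyg"):
        assert via_sens.mean(key) == pytest.approx(direct.mean(key), rel=1e-12)


def test_sensitivity_unknown_variant(nsw_schedule, ref_params):
    with pytest.raises(ValueError):
        sensitivity_run(
            "bogus", None, nsw_schedule, ref_params, {}, None, recalibrate=False
        )


class TestVarianceDecomposition:
    def _particles(self, n=80, p=4, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(n, p))
        return ParticleSet(
            names=[f"x{i}" for i in range(p)],
            values=values,
            weights=np.full(n, 1.0 / n),
            distances=np.zeros(n),
            generation=0,
            seed=0,
        )

    def test_constant_outcome_all_zero(self):
        ps = self._particles()
        shares = variance_decomposition(ps, np.full(len(ps), 5.0))
        assert np.allclose(shares.to_numpy(), 0.0)

    def test_exact_linear_outcome_attributed_fully(self):
        ps = self._particles(seed=4)
        outcome = 3.0 * ps.column("x1") - 1.0
        shares = variance_decomposition(ps, outcome)
        # partial (type II) attribution: incidental sampling correlation with
        # the other regressors leaves a percent or two unattributed
        assert shares["x1"] == pytest.approx(100.0, abs=2.0)
        assert shares.drop("x1").max() < 2.0
        assert shares.index[0] == "x1"

    def test_shares_bounded_and_sum_reasonable(self):
        ps = self._particles(seed=9)
        rng = np.random.default_rng(1)
        outcome = (
            2 * ps.column("x0") + ps.column("x2") + 0.5 * rng.normal(size=len(ps))
        )
        shares = variance_decomposition(ps, outcome)
        assert (shares >= 0).all() and (shares <= 100).all()
        assert shares.sum() <= 100.0 + 1e-6

    def test_too_few_particles_rejected(self):
        ps = self._particles(n=20)
        with pytest.raises(ValueError):
            variance_decomposition(ps, np.zeros(20))

    def test_collinear_parameter_dropped_with_warning(self):
        ps = self._particles(n=60, p=3, seed=2)
        values = ps.values.copy()
        values[:, 2] = 2.0 * values[:, 0]  # exact collinearity
        ps2 = ParticleSet(
            names=ps.names,
            values=values,
            weights=ps.weights,
            distances=ps.distances,
            generation=0,
            seed=0,
        )
        outcome = values[:, 0] + np.random.default_rng(0).normal(size=60) * 0.1
        with pytest.warns(UserWarning):
            shares = variance_decomposition(ps2, outcome)
        assert "x2" not in shares.index
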