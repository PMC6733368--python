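"""Scenario enumeration, deviation scoring, sigma* search and fingerprints."""

import itertools

import numpy as np
import pytest

from fbgtwin.recipe_model import DesignSpace, ParameterStdDevs, PARAM_NAMES
from fbgtwin.robustness import (
    MaxTolerableResult,
    ScenarioResult,
    ScenarioSpec,
    build_scenarios,
    center_recipe,
    deviation_score,
    fraction_out_by_score,
    max_tolerable_deviation,
    risk_fingerprint,
    run_scenario,
    scenario_recipe,
)
from fbgtwin.simulator import simulate
from fbgtwin.synthetic_data import make_recipe


class TestDeviationScore:
    def test_worst_case_fifteen(self):
        spec = ScenarioSpec("I", "wet", 5.0, PARAM_NAMES, magnitude=2.0,
                            subphases=(0, 1, 2, 3, 4))
        assert deviation_score(spec) == 15

    def test_one_by_one(self):
        spec = ScenarioSpec("II", "wet", 5.0, ("F_spray",), subphases=(2,))
        assert deviation_score(spec) == 1

    def test_two_by_three(self):
        spec = ScenarioSpec("I", "dry", 5.0, ("F_spray", "T_in"), magnitude=2.0,
                            subphases=(0, 2, 4))
        assert deviation_score(spec) == 6

    def test_zero_magnitude_scores_zero(self):
        spec = ScenarioSpec("I", "wet", 5.0, ())
        assert deviation_score(spec) == 0

    def test_pulse_scenario_counts_parameters(self):
        spec = ScenarioSpec("III", "wet", 5.0, PARAM_NAMES,
                            pulses=((0.0, 300.0),))
        assert deviation_score(spec) == 3


def _brute_force_set_i_count(n_params: int, n_sub: int) -> int:
    """Independent enumeration oracle over explicit subsets."""
    count = 0
    for k in range(1, n_params + 1):
        for _ in itertools.combinations(range(n_params), k):
            for f in range(1, n_sub + 1):
                for _ in itertools.combinations(range(n_sub), f):
                    count += 1
    return count


class TestEnumeration:
    def test_set_i_count_matches_oracle(self, target_recipe):
        specs = build_scenarios("I", target_recipe, [5.0], ["wet"])
        assert len(specs) == _brute_force_set_i_count(3, 5) == 217

    def test_set_i_scores_span_1_to_15(self, target_recipe):
        specs = build_scenarios("I", target_recipe, [5.0], ["wet"])
        assert sorted(set(map(deviation_score, specs))) == sorted(
            {k * f for k in (1, 2, 3) for f in (1, 2, 3, 4, 5)}
        )
        assert max(map(deviation_score, specs)) == 15

    @pytest.mark.parametrize("n_sub", [1, 2, 3, 4])
    def test_set_i_closed_form_other_subphase_counts(self, n_sub):
        recipe = make_recipe("pilot", "target")
        spray = [p for p in recipe.phases if p.kind == "spray"][:n_sub]
        other = [p for p in recipe.phases if p.kind != "spray"]
        import dataclasses
        r = dataclasses.replace(recipe, phases=(other[0], *spray, *other[1:]))
        specs = build_scenarios("I", r, [5.0], ["wet"])
        assert len(specs) == (2**3 - 1) * (2**n_sub - 1)

    def test_set_ii_grid(self, target_recipe):
        specs = build_scenarios("II", target_recipe, [5.0], ["wet"])
        assert len(specs) == 15  # 3 parameters x 5 subphases
        assert all(s.search_range == tuple(range(1, 31)) for s in specs)

    def test_set_iii_six_five_minute_pulses(self, target_recipe):
        specs = build_scenarios("III", target_recipe, [5.0], ["wet"])
        assert len(specs) == 7  # parameter subsets of size 1-3
        for s in specs:
            assert len(s.pulses) == 6
            assert all(d == pytest.approx(300.0) for _, d in s.pulses)

    def test_set_iv_full_spray(self, target_recipe):
        specs = build_scenarios("IV", target_recipe, [5.0], ["wet", "dry"])
        assert len(specs) == 6
        assert all(s.subphases == (0, 1, 2, 3, 4) for s in specs)

    def test_recipe_without_spray_rejected(self):
        import dataclasses
        r = make_recipe("pilot", "target")
        dry_only = dataclasses.replace(
            r, phases=tuple(p for p in r.phases if p.kind != "spray"))
        with pytest.raises(Exception):
            build_scenarios("I", dry_only, [5.0], ["wet"])


class TestRunScenario:
    def test_zero_magnitude_nominal(self, target_recipe, true_params, sigmas,
                                    props, equip):
        ds = DesignSpace(5.0, 15.0)
        spec = ScenarioSpec("I", "wet", 5.0, ())
        res = run_scenario(target_recipe, true_params, spec, sigmas, ds,
                           props, equip)
        nominal = simulate(target_recipe.with_humidity(0.005), true_params,
                           props, equip).lod_max
        assert res.lod_max == pytest.approx(nominal)
        assert res.score == 0

    def test_wet_full_deviation_raises_lod_max(self, target_recipe, true_params,
                                               sigmas, props, equip):
        ds = DesignSpace(5.0, 15.0)
        nominal = simulate(target_recipe.with_humidity(0.005), true_params,
                           props, equip).lod_max
        spec = ScenarioSpec("I", "wet", 5.0, PARAM_NAMES, magnitude=2.0,
                            subphases=(0, 1, 2, 3, 4))
        res = run_scenario(target_recipe, true_params, spec, sigmas, ds,
                           props, equip)
        assert res.lod_max > nominal

    def test_direction_flip_straddles_nominal(self, target_recipe, true_params,
                                              sigmas, props, equip):
        ds = DesignSpace(0.1, 50.0)
        nominal = simulate(target_recipe.with_humidity(0.005), true_params,
                           props, equip).lod_max
        lods = {}
        for direction in ("wet", "dry"):
            spec = ScenarioSpec("I", direction, 5.0, ("F_spray",), magnitude=2.0,
                                subphases=(1, 2))
            lods[direction] = run_scenario(target_recipe, true_params, spec,
                                           sigmas, ds, props, equip).lod_max
        assert lods["dry"] < nominal < lods["wet"]


class TestFractionOut:
    def _result(self, score, out):
        spec = ScenarioSpec("I", "wet", 5.0, ("F_spray",), magnitude=2.0,
                            subphases=(0,))
        return ScenarioResult(spec, 10.0, not out, score)

    def test_all_in_range(self):
        res = [self._result(s, False) for s in (1, 2, 3)]
        assert fraction_out_by_score(res) == {1: 0.0, 2: 0.0, 3: 0.0}

    def test_counting(self):
        res = [self._result(6, True), self._result(6, True),
               self._result(6, False), self._result(6, False),
               self._result(2, True)]
        out = fraction_out_by_score(res)
        assert out[6] == 0.5
        assert out[2] == 1.0

    def test_empty(self):
        assert fraction_out_by_score([]) == {}


class TestMaxTolerableDeviation:
    def test_equals_exhaustive_grid_oracle(self, target_recipe, true_params,
                                           sigmas, props, equip):
        nominal = simulate(target_recipe.with_humidity(0.005), true_params,
                           props, equip).lod_max
        ds = DesignSpace(nominal - 2.0, nominal + 1.2)
        template = ScenarioSpec("IV", "wet", 5.0, ("F_spray",),
                                subphases=(0, 1, 2, 3, 4),
                                search_range=tuple(range(1, 11)))
        res = max_tolerable_deviation(target_recipe, true_params, template,
                                      sigmas, ds, props=props, equip=equip)
        # brute-force: simulate every grid magnitude, first failure rule
        star = 0
        for mag in range(1, 11):
            r = scenario_recipe(target_recipe, template, sigmas, float(mag))
            if not ds.contains(simulate(r, true_params, props, equip).lod_max):
                break
            star = mag
        assert res.sigma_star == star
        assert res.nominal_in_range

    def test_knife_edge_zero(self, target_recipe, true_params, sigmas, props,
                             equip):
        nominal = simulate(target_recipe.with_humidity(0.005), true_params,
                           props, equip).lod_max
        ds = DesignSpace(nominal - 1e-6, nominal + 1e-6)
        template = ScenarioSpec("IV", "wet", 5.0, ("F_spray",),
                                subphases=(0, 1, 2, 3, 4),
                                search_range=tuple(range(1, 6)))
        res = max_tolerable_deviation(target_recipe, true_params, template,
                                      sigmas, ds, props=props, equip=equip)
        assert res.sigma_star == 0
        assert not res.capped

    def test_wide_space_capped_at_grid_top(self, target_recipe, true_params,
                                           sigmas, props, equip):
        ds = DesignSpace(0.01, 90.0)
        template = ScenarioSpec("IV", "dry", 5.0, ("T_in",),
                                subphases=(0, 1, 2, 3, 4),
                                search_range=tuple(range(1, 6)))
        res = max_tolerable_deviation(target_recipe, true_params, template,
                                      sigmas, ds, props=props, equip=equip)
        assert res.sigma_star == 5
        assert res.capped

    def test_nominal_out_is_flagged(self, target_recipe, true_params, sigmas,
                                    props, equip):
        ds = DesignSpace(90.0, 95.0)
        template = ScenarioSpec("IV", "wet", 5.0, ("F_spray",),
                                subphases=(0, 1, 2, 3, 4),
                                search_range=(1, 2))
        res = max_tolerable_deviation(target_recipe, true_params, template,
                                      sigmas, ds, props=props, equip=equip)
        assert res.sigma_star is None
        assert not res.nominal_in_range

    def test_narrower_space_never_more_tolerant(self, target_recipe, true_params,
                                                sigmas, props, equip):
        nominal = simulate(target_recipe.with_humidity(0.005), true_params,
                           props, equip).lod_max
        template = ScenarioSpec("IV", "wet", 5.0, ("F_spray",),
                                subphases=(0, 1, 2, 3, 4),
                                search_range=tuple(range(1, 9)))
        wide = max_tolerable_deviation(
            target_recipe, true_params, template, sigmas,
            DesignSpace(nominal - 3.0, nominal + 2.0), props=props, equip=equip)
        narrow = max_tolerable_deviation(
            target_recipe, true_params, template, sigmas,
            DesignSpace(nominal - 1.0, nominal + 0.7), props=props, equip=equip)
        assert narrow.sigma_star <= wide.sigma_star


class TestFingerprintDeterminism:
    def test_identical_reruns(self, target_recipe, true_params, sigmas, props,
                              equip):
        ds = DesignSpace(5.0, 15.0)
        kw = dict(humidity_levels=[5.0], sets=("IV",), directions=("wet",),
                  props=props, equip=equip)
        a = risk_fingerprint(target_recipe, true_params, sigmas, ds, **kw)
        b = risk_fingerprint(target_recipe, true_params, sigmas, ds, **kw)
        assert [r.sigma_star for r in a.set_iv] == [r.sigma_star for r in b.set_iv]


class TestHumidityGroupedFingerprint:
    def test_each_level_uses_its_group_recipe(self, target_recipe, true_params,
                                              sigmas, props, equip):
        import dataclasses
        wetter = dataclasses.replace(
            target_recipe,
            phases=tuple(
                dataclasses.replace(p, F_spray_set=p.F_spray_set * 1.05)
                if p.kind == "spray" else p
                for p in target_recipe.phases
            ),
        )
        groups = {(1.0, 3.0): wetter, (4.0, 6.0): target_recipe,
                  (7.0, 10.0): target_recipe}
        ds = DesignSpace(5.0, 20.0)
        fp = risk_fingerprint(groups, true_params, sigmas, ds,
                              humidity_levels=(1.0, 5.0), sets=("IV",),
                              directions=("wet",), props=props, equip=equip)
        # dry-season group runs the compensating (wetter-spray) recipe
        lows = [r for r in fp.set_iv if r.spec.humidity_gkg == 1.0]
        mids = [r for r in fp.set_iv if r.spec.humidity_gkg == 5.0]
        assert lows and mids
        nominal_low = lows[0].lod_max_nominal
        nominal_mid = mids[0].lod_max_nominal
        base_low = simulate(target_recipe.with_humidity(0.001), true_params,
                            props, equip).lod_max
        assert nominal_low > base_low  # compensation pushed it wetter
        assert abs(nominal_low - nominal_mid) < abs(base_low - nominal_mid)


class TestCenterRecipe:
    def test_centers_and_conserves_binder(self, target_recipe, true_params,
                                          props, equip):
        from fbgtwin.recipe_model import total_binder_solution
        ds = DesignSpace(9.0, 13.0)
        centered = center_recipe(target_recipe, true_params, ds, props, equip)
        m = simulate(centered, true_params, props, equip).lod_max
        assert m == pytest.approx(ds.center, abs=0.05)
        assert total_binder_solution(centered) == pytest.approx(
            total_binder_solution(target_recipe)
        )
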