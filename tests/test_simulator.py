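"""Simulator unit and property tests: closures, ODE structure, trajectories."""

import dataclasses
import math

import numpy as np
import pytest

from fbgtwin.recipe_model import Phase, Recipe
from fbgtwin.simulator import (
    ModelParameters,
    SimulationState,
    corrected_flows,
    evaporation_efficiency,
    evaporation_rate,
    loss_on_drying,
    mass_transfer_coefficient,
    particle_surface_area,
    rhs,
    simulate,
)
from fbgtwin.thermo import EquipmentProperties, MaterialProperties


def _state(m_bed_w=1.0, m_bed_b=0.0, m_air_w=0.005, T_bed=25.0, T_air=30.0,
           T_wall=25.0, m_bed_s=60.0):
    return SimulationState(m_bed_w, m_bed_b, m_air_w, T_bed, T_air, T_wall, m_bed_s)


class TestLossOnDrying:
    def test_dry_bed(self):
        assert loss_on_drying(_state(m_bed_w=0.0)) == 0.0

    def test_arithmetic(self):
        assert loss_on_drying(_state(m_bed_w=2.0, m_bed_s=58.0)) == pytest.approx(
            3.3333, rel=1e-4
        )

    def test_binder_dilutes(self):
        base = loss_on_drying(_state(m_bed_w=2.0, m_bed_b=0.0))
        assert loss_on_drying(_state(m_bed_w=2.0, m_bed_b=5.0)) < base

    def test_empty_bed_raises(self):
        with pytest.raises((ZeroDivisionError, ValueError)):
            loss_on_drying(SimulationState(0, 0, 0, 25, 25, 25, 0))


class TestEvaporationEfficiency:
    def test_zero_at_dry(self):
        assert evaporation_efficiency(0.0, 5.0) == 0.0

    def test_cap_boundary(self):
        theta_e = 7.3
        assert evaporation_efficiency(theta_e * math.log(2.0), theta_e) == pytest.approx(1.0)

    def test_direct_value(self):
        assert evaporation_efficiency(5.0, 10.0) == pytest.approx(
            math.exp(0.5) - 1.0, rel=1e-12
        )

    def test_nondecreasing_and_bounded(self):
        lods = np.linspace(0, 30, 200)
        etas = [evaporation_efficiency(l, 5.0) for l in lods]
        assert all(0.0 <= e <= 1.0 for e in etas)
        assert all(b >= a for a, b in zip(etas, etas[1:]))


class TestParticleSurfaceArea:
    def test_worked_example(self):
        # 6 * 60 / (1500 * 2e-4) = 1200 m^2
        assert particle_surface_area(200e-6, 60.0, 1500.0) == pytest.approx(1200.0)

    def test_scaling(self):
        a = particle_surface_area(200e-6, 60.0, 1500.0)
        assert particle_surface_area(400e-6, 60.0, 1500.0) == pytest.approx(a / 2)
        assert particle_surface_area(200e-6, 120.0, 1500.0) == pytest.approx(2 * a)


class TestMassTransferCoefficient:
    def test_zero_efficiency(self, props):
        assert mass_transfer_coefficient(2e-3, 0.0, props, 0.6) == 0.0

    def test_stagnant_film_limit(self, props):
        # Re = 0 -> Sh = 2 -> k0 = 2 D / theta_p
        k = mass_transfer_coefficient(2e-3, 1.0, props, 0.0)
        assert k == pytest.approx(2 * props.D_w / 2e-3, rel=1e-12)

    def test_matches_correlation_oracle(self, props):
        theta_p, u = 200e-6, 0.9
        Re = props.rho_air * u * theta_p / props.mu_air
        Sc = props.mu_air / (props.rho_air * props.D_w)
        Sh = 2 + 0.6 * Re**0.5 * Sc ** (1 / 3)
        expected = Sh * props.D_w / theta_p
        assert mass_transfer_coefficient(theta_p, 1.0, props, u) == pytest.approx(expected)


class TestEvaporationRate:
    def test_dry_bed_zero(self, true_params, props, equip):
        assert evaporation_rate(_state(m_bed_w=0.0), true_params, props, equip, 0.35) == 0.0

    def test_saturated_chamber_zero(self, true_params, props, equip):
        from fbgtwin.thermo import saturation_concentration
        c_sat = saturation_concentration(25.0)
        st = _state(m_air_w=c_sat * equip.V_chamber, T_bed=25.0)
        assert evaporation_rate(st, true_params, props, equip, 0.35) == 0.0

    def test_arithmetic(self):
        # k * A_p * dc with k = 0.05, A_p = 1200, dc = 0.01 -> 0.6 kg/s
        assert 0.05 * 1200.0 * 0.01 == pytest.approx(0.6)


def test_corrected_flows():
    p = ModelParameters(2e-3, 5.0, alpha_spray=0.95, alpha_air=1.0)
    assert corrected_flows(0.10, 0.35, p) == (pytest.approx(0.095), pytest.approx(0.35))
    ident = ModelParameters(2e-3, 5.0)
    assert corrected_flows(0.10, 0.35, ident) == (0.10, 0.35)


class TestRHS:
    def test_equilibrium_fixed_point(self, true_params, props):
        equip = EquipmentProperties(T_env=40.0)
        x = 0.005
        st = SimulationState(
            m_bed_w=0.0, m_bed_b=0.0, m_air_w=x * equip.m_air,
            T_bed=40.0, T_air=40.0, T_wall=40.0, m_bed_s=60.0,
        )
        recipe = Recipe((Phase("p", "premix", 100.0, 40.0, 0.35, 0.0, x),),
                        m_solids_0=60.0, lod_0=0.0, T_bed_0=40.0, T_air_0=40.0,
                        T_wall_0=40.0)
        d = rhs(0.0, st, F_spray=0.0, F_air=0.35, T_in=40.0, x_in=x,
                recipe=recipe, params=true_params, props=props, equip=equip)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_binder_deposition_rate(self, true_params, props, equip, target_recipe):
        st = _state()
        d = rhs(0.0, st, F_spray=0.02, F_air=0.35, T_in=55.0, x_in=0.005,
                recipe=target_recipe, params=true_params, props=props, equip=equip)
        assert d[1] == pytest.approx(target_recipe.w_s * 0.02)

    def test_evaporation_cancels_in_water_sum(self, true_params, props, equip,
                                              target_recipe):
        st = _state(m_bed_w=5.0, T_bed=35.0)
        F_spray, F_air, x_in = 0.01, 0.35, 0.005
        d = rhs(0.0, st, F_spray=F_spray, F_air=F_air, T_in=55.0, x_in=x_in,
                recipe=target_recipe, params=true_params, props=props, equip=equip)
        x = st.m_air_w / equip.m_air
        expected = F_spray * (1 - target_recipe.w_s) + F_air * (x_in - x)
        assert d[0] + d[2] == pytest.approx(expected, rel=1e-12)

    def test_wall_balance_matches_heat_rates(self, true_params, props, equip,
                                             target_recipe):
        from fbgtwin.thermo import heat_transfer_rates
        st = _state(T_bed=30.0, T_air=50.0, T_wall=35.0)
        d = rhs(0.0, st, F_spray=0.0, F_air=0.35, T_in=55.0, x_in=0.005,
                recipe=target_recipe, params=true_params, props=props, equip=equip)
        Q = heat_transfer_rates(30.0, 50.0, 35.0, equip)
        expected = (Q["Q_bed_wall"] + Q["Q_air_wall"] - Q["Q_wall_env"]) / (
            equip.m_wall * props.cp_steel
        )
        assert d[5] == pytest.approx(expected, rel=1e-9)


class TestSimulate:
    def test_premix_only_equilibrated_flat(self, true_params, props):
        equip = EquipmentProperties(T_env=40.0)
        recipe = Recipe(
            (Phase("p", "premix", 1200.0, 40.0, 0.35, 0.0, 0.005),),
            m_solids_0=60.0, lod_0=0.0, T_bed_0=40.0, T_air_0=40.0, T_wall_0=40.0,
        )
        traj = simulate(recipe, true_params, props, equip)
        assert np.all(traj.lod == 0.0)

    def test_three_phase_shape(self, target_trajectory, target_recipe):
        traj = target_trajectory
        bounds = target_recipe.phase_start_times()
        spray_start, spray_end = target_recipe.spray_window()
        premix = traj.lod[traj.t <= spray_start]
        spray = traj.lod[(traj.t >= spray_start) & (traj.t <= spray_end)]
        dry = traj.lod[traj.t >= spray_end]
        # premix varies by no more than the small initial moisture charge
        assert premix.max() - premix.min() <= target_recipe.lod_0
        assert np.all(np.diff(spray) > 0)      # rising while spraying
        assert np.all(np.diff(dry) <= 1e-8)     # declining while drying
        assert traj.lod[-1] < 0.05             # dries out

    def test_lod_max_at_end_of_spray(self, target_trajectory, target_recipe):
        _, spray_end = target_recipe.spray_window()
        assert target_trajectory.t_at_lod_max == pytest.approx(spray_end)
        assert target_trajectory.lod_max == target_trajectory.lod.max()

    def test_bed_below_inlet_during_spray(self, target_trajectory, target_recipe):
        s0, s1 = target_recipe.spray_window()
        mask = (target_trajectory.t >= s0 + 60) & (target_trajectory.t <= s1)
        T_in = 55.0
        assert np.all(target_trajectory.states[mask, 3] < T_in)

    def test_deterministic(self, target_recipe, true_params, props, equip):
        a = simulate(target_recipe, true_params, props, equip)
        b = simulate(target_recipe, true_params, props, equip)
        assert np.array_equal(a.lod, b.lod)
        assert np.array_equal(a.states, b.states)

    def test_phase_boundaries_on_grid(self, target_trajectory, target_recipe):
        for tb in target_recipe.phase_start_times():
            assert np.any(np.isclose(target_trajectory.t, tb))

    def test_eta_and_evap_bounds_along_trajectory(self, target_trajectory,
                                                  true_params):
        assert np.all(target_trajectory.m_evap >= -1e-12)
        etas = np.minimum(np.exp(target_trajectory.lod / true_params.theta_e) - 1, 1.0)
        assert np.all((etas >= 0) & (etas <= 1))

    def test_no_spray_dry_air_lod_nonincreasing(self, true_params, props, equip):
        recipe = Recipe(
            (Phase("d", "dry", 3600.0, 70.0, 0.40, 0.0, 0.0),),
            m_solids_0=60.0, lod_0=6.0,
        )
        traj = simulate(recipe, true_params, props, equip)
        assert np.all(np.diff(traj.lod) <= 1e-8)
        assert traj.lod[-1] < 0.2


class TestInputSensitivities:
    """Finite-difference monotonicity of lod_max on the fixture recipe."""

    def _lod_max(self, recipe, true_params, props, equip):
        return simulate(recipe, true_params, props, equip).lod_max

    def _perturb(self, recipe, **changes):
        phases = []
        for p in recipe.phases:
            kw = {}
            for k, dv in changes.items():
                if k == "F_spray_set" and p.kind != "spray":
                    continue
                kw[k] = getattr(p, k) + dv
            phases.append(dataclasses.replace(p, **kw))
        return dataclasses.replace(recipe, phases=tuple(phases))

    @pytest.mark.parametrize(
        "change, direction",
        [
            ({"F_spray_set": +0.001}, +1),
            ({"T_in_set": +3.0}, -1),
            ({"F_air_set": +0.03}, -1),
            ({"x_in": +0.002}, +1),
        ],
    )
    def test_monotone(self, target_recipe, true_params, props, equip, change,
                      direction):
        base = self._lod_max(target_recipe, true_params, props, equip)
        up = self._lod_max(self._perturb(target_recipe, **change), true_params,
                           props, equip)
        assert (up - base) * direction > 0


def test_model_parameters_validation():
    with pytest.raises(ValueError):
        ModelParameters(-1e-3, 5.0)
    with pytest.raises(ValueError):
        ModelParameters(2e-3, 5.0, covariance=np.array([[1.0, 2.0], [0.0, 1.0]]))
    cov = np.array([[1e-8, 0], [0, 0.1]])
    p = ModelParameters(2e-3, 5.0, covariance=cov)
    assert p.covariance.shape == (2, 2)
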