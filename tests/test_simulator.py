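"""Simulator: step operations, routing, closed forms, brute-force oracle."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilleach import (
    ApplicationEvent,
    InvalidInputError,
    PesticideParams,
    SoilLayer,
    initial_topsoil_concentration,
    partition_subsurface,
    partition_topsoil,
    route_desorbed,
    simulate,
    step_solid,
    step_subsurface_water,
    step_topsoil_water,
)


class TestInitialConcentration:
    def test_dimensional_analysis_oracle(self):
        # 1 kg/ha fully deposited over 0.1 m of 0.5 kg/L soil:
        # 100 mg/m2 into 50 kg soil/m2 -> 2 mg/kg
        assert initial_topsoil_concentration(1e6, 1.0, 0.1, 0.5) == pytest.approx(2.0)

    def test_zero_deposition(self):
        assert initial_topsoil_concentration(1e6, 0.0, 0.1, 0.5) == 0.0

    def test_field_dose_hand_evaluation(self):
        # 0.64 kg/ha, 25.44% deposited, mixed over 0.12 m of 0.48 kg/L soil
        c0 = initial_topsoil_concentration(0.64e6, 0.2544, 0.12, 0.48)
        assert c0 == pytest.approx(0.64e6 * 0.2544 * 1e-4 / (0.12 * 0.48 * 1000))
        assert c0 == pytest.approx(0.28267, abs=1e-5)

    @pytest.mark.parametrize("p_dp,rho_b", [(0.0, 0.5), (0.1, 0.0), (-0.1, 0.5)])
    def test_nonpositive_geometry_rejected(self, p_dp, rho_b):
        with pytest.raises(InvalidInputError):
            initial_topsoil_concentration(1e6, 1.0, p_dp, rho_b)


class TestPartitioning:
    def test_topsoil_split(self):
        solid, water = partition_topsoil(10.0, 0.933, 0.48)
        assert solid == pytest.approx(9.33)
        assert water == pytest.approx(0.3216)

    @pytest.mark.parametrize(
        "f_ads,rho_b,expected",
        [(1.0, 0.48, (10.0, 0.0)), (0.0, 1.0, (0.0, 10.0))],
    )
    def test_topsoil_extremes(self, f_ads, rho_b, expected):
        assert partition_topsoil(10.0, f_ads, rho_b) == pytest.approx(expected)

    def test_subsurface_split(self):
        solid, water = partition_subsurface(1.0, 0.930, 0.57)
        assert solid == pytest.approx(1.6316, abs=1e-4)
        assert water == pytest.approx(0.070)

    @pytest.mark.parametrize(
        "f_ads,rho_b,expected",
        [(0.0, 0.57, (0.0, 1.0)), (0.5, 1.0, (0.5, 0.5))],
    )
    def test_subsurface_extremes(self, f_ads, rho_b, expected):
        assert partition_subsurface(1.0, f_ads, rho_b) == pytest.approx(expected)

    def test_topsoil_partition_is_mass_consistent(self):
        # total = c_solid + c_aqueous / rho_b returns exactly c0
        solid, water = partition_topsoil(7.3, 0.8, 0.55)
        assert solid + water / 0.55 == pytest.approx(7.3, abs=1e-12)


class TestStepOperations:
    def test_inert_solid_step(self):
        assert step_solid(100.0, 0.0, 1.0, 0.0, 0.0) == (100.0, 0.0)

    def test_decay_then_desorb_hand_values(self):
        c_next, desorbed = step_solid(100.0, 0.039, 1.0, 0.039, 0.0)
        decayed = 100.0 * math.exp(-0.039)
        assert desorbed == pytest.approx(decayed * 0.039)
        assert c_next == pytest.approx(decayed - desorbed)
        assert c_next == pytest.approx(92.42, abs=0.01)
        assert desorbed == pytest.approx(3.751, abs=0.001)

    def test_pure_application_step(self):
        assert step_solid(0.0, 0.5, 1.0, 0.2, 50.0) == (50.0, 0.0)

    def test_topsoil_water_one_half_life(self):
        k = 0.039
        assert step_topsoil_water(0.32, k, math.log(2) / k) == pytest.approx(0.16)

    @pytest.mark.parametrize("k,t,expected", [(0.0, 5.0, 0.32), (0.1, 0.0, 0.32)])
    def test_topsoil_water_identities(self, k, t, expected):
        assert step_topsoil_water(0.32, k, t) == pytest.approx(expected)

    def test_subsurface_water_memoryless_limit(self):
        # e^-k ~ 0: each day only the fresh input remains
        assert step_subsurface_water(1.0, 50.0, 1.0, 0.0) == pytest.approx(1.0)

    def test_subsurface_water_geometric_convergence(self):
        k = math.log(2)  # e^-k = 0.5
        c = 1.0
        assert step_subsurface_water(c, k, 1.0) == pytest.approx(1.5)
        for _ in range(60):
            c = step_subsurface_water(c, k, 1.0)
        assert c == pytest.approx(1.0 / (1 - 0.5), abs=1e-9)

    def test_subsurface_water_pure_accumulation(self):
        c = 1.0
        for _ in range(5):
            c = step_subsurface_water(c, 0.0, 1.0)
        assert c == pytest.approx(6.0)


class TestRouting:
    def test_five_day_hand_trace(self, two_layer_profile):
        fluxes = {"top": [0.0, 0.4, 0.3, 0.2, 0.1, 0.05], "sub": [0.0] * 6}
        routed = route_desorbed(two_layer_profile, fluxes)
        # arrival at the top/sub boundary is day 3: days 1-2 stay in the
        # top layer's own water, days 3+ become the lower layer's input
        np.testing.assert_allclose(routed["sub"], [0, 0, 0, 0.2, 0.1, 0.05])

    def test_zero_desorption_routes_nothing(self, two_layer_profile):
        routed = route_desorbed(two_layer_profile, {"top": [0.0] * 4, "sub": [0.0] * 4})
        assert not routed["sub"].any()

    def test_single_layer_profile_is_degenerate(self):
        layer = SoilLayer("only", 0.0, 0.2, 0.5, 0.9, 0.05, 0.1)
        assert route_desorbed([layer], {"only": [0.1, 0.2]}) == {}

    def test_non_monotone_arrivals_rejected(self):
        layers = [
            SoilLayer("a", 0.0, 0.2, 0.5, 0.9, 0.05, 0.1, tracer_arrival_day=3),
            SoilLayer("b", 0.2, 0.4, 0.5, 0.9, 0.05, 0.1, tracer_arrival_day=2),
        ]
        with pytest.raises(InvalidInputError):
            route_desorbed(layers, {"a": [0.0], "b": [0.0]})


def brute_force_trajectory(profile, pesticide, schedule, horizon):
    """Independent day-by-day reference loop, coded directly from the
    update rules without reusing the simulator internals."""
    solid = {L.layer_id: 0.0 for L in profile}
    water = {L.layer_id: 0.0 for L in profile}
    out = {}
    for day in range(horizon + 1):
        if day > 0:
            incoming = {L.layer_id: 0.0 for L in profile}
            new_solid, new_water = {}, {}
            for idx, L in enumerate(profile):
                dec = solid[L.layer_id] * math.exp(-L.k)
                des = dec * L.f_des
                new_solid[L.layer_id] = dec - des
                w = water[L.layer_id] * math.exp(-L.k)
                if L.tracer_arrival_day is None or day < L.tracer_arrival_day:
                    w = w + des * L.rho_b
                elif idx + 1 < len(profile):
                    incoming[profile[idx + 1].layer_id] = des * L.rho_b
                new_water[L.layer_id] = w
            for L in profile:
                c_in = incoming[L.layer_id]
                new_solid[L.layer_id] += c_in * L.f_ads / L.rho_b
                new_water[L.layer_id] += c_in * (1.0 - L.f_ads)
            solid, water = new_solid, new_water
        for ev in sorted(
            (e for e in schedule if e.day == day),
            key=lambda e: 0 if e.route == "soil" else 1,
        ):
            top = profile[0]
            if ev.route == "soil":
                c0 = ev.dose * 1.0 * 1e-4 / (pesticide.p_dp_soil * top.rho_b * 1000.0)
            else:
                c0 = (
                    ev.dose
                    * pesticide.f_soil
                    * 1e-4
                    / (pesticide.p_dp_foliar * top.rho_b * 1000.0)
                )
            solid[top.layer_id] += c0 * top.f_ads
            water[top.layer_id] += c0 * (1.0 - top.f_ads) * top.rho_b
        for L in profile:
            out[(L.layer_id, day)] = (solid[L.layer_id], water[L.layer_id])
    return out


class TestSimulate:
    def test_matches_brute_force_oracle_everywhere(self, dimethomorph):
        profile = [
            SoilLayer("L1", 0.0, 0.2, 0.5, 0.9, 0.05, 0.1, tracer_arrival_day=3),
            SoilLayer("L2", 0.2, 0.4, 0.6, 0.8, 0.05, 0.01, tracer_arrival_day=40),
        ]
        schedule = [
            ApplicationEvent(day=0, route="soil", dose=1.0e6),
            ApplicationEvent(day=10, route="foliar", dose=0.5e6),
        ]
        result = simulate(profile, dimethomorph, schedule, horizon=30)
        oracle = brute_force_trajectory(profile, dimethomorph, schedule, 30)
        for (lid, day), (solid, water) in oracle.items():
            state = result.trajectory[(lid, day)]
            assert state.c_solid == pytest.approx(solid, abs=1e-10)
            assert state.c_aqueous == pytest.approx(water, abs=1e-10)

    def test_topsoil_closed_form_decay_without_desorption(self, dimethomorph):
        profile = [SoilLayer("top", 0.0, 0.2, 0.48, 0.933, 0.0, 0.039, tracer_arrival_day=1)]
        schedule = [ApplicationEvent(day=0, route="soil", dose=0.64e6)]
        result = simulate(profile, dimethomorph, schedule, horizon=60)
        c0 = initial_topsoil_concentration(0.64e6, 1.0, 0.12, 0.48)
        for day in range(61):
            assert result.total_at("top", day) == pytest.approx(
                c0 * math.exp(-0.039 * day), abs=1e-12
            )

    def test_day_zero_total_recovers_initial_concentration(self, dimethomorph):
        profile = [SoilLayer("top", 0.0, 0.2, 0.48, 0.933, 0.039, 0.039)]
        schedule = [ApplicationEvent(day=0, route="soil", dose=0.64e6)]
        result = simulate(profile, dimethomorph, schedule, horizon=1)
        c0 = initial_topsoil_concentration(0.64e6, 1.0, 0.12, 0.48)
        assert result.total_at("top", 0) == pytest.approx(c0, abs=1e-12)

    def test_constant_input_fixed_point(self, dimethomorph):
        # frozen routed flux: the receiving layer's water converges to
        # input / (1 - e^-k) within 0.1% by day 10/k
        k2 = 0.2
        profile = [
            SoilLayer("top", 0.0, 0.2, 0.5, 0.9, 0.05, 0.05, tracer_arrival_day=1),
            SoilLayer("sub", 0.2, 0.4, 0.6, 0.0, 0.0, k2),
        ]
        schedule = [ApplicationEvent(day=0, route="soil", dose=1.0e6)]
        horizon = int(10 / k2) + 2
        result = simulate(profile, dimethomorph, schedule, horizon, flux_mode="constant")
        # the frozen daily input equals the flux delivered on arrival day 1
        top = result.trajectory[("top", 1)]
        frozen_input = top.desorbed_flux
        fixed_point = frozen_input / (1 - math.exp(-k2))
        final = result.trajectory[("sub", horizon)].c_aqueous
        assert final == pytest.approx(fixed_point, rel=1e-3)
        # convergence is monotone from below
        series = [result.trajectory[("sub", d)].c_aqueous for d in range(1, horizon + 1)]
        assert all(a <= b + 1e-15 for a, b in zip(series, series[1:]))

    def test_linearity_in_dose(self, andisol_profile, dimethomorph):
        schedule1 = [ApplicationEvent(day=0, route="soil", dose=0.64e6)]
        schedule2 = [ApplicationEvent(day=0, route="soil", dose=1.28e6)]
        r1 = simulate(andisol_profile, dimethomorph, schedule1, horizon=120)
        r2 = simulate(andisol_profile, dimethomorph, schedule2, horizon=120)
        for key, state in r1.trajectory.items():
            doubled = r2.trajectory[key]
            assert doubled.c_solid == pytest.approx(2 * state.c_solid, abs=1e-12)
            assert doubled.c_aqueous == pytest.approx(2 * state.c_aqueous, abs=1e-12)

    def test_deterministic_rerun(self, andisol_profile, dimethomorph, single_soil_dose):
        r1 = simulate(andisol_profile, dimethomorph, single_soil_dose, horizon=100)
        r2 = simulate(andisol_profile, dimethomorph, single_soil_dose, horizon=100)
        assert r1.trajectory == r2.trajectory

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        f_ads=st.floats(0, 1),
        f_des=st.floats(0, 1),
        k=st.floats(0, 1),
        dose=st.floats(0, 5e6),
    )
    def test_concentrations_never_negative(self, f_ads, f_des, k, dose):
        profile = [
            SoilLayer("a", 0.0, 0.2, 0.5, f_ads, f_des, k, tracer_arrival_day=2),
            SoilLayer("b", 0.2, 0.4, 0.6, f_ads, f_des, k / 2),
        ]
        pest = PesticideParams(name="x", f_soil=0.3, p_dp_soil=0.1, p_dp_foliar=0.02)
        schedule = [
            ApplicationEvent(day=0, route="soil", dose=dose),
            ApplicationEvent(day=3, route="foliar", dose=dose),
        ]
        result = simulate(profile, pest, schedule, horizon=15)
        for state in result.trajectory.values():
            assert state.c_solid >= 0
            assert state.c_aqueous >= 0

    def test_event_beyond_horizon_warns_and_is_ignored(self, dimethomorph):
        profile = [SoilLayer("top", 0.0, 0.2, 0.5, 0.9, 0.0, 0.1)]
        schedule = [ApplicationEvent(day=50, route="soil", dose=1e6)]
        with pytest.warns(UserWarning, match="beyond horizon"):
            result = simulate(profile, dimethomorph, schedule, horizon=10)
        assert all(s.c_solid == 0 for s in result.trajectory.values())

    def test_negative_dose_rejected(self):
        with pytest.raises(InvalidInputError):
            ApplicationEvent(day=0, route="soil", dose=-1.0)

    def test_tidy_frame_shape_and_totals(self, andisol_profile, dimethomorph, single_soil_dose):
        result = simulate(andisol_profile, dimethomorph, single_soil_dose, horizon=30)
        df = result.to_frame()
        assert len(df) == 5 * 31
        row = df[(df.layer_id == "SL1") & (df.day == 0)].iloc[0]
        assert row.total_mg_kg == pytest.approx(
            row.c_solid_mg_kg + row.c_aqueous_mg_L / 0.48
        )
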