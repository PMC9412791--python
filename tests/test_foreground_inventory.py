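"""Quantity arithmetic and foreground-system construction."""

import dataclasses

import networkx as nx
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brushlca.errors import ConfigurationError, DomainError
from brushlca.foreground_inventory import (
    Scenario,
    annual_water_litres,
    apply_scenario,
    build_provision_system,
    build_supervised_system,
    default_grouping,
    mixing_energy_per_tube,
    per_child_bus_mass,
    per_child_travel_km,
    provision_defaults,
    supervised_defaults,
    tap_run_litres,
    toothpaste_recipe,
    TOOTHPASTE_MASS_FRACTIONS,
)


@pytest.mark.parametrize(
    "flow,seconds,expected",
    [(6, 20, 2.0), (6, 0, 0.0), (12, 20, 4.0)],
)
def test_tap_run_litres(flow, seconds, expected):
    assert tap_run_litres(flow, seconds) == pytest.approx(expected)


@pytest.mark.parametrize(
    "per_episode,episodes,expected",
    [(2, 195, 390.0), (2, 730, 1460.0), (0, 195, 0.0)],
)
def test_annual_water_litres(per_episode, episodes, expected):
    assert annual_water_litres(per_episode, episodes) == pytest.approx(expected)


@pytest.mark.parametrize(
    "func,args",
    [
        (tap_run_litres, (-1, 20)),
        (annual_water_litres, (2, -1)),
        (toothpaste_recipe, (-5,)),
    ],
)
def test_negative_inputs_rejected(func, args):
    with pytest.raises(DomainError):
        func(*args)


def test_recipe_fractions_sum_to_one_exactly():
    assert sum(TOOTHPASTE_MASS_FRACTIONS.values()) == pytest.approx(1.0, rel=1e-12)


def test_recipe_of_100g():
    masses = toothpaste_recipe(100.0)
    assert len(masses) == 7
    assert masses["sorbitol"] == pytest.approx(53.66)
    assert sum(masses.values()) == pytest.approx(100.0, rel=1e-12)


@given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
def test_recipe_conserves_mass(total):
    masses = toothpaste_recipe(total)
    assert all(m >= 0 for m in masses.values())
    assert sum(masses.values()) == pytest.approx(total, rel=1e-12, abs=1e-12)


@pytest.mark.parametrize(
    "power,hours,batch,tube,expected",
    [(68, 2.4, 500, 100, 0.03264), (68, 0, 500, 100, 0.0), (68, 2.4, 500, 500, 0.1632)],
)
def test_mixing_energy_per_tube(power, hours, batch, tube, expected):
    assert mixing_energy_per_tube(power, hours, batch, tube) == pytest.approx(expected)


def test_mixing_energy_rejects_zero_volumes():
    with pytest.raises(DomainError):
        mixing_energy_per_tube(68, 2.4, 0, 100)


@pytest.mark.parametrize(
    "round_trip,children,trips,commute,expected",
    [(13, 180, 4, 0, 0.28889), (13, 180, 1, 0, 0.07222), (0, 180, 4, 0, 0.0)],
)
def test_per_child_travel_km(round_trip, children, trips, commute, expected):
    got = per_child_travel_km(round_trip, children, trips, commute)
    assert got == pytest.approx(expected, abs=1e-4)


def test_travel_requires_children():
    with pytest.raises(DomainError):
        per_child_travel_km(13, 0, 4, 0)


@pytest.mark.parametrize(
    "mass,buses,children,expected",
    [(177, 3, 10, 53.1), (177, 1, 10, 17.7), (177, 0, 10, 0.0)],
)
def test_per_child_bus_mass(mass, buses, children, expected):
    assert per_child_bus_mass(mass, buses, children) == pytest.approx(expected)


def test_supervised_demand_covers_stated_quantities(supervised_system):
    demand = supervised_system.demand
    assert demand["tap_water_service"] == pytest.approx(390.0)
    assert demand["toothbrush_plastic"] == 5
    assert demand["toothpaste_tube"] == pytest.approx(0.65)
    assert demand["bus_service"] == pytest.approx(53.1)
    assert demand["travel_service"] == pytest.approx(13 * 4 / 180)


def test_provision_demand_covers_stated_quantities(provision_system):
    demand = provision_system.demand
    assert demand["toothpaste_tube"] == 4
    assert demand["toothbrush_plastic"] == 4
    assert demand["tap_water_service"] == pytest.approx(1460.0)
    assert demand["bag_service"] == 4
    assert "bus_service" not in demand


def test_provision_bag_mass_is_1_5_g(provision_system):
    proc = provision_system.processes["bag_mfg"]
    pp = dict(proc.product_inputs)["polypropylene_film_bag"]
    assert pp == pytest.approx(1.5e-3)


def test_bamboo_scenario_swaps_brush_process():
    params = apply_scenario(
        supervised_defaults(), Scenario("bamboo", {"brush_material": "bamboo"})
    )
    system = build_supervised_system(params)
    assert "brush_bamboo_mfg" in system.processes
    assert "brush_plastic_mfg" not in system.processes
    assert system.demand["tap_water_service"] == pytest.approx(390.0)


def test_exclude_water_zeroes_only_water_demand():
    base = build_provision_system(provision_defaults())
    varied = build_provision_system(
        apply_scenario(
            provision_defaults(), Scenario("nw", {"water_L_per_episode": 0.0})
        )
    )
    assert varied.demand["tap_water_service"] == 0.0
    for fid, amount in base.demand.items():
        if fid != "tap_water_service":
            assert varied.demand[fid] == amount


def test_built_systems_are_acyclic_and_covered(supervised_system, provision_system):
    for system in (supervised_system, provision_system):
        system.validate()
        assert nx.is_directed_acyclic_graph(system.product_graph())


def test_default_grouping_covers_all_processes(supervised_system):
    grouping = default_grouping(supervised_system)
    assert set(grouping) == set(supervised_system.processes)
    assert set(grouping.values()) == {
        "toothbrush", "toothpaste", "water", "staff travel", "holder/bag",
    }


def test_scenario_unknown_key_rejected():
    with pytest.raises(ConfigurationError):
        apply_scenario(supervised_defaults(), Scenario("bad", {"nope": 1}))


def test_scenario_application_is_idempotent():
    scenario = Scenario("double", {"tubes_per_year": 1.3})
    once = apply_scenario(supervised_defaults(), scenario)
    twice = apply_scenario(once, scenario)
    assert once == twice
    assert once.tubes_per_year == pytest.approx(1.3)


def test_empty_scenario_is_identity():
    params = supervised_defaults()
    assert apply_scenario(params, Scenario("noop", {})) == params


def test_scenario_overrides_touch_only_named_fields():
    params = provision_defaults()
    varied = apply_scenario(params, Scenario("paper", {"bag_material": "paper"}))
    for f in dataclasses.fields(params):
        if f.name != "bag_material":
            assert getattr(varied, f.name) == getattr(params, f.name)
    assert varied.bag_material == "paper"
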