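"""Inventory solve, characterization, normalization, contributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brushlca.errors import (
    CoverageError,
    InventorySolveError,
    MissingFactorError,
    ValidationError,
)
from brushlca.foreground_inventory import Flow, ForegroundSystem, Process
from brushlca.lcia_engine import (
    CharacterizationTable,
    LCIAResult,
    aggregate_inventory,
    build_intervention_matrix,
    build_technology_matrix,
    characterize,
    contribution_by_group,
    contribution_summary,
    normalize,
    solve_scaling,
)


def _two_level_chain():
    """Brush process drawing 0.015 kg polymer per item from a polymer process."""
    system = ForegroundSystem()
    system.flows = {
        "brush": Flow("brush", "brush", "item", "product"),
        "polymer": Flow("polymer", "polymer", "kg", "product"),
        "raw_polymer": Flow("raw_polymer", "raw", "kg", "elementary"),
    }
    system.processes = {
        "brush_mfg": Process(
            "brush_mfg", "brush", ("brush", 1.0),
            product_inputs=(("polymer", 0.015),),
        ),
        "polymer_supply": Process(
            "polymer_supply", "polymer", ("polymer", 1.0),
            elementary_exchanges=(("raw_polymer", 1.0),),
        ),
    }
    system.demand = {"brush": 5.0}
    return system


def test_identity_system_scaling_equals_demand():
    A = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("pqr"))
    s = solve_scaling(A, {"a": 2.0, "c": 7.0})
    assert s.tolist() == [2.0, 0.0, 7.0]


def test_two_level_chain_draws_0075_kg_polymer():
    system = _two_level_chain()
    A = build_technology_matrix(system)
    s = solve_scaling(A, system.demand)
    assert s["polymer_supply"] == pytest.approx(0.075)
    g = aggregate_inventory(build_intervention_matrix(system), s)
    assert g["raw_polymer"] == pytest.approx(0.075)


def test_zero_column_matrix_raises():
    A = pd.DataFrame(
        [[1.0, 0.0], [0.0, 0.0]], index=["a", "b"], columns=["p", "q"]
    )
    with pytest.raises(InventorySolveError):
        solve_scaling(A, {"a": 1.0})


def test_demand_for_unproduced_flow_raises():
    A = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["p", "q"])
    with pytest.raises(CoverageError):
        solve_scaling(A, {"zzz": 1.0})


def test_aggregate_inventory_matches_row_dot_products():
    rng = np.random.default_rng(11)
    B = pd.DataFrame(
        rng.uniform(0, 3, size=(4, 5)),
        index=[f"e{i}" for i in range(4)],
        columns=[f"p{i}" for i in range(5)],
    )
    s = pd.Series(rng.uniform(0, 2, size=5), index=B.columns)
    g = aggregate_inventory(B, s)
    for fid in B.index:
        assert g[fid] == pytest.approx(
            sum(B.loc[fid, p] * s[p] for p in B.columns)
        )


def test_aggregate_inventory_dimension_mismatch():
    B = pd.DataFrame(np.ones((1, 2)), index=["e"], columns=["p", "q"])
    with pytest.raises(ValidationError):
        aggregate_inventory(B, pd.Series({"p": 1.0}))


def _unit_cf(registry, flows, factor=1.0):
    rows = [
        (cat.id, fid, factor, "u") for cat in registry for fid in flows
    ]
    return CharacterizationTable(
        pd.DataFrame(rows, columns=["category_id", "flow_id", "factor", "unit"])
    )


def test_characterize_unit_factor(registry):
    cf = _unit_cf(registry, ["co2"])
    result = characterize({"co2": 2.0}, cf, registry)
    assert result.scores["CC"] == pytest.approx(2.0)
    assert len(result.scores) == 16


def test_characterize_matches_double_loop(registry, foreground_cf):
    rng = np.random.default_rng(5)
    flows = sorted(foreground_cf.flow_ids())
    g = pd.Series(rng.uniform(0, 4, len(flows)), index=flows)
    result = characterize(g, foreground_cf, registry)
    for cid in registry.ids():
        brute = sum(foreground_cf.factor(cid, f) * g[f] for f in flows)
        assert result.scores[cid] == pytest.approx(brute, rel=1e-9)


def test_characterize_is_additive(registry, foreground_cf):
    rng = np.random.default_rng(9)
    flows = sorted(foreground_cf.flow_ids())
    g1 = pd.Series(rng.uniform(0, 2, len(flows)), index=flows)
    g2 = pd.Series(rng.uniform(0, 2, len(flows)), index=flows)
    r12 = characterize(g1 + g2, foreground_cf, registry)
    r1 = characterize(g1, foreground_cf, registry)
    r2 = characterize(g2, foreground_cf, registry)
    for cid in registry.ids():
        assert r12.scores[cid] == pytest.approx(
            r1.scores[cid] + r2.scores[cid], rel=1e-9, abs=1e-12
        )


def test_characterize_strict_missing_factor(registry):
    cf = _unit_cf(registry, ["co2"])
    with pytest.raises(MissingFactorError):
        characterize({"mystery": 1.0}, cf, registry, strict=True)
    lenient = characterize({"mystery": 1.0}, cf, registry, strict=False)
    assert all(v == 0.0 for v in lenient.scores.values())


def test_normalize_unit_reference_and_exclusions(registry):
    scores = {cid: 5.0 for cid in registry.ids()}
    result = LCIAResult("supervised", "baseline", scores)
    refs = {cid: 1.0 for cid in registry.ids()}
    norm = normalize(result, refs)
    assert norm.excluded == {"ECF", "HCE", "HNC"}
    assert set(norm.values) == set(registry.ids()) - norm.excluded
    assert all(v == pytest.approx(5.0) for v in norm.values.values())


def test_normalize_division(registry):
    scores = {cid: 8.37 for cid in registry.ids()}
    refs = {cid: 8370.0 for cid in registry.ids()}
    norm = normalize(LCIAResult("p", "b", scores), refs)
    assert norm.values["RDW"] == pytest.approx(0.001)


def test_normalize_rejects_bad_references(registry):
    result = LCIAResult("p", "b", {cid: 1.0 for cid in registry.ids()})
    with pytest.raises(ValidationError):
        normalize(result, {})
    bad = {cid: 1.0 for cid in registry.ids()}
    bad["CC"] = 0.0
    with pytest.raises(ValidationError):
        normalize(result, bad)


@given(st.floats(min_value=0.5, max_value=8.0))
def test_linearity_doubling_demand_doubles_scores(k):
    from brushlca.impact_schema import register_default_categories
    from brushlca.lcia_engine import compute_lcia
    from brushlca.synthetic_background import (
        SyntheticBackgroundSpec,
        generate_cf_table,
    )

    registry = register_default_categories()
    system = _two_level_chain()
    cf = generate_cf_table(
        SyntheticBackgroundSpec(seed=2), flow_ids=["raw_polymer"],
        registry=registry,
    )
    base = compute_lcia(system, cf, registry)
    scaled = ForegroundSystem(
        system.flows, system.processes,
        {fid: k * amt for fid, amt in system.demand.items()},
    )
    res = compute_lcia(scaled, cf, registry)
    for cid, val in base.scores.items():
        assert res.scores[cid] == pytest.approx(k * val, rel=1e-9, abs=1e-300)


def test_contribution_single_group_is_100pct(registry):
    system = _two_level_chain()
    cf = _unit_cf(registry, ["raw_polymer"])
    grouping = {pid: "all" for pid in system.processes}
    breakdown = contribution_by_group(
        system, system.demand, cf, grouping, registry
    )
    np.testing.assert_allclose(
        breakdown.shares["all"].dropna().to_numpy(), 100.0, rtol=1e-9
    )


def test_contribution_symmetry_two_equal_groups(registry):
    system = ForegroundSystem()
    for tag in ("x", "y"):
        system.flows[tag] = Flow(tag, tag, "kg", "product")
        system.processes[tag] = Process(
            tag, tag, (tag, 1.0), elementary_exchanges=(("co2", 1.0),)
        )
    system.flows["co2"] = Flow("co2", "co2", "kg", "elementary")
    system.demand = {"x": 1.0, "y": 1.0}
    cf = _unit_cf(registry, ["co2"])
    breakdown = contribution_by_group(
        system, system.demand, cf, {"x": "gx", "y": "gy"}, registry
    )
    assert breakdown.shares.loc["CC", "gx"] == pytest.approx(50.0)
    assert breakdown.shares.loc["CC", "gy"] == pytest.approx(50.0)


def test_contribution_conserves_total(registry, supervised_system, foreground_cf):
    from brushlca.foreground_inventory import default_grouping
    from brushlca.lcia_engine import compute_lcia

    breakdown = contribution_by_group(
        supervised_system,
        supervised_system.demand,
        foreground_cf,
        default_grouping(supervised_system),
        registry,
    )
    total = compute_lcia(supervised_system, foreground_cf, registry)
    for cid in registry.ids():
        assert breakdown.scores.loc[cid].sum() == pytest.approx(
            total.scores[cid], rel=1e-9
        )
        if total.scores[cid] > 0:
            assert breakdown.shares.loc[cid].sum() == pytest.approx(
                100.0, rel=1e-6
            )


def test_contribution_unlabelled_process_raises(registry, supervised_system,
                                                foreground_cf):
    with pytest.raises(ValidationError):
        contribution_by_group(
            supervised_system, supervised_system.demand, foreground_cf,
            {}, registry,
        )


def test_contribution_summary_mean_and_range(registry):
    shares = pd.DataFrame(
        {"g1": [10.0, 50.0], "g2": [90.0, 50.0]}, index=["CC", "EAC"]
    )
    scores = shares.copy()
    from brushlca.lcia_engine import ContributionBreakdown

    summary = contribution_summary(ContributionBreakdown(scores, shares))
    assert summary.loc["g1", "mean_share_pct"] == pytest.approx(30.0)
    assert summary.loc["g1", "min_share_pct"] == pytest.approx(10.0)
    assert summary.loc["g1", "max_share_pct"] == pytest.approx(50.0)


def test_contribution_summary_empty_raises():
    from brushlca.lcia_engine import ContributionBreakdown

    empty = pd.DataFrame()
    with pytest.raises(ValidationError):
        contribution_summary(ContributionBreakdown(empty, empty))
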