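import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from brushlca.foreground_inventory import (  # noqa: E402
    build_provision_system,
    build_supervised_system,
    provision_defaults,
    supervised_defaults,
)
from brushlca.impact_schema import register_default_categories  # noqa: E402
from brushlca.synthetic_background import (  # noqa: E402
    SyntheticBackgroundSpec,
    generate_cf_table,
)


@pytest.fixture(scope="session")
def registry():
    return register_default_categories()


@pytest.fixture(scope="session")
def supervised_system():
    return build_supervised_system(supervised_defaults())


@pytest.fixture(scope="session")
def provision_system():
    return build_provision_system(provision_defaults())


@pytest.fixture(scope="session")
def foreground_cf(registry, supervised_system, provision_system):
    """One synthetic CF table covering both programmes and all scenarios."""
    from brushlca.foreground_inventory import Scenario, apply_scenario
    from brushlca.scenario_analysis import default_scenarios

    flows: dict = {}
    for programme, builder, defaults in (
        ("supervised", build_supervised_system, supervised_defaults),
        ("provision", build_provision_system, provision_defaults),
    ):
        for scn in [Scenario("baseline", {})] + default_scenarios(programme):
            system = builder(apply_scenario(defaults(), scn))
            for fid in system.elementary_flow_ids():
                flows.setdefault(fid)
    return generate_cf_table(
        SyntheticBackgroundSpec(seed=42), flow_ids=list(flows), registry=registry
    )
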