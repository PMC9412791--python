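"""Sensitivity scenarios and programme comparisons.

Each programme ships with its published sensitivity set:

* supervised — swap plastic brushes for bamboo; double the toothpaste
  dose (0.5 g instead of 0.25 g per episode, i.e. 1.3 tubes/year
  instead of 0.65);
* provision — bamboo brushes; paper instead of plastic bag; both swaps
  together; exclude at-home water use entirely.

Percent changes are computed relative to the baseline column, with a
round-half-away-from-zero integer helper for report-style figures
("climate change reduced by 15%"); raw signed floats are always kept in
the data model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, DomainError, ValidationError
from .foreground_inventory import (
    ForegroundSystem,
    ProgrammeParameters,
    Scenario,
    apply_scenario,
    build_provision_system,
    build_supervised_system,
    provision_defaults,
    supervised_defaults,
)
from .impact_schema import CategoryRegistry
from .lcia_engine import CharacterizationTable, LCIAResult, compute_lcia

__all__ = [
    "percent_change",
    "rounded_percent_change",
    "ScenarioComparison",
    "default_scenarios",
    "programme_builder",
    "run_scenarios",
    "compare_programmes",
]


def percent_change(baseline: float, variant: float) -> float:
    """Signed percent change of ``variant`` relative to ``baseline``."""
    if baseline == 0:
        raise DomainError("percent change undefined for zero baseline")
    return (variant - baseline) / baseline * 100.0


def rounded_percent_change(baseline: float, variant: float) -> int:
    """Percent change rounded half-away-from-zero to the nearest integer.

    This is the convention used for headline figures: -14.87 reports as
    a 15% reduction, +67.5 as a 68% increase.
    """
    raw = percent_change(baseline, variant)
    return int(math.copysign(math.floor(abs(raw) + 0.5), raw))


SUPERVISED_SCENARIOS: List[Scenario] = [
    Scenario("bamboo_brush", {"brush_material": "bamboo"}),
    Scenario("double_paste", {"tubes_per_year": 1.3, "paste_g_per_episode": 0.5}),
]

PROVISION_SCENARIOS: List[Scenario] = [
    Scenario("bamboo_brush", {"brush_material": "bamboo"}),
    Scenario("paper_bag", {"bag_material": "paper"}),
    Scenario(
        "bamboo_and_paper",
        {"brush_material": "bamboo", "bag_material": "paper"},
    ),
    Scenario("exclude_water", {"water_L_per_episode": 0.0}),
]

_BUILDERS: Dict[str, Callable[[ProgrammeParameters], ForegroundSystem]] = {
    "supervised": build_supervised_system,
    "provision": build_provision_system,
}

_DEFAULT_PARAMS: Dict[str, Callable[[], ProgrammeParameters]] = {
    "supervised": supervised_defaults,
    "provision": provision_defaults,
}


def default_scenarios(programme: str) -> List[Scenario]:
    """The published sensitivity set for a programme."""
    if programme == "supervised":
        return list(SUPERVISED_SCENARIOS)
    if programme == "provision":
        return list(PROVISION_SCENARIOS)
    raise ConfigurationError(f"unknown programme {programme!r}")


def programme_builder(
    programme: str,
) -> Callable[[ProgrammeParameters], ForegroundSystem]:
    try:
        return _BUILDERS[programme]
    except KeyError:
        raise ConfigurationError(f"unknown programme {programme!r}") from None


def default_parameters(programme: str) -> ProgrammeParameters:
    try:
        return _DEFAULT_PARAMS[programme]()
    except KeyError:
        raise ConfigurationError(f"unknown programme {programme!r}") from None


@dataclass
class ScenarioComparison:
    """Baseline plus per-scenario results and percent changes."""

    programme: str
    baseline: LCIAResult
    results: Dict[str, LCIAResult]
    percent_changes: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def result_columns(self) -> List[str]:
        """Baseline plus scenario names, in run order."""
        return ["baseline"] + list(self.results)

    def as_frame(self, include_percent: bool = True) -> pd.DataFrame:
        """Category-by-column table: baseline, scenarios, percent changes."""
        data = {"baseline": pd.Series(self.baseline.scores)}
        for name, result in self.results.items():
            data[name] = pd.Series(result.scores)
        frame = pd.DataFrame(data)
        if include_percent:
            for name, changes in self.percent_changes.items():
                frame[f"{name}_pct_change"] = pd.Series(changes)
        frame.index.name = "category_id"
        return frame


def run_scenarios(
    programme: str,
    cf: CharacterizationTable,
    registry: CategoryRegistry,
    params: Optional[ProgrammeParameters] = None,
    scenarios: Optional[Sequence[Scenario]] = None,
) -> ScenarioComparison:
    """Compute baseline + scenario LCIA results with a single CF table."""
    builder = programme_builder(programme)
    params = params if params is not None else default_parameters(programme)
    scenarios = (
        list(scenarios) if scenarios is not None else default_scenarios(programme)
    )
    baseline = compute_lcia(
        builder(params), cf, registry, programme=programme, scenario="baseline"
    )
    results: Dict[str, LCIAResult] = {}
    changes: Dict[str, Dict[str, float]] = {}
    for scenario in scenarios:
        varied = apply_scenario(params, scenario)
        result = compute_lcia(
            builder(varied), cf, registry,
            programme=programme, scenario=scenario.name,
        )
        results[scenario.name] = result
        changes[scenario.name] = {
            cid: percent_change(baseline.scores[cid], result.scores[cid])
            for cid in baseline.scores
            if baseline.scores[cid] != 0
        }
    return ScenarioComparison(programme, baseline, results, changes)


def compare_programmes(a: LCIAResult, b: LCIAResult) -> pd.DataFrame:
    """Per-category difference (b - a) and ratio (b / a) table."""
    if set(a.scores) != set(b.scores):
        raise ValidationError(
            "results use different category registries; cannot compare"
        )
    rows = []
    for cid in a.scores:
        sa, sb = a.scores[cid], b.scores[cid]
        rows.append(
            (cid, sa, sb, sb - sa, sb / sa if sa != 0 else float("nan"))
        )
    frame = pd.DataFrame(
        rows,
        columns=["category_id", "score_a", "score_b", "difference", "ratio"],
    )
    return frame.set_index("category_id")
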