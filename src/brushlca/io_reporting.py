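"""Readers/writers for the CSV schemas, run configuration and pipeline.

``run_pipeline`` glues the stages together for one programme: build the
foreground, characterize baseline + sensitivity scenarios with a single
characterization table (loaded from CSV or generated synthetically from
a seed), normalize, decompose contributions, convert to DALYs, and write
the four result tables plus a manifest.  All outputs are deterministic
for a fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import __version__
from .endpoint_daly import (
    ENDPOINT_CATEGORIES,
    DALYResult,
    EndpointFactorSet,
    MIDPOINT_TO_ENDPOINT,
    endpoint_convert,
    read_endpoint_factors,
)
from .errors import ConfigurationError, ValidationError
from .foreground_inventory import default_grouping
from .impact_schema import (
    CategoryRegistry,
    default_normalization_references,
    read_normalization_references,
    register_default_categories,
)
from .lcia_engine import (
    CharacterizationTable,
    contribution_by_group,
    normalize,
)
from .scenario_analysis import (
    ScenarioComparison,
    default_parameters,
    programme_builder,
    run_scenarios,
)
from .synthetic_background import (
    SyntheticBackgroundSpec,
    generate_cf_table,
    generate_endpoint_factors,
)
from .foreground_inventory import apply_scenario, Scenario
from .scenario_analysis import default_scenarios

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_cf_table",
    "write_cf_table",
    "run_pipeline",
]

_PROGRAMMES = ("supervised", "provision")


@dataclass
class RunConfig:
    """Everything needed for one end-to-end pipeline run."""

    programme: str
    out_dir: Path
    overrides: Dict[str, object] = field(default_factory=dict)
    cf_path: Optional[Path] = None
    synthetic_seed: Optional[int] = None
    normalization_path: Optional[Path] = None
    endpoint_path: Optional[Path] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.programme not in _PROGRAMMES:
            raise ConfigurationError(
                f"unknown programme {self.programme!r}; "
                f"expected one of {_PROGRAMMES}"
            )
        if (self.cf_path is None) == (self.synthetic_seed is None):
            raise ConfigurationError(
                "exactly one characterization source required: "
                "cf_path or synthetic_seed"
            )
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cf_path", "normalization_path", "endpoint_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        # out_dir and log_level do not affect the computation, so they are
        # left out: runs writing to different places hash identically.
        payload = {
            f.name: str(getattr(self, f.name))
            for f in dataclasses.fields(self)
            if f.name not in ("out_dir", "log_level")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def foreground_flow_union(programme: str, params=None) -> list:
    """Elementary flows appearing in any default scenario of a programme."""
    builder = programme_builder(programme)
    params = params if params is not None else default_parameters(programme)
    flows: Dict[str, None] = {}
    for scn in [Scenario("baseline", {})] + default_scenarios(programme):
        system = builder(apply_scenario(params, scn))
        for fid in system.elementary_flow_ids():
            flows.setdefault(fid)
    return list(flows)


def read_cf_table(path) -> CharacterizationTable:
    """Load a characterization-factor CSV, reporting bad rows by line."""
    frame = pd.read_csv(path, dtype=str)
    missing = set(CharacterizationTable.COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing columns {sorted(missing)}"
        )
    factors = []
    for i, raw in enumerate(frame["factor"], start=2):
        try:
            factors.append(float(raw))
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: line {i}: factor {raw!r} is not a number"
            ) from None
    frame = frame.assign(factor=factors)
    return CharacterizationTable(frame)


def write_cf_table(cf: CharacterizationTable, path) -> None:
    cf.frame.to_csv(path, index=False)


def _resolve_cf(
    config: RunConfig, flow_ids, registry: CategoryRegistry
) -> CharacterizationTable:
    if config.cf_path is not None:
        return read_cf_table(config.cf_path)
    spec = SyntheticBackgroundSpec(seed=int(config.synthetic_seed))
    return generate_cf_table(spec, flow_ids=flow_ids, registry=registry)


def midpoint_scores_to_dalys(
    scores: Dict[str, float], factors: EndpointFactorSet, programme: str
) -> DALYResult:
    """Map the 8 human-health midpoints onto endpoint DALYs and total."""
    per_endpoint = {
        endpoint: scores[mid]
        for mid, endpoint in MIDPOINT_TO_ENDPOINT.items()
    }
    dalys = endpoint_convert(per_endpoint, factors)
    return DALYResult.from_per_category(programme, dalys)


def run_pipeline(config: RunConfig) -> ScenarioComparison:
    """Run programme -> scenarios -> reports; write results and manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    registry = register_default_categories()
    params = default_parameters(config.programme)
    if config.overrides:
        params = apply_scenario(
            params, Scenario("config_overrides", dict(config.overrides))
        )
    builder = programme_builder(config.programme)
    scenarios = default_scenarios(config.programme)

    # One CF table must cover the union of flows over all scenarios.
    cf = _resolve_cf(
        config, foreground_flow_union(config.programme, params), registry
    )

    comparison = run_scenarios(
        config.programme, cf, registry, params=params, scenarios=scenarios
    )

    refs = (
        read_normalization_references(config.normalization_path)
        if config.normalization_path is not None
        else default_normalization_references(registry)
    )
    normalized = normalize(comparison.baseline, refs)

    baseline_system = builder(params)
    breakdown = contribution_by_group(
        baseline_system,
        baseline_system.demand,
        cf,
        default_grouping(baseline_system),
        registry,
    )

    endpoint_factors = (
        read_endpoint_factors(config.endpoint_path)
        if config.endpoint_path is not None
        else generate_endpoint_factors(config.seed)
    )
    daly = midpoint_scores_to_dalys(
        comparison.baseline.scores, endpoint_factors, config.programme
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_outputs(config, registry, comparison, normalized, breakdown, daly, out)
    return comparison


def _write_outputs(config, registry, comparison, normalized, breakdown, daly, out):
    units = {c.id: c.unit for c in registry}

    frame = comparison.as_frame()
    frame.insert(0, "unit", pd.Series(units))
    frame.to_csv(out / "lcia_scenarios.csv")

    rows = []
    for cid in registry.ids():
        excluded = cid in normalized.excluded
        rows.append((
            cid,
            "" if excluded else repr(normalized.values[cid]),
            excluded,
        ))
    pd.DataFrame(
        rows, columns=["category_id", "normalized_value", "excluded"]
    ).to_csv(out / "normalized.csv", index=False)

    contrib_rows = []
    for cid in breakdown.scores.index:
        for group in breakdown.scores.columns:
            contrib_rows.append((
                cid, group,
                breakdown.scores.loc[cid, group],
                breakdown.shares.loc[cid, group],
            ))
    pd.DataFrame(
        contrib_rows, columns=["category_id", "group", "score", "share_pct"]
    ).to_csv(out / "contributions.csv", index=False)

    daly_rows = [(c, daly.per_category[c]) for c in ENDPOINT_CATEGORIES]
    daly_rows.append(("total_dalys", daly.total))
    daly_rows.append(("daly_seconds", daly.seconds))
    pd.DataFrame(daly_rows, columns=["category", "dalys"]).to_csv(
        out / "dalys.csv", index=False
    )

    manifest = {
        "package_version": __version__,
        "programme": config.programme,
        "seed": config.seed,
        "synthetic_seed": config.synthetic_seed,
        "config_sha256": config.digest(),
        "outputs": [
            "lcia_scenarios.csv", "normalized.csv",
            "contributions.csv", "dalys.csv",
        ],
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
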