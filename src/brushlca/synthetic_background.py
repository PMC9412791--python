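"""Seeded synthetic stand-in for a background LCI database.

Real LCIA runs couple a foreground model to a licensed background
database (thousands of linked processes plus characterization factors).
That data cannot be shipped, so this module generates structurally
faithful stand-ins from a seed:

* characterization factors, log-uniform across a configurable magnitude
  range (real factors span many orders of magnitude) with a configurable
  fraction of exact zeros;
* acyclic background supply chains of configurable depth whose leaf
  exchanges draw from a small fixed vocabulary of recognisable
  elementary flows (CO2, CH4, N2O, nutrients, particulates, NMVOC,
  CFC-11, U-235 eq, water, land, fossil energy, Sb-eq minerals);
* a breadth-first demand-expansion oracle that computes inventories
  without matrix algebra, used to cross-validate the dense solver.

Every generator is a pure function of its spec: the same seed yields
byte-identical artifacts.  Factors are derived per (seed, category,
flow), so enlarging the flow set never changes existing factors.

No numeric resemblance to any real database is intended.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .foreground_inventory import Flow, ForegroundSystem, Process
from .impact_schema import CategoryRegistry, register_default_categories
from .lcia_engine import CharacterizationTable

__all__ = [
    "FIXED_FLOW_VOCABULARY",
    "SyntheticBackgroundSpec",
    "generate_cf_table",
    "generate_endpoint_factors",
    "generate_background_processes",
    "random_acyclic_system",
    "expansion_oracle",
]

# One interpretable elementary flow per default impact category, plus
# extras; keeps per-category contributions readable in tests.
FIXED_FLOW_VOCABULARY = (
    "co2_air",
    "ch4_air",
    "n2o_air",
    "p_to_freshwater",
    "n_to_marine",
    "particulates_air",
    "nmvoc_air",
    "cfc11_air",
    "u235_eq_air",
    "water_consumed",
    "land_occupation",
    "fossil_energy",
    "sb_eq_minerals",
)


@dataclass(frozen=True)
class SyntheticBackgroundSpec:
    """Parameters of the synthetic background generator.

    ``factor_range`` gives log-uniform bounds for characterization
    factors; ``depth`` is the number of supply-chain levels below the
    top background processes; ``sparsity`` is the fraction of
    (category, flow) pairs with an exactly-zero factor.
    """

    seed: int = 0
    n_flows: int = len(FIXED_FLOW_VOCABULARY)
    factor_range: Tuple[float, float] = (1e-3, 1e1)
    depth: int = 2
    sparsity: float = 0.3
    processes_per_level: int = 3
    flow_ids: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        lo, hi = self.factor_range
        if not (0 < lo <= hi):
            raise ValidationError("factor_range bounds must be positive, lo <= hi")
        if self.depth < 0:
            raise ValidationError("depth must be >= 0")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValidationError("sparsity must be in [0, 1]")
        if self.n_flows < 1 or self.processes_per_level < 1:
            raise ValidationError("n_flows and processes_per_level must be >= 1")

    def vocabulary(self) -> List[str]:
        if self.flow_ids is not None:
            return list(self.flow_ids)
        vocab = list(FIXED_FLOW_VOCABULARY[: self.n_flows])
        for i in range(len(vocab), self.n_flows):
            vocab.append(f"synthetic_flow_{i}")
        return vocab


def _pair_rng(seed: int, *tokens: str) -> np.random.Generator:
    """Generator keyed by (seed, tokens): stable across flow-set changes."""
    return np.random.default_rng(
        [seed % (2**31)] + [zlib.crc32(t.encode()) for t in tokens]
    )


def generate_cf_table(
    spec: SyntheticBackgroundSpec,
    flow_ids: Optional[Sequence[str]] = None,
    registry: Optional[CategoryRegistry] = None,
) -> CharacterizationTable:
    """Nonnegative seeded factors for every (category, flow) pair.

    A factor depends only on (seed, category, flow), so tables generated
    for overlapping flow sets agree on the overlap.
    """
    registry = registry if registry is not None else register_default_categories()
    flows = list(flow_ids) if flow_ids is not None else spec.vocabulary()
    lo, hi = spec.factor_range
    rows = []
    for cat in registry:
        for fid in flows:
            rng = _pair_rng(spec.seed, cat.id, fid)
            zero = rng.uniform() < spec.sparsity
            factor = 0.0 if zero else float(
                np.exp(rng.uniform(np.log(lo), np.log(hi)))
            )
            rows.append((cat.id, fid, factor, f"{cat.unit}/unit"))
    return CharacterizationTable(
        pd.DataFrame(rows, columns=["category_id", "flow_id", "factor", "unit"])
    )


def generate_endpoint_factors(seed: int) -> "EndpointFactorSet":
    """Seeded positive DALY damage factors for the 8 endpoint categories."""
    from .endpoint_daly import ENDPOINT_CATEGORIES, EndpointFactorSet

    factors = {}
    for cat in ENDPOINT_CATEGORIES:
        rng = _pair_rng(seed, "endpoint", cat)
        factors[cat] = float(np.exp(rng.uniform(np.log(1e-8), np.log(1e-5))))
    return EndpointFactorSet(factors)


def generate_background_processes(spec: SyntheticBackgroundSpec) -> ForegroundSystem:
    """Acyclic background supply chains of ``spec.depth`` levels.

    Level 0 processes have elementary exchanges only; each level-k
    process consumes one to three level-(k-1) products.  Top-level
    products (``bg_product_{depth}_{i}``) are attachable to foreground
    product inputs (polymer, electricity, transport, water supply,
    waste treatment stand-ins).
    """
    rng = np.random.default_rng(spec.seed % (2**31))
    vocab = spec.vocabulary()
    system = ForegroundSystem()
    for fid in vocab:
        system.flows[fid] = Flow(fid, fid, "kg", "elementary")
    prev_products: List[str] = []
    for level in range(spec.depth + 1):
        products = []
        for i in range(spec.processes_per_level):
            fid = f"bg_product_{level}_{i}"
            pid = f"bg_process_{level}_{i}"
            system.flows[fid] = Flow(fid, fid, "kg", "product")
            n_elem = int(rng.integers(1, 4))
            elem_ids = rng.choice(len(vocab), size=n_elem, replace=False)
            elementary = tuple(
                (vocab[j], float(np.exp(rng.uniform(np.log(1e-2), np.log(1e1)))))
                for j in elem_ids
            )
            inputs: Tuple[Tuple[str, float], ...] = ()
            if level > 0:
                n_in = int(rng.integers(1, min(3, len(prev_products)) + 1))
                chosen = rng.choice(len(prev_products), size=n_in, replace=False)
                inputs = tuple(
                    (prev_products[j],
                     float(np.exp(rng.uniform(np.log(1e-2), np.log(1e0)))))
                    for j in chosen
                )
            system.processes[pid] = Process(
                id=pid,
                name=f"synthetic background process, level {level}, #{i}",
                reference_product=(fid, 1.0),
                product_inputs=inputs,
                elementary_exchanges=elementary,
            )
            products.append(fid)
        prev_products = products
    system.validate()
    return system


def random_acyclic_system(
    seed: int, depth: int = 3, processes_per_level: int = 3
) -> Tuple[ForegroundSystem, Dict[str, float]]:
    """A seeded background system plus a demand on its top-level products."""
    spec = SyntheticBackgroundSpec(
        seed=seed, depth=depth, processes_per_level=processes_per_level
    )
    system = generate_background_processes(spec)
    rng = np.random.default_rng((seed + 10_007) % (2**31))
    demand = {
        f"bg_product_{depth}_{i}": float(rng.uniform(0.1, 5.0))
        for i in range(processes_per_level)
    }
    system.demand = demand
    return system, demand


def expansion_oracle(
    system: ForegroundSystem, demand: Mapping[str, float]
) -> pd.Series:
    """Inventory totals by breadth-first demand expansion (no matrices).

    Walks the supply chain pushing scaled product requirements onto a
    queue and accumulating elementary exchanges; valid only for acyclic
    systems (a cycle raises).
    """
    if not nx.is_directed_acyclic_graph(system.product_graph()):
        raise ValidationError("expansion oracle requires an acyclic system")
    producers = system.producers()
    totals: Dict[str, float] = {}
    queue: List[Tuple[str, float]] = list(demand.items())
    while queue:
        fid, amount = queue.pop(0)
        if fid not in producers:
            raise ValidationError(f"no producer for demanded flow {fid!r}")
        proc = system.processes[producers[fid]]
        scale = amount / proc.reference_product[1]
        for ef, ea in proc.elementary_exchanges:
            totals[ef] = totals.get(ef, 0.0) + scale * ea
        for pf, pa in proc.product_inputs:
            queue.append((pf, scale * pa))
    return pd.Series(totals, dtype=float)
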