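"""Foreground product systems for the two toothbrushing programmes.

Two community caries-prevention programmes are modelled, each per the
functional unit *one five-year-old child receiving the programme for one
year*:

* **Supervised toothbrushing in schools** — the dental service supplies
  materials and training; children brush once per school day (195 days).
  Per child-year: 5 toothbrushes, 0.65 tubes of toothpaste, 390 L of tap
  water (2 L per episode), a share of three 177 g toothbrush-holder
  "buses" shared by ten children, and a share of quarterly delivery
  trips (13 km round trip covering 180 children).
* **Targeted provision of toothbrushes and toothpaste** — quarterly
  packs (toothbrush + 100 ml tube in a 1.5 g zip-lock bag) for brushing
  twice daily at home (730 episodes, 1,460 L of water); no holder.

The foreground is built as a two-tier acyclic process network: tier-1
component processes (toothbrush, toothpaste tube, tap-water use, staff
travel, holder/bag) consume tier-2 material-supply processes, each of
which draws one unit of a matching raw elementary flow.  Characterization
factors attach to the elementary flows, so the whole system solves with
standard matrix LCI machinery and every supply chain remains attributable
to exactly one foreground component for contribution analysis.

Material bills for the brushes and packaging are representative
placeholder masses informed by product teardowns (a children's plastic
brush: 15 g polypropylene handle, 0.5 g nylon bristles; bamboo: 10 g
handle, brass staples); they are configuration defaults, not measured
values, and are expected to be overridden when better data exist.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import networkx as nx

from .errors import ConfigurationError, CoverageError, DomainError, ValidationError

__all__ = [
    "Flow",
    "Process",
    "ForegroundSystem",
    "ProgrammeParameters",
    "Scenario",
    "supervised_defaults",
    "provision_defaults",
    "tap_run_litres",
    "annual_water_litres",
    "toothpaste_recipe",
    "TOOTHPASTE_MASS_FRACTIONS",
    "mixing_energy_per_tube",
    "per_child_travel_km",
    "per_child_bus_mass",
    "build_supervised_system",
    "build_provision_system",
    "apply_scenario",
    "default_grouping",
]


# --------------------------------------------------------------------------
# Core system types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Flow:
    """A product or elementary flow.

    ``kind="product"`` flows move between processes; ``kind="elementary"``
    flows cross the system boundary (emissions, raw resources, waste).
    """

    id: str
    name: str
    unit: str
    kind: str

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValidationError(f"flow {self.id!r}: unit must be non-empty")
        if self.kind not in ("product", "elementary"):
            raise ValidationError(
                f"flow {self.id!r}: kind must be 'product' or 'elementary', "
                f"got {self.kind!r}"
            )


@dataclass(frozen=True)
class Process:
    """A unit process with one reference product.

    ``reference_product`` is ``(flow_id, amount > 0)``; ``product_inputs``
    are consumed product flows; ``elementary_exchanges`` are signed
    exchanges with the environment (emissions and resource draws
    positive by convention).
    """

    id: str
    name: str
    reference_product: Tuple[str, float]
    product_inputs: Tuple[Tuple[str, float], ...] = ()
    elementary_exchanges: Tuple[Tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        flow_id, amount = self.reference_product
        if not amount > 0:
            raise ValidationError(
                f"process {self.id!r}: reference amount must be > 0"
            )
        for fid, amt in self.product_inputs:
            if fid == flow_id:
                raise ValidationError(
                    f"process {self.id!r} consumes its own reference product"
                )
            if amt < 0:
                raise ValidationError(
                    f"process {self.id!r}: product input {fid!r} amount < 0"
                )


@dataclass
class ForegroundSystem:
    """A set of processes plus the functional-unit demand.

    Invariants (checked by :meth:`validate`): every demanded flow is the
    reference product of exactly one process, every consumed product flow
    has exactly one producer, and the product-input graph is acyclic.
    """

    flows: Dict[str, Flow] = field(default_factory=dict)
    processes: Dict[str, Process] = field(default_factory=dict)
    demand: Dict[str, float] = field(default_factory=dict)

    def producers(self) -> Dict[str, str]:
        """Map product flow id -> producing process id."""
        out: Dict[str, str] = {}
        for proc in self.processes.values():
            fid = proc.reference_product[0]
            if fid in out:
                raise ValidationError(
                    f"product flow {fid!r} produced by both {out[fid]!r} "
                    f"and {proc.id!r}"
                )
            out[fid] = proc.id
        return out

    def product_graph(self) -> nx.DiGraph:
        """Directed graph: edge producer -> consumer along product inputs."""
        producers = self.producers()
        graph = nx.DiGraph()
        graph.add_nodes_from(self.processes)
        for proc in self.processes.values():
            for fid, _ in proc.product_inputs:
                if fid in producers:
                    graph.add_edge(producers[fid], proc.id)
        return graph

    def validate(self) -> None:
        producers = self.producers()
        for fid in self.demand:
            if fid not in producers:
                raise CoverageError(f"demanded flow {fid!r} has no producer")
        for proc in self.processes.values():
            for fid, _ in proc.product_inputs:
                if fid not in producers:
                    raise CoverageError(
                        f"process {proc.id!r} consumes {fid!r} which has "
                        "no producer"
                    )
        if not nx.is_directed_acyclic_graph(self.product_graph()):
            raise ValidationError("product-input graph contains a cycle")

    def elementary_flow_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for proc in self.processes.values():
            for fid, _ in proc.elementary_exchanges:
                seen.setdefault(fid)
        return list(seen)

    def merged_with(self, other: "ForegroundSystem") -> "ForegroundSystem":
        """Union of flows and processes; demand taken from ``self``."""
        flows = {**other.flows, **self.flows}
        processes = {**other.processes, **self.processes}
        return ForegroundSystem(flows, processes, dict(self.demand))


# --------------------------------------------------------------------------
# Programme parameters and scenarios
# --------------------------------------------------------------------------

_MATERIAL_CHOICES = {"brush_material": ("plastic", "bamboo"),
                     "bag_material": ("plastic", "paper")}


@dataclass(frozen=True)
class ProgrammeParameters:
    """All scenario-relevant quantities for one programme, per child-year."""

    brushes_per_year: float
    tubes_per_year: float
    paste_g_per_episode: float
    episodes_per_year: float
    water_L_per_episode: float
    bus_units_per_year: float
    bus_mass_g: float
    children_per_bus: float
    bag_mass_g: float
    bags_per_year: float
    round_trip_km: float
    children_per_trip: float
    trips_per_year: float
    commute_km: float
    brush_material: str = "plastic"
    bag_material: str = "plastic"

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name in _MATERIAL_CHOICES:
                if value not in _MATERIAL_CHOICES[f.name]:
                    raise ConfigurationError(
                        f"{f.name} must be one of {_MATERIAL_CHOICES[f.name]}, "
                        f"got {value!r}"
                    )
            elif value < 0:
                raise DomainError(f"{f.name} must be >= 0, got {value}")
        if self.children_per_trip <= 0:
            raise DomainError("children_per_trip must be > 0")
        if self.bus_units_per_year > 0 and self.children_per_bus <= 0:
            raise DomainError(
                "children_per_bus must be > 0 when buses are used"
            )


def supervised_defaults() -> ProgrammeParameters:
    """Default parameters for supervised toothbrushing in schools."""
    return ProgrammeParameters(
        brushes_per_year=5,
        tubes_per_year=0.65,
        paste_g_per_episode=0.25,
        episodes_per_year=195,
        water_L_per_episode=2.0,
        bus_units_per_year=3,
        bus_mass_g=177.0,
        children_per_bus=10,
        bag_mass_g=0.0,
        bags_per_year=0,
        round_trip_km=13.0,
        children_per_trip=180,
        trips_per_year=4,
        commute_km=0.0,
        brush_material="plastic",
        bag_material="plastic",
    )


def provision_defaults() -> ProgrammeParameters:
    """Default parameters for targeted provision of brushes and toothpaste."""
    return ProgrammeParameters(
        brushes_per_year=4,
        tubes_per_year=4,
        paste_g_per_episode=_TUBE_CONTENT_G * 4 / 730,
        episodes_per_year=730,
        water_L_per_episode=2.0,
        bus_units_per_year=0,
        bus_mass_g=0.0,
        children_per_bus=0,
        bag_mass_g=1.5,
        bags_per_year=4,
        round_trip_km=13.0,
        children_per_trip=180,
        trips_per_year=4,
        commute_km=0.0,
        brush_material="plastic",
        bag_material="plastic",
    )


@dataclass(frozen=True)
class Scenario:
    """Named partial override of :class:`ProgrammeParameters`."""

    name: str
    overrides: Mapping[str, object] = field(default_factory=dict)


_PARAM_NAMES = frozenset(f.name for f in dataclasses.fields(ProgrammeParameters))


def apply_scenario(
    params: ProgrammeParameters, scenario: Scenario
) -> ProgrammeParameters:
    """Return ``params`` with the scenario's overrides applied."""
    unknown = set(scenario.overrides) - _PARAM_NAMES
    if unknown:
        raise ConfigurationError(
            f"scenario {scenario.name!r} overrides unknown parameters: "
            f"{sorted(unknown)}"
        )
    return replace(params, **dict(scenario.overrides))


# --------------------------------------------------------------------------
# Quantity arithmetic
# --------------------------------------------------------------------------

def tap_run_litres(flow_L_per_min: float, seconds: float) -> float:
    """Litres drawn by a tap running at ``flow_L_per_min`` for ``seconds``.

    A typical UK tap delivers 6 L/min; 20 s of running (rinsing the brush
    before and after, tap off during brushing) draws 2 L.
    """
    if flow_L_per_min < 0 or seconds < 0:
        raise DomainError("flow rate and duration must be >= 0")
    return flow_L_per_min * seconds / 60.0


def annual_water_litres(L_per_episode: float, episodes_per_year: float) -> float:
    """Annual tap-water use: litres per episode times episodes per year."""
    if L_per_episode < 0 or episodes_per_year < 0:
        raise DomainError("water per episode and episode count must be >= 0")
    return L_per_episode * episodes_per_year


# Generic fluoride-toothpaste formulation (mass fractions summing to 1):
# sodium fluoride active, silica abrasive, xanthan binder, sorbitol
# humectant, water solvent, sodium benzoate preservative, SLS foaming
# agent.  Flavourings/colourants excluded (manufacturer-specific, trace).
TOOTHPASTE_MASS_FRACTIONS: Dict[str, float] = {
    "sodium_fluoride": 0.00315,
    "silica": 0.25,
    "xanthan_gum": 0.015,
    "sorbitol": 0.5366,
    "water": 0.175,
    "sodium_benzoate": 0.00275,
    "sodium_lauryl_sulphate": 0.0175,
}


def toothpaste_recipe(total_mass: float) -> Dict[str, float]:
    """Split ``total_mass`` grams of toothpaste into its 7 ingredients."""
    if total_mass < 0:
        raise DomainError("total mass must be >= 0")
    return {name: frac * total_mass for name, frac in TOOTHPASTE_MASS_FRACTIONS.items()}


def mixing_energy_per_tube(
    power_kW: float, hours: float, batch_volume_L: float, tube_volume_mL: float
) -> float:
    """kWh of batch-mixing energy allocated to a single tube.

    A 68 kW, 500 L barrel mixer run for 2.4 h allocates 0.03264 kWh to a
    100 ml tube.
    """
    if batch_volume_L <= 0 or tube_volume_mL <= 0:
        raise DomainError("batch and tube volumes must be > 0")
    if power_kW < 0 or hours < 0:
        raise DomainError("power and hours must be >= 0")
    return power_kW * hours * tube_volume_mL / (batch_volume_L * 1000.0)


def per_child_travel_km(
    round_trip_km: float,
    children_per_trip: float,
    trips_per_year: float,
    commute_km: float,
) -> float:
    """Delivery-travel kilometres allocated to one child for one year.

    One staff member drives a small van on a 13 km round trip covering
    two schools (180 children) each quarterly delivery.
    """
    if children_per_trip <= 0:
        raise DomainError("children_per_trip must be > 0")
    if round_trip_km < 0 or trips_per_year < 0 or commute_km < 0:
        raise DomainError("distances and trip counts must be >= 0")
    return trips_per_year * (round_trip_km + commute_km) / children_per_trip


def per_child_bus_mass(
    bus_mass_g: float, buses_per_year: float, children_per_bus: float
) -> float:
    """Grams of toothbrush-holder plastic allocated to one child-year.

    The ten-brush holder weighs 177 g of ABS and is replaced each term
    (three per year), giving 53.1 g per child-year.
    """
    if children_per_bus <= 0:
        raise DomainError("children_per_bus must be > 0")
    if bus_mass_g < 0 or buses_per_year < 0:
        raise DomainError("mass and count must be >= 0")
    return bus_mass_g * buses_per_year / children_per_bus


# --------------------------------------------------------------------------
# Material assumptions (placeholder bills of materials, grams)
# --------------------------------------------------------------------------

# Children's plastic brush: PP handle + nylon bristles; PET blister and
# printed cardboard packaging (recycled); brush itself binned.
PLASTIC_BRUSH_BOM_G = {
    "polypropylene": 15.0,
    "nylon": 0.5,
    "pet": 3.0,
    "cardboard": 2.0,
}
# Children's bamboo brush: bamboo handle, nylon bristles, brass staples,
# single printed cardboard box.
BAMBOO_BRUSH_BOM_G = {
    "bamboo": 10.0,
    "nylon": 0.5,
    "brass": 0.2,
    "cardboard": 2.0,
}

_TUBE_CONTENT_G = 100.0     # 100 ml tube at density 1.0 g/ml
_TUBE_HDPE_G = 10.0         # HDPE tube body (binned)
_TUBE_BOX_G = 5.0           # printed cardboard box (recycled)
_FILLING_KWH_PER_TUBE = 0.01  # fill/seal/cap machinery allocation
_MIXER_POWER_KW = 68.0
_MIXER_HOURS = 2.4
_MIXER_BATCH_L = 500.0
_FREIGHT_KM = 1500.0        # Europe -> UK population centre, road + sea

_UNITS = {"kg": "kg", "L": "L", "kWh": "kWh", "km": "km",
          "item": "item", "g": "g", "kg_km": "kg*km"}


class _SystemBuilder:
    """Accumulates flows/processes; one material-supply chain per component."""

    def __init__(self) -> None:
        self.system = ForegroundSystem()

    def flow(self, fid: str, name: str, unit: str, kind: str) -> str:
        if fid not in self.system.flows:
            self.system.flows[fid] = Flow(fid, name, unit, kind)
        return fid

    def supply(self, material: str, component: str, unit: str = "kg") -> str:
        """Tier-2 supply process: 1 unit of product draws 1 unit of the
        matching raw elementary flow.  Component-scoped so each supply
        chain belongs to exactly one contribution group."""
        pid = f"supply_{material}_{component}"
        fid = f"{material}_{component}"
        raw = f"raw_{material}_{component}"
        self.flow(fid, f"{material} ({component})", unit, "product")
        self.flow(raw, f"{material}, raw ({component})", unit, "elementary")
        if pid not in self.system.processes:
            self.system.processes[pid] = Process(
                id=pid,
                name=f"{material} supply for {component}",
                reference_product=(fid, 1.0),
                elementary_exchanges=((raw, 1.0),),
            )
        return fid

    def process(self, proc: Process) -> None:
        self.system.processes[proc.id] = proc


def _add_brush(b: _SystemBuilder, material: str) -> str:
    """Add the toothbrush manufacture chain; return the brush flow id."""
    bom = PLASTIC_BRUSH_BOM_G if material == "plastic" else BAMBOO_BRUSH_BOM_G
    fid = f"toothbrush_{material}"
    b.flow(fid, f"{material} toothbrush", "item", "product")
    b.flow("residual_waste", "residual waste to bin", "kg", "elementary")
    b.flow("recycled_waste", "material to recycling", "kg", "elementary")
    inputs = [(b.supply(mat, "brush"), grams / 1000.0) for mat, grams in bom.items()]
    mass_kg = sum(bom.values()) / 1000.0
    pack_kg = bom["cardboard"] / 1000.0 + bom.get("pet", 0.0) / 1000.0
    inputs.append((b.supply("freight", "brush", "kg*km"), mass_kg * _FREIGHT_KM))
    b.process(Process(
        id=f"brush_{material}_mfg",
        name=f"{material} toothbrush, manufactured, packed and shipped",
        reference_product=(fid, 1.0),
        product_inputs=tuple(inputs),
        elementary_exchanges=(
            ("residual_waste", mass_kg - pack_kg),  # brush binned
            ("recycled_waste", pack_kg),            # packaging recycled
        ),
    ))
    return fid


def _add_toothpaste(b: _SystemBuilder) -> str:
    fid = "toothpaste_tube"
    b.flow(fid, "toothpaste, 100 ml tube", "item", "product")
    b.flow("residual_waste", "residual waste to bin", "kg", "elementary")
    b.flow("recycled_waste", "material to recycling", "kg", "elementary")
    b.flow("paste_to_drain", "excess toothpaste to drain", "kg", "elementary")
    inputs = [
        (b.supply(ing, "toothpaste"), grams / 1000.0)
        for ing, grams in toothpaste_recipe(_TUBE_CONTENT_G).items()
    ]
    inputs.append((b.supply("hdpe", "toothpaste"), _TUBE_HDPE_G / 1000.0))
    inputs.append((b.supply("cardboard", "toothpaste"), _TUBE_BOX_G / 1000.0))
    energy = mixing_energy_per_tube(
        _MIXER_POWER_KW, _MIXER_HOURS, _MIXER_BATCH_L, 100.0
    ) + _FILLING_KWH_PER_TUBE
    inputs.append((b.supply("electricity", "toothpaste", "kWh"), energy))
    ship_kg = (_TUBE_CONTENT_G + _TUBE_HDPE_G + _TUBE_BOX_G) / 1000.0
    inputs.append((b.supply("freight", "toothpaste", "kg*km"), ship_kg * _FREIGHT_KM))
    b.process(Process(
        id="toothpaste_tube_mfg",
        name="fluoride toothpaste, mixed, filled and shipped (100 ml tube)",
        reference_product=(fid, 1.0),
        product_inputs=tuple(inputs),
        elementary_exchanges=(
            ("residual_waste", _TUBE_HDPE_G / 1000.0),   # empty tube binned
            ("recycled_waste", _TUBE_BOX_G / 1000.0),    # box recycled
            ("paste_to_drain", _TUBE_CONTENT_G / 1000.0),
        ),
    ))
    return fid


def _add_water(b: _SystemBuilder) -> str:
    fid = "tap_water_service"
    b.flow(fid, "tap water used for brushing", "L", "product")
    b.flow("wastewater", "wastewater to drain", "L", "elementary")
    b.process(Process(
        id="tap_water_use",
        name="tap water drawn and discharged to drain",
        reference_product=(fid, 1.0),
        product_inputs=((b.supply("tap_water", "water", "L"), 1.0),),
        elementary_exchanges=(("wastewater", 1.0),),
    ))
    return fid


def _add_travel(b: _SystemBuilder) -> str:
    fid = "travel_service"
    b.flow(fid, "staff delivery travel", "km", "product")
    b.process(Process(
        id="staff_travel",
        name="staff delivery travel, small van (EUR05)",
        reference_product=(fid, 1.0),
        product_inputs=((b.supply("van_transport", "travel", "km"), 1.0),),
    ))
    return fid


def _add_bus(b: _SystemBuilder) -> str:
    fid = "bus_service"
    b.flow(fid, "toothbrush-holder share", "g", "product")
    b.flow("residual_waste", "residual waste to bin", "kg", "elementary")
    b.process(Process(
        id="bus_mfg",
        name="ABS toothbrush holder, injection moulded and shipped (per g)",
        reference_product=(fid, 1.0),
        product_inputs=(
            (b.supply("abs", "holder"), 1e-3),
            (b.supply("freight", "holder", "kg*km"), 1e-3 * _FREIGHT_KM),
        ),
        elementary_exchanges=(("residual_waste", 1e-3),),
    ))
    return fid


def _add_bag(b: _SystemBuilder, material: str, mass_g: float) -> str:
    fid = "bag_service"
    b.flow(fid, "delivery bag", "item", "product")
    b.flow("recycled_waste", "material to recycling", "kg", "elementary")
    mat = "polypropylene_film" if material == "plastic" else "paper"
    b.process(Process(
        id="bag_mfg",
        name=f"{material} zip-lock bag, {mass_g} g",
        reference_product=(fid, 1.0),
        product_inputs=(
            (b.supply(mat, "bag"), mass_g / 1000.0),
            (b.supply("freight", "bag", "kg*km"), mass_g / 1000.0 * _FREIGHT_KM),
        ),
        elementary_exchanges=(("recycled_waste", mass_g / 1000.0),),
    ))
    return fid


def build_supervised_system(params: ProgrammeParameters) -> ForegroundSystem:
    """Foreground system for supervised school toothbrushing, per child-year."""
    b = _SystemBuilder()
    brush = _add_brush(b, params.brush_material)
    paste = _add_toothpaste(b)
    water = _add_water(b)
    travel = _add_travel(b)
    bus = _add_bus(b)
    b.system.demand = {
        brush: params.brushes_per_year,
        paste: params.tubes_per_year,
        water: annual_water_litres(
            params.water_L_per_episode, params.episodes_per_year
        ),
        travel: per_child_travel_km(
            params.round_trip_km,
            params.children_per_trip,
            params.trips_per_year,
            params.commute_km,
        ),
        bus: per_child_bus_mass(
            params.bus_mass_g, params.bus_units_per_year, params.children_per_bus
        ),
    }
    b.system.validate()
    return b.system


def build_provision_system(params: ProgrammeParameters) -> ForegroundSystem:
    """Foreground system for targeted brush/toothpaste provision, per child-year."""
    b = _SystemBuilder()
    brush = _add_brush(b, params.brush_material)
    paste = _add_toothpaste(b)
    water = _add_water(b)
    travel = _add_travel(b)
    bag = _add_bag(b, params.bag_material, params.bag_mass_g)
    b.system.demand = {
        brush: params.brushes_per_year,
        paste: params.tubes_per_year,
        water: annual_water_litres(
            params.water_L_per_episode, params.episodes_per_year
        ),
        travel: per_child_travel_km(
            params.round_trip_km,
            params.children_per_trip,
            params.trips_per_year,
            params.commute_km,
        ),
        bag: params.bags_per_year,
    }
    b.system.validate()
    return b.system


_GROUP_OF_COMPONENT = {
    "brush": "toothbrush",
    "toothpaste": "toothpaste",
    "water": "water",
    "travel": "staff travel",
    "holder": "holder/bag",
    "bag": "holder/bag",
}

_TIER1_GROUPS = {
    "brush_plastic_mfg": "toothbrush",
    "brush_bamboo_mfg": "toothbrush",
    "toothpaste_tube_mfg": "toothpaste",
    "tap_water_use": "water",
    "staff_travel": "staff travel",
    "bus_mfg": "holder/bag",
    "bag_mfg": "holder/bag",
}


def default_grouping(system: ForegroundSystem) -> Dict[str, str]:
    """Contribution-analysis labels: one group per foreground component.

    Tier-2 supply processes inherit the component encoded in their id, so
    each group covers a component and its whole supply chain.
    """
    grouping: Dict[str, str] = {}
    for pid in system.processes:
        if pid in _TIER1_GROUPS:
            grouping[pid] = _TIER1_GROUPS[pid]
        elif pid.startswith("supply_"):
            component = pid.rsplit("_", 1)[-1]
            grouping[pid] = _GROUP_OF_COMPONENT.get(component, "background")
        else:
            grouping[pid] = "background"
    return grouping
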