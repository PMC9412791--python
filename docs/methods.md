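# Methods

## Scope and functional unit

The package models the environmental footprint of two community
caries-prevention programmes, each expressed per *one five-year-old
child receiving the programme for one year*. Outputs are midpoint scores
across the 16 PEF impact categories, PEF-style normalized scores,
a contribution decomposition by foreground component, human-health
endpoint DALYs, and sensitivity-scenario comparisons.

## Foreground inventory

Each programme is a small acyclic product system built from its stated
assumptions:

| parameter | supervised | provision | unit |
|---|---|---|---|
| toothbrushes per year | 5 | 4 | item |
| toothpaste tubes (100 ml) per year | 0.65 | 4 | item |
| brushing episodes per year | 195 | 730 | — |
| tap water per episode | 2 | 2 | L |
| annual tap water | 390 | 1,460 | L |
| holder ("bus") | 3 × 177 g ABS ÷ 10 children | — | g/child-yr |
| zip-lock bag | — | 4 × 1.5 g PP film | g/child-yr |
| delivery travel | 4 × 13 km ÷ 180 children | same | km/child-yr |

Water per episode derives from a 6 L/min tap running 20 s. The
toothpaste is a generic 1,450 ppm NaF formulation with seven ingredients
(mass fractions summing to exactly 100%: sorbitol 53.66%, silica 25%,
water 17.5%, SLS 1.75%, xanthan 1.5%, NaF 0.315%, sodium benzoate
0.275%); mixing energy allocates a 68 kW, 500 L, 2.4 h batch mixer to
one 100 ml tube (0.03264 kWh), plus a 0.01 kWh filling/sealing
allocation.

Quantities the programme documentation does not state numerically are
configuration defaults chosen once and flagged as placeholders:
toothbrush bills of materials (plastic: 15 g polypropylene handle,
0.5 g nylon bristles, 3 g PET + 2 g cardboard packaging; bamboo: 10 g
handle, 0.5 g nylon, 0.2 g brass staples, 2 g cardboard), toothpaste
packaging (10 g HDPE tube, 5 g cardboard box), and a 1,500 km
road-and-sea freight distance from the assumed European manufacturing
location to the UK population centre. Staff commuting distance defaults
to 0 km (mentioned qualitatively in the programme description but never
quantified); delivery frequency defaults to quarterly, the only stated
frequency. These are parameters, not claims; sensitivity to them is
exactly what the scenario machinery is for.

Disposal is modelled as named boundary flows (residual waste mass,
recycled mass, wastewater litres, paste-to-drain mass) rather than full
end-of-life treatment chains, because the programme descriptions state
routes (bin, recycling, drain), not treatment inventories.

### System structure

The foreground has two tiers. Tier-1 component processes (toothbrush
manufacture, toothpaste tube, tap-water use, staff travel, holder/bag)
carry the disposal exchanges and consume tier-2 *material-supply*
processes, each of which converts one unit of a raw elementary flow into
one unit of material product. Tier-2 supply chains are instantiated per
component (`cardboard_brush` and `cardboard_toothpaste` are distinct
flows): this slightly enlarges the matrix but guarantees that every
process belongs to exactly one contribution group, so group scores are
well-defined without allocation rules for shared upstream processes.
Background chains generated by `synthetic_background` can be attached to
any tier-2 product input for deeper systems.

## LCIA computation

Standard matrix formulation: technology matrix **A** (reference products
positive, consumed products negative — the convention that keeps all
category scores positive for credit-free systems), intervention matrix
**B** (emissions and resource draws positive), demand **f**. The scaling
vector solves **A s = f** by a direct dense solve (scipy); foreground
systems have tens of processes, so sparse or iterative methods would be
over-engineering. A solve is rejected if the matrix is singular or its
condition number exceeds 1e12. A breadth-first demand-expansion oracle
(no matrix algebra) is kept in `synthetic_background` purely as an
independent cross-check; solver and oracle agree to 1e-9 relative on
100 seeded acyclic systems of depth ≤ 3 in the test suite.

Characterization is strict by default: a nonzero inventory flow with no
factor row anywhere in the table raises, because completeness of user
data cannot be assumed; lenient mode treats such flows as zero and logs
them. Normalization requires a positive reference for every included
category and carries the three PEF-excluded toxicity categories (ECF,
HCE, HNC) as explicitly excluded — never as zero. Percentage
contribution shares are computed on absolute scores and reported as
undefined (NaN, with a warning) for any category containing a negative
group score, where percentages stop being meaningful.

## Endpoint DALYs

Eight human-health endpoint pathways (global warming, stratospheric
ozone depletion, ionising radiation, particulate matter, photochemical
ozone formation, cancer and non-cancer effects, water consumption) are
fed by the corresponding midpoints and multiplied by DALY damage
factors. Damage factors are user- or synthetically-supplied data, not
package constants. The DALY-second conversion uses a 365-day year
(31,536,000 s) — the constant verified to reproduce both shipped
reported total↔seconds pairs to better than 0.001%.

The shipped reference DALY table puts 99.81% (supervised) and 99.88%
(provision) of the total burden in global warming plus water
consumption; the tests assert that dominance structure (each other
pathway < 0.2%).

## Scenarios and reporting conventions

Percent changes are always computed against the baseline column,
`(variant − baseline)/baseline × 100`; headline integers use
round-half-away-from-zero (−14.87 → "15% reduction"), which reproduces
every integer percentage derivable from the shipped scenario tables
(−15, +68, −28, −23, −5 supervised-bamboo; −36, −81, −49
provision-exclude-water; −6 provision-bamboo). Raw signed floats are
retained alongside. Sub-integer published figures (a 0.47% bag effect)
derive from unrounded internals not available at table precision and
are deliberately not asserted.

## Synthetic background data

The generator stands in for a proprietary background database. Its
defaults: 13-flow fixed vocabulary (CO₂, CH₄, N₂O, P/N nutrients,
particulates, NMVOC, CFC-11, U-235 eq, water, land, fossil energy,
Sb-eq minerals — roughly one interpretable flow per category),
characterization factors log-uniform on [1e-3, 1e1] (real factor tables
span orders of magnitude, which stresses numerical robustness), 30%
exact zeros, supply chains of depth 2 with 3 processes per level. Every
factor is a pure function of (seed, category, flow), so enlarging the
flow set never perturbs existing factors and pipeline outputs are
byte-identical for a fixed configuration and seed.

What passing tests on synthetic data do show: the computational chain
(solve → inventory → characterize → normalize → contribute → DALY) is
exact, linear, conservative and deterministic. What they cannot show:
agreement with any real background database's magnitudes — absolute
category scores from this package are only as meaningful as the factor
tables supplied to it. The published absolute scores are therefore
shipped as reference data for arithmetic cross-checks, not recomputed.

## Numerical choices and degenerate inputs

Zero demand, zero-mass components and empty scenario lists are valid and
exercised; negative physical quantities raise domain errors at
construction. Recipe mass conservation is exact to 1e-12 relative.
Linearity and contribution-conservation tolerances are 1e-9 relative.
The acceptance script runs the solver/oracle comparison on 100 systems
and the full pipeline for both programmes; everything completes in a few
seconds on one CPU, so no scaling-down of problem sizes was needed.

## Known limitations

* Foreground material masses for brushes and packaging are placeholder
  teardown-informed defaults, not measured data.
* No uncertainty propagation (no Monte Carlo over factors) and no
  regionalized characterization.
* Ecosystem-damage and resource-scarcity endpoints are out of scope; the
  DALY module covers human health only.
* At-home brushing resources are deliberately absent from the supervised
  programme model, and the provision model assumes full compliance with
  twice-daily brushing — both inherited modelling choices, so the two
  programmes are not symmetric and direct superiority claims need care.
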