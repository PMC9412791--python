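# brushlca

Life cycle assessment (LCA) of two community caries-prevention
programmes for young children, per the functional unit *one five-year-old
child receiving the programme for one year*:

* **supervised toothbrushing in schools** — staff-supervised brushing
  once per school day (195 days/year): 5 toothbrushes, 0.65 toothpaste
  tubes, 390 L of tap water, a per-child share of ABS toothbrush-holder
  "buses" and of quarterly delivery travel;
* **targeted provision of toothbrushes and toothpaste** — quarterly
  packs (brush + 100 ml tube in a 1.5 g zip-lock bag) supporting
  twice-daily brushing at home (730 episodes, 1,460 L of water).

It is aimed at dental public-health and healthcare-sustainability
analysts who want a reproducible, parameterized version of these
programme models: every assumption (brushes per year, water per episode,
holder mass, trip distance, materials…) is a configuration parameter,
and each programme ships with its published sensitivity scenarios
(bamboo instead of plastic brushes, doubled toothpaste dose, paper bags,
excluding home water use).

## Model

The computation follows the standard matrix formulation of life cycle
inventory analysis. With technology matrix **A** (product flows ×
processes; reference products positive, consumed products negative),
intervention matrix **B** (elementary flows × processes) and
functional-unit demand **f**:

    A s = f            (process scaling vector s)
    g = B s            (life cycle inventory)
    h = Q g            (midpoint scores; Q = characterization factors)

Midpoint scores cover the 16 PEF impact categories (climate change *CC*
in kg CO₂ eq, acidification *EAC*, three eutrophication pathways,
toxicity, ionising radiation, particulate matter, ozone formation and
depletion, land/fossil/mineral/water resource use). Normalization
divides included scores by annual per-person references, with the three
toxicity categories (*ECF*, *HCE*, *HNC*) carried as explicitly excluded
per PEF practice. Contribution analysis decomposes each category score
into labelled foreground-component groups (toothbrush, toothpaste,
water, staff travel, holder/bag). Human-health endpoint conversion maps
the eight health-relevant midpoints to DALYs via damage factors and
reports totals in DALYs and DALY-seconds (31,536,000 s/year).

Real LCIA runs need a licensed background database. That layer is out of
scope here; `brushlca.synthetic_background` generates seeded, structurally
faithful stand-ins (log-uniform characterization factors, acyclic supply
chains), so the whole pipeline is runnable and testable end to end, and
the package ships the published midpoint and DALY tables as reference
data for the arithmetic that *is* exactly reproducible (scenario percent
changes, DALY totals and seconds).

## Worked example

```python
from brushlca.foreground_inventory import supervised_defaults, annual_water_litres
from brushlca.refdata import reference_daly_breakdown, reference_score
from brushlca.endpoint_daly import total_dalys, daly_seconds
from brushlca.scenario_analysis import rounded_percent_change

p = supervised_defaults()
print(annual_water_litres(p.water_L_per_episode, p.episodes_per_year))
# 390.0  -> litres of tap water per child-year (2 L x 195 school days)

total = total_dalys(reference_daly_breakdown()["supervised"])
print(total, daly_seconds(total))
# 3.60977608894885e-06 113.83789874109092
# -> total health burden of one child-year of the programme: ~114 seconds
#    of healthy life lost, dominated by global warming and water use

cc0 = reference_score("supervised", "baseline", "CC")
cc1 = reference_score("supervised", "bamboo_brush", "CC")
print(rounded_percent_change(cc0, cc1))
# -15  -> switching to bamboo brushes cuts the climate-change score 15%
```

End-to-end run from the shell (synthetic background, deterministic for a
given seed):

```sh
brushlca run --programme supervised --synthetic-seed 1 --out results/supervised
```

writes `lcia_scenarios.csv` (baseline + sensitivity columns per
category), `normalized.csv`, `contributions.csv`, `dalys.csv` and a
`manifest.json` recording the seed and configuration hash.

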