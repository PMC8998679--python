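# nanossbd

A prospective life-cycle-assessment (LCA) toolkit for *safe-and-sustainable-
by-design* (SSbD) screening of engineered nanomaterials, aimed at material
developers who need an early read on both environmental sustainability and
nano-specific toxicity — before market-ready data exist.

## What it computes

**Inventory.** A product system is a set of unit processes, each with one
reference product. The life-cycle inventory for a functional unit `f` comes
from the standard matrix formulation:

```
A s = f        # technology matrix × scaling vector = final demand
g   = B s      # intervention matrix × scaling vector = inventory
```

with outputs positive / inputs negative in `A`, and emissions positive /
resource draws negative in `B`. Nanomaterial releases enter `B` through
per-stage release fractions (manufacture, coating, use, disposal) with an
explicit sewer→freshwater routing step (transfer coefficient 1 by default —
precautionary).

**Impact assessment.** Four indicators: global warming potential (GWP,
kg CO₂-eq), cumulative energy demand (CED, MJ), human toxicity non-cancer
(HTP) and freshwater ecotoxicity (FEP, PAF·m³·d — potentially affected
fraction of species). Nano toxicity factors follow the fate × exposure ×
effect decomposition

```
CF = FF [d] × XF [–] × EF [PAF·m³/kg]
```

with a tiered resolution cascade when a nanoform lacks data: own entry →
user-declared read-across surrogate (another nanoform of the same
substance) → composition with missing FF/XF defaulted to 1 (precautionary —
the estimate cannot understate risk). Every fallback is recorded with a
provenance tier (`measured_industrial … literature, read_across,
default_precautionary, assumption`). HTP and FEP are reported separately
for bulk-phase and nano-phase flows, which typically differ by orders of
magnitude.

**Decision engine.** A stepwise data-availability walk decides between a
full prospective LCA and a green-chemistry KPI fallback (solvent, energy,
heat, pollutant and waste intensities per gram of nanomaterial), and emits
a deterministic decision trace plus a data plan (one tier per quantity).

**Interpretation.** Hotspot screening (size < 50 nm, aspect ratio > 1:5,
fibrous insolubility, unstable coatings, persistence, reactivity,
agglomeration, high release rate; process dominance > 50 % of an
indicator), reference-vs-original comparison with an explicit **trade-off
flag** (some indicator improves while another worsens), and two
uncertainty heat maps: process × indicator (inventory provenance) and
nanoform × toxicity indicator (factor provenance).

## Worked example

The bundled case-study-shaped fixture compares hydrogen photocatalysis
(functional unit: 1 g H₂) with a bare 20 nm titania catalyst (P25-TiO₂,
literature factors FEP 3443 PAF·d·m³/kg, HTP 222 cases·d/kg) against a
Cu₂O-decorated variant with better photocatalytic efficiency (FEP 17,700
via read-across from CuO nanoforms; HTP 0.99). Inventory magnitudes are
synthetic (see `docs/methods.md`).

```bash
nanossbd fixture --out demo --seed 1
nanossbd run --config demo/config.yaml
```

prints:

```
mode: prospective_lca
reference GWP (bulk): 0.087 kg CO2-eq
reference CED (bulk): 1.59 MJ
reference FEP (bulk): 0.0007508 PAF·m3·d
reference FEP (nano): 0.051645 PAF·m3·d
reference HTP (bulk): 1.9e-12 cases·d
reference HTP (nano): 0.0035076 cases·d
original GWP (bulk): 0.052572 kg CO2-eq
original CED (bulk): 0.96108 MJ
original FEP (bulk): 0.00045048 PAF·m3·d
original FEP (nano): 0.169629 PAF·m3·d
original HTP (bulk): 1.14e-12 cases·d
original HTP (nano): 0.0007819452 cases·d
overall: mixed; trade_off_flag: True
```

Reading: the coated catalyst cuts GWP and CED by ~40 % (less catalyst,
methanol and electricity per gram of H₂), but nano-basis freshwater
ecotoxicity more than triples — the released coated nanoform carries a
read-across CF five times that of bare titania. The trade-off flag marks
exactly this burden shift; the design screen additionally flags the 20 nm
particle size, and the heat maps show the coated-form FEP factor at the
`read_across` tier. Artifacts (impact tables, contribution rankings,
decision traces, heat-map grids, comparison report) land in `demo/out/`.

Other subcommands: `nanossbd kpi` (green-chemistry KPIs), `nanossbd
compare` (two results tables), `nanossbd validate` (schema checks only).

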