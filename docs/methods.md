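# Methods

## Model and assumptions

The toolkit implements a screening-level, attributional, matrix-based LCA
for nanomaterial-containing product systems. Each unit process produces
exactly one reference product (no allocation, no by-products; the intended
systems are linear chains), so the technology matrix `A` is square with one
column per process and one row per product flow, outputs positive and
inputs negative. Solving `A s = f` for the scaling vector and applying the
intervention matrix `g = B s` gives the inventory per functional unit. A
reciprocal-condition guard (rcond < 1e-12) turns near-singular systems into
an explicit error naming an unproducible product flow where one can be
identified, rather than returning silent garbage; the solve is additionally
checked against a 1e-9 relative residual.

Sign conventions follow standard computational LCA: emissions positive,
resource draws negative in `B`. Cumulative energy demand is therefore
computed with a factor of −1 MJ per MJ of primary-energy draw, so the
indicator total is positive. Units are carried as labels and validated per
flow; the only automatic conversions are g↔kg and MJ↔kWh, each logged.

**Release accounting.** Nanomaterial emissions are modelled as per-stage
release fractions of handled mass into air, sewer, freshwater or soil, with
the constraint that fractions per stage sum to ≤ 1 (mass balance). Sewer
loads are routed to freshwater with a configurable transfer coefficient,
default 1.0 — the precautionary worst case in which wastewater treatment
retains nothing. Disposal-stage release is a parameter
(`disposal_release_freshwater`, default 0.05): a leak-free recycling
filtration would make it 0, but a small residual to surface water is the
conservative screening default.

**Toxicity characterization.** Nano CFs compose as fate factor (days of
residence in the compartment) × exposure factor (available fraction, 0–1)
× effect factor (PAF·m³/kg for ecotoxicity; cases/kg intake for human
toxicity). Resolution is tiered: a nanoform's own entry; else a
user-declared read-across surrogate (never auto-inferred from
physicochemical similarity — the mapping and its rationale are inputs);
else composition with missing FF or XF defaulted to 1. The default cannot
understate impact: for fixed effect factor, CF(FF=1, XF=1) bounds every
admissible combination with FF ≤ 1, XF ≤ 1. Every fallback is recorded in
a resolution trace and surfaces in the CF heat map at its own tier.
HTP factors are stored and applied in cases·d/kg as registries print them;
sources are inconsistent about where the day dimension cancels, so totals
are reported in cases·d rather than silently rescaled. Bulk-phase and
nano-phase flows feed separate HTP/FEP results; a flow's phase attribute
decides its column, so nothing is double-counted.

A nanoform with *no* entry and no surrogate is a hard error that instructs
the KPI-only fallback; a nanoform merely missing one (compartment,
indicator) pair — e.g. no freshwater-ecotoxicity factor for an air
emission — contributes zero there with an explicit warning, since such a
factor often does not exist physically.

## Decision engine

The availability profile answers every decision node explicitly (no
nulls); toxicity/fate availability may be answered per nanoform. The walk
is deterministic: no process-level data or unknown system boundaries →
KPI-only mode; otherwise each required quantity (release, per-nanoform CF
and FF, XF, inventory flows) gets the least-uncertain tier the profile
supports, with the fallback chain toxicity → database → read-across →
bulk proxy, and XF defaulting to 1 (precautionary) when not annotated.
Intermediate interpretation steps between inventory and scale-up have no
defined semantics in this toolkit and are recorded as an explicit
"not modelled" gap; scale-up is a report stub restating its data need
(thermodynamics and efficiencies of larger equipment) — no scale-up
computation is invented. Iteration is the user rerunning with an updated
profile. KPI comparisons stay per-indicator; no aggregate score exists
because no defensible weighting across the five KPIs does.

## Hotspot rules

Numeric thresholds are encoded literally: particle size < 50 nm, aspect
ratio > 1:5 (HARN). Fibrous insolubility combines non-solubility with HARN
geometry. Categorical criteria (coating stability, persistence,
reactivity, agglomeration) fire on the hazardous category; an "unknown"
value produces an information-gap ("needs characterization") flag, never a
silent pass. The coating-stability rule is skipped for uncoated forms.
Reactive-oxygen-species generation is screened through the `reactivity`
attribute (ROS formation is the main mechanism behind high reactivity at
this screening level); an exposure-route rule (inhalation of powders) is
not in the default set because no nanoform attribute carries the handling
form — users can add it as a custom categorical rule.
Two thresholds are tool defaults with no literature value: a stage is
flagged for high release when its summed fractions exceed 0.01, and a
process is dominant when it carries more than 50 % of an indicator
(ties in rankings break by process id, so output is independent of input
order). Both are configurable.

Comparison polarity is lower-is-better for all four indicators (they are
impact potentials). The trade-off flag is raised exactly when at least one
indicator improves and another worsens.

## Synthetic case fixture

The fixture emulates photocatalytic hydrogen production (functional unit
1 g H₂): a reference system with a bare 20 nm / 50 m²·g⁻¹ titania
photocatalyst and an original system whose Cu₂O-decorated variant improves
efficiency, cutting catalyst, methanol-scavenger and electricity demand by
`efficiency_gain` (default 0.4) while paying a coating chain (5 kWh and
0.15 kg copper precursor per kg coated catalyst). The characterization
factors are the published per-nanoform values (bare form: FEP 3443,
HTP 222; coated form: FEP 17,700 through the declared CuO read-across
surrogate, HTP 0.99) at their correct provenance tiers, and the
availability profile reproduces the documented data situation
(lab-tier inventory, literature factors for the bare form, read-across +
precautionary exposure for the coated form).

Everything else — background emission factors (0.5 kg CO₂/kWh and
10 MJ/kWh electricity; 2 kg CO₂/kg and 35 MJ/kg methanol; 4 kg CO₂/kg and
60 MJ/kg precursor), demands (2×10⁻⁴ kg catalyst, 0.03 kg methanol,
0.05 kWh per g H₂; 20 kWh/kg catalyst manufacture), release fractions
(manufacture and coating: 0.4 % to air, 2.5 % to sewer; use: none;
disposal: 5 % to freshwater) — is **synthetic**: magnitudes plausible for a
lab-scale energy-conversion chain, chosen once so the qualitative pattern
the trade-off detector must catch (climate and energy improve, nano
ecotoxicity worsens) holds at the defaults, with methanol supply the
dominant GWP contributor. They are not measured inventory data, and
passing tests therefore demonstrates correct mechanics and faithful
qualitative behaviour, not the absolute impacts of any real process. What
the fixture does not emulate: background-database depth (each background
process is one aggregate row), regionalization, multimedia fate dynamics
(FF/XF/EF are inputs, not simulated), and temporal or scale-up effects.

The random-system generator draws strictly diagonally dominant technology
matrices (hence invertible) of up to 8 processes with non-negative
synthetic factors, fully determined by one seed; it exists to property-test
the solver and characterization, not to resemble any real system.

## Numerical and design choices

* Solver: LAPACK LU via `numpy.linalg.solve`; correctness is checked in
  tests against an independent adjugate/cofactor inverse on 200 seeded
  systems (≤ 5 processes), at 1e-9 relative tolerance — sized so the whole
  suite runs in seconds on one CPU.
* Contributions must sum to their total within 1e-9 relative;
  the end-to-end fixture totals are verified against an independent
  chain-arithmetic hand computation at 1e-12 relative.
* CSV dialect: comma, UTF-8, dot decimal, header mandatory, numbers at 12
  significant digits; reruns with the same config are byte-identical.
* Every precautionary default, read-across substitution, unit coercion and
  sewer routing is logged at warning level — the audit trail is part of
  the method.
* Exit codes: 0 ok, 1 validation error, 2 computation error.

## Known limitations

No background-database import (ecoinvent/ILCD/ecospold), no multimedia
fate simulation, no species-sensitivity-distribution fitting (EF/HEF are
inputs), no allocation or by-products, no regionalized or dynamic LCA, no
multi-criteria weighting or monetization, and no automated retrieval from
regulatory databases — database availability is an input answer, keeping
the engine pure and reproducible.
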