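"""Synthetic input generators.

Two generators:

* :func:`make_case_fixture` — a photocatalytic-hydrogen case study shaped
  like the study conditions this toolkit targets: a reference system using a
  bare 20 nm titania photocatalyst (P25-TiO2) and an original system using a
  Cu2O-decorated variant with better photocatalytic efficiency. The
  toxicity characterization factors are the published values for these
  nanoforms (P25: FEP 3443 PAF·d·m3/kg, HTP 222 cases·d/kg; coated form:
  FEP 17,700 via read-across from CuO, HTP 0.99). The *inventory*
  magnitudes (catalyst, methanol, electricity demands; background emission
  factors) are synthetic: they are chosen so the qualitative outcome —
  climate and energy indicators improve with the coated catalyst while nano
  ecotoxicity worsens — holds at the defaults, which is the pattern the
  trade-off detector must catch. They are NOT measured inventory data.

* :func:`make_random_system` — seeded random, diagonally dominant product
  systems with a synthetic factor registry, for property-based testing of
  the solver and characterization.

All randomness flows through one explicitly seeded generator; no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .characterization import (CharacterizationRegistry, CharFactorSet,
                               NanoForm, SurrogateLink)
from .errors import ValidationError
from .framework_engine import AvailabilityProfile, DataTier
from .system_model import (Exchange, Flow, Process, ProductSystem,
                           ReleaseModel, apply_release, route_sewer)

P25 = "p25_tio2"
COATED = "cu2o_p25"
CUO_SURROGATE = "cuo_nm"

#: Published characterization factors per nanoform (freshwater emission).
CASE_CF = {
    (P25, "FEP"): 3443.0,
    (P25, "HTP"): 222.0,
    (CUO_SURROGATE, "FEP"): 17700.0,
    (COATED, "HTP"): 0.99,
}


def _default_release_fractions() -> dict[str, dict[str, float]]:
    return {
        "nm_manufacture": {"air": 0.004, "sewer": 0.025},
        "nano_coating": {"air": 0.004, "sewer": 0.025},
        "use": {},
        "disposal": {},  # filled from disposal_release_freshwater
    }


@dataclass(frozen=True)
class CaseParams:
    """Parameters of the case-study-shaped scenario (synthetic defaults).

    ``efficiency_gain`` is the fraction by which the coated catalyst reduces
    catalyst, scavenger and electricity demand per gram of hydrogen.
    ``disposal_release_freshwater`` covers the end-of-life residual: with a
    leak-free recycling filtration it would be 0; the default keeps a small
    residual to freshwater.
    """

    seed: int = 0
    functional_unit_g_h2: float = 1.0
    catalyst_per_g_h2: float = 2e-4  # kg catalyst per g H2
    methanol_per_g_h2: float = 0.03  # kg scavenger per g H2
    electricity_per_g_h2: float = 0.05  # kWh per g H2 (auxiliaries)
    electricity_per_kg_catalyst: float = 20.0  # kWh per kg P25
    electricity_per_kg_coating: float = 5.0  # kWh per kg coated catalyst
    precursor_per_kg_coating: float = 0.15  # kg Cu precursor per kg coated
    efficiency_gain: float = 0.4
    sewer_transfer: float = 1.0
    disposal_release_freshwater: float = 0.05
    release_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_release_fractions)
    # synthetic background factors
    electricity_gwp: float = 0.5  # kg CO2 per kWh
    electricity_ced: float = 10.0  # MJ per kWh
    methanol_gwp: float = 2.0  # kg CO2 per kg
    methanol_ced: float = 35.0  # MJ per kg
    precursor_gwp: float = 4.0
    precursor_ced: float = 60.0
    tio2_bulk_fw_per_kg: float = 0.002  # kg bulk TiO2 to freshwater per kg P25
    methanol_fw_per_kg: float = 5e-4  # kg methanol to freshwater per kg supplied

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency_gain < 1.0:
            raise ValidationError("efficiency_gain must be in [0, 1)")
        for frac in (self.sewer_transfer, self.disposal_release_freshwater):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("fractions must be in [0, 1]")
        fractions = {stage: dict(comp) for stage, comp
                     in dict(self.release_fractions).items()}
        object.__setattr__(self, "release_fractions", fractions)

    def stage_fractions(self, stage: str) -> dict[str, float]:
        fracs = dict(self.release_fractions.get(stage, {}))
        if stage == "disposal" and not fracs:
            fracs = {"freshwater": self.disposal_release_freshwater}
        return fracs


@dataclass
class ScenarioBundle:
    """Everything one system needs to run end to end."""

    name: str
    system: ProductSystem
    registry: CharacterizationRegistry
    profile: AvailabilityProfile
    nanoforms: dict[str, NanoForm]
    nanoform_assignment: dict[str, str]
    release_models: list[ReleaseModel]


@dataclass
class CaseFixture:
    params: CaseParams
    reference: ScenarioBundle
    original: ScenarioBundle


def _case_flows(include_coating: bool) -> list[Flow]:
    flows = [
        Flow("h2", "hydrogen", "product", unit="g"),
        Flow("catalyst_p25", "P25-TiO2 catalyst", "product", unit="kg"),
        Flow("electricity", "electricity", "product", unit="kWh"),
        Flow("methanol", "methanol", "product", unit="kg"),
        Flow("co2_air", "carbon dioxide", "elementary", "bulk", "air", "kg"),
        Flow("primary_energy", "primary energy carriers", "elementary",
             "bulk", "soil", "MJ"),
        Flow("tio2_bulk_fw", "TiO2", "elementary", "bulk", "freshwater", "kg"),
        Flow("methanol_fw", "methanol", "elementary", "bulk", "freshwater",
             "kg"),
        Flow("nano_p25_air", "P25-TiO2 nanoform", "elementary", "nano", "air",
             "kg"),
        Flow("nano_p25_fw", "P25-TiO2 nanoform", "elementary", "nano",
             "freshwater", "kg"),
    ]
    if include_coating:
        flows += [
            Flow("catalyst_coated", "Cu2O/P25-TiO2 catalyst", "product",
                 unit="kg"),
            Flow("cu_precursor", "copper precursor", "product", unit="kg"),
            Flow("nano_coated_air", "Cu2O/P25-TiO2 nanoform", "elementary",
                 "nano", "air", "kg"),
            Flow("nano_coated_fw", "Cu2O/P25-TiO2 nanoform", "elementary",
                 "nano", "freshwater", "kg"),
        ]
    return flows


def _release_exchanges(stages: list[tuple[float, ReleaseModel]],
                       sewer_transfer: float, air_flow: str,
                       fw_flow: str) -> list[Exchange]:
    """Nano emissions of one or more stages, merged into process exchanges
    (sewer routed to freshwater; one exchange per flow)."""
    merged: dict[str, float] = {}
    for handled_mass, model in stages:
        emitted = route_sewer(apply_release(handled_mass, model),
                              sewer_transfer)
        for comp, mass in emitted.items():
            flow = {"air": air_flow, "freshwater": fw_flow}.get(comp)
            if flow is None:
                raise ValidationError(
                    f"no flow mapped for compartment {comp!r}")
            merged[flow] = merged.get(flow, 0.0) + mass
    return [Exchange(flow, mass, "output") for flow, mass in merged.items()]


def make_case_registry() -> CharacterizationRegistry:
    """The case factor registry: published CFs with their provenance tiers.

    The coated form has no ecotoxicity entry of its own; it resolves through
    the declared read-across surrogate (CuO nanoforms of the same metal
    oxide family), exactly the substitution the data plan prescribes.
    """
    lit = DataTier.literature
    entries = [
        CharFactorSet(P25, "freshwater", "FEP", cf=CASE_CF[(P25, "FEP")],
                      cf_unit="PAF·d·m3/kg", source_tier=lit,
                      source_ref="freshwater fate/effect literature"),
        CharFactorSet(P25, "freshwater", "HTP", cf=CASE_CF[(P25, "HTP")],
                      cf_unit="cases·d/kg", source_tier=lit,
                      source_ref="human-toxicity literature"),
        CharFactorSet(P25, "air", "HTP", cf=CASE_CF[(P25, "HTP")],
                      cf_unit="cases·d/kg", source_tier=lit,
                      source_ref="human-toxicity literature"),
        CharFactorSet(CUO_SURROGATE, "freshwater", "FEP",
                      cf=CASE_CF[(CUO_SURROGATE, "FEP")],
                      cf_unit="PAF·d·m3/kg", source_tier=lit,
                      source_ref="CuO nanoform fate/effect literature"),
        CharFactorSet(COATED, "freshwater", "HTP", cf=CASE_CF[(COATED, "HTP")],
                      cf_unit="cases·d/kg", source_tier=lit,
                      source_ref="human-toxicity literature"),
        CharFactorSet(COATED, "air", "HTP", cf=CASE_CF[(COATED, "HTP")],
                      cf_unit="cases·d/kg", source_tier=lit,
                      source_ref="human-toxicity literature"),
    ]
    surrogates = [SurrogateLink(
        COATED, CUO_SURROGATE,
        "no ecotoxicity data for the Cu2O-coated form; CuO nanoform data "
        "used as read-across surrogate for the copper oxide coating")]
    bulk = {
        ("TiO2", "freshwater", "FEP"): 2.0,
        ("TiO2", "freshwater", "HTP"): 1e-6,
        ("methanol", "freshwater", "FEP"): 50.0,
        ("methanol", "freshwater", "HTP"): 1e-7,
    }
    gwp_ced = {
        ("co2_air", "GWP"): 1.0,
        # resource draws are negative in the intervention matrix, so the
        # factor of -1 MJ/MJ yields a positive cumulative energy demand
        ("primary_energy", "CED"): -1.0,
    }
    return CharacterizationRegistry(entries, surrogates, bulk, gwp_ced)


def case_nanoforms() -> dict[str, NanoForm]:
    p25 = NanoForm(P25, "TiO2", particle_size_nm=20.0, surface_area_m2_g=50.0,
                   aspect_ratio=1.0, solubility_class="non_soluble",
                   persistence="persistent", reactivity="high",
                   agglomeration="agglomerating")
    coated = NanoForm(COATED, "TiO2", coating="Cu2O", particle_size_nm=20.0,
                      surface_area_m2_g=50.0, aspect_ratio=1.0,
                      solubility_class="non_soluble",
                      coating_stability="unknown", persistence="persistent",
                      reactivity="high", agglomeration="agglomerating")
    return {P25: p25, COATED: coated}


def _case_profile(coated_in_system: bool, notes: str) -> AvailabilityProfile:
    nanoforms = (P25, COATED) if coated_in_system else (P25,)
    return AvailabilityProfile(
        reference_product_exists=True,
        process_level_data_available=True,
        system_boundaries_known=True,
        release_rate_known=True,
        nanoforms=nanoforms,
        nanotox_data_exist={P25: True, COATED: False} if coated_in_system
        else {P25: True},
        nano_database_entry_exists=False,
        fate_data_exist={P25: True, COATED: False} if coated_in_system
        else {P25: True},
        read_across_possible=True,
        tier_annotations={
            "lci_flows": DataTier.measured_lab,
            "release": DataTier.literature,
            f"cf:{P25}": DataTier.literature,
            f"ff:{P25}": DataTier.literature,
        },
        safety_notes=notes,
    )


def make_case_fixture(params: CaseParams | None = None) -> CaseFixture:
    """Build reference and original scenario bundles from one parameter set.

    Deterministic: identical params give identical fixtures. The original
    system consumes ``1 - efficiency_gain`` of the reference's catalyst,
    methanol and auxiliary electricity per gram of hydrogen, but pays the
    coating chain (extra electricity and a copper precursor) and swaps the
    emitted nanoform in the coating and disposal stages.
    """
    p = params or CaseParams()
    registry = make_case_registry()
    nanoforms = case_nanoforms()

    rel_manu = ReleaseModel("nm_manufacture", P25,
                            p.stage_fractions("nm_manufacture"))
    rel_coat = ReleaseModel("nano_coating", COATED,
                            p.stage_fractions("nano_coating"))
    rel_use_ref = ReleaseModel("use", P25, p.stage_fractions("use"))
    rel_use_org = ReleaseModel("use", COATED, p.stage_fractions("use"))
    rel_disp_ref = ReleaseModel("disposal", P25, p.stage_fractions("disposal"))
    rel_disp_org = ReleaseModel("disposal", COATED,
                                p.stage_fractions("disposal"))

    def background_processes() -> list[Process]:
        return [
            Process("electricity_supply", "electricity supply", "electricity",
                    (Exchange("electricity", 1.0, "output"),
                     Exchange("co2_air", p.electricity_gwp, "output"),
                     Exchange("primary_energy", p.electricity_ced, "input")),
                    data_tier="database"),
            Process("methanol_supply", "methanol supply", "methanol",
                    (Exchange("methanol", 1.0, "output"),
                     Exchange("co2_air", p.methanol_gwp, "output"),
                     Exchange("primary_energy", p.methanol_ced, "input"),
                     Exchange("methanol_fw", p.methanol_fw_per_kg, "output")),
                    data_tier="database"),
        ]

    def p25_process(extra_release: list[Exchange]) -> Process:
        exchanges = [
            Exchange("catalyst_p25", 1.0, "output"),
            Exchange("electricity", p.electricity_per_kg_catalyst, "input"),
            Exchange("tio2_bulk_fw", p.tio2_bulk_fw_per_kg, "output"),
        ] + extra_release
        return Process("p25_manufacture", "P25-TiO2 manufacture",
                       "catalyst_p25", tuple(exchanges),
                       data_tier="measured_industrial")

    # reference system: bare P25 catalyst
    manu_rel = _release_exchanges([(1.0, rel_manu)], p.sewer_transfer,
                                  "nano_p25_air", "nano_p25_fw")
    h2_rel_ref = _release_exchanges(
        [(p.catalyst_per_g_h2, rel_use_ref),
         (p.catalyst_per_g_h2, rel_disp_ref)],
        p.sewer_transfer, "nano_p25_air", "nano_p25_fw")
    h2_ref = Process(
        "h2_production", "photocatalytic hydrogen production", "h2",
        tuple([Exchange("h2", p.functional_unit_g_h2, "output"),
               Exchange("catalyst_p25", p.catalyst_per_g_h2, "input"),
               Exchange("methanol", p.methanol_per_g_h2, "input"),
               Exchange("electricity", p.electricity_per_g_h2, "input")]
              + h2_rel_ref),
        data_tier="measured_lab")
    reference_system = ProductSystem(
        _case_flows(include_coating=False),
        background_processes() + [p25_process(manu_rel), h2_ref],
        {"h2": p.functional_unit_g_h2})
    reference = ScenarioBundle(
        "reference", reference_system, registry,
        _case_profile(False, "titania nanoforms persistent and "
                      "photocatalytically reactive; agglomerates may release "
                      "individual particles"),
        {P25: nanoforms[P25]},
        {"nano_p25_air": P25, "nano_p25_fw": P25},
        [rel_manu, rel_use_ref, rel_disp_ref])

    # original system: coated catalyst, reduced demands, coating chain
    shrink = 1.0 - p.efficiency_gain
    coat_rel = _release_exchanges([(1.0, rel_coat)], p.sewer_transfer,
                                  "nano_coated_air", "nano_coated_fw")
    coating = Process(
        "nano_coating", "Cu2O coating of P25-TiO2", "catalyst_coated",
        tuple([Exchange("catalyst_coated", 1.0, "output"),
               Exchange("catalyst_p25", 1.0, "input"),
               Exchange("electricity", p.electricity_per_kg_coating, "input"),
               Exchange("cu_precursor", p.precursor_per_kg_coating, "input")]
              + coat_rel),
        data_tier="measured_lab")
    precursor = Process(
        "precursor_supply", "copper precursor supply", "cu_precursor",
        (Exchange("cu_precursor", 1.0, "output"),
         Exchange("co2_air", p.precursor_gwp, "output"),
         Exchange("primary_energy", p.precursor_ced, "input")),
        data_tier="database")
    catalyst_org = p.catalyst_per_g_h2 * shrink
    h2_rel_org = _release_exchanges(
        [(catalyst_org, rel_use_org), (catalyst_org, rel_disp_org)],
        p.sewer_transfer, "nano_coated_air", "nano_coated_fw")
    h2_org = Process(
        "h2_production", "photocatalytic hydrogen production", "h2",
        tuple([Exchange("h2", p.functional_unit_g_h2, "output"),
               Exchange("catalyst_coated", catalyst_org, "input"),
               Exchange("methanol", p.methanol_per_g_h2 * shrink, "input"),
               Exchange("electricity", p.electricity_per_g_h2 * shrink,
                        "input")]
              + h2_rel_org),
        data_tier="measured_lab")
    original_system = ProductSystem(
        _case_flows(include_coating=True),
        background_processes() + [p25_process(manu_rel), precursor, coating,
                                  h2_org],
        {"h2": p.functional_unit_g_h2})
    original = ScenarioBundle(
        "original", original_system, registry,
        _case_profile(True, "copper oxide nanoform toxicity varies with "
                      "physicochemical properties; coated form "
                      "uncharacterized — read-across applied"),
        dict(nanoforms),
        {"nano_p25_air": P25, "nano_p25_fw": P25,
         "nano_coated_air": COATED, "nano_coated_fw": COATED},
        [rel_manu, rel_coat, rel_use_org, rel_disp_org])

    return CaseFixture(p, reference, original)


@dataclass(frozen=True)
class RandomSystemParams:
    seed: int = 0
    n_processes: int = 4
    n_elementary: int = 3
    sparsity: float = 0.5  # probability an off-diagonal/B entry is nonzero
    magnitude: float = 2.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_processes <= 8:
            raise ValidationError("n_processes must be in [1, 8]")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValidationError("sparsity must be in [0, 1]")


def make_random_system(params: RandomSystemParams,
                       ) -> tuple[ProductSystem, CharacterizationRegistry]:
    """Seeded random product system with a diagonally dominant technology
    matrix (hence invertible) and a synthetic non-negative factor registry."""
    rng = np.random.default_rng(params.seed)
    n, m = params.n_processes, params.n_elementary
    compartments = ["air", "freshwater", "soil"]

    flows = [Flow(f"prod_{i}", f"product {i}", "product", unit="kg")
             for i in range(n)]
    flows += [Flow(f"elem_{j}", f"emission {j}", "elementary", "bulk",
                   compartments[j % len(compartments)], "kg")
              for j in range(m)]

    diag = rng.uniform(1.0, params.magnitude, size=n)
    processes = []
    for i in range(n):
        exchanges = [Exchange(f"prod_{i}", diag[i], "output")]
        # strict diagonal dominance by rows: inputs to process i draw on
        # other products with total magnitude below every diagonal entry
        budget = 0.8 * diag.min() / max(1, n - 1)
        for k in range(n):
            if k == i:
                continue
            if rng.random() < params.sparsity:
                exchanges.append(
                    Exchange(f"prod_{k}", rng.uniform(0.05, 1.0) * budget,
                             "input"))
        for j in range(m):
            if rng.random() < params.sparsity:
                exchanges.append(
                    Exchange(f"elem_{j}",
                             rng.uniform(0.0, params.magnitude), "output"))
        processes.append(Process(f"proc_{i}", f"process {i}", f"prod_{i}",
                                 tuple(exchanges), data_tier="assumption"))

    demand = {f"prod_{rng.integers(n)}": float(rng.uniform(0.1, 10.0))}
    system = ProductSystem(flows, processes, demand)

    gwp_ced = {}
    bulk = {}
    for j in range(m):
        gwp_ced[(f"elem_{j}", "GWP")] = float(rng.uniform(0.0, 5.0))
        gwp_ced[(f"elem_{j}", "CED")] = float(rng.uniform(0.0, 5.0))
        comp = compartments[j % len(compartments)]
        bulk[(f"emission {j}", comp, "FEP")] = float(rng.uniform(0.0, 100.0))
        bulk[(f"emission {j}", comp, "HTP")] = float(rng.uniform(0.0, 1.0))
    registry = CharacterizationRegistry([], [], bulk, gwp_ced)
    return system, registry
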