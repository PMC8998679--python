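"""Hotspot screening, system comparison, and uncertainty heat maps.

Three interpretation products:

* a *hotspot report*: design-level flags from screening the nanoform's
  physicochemical profile and release behaviour against known hazard
  criteria (small size, high aspect ratio, fibrous insolubility, unstable
  coating, persistence, reactivity, agglomeration, high release rate), plus
  process-level dominance flags from contribution analysis;
* a *comparison report* between a reference and a modified (original)
  system, per indicator, with an explicit trade-off flag when one indicator
  improves while another worsens — the signature outcome the framework is
  designed to catch early;
* *uncertainty heat maps*: grids of data-provenance tiers, one over the
  inventory (process x indicator) and one over the characterization factors
  (nanoform x toxicity indicator), so precautionary defaults and read-across
  substitutions stay visible in the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .characterization import (CharacterizationRegistry, ImpactResult,
                               NanoForm, resolve_factors)
from .errors import CannotCharacterizeError, ValidationError
from .framework_engine import DataTier, DecisionTrace
from .system_model import ProductSystem, ReleaseModel

#: Particle size below which a nanoform is flagged as a size hotspot (nm).
SMALL_SIZE_NM = 50.0
#: Aspect ratio beyond which a nanoform counts as high-aspect-ratio (HARN).
HARN_ASPECT_RATIO = 5.0
#: Tool default: flag a life-cycle stage whose summed release fraction
#: exceeds this share of handled mass. No literature threshold exists for
#: "high release rate"; this is a configurable screening default.
HIGH_RELEASE_FRACTION = 0.01
#: Tool default share above which a single process is flagged dominant.
DOMINANCE_SHARE = 0.5


@dataclass(frozen=True)
class HotspotRule:
    """One screening criterion.

    ``kind`` selects the predicate machinery: ``threshold_lt``/``threshold_gt``
    compare a numeric attribute against ``threshold``; ``category`` fires when
    the attribute equals ``category`` (and raises an information-gap flag on
    "unknown"); ``fibrous_non_soluble`` combines insolubility with HARN
    geometry; ``release_rate`` checks summed stage release fractions.
    """

    parameter: str
    kind: str
    action: str
    attribute: str = ""
    threshold: float | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.action:
            raise ValidationError(f"rule {self.parameter}: empty action")
        if self.kind not in ("threshold_lt", "threshold_gt", "category",
                             "fibrous_non_soluble", "release_rate"):
            raise ValidationError(f"rule {self.parameter}: bad kind {self.kind!r}")


@dataclass(frozen=True)
class HotspotFlag:
    parameter: str
    flag_type: str  # "design" | "information_gap"
    triggering_value: object
    action: str


def default_hotspot_rules() -> list[HotspotRule]:
    """The built-in screening rule set.

    Numeric thresholds are encoded literally (size < 50 nm, aspect ratio
    > 1:5); categorical criteria fire on the hazardous category and emit an
    information-gap flag when the attribute is "unknown". The
    coating-stability rule only applies to coated forms.
    """
    return [
        HotspotRule("size", "threshold_lt",
                    "Alter design to avoid NMs below this threshold",
                    attribute="particle_size_nm", threshold=SMALL_SIZE_NM),
        HotspotRule("shape", "threshold_gt",
                    "Alter design to avoid NMs with HARN",
                    attribute="aspect_ratio", threshold=HARN_ASPECT_RATIO),
        HotspotRule("solubility", "fibrous_non_soluble",
                    "Alter design to avoid fibrous, non-soluble materials"),
        HotspotRule("coating_stability", "category",
                    "Alter design with stable coating",
                    attribute="coating_stability", category="unstable"),
        HotspotRule("persistence", "category",
                    "Alter design to avoid environmentally persistent NMs",
                    attribute="persistence", category="persistent"),
        HotspotRule("reactivity", "category",
                    "Alter design to avoid reactive NMs",
                    attribute="reactivity", category="high"),
        HotspotRule("agglomeration", "category",
                    "Alter design to NMs that do not agglomerate if lung "
                    "exposure is expected",
                    attribute="agglomeration", category="agglomerating"),
        HotspotRule("release_rate", "release_rate",
                    "Alter matrix design to avoid NM environmental release",
                    threshold=HIGH_RELEASE_FRACTION),
    ]


@dataclass
class HotspotReport:
    flags: list[HotspotFlag] = field(default_factory=list)
    #: per (indicator, basis) key: ranked [(process, contribution, share)]
    process_hotspots: dict[str, list[tuple[str, float, float]]] = field(
        default_factory=dict)
    dominant: dict[str, str | None] = field(default_factory=dict)


def screen_nanoform(form: NanoForm,
                    releases: ReleaseModel | Iterable[ReleaseModel] = (),
                    rules: Sequence[HotspotRule] | None = None,
                    ) -> HotspotReport:
    """Screen a nanoform (and its release behaviour) against hotspot rules.

    Unknown categorical attributes produce an ``information_gap`` flag —
    "needs characterization" — never a silent pass.
    """
    if rules is None:
        rules = default_hotspot_rules()
    if isinstance(releases, ReleaseModel):
        releases = [releases]
    releases = list(releases)

    report = HotspotReport()
    for rule in rules:
        if rule.kind in ("threshold_lt", "threshold_gt"):
            value = getattr(form, rule.attribute)
            hit = (value < rule.threshold if rule.kind == "threshold_lt"
                   else value > rule.threshold)
            if hit:
                report.flags.append(HotspotFlag(rule.parameter, "design",
                                                value, rule.action))
        elif rule.kind == "category":
            if rule.attribute == "coating_stability" and form.coating is None:
                continue  # not applicable to uncoated forms
            value = getattr(form, rule.attribute)
            if value == "unknown":
                report.flags.append(HotspotFlag(
                    rule.parameter, "information_gap", value,
                    f"needs characterization: {rule.attribute} unknown"))
            elif value == rule.category:
                report.flags.append(HotspotFlag(rule.parameter, "design",
                                                value, rule.action))
        elif rule.kind == "fibrous_non_soluble":
            sol = form.solubility_class
            if sol == "unknown":
                report.flags.append(HotspotFlag(
                    rule.parameter, "information_gap", sol,
                    "needs characterization: solubility_class unknown"))
            elif sol == "non_soluble" and form.aspect_ratio > HARN_ASPECT_RATIO:
                report.flags.append(HotspotFlag(
                    rule.parameter, "design",
                    (sol, form.aspect_ratio), rule.action))
        elif rule.kind == "release_rate":
            for model in releases:
                total = sum(model.fractions.values())
                if total > rule.threshold:
                    report.flags.append(HotspotFlag(
                        rule.parameter, "design",
                        (model.stage, total), rule.action))
    return report


def find_process_hotspots(results: Iterable[ImpactResult],
                          dominance_share: float = DOMINANCE_SHARE,
                          ) -> HotspotReport:
    """Rank process contributions per indicator and flag dominance.

    Processes sort by contribution descending, ties broken by process id, so
    the ranking is independent of input order. A process is flagged dominant
    when its share of a positive total exceeds ``dominance_share``.
    """
    report = HotspotReport()
    for res in results:
        res.check()
        key = f"{res.indicator}/{res.basis}"
        ranked = sorted(res.contributions.items(),
                        key=lambda kv: (-kv[1], kv[0]))
        total = res.total
        rows = [(proc, val, (val / total if total != 0 else 0.0))
                for proc, val in ranked]
        report.process_hotspots[key] = rows
        report.dominant[key] = (
            rows[0][0] if rows and total > 0 and rows[0][2] > dominance_share
            else None)
    return report


@dataclass
class ComparisonRow:
    indicator: str
    basis: str
    unit: str
    reference: float
    original: float
    delta: float
    relative_delta: float | None  # None when reference is 0
    verdict: str  # better | worse | equal  (for the original system)


@dataclass
class ComparisonReport:
    rows: list[ComparisonRow]
    trade_off_flag: bool
    overall: str  # "better" | "worse" | "equal" | "mixed"

    def row(self, indicator: str, basis: str | None = None) -> ComparisonRow:
        for r in self.rows:
            if r.indicator == indicator and (basis is None or r.basis == basis):
                return r
        raise KeyError((indicator, basis))


def compare_systems(reference: Iterable[ImpactResult],
                    original: Iterable[ImpactResult]) -> ComparisonReport:
    """Compare original against reference, lower-is-better on every indicator.

    ``trade_off_flag`` is true iff some indicator improves while another
    worsens — the situation in which a redesign shifts burden rather than
    removing it.
    """
    ref = {(r.indicator, r.basis): r for r in reference}
    org = {(r.indicator, r.basis): r for r in original}
    if set(ref) != set(org):
        raise ValidationError(
            f"indicator sets differ: {sorted(set(ref) ^ set(org))}")
    rows = []
    for key in sorted(ref):
        a, b = ref[key], org[key]
        if a.unit != b.unit:
            raise ValidationError(
                f"{key}: unit mismatch {a.unit!r} vs {b.unit!r}")
        delta = b.total - a.total
        rel = delta / a.total if a.total != 0 else None
        verdict = "better" if delta < 0 else "worse" if delta > 0 else "equal"
        rows.append(ComparisonRow(key[0], key[1], a.unit, a.total, b.total,
                                  delta, rel, verdict))
    verdicts = {r.verdict for r in rows}
    trade_off = "better" in verdicts and "worse" in verdicts
    if verdicts <= {"equal"}:
        overall = "equal"
    elif "worse" not in verdicts:
        overall = "better"
    elif "better" not in verdicts:
        overall = "worse"
    else:
        overall = "mixed"
    return ComparisonReport(rows, trade_off, overall)


@dataclass
class HeatMap:
    """A complete grid of data-provenance tiers.

    ``cells`` is a rows x columns DataFrame of :class:`DataTier`; the legend
    is the tier ordering from lowest to highest uncertainty.
    """

    name: str
    cells: pd.DataFrame
    legend: tuple[DataTier, ...] = tuple(DataTier)

    def __post_init__(self) -> None:
        if self.cells.isna().any().any():
            raise ValidationError(f"heat map {self.name}: unfilled cells")
        for col in self.cells.columns:
            for row in self.cells.index:
                DataTier.parse(self.cells.loc[row, col])

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0] * self.cells.shape[1]

    def to_string_frame(self) -> pd.DataFrame:
        return self.cells.map(lambda t: DataTier.parse(t).value)


INDICATORS = ("GWP", "CED", "HTP", "FEP")


def build_heatmap(plan: Mapping[str, DataTier],
                  systems: Iterable[ProductSystem],
                  registry: CharacterizationRegistry | None = None,
                  compartment: str = "freshwater",
                  trace: DecisionTrace | None = None,
                  ) -> tuple[HeatMap, HeatMap]:
    """Build the two uncertainty heat maps.

    The LCI map has one row per process across all systems and one column
    per impact indicator; cells carry the process' inventory data tier. The
    CF map has one row per nanoform in the plan and one column per toxicity
    indicator; cells carry the tier at which the factor actually resolves
    (so a read-across substitution or a precautionary default surfaces at
    its own, higher-uncertainty tier). ``trace`` is accepted for audit
    output but does not alter the grids.
    """
    proc_tiers: dict[str, DataTier] = {}
    for system in systems:
        for proc in system.processes.values():
            tier = DataTier.parse(proc.data_tier)
            if proc.id in proc_tiers and proc_tiers[proc.id] != tier:
                raise ValidationError(
                    f"process {proc.id} has conflicting data tiers")
            proc_tiers[proc.id] = tier
    if not proc_tiers:
        raise ValidationError("no processes to map")
    lci_cells = pd.DataFrame({ind: [proc_tiers[p] for p in sorted(proc_tiers)]
                              for ind in INDICATORS},
                             index=sorted(proc_tiers))
    lci_map = HeatMap("lci_data_tiers", lci_cells)

    nanoforms = sorted(k.split(":", 1)[1] for k in plan if k.startswith("cf:"))
    if not nanoforms:
        raise ValidationError("plan contains no characterization-factor "
                              "quantities (cf:<nanoform>)")
    gaps = []
    cf_rows: dict[str, list[DataTier]] = {}
    for nf in nanoforms:
        row = []
        for ind in ("FEP", "HTP"):
            tier: DataTier | None = None
            if registry is not None:
                try:
                    tier = resolve_factors(nf, compartment, ind,
                                           registry).source_tier
                except CannotCharacterizeError:
                    tier = None
            if tier is None:
                tier = plan.get(f"cf:{nf}")
            if tier is None:
                gaps.append((nf, ind))
            row.append(tier)
        cf_rows[nf] = row
    if gaps:
        raise ValidationError(f"characterization sources not covered: {gaps}")
    cf_cells = pd.DataFrame.from_dict(cf_rows, orient="index",
                                      columns=["FEP", "HTP"])
    cf_map = HeatMap("cf_data_tiers", cf_cells)
    return lci_map, cf_map
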