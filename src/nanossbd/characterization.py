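"""Nanoform attributes, characterization factors, and impact assessment.

Toxicity characterization for nanoforms follows the fate x exposure x effect
decomposition used for freshwater ecotoxicity and human toxicity:

    CF = FF [d] x XF [-] x EF [PAF.m3/kg]   (ecotoxicity, FEP)
    CF = FF [d] x XF [-] x HEF [cases/kg]   (human toxicity, HTP)

Factors come from a registry with explicit provenance tiers. When a nanoform
has no factor of its own, resolution falls back in order: a user-declared
read-across surrogate (another nanoform of the same substance), then
composition from whatever partial factors exist with the missing fate or
exposure factor defaulted to 1 — the precautionary choice that cannot
understate impact. Every fallback is recorded in a resolution trace so the
uncertainty heat map can surface it.

Impact results are reported on two bases: bulk-phase flows (conventional
factors) and nano-phase flows (the nanoform-specific factors above), so the
orders-of-magnitude difference between them stays visible.

Unit note: HTP characterization factors are stored and applied in
cases.d/kg_emitted as supplied by the registry, so HTP totals carry a day
dimension (cases.d). Sources differ on where the day dimension cancels; this
toolkit reports the registry's unit unchanged rather than guessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import CannotCharacterizeError, ValidationError
from .framework_engine import DataTier
from .system_model import Flow

logger = logging.getLogger("nanossbd")

TOX_INDICATORS = ("FEP", "HTP")
INDICATOR_UNITS = {
    "GWP": "kg CO2-eq",
    "CED": "MJ",
    "FEP": "PAF·m3·d",
    "HTP": "cases·d",
}


@dataclass(frozen=True)
class NanoForm:
    """Physicochemical identity of a manufactured nanomaterial variant.

    The screening attributes (solubility, coating stability, persistence,
    reactivity, agglomeration) take "unknown" when uncharacterized, which the
    hotspot screen turns into an information-gap flag rather than a pass.
    ``aspect_ratio`` is the length:width ratio normalized to width 1, so a
    sphere is 1 and a fibre with 1:6 width:length is 6.
    """

    id: str
    substance: str
    particle_size_nm: float
    surface_area_m2_g: float
    coating: str | None = None
    aspect_ratio: float = 1.0
    solubility_class: str = "unknown"  # soluble | non_soluble | unknown
    coating_stability: str = "unknown"  # stable | unstable | unknown
    persistence: str = "unknown"  # persistent | non_persistent | unknown
    reactivity: str = "unknown"  # high | low | unknown
    agglomeration: str = "unknown"  # agglomerating | non_agglomerating | unknown

    def __post_init__(self) -> None:
        if self.particle_size_nm <= 0:
            raise ValidationError(f"nanoform {self.id}: particle size must be > 0")
        if self.surface_area_m2_g <= 0:
            raise ValidationError(f"nanoform {self.id}: surface area must be > 0")
        if self.aspect_ratio < 1:
            raise ValidationError(f"nanoform {self.id}: aspect ratio must be >= 1")


@dataclass(frozen=True)
class CharFactorSet:
    """Factors for one (nanoform, compartment, indicator) with provenance.

    Either ``cf`` is given directly (e.g. a literature value) or an effect
    factor (``ef`` for FEP, ``hef`` for HTP) is present so a CF can be
    composed, with missing fate/exposure factors defaulted precautionarily.
    """

    nanoform_id: str
    compartment: str
    indicator: str  # "FEP" | "HTP"
    ff_days: float | None = None
    xf: float | None = None
    ef: float | None = None  # PAF.m3/kg
    hef: float | None = None  # cases/kg intake
    cf: float | None = None
    cf_unit: str = ""
    source_tier: DataTier = DataTier.assumption
    source_ref: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_tier", DataTier.parse(self.source_tier))
        if self.indicator not in TOX_INDICATORS:
            raise ValidationError(f"bad toxicity indicator {self.indicator!r}")
        if self.xf is not None and not 0.0 <= self.xf <= 1.0:
            raise ValidationError(
                f"{self.nanoform_id}/{self.indicator}: XF must be in [0,1]")
        for name in ("ff_days", "ef", "hef", "cf"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(
                    f"{self.nanoform_id}/{self.indicator}: {name} must be >= 0")
        if self.cf is None and self.effect_factor() is None:
            raise ValidationError(
                f"{self.nanoform_id}/{self.compartment}/{self.indicator}: "
                "needs either a CF or an effect factor")

    def effect_factor(self) -> float | None:
        return self.ef if self.indicator == "FEP" else self.hef


def compose_cf(ff_days: float, xf: float, effect: float) -> float:
    """Compose a characterization factor as fate x exposure x effect."""
    if ff_days < 0 or effect < 0 or xf < 0:
        raise ValidationError("characterization factor operands must be >= 0")
    if xf > 1.0:
        raise ValidationError(f"exposure factor {xf} exceeds 1")
    return ff_days * xf * effect


@dataclass(frozen=True)
class SurrogateLink:
    """User-declared read-across mapping: use the surrogate nanoform's data
    for the target. Rationale is free text; the tool never infers surrogates
    from physicochemical similarity."""

    target_id: str
    surrogate_id: str
    rationale: str = ""


@dataclass
class CharacterizationRegistry:
    """All factors needed to characterize an inventory.

    ``bulk_factors`` maps (substance, compartment, indicator) -> CF for
    bulk-phase toxicity; ``gwp_ced_factors`` maps (flow_id, indicator) ->
    per-unit factor for GWP (kg CO2-eq/unit) and CED (MJ/unit).
    """

    entries: list[CharFactorSet] = field(default_factory=list)
    surrogate_map: list[SurrogateLink] = field(default_factory=list)
    bulk_factors: dict[tuple[str, str, str], float] = field(default_factory=dict)
    gwp_ced_factors: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for e in self.entries:
            key = (e.nanoform_id, e.compartment, e.indicator)
            if key in seen:
                raise ValidationError(f"duplicate registry entry {key}")
            seen.add(key)
        # surrogate chains must be acyclic
        targets = {}
        for link in self.surrogate_map:
            if link.target_id in targets:
                raise ValidationError(
                    f"nanoform {link.target_id} has two surrogates")
            targets[link.target_id] = link.surrogate_id
        for start in targets:
            node, hops = start, 0
            while node in targets:
                node = targets[node]
                hops += 1
                if hops > len(targets):
                    raise ValidationError(
                        f"surrogate chain starting at {start!r} is cyclic")

    def entry(self, nanoform_id: str, compartment: str,
              indicator: str) -> CharFactorSet | None:
        for e in self.entries:
            if (e.nanoform_id, e.compartment, e.indicator) == (
                    nanoform_id, compartment, indicator):
                return e
        return None

    def surrogate_for(self, nanoform_id: str) -> SurrogateLink | None:
        for link in self.surrogate_map:
            if link.target_id == nanoform_id:
                return link
        return None

    def has_any_entry(self, nanoform_id: str) -> bool:
        return any(e.nanoform_id == nanoform_id for e in self.entries)


@dataclass(frozen=True)
class FactorResolution:
    cf: float
    source_tier: DataTier
    trace: tuple[str, ...]


def _compose_with_defaults(entry: CharFactorSet, base_tier: DataTier,
                           trace: list[str]) -> FactorResolution | None:
    effect = entry.effect_factor()
    if effect is None:
        return None
    tier = base_tier
    ff = entry.ff_days
    if ff is None:
        ff = 1.0
        tier = max(tier, DataTier.default_precautionary)
        trace.append("fate factor missing: defaulted FF=1 (precautionary)")
    xf = entry.xf
    if xf is None:
        xf = 1.0
        tier = max(tier, DataTier.default_precautionary)
        trace.append("exposure factor missing: defaulted XF=1 (precautionary)")
    cf = compose_cf(ff, xf, effect)
    trace.append(f"composed CF = FF({ff}) x XF({xf}) x effect({effect}) = {cf}")
    return FactorResolution(cf, tier, tuple(trace))


def resolve_factors(nanoform_id: str, compartment: str, indicator: str,
                    registry: CharacterizationRegistry) -> FactorResolution:
    """Resolve a CF for (nanoform, compartment, indicator).

    Resolution order: (1) the nanoform's own entry (direct CF, else composed
    from its factors); (2) a read-across surrogate's entry, at tier
    read_across; (3) composition with missing fate/exposure defaulted to 1,
    at tier default_precautionary; (4) error instructing KPI-only mode.
    Every fallback taken is recorded in the returned trace. Deterministic:
    identical registry and query give identical results.
    """
    trace: list[str] = []
    entry = registry.entry(nanoform_id, compartment, indicator)
    if entry is not None:
        if entry.cf is not None:
            trace.append(f"direct entry for {nanoform_id} "
                         f"({entry.source_tier.value})")
            return FactorResolution(entry.cf, entry.source_tier, tuple(trace))
        res = _compose_with_defaults(entry, entry.source_tier, trace)
        if res is not None:
            return res

    link = registry.surrogate_for(nanoform_id)
    visited = {nanoform_id}
    while link is not None:
        sid = link.surrogate_id
        if sid in visited:
            break
        visited.add(sid)
        trace.append(f"read-across: {link.target_id} -> {sid}"
                     + (f" ({link.rationale})" if link.rationale else ""))
        logger.warning("read-across substitution: %s -> %s for %s/%s",
                       link.target_id, sid, compartment, indicator)
        s_entry = registry.entry(sid, compartment, indicator)
        if s_entry is not None:
            if s_entry.cf is not None:
                trace.append(f"surrogate entry ({s_entry.source_tier.value}) "
                             "applied at tier read_across")
                return FactorResolution(s_entry.cf, DataTier.read_across,
                                        tuple(trace))
            res = _compose_with_defaults(s_entry, DataTier.read_across, trace)
            if res is not None:
                return res
        link = registry.surrogate_for(sid)

    raise CannotCharacterizeError(
        f"no characterization factor resolvable for nanoform "
        f"{nanoform_id!r}, compartment {compartment!r}, indicator "
        f"{indicator!r} at any tier; fall back to a KPI-only assessment")


@dataclass
class ImpactResult:
    """One indicator total with per-process contributions.

    ``basis`` separates conventional bulk-flow results from nano-flow results
    so nanoform toxicity is never hidden inside (or double-counted with) the
    bulk columns.
    """

    indicator: str
    basis: str  # "bulk" | "nano"
    total: float
    unit: str
    contributions: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def check(self) -> None:
        s = sum(self.contributions.values())
        scale = max(abs(self.total), 1e-300)
        if abs(s - self.total) > 1e-9 * scale:
            raise ValidationError(
                f"{self.indicator}/{self.basis}: contributions sum {s} != "
                f"total {self.total}")


def _as_frame(inventory) -> pd.DataFrame:
    if isinstance(inventory, pd.DataFrame):
        return inventory
    if isinstance(inventory, pd.Series):
        return inventory.to_frame(name="total")
    return pd.Series(dict(inventory), dtype=float).to_frame(name="total")


def characterize(inventory, flows: Mapping[str, Flow],
                 registry: CharacterizationRegistry,
                 nanoform_assignment: Mapping[str, str] | None = None,
                 ) -> list[ImpactResult]:
    """Apply characterization factors to an inventory.

    ``inventory`` is either a flows x processes DataFrame (per-process
    contributions, e.g. from :meth:`ProductSystem.process_inventory`) or a
    plain flow -> amount mapping/Series (treated as a single "total" column).
    ``nanoform_assignment`` maps each nano-phase flow id to its nanoform id.

    Returns six results: GWP and CED (bulk basis) and HTP/FEP on bulk and
    nano bases. Bulk flows with a nonzero amount but no factor anywhere are
    reported in the warnings of every result rather than silently dropped.
    A nano flow whose nanoform has no registry entry or surrogate at all
    raises; a nanoform merely missing one (compartment, indicator) pair
    contributes zero there with a warning.
    """
    frame = _as_frame(inventory)
    assignment = dict(nanoform_assignment or {})
    warnings: list[str] = []

    nano_rows, bulk_rows = [], []
    for flow_id in frame.index:
        if flow_id not in flows:
            raise ValidationError(f"inventory names unknown flow {flow_id!r}")
        fl = flows[flow_id]
        if fl.kind != "elementary":
            raise ValidationError(f"inventory flow {flow_id!r} is not elementary")
        (nano_rows if fl.phase == "nano" else bulk_rows).append(flow_id)

    for flow_id in nano_rows:
        if frame.loc[flow_id].abs().sum() == 0:
            continue
        if flow_id not in assignment:
            raise CannotCharacterizeError(
                f"nano flow {flow_id!r} has no nanoform assignment")
        nf = assignment[flow_id]
        if not (registry.has_any_entry(nf) or registry.surrogate_for(nf)):
            raise CannotCharacterizeError(
                f"nano flow {flow_id!r}: nanoform {nf!r} has no registry "
                "entry or surrogate")

    results: list[ImpactResult] = []

    # GWP / CED over per-flow multipliers (background + bulk basis)
    for indicator in ("GWP", "CED"):
        contributions = {p: 0.0 for p in frame.columns}
        for flow_id in frame.index:
            factor = registry.gwp_ced_factors.get((flow_id, indicator))
            if factor is None:
                continue
            for proc in frame.columns:
                contributions[proc] += factor * frame.loc[flow_id, proc]
        results.append(ImpactResult(indicator, "bulk",
                                    sum(contributions.values()),
                                    INDICATOR_UNITS[indicator], contributions))

    # bulk flows with no factor under any indicator -> explicit warning
    for flow_id in bulk_rows:
        if frame.loc[flow_id].abs().sum() == 0:
            continue
        fl = flows[flow_id]
        has_gwp_ced = any((flow_id, ind) in registry.gwp_ced_factors
                          for ind in ("GWP", "CED"))
        has_tox = any((fl.name, fl.compartment, ind) in registry.bulk_factors
                      for ind in TOX_INDICATORS)
        if not has_gwp_ced and not has_tox:
            msg = (f"bulk flow {flow_id!r} ({fl.name} -> {fl.compartment}) "
                   "is uncharacterized under every indicator")
            warnings.append(msg)
            logger.warning(msg)

    for indicator in TOX_INDICATORS:
        # bulk basis
        contributions = {p: 0.0 for p in frame.columns}
        for flow_id in bulk_rows:
            fl = flows[flow_id]
            cf = registry.bulk_factors.get((fl.name, fl.compartment, indicator))
            if cf is None:
                continue
            for proc in frame.columns:
                contributions[proc] += cf * frame.loc[flow_id, proc]
        results.append(ImpactResult(indicator, "bulk",
                                    sum(contributions.values()),
                                    INDICATOR_UNITS[indicator], contributions))

        # nano basis
        contributions = {p: 0.0 for p in frame.columns}
        nano_warnings: list[str] = []
        for flow_id in nano_rows:
            if frame.loc[flow_id].abs().sum() == 0:
                continue
            fl = flows[flow_id]
            nf = assignment[flow_id]
            try:
                res = resolve_factors(nf, fl.compartment, indicator, registry)
            except CannotCharacterizeError:
                nano_warnings.append(
                    f"no {indicator} factor for nanoform {nf!r} in "
                    f"{fl.compartment}; contribution of {flow_id!r} omitted")
                continue
            for proc in frame.columns:
                contributions[proc] += res.cf * frame.loc[flow_id, proc]
        results.append(ImpactResult(indicator, "nano",
                                    sum(contributions.values()),
                                    INDICATOR_UNITS[indicator], contributions,
                                    warnings=nano_warnings))

    for res in results:
        res.warnings = list(warnings) + res.warnings
        res.check()
    return results
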