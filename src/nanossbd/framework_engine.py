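"""Stepwise decision engine for the prospective-LCA screening framework.

The framework has two parts: a preliminary assessment (concept design,
steps 1-5) and a prospective LCA (system-level design, steps 6-12 and 16).
Given a data-availability profile it deterministically walks the decision
nodes, records the question/answer/action at each step in a
:class:`DecisionTrace`, assigns a provenance :class:`DataTier` to every
quantity the chosen mode needs (the "data plan"), and — when process-level
data are absent or system boundaries unknown — falls back to a KPI-only
assessment built on green-chemistry key performance indicators.

The engine is pure: it never queries a database; "a database entry exists"
is an input answer.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ValidationError


@functools.total_ordering
class DataTier(enum.Enum):
    """Provenance tiers ordered from lowest to highest uncertainty.

    ``a < b`` means a is *less* uncertain than b; the ordering drives the
    uncertainty heat map legend and the tier-soundness checks.
    """

    measured_industrial = "measured_industrial"
    measured_lab = "measured_lab"
    database = "database"
    literature = "literature"
    read_across = "read_across"
    bulk_proxy = "bulk_proxy"
    default_precautionary = "default_precautionary"
    assumption = "assumption"

    @property
    def rank(self) -> int:
        return _TIER_ORDER.index(self)

    def __lt__(self, other: "DataTier") -> bool:
        if not isinstance(other, DataTier):
            return NotImplemented
        return self.rank < other.rank

    @classmethod
    def parse(cls, value: "DataTier | str") -> "DataTier":
        if isinstance(value, DataTier):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ValidationError(f"unknown data tier {value!r}") from None


_TIER_ORDER = list(DataTier)


@dataclass(frozen=True)
class TraceStep:
    step: str  # "1".."12", "13-15", "16"
    question: str
    answer: str
    action: str
    fallback: DataTier | None = None


@dataclass
class DecisionTrace:
    """Ordered record of the path taken through the framework steps."""

    steps: list[TraceStep] = field(default_factory=list)

    def add(self, step: str, question: str, answer: str, action: str,
            fallback: DataTier | None = None) -> None:
        self.steps.append(TraceStep(step, question, answer, action, fallback))

    def to_text(self) -> str:
        lines = []
        for st in self.steps:
            fb = f" [fallback tier: {st.fallback.value}]" if st.fallback else ""
            lines.append(f"Step {st.step}: {st.question} -> {st.answer}; "
                         f"{st.action}{fb}")
        return "\n".join(lines)

    def to_records(self) -> list[dict]:
        return [
            {"step": st.step, "question": st.question, "answer": st.answer,
             "action": st.action,
             "fallback_tier": st.fallback.value if st.fallback else ""}
            for st in self.steps
        ]

    def fallbacks(self) -> list[TraceStep]:
        return [st for st in self.steps if st.fallback is not None]


def _per_nanoform(value, nanoforms: tuple[str, ...], what: str) -> dict[str, bool]:
    """Normalize a bool-or-mapping availability answer to one bool per form."""
    if isinstance(value, bool):
        return {nf: value for nf in nanoforms}
    out = {}
    for nf in nanoforms:
        if nf not in value:
            raise ValidationError(f"{what}: no answer for nanoform {nf!r}")
        out[nf] = bool(value[nf])
    extra = set(value) - set(nanoforms)
    if extra:
        raise ValidationError(f"{what}: answers for undeclared nanoforms {extra}")
    return out


@dataclass(frozen=True)
class AvailabilityProfile:
    """Explicit yes/no answers for every decision node, plus tier annotations.

    ``nanotox_data_exist``, ``nano_database_entry_exists`` and
    ``fate_data_exist`` may be a single bool (applies to every declared
    nanoform) or a per-nanoform mapping. ``tier_annotations`` states the
    provenance tier of each quantity that *is* available, keyed by the plan
    quantity name (``lci_flows``, ``release``, ``xf``, ``cf:<nanoform>``,
    ``ff:<nanoform>``, ``kpis``).
    """

    reference_product_exists: bool
    process_level_data_available: bool
    system_boundaries_known: bool
    release_rate_known: bool
    nanoforms: tuple[str, ...] = ()
    nanotox_data_exist: bool | Mapping[str, bool] = False
    nano_database_entry_exists: bool | Mapping[str, bool] = False
    fate_data_exist: bool | Mapping[str, bool] = False
    read_across_possible: bool = False
    tier_annotations: Mapping[str, DataTier | str] = field(default_factory=dict)
    safety_notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "nanoforms", tuple(self.nanoforms))
        annotations = {k: DataTier.parse(v)
                       for k, v in dict(self.tier_annotations).items()}
        object.__setattr__(self, "tier_annotations", annotations)
        # Normalize per-nanoform answers early so contradictions surface here.
        for name in ("nanotox_data_exist", "nano_database_entry_exists",
                     "fate_data_exist"):
            value = getattr(self, name)
            if not isinstance(value, bool):
                object.__setattr__(self, name,
                                   _per_nanoform(dict(value), self.nanoforms, name))
        if not self.nanoforms:
            for name in ("nanotox_data_exist", "fate_data_exist"):
                value = getattr(self, name)
                if value is True or (isinstance(value, dict) and any(value.values())):
                    raise ValidationError(
                        f"profile contradiction: {name} is true but no "
                        "nanoform is declared")

    def answers_for(self, name: str) -> dict[str, bool]:
        return _per_nanoform(getattr(self, name), self.nanoforms, name)

    def annotation(self, quantity: str, default: DataTier) -> DataTier:
        return self.tier_annotations.get(quantity, default)


@dataclass(frozen=True)
class FrameworkResult:
    mode: str  # "kpi_only" | "prospective_lca"
    plan: dict[str, DataTier]
    trace: DecisionTrace


def run_framework(profile: AvailabilityProfile) -> FrameworkResult:
    """Walk the framework's decision nodes over an availability profile.

    Returns the assessment mode, the data plan (one provenance tier per
    required quantity) and the complete decision trace. Identical profiles
    yield identical results.
    """
    trace = DecisionTrace()
    plan: dict[str, DataTier] = {}

    trace.add("1", "What is the functionality of the nanomaterial?",
              "defined", "functional unit and designed product identified")
    if profile.reference_product_exists:
        trace.add("2", "Does a reference product exist?", "yes",
                  "compare against the reference system")
        trace.add("3", "Gather reference-system data",
                  "databases/literature", "LCA of the reference system")
    else:
        trace.add("2", "Does a reference product exist?", "no",
                  "proceed directly to process-level data collection")

    if not profile.process_level_data_available:
        trace.add("4", "Can process-level data be collected?", "no",
                  "estimate green-chemistry KPIs instead",
                  fallback=DataTier.assumption)
        trace.add("5", "Estimate KPIs",
                  "kpi-only mode",
                  "compute KPIs per nanomaterial mass and optimize")
        plan["kpis"] = profile.annotation("kpis", DataTier.measured_lab)
        return FrameworkResult("kpi_only", plan, trace)
    trace.add("4", "Can process-level data be collected?", "yes",
              "proceed to system-level design")

    if not profile.system_boundaries_known:
        trace.add("6", "Are the original system boundaries known?", "no",
                  "estimation of KPIs", fallback=DataTier.assumption)
        plan["kpis"] = profile.annotation("kpis", DataTier.measured_lab)
        return FrameworkResult("kpi_only", plan, trace)
    trace.add("6", "Are the original system boundaries known?", "yes",
              "life-cycle stages identified")

    if profile.release_rate_known:
        plan["release"] = profile.annotation("release", DataTier.literature)
        trace.add("7", "What is the expected release rate of the NM?",
                  "known", f"release fractions at tier "
                  f"{plan['release'].value}")
    else:
        plan["release"] = DataTier.bulk_proxy
        trace.add("7", "What is the expected release rate of the NM?",
                  "unknown", "build the LCI on bulk material flows",
                  fallback=DataTier.bulk_proxy)

    tox = profile.answers_for("nanotox_data_exist")
    dbs = profile.answers_for("nano_database_entry_exists")
    fate = profile.answers_for("fate_data_exist")

    for nf in profile.nanoforms:
        key = f"cf:{nf}"
        if tox[nf]:
            plan[key] = profile.annotation(key, DataTier.literature)
            trace.add("8", f"Do nano-toxicological data exist for {nf}?",
                      "yes", f"collect EF/HEF/XF at tier {plan[key].value}")
        elif dbs[nf]:
            plan[key] = DataTier.database
            trace.add("8", f"Do nano-toxicological data exist for {nf}?",
                      "no", "use nano-databases", fallback=DataTier.database)
            trace.add("9", f"Can a nano-database be used for {nf}?", "yes",
                      "collect EF and XF from the database")
        elif profile.read_across_possible:
            plan[key] = DataTier.read_across
            trace.add("8", f"Do nano-toxicological data exist for {nf}?",
                      "no", "use nano-databases", fallback=DataTier.database)
            trace.add("9", f"Can a nano-database be used for {nf}?", "no",
                      "use the read-across method",
                      fallback=DataTier.read_across)
        else:
            plan[key] = DataTier.bulk_proxy
            trace.add("8", f"Do nano-toxicological data exist for {nf}?",
                      "no", "use nano-databases", fallback=DataTier.database)
            trace.add("9", f"Can a nano-database be used for {nf}?", "no",
                      "no read-across either: build the LCI on bulk flows",
                      fallback=DataTier.bulk_proxy)

    if "xf" in profile.tier_annotations:
        plan["xf"] = profile.tier_annotations["xf"]
        trace.add("9", "Is an exposure factor available?", "yes",
                  f"XF at tier {plan['xf'].value}")
    else:
        plan["xf"] = DataTier.default_precautionary
        trace.add("9", "Is an exposure factor available?", "no",
                  "set XF = 1 (precautionary)",
                  fallback=DataTier.default_precautionary)

    for nf in profile.nanoforms:
        key = f"ff:{nf}"
        if fate[nf]:
            plan[key] = profile.annotation(key, DataTier.literature)
            trace.add("10a", f"Do fate data exist for {nf}?", "yes",
                      f"fate factor at tier {plan[key].value}")
        elif profile.read_across_possible:
            plan[key] = DataTier.read_across
            trace.add("10a", f"Do fate data exist for {nf}?", "no",
                      "use the read-across method",
                      fallback=DataTier.read_across)
            trace.add("10b", f"Is it possible to read across for {nf}?",
                      "yes", "use fate data from a surrogate nanoform of the "
                      "same substance")
        else:
            plan[key] = DataTier.default_precautionary
            trace.add("10a", f"Do fate data exist for {nf}?", "no",
                      "use the read-across method",
                      fallback=DataTier.read_across)
            trace.add("10b", f"Is it possible to read across for {nf}?",
                      "no", "set FF = 1 (precautionary)",
                      fallback=DataTier.default_precautionary)

    plan["lci_flows"] = profile.annotation("lci_flows", DataTier.measured_lab)
    trace.add("11", "Collect data for the LCI build-up",
              "material, nano-material and energy flows",
              f"foreground/background inventory at tier "
              f"{plan['lci_flows'].value}")
    trace.add("12", "Safety assessment",
              "free-text hazard notes recorded",
              profile.safety_notes or "no additional safety notes provided")
    trace.add("13-15", "Intermediate interpretation steps",
              "not modelled",
              "no semantics defined for these steps in this toolkit")
    trace.add("16", "Scaling up",
              "data need restated",
              "requires good knowledge of thermodynamics and efficiencies "
              "for larger-scale equipment; no scale-up computation performed")
    return FrameworkResult("prospective_lca", plan, trace)


# -- Green-chemistry KPIs ---------------------------------------------------


@dataclass(frozen=True)
class KPIRecord:
    """Green-chemistry key performance indicators per nanomaterial mass.

    All five are lower-is-better intensity measures in the units shown.
    """

    solvent_consumption: float  # mL/g
    electricity_consumption: float  # kWh/g
    heat_consumption: float  # kJ/g
    pollutant_emissions: float  # g/g
    waste_production: float  # g/g

    def __post_init__(self) -> None:
        for name in ("solvent_consumption", "electricity_consumption",
                     "heat_consumption", "pollutant_emissions",
                     "waste_production"):
            if getattr(self, name) < 0:
                raise ValidationError(f"KPI {name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "solvent_consumption": self.solvent_consumption,
            "electricity_consumption": self.electricity_consumption,
            "heat_consumption": self.heat_consumption,
            "pollutant_emissions": self.pollutant_emissions,
            "waste_production": self.waste_production,
        }


KPI_UNITS = {
    "solvent_consumption": "mL/g",
    "electricity_consumption": "kWh/g",
    "heat_consumption": "kJ/g",
    "pollutant_emissions": "g/g",
    "waste_production": "g/g",
}


def compute_kpis(solvent_ml: float, electricity_kwh: float, heat_kj: float,
                 pollutants_g: float, waste_g: float,
                 nm_mass_g: float) -> KPIRecord:
    """Batch amounts divided by the nanomaterial mass produced."""
    if nm_mass_g <= 0:
        raise ValidationError("nanomaterial mass must be > 0")
    amounts = (solvent_ml, electricity_kwh, heat_kj, pollutants_g, waste_g)
    if any(a < 0 for a in amounts):
        raise ValidationError("batch amounts must be >= 0")
    return KPIRecord(*(a / nm_mass_g for a in amounts))


def compare_kpis(a: KPIRecord, b: KPIRecord) -> dict[str, dict]:
    """Per-indicator improvement report of b relative to a (lower is better).

    No aggregate score is produced: the framework defines no weighting
    across KPIs.
    """
    report: dict[str, dict] = {}
    for name, av in a.as_dict().items():
        bv = b.as_dict()[name]
        if bv < av:
            verdict = "improved"
        elif bv > av:
            verdict = "worsened"
        else:
            verdict = "equal"
        rel = (bv - av) / av if av != 0 else (None if bv != av else 0.0)
        report[name] = {"verdict": verdict, "a": av, "b": bv,
                        "relative_change": rel, "unit": KPI_UNITS[name]}
    return report
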