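"""Product-system model and life-cycle inventory solver.

A product system is a set of unit processes, each producing exactly one
reference product, linked by product flows and emitting/consuming elementary
flows. The inventory for a functional unit is obtained from the standard
matrix formulation of computational LCA:

    A s = f        (technology matrix x scaling vector = final demand)
    g   = B s      (intervention matrix x scaling vector = inventory)

Sign convention: in ``A`` process outputs are positive and inputs negative;
in ``B`` emissions are positive and resource draws negative.

Nanomaterial release accounting (release fractions per life-cycle stage and
compartment) and the sewer-to-freshwater routing step live here too, since
they determine the nano rows of ``B``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, SingularSystemError, ValidationError

logger = logging.getLogger("nanossbd")

COMPARTMENTS = ("none", "air", "freshwater", "sewer", "soil")

#: Reciprocal-condition threshold below which the technology matrix is
#: treated as numerically singular rather than silently inverted.
RCOND_LIMIT = 1e-12

#: The only automatic unit conversions performed: factor converting the
#: first unit into the second.
UNIT_CONVERSIONS = {
    ("g", "kg"): 1e-3,
    ("kg", "g"): 1e3,
    ("MJ", "kWh"): 1.0 / 3.6,
    ("kWh", "MJ"): 3.6,
}


def convert_amount(amount: float, from_unit: str, to_unit: str) -> float:
    """Convert between the documented unit pairs (g<->kg, MJ<->kWh).

    Any other cross-unit combination is a validation error: units are
    otherwise carried as opaque labels.
    """
    if from_unit == to_unit:
        return amount
    try:
        factor = UNIT_CONVERSIONS[(from_unit, to_unit)]
    except KeyError:
        raise ValidationError(
            f"no conversion defined from {from_unit!r} to {to_unit!r}"
        ) from None
    logger.warning("unit coercion: %g %s -> %g %s", amount, from_unit,
                   amount * factor, to_unit)
    return amount * factor


@dataclass(frozen=True)
class Flow:
    """A product or elementary flow.

    Product flows link processes and carry no compartment; elementary flows
    cross the system boundary into an environmental compartment. ``phase``
    distinguishes bulk from nanoform flows, which feed separate toxicity
    columns downstream.
    """

    id: str
    name: str
    kind: str  # "product" | "elementary"
    phase: str = "bulk"  # "bulk" | "nano"
    compartment: str = "none"
    unit: str = "kg"

    def __post_init__(self) -> None:
        if self.kind not in ("product", "elementary"):
            raise ValidationError(f"flow {self.id}: bad kind {self.kind!r}")
        if self.phase not in ("bulk", "nano"):
            raise ValidationError(f"flow {self.id}: bad phase {self.phase!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"flow {self.id}: bad compartment {self.compartment!r}")
        if self.kind == "product" and self.compartment != "none":
            raise ValidationError(
                f"flow {self.id}: product flows carry no compartment")
        if self.kind == "elementary" and self.compartment == "none":
            raise ValidationError(
                f"flow {self.id}: elementary flows need a compartment")
        if not self.unit:
            raise ValidationError(f"flow {self.id}: empty unit")


@dataclass(frozen=True)
class Exchange:
    flow_id: str
    amount: float
    direction: str  # "input" | "output"
    unit: str | None = None  # defaults to the flow's unit

    def __post_init__(self) -> None:
        if self.direction not in ("input", "output"):
            raise ValidationError(f"bad exchange direction {self.direction!r}")
        if not math.isfinite(self.amount):
            raise ValidationError(f"non-finite exchange amount for {self.flow_id}")


@dataclass(frozen=True)
class Process:
    """A unit process with exactly one reference product output.

    ``data_tier`` records the provenance of the process' inventory data
    (a :class:`~nanossbd.framework_engine.DataTier` value or its string name)
    and feeds the uncertainty heat map.
    """

    id: str
    name: str
    reference_product: str
    exchanges: tuple[Exchange, ...]
    data_tier: str = "assumption"

    def __post_init__(self) -> None:
        object.__setattr__(self, "exchanges", tuple(self.exchanges))
        seen: set[tuple[str, str]] = set()
        for ex in self.exchanges:
            key = (ex.flow_id, ex.direction)
            if key in seen:
                raise ValidationError(
                    f"process {self.id}: duplicate exchange {key}")
            seen.add(key)
        ref = [ex for ex in self.exchanges
               if ex.flow_id == self.reference_product and ex.direction == "output"]
        if len(ref) != 1:
            raise ValidationError(
                f"process {self.id}: needs exactly one reference-product output "
                f"({self.reference_product})")
        if ref[0].amount <= 0:
            raise ValidationError(
                f"process {self.id}: reference-product amount must be > 0")


class ProductSystem:
    """Processes + flows assembled into labelled A and B matrices.

    ``technology_matrix`` (A) is product-flow x process with outputs positive
    and inputs negative; ``intervention_matrix`` (B) is elementary-flow x
    process with emissions positive and resource draws negative. The demand
    vector ``f`` expresses the functional unit.
    """

    def __init__(self, flows: Iterable[Flow], processes: Iterable[Process],
                 demand: Mapping[str, float]):
        self.flows: dict[str, Flow] = {}
        for fl in flows:
            if fl.id in self.flows:
                raise ValidationError(f"duplicate flow id {fl.id}")
            self.flows[fl.id] = fl
        self.processes: dict[str, Process] = {}
        for pr in processes:
            if pr.id in self.processes:
                raise ValidationError(f"duplicate process id {pr.id}")
            self.processes[pr.id] = pr

        product_ids = [f for f in self.flows if self.flows[f].kind == "product"]
        elementary_ids = [f for f in self.flows
                          if self.flows[f].kind == "elementary"]
        proc_ids = list(self.processes)

        producers: dict[str, str] = {}
        for pr in self.processes.values():
            if pr.reference_product not in self.flows:
                raise SchemaError(
                    f"process {pr.id}: unknown reference product "
                    f"{pr.reference_product}")
            if self.flows[pr.reference_product].kind != "product":
                raise ValidationError(
                    f"process {pr.id}: reference product must be a product flow")
            if pr.reference_product in producers:
                raise ValidationError(
                    f"product {pr.reference_product} produced by both "
                    f"{producers[pr.reference_product]} and {pr.id}")
            producers[pr.reference_product] = pr.id

        if len(product_ids) != len(proc_ids):
            raise ValidationError(
                f"technology matrix not square: {len(product_ids)} product "
                f"flows vs {len(proc_ids)} processes")

        A = pd.DataFrame(0.0, index=product_ids, columns=proc_ids)
        B = pd.DataFrame(0.0, index=elementary_ids, columns=proc_ids)
        for pr in self.processes.values():
            for ex in pr.exchanges:
                if ex.flow_id not in self.flows:
                    raise SchemaError(
                        f"process {pr.id}: unknown flow {ex.flow_id}")
                fl = self.flows[ex.flow_id]
                amount = ex.amount
                if ex.unit is not None and ex.unit != fl.unit:
                    amount = convert_amount(amount, ex.unit, fl.unit)
                sign = 1.0 if ex.direction == "output" else -1.0
                target = A if fl.kind == "product" else B
                target.loc[ex.flow_id, pr.id] += sign * amount

        f = pd.Series(0.0, index=product_ids)
        for flow_id, amount in demand.items():
            if flow_id not in product_ids:
                raise SchemaError(
                    f"demand names {flow_id!r}, which is not a product flow")
            f.loc[flow_id] = amount

        self.technology_matrix = A
        self.intervention_matrix = B
        self.demand = f

    # -- convenience -------------------------------------------------------

    @property
    def product_flow_ids(self) -> list[str]:
        return list(self.technology_matrix.index)

    @property
    def elementary_flow_ids(self) -> list[str]:
        return list(self.intervention_matrix.index)

    def process_inventory(self, scaling: pd.Series) -> pd.DataFrame:
        """Per-process elementary-flow contributions: B scaled column-wise.

        Row sums equal the total inventory ``g``; columns attribute every
        emission to the process that performs it (the basis of contribution
        analysis).
        """
        B = self.intervention_matrix
        return B.mul(scaling.reindex(B.columns), axis="columns")


def solve_inventory(system: ProductSystem) -> tuple[pd.Series, pd.Series]:
    """Solve ``A s = f`` and return (scaling ``s``, inventory ``g = B s``).

    Raises :class:`SingularSystemError` when A is singular or its reciprocal
    condition estimate falls below ``RCOND_LIMIT``, naming the unproducible
    product flow when an all-zero row identifies one.
    """
    A = system.technology_matrix
    f = system.demand
    mat = A.to_numpy()
    if mat.size == 0:
        return (pd.Series(dtype=float, index=A.columns),
                pd.Series(dtype=float, index=system.intervention_matrix.index))

    unproduced = np.where(~np.any(mat > 0.0, axis=1))[0]
    if unproduced.size:
        bad = A.index[unproduced[0]]
        raise SingularSystemError(
            f"product flow {bad!r} has no net producing process")

    # 1-norm reciprocal condition estimate; cheap at these sizes.
    norm = np.linalg.norm(mat, 1)
    try:
        inv = np.linalg.inv(mat)
    except np.linalg.LinAlgError:
        raise SingularSystemError(
            "technology matrix is singular; some product flow cannot be "
            "produced independently") from None
    rcond = 1.0 / (norm * np.linalg.norm(inv, 1))
    if rcond < RCOND_LIMIT:
        raise SingularSystemError(
            f"technology matrix is ill-conditioned (rcond ~ {rcond:.2e})")

    s = np.linalg.solve(mat, f.to_numpy())
    residual = np.linalg.norm(mat @ s - f.to_numpy())
    scale = max(np.linalg.norm(f.to_numpy()), 1.0)
    if residual > 1e-9 * scale:
        raise SingularSystemError(
            f"inventory solve residual {residual:.2e} exceeds tolerance")

    scaling = pd.Series(s, index=A.columns)
    g = pd.Series(system.intervention_matrix.to_numpy() @ s,
                  index=system.intervention_matrix.index)
    return scaling, g


@dataclass(frozen=True)
class ReleaseModel:
    """Fraction of handled nanomaterial mass released per compartment at one
    life-cycle stage (e.g. nm_manufacture, nano_coating, use, disposal)."""

    stage: str
    nanoform_id: str
    fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fractions", dict(self.fractions))
        total = 0.0
        for comp, frac in self.fractions.items():
            if comp not in COMPARTMENTS or comp == "none":
                raise ValidationError(
                    f"release stage {self.stage}: bad compartment {comp!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(
                    f"release stage {self.stage}: fraction {frac} outside [0,1]")
            total += frac
        if total > 1.0 + 1e-12:
            raise ValidationError(
                f"release stage {self.stage}: fractions sum to {total} > 1 "
                "(mass balance violated)")


def apply_release(handled_mass: float, model: ReleaseModel) -> dict[str, float]:
    """Emitted nano mass per compartment for a handled mass at one stage."""
    if handled_mass < 0:
        raise ValidationError("handled mass must be >= 0")
    return {comp: handled_mass * frac for comp, frac in model.fractions.items()}


def route_sewer(emissions: Mapping[str, float],
                transfer_coefficient: float = 1.0) -> dict[str, float]:
    """Route the sewer load to freshwater with a transfer coefficient.

    The default coefficient of 1.0 is precautionary: everything entering the
    sewer is assumed to reach freshwater. Zero-valued entries are dropped.
    """
    if not 0.0 <= transfer_coefficient <= 1.0:
        raise ValidationError("sewer transfer coefficient must be in [0,1]")
    out = {c: m for c, m in emissions.items() if c != "sewer" and m != 0.0}
    sewer = emissions.get("sewer", 0.0)
    transferred = sewer * transfer_coefficient
    if transferred:
        out["freshwater"] = out.get("freshwater", 0.0) + transferred
        logger.warning("sewer routing: %g kg sewer -> %g kg freshwater "
                       "(coefficient %g)", sewer, transferred,
                       transfer_coefficient)
    return out
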