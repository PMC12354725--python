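"""Canonical data model for the reaction dataset.

One :class:`ReactionRecord` is one reaction trial: a cross-coupling reaction
run with a self-assembled nanoparticle catalyst at a given reuse cycle ``n``
(0 = first use), with its observed yield ``Yld(%)_n``, the qualitative
condition labels used for condition partitioning, and the reagent roles
(catalyst, electrophile, nucleophile, solvent, base) with their quantities.

Quantitative per-molecule descriptors ``D_k`` and per-reaction condition
variables ``V_k`` live in separate keyed tables
(:class:`DescriptorTable`, :class:`VariableTable`) so that the perturbation
engine can address them uniformly by id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import SchemaError, ValidationError

#: The seven reaction families covered by the dataset.
REACTION_TYPES = (
    "suzuki_miyaura",
    "kumada",
    "negishi",
    "buchwald_hartwig",
    "csp2_h",
    "csp3_h",
    "double_carbonylation",
)

#: Reagent roles tracked per reaction. ``catalyst`` is mandatory.
ROLES = ("catalyst", "electrophile", "nucleophile", "solvent", "base")

#: The nine qualitative condition variables used to build condition
#: partitions.  ``reaction_type`` is stored as a record field; the grouping
#: machinery additionally understands the derived variables ``reuse_cycle``
#: and ``nucleophile_step``.
CONDITION_VARIABLES = (
    "catalyst_nature",
    "support_type",
    "support_form",
    "metal",
    "preparation_process",
    "support_treatment",
    "assembly_generation",
    "reaction_type",
    "detection_method",
)

#: Grouping variables derived from record fields rather than labels.
DERIVED_CONDITION_VARIABLES = ("reaction_type", "reuse_cycle", "nucleophile_step")

STEP_VALUES = ("1", "2", "both", "n/a")

SPLIT_LABELS = ("t", "v", "unassigned")


@dataclass
class RoleEntry:
    """One reagent in one reaction: molecule, amount, unit, addition step."""

    molecule_id: str
    quantity: float | None = None
    unit: str = ""
    step: str = "n/a"


@dataclass
class ReactionRecord:
    reaction_id: str
    reaction_type: str
    reuse_cycle: int
    yield_pct: float | None = None
    nucleophile_step_code: int | None = None
    condition_labels: dict[str, str] = field(default_factory=dict)
    roles: dict[str, RoleEntry] = field(default_factory=dict)
    split_label: str = "unassigned"
    metadata: dict = field(default_factory=dict)

    def condition_value(self, name: str) -> str:
        """Value of a condition/grouping variable, as a normalized string.

        Raises ``KeyError`` if the variable is absent on this record.
        """
        if name == "reaction_type":
            return str(self.reaction_type).strip()
        if name == "reuse_cycle":
            return str(self.reuse_cycle)
        if name == "nucleophile_step":
            if self.nucleophile_step_code is None:
                raise KeyError(name)
            return str(self.nucleophile_step_code)
        value = self.condition_labels.get(name)
        if value is None:
            raise KeyError(name)
        return str(value).strip()

    def problems(self) -> list[str]:
        """Invariant violations on this record (empty list = valid)."""
        out: list[str] = []
        if self.reaction_type not in REACTION_TYPES:
            out.append(f"unknown reaction_type {self.reaction_type!r}")
        if self.reuse_cycle < 0:
            out.append(f"reuse_cycle {self.reuse_cycle} < 0")
        y = self.yield_pct
        if y is not None and not (0.0 <= y <= 100.0):
            out.append(f"yield_pct {y} outside [0, 100]")
        code = self.nucleophile_step_code
        if code is not None and code not in (0, 1, 2, 3):
            out.append(f"nucleophile_step_code {code} not in {{0,1,2,3}}")
        ctype = self.condition_labels.get("reaction_type")
        if ctype is not None and str(ctype).strip() != self.reaction_type:
            out.append(
                f"condition label reaction_type {ctype!r} inconsistent with "
                f"record reaction_type {self.reaction_type!r}"
            )
        for role, entry in self.roles.items():
            if role not in ROLES:
                out.append(f"unknown role {role!r}")
                continue
            if entry.quantity is not None:
                if entry.quantity < 0:
                    out.append(f"{role} quantity {entry.quantity} < 0")
                if not entry.unit:
                    out.append(f"{role} has a quantity but no unit")
            if entry.step not in STEP_VALUES:
                out.append(f"{role} step {entry.step!r} not in {STEP_VALUES}")
        if self.split_label not in SPLIT_LABELS:
            out.append(f"split_label {self.split_label!r} invalid")
        return out

    def copy(self) -> "ReactionRecord":
        return replace(
            self,
            condition_labels=dict(self.condition_labels),
            roles={r: replace(e) for r, e in self.roles.items()},
            metadata=dict(self.metadata),
        )


class _KeyedTable:
    """Two-level keyed table of real values with per-id unit metadata."""

    #: human name of the first key component, for error messages
    _key_name = "key"

    def __init__(self) -> None:
        self.entries: dict[tuple[str, str], float] = {}
        self.units: dict[str, str] = {}

    def add(self, key: str, var_id: str, value: float, unit: str | None = None) -> None:
        k = (key, var_id)
        if k in self.entries:
            raise SchemaError(f"duplicate ({self._key_name}={key!r}, id={var_id!r})")
        if value is not None and not math.isfinite(float(value)):
            raise ValidationError(f"non-finite value for ({key!r}, {var_id!r})")
        self.entries[k] = float(value)
        if unit is not None:
            self.units[var_id] = unit

    def get(self, key: str, var_id: str) -> float:
        return self.entries[(key, var_id)]

    def has(self, key: str, var_id: str) -> bool:
        return (key, var_id) in self.entries

    def remove(self, key: str, var_id: str) -> None:
        del self.entries[(key, var_id)]

    def ids(self) -> set[str]:
        return {var_id for _, var_id in self.entries}

    def keys(self) -> set[str]:
        return {key for key, _ in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def copy(self):
        out = type(self)()
        out.entries = dict(self.entries)
        out.units = dict(self.units)
        return out


class DescriptorTable(_KeyedTable):
    """``D_k(m_i)``: molecular descriptor *k* of molecule *m_i*.

    Descriptors are consumed as externally computed input (constitutional,
    functional-group and property descriptors); this package never computes
    them from structure.
    """

    _key_name = "molecule_id"


class VariableTable(_KeyedTable):
    """``V_k(r_i)``: quantitative condition variable *k* of reaction *r_i*
    (reagent amounts, time, temperature, step codes, ...)."""

    _key_name = "reaction_id"


def records_dataframe(records: Iterable[ReactionRecord]):
    """Flat pandas view of the scalar record fields (for reporting)."""
    import pandas as pd

    rows = []
    for r in records:
        row: dict = {
            "reaction_id": r.reaction_id,
            "reaction_type": r.reaction_type,
            "reuse_cycle": r.reuse_cycle,
            "yield_pct": r.yield_pct,
            "nucleophile_step": r.nucleophile_step_code,
            "split_label": r.split_label,
        }
        row.update({k: v for k, v in r.condition_labels.items()})
        for role, entry in r.roles.items():
            row[f"{role}_id"] = entry.molecule_id
            row[f"{role}_qty"] = entry.quantity
        rows.append(row)
    return pd.DataFrame(rows)
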