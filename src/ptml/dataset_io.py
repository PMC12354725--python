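"""Reading, writing and validating the reaction dataset.

Two on-disk forms are supported:

* the **canonical flat table** (CSV or XLSX): one row = one reaction trial
  at one reuse cycle, with scalar fields, condition-label columns, per-role
  columns suffixed ``_id/_qty/_unit/_step``, per-reaction variable columns
  ``V<k>`` and per-molecule descriptor columns ``D<k>@<role>``;
* **SURF** (Simple User-Friendly Reaction Format): tab-separated, one
  reaction per line with role-tagged components.  The exact column set of
  this dialect is frozen in ``docs/formats.md``.

A :class:`Dialect` maps arbitrary file columns onto the canonical fields so
SI-style spreadsheets with different headers can be ingested unchanged.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from .data_model import (
    CONDITION_VARIABLES,
    REACTION_TYPES,
    ROLES,
    STEP_VALUES,
    DescriptorTable,
    ReactionRecord,
    RoleEntry,
    VariableTable,
)
from .errors import RowParseError, SchemaError, SurfParseError, ValidationError

_MANDATORY = ("reaction_id", "reaction_type", "reuse_cycle", "yield_pct")

_DESCRIPTOR_COL = re.compile(r"^(D\d+)@(\w+)$")
_VARIABLE_COL = re.compile(r"^V\d+$")


@dataclass
class Dialect:
    """Mapping from file columns to canonical fields.

    ``columns`` maps canonical scalar field names to file column names;
    ``condition_columns`` maps condition-variable names to columns;
    ``role_columns[role]`` maps ``molecule/quantity/unit/step`` to columns;
    ``variable_columns`` maps file columns to ``V_k`` ids and
    ``descriptor_columns`` maps file columns to ``(role, D_k)`` pairs.
    Unmapped ``V<k>`` / ``D<k>@<role>`` columns are auto-detected.
    """

    columns: dict[str, str] = dc_field(default_factory=dict)
    condition_columns: dict[str, str] = dc_field(default_factory=dict)
    role_columns: dict[str, dict[str, str]] = dc_field(default_factory=dict)
    variable_columns: dict[str, str] = dc_field(default_factory=dict)
    descriptor_columns: dict[str, tuple[str, str]] = dc_field(default_factory=dict)
    units: dict[str, str] = dc_field(default_factory=dict)
    provenance_columns: dict[str, str] = dc_field(default_factory=dict)

    @classmethod
    def default(cls) -> "Dialect":
        return cls(
            columns={
                "reaction_id": "reaction_id",
                "reaction_type": "reaction_type",
                "reuse_cycle": "reuse_cycle",
                "yield_pct": "yield_pct",
                "nucleophile_step": "nucleophile_step_code",
                "split_label": "split_label",
            },
            condition_columns={c: c for c in CONDITION_VARIABLES if c != "reaction_type"},
            role_columns={
                role: {
                    "molecule": f"{role}_id",
                    "quantity": f"{role}_qty",
                    "unit": f"{role}_unit",
                    "step": f"{role}_step",
                }
                for role in ROLES
            },
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Dialect":
        raw = json.loads(Path(path).read_text())
        base = cls.default()
        base.columns.update(raw.get("columns", {}))
        base.condition_columns.update(raw.get("condition_columns", {}))
        for role, m in raw.get("role_columns", {}).items():
            base.role_columns.setdefault(role, {}).update(m)
        base.variable_columns.update(raw.get("variable_columns", {}))
        base.descriptor_columns.update(
            {k: tuple(v) for k, v in raw.get("descriptor_columns", {}).items()}
        )
        base.units.update(raw.get("units", {}))
        base.provenance_columns.update(raw.get("provenance_columns", {}))
        return base


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
            frame = pd.read_excel(path)
        else:
            frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, no header") from exc
    if frame.shape[1] == 0:
        raise SchemaError(f"{path}: no columns found")
    return frame


def read_dataset(
    path: str | Path, dialect: Dialect | None = None
) -> tuple[list[ReactionRecord], DescriptorTable, VariableTable]:
    """Read the canonical flat table into records plus keyed tables.

    Row order of the file is preserved.  Missing cells are read as missing,
    never as zero.  Provenance flag columns named in the dialect are carried
    into ``record.metadata['provenance']``.
    """
    dialect = dialect or Dialect.default()
    frame = _read_table(path)

    for f in _MANDATORY:
        col = dialect.columns.get(f, f)
        if col not in frame.columns:
            raise SchemaError(f"missing mandatory column {col!r} (field {f})")

    # auto-detect V<k> and D<k>@<role> columns not explicitly mapped
    var_cols = dict(dialect.variable_columns)
    desc_cols = dict(dialect.descriptor_columns)
    for col in frame.columns:
        if col in var_cols or col in desc_cols:
            continue
        if _VARIABLE_COL.match(str(col)):
            var_cols[col] = str(col)
        else:
            m = _DESCRIPTOR_COL.match(str(col))
            if m:
                desc_cols[col] = (m.group(2), m.group(1))

    records: list[ReactionRecord] = []
    descriptors = DescriptorTable()
    variables = VariableTable()
    col = dialect.columns

    for i, row in enumerate(frame.to_dict(orient="records")):
        rid = row.get(col.get("reaction_id", "reaction_id"))
        if _is_missing(rid):
            raise RowParseError(i, "missing reaction_id")
        rid = str(rid)
        raw_yield = row.get(col.get("yield_pct", "yield_pct"))
        if _is_missing(raw_yield):
            yield_pct = None
        else:
            try:
                yield_pct = float(raw_yield)
            except (TypeError, ValueError):
                raise RowParseError(i, f"non-numeric yield {raw_yield!r}") from None
        try:
            cycle = int(row.get(col.get("reuse_cycle", "reuse_cycle")))
        except (TypeError, ValueError):
            raise RowParseError(i, "non-integer reuse_cycle") from None

        step_raw = row.get(col.get("nucleophile_step", "nucleophile_step_code"))
        step_code = None if _is_missing(step_raw) else int(step_raw)

        labels = {}
        for name, c in dialect.condition_columns.items():
            v = row.get(c)
            if not _is_missing(v):
                labels[name] = str(v).strip()

        roles: dict[str, RoleEntry] = {}
        for role, m in dialect.role_columns.items():
            mol = row.get(m.get("molecule", f"{role}_id"))
            if _is_missing(mol):
                continue
            qty_raw = row.get(m.get("quantity", f"{role}_qty"))
            qty = None if _is_missing(qty_raw) else float(qty_raw)
            unit_raw = row.get(m.get("unit", f"{role}_unit"))
            unit = "" if _is_missing(unit_raw) else str(unit_raw)
            st_raw = row.get(m.get("step", f"{role}_step"))
            st = "n/a" if _is_missing(st_raw) else str(st_raw)
            roles[role] = RoleEntry(str(mol), qty, unit, st)

        metadata: dict = {}
        prov = {}
        for f, c in dialect.provenance_columns.items():
            v = row.get(c)
            if not _is_missing(v):
                prov[f] = str(v)
        if prov:
            metadata["provenance"] = prov

        split_raw = row.get(col.get("split_label", "split_label"))
        split = "unassigned" if _is_missing(split_raw) else str(split_raw)

        records.append(
            ReactionRecord(
                reaction_id=rid,
                reaction_type=str(row.get(col.get("reaction_type", "reaction_type"))).strip(),
                reuse_cycle=cycle,
                yield_pct=yield_pct,
                nucleophile_step_code=step_code,
                condition_labels=labels,
                roles=roles,
                split_label=split,
                metadata=metadata,
            )
        )

        for c, vk in var_cols.items():
            v = row.get(c)
            if not _is_missing(v):
                variables.add(rid, vk, float(v), dialect.units.get(vk))
        for c, (role, dk) in desc_cols.items():
            v = row.get(c)
            if _is_missing(v) or role not in roles:
                continue
            mol = roles[role].molecule_id
            if descriptors.has(mol, dk):
                if abs(descriptors.get(mol, dk) - float(v)) > 1e-9:
                    raise RowParseError(
                        i, f"conflicting value of {dk} for molecule {mol!r}"
                    )
            else:
                descriptors.add(mol, dk, float(v), dialect.units.get(dk))

    return records, descriptors, variables


def write_dataset(
    records: list[ReactionRecord],
    descriptors: DescriptorTable,
    variables: VariableTable,
    path: str | Path,
) -> None:
    """Write the canonical flat table (dialect = :meth:`Dialect.default`)."""
    var_ids = sorted(variables.ids(), key=lambda v: (len(v), v))
    desc_by_role: dict[tuple[str, str], None] = {}
    for r in records:
        for role, entry in r.roles.items():
            for dk in sorted(descriptors.ids(), key=lambda v: (len(v), v)):
                if descriptors.has(entry.molecule_id, dk):
                    desc_by_role[(dk, role)] = None
    rows = []
    for r in records:
        row: dict = {
            "reaction_id": r.reaction_id,
            "reaction_type": r.reaction_type,
            "reuse_cycle": r.reuse_cycle,
            "yield_pct": r.yield_pct,
            "nucleophile_step_code": r.nucleophile_step_code,
            "split_label": r.split_label,
        }
        for name in CONDITION_VARIABLES:
            if name == "reaction_type":
                continue
            row[name] = r.condition_labels.get(name)
        for role in ROLES:
            entry = r.roles.get(role)
            row[f"{role}_id"] = entry.molecule_id if entry else None
            row[f"{role}_qty"] = entry.quantity if entry else None
            row[f"{role}_unit"] = entry.unit if entry else None
            row[f"{role}_step"] = entry.step if entry else None
        for vk in var_ids:
            row[vk] = variables.get(r.reaction_id, vk) if variables.has(r.reaction_id, vk) else None
        for dk, role in desc_by_role:
            entry = r.roles.get(role)
            if entry and descriptors.has(entry.molecule_id, dk):
                row[f"{dk}@{role}"] = descriptors.get(entry.molecule_id, dk)
            else:
                row[f"{dk}@{role}"] = None
        rows.append(row)
    frame = pd.DataFrame(rows)
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SURF
# ---------------------------------------------------------------------------

SURF_COLUMNS: tuple[str, ...] = (
    "rxn_id",
    "rxn_type",
    "reuse_cycle",
    "yield_pct",
    "nucleophile_step_code",
    *(c for c in CONDITION_VARIABLES if c != "reaction_type"),
    *(f"{role}_{f}" for role in ROLES for f in ("molecule", "qty", "unit", "step")),
    "split",
)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return format(value, ".10g")
    return str(value)


def write_surf(records: list[ReactionRecord], path: str | Path) -> None:
    """Write one tab-separated SURF line per reaction.

    All records must be valid; a record without a catalyst role is refused.
    """
    lines = ["\t".join(SURF_COLUMNS)]
    for idx, r in enumerate(records):
        probs = r.problems()
        if probs:
            raise ValidationError(f"record {r.reaction_id}: " + "; ".join(probs))
        if "catalyst" not in r.roles:
            raise ValidationError(f"record {r.reaction_id}: missing mandatory catalyst role")
        row = [
            r.reaction_id,
            r.reaction_type,
            str(r.reuse_cycle),
            _fmt(r.yield_pct),
            _fmt(r.nucleophile_step_code),
        ]
        row += [_fmt(r.condition_labels.get(c)) for c in CONDITION_VARIABLES if c != "reaction_type"]
        for role in ROLES:
            entry = r.roles.get(role)
            if entry is None:
                row += ["", "", "", ""]
            else:
                row += [entry.molecule_id, _fmt(entry.quantity), entry.unit, entry.step]
        row.append(r.split_label)
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_surf(path: str | Path) -> list[ReactionRecord]:
    """Read a SURF file written by :func:`write_surf`."""
    text = Path(path).read_text()
    lines = [ln for ln in text.split("\n") if ln != ""]
    if not lines:
        raise SchemaError(f"{path}: empty SURF file")
    header = tuple(lines[0].split("\t"))
    if header != SURF_COLUMNS:
        raise SchemaError(f"{path}: unexpected SURF header")
    records = []
    n_cond = len(CONDITION_VARIABLES) - 1
    for idx, line in enumerate(lines[1:]):
        parts = line.split("\t")
        if len(parts) != len(SURF_COLUMNS):
            raise SurfParseError(idx, f"expected {len(SURF_COLUMNS)} fields, got {len(parts)}")
        it = iter(parts)
        rid, rtype, cycle, yld, step = (next(it) for _ in range(5))
        try:
            cycle_i = int(cycle)
        except ValueError:
            raise SurfParseError(idx, f"bad reuse_cycle {cycle!r}") from None
        labels = {}
        for name in CONDITION_VARIABLES:
            if name == "reaction_type":
                continue
            v = next(it)
            if v:
                labels[name] = v
        roles: dict[str, RoleEntry] = {}
        for role in ROLES:
            mol, qty, unit, st = (next(it) for _ in range(4))
            if mol:
                roles[role] = RoleEntry(
                    mol, float(qty) if qty else None, unit, st or "n/a"
                )
        split = next(it) or "unassigned"
        records.append(
            ReactionRecord(
                reaction_id=rid,
                reaction_type=rtype,
                reuse_cycle=cycle_i,
                yield_pct=float(yld) if yld else None,
                nucleophile_step_code=int(step) if step else None,
                condition_labels=labels,
                roles=roles,
                split_label=split,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass
class Finding:
    rule: str
    reaction_id: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding]

    def __bool__(self) -> bool:  # truthy when clean
        return not self.findings

    def by_rule(self, rule: str) -> list[Finding]:
        return [f for f in self.findings if f.rule == rule]

    def to_json(self) -> str:
        return json.dumps(
            [
                {"rule": f.rule, "reaction_id": f.reaction_id, "message": f.message}
                for f in self.findings
            ],
            indent=2,
        )


def validate_dataset(
    records: list[ReactionRecord],
    descriptors: DescriptorTable | None = None,
    variables: VariableTable | None = None,
) -> ValidationReport:
    """Report-only consistency check; never mutates its inputs.

    Rules: record-level invariants (``invariant``), yields outside [0, 100]
    (``yield_range``), condition labels outside the canonical vocabulary
    (``unknown_condition``), role molecules absent from the descriptor table
    (``dangling_molecule``), roles with a missing quantity
    (``missing_quantity``).
    """
    findings: list[Finding] = []
    known_molecules = descriptors.keys() if descriptors is not None else None
    for r in records:
        y = r.yield_pct
        if y is not None and not (0.0 <= y <= 100.0):
            findings.append(Finding("yield_range", r.reaction_id, f"yield {y} outside [0, 100]"))
        for p in r.problems():
            if "yield_pct" in p:
                continue  # already reported under yield_range
            findings.append(Finding("invariant", r.reaction_id, p))
        for name in r.condition_labels:
            if name not in CONDITION_VARIABLES:
                findings.append(
                    Finding("unknown_condition", r.reaction_id, f"unknown condition variable {name!r}")
                )
        for role, entry in r.roles.items():
            if entry.quantity is None:
                findings.append(
                    Finding("missing_quantity", r.reaction_id, f"{role} quantity missing")
                )
            if known_molecules is not None and entry.molecule_id not in known_molecules:
                findings.append(
                    Finding(
                        "dangling_molecule",
                        r.reaction_id,
                        f"{role} molecule {entry.molecule_id!r} absent from descriptor table",
                    )
                )
    return ValidationReport(findings)
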