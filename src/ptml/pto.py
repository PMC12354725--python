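"""Perturbation-theory operators over condition partitions.

The central idea: a reaction trial is described not by raw descriptor and
condition values but by their deviation from the moving average of the
population of trials run under "similar" conditions,

    dD_k(m_i, c_j) = D_k(m_i) - <D_k(m_i)>_{c_j}
    dV_k(r_i, c_j) = V_k(r_i) - <V_k(r_i)>_{c_j}

where the similarity classes are defined by a :class:`PartitionScheme`: a
grouping of the qualitative condition variables into one or more named
blocks (c_I, c_II, ...).  Four schemes are built in, differing in how
coarsely the conditions are blocked:

* ``PTML1`` — three blocks: catalyst identity (nature, support type/form,
  metal), catalyst preparation (process, support treatment, assembly
  generation), and reaction characteristics (reuse frequency, reaction
  type, detection method);
* ``PTML2`` — PTML1 with the reuse-frequency grouping variable replaced by
  the nucleophile addition step (the output already conditions on reuse);
* ``PTML3`` — two blocks: everything catalyst-related vs. everything
  reaction-related;
* ``PTML4`` — a single all-inclusive block.

The baseline that the perturbation terms correct is the *reference
function*: the mean observed yield of the record's conditioning cohort
(by default, its reuse-cycle cohort).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import DescriptorTable, ReactionRecord, VariableTable
from .errors import ConfigError, KeyingError, RecipeError, ReferenceError_

__all__ = [
    "PartitionScheme",
    "SCHEMES",
    "MovingAverageTable",
    "Term",
    "FeatureRecipe",
    "group_key",
    "moving_averages",
    "compute_pto",
    "reference_yield",
    "assemble_features",
    "published_recipe",
]


@dataclass(frozen=True)
class PartitionScheme:
    """Named grouping of condition variables into ordered blocks."""

    scheme_id: str
    blocks: tuple[tuple[str, tuple[str, ...]], ...]

    def block(self, name: str) -> tuple[str, ...]:
        for bname, variables in self.blocks:
            if bname == name:
                return variables
        raise ConfigError(f"scheme {self.scheme_id}: no block {name!r}")

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.blocks)

    def to_json(self) -> str:
        return json.dumps(
            {"scheme_id": self.scheme_id, "blocks": {n: list(v) for n, v in self.blocks}}
        )

    @classmethod
    def from_json(cls, text: str) -> "PartitionScheme":
        raw = json.loads(text)
        return cls(
            raw["scheme_id"],
            tuple((n, tuple(v)) for n, v in raw["blocks"].items()),
        )


_CATALYST_VARS = (
    "catalyst_nature",
    "support_type",
    "support_form",
    "metal",
)
_PREPARATION_VARS = (
    "preparation_process",
    "support_treatment",
    "assembly_generation",
)
_REACTION_VARS = ("reaction_type", "detection_method")

SCHEMES: dict[str, PartitionScheme] = {
    "PTML1": PartitionScheme(
        "PTML1",
        (
            ("c_I", _CATALYST_VARS),
            ("c_II", _PREPARATION_VARS),
            ("c_III", ("reuse_cycle",) + _REACTION_VARS),
        ),
    ),
    "PTML2": PartitionScheme(
        "PTML2",
        (
            ("c_I", _CATALYST_VARS),
            ("c_II", _PREPARATION_VARS),
            ("c_III", ("nucleophile_step",) + _REACTION_VARS),
        ),
    ),
    "PTML3": PartitionScheme(
        "PTML3",
        (
            ("c_I", _CATALYST_VARS + _PREPARATION_VARS),
            ("c_II", ("nucleophile_step",) + _REACTION_VARS),
        ),
    ),
    "PTML4": PartitionScheme(
        "PTML4",
        (("c_I", _CATALYST_VARS + _PREPARATION_VARS + _REACTION_VARS),),
    ),
}


def group_key(record: ReactionRecord, block: Sequence[str]) -> tuple[str, ...]:
    """Deterministic label tuple of a record under a block's variables.

    Labels are compared as trimmed, case-preserved strings.
    """
    out = []
    for name in block:
        try:
            out.append(record.condition_value(name))
        except KeyError:
            raise KeyingError(
                f"record {record.reaction_id}: missing condition variable {name!r}"
            ) from None
    return tuple(out)


@dataclass
class MovingAverageTable:
    """Per-group arithmetic means and member counts."""

    means: dict[tuple, float] = dc_field(default_factory=dict)
    counts: dict[tuple, int] = dc_field(default_factory=dict)

    def mean(self, label: tuple) -> float:
        return self.means[label]


def moving_averages(
    values: Mapping[str, float], labels: Mapping[str, tuple]
) -> MovingAverageTable:
    """Group means of ``values`` under the grouping given by ``labels``."""
    sums: dict[tuple, float] = {}
    counts: dict[tuple, int] = {}
    for rid, v in values.items():
        if rid not in labels:
            raise KeyingError(f"no group label for id {rid!r}")
        lab = labels[rid]
        sums[lab] = sums.get(lab, 0.0) + float(v)
        counts[lab] = counts.get(lab, 0) + 1
    return MovingAverageTable(
        means={lab: sums[lab] / counts[lab] for lab in sums}, counts=counts
    )


def compute_pto(value: float, group_mean: float) -> float:
    """A perturbation-theory operator: raw value minus its group mean."""
    return float(value) - float(group_mean)


def reference_yield(
    records: Iterable[ReactionRecord],
    conditioner: str = "reuse_cycle",
    population: Iterable[ReactionRecord] | None = None,
) -> dict[str, float]:
    """Reference function: mean observed yield of each record's cohort.

    The conditioner defaults to the reuse cycle, so the reference of a trial
    is the average yield of all trials at the same number of catalyst
    reuses.  ``population`` (default: the records themselves) is the set
    whose yields define the cohort means.
    """
    records = list(records)
    population = records if population is None else list(population)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for r in population:
        if r.yield_pct is None:
            continue
        key = r.condition_value(conditioner)
        sums[key] = sums.get(key, 0.0) + r.yield_pct
        counts[key] = counts.get(key, 0) + 1
    out: dict[str, float] = {}
    global_mean = sum(sums.values()) / sum(counts.values()) if counts else None
    for r in records:
        key = r.condition_value(conditioner)
        if key in sums:
            out[r.reaction_id] = sums[key] / counts[key]
        elif global_mean is not None:
            warnings.warn(
                f"record {r.reaction_id}: conditioner cohort {key!r} has no "
                "yields in the fit population; using the global mean",
                stacklevel=2,
            )
            out[r.reaction_id] = global_mean
        else:
            raise ReferenceError_(
                f"record {r.reaction_id}: cohort {key!r} has no observed yields"
            )
    return out


# ---------------------------------------------------------------------------
# Feature recipes
# ---------------------------------------------------------------------------

# Expression AST (nested tuples):
#   ("V", k)          -> V_k of the reaction
#   ("D", k, role)    -> D_k of the molecule playing `role`
#   ("prod", e1, e2, ...) / ("sum", e1, e2, ...)
Expr = tuple


@dataclass(frozen=True)
class Term:
    """One perturbation feature: an algebraic combination of raw D/V values
    centered by its group moving average within ``block``."""

    term_id: str
    expr: Expr
    block: str
    unit: str = ""


@dataclass(frozen=True)
class FeatureRecipe:
    recipe_id: str
    terms: tuple[Term, ...]
    #: combine raw values first, then center the combined quantity (the
    #: reading d(D·V) = D·V − <D·V>); False centers each leaf first.
    center_combined: bool = True

    def term_ids(self) -> tuple[str, ...]:
        return tuple(t.term_id for t in self.terms)

    def to_json(self) -> str:
        return json.dumps(
            {
                "recipe_id": self.recipe_id,
                "center_combined": self.center_combined,
                "terms": [
                    {"term_id": t.term_id, "expr": t.expr, "block": t.block, "unit": t.unit}
                    for t in self.terms
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureRecipe":
        raw = json.loads(text)

        def tup(e):
            return tuple(tup(x) if isinstance(x, list) else x for x in e)

        return cls(
            raw["recipe_id"],
            tuple(
                Term(t["term_id"], tup(t["expr"]), t["block"], t.get("unit", ""))
                for t in raw["terms"]
            ),
            raw.get("center_combined", True),
        )


def _eval_expr(
    expr: Expr,
    record: ReactionRecord,
    descriptors: DescriptorTable,
    variables: VariableTable,
    term_id: str,
) -> float:
    op = expr[0]
    if op == "V":
        k = expr[1]
        if not variables.has(record.reaction_id, k):
            raise RecipeError(
                f"term {term_id!r}: variable {k} missing for reaction {record.reaction_id}"
            )
        return variables.get(record.reaction_id, k)
    if op == "D":
        k, role = expr[1], expr[2]
        entry = record.roles.get(role)
        if entry is None:
            raise RecipeError(
                f"term {term_id!r}: record {record.reaction_id} has no {role} role"
            )
        if not descriptors.has(entry.molecule_id, k):
            raise RecipeError(
                f"term {term_id!r}: descriptor {k} missing for molecule {entry.molecule_id!r}"
            )
        return descriptors.get(entry.molecule_id, k)
    if op == "prod":
        out = 1.0
        for sub in expr[1:]:
            out *= _eval_expr(sub, record, descriptors, variables, term_id)
        return out
    if op == "sum":
        return sum(_eval_expr(sub, record, descriptors, variables, term_id) for sub in expr[1:])
    raise RecipeError(f"term {term_id!r}: unknown expression op {op!r}")


def _centered_column(
    raw: dict[str, float],
    labels: dict[str, tuple],
    fit_ids: Sequence[str],
    term_id: str,
) -> dict[str, float]:
    fit_values = {rid: raw[rid] for rid in fit_ids}
    fit_labels = {rid: labels[rid] for rid in fit_ids}
    table = moving_averages(fit_values, fit_labels)
    global_mean = float(np.mean(list(fit_values.values())))
    out = {}
    for rid, v in raw.items():
        lab = labels[rid]
        if lab in table.means:
            out[rid] = compute_pto(v, table.means[lab])
        else:
            warnings.warn(
                f"term {term_id!r}: group {lab!r} unseen in the fit population; "
                "centering on the global mean",
                stacklevel=3,
            )
            out[rid] = compute_pto(v, global_mean)
    return out


def assemble_features(
    records: Sequence[ReactionRecord],
    descriptors: DescriptorTable,
    variables: VariableTable,
    scheme: PartitionScheme | str,
    recipe: FeatureRecipe,
    fit_population: Sequence[str] | None = None,
    reference: Mapping[str, float] | None = None,
    conditioner: str = "reuse_cycle",
) -> pd.DataFrame:
    """Build the feature table: one row per record, a ``reference`` column
    plus one centered column per recipe term.

    Moving averages (and the reference cohort means) are computed over
    ``fit_population`` — a list of reaction ids, defaulting to the full
    record set.  Restricting it to the training split avoids information
    leakage at the cost of diverging from whole-dataset centering.
    ``reference`` may supply precomputed reference values (e.g. a synthetic
    ground truth) instead of cohort means of the observed yields.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    records = list(records)
    ids = [r.reaction_id for r in records]
    by_id = {r.reaction_id: r for r in records}
    if fit_population is None:
        fit_ids = list(ids)
    else:
        fit_ids = [rid for rid in fit_population]
        unknown = [rid for rid in fit_ids if rid not in by_id]
        if unknown:
            raise ConfigError(f"fit_population ids not in records: {unknown[:5]}")

    if reference is None:
        ref = reference_yield(
            records, conditioner=conditioner, population=[by_id[i] for i in fit_ids]
        )
    else:
        ref = {rid: float(reference[rid]) for rid in ids}

    columns: dict[str, dict[str, float]] = {"reference": ref}
    for term in recipe.terms:
        block_vars = scheme.block(term.block)
        labels = {r.reaction_id: group_key(r, block_vars) for r in records}
        if recipe.center_combined:
            raw = {
                r.reaction_id: _eval_expr(term.expr, r, descriptors, variables, term.term_id)
                for r in records
            }
            columns[term.term_id] = _centered_column(raw, labels, fit_ids, term.term_id)
        else:
            columns[term.term_id] = _center_leaves_column(
                term, records, descriptors, variables, labels, fit_ids
            )

    frame = pd.DataFrame({name: [col[rid] for rid in ids] for name, col in columns.items()})
    frame.index = pd.Index(ids, name="reaction_id")
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise RecipeError(f"missing cells after assembly in columns {bad}")
    frame.attrs["scheme_id"] = scheme.scheme_id
    frame.attrs["recipe_id"] = recipe.recipe_id
    frame.attrs["conditioner"] = conditioner
    frame.attrs["fit_population"] = "all" if fit_population is None else "subset"
    frame.attrs["term_blocks"] = {t.term_id: t.block for t in recipe.terms}
    frame.attrs["term_units"] = {t.term_id: t.unit for t in recipe.terms}
    return frame


def _center_leaves_column(
    term: Term,
    records: Sequence[ReactionRecord],
    descriptors: DescriptorTable,
    variables: VariableTable,
    labels: dict[str, tuple],
    fit_ids: Sequence[str],
) -> dict[str, float]:
    """Alternative reading: center each leaf D/V value, then combine."""

    def walk(expr: Expr) -> dict[str, float]:
        op = expr[0]
        if op in ("V", "D"):
            raw = {
                r.reaction_id: _eval_expr(expr, r, descriptors, variables, term.term_id)
                for r in records
            }
            return _centered_column(raw, labels, fit_ids, term.term_id)
        if op == "prod":
            cols = [walk(sub) for sub in expr[1:]]
            return {
                rid: float(np.prod([c[rid] for c in cols])) for rid in cols[0]
            }
        if op == "sum":
            cols = [walk(sub) for sub in expr[1:]]
            return {rid: sum(c[rid] for c in cols) for rid in cols[0]}
        raise RecipeError(f"term {term.term_id!r}: unknown op {op!r}")

    return walk(term.expr)


def feature_table_csv(frame: pd.DataFrame, path) -> None:
    """Export a feature table as CSV with a provenance header block."""
    lines = [
        f"# scheme_id: {frame.attrs.get('scheme_id')}",
        f"# recipe_id: {frame.attrs.get('recipe_id')}",
        f"# conditioner: {frame.attrs.get('conditioner')}",
        f"# fit_population: {frame.attrs.get('fit_population')}",
    ]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n" + frame.to_csv())


# ---------------------------------------------------------------------------
# Published feature recipes
# ---------------------------------------------------------------------------

def _published_terms() -> tuple[Term, ...]:
    """The nine-input recipe of the published PTML 3 linear equations:
    eight perturbation terms (in printed order) plus the reference column
    added by the model.

    The descriptor roles (D2 → catalyst, D6 → nucleophile, D15 → base) and
    per-term blocks are the package's frozen reading of the supporting
    tables; the printed equations name only the ids and units.
    """
    return (
        Term("d(D2*V2)", ("prod", ("D", "D2", "catalyst"), ("V", "V2")), "c_I", "pm·µg"),
        Term("dV31", ("V", "V31"), "c_II", "h"),
        Term("dV33", ("V", "V33"), "c_II", ""),
        Term("d(V11*V13)", ("prod", ("V", "V11"), ("V", "V13")), "c_II", "mmol"),
        Term(
            "d(V29*(V22+V26))",
            ("prod", ("V", "V29"), ("sum", ("V", "V22"), ("V", "V26"))),
            "c_II",
            "D·mL",
        ),
        Term("d(D6*V8)", ("prod", ("D", "D6", "nucleophile"), ("V", "V8")), "c_II", "D·mmol"),
        Term(
            "d(D15*(V10+V35))",
            ("prod", ("D", "D15", "base"), ("sum", ("V", "V10"), ("V", "V35"))),
            "c_II",
            "",
        ),
        Term("dV30", ("V", "V30"), "c_II", "°C"),
    )


def published_recipe(model_id: str) -> FeatureRecipe:
    """Feature recipe of a published linear model (``eq5`` full-dataset
    PTML 3, ``eq6`` PTML 3 without the double-carbonylation subset).

    Both printed equations share the same eight perturbation terms; the
    full-dataset equation's sixth term is typeset with ``E6`` where the
    reduced equation uses ``D6`` — read here as the same descriptor.
    """
    if model_id not in ("eq5", "eq6"):
        raise ConfigError(f"unknown published recipe {model_id!r}")
    return FeatureRecipe(model_id, _published_terms())
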