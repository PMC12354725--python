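"""Dataset preprocessing: imputation, quantity weighting, step encoding.

Catalyst-amount fields are the ones that are commonly unreported in the
source literature.  Missing amounts are filled with the mean of the known
amounts of catalysts sharing the same metal, support, synthesis procedure
and reuse time; when that exact group has no known value the key is relaxed
along a fallback ladder (drop reuse cycle, then synthesis procedure, then
support, finally the global mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .data_model import ReactionRecord, VariableTable
from .errors import DomainError, ImputationError, ValidationError

#: Condition variables making up the exact imputation key, most specific last.
IMPUTATION_KEY = ("metal", "support_type", "preparation_process", "reuse_cycle")

#: Ladder of key levels, from the exact key to the global mean.  Each level
#: lists the key components retained.
DEFAULT_LADDER: tuple[tuple[str, ...], ...] = (
    ("metal", "support_type", "preparation_process", "reuse_cycle"),
    ("metal", "support_type", "preparation_process"),
    ("metal", "support_type"),
    ("metal",),
    (),
)


@dataclass
class ImputationEntry:
    reaction_id: str
    field: str
    value: float
    ladder_level: int  # 0 = exact key


def _field_access(target_field: str) -> tuple[Callable, Callable]:
    """Getter/setter for a numeric record field.

    ``target_field`` is either ``"<role>_quantity"`` (a role's amount) or a
    plain record attribute name.
    """
    if target_field.endswith("_quantity"):
        role = target_field[: -len("_quantity")]

        def get(r: ReactionRecord):
            entry = r.roles.get(role)
            return None if entry is None else entry.quantity

        def set_(r: ReactionRecord, v: float):
            r.roles[role].quantity = v

        return get, set_

    def get(r: ReactionRecord):
        return getattr(r, target_field)

    def set_(r: ReactionRecord, v: float):
        setattr(r, target_field, v)

    return get, set_


def _key_for(record: ReactionRecord, components: Sequence[str]) -> tuple:
    return tuple(record.condition_value(c) for c in components)


def impute_group_mean(
    records: Iterable[ReactionRecord],
    target_field: str = "catalyst_quantity",
    fallback_ladder: Sequence[Sequence[str]] = DEFAULT_LADDER,
) -> tuple[list[ReactionRecord], list[ImputationEntry]]:
    """Fill missing values of ``target_field`` with group means.

    Returns new record copies plus a log of (record, field, value, ladder
    level).  Filled records are flagged in ``metadata['imputed']`` so that
    downstream stages can exclude or down-weight them.  Raises
    :class:`ImputationError` when no ladder level (including the global
    mean) has any observed value.
    """
    records = [r.copy() for r in records]
    get, set_ = _field_access(target_field)

    known = [(r, get(r)) for r in records]
    observed = [(r, v) for r, v in known if v is not None]
    missing = [r for r, v in known if v is None]
    if not missing:
        return records, []
    if not observed:
        raise ImputationError(
            [r.reaction_id for r in missing],
            f"no observed values of {target_field!r} at any ladder level",
        )

    # group sums per ladder level
    levels = [tuple(level) for level in fallback_ladder]
    sums: list[dict[tuple, tuple[float, int]]] = []
    for level in levels:
        acc: dict[tuple, tuple[float, int]] = {}
        for r, v in observed:
            k = _key_for(r, level)
            s, n = acc.get(k, (0.0, 0))
            acc[k] = (s + v, n + 1)
        sums.append(acc)

    log: list[ImputationEntry] = []
    for r in missing:
        for li, level in enumerate(levels):
            k = _key_for(r, level)
            if k in sums[li]:
                s, n = sums[li][k]
                value = s / n
                set_(r, value)
                r.metadata.setdefault("imputed", {})[target_field] = li
                log.append(ImputationEntry(r.reaction_id, target_field, value, li))
                break
        else:  # pragma: no cover - guarded by the global-mean level
            raise ImputationError([r.reaction_id], "unresolvable imputation")
    return records, log


def imputation_log_frame(log: list[ImputationEntry]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "reaction_id": e.reaction_id,
                "field": e.field,
                "value": e.value,
                "ladder_level": e.ladder_level,
            }
            for e in log
        ]
    )


def quantity_weight(
    value: float,
    quantity: float | None = None,
    steps: dict[int, float] | None = None,
) -> float:
    """Weight a descriptor/variable value by its reagent quantity.

    For reagents added in both reaction steps the total quantity
    (``q_step1 + q_step2``) is used.  Quantities must be non-negative.
    """
    if steps is not None:
        total = 0.0
        for step, q in steps.items():
            if q < 0:
                raise DomainError(f"negative quantity {q} in step {step}")
            total += q
        return value * total
    if quantity is None:
        raise DomainError("either quantity or steps must be given")
    if quantity < 0:
        raise DomainError(f"negative quantity {quantity}")
    return value * quantity


def encode_nucleophile_step(record: ReactionRecord) -> int:
    """Nucleophile addition-step code: 0 intramolecular, 1 step 1, 2 step 2,
    3 both steps.

    Intramolecular reactions are marked with ``metadata['intramolecular']``.
    A record that is both intramolecular and step-tagged is contradictory.
    """
    intra = bool(record.metadata.get("intramolecular"))
    entry = record.roles.get("nucleophile")
    step = entry.step if entry is not None else "n/a"
    if intra:
        if step not in ("n/a", ""):
            raise ValidationError(
                f"record {record.reaction_id}: intramolecular but nucleophile "
                f"tagged with step {step!r}"
            )
        return 0
    mapping = {"1": 1, "2": 2, "both": 3}
    if step not in mapping:
        raise ValidationError(
            f"record {record.reaction_id}: nucleophile step tag {step!r} "
            "is neither a step nor intramolecular"
        )
    return mapping[step]


def restore_catalyst_variable(
    records: list[ReactionRecord], variables: VariableTable
) -> None:
    """Copy (possibly imputed) catalyst role amounts back into ``V2`` so
    feature assembly sees a complete variable table."""
    for r in records:
        q = r.roles.get("catalyst")
        if q is not None and q.quantity is not None and not variables.has(r.reaction_id, "V2"):
            variables.add(r.reaction_id, "V2", q.quantity, "µg")


def encode_all_steps(records: Iterable[ReactionRecord]) -> list[ReactionRecord]:
    """Fill ``nucleophile_step_code`` on record copies."""
    out = []
    for r in records:
        c = r.copy()
        c.nucleophile_step_code = encode_nucleophile_step(c)
        out.append(c)
    return out
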