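# File formats

## Canonical flat table (CSV / XLSX)

One row = one reaction trial at one reuse cycle.  Columns of the default
dialect (a `Dialect` JSON can remap any of them):

| column | meaning |
| --- | --- |
| `reaction_id` | opaque trial identifier (mandatory) |
| `reaction_type` | one of `suzuki_miyaura`, `kumada`, `negishi`, `buchwald_hartwig`, `csp2_h`, `csp3_h`, `double_carbonylation` (mandatory) |
| `reuse_cycle` | integer ≥ 0, catalyst reuse count (mandatory) |
| `yield_pct` | observed yield in [0, 100], empty = missing (mandatory column) |
| `nucleophile_step_code` | 0 intramolecular / 1 step 1 / 2 step 2 / 3 both |
| `catalyst_nature`, `support_type`, `support_form`, `metal`, `preparation_process`, `support_treatment`, `assembly_generation`, `detection_method` | qualitative condition labels |
| `<role>_id`, `<role>_qty`, `<role>_unit`, `<role>_step` | per-role reagent columns for `catalyst`, `electrophile`, `nucleophile`, `solvent`, `base`; step is `1`, `2`, `both` or `n/a` |
| `V<k>` | per-reaction quantitative condition variable k (auto-detected) |
| `D<k>@<role>` | per-molecule descriptor k of the molecule playing `<role>` (auto-detected) |
| `split_label` | `t` / `v` / empty |

Missing cells are read as missing, never as zero; imputation is an explicit
stage.  Two-step reactions carry step-specific quantities in `_s1`/`_s2`
suffixed variable columns of the source spreadsheet; after quantity
weighting the total of both steps is used.

## SURF (Simple User-Friendly Reaction Format)

Tab-separated, one reaction per line, UTF-8, `\n` line endings.  The column
vocabulary of the original format is not fully standardized, so this
package freezes its own documented dialect with this exact column order:

```
rxn_id  rxn_type  reuse_cycle  yield_pct  nucleophile_step_code
catalyst_nature  support_type  support_form  metal  preparation_process
support_treatment  assembly_generation  detection_method
catalyst_molecule  catalyst_qty  catalyst_unit  catalyst_step
electrophile_molecule  electrophile_qty  electrophile_unit  electrophile_step
nucleophile_molecule  nucleophile_qty  nucleophile_unit  nucleophile_step
solvent_molecule  solvent_qty  solvent_unit  solvent_step
base_molecule  base_qty  base_unit  base_step
split
```

Empty string = missing.  Floats are serialized with `%.10g`, making
write∘read∘write byte-idempotent.  A record must carry a catalyst role to
be written.  Descriptor and variable tables are not part of SURF; they
travel in the flat table or separate keyed files.
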