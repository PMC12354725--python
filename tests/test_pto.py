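"""Perturbation operators: grouping, moving averages, Δ features."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ptml.data_model import DescriptorTable, ReactionRecord, RoleEntry, VariableTable
from ptml.errors import ConfigError, KeyingError, RecipeError
from ptml.pto import (
    SCHEMES,
    FeatureRecipe,
    Term,
    assemble_features,
    compute_pto,
    group_key,
    moving_averages,
    published_recipe,
    reference_yield,
)


def _rec(rid, rtype="suzuki_miyaura", cycle=0, yld=80.0, **labels):
    return ReactionRecord(rid, rtype, cycle, yld, condition_labels=labels)


class TestGroupKey:
    def test_single_and_multi_variable_blocks(self):
        r = _rec("a", metal="Pd", support_type="Au")
        assert group_key(r, ["metal"]) == ("Pd",)
        assert group_key(r, ["metal", "support_type"]) == ("Pd", "Au")

    def test_identical_block_values_give_identical_keys(self):
        r1 = _rec("a", metal="Pd ", support_type="Au")  # trailing space trimmed
        r2 = _rec("b", metal="Pd", support_type="Au")
        assert group_key(r1, ["metal", "support_type"]) == group_key(
            r2, ["metal", "support_type"]
        )

    def test_missing_variable_names_the_variable(self):
        with pytest.raises(KeyingError, match="support_form"):
            group_key(_rec("a", metal="Pd"), ["support_form"])

    def test_derived_variables_come_from_record_fields(self):
        r = _rec("a", cycle=3)
        r.nucleophile_step_code = 2
        assert group_key(r, ["reuse_cycle", "nucleophile_step", "reaction_type"]) == (
            "3",
            "2",
            "suzuki_miyaura",
        )


class TestMovingAverages:
    def test_hand_cases(self):
        table = moving_averages({"a": 2, "b": 4, "c": 6}, {k: ("g",) for k in "abc"})
        assert table.means[("g",)] == pytest.approx(4.0)
        assert table.counts[("g",)] == 3
        single = moving_averages({"a": 7.0}, {"a": ("s",)})
        assert single.means[("s",)] == 7.0 and single.counts[("s",)] == 1
        two = moving_averages({"a": 1.0, "b": 3.0}, {"a": ("x",), "b": ("y",)})
        assert two.means == {("x",): 1.0, ("y",): 3.0}

    def test_empty_input_gives_empty_table(self):
        table = moving_averages({}, {})
        assert table.means == {} and table.counts == {}

    @given(
        st.lists(
            st.tuples(st.floats(-1e6, 1e6), st.integers(0, 3)), min_size=1, max_size=40
        )
    )
    def test_matches_brute_force_oracle(self, pairs):
        values = {f"i{k}": v for k, (v, _) in enumerate(pairs)}
        labels = {f"i{k}": (str(g),) for k, (_, g) in enumerate(pairs)}
        table = moving_averages(values, labels)
        for lab in set(labels.values()):
            member_values = [values[i] for i in values if labels[i] == lab]
            expected = sum(member_values) / len(member_values)
            assert table.means[lab] == pytest.approx(expected, rel=1e-12, abs=1e-9)
            assert table.counts[lab] == len(member_values)


class TestComputePto:
    def test_deviation_from_group_mean(self):
        assert compute_pto(6.0, 4.0) == pytest.approx(2.0)  # group {2,4,6}
        assert compute_pto(5.0, 5.0) == 0.0
        assert compute_pto(7.0, 7.0) == 0.0  # singleton group: own mean


class TestReferenceYield:
    def test_constant_yields_give_constant_reference(self):
        records = [_rec(f"r{i}", yld=80.0, cycle=i % 2) for i in range(4)]
        assert set(reference_yield(records).values()) == {80.0}

    def test_cohort_means_by_reuse_cycle(self):
        records = [
            _rec("a", cycle=0, yld=70.0),
            _rec("b", cycle=0, yld=90.0),
            _rec("c", cycle=1, yld=50.0),
        ]
        ref = reference_yield(records)
        assert ref == {"a": 80.0, "b": 80.0, "c": 50.0}

    def test_single_record_references_its_own_yield(self):
        assert reference_yield([_rec("a", yld=42.0)]) == {"a": 42.0}


class TestAssembleFeatures:
    def test_worked_fixture_deltas_and_reference(self, worked):
        records, descriptors, variables, expected = worked
        recipe = FeatureRecipe("v33", (Term("dV33", ("V", "V33"), "c_I"),))
        frame = assemble_features(records, descriptors, variables, "PTML4", recipe)
        assert frame["dV33"].tolist() == pytest.approx(expected["v33_delta"])
        for r in records:
            assert frame.loc[r.reaction_id, "reference"] == pytest.approx(
                expected["reference"][r.reuse_cycle]
            )

    def test_single_group_column_sums_to_zero(self, worked):
        records, descriptors, variables, _ = worked
        # PTML3 c_I: all catalyst-side labels identical -> one group
        recipe = FeatureRecipe("v33", (Term("dV33", ("V", "V33"), "c_I"),))
        frame = assemble_features(records, descriptors, variables, "PTML3", recipe)
        assert frame["dV33"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_combine_then_center_product_term(self):
        # D=2, V=3 on every record -> product 6 == group mean -> delta 0
        descriptors = DescriptorTable()
        descriptors.add("m", "D1", 2.0)
        variables = VariableTable()
        records = []
        for i in range(3):
            r = _rec(f"r{i}", metal="Pd")
            r.roles["catalyst"] = RoleEntry("m", 1.0, "µg")
            records.append(r)
            variables.add(f"r{i}", "V1", 3.0)
        recipe = FeatureRecipe(
            "p", (Term("d(D1*V1)", ("prod", ("D", "D1", "catalyst"), ("V", "V1")), "c_I"),)
        )
        scheme = SCHEMES["PTML1"].__class__("S", (("c_I", ("metal",)),))
        frame = assemble_features(records, descriptors, variables, scheme, recipe)
        assert frame["d(D1*V1)"].tolist() == pytest.approx([0.0, 0.0, 0.0])

    def test_same_variable_in_two_blocks_gives_distinct_columns(self):
        variables = VariableTable()
        records = []
        # metal splits {a,b}|{c,d}; detection splits {a,c}|{b,d}
        for rid, metal, det, v in (
            ("a", "Pd", "GC", 1.0),
            ("b", "Pd", "NMR", 2.0),
            ("c", "Ni", "GC", 5.0),
            ("d", "Ni", "NMR", 10.0),
        ):
            records.append(_rec(rid, metal=metal, detection_method=det))
            variables.add(rid, "V1", v)
        scheme = SCHEMES["PTML1"].__class__(
            "S", (("c_I", ("metal",)), ("c_II", ("detection_method",)))
        )
        recipe = FeatureRecipe(
            "two",
            (
                Term("dV1_cat", ("V", "V1"), "c_I"),
                Term("dV1_rxn", ("V", "V1"), "c_II"),
            ),
        )
        frame = assemble_features(records, DescriptorTable(), variables, scheme, recipe)
        # metal groups: means 1.5 and 7.5; detection groups: means 3.0 and 6.0
        assert frame["dV1_cat"].tolist() == pytest.approx([-0.5, 0.5, -2.5, 2.5])
        assert frame["dV1_rxn"].tolist() == pytest.approx([-2.0, -4.0, 2.0, 4.0])

    def test_shift_invariance_within_group(self, worked):
        records, descriptors, variables, _ = worked
        recipe = FeatureRecipe("v33", (Term("dV33", ("V", "V33"), "c_I"),))
        base = assemble_features(records, descriptors, variables, "PTML4", recipe)
        shifted = variables.copy()
        for r in records:
            if r.reaction_type == "kumada":
                v = shifted.get(r.reaction_id, "V33")
                shifted.remove(r.reaction_id, "V33")
                shifted.add(r.reaction_id, "V33", v + 100.0)
        moved = assemble_features(records, descriptors, shifted, "PTML4", recipe)
        assert moved["dV33"].tolist() == pytest.approx(base["dV33"].tolist())

    def test_matches_naive_double_loop_oracle(self, small_synth):
        records, descriptors, variables, _ = small_synth
        sub = records[:50]
        recipe = published_recipe("eq6")
        scheme = SCHEMES["PTML3"]
        # drop rows whose catalyst amount was masked
        sub = [r for r in sub if variables.has(r.reaction_id, "V2")]
        frame = assemble_features(sub, descriptors, variables, scheme, recipe)

        def raw(term, r):
            def ev(expr):
                if expr[0] == "V":
                    return variables.get(r.reaction_id, expr[1])
                if expr[0] == "D":
                    return descriptors.get(r.roles[expr[2]].molecule_id, expr[1])
                if expr[0] == "prod":
                    out = 1.0
                    for sub_e in expr[1:]:
                        out *= ev(sub_e)
                    return out
                return sum(ev(e) for e in expr[1:])

            return ev(term.expr)

        for term in recipe.terms:
            block = scheme.block(term.block)
            for r in sub:
                peers = [
                    q for q in sub if group_key(q, block) == group_key(r, block)
                ]
                mean = sum(raw(term, q) for q in peers) / len(peers)
                expected = raw(term, r) - mean
                assert frame.loc[r.reaction_id, term.term_id] == pytest.approx(
                    expected, rel=1e-12, abs=1e-9
                )

    def test_unseen_group_centers_on_global_mean_with_warning(self):
        variables = VariableTable()
        records = []
        for rid, metal, v in (("a", "Pd", 1.0), ("b", "Pd", 3.0), ("c", "Ni", 10.0)):
            records.append(_rec(rid, metal=metal))
            variables.add(rid, "V1", v)
        scheme = SCHEMES["PTML1"].__class__("S", (("c_I", ("metal",)),))
        recipe = FeatureRecipe("one", (Term("dV1", ("V", "V1"), "c_I"),))
        with pytest.warns(UserWarning, match="unseen"):
            frame = assemble_features(
                records, DescriptorTable(), variables, scheme, recipe,
                fit_population=["a", "b"],
            )
        # Ni record centered on the fit-population global mean (1+3)/2 = 2
        assert frame.loc["c", "dV1"] == pytest.approx(8.0)

    def test_unresolvable_term_names_the_term(self, worked):
        records, descriptors, variables, _ = worked
        recipe = FeatureRecipe("bad", (Term("dV99", ("V", "V99"), "c_I"),))
        with pytest.raises(RecipeError, match="dV99"):
            assemble_features(records, descriptors, variables, "PTML4", recipe)


class TestPublishedRecipe:
    def test_nine_model_inputs(self):
        for mid in ("eq5", "eq6"):
            recipe = published_recipe(mid)
            assert len(recipe.terms) == 8  # eight perturbation terms
            assert len(recipe.terms) + 1 == 9  # plus the reference input
        with pytest.raises(ConfigError):
            published_recipe("eq7")

    def test_printed_order_and_units(self):
        recipe = published_recipe("eq6")
        ids = recipe.term_ids()
        assert ids[0] == "d(D2*V2)" and ids[-1] == "dV30"
        assert recipe.terms[1].term_id == "dV31"
        assert recipe.terms[1].unit == "h"
        assert recipe.terms[-1].unit == "°C"

    def test_partition_schemes_reference_declared_variables(self):
        from ptml.data_model import CONDITION_VARIABLES, DERIVED_CONDITION_VARIABLES

        known = set(CONDITION_VARIABLES) | set(DERIVED_CONDITION_VARIABLES)
        for scheme in SCHEMES.values():
            for name, block in scheme.blocks:
                assert block, f"{scheme.scheme_id}:{name} empty"
                assert set(block) <= known
        # the second scheme swaps reuse frequency for the nucleophile step
        ptml1 = dict(SCHEMES["PTML1"].blocks)
        ptml2 = dict(SCHEMES["PTML2"].blocks)
        assert "reuse_cycle" in ptml1["c_III"] and "nucleophile_step" in ptml2["c_III"]
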