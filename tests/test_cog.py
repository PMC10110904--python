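import math

import pandas as pd
import pytest

from panchol import abundance, classify, fold_abundance, group_exclusive
from panchol.cog import ABUNDANCE_COLUMNS
from panchol.orthogroups import Orthogroup
from panchol.io import ProteinRecord

from conftest import build_matrix

STRAINS = list("ABCDE")


def og(og_id, members):
    """members: list of (protein_id, strain, cog_class)"""
    return Orthogroup(
        og_id, [ProteinRecord(pid, s, "MKVLWAALLVTF", cls) for pid, s, cls in members]
    )


def abundance_table(values: dict[str, float]) -> pd.DataFrame:
    rows = [
        (cls, "x", 0, 0, 0, pct) for cls, pct in values.items()
    ]
    return pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS)


FIXTURE_OGS = [
    og("og1", [("a1", "A", "G"), ("b1", "B", "G"), ("c1", "C", "G"),
               ("d1", "D", "G"), ("e1", "E", "G")]),
    og("og2", [("a2", "A", "M"), ("b2", "B", "M"), ("c2", "C", None),
               ("d2", "D", "M"), ("e2", "E", "M")]),
    og("og3", [("a3", "A", "G"), ("b3", "B", "G")]),
    og("og4", [("a4", "A", "K")]),
]
FIXTURE_MATRIX = build_matrix(
    {
        "og1": [1, 1, 1, 1, 1],
        "og2": [1, 1, 1, 1, 1],
        "og3": [1, 1, 0, 0, 0],
        "og4": [1, 0, 0, 0, 0],
    },
    STRAINS,
)
FIXTURE_LABELS = classify(FIXTURE_MATRIX)


class TestAbundance:
    def test_single_class_scope_is_100_percent(self):
        table = abundance(FIXTURE_OGS, FIXTURE_LABELS, "accessory")
        g = table[table["cog_class"] == "G"].iloc[0]
        assert g["gene_count"] == 2
        assert g["abundance_pct"] == 100.0  # only class G in the accessory scope

    def test_empty_scope_gives_zero_table(self):
        ogs = [og("og1", [("a1", "A", "G"), ("b1", "B", "G"), ("c1", "C", "G"),
                          ("d1", "D", "G"), ("e1", "E", "G")])]
        matrix = build_matrix({"og1": [1, 1, 1, 1, 1]}, STRAINS)
        table = abundance(ogs, classify(matrix), "unique")
        assert (table["gene_count"] == 0).all()
        assert (table["abundance_pct"] == 0.0).all()

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError, match="unknown scope"):
            abundance(FIXTURE_OGS, FIXTURE_LABELS, "nonsense")

    def test_unannotated_members_excluded_from_denominator(self):
        table = abundance(FIXTURE_OGS, FIXTURE_LABELS, "core")
        m = table[table["cog_class"] == "M"].iloc[0]
        assert m["gene_count"] == 4  # c2 is unannotated
        assert m["scope_total"] == 9  # 5 G + 4 M
        assert m["abundance_pct"] == pytest.approx(100 * 4 / 9)

    def test_group_scope_restricted_to_accessory(self):
        groups = {"left": ["A", "B"], "right": ["C", "D", "E"]}
        table = abundance(
            FIXTURE_OGS, FIXTURE_LABELS, "left", groups=groups, restrict_to="accessory"
        )
        g = table[table["cog_class"] == "G"].iloc[0]
        assert g["gene_count"] == 2  # a3, b3
        k = table[table["cog_class"] == "K"].iloc[0]
        assert k["gene_count"] == 0  # og4 is unique, not accessory

    def test_family_total_denominator_mode(self):
        table = abundance(FIXTURE_OGS, FIXTURE_LABELS, "core", denominator="family_total")
        g = table[table["cog_class"] == "G"].iloc[0]
        assert g["abundance_pct"] == pytest.approx(100 * 5 / 7)  # 5 of 7 G genes are core

    def test_partition_scopes_conserve_class_totals(self, small_inference):
        _, _, ogs, matrix, _ = small_inference
        labels = classify(matrix)
        tables = {s: abundance(ogs, labels, s) for s in ("core", "accessory", "unique")}
        totals = {}
        for t in tables.values():
            for _, row in t.iterrows():
                totals[row["cog_class"]] = totals.get(row["cog_class"], 0) + row["gene_count"]
        family_totals = dict(
            zip(tables["core"]["cog_class"], tables["core"]["family_total"])
        )
        assert totals == family_totals

    def test_recount_against_generator_truth(self, small_inference):
        """Class counts in each scope equal a plain recount over the truth."""
        _, truth, ogs, matrix, _ = small_inference
        labels = classify(matrix)
        table = abundance(ogs, labels, "core")
        expected: dict[str, int] = {}
        for fam in truth.families.values():
            if fam.label.value != "core" or fam.cog_class is None:
                continue
            n = sum(fam.copy_numbers.values())
            expected[fam.cog_class] = expected.get(fam.cog_class, 0) + n
        got = {
            r["cog_class"]: r["gene_count"]
            for _, r in table.iterrows()
            if r["gene_count"]
        }
        assert got == expected


class TestFoldAbundance:
    def test_printed_accessory_contrast(self):
        a = abundance_table({"M": 3.0})
        b = abundance_table({"M": 0.7})
        ratio = fold_abundance(a, b, "M")
        assert ratio == pytest.approx(3.0 / 0.7)
        assert ratio >= 4.28  # "at least a 4.28-fold" enrichment

    def test_equal_abundances_give_unity(self):
        a = abundance_table({"G": 12.5})
        assert fold_abundance(a, a, "G") == 1.0

    def test_52_vs_17_contrast(self):
        ratio = fold_abundance(
            abundance_table({"G": 52.0}), abundance_table({"G": 17.0}), "G"
        )
        assert ratio == pytest.approx(52 / 17)
        assert round(ratio, 4) == 3.0588

    def test_zero_denominator_flags_infinite(self):
        ratio = fold_abundance(
            abundance_table({"M": 3.0}), abundance_table({"M": 0.0}), "M"
        )
        assert math.isinf(ratio)

    def test_missing_class_rejected(self):
        with pytest.raises(KeyError):
            fold_abundance(abundance_table({"M": 1.0}), abundance_table({"M": 1.0}), "Z")


def contrast_fixture(n_exclusive=21, n_background=100):
    """Presence matrix with n_exclusive rows private to {A, B} among
    background rows covering other presence patterns."""
    rows = {}
    i = 0
    for _ in range(n_exclusive):
        rows[f"x{i:04d}"] = [1, 1, 0, 0, 0]
        i += 1
    patterns = [
        [1, 1, 1, 1, 1],
        [1, 0, 0, 0, 0],
        [0, 0, 1, 1, 1],
        [1, 1, 1, 0, 0],
        [0, 1, 0, 0, 0],
        [1, 0, 1, 0, 1],
        [0, 0, 0, 1, 1],
    ]
    for j in range(n_background):
        rows[f"bg{j:04d}"] = patterns[j % len(patterns)]
    return build_matrix(rows, STRAINS)


class TestGroupExclusive:
    def test_ubiquitous_orthogroup_is_never_exclusive(self):
        m = build_matrix({"og1": [1, 1, 1, 1, 1]}, STRAINS)
        assert group_exclusive(m, ["A", "B"], ["C", "D"]).count == 0

    def test_private_orthogroup_is_returned(self):
        m = build_matrix({"og1": [1, 1, 0, 0, 0], "og2": [1, 1, 1, 0, 0]}, STRAINS)
        res = group_exclusive(m, ["A", "B"], ["C", "D", "E"])
        assert res.exclusive_orthogroups == ["og1"]

    def test_table3_pattern_counts_21(self):
        m = contrast_fixture()
        res = group_exclusive(m, ["A", "B"], ["C", "D", "E"])
        assert res.count == 21

    def test_direction_exclusives_are_disjoint(self):
        m = contrast_fixture()
        ab = set(group_exclusive(m, ["A", "B"], ["C", "D", "E"]).exclusive_orthogroups)
        ba = set(group_exclusive(m, ["C", "D", "E"], ["A", "B"]).exclusive_orthogroups)
        assert ab & ba == set()

    def test_growing_either_group_shrinks_the_exclusive_set(self):
        m = contrast_fixture()
        base = set(group_exclusive(m, ["A"], ["C", "D"]).exclusive_orthogroups)
        grown_a = set(group_exclusive(m, ["A", "B"], ["C", "D"]).exclusive_orthogroups)
        grown_b = set(group_exclusive(m, ["A"], ["C", "D", "E"]).exclusive_orthogroups)
        assert grown_a <= base
        assert grown_b <= base

    @pytest.mark.parametrize(
        "a,b,err",
        [
            (["A"], ["A", "B"], "overlap"),
            ([], ["A"], "non-empty"),
            (["A"], ["Z"], "not in matrix"),
        ],
    )
    def test_invalid_groups_rejected(self, a, b, err):
        with pytest.raises(ValueError, match=err):
            group_exclusive(contrast_fixture(1, 5), a, b)

    def test_generator_marker_families_found(self, small_inference):
        proteomes, truth, _, matrix, _ = small_inference
        groups = {}
        for p in proteomes:
            groups.setdefault(p.group_label, []).append(p.strain_id)
        res = group_exclusive(
            matrix, groups["hypocholesterolemic"], groups["general"]
        )
        assert res.count == len(truth.marker_ids)
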