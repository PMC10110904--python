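import numpy as np
import pandas as pd
import pytest

from panchol import (
    AlignParams,
    ProteinRecord,
    StrainProteome,
    all_vs_all,
    build_orthogroups,
    infer_orthogroups,
    presence_matrix,
    reciprocal_best_hits,
)
from panchol.align import HIT_COLUMNS, HitTable
from panchol.orthogroups import Orthogroup, consensus_cog

from oracles import best_hit_scan

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def hit_table(rows):
    """rows: (query_id, subject_id, qstrain, sstrain, score, ident, qcov, scov)"""
    return HitTable(hits=pd.DataFrame(rows, columns=HIT_COLUMNS))


class TestReciprocalBestHits:
    def test_single_pair_is_an_edge(self):
        table = hit_table([("a1", "b1", "A", "B", 50.0, 95.0, 100.0, 100.0)])
        assert reciprocal_best_hits(table) == [("a1", "b1")]

    def test_asymmetric_best_hits_make_no_edge(self):
        # a1's best in B is b1, but b1's best in A is a2
        table = hit_table(
            [
                ("a1", "b1", "A", "B", 50.0, 90.0, 100.0, 100.0),
                ("a2", "b1", "A", "B", 60.0, 95.0, 100.0, 100.0),
            ]
        )
        assert reciprocal_best_hits(table) == [("a2", "b1")]

    def test_quality_gate_drops_weak_edges(self):
        table = hit_table([("a1", "b1", "A", "B", 50.0, 20.0, 100.0, 100.0)])
        assert reciprocal_best_hits(table) == []
        table = hit_table([("a1", "b1", "A", "B", 50.0, 95.0, 30.0, 30.0)])
        assert reciprocal_best_hits(table) == []

    def test_random_instance_matches_definition_scan(self, rng):
        """3 strains, <=10 proteins each: edge set equals the brute-force
        reciprocal-best definition applied to the same scores."""
        prots = []
        families = [
            "".join(rng.choice(list(AA20), 50)) for _ in range(6)
        ]
        for s in "ABC":
            members = []
            for i in range(rng.integers(4, 10)):
                fam = families[rng.integers(len(families))]
                seq = "".join(
                    c if rng.random() > 0.05 else rng.choice(list(AA20)) for c in fam
                )
                members.append(ProteinRecord(f"{s.lower()}{i}", s, seq))
            prots.append(StrainProteome(s, members))
        table = all_vs_all(prots, stats="full")
        edges = set(reciprocal_best_hits(table, min_identity_pct=0, min_coverage_pct=0))

        score = {}
        strain_of = {}
        for _, r in table.hits.iterrows():
            score[(r["query_id"], r["subject_id"])] = r["score"]
            score[(r["subject_id"], r["query_id"])] = r["score"]
            strain_of[r["query_id"]] = r["query_strain"]
            strain_of[r["subject_id"]] = r["subject_strain"]
        assert edges == best_hit_scan(score, strain_of)


def make_family(strains, rng, length=45, rate=0.03):
    ancestral = "".join(rng.choice(list(AA20), length))
    out = {}
    for s in strains:
        out[s] = "".join(
            c if rng.random() > rate else rng.choice(list(AA20)) for c in ancestral
        )
    return out


class TestBuildOrthogroups:
    def test_five_strain_family_is_one_group(self, rng):
        strains = list("ABCDE")
        fam = make_family(strains, rng)
        prots = [
            StrainProteome(s, [ProteinRecord(f"{s.lower()}1", s, fam[s])])
            for s in strains
        ]
        table = all_vs_all(prots, stats="full")
        edges = reciprocal_best_hits(table)
        groups = build_orthogroups(edges, table, prots)
        assert len(groups) == 1
        assert groups[0].strains_present == frozenset(strains)

    def test_no_edges_gives_singletons(self, rng):
        # unrelated random proteins; no RBH edges supplied
        prots = [
            StrainProteome(
                s, [ProteinRecord(f"{s.lower()}1", s, "".join(rng.choice(list(AA20), 40)))]
            )
            for s in "AB"
        ]
        table = all_vs_all(prots, stats="full")
        groups = build_orthogroups([], table, prots)
        assert len(groups) == 2
        assert all(len(g) == 1 for g in groups)

    def test_duplicated_gene_joins_its_family(self, rng):
        """Two near-identical copies in one strain end up in one orthogroup
        with copy number 2 via the paralog-attachment rule."""
        strains = list("AB")
        fam = make_family(strains, rng)
        dup = "".join(
            c if rng.random() > 0.02 else rng.choice(list(AA20)) for c in fam["A"]
        )
        prots = [
            StrainProteome(
                "A",
                [ProteinRecord("a1", "A", fam["A"]), ProteinRecord("a2", "A", dup)],
            ),
            StrainProteome("B", [ProteinRecord("b1", "B", fam["B"])]),
        ]
        table = all_vs_all(prots, stats="full")
        edges = reciprocal_best_hits(table)
        groups = build_orthogroups(edges, table, prots)
        assert len(groups) == 1
        assert groups[0].copy_number("A") == 2

    def test_clustering_partitions_protein_set(self, small_inference):
        proteomes, _, ogs, _, _ = small_inference
        total = sum(len(p) for p in proteomes)
        assert sum(len(g) for g in ogs) == total
        ids = [m.protein_id for g in ogs for m in g.members]
        assert len(ids) == len(set(ids))

    def test_inference_is_deterministic(self, small_pangenome):
        proteomes, _ = small_pangenome
        a, ma, _ = infer_orthogroups(proteomes)
        b, mb, _ = infer_orthogroups(proteomes)
        assert [(g.orthogroup_id, [m.protein_id for m in g.members]) for g in a] == [
            (g.orthogroup_id, [m.protein_id for m in g.members]) for g in b
        ]
        assert ma.counts.equals(mb.counts)

    def test_recovers_generator_truth(self, small_inference):
        _, truth, ogs, matrix, _ = small_inference
        inferred = {frozenset(m.protein_id for m in g.members) for g in ogs}
        assert inferred == truth.membership_sets()
        # presence matrix equals the generator's truth matrix (up to row names)
        truth_rows = sorted(
            map(tuple, truth.presence_frame()[matrix.strain_ids].to_numpy())
        )
        got_rows = sorted(map(tuple, matrix.presence.to_numpy()))
        assert got_rows == truth_rows


class TestConsensusAndMatrix:
    def test_consensus_cog_modal_and_ties(self):
        mk = lambda cls: ProteinRecord("p" + (cls or "x"), "S", "MKV", cls)
        assert consensus_cog([mk("G"), mk("G"), mk("J")]) == "G"
        assert consensus_cog([mk("J"), mk("G")]) == "G"  # tie -> smallest letter
        assert consensus_cog([mk(None)]) is None

    def test_presence_matrix_counts_members(self):
        og1 = Orthogroup(
            "OG1",
            [
                ProteinRecord("a1", "A", "MKV"),
                ProteinRecord("a2", "A", "MKL"),
                ProteinRecord("b1", "B", "MKV"),
            ],
        )
        og2 = Orthogroup("OG2", [ProteinRecord("b2", "B", "ACD")])
        m = presence_matrix([og1, og2], ["A", "B"])
        assert m.counts.loc["OG1", "A"] == 2
        assert m.counts.loc["OG1", "B"] == 1
        assert list(m.presence.loc["OG2"]) == [False, True]

    def test_presence_matrix_rejects_unknown_strain(self):
        og = Orthogroup("OG1", [ProteinRecord("a1", "A", "MKV")])
        with pytest.raises(ValueError, match="not in strain_ids"):
            presence_matrix([og], ["B"])
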