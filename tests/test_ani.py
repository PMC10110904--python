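import math

import numpy as np
import pandas as pd
import pytest

from panchol import (
    AniParams,
    DistanceMatrix,
    GenomeSequence,
    ani,
    ani_matrix,
    divergence_matrix,
    neighbor_joining,
    to_newick,
)
from panchol.ani import genome_fragments, write_newick
from panchol.simulate import NT, mutate_sequence

from oracles import random_additive_matrix


def random_genome(rng, n=50_000):
    return "".join(rng.choice(NT, n))


class TestFragmentAni:
    def test_self_ani_is_100(self, rng):
        g = GenomeSequence("g", [random_genome(rng)])
        assert ani(g, g) == 100.0

    def test_mutated_copy_matches_binomial_expectation(self, rng):
        """50 kb genome mutated at r=0.01 per site: ANI ~ 99.0 +/- 0.2."""
        base = random_genome(rng)
        mutated = mutate_sequence(base, 0.01, rng, NT)
        value = ani(GenomeSequence("a", [base]), GenomeSequence("b", [mutated]))
        assert value == pytest.approx(99.0, abs=0.2)

    def test_unrelated_genomes_are_undefined(self, rng):
        a = GenomeSequence("a", [random_genome(rng)])
        b = GenomeSequence("b", [random_genome(rng)])
        assert math.isnan(ani(a, b))

    def test_ani_decreases_with_substitution_rate(self, rng):
        base = random_genome(rng)
        values = []
        for r in (0.0, 0.005, 0.01, 0.02, 0.05):
            mutated = mutate_sequence(base, r, rng, NT)
            values.append(
                ani(GenomeSequence("a", [base]), GenomeSequence("b", [mutated]))
            )
        assert values[0] == 100.0
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_bidirectional_averaging_is_symmetric(self, rng):
        base = random_genome(rng, 20_000)
        a = GenomeSequence("a", [base])
        b = GenomeSequence("b", [mutate_sequence(base, 0.02, rng, NT)])
        assert ani(a, b) == ani(b, a)

    def test_fragments_drop_remainder_and_n_rich_windows(self):
        params = AniParams(fragment_length=1000)
        contig = "A" * 2500
        g = GenomeSequence("g", [contig])
        assert len(genome_fragments(g, params)) == 2  # 500 bp remainder dropped
        noisy = "A" * 1000 + "N" * 150 + "A" * 850
        g2 = GenomeSequence("g", [noisy])
        assert len(genome_fragments(g2, params)) == 1  # >10% N window skipped


class TestDivergence:
    @pytest.mark.parametrize("ani_val,expected", [(98.91, 1.09), (94.85, 5.15), (100.0, 0.0)])
    def test_divergence_is_100_minus_ani(self, ani_val, expected):
        m = pd.DataFrame(
            [[100.0, ani_val], [ani_val, 100.0]], index=["a", "b"], columns=["a", "b"]
        )
        div = divergence_matrix(m)
        assert div.loc["a", "b"] == pytest.approx(expected)
        assert div.loc["a", "a"] == 0.0

    def test_involution_with_ani(self, rng):
        vals = 100.0 - rng.uniform(0, 30, size=(4, 4))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 100.0)
        ids = list("abcd")
        dm = DistanceMatrix(ani=pd.DataFrame(vals, index=ids, columns=ids))
        recovered = 100.0 - dm.divergence
        off_diag = ~np.eye(4, dtype=bool)
        assert np.allclose(recovered.to_numpy()[off_diag], vals[off_diag])

    def test_undefined_pair_rejected_with_guidance(self):
        m = pd.DataFrame(
            [[100.0, math.nan], [math.nan, 100.0]], index=["a", "b"], columns=["a", "b"]
        )
        with pytest.raises(ValueError, match="sentinel|undefined"):
            divergence_matrix(m)


def tree_distances(tree):
    return tree.leaf_distances()


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = list("abc")
        d = pd.DataFrame(
            [[0.0, 5.0, 9.0], [5.0, 0.0, 8.0], [9.0, 8.0, 0.0]],
            index=ids, columns=ids,
        )
        tree = neighbor_joining(d)
        lengths = {child.name: l for child, l in tree.root.children}
        assert lengths["a"] == pytest.approx((5 + 9 - 8) / 2)
        assert lengths["b"] == pytest.approx((5 + 8 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 8 - 5) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_additive_matrix_recovered_exactly(self, n_taxa, rng):
        labels, dist, _ = random_additive_matrix(n_taxa, rng)
        d = pd.DataFrame(dist, index=labels, columns=labels)
        tree = neighbor_joining(d)
        got = tree_distances(tree).loc[labels, labels].to_numpy()
        assert np.abs(got - dist).max() < 1e-9

    def test_agrees_with_scikit_bio_on_additive_input(self, rng):
        skbio = pytest.importorskip("skbio")
        labels, dist, _ = random_additive_matrix(6, rng)
        d = pd.DataFrame(dist, index=labels, columns=labels)
        ours = tree_distances(neighbor_joining(d))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dist, ids=labels))
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert ours.loc[a, b] == pytest.approx(
                    sk_tree.find(a).distance(sk_tree.find(b)), abs=1e-6
                )

    def test_equal_distances_preserve_path_lengths(self):
        ids = list("abcd")
        vals = np.full((4, 4), 6.0)
        np.fill_diagonal(vals, 0.0)
        d = pd.DataFrame(vals, index=ids, columns=ids)
        got = tree_distances(neighbor_joining(d))
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(got.to_numpy()[off], 6.0)

    def test_two_leaves_split_evenly(self):
        d = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        tree = neighbor_joining(d)
        lengths = sorted(l for _, l in tree.root.children)
        assert lengths == [1.5, 1.5]

    def test_branch_lengths_never_negative(self, rng):
        # noisy near-additive matrices can push NJ limbs negative; they clamp
        for trial in range(5):
            labels, dist, _ = random_additive_matrix(5, rng)
            noisy = dist + rng.normal(0, 0.3, dist.shape)
            noisy = np.abs((noisy + noisy.T) / 2)
            np.fill_diagonal(noisy, 0.0)
            d = pd.DataFrame(noisy, index=labels, columns=labels)
            tree = neighbor_joining(d)

            def lengths(node):
                for child, l in node.children:
                    yield l
                    yield from lengths(child)

            assert all(l >= 0 for l in lengths(tree.root))

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d)


class TestNewick:
    def test_two_leaf_form(self):
        d = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["A", "B"], columns=["A", "B"])
        s = to_newick(neighbor_joining(d))
        assert s == "(A:1.500000,B:1.500000);"

    def test_round_trip_preserves_distances(self, rng, tmp_path):
        skbio = pytest.importorskip("skbio")
        labels, dist, _ = random_additive_matrix(7, rng)
        d = pd.DataFrame(dist, index=labels, columns=labels)
        tree = neighbor_joining(d)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = skbio.TreeNode.read(str(path))
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert parsed.find(a).distance(parsed.find(b)) == pytest.approx(
                    dist[labels.index(a), labels.index(b)], abs=1e-5
                )

    def test_names_with_spaces_are_quoted(self):
        d = pd.DataFrame(
            [[0.0, 2.0], [2.0, 0.0]],
            index=["strain one", "strain two"],
            columns=["strain one", "strain two"],
        )
        s = to_newick(neighbor_joining(d))
        assert "'strain one'" in s and "'strain two'" in s
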