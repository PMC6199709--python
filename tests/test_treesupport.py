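import math
import random
from collections import Counter

import pytest

from capcure.seqio_core import parse_newick
from capcure.treesupport import (
    Bipartition,
    bipartitions,
    internode_certainty,
    nj_tree,
)


# ---------------------------------------------------------------------------
# independent naive oracle: a tiny recursive Newick parser plus direct
# frequency counting and the entropy formula evaluated in-place


def _oracle_clades(newick: str) -> tuple[frozenset, list[frozenset]]:
    newick = newick.strip().rstrip(";")

    def parse(s, i):
        clades = []
        if s[i] == "(":
            leaves = set()
            i += 1
            while True:
                sub_leaves, sub_clades, i = parse(s, i)
                leaves |= sub_leaves
                clades += sub_clades
                if s[i] == ",":
                    i += 1
                    continue
                assert s[i] == ")"
                i += 1
                break
            # skip branch length / label
            while i < len(s) and s[i] not in ",()":
                i += 1
            clades.append(frozenset(leaves))
            return frozenset(leaves), clades, i
        j = i
        while j < len(s) and s[j] not in ",():":
            j += 1
        label = s[i:j]
        while j < len(s) and s[j] not in ",()":
            j += 1
        return frozenset({label}), [], j

    leaves, clades, _ = parse(newick, 0)
    return leaves, clades


def oracle_bipartitions(newick: str) -> set[frozenset]:
    """Each nontrivial split as frozenset({side_a, side_b})."""
    universe, clades = _oracle_clades(newick)
    splits = set()
    for clade in clades:
        other = universe - clade
        if len(clade) >= 2 and len(other) >= 2:
            splits.add(frozenset({clade, other}))
    return splits


def oracle_ic(ref_newick: str, gene_newicks: list[str]):
    """Naive per-branch IC over same-leaf-set gene trees."""
    gene_splits = [oracle_bipartitions(n) for n in gene_newicks]
    n_trees = len(gene_newicks)
    result = {}
    for split in oracle_bipartitions(ref_newick):
        side_a, side_b = tuple(split)
        f = sum(split in s for s in gene_splits) / n_trees
        conflicts = Counter()
        for splits in gene_splits:
            for other in splits:
                oa, ob = tuple(other)
                if all((side_a & oa, side_a & ob, side_b & oa, side_b & ob)):
                    conflicts[other] += 1
        if not conflicts:
            result[split] = 1.0 if f > 0 else 0.0
            continue
        f1 = max(conflicts.values()) / n_trees
        p = f / (f + f1)
        ic = 1.0
        for q in (p, 1 - p):
            if q > 0:
                ic += q * math.log2(q)
        result[split] = ic if f1 <= f else -ic
    return result


def random_tree_newick(labels, rng) -> str:
    parts = list(labels)
    rng.shuffle(parts)
    while len(parts) > 1:
        i, j = sorted(rng.sample(range(len(parts)), 2), reverse=True)
        a, b = parts.pop(i), parts.pop(j)
        parts.append(f"({a},{b})")
    return parts[0] + ";"


def as_split_set(bip: Bipartition) -> frozenset:
    return frozenset({bip.side_a, bip.side_b})


# ---------------------------------------------------------------------------


class TestBipartitions:
    def test_quartet(self):
        tree = parse_newick("((a,b),(c,d));")
        assert bipartitions(tree) == {Bipartition.of({"a", "b"}, "abcd")}

    def test_caterpillar_five_leaves(self):
        tree = parse_newick("((((a,b),c),d),e);")
        bips = bipartitions(tree)
        assert {as_split_set(b) for b in bips} == {
            frozenset({frozenset("ab"), frozenset("cde")}),
            frozenset({frozenset("abc"), frozenset("de")}),
        }

    def test_star_tree_empty(self):
        tree = parse_newick("(a,b,c,d,e);")
        assert bipartitions(tree) == set()

    def test_fewer_than_four_leaves_empty(self):
        tree = parse_newick("((a,b),c);")
        assert bipartitions(tree) == set()

    def test_agrees_with_oracle_on_random_trees(self):
        rng = random.Random(5)
        labels = [f"x{i}" for i in range(8)]
        for _ in range(20):
            newick = random_tree_newick(labels, rng)
            tree = parse_newick(newick)
            assert {as_split_set(b) for b in bipartitions(tree)} == \
                oracle_bipartitions(newick)

    def test_canonical_orientation(self):
        bip = Bipartition.of({"z", "y"}, {"a", "b", "z", "y"})
        assert "a" in bip.side_a


class TestInternodeCertainty:
    def test_unanimous_support_gives_one(self):
        ref = parse_newick("((a,b),(c,d));")
        genes = [parse_newick("((a,b),(c,d));") for _ in range(100)]
        result = internode_certainty(ref, genes)
        (branch,) = result.per_branch.values()
        assert branch.ic == 1.0 and branch.ica == 1.0
        assert branch.n_evaluable_trees == 100

    def test_even_conflict_gives_zero(self):
        ref = parse_newick("((a,b),(c,d));")
        genes = [parse_newick("((a,b),(c,d));")] * 50 + \
                [parse_newick("((a,c),(b,d));")] * 50
        (branch,) = internode_certainty(ref, genes).per_branch.values()
        assert branch.ic == pytest.approx(0.0, abs=1e-12)

    def test_seventy_thirty(self):
        ref = parse_newick("((a,b),(c,d));")
        genes = [parse_newick("((a,b),(c,d));")] * 70 + \
                [parse_newick("((a,c),(b,d));")] * 30
        (branch,) = internode_certainty(ref, genes).per_branch.values()
        expected = 1 + 0.7 * math.log2(0.7) + 0.3 * math.log2(0.3)
        assert branch.ic == pytest.approx(expected, abs=1e-9)
        assert branch.ic == pytest.approx(0.1187, abs=2e-4)
        # single conflictor: ICA equals IC
        assert branch.ica == pytest.approx(branch.ic)

    def test_thirty_seventy_sign_flip(self):
        ref = parse_newick("((a,b),(c,d));")
        genes = [parse_newick("((a,b),(c,d));")] * 30 + \
                [parse_newick("((a,c),(b,d));")] * 70
        (branch,) = internode_certainty(ref, genes).per_branch.values()
        assert branch.ic == pytest.approx(-0.1187, abs=2e-4)
        assert branch.ica < 0

    def test_partial_trees_excluded_from_denominator(self):
        ref = parse_newick("(((a,b),(c,d)),(e,f));")
        full = parse_newick("((a,b),((c,d),(e,f)));")
        partial = parse_newick("((a,c),(d,e));")  # ab|rest is trivial here
        result = internode_certainty(ref, [full, partial])
        ab = Bipartition.of({"a", "b"}, "abcdef")
        assert result.per_branch[ab].n_evaluable_trees == 1
        assert result.per_branch[ab].support_freq == 1.0

    def test_foreign_leaf_rejected(self):
        ref = parse_newick("((a,b),(c,d));")
        bad = parse_newick("((a,b),(c,zz));")
        with pytest.raises(ValueError, match="zz"):
            internode_certainty(ref, [bad])

    def test_gene_tree_order_invariance(self):
        rng = random.Random(1)
        labels = [f"x{i}" for i in range(8)]
        ref = random_tree_newick(labels, rng)
        genes = [random_tree_newick(labels, rng) for _ in range(10)]
        r1 = internode_certainty(parse_newick(ref),
                                 [parse_newick(g) for g in genes])
        r2 = internode_certainty(parse_newick(ref),
                                 [parse_newick(g) for g in genes[::-1]])
        for bip, branch in r1.per_branch.items():
            assert r2.per_branch[bip].ic == pytest.approx(branch.ic)
            assert r2.per_branch[bip].ica == pytest.approx(branch.ica)

    def test_tc_is_sum_of_ic(self):
        rng = random.Random(2)
        labels = [f"x{i}" for i in range(8)]
        ref = parse_newick(random_tree_newick(labels, rng))
        genes = [parse_newick(random_tree_newick(labels, rng)) for _ in range(15)]
        result = internode_certainty(ref, genes)
        assert result.tc == pytest.approx(
            sum(b.ic for b in result.per_branch.values())
        )
        assert result.relative_tc == pytest.approx(
            result.tc / len(result.per_branch)
        )
        ics = [b.ic for b in result.per_branch.values()]
        assert min(ics) <= result.relative_tc <= max(ics)

    def test_matches_naive_oracle_random_instances(self):
        rng = random.Random(3)
        labels = [f"x{i}" for i in range(8)]
        for _ in range(20):
            ref_newick = random_tree_newick(labels, rng)
            gene_newicks = [random_tree_newick(labels, rng) for _ in range(12)]
            result = internode_certainty(
                parse_newick(ref_newick),
                [parse_newick(g) for g in gene_newicks],
            )
            expected = oracle_ic(ref_newick, gene_newicks)
            assert len(result.per_branch) == len(expected)
            for bip, branch in result.per_branch.items():
                assert branch.ic == pytest.approx(
                    expected[as_split_set(bip)], abs=1e-9
                )


class TestNeighborJoining:
    @staticmethod
    def path_distances(newick: str) -> dict:
        tree = parse_newick(newick)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        return {
            a: {b: pdm.distance(taxa[a], taxa[b]) for b in taxa}
            for a in taxa
        }

    def test_additive_five_taxon_recovery(self):
        truth = "((a:0.2,b:0.3):0.15,(c:0.25,d:0.1):0.2,e:0.4);"
        d = self.path_distances(truth)
        tree = nj_tree(d)
        assert bipartitions(tree) == bipartitions(parse_newick(truth))

    def test_ultrametric_cherry_pairing(self):
        d = {
            "a": {"a": 0.0, "b": 0.2, "c": 0.6, "d": 0.6},
            "b": {"a": 0.2, "b": 0.0, "c": 0.6, "d": 0.6},
            "c": {"a": 0.6, "b": 0.6, "c": 0.0, "d": 0.2},
            "d": {"a": 0.6, "b": 0.6, "c": 0.2, "d": 0.0},
        }
        tree = nj_tree(d)
        assert bipartitions(tree) == {Bipartition.of({"a", "b"}, "abcd")}

    def test_three_taxa_rejected(self):
        d = {
            "a": {"a": 0.0, "b": 0.1, "c": 0.2},
            "b": {"a": 0.1, "b": 0.0, "c": 0.2},
            "c": {"a": 0.2, "b": 0.2, "c": 0.0},
        }
        with pytest.raises(ValueError, match=">= 4"):
            nj_tree(d)

    def test_undefined_entry_rejected(self):
        d = {
            "a": {"a": 0.0, "b": 0.1},
            "b": {"a": 0.1, "b": 0.0},
            "c": {"c": 0.0},
            "d": {"d": 0.0},
        }
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(d)

    def test_branch_lengths_nonnegative(self):
        truth = "((a:0.2,b:0.3):0.15,((c:0.25,d:0.1):0.2,e:0.4):0.1,f:0.3);"
        tree = nj_tree(self.path_distances(truth))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0
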