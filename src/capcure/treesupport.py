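"""Internode certainty over gene trees, bipartition utilities and a
neighbor-joining builder.

For each internal branch of the reference tree, the gene trees are polled
for the induced bipartition and for bipartitions conflicting with it; the
entropy-based internode certainty (IC) scores how decisively the most
frequent conflictor is beaten, and ICA generalizes over all prevalent
conflictors.  Gene trees may be partial: a tree counts for a branch only if
the branch restricted to its leaves is still a nontrivial split.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy

from .seqio_core import leaf_labels, parse_newick

__all__ = [
    "Bipartition",
    "BranchCertainty",
    "CertaintyResult",
    "bipartitions",
    "internode_certainty",
    "nj_tree",
]


@dataclass(frozen=True)
class Bipartition:
    """An unrooted split of a leaf set; canonical orientation puts the
    lexicographically smallest label in side_a."""

    side_a: frozenset[str]
    side_b: frozenset[str]

    @classmethod
    def of(cls, one_side: Iterable[str], universe: Iterable[str]) -> "Bipartition":
        side = frozenset(one_side)
        other = frozenset(universe) - side
        return cls.canonical(side, other)

    @classmethod
    def canonical(cls, x: Iterable[str], y: Iterable[str]) -> "Bipartition":
        x, y = frozenset(x), frozenset(y)
        if not x or not y:
            raise ValueError("both sides of a bipartition must be non-empty")
        if x & y:
            raise ValueError("bipartition sides overlap")
        if min(x) > min(y):
            x, y = y, x
        return cls(x, y)

    @property
    def universe(self) -> frozenset[str]:
        return self.side_a | self.side_b

    @property
    def is_trivial(self) -> bool:
        return len(self.side_a) < 2 or len(self.side_b) < 2

    def restrict(self, leaves: frozenset[str]) -> "Bipartition | None":
        """The split induced on a leaf subset, or None when it collapses
        to a trivial split."""
        a = self.side_a & leaves
        b = self.side_b & leaves
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition.canonical(a, b)

    def conflicts_with(self, other: "Bipartition") -> bool:
        """Four-intersection incompatibility test; both splits must live
        on the same universe."""
        return all((
            self.side_a & other.side_a,
            self.side_a & other.side_b,
            self.side_b & other.side_a,
            self.side_b & other.side_b,
        ))

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.side_a)), tuple(sorted(self.side_b)))


def bipartitions(tree: dendropy.Tree) -> set[Bipartition]:
    """Nontrivial bipartitions, one per internal branch (unrooted view)."""
    universe = frozenset(leaf_labels(tree))
    if len(universe) < 4:
        return set()
    result: set[Bipartition] = set()
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset({node.taxon.label})
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
            if node.parent_node is None:
                continue
            side = below[node]
            if 2 <= len(side) <= len(universe) - 2:
                result.add(Bipartition.of(side, universe))
    return result


@dataclass(frozen=True)
class BranchCertainty:
    ic: float
    ica: float
    support_freq: float
    top_conflict_freq: float
    n_evaluable_trees: int


@dataclass
class CertaintyResult:
    per_branch: dict[Bipartition, BranchCertainty] = field(default_factory=dict)

    @property
    def tc(self) -> float:
        return sum(b.ic for b in self.per_branch.values())

    @property
    def relative_tc(self) -> float:
        n = len(self.per_branch)
        return self.tc / n if n else 0.0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("side_a\tic\tica\tsupport_freq\ttop_conflict_freq\tn_trees\n")
            for bip, res in sorted(
                self.per_branch.items(), key=lambda kv: kv[0].sort_key()
            ):
                fh.write(
                    f"{','.join(sorted(bip.side_a))}\t{res.ic:.6f}\t{res.ica:.6f}"
                    f"\t{res.support_freq:.6f}\t{res.top_conflict_freq:.6f}"
                    f"\t{res.n_evaluable_trees}\n"
                )
            fh.write(f"#TC\t{self.tc:.6f}\n")
            fh.write(f"#relative_TC\t{self.relative_tc:.6f}\n")


def _entropy_certainty(freqs: list[float], base: int) -> float:
    """1 + sum q log_base q over normalized frequencies (0 log 0 := 0)."""
    total = sum(freqs)
    value = 1.0
    for f in freqs:
        q = f / total
        if q > 0:
            value += q * math.log(q, base)
    return value


def internode_certainty(
    reference: dendropy.Tree,
    gene_trees: list[dendropy.Tree],
    ica_threshold: float = 0.05,
) -> CertaintyResult:
    """IC/ICA per reference branch and TC over the tree.

    Gene-tree leaf sets must be subsets of the reference leaf set.  For a
    branch, a gene tree is evaluable iff the branch restricted to the
    tree's leaves still splits >= 2 vs >= 2; frequencies are over
    evaluable trees.  IC is negative when the top conflictor is more
    frequent than the reference split.
    """
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    ref_leaves = frozenset(leaf_labels(reference))
    prepared = []
    for i, tree in enumerate(gene_trees):
        leaves = frozenset(leaf_labels(tree))
        extra = leaves - ref_leaves
        if extra:
            raise ValueError(
                f"gene tree {i} has leaves outside the reference: "
                f"{', '.join(sorted(extra))}"
            )
        prepared.append((leaves, bipartitions(tree)))

    result = CertaintyResult()
    for ref_bip in bipartitions(reference):
        n_eval = 0
        n_support = 0
        conflict_counts: Counter[Bipartition] = Counter()
        for leaves, bips in prepared:
            restricted = ref_bip.restrict(leaves)
            if restricted is None:
                continue
            n_eval += 1
            if restricted in bips:
                n_support += 1
            for bip in bips:
                if bip.conflicts_with(restricted):
                    conflict_counts[bip] += 1
        f_ref = n_support / n_eval if n_eval else 0.0
        if not conflict_counts:
            ic = ica = 1.0 if f_ref > 0 else 0.0
            result.per_branch[ref_bip] = BranchCertainty(ic, ica, f_ref, 0.0, n_eval)
            continue
        ranked = sorted(
            conflict_counts.items(),
            key=lambda kv: (-kv[1], kv[0].sort_key()),
        )
        f_top = ranked[0][1] / n_eval
        sign = -1.0 if f_top > f_ref else 1.0
        ic = sign * _entropy_certainty([f_ref, f_top], base=2)
        prevalent = [f_ref] + [
            count / n_eval for _, count in ranked
            if count / n_eval >= ica_threshold * max(f_ref, f_top)
        ]
        if len(prevalent) < 2:
            ica = ic
        else:
            ica = sign * _entropy_certainty(prevalent, base=len(prevalent))
        result.per_branch[ref_bip] = BranchCertainty(ic, ica, f_ref, f_top, n_eval)
    return result


# ---------------------------------------------------------------------------
# neighbor joining (test surrogate for externally inferred gene trees)


def nj_tree(d: Mapping[str, Mapping[str, float]]) -> dendropy.Tree:
    """Standard neighbor joining with deterministic lexicographic
    tie-breaking; returns an unrooted tree with branch lengths.

    ``d`` must be symmetric with a zero diagonal over >= 4 taxa; a missing
    entry raises ``ValueError``.
    """
    taxa = sorted(d)
    if len(taxa) < 4:
        raise ValueError("neighbor joining requires >= 4 taxa")
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(taxa):
        if not math.isclose(d[a].get(a, 0.0), 0.0, abs_tol=1e-12):
            raise ValueError(f"nonzero diagonal for {a}")
        for b in taxa[i + 1:]:
            try:
                ab, ba = d[a][b], d[b][a]
            except KeyError as exc:
                raise ValueError(f"undefined distance {a}-{b}") from exc
            if not math.isclose(ab, ba, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(f"asymmetric distance {a}-{b}")
            dist[(a, b)] = dist[(b, a)] = ab

    # each active cluster: newick fragment + lexicographic key for ties
    newick = {t: t for t in taxa}
    key = {t: t for t in taxa}
    active = list(taxa)

    def get(a, b):
        return dist[(a, b)]

    counter = 0
    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (r - 2) * get(a, b) - row_sum[a] - row_sum[b]
                tie = tuple(sorted((key[a], key[b])))
                if best is None or (q, tie) < (best[0], best[1]):
                    best = (q, tie, a, b)
        _, _, a, b = best
        la = 0.5 * get(a, b) + (row_sum[a] - row_sum[b]) / (2 * (r - 2))
        lb = get(a, b) - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = f"__nj{counter}"
        counter += 1
        newick[new] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
        key[new] = min(key[a], key[b])
        for c in active:
            if c in (a, b):
                continue
            dist[(new, c)] = dist[(c, new)] = 0.5 * (
                get(a, c) + get(b, c) - get(a, b)
            )
        active = [c for c in active if c not in (a, b)] + [new]

    a, b, c = sorted(active, key=lambda x: key[x])
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick_str = (
        f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g},{newick[c]}:{lc:.10g});"
    )
    return parse_newick(newick_str)
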