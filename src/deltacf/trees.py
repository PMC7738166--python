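"""Phylogenetic tree plumbing: newick I/O, restriction, splits, branch contexts.

Trees are thin wrappers around :mod:`dendropy` trees.  All taxon-name matching
throughout this package is **exact string equality** -- no case folding, no
whitespace or underscore normalisation.  Labels that differ in any character
are different taxa.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
from dendropy.utility import error as _dendropy_error

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "Bipartition",
    "BranchContext",
    "Tree",
    "parse_newick",
    "write_newick",
    "restrict",
    "bipartitions",
    "branch_contexts",
    "read_tree_list",
]


class NewickParseError(ValueError):
    """Raised when newick text cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


@dataclass(frozen=True)
class Bipartition:
    """An unrooted split of a taxon universe into two non-empty sides.

    Sides are stored as sorted tuples in canonical order: the side containing
    the lexicographically smallest label of the universe comes first.
    """

    side_a: tuple[str, ...]
    side_b: tuple[str, ...]

    @classmethod
    def from_sets(cls, x: Iterable[str], y: Iterable[str]) -> "Bipartition":
        xs, ys = sorted(set(x)), sorted(set(y))
        if not xs or not ys:
            raise TreeValidationError("bipartition sides must be non-empty")
        if set(xs) & set(ys):
            raise TreeValidationError("bipartition sides must be disjoint")
        if ys[0] < xs[0]:
            xs, ys = ys, xs
        return cls(tuple(xs), tuple(ys))

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.side_a) | frozenset(self.side_b)

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) < 2

    @property
    def smaller_side(self) -> tuple[str, ...]:
        a, b = self.side_a, self.side_b
        if len(a) != len(b):
            return a if len(a) < len(b) else b
        return min(a, b)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "{%s} | {%s}" % (",".join(self.side_a), ",".join(self.side_b))


def _branch_id_for(smaller_side: Sequence[str]) -> str:
    key = "|".join(sorted(smaller_side)).encode("utf-8")
    return hashlib.sha1(key).hexdigest()[:12]


@dataclass(frozen=True)
class BranchContext:
    """The four disjoint taxon groups around one internal species-tree branch.

    ``a`` and ``b`` are the two child clades below the branch's distal node;
    ``c`` and ``d`` partition the far side of the branch (for a non-root
    branch they are the sister clade and the remaining taxa; for the branch
    at the root they are the two child clades of the far root child).  Within
    each pair the group holding the smallest label comes first, which fixes
    the ALT1/ALT2 naming deterministically.  The
    branch's concordant (species-tree) split is ``(a|b) vs (c|d)``; the two
    alternative nearest-neighbour arrangements are ``(a|c) vs (b|d)`` (ALT1)
    and ``(a|d) vs (b|c)`` (ALT2).
    """

    branch_id: str
    a: frozenset[str]
    b: frozenset[str]
    c: frozenset[str]
    d: frozenset[str]

    def __post_init__(self) -> None:
        groups = [self.a, self.b, self.c, self.d]
        if any(not g for g in groups):
            raise TreeValidationError("all four context groups must be non-empty")
        total = sum(len(g) for g in groups)
        if total != len(self.a | self.b | self.c | self.d):
            raise TreeValidationError("context groups must be pairwise disjoint")

    @property
    def universe(self) -> frozenset[str]:
        return self.a | self.b | self.c | self.d

    @property
    def split(self) -> Bipartition:
        """The concordant species-tree split induced by this branch."""
        return Bipartition.from_sets(self.a | self.b, self.c | self.d)

    @property
    def clade(self) -> tuple[str, ...]:
        """Sorted labels of the smaller side of the concordant split."""
        return self.split.smaller_side


class Tree:
    """A leaf-labelled tree with optional branch lengths.

    Wraps a :class:`dendropy.Tree`.  Leaf labels are unique non-empty strings;
    branch lengths, when present, are non-negative.
    """

    __slots__ = ("_dt", "_leaves", "_clades")

    def __init__(self, dtree: dendropy.Tree):
        self._dt = dtree
        self._leaves: frozenset[str] | None = None
        self._clades: tuple[frozenset[str], ...] | None = None
        self._validate()

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        text = text.strip()
        if not text.endswith(";"):
            raise NewickParseError("newick string must end with ';'")
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except _dendropy_error.DataParseError as exc:
            if "Multiple occurrences of the same taxa" in str(exc):
                raise TreeValidationError(f"duplicate leaf labels: {exc}") from exc
            raise NewickParseError(f"malformed newick: {exc}") from exc
        return cls(dt)

    def to_newick(self) -> str:
        s = self._dt.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip()

    # ------------------------------------------------------------ structure
    def _validate(self) -> None:
        labels = []
        for leaf in self._dt.leaf_node_iter():
            lab = None if leaf.taxon is None else leaf.taxon.label
            if not lab:
                raise TreeValidationError("every leaf must carry a non-empty label")
            labels.append(lab)
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise TreeValidationError(f"duplicate leaf labels: {', '.join(dupes)}")
        for edge in self._dt.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeValidationError("branch lengths must be >= 0")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dt

    @property
    def leaves(self) -> frozenset[str]:
        if self._leaves is None:
            self._leaves = frozenset(
                leaf.taxon.label for leaf in self._dt.leaf_node_iter()
            )
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def is_binary_rooted(self) -> bool:
        """True iff every internal node (including the root) has exactly 2 children."""
        for node in self._dt.preorder_node_iter():
            if not node.is_leaf() and len(node.child_nodes()) != 2:
                return False
        return True

    def leaf_sets_below(self) -> dict:
        """Map each node to the frozenset of leaf labels below it (postorder)."""
        below: dict = {}
        for node in self._dt.postorder_node_iter():
            if node.is_leaf():
                below[node] = frozenset([node.taxon.label])
            else:
                acc: frozenset[str] = frozenset()
                for ch in node.child_nodes():
                    acc |= below[ch]
                below[node] = acc
        return below

    def clade_sets(self) -> tuple[frozenset[str], ...]:
        """Leaf-label sets below every non-root internal edge (with duplicates
        across the root edge possible); substrate for split membership tests."""
        if self._clades is None:
            below = self.leaf_sets_below()
            out = []
            for node in self._dt.preorder_node_iter():
                if node.parent_node is None or node.is_leaf():
                    continue
                out.append(below[node])
            self._clades = tuple(out)
        return self._clades

    # ---------------------------------------------------------- operations
    def restrict(self, keep: Iterable[str]) -> "Tree":
        keep = set(keep)
        missing = sorted(keep - self.leaves)
        if missing:
            raise TreeValidationError(
                f"labels not present in tree: {', '.join(missing)}"
            )
        if len(keep) < 2:
            raise TreeValidationError("restriction requires at least 2 taxa")
        sub = self._dt.extract_tree_with_taxa_labels(
            labels=keep, suppress_unifurcations=True
        )
        return Tree(sub)

    def copy(self) -> "Tree":
        return Tree(self._dt.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Tree(n_leaves={self.n_leaves})"


# ---------------------------------------------------------------------------
# Module-level operation surface
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> Tree:
    """Parse a single newick tree; see :meth:`Tree.from_newick`."""
    return Tree.from_newick(text)


def write_newick(tree: Tree) -> str:
    return tree.to_newick()


def restrict(tree: Tree, keep: Iterable[str]) -> Tree:
    """Induced subtree on ``keep``; suppressed degree-2 nodes sum their lengths."""
    return tree.restrict(keep)


def bipartitions(tree: Tree) -> frozenset[Bipartition]:
    """All non-trivial unrooted splits of ``tree`` (root edge counted once).

    Trees with fewer than 4 leaves induce no non-trivial splits and yield an
    empty set.
    """
    universe = tree.leaves
    if len(universe) < 4:
        return frozenset()
    out = set()
    for below in tree.clade_sets():
        rest = universe - below
        if len(below) >= 2 and len(rest) >= 2:
            out.add(Bipartition.from_sets(below, rest))
    return frozenset(out)


def branch_contexts(species_tree: Tree) -> list[BranchContext]:
    """One four-group context per internal branch of a rooted binary species tree.

    The two branches incident to the root induce the same unrooted split and
    contribute a single context; for that context the groups C and D are the
    two child clades on the far side of the root.  Branch ids are derived from
    the sorted smaller side of the split and are therefore stable across runs
    and across re-parsing of the same topology.
    """
    if species_tree.n_leaves < 4:
        raise TreeValidationError("branch contexts require >= 4 leaves")
    if not species_tree.is_binary_rooted():
        raise TreeValidationError(
            "species tree must be rooted and strictly binary (no polytomies)"
        )
    dt = species_tree.dendropy_tree
    universe = species_tree.leaves
    below = species_tree.leaf_sets_below()
    contexts: list[BranchContext] = []
    seen: set[frozenset[str]] = set()

    for node in dt.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        parent = node.parent_node
        kids = node.child_nodes()
        node_below = below[node]
        if parent.parent_node is None:
            # Root-incident edge: emit the root split once, with A,B taken from
            # the root child whose clade holds the globally smallest label.
            sib = next(ch for ch in parent.child_nodes() if ch is not node)
            if sib.is_leaf():
                continue  # unrooted split {leaf}|rest is trivial
            near, far = node, sib
            if min(below[sib]) < min(node_below):
                near, far = sib, near
            a_set, b_set = (below[ch] for ch in near.child_nodes())
            c_set, d_set = (below[ch] for ch in far.child_nodes())
            split_key = frozenset(below[near])
        else:
            sib = next(ch for ch in parent.child_nodes() if ch is not node)
            a_set, b_set = (below[ch] for ch in kids)
            c_set = below[sib]
            d_set = universe - node_below - c_set
            if not d_set:
                continue
            split_key = frozenset(node_below)
        canon = min(split_key, universe - split_key, key=lambda s: (len(s), sorted(s)))
        if canon in seen:
            continue
        seen.add(canon)
        if min(b_set) < min(a_set):
            a_set, b_set = b_set, a_set
        if min(d_set) < min(c_set):
            c_set, d_set = d_set, c_set
        contexts.append(
            BranchContext(
                branch_id=_branch_id_for(sorted(canon)),
                a=frozenset(a_set),
                b=frozenset(b_set),
                c=frozenset(c_set),
                d=frozenset(d_set),
            )
        )
    return contexts


def read_tree_list(path) -> list[Tree]:
    """Read a newick tree-set file: one tree per line (blank lines skipped)."""
    trees = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                trees.append(Tree.from_newick(line))
            except (NewickParseError, TreeValidationError) as exc:
                raise NewickParseError(f"{path}, line {i}: {exc}") from exc
    return trees
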