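"""Rooted phylogenies with integer branch marks.

The :class:`Phylogeny` wraps a simple node structure tailored to what the
selection pipeline needs: restriction (pruning) to a taxon subset with
branch-length preservation, unrooted bipartition queries for monophyly
checks, and integer marks on branches designating foreground clades.
Newick parsing is delegated to dendropy; writing is done locally so the
PAML mark dialects (``#k`` / ``$k``) can be emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


class TreeError(ValueError):
    """Malformed or inconsistent tree input."""


@dataclass
class Node:
    label: str | None = None
    length: float | None = None
    mark: int = 0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        n = Node(self.label, self.length, self.mark)
        n.children = [c.copy() for c in self.children]
        return n


def _sum_lengths(a: float | None, b: float | None) -> float | None:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


class Phylogeny:
    """A rooted tree; leaf labels are taxon names, marks default to 0."""

    def __init__(self, root: Node):
        self.root = root
        labels = [leaf.label for leaf in self.leaves()]
        if any(lab is None for lab in labels):
            raise TreeError("unlabeled leaf")
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")

    # ------------------------------------------------------------------
    # construction / serialization
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises schema-specific errors
            raise TreeError(f"newick parse failure: {exc}") from exc
        n_leaves = sum(1 for _ in tree.leaf_node_iter())
        labels = {lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon}
        if len(labels) != n_leaves:
            raise TreeError("duplicate leaf labels")

        def convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon else (dnode.label or None)
            node = Node(label=label, length=dnode.edge.length)
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        return cls(convert(tree.seed_node))

    @classmethod
    def from_newick_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            text = fh.read().strip()
        if not text:
            raise TreeError(f"empty tree file: {path}")
        return cls.from_newick(text)

    def to_newick(self, lengths: bool = True, mark_style: str | None = None) -> str:
        """Serialize to Newick.

        ``mark_style`` is ``None`` (no marks), ``"#"`` (PAML branch marks on
        every marked node) or ``"$"`` (PAML clade mark: emitted only at the
        rootmost marked node, marking the whole subtree).
        """

        def mark_suffix(node: Node, parent_marked: bool) -> str:
            if not mark_style or node.mark == 0:
                return ""
            if mark_style == "$" and parent_marked:
                return ""
            return f" {mark_style}{node.mark}"

        def render(node: Node, parent_marked: bool = False) -> str:
            marked = node.mark != 0
            if node.is_leaf:
                out = node.label or ""
            else:
                inner = ",".join(render(c, marked) for c in node.children)
                out = f"({inner})" + (node.label or "")
            out += mark_suffix(node, parent_marked)
            if lengths and node.length is not None:
                out += f":{node.length:.6g}"
            return out

        return render(self.root) + ";"

    def write(self, path, **kwargs) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write(self.to_newick(**kwargs) + "\n")

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.root.copy())

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    def leaves(self) -> list[Node]:
        out = []

        def walk(n: Node):
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(leaf.label for leaf in self.leaves())

    def postorder(self) -> list[Node]:
        out = []

        def walk(n: Node):
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial unrooted bipartitions, each as its canonical side.

        The canonical side is the one containing the lexicographically
        smallest taxon.  Trivial splits (single leaf / whole set) excluded.
        """
        all_taxa = self.taxa
        anchor = min(all_taxa)
        out: set[frozenset[str]] = set()

        def below(n: Node) -> frozenset[str]:
            if n.is_leaf:
                return frozenset([n.label])
            side = frozenset().union(*(below(c) for c in n.children))
            if 1 < len(side) < len(all_taxa) - 1:
                out.add(side if anchor in side else all_taxa - side)
            return side

        below(self.root)
        return out

    def is_monophyletic(self, taxa: set[str]) -> bool:
        """True if ``taxa`` form one side of an unrooted bipartition.

        Singletons and the full leaf set are monophyletic by convention.
        """
        present = frozenset(taxa) & self.taxa
        if not present:
            raise TreeError("no queried taxon present in tree")
        if len(present) == 1 or present == self.taxa:
            return True
        if len(present) == len(self.taxa) - 1:
            return True  # complement of a single leaf: always a split
        canon = present if min(self.taxa) in present else self.taxa - present
        return canon in self.bipartitions()

    def mrca(self, taxa: set[str]) -> Node:
        target = frozenset(taxa) & self.taxa
        if not target:
            raise TreeError("no queried taxon present in tree")

        # the deepest node whose leaf set contains all targets
        def deepest(n: Node) -> Node | None:
            for c in n.children:
                hit = deepest(c)
                if hit is not None:
                    return hit
            leafset = frozenset(lf.label for lf in _leaves_of(n))
            return n if target <= leafset else None

        hit = deepest(self.root)
        if hit is None:
            raise TreeError("no common ancestor found")
        return hit

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""

        def trace(n: Node, label: str, acc: list[Node]) -> bool:
            acc.append(n)
            if n.is_leaf and n.label == label:
                return True
            for c in n.children:
                if trace(c, label, acc):
                    return True
            acc.pop()
            return False

        pa: list[Node] = []
        pb: list[Node] = []
        if not (trace(self.root, a, pa) and trace(self.root, b, pb)):
            raise TreeError("leaf not found")
        k = 0
        while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
            k += 1
        return sum((n.length or 0.0) for n in pa[k:]) + sum((n.length or 0.0) for n in pb[k:])

    # ------------------------------------------------------------------
    # restriction (pruning)
    # ------------------------------------------------------------------
    def pruned_to(self, taxa: set[str]) -> "Phylogeny":
        """Restriction of the tree to ``taxa``.

        Unsampled leaves are removed, degree-2 nodes suppressed with their
        incident branch lengths summed, so every leaf-to-leaf path length
        among surviving taxa is preserved.
        """
        taxa = set(taxa)
        missing = taxa - self.taxa
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        if len(taxa) < 2:
            raise TreeError("pruning requires at least 2 taxa")

        def restrict(node: Node) -> Node | None:
            if node.is_leaf:
                return Node(node.label, node.length, node.mark) if node.label in taxa else None
            kept = [r for r in (restrict(c) for c in node.children) if r is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                child.length = _sum_lengths(child.length, node.length)
                return child
            new = Node(node.label, node.length, node.mark)
            new.children = kept
            return new

        root = restrict(self.root)
        assert root is not None
        if len(root.children) == 1:  # pendant root edge carries no signal
            root = root.children[0]
            root.length = None
        return Phylogeny(root)


def _leaves_of(node: Node) -> list[Node]:
    if node.is_leaf:
        return [node]
    out = []
    for c in node.children:
        out.extend(_leaves_of(c))
    return out
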