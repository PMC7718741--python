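"""Gene admission rules, per-gene tree pruning, foreground marking.

A gene enters the analysis only if it has no duplicated taxa and meets the
minimum foreground/background sequence counts (both default 0).  The
species tree is then restricted to the taxa present in the alignment and
the tested clade's branches are marked as foreground.  An optional
gene-tree check (neighbor joining on nucleotide p-distances) flags genes
whose foreground clade is not monophyletic in the gene tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .io import BranchLabelMap, CodonAlignment
from .trees import Node, Phylogeny, TreeError

FLAG_REASONS = (
    "duplicate_taxon",
    "below_min_foreground",
    "below_min_background",
    "foreground_not_monophyletic_species_tree",
    "foreground_not_monophyletic_gene_tree",
    "no_foreground_taxon",
    "read_error",
    "fit_error",
)


@dataclass(frozen=True)
class FilterPolicy:
    """Minimum sequence counts a gene must reach to be analyzed."""

    min_foreground: int = 0
    min_background: int = 0


@dataclass(frozen=True)
class GeneFlag:
    gene_id: str
    reason: str
    detail: str = ""

    def __post_init__(self):
        if self.reason not in FLAG_REASONS:
            raise ValueError(f"unknown flag reason {self.reason!r}")


def admit(
    alignment: CodonAlignment,
    labels: BranchLabelMap,
    clade_id: int | None,
    policy: FilterPolicy,
) -> GeneFlag | None:
    """Apply the admission rules; returns None if admitted, else the flag.

    Foreground count is the number of alignment taxa labeled with the
    tested clade id; every other taxon counts as background.  With
    ``clade_id=None`` (site model, no specific tested clade) any taxon
    with a positive label counts as foreground.
    """
    if clade_id is None:
        n_fg = sum(1 for t in alignment.taxa if labels.clade_of(t) >= 1)
    else:
        n_fg = sum(1 for t in alignment.taxa if labels.clade_of(t) == clade_id)
    n_bg = alignment.n_taxa - n_fg
    if n_fg < policy.min_foreground:
        return GeneFlag(
            alignment.gene_id,
            "below_min_foreground",
            f"{n_fg} < {policy.min_foreground}",
        )
    if n_bg < policy.min_background:
        return GeneFlag(
            alignment.gene_id,
            "below_min_background",
            f"{n_bg} < {policy.min_background}",
        )
    return None


def prune_to_alignment(tree: Phylogeny, taxa) -> Phylogeny:
    """Restrict the species tree to the taxa present in an alignment."""
    return tree.pruned_to(set(taxa))


def mark_foreground(
    tree: Phylogeny,
    labels: BranchLabelMap,
    clade_id: int,
    scope: str = "clade",
) -> tuple[Phylogeny | None, bool]:
    """Mark the tested clade's branches on a copy of the tree.

    Returns ``(marked_tree, monophyletic)``.  With ``scope="clade"`` the
    stem branch and every branch inside the clade get the mark; with
    ``scope="stem"`` only the stem branch.  If the clade's taxa present in
    the tree are not monophyletic the tree is not marked and the verdict
    is False (the caller skips the gene).
    """
    if scope not in ("clade", "stem"):
        raise ValueError(f"unknown foreground scope {scope!r}")
    fg = labels.taxa_in_clade(clade_id) & tree.taxa
    if not fg:
        raise TreeError(f"no foreground taxon of clade {clade_id} in tree")
    if not tree.is_monophyletic(fg):
        return None, False
    marked = tree.copy()
    mrca = marked.mrca(fg)

    def paint(node: Node):
        node.mark = clade_id
        if scope == "clade":
            for c in node.children:
                paint(c)

    paint(mrca)
    return marked, True


def select_complete_orthologs(alignments, species) -> list[str]:
    """Gene ids whose taxon set equals the full species set exactly."""
    species = frozenset(species)
    return [a.gene_id for a in alignments if frozenset(a.taxa) == species]


def _pairwise_p_distance(seq_a: np.ndarray, seq_b: np.ndarray) -> float:
    """Nucleotide p-distance, positions with missing data excluded pairwise."""
    ok = (seq_a >= 0) & (seq_b >= 0)
    n = int(ok.sum())
    if n == 0:
        return 0.0
    return float((seq_a[ok] != seq_b[ok]).sum() / n)


_NUC_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _nucleotide_rows(alignment: CodonAlignment) -> dict[str, np.ndarray]:
    rows = {}
    for taxon in alignment.taxa:
        seq = "".join(alignment.row(taxon))
        rows[taxon] = np.array([_NUC_CODE.get(ch, -1) for ch in seq], dtype=np.int8)
    return rows


def build_gene_tree(alignment: CodonAlignment) -> Phylogeny:
    """Neighbor-joining gene tree from pairwise nucleotide p-distances.

    Taxa are processed in sorted order, so the result is deterministic for
    a given alignment.  All-identical sequences produce a star tree with
    zero branch lengths.
    """
    if alignment.n_taxa < 3:
        raise ValueError("gene tree requires at least 3 taxa")
    taxa = sorted(alignment.taxa)
    rows = _nucleotide_rows(alignment)
    n = len(taxa)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _pairwise_p_distance(rows[taxa[i]], rows[taxa[j]])
    if not dm.any():
        root = Node()
        root.children = [Node(t, 0.0) for t in taxa]
        return Phylogeny(root)
    tree = nj(DistanceMatrix(dm, ids=taxa))
    return Phylogeny.from_newick(str(tree))


def check_monophyly(gene_tree: Phylogeny, foreground_taxa) -> bool:
    """Is the foreground a clade (one side of a bipartition) of the gene tree?"""
    return gene_tree.is_monophyletic(set(foreground_taxa))
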