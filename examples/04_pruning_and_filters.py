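"""Species-tree pruning, admission filters, and monophyly checks.

A gene missing some taxa is analyzed on the species tree restricted to
the taxa it contains; branch lengths along suppressed paths are summed so
leaf-to-leaf distances are unchanged.  The admission filter rejects genes
with too few foreground/background sequences, and the gene-tree check
flags foreground clades that the alignment itself does not support.
"""

from omegascan import (
    BranchLabelMap,
    CodonAlignment,
    FilterPolicy,
    admit,
    build_gene_tree,
    check_monophyly,
    prune_to_alignment,
)
from omegascan.trees import Phylogeny

tree = Phylogeny.from_newick("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
print("species tree taxa:", sorted(tree.taxa))

pruned = prune_to_alignment(tree, {"A", "C", "D"})
print("pruned to {A,C,D}: ", pruned.to_newick())
print(f"A-C path length preserved: {tree.path_length('A','C')} == "
      f"{pruned.path_length('A','C')}")

labels = BranchLabelMap({"A": 1, "B": 1})
small = CodonAlignment("gene1", ("A", "C"), [["ATG"], ["ATG"]])
flag = admit(small, labels, 1, FilterPolicy(min_foreground=2, min_background=1))
print(f"gene1 with 1 foreground sequence: rejected ({flag.reason})")

# gene tree pairing A with C: the (A,B) foreground is not monophyletic here
rows = {
    "A": ["GTA"] * 10 + ["ATG"] * 20,
    "C": ["GTA"] * 10 + ["ATG"] * 20,
    "B": ["ATG"] * 10 + ["CTC"] * 10 + ["ATG"] * 10,
    "D": ["ATG"] * 10 + ["CTC"] * 10 + ["ATG"] * 10,
}
aln = CodonAlignment("gene2", tuple(rows), [rows[t] for t in rows])
gtree = build_gene_tree(aln)
print("gene tree:", gtree.to_newick(lengths=False))
print("foreground {A,B} monophyletic in gene tree:",
      check_monophyly(gtree, {"A", "B"}), "-> gene would be flagged")
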