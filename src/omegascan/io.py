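"""Input readers: codon alignments, species trees, branch-label files.

Sequence names in ortholog FASTA files rarely equal the tree taxon labels
exactly; they are resolved by requiring the taxon label to occur as a
substring of the record name, uniquely.  Exact equality counts as an
occurrence, so identity naming always resolves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .codons import MISSING_CHARS, STOP_CODONS, codon_state
from .trees import Phylogeny

log = logging.getLogger(__name__)

_VALID_CHARS = frozenset("ACGTN-")


class AlignmentError(ValueError):
    """Malformed codon alignment."""


class FrameError(AlignmentError):
    """Sequence length not divisible by 3."""


class NameResolutionError(AlignmentError):
    """FASTA record name matches zero or several tree taxa."""


class DuplicateTaxonError(AlignmentError):
    """Two records in one file resolve to the same taxon.

    Genome-wide runs report the gene and continue; this is not fatal.
    """


class BranchLabelError(ValueError):
    """Malformed branch-label file."""


@dataclass
class CodonAlignment:
    """One ortholog group's aligned codon sequences, keyed by taxon."""

    gene_id: str
    taxa: tuple[str, ...]
    codons: list[list[str]]  # one row per taxon, one 3-char cell per site

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise DuplicateTaxonError(f"{self.gene_id}: duplicate taxa")
        lengths = {len(row) for row in self.codons}
        if len(lengths) > 1:
            raise AlignmentError(f"{self.gene_id}: ragged alignment")
        for taxon, row in zip(self.taxa, self.codons):
            for i, cell in enumerate(row):
                if len(cell) != 3 or not set(cell) <= _VALID_CHARS:
                    raise AlignmentError(
                        f"{self.gene_id}/{taxon}: invalid codon {cell!r} at site {i + 1}"
                    )
                if cell in STOP_CODONS:
                    raise AlignmentError(
                        f"{self.gene_id}/{taxon}: stop codon {cell} at site {i + 1}"
                    )

    @property
    def n_sites(self) -> int:
        return len(self.codons[0]) if self.codons else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> list[str]:
        return self.codons[self.taxa.index(taxon)]

    def states(self) -> np.ndarray:
        """(n_taxa, n_sites) integer codon states; -1 marks missing data."""
        return np.array(
            [[codon_state(c) for c in row] for row in self.codons], dtype=np.int64
        )

    def subset(self, taxa) -> "CodonAlignment":
        keep = [t for t in self.taxa if t in set(taxa)]
        return CodonAlignment(
            self.gene_id, tuple(keep), [list(self.row(t)) for t in keep]
        )


@dataclass
class BranchLabelMap:
    """Taxon -> integer clade id; 0 is background, >=1 are foreground clades."""

    labels: dict[str, int] = field(default_factory=dict)

    def clade_of(self, taxon: str) -> int:
        return self.labels.get(taxon, 0)

    def foreground_clades(self) -> list[int]:
        return sorted({v for v in self.labels.values() if v >= 1})

    def taxa_in_clade(self, clade_id: int) -> set[str]:
        return {t for t, v in self.labels.items() if v == clade_id}


def split_codons(sequence: str) -> list[str]:
    seq = sequence.upper()
    if len(seq) % 3 != 0:
        raise FrameError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def resolve_name(record_name: str, tree_taxa) -> str:
    """Resolve a FASTA record name to the unique taxon it contains."""
    hits = sorted(t for t in tree_taxa if t in record_name)
    if len(hits) != 1:
        raise NameResolutionError(
            f"record {record_name!r} matches {len(hits)} tree taxa: {hits}"
        )
    return hits[0]


def read_codon_fasta(path, tree_taxa, gene_id: str | None = None) -> CodonAlignment:
    """Read one ortholog group's codon alignment from FASTA.

    Each record name must contain exactly one tree taxon label as a
    substring; the alignment is keyed by the resolved taxa.  Raises
    :class:`FrameError`, :class:`NameResolutionError`,
    :class:`DuplicateTaxonError` or :class:`AlignmentError`.
    """
    tree_taxa = set(tree_taxa)
    if not tree_taxa:
        raise ValueError("tree_taxa must be nonempty")
    if gene_id is None:
        gene_id = _stem(path)
    taxa: list[str] = []
    rows: list[list[str]] = []
    for record in SeqIO.parse(str(path), "fasta"):
        taxon = resolve_name(record.id, tree_taxa)
        if taxon in taxa:
            raise DuplicateTaxonError(f"{gene_id}: two records resolve to {taxon}")
        taxa.append(taxon)
        try:
            rows.append(split_codons(str(record.seq)))
        except FrameError as exc:
            raise FrameError(f"{gene_id}/{record.id}: {exc}") from None
    if not taxa:
        raise AlignmentError(f"{gene_id}: no FASTA records")
    return CodonAlignment(gene_id, tuple(taxa), rows)


def read_newick(path) -> Phylogeny:
    """Read a species topology; unrooted input keeps its first basal node."""
    tree = Phylogeny.from_newick_file(path)
    if len(tree.root.children) > 2:
        log.info(
            "tree %s is unrooted (basal %sfurcation); rooted at its first "
            "internal node",
            path,
            len(tree.root.children),
        )
    return tree


def write_newick(tree: Phylogeny, path, **kwargs) -> None:
    tree.write(path, **kwargs)


def read_branch_labels(path, tree: Phylogeny) -> BranchLabelMap:
    """Read ``taxon <int>`` lines (whitespace or comma separated, # comments).

    Taxa absent from the file default to clade 0 (background).
    """
    taxa = tree.taxa
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise BranchLabelError(f"{path}:{lineno}: expected 'taxon integer'")
            taxon, token = parts
            if taxon not in taxa:
                raise BranchLabelError(f"{path}:{lineno}: unknown taxon {taxon!r}")
            try:
                clade = int(token)
            except ValueError:
                raise BranchLabelError(
                    f"{path}:{lineno}: non-integer clade id {token!r}"
                ) from None
            if clade < 0:
                raise BranchLabelError(f"{path}:{lineno}: negative clade id {clade}")
            labels[taxon] = clade
    for taxon in taxa:
        labels.setdefault(taxon, 0)
    return BranchLabelMap(labels)


def _stem(path) -> str:
    import os

    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0] if "." in base else base
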