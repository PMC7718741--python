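"""Genetic-code tables and codon equilibrium frequencies.

Everything here is restricted to the universal (standard) genetic code,
whose 61 sense codons are the state space of the substitution models.
The tables are built once at import time from Biopython's codon table.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_NUCS = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_TABLE.stop_codons)

#: The 61 sense codons of the universal code, lexicographic in A<C<G<T.
CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in _NUCS
    for b in _NUCS
    for c in _NUCS
    if a + b + c not in STOP_CODONS
)
N_CODONS = len(CODONS)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: Amino acid (one-letter) encoded by each sense codon.
AMINO_ACIDS: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in CODONS)

_PURINES = {"A", "G"}


def _is_transition(x: str, y: str) -> bool:
    return x != y and ((x in _PURINES) == (y in _PURINES))


def _build_pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    ti = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            ti[i, j] = _is_transition(*diffs[0])
            nonsyn[i, j] = AMINO_ACIDS[i] != AMINO_ACIDS[j]
    return single, ti, nonsyn


#: Boolean (61, 61) tables over ordered codon pairs differing at one site.
SINGLE_STEP, IS_TRANSITION, IS_NONSYNONYMOUS = _build_pair_tables()

#: Codons treated as missing data (any gap or ambiguity character).
MISSING_CHARS = frozenset("-N")


def codon_state(codon: str) -> int:
    """Map a codon string to its state index, or -1 for missing data.

    A codon containing ``-`` or ``N`` anywhere is treated as entirely
    missing for that taxon at that site (the partial-likelihood vector
    becomes all ones), mirroring a cleandata=0 style of gap handling.
    """
    if any(ch in MISSING_CHARS for ch in codon):
        return -1
    try:
        return CODON_INDEX[codon]
    except KeyError:
        raise ValueError(f"not a sense codon: {codon!r}") from None


def uniform_frequencies() -> np.ndarray:
    """Uniform equilibrium frequencies over the 61 sense codons."""
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(codon_rows: list[list[str]], floor: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies from an alignment.

    Nucleotide frequencies are counted separately at the three codon
    positions (gaps and ambiguities skipped), the per-position products
    are formed for the 61 sense codons and renormalized.  ``floor`` is a
    small pseudo-frequency guarding against unobserved nucleotides, which
    would otherwise produce structurally zero equilibrium frequencies.
    """
    counts = np.zeros((3, 4))
    nuc_index = {n: k for k, n in enumerate(_NUCS)}
    for row in codon_rows:
        for codon in row:
            for pos, ch in enumerate(codon):
                k = nuc_index.get(ch)
                if k is not None:
                    counts[pos, k] += 1
    freqs = counts + floor * counts.sum(axis=1, keepdims=True).clip(min=1.0)
    freqs /= freqs.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, nuc_index[c[0]]] * freqs[1, nuc_index[c[1]]] * freqs[2, nuc_index[c[2]]] for c in CODONS]
    )
    return pi / pi.sum()
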