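"""Genetic-code tables and codon-level structural matrices.

Everything downstream (rate matrices, Nei–Gojobori counting, 4-fold
degenerate site extraction) is driven by a :class:`GeneticCode`, which is
built from Biopython's NCBI translation tables.  The standard code
(table 1) is the default; any unambiguous-DNA NCBI table id works.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
ALL_CODONS = ["".join(c) for c in product(NUCLEOTIDES, repeat=3)]

#: purine/pyrimidine partners: a substitution within a pair is a transition
_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


def is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITION_PAIRS


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code plus precomputed 61x61 structural matrices.

    Attributes
    ----------
    table_id:
        NCBI translation table id (1 = standard).
    codons:
        Sense codons in fixed TCAG order; indices into this list are the
        codon states used throughout the package.
    stops:
        Stop codons of the code.
    """

    table_id: int
    codons: tuple[str, ...]
    stops: frozenset[str]
    aa: tuple[str, ...]
    codon_index: dict[str, int] = field(repr=False)
    # pairwise structure over sense codons
    ndiff: np.ndarray = field(repr=False)      # (61,61) int8, # differing positions
    is_syn: np.ndarray = field(repr=False)     # (61,61) bool, same amino acid
    is_ts: np.ndarray = field(repr=False)      # (61,61) bool, single-diff transition

    def __post_init__(self):
        sense = set(self.codons)
        if sense & self.stops or len(sense) + len(self.stops) != 64:
            raise ValueError("sense and stop codons must partition the 64 codons")

    @property
    def n_sense(self) -> int:
        return len(self.codons)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def translate(self, codon: str) -> str:
        return self.aa[self.codon_index[codon]]

    def fourfold_family(self, codon: str) -> bool:
        """True if all four third-position variants of ``codon`` encode the
        same amino acid (and none is a stop)."""
        prefix = codon[:2]
        aas = set()
        for n in NUCLEOTIDES:
            c = prefix + n
            if c in self.stops:
                return False
            aas.add(self.translate(c))
        return len(aas) == 1

    def encode(self, codon: str) -> int:
        """Sense-codon index, or a negative sentinel.

        Returns -1 for a gap codon (any '-'), -2 for an ambiguous codon
        (non-ACGT character), -3 for a stop codon.
        """
        codon = codon.upper().replace("U", "T")
        if "-" in codon:
            return GAP
        if any(c not in "ACGT" for c in codon):
            return AMBIG
        if codon in self.stops:
            return STOP
        return self.codon_index[codon]


GAP = -1
AMBIG = -2
STOP = -3


@lru_cache(maxsize=None)
def get_code(table_id: int = 1) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = frozenset(table.stop_codons)
    codons = tuple(c for c in ALL_CODONS if c not in stops)
    aa = tuple(table.forward_table[c] for c in codons)
    idx = {c: i for i, c in enumerate(codons)}
    n = len(codons)
    ndiff = np.zeros((n, n), dtype=np.int8)
    is_syn = np.zeros((n, n), dtype=bool)
    is_ts = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            ndiff[i, j] = len(diffs)
            is_syn[i, j] = aa[i] == aa[j]
            if len(diffs) == 1:
                k = diffs[0]
                is_ts[i, j] = is_transition(ci[k], cj[k])
    return GeneticCode(
        table_id=table_id,
        codons=codons,
        stops=stops,
        aa=aa,
        codon_index=idx,
        ndiff=ndiff,
        is_syn=is_syn,
        is_ts=is_ts,
    )


STANDARD_CODE = get_code(1)
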