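"""Codon alignments: container, FASTA I/O, QC filters, 4D-site extraction.

A :class:`CodonAlignment` stores one codon-aware multiple sequence
alignment as an integer state matrix (sense-codon index, or a negative
sentinel for gap / ambiguous / stop codons).  The QC contract used by the
rest of the pipeline is whole-column deletion: after
:func:`remove_ambiguous_columns` every remaining column contains only
sense codons in every taxon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import AMBIG, GAP, STOP, GeneticCode, STANDARD_CODE

log = logging.getLogger(__name__)


@dataclass
class CodonAlignment:
    """Aligned codon sequences for one gene across taxa.

    ``states[i, j]`` is the codon state of taxon ``i`` at codon column
    ``j``: an index into ``code.codons`` or one of the sentinels
    ``GAP`` (-1), ``AMBIG`` (-2), ``STOP`` (-3).  ``raw`` optionally keeps
    the original codon strings so that pre-QC alignments round-trip
    through FASTA exactly.
    """

    taxa: list[str]
    states: np.ndarray  # (ntaxa, ncodons) int16
    gene_id: str = ""
    code: GeneticCode = STANDARD_CODE
    raw: list[str] | None = field(default=None, repr=False)
    #: original (0-based) codon-column indices removed by QC, if any
    removed_columns: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int16)
        if self.states.ndim != 2 or self.states.shape[0] != len(self.taxa):
            raise ValueError("states must be (ntaxa, ncodons)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"duplicate taxon names in {self.gene_id!r}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return self.states.shape[1]

    @property
    def is_clean(self) -> bool:
        """True if every entry is a sense codon."""
        return bool((self.states >= 0).all())

    def sequence(self, taxon: str) -> str:
        """Nucleotide sequence of one taxon, reconstructed from states."""
        i = self.taxa.index(taxon)
        if self.raw is not None:
            return self.raw[i]
        return "".join(self._codon_str(s) for s in self.states[i])

    def _codon_str(self, state: int) -> str:
        if state >= 0:
            return self.code.codons[state]
        if state == GAP:
            return "---"
        return "NNN"  # ambiguous; stops keep identity only via raw

    @classmethod
    def from_sequences(
        cls,
        taxa: list[str],
        seqs: list[str],
        gene_id: str = "",
        code: GeneticCode = STANDARD_CODE,
    ) -> "CodonAlignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in {gene_id!r}: {sorted(lengths)}")
        (nt_len,) = lengths
        if nt_len % 3 != 0:
            raise ValueError(f"alignment length {nt_len} of {gene_id!r} not divisible by 3")
        ncod = nt_len // 3
        states = np.empty((len(taxa), ncod), dtype=np.int16)
        for i, s in enumerate(seqs):
            s = s.upper().replace("U", "T")
            for j in range(ncod):
                states[i, j] = code.encode(s[3 * j : 3 * j + 3])
        return cls(taxa=list(taxa), states=states, gene_id=gene_id, code=code,
                   raw=[s.upper().replace("U", "T") for s in seqs])


def read_codon_fasta(path, gene_id: str | None = None,
                     code: GeneticCode = STANDARD_CODE) -> CodonAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    if gene_id is None:
        import os
        gene_id = os.path.splitext(os.path.basename(str(path)))[0]
    return CodonAlignment.from_sequences(
        [r.id for r in records], [str(r.seq) for r in records], gene_id, code
    )


def write_codon_fasta(aln: CodonAlignment, path) -> None:
    """Write the alignment as FASTA wrapped at 60 nt, taxon names verbatim."""
    records = [
        SeqRecord(Seq(aln.sequence(t)), id=t, description="") for t in aln.taxa
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def remove_ambiguous_columns(aln: CodonAlignment) -> CodonAlignment:
    """Drop every codon column containing a gap, ambiguous, or stop codon.

    Matches the QC rule of discarding sites with ambiguous data before any
    rate estimation; stop-containing columns are deleted rather than
    raising because trimmed CDS predictions can carry terminal stops
    (deletions are logged).  Idempotent.  Taxon order is preserved and the
    removed original column indices are recorded on the result.
    """
    bad = (aln.states < 0).any(axis=0)
    if not bad.any():
        return replace(aln, removed_columns=np.empty(0, dtype=int))
    n_stop = int(((aln.states == STOP).any(axis=0)).sum())
    if n_stop:
        log.info("%s: removed %d stop-containing column(s) during QC",
                 aln.gene_id or "<alignment>", n_stop)
    keep = ~bad
    raw = None
    if aln.raw is not None:
        keep_nt = np.repeat(keep, 3)
        raw = ["".join(np.array(list(s))[keep_nt]) for s in aln.raw]
    return CodonAlignment(
        taxa=list(aln.taxa),
        states=aln.states[:, keep],
        gene_id=aln.gene_id,
        code=aln.code,
        raw=raw,
        removed_columns=np.nonzero(bad)[0],
    )


def passes_min_length(aln: CodonAlignment, min_nt: int = 150) -> bool:
    """True iff the QC'd alignment is at least ``min_nt`` nucleotides long.

    The retention rule is strict: alignments *shorter than* the threshold
    are discarded, so exactly ``min_nt`` passes.  A threshold not on a
    codon boundary is rounded up to the next one (logged).
    """
    if min_nt % 3 != 0:
        rounded = 3 * math.ceil(min_nt / 3)
        log.warning("min_nt=%d is not a codon multiple; using %d", min_nt, rounded)
        min_nt = rounded
    return 3 * aln.n_codons >= min_nt


def extract_4d_sites(aln: CodonAlignment) -> tuple[list[str], list[str]]:
    """Third-position nucleotides of columns 4-fold degenerate in every taxon.

    A column qualifies only if, for each taxon, the codon's first two bases
    place it in a family where all four third-position bases encode the
    same amino acid.  Returns ``(taxa, sequences)`` as a nucleotide
    alignment (possibly of length 0).
    """
    code = aln.code
    is_4d = np.array([code.fourfold_family(c) for c in code.codons])
    clean = (aln.states >= 0).all(axis=0)
    col_4d = clean.copy()
    col_4d[clean] = is_4d[aln.states[:, clean]].all(axis=0)
    third = [
        "".join(code.codons[s][2] for s in row) for row in aln.states[:, col_4d]
    ]
    return list(aln.taxa), third


def write_nt_fasta(taxa: list[str], seqs: list[str], path) -> None:
    records = [SeqRecord(Seq(s), id=t, description="") for t, s in zip(taxa, seqs)]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def concatenate(alns: list[CodonAlignment], taxa: list[str]) -> CodonAlignment:
    """Concatenate alignments in order, rows following ``taxa``.

    Every input must contain every requested taxon; a missing taxon is an
    error naming the gene and taxon.
    """
    if not alns:
        raise ValueError("nothing to concatenate")
    blocks = []
    for aln in alns:
        try:
            rows = [aln.taxa.index(t) for t in taxa]
        except ValueError:
            missing = sorted(set(taxa) - set(aln.taxa))
            raise ValueError(
                f"gene {aln.gene_id!r} is missing taxa {missing}"
            ) from None
        blocks.append(aln.states[rows])
    return CodonAlignment(
        taxa=list(taxa),
        states=np.concatenate(blocks, axis=1),
        gene_id="+".join(a.gene_id for a in alns if a.gene_id) or "concat",
        code=alns[0].code,
    )
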