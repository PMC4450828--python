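import numpy as np
import pytest

from omegascan.alignment import CodonAlignment
from omegascan.genetics import STANDARD_CODE
from omegascan.trees import parse_newick


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture
def three_taxon_tree():
    return parse_newick("(A:0.2,B:0.1,C:0.3);")


@pytest.fixture
def five_taxon_tree():
    return parse_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05,E:0.15);")


def aln_from_codons(rows: dict[str, str], gene_id: str = "g") -> CodonAlignment:
    """Build an alignment from {taxon: nucleotide string}."""
    taxa = list(rows)
    return CodonAlignment.from_sequences(taxa, [rows[t] for t in taxa], gene_id)


def random_clean_alignment(taxa, n_codons, seed, code=STANDARD_CODE):
    """Uniform random sense-codon alignment (no phylogenetic signal)."""
    rng = np.random.default_rng(seed)
    states = rng.integers(0, code.n_sense, size=(len(taxa), n_codons)).astype(np.int16)
    return CodonAlignment(list(taxa), states, gene_id=f"rand{seed}", code=code)
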