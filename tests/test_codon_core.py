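"""Genetic code, alignment QC, 4D-site extraction, concatenation, clusters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omegascan.alignment import (
    CodonAlignment,
    concatenate,
    extract_4d_sites,
    passes_min_length,
    read_codon_fasta,
    remove_ambiguous_columns,
    write_codon_fasta,
)
from omegascan.genetics import AMBIG, GAP, STOP, get_code
from omegascan.orthologs import (
    ClusterMember,
    OrthologCluster,
    filter_single_copy_clusters,
)

from conftest import aln_from_codons, random_clean_alignment


class TestGeneticCode:
    def test_standard_code_partition(self, code):
        assert code.n_sense == 61
        assert len(code.stops) == 3
        assert set(code.codons) | code.stops == {
            a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"
        }
        assert not (set(code.codons) & code.stops)

    def test_alternative_code(self):
        # vertebrate mitochondrial code: 60 sense codons, 4 stops
        mito = get_code(2)
        assert mito.n_sense == 60
        assert "TGA" in set(mito.codons)  # Trp in the mito code
        assert "AGA" in mito.stops

    @pytest.mark.parametrize(
        "codon,expected",
        [("GGA", True), ("GGT", True), ("CTC", True), ("TTT", False),
         ("TTA", False), ("ATG", False), ("CGA", True)],
    )
    def test_fourfold_family(self, code, codon, expected):
        assert code.fourfold_family(codon) is expected

    def test_encode_sentinels(self, code):
        assert code.encode("---") == GAP
        assert code.encode("A-G") == GAP
        assert code.encode("NNA") == AMBIG
        assert code.encode("TAA") == STOP
        assert code.encode("atg") == code.codon_index["ATG"]


class TestQC:
    def test_ambiguous_column_dropped(self):
        aln = aln_from_codons({"a": "NNAGGG", "b": "ATGGGG"})
        out = remove_ambiguous_columns(aln)
        assert out.n_codons == 1
        assert out.sequence("a") == "GGG"
        assert list(out.removed_columns) == [0]

    def test_clean_alignment_unchanged(self):
        aln = aln_from_codons({"a": "ATGGGA", "b": "ATGGGC"})
        out = remove_ambiguous_columns(aln)
        assert out.n_codons == 2
        assert out.sequence("a") == "ATGGGA"

    def test_gap_column_dropped(self):
        aln = aln_from_codons({"a": "ATGGGATTT", "b": "ATG---TTT"})
        out = remove_ambiguous_columns(aln)
        assert out.n_codons == 2
        assert [out.sequence(t) for t in out.taxa] == ["ATGTTT", "ATGTTT"]

    def test_stop_column_dropped_and_taxon_order_kept(self):
        aln = aln_from_codons({"x": "TAAATG", "y": "CAAATG", "z": "GAAATG"})
        out = remove_ambiguous_columns(aln)
        assert out.taxa == ["x", "y", "z"]
        assert out.n_codons == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        states = rng.integers(-3, 61, size=(3, 12)).astype(np.int16)
        aln = CodonAlignment(["a", "b", "c"], states)
        once = remove_ambiguous_columns(aln)
        twice = remove_ambiguous_columns(once)
        assert np.array_equal(once.states, twice.states)
        assert once.is_clean

    @pytest.mark.parametrize(
        "n_codons,expected", [(49, False), (50, True), (0, False), (51, True)]
    )
    def test_min_length_boundary(self, n_codons, expected):
        # retention requires >= 150 nt: "shorter than 150 bp" is discarded
        aln = random_clean_alignment(["a", "b"], n_codons, seed=1) if n_codons \
            else CodonAlignment(["a", "b"], np.empty((2, 0), dtype=np.int16))
        assert passes_min_length(aln, 150) is expected

    def test_min_length_rounds_up_to_codon_boundary(self):
        aln = random_clean_alignment(["a", "b"], 50, seed=2)  # 150 nt
        assert passes_min_length(aln, 149) is True   # rounded up to 150
        assert passes_min_length(aln, 151) is False  # rounded up to 153


class TestFourfoldExtraction:
    def test_fourfold_column_emitted(self):
        aln = aln_from_codons({"a": "GGA", "b": "GGG"})
        taxa, seqs = extract_4d_sites(aln)
        assert taxa == ["a", "b"]
        assert seqs == ["A", "G"]

    def test_twofold_column_not_emitted(self):
        aln = aln_from_codons({"a": "TTT", "b": "TTC"})
        _, seqs = extract_4d_sites(aln)
        assert seqs == ["", ""]

    def test_mixed_family_column_not_emitted(self):
        # GGA is 4-fold but TTA is not: the rule demands every taxon
        aln = aln_from_codons({"a": "GGA", "b": "TTA"})
        _, seqs = extract_4d_sites(aln)
        assert seqs == ["", ""]

    def test_all_ggn_alignment_yields_one_site_per_codon(self):
        aln = aln_from_codons({"a": "GGAGGTGGC", "b": "GGGGGAGGT"})
        _, seqs = extract_4d_sites(aln)
        assert [len(s) for s in seqs] == [3, 3]


class TestConcatenate:
    def test_additivity_and_identity(self):
        a = random_clean_alignment(["x", "y"], 10, seed=3)
        b = random_clean_alignment(["x", "y"], 10, seed=4)
        out = concatenate([a, b], ["x", "y"])
        assert out.n_codons == 20
        single = concatenate([a], ["x", "y"])
        assert np.array_equal(single.states, a.states)

    def test_taxon_order_follows_request(self):
        a = random_clean_alignment(["x", "y"], 5, seed=5)
        out = concatenate([a], ["y", "x"])
        assert out.taxa == ["y", "x"]
        assert np.array_equal(out.states[0], a.states[1])

    def test_missing_taxon_error_names_gene_and_taxon(self):
        a = random_clean_alignment(["x", "y"], 5, seed=6)
        a.gene_id = "geneZ"
        with pytest.raises(ValueError, match=r"geneZ.*\['z'\]"):
            concatenate([a], ["x", "z"])

    def test_associativity(self):
        alns = [random_clean_alignment(["x", "y"], 4, seed=s) for s in (7, 8, 9)]
        taxa = ["x", "y"]
        left = concatenate([concatenate(alns[:2], taxa), alns[2]], taxa)
        right = concatenate([alns[0], concatenate(alns[1:], taxa)], taxa)
        assert np.array_equal(left.states, right.states)


class TestFastaRoundtrip:
    def test_wrap_and_names(self, tmp_path):
        aln = random_clean_alignment(["taxon one", "t|2"], 30, seed=10)
        path = tmp_path / "x.fasta"
        write_codon_fasta(aln, path)
        text = path.read_text()
        lines = [l for l in text.splitlines() if not l.startswith(">")]
        assert max(len(l) for l in lines) == 60
        back = read_codon_fasta(path)
        assert np.array_equal(back.states, aln.states)


def _cluster(cid, members):
    return OrthologCluster(cid, [ClusterMember(*m) for m in members])


class TestSingleCopyFilter:
    SPECIES = {"s1", "s2"}

    def test_low_score_cluster_removed(self):
        # a sub-threshold member is removed, leaving the species uncovered
        clusters = [_cluster("c1", [("s1", "g1", 0.8), ("s2", "g2", 1.0)])]
        assert filter_single_copy_clusters(clusters, self.SPECIES) == []

    def test_multicopy_cluster_removed(self):
        clusters = [_cluster("c1", [("s1", "g1", 1.0), ("s1", "g1b", 1.0),
                                    ("s2", "g2", 1.0)])]
        assert filter_single_copy_clusters(clusters, self.SPECIES) == []

    def test_clean_single_copy_cluster_retained(self):
        clusters = [_cluster("c1", [("s1", "g1", 1.0), ("s2", "g2", 1.0)])]
        kept = filter_single_copy_clusters(clusters, self.SPECIES)
        assert [c.cluster_id for c in kept] == ["c1"]
        assert all(m.score >= 1.0 for c in kept for m in c.members)

    def test_low_score_duplicate_is_pruned_then_cluster_kept(self):
        # the score rule removes the duplicate; the survivor set is 1:1
        clusters = [_cluster("c1", [("s1", "g1", 1.0), ("s1", "g1b", 0.3),
                                    ("s2", "g2", 1.0)])]
        kept = filter_single_copy_clusters(clusters, self.SPECIES)
        assert len(kept) == 1 and len(kept[0].members) == 2

    def test_empty_species_set_is_config_error(self):
        with pytest.raises(ValueError, match="species"):
            filter_single_copy_clusters([], set())

    def test_score_outside_unit_interval_rejected(self):
        clusters = [_cluster("c1", [("s1", "g1", 1.2)])]
        with pytest.raises(ValueError, match="score"):
            filter_single_copy_clusters(clusters, self.SPECIES)
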