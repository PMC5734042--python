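"""Sequence types, genetic code, ORF scanning, FASTA round trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aadscan.seq_core import (
    AlphabetError,
    FastaFormatError,
    GeneLocus,
    NucleotideSequence,
    ProteinSequence,
    read_fasta,
    read_loci,
    reverse_complement,
    scan_orfs,
    translate,
    write_fasta,
    write_loci,
)
from conftest import random_dna
from helpers_oracles import orf_oracle

dna_strings = st.text(alphabet="ACGTN", max_size=120)

# the two site-directed-mutagenesis primers of the G-insertion fusion are an
# exact reverse-complement pair -- a convenient external fixture
PRIMER_F2C = "AGTTTACACATTCTAGTGCAGCAGGGCAAGGTCCTCTATTTGGGTGTGTCT"
PRIMER_R1B = "AGACACACCCAAATAGAGGACCTTGCCCTGCTGCACTAGAATGTGTAAACT"


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", "GCAT"), ("", ""), ("NNA", "TNN"), (PRIMER_F2C, PRIMER_R1B)],
    )
    def test_known_pairs(self, seq, expected):
        assert reverse_complement(NucleotideSequence("s", seq)).residues == expected

    @given(dna_strings)
    def test_involution(self, s):
        seq = NucleotideSequence("s", s)
        assert reverse_complement(reverse_complement(seq)).residues == seq.residues

    def test_length_preserved_and_alphabet_closed(self, rng):
        s = NucleotideSequence("s", random_dna(rng, 500))
        rc = reverse_complement(s)
        assert len(rc) == len(s)
        assert set(rc.residues) <= set("ACGTN")

    def test_rejects_non_iupac(self):
        with pytest.raises(AlphabetError):
            NucleotideSequence("s", "ACGU")


class TestTranslate:
    @pytest.mark.parametrize(
        "dna,aa",
        [
            ("ATGTAA", "M*"),
            ("TAC", "Y"),  # the codon pair of the catalytic-site lesion:
            ("TGC", "C"),  # Tyr (TAC) <-> Cys (TGC) via the middle base
            ("ATGAANTGA", "MX*"),
            ("", ""),
        ],
    )
    def test_known_translations(self, dna, aa):
        assert translate(dna).residues == aa

    def test_offsets_drop_partial_codons(self):
        assert translate("AATGTA", 1).residues == "M"
        assert translate("AATGTAA", 1).residues == "M*"
        with pytest.raises(ValueError):
            translate("ATG", 3)

    def test_264_nt_segment_gives_88_residues(self, rng):
        # the length arithmetic behind the N-terminal extension: 264 in-frame
        # nucleotides encode 88 residues
        codons = []
        while len(codons) < 88:
            c = random_dna(rng, 3)
            if c not in ("TAA", "TAG", "TGA"):
                codons.append(c)
        seg = "".join(codons)
        assert len(seg) == 264
        assert len(translate(seg)) == 88

    def test_never_errors_on_random_plus_revcomp(self, rng):
        s = NucleotideSequence("s", random_dna(rng, 99))
        both = NucleotideSequence("b", s.residues + reverse_complement(s).residues)
        out = translate(both)
        assert set(out.residues) <= set("ACDEFGHIKLMNPQRSTVWY*X")


class TestScanOrfs:
    def test_minimal_orf(self):
        orfs = scan_orfs(NucleotideSequence("t", "ATGAAATAA"), min_aa=1)
        assert [(o.start, o.end, o.strand) for o in orfs] == [(1, 9, "+")]
        assert translate("ATGAAATAA").residues == "MK*"

    def test_no_orf_in_homopolymer(self):
        assert scan_orfs(NucleotideSequence("t", "C" * 120), min_aa=1) == []

    def test_internal_stop_splits_run(self):
        # ATG aaa TAG ATG aaa TAA: the internal TAG ends the first ORF
        seq = NucleotideSequence("t", "ATGAAATAGATGAAATAA")
        orfs = [o for o in scan_orfs(seq, min_aa=1) if o.strand == "+"]
        assert [(o.start, o.end) for o in orfs] == [(1, 9), (10, 18)]

    @pytest.mark.parametrize("length", [30, 90, 150, 300])
    @pytest.mark.parametrize("min_aa", [1, 5])
    def test_agrees_with_six_frame_oracle(self, rng, length, min_aa):
        for _ in range(8):
            s = random_dna(rng, length)
            got = [
                (o.start, o.end, o.strand, o.frame)
                for o in scan_orfs(NucleotideSequence("t", s), min_aa=min_aa)
            ]
            assert sorted(got) == orf_oracle(s, min_aa)

    def test_invariants_hold(self, rng):
        s = NucleotideSequence("t", random_dna(rng, 400))
        for o in scan_orfs(s, min_aa=2):
            assert (o.end - o.start + 1) % 3 == 0
            sub = s.residues[o.start - 1 : o.end]
            if o.strand == "-":
                sub = reverse_complement(NucleotideSequence("x", sub)).residues
            prot = translate(sub).residues
            assert prot.endswith("*") and "*" not in prot[:-1]


class TestFasta:
    def test_round_trip(self, tmp_path, rng):
        seqs = [
            NucleotideSequence(f"seq{i}", random_dna(rng, 150), f"desc {i}")
            for i in range(3)
        ]
        path = tmp_path / "x.fasta"
        write_fasta(seqs, path)
        back = read_fasta(path)
        assert [(s.id, s.residues) for s in back] == [
            (s.id, s.residues) for s in seqs
        ]
        # wrapped at 60 columns
        body = [l for l in path.read_text().splitlines() if not l.startswith(">")]
        assert max(len(l) for l in body) <= 60

    def test_lowercase_normalized_on_read(self, tmp_path):
        (tmp_path / "x.fasta").write_text(">a\nacgtn\n")
        assert read_fasta(tmp_path / "x.fasta")[0].residues == "ACGTN"

    def test_duplicate_ids_warn_but_kept(self, tmp_path, caplog):
        (tmp_path / "x.fasta").write_text(">a\nACGT\n>a\nTTTT\n")
        with caplog.at_level("WARNING"):
            seqs = read_fasta(tmp_path / "x.fasta")
        assert len(seqs) == 2
        assert any("duplicate" in r.message for r in caplog.records)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(FastaFormatError):
            read_fasta(p)


class TestGeneLocus:
    def test_coordinates_skip_zero(self):
        ctx = NucleotideSequence("c", "AAAATGGGGTAA")
        locus = GeneLocus("l", ctx, cds_start=4, cds_end=12)
        assert locus.to_index(1) == 3  # the A of ATG
        assert locus.to_index(-1) == 2  # immediately 5' of it
        assert locus.to_position(3) == 1
        assert locus.to_position(2) == -1
        with pytest.raises(ValueError):
            locus.to_index(0)

    def test_reverse_strand_normalization(self):
        cds = "ATGAAATAA"
        ctx_fwd = "CC" + cds + "GGG"
        rc = reverse_complement(NucleotideSequence("c", ctx_fwd)).residues
        locus = GeneLocus(
            "l", NucleotideSequence("c", rc), cds_start=4, cds_end=12, strand="-"
        )
        fwd = locus.forward()
        assert fwd.strand == "+"
        assert fwd.cds.residues == cds

    def test_loci_sidecar_round_trip(self, tmp_path, rng):
        ctx = NucleotideSequence("ctx1", random_dna(rng, 60))
        loci = [GeneLocus("locusA", ctx, cds_start=10, cds_end=30, strand="+")]
        write_loci(loci, tmp_path / "l.fasta", tmp_path / "l.tsv")
        back = read_loci(tmp_path / "l.fasta", tmp_path / "l.tsv")
        assert back[0].label == "locusA"
        assert back[0].cds_start == 10 and back[0].cds_end == 30
        assert back[0].context.residues == ctx.residues
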