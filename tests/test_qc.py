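"""Read trimming, initiation-codon calling, translation and NUMT screening."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from trna_anchor.qc import (
    IndelEvent,
    UntrimmableError,
    annotate_quadruplet,
    call_initiation_codon,
    detect_indels,
    numt_screen,
    qc_read,
    translate_mito,
    trim_upstream,
)
from trna_anchor.records import Thresholds
from trna_anchor.simulate import (
    REFERENCE_PROTEIN,
    SimConfig,
    back_translate,
    generate_mitogenome,
    generate_read,
)

#: stop codons in every reading frame; free of canonical initiators with a
#: long stop-free run, so it can never be mistaken for coding sequence
STOPPY = "TTAATTAGTTAA"


def _clean_orf(rng, n_codons=220):
    return back_translate(REFERENCE_PROTEIN[:n_codons], rng)


class TestTranslate:
    def test_agrees_with_biopython_table5_for_all_64_codons(self):
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            expected = str(Seq(codon).translate(table=5))
            assert translate_mito(codon) == expected

    def test_g_to_a_transition_changes_gly_ser_and_asp_asn(self):
        assert translate_mito("GGA") == "G" and translate_mito("AGA") == "S"
        assert translate_mito("GAT") == "D" and translate_mito("AAT") == "N"
        assert translate_mito("TGA") == "W"
        assert translate_mito("ATA") == "M"

    def test_frames_and_partial_codons(self):
        assert translate_mito("AATGGGA", frame=1) == "MG"
        assert translate_mito("GGGTT") == "G"  # trailing partial dropped

    def test_ambiguous_codon_rules(self):
        assert translate_mito("GGN") == "G"  # all expansions agree
        assert translate_mito("ANA") == "X"
        with pytest.raises(ValueError):
            translate_mito("AC")


class TestInitiationCall:
    def test_canonical_codons(self):
        for codon, cls in [
            ("ATG", "ATN"), ("ATA", "ATN"), ("ATT", "ATN"), ("ATC", "ATN"),
            ("TTG", "TTG"), ("GTG", "GTG"),
        ]:
            assert call_initiation_codon(codon + "A" * 30) == cls

    def test_tcg_requires_upstream_stop_context(self):
        # TAA immediately 5', no canonical start within 30 bp downstream
        seq = STOPPY[:9] + "TAA" + "TCG" + "GCTCCCGCTCCCGCTCCCGCTCCCGCTCCC"
        assert call_initiation_codon(seq, offset=12) == "TCG_type"
        assert call_initiation_codon(seq.replace("TCG", "CCG", 1), 12) == "TCG_type"
        # same codon without the stop is uncertain
        assert call_initiation_codon("CCC" + "TCG" + "A" * 30, 3) == "uncertain"

    def test_cga_type_and_the_30bp_rule(self):
        seq = "TAA" + "CGA" + "CCCGCTCCCGCTCCCGCTCCCGCTCCCGCT"
        assert call_initiation_codon(seq, 3) == "CGA_type"
        # a canonical ATT 12 bp after the stop defeats the CGA call ...
        conflicted = "TAA" + "CGA" + "CCCGCTCCC" + "ATT" + "CCCGCTCCCGCTCCC"
        assert call_initiation_codon(conflicted, 3) == "uncertain"

    def test_canonical_start_preferred_over_defeated_cga(self):
        filler = STOPPY * 10
        orf = back_translate(REFERENCE_PROTEIN, np.random.default_rng(0))
        read = filler + "TAA" + "CGA" + "CCCGCTCCC" + "ATT" + orf
        tr = trim_upstream(read)
        assert tr.initiation_call == "ATN"
        assert tr.coi_start == len(filler) + 3 + 3 + 9

    def test_sequence_shorter_than_codon(self):
        with pytest.raises(ValueError):
            call_initiation_codon("AT")

    def test_quadruplets_annotated_never_called(self):
        assert annotate_quadruplet("ATAAGGG") == "ATAA"
        assert annotate_quadruplet("ATGAGGG") is None


class TestTrim:
    def test_filler_of_120_bp(self):
        rng = np.random.default_rng(21)
        read = STOPPY * 10 + "ATG" + _clean_orf(rng)[3:]
        tr = trim_upstream(read)
        assert tr.coi_start == 120
        assert tr.initiation_call == "ATN"
        assert tr.trimmed == read[120:]

    def test_read_starting_at_orf(self):
        rng = np.random.default_rng(22)
        read = "ATG" + _clean_orf(rng)[3:]
        tr = trim_upstream(read)
        assert tr.coi_start == 0

    def test_filler_of_200_bp_upper_trim_band(self):
        rng = np.random.default_rng(24)
        filler = (STOPPY * 17)[:200]
        read = filler + "ATG" + _clean_orf(rng)[3:]
        tr = trim_upstream(read)
        assert tr.coi_start == 200

    def test_untrimmable_read_raises(self):
        with pytest.raises(UntrimmableError):
            trim_upstream(STOPPY * 40)

    def test_short_read_rejected(self):
        with pytest.raises(ValueError):
            trim_upstream("ATG" + "A" * 100)


class TestNumtScreen:
    def test_clean_orf_no_flags(self):
        rng = np.random.default_rng(25)
        dna = _clean_orf(rng)
        flags = numt_screen(dna, translate_mito(dna), reference_dna=dna)
        assert flags == set()

    def test_planted_frameshift_flagged(self):
        rng = np.random.default_rng(26)
        dna = _clean_orf(rng)
        mutated = dna[:301] + dna[302:]  # 1 bp deletion mid-read
        flags = numt_screen(mutated, translate_mito(mutated), reference_dna=dna)
        assert "FRAMESHIFT" in flags

    def test_planted_internal_stop_flagged(self):
        rng = np.random.default_rng(27)
        dna = _clean_orf(rng)
        mutated = dna[:300] + "TAA" + dna[303:]
        flags = numt_screen(mutated, translate_mito(mutated), reference_dna=dna)
        assert "INTERNAL_STOP" in flags
        assert "FRAMESHIFT" not in flags

    def test_in_frame_deletion_not_a_frameshift(self):
        rng = np.random.default_rng(28)
        dna = _clean_orf(rng)
        mutated = dna[:300] + dna[309:]  # 9 bp, in frame
        flags = numt_screen(mutated, translate_mito(mutated), reference_dna=dna)
        assert "FRAMESHIFT" not in flags

    def test_short_flag_below_barcode_floor(self):
        rng = np.random.default_rng(29)
        dna = _clean_orf(rng)[:450]
        assert "SHORT" in numt_screen(dna, translate_mito(dna))


class TestDetectIndels:
    def test_scale_insect_style_deletion_131_length_3(self):
        query = REFERENCE_PROTEIN[:130] + REFERENCE_PROTEIN[133:]
        events = detect_indels(query, REFERENCE_PROTEIN)
        assert events == [IndelEvent(131, 3, "deletion")]

    def test_pompilid_style_deletion_175_length_2(self):
        query = REFERENCE_PROTEIN[:174] + REFERENCE_PROTEIN[176:]
        events = detect_indels(query, REFERENCE_PROTEIN)
        assert events == [IndelEvent(175, 2, "deletion")]

    def test_identical_proteins_no_events(self):
        assert detect_indels(REFERENCE_PROTEIN, REFERENCE_PROTEIN) == []

    def test_3prime_truncation_is_not_an_event(self):
        assert detect_indels(REFERENCE_PROTEIN[:180], REFERENCE_PROTEIN) == []

    def test_insertion_reported_symmetrically(self):
        query = REFERENCE_PROTEIN[:99] + "WQ" + REFERENCE_PROTEIN[99:]
        assert detect_indels(query, REFERENCE_PROTEIN) == [
            IndelEvent(100, 2, "insertion")
        ]

    def test_low_identity_rejected(self):
        rng = np.random.default_rng(33)
        junk = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 230))
        with pytest.raises(ValueError, match="identity"):
            detect_indels(junk, REFERENCE_PROTEIN)

    def test_short_proteins_rejected(self):
        with pytest.raises(ValueError):
            detect_indels("M" * 40, REFERENCE_PROTEIN)


class TestQcRead:
    def test_full_chain_on_simulated_read(self):
        cfg = SimConfig(
            seed=41, n_genomes=4, coi_initiator="ATN", reject_confounders=True
        )
        genome, truth = generate_mitogenome(cfg, 0)
        read, rt = generate_read(genome, truth, cfg, index=0)
        br = qc_read(read, reference_protein=truth.protein)
        assert br.coi_start == rt.coi_start
        assert br.initiation_call == "ATN"
        assert br.flags - {"SHORT"} == set()
        assert br.indels == []
        assert br.barcode_compliant == (len(br.trimmed) >= 500)

    def test_compliance_needs_length_and_clean_flags(self):
        rng = np.random.default_rng(42)
        dna = _clean_orf(rng)
        br = qc_read(dna)
        assert br.barcode_compliant
        short = qc_read(dna[:460], thresholds=Thresholds())
        assert not short.barcode_compliant
        assert "SHORT" in short.flags
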