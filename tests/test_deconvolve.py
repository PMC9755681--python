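"""The six-step extraction: orientation, borders, repair, codons, translation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phagedeconv.amplicon import ConstructLayout
from phagedeconv.deconvolve import (
    ACCEPTED,
    AMBIGUOUS_ORIENTATION,
    BORDER_NOT_FOUND,
    CODON_INVALID,
    DISCARDED,
    FORWARD,
    INCOMPLETE_BARCODE,
    NNK_CODONS,
    NO_ANCHOR_MATCH,
    REPAIR_FAILED,
    REVERSE,
    STOP_CODON,
    TOO_SHORT,
    UNDER_LENGTH,
    deconvolve_read,
    extract_insert,
    length_prefilter,
    orient_and_barcode,
    repair_insert,
    reverse_complement,
    translate_insert,
    validate_codons,
)
from phagedeconv.io_seq import SeqRead
from phagedeconv.simulate import encode_peptide_nnk

from conftest import make_clean_read, make_wt_read, random_peptide

dna = st.text(alphabet="ACGTN", min_size=0, max_size=60)


class TestReverseComplement:
    def test_palindrome(self):
        assert reverse_complement("ACGT") == "ACGT"

    def test_simple(self):
        assert reverse_complement("AAAC") == "GTTT"

    def test_n_maps_to_n(self):
        assert reverse_complement("ANG") == "CNT"

    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")


class TestLengthPrefilter:
    def test_short_read_fails(self, layout):
        assert not length_prefilter(SeqRead("r", "ACGTACGTAC"), layout)

    def test_boundary_length_passes(self, layout):
        n = 12 + 3 + 12 + 36 + 12
        assert length_prefilter(SeqRead("r", "A" * n), layout)
        assert not length_prefilter(SeqRead("r", "A" * (n - 1)), layout)

    def test_simulated_full_length_reads_pass(self, layout, regions):
        rng = np.random.default_rng(0)
        for i in range(20):
            read, _ = make_clean_read(layout, regions, "ACT", random_peptide(rng), rng)
            assert length_prefilter(read, layout)


class TestOrientAndBarcode:
    def test_forward_read_with_act_barcode(self, layout, regions):
        rng = np.random.default_rng(1)
        read, _ = make_clean_read(layout, regions, "ACT", "FIPAQLHFHWRS", rng)
        assert orient_and_barcode(read, layout) == (FORWARD, "ACT")

    def test_reverse_read_with_parental_barcode(self, layout, regions):
        rng = np.random.default_rng(2)
        read, _ = make_clean_read(
            layout, regions, "AAA", "FIPAQLHFHWRS", rng, orientation=REVERSE
        )
        assert orient_and_barcode(read, layout) == (REVERSE, "AAA")

    def test_no_anchor(self, layout):
        read = SeqRead("r", "T" * 100)
        assert orient_and_barcode(read, layout) == NO_ANCHOR_MATCH

    def test_anchor_outside_window_not_matched(self, layout):
        # anchor buried deep in the read: the 5' window scan must miss it
        read = SeqRead("r", "T" * 40 + layout.fwd_anchor + "ACT" + "T" * 60)
        assert orient_and_barcode(read, layout) == NO_ANCHOR_MATCH

    def test_truncated_barcode(self, layout):
        read = SeqRead("r", layout.fwd_anchor + "AC")
        assert orient_and_barcode(read, layout) == INCOMPLETE_BARCODE

    def test_n_in_barcode(self, layout):
        read = SeqRead("r", layout.fwd_anchor + "ANT" + "G" * 80)
        assert orient_and_barcode(read, layout) == INCOMPLETE_BARCODE

    def test_both_anchors_in_window_is_ambiguous(self):
        lay = ConstructLayout(
            fwd_anchor="AAGG", rev_anchor="CCTT",
            left_border="TATTCTCACTCT", right_border="GGTGGAGGTTCG",
            anchor_min_length=4,
        )
        read = SeqRead("r", "AAGGCCTT" + "G" * 80)
        assert orient_and_barcode(read, lay) == AMBIGUOUS_ORIENTATION


class TestExtractInsert:
    def test_forward_slicing(self, layout, regions):
        rng = np.random.default_rng(3)
        read, insert = make_clean_read(layout, regions, "ACT", "AKFDMHIATRLS", rng)
        raw, quals = extract_insert(read, FORWARD, layout)
        assert raw == insert
        assert len(quals) == 36

    def test_strand_equivalence(self, layout, regions):
        rng = np.random.default_rng(4)
        fwd, insert = make_clean_read(layout, regions, "ACT", "AKFDMHIATRLS", rng)
        rev = SeqRead("r", reverse_complement(fwd.bases), fwd.quals[::-1])
        raw_f, q_f = extract_insert(fwd, FORWARD, layout)
        raw_r, q_r = extract_insert(rev, REVERSE, layout)
        assert raw_r == raw_f == insert
        assert q_r == q_f

    def test_missing_right_border(self, layout, regions):
        read = make_wt_read(layout, regions, "ACT")
        assert extract_insert(read, FORWARD, layout) == BORDER_NOT_FOUND


def _repair_oracle(seq: str, quals: list[int], target: int) -> str:
    """Remove the (len - target) lowest-quality positions; equal qualities
    are dropped 3'-most first."""
    n = len(seq)
    drop = set(sorted(range(n), key=lambda i: (quals[i], -i))[: n - target])
    return "".join(b for i, b in enumerate(seq) if i not in drop)


class TestRepair:
    def test_exact_length_is_identity(self, layout):
        seq = "GCT" * 12
        assert repair_insert(seq, [30] * 36, layout) == (seq, None)

    def test_two_lowest_quality_bases_removed(self, layout):
        seq = "A" * 38
        quals = [30] * 38
        quals[5] = 3
        quals[20] = 7
        seq = "".join("ACGT"[i % 4] for i in range(38))
        fixed, reason = repair_insert(seq, quals, layout)
        assert reason is None
        assert fixed == "".join(c for i, c in enumerate(seq) if i not in (5, 20))

    def test_under_length_discarded(self, layout):
        assert repair_insert("A" * 30, [30] * 30, layout) == (None, UNDER_LENGTH)

    def test_no_qualities_cannot_repair(self, layout):
        assert repair_insert("A" * 38, None, layout) == (None, REPAIR_FAILED)

    def test_tie_removes_three_prime_most_by_default(self, layout):
        seq = "C" + "A" * 36
        quals = [10] + [30] * 36
        quals[36] = 10  # same minimum at both ends
        fixed, _ = repair_insert(seq, quals, layout)
        assert fixed == "C" + "A" * 35  # 3'-most minimum removed first

    def test_tie_five_prime_option(self, layout):
        seq = "C" + "A" * 36
        quals = [10] + [30] * 36
        fixed, _ = repair_insert(seq, quals, layout, tie="fiveprime")
        assert fixed == "A" * 36

    @given(st.data())
    def test_matches_bruteforce_oracle(self, layout, data):
        n = data.draw(st.integers(36, 45))
        seq = data.draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
        quals = data.draw(st.lists(st.integers(0, 40), min_size=n, max_size=n))
        fixed, reason = repair_insert(seq, quals, layout)
        assert reason is None
        assert fixed == _repair_oracle(seq, quals, 36)


class TestCodonValidation:
    def test_all_ala_passes(self):
        assert validate_codons("GCT" * 12) is None

    def test_amber_rejected_by_default(self):
        assert validate_codons("TAG" + "GGT" * 11) == STOP_CODON

    def test_amber_allowed_under_suppression(self):
        assert validate_codons("TAG" + "GGT" * 11, amber_policy="suppress") is None

    def test_opal_is_stop_even_under_suppression(self):
        assert validate_codons("TGA" + "GGT" * 11, amber_policy="suppress") == STOP_CODON

    def test_non_nnk_codon_invalid(self):
        assert validate_codons("AAA" + "GGT" * 11) == CODON_INVALID

    def test_n_renders_codon_invalid(self):
        assert validate_codons("GNT" + "GGT" * 11) == CODON_INVALID

    def test_length_not_multiple_of_three_is_hard_error(self):
        with pytest.raises(ValueError):
            validate_codons("GCTA")

    def test_all_64_codons_against_enumeration(self):
        # independent oracle: the NNK set enumerated from its definition
        nnk = {a + b + c for a in "ACGT" for b in "ACGT" for c in "GT"}
        assert NNK_CODONS == frozenset(nnk)
        stops = {"TAA", "TAG", "TGA"}
        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    codon = a + b + c
                    result = validate_codons(codon + "GGT" * 11)
                    if codon in stops:
                        assert result == STOP_CODON, codon
                    elif codon not in nnk:
                        assert result == CODON_INVALID, codon
                    else:
                        assert result is None, codon


class TestTranslation:
    def test_poly_gly(self):
        assert translate_insert("GGT" * 12) == "G" * 12

    @pytest.mark.parametrize("peptide", ["FIPAQLHFHWRS", "AKFDMHIATRLS"])
    def test_encode_translate_round_trip(self, peptide):
        rng = np.random.default_rng(6)
        for _ in range(5):
            insert = encode_peptide_nnk(peptide, rng)
            assert validate_codons(insert) is None
            assert translate_insert(insert) == peptide

    def test_amber_suppression_reads_tag_as_gln(self):
        assert translate_insert("TAG" + "GGT" * 11, amber_policy="suppress") == (
            "Q" + "G" * 11
        )

    def test_unsuppressed_stop_is_hard_error(self):
        with pytest.raises(ValueError):
            translate_insert("TAG" + "GGT" * 11)


class TestDeconvolveRead:
    def test_clean_forward_read_accepted(self, layout, sheet, regions):
        rng = np.random.default_rng(7)
        read, insert = make_clean_read(layout, regions, "ACT", "FIPAQLHFHWRS", rng)
        rec = deconvolve_read(read, layout, sheet)
        assert rec.fate == ACCEPTED
        assert (rec.barcode, rec.orientation) == ("ACT", FORWARD)
        assert rec.insert_nt == insert
        assert rec.peptide == "FIPAQLHFHWRS"
        assert rec.assigned is True

    def test_wild_type_read_discarded_border_not_found(self, layout, sheet, regions):
        rec = deconvolve_read(make_wt_read(layout, regions, "ACT"), layout, sheet)
        assert (rec.fate, rec.discard_reason) == (DISCARDED, BORDER_NOT_FOUND)

    def test_low_quality_insertion_repaired_to_truth(self, layout, sheet, regions):
        rng = np.random.default_rng(8)
        read, insert = make_clean_read(layout, regions, "ACT", "AKFDMHIATRLS", rng)
        # duplicate a base inside the variable region at strictly minimal quality
        pos = read.bases.find(insert) + 10
        bases = read.bases[:pos] + read.bases[pos] + read.bases[pos:]
        quals = read.quals[:pos] + [5] + read.quals[pos:]
        rec = deconvolve_read(SeqRead("r", bases, quals), layout, sheet)
        assert rec.fate == ACCEPTED
        assert rec.peptide == "AKFDMHIATRLS"

    def test_unknown_barcode_retained_but_unassigned(self, layout, sheet, regions):
        rng = np.random.default_rng(9)
        read, _ = make_clean_read(layout, regions, "GGG", "FIPAQLHFHWRS", rng)
        rec = deconvolve_read(read, layout, sheet)
        assert rec.fate == ACCEPTED
        assert rec.assigned is False

    def test_too_short_read(self, layout, sheet):
        rec = deconvolve_read(SeqRead("r", "ACGT"), layout, sheet)
        assert (rec.fate, rec.discard_reason) == (DISCARDED, TOO_SHORT)

    def test_strand_equivalence_full_pipeline(self, layout, sheet, regions):
        rng = np.random.default_rng(10)
        for i in range(25):
            pep = random_peptide(rng)
            fwd, _ = make_clean_read(layout, regions, "ATC", pep, rng)
            rev = SeqRead(fwd.read_id, reverse_complement(fwd.bases), fwd.quals[::-1])
            rec_f = deconvolve_read(fwd, layout, sheet)
            rec_r = deconvolve_read(rev, layout, sheet)
            assert rec_f.fate == rec_r.fate == ACCEPTED
            assert rec_f.insert_nt == rec_r.insert_nt
            assert rec_f.peptide == rec_r.peptide
            assert rec_r.orientation == REVERSE

    def test_amber_policy_changes_only_tag_reads(self, layout, sheet, regions):
        # hand-build an insert whose first codon is amber
        rng = np.random.default_rng(12)
        insert = "TAG" + encode_peptide_nnk("KFDMHIATRLS", rng)
        from phagedeconv.simulate import assemble_library_amplicon

        seq = assemble_library_amplicon(layout, regions, "ACT", insert)
        read = SeqRead("r", seq, [30] * len(seq))
        rejected = deconvolve_read(read, layout, sheet, amber_policy="reject")
        suppressed = deconvolve_read(read, layout, sheet, amber_policy="suppress")
        assert (rejected.fate, rejected.discard_reason) == (DISCARDED, STOP_CODON)
        assert suppressed.fate == ACCEPTED
        assert suppressed.peptide == "QKFDMHIATRLS"
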