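"""Mutation calling: simple path, DP fallback, nomenclature, normalization."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilecall import (
    COMPLEX,
    DPScoring,
    IndexParams,
    MutationCall,
    align_nw,
    align_sw,
    alignment_to_calls,
    apply_calls,
    call_simple,
    complex_window_span,
    format_hgvs,
    left_normalize,
)
from tilecall.align import align_semiglobal

dna = st.text(alphabet="ACGT", min_size=1, max_size=6)


def brute_force_best_score(a: str, b: str, scoring: DPScoring) -> float:
    """Enumerate every global alignment of two tiny strings and score it
    with affine gaps (gap of length L costs open + L*extend)."""

    def score(cols):
        total, i = 0.0, 0
        while i < len(cols):
            x, y = cols[i]
            if x != "-" and y != "-":
                total += scoring.match if x == y else scoring.mismatch
                i += 1
            else:
                which = 0 if x == "-" else 1
                j = i
                while j < len(cols) and cols[j][which] == "-":
                    j += 1
                total += scoring.gap_cost(j - i)
                i = j
        return total

    def alignments(i, j, cols):
        if i == len(a) and j == len(b):
            yield list(cols)
            return
        if i < len(a) and j < len(b):
            cols.append((a[i], b[j]))
            yield from alignments(i + 1, j + 1, cols)
            cols.pop()
        if i < len(a):
            cols.append((a[i], "-"))
            yield from alignments(i + 1, j, cols)
            cols.pop()
        if j < len(b):
            cols.append(("-", b[j]))
            yield from alignments(i, j + 1, cols)
            cols.pop()

    return max(score(cols) for cols in alignments(0, 0, []))


class TestCallSimple:
    def kw(self, reference, offset=0):
        return dict(reference=reference, ref_offset=offset, w=15)

    def test_single_substitution(self):
        calls = call_simple("ACGTA", "ACCTA", **self.kw("ACGTA"))
        assert [c.name for c in calls] == ["3G>C"]

    def test_two_close_substitutions_are_complex(self):
        ref = "AAAAACAAAACAAAAAAAAA"
        read = "AAAAATAAAATAAAAAAAAA"  # 5 bp apart < w
        assert call_simple(ref, read, **self.kw(ref)) == COMPLEX

    def test_two_distant_substitutions_called_separately(self):
        ref = "A" * 40
        read = "C" + "A" * 20 + "C" + "A" * 18  # 21 apart > w=15
        calls = call_simple(ref, read, **self.kw(ref))
        assert [c.name for c in calls] == ["1A>C", "22A>C"]

    def test_block_deletion_via_prefix_suffix(self):
        ref = "TTGGAATTCCAAGGTT"
        read = "TTGGCCAAGGTT"
        calls = call_simple(ref, read, **self.kw(ref))
        assert [c.name for c in calls] == ["5delAATT"]

    def test_block_insertion(self):
        ref = "TTGGCCAAGGTT"
        read = "TTGGAATTCCAAGGTT"
        calls = call_simple(ref, read, **self.kw(ref))
        assert [c.name for c in calls] == ["4insAATT"]

    def test_ambiguous_indel_in_repeat_left_aligned(self):
        ref = "GCATATATGC"
        read = "GCATATGC"  # deleting any AT unit is equivalent
        calls = call_simple(ref, read, **self.kw(ref))
        assert [c.name for c in calls] == ["3delAT"]

    def test_indel_plus_nearby_mismatch_is_complex(self):
        ref = "AACCGGTTACGTACGT"
        read = "AACCGTTACGAACGT"  # 1 bp deletion + substitution
        assert call_simple(ref, read, **self.kw(ref)) == COMPLEX

    def test_empty_region_is_internal_error(self):
        with pytest.raises(ValueError):
            call_simple("", "", **self.kw("ACGT"))


class TestComplexWindowSpan:
    @pytest.mark.parametrize(
        "w,delta,expected", [(15, 5, 35), (1, 1, 3), (20, 10, 50)]
    )
    def test_formula(self, w, delta, expected):
        assert complex_window_span(IndexParams(w=w, delta=delta)) == expected


class TestAlignNW:
    def test_identity_scores_four_matches(self):
        aln = align_nw("ACGT", "ACGT")
        assert aln.score == 32
        assert aln.aligned_a == aln.aligned_b == "ACGT"

    def test_single_gap_matches_brute_force(self):
        scoring = DPScoring()
        aln = align_nw("ACGT", "AGT", scoring)
        assert aln.score == brute_force_best_score("ACGT", "AGT", scoring)

    @given(a=dna, b=dna)
    @settings(max_examples=150, deadline=None)
    def test_score_matches_exhaustive_enumeration(self, a, b):
        scoring = DPScoring()
        aln = align_nw(a, b, scoring)
        assert aln.score == brute_force_best_score(a, b, scoring)
        # the reported alignment must itself attain the reported score
        assert len(aln.aligned_a) == len(aln.aligned_b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b

    def test_recovers_planted_cluster(self, exon_ref):
        seq = exon_ref.sequence[60:110]
        edits = [
            MutationCall("substitution", 10, seq[9], "A" if seq[9] != "A" else "C"),
            MutationCall("deletion", 15, seq[14:18], ""),
            MutationCall("substitution", 22, seq[21], "A" if seq[21] != "A" else "C"),
        ]
        read = apply_calls(seq, edits)
        aln = align_nw(seq, read)
        calls = alignment_to_calls(aln, 0, seq)
        assert apply_calls(seq, calls) == read


class TestAlignSW:
    def test_exact_substring_aligns_without_mutations(self, exon_ref):
        half = exon_ref.sequence[112:]
        aln = align_sw(exon_ref.sequence, half)
        assert aln.aligned_a == aln.aligned_b == half
        assert (aln.a_start, aln.a_end) == (112, 225)

    def test_disjoint_sequences_align_nothing(self):
        aln = align_sw("AAAAAAAA", "CCCCCCCC")
        assert aln.score == 0
        assert aln.aligned_a == ""

    def test_local_alignment_trims_terminal_mismatch(self):
        aln = align_sw("TACGTACGT", "AACGTACGT")
        assert aln.a_start == 1 and aln.b_start == 1


class TestAlignSemiglobal:
    def test_free_prefix_reports_overhang_not_deletion(self, exon_ref):
        ref_seg = exon_ref.sequence[:115]
        read_seg = exon_ref.sequence[112:115]
        aln = align_semiglobal(ref_seg, read_seg, free_prefix=True)
        assert aln.a_start == 112
        assert "-" not in aln.aligned_b

    def test_terminal_substitution_stays_aligned(self):
        ref_seg = "TACGT"
        read_seg = "GACGT"
        aln = align_semiglobal(ref_seg, read_seg, free_prefix=True)
        assert aln.aligned_a == "TACGT" and aln.aligned_b == "GACGT"


class TestAlignmentToCalls:
    def test_identity_yields_no_calls(self):
        aln = align_nw("ACGTACGT", "ACGTACGT")
        assert alignment_to_calls(aln, 0, "ACGTACGT") == []

    def test_full_reference_coordinates(self, exon_ref):
        seq = exon_ref.sequence
        read = seq[:127] + "T" + seq[128:]
        aln = align_nw(seq, read)
        calls = alignment_to_calls(aln, 0, seq)
        assert [c.name for c in calls] == [f"128{seq[127]}>T"]


class TestNomenclature:
    @pytest.mark.parametrize(
        "call,expected",
        [
            (MutationCall("substitution", 128, "C", "T"), "128C>T"),
            (
                MutationCall("deletion", 137, "GGAATTAAGAGAAGCA", ""),
                "137delGGAATTAAGAGAAGCA",
            ),
            (MutationCall("insertion", 10, "", "GG"), "10insGG"),
        ],
    )
    def test_format(self, call, expected):
        assert format_hgvs(call) == expected

    def test_left_normalize_shifts_deletion_in_repeat(self):
        ref = "GCATATATGC"
        call = MutationCall("deletion", 7, "AT", "")
        assert left_normalize(call, ref).name == "3delAT"

    def test_left_normalize_shifts_insertion_in_repeat(self):
        ref = "GCATATGC"
        call = MutationCall("insertion", 6, "", "AT")
        assert left_normalize(call, ref).name == "2insAT"

    def test_apply_calls_round_trip(self, exon_ref):
        seq = exon_ref.sequence
        calls = [
            MutationCall("substitution", 20, seq[19], "A" if seq[19] != "A" else "T"),
            MutationCall("deletion", 50, seq[49:52], ""),
            MutationCall("insertion", 100, "", "GGA"),
        ]
        mutated = apply_calls(seq, calls)
        assert len(mutated) == len(seq) - 3 + 3
        with pytest.raises(ValueError, match="mismatch"):
            apply_calls(seq, [MutationCall("substitution", 20, "N", "A")])
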