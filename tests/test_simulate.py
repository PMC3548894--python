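"""Synthetic data generator: fidelity, determinism, structure."""

import numpy as np
import pytest
from scipy import stats

from tilecall import (
    IndelSpec,
    MutationSpec,
    RepeatRegionSpec,
    apply_calls,
    make_complex_read,
    make_dataset,
    make_egfr_like_reference,
    make_reference,
    make_repeat_reference,
    mutate_read,
)


class TestMutateRead:
    def test_zero_mutations_returns_reference(self, exon_ref):
        read, truth = mutate_read(exon_ref, MutationSpec(), seed=0)
        assert read == exon_ref.sequence
        assert truth == []

    @pytest.mark.parametrize(
        "spec",
        [
            MutationSpec(n_substitutions=1),
            MutationSpec(n_substitutions=3),
            MutationSpec(indels=(IndelSpec("deletion", 3),)),
            MutationSpec(indels=(IndelSpec("deletion", 100),)),
            MutationSpec(indels=(IndelSpec("insertion", 48),)),
            MutationSpec(
                n_substitutions=1,
                indels=(IndelSpec("deletion", 5), IndelSpec("insertion", 2)),
            ),
        ],
    )
    def test_truth_reapplied_reproduces_read(self, exon_ref, spec):
        rng = np.random.default_rng(42)
        for _ in range(50):
            read, truth = mutate_read(exon_ref, spec, rng)
            assert apply_calls(exon_ref.sequence, truth) == read

    def test_substitutions_never_silent(self, exon_ref):
        rng = np.random.default_rng(7)
        for _ in range(200):
            _, truth = mutate_read(
                exon_ref, MutationSpec(n_substitutions=2), rng
            )
            for call in truth:
                assert call.ref_allele != call.alt_allele

    def test_fixed_position_substitution(self, exon_ref):
        spec = MutationSpec(
            n_substitutions=1,
            substitution_positions=(128,),
            substitution_alts=("T",),
        )
        read, truth = mutate_read(exon_ref, spec, seed=0)
        assert truth[0].ref_position == 128
        assert read[127] == "T"

    def test_indel_longer_than_reference_rejected(self, exon_ref):
        with pytest.raises(ValueError, match="longer"):
            mutate_read(
                exon_ref,
                MutationSpec(indels=(IndelSpec("deletion", 500),)),
                seed=0,
            )

    def test_seed_determinism(self, exon_ref):
        spec = MutationSpec(n_substitutions=2, indels=(IndelSpec("deletion", 4),))
        a = mutate_read(exon_ref, spec, seed=123)
        b = mutate_read(exon_ref, spec, seed=123)
        assert a == b

    def test_substitution_positions_approximately_uniform(self, exon_ref):
        """Chi-square sanity check over 10,000 single-SNP placements."""
        rng = np.random.default_rng(99)
        counts = np.zeros(exon_ref.length)
        for _ in range(10000):
            _, truth = mutate_read(exon_ref, MutationSpec(n_substitutions=1), rng)
            counts[truth[0].ref_position - 1] += 1
        # bin positions to keep expected counts comfortably large
        binned = counts.reshape(45, 5).sum(axis=1)
        p = stats.chisquare(binned).pvalue
        assert p > 1e-6


class TestComplexRead:
    def test_edits_span_at_most_15nt(self, exon_ref):
        rng = np.random.default_rng(5)
        for _ in range(100):
            _, truth = make_complex_read(exon_ref, rng)
            starts = [c.ref_position - 1 for c in truth]
            ends = [
                c.ref_position - 1 + max(len(c.ref_allele), 1) for c in truth
            ]
            assert max(ends) - min(starts) <= 15
            kinds = sorted(c.kind for c in truth)
            assert kinds == ["deletion", "substitution", "substitution"]
            assert len([c for c in truth if c.kind == "deletion"][0].ref_allele) == 4

    def test_reproducible_and_round_trips(self, exon_ref):
        a = make_complex_read(exon_ref, seed=17)
        b = make_complex_read(exon_ref, seed=17)
        assert a == b
        read, truth = a
        assert apply_calls(exon_ref.sequence, truth) == read


class TestRepeatReference:
    def test_wild_type_structure(self):
        spec = RepeatRegionSpec(seed=5)
        ref = make_repeat_reference(spec)
        f, u = spec.flank_length, spec.unit_length
        assert ref.length == 2 * f + 5 * u
        units = [
            ref.sequence[f + i * u : f + (i + 1) * u] for i in range(5)
        ]
        r1, r2a, r2b, r3, r4 = units
        assert r2a == r2b, "R2 present in two identical copies"
        for other in (r1, r3, r4):
            diffs = sum(x != y for x, y in zip(other, r2a))
            assert diffs == 1, "near-perfect: one substitution from R2"

    def test_deletion_allele_is_24bp_shorter(self):
        wt = make_repeat_reference(RepeatRegionSpec(seed=5))
        d = make_repeat_reference(RepeatRegionSpec(seed=5, allele="deletion_24bp"))
        assert wt.length - d.length == 24

    def test_insertion_allele_is_48bp_longer_with_r2prime(self):
        spec = RepeatRegionSpec(seed=5)
        wt = make_repeat_reference(spec)
        ins = make_repeat_reference(
            RepeatRegionSpec(seed=5, allele="insertion_48bp")
        )
        assert ins.length - wt.length == 48
        f, u = spec.flank_length, spec.unit_length
        units = [ins.sequence[f + i * u : f + (i + 1) * u] for i in range(7)]
        r2 = units[1]
        assert units[3] == r2
        assert units[2] == units[4] != r2
        assert sum(x != y for x, y in zip(units[2], r2)) == 1


class TestDatasets:
    def test_count_conservation_and_determinism(self, exon_ref):
        spec = MutationSpec(n_substitutions=1)
        a = make_dataset(exon_ref, 100, spec, seed=8)
        b = make_dataset(exon_ref, 100, spec, seed=8)
        assert len(a.reads) == 100
        assert len(a.truth) == 100
        assert a.reads == b.reads and a.truth == b.truth

    def test_reverse_fraction_produces_rc_reads(self, exon_ref):
        from tilecall import revcomp

        spec = MutationSpec()
        ds = make_dataset(exon_ref, 200, spec, seed=9, reverse_fraction=0.5)
        n_rev = sum(1 for _, seq in ds.reads if seq == revcomp(exon_ref.sequence))
        n_fwd = sum(1 for _, seq in ds.reads if seq == exon_ref.sequence)
        assert n_rev + n_fwd == 200
        assert 60 <= n_rev <= 140

    def test_mid_prefix_and_rc_suffix(self, exon_ref):
        mids = [("MID1", "ACGAGTGCGT")]
        ds = make_dataset(
            exon_ref,
            50,
            MutationSpec(),
            seed=10,
            mids=mids,
            reverse_fraction=0.5,
        )
        from tilecall import revcomp

        for _, seq in ds.reads:
            assert seq.startswith("ACGAGTGCGT") or seq.endswith(
                revcomp("ACGAGTGCGT")
            )


class TestWorkedExampleReference:
    def test_hotspot_layout(self):
        ref = make_egfr_like_reference(seed=0)
        assert ref.length == 225
        assert ref.sequence[127] == "C"
        assert ref.sequence[136:152] == "GGAATTAAGAGAAGCA"
        assert ref.sequence[135] != "A"  # deletion call must not left-shift

    def test_nonrepetitive(self):
        ref = make_egfr_like_reference(seed=0)
        words = [ref.sequence[i : i + 15] for i in range(211)]
        assert len(set(words)) == 211
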