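import numpy as np
import pytest

from ampedit.ops import Deletion, Insertion, Substitution, apply_ops
from ampedit.quantify import (
    EmptyTableError,
    align_read,
    alignment_edits,
    build_allele_table,
    qc_filter,
    top_alleles,
    window_allele,
)
from ampedit.refmodel import RunConfig, cut_site, quant_window
from ampedit.simdata import (
    EditingProfile,
    ErrorModel,
    FastqRecord,
    cas9_profile,
    simulate_reads,
)

from conftest import perfect_read, read_with_ops, rng_dna, window_seq_of


class TestQcFilter:
    def test_boundary_inclusive(self):
        read = FastqRecord("r", "ACGT", [33, 33, 33, 33])
        kept, n_kept, n_disc = qc_filter([read], 33)
        assert n_kept == 1 and n_disc == 0

    def test_mean_just_below_discarded(self):
        read = FastqRecord("r", "ACGTACGTAC", [33] * 9 + [32])  # mean 32.9
        kept, n_kept, n_disc = qc_filter([read], 33)
        assert n_kept == 0 and n_disc == 1

    def test_empty_input(self):
        kept, n_kept, n_disc = qc_filter([], 33)
        assert kept == [] and n_kept == 0 and n_disc == 0


class TestAlignRead:
    def test_reference_read_scores_2L(self, a_toy):
        aln = align_read(perfect_read(a_toy.amplicon_seq), a_toy)
        assert aln.score == 2 * len(a_toy.amplicon_seq)
        assert aln.blocks == [(0, 0, len(a_toy.amplicon_seq))]

    def test_two_bp_deletion_recovered(self, a_toy):
        cut = cut_site(a_toy)
        read = read_with_ops(a_toy, [Deletion(cut - 1, 2)])
        aln = align_read(read, a_toy)
        edits = alignment_edits(aln, a_toy)
        dels = [op for op in edits if isinstance(op, Deletion)]
        assert len(dels) == 1 and dels[0].length == 2
        assert not any(isinstance(op, Substitution) for op in edits)

    def test_random_sequence_unalignable(self, a_toy):
        junk = rng_dna(len(a_toy.amplicon_seq), seed=99)
        assert align_read(perfect_read(junk), a_toy) is None

    def test_indels_left_aligned(self, syn_target):
        # a deletion in a homopolymer-adjacent context must land on the
        # leftmost equivalent placement regardless of where it was applied
        cut = cut_site(syn_target)
        read = read_with_ops(syn_target, [Deletion(cut, 1)])
        edits = alignment_edits(align_read(read, syn_target), syn_target)
        (op,) = edits
        ref = syn_target.amplicon_seq
        pos = op.pos
        assert not (pos > 0 and ref[pos - 1] == ref[pos + op.length - 1])


class TestWindowAllele:
    def test_unedited_read_reference_window(self, a_toy):
        a, b = quant_window(a_toy)
        aln = align_read(perfect_read(a_toy.amplicon_seq), a_toy)
        window_seq, edits = window_allele(aln, a_toy)
        assert window_seq == a_toy.amplicon_seq[a:b]
        assert edits == ()

    def test_in_window_substitution_mapped(self, a_toy):
        # C->T at protospacer position 7 appears as G->A at amplicon coord 24
        coord = a_toy.position_to_coord(7)
        assert coord == 24
        aln = align_read(read_with_ops(a_toy, [Substitution(coord, "A")]), a_toy)
        window_seq, edits = window_allele(aln, a_toy)
        assert edits == (Substitution(24, "A"),)

    def test_substitution_outside_window_ignored(self, syn_target):
        a, b = quant_window(syn_target)
        far = b + 40
        aln = align_read(read_with_ops(syn_target, [Substitution(far, "A" if syn_target.amplicon_seq[far] != "A" else "C")]), syn_target)
        window_seq, edits = window_allele(aln, syn_target)
        assert edits == ()
        assert window_seq == syn_target.amplicon_seq[a:b]

    def test_deletion_marked_in_window_seq(self, a_toy):
        cut = cut_site(a_toy)
        aln = align_read(read_with_ops(a_toy, [Deletion(cut - 1, 2)]), a_toy)
        window_seq, edits = window_allele(aln, a_toy)
        assert window_seq.count("-") == 2
        assert any(isinstance(op, Deletion) and op.length == 2 for op in edits)

    def test_right_edge_insertion_included_left_edge_excluded(self, a_toy):
        a, b = quant_window(a_toy)
        # left neighbour = last window base -> belongs to the allele
        aln = align_read(read_with_ops(a_toy, [Insertion(b, "ACGTA")]), a_toy)
        _, edits = window_allele(aln, a_toy)
        assert any(isinstance(op, Insertion) for op in edits)
        # left neighbour outside the window -> not part of the allele
        aln = align_read(read_with_ops(a_toy, [Insertion(a, "ACGTA")]), a_toy)
        _, edits = window_allele(aln, a_toy)
        assert not any(isinstance(op, Insertion) for op in edits)


class TestBuildAlleleTable:
    def _reads(self, t, n_ref, edited: dict):
        reads = [perfect_read(t.amplicon_seq, f"ref_{i}") for i in range(n_ref)]
        for name, (ops, count) in edited.items():
            seq = apply_ops(t.amplicon_seq, ops)
            reads += [perfect_read(seq, f"{name}_{i}") for i in range(count)]
        return reads

    def test_floor_is_strict_less_than(self, a_toy):
        # 2 reads in 20,000 is exactly 0.01% -> retained
        reads = self._reads(a_toy, 19_998, {"edit": ([Substitution(23, "A")], 2)})
        table = build_allele_table(reads, a_toy, RunConfig())
        assert len(table.records) == 2
        assert table.excluded_lowfreq_mass == 0.0

    def test_below_floor_excluded_with_mass(self, a_toy):
        # 1 read in 20,000 is 0.005% -> excluded, mass reported
        reads = self._reads(a_toy, 19_999, {"edit": ([Substitution(23, "A")], 1)})
        table = build_allele_table(reads, a_toy, RunConfig())
        assert len(table.records) == 1
        assert table.excluded_lowfreq_mass == pytest.approx(0.00005)

    def test_spectrum_recovered_within_half_point(self, a_toy):
        cut = cut_site(a_toy)
        prof = EditingProfile(
            p_edit=0.2,
            allele_spectrum=(
                ((Deletion(cut - 1, 2),), 0.75),
                ((Substitution(23, "A"),), 0.25),
            ),
        )
        reads, truth = simulate_reads(a_toy, prof, ErrorModel(per_base_error=0), 50_000, 3)
        table = build_allele_table(reads, a_toy, RunConfig())
        freq = {r.window_seq: r.frequency for r in table.records}
        expected = {
            window_seq_of(a_toy, []): 0.8,
            window_seq_of(a_toy, [Deletion(cut - 1, 2)]): 0.15,
            window_seq_of(a_toy, [Substitution(23, "A")]): 0.05,
        }
        for wseq, p in expected.items():
            assert freq[wseq] == pytest.approx(p, abs=0.005)

    def test_conservation_counters(self, a_toy):
        prof = cas9_profile(a_toy, p_edit=0.3)
        # low mean quality so the QC filter actually removes reads
        reads, _ = simulate_reads(
            a_toy, prof, ErrorModel(quality_mean=33.2, quality_sd=3), 3000, 6
        )
        reads.append(perfect_read(rng_dna(len(a_toy.amplicon_seq), 5), "junk"))
        table = build_allele_table(reads, a_toy, RunConfig())
        table.check_conservation()
        assert table.qc_discarded > 0
        assert table.unalignable >= 1

    def test_zero_usable_reads_raises(self, a_toy):
        junk = [perfect_read(rng_dna(len(a_toy.amplicon_seq), s), f"j{s}") for s in range(5)]
        with pytest.raises(EmptyTableError):
            build_allele_table(junk, a_toy, RunConfig())

    def test_frequency_normalisation(self, a_toy):
        prof = cas9_profile(a_toy, p_edit=0.4)
        reads, _ = simulate_reads(a_toy, prof, ErrorModel(), 5000, 8)
        table = build_allele_table(reads, a_toy, RunConfig())
        total = sum(r.frequency for r in table.records) + table.excluded_lowfreq_mass
        assert total == pytest.approx(1.0, abs=1e-9)


class TestTopAlleles:
    def test_returns_all_when_fewer_than_n(self, a_toy):
        reads = [perfect_read(a_toy.amplicon_seq, f"r{i}") for i in range(10)]
        reads += [perfect_read(apply_ops(a_toy.amplicon_seq, [Substitution(23, "A")]), "e1")]
        reads += [perfect_read(apply_ops(a_toy.amplicon_seq, [Substitution(24, "A")]), "e2")]
        table = build_allele_table(reads, a_toy, RunConfig(allele_freq_floor=0))
        assert len(top_alleles(table, 10)) == 3

    def test_equal_counts_tie_broken_lexicographically(self, a_toy):
        reads = [
            perfect_read(apply_ops(a_toy.amplicon_seq, [Substitution(23, "A")]), "x"),
            perfect_read(apply_ops(a_toy.amplicon_seq, [Substitution(23, "T")]), "y"),
        ]
        table = build_allele_table(reads, a_toy, RunConfig(allele_freq_floor=0))
        tops = top_alleles(table, 10)
        assert tops[0].window_seq < tops[1].window_seq

    def test_reference_ranked_first_in_mixture(self, a_toy):
        prof = cas9_profile(a_toy, p_edit=0.3)
        reads, _ = simulate_reads(a_toy, prof, ErrorModel(per_base_error=0), 2000, 2)
        table = build_allele_table(reads, a_toy, RunConfig())
        assert top_alleles(table, 10)[0].is_reference
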