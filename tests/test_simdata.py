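import numpy as np
import pytest
from scipy.stats import chisquare

from ampedit.ops import Deletion, Insertion, ProfileError, Substitution, apply_ops, parse_ops
from ampedit.refmodel import cut_site
from ampedit.simdata import (
    EditingProfile,
    ErrorModel,
    FastqParseError,
    TruthTable,
    be3_profile,
    cas9_profile,
    make_synthetic_target,
    read_fastq,
    simulate_fusion_library,
    simulate_reads,
    write_fastq,
)

from conftest import GM, GMH, binom99


class TestEditOps:
    def test_apply_substitution_insertion_deletion(self):
        assert apply_ops("ACGTACGT", [Substitution(1, "T")]) == "ATGTACGT"
        assert apply_ops("ACGTACGT", [Insertion(4, "GG")]) == "ACGTGGACGT"
        assert apply_ops("ACGTACGT", [Deletion(2, 3)]) == "ACCGT"

    def test_overlapping_ops_rejected(self):
        prof_ops = [Deletion(2, 3), Substitution(3, "A")]
        with pytest.raises(ProfileError, match="overlap"):
            apply_ops("ACGTACGT", prof_ops)

    def test_ops_serialisation_roundtrip(self):
        ops = [Substitution(23, "A"), Deletion(10, 2), Insertion(14, "AC")]
        from ampedit.ops import format_ops

        assert parse_ops(format_ops(ops)) == sorted(
            ops, key=lambda o: (o.pos, {Insertion: 0, Substitution: 1, Deletion: 2}[type(o)])
        )


class TestSimulateReads:
    def test_no_editing_no_error_gives_reference_reads(self, a_toy):
        prof = EditingProfile(p_edit=0.0, allele_spectrum=())
        reads, truth = simulate_reads(a_toy, prof, ErrorModel(per_base_error=0), 50, 1)
        assert len(reads) == 50
        assert all(r.seq == a_toy.amplicon_seq for r in reads)
        assert (truth.rows["allele_id"] == "ref").all()

    def test_full_penetrance_deletion(self, a_toy):
        cut = cut_site(a_toy)
        prof = EditingProfile(p_edit=1.0, allele_spectrum=(((Deletion(cut - 1, 2),), 1.0),))
        expected = apply_ops(a_toy.amplicon_seq, [Deletion(cut - 1, 2)])
        reads, truth = simulate_reads(a_toy, prof, ErrorModel(per_base_error=0), 30, 2)
        assert all(r.seq == expected for r in reads)
        assert (truth.rows["allele_id"] == "allele_0").all()

    def test_edited_fraction_within_binomial_interval(self, a_toy):
        prof = cas9_profile(a_toy, p_edit=0.2)
        _, truth = simulate_reads(a_toy, prof, ErrorModel(per_base_error=0), 5000, 1)
        lo, hi = binom99(5000, 0.2)
        assert lo <= truth.edited_fraction() <= hi

    def test_reads_match_truth_alleles_at_zero_error(self, a_toy):
        prof = cas9_profile(a_toy, p_edit=0.5)
        reads, truth = simulate_reads(a_toy, prof, ErrorModel(per_base_error=0), 500, 4)
        by_id = {r.read_id: r.seq for r in reads}
        for row in truth.rows.itertuples(index=False):
            expected = apply_ops(a_toy.amplicon_seq, truth.alleles[row.allele_id])
            assert by_id[row.read_id] == expected

    def test_determinism_byte_identical(self, a_toy, tmp_path):
        prof = be3_profile(a_toy, p_edit=0.3)
        for tag in ("a", "b"):
            reads, truth = simulate_reads(a_toy, prof, ErrorModel(), 400, 9)
            write_fastq(reads, tmp_path / f"{tag}.fastq")
            truth.to_tsv(tmp_path / f"{tag}.truth.tsv")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
        assert (
            tmp_path / "a.truth.tsv"
        ).read_bytes() == (tmp_path / "b.truth.tsv").read_bytes()

    def test_truth_conservation_and_spectrum_convergence(self, a_toy):
        """Allele counts sum to n and empirical fractions match the spectrum
        (chi-square goodness of fit not rejected at alpha=0.001)."""
        prof = EditingProfile(
            p_edit=0.4,
            allele_spectrum=(
                ((Substitution(23, "A"),), 0.5),
                ((Deletion(13, 2),), 0.3),
                ((Insertion(14, "A"),), 0.2),
            ),
        )
        n = 50_000
        _, truth = simulate_reads(a_toy, prof, ErrorModel(per_base_error=0), n, 13)
        counts = truth.allele_counts()
        assert counts.sum() == n
        expected = {
            "ref": 0.6,
            "allele_0": 0.4 * 0.5,
            "allele_1": 0.4 * 0.3,
            "allele_2": 0.4 * 0.2,
        }
        obs = [counts.get(k, 0) for k in expected]
        exp = [n * v for v in expected.values()]
        assert chisquare(obs, exp).pvalue > 0.001


class TestBe3Profile:
    def test_enumerates_c_subsets(self, a_toy):
        prof = be3_profile(a_toy, p_edit=1.0, purity=1.0, byproduct_weight=0, indel_weight=0)
        assert len(prof.allele_spectrum) == 3  # {7}, {8}, {7,8}
        # minus-strand protospacer: C->T on the guide strand is G->A on plus
        alleles = {tuple(sorted(op.pos for op in ops)) for ops, _ in prof.allele_spectrum}
        assert alleles == {(24,), (23,), (23, 24)}
        assert all(
            isinstance(op, Substitution) and op.alt == "A"
            for ops, _ in prof.allele_spectrum
            for op in ops
        )

    def test_purity_one_has_no_indels(self, a_toy):
        prof = be3_profile(a_toy, p_edit=0.5, purity=1.0, byproduct_weight=0, indel_weight=0)
        assert not any(
            isinstance(op, (Insertion, Deletion))
            for ops, _ in prof.allele_spectrum
            for op in ops
        )

    def test_c_free_window_rejected(self):
        t = make_synthetic_target(GM, target_id="gM", seed=7)
        assert t.window_c_positions() == []
        with pytest.raises(ProfileError, match="no cytosine"):
            be3_profile(t, p_edit=0.5)


@pytest.fixture(scope="module")
def loci():
    tA = make_synthetic_target(GM, "locusA", flank=60, seed=21)
    tB = make_synthetic_target(GMH, "locusB", flank=60, seed=22)
    return tA, tB


class TestFusionLibrary:

    def test_no_fusion(self, loci):
        _, truth = simulate_fusion_library(*loci, "balanced", 0.0, 200, 1)
        assert not truth.rows["is_fusion"].any()

    def test_all_fusion(self, loci):
        _, truth = simulate_fusion_library(*loci, "balanced", 1.0, 100, 1)
        assert truth.rows["is_fusion"].sum() == 100

    def test_fusion_rate_within_binomial_interval(self, loci):
        _, truth = simulate_fusion_library(*loci, "acentric", 0.05, 4000, 7)
        lo, hi = binom99(4000, 0.05)
        assert lo <= truth.rows["is_fusion"].mean() <= hi

    def test_invalid_p_fusion(self, loci):
        with pytest.raises(ValueError):
            simulate_fusion_library(*loci, "balanced", 1.5, 10, 1)


class TestFastqIO:
    def test_roundtrip_lossless(self, a_toy, tmp_path):
        prof = cas9_profile(a_toy, p_edit=0.5)
        reads, _ = simulate_reads(a_toy, prof, ErrorModel(), 100, 3)
        path = tmp_path / "x.fastq"
        write_fastq(reads, path)
        back = read_fastq(path)
        assert len(back) == 100
        for orig, rt in zip(reads, back):
            assert rt.read_id == orig.read_id
            assert rt.seq == orig.seq
            assert list(map(int, rt.quals)) == list(map(int, orig.quals))

    def test_truncated_file_raises_at_record_boundary(self, tmp_path):
        path = tmp_path / "t.fastq"
        path.write_text("@r1\nACGT\n+\n")
        with pytest.raises(FastqParseError, match="line"):
            read_fastq(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.fastq"
        path.write_text("")
        assert read_fastq(path) == []

    def test_truth_table_roundtrip(self, a_toy, tmp_path):
        prof = cas9_profile(a_toy, p_edit=0.4)
        _, truth = simulate_reads(a_toy, prof, ErrorModel(), 50, 5)
        path = tmp_path / "truth.tsv"
        truth.to_tsv(path)
        back = TruthTable.from_tsv(path)
        assert back.rows["allele_id"].tolist() == truth.rows["allele_id"].tolist()
        for aid in truth.rows["allele_id"].unique():
            assert back.alleles[aid] == tuple(truth.alleles[aid])


class TestErrorModel:
    def test_error_rate_bounds(self):
        with pytest.raises(ProfileError):
            ErrorModel(per_base_error=0.1)

    def test_qualities_clipped(self, a_toy):
        prof = EditingProfile(p_edit=0.0, allele_spectrum=())
        reads, _ = simulate_reads(
            a_toy, prof, ErrorModel(quality_mean=40, quality_sd=15), 200, 1
        )
        quals = np.concatenate([np.asarray(r.quals) for r in reads])
        assert quals.min() >= 2 and quals.max() <= 41
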