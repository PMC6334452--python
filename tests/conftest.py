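import numpy as np
import pytest

from ampedit.ops import EditOp, apply_ops
from ampedit.quantify import align_read, window_allele
from ampedit.refmodel import GuideTarget
from ampedit.simdata import FastqRecord, make_synthetic_target

GMH = "CAGGTTCCATGGGATGCTCT"  # guide matching both loci (1 human mismatch)
GM = "GGCTGATGAGGCCGCACATG"  # mouse-specific guide (no editing-window C)
GH = "GTCCCGCGGGCGCCCGTGCGC"  # human-specific guide, 21 nt as printed

# Toy fixture: the 20-mer in the middle is revcomp(GMH), so the protospacer
# sits on the minus strand; PAM on the protospacer strand is TGG (plus-strand
# CCA at offsets 8-10).  Plus-strand bases 22-24 form a TGG codon standing in
# for the targeted tryptophan.
A_TOY_SEQ = "ACGTACGTCCA" + "AGAGCATCCCATGGAACCTG" + "GATCTAGGCATCGGATTACA"


@pytest.fixture(scope="session")
def a_toy() -> GuideTarget:
    return GuideTarget(
        target_id="A_toy",
        amplicon_seq=A_TOY_SEQ,
        protospacer=GMH,
        pam="TGG",
        strand="-",
        protospacer_start=30,
        frame_anchor=22,
        cds_bounds=(1, 49),
        quant_halfwidth=12,
    )


@pytest.fixture(scope="session")
def syn_target() -> GuideTarget:
    """Larger synthetic amplicon around the same guide, default 30-bp window."""
    return make_synthetic_target(GMH, target_id="syn_gMH", flank=75, seed=5)


def perfect_read(seq: str, read_id: str = "r") -> FastqRecord:
    return FastqRecord(read_id, seq, [40] * len(seq))


def read_with_ops(t: GuideTarget, ops: list[EditOp], read_id: str = "r") -> FastqRecord:
    return perfect_read(apply_ops(t.amplicon_seq, ops), read_id)


def window_seq_of(t: GuideTarget, ops: list[EditOp]) -> str:
    """Window sequence an error-free read carrying ``ops`` consolidates to."""
    aln = align_read(read_with_ops(t, ops), t)
    assert aln is not None
    result = window_allele(aln, t)
    assert result is not None
    return result[0]


def binom99(n: int, p: float) -> tuple[float, float]:
    """Central 99% interval of a binomial proportion."""
    from scipy.stats import binom

    lo, hi = binom.ppf(0.005, n, p), binom.ppf(0.995, n, p)
    return lo / n, hi / n


def rng_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
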