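"""Read QC, alignment, and windowed allele quantification.

The analysis window is a fixed interval (default 30 bp) centred on the
predicted cleavage site.  Reads passing QC are globally aligned to the
reference amplicon; reads sharing the same window sequence are consolidated
into one allele, and alleles below the frequency floor (default 0.01%,
strict less-than) are dropped with their mass reported separately rather
than renormalised away.

Alignment scoring is match +2 / mismatch -4 / gap open -10 / gap extend
-1 (a length-k gap costs 10 + (k-1)); indels are left-aligned after the
fact so allele descriptions are canonical and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .ops import Deletion, EditOp, Insertion, Substitution, format_ops
from .refmodel import GuideTarget, RunConfig, quant_window
from .simdata import FastqRecord

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -4, -10, -1
MIN_IDENTITY = 0.60


class EmptyTableError(ValueError):
    """No read survived QC, alignment, and window-spanning filters."""


@dataclass
class ReadAlignment:
    """A global read-to-amplicon alignment in block form.

    ``blocks`` are (ref_start, read_start, length) runs of aligned
    (gap-free) columns with strictly increasing reference coordinates;
    gaps are implicit between blocks, so no column is gapped on both sides.
    """

    read_id: str
    score: float
    blocks: list[tuple[int, int, int]]
    read_seq: str
    identity: float

    @property
    def ref_span(self) -> tuple[int, int]:
        """First and last+1 reference coordinates covered by read bases."""
        return (self.blocks[0][0], self.blocks[-1][0] + self.blocks[-1][2])


@dataclass
class AlleleRecord:
    """One consolidated window allele.

    ``window_seq`` holds the read bases aligned within the quantification
    window, with deleted reference columns marked '-' and included
    insertions spliced in; ``edits`` is the canonical, left-aligned edit
    list relative to the reference (window-restricted).
    """

    window_seq: str
    count: int
    frequency: float
    edits: tuple[EditOp, ...]

    @property
    def is_reference(self) -> bool:
        return not self.edits


@dataclass
class AlleleTable:
    sample_id: str
    target_id: str
    total_reads: int
    qc_discarded: int
    unalignable: int
    non_spanning: int
    qc_passing_reads: int  # denominator: QC-passed, alignable, window-spanning
    excluded_lowfreq_mass: float
    records: list[AlleleRecord] = field(default_factory=list)

    def check_conservation(self) -> None:
        tabled = sum(r.count for r in self.records)
        excluded = round(self.excluded_lowfreq_mass * self.qc_passing_reads)
        assert tabled + excluded == self.qc_passing_reads
        assert (
            self.qc_passing_reads
            + self.qc_discarded
            + self.unalignable
            + self.non_spanning
            == self.total_reads
        )
        total_mass = sum(r.frequency for r in self.records) + self.excluded_lowfreq_mass
        assert abs(total_mass - 1.0) < 1e-9

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_seq": [r.window_seq for r in self.records],
                "count": [r.count for r in self.records],
                "frequency": [r.frequency for r in self.records],
                "edits": [format_ops(r.edits) for r in self.records],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# sample={self.sample_id} target={self.target_id} "
                f"coords=1-based-inclusive\n"
                f"# total_reads={self.total_reads} qc_discarded={self.qc_discarded} "
                f"unalignable={self.unalignable} non_spanning={self.non_spanning} "
                f"denominator={self.qc_passing_reads} "
                f"excluded_lowfreq_mass={self.excluded_lowfreq_mass:.9g} "
                f"frequencies_not_renormalized=true\n"
            )
            self.to_frame().to_csv(fh, sep="\t", index=False)


def qc_filter(
    reads: Sequence[FastqRecord], min_mean_quality: float = 33.0
) -> tuple[list[FastqRecord], int, int]:
    """Keep reads whose arithmetic-mean Phred is >= the threshold
    (boundary inclusive).  Returns (kept, n_kept, n_discarded)."""
    kept = [
        r
        for r in reads
        if len(r.quals) > 0 and float(np.mean(r.quals)) >= min_mean_quality
    ]
    return kept, len(kept), len(reads) - len(kept)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def align_read(read: FastqRecord, t: GuideTarget) -> ReadAlignment | None:
    """Global affine-gap alignment of a read to the amplicon.

    Returns None for unalignable reads (identity < 60%).  Of the co-optimal
    alignments the engine's first is taken and indels are then left-shifted
    into canonical form, which fixes tie-breaking deterministically.
    """
    ref = t.amplicon_seq
    if read.seq == ref:  # fast path: the overwhelmingly common case
        return ReadAlignment(read.read_id, MATCH * len(ref), [(0, 0, len(ref))], read.seq, 1.0)
    aln = _ALIGNER.align(ref, read.seq)[0]
    blocks = []
    matches = 0
    for (r0, r1), (q0, q1) in zip(*(a.tolist() for a in aln.aligned)):
        blocks.append((r0, q0, r1 - r0))
        matches += sum(ref[r0 + i] == read.seq[q0 + i] for i in range(r1 - r0))
    identity = matches / max(len(ref), len(read.seq))
    if identity < MIN_IDENTITY:
        return None
    return ReadAlignment(read.read_id, float(aln.score), blocks, read.seq, identity)


def alignment_edits(aln: ReadAlignment, t: GuideTarget) -> list[EditOp]:
    """Canonical edit list for a full alignment, indels left-aligned."""
    ref = t.amplicon_seq
    read = aln.read_seq
    ops: list[EditOp] = []
    prev_ref_end: int | None = None
    prev_read_end: int | None = None
    for r0, q0, length in aln.blocks:
        if prev_ref_end is not None:
            if r0 > prev_ref_end:
                ops.append(_left_align_del(ref, prev_ref_end, r0 - prev_ref_end))
            if q0 > prev_read_end:
                ops.append(_left_align_ins(ref, r0, read[prev_read_end:q0]))
        for i in range(length):
            if ref[r0 + i] != read[q0 + i]:
                ops.append(Substitution(r0 + i, read[q0 + i]))
        prev_ref_end, prev_read_end = r0 + length, q0 + length
    return ops


def _left_align_del(ref: str, pos: int, length: int) -> Deletion:
    while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
        pos -= 1
    return Deletion(pos, length)


def _left_align_ins(ref: str, pos: int, seq: str) -> Insertion:
    while pos > 0 and seq and ref[pos - 1] == seq[-1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return Insertion(pos, seq)


def window_allele(
    aln: ReadAlignment, t: GuideTarget
) -> tuple[str, tuple[EditOp, ...]] | None:
    """Window sequence and window-restricted canonical edits for one read.

    Returns None when the alignment does not span the window.  Insertions
    belong to the window when their left reference neighbour is inside it
    (so right-edge insertions count, left-edge ones do not); edits outside
    the window never affect allele identity.
    """
    a, b = quant_window(t)
    lo_cov, hi_cov = aln.ref_span
    if lo_cov > a or hi_cov < b:
        return None

    ref = t.amplicon_seq
    read = aln.read_seq
    # read bases (or '-') per window reference column, insertions spliced in
    cols: dict[int, str] = {}
    inserts: dict[int, str] = {}
    prev_ref_end: int | None = None
    prev_read_end: int | None = None
    for r0, q0, length in aln.blocks:
        if prev_ref_end is not None:
            if r0 > prev_ref_end:
                for p in range(prev_ref_end, r0):
                    cols[p] = "-"
            if q0 > prev_read_end:
                ins = _left_align_ins(ref, r0, read[prev_read_end:q0])
                inserts[ins.pos] = inserts.get(ins.pos, "") + ins.seq
        for i in range(length):
            cols[r0 + i] = read[q0 + i]
        prev_ref_end, prev_read_end = r0 + length, q0 + length

    pieces = []
    edits: list[EditOp] = []
    run_start = None
    for p in range(a, b + 1):
        # insertion before column p counts iff its left neighbour p-1 is
        # inside the window, i.e. p in (a, b]
        if a < p <= b and p in inserts:
            pieces.append(inserts[p])
            edits.append(Insertion(p, inserts[p]))
        if p == b:
            break
        base = cols[p]
        pieces.append(base)
        if base == "-":
            if run_start is None:
                run_start = p
        else:
            if run_start is not None:
                edits.append(_clip_del(ref, run_start, p - run_start, a))
                run_start = None
            if base != ref[p]:
                edits.append(Substitution(p, base))
    if run_start is not None:
        edits.append(_clip_del(ref, run_start, b - run_start, a))
    window_seq = "".join(pieces)
    return window_seq, tuple(sorted(edits, key=lambda o: (o.pos, str(o))))


def _clip_del(ref: str, pos: int, length: int, window_start: int) -> Deletion:
    d = _left_align_del(ref, pos, length)
    return Deletion(max(d.pos, window_start), length)


def build_allele_table(
    reads: Sequence[FastqRecord],
    t: GuideTarget,
    cfg: RunConfig = RunConfig(),
    sample_id: str = "sample",
) -> AlleleTable:
    """QC, align, window, and consolidate reads into an allele table.

    Frequencies use reads surviving QC, alignment, and window-spanning as
    the denominator.  Alleles with frequency strictly below
    ``cfg.allele_freq_floor`` are excluded; their summed mass is reported
    as ``excluded_lowfreq_mass`` (frequencies are not renormalised).
    """
    total = len(reads)
    kept, _, n_discarded = qc_filter(reads, cfg.min_mean_quality)

    n_unalignable = 0
    n_nonspanning = 0
    groups: dict[str, dict] = {}
    aln_cache: dict[str, tuple[str, tuple[EditOp, ...]] | None | str] = {}
    for read in kept:
        cached = aln_cache.get(read.seq, "MISS")
        if cached == "MISS":
            aln = align_read(read, t)
            if aln is None:
                cached = "UNALIGNABLE"
            else:
                cached = window_allele(aln, t)
            aln_cache[read.seq] = cached
        if cached == "UNALIGNABLE":
            n_unalignable += 1
            continue
        if cached is None:
            n_nonspanning += 1
            continue
        window_seq, edits = cached
        g = groups.setdefault(window_seq, {"count": 0, "edits": edits})
        g["count"] += 1

    denom = len(kept) - n_unalignable - n_nonspanning
    if denom == 0:
        raise EmptyTableError(
            f"sample {sample_id!r}, target {t.target_id!r}: no usable reads "
            f"(total={total}, qc_discarded={n_discarded}, "
            f"unalignable={n_unalignable}, non_spanning={n_nonspanning})"
        )

    records = []
    excluded_mass = 0.0
    for window_seq, g in groups.items():
        freq = g["count"] / denom
        if freq < cfg.allele_freq_floor:
            excluded_mass += freq
            continue
        records.append(AlleleRecord(window_seq, g["count"], freq, g["edits"]))
    records.sort(key=lambda r: (-r.count, r.window_seq))

    table = AlleleTable(
        sample_id=sample_id,
        target_id=t.target_id,
        total_reads=total,
        qc_discarded=n_discarded,
        unalignable=n_unalignable,
        non_spanning=n_nonspanning,
        qc_passing_reads=denom,
        excluded_lowfreq_mass=excluded_mass,
        records=records,
    )
    return table


def top_alleles(table: AlleleTable, n: int = 10) -> list[AlleleRecord]:
    """The ``min(n, len)`` most frequent alleles; ties broken by the
    table's deterministic sort (lexicographically smaller window_seq first)."""
    return table.records[: max(0, n)]


def align_reads(
    reads: Sequence[FastqRecord], t: GuideTarget
) -> tuple[list[ReadAlignment], int]:
    """Align many reads; returns (alignments, n_unalignable).  Caches by
    sequence since amplicon libraries are dominated by duplicate reads."""
    cache: dict[str, ReadAlignment | None] = {}
    out: list[ReadAlignment] = []
    n_un = 0
    for read in reads:
        if read.seq not in cache:
            cache[read.seq] = align_read(read, t)
        hit = cache[read.seq]
        if hit is None:
            n_un += 1
        else:
            out.append(
                ReadAlignment(read.read_id, hit.score, hit.blocks, hit.read_seq, hit.identity)
            )
    return out, n_un
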