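"""Amplicon read simulation with ground truth.

Emulates the library types the analysis is built for: Cas9-style lesions
(NHEJ indel spectra centred on the cut site), BE3-style outcomes (C-to-T
conversions confined to the editing window, with rare non-C-to-T
byproducts and rare small indels), untreated controls, and fusion
libraries carrying translocation junction reads.

Reads are single-end, amplicon-length, Phred+33.  Sequencing error is
substitution-only at a uniform per-base rate, so every read maps back to
its source allele exactly when the error rate is zero; the truth table
records the source allele of every emitted read.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ops import (
    Deletion,
    EditOp,
    Insertion,
    ProfileError,
    Substitution,
    apply_ops,
    check_compatible,
    format_ops,
    parse_ops,
)
from .refmodel import GuideTarget, cut_site, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class EditingProfile:
    """A mixture over edited alleles.

    ``p_edit`` is the fraction of reads drawn from non-reference alleles;
    ``allele_spectrum`` lists (edit-op list, relative weight) pairs in
    amplicon coordinates.  Weights are normalised internally.
    """

    p_edit: float
    allele_spectrum: tuple[tuple[tuple[EditOp, ...], float], ...]

    def __post_init__(self) -> None:
        if not 0 <= self.p_edit <= 1:
            raise ProfileError(f"p_edit {self.p_edit} outside [0, 1]")
        for ops, w in self.allele_spectrum:
            if w <= 0:
                raise ProfileError(f"non-positive weight {w} for allele {format_ops(ops)}")

    def validate_against(self, amplicon_len: int) -> None:
        for ops, _ in self.allele_spectrum:
            check_compatible(ops, amplicon_len)

    @property
    def weights(self) -> np.ndarray:
        w = np.array([w for _, w in self.allele_spectrum], dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class ErrorModel:
    """Uniform substitution error with a Gaussian Phred quality model."""

    per_base_error: float = 0.0002
    quality_mean: float = 37.0
    quality_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.per_base_error <= 0.05:
            raise ProfileError("per_base_error outside [0, 0.05]")


@dataclass
class FastqRecord:
    read_id: str
    seq: str
    quals: "list[int] | np.ndarray"  # Phred values, clipped to [2, 41] by the simulator


@dataclass
class TruthTable:
    """Ground truth: one row per emitted read.

    ``allele_id`` is "ref" for unedited reads, "allele_<k>" for spectrum
    entry k, or a library label for fusion reads.
    """

    rows: pd.DataFrame  # columns: read_id, allele_id, ops, is_fusion
    alleles: dict[str, tuple[EditOp, ...]] = field(default_factory=dict)

    def allele_counts(self) -> pd.Series:
        return self.rows["allele_id"].value_counts()

    def edited_fraction(self) -> float:
        return float((self.rows["allele_id"] != "ref").mean())

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        rows = pd.read_csv(path, sep="\t", dtype={"read_id": str, "allele_id": str, "ops": str})
        rows["ops"] = rows["ops"].fillna(".")
        alleles = {
            aid: tuple(parse_ops(op_str))
            for aid, op_str in rows.drop_duplicates("allele_id")[["allele_id", "ops"]].itertuples(index=False)
        }
        return cls(rows=rows, alleles=alleles)


def _emit_reads(
    sources: list[str],
    choices: np.ndarray,
    err: ErrorModel,
    rng: np.random.Generator,
    prefix: str,
) -> list[FastqRecord]:
    """Emit one read per entry of ``choices`` (an index into ``sources``),
    with substitution errors and qualities drawn in source-grouped batches.
    The RNG consumption order is fixed by source index, so output is
    deterministic for a given seed."""
    n = choices.size
    seq_bytes = [np.frombuffer(s.encode(), dtype=np.uint8) for s in sources]
    read_seqs: list[str] = [""] * n
    read_quals: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * n
    for k in range(len(sources)):
        idx = np.nonzero(choices == k)[0]
        if idx.size == 0:
            continue
        mat = np.tile(seq_bytes[k], (idx.size, 1))
        if err.per_base_error > 0:
            mask = rng.random(mat.shape) < err.per_base_error
            n_err = int(mask.sum())
            if n_err:
                # uniformly random *different* base at each error position
                base_idx = np.searchsorted(_BASES, mat[mask])
                mat[mask] = _BASES[(base_idx + rng.integers(1, 4, size=n_err)) % 4]
        quals = np.clip(
            np.rint(rng.normal(err.quality_mean, err.quality_sd, size=mat.shape)),
            2,
            41,
        ).astype(np.int64)
        for row, i in enumerate(idx):
            read_seqs[i] = mat[row].tobytes().decode()
            read_quals[i] = quals[row]
    return [
        FastqRecord(f"{prefix}_{i}", read_seqs[i], read_quals[i]) for i in range(n)
    ]


def simulate_reads(
    t: GuideTarget,
    prof: EditingProfile,
    err: ErrorModel,
    n: int,
    seed: int,
    read_prefix: str = "read",
) -> tuple[list[FastqRecord], TruthTable]:
    """Draw ``n`` reads from the allele mixture, then apply sequencing error.

    Deterministic for a fixed seed: one RNG stream, fixed draw order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prof.validate_against(len(t.amplicon_seq))
    rng = np.random.default_rng(seed)

    allele_ids = ["ref"] + [f"allele_{k}" for k in range(len(prof.allele_spectrum))]
    allele_seqs = [t.amplicon_seq] + [
        apply_ops(t.amplicon_seq, list(ops)) for ops, _ in prof.allele_spectrum
    ]
    allele_ops: dict[str, tuple[EditOp, ...]] = {"ref": ()}
    for k, (ops, _) in enumerate(prof.allele_spectrum):
        allele_ops[f"allele_{k}"] = tuple(ops)

    if prof.allele_spectrum:
        probs = np.concatenate(([1 - prof.p_edit], prof.p_edit * prof.weights))
    else:
        probs = np.array([1.0])
    choices = rng.choice(len(allele_ids), size=n, p=probs)

    records = _emit_reads(allele_seqs, choices, err, rng, read_prefix)
    truth_rows = []
    for i, k in enumerate(choices):
        aid = allele_ids[k]
        truth_rows.append((records[i].read_id, aid, format_ops(allele_ops[aid]), False))
    truth = TruthTable(
        rows=pd.DataFrame(truth_rows, columns=["read_id", "allele_id", "ops", "is_fusion"]),
        alleles=allele_ops,
    )
    return records, truth


def be3_profile(
    t: GuideTarget,
    p_edit: float,
    purity: float = 0.75,
    byproduct_weight: float = 0.15,
    indel_weight: float = 0.10,
) -> EditingProfile:
    """BE3-like spectrum for a target.

    Pure outcomes enumerate every non-empty subset of editing-window
    cytosines (protospacer strand) converted C->T, sharing ``purity`` of
    the edited mass.  ``byproduct_weight`` goes to non-C->T conversions at
    the same cytosines (C->G, C->A) and ``indel_weight`` to 1-2 bp
    deletions at the cut, the rare BE3 byproducts.  On a minus-strand
    protospacer the emitted plus-strand change is G->A, the strand mirror
    of the C->T edit.
    """
    c_positions = t.window_c_positions()
    if not c_positions:
        raise ProfileError(
            f"target {t.target_id!r}: no cytosine in editing window "
            f"{t.edit_window} (protospacer strand)"
        )

    def sub_at(p: int, proto_alt: str) -> Substitution:
        coord = t.position_to_coord(p)
        alt = proto_alt if t.strand == "+" else revcomp(proto_alt)
        return Substitution(coord, alt)

    spectrum: list[tuple[tuple[EditOp, ...], float]] = []
    subsets = [
        combo
        for r in range(1, len(c_positions) + 1)
        for combo in itertools.combinations(c_positions, r)
    ]
    for combo in subsets:
        ops = tuple(sub_at(p, "T") for p in combo)
        spectrum.append((ops, purity / len(subsets)))

    if byproduct_weight > 0:
        byproducts = [(p, alt) for p in c_positions for alt in ("G", "A")]
        for p, alt in byproducts:
            spectrum.append(((sub_at(p, alt),), byproduct_weight / len(byproducts)))
    if indel_weight > 0:
        cut = cut_site(t)
        for length in (1, 2):
            spectrum.append(((Deletion(cut - 1, length),), indel_weight / 2))
    return EditingProfile(p_edit=p_edit, allele_spectrum=tuple(spectrum))


def cas9_profile(
    t: GuideTarget,
    p_edit: float,
    substitution_weight: float = 0.05,
    insertion_weight: float = 0.10,
) -> EditingProfile:
    """Cas9/NHEJ-like spectrum: deletions of 1-9 bp and 1-bp insertions at
    the cut, geometrically decaying with size (deletion-dominated, roughly
    a quarter of deletions in-frame), plus a small share of cut-proximal
    substitutions (the non-indel tail seen in deep sequencing)."""
    cut = cut_site(t)
    spectrum: list[tuple[tuple[EditOp, ...], float]] = []
    del_weight = 1.0 - substitution_weight - insertion_weight
    del_sizes = list(range(1, 10))
    raw = np.array([0.85 ** s for s in del_sizes])
    for size, w in zip(del_sizes, del_weight * raw / raw.sum()):
        start = max(0, cut - (size + 1) // 2)
        spectrum.append(((Deletion(start, size),), float(w)))
    for base, w in (("A", 0.6), ("T", 0.4)):
        spectrum.append(((Insertion(cut, base),), insertion_weight * w))
    if substitution_weight > 0:
        ref_base = t.amplicon_seq[cut]
        alt = "A" if ref_base != "A" else "G"
        spectrum.append(((Substitution(cut, alt),), substitution_weight))
    return EditingProfile(p_edit=p_edit, allele_spectrum=tuple(spectrum))


def simulate_fusion_library(
    tA: GuideTarget,
    tB: GuideTarget,
    geometry: str,
    p_fusion: float,
    n: int,
    seed: int,
    err: ErrorModel = ErrorModel(),
    read_prefix: str = "fusion",
) -> tuple[list[FastqRecord], TruthTable]:
    """Mixture of intact-locus reads (tA/tB references) and junction reads
    drawn from the requested fusion geometry (balanced or acentric)."""
    from .transloc import build_fusion_templates  # local import: avoid cycle

    if not 0 <= p_fusion <= 1:
        raise ValueError(f"p_fusion {p_fusion} outside [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    templates = build_fusion_templates(tA, tB)
    if geometry not in templates:
        raise ValueError(f"geometry must be one of {sorted(templates)}")
    fusion_seq = templates[geometry].sequence

    rng = np.random.default_rng(seed)
    sources = [tA.amplicon_seq, tB.amplicon_seq, fusion_seq]
    labels = [f"locus_{tA.target_id}", f"locus_{tB.target_id}", f"fusion_{geometry}"]
    probs = np.array([(1 - p_fusion) / 2, (1 - p_fusion) / 2, p_fusion])
    choices = rng.choice(3, size=n, p=probs)

    records = _emit_reads(sources, choices, err, rng, read_prefix)
    truth_rows = [
        (records[i].read_id, labels[k], ".", bool(k == 2))
        for i, k in enumerate(choices)
    ]
    truth = TruthTable(
        rows=pd.DataFrame(truth_rows, columns=["read_id", "allele_id", "ops", "is_fusion"]),
        alleles={lab: () for lab in labels},
    )
    return records, truth


# -- FASTQ I/O ------------------------------------------------------------


class FastqParseError(ValueError):
    pass


def write_fastq(records: list[FastqRecord], path: str | Path) -> None:
    """Write Phred+33 4-line FASTQ."""
    seq_records = []
    for r in records:
        sr = SeqRecord(Seq(r.seq), id=r.read_id, description="")
        sr.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
        seq_records.append(sr)
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fastq")


def read_fastq(path: str | Path) -> list[FastqRecord]:
    """Read Phred+33 FASTQ; malformed records raise with the line reached."""
    with open(path) as fh:
        n_lines = sum(1 for _ in fh)
    if n_lines % 4 != 0:
        raise FastqParseError(
            f"{path}: truncated FASTQ, {n_lines} lines is not a multiple of 4 "
            f"(record boundary at line {n_lines - n_lines % 4 + 1})"
        )
    try:
        return [
            FastqRecord(
                rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"])
            )
            for rec in SeqIO.parse(str(path), "fastq")
        ]
    except ValueError as exc:
        raise FastqParseError(f"{path}: {exc}") from exc


def make_synthetic_target(
    guide: str,
    target_id: str = "synthetic",
    flank: int = 75,
    seed: int = 101,
    quant_halfwidth: int = 15,
    edit_window: tuple[int, int] = (4, 8),
    coding: bool = True,
) -> GuideTarget:
    """Synthetic amplicon embedding ``guide`` as a minus-strand protospacer.

    The construct mirrors the analysed locus geometry: the plus strand reads
    ``<flank> CCA <revcomp(guide)> <flank>``, so the protospacer sits on the
    minus strand with its PAM (TGG on the protospacer strand) immediately
    3' of it.  Flanks are random, GC-balanced, generated from ``seed``.
    With ``coding=True`` the amplicon emulates a coding exon: flank codons
    are resampled until the whole in-frame reference segment is stop-free,
    and the frame anchor is placed on the codon spanning protospacer
    positions 7-9, the position targeted for stop-codon creation by C->T
    editing when that codon is TGG.  With ``coding=False`` (off-target
    panel sites) no reading frame is imposed.
    """
    rng = np.random.default_rng(seed)
    core = "CCA" + revcomp(guide)
    L = len(guide)

    def draw_flank(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    frame_anchor = flank + 3 + L - 9  # first base of the codon at positions 9,8,7
    cds_start = frame_anchor % 3
    # emulate a coding exon: the in-frame reference segment is stop-free, so
    # premature stops can only come from edits; in-frame stop codons landing
    # in the flanks are resampled base by base
    bases = list(draw_flank(flank) + core + draw_flank(flank))
    core_lo, core_hi = flank, flank + len(core)
    stops = ("TAA", "TAG", "TGA")
    for c0 in range(cds_start, len(bases) - 2, 3) if coding else ():
        for _ in range(100):
            if "".join(bases[c0 : c0 + 3]) not in stops:
                break
            mutable = [i for i in range(c0, c0 + 3) if not core_lo <= i < core_hi]
            if not mutable:
                raise ValueError(
                    f"guide {guide!r} encodes an in-frame stop at the anchored frame"
                )
            for i in mutable:
                bases[i] = "ACGT"[rng.integers(0, 4)]
        else:  # pragma: no cover - a non-stop choice always exists
            raise RuntimeError("could not resample a stop-free codon")
    amplicon = "".join(bases)

    return GuideTarget(
        target_id=target_id,
        amplicon_seq=amplicon,
        protospacer=guide,
        pam="TGG",
        strand="-",
        protospacer_start=flank + 3 + L - 1,
        frame_anchor=frame_anchor if coding else None,
        cds_bounds=(cds_start, len(amplicon) - (len(amplicon) - cds_start) % 3)
        if coding
        else None,
        quant_halfwidth=quant_halfwidth,
        edit_window=edit_window,
    )
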