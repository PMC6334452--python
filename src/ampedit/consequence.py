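"""Translation-based classification of window alleles.

Each consolidated allele is spliced back into the amplicon, translated in
the anchored reading frame with the standard genetic code, and binned into
one of six disjoint classes: reference, silent, missense, in-frame indel,
frameshift, nonsense.  Frameshift and nonsense alleles are "null" (the
protein is predicted non-functional).  For base-editing outcomes the
classifier additionally flags "targeted stops": premature stops created
solely by editing-window C->T conversions, which truncate the protein
without introducing any non-reference residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from difflib import SequenceMatcher
from typing import Sequence

from Bio.Seq import Seq

from .ops import Deletion, EditOp, Insertion, Substitution, net_indel
from .quantify import AlleleRecord, AlleleTable
from .refmodel import GuideTarget, quant_window

CLASSES = ("reference", "silent", "missense", "in_frame_indel", "frameshift", "nonsense")


@dataclass(frozen=True)
class ConsequenceCall:
    allele_id: str
    klass: str
    is_null: bool
    stop_codon_coordinate: int | None
    novel_residue_count: int
    carries_targeted_stop: bool
    frequency: float


@dataclass(frozen=True)
class TranslationResult:
    peptide: str  # residues up to and including the first stop ('*') if any
    full_peptide: str
    stop_index: int | None  # codon index of the first stop, None if absent
    stop_codon_coordinate: int | None  # amplicon coordinate (reference-projected)


def _translation_start(t: GuideTarget) -> int:
    """First in-frame coordinate at or after the CDS start."""
    if t.frame_anchor is None or t.cds_bounds is None:
        raise ValueError(
            f"target {t.target_id!r} has no frame_anchor/cds_bounds; "
            "consequence calling needs both"
        )
    c0, _ = t.cds_bounds
    return c0 + (t.frame_anchor - c0) % 3


def _translate(seq: str) -> str:
    # truncate to whole codons; ambiguous codons become X, stops are '*'
    usable = seq[: len(seq) - len(seq) % 3]
    return str(Seq(usable).translate())


def splice_and_translate(
    allele: AlleleRecord, t: GuideTarget
) -> TranslationResult:
    """Rebuild the mutant amplicon from the window allele and translate the
    CDS segment in the anchored frame through the first stop or segment end."""
    a, b = quant_window(t)
    ref = t.amplicon_seq
    window_read = allele.window_seq.replace("-", "")
    mutant = ref[:a] + window_read + ref[b:]

    t0 = _translation_start(t)
    _, c1 = t.cds_bounds
    shift = net_indel(allele.edits)
    # edits are confined to the window, so coordinates < a are unshifted
    mut_end = c1 + shift if c1 >= b else c1
    segment = mutant[t0:mut_end]
    peptide = _translate(segment)

    stop_index = peptide.find("*")
    if stop_index == -1:
        return TranslationResult(peptide, peptide, None, None)
    # project the stop's first base back onto reference coordinates
    mut_coord = t0 + 3 * stop_index
    offset = 0
    for op in allele.edits:
        if isinstance(op, Insertion) and op.pos <= mut_coord - offset:
            offset += len(op.seq)
        elif isinstance(op, Deletion) and op.pos < mut_coord - offset:
            offset -= op.length
    return TranslationResult(
        peptide[: stop_index + 1], peptide, stop_index, mut_coord - offset
    )


def _reference_translation(t: GuideTarget) -> TranslationResult:
    t0 = _translation_start(t)
    peptide = _translate(t.amplicon_seq[t0 : t.cds_bounds[1]])
    stop = peptide.find("*")
    if stop == -1:
        return TranslationResult(peptide, peptide, None, None)
    return TranslationResult(peptide[: stop + 1], peptide, stop, t0 + 3 * stop)


def _is_window_c_to_t(op: EditOp, t: GuideTarget) -> bool:
    """True for a substitution that is a C->T conversion, on the protospacer
    strand, at an editing-window position."""
    if not isinstance(op, Substitution):
        return False
    p = t.coord_to_position(op.pos)
    if p is None or not (t.edit_window[0] <= p <= t.edit_window[1]):
        return False
    if t.protospacer[p - 1] != "C":
        return False
    expected_alt = "T" if t.strand == "+" else "A"  # G->A on the plus strand
    return op.alt == expected_alt


def _novel_residues(mut_prefix: str, ref_prefix: str) -> int:
    """Mutant residues (before the first stop) not matched to the reference
    peptide; alignment-based so residues that merely shift after an in-frame
    indel are not counted as novel."""
    matcher = SequenceMatcher(None, mut_prefix, ref_prefix, autojunk=False)
    matched = sum(block.size for block in matcher.get_matching_blocks())
    return len(mut_prefix) - matched


def classify_allele(allele: AlleleRecord, t: GuideTarget, allele_id: str | None = None) -> ConsequenceCall:
    """Classify one allele.  Rules, in precedence order: reference (no
    edits); frameshift (net indel not a multiple of 3); nonsense (premature
    stop); in-frame indel; missense; silent."""
    aid = allele_id if allele_id is not None else allele.window_seq
    if not allele.edits:
        return ConsequenceCall(aid, "reference", False, None, 0, False, allele.frequency)

    mut = splice_and_translate(allele, t)
    ref = _reference_translation(t)
    premature = mut.stop_index is not None and (
        ref.stop_index is None or mut.stop_index < ref.stop_index
    )
    shift = net_indel(allele.edits)
    has_indel = any(not isinstance(op, Substitution) for op in allele.edits)

    if shift % 3 != 0:
        klass = "frameshift"
    elif premature:
        klass = "nonsense"
    elif has_indel:
        klass = "in_frame_indel"
    else:
        mut_prefix = mut.peptide.rstrip("*")
        ref_prefix = ref.peptide.rstrip("*")
        klass = "missense" if mut_prefix != ref_prefix else "silent"

    is_null = klass in ("frameshift", "nonsense")
    targeted = klass == "nonsense" and all(
        _is_window_c_to_t(op, t) for op in allele.edits
    )
    mut_prefix = mut.peptide.rstrip("*")
    ref_prefix = ref.peptide.rstrip("*")
    novel = 0 if targeted else _novel_residues(mut_prefix, ref_prefix)
    stop_coord = mut.stop_codon_coordinate if premature else None
    return ConsequenceCall(aid, klass, is_null, stop_coord, novel, targeted, allele.frequency)


def classify_table(table: AlleleTable, t: GuideTarget) -> list[ConsequenceCall]:
    return [
        classify_allele(rec, t, allele_id=f"allele_{i}")
        for i, rec in enumerate(table.records)
    ]


def mutation_spectrum(
    table: AlleleTable, calls: Sequence[ConsequenceCall]
) -> dict:
    """Composition of the edited read mass by mutation type.

    Categories (disjoint, summing to 1 over edited mass): single
    substitution, multiple substitutions, insertion-containing,
    deletion-containing, mixed (insertion and deletion).
    """
    fractions = {
        "single_substitution": 0.0,
        "multi_substitution": 0.0,
        "insertion": 0.0,
        "deletion": 0.0,
        "mixed_indel": 0.0,
    }
    edited_mass = 0.0
    for rec in table.records:
        if rec.is_reference:
            continue
        edited_mass += rec.frequency
        has_ins = any(isinstance(op, Insertion) for op in rec.edits)
        has_del = any(isinstance(op, Deletion) for op in rec.edits)
        n_subs = sum(isinstance(op, Substitution) for op in rec.edits)
        if has_ins and has_del:
            key = "mixed_indel"
        elif has_ins:
            key = "insertion"
        elif has_del:
            key = "deletion"
        elif n_subs == 1:
            key = "single_substitution"
        else:
            key = "multi_substitution"
        fractions[key] += rec.frequency
    if edited_mass == 0:
        return {"empty": True, "edited_mass": 0.0, "fractions": fractions}
    return {
        "empty": False,
        "edited_mass": edited_mass,
        "fractions": {k: v / edited_mass for k, v in fractions.items()},
    }


def null_allele_stats(
    table: AlleleTable, calls: Sequence[ConsequenceCall]
) -> dict:
    """Null-allele burden.

    ``absolute_null_frequency`` is the summed frequency of frameshift and
    nonsense alleles over all usable reads.  ``relative_null_percentage``
    divides that by the edited mass, where "edited" excludes reference and
    silent alleles (a silent substitution edits nothing at the protein
    level); the denominator definition is recorded in the output.
    """
    by_id = {c.allele_id: c for c in calls}
    absolute = 0.0
    edited = 0.0
    targeted_stop = 0.0
    per_class = {k: 0.0 for k in CLASSES}
    for i, rec in enumerate(table.records):
        call = by_id.get(f"allele_{i}") or calls[i]
        per_class[call.klass] += rec.frequency
        if call.klass in ("reference", "silent"):
            continue
        edited += rec.frequency
        if call.is_null:
            absolute += rec.frequency
        if call.carries_targeted_stop:
            targeted_stop += rec.frequency
    relative = 100.0 * absolute / edited if edited > 0 else None
    return {
        "absolute_null_frequency": absolute,
        "relative_null_percentage": relative,
        "edited_mass": edited,
        "targeted_stop_frequency": targeted_stop,
        "per_class": per_class,
        "denominator": "edited mass = non-reference, non-silent allele frequency",
    }
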