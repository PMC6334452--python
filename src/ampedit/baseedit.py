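"""Per-position base-substitution profiling over the protospacer.

Counts base changes per protospacer position across aligned reads,
reported on the protospacer strand (a plus-strand G->A over a minus-strand
protospacer is recorded as C->T).  Positions spanned by an indel in a read
are excluded from that position's denominator so indel-rich libraries do
not dilute substitution percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .ops import Deletion, Insertion
from .quantify import AlleleTable, ReadAlignment
from .refmodel import GuideTarget, convert_position, revcomp


@dataclass
class SubstitutionMatrix:
    """Base-change frequencies per protospacer position (PAM-distal
    numbering 1..L internally).  ``counts[p][(ref, alt)]`` are read counts;
    ``coverage[p]`` counts reads with an aligned (non-gap) base at p."""

    L: int
    counts: dict[int, dict[tuple[str, str], int]] = field(default_factory=dict)
    coverage: dict[int, int] = field(default_factory=dict)

    def frequency(self, p: int, ref: str, alt: str) -> float | None:
        cov = self.coverage.get(p, 0)
        if cov == 0:
            return None
        return self.counts.get(p, {}).get((ref, alt), 0) / cov

    def substitution_mass(self, p: int) -> int:
        return sum(self.counts.get(p, {}).values())

    def to_frame(self, numbering: str = "pam_distal") -> pd.DataFrame:
        """Long-format table (position, numbering, ref_base, alt_base,
        frequency, coverage); zero-coverage positions are absent."""
        rows = []
        for p in range(1, self.L + 1):
            cov = self.coverage.get(p, 0)
            if cov == 0:
                continue
            p_out = convert_position(p, "pam_distal", numbering, self.L)
            for (ref, alt), n in sorted(self.counts.get(p, {}).items()):
                rows.append((p_out, numbering, ref, alt, n / cov, cov))
        return pd.DataFrame(
            rows,
            columns=["position", "numbering", "ref_base", "alt_base", "frequency", "coverage"],
        ).sort_values(["position", "ref_base", "alt_base"], ignore_index=True)

    def to_tsv(self, path: str | Path, numbering: str = "pam_distal") -> None:
        with open(path, "w") as fh:
            fh.write(f"# numbering={numbering} coords=1-based-inclusive strand=protospacer\n")
            self.to_frame(numbering).to_csv(fh, sep="\t", index=False)


def substitution_matrix(
    alignments: Sequence[ReadAlignment], t: GuideTarget
) -> SubstitutionMatrix:
    """Tally per-position substitutions from read alignments.

    A read contributes to position p's denominator only when p's amplicon
    coordinate is aligned to a read base (not under a deletion, and the read
    covers it).  Entries are strand-adjusted onto the protospacer strand.
    """
    m = SubstitutionMatrix(L=t.L)
    ref = t.amplicon_seq
    coords = {p: t.position_to_coord(p) for p in range(1, t.L + 1)}
    for aln in alignments:
        covered: dict[int, str] = {}
        for r0, q0, length in aln.blocks:
            for i in range(length):
                covered[r0 + i] = aln.read_seq[q0 + i]
        for p, c in coords.items():
            base = covered.get(c)
            if base is None:
                continue  # deleted or uncovered in this read
            m.coverage[p] = m.coverage.get(p, 0) + 1
            if base != ref[c]:
                if t.strand == "+":
                    key = (ref[c], base)
                else:
                    key = (revcomp(ref[c]), revcomp(base))
                bucket = m.counts.setdefault(p, {})
                bucket[key] = bucket.get(key, 0) + 1
    return m


def targeted_transition_fraction(
    matrix: SubstitutionMatrix, t: GuideTarget
) -> float | None:
    """Share of all substitution events (positions 1..L) that are C->T at
    editing-window cytosines — the programmed base-editing outcome.
    Returns None when there are no substitutions at all (0/0)."""
    total = sum(matrix.substitution_mass(p) for p in range(1, t.L + 1))
    if total == 0:
        return None
    lo, hi = t.edit_window
    targeted = sum(
        matrix.counts.get(p, {}).get(("C", "T"), 0)
        for p in range(lo, hi + 1)
        if t.protospacer[p - 1] == "C"
    )
    return targeted / total


def indel_rate(table: AlleleTable) -> dict:
    """Read-mass fraction of alleles carrying at least one indel op."""
    mass = sum(
        rec.frequency
        for rec in table.records
        if any(isinstance(op, (Insertion, Deletion)) for op in rec.edits)
    )
    edited = sum(rec.frequency for rec in table.records if not rec.is_reference)
    return {"indel_rate": mass, "empty": edited == 0.0}
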