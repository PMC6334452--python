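"""Translocation junction templates, in-silico PCR, and junction reads.

Two cut loci A and B can rejoin in two geometries.  The *balanced*
(reciprocal) junction joins A's upstream segment to B's downstream segment
co-directionally: ``A[0:cut_A] + B[cut_B:]``.  The *acentric* junction is a
head-to-head join of the two upstream segments,
``A[0:cut_A] + revcomp(B[0:cut_B])``; on such a fragment two primers that
are both "forward" on their own loci become convergent, which is what makes
the acentric junction PCR-detectable with a forward/forward primer pair.
The acentric strand arrangement is an assumption inferred from that primer
geometry and is labelled as such in report headers.

PCR primers use exact-match semantics: the assay is presence/absence, and
mismatch tolerance would manufacture bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .refmodel import GuideTarget, cut_site, revcomp
from .simdata import FastqRecord, TruthTable

ACENTRIC_ASSUMPTION = (
    "acentric geometry assumed head-to-head (upstream+revcomp(upstream)), "
    "inferred from convergent forward/forward primer design"
)


class DegenerateTemplateError(ValueError):
    pass


@dataclass(frozen=True)
class FusionTemplate:
    geometry: str  # balanced | acentric
    sequence: str
    junction_offset: int  # coordinate of the first base 3' of the junction
    provenance: tuple  # (target_id_A, cut_A, target_id_B, cut_B, arrangement)


def build_fusion_templates(
    tA: GuideTarget, tB: GuideTarget
) -> dict[str, FusionTemplate]:
    """Balanced and acentric junction templates for two cut loci."""
    cut_a, cut_b = cut_site(tA), cut_site(tB)
    A, B = tA.amplicon_seq, tB.amplicon_seq
    for name, cut, seq in (("A", cut_a, A), ("B", cut_b, B)):
        if cut <= 0 or cut >= len(seq):
            raise DegenerateTemplateError(
                f"locus {name}: cut {cut} at sequence boundary"
            )
    balanced = FusionTemplate(
        "balanced",
        A[:cut_a] + B[cut_b:],
        cut_a,
        (tA.target_id, cut_a, tB.target_id, cut_b, "A_up + B_down"),
    )
    acentric = FusionTemplate(
        "acentric",
        A[:cut_a] + revcomp(B[:cut_b]),
        cut_a,
        (tA.target_id, cut_a, tB.target_id, cut_b, "A_up + revcomp(B_up)"),
    )
    return {"balanced": balanced, "acentric": acentric}


@dataclass(frozen=True)
class PcrProduct:
    start: int  # 5' end of the forward primer on the template
    end: int  # 5' end of the second primer (rightmost template coordinate)
    length: int


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def in_silico_pcr(
    template: str,
    fwd_primer: str,
    second_primer: str,
    second_orientation: str = "reverse",
    max_product: int = 2000,
) -> tuple[list[PcrProduct], bool]:
    """Exact-match PCR prediction on one template strand.

    The forward primer must match the plus strand; the second primer must
    anneal to the minus strand downstream (so the pair is convergent),
    i.e. its reverse complement must appear in the template 3' of the
    forward site.  ``second_orientation`` records whether the second
    primer was designed as a reverse primer of the template locus or as a
    forward primer of the partner locus (which only becomes convergent on
    a head-to-head fusion); the search is identical, the label is kept for
    reporting.  Product length runs from the forward primer's 5' end to
    the second primer's 5' end, inclusive.

    Returns (products, ambiguous): multiple primer binding sites yield all
    products with the ambiguity flag set.
    """
    if len(fwd_primer) < 15 or len(second_primer) < 15:
        raise ValueError("primers must be >= 15 nt")
    if second_orientation not in ("reverse", "forward"):
        raise ValueError(f"unknown orientation {second_orientation!r}")
    fwd_hits = _find_all(template, fwd_primer)
    rev_site = revcomp(second_primer)
    rev_hits = _find_all(template, rev_site)
    products = []
    for i in fwd_hits:
        for j in rev_hits:
            five_prime = j + len(second_primer) - 1  # 5' end on the minus strand
            length = five_prime - i + 1
            if j >= i and length <= max_product:
                products.append(PcrProduct(i, five_prime, length))
    ambiguous = len(fwd_hits) > 1 or len(rev_hits) > 1
    return products, ambiguous


def detect_junction_reads(
    reads: Sequence[FastqRecord],
    template: FusionTemplate,
    min_flank: int = 15,
) -> tuple[int, list[str]]:
    """Count reads spanning the junction with >= ``min_flank`` exactly
    matching bases on each side of it."""
    j = template.junction_offset
    if j < min_flank or j + min_flank > len(template.sequence):
        raise ValueError(
            f"template too short for min_flank={min_flank} at junction {j}"
        )
    probe = template.sequence[j - min_flank : j + min_flank]
    ids = [r.read_id for r in reads if probe in r.seq]
    return len(ids), ids


def translocation_report(
    samples: dict[str, dict],
    expected_products: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per sample x geometry: junction read count, fraction, expected PCR
    product size (a configuration input), and a presence/absence "band"
    column.  Samples with no reads report band as NA.

    ``samples`` maps sample_id -> {geometry: (junction_count, total_reads)}.
    """
    expected_products = expected_products or {}
    rows = []
    for sample_id, per_geom in samples.items():
        for geometry, (count, total) in per_geom.items():
            rows.append(
                {
                    "sample_id": sample_id,
                    "geometry": geometry,
                    "junction_reads": count if total else pd.NA,
                    "total_reads": total,
                    "junction_fraction": (count / total) if total else pd.NA,
                    "expected_product_bp": expected_products.get(geometry, pd.NA),
                    "band": (count > 0) if total else pd.NA,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["assumption"] = ACENTRIC_ASSUMPTION
    return df


def count_junctions_by_truth(
    detected_ids: Sequence[str], truth: TruthTable
) -> dict[str, int]:
    """Cross-tabulate detected junction reads against simulator truth."""
    is_fusion = dict(zip(truth.rows["read_id"], truth.rows["is_fusion"]))
    tp = sum(1 for rid in detected_ids if is_fusion.get(rid, False))
    fp = len(detected_ids) - tp
    fn = int(truth.rows["is_fusion"].sum()) - tp
    return {"true_positive": tp, "false_positive": fp, "false_negative": fn}
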