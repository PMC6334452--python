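"""Off-target panel selection and treated-vs-control comparison.

The panel rule mirrors the base-editing off-target screen: among candidate
sites (nominated upstream by CIRCLE-seq or bioinformatic prediction, and
consumed here as a TSV), keep those with at most 3 mismatches to the
on-target guide AND at least one cytosine in the editing window on the
protospacer strand.  Per-site mutation frequencies come from the windowed
allele quantification; group comparison defaults to a two-sided Fisher
exact test on pooled counts with Benjamini-Hochberg adjustment across the
panel (a per-sample rank-sum alternative is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import EmptyTableError, build_allele_table
from .refmodel import GuideTarget, RunConfig, convert_position
from .simdata import FastqRecord


@dataclass(frozen=True)
class OffTargetSite:
    """A candidate off-target locus: a protospacer-like sequence with its
    own amplicon context, plus its mismatch annotation vs the guide
    (PAM-distal numbering internally)."""

    site_id: str
    locus_label: str
    sequence: str
    pam: str
    mismatch_positions: tuple[int, ...]
    source: str
    target: GuideTarget | None = None

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)

    def has_window_c(self, edit_window: tuple[int, int]) -> bool:
        lo, hi = edit_window
        return any(self.sequence[p - 1] == "C" for p in range(lo, hi + 1))


@dataclass
class GroupComparison:
    site_id: str
    treated: list[tuple[int, int]]  # per-sample (edited, total)
    control: list[tuple[int, int]]
    treated_frequency: float | None
    control_frequency: float | None
    p_value: float | None
    q_value: float | None = None
    significant: bool = False


def mismatches(site_seq: str, guide: str) -> tuple[int, ...]:
    """PAM-distal positions where the site differs from the guide."""
    if len(site_seq) != len(guide):
        raise ValueError(
            f"site length {len(site_seq)} != guide length {len(guide)}"
        )
    return tuple(p for p in range(1, len(guide) + 1) if site_seq[p - 1] != guide[p - 1])


def read_panel_tsv(path: str | Path) -> list[OffTargetSite]:
    df = pd.read_csv(path, sep="\t", comment="#")
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            OffTargetSite(
                site_id=str(row.site_id),
                locus_label=str(getattr(row, "locus_label", row.site_id)),
                sequence=str(row.sequence).upper(),
                pam=str(row.pam).upper(),
                mismatch_positions=(),
                source=str(getattr(row, "source", "unknown")),
            )
        )
    return sites


def select_be_panel(
    candidates: Sequence[OffTargetSite],
    guide: str,
    max_mismatches: int = 3,
    edit_window: tuple[int, int] = (4, 8),
) -> tuple[list[OffTargetSite], list[dict]]:
    """Apply the panel rule: <= ``max_mismatches`` mismatches to the guide
    (boundary inclusive) and >= 1 editing-window cytosine.  Returns the
    selected panel (with mismatch annotations recomputed from the guide)
    and a per-candidate decision log."""
    panel: list[OffTargetSite] = []
    log: list[dict] = []
    for site in candidates:
        try:
            mm = mismatches(site.sequence, guide)
        except ValueError as exc:
            log.append({"site_id": site.site_id, "included": False, "reason": str(exc)})
            continue
        annotated = OffTargetSite(
            site.site_id, site.locus_label, site.sequence, site.pam,
            mm, site.source, site.target,
        )
        if len(mm) > max_mismatches:
            reason = f"{len(mm)} mismatches > {max_mismatches}"
            included = False
        elif not annotated.has_window_c(edit_window):
            reason = f"no cytosine in editing window {edit_window}"
            included = False
        else:
            reason = f"{len(mm)} mismatches, window C present"
            included = True
            panel.append(annotated)
        log.append({"site_id": site.site_id, "included": included, "reason": reason})
    return panel, log


def site_mutation_frequency(
    reads: Sequence[FastqRecord],
    site: GuideTarget,
    cfg: RunConfig = RunConfig(),
    sample_id: str = "sample",
) -> tuple[int, int] | None:
    """(edited, total) read counts at one site, where "edited" is the read
    count of retained non-reference alleles.  None (absent, not zero) when
    no read is usable at the site."""
    try:
        table = build_allele_table(reads, site, cfg, sample_id=sample_id)
    except EmptyTableError:
        return None
    edited = sum(rec.count for rec in table.records if not rec.is_reference)
    return edited, table.qc_passing_reads


def _pool(counts: Sequence[tuple[int, int]]) -> tuple[int, int]:
    return sum(c[0] for c in counts), sum(c[1] for c in counts)


def compare_site(
    treated: Sequence[tuple[int, int]],
    control: Sequence[tuple[int, int]],
    site_id: str = "site",
    method: str = "fisher",
) -> GroupComparison:
    """Compare one site's treated vs control counts.

    ``fisher``: two-sided Fisher exact test on pooled (edited, total)
    counts.  ``ranksum``: two-sided Mann-Whitney U on per-sample edited
    fractions (per-animal view).
    """
    if not treated or not control:
        raise ValueError("need >= 1 sample per group")
    te, tt = _pool(treated)
    ce, ct = _pool(control)
    tf = te / tt if tt else None
    cf = ce / ct if ct else None
    if tt == 0 and ct == 0:
        return GroupComparison(site_id, list(treated), list(control), tf, cf, None)
    if method == "fisher":
        _, p = stats.fisher_exact(
            [[te, tt - te], [ce, ct - ce]], alternative="two-sided"
        )
    elif method == "ranksum":
        tfrac = [e / n for e, n in treated if n]
        cfrac = [e / n for e, n in control if n]
        if tfrac == cfrac:
            p = 1.0
        else:
            _, p = stats.mannwhitneyu(tfrac, cfrac, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(site_id, list(treated), list(control), tf, cf, float(p))


def compare_groups(
    per_site_counts: dict[str, tuple[Sequence[tuple[int, int]], Sequence[tuple[int, int]]]],
    method: str = "fisher",
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Compare every panel site and adjust p-values across sites
    (Benjamini-Hochberg); ``significant`` means q < ``alpha``."""
    comparisons = [
        compare_site(tr, co, site_id=sid, method=method)
        for sid, (tr, co) in per_site_counts.items()
    ]
    tested = [c for c in comparisons if c.p_value is not None]
    if tested:
        reject, q, _, _ = multipletests(
            [c.p_value for c in tested], alpha=alpha, method="fdr_bh"
        )
        for c, qi, rej in zip(tested, q, reject):
            c.q_value = float(qi)
            c.significant = bool(rej)
    return comparisons


def heatmap_table(
    panel: Sequence[OffTargetSite],
    comparisons: Sequence[GroupComparison],
    numbering: str = "pam_distal",
) -> pd.DataFrame:
    """Long-format table for heat-map plotting: one row per (site, group,
    sample), with the mismatch mask rendered in the requested numbering.
    Absent coverage is NA, never 0."""
    by_id = {c.site_id: c for c in comparisons}
    rows = []
    for site in panel:
        L = len(site.sequence)
        mask = ";".join(
            str(convert_position(p, "pam_distal", numbering, L))
            for p in sorted(
                site.mismatch_positions,
                key=lambda p: convert_position(p, "pam_distal", numbering, L),
            )
        )
        comp = by_id.get(site.site_id)
        groups = (
            [("treated", comp.treated), ("control", comp.control)] if comp else []
        )
        for group, counts in groups:
            for i, (e, n) in enumerate(counts):
                rows.append(
                    {
                        "site_id": site.site_id,
                        "locus_label": site.locus_label,
                        "source": site.source,
                        "group": group,
                        "sample_index": i,
                        "frequency": (e / n) if n else pd.NA,
                        "n_mismatches": site.n_mismatches,
                        "mismatch_positions": mask,
                        "numbering": numbering,
                        "significant": comp.significant if comp else pd.NA,
                    }
                )
    return pd.DataFrame(rows)
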