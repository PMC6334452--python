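"""Target geometry: amplicons, protospacers, cut sites, windows, numbering.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open, on the plus strand of the
amplicon.  Protospacer positions use 1-based *PAM-distal* numbering
internally (position 1 is the 5'-most protospacer base, position L abuts
the PAM); reports can request PAM-proximal numbering, related by
``p' = L + 1 - p``.

The cut site follows the canonical SpCas9 blunt-cut rule: the double-strand
break falls 3 bp 5' of the PAM, between protospacer positions L-3 and L-2
(17|18 for a 20-mer).  ``cut_site`` returns the plus-strand coordinate of
the first base 3' of the break.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq


class ConfigurationError(ValueError):
    """Missing or malformed configuration input."""


class ValidationError(ValueError):
    """A target that violates its geometric invariants."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


_PAM_RE = re.compile(r"^[ACGTN]GG$")
_DNA_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class GuideTarget:
    """One amplicon with its guide geometry and analysis windows.

    ``protospacer_start`` is the amplicon coordinate of the protospacer's
    5'-most base: the leftmost base for a plus-strand protospacer, the
    rightmost for a minus-strand one.  ``edit_window`` is an inclusive
    interval of protospacer positions in PAM-distal numbering (default
    4..8, the canonical BE3 deamination window).
    """

    target_id: str
    amplicon_seq: str
    protospacer: str
    pam: str
    strand: str
    protospacer_start: int
    frame_anchor: int | None = None
    cds_bounds: tuple[int, int] | None = None
    quant_halfwidth: int = 15
    edit_window: tuple[int, int] = (4, 8)

    def __post_init__(self) -> None:
        errors = validate_target(self)
        if errors:
            raise ValidationError(
                f"target {self.target_id!r}: " + "; ".join(errors)
            )

    # -- geometry helpers -------------------------------------------------

    @property
    def L(self) -> int:
        return len(self.protospacer)

    @property
    def protospacer_plus_interval(self) -> tuple[int, int]:
        """Half-open plus-strand interval occupied by the protospacer."""
        if self.strand == "+":
            return (self.protospacer_start, self.protospacer_start + self.L)
        return (self.protospacer_start - self.L + 1, self.protospacer_start + 1)

    def position_to_coord(self, p: int) -> int:
        """Plus-strand amplicon coordinate of protospacer position ``p``
        (PAM-distal numbering, 1..L)."""
        if not 1 <= p <= self.L:
            raise ValueError(f"protospacer position {p} outside 1..{self.L}")
        if self.strand == "+":
            return self.protospacer_start + p - 1
        return self.protospacer_start - (p - 1)

    def coord_to_position(self, coord: int) -> int | None:
        """Inverse of position_to_coord; None for coords off the protospacer."""
        lo, hi = self.protospacer_plus_interval
        if not lo <= coord < hi:
            return None
        if self.strand == "+":
            return coord - self.protospacer_start + 1
        return self.protospacer_start - coord + 1

    def window_c_positions(self) -> list[int]:
        """Protospacer positions in the editing window whose protospacer-strand
        base is C (the BE3 substrate positions)."""
        lo, hi = self.edit_window
        return [p for p in range(lo, hi + 1) if self.protospacer[p - 1] == "C"]


@dataclass(frozen=True)
class RunConfig:
    """Run-wide analysis settings (QC threshold, allele floor, reporting)."""

    min_mean_quality: float = 33.0
    allele_freq_floor: float = 0.0001
    top_n_alleles: int = 10
    position_numbering: str = "pam_distal"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.allele_freq_floor < 1:
            raise ConfigurationError("allele_freq_floor must be in [0, 1)")
        if self.top_n_alleles < 1:
            raise ConfigurationError("top_n_alleles must be >= 1")
        if self.position_numbering not in ("pam_distal", "pam_proximal"):
            raise ConfigurationError(
                "position_numbering must be pam_distal or pam_proximal"
            )


def validate_target(t: GuideTarget) -> list[str]:
    """All invariant violations for a target, aggregated (empty = valid)."""
    errors: list[str] = []
    if not _DNA_RE.match(t.amplicon_seq or ""):
        errors.append("amplicon_seq must be uppercase ACGTN")
        return errors
    if not _DNA_RE.match(t.protospacer or "") or len(t.protospacer) not in (20, 21):
        errors.append("protospacer must be ACGTN of length 20 or 21")
        return errors
    if t.strand not in ("+", "-"):
        errors.append(f"strand must be '+' or '-', got {t.strand!r}")
        return errors
    if not _PAM_RE.match(t.pam or ""):
        errors.append(f"PAM {t.pam!r} does not match NGG")

    L = len(t.protospacer)
    lo, hi = t.protospacer_plus_interval
    if lo < 0 or hi > len(t.amplicon_seq):
        errors.append("protospacer extends outside the amplicon")
        return errors
    observed = t.amplicon_seq[lo:hi]
    if t.strand == "-":
        observed = revcomp(observed)
    if observed != t.protospacer:
        errors.append(
            f"protospacer mismatch at amplicon offset {t.protospacer_start} "
            f"({t.strand} strand): found {observed}"
        )
    # PAM immediately 3' of the protospacer on the protospacer strand
    if t.strand == "+":
        pam_lo, pam_hi = hi, hi + 3
        pam_obs = t.amplicon_seq[pam_lo:pam_hi] if pam_hi <= len(t.amplicon_seq) else ""
    else:
        pam_lo, pam_hi = lo - 3, lo
        pam_obs = revcomp(t.amplicon_seq[pam_lo:pam_hi]) if pam_lo >= 0 else ""
    if len(pam_obs) != 3:
        errors.append("PAM site extends outside the amplicon")
    elif _PAM_RE.match(t.pam or "") and pam_obs != t.pam:
        errors.append(f"declared PAM {t.pam} != amplicon PAM {pam_obs}")

    if t.quant_halfwidth < 1:
        errors.append("quant_halfwidth must be >= 1")
    elif not errors:
        c = cut_site(t, _validated=True)
        if c - t.quant_halfwidth < 0 or c + t.quant_halfwidth > len(t.amplicon_seq):
            errors.append(
                f"quantification window [{c - t.quant_halfwidth}, "
                f"{c + t.quant_halfwidth}) overhangs the amplicon"
            )

    wlo, whi = t.edit_window
    if not (1 <= wlo <= whi <= L):
        errors.append(f"edit_window {t.edit_window} outside 1..{L}")

    if t.frame_anchor is not None:
        if not 0 <= t.frame_anchor < len(t.amplicon_seq):
            errors.append("frame_anchor outside the amplicon")
        if t.cds_bounds is not None:
            c0, c1 = t.cds_bounds
            if not 0 <= c0 < c1 <= len(t.amplicon_seq):
                errors.append("cds_bounds outside the amplicon")
            elif (t.frame_anchor - c0) % 3 != 0:
                errors.append("(frame_anchor - cds_bounds.start) mod 3 != 0")
    return errors


def cut_site(t: GuideTarget, _validated: bool = False) -> int:
    """Plus-strand coordinate of the base immediately 3' of the blunt cut.

    The break sits 3 bp 5' of the PAM on the protospacer strand (between
    protospacer positions L-3 and L-2 in PAM-distal numbering).
    """
    lo, hi = t.protospacer_plus_interval
    return hi - 3 if t.strand == "+" else lo + 3


def quant_window(t: GuideTarget) -> tuple[int, int]:
    """Half-open plus-strand interval of the quantification window,
    ``2 * quant_halfwidth`` wide and centred on the cut."""
    c = cut_site(t)
    lo, hi = c - t.quant_halfwidth, c + t.quant_halfwidth
    if lo < 0 or hi > len(t.amplicon_seq):
        raise ValidationError(
            f"target {t.target_id!r}: window [{lo},{hi}) outside amplicon"
        )
    return (lo, hi)


def convert_position(p: int, from_numbering: str, to_numbering: str, L: int) -> int:
    """Convert a protospacer position between PAM-distal and PAM-proximal
    numbering.  ``p' = L + 1 - p`` when the conventions differ."""
    for name in (from_numbering, to_numbering):
        if name not in ("pam_distal", "pam_proximal"):
            raise ValueError(f"unknown numbering {name!r}")
    if not 1 <= p <= L:
        raise ValueError(f"position {p} outside 1..{L}")
    return p if from_numbering == to_numbering else L + 1 - p


def load_targets(fasta_path: str | Path, config_path: str | Path) -> list[GuideTarget]:
    """Load amplicons from FASTA and guide geometry from a YAML/JSON config.

    The config holds a ``targets`` list; each entry names its FASTA record
    via ``amplicon``.  All validation failures across all targets are
    aggregated into one error.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "targets" not in config:
        raise ConfigurationError(f"{config_path}: no 'targets' list")

    targets: list[GuideTarget] = []
    problems: list[str] = []
    for entry in config["targets"]:
        tid = entry.get("target_id", "<unnamed>")
        rec = entry.get("amplicon")
        if rec not in records:
            problems.append(f"target {tid!r}: FASTA record {rec!r} not found")
            continue
        try:
            targets.append(
                GuideTarget(
                    target_id=tid,
                    amplicon_seq=records[rec],
                    protospacer=str(entry["protospacer"]).upper(),
                    pam=str(entry["pam"]).upper(),
                    strand=str(entry["strand"]),
                    protospacer_start=int(entry["protospacer_start"]),
                    frame_anchor=entry.get("frame_anchor"),
                    cds_bounds=tuple(entry["cds_bounds"]) if "cds_bounds" in entry else None,
                    quant_halfwidth=int(entry.get("quant_halfwidth", 15)),
                    edit_window=tuple(entry.get("edit_window", (4, 8))),
                )
            )
        except KeyError as exc:
            problems.append(f"target {tid!r}: missing field {exc}")
        except (ValidationError, ConfigurationError, TypeError, ValueError) as exc:
            problems.append(str(exc))
    if problems:
        raise ValidationError("; ".join(problems))
    return targets
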