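"""Edit operations on amplicon sequences.

Edits are expressed in 0-based reference (amplicon) coordinates.  An
insertion at position ``pos`` places its bases *before* the reference base
at ``pos``; its left reference neighbour is therefore ``pos - 1``.  This
half-open convention is what makes window membership of edge insertions
unambiguous downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence


class ProfileError(ValueError):
    """Raised when an edit set is internally inconsistent (e.g. overlaps)."""


@dataclass(frozen=True, order=True)
class Substitution:
    pos: int
    alt: str

    def __str__(self) -> str:
        return f"S{self.pos}{self.alt}"


@dataclass(frozen=True, order=True)
class Insertion:
    pos: int  # inserted bases go immediately before reference base `pos`
    seq: str

    def __str__(self) -> str:
        return f"I{self.pos}:{self.seq}"


@dataclass(frozen=True, order=True)
class Deletion:
    pos: int
    length: int

    def __str__(self) -> str:
        return f"D{self.pos}:{self.length}"


EditOp = Substitution | Insertion | Deletion

_OP_RE = re.compile(r"^(S(\d+)([ACGTN]))|(I(\d+):([ACGTN]+))|(D(\d+):(\d+))$")


def parse_op(text: str) -> EditOp:
    m = _OP_RE.match(text)
    if m is None:
        raise ValueError(f"unparseable edit op: {text!r}")
    if m.group(1):
        return Substitution(int(m.group(2)), m.group(3))
    if m.group(4):
        return Insertion(int(m.group(5)), m.group(6))
    return Deletion(int(m.group(8)), int(m.group(9)))


def format_ops(ops: Iterable[EditOp]) -> str:
    return ",".join(str(o) for o in sorted(ops, key=_sort_key)) or "."


def parse_ops(text: str) -> list[EditOp]:
    if text in (".", ""):
        return []
    return [parse_op(tok) for tok in text.split(",")]


def _sort_key(op: EditOp) -> tuple[int, int]:
    # insertions sort before the base they precede; deterministic order
    kind = {Substitution: 1, Insertion: 0, Deletion: 2}[type(op)]
    return (op.pos, kind)


def _span(op: EditOp) -> tuple[int, int]:
    """Half-open reference span consumed by an op (empty for insertions)."""
    if isinstance(op, Substitution):
        return (op.pos, op.pos + 1)
    if isinstance(op, Deletion):
        return (op.pos, op.pos + op.length)
    return (op.pos, op.pos)


def check_compatible(ops: Sequence[EditOp], seq_len: int) -> None:
    """Validate that ops fit inside ``seq_len`` and do not overlap."""
    spans = []
    for op in ops:
        lo, hi = _span(op)
        if lo < 0 or hi > seq_len or (isinstance(op, Insertion) and op.pos > seq_len):
            raise ProfileError(f"op {op} outside sequence of length {seq_len}")
        if isinstance(op, Deletion) and op.length < 1:
            raise ProfileError(f"zero-length deletion {op}")
        spans.append((lo, hi, op))
    spans.sort(key=lambda t: (t[0], t[1]))
    for (lo1, hi1, a), (lo2, hi2, b) in zip(spans, spans[1:]):
        if hi1 > lo2 and not (isinstance(a, Insertion) or isinstance(b, Insertion)):
            raise ProfileError(f"overlapping edits {a} and {b}")


def apply_ops(seq: str, ops: Sequence[EditOp]) -> str:
    """Apply edits to ``seq``; ops must be compatible (see check_compatible)."""
    check_compatible(ops, len(seq))
    out = []
    cursor = 0
    for op in sorted(ops, key=_sort_key):
        lo, _ = _span(op)
        out.append(seq[cursor:lo])
        if isinstance(op, Substitution):
            out.append(op.alt)
            cursor = lo + 1
        elif isinstance(op, Insertion):
            out.append(op.seq)
            cursor = lo
        else:
            cursor = lo + op.length
    out.append(seq[cursor:])
    return "".join(out)


def net_indel(ops: Iterable[EditOp]) -> int:
    """Net length change: inserted bases minus deleted bases."""
    n = 0
    for op in ops:
        if isinstance(op, Insertion):
            n += len(op.seq)
        elif isinstance(op, Deletion):
            n -= op.length
    return n
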