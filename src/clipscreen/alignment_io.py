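"""SAM/BAM access, read filters, CIGAR parsing and clip-event extraction.

Soft clipping (CIGAR ``S``) marks terminal read bases that the aligner could
not place against the reference while keeping them in the record.  A read
end that abuts a structural-variant junction is typically soft-clipped at
the junction, so the aligned base adjacent to a clip — the *anchor* — is a
direct breakpoint observation.  This module turns alignment records into
:class:`ClipEvent` objects carrying that anchor.

File access goes through :mod:`pysam`; :class:`AlignedRead` is the minimal
in-memory record the rest of the package consumes, so simulated reads can
bypass the filesystem entirely.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

from .genome_model import GenomicInterval

__all__ = [
    "CigarError",
    "CigarOp",
    "AlignedRead",
    "ClipEvent",
    "parse_cigar",
    "cigar_to_string",
    "reference_span",
    "query_span",
    "passes_filters",
    "clip_events",
    "stream_region",
]

logger = logging.getLogger(__name__)

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")

REF_CONSUMING = frozenset("MDN=X")
QUERY_CONSUMING = frozenset("MIS=X")


class CigarError(ValueError):
    """Malformed CIGAR string (bad token or misplaced S/H op)."""


@dataclass(frozen=True)
class CigarOp:
    op: str
    length: int

    def __post_init__(self) -> None:
        if self.op not in "MIDNSHP=X":
            raise CigarError(f"unknown CIGAR op {self.op!r}")
        if self.length < 1:
            raise CigarError(f"CIGAR length must be >= 1, got {self.length}")

    def __str__(self) -> str:
        return f"{self.length}{self.op}"


def parse_cigar(text: str) -> list[CigarOp]:
    """Parse a CIGAR string, enforcing SAM clip-placement rules.

    ``H`` may appear only as the first/last op; ``S`` only at the ends after
    any ``H``.  Errors name the character offset of the offending token.
    """
    if text == "*" or not text:
        return []
    ops: list[CigarOp] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(text):
        if m.start() != pos:
            raise CigarError(f"malformed CIGAR token at offset {pos} in {text!r}")
        ops.append(CigarOp(m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(text):
        raise CigarError(f"malformed CIGAR token at offset {pos} in {text!r}")
    _check_clip_placement(ops, text)
    return ops


def _check_clip_placement(ops: list[CigarOp], text: str) -> None:
    offset = 0
    n = len(ops)
    for i, op in enumerate(ops):
        if op.op == "H" and i not in (0, n - 1):
            raise CigarError(f"H op not terminal at offset {offset} in {text!r}")
        if op.op == "S":
            left_ok = all(o.op == "H" for o in ops[:i])
            right_ok = all(o.op == "H" for o in ops[i + 1:])
            if not (left_ok or right_ok):
                raise CigarError(
                    f"S op not at a read end at offset {offset} in {text!r}"
                )
        offset += len(str(op))
    body = [o for o in ops if o.op not in "SH"]
    if ops and not body:
        raise CigarError(f"CIGAR {text!r} has no aligned bases")


def cigar_to_string(ops: Iterable[CigarOp]) -> str:
    return "".join(str(op) for op in ops)


def reference_span(ops: Iterable[CigarOp]) -> int:
    """Reference bases consumed: sum over M/D/N/=/X."""
    return sum(op.length for op in ops if op.op in REF_CONSUMING)


def query_span(ops: Iterable[CigarOp]) -> int:
    """Query bases present in SEQ: sum over M/I/S/=/X."""
    return sum(op.length for op in ops if op.op in QUERY_CONSUMING)


@dataclass(frozen=True)
class AlignedRead:
    """Minimal alignment record sufficient for clip analysis."""

    name: str
    contig: str
    pos: int  # leftmost aligned reference position, 1-based
    mapq: int
    cigar: tuple[CigarOp, ...]
    unmapped: bool = False
    secondary: bool = False
    supplementary: bool = False
    duplicate: bool = False
    sequence: Optional[str] = None

    @property
    def reference_span(self) -> int:
        return reference_span(self.cigar)

    @property
    def reference_end(self) -> int:
        """Rightmost aligned reference position (1-based, inclusive)."""
        return self.pos + self.reference_span - 1

    def overlaps(self, region: GenomicInterval) -> bool:
        return (
            self.contig == region.contig
            and self.pos <= region.end
            and self.reference_end >= region.start
        )

    @classmethod
    def from_pysam(cls, aln: "pysam.AlignedSegment") -> "AlignedRead":
        cigar = tuple(parse_cigar(aln.cigarstring or ""))
        seq = aln.query_sequence
        return cls(
            name=aln.query_name or "",
            contig=aln.reference_name or "",
            pos=(aln.reference_start or 0) + 1,
            mapq=aln.mapping_quality,
            cigar=cigar,
            unmapped=aln.is_unmapped,
            secondary=aln.is_secondary,
            supplementary=aln.is_supplementary,
            duplicate=aln.is_duplicate,
            sequence=seq,
        )


@dataclass(frozen=True)
class ClipEvent:
    """One soft-clipped read end anchored to a genomic position.

    The anchor is the aligned base adjacent to the clip: the first aligned
    base for a left clip, the last aligned base for a right clip.  For a
    deletion, right-clip anchors pile up at (deletion start - 1) and
    left-clip anchors at (deletion end + 1).
    """

    read_name: str
    contig: str
    side: str  # "left" | "right"
    clip_len: int
    anchor: int
    clipped_seq: Optional[str] = None


def passes_filters(read: AlignedRead, min_mapq: int = 20) -> bool:
    """The read-level filter applied to numerator and denominator alike.

    Unmapped, secondary, supplementary and duplicate records are excluded
    (supplementary alignments would double-count split reads at exactly the
    junctions this screen targets), as are reads below ``min_mapq``.
    """
    if read.unmapped or read.secondary or read.supplementary or read.duplicate:
        return False
    return read.mapq >= min_mapq


def clip_events(read: AlignedRead, min_clip_len: int = 1) -> list[ClipEvent]:
    """Extract 0-2 clip events from a read; hard clips never shift anchors."""
    events: list[ClipEvent] = []
    ops = [op for op in read.cigar if op.op != "H"]
    if not ops:
        return events
    if ops[0].op == "S" and ops[0].length >= min_clip_len:
        seq = read.sequence[: ops[0].length] if read.sequence else None
        events.append(
            ClipEvent(read.name, read.contig, "left", ops[0].length, read.pos, seq)
        )
    if len(ops) > 1 and ops[-1].op == "S" and ops[-1].length >= min_clip_len:
        seq = read.sequence[-ops[-1].length:] if read.sequence else None
        events.append(
            ClipEvent(
                read.name,
                read.contig,
                "right",
                ops[-1].length,
                read.reference_end,
                seq,
            )
        )
    return events


def stream_region(
    path: str | Path,
    region: Optional[GenomicInterval] = None,
    mode: str = "auto",
) -> Iterator[AlignedRead]:
    """Yield reads whose reference span overlaps ``region`` by >= 1 base.

    ``mode`` is one of ``auto`` (use the index when available, else scan),
    ``index`` (require random access; raise without an index) or ``scan``
    (always read the whole file).  Order is file order in scan mode and
    coordinate order under index-backed fetch.  An unknown contig yields an
    empty iterator with a warning, so multi-target screens do not abort.
    """
    if mode not in ("auto", "index", "scan"):
        raise ValueError(f"mode must be auto|index|scan, got {mode!r}")
    save = pysam.set_verbosity(0)  # silence htslib "no index" chatter
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    finally:
        pysam.set_verbosity(save)
    with af:
        if region is not None and region.contig not in af.references:
            logger.warning(
                "contig %r absent from %s; returning no reads", region.contig, path
            )
            return
        indexed = False
        if region is not None and mode != "scan":
            try:
                indexed = af.check_index()
            except (AttributeError, ValueError, OSError):
                indexed = False
            if mode == "index" and not indexed:
                raise FileNotFoundError(
                    f"{path} has no index; random access unavailable "
                    "(use mode='scan' for a full-file scan)"
                )
        if region is not None and indexed:
            it = af.fetch(region.contig, region.start - 1, region.end)
        else:
            it = af
        for aln in it:
            if aln.is_unmapped:
                if region is None:
                    yield AlignedRead.from_pysam(aln)
                continue
            read = AlignedRead.from_pysam(aln)
            if region is None or read.overlaps(region):
                yield read
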