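"""Coordinate systems, intervals and transcript models.

All genomic coordinates in this package are 1-based and inclusive on both
ends, matching HGVS g. positions and the SAM ``POS`` field.  BED input and
output converts from/to the 0-based half-open convention at the boundary.

The central object is :class:`TranscriptModel`, which projects genomic
positions into CDS (c.) coordinates and back, including intronic offsets
(``c.1029+16`` style).  Projection follows the HGVS convention: positions in
the 5' half of an intron are expressed as a positive offset from the last
CDS base of the preceding exon (the donor side), positions in the 3' half as
a negative offset from the first CDS base of the following exon, and the
midpoint of an even-length intron goes to the donor side.

UTR (c.-n / c.*n) and non-coding (n.) coordinates are out of scope; asking
for them raises :class:`UnsupportedRegionError`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "CoordinateError",
    "OutOfRangeError",
    "UnsupportedRegionError",
    "GenomicInterval",
    "CodingPosition",
    "TranscriptModel",
    "interval_overlap",
    "read_bed",
    "write_bed",
]


class CoordinateError(ValueError):
    """Base class for coordinate-system errors."""


class OutOfRangeError(CoordinateError):
    """A position falls outside the span it is being projected onto."""


class UnsupportedRegionError(CoordinateError):
    """A position lies in a region (UTR, non-coding) this model cannot name."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Closed genomic interval ``[start, end]``, 1-based on both ends."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CoordinateError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise CoordinateError(
                f"end ({self.end}) must be >= start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 when disjoint or on
    different contigs; adjacency under inclusive coordinates is 0)."""
    if a.contig != b.contig:
        return 0
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    return max(0, hi - lo + 1)


_CPOS_RE = re.compile(r"^(\d+)(?:([+-])(\d+))?$")


@dataclass(frozen=True)
class CodingPosition:
    """A c. coordinate: CDS base number plus signed intronic offset.

    ``intron_offset == 0`` means the position is exonic.  A positive offset
    counts downstream of a donor site (``1029+16``), a negative offset counts
    upstream of an acceptor (``1030-20``).
    """

    base: int
    intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.base < 1:
            raise CoordinateError(f"c. base must be >= 1, got {self.base}")

    @property
    def is_intronic(self) -> bool:
        return self.intron_offset != 0

    def sort_key(self) -> tuple[int, int]:
        """Transcript-order key: exonic sits between the -n (before) and +n
        (after) positions of its flanking introns."""
        return (self.base, self.intron_offset)

    def __str__(self) -> str:
        if self.intron_offset == 0:
            return str(self.base)
        sign = "+" if self.intron_offset > 0 else "-"
        return f"{self.base}{sign}{abs(self.intron_offset)}"

    @classmethod
    def parse(cls, text: str) -> "CodingPosition":
        m = _CPOS_RE.match(text.strip())
        if not m:
            raise CoordinateError(f"cannot parse coding position {text!r}")
        base = int(m.group(1))
        offset = 0
        if m.group(2):
            offset = int(m.group(3))
            if m.group(2) == "-":
                offset = -offset
        return cls(base, offset)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure plus CDS bounds; the backbone for g<->c projection.

    ``exons`` are in transcript order (genomically ascending on '+',
    descending on '-').  ``cds_start_g`` is the genomic position of c.1 and
    ``cds_end_g`` the genomic position of the last CDS base, so on the minus
    strand ``cds_start_g > cds_end_g``.
    """

    transcript_id: str
    contig: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_start_g: int
    cds_end_g: int
    source: str = ""  # provenance of the model (e.g. RefSeq release), free text

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise CoordinateError("transcript model needs at least one exon")
        object.__setattr__(self, "exons", tuple(self.exons))
        genomic_sorted = sorted(self.exons, key=lambda e: e.start)
        for prev, nxt in zip(genomic_sorted, genomic_sorted[1:]):
            if nxt.start <= prev.end + 1:
                raise CoordinateError(
                    f"exons must be separated by >= 1 intronic base: "
                    f"{prev} vs {nxt}"
                )
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if tuple(expected) != self.exons:
            raise CoordinateError("exons must be listed in transcript order")
        for pos, name in ((self.cds_start_g, "cds_start_g"), (self.cds_end_g, "cds_end_g")):
            if not any(e.contains(pos) for e in self.exons):
                raise CoordinateError(f"{name}={pos} does not lie inside an exon")
        if self.strand == "+" and self.cds_start_g > self.cds_end_g:
            raise CoordinateError("cds_start_g must be <= cds_end_g on '+' strand")
        if self.strand == "-" and self.cds_start_g < self.cds_end_g:
            raise CoordinateError("cds_start_g must be >= cds_end_g on '-' strand")

    # -- transcript geometry -------------------------------------------------

    @property
    def span(self) -> GenomicInterval:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.contig, lo, hi, self.strand)

    def _t_of_g(self, gpos: int) -> int | None:
        """0-based transcript offset of an exonic genomic position, else None."""
        t = 0
        for e in self.exons:
            if e.contains(gpos):
                return t + (gpos - e.start if self.strand == "+" else e.end - gpos)
            t += e.length
        return None

    def _g_of_t(self, t: int) -> int:
        off = t
        for e in self.exons:
            if off < e.length:
                return e.start + off if self.strand == "+" else e.end - off
            off -= e.length
        raise OutOfRangeError(f"transcript offset {t} beyond exonic length")

    @property
    def cds_length(self) -> int:
        t0 = self._t_of_g(self.cds_start_g)
        t1 = self._t_of_g(self.cds_end_g)
        assert t0 is not None and t1 is not None
        return t1 - t0 + 1

    def exon_id(self, index: int) -> str:
        return f"exon{index + 1}"

    # -- projection ----------------------------------------------------------

    def g_to_c(self, gpos: int) -> CodingPosition:
        """Project a genomic position to a c. coordinate.

        Exonic CDS positions map to offset 0; intronic positions map to the
        nearest exon-boundary CDS base with a signed offset (midpoint ties go
        to the donor side).  UTR positions raise UnsupportedRegionError.
        """
        span = self.span
        if not span.contains(gpos):
            raise OutOfRangeError(
                f"g.{gpos} outside transcript span {span.start}-{span.end}"
            )
        t = self._t_of_g(gpos)
        t_cds0 = self._t_of_g(self.cds_start_g)
        assert t_cds0 is not None
        if t is not None:
            c = t - t_cds0 + 1
            if c < 1 or c > self.cds_length:
                raise UnsupportedRegionError(
                    f"g.{gpos} is exonic but outside the CDS (UTR naming "
                    "is not supported)"
                )
            return CodingPosition(c)
        # intronic: locate the flanking exons in transcript order
        for i, (up, down) in enumerate(zip(self.exons, self.exons[1:])):
            if self.strand == "+":
                inside = up.end < gpos < down.start
                d_donor = gpos - up.end
                d_accept = down.start - gpos
                donor_g, accept_g = up.end, down.start
            else:
                inside = down.end < gpos < up.start
                d_donor = up.start - gpos
                d_accept = gpos - down.end
                donor_g, accept_g = up.start, down.end
            if not inside:
                continue
            if d_donor <= d_accept:  # tie -> donor side
                anchor_g, offset = donor_g, d_donor
            else:
                anchor_g, offset = accept_g, -d_accept
            ta = self._t_of_g(anchor_g)
            assert ta is not None
            c = ta - t_cds0 + 1
            if c < 1 or c > self.cds_length:
                raise UnsupportedRegionError(
                    f"g.{gpos}: nearest exon boundary is outside the CDS"
                )
            return CodingPosition(c, offset)
        raise OutOfRangeError(f"g.{gpos} not locatable in {self.transcript_id}")

    def c_to_g(self, cpos: CodingPosition) -> int:
        """Inverse of :meth:`g_to_c` for valid coding positions."""
        if cpos.base > self.cds_length:
            raise OutOfRangeError(
                f"c.{cpos.base} beyond CDS length {self.cds_length}"
            )
        t_cds0 = self._t_of_g(self.cds_start_g)
        assert t_cds0 is not None
        g_exonic = self._g_of_t(t_cds0 + cpos.base - 1)
        if cpos.intron_offset == 0:
            return g_exonic
        step = 1 if self.strand == "+" else -1
        if cpos.intron_offset > 0:
            if not self._is_exon_edge(g_exonic, donor=True):
                raise CoordinateError(
                    f"c.{cpos}: +offset requires the base to end an exon"
                )
            g = g_exonic + step * cpos.intron_offset
        else:
            if not self._is_exon_edge(g_exonic, donor=False):
                raise CoordinateError(
                    f"c.{cpos}: -offset requires the base to start an exon"
                )
            g = g_exonic + step * cpos.intron_offset
        if self._t_of_g(g) is not None or not self.span.contains(g):
            raise OutOfRangeError(f"c.{cpos} does not land in an intron")
        return g

    def _is_exon_edge(self, gpos: int, donor: bool) -> bool:
        for i, e in enumerate(self.exons):
            tx_last = e.end if self.strand == "+" else e.start
            tx_first = e.start if self.strand == "+" else e.end
            if donor and gpos == tx_last and i < len(self.exons) - 1:
                return True
            if not donor and gpos == tx_first and i > 0:
                return True
        return False

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "transcript_id": self.transcript_id,
                "contig": self.contig,
                "strand": self.strand,
                "exons": [[e.start, e.end] for e in self.exons],
                "cds_start_g": self.cds_start_g,
                "cds_end_g": self.cds_end_g,
                "source": self.source,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TranscriptModel":
        d = json.loads(text)
        strand = d["strand"]
        exons = tuple(
            GenomicInterval(d["contig"], s, e, strand) for s, e in d["exons"]
        )
        return cls(
            transcript_id=d["transcript_id"],
            contig=d["contig"],
            strand=strand,
            exons=exons,
            cds_start_g=d["cds_start_g"],
            cds_end_g=d["cds_end_g"],
            source=d.get("source", ""),
        )

    def to_tsv(self, path: str | Path) -> None:
        """Tabular form: one exon per row plus CDS bounds in a header line."""
        with open(path, "w") as fh:
            fh.write(
                f"#transcript_id={self.transcript_id}\tcontig={self.contig}\t"
                f"strand={self.strand}\tcds_start_g={self.cds_start_g}\t"
                f"cds_end_g={self.cds_end_g}\tsource={self.source}\n"
            )
            fh.write("transcript_id\tcontig\tstrand\texon_start\texon_end\n")
            for e in self.exons:
                fh.write(
                    f"{self.transcript_id}\t{self.contig}\t{self.strand}\t"
                    f"{e.start}\t{e.end}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TranscriptModel":
        meta: dict[str, str] = {}
        rows: list[tuple[int, int]] = []
        contig = strand = tid = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for kv in line[1:].split("\t"):
                        k, _, v = kv.partition("=")
                        meta[k] = v
                    continue
                if line.startswith("transcript_id\t") or not line:
                    continue
                tid, contig, strand, s, e = line.split("\t")[:5]
                rows.append((int(s), int(e)))
        if not rows or contig is None:
            raise CoordinateError(f"no exon rows in {path}")
        rows.sort()
        if meta.get("strand", strand) == "-":
            rows = rows[::-1]
        strand = meta.get("strand", strand)
        exons = tuple(GenomicInterval(contig, s, e, strand) for s, e in rows)
        return cls(
            transcript_id=meta.get("transcript_id", tid),
            contig=contig,
            strand=strand,
            exons=exons,
            cds_start_g=int(meta["cds_start_g"]),
            cds_end_g=int(meta["cds_end_g"]),
            source=meta.get("source", ""),
        )


# -- BED I/O (0-based half-open on disk, 1-based inclusive in memory) --------

def read_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """Read BED3/BED4 target intervals as ``(name, interval)`` pairs.

    Unnamed rows get ``contig:start-end`` names.
    """
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CoordinateError(f"{path}:{ln}: BED needs >= 3 columns")
            contig, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            iv = GenomicInterval(contig, start0 + 1, end0)
            name = parts[3] if len(parts) >= 4 and parts[3] else f"{contig}:{start0 + 1}-{end0}"
            out.append((name, iv))
    return out


def write_bed(path: str | Path, items: Iterable[tuple[str, GenomicInterval]]) -> None:
    with open(path, "w") as fh:
        for name, iv in items:
            fh.write(f"{iv.contig}\t{iv.start - 1}\t{iv.end}\t{name}\n")
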