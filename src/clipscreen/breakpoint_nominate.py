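"""Clip-site clustering, deletion-breakpoint pairing and VCF emission.

A deletion removes reference bases [delStart, delEnd].  Reads anchored on
the left flank are soft-clipped on their *right* end with anchor
delStart - 1; reads anchored on the right flank are clipped on their *left*
end with anchor delEnd + 1.  Clustering the anchors per side and pairing a
right-side cluster with a downstream left-side cluster therefore nominates

    interval = [right.position + 1, left.position - 1]
    length   = left.position - right.position - 1

This is the computational analog of the confirmatory Sanger step: the
screen marks an exon, nomination proposes exact breakpoints, and optional
realignment of the clipped sequences across the mate junction stands in
for sequence-level confirmation.

Only deletions are paired (right-before-left geometry).  Insertions and
duplications produce opposing clips at the same position and surface as
unpaired clusters, without a call.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from . import __version__ as _version
from .alignment_io import AlignedRead, ClipEvent, clip_events, passes_filters
from .genome_model import GenomicInterval
from .hgvs import HgvsGDeletion

__all__ = [
    "PairingError",
    "BreakpointCluster",
    "DeletionCall",
    "cluster_clip_sites",
    "pair_deletion",
    "realign_clip_support",
    "nominate",
    "write_vcf",
]

DEFAULT_WINDOW = 5
DEFAULT_MIN_SUPPORT = 4
DEFAULT_PADDING = 200
DEFAULT_MAX_SPAN = 100_000
DEFAULT_MAX_MISMATCH_FRAC = 0.1


class PairingError(ValueError):
    """Cluster pair with invalid deletion geometry."""


@dataclass(frozen=True)
class BreakpointCluster:
    """A pile-up of same-side clip anchors within a small window."""

    contig: str
    position: int  # modal anchor (ties -> smaller position)
    side: str  # "left" | "right"
    support: int
    median_clip_len: int
    events: tuple[ClipEvent, ...] = ()


@dataclass(frozen=True)
class DeletionCall:
    """A paired-cluster deletion nomination."""

    interval: GenomicInterval
    support_left: int
    support_right: int
    hgvs_g: str
    realign_support: Optional[int] = None

    @property
    def length(self) -> int:
        return self.interval.length


def cluster_clip_sites(
    events: Iterable[ClipEvent],
    window: int = DEFAULT_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[BreakpointCluster]:
    """Single-linkage clustering of clip anchors, separately per side.

    Anchors whose consecutive gap is <= ``window`` join the same cluster;
    clusters with support < ``min_support`` are dropped.  The cluster
    position is the modal anchor, smaller position winning ties, so the
    result is deterministic regardless of input order.
    """
    events = list(events)
    if not events:
        return []
    contigs = {e.contig for e in events}
    if len(contigs) > 1:
        raise ValueError(f"events span multiple contigs: {sorted(contigs)}")
    clusters: list[BreakpointCluster] = []
    for side in ("left", "right"):
        side_events = sorted(
            (e for e in events if e.side == side),
            key=lambda e: (e.anchor, e.read_name),
        )
        if not side_events:
            continue
        run: list[ClipEvent] = [side_events[0]]
        for ev in side_events[1:]:
            if ev.anchor - run[-1].anchor <= window:
                run.append(ev)
            else:
                clusters.append(_finish_cluster(run, side))
                run = [ev]
        clusters.append(_finish_cluster(run, side))
    clusters = [c for c in clusters if c.support >= min_support]
    clusters.sort(key=lambda c: (c.position, c.side))
    return clusters


def _finish_cluster(run: Sequence[ClipEvent], side: str) -> BreakpointCluster:
    counts: dict[int, int] = {}
    for ev in run:
        counts[ev.anchor] = counts.get(ev.anchor, 0) + 1
    modal = min(counts, key=lambda a: (-counts[a], a))
    med = int(statistics.median(ev.clip_len for ev in run))
    return BreakpointCluster(
        contig=run[0].contig,
        position=modal,
        side=side,
        support=len(run),
        median_clip_len=med,
        events=tuple(run),
    )


def pair_deletion(
    right: BreakpointCluster,
    left: BreakpointCluster,
    max_span: int = DEFAULT_MAX_SPAN,
    contig_accession: Optional[str] = None,
) -> DeletionCall:
    """Pair a right-clip cluster with a downstream left-clip cluster.

    The deleted interval sits strictly between the two anchors.  Swapped
    sides or a non-positive span raise :class:`PairingError` (deletions are
    directional; there is no negative length).
    """
    if right.side != "right" or left.side != "left":
        raise PairingError(
            f"expected (right, left) cluster sides, got "
            f"({right.side}, {left.side})"
        )
    if right.contig != left.contig:
        raise PairingError("clusters on different contigs")
    if left.position <= right.position + 1:
        raise PairingError(
            f"zero/negative deletion span: right anchor {right.position}, "
            f"left anchor {left.position}"
        )
    iv = GenomicInterval(right.contig, right.position + 1, left.position - 1)
    if iv.length > max_span:
        raise PairingError(f"span {iv.length} exceeds max_span {max_span}")
    acc = contig_accession or right.contig
    hgvs_g = HgvsGDeletion(acc, iv).render()
    return DeletionCall(
        interval=iv,
        support_left=left.support,
        support_right=right.support,
        hgvs_g=hgvs_g,
    )


def realign_clip_support(
    cluster: BreakpointCluster,
    mate_side_start: int,
    reference: str,
    ref_start: int = 1,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> int:
    """Count clipped segments that realign ungapped across the mate junction.

    For a right-side cluster (clip at the deletion start) the clipped bases
    should match the reference reading forward from ``mate_side_start``
    (the base after the deletion); for a left-side cluster they should
    match reading backward so that the last clipped base sits at
    ``mate_side_start`` (the base before the deletion).  ``reference`` is a
    sequence window whose first base is genomic position ``ref_start``.
    Events without stored sequence contribute 0.
    """
    support = 0
    ref = reference.upper()
    for ev in cluster.events:
        if not ev.clipped_seq:
            continue
        seq = ev.clipped_seq.upper()
        if cluster.side == "right":
            lo = mate_side_start - ref_start
            hi = lo + len(seq)
        else:
            hi = mate_side_start - ref_start + 1
            lo = hi - len(seq)
        if lo < 0 or hi > len(ref):
            raise ValueError(
                "reference window too short to realign a "
                f"{len(seq)}-base clip at g.{mate_side_start}"
            )
        target = ref[lo:hi]
        mism = sum(1 for a, b in zip(seq, target) if a != b)
        if mism / len(seq) <= max_mismatch_frac:
            support += 1
    return support


def nominate(
    reads: Iterable[AlignedRead],
    region: GenomicInterval,
    padding: int = DEFAULT_PADDING,
    min_mapq: int = 20,
    min_clip_len: int = 1,
    window: int = DEFAULT_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
    max_span: int = DEFAULT_MAX_SPAN,
    reference: Optional[str] = None,
    ref_start: int = 1,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    contig_accession: Optional[str] = None,
) -> tuple[list[DeletionCall], list[BreakpointCluster]]:
    """Full nomination pass over a flagged region.

    Clip events are collected from region +/- ``padding`` (intron-anchored
    mates of a boundary-spanning deletion must contribute), clustered per
    side, and paired greedily: highest-support right cluster first, each
    matched to the nearest eligible left cluster.  Returns the calls
    (descending combined support) plus *all* clusters, so unpaired ones —
    possible insertion/duplication signatures — stay visible.
    """
    window_iv = GenomicInterval(
        region.contig, max(1, region.start - padding), region.end + padding,
        region.strand,
    )
    events: list[ClipEvent] = []
    for read in reads:
        if not passes_filters(read, min_mapq):
            continue
        if not read.overlaps(window_iv):
            continue
        for ev in clip_events(read, min_clip_len):
            if window_iv.start <= ev.anchor <= window_iv.end:
                events.append(ev)
    clusters = cluster_clip_sites(events, window=window, min_support=min_support)
    rights = sorted(
        (c for c in clusters if c.side == "right"),
        key=lambda c: (-c.support, c.position),
    )
    lefts = [c for c in clusters if c.side == "left"]
    used: set[int] = set()
    calls: list[DeletionCall] = []
    for rc in rights:
        candidates = [
            (i, lc) for i, lc in enumerate(lefts)
            if i not in used
            and lc.position > rc.position + 1
            and lc.position - rc.position - 1 <= max_span
        ]
        if not candidates:
            continue
        i, lc = min(candidates, key=lambda t: (t[1].position - rc.position,
                                               -t[1].support))
        used.add(i)
        call = pair_deletion(rc, lc, max_span=max_span,
                             contig_accession=contig_accession)
        if reference is not None:
            realn = realign_clip_support(
                rc, lc.position, reference, ref_start, max_mismatch_frac
            ) + realign_clip_support(
                lc, rc.position, reference, ref_start, max_mismatch_frac
            )
            call = DeletionCall(
                interval=call.interval,
                support_left=call.support_left,
                support_right=call.support_right,
                hgvs_g=call.hgvs_g,
                realign_support=realn,
            )
        calls.append(call)
    calls.sort(key=lambda c: (-(c.support_left + c.support_right),
                              c.interval.start))
    return calls, clusters


def write_vcf(
    calls: Sequence[DeletionCall],
    path: str | Path,
    contig_lengths: dict[str, int],
    reference: Optional[str] = None,
    ref_start: int = 1,
) -> None:
    """Write calls as VCF 4.2 deletion records.

    POS is the anchor base before the deleted interval; REF/ALT carry the
    exact sequence when a reference window is supplied and N placeholders
    otherwise.  SVLEN is negative for deletions.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=clipscreen {_version}",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length difference, negative for deletions">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="Last deleted base">',
        '##INFO=<ID=SUPPORT_L,Number=1,Type=Integer,Description="Left-clip cluster support">',
        '##INFO=<ID=SUPPORT_R,Number=1,Type=Integer,Description="Right-clip cluster support">',
        '##INFO=<ID=REALN,Number=1,Type=Integer,Description="Clipped segments realigned across the junction">',
    ]
    for contig, length in contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for call in calls:
        iv = call.interval
        pos = iv.start - 1
        if reference is not None and pos >= ref_start:
            lo = pos - ref_start
            ref_field = reference[lo: lo + iv.length + 1].upper()
            alt_field = ref_field[0]
        else:
            ref_field = "N" * (iv.length + 1)
            alt_field = "N"
        info = (
            f"SVTYPE=DEL;SVLEN=-{iv.length};END={iv.end};"
            f"SUPPORT_L={call.support_left};SUPPORT_R={call.support_right}"
        )
        if call.realign_support is not None:
            info += f";REALN={call.realign_support}"
        lines.append(
            f"{iv.contig}\t{pos}\t.\t{ref_field}\t{alt_field}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
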