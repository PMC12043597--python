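"""HGVS deletion descriptions and frameshift consequence prediction.

Scope is deliberately narrow: genomic (g.) and coding (c.) *deletions*,
which is what a clip-based deletion screen produces.  Insertions,
duplications, delins and repeat notations are out of scope, as is protein
normalization beyond the frameshift case.

Coding names carry intronic offsets (``c.990_1029+16del``) through
:class:`~clipscreen.genome_model.CodingPosition`.  When a reference
sequence is available, deletions are 3'-shifted on the transcript strand to
the most-3' equivalent interval before naming, per the HGVS normalization
rule; without a reference the name is emitted as-is and tagged
unnormalized.

The frameshift model for deletions that remove a splice-donor site is
intron read-through: translation continues from the last intact exonic base
into the residual intron sequence until a stop codon appears.  Exon
skipping and cryptic-splice outcomes are not modelled, and reports label
the assumption.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genome_model import (
    CodingPosition,
    CoordinateError,
    GenomicInterval,
    TranscriptModel,
)

__all__ = [
    "HgvsError",
    "HgvsGDeletion",
    "HgvsCDeletion",
    "ProteinConsequence",
    "InFrameDeletion",
    "parse_g_deletion",
    "parse_c_deletion",
    "deletion_length",
    "shift_3prime",
    "name_c_deletion",
    "frameshift_consequence",
    "consequence_report",
]


class HgvsError(ValueError):
    """Unparseable or unsupported HGVS description."""


_G_DEL_RE = re.compile(r"^([A-Za-z0-9_.]+):g\.(\d+)(?:_(\d+))?del$")
_C_DEL_RE = re.compile(
    r"^([A-Za-z0-9_.]+):c\.(\d+(?:[+-]\d+)?)(?:_(\d+(?:[+-]\d+)?))?del$"
)


@dataclass(frozen=True)
class HgvsGDeletion:
    """A genomic deletion such as ``NC_000011.10:g.57606508_57606563del``."""

    refseq_contig: str
    interval: GenomicInterval

    def render(self) -> str:
        iv = self.interval
        if iv.start == iv.end:
            return f"{self.refseq_contig}:g.{iv.start}del"
        return f"{self.refseq_contig}:g.{iv.start}_{iv.end}del"

    def __str__(self) -> str:
        return self.render()


@dataclass(frozen=True)
class HgvsCDeletion:
    """A coding deletion such as ``NM_000062:c.990_1029+16del``."""

    transcript_id: str
    start: CodingPosition
    end: CodingPosition
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.start.sort_key() > self.end.sort_key():
            raise HgvsError(
                f"c. deletion ends out of transcript order: "
                f"{self.start} > {self.end}"
            )

    def render(self) -> str:
        if self.start == self.end:
            return f"{self.transcript_id}:c.{self.start}del"
        return f"{self.transcript_id}:c.{self.start}_{self.end}del"

    def __str__(self) -> str:
        return self.render()


def parse_g_deletion(text: str) -> HgvsGDeletion:
    """Parse ``ACC:g.START_ENDdel`` or ``ACC:g.POSdel`` (both ends inclusive)."""
    m = _G_DEL_RE.match(text.strip())
    if not m:
        if "del" not in text:
            raise HgvsError(f"only deletions are supported: {text!r}")
        raise HgvsError(f"cannot parse genomic deletion {text!r}")
    contig = m.group(1)
    start = int(m.group(2))
    end = int(m.group(3)) if m.group(3) else start
    if end < start:
        raise HgvsError(f"deletion end {end} precedes start {start}")
    return HgvsGDeletion(contig, GenomicInterval(contig, start, end))


def parse_c_deletion(text: str) -> HgvsCDeletion:
    m = _C_DEL_RE.match(text.strip())
    if not m:
        raise HgvsError(f"cannot parse coding deletion {text!r}")
    start = CodingPosition.parse(m.group(2))
    end = CodingPosition.parse(m.group(3)) if m.group(3) else start
    return HgvsCDeletion(m.group(1), start, end)


def deletion_length(d: HgvsGDeletion) -> int:
    """Number of deleted bases: end - start + 1."""
    return d.interval.length


def _base_at(reference, contig: str, pos: int) -> Optional[str]:
    """1-based base lookup on a plain string or a FASTA handle with fetch()."""
    if isinstance(reference, str):
        if 1 <= pos <= len(reference):
            return reference[pos - 1].upper()
        return None
    try:
        b = reference.fetch(contig, pos - 1, pos)
    except (ValueError, KeyError, IndexError):
        return None
    return b.upper() if b else None


def shift_3prime(reference, interval: GenomicInterval, strand: str,
                 contig: Optional[str] = None) -> GenomicInterval:
    """Shift a deletion to its most-3' equivalent interval on ``strand``.

    Two deletion intervals are equivalent when they leave the same sequence
    behind; shifting moves the window one base at a time in the transcript
    3' direction while the base entering the window equals the base leaving
    it.  ``reference`` is either the full contig sequence as a string or an
    object with a pysam-style ``fetch(contig, start0, end0)``.
    """
    contig = contig or interval.contig
    s, e = interval.start, interval.end
    if strand == "+":
        while True:
            nxt = _base_at(reference, contig, e + 1)
            cur = _base_at(reference, contig, s)
            if nxt is None or cur is None or nxt != cur:
                break
            s += 1
            e += 1
    else:
        while True:
            prv = _base_at(reference, contig, s - 1)
            cur = _base_at(reference, contig, e)
            if prv is None or cur is None or prv != cur:
                break
            s -= 1
            e -= 1
    return GenomicInterval(interval.contig, s, e, interval.strand)


def name_c_deletion(
    tm: TranscriptModel,
    d: HgvsGDeletion,
    reference=None,
) -> HgvsCDeletion:
    """Project a genomic deletion into coding coordinates on ``tm``.

    With ``reference`` supplied the interval is first 3'-shifted (HGVS
    normalization); otherwise it is named as-is with ``normalized=False``.
    Both projected ends are round-tripped back to genomic coordinates as an
    internal consistency check, which for a boundary-spanning call enforces
    exonic span + intronic offset = genomic length.
    """
    iv = d.interval
    if reference is not None:
        iv = shift_3prime(reference, iv, tm.strand, contig=tm.contig)
    if tm.strand == "+":
        g_first, g_last = iv.start, iv.end
    else:
        g_first, g_last = iv.end, iv.start
    c_start = tm.g_to_c(g_first)
    c_end = tm.g_to_c(g_last)
    # round-trip consistency: the named ends must denote the same bases
    if tm.c_to_g(c_start) != g_first or tm.c_to_g(c_end) != g_last:
        raise CoordinateError(
            f"c-projection of {iv} is not invertible on {tm.transcript_id}"
        )
    return HgvsCDeletion(tm.transcript_id, c_start, c_end,
                         normalized=reference is not None)


@dataclass(frozen=True)
class InFrameDeletion:
    """Explicit not-a-frameshift result for in-frame exonic deletions."""

    del_start_c: int
    deleted_cds_bases: int

    @property
    def is_frameshift(self) -> bool:
        return False


@dataclass(frozen=True)
class ProteinConsequence:
    """A frameshift consequence rendered as ``p.(Ref)(Pos)(New)fs*N``.

    ``stop_offset`` counts the first changed residue as 1 (HGVS fs*N); it is
    None when no stop codon occurs within the provided sequence, in which
    case ``rendered`` uses ``fs*?``.  ``mutant_protein_length`` is the
    number of amino acids preceding the new stop.
    """

    first_changed_residue: int
    ref_aa: str
    new_aa: str
    stop_offset: Optional[int]
    rendered: str
    mutant_protein_length: Optional[int]

    @property
    def is_frameshift(self) -> bool:
        return True

    @property
    def no_stop(self) -> bool:
        return self.stop_offset is None


def _translate(nt: str) -> str:
    nt = nt[: len(nt) - len(nt) % 3]
    return str(Seq(nt).translate())


def frameshift_consequence(
    cds_plus_downstream: str,
    del_start_c: int,
    deleted_cds_bases: int,
    readthrough: Optional[str] = None,
) -> Union[ProteinConsequence, InFrameDeletion]:
    """Predict the protein consequence of a CDS deletion.

    ``cds_plus_downstream`` is the reference coding sequence starting at
    c.1 (extra downstream sequence after the stop is harmless).
    ``del_start_c`` is the first deleted CDS base and ``deleted_cds_bases``
    the number of CDS bases removed.  ``readthrough`` is the sequence
    assumed to follow the break in the mutant transcript: for a deletion
    that removes the splice donor this is the residual intron (intron
    read-through model); None means the remaining CDS follows (exon-internal
    deletion).

    An exon-internal deletion of a multiple of 3 bases is not a frameshift
    and returns :class:`InFrameDeletion`.
    """
    cds = cds_plus_downstream.upper().replace("U", "T")
    if del_start_c < 1 or del_start_c > len(cds):
        raise HgvsError(f"del_start_c {del_start_c} outside the CDS")
    if deleted_cds_bases < 1:
        raise HgvsError("deleted_cds_bases must be >= 1")
    if readthrough is None and deleted_cds_bases % 3 == 0:
        return InFrameDeletion(del_start_c, deleted_cds_bases)
    if readthrough is None:
        tail = cds[del_start_c - 1 + deleted_cds_bases:]
    else:
        tail = readthrough.upper().replace("U", "T")
    mutant = cds[: del_start_c - 1] + tail

    ref_prot = _translate(cds)
    mut_prot = _translate(mutant)
    ref_stop = ref_prot.find("*")
    if ref_stop != -1:
        ref_prot = ref_prot[:ref_stop]

    changed = None
    for i in range(len(mut_prot)):
        ref_aa_i = ref_prot[i] if i < len(ref_prot) else None
        if mut_prot[i] == "*":
            if ref_aa_i is None:
                break  # mutant stops after the reference protein ended
            if ref_aa_i != "*":
                changed = i
            break
        if ref_aa_i is None or mut_prot[i] != ref_aa_i:
            changed = i
            break
    if changed is None:
        # deletion silent at the protein level within the window provided
        raise HgvsError(
            "no changed residue found; the deletion does not alter the "
            "protein within the provided sequence"
        )

    pos1 = changed + 1
    ref_aa = ref_prot[changed] if changed < len(ref_prot) else "?"
    new_aa = mut_prot[changed]
    stop_idx = mut_prot.find("*", changed)
    if new_aa == "*":
        rendered = f"p.{seq3(ref_aa)}{pos1}Ter"
        return ProteinConsequence(pos1, seq3(ref_aa), "Ter", 1, rendered, changed)
    if stop_idx == -1:
        rendered = f"p.{seq3(ref_aa)}{pos1}{seq3(new_aa)}fs*?"
        return ProteinConsequence(pos1, seq3(ref_aa), seq3(new_aa), None,
                                  rendered, None)
    stop_offset = stop_idx - changed + 1
    rendered = f"p.{seq3(ref_aa)}{pos1}{seq3(new_aa)}fs*{stop_offset}"
    return ProteinConsequence(pos1, seq3(ref_aa), seq3(new_aa), stop_offset,
                              rendered, stop_idx)


def consequence_report(
    hgvs_g: HgvsGDeletion,
    hgvs_c: Optional[HgvsCDeletion],
    consequence: Union[ProteinConsequence, InFrameDeletion, None],
    transcript_id: str = "",
    model_source: str = "",
) -> dict:
    """Assemble the JSON-ready annotation record for one deletion call."""
    hgvs_p = None
    if isinstance(consequence, ProteinConsequence):
        hgvs_p = consequence.rendered
    elif isinstance(consequence, InFrameDeletion):
        hgvs_p = "in-frame deletion (no frameshift)"
    return {
        "hgvs_g": hgvs_g.render(),
        "hgvs_c": hgvs_c.render() if hgvs_c else None,
        "hgvs_c_normalized": hgvs_c.normalized if hgvs_c else None,
        "hgvs_p": hgvs_p,
        "mutant_protein_length": (
            consequence.mutant_protein_length
            if isinstance(consequence, ProteinConsequence) else None
        ),
        "assumptions": [
            "donor-site deletions modelled as intron read-through; "
            "exon skipping and cryptic splice sites not considered",
        ],
        "transcript_id": transcript_id,
        "model_source": model_source,
    }
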