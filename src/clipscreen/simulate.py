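"""Synthetic targeted-sequencing scenes with constructed soft-clip CIGARs.

The generator emulates the study design this package screens for: an
exome-like 8-exon locus, a heterozygous deletion of a few dozen bases
spanning an exon's 3' boundary, a GC-rich second exon whose reads clip
spuriously at an elevated rate in *every* sample, and a low baseline of
spurious clipping elsewhere.  Reads are emitted pre-aligned: instead of
invoking a real aligner, junction-spanning reads from the deleted
haplotype are anchored on their longer flank and the junction-distal
segment becomes a terminal soft clip — the alignment regime a BWA-style
mapper produces around a deletion too large to absorb into the CIGAR.
That keeps every downstream module testable hermetically and
deterministically; a FASTQ writer is provided for users who want to run
their own aligner.

Junction clips are exact by construction: right-side clip anchors sit at
(deletion start - 1) and left-side anchors at (deletion end + 1), which is
the ground truth breakpoint nomination must recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alignment_io import AlignedRead, CigarOp, cigar_to_string
from .genome_model import GenomicInterval, TranscriptModel

__all__ = [
    "SimConfigError",
    "VariantSpec",
    "SimConfig",
    "Locus",
    "SimRead",
    "SimTruth",
    "SimAlignment",
    "make_locus",
    "make_reads",
    "make_aligned_sam",
    "write_sam",
    "write_fastq",
    "simulate_scene",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SimConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class VariantSpec:
    """A deletion to plant, in reference coordinates (1-based inclusive)."""

    start: int
    end: int
    zygosity: str = "het"  # het | hom

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise SimConfigError("variant end precedes start")
        if self.zygosity not in ("het", "hom"):
            raise SimConfigError(f"zygosity must be het|hom, got {self.zygosity!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SimConfig:
    """Scene parameters.

    Defaults reproduce the screening conditions this package was built
    around: 8 exons, 100x depth, 100-bp paired reads, a GC-rich exon 2
    (70% GC) with ~5% of reads spuriously clipped versus a ~1.5% baseline
    elsewhere (0.0075 per read end), and — when
    :func:`SimConfig.with_boundary_deletion` is used — a heterozygous
    56-bp deletion removing the last 40 bases of exon 6 plus the first 16
    bases of the downstream intron.
    """

    seed: int = 7
    exon_lengths: tuple[int, ...] = (120, 300, 180, 150, 140, 210, 130, 252)
    intron_length: int = 600
    # flank must exceed max intronic deletion extent + target flank +
    # fragment length, or edge reads get truncated (no real-genome analog)
    locus_flank: int = 900
    gc_default: float = 0.45
    gc_by_region: dict = field(default_factory=lambda: {"exon2": 0.70})
    variant: Optional[VariantSpec] = None
    depth: float = 100.0
    read_length: int = 100
    substitution_error: float = 0.001
    background_clip: dict = field(
        default_factory=lambda: {"default": 0.0075, "exon2": 0.025}
    )
    clip_len_range: tuple[int, int] = (5, 30)
    low_mapq_fraction: float = 0.02
    low_mapq_value: int = 5
    target_flank: int = 150
    fragment_length: Optional[int] = None  # default 2 * read_length + 50
    contig: str = "sim1"
    read_seed: Optional[int] = None  # per-sample read randomness; locus stays
    #   tied to `seed`, so cohort members share one reference

    def __post_init__(self) -> None:
        for name, p in [("gc_default", self.gc_default),
                        ("substitution_error", self.substitution_error),
                        ("low_mapq_fraction", self.low_mapq_fraction)]:
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"{name} must be in [0,1], got {p}")
        for k, v in {**self.gc_by_region, **self.background_clip}.items():
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"probability for {k!r} out of [0,1]: {v}")
        if self.depth <= 0:
            raise SimConfigError("depth must be > 0")
        if min(self.exon_lengths) < 20:
            raise SimConfigError("exons shorter than 20 bp are not supported")
        lo, hi = self.clip_len_range
        if not (1 <= lo <= hi < self.read_length):
            raise SimConfigError("clip_len_range must satisfy 1 <= lo <= hi < read length")
        if self.fragment_len < self.read_length:
            raise SimConfigError("fragment length shorter than read length")

    @property
    def fragment_len(self) -> int:
        return self.fragment_length or 2 * self.read_length + 50

    def exon_layout(self) -> list[GenomicInterval]:
        """Deterministic exon coordinates implied by the length config."""
        exons = []
        pos = self.locus_flank + 1
        for length in self.exon_lengths:
            exons.append(GenomicInterval(self.contig, pos, pos + length - 1))
            pos += length + self.intron_length
        return exons

    @property
    def locus_length(self) -> int:
        last = self.exon_layout()[-1]
        return last.end + self.locus_flank

    def with_boundary_deletion(
        self,
        exon_index: int = 5,
        exonic: int = 40,
        intronic: int = 16,
        zygosity: str = "het",
    ) -> "SimConfig":
        """Plant a deletion spanning the 3' boundary of an exon (default:
        exon 6, 40 exonic + 16 intronic = 56 bp, heterozygous)."""
        exon = self.exon_layout()[exon_index]
        if exonic >= exon.length:
            raise SimConfigError("exonic part must leave part of the exon intact")
        if intronic >= self.intron_length:
            raise SimConfigError("intronic part exceeds the intron")
        var = VariantSpec(exon.end - exonic + 1, exon.end + intronic, zygosity)
        return replace(self, variant=var)

    def variant_in_bounds(self) -> None:
        if self.variant and self.variant.end > self.locus_length:
            raise SimConfigError("variant extends beyond the locus")


@dataclass(frozen=True)
class Locus:
    """A synthetic locus: sequence, transcript model and named exon targets."""

    contig: str
    reference: str
    model: TranscriptModel
    exons: tuple[tuple[str, GenomicInterval], ...]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.contig}\n")
            seq = self.reference
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")


def _composition_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """Random sequence with *exact* GC composition (round(gc * length))."""
    n_gc = int(round(gc * length))
    strong = rng.integers(0, 2, size=n_gc)        # 0 -> G, 1 -> C
    weak = rng.integers(0, 2, size=length - n_gc)  # 0 -> A, 1 -> T
    codes = np.concatenate([
        np.where(strong == 0, 2, 3),
        np.where(weak == 0, 0, 1),
    ])
    return rng.permutation(codes)


_BASES = np.array(list("ATGC"))


def make_locus(cfg: SimConfig) -> Locus:
    """Build the reference sequence and transcript model for a config.

    Deterministic for a given seed.  Each region (flanks, exons, introns)
    gets an exact per-region GC composition, so any region of >= 300 bp is
    within rounding error of its target fraction.
    """
    cfg.variant_in_bounds()
    rng = np.random.default_rng([cfg.seed, 0])
    exons = cfg.exon_layout()
    segments: list[tuple[str, int]] = [("flank5", cfg.locus_flank)]
    for i, e in enumerate(exons):
        segments.append((f"exon{i + 1}", e.length))
        if i < len(exons) - 1:
            segments.append((f"intron{i + 1}", cfg.intron_length))
    segments.append(("flank3", cfg.locus_flank))
    parts = []
    for region, length in segments:
        gc = cfg.gc_by_region.get(region, cfg.gc_default)
        parts.append(_composition_sequence(length, gc, rng))
    seq = "".join(_BASES[np.concatenate(parts)])
    model = TranscriptModel(
        transcript_id="SIMT1",
        contig=cfg.contig,
        strand="+",
        exons=tuple(exons),
        cds_start_g=exons[0].start,
        cds_end_g=exons[-1].end,
        source=f"clipscreen simulator seed={cfg.seed}",
    )
    named = tuple((f"exon{i + 1}", e) for i, e in enumerate(exons))
    return Locus(cfg.contig, seq, model, named)


@dataclass(frozen=True)
class SimRead:
    """Placement and artifact decisions for one read, pre-alignment.

    ``start`` is in haplotype coordinates (identical to reference
    coordinates on the unaltered haplotype).
    """

    name: str
    mate: int  # 1 | 2
    haplotype: int  # 0 = reference, 1 = variant-carrying
    start: int
    region: str
    spurious_left: int = 0   # spurious clip length, 0 = none
    spurious_right: int = 0
    low_mapq: bool = False
    index: int = 0  # scene-wide ordinal, seeds per-read error draws


@dataclass
class SimTruth:
    """Ground truth for one scene: the variant plus per-read provenance."""

    variant: Optional[VariantSpec]
    reads: list[SimRead]

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": (
                    None if self.variant is None else {
                        "start": self.variant.start,
                        "end": self.variant.end,
                        "zygosity": self.variant.zygosity,
                    }
                ),
                "n_reads": len(self.reads),
                "reads": [
                    {
                        "name": r.name, "mate": r.mate, "haplotype": r.haplotype,
                        "start": r.start, "region": r.region,
                        "spurious_left": r.spurious_left,
                        "spurious_right": r.spurious_right,
                        "low_mapq": r.low_mapq,
                    }
                    for r in self.reads
                ],
            },
            indent=1,
        )


def _ref_to_hap(x: int, ds: int, de: int, dlen: int) -> int:
    if x < ds:
        return x
    if x <= de:
        return ds
    return x - dlen


def make_reads(locus: Locus, cfg: SimConfig) -> tuple[list[SimRead], SimTruth]:
    """Sample paired fragments uniformly over each exon +/- flank.

    Pair count per target is depth * window / (2 * read length), the
    window being exon + 2 flank + fragment - 1 in reference coordinates.
    For heterozygous variants each fragment's haplotype is an independent
    fair coin; spurious-clip and low-MAPQ indicators are drawn here so the
    truth record is complete before any alignment is constructed.
    """
    rng = np.random.default_rng(
        [cfg.read_seed if cfg.read_seed is not None else cfg.seed, 1]
    )
    L = cfg.read_length
    F = cfg.fragment_len
    var = cfg.variant
    dlen = var.length if var else 0
    hap_len = len(locus.reference) - dlen
    reads: list[SimRead] = []
    idx = 0
    for t_i, (region, exon) in enumerate(locus.exons):
        w_lo = exon.start - cfg.target_flank - (F - 1)
        w_hi = exon.end + cfg.target_flank
        n_pairs = int(round(cfg.depth * (w_hi - w_lo + 1) / (2 * L)))
        p_clip = cfg.background_clip.get(
            region, cfg.background_clip.get("default", 0.0)
        )
        if var:
            h_lo = max(1, _ref_to_hap(w_lo, var.start, var.end, dlen))
            h_hi = min(hap_len - F + 1,
                       _ref_to_hap(w_hi, var.start, var.end, dlen))
        else:
            h_lo, h_hi = w_lo, w_hi
        r_lo = max(1, w_lo)
        r_hi = min(len(locus.reference) - F + 1, w_hi)
        for i in range(n_pairs):
            if var is None:
                hap = 0
            elif var.zygosity == "hom":
                hap = 1
            else:
                hap = int(rng.integers(0, 2))
            lo, hi = (h_lo, h_hi) if hap == 1 else (r_lo, r_hi)
            s = int(rng.integers(lo, hi + 1))
            name = f"sim{t_i}_{i:05d}"
            for mate, start in ((1, s), (2, s + F - L)):
                clips = rng.random(2) < p_clip
                kl = int(rng.integers(*cfg.clip_len_range, endpoint=True)) if clips[0] else 0
                kr = int(rng.integers(*cfg.clip_len_range, endpoint=True)) if clips[1] else 0
                reads.append(
                    SimRead(
                        name=name, mate=mate, haplotype=hap, start=start,
                        region=region, spurious_left=kl, spurious_right=kr,
                        low_mapq=bool(rng.random() < cfg.low_mapq_fraction),
                        index=idx,
                    )
                )
                idx += 1
    return reads, SimTruth(variant=var, reads=reads)


@dataclass(frozen=True)
class SimAlignment:
    """One SAM record: the in-memory read plus pairing fields."""

    read: AlignedRead
    flag: int
    mate_pos: int
    tlen: int

    def sam_line(self) -> str:
        r = self.read
        seq = r.sequence or "*"
        qual = "I" * len(seq) if r.sequence else "*"
        return "\t".join([
            r.name, str(self.flag), r.contig, str(r.pos), str(r.mapq),
            cigar_to_string(r.cigar), "=", str(self.mate_pos),
            str(self.tlen), seq, qual,
        ])


def _hap_sequence(locus: Locus, var: Optional[VariantSpec]) -> tuple[str, str]:
    ref = locus.reference
    if var is None:
        return ref, ref
    mut = ref[: var.start - 1] + ref[var.end:]
    return ref, mut


def _read_alignment(
    sr: SimRead, var: Optional[VariantSpec], L: int
) -> tuple[int, list[tuple[str, int]]]:
    """Reference POS and CIGAR op list for one read, before spurious clips."""
    s = sr.start
    if sr.haplotype == 0 or var is None:
        return s, [("M", L)]
    ds, dlen = var.start, var.length
    if s < ds <= s + L - 1:
        p = ds - s
        q = L - p
        if p >= q:
            return s, [("M", p), ("S", q)]
        return var.end + 1, [("S", p), ("M", q)]
    return (s if s + L - 1 < ds else s + dlen), [("M", L)]


def _apply_spurious(
    pos: int, ops: list[tuple[str, int]], kl: int, kr: int
) -> tuple[int, list[tuple[str, int]]]:
    """Convert terminal aligned bases to soft clips (the artifact regime).

    A junction-clipped end is left alone; clips are clamped so at least
    one aligned base remains.
    """
    if kl and ops[0][0] == "M":
        m = ops[0][1]
        k = min(kl, m - 1)
        if k >= 1:
            ops = [("S", k), ("M", m - k)] + ops[1:]
            pos += k
    if kr and ops[-1][0] == "M":
        m = ops[-1][1]
        k = min(kr, m - 1)
        if k >= 1:
            ops = ops[:-1] + [("M", m - k), ("S", k)]
    return pos, ops


def _seq_seed(cfg: SimConfig) -> int:
    return cfg.read_seed if cfg.read_seed is not None else cfg.seed


def _read_seq(
    hap_seq: str, sr: SimRead, L: int, err: float, seed: int
) -> str:
    raw = hap_seq[sr.start - 1: sr.start + L - 1]
    if err <= 0:
        return raw
    rng = np.random.default_rng([seed, 2, sr.index])
    k = rng.binomial(L, err)
    if k == 0:
        return raw
    out = list(raw)
    for p in rng.choice(L, size=k, replace=False):
        alts = [b for b in "ACGT" if b != out[p]]
        out[p] = alts[int(rng.integers(0, 3))]
    return "".join(out)


def make_aligned_sam(
    locus: Locus,
    reads: Sequence[SimRead],
    cfg: SimConfig,
    out: Optional[str | Path] = None,
    with_sequence: bool = True,
) -> list[SimAlignment]:
    """Construct coordinate-sorted alignments with soft-clip CIGARs.

    Reference-haplotype reads get full-M CIGARs (substitution errors stay
    M); junction-spanning reads from the deleted haplotype are anchored on
    their longer segment with the other segment soft-clipped; spurious
    background clips convert terminal M bases to S.  When ``out`` is given
    a valid coordinate-sorted SAM file is written.  ``with_sequence=False``
    skips base synthesis (the screen statistic never looks at bases),
    which makes large replicate experiments cheap.
    """
    L = cfg.read_length
    var = cfg.variant
    ref_seq, mut_seq = _hap_sequence(locus, var)
    pending: dict[tuple[str, int], tuple[int, SimAlignment]] = {}
    rows: list[tuple[int, int, SimAlignment]] = []
    half: dict[str, tuple[SimRead, int, list[tuple[str, int]]]] = {}
    for sr in reads:
        pos, ops = _read_alignment(sr, var, L)
        pos, ops = _apply_spurious(pos, ops, sr.spurious_left, sr.spurious_right)
        if sr.name in half:
            other, opos, oops = half.pop(sr.name)
            first, fpos, fops = (other, opos, oops)
            second, spos, sops = (sr, pos, ops)
            if first.mate == 2:
                first, fpos, fops, second, spos, sops = (
                    second, spos, sops, first, fpos, fops
                )
            end2 = spos + sum(l for o, l in sops if o in "MDN=X") - 1
            tlen = end2 - fpos + 1
            for mate_sr, mpos, mops, mate_pos, mtlen, flag in (
                (first, fpos, fops, spos, tlen, 99),
                (second, spos, sops, fpos, -tlen, 147),
            ):
                hap_seq = mut_seq if mate_sr.haplotype == 1 else ref_seq
                seq = (
                    _read_seq(hap_seq, mate_sr, L, cfg.substitution_error, _seq_seed(cfg))
                    if with_sequence else None
                )
                aread = AlignedRead(
                    name=mate_sr.name,
                    contig=locus.contig,
                    pos=mpos,
                    mapq=cfg.low_mapq_value if mate_sr.low_mapq else 60,
                    cigar=tuple(CigarOp(o, l) for o, l in mops),
                    sequence=seq,
                )
                rows.append(
                    (mpos, mate_sr.index,
                     SimAlignment(aread, flag, mate_pos, mtlen))
                )
        else:
            half[sr.name] = (sr, pos, ops)
    for sr, pos, ops in half.values():  # unpaired leftovers, if any
        hap_seq = mut_seq if sr.haplotype == 1 else ref_seq
        seq = (
            _read_seq(hap_seq, sr, L, cfg.substitution_error, _seq_seed(cfg))
            if with_sequence else None
        )
        aread = AlignedRead(
            name=sr.name, contig=locus.contig, pos=pos,
            mapq=cfg.low_mapq_value if sr.low_mapq else 60,
            cigar=tuple(CigarOp(o, l) for o, l in ops), sequence=seq,
        )
        rows.append((pos, sr.index, SimAlignment(aread, 0, pos, 0)))
    rows.sort(key=lambda t: (t[0], t[1]))
    alignments = [a for _, _, a in rows]
    if out is not None:
        write_sam(alignments, locus, out)
    return alignments


def write_sam(
    alignments: Sequence[SimAlignment], locus: Locus, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{locus.contig}\tLN:{len(locus.reference)}\n")
        fh.write("@PG\tID:clipscreen-sim\tPN:clipscreen\n")
        for a in alignments:
            fh.write(a.sam_line() + "\n")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def write_fastq(
    locus: Locus, reads: Sequence[SimRead], cfg: SimConfig, prefix: str | Path
) -> tuple[Path, Path]:
    """Write the read pairs as R1/R2 FASTQ (R2 reverse-complemented)."""
    ref_seq, mut_seq = _hap_sequence(locus, cfg.variant)
    p1 = Path(f"{prefix}_R1.fastq")
    p2 = Path(f"{prefix}_R2.fastq")
    qual = "I" * cfg.read_length
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for sr in sorted(reads, key=lambda r: (r.name, r.mate)):
            hap_seq = mut_seq if sr.haplotype == 1 else ref_seq
            seq = _read_seq(hap_seq, sr, cfg.read_length,
                            cfg.substitution_error, _seq_seed(cfg))
            if sr.mate == 1:
                f1.write(f"@{sr.name}/1\n{seq}\n+\n{qual}\n")
            else:
                f2.write(f"@{sr.name}/2\n{_revcomp(seq)}\n+\n{qual}\n")
    return p1, p2


def simulate_scene(
    cfg: SimConfig,
    out_dir: Optional[str | Path] = None,
    with_sequence: bool = True,
) -> tuple[Locus, SimTruth, list[SimAlignment]]:
    """Locus + reads + alignments in one call; optionally write all files.

    With ``out_dir`` set, writes reference FASTA, R1/R2 FASTQ, a
    coordinate-sorted SAM, the truth JSON, the transcript-model TSV and a
    BED4 of exon targets.
    """
    locus = make_locus(cfg)
    reads, truth = make_reads(locus, cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        alignments = make_aligned_sam(
            locus, reads, cfg, out=out / "scene.sam", with_sequence=True
        )
        locus.write_fasta(out / "reference.fa")
        write_fastq(locus, reads, cfg, out / "reads")
        (out / "truth.json").write_text(truth.to_json())
        locus.model.to_tsv(out / "transcript_model.tsv")
        from .genome_model import write_bed

        write_bed(out / "targets.bed", locus.exons)
    else:
        alignments = make_aligned_sam(
            locus, reads, cfg, with_sequence=with_sequence
        )
    return locus, truth, alignments


def simulate_cohort(
    seed: int,
    n_controls: int = 2,
    case_variant: Optional[VariantSpec] = None,
    base: Optional[SimConfig] = None,
    boundary_deletion: bool = False,
    with_sequence: bool = False,
) -> tuple[Locus, dict[str, list[SimAlignment]], Optional[VariantSpec]]:
    """One case plus ``n_controls`` control samples over a shared locus.

    All samples share the reference sequence (``seed`` fixes the locus);
    read-level randomness differs per sample via ``read_seed``.  The case
    carries ``case_variant`` (or the default het 56-bp boundary deletion
    when ``boundary_deletion`` is set); controls carry no variant.
    Returns the locus, a sample -> alignments map (case first), and the
    variant actually planted.
    """
    base = base if base is not None else SimConfig(seed=seed)
    base = replace(base, seed=seed, variant=None)
    if boundary_deletion and case_variant is None:
        case_variant = base.with_boundary_deletion().variant
    locus = make_locus(base)
    cohort: dict[str, list[SimAlignment]] = {}
    for i, sample in enumerate(
        ["case"] + [f"control{j + 1}" for j in range(n_controls)]
    ):
        cfg_i = replace(
            base,
            variant=case_variant if i == 0 else None,
            read_seed=seed * (n_controls + 1) + i,
        )
        reads, _ = make_reads(locus, cfg_i)
        cohort[sample] = make_aligned_sam(
            locus, reads, cfg_i, with_sequence=with_sequence
        )
    return locus, cohort, case_variant


def random_deletion_config(
    base: SimConfig, rng: np.random.Generator,
    min_len: int = 20, max_len: int = 500, zygosity: str = "het",
) -> SimConfig:
    """A deletion of random length hitting a random exon.

    The deleted interval always retains >= 10 bases of the exon upstream of
    the junction; what does not fit in the exon extends into the downstream
    intron (the boundary-spanning geometry a capture panel is blind to).
    Deletions short enough to fit inside the exon may instead be placed
    fully interior, at a random offset.
    """
    exons = base.exon_layout()
    exon_index = int(rng.integers(0, len(exons)))
    exon = exons[exon_index]
    length = int(rng.integers(min_len, max_len + 1))
    max_exonic = min(length, exon.length - 10)
    min_exonic = max(10, length - (base.intron_length - 10))
    if min_exonic > max_exonic:
        raise SimConfigError(
            f"deletion of {length} bp cannot be placed at exon {exon_index + 1}"
        )
    exonic = int(rng.integers(min_exonic, max_exonic + 1))
    intronic = length - exonic
    if intronic == 0 and exon.length - 10 - length > 0 and rng.random() < 0.5:
        # interior placement, away from the boundary
        offset = int(rng.integers(0, exon.length - 10 - length))
        start = exon.start + 10 + offset
        var = VariantSpec(start, start + length - 1, zygosity)
    else:
        var = VariantSpec(exon.end - exonic + 1, exon.end + intronic, zygosity)
    return replace(base, variant=var)
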