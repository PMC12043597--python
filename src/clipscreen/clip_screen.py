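"""Per-exon soft-clip percentage statistic and cross-sample outlier flagging.

The screen statistic for one (sample, exon) cell is

    pct = 100 * n_clipped / n_reads

where ``n_reads`` counts filtered reads overlapping the exon interval by at
least one base and ``n_clipped`` the subset carrying at least one qualifying
soft clip.  Counting is per read: a read clipped at both ends still counts
once.  Cells with no coverage are reported as missing, never as 0%.

Flagging compares each case cell against the median of the control cells
for the same exon:

    fold = (pct + eps) / (median_control_pct + eps)

and a cell is flagged when ``fold >= fold_min`` AND ``pct >= abs_min``.
The pseudocount eps (default 0.25 percentage points) keeps the fold finite
when controls are clip-free.  The two-condition rule deliberately leaves
systematic artifacts alone: an exon elevated in every sample (e.g. a
GC-rich exon that clips at ~5% across the board) has fold ~ 1 and is never
flagged.  No multiple-testing correction is applied — this is a thresholded
screen and the report carries ranks so users can impose their own control.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .alignment_io import AlignedRead, clip_events, passes_filters, stream_region
from .genome_model import GenomicInterval

__all__ = [
    "ExonClipStat",
    "FlagResult",
    "ScreenReport",
    "exon_clip_stat",
    "stats_to_frame",
    "compare_samples",
    "screen",
    "screen_reads",
    "read_sample_sheet",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_CLIP_LEN = 1
DEFAULT_FOLD_MIN = 3.0
DEFAULT_ABS_MIN = 3.0
DEFAULT_EPSILON = 0.25


@dataclass(frozen=True)
class ExonClipStat:
    """Clip statistic for one (sample, exon) cell."""

    sample_id: str
    exon_id: str
    n_reads: int
    n_clipped: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_clipped <= self.n_reads):
            raise ValueError(
                f"need 0 <= n_clipped <= n_reads, got {self.n_clipped}/{self.n_reads}"
            )

    @property
    def no_coverage(self) -> bool:
        return self.n_reads == 0

    @property
    def pct(self) -> Optional[float]:
        """Percent clipped, or None when the exon has no coverage."""
        if self.n_reads == 0:
            return None
        return 100.0 * self.n_clipped / self.n_reads


@dataclass(frozen=True)
class FlagResult:
    """Outlier decision for one case (sample, exon) cell."""

    sample_id: str
    exon_id: str
    pct: Optional[float]
    control_summary: Optional[float]
    fold: Optional[float]
    flagged: bool
    status: str = "ok"  # ok | no_coverage | uncomparable


def exon_clip_stat(
    reads: Iterable[AlignedRead],
    exon: GenomicInterval,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_clip_len: int = DEFAULT_MIN_CLIP_LEN,
    flank: int = 0,
    sample_id: str = "",
    exon_id: str = "",
) -> ExonClipStat:
    """Compute the clip statistic for one exon from an iterator of reads.

    ``flank`` widens the denominator window to exon +/- flank (capture
    probes extend past exons; default 0 keeps the per-exon framing).
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    window = GenomicInterval(
        exon.contig, max(1, exon.start - flank), exon.end + flank, exon.strand
    )
    n_reads = 0
    n_clipped = 0
    for read in reads:
        if not passes_filters(read, min_mapq):
            continue
        if not read.overlaps(window):
            continue
        n_reads += 1
        if clip_events(read, min_clip_len):
            n_clipped += 1
    return ExonClipStat(
        sample_id=sample_id, exon_id=exon_id or str(exon), n_reads=n_reads,
        n_clipped=n_clipped,
    )


def stats_to_frame(stats: Iterable[ExonClipStat]) -> pd.DataFrame:
    """Pivot stats into an exon x sample percentage matrix (NaN = no coverage)."""
    rows = [
        {"exon_id": s.exon_id, "sample_id": s.sample_id,
         "pct": np.nan if s.pct is None else s.pct}
        for s in stats
    ]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    wide = df.pivot(index="exon_id", columns="sample_id", values="pct")
    # keep first-seen order rather than lexicographic
    exon_order = list(dict.fromkeys(r["exon_id"] for r in rows))
    sample_order = list(dict.fromkeys(r["sample_id"] for r in rows))
    return wide.reindex(index=exon_order, columns=sample_order)


def compare_samples(
    pct: pd.DataFrame | Iterable[ExonClipStat],
    control_ids: Iterable[str],
    fold_min: float = DEFAULT_FOLD_MIN,
    abs_min: float = DEFAULT_ABS_MIN,
    epsilon: float = DEFAULT_EPSILON,
) -> list[FlagResult]:
    """Flag case cells elevated over the control median for the same exon.

    ``pct`` is an exon x sample percentage matrix (or an iterable of
    ExonClipStat, which is pivoted first).  Returns one FlagResult per case
    cell, sorted by descending fold.  An exon with no coverage in every
    control is reported ``uncomparable`` and never flagged as an outlier.
    """
    if not isinstance(pct, pd.DataFrame):
        pct = stats_to_frame(pct)
    controls = [c for c in control_ids]
    if not controls:
        raise ValueError("at least one control sample is required")
    missing = [c for c in controls if c not in pct.columns]
    if missing:
        raise ValueError(f"control sample(s) absent from the matrix: {missing}")
    cases = [c for c in pct.columns if c not in controls]
    results: list[FlagResult] = []
    for exon_id, row in pct.iterrows():
        ctrl_vals = row[controls].astype(float).dropna()
        ctrl_median = float(ctrl_vals.median()) if len(ctrl_vals) else None
        for sample in cases:
            val = row[sample]
            if pd.isna(val):
                results.append(
                    FlagResult(sample, exon_id, None, ctrl_median, None,
                               flagged=False, status="no_coverage")
                )
                continue
            val = float(val)
            if ctrl_median is None:
                results.append(
                    FlagResult(sample, exon_id, val, None, None,
                               flagged=False, status="uncomparable")
                )
                continue
            fold = (val + epsilon) / (ctrl_median + epsilon)
            flagged = fold >= fold_min and val >= abs_min
            results.append(
                FlagResult(sample, exon_id, val, ctrl_median, fold, flagged)
            )
    results.sort(
        key=lambda r: (-(r.fold if r.fold is not None else -math.inf),
                       r.exon_id, r.sample_id)
    )
    return results


@dataclass
class ScreenReport:
    """Everything one end-to-end screen run produced."""

    stats: list[ExonClipStat]
    matrix: pd.DataFrame
    flags: list[FlagResult]
    params: dict
    failures: dict[str, str] = field(default_factory=dict)

    def flagged(self) -> list[FlagResult]:
        return [f for f in self.flags if f.flagged]

    def write(self, out_dir: str | Path) -> None:
        """Write the TSV matrix (2-decimal percentages), the JSON flag
        report, and per-exon plot data (CSV)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.matrix.round(2).to_csv(out / "clip_percentages.tsv", sep="\t",
                                    na_rep="NA", float_format="%.2f")
        report = {
            "tool": "clipscreen",
            "version": _version,
            "params": self.params,
            "failures": self.failures,
            "flags": [
                {**asdict(f), "rank": i + 1} for i, f in enumerate(self.flags)
            ],
        }
        (out / "flag_report.json").write_text(json.dumps(report, indent=2))
        long = self.matrix.reset_index().melt(
            id_vars="exon_id", var_name="sample_id", value_name="pct"
        )
        long.to_csv(out / "clip_percentages_long.csv", index=False)


def screen_reads(
    reads_by_sample: Mapping[str, Sequence[AlignedRead]],
    targets: Sequence[tuple[str, GenomicInterval]],
    control_ids: Iterable[str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_clip_len: int = DEFAULT_MIN_CLIP_LEN,
    flank: int = 0,
    fold_min: float = DEFAULT_FOLD_MIN,
    abs_min: float = DEFAULT_ABS_MIN,
    epsilon: float = DEFAULT_EPSILON,
) -> ScreenReport:
    """Screen in-memory read sets (e.g. simulator output) without files.

    Reads are pre-binned per target window by position so replicate
    experiments stay cheap; the statistic itself is still
    :func:`exon_clip_stat` on each bin.
    """
    import bisect

    control_set = set(control_ids)
    stats: list[ExonClipStat] = []
    for sample_id, reads in reads_by_sample.items():
        order = sorted(reads, key=lambda r: r.pos)
        pos = [r.pos for r in order]
        max_span = max((r.reference_span for r in order), default=1)
        for exon_id, iv in targets:
            lo = bisect.bisect_left(pos, iv.start - flank - max_span)
            hi = bisect.bisect_right(pos, iv.end + flank)
            stats.append(
                exon_clip_stat(
                    order[lo:hi], iv, min_mapq=min_mapq,
                    min_clip_len=min_clip_len, flank=flank,
                    sample_id=sample_id, exon_id=exon_id,
                )
            )
    matrix = stats_to_frame(stats)
    flags = compare_samples(
        matrix, control_set, fold_min=fold_min, abs_min=abs_min, epsilon=epsilon
    )
    params = {
        "min_mapq": min_mapq, "min_clip_len": min_clip_len, "flank": flank,
        "fold_min": fold_min, "abs_min": abs_min, "epsilon": epsilon,
        "controls": sorted(control_set),
    }
    return ScreenReport(stats=stats, matrix=matrix, flags=flags, params=params)


def read_sample_sheet(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a TSV sample sheet: sample_id, path, role (case|control)."""
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "sample_id":
                continue
            if len(parts) < 3 or parts[2] not in ("case", "control"):
                raise ValueError(
                    f"{path}:{ln}: expected 'sample_id<TAB>path<TAB>case|control'"
                )
            rows.append((parts[0], parts[1], parts[2]))
    if not rows:
        raise ValueError(f"empty sample sheet: {path}")
    return rows


def screen(
    sample_paths: Mapping[str, str | Path],
    targets: Sequence[tuple[str, GenomicInterval]],
    control_ids: Iterable[str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_clip_len: int = DEFAULT_MIN_CLIP_LEN,
    flank: int = 0,
    fold_min: float = DEFAULT_FOLD_MIN,
    abs_min: float = DEFAULT_ABS_MIN,
    epsilon: float = DEFAULT_EPSILON,
) -> ScreenReport:
    """Run the full screen over per-sample alignment files.

    Per-sample failures are isolated and recorded; the run aborts only when
    a *control* sample fails (the comparison would be meaningless).
    """
    if not targets:
        raise ValueError("no target intervals supplied")
    control_set = set(control_ids)
    stats: list[ExonClipStat] = []
    failures: dict[str, str] = {}
    for sample_id, path in sample_paths.items():
        try:
            for exon_id, iv in targets:
                reads = stream_region(
                    path,
                    GenomicInterval(iv.contig, max(1, iv.start - flank),
                                    iv.end + flank, iv.strand),
                )
                stats.append(
                    exon_clip_stat(
                        reads, iv, min_mapq=min_mapq, min_clip_len=min_clip_len,
                        flank=flank, sample_id=sample_id, exon_id=exon_id,
                    )
                )
        except Exception as exc:  # noqa: BLE001 - per-sample isolation
            if sample_id in control_set:
                raise RuntimeError(
                    f"control sample {sample_id} failed: {exc}"
                ) from exc
            logger.error("sample %s failed: %s", sample_id, exc)
            failures[sample_id] = str(exc)
            stats = [s for s in stats if s.sample_id != sample_id]
    matrix = stats_to_frame(stats)
    flags = compare_samples(
        matrix, control_set, fold_min=fold_min, abs_min=abs_min, epsilon=epsilon
    )
    params = {
        "min_mapq": min_mapq, "min_clip_len": min_clip_len, "flank": flank,
        "fold_min": fold_min, "abs_min": abs_min, "epsilon": epsilon,
        "controls": sorted(control_set),
    }
    return ScreenReport(stats=stats, matrix=matrix, flags=flags,
                        params=params, failures=failures)
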