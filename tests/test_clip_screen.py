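"""The per-exon clip statistic and the cross-sample flagging rule."""

import math

import numpy as np
import pandas as pd
import pytest

from clipscreen.alignment_io import AlignedRead, parse_cigar
from clipscreen.clip_screen import (
    ExonClipStat,
    compare_samples,
    exon_clip_stat,
    screen,
    screen_reads,
    stats_to_frame,
)
from clipscreen.datasets import (
    SERPING1_CONTROLS,
    load_serping1_clip_matrix,
)
from clipscreen.genome_model import GenomicInterval, read_bed
from clipscreen.simulate import SimConfig, simulate_cohort, simulate_scene


def make_read(pos, cigar, mapq=60, name="r", **flags):
    return AlignedRead(
        name=name, contig="sim1", pos=pos, mapq=mapq,
        cigar=tuple(parse_cigar(cigar)), **flags,
    )


EXON = GenomicInterval("sim1", 1000, 1199)


class TestExonClipStat:
    def test_direct_arithmetic(self):
        reads = [make_read(1000 + i, "100M", name=f"r{i}") for i in range(7)]
        reads += [make_read(1100 + i, "10S90M", name=f"c{i}") for i in range(3)]
        stat = exon_clip_stat(reads, EXON)
        assert (stat.n_reads, stat.n_clipped) == (10, 3)
        assert stat.pct == pytest.approx(30.0)

    def test_no_coverage_is_missing_not_zero(self):
        stat = exon_clip_stat([], EXON)
        assert stat.no_coverage
        assert stat.pct is None
        frame = stats_to_frame([ExonClipStat("s", "e", 0, 0)])
        assert frame.isna().all().all()

    def test_double_clipped_read_counts_once(self):
        reads = [make_read(1050, "10S80M10S")]
        stat = exon_clip_stat(reads, EXON)
        assert (stat.n_reads, stat.n_clipped) == (1, 1)

    def test_filters_apply_to_both_counts(self):
        reads = [
            make_read(1000, "50S50M", mapq=5),        # fails MAPQ
            make_read(1000, "100M", duplicate=True),  # excluded flag
            make_read(1000, "100M"),
        ]
        stat = exon_clip_stat(reads, EXON, min_mapq=20)
        assert (stat.n_reads, stat.n_clipped) == (1, 0)

    def test_flank_widens_denominator(self):
        reads = [make_read(900, "50M")]  # ends at 949, 51 bp short of exon
        assert exon_clip_stat(reads, EXON, flank=0).n_reads == 0
        assert exon_clip_stat(reads, EXON, flank=60).n_reads == 1
        with pytest.raises(ValueError):
            exon_clip_stat(reads, EXON, flank=-1)

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(31)
        reads = [
            make_read(int(rng.integers(900, 1200)),
                      "100M" if rng.random() < 0.8 else "20S80M",
                      name=f"r{i}")
            for i in range(200)
        ]
        a = exon_clip_stat(reads, EXON)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        b = exon_clip_stat(shuffled, EXON)
        assert (a.n_reads, a.n_clipped) == (b.n_reads, b.n_clipped)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(32)
        reads = []
        for i in range(300):
            clip = int(rng.integers(0, 20))
            cigar = f"{clip}S{100 - clip}M" if clip else "100M"
            reads.append(
                make_read(int(rng.integers(900, 1200)), cigar,
                          mapq=int(rng.integers(0, 61)), name=f"r{i}")
            )
        prev_clipped = None
        for mcl in (1, 5, 10, 20):
            s = exon_clip_stat(reads, EXON, min_clip_len=mcl)
            if prev_clipped is not None:
                assert s.n_clipped <= prev_clipped
            prev_clipped = s.n_clipped
        prev_reads = None
        for mq in (0, 20, 40, 60):
            s = exon_clip_stat(reads, EXON, min_mapq=mq)
            if prev_reads is not None:
                assert s.n_reads <= prev_reads
                assert s.n_clipped <= prev_clipped
            prev_reads, prev_clipped = s.n_reads, s.n_clipped


class TestStatAgainstPlacementEnumeration:
    def test_het_deletion_scene_matches_enumeration_oracle(self):
        """Observed exon-6 clip pct within 3 binomial SE of the expectation
        obtained by enumerating every fragment placement on both haplotypes."""
        cfg = SimConfig(
            seed=7,
            background_clip={"default": 0.0},
            low_mapq_fraction=0.0,
            substitution_error=0.0,
        ).with_boundary_deletion()
        locus, _, alignments = simulate_scene(cfg, with_sequence=False)
        exon = dict(locus.exons)["exon6"]
        var = cfg.variant
        L, F = cfg.read_length, cfg.fragment_len
        ds, dlen = var.start, var.length

        # enumerate fragment starts uniform over the exon-6 sampling window,
        # per haplotype, and classify each of the two reads geometrically
        w_lo = exon.start - cfg.target_flank - (F - 1)
        w_hi = exon.end + cfg.target_flank
        num = {0: 0, 1: 0}
        den = {0: 0, 1: 0}
        tot = {0: 0, 1: 0}

        def ref_span_of(hap, s):
            """(ref_start, ref_end, clipped) of a read at hap coordinate s."""
            if hap == 0:
                return s, s + L - 1, False
            if s < ds <= s + L - 1:
                p = ds - s
                q = L - p
                if p >= q:
                    return s, s + p - 1, True
                return var.end + 1, var.end + q, True
            if s + L - 1 < ds:
                return s, s + L - 1, False
            return s + dlen, s + dlen + L - 1, False

        def hap_window(hap):
            if hap == 0:
                return w_lo, w_hi
            lo = w_lo if w_lo < ds else (ds if w_lo <= var.end else w_lo - dlen)
            hi = w_hi if w_hi < ds else (ds if w_hi <= var.end else w_hi - dlen)
            return lo, hi

        for hap in (0, 1):
            lo, hi = hap_window(hap)
            for s in range(lo, hi + 1):
                for rs in (s, s + F - L):
                    a, b, clipped = ref_span_of(hap, rs)
                    tot[hap] += 1
                    if a <= exon.end and b >= exon.start:
                        den[hap] += 1
                        num[hap] += clipped

        # haplotypes are a fair coin per fragment: weight each haplotype's
        # per-placement rates equally
        p_overlap = 0.5 * (den[0] / tot[0]) + 0.5 * (den[1] / tot[1])
        p_clip = 0.5 * (num[0] / tot[0]) + 0.5 * (num[1] / tot[1])
        expected_pct = 100.0 * p_clip / p_overlap

        reads = [a.read for a in alignments]
        stat = exon_clip_stat(reads, exon)
        se = 100.0 * math.sqrt(
            expected_pct / 100 * (1 - expected_pct / 100) / stat.n_reads
        )
        assert stat.pct == pytest.approx(expected_pct, abs=3 * se)
        assert expected_pct > 5.0  # the signal is far above background


def brute_force_flags(matrix, controls, fold_min=3.0, abs_min=3.0, eps=0.25):
    """Independent reimplementation of the flagging rule."""
    flags = set()
    for exon in matrix.index:
        ctrl = sorted(
            matrix.loc[exon, c] for c in controls
            if not pd.isna(matrix.loc[exon, c])
        )
        if not ctrl:
            continue
        n = len(ctrl)
        med = (ctrl[(n - 1) // 2] + ctrl[n // 2]) / 2
        for sample in matrix.columns:
            if sample in controls:
                continue
            v = matrix.loc[exon, sample]
            if pd.isna(v):
                continue
            if (v + eps) / (med + eps) >= fold_min and v >= abs_min:
                flags.add((sample, exon))
    return flags


class TestCompareSamples:
    def test_published_family_matrix_flags_only_exon6_cases(self):
        matrix = load_serping1_clip_matrix()
        flags = compare_samples(matrix, SERPING1_CONTROLS)
        flagged = {(f.sample_id, f.exon_id) for f in flags if f.flagged}
        assert flagged == {
            ("0002-HAE-001", "exon6"),
            ("0058-HAE-001", "exon6"),
        }
        # the GC-artifact exon is elevated in every sample and must not flag
        assert not any(f.exon_id == "exon2" and f.flagged for f in flags)
        top = flags[0]
        assert (top.sample_id, top.exon_id) == ("0002-HAE-001", "exon6")
        assert top.control_summary == pytest.approx(1.365)

    def test_identical_samples_yield_zero_flags(self):
        matrix = pd.DataFrame(
            {s: [2.0, 3.0, 1.0] for s in ["a", "b", "ctrl"]},
            index=["e1", "e2", "e3"],
        )
        matrix.index.name = "exon_id"
        assert not any(f.flagged for f in compare_samples(matrix, ["ctrl"]))

    def test_randomized_matrices_match_rule_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(500):
            n_exons = int(rng.integers(1, 6))
            n_samples = int(rng.integers(2, 6))
            n_ctrl = int(rng.integers(1, n_samples))
            cols = [f"s{i}" for i in range(n_samples)]
            data = rng.gamma(1.0, 2.0, size=(n_exons, n_samples)).round(2)
            matrix = pd.DataFrame(
                data, columns=cols, index=[f"e{i}" for i in range(n_exons)]
            )
            matrix.index.name = "exon_id"
            controls = list(rng.choice(cols, size=n_ctrl, replace=False))
            got = {
                (f.sample_id, f.exon_id)
                for f in compare_samples(matrix, controls)
                if f.flagged
            }
            assert got == brute_force_flags(matrix, controls)

    def test_flags_invariant_to_sample_column_order(self):
        matrix = load_serping1_clip_matrix()
        reversed_cols = matrix[matrix.columns[::-1]]
        a = {(f.sample_id, f.exon_id)
             for f in compare_samples(matrix, SERPING1_CONTROLS) if f.flagged}
        b = {(f.sample_id, f.exon_id)
             for f in compare_samples(reversed_cols, SERPING1_CONTROLS)
             if f.flagged}
        assert a == b

    def test_empty_control_set_is_an_error(self):
        with pytest.raises(ValueError):
            compare_samples(load_serping1_clip_matrix(), [])

    def test_exon_with_no_control_coverage_is_uncomparable(self):
        matrix = pd.DataFrame(
            {"case": [5.0], "ctrl": [float("nan")]}, index=["e1"]
        )
        matrix.index.name = "exon_id"
        (res,) = compare_samples(matrix, ["ctrl"])
        assert res.status == "uncomparable"
        assert not res.flagged


class TestScreenEndToEnd:
    def test_deletion_flagged_for_carrier_only(self):
        locus, cohort, var = simulate_cohort(41, boundary_deletion=True)
        reads = {s: [a.read for a in alns] for s, alns in cohort.items()}
        report = screen_reads(reads, locus.exons, ["control1", "control2"])
        flagged = {(f.sample_id, f.exon_id) for f in report.flagged()}
        assert flagged == {("case", "exon6")}

    def test_null_cohort_yields_no_flags(self):
        locus, cohort, _ = simulate_cohort(42)
        reads = {s: [a.read for a in alns] for s, alns in cohort.items()}
        report = screen_reads(reads, locus.exons, ["control1", "control2"])
        assert report.flagged() == []

    def test_shared_gc_artifact_exon_never_flagged(self):
        # exon-2 background elevated to ~10%/read in ALL samples
        base = SimConfig(
            seed=43, background_clip={"default": 0.0075, "exon2": 0.05}
        )
        locus, cohort, _ = simulate_cohort(43, base=base, boundary_deletion=True)
        reads = {s: [a.read for a in alns] for s, alns in cohort.items()}
        report = screen_reads(reads, locus.exons, ["control1", "control2"])
        assert not any(f.exon_id == "exon2" for f in report.flagged())
        assert ("case", "exon6") in {
            (f.sample_id, f.exon_id) for f in report.flagged()
        }

    def test_file_based_screen_matches_in_memory(self, tmp_path):
        cfg = SimConfig(seed=44).with_boundary_deletion()
        case_dir = tmp_path / "case"
        ctrl_dir = tmp_path / "ctrl"
        locus, _, _ = simulate_scene(cfg, out_dir=case_dir)
        simulate_scene(SimConfig(seed=44), out_dir=ctrl_dir)
        targets = read_bed(case_dir / "targets.bed")
        report = screen(
            {"case": case_dir / "scene.sam", "ctrl": ctrl_dir / "scene.sam"},
            targets,
            ["ctrl"],
        )
        assert {(f.sample_id, f.exon_id) for f in report.flagged()} == {
            ("case", "exon6")
        }
        out = tmp_path / "report"
        report.write(out)
        matrix = pd.read_csv(out / "clip_percentages.tsv", sep="\t",
                             index_col="exon_id")
        assert matrix.shape == (8, 2)

    def test_case_failure_isolated_control_failure_fatal(self, tmp_path):
        cfg = SimConfig(seed=45)
        d = tmp_path / "ok"
        locus, _, _ = simulate_scene(cfg, out_dir=d)
        targets = read_bed(d / "targets.bed")
        report = screen(
            {"case": tmp_path / "missing.sam", "ctrl": d / "scene.sam"},
            targets,
            ["ctrl"],
        )
        assert "case" in report.failures
        with pytest.raises(RuntimeError, match="control"):
            screen(
                {"case": d / "scene.sam", "ctrl": tmp_path / "missing.sam"},
                targets,
                ["ctrl"],
            )
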