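"""Clip-anchor clustering, deletion pairing, realignment and VCF output."""

import numpy as np
import pysam
import pytest

from clipscreen.alignment_io import AlignedRead, ClipEvent, parse_cigar
from clipscreen.breakpoint_nominate import (
    BreakpointCluster,
    PairingError,
    cluster_clip_sites,
    nominate,
    pair_deletion,
    realign_clip_support,
    write_vcf,
)
from clipscreen.genome_model import GenomicInterval
from clipscreen.simulate import SimConfig, simulate_scene


def ev(anchor, side="right", name=None, clip_len=20, seq=None):
    return ClipEvent(
        read_name=name or f"r{anchor}", contig="sim1", side=side,
        clip_len=clip_len, anchor=anchor, clipped_seq=seq,
    )


def brute_force_single_linkage(anchors, window):
    """Oracle: clusters = connected components under |a - b| <= window
    chaining on the sorted anchors."""
    if not anchors:
        return []
    anchors = sorted(anchors)
    groups = [[anchors[0]]]
    for a in anchors[1:]:
        if a - groups[-1][-1] <= window:
            groups[-1].append(a)
        else:
            groups.append([a])
    return groups


class TestClusterClipSites:
    def test_uniform_pileup_gives_one_cluster(self):
        events = [ev(57606507, "right", name=f"n{i}") for i in range(20)]
        (c,) = cluster_clip_sites(events, window=5, min_support=4)
        assert (c.position, c.side, c.support) == (57606507, "right", 20)

    def test_modal_tie_and_min_support(self):
        events = [ev(100), ev(101), ev(250)]
        (c,) = cluster_clip_sites(events, window=5, min_support=2)
        assert c.position == 100  # tie 100 vs 101 -> smaller wins
        assert c.support == 2  # singleton at 250 dropped

    def test_sides_cluster_independently(self):
        events = [ev(100, "right"), ev(100, "right"), ev(102, "left"),
                  ev(103, "left")]
        clusters = cluster_clip_sites(events, window=5, min_support=2)
        assert {(c.side, c.support) for c in clusters} == {
            ("right", 2), ("left", 2)
        }

    def test_randomized_against_single_linkage_oracle(self):
        rng = np.random.default_rng(51)
        for _ in range(500):
            n = int(rng.integers(0, 40))
            window = int(rng.integers(1, 10))
            anchors = [int(a) for a in rng.integers(1, 300, size=n)]
            events = [ev(a, "right", name=f"r{i}") for i, a in enumerate(anchors)]
            got = cluster_clip_sites(events, window=window, min_support=1)
            expected = brute_force_single_linkage(anchors, window)
            assert [c.support for c in got] == [len(g) for g in expected]
            for cluster, group in zip(got, expected):
                counts = {a: group.count(a) for a in group}
                modal = min(counts, key=lambda a: (-counts[a], a))
                assert cluster.position == modal

    def test_input_order_invariance(self):
        rng = np.random.default_rng(52)
        anchors = [int(a) for a in rng.integers(1, 100, size=30)]
        events = [ev(a, "left", name=f"r{i}") for i, a in enumerate(anchors)]
        a = cluster_clip_sites(events, window=3, min_support=1)
        shuffled = list(events)
        rng.shuffle(shuffled)
        b = cluster_clip_sites(shuffled, window=3, min_support=1)
        assert [(c.position, c.support) for c in a] == [
            (c.position, c.support) for c in b
        ]


def cluster(position, side, support=10, contig="sim1"):
    return BreakpointCluster(
        contig=contig, position=position, side=side, support=support,
        median_clip_len=20,
    )


class TestPairDeletion:
    def test_paired_clusters_give_exact_interval(self):
        call = pair_deletion(
            cluster(57606507, "right"), cluster(57606564, "left"),
            contig_accession="NC_000011.10",
        )
        assert (call.interval.start, call.interval.end) == (57606508, 57606563)
        assert call.length == 56
        assert call.hgvs_g == "NC_000011.10:g.57606508_57606563del"

    def test_minimal_single_base_deletion(self):
        call = pair_deletion(cluster(100, "right"), cluster(102, "left"))
        assert call.length == 1
        assert call.interval.start == call.interval.end == 101

    def test_zero_or_negative_span_invalid(self):
        with pytest.raises(PairingError):
            pair_deletion(cluster(100, "right"), cluster(101, "left"))
        with pytest.raises(PairingError):
            pair_deletion(cluster(100, "right"), cluster(90, "left"))

    def test_swapped_sides_always_invalid_never_negative_length(self):
        with pytest.raises(PairingError):
            pair_deletion(cluster(100, "left"), cluster(200, "right"))

    def test_span_cap(self):
        with pytest.raises(PairingError):
            pair_deletion(cluster(100, "right"), cluster(10_000, "left"),
                          max_span=500)


class TestSingleReadGeometry:
    """Length arithmetic holds exactly for each clip side and CIGAR shape."""

    @pytest.mark.parametrize(
        "pos,cigar,side,anchor",
        [
            (1000, "60M40S", "right", 1059),
            (1060, "40S60M", "left", 1060),
            (1000, "5H60M40S", "right", 1059),
            (1060, "40S60M5H", "left", 1060),
        ],
    )
    def test_clip_anchor_to_deletion_edge(self, pos, cigar, side, anchor):
        from clipscreen.alignment_io import clip_events

        read = AlignedRead(
            name="r", contig="sim1", pos=pos, mapq=60,
            cigar=tuple(parse_cigar(cigar)),
        )
        (event,) = clip_events(read)
        assert (event.side, event.anchor) == (side, anchor)
        # a right anchor at a and left anchor at b imply deletion [a+1, b-1]
        if side == "right":
            call = pair_deletion(
                cluster(anchor, "right", 1), cluster(anchor + 57, "left", 1)
            )
            assert call.length == 56


class TestRealignSupport:
    def make_scene(self):
        cfg = SimConfig(
            seed=9, substitution_error=0.0,
            background_clip={"default": 0.0}, low_mapq_fraction=0.0,
        ).with_boundary_deletion()
        locus, _, alignments = simulate_scene(cfg)
        return cfg, locus, [a.read for a in alignments]

    def test_error_free_reads_fully_realign(self):
        cfg, locus, reads = self.make_scene()
        exon6 = dict(locus.exons)["exon6"]
        calls, clusters = nominate(
            reads, exon6, reference=locus.reference, padding=250
        )
        (call,) = calls
        assert call.realign_support == call.support_left + call.support_right

    def test_randomized_clipped_sequences_do_not_realign(self):
        cfg, locus, reads = self.make_scene()
        exon6 = dict(locus.exons)["exon6"]
        _, clusters = nominate(reads, exon6, padding=250)
        right = next(c for c in clusters if c.side == "right")
        left = next(c for c in clusters if c.side == "left")
        rng = np.random.default_rng(53)
        scrambled = BreakpointCluster(
            contig=right.contig, position=right.position, side="right",
            support=right.support, median_clip_len=right.median_clip_len,
            events=tuple(
                ClipEvent(
                    e.read_name, e.contig, e.side, e.clip_len, e.anchor,
                    "".join(rng.choice(list("ACGT"), size=e.clip_len)),
                )
                for e in right.events
            ),
        )
        support = realign_clip_support(
            scrambled, left.position, locus.reference, ref_start=1,
            max_mismatch_frac=0.1,
        )
        assert support < 0.05 * right.support + 1

    def test_one_percent_errors_barely_reduce_support(self):
        cfg = SimConfig(
            seed=9, substitution_error=0.01,
            background_clip={"default": 0.0}, low_mapq_fraction=0.0,
        ).with_boundary_deletion()
        locus, _, alignments = simulate_scene(cfg)
        reads = [a.read for a in alignments]
        exon6 = dict(locus.exons)["exon6"]
        (call,), _ = nominate(
            reads, exon6, reference=locus.reference, padding=250
        )
        total = call.support_left + call.support_right
        assert call.realign_support >= 0.9 * total

    def test_short_reference_window_is_an_error(self):
        c = BreakpointCluster(
            contig="sim1", position=100, side="right", support=1,
            median_clip_len=10,
            events=(ev(100, "right", seq="ACGTACGTAC"),),
        )
        with pytest.raises(ValueError, match="window"):
            realign_clip_support(c, 500, "ACGT", ref_start=499)


class TestNominateEndToEnd:
    def test_default_scene_recovers_exact_interval(self, default_scene):
        cfg, locus, _, alignments = default_scene
        exon6 = dict(locus.exons)["exon6"]
        calls, _ = nominate([a.read for a in alignments], exon6)
        var = cfg.variant
        best = calls[0]
        assert (best.interval.start, best.interval.end) == (var.start, var.end)
        assert best.length == 56

    def test_vcf_output_parses_and_matches_call(self, default_scene, tmp_path):
        cfg, locus, _, alignments = default_scene
        exon6 = dict(locus.exons)["exon6"]
        calls, _ = nominate(
            [a.read for a in alignments], exon6, reference=locus.reference
        )
        path = tmp_path / "calls.vcf"
        write_vcf(calls, path, {locus.contig: len(locus.reference)},
                  reference=locus.reference)
        recs = list(pysam.VariantFile(str(path)))
        (rec,) = recs
        assert rec.pos == calls[0].interval.start - 1
        assert rec.info["SVLEN"] == -56
        assert rec.stop == calls[0].interval.end  # INFO END
        assert len(rec.ref) == 57  # anchor base + deleted sequence
        assert rec.alts == (rec.ref[0],)

    def test_vcf_without_reference_uses_placeholders(self, tmp_path):
        call = pair_deletion(cluster(100, "right"), cluster(157, "left"))
        path = tmp_path / "calls.vcf"
        write_vcf([call], path, {"sim1": 10_000})
        line = [l for l in path.read_text().splitlines()
                if not l.startswith("#")][0]
        fields = line.split("\t")
        assert fields[3] == "N" * 57 and fields[4] == "N"
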