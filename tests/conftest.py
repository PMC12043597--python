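import numpy as np
import pytest

from clipscreen.genome_model import GenomicInterval, TranscriptModel
from clipscreen.simulate import SimConfig, simulate_scene


def random_transcript_model(
    rng: np.random.Generator,
    n_exons: int = 8,
    strand: str | None = None,
    contig: str = "chrT",
) -> TranscriptModel:
    """A random multi-exon model whose CDS spans all exonic bases."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    pos = int(rng.integers(1, 1000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 400))
        exons.append(GenomicInterval(contig, pos, pos + length - 1, strand))
        pos += length + int(rng.integers(50, 800))
    tx_exons = tuple(exons if strand == "+" else exons[::-1])
    first, last = tx_exons[0], tx_exons[-1]
    cds_start = first.start if strand == "+" else first.end
    cds_end = last.end if strand == "+" else last.start
    return TranscriptModel(
        transcript_id="TX1",
        contig=contig,
        strand=strand,
        exons=tx_exons,
        cds_start_g=cds_start,
        cds_end_g=cds_end,
    )


@pytest.fixture(scope="session")
def default_scene():
    """The default study scene: het 56-bp deletion at exon 6's 3' boundary."""
    cfg = SimConfig(seed=7).with_boundary_deletion()
    locus, truth, alignments = simulate_scene(cfg)
    return cfg, locus, truth, alignments


@pytest.fixture(scope="session")
def default_reads(default_scene):
    _, _, _, alignments = default_scene
    return [a.read for a in alignments]
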