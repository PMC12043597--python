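"""Bundled example data.

The package ships one small published measurement: per-exon soft-clip
percentages for a hereditary-angioedema type I family (proband
``0002-HAE-001`` and mother ``0058-HAE-001``) and two unrelated HAE control
samples (``0045-HAE-001``, carrying a SERPING1 missense variant in exon 3,
and ``0046-HAE-001``, carrying a heterozygous exon 4 deletion) across the
eight SERPING1 exons.  The proband and mother carry a heterozygous 56-bp
deletion spanning the 3' boundary of exon 6 that standard variant calling
and MLPA both missed; it shows up here as exon-6 clip rates of 7.84% and
5.79% against a control median of 1.365%.  Exon 2 is elevated in *all four*
samples (~4-5%) because of its ~70% GC content — a systematic artifact the
fold-over-controls rule must not flag.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_serping1_clip_matrix", "SERPING1_CONTROLS", "SERPING1_CASES"]

SERPING1_CASES = ("0002-HAE-001", "0058-HAE-001")
SERPING1_CONTROLS = ("0045-HAE-001", "0046-HAE-001")


def load_serping1_clip_matrix() -> pd.DataFrame:
    """Return the SERPING1 family clip-percentage matrix (exon x sample)."""
    ref = resources.files("clipscreen.data").joinpath(
        "serping1_exon_clip_percentages.tsv"
    )
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col="exon_id")
    return df
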