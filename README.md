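# clipscreen

Soft-clip screening for structural variants that standard short-read
pipelines and MLPA both miss.

## The problem

Clinical targeted sequencing detects SNVs and indels up to ~15 bp well, and
MLPA detects whole-exon copy-number changes — but a deletion of a few dozen
to a few hundred bases can fall between the two: too large for the gap-aware
aligner to represent in a CIGAR, too small (or mis-placed relative to the
probe) for MLPA. The motivating case is hereditary angioedema (HAE) type I:
a family with clear C1-inhibitor deficiency, negative SERPING1 results by
both NGS variant calling and MLPA, and the true cause a heterozygous 56-bp
deletion spanning exon 6's 3' boundary
(`NC_000011.10:g.57606508_57606563del`, `c.990_1029+16del`,
`p.Val332Serfs*3`).

Such an event still leaves an alignment footprint: reads crossing a
breakpoint cannot align end-to-end, so the aligner *soft-clips* the
junction-distal bases (CIGAR `S`), keeping them in the record. `clipscreen`
turns that footprint into a screen:

1. **Statistic** — for each sample and exon, the clipping percentage

   `pct = 100 · n_clipped / n_reads`

   where `n_reads` counts MAPQ-filtered primary reads overlapping the exon
   and `n_clipped` the subset with at least one soft-clipped end.

2. **Comparison** — each case cell is compared to the median of the control
   samples for the same exon:

   `fold = (pct + ε) / (median_ctrl + ε)`, ε = 0.25

   and flagged when `fold ≥ 3` **and** `pct ≥ 3%`. The two-sided rule
   ignores systematic artifacts shared by all samples (e.g. a ~70% GC exon
   that clips at ~5% everywhere).

3. **Breakpoint nomination** — clip anchors (the aligned base adjacent to
   each clip) are clustered per side; a right-clip cluster at position *a*
   paired with a downstream left-clip cluster at *b* nominates the deletion
   `[a+1, b−1]` of length `b − a − 1`. Clipped sequences are optionally
   realigned across the mate junction as in-silico confirmation.

4. **Annotation** — calls are rendered as HGVS g. deletions, projected to
   c. coordinates (with intronic offsets, 3'-shifted when a reference is
   supplied) on a user-provided transcript model, and donor-site deletions
   get a frameshift consequence under an intron read-through model
   (`p.Xxx123Yyyfs*N`).

A fully seeded simulator generates exome-like scenes (8-exon locus, diploid
reads, constructed soft-clip CIGARs, GC-artifact background) so the whole
pipeline is testable without any external data.

## Worked example

```bash
# 1. simulate the motivating scene: het 56-bp deletion at exon 6's 3' boundary
clipscreen simulate --seed 7 --out case
# a matched variant-free control
echo '{"seed": 13, "variant": null}' > null.json
clipscreen simulate --config null.json --out ctrl

# 2. screen the cohort
printf 'case\t%s\tcase\nctrl\t%s\tcontrol\n' case/scene.sam ctrl/scene.sam > samples.tsv
clipscreen screen --samples samples.tsv --targets case/targets.bed --out screen_out
#   FLAG case exon6: 14.53% (control median 1.30%, fold 9.5)

# 3. nominate breakpoints in the flagged exon
clipscreen nominate --bam case/scene.sam --region sim1:4791-5000 \
    --ref case/reference.fa --out calls.vcf
#   DEL sim1:g.4961_5016del len=56 support=37/25
```

The screen output is the exon × sample percentage matrix
(`clip_percentages.tsv`), a JSON flag report with parameters and ranks, and
plot-ready long-format CSV. The VCF carries `SVLEN=-56`,
`SUPPORT_R`/`SUPPORT_L` (reads clipped at the two junctions) and `REALN`
(clipped segments that realign across the junction). Projecting the call
through the scene's transcript model names it `SIMT1:c.1061_1100+16del` — a
boundary-spanning deletion with a positive intronic offset, the same shape
as the clinical `c.990_1029+16del`.

The package also bundles the published family's measured matrix:

```python
>>> from clipscreen.datasets import load_serping1_clip_matrix, SERPING1_CONTROLS
>>> from clipscreen.clip_screen import compare_samples
>>> flags = compare_samples(load_serping1_clip_matrix(), SERPING1_CONTROLS)
>>> [(f.sample_id, f.exon_id, round(f.fold, 2)) for f in flags if f.flagged]
[('0002-HAE-001', 'exon6', 5.01), ('0058-HAE-001', 'exon6', 3.74)]
```

Exactly the proband and mother flag at exon 6 (7.84% and 5.79% against a
control median of 1.365%); the GC-rich exon 2, elevated in every sample,
does not.

## Using real data

The screen consumes coordinate-sorted SAM/BAM (indexed BAM enables random
access; plain SAM falls back to a full scan), BED4 target intervals, and a
TSV sample sheet. For HGVS c. naming supply a transcript model
(JSON or TSV: exons, strand, CDS bounds). The model is deliberately *not*
hardcoded: extract it from a specific RefSeq release (e.g. the NM_000062
exons from the RefSeq GRCh38 annotation GFF3) and record that release in
the file's `source` field, which is propagated to reports.
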