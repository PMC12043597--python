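# Methods

## The screen

`clipscreen` screens targeted short-read alignments for structural variants
through the soft-clip channel. The unit of decision is one (sample, exon)
cell. For each cell the clipping percentage is

    pct = 100 · n_clipped / n_reads

with `n_reads` the number of reads that pass the read filter and overlap
the exon interval by at least one base, and `n_clipped` the subset carrying
at least one terminal soft clip (CIGAR `S`) of at least `min_clip_len`
bases. Counting is per read — a read clipped at both ends counts once. A
cell with `n_reads = 0` is *missing*, never 0%: a zero would read as
"confidently unclipped" where there is no evidence at all.

The read filter drops unmapped, secondary, supplementary and duplicate
records and reads with MAPQ below `min_mapq` (default 20, the conventional
cutoff for "low-quality MAPQ"). Supplementary alignments are excluded from
numerator and denominator alike because split-read representations would
double-count exactly the junction reads this statistic is built on.

Cells are compared across samples sequenced in the same run. For a case
cell with value `pct` and control values for the same exon with median `m`:

    fold = (pct + ε) / (m + ε),   ε = 0.25 percentage points

and the cell is flagged when `fold ≥ fold_min` and `pct ≥ abs_min`
(defaults 3.0 and 3.0%). The median is robust to one aberrant control; the
pseudocount keeps the ratio finite when controls are clip-free. The
published family matrix fixes these defaults: the two true cells sit at
folds ≈ 5.0 and 3.7 over a 1.365% control median, while the GC-rich exon —
elevated to ~4–5% in *every* sample — fails the fold condition, and every
other cell fails one or both conditions. They are the loosest round values
that reproduce that decision, and both are exposed as flags. No
multiple-testing correction is applied: the procedure is a thresholded
screen whose hits go to orthogonal confirmation, and the report carries
fold ranks for users who want to impose their own control.

## Breakpoint nomination

A deletion of `[delStart, delEnd]` soft-clips reads on its left flank at
their right end (anchor `delStart − 1`) and reads on its right flank at
their left end (anchor `delEnd + 1`). Nomination:

1. collect clip events from the flagged exon ± `padding` (default 200 bp;
   capture reads extend into the intron, and the distal junction of a
   boundary-spanning deletion is intronic);
2. single-linkage cluster anchors per side with gap ≤ `window` (default
   5 bp, enough to absorb alignment jitter yet far smaller than any
   deletion of interest); drop clusters with support < `min_support`
   (default 4); cluster position is the modal anchor, smaller position on
   ties, so results are independent of input order;
3. pair each right cluster with the nearest downstream left cluster:
   `interval = [right + 1, left − 1]`, `length = left − right − 1`.
   Swapped geometry is an error, never a negative length; insertions and
   duplications produce opposing clips at the same position and are
   reported as unpaired clusters without a call.

When a reference sequence is available, each cluster's clipped segments are
realigned ungapped across the mate junction and counted as `REALN` support
at mismatch fraction ≤ 0.1 — an in-silico stand-in for confirmatory Sanger
sequencing. Calls are emitted as VCF 4.2 with `SVTYPE=DEL`, negative
`SVLEN`, and exact `REF`/`ALT` when a FASTA is supplied (N placeholders
otherwise).

## Coordinates and HGVS

Genomic coordinates are 1-based inclusive throughout (HGVS g. and SAM
`POS`); BED converts at the file boundary. The transcript model (exons in
transcript order, strand, CDS bounds) supports g.↔c. projection with
HGVS intronic offsets: `+n` from the last CDS base of the preceding exon in
the 5' half of an intron, `−n` from the first CDS base of the following
exon in the 3' half, midpoint ties to the donor side. Deletions are
3'-shifted on the transcript strand before naming when a reference is
available; otherwise the name is emitted tagged `unnormalized`. UTR and
non-coding coordinates are out of scope and raise explicit errors. The
boundary identity (exonic span + intronic offset = genomic length) is
enforced by round-tripping both projected ends.

For deletions that remove a splice donor, the protein consequence is
modelled as intron read-through: translation continues from the last intact
exonic base into the residual intron until a stop appears, rendered
`p.(Ref)(Pos)(New)fs*N` with three-letter codes, counting the first changed
residue as 1. Exon skipping and cryptic splice activation are *not*
modelled and reports label the assumption. The mutant protein length is
reported as computed (number of residues before the new stop) rather than
asserting any externally quoted figure, since conventions differ on whether
the stop codon is counted. An exon-internal deletion of a multiple of three
bases returns an explicit in-frame result, and a frameshift whose window
contains no stop returns a `fs*?` marker rather than raising.

## The simulator

The generator emulates the study conditions the screen was designed for,
not sequencing in general. One scene is an 8-exon locus (exon lengths
120–300 bp, 600-bp introns, 900-bp outer flanks) with per-region *exact* GC
composition — exon 2 at 70% GC, the rest at 45%. Reads are 100-bp pairs
(fragment = 250 bp) sampled uniformly over each exon ± 150 bp at 100× mean
depth, with i.i.d. substitution errors at 10⁻³/base. The default variant is
a heterozygous 56-bp deletion removing the last 40 bases of exon 6 plus the
first 16 intronic bases; haplotype per fragment is a fair coin.

Alignment is constructed, not run: reference-haplotype reads get full-M
CIGARs; a junction-spanning read from the deleted haplotype is anchored on
its longer segment and the other segment becomes a terminal `S` — the
regime a BWA-class aligner produces for deletions too large to absorb as a
`D` op. Junction anchors are therefore exact by construction
(`delStart − 1` / `delEnd + 1`), which is the ground truth the nomination
step must recover. Spurious background clips convert terminal aligned bases
to `S` (lengths 5–30) at a per-read-end probability of 0.0075 baseline
(≈1.5% of reads clipped, matching the published control rows) and 0.025 for
exon 2 (≈5%, the shared GC artifact). 2% of reads get MAPQ 5 to exercise
the filter. All randomness descends from a seed; FASTA/FASTQ/SAM output is
byte-deterministic. The locus flank (900 bp) deliberately exceeds the
maximal intronic deletion extent plus target flank plus fragment length so
that edge reads are never truncated — a real genome continues past the
capture target.

What the simulator does **not** model: indel sequencing errors, base
quality variation, PCR duplicates, capture-efficiency bias, insert-size
dispersion, alignment ambiguity in repeats (every junction read clips
cleanly and exactly), and aligners that absorb mid-size deletions into `D`
CIGARs (a `--d-op-fraction`-style robustness probe was considered and left
out; the constructed regime *is* the clip regime under test). Passing tests
therefore demonstrate the statistic, the comparison rule and the geometry
of breakpoint recovery — not robustness to messy real-world alignment.

## Replicate experiments and their sizes

Two seeded experiments quantify the method (also run by
`scripts/acceptance.py`):

- **Recovery** — 50 replicates; each plants a heterozygous deletion of
  random length 20–500 bp at a random exon (boundary-spanning, or interior
  when it fits), simulates a case and two controls at default depth,
  screens the cohort and nominates breakpoints around the true exon
  (padding 550 bp so intron-anchored junctions are always in window).
  Measured: fraction of replicates whose true exon is flagged, breakpoint
  error, and length error of the best call. Recovery uses the uniform
  baseline background: a deletion inside a *shared* high-background exon is
  partially masked by the fold rule (a ~13% case against a ~5.8% shared
  artifact is fold ≈ 2.2, below threshold) — an inherent limitation of
  comparing against controls that carry the same artifact, documented here
  rather than averaged into the recovery number.
- **Null specificity** — 200 variant-free cohorts (1 case, 2 controls)
  under the full default background including the exon-2 artifact. The
  reported rate is per cell (the decision unit): fraction of case cells
  falsely flagged, ≈0.3–0.6% at defaults. The per-scene rate (any of 8
  exons flagged) is ≈2–4% and is reported alongside: with ~250–600 reads
  per exon, binomial noise alone occasionally lifts one cell over both
  thresholds, so users screening many exons should expect — and triage —
  the occasional singleton hit.

These sizes keep a full run to a few minutes on one CPU while leaving the
binomial standard errors of the reported rates well below the margins they
are compared against.

## Numerical and degenerate-input choices

- Ties: modal cluster position → smaller coordinate; intron midpoint →
  donor side; flag ordering → descending fold, then exon and sample id.
- `fold` is undefined (reported as missing, status `uncomparable`) when no
  control has coverage for the exon; such cells are never flagged.
- Per-sample screen failures are isolated and reported; a failed *control*
  aborts the run, since every comparison would be against a crippled
  baseline.
- An unknown contig in a region query yields an empty result plus a
  warning, not an error, so multi-target screens survive partial
  references.
- Monotonicity guarantees: raising `min_mapq` never increases `n_reads` or
  `n_clipped`; raising `min_clip_len` never increases `n_clipped`.

## Known limitations

- The comparison rule presumes ≥1 honest control from the same run; it
  cannot separate a variant shared by case and all controls (it would look
  like a systematic artifact), and sensitivity inside high-background
  exons is reduced (see above).
- Only deletions are paired into calls. Insertion/duplication signatures
  surface as unpaired clusters for manual review.
- The frameshift model assumes intron read-through at donor-site deletions.
- Transcript models must be supplied by the user from a pinned annotation
  release; nothing genome-specific is hardcoded.
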