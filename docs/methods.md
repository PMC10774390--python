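# Methods

This note documents the models and procedures implemented in `c9quant`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## The locus model

Every long-read stage works in one coordinate frame, `LocusConfig`: a
plus-strand repeat unit (GGGGCC), a short 5′ anchor (CGCCC) that sits
immediately upstream of the tract and registers the counting start, the
start of the 3′ flank, reference flank sequences, and the heterozygous
SNPs used for phasing.  Coordinates are 0-based, half-open, on the plus
strand of the unedited template.  The sequenced molecule is the
Cas9-excised fragment: 5′ flank, tract, 3′ flank; molecules are read in
both orientations, so the minus-strand unit appears as GGCCCC.

## Per-read repeat counting

Orientation chooses the strand on which the 5′ anchor is found (exact
hits preferred over single-mismatch hits, then leftmost; a read with the
anchor on neither strand is flagged off-target, never dropped).  The
scanner then classifies successive windows after the anchor:

* a window is a **repeat** when its edit distance to the unit is at most
  `max_unit_edit_distance` (default 1), testing aligned window lengths
  6, 5 and 7 nt so that a single insertion or deletion advances the scan
  by the aligned length and the reading frame is preserved;
* a failed window is **sequencing error**: the scanner searches ahead up
  to `termination_run` × 6 nt (default 3 unit-widths) for the next
  in-tolerance window or the 3′ anchor and resynchronises there,
  counting the skipped span as error windows.  A literal 1-nt advance
  after a failed window cannot work: every frame-shifted window of a
  perfect downstream tract is ≥ 2 edits from the unit, so the first
  corrupted unit would terminate the tract.
* the tract ends at the 3′ anchor, at resynchronisation failure, or at
  the read end; trailing error windows that merely ran into the flank
  are discarded from the tract.

Error windows are excluded from the repeat count (they are the grey
windows of a waterfall rendering; partial trailing units are likewise
not counted), so a per-read count under-reports truth by the number of
≥ 2-error windows — about 0.15 % of windows at 1 % per-base error.  The
modal count over reads is therefore the headline per-allele size; the
mean is reported alongside because blot-based size estimates track the
mean.  Tract lengths in nucleotides convert to units by floor division
(8950 nt → 1491 repeats).

The edit-distance tolerance of 1 per window tolerates ~1 % consensus
error without inflating counts; windows need ≥ 2 errors to be
misclassified, and the count was checked against an independent
exhaustive oracle (minimising the alignment distance of the tract
against unit^k over all k) on templates up to 60 repeats.

**On-target filter.** A read is on-target when both flanking anchors
were found and the molecule was traversed at least `min_passes` times
(default 3, configurable; the pass count arrives as read metadata,
`np=` in FASTA/FASTQ descriptions or an integer BAM tag).

**SNP genotyping.** For each SNP two 25-nt probes are built from the
reference flank context, one per base, and aligned infix against the
read; the genotype is the base with the smaller edit distance.  Ties,
or both probes aligning poorly (distance > probe length/4), yield a
missing genotype — e.g. when the SNP region was excised.

## Allele clustering

The SNP partition takes precedence whenever a phase-informative SNP
shows both bases at depth ≥ `min_reads_per_allele` (default 5 —
below that a base observation can be sequencing error), because a
phased SNP identifies the allele even when repeat lengths collide after
editing.  Otherwise reads split at the largest gap in the sorted repeat
counts, subject to `min_mode_gap` (default 5 units; chosen so ~1-unit
counting scatter never fabricates a second allele); with no valid split
a single homozygous-like cluster is returned.  Reads missing the
informative genotype go to the nearest repeat-length cluster, ties to
the larger cluster, so the partition stays total.  Clusters whose
repeat-count SD exceeds 3 are flagged high-dispersion (merged alleles
or a mixed clone).

## Excision measurement and clonality

Excision sizes are measured against each allele's unedited template by
**flank landmarks**, not whole-read alignment — the expanded tract is
unalignable at scale while the flanks are unique.  Two 60-nt probes are
taken just outside the maximal excisable window (tract ±
`flank_margin`, default 30 nt per side, with a 6-nt guard gap);
excision = expected unedited span − observed span between the aligned
probe boundaries.  Reads whose landmarks cannot be aligned (probe
distance > 15) land in a QC bucket, excluded from grouping but counted.

A read still carrying ≥ `retained_min_repeats` units (default 50 — the
gap between wild-type alleles, ≤ 30 or so, and pathogenic expansions,
≥ 145) is a **retained expansion**, classified before the span is
consulted: against its own expanded reference the span of a retained
read is ~0 ± indel drift, and over a multi-kb tract that drift is many
nucleotides.

**Outcome grouping.** Measurements group by (allele, kind, excision
length).  `collapse_tolerance` (default 0) optionally merges genuinely
close outcomes; it is 0 because outcomes differing by only a few
nucleotides are real and must stay distinct.  Separately, random indel
errors between the landmarks scatter a true outcome's measurements by
±1–2 nt, so a **satellite-absorption** step folds sparse neighbouring
lengths into their peaks: peaks are identified on the raw histogram in
descending count order (a length is a satellite only when an accepted
peak within `snap_radius` = 2 nt holds at least 1/0.45 ≈ 2.2× its
reads), and each satellite's reads are divided among the peaks in reach
proportionally to peak abundance — the posterior under symmetric noise.
The 0.45 count-ratio guard keeps genuinely distinct outcomes of
comparable abundance (including a 2:1 pair two nucleotides apart)
separate; a genuine minor outcome below ~0.45× of a neighbour within
2 nt would be absorbed, a stated resolution limit (set `snap_radius=0`
to disable).

**Clonality.** Outcomes below `min_outcome_fraction` (default 0.05) are
discarded as noise — the threshold is this package's construct, not an
established criterion for separating an impure clone from mosaicism.
An allele with ≥ 2 surviving outcomes marks the clone impure; otherwise
the per-allele kinds give unedited / heterozygous / homozygous
excision.  The dominant outcome is the highest-fraction one, ties
breaking toward the larger excision, then the lexically smaller allele
label.  Raising the threshold can only remove outcomes, so it never
converts a non-impure call to impure.

Excision sizes are reported relative to a compact reference template:
the post-excision molecule is independent of the pre-edit tract length
given the same cut positions, so a clone whose expanded allele lost its
tract is simulated and measured against a reference-like template whose
tract fits inside the excision window.

## ddPCR quantification

λ = −ln(1 − positives/total) copies per droplet, the standard Poisson
correction for random partitioning (implemented explicitly rather than
delegated to vendor software: closed-form and testable).  Wells with
≤ 10 positive droplets are **non-detected** — flagged, excluded from
means, never zero, which would bias fold changes.  Technical replicates
average within each biological replicate before any cross-replicate
statistic (a 3 × 3 design; pooling all nine wells would pseudo-
replicate).  Normalised abundance = λ_target / λ_reference per
biological replicate, with mean and SEM across biological replicates;
variant fractions are computed on normalised abundances and sum to 1
when defined; fold changes carry first-order-propagated SEM.  Abundances
stay in copies per droplet — droplet volume is not modelled, and every
downstream quantity is a ratio.  Significance testing across lines
(e.g. many-to-one comparisons) is out of scope.

## MSD signal ratios

ratio = mean(positive replicate signals) / mean(matched negative
signals), with the pairing type-matched and condition-matched enforced
(patient iPSC-MN vs isogenic KO, patient postmortem vs control tissue,
transgenic vs WT mouse).  Replicate SDs propagate to the ratio in
quadrature.  The specificity call is **strict**: ratio > threshold
(default 1.5), per pairing, and overall validation requires every
pairing to pass; the boundary (exactly 1.5 fails) is a documented
choice and the threshold is configurable.  Replicate aggregation is a
plain mean of n = 2 technical replicates with no outlier rejection.
The screen summary ranks (antibody pair, condition) ratios and flags
pairs exceeding the threshold in the iPSC-MN pairing, the first-pass
screen.

## The synthetic-data generator

The generator emulates the statistical structure each assay assumes:

* diploid excised-fragment templates with 500-nt flanks (long enough to
  host SNPs, landmarks and excision windows; short enough for fast
  simulation), a terminal CGCCC anchor, GGGGCC tracts of 0–2000 units,
  and per-allele SNP overrides;
* CCS reads with i.i.d. per-base errors (defaults 0.4 % substitution,
  0.3 % insertion, 0.3 % deletion — 1 % total, a stand-in for
  unpublished consensus error rates), reverse-complement emission at
  probability 0.5 so orientation logic is always exercised, and pass
  counts sampled from a distribution whose default leaves ~10 % of
  reads below the 3-pass filter;
* edited pools drawn multinomially from per-outcome templates, each
  excision removing its stated nucleotide count centred on the tract;
* droplet wells with positives ~ Binomial(N, 1 − e^(−λ));
* plate signals = background × abundance scale × lognormal noise with a
  given CV, negative-control sample types pinned to scale 1.

Flanks are scrubbed so no window lies within one edit of the repeat
unit or one mismatch of an anchor on either strand — the real locus
flanks are likewise distinguishable from the tract, and scrubbing makes
noiseless recovery exact by construction.  All randomness flows through
seeded integer-state generators; fixed seeds give identical output
across runs and platforms.

Not emulated: raw subreads and consensus generation (reads arrive as
CCS output), homopolymer- or context-dependent error, chimeric and
adapter artefacts, amplification bias, somatic repeat mosaicism, more
than two germline alleles, droplet fluorescence gating, and plate
spatial effects.  Passing tests therefore demonstrate correctness of
the analysis logic under the stated error model, not robustness to
every artefact of real instruments.

## Problem sizes and determinism

The test suite and the acceptance script run simulations sized for
seconds-scale turnaround on one CPU: 100–200 reads per allele for
sizing, 300–2000 reads per clone pool for editing outcomes, 20000
droplets × 9 wells per ddPCR sample, duplicate wells per plate
condition.  Stochastic recovery checks use 3-standard-error bounds (or
analytic Monte-Carlo SE for fold changes) at those sizes.  Every
simulation is seeded; reports are byte-identical across reruns.

## Known limitations

* Counting under-reports by one unit per ≥ 2-error window; at expansion
  scale (>1000 units) the modal count sits 1–3 units below truth at 1 %
  error.  Noiseless recovery is exact up to 2000 units.
* Outcome resolution: genuinely distinct excisions < 2 nt apart at
  abundance ratios beyond ~2:1 can be merged by satellite absorption.
* The SNP genotyper assumes SNPs live in the flanks (positions inside
  the tract are rejected as an undefined frame) and uses the left-flank
  context; right-flank SNP coordinates would shift with tract length.
* Pass counts are trusted as given; no consensus-quality model beyond
  the pass filter.
* The impure-vs-mosaic boundary (`min_outcome_fraction`) is a
  convention, not a validated biological threshold.
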