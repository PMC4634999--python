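# Methods

`mosaicscan` re-implements, as a tested library and CLI, a computational
strategy for finding pathogenic *TSC1*/*TSC2* mutations in tuberous
sclerosis (TSC) patients in whom conventional exon sequencing and deletion
testing found nothing ("no mutation identified", NMI).  The strategy rests
on very deep targeted sequencing (500–5,000×) of the full genomic extent of
both genes, because the missed mutations are dominated by two classes:
somatic mosaicism (mutant allele fraction far below the heterozygous 50%,
down to ~0.2%) and intronic variants away from the canonical splice
dinucleotides.

## Low allele-fraction calling (`caller`)

The calling model is a deliberately transparent frequency test on an
orientation-split pileup, not a genotype-likelihood model — at AF 0.2–1%
the signal is a handful of reads and the dominant enemy is systematic
artifact, which the pipeline addresses structurally:

1. **Quality filtering.** Reads with mapping quality < 20 are dropped; base
   calls with Phred quality < 20 are masked to `N` (excluded from all
   counts) while the read is retained.  The 20/20 defaults are community
   convention and are exposed in `TierConfig`.
2. **Redundancy normalisation.** For every (start position, read
   orientation) at most 50 reads are kept, so PCR jackpot duplicates cannot
   fabricate frequency.  Selection keeps the highest-mapping-quality reads,
   ties broken by read id, making the subsample deterministic; the cap is
   carrier-blind, so it does not bias the allele fraction.
3. **Orientation-split pileup.** Base calls are tallied per position per
   orientation.  Insertions are keyed `+SEQ` and short deletions `-LEN` at
   the anchor base before the event (left-aligned, VCF style).
4. **Tiered thresholds.** Any non-reference allele at AF ≥ 1% is emitted as
   a `review`-tier candidate (the direct-review set).  The `sensitive` tier
   lowers the cut-off to AF ≥ 0.5% with ≥ 3 supporting reads for SNVs and
   AF ≥ 0.2% with ≥ 2 reads for indels.  AF is always combined-orientation
   support over combined depth at the column; the support minimum is a
   total across orientations.
5. **Artifact filters.** A call whose support is confined to one read
   orientation is flagged `single_orientation` (true variants on
   double-stranded template appear in both; many polymerase/alignment
   artifacts do not).  A (position, alt) recurring as a candidate in ≥ 2
   other samples of a cohort is flagged `panel_recurrent` (process
   artifacts strike the same sites in everyone).  Flags are annotations,
   not deletions — review-tier semantics replace manual inspection.

The orientation filter is applied to both tiers; whether the original
sensitive tier also required both orientations is not documented, and
applying it uniformly is the conservative reading.

**A boundary fact worth knowing.**  A variant whose true AF equals a
frequency cut-off exactly is called in ~50% of replicates at *any* depth:
the binomial estimate's median sits on the threshold.  Detection power
statements are therefore only meaningful strictly above the cut-off (a 1%
SNV at 5,000× is called in > 95% of replicates; a 0.2% SNV at 500× in
< 50%), and estimator accuracy is assessed on the pileup frequency itself
rather than gated on the call.  Under the substitution-error model the
observed alt frequency has expectation `af·(1−e) + (1−af)·e/3` — the same
error background that motivates control panels in the real assay — and the
recovery tests compare against that expectation.

## Genomic deletion detection (`deletions`)

Multi-kilobase deletions at a few percent AF are invisible to pileup
calling but leave a paired-end signature: a read pair straddling the
deletion aligns with its outer distance (insert) inflated by the deletion
length.  Pairs with insert > 1,200 nt are flagged and binned as *large*
(> 2,000) or *intermediate* (1,200–2,000).  A deletion is called for every
maximal set of flagged pairs of one category whose leftmost coordinates
span ≤ 500 nt and whose size reaches the category minimum (3 large, or 5
intermediate); overlapping qualifying windows are merged.  Categories are
never pooled.  The sliding-window-with-merge reading is the least
arbitrary interpretation of "clustering within a 500 nt region", and the
clustering is verified against an exhaustive O(n²) all-windows oracle.

Breakpoints are reported as medians of the flanking read ends — exact
junctions are a wet-lab (junction PCR) concern and out of scope.  The
allele fraction is local: discordant pairs over discordant plus concordant
pairs whose fragment straddles the deletion start, making it directly
comparable to an SNV AF.  For the straddle test the deletion start is
bounded by the rightmost discordant left-read end (+1), the tightest
estimate the flanking reads give; using the median-based estimate here
would systematically undercount concordant pairs that begin between the
median and the true breakpoint and inflate the AF by tens of percent
relative terms.

## Amplicon k-mer quantification (`amplicon`)

For confirming and quantifying a known variant far below pileup resolution,
a 20-nt sequence matching the wild-type allele and one matching the mutant
allele are counted over an ultra-deep single-amplicon pool (10⁴–10⁶ reads)
— the computational equivalent of `grep -c` on the read file.  Matching
includes the reverse complement (both strands of an amplicon are
sequenced); each read counts at most once; AF = mut/(mut + wt), reads
matching neither k-mer (errors at the locus) are excluded from the
denominator.  SNV k-mers take ⌈k/2⌉ bases of left flank; indel k-mers span
the novel junction; non-unique k-mers in the amplicon context are rejected
with advice to raise k.

Significance against sequencing noise uses a 25-sample control panel: the
sample is `above_noise` only if its AF strictly exceeds the panel maximum
AND the one-sided binomial tail probability of its mutant count at the
pooled panel rate is < 0.01.  The explicit two-part rule replaces the
informal "always higher than controls" comparison and both parts are
configurable.

## Splice classification and allelic distortion (`splice`)

Intronic variants in coding notation ("c.976-15G>A") are binned by signed
intron offset: |offset| ≤ 2 **canonical** (the invariant GT/AG); acceptor
side −10..−40 **branch region** (bracketing the typical branch-point
adenosine); the remaining offsets ≤ 50 **near exon**; beyond 50
**deep intronic**.  The published figure underlying these bins gives no
numeric boundaries, so the windows are configurable and only the certain
assignments (canonical ±1/±2; the two variants at −126 and +281 as deep
intronic) are treated as fixed points.  Whole-gene/fusion deletions and
5'UTR-anchored forms parse into a `complex` bucket and are excluded from
classification rather than mis-binned.

Allelic distortion scores nonsense-mediated decay in expression data: for
a heterozygous exonic SNP, ratio = lower/higher allele count; ratios
strictly below 0.43 — the 99th percentile of the lower-allele ratio in
GTEx RNA-seq of a *TSC2* coding SNP — are called distorted.  The threshold
is configurable; the boundary value itself is *not* distorted, since the
population bound is attained.

## Cohort statistics (`cohort`)

The packaged 53-subject table transcribes the study cohort: per-subject
mutation (gene, type, AF, tissues) and per-organ major-feature counts over
four organ systems, kidney and lung merged (renal angiomyolipoma and
pulmonary LAM share mutations and pathogenesis).  The loader verifies a
content hash so a silently edited table cannot pass as the study data.
Two transcription choices are recorded: skin-only detections (mutation
demonstrable only in skin-lesion DNA) are counted as mosaic and in the
AF < 5% bin but not in the measured AF < 1% bin, and truncated range
notations are normalised to full HGVS-like form.

Association tests are thin wrappers with explicit conventions: Pearson
chi-square without continuity correction (Yates optional for 2×2), and
two-sided Mann-Whitney using the exact U null for small tie-free samples
(n_a·n_b ≤ 400) and the tie-corrected normal approximation otherwise.  On
the packaged table the organ-systems × status chi-square gives p ≈ 0.003
and heterozygous-vs-NMI severity p ≈ 0.013; the mosaic-vs-NMI comparison
lands at p ≈ 0.06 under every standard variant of the test, so no test
asserts it below 0.05.

## Synthetic data (`simulate`)

The generators produce every input the pipeline consumes, with the study's
statistical structure and none of its raw data:

- **Reads** — uniform starts, Bernoulli(0.5) orientation, per-base
  substitution errors (no indel errors by default, keeping indel-caller
  tests unconfounded), optional error multiplier on reverse reads to
  exercise the orientation filter, spike-in SNV/indel carriers at a target
  AF.  Defaults: 75-nt reads, depth 5,000 (long-range-PCR regime) or 500
  (hybrid capture), error 0.1%.
- **Deletion libraries** — inserts Normal(μ=400, σ=80), SAM-style signed
  outer distance, carrier pairs inflated by the deletion length, all pairs
  drawn to straddle the breakpoint region.
- **Amplicon pools and panels** — pools of exact or binomial allele
  counts, half reverse-complemented; panels of 25 wild-type-only pools
  whose per-base error is drawn from 0.21–0.48%, yielding background
  k-mer AFs near e/3 ≈ 0.07–0.16%, the noise band observed in real
  control samples.  The study reports no sequencing error rate, so this
  calibration to the observed panel noise is the one free choice.
- **Cohorts** — per-status Poisson organ-feature rates echoing the study's
  severity gradient, log-uniform mosaic AFs over 0.2–34%.

Everything is deterministic under a seed; a run-level seed derives
per-generator child seeds.  What the generators do **not** model: PCR
duplicate families, quality-score miscalibration, alignment error around
repeats, indel sequencing errors, GC-coverage bias.  Passing tests
therefore demonstrate the algorithms' correctness and statistical power
under clean-but-realistic noise, not robustness to every failure mode of
real libraries.

## Problem sizes in the tests and acceptance script

The simulation scales are chosen to make the statistics decisive while
keeping a full run in minutes: AF recovery uses a 100-nt locus at profile
depth 5,000 (the toy geometry concentrates read starts, so the redundancy
cap yields an effective column depth of 2,600 — estimates remain unbiased),
200 replicates per AF in {0.5%, 1%, 3%, 34%}; deletion recovery uses a
13,282-nt deletion at 3% carrier fraction with 1,300 breakpoint-spanning
pairs (the fragment coverage a 500× library implies) and 100 replicates;
amplicon checks use the real pool size of 955,336 reads once and 2·10⁴–2·10⁵
reads elsewhere.  Clustering equivalence is checked against the exhaustive
oracle at up to 500 flagged pairs.

## Known limitations

- The pileup engine supports M/I/D CIGAR alignments only; clipped or
  spliced reads are counted and skipped.
- Deletion breakpoints are windowed estimates (± ~half an insert size);
  no split-read refinement.
- The panel filter needs candidate lists from multiple samples; it cannot
  flag artifacts private to a single run.
- The splice classifier is positional only — it does not score splice-site
  strength (no PWM/MaxEnt models) and cannot adjudicate the
  branch-region/near-exon boundary cases the source figure leaves
  ambiguous.
- `exact` Mann-Whitney p-values require tie-free data; tied small samples
  fall back to the asymptotic approximation.
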