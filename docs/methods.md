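# Methods

## Scope and model of the data

The package compares two inbred (hence essentially homozygous) strains
against a reference genome using four evidence types — per-site pileup
summaries, binned read-depth, mate-pair geometry and RNA-seq counts — and
then links variant classes to expression. Alignment itself is out of
scope: every stage consumes tabular summaries of alignments (site
summaries, read starts, pair end positions, count matrices), which keeps
the statistical rules separable from any particular aligner.

## Synthetic data: what it emulates and what it does not

The generator produces all inputs with known truth. Noise models are the
simplest ones consistent with each data type, and each is a parameter so
harsher models can be substituted:

- site coverage: Poisson(depth); allele sampling: Binomial —
  Binomial(depth, 1 − e) at homozygous alt sites, Binomial(depth, 0.5) at
  heterozygous sites, Binomial(depth, e) at reference sites, with
  sequencing error e ≤ 0.05 (default 0.01; the platforms' true error and
  dispersion are not published, so defaults are conventional choices).
  A fraction of reads is emitted as multi-mapped/clonal counts and a
  fraction (default 5%) as low mapping quality, so the read filters and
  the MQ > 30 rule are exercisable.
- binned coverage: Poisson(mean_per_bin × copy_ratio) for the sample
  against Poisson(mean_per_bin) for the reference, with length-weighted
  partial bins.
- mate pairs: inserts Normal(median, sd) with FR orientation. Deletions
  inflate spanning inserts by the deleted length; insertions deflate them
  (and a spanning fragment only yields a mapped pair when it protrudes
  ≥ 500 bp beyond the inserted sequence — the mappability margin that
  makes insertions at or above the library insert size invisible, which
  is why only a large-insert library resolves them); inversions flip the
  strand of any end inside the inverted segment via the coordinate
  reflection x → s + e − x; tandem duplications add everted pairs across
  the copy junction.
- RNA-seq: gene counts are Gamma-Poisson (negative binomial,
  var = μ + αμ², default dispersion α = 0.05; α = 0 is the deterministic
  limit, counts = rounded means, used as a scaling oracle). A truth fold
  f > 1 is realized as up-regulation in strain 1 and f < 1 as
  up-regulation in strain 2, so the truth ratio is f either way while
  sequencing-depth composition stays symmetric between strains — each
  strain's expected column sum equals the library size, as in a
  fixed-depth sequencing run. Junction counts are Poisson around a
  per-junction depth, with truth exon skips re-routing reads from the two
  flanking junctions to the skipping junction in the affected strain.
  Allele counts at heterozygous exonic sites are Binomial(coverage,
  allele fraction).

Real data differ in ways the generator deliberately omits: GC and
mappability bias, indel-induced misalignment (the caller's indel-proximity
mask is therefore exercised structurally, not mechanistically),
overdispersed and autocorrelated coverage, chimeric pairs, and multi-modal
insert-size distributions. Passing tests demonstrate that the decision
rules implement their definitions and recover truth under the stated
noise models — not that the thresholds are optimal for any particular
instrument.

Coordinates are 0-based half-open internally; emitted VCF is 1-based,
BED 0-based. One designated pseudo-strain ("reference") emulates
resequencing of the reference animal, which the cross-filter requires.

## Small-variant cascade

Decision bands on the percentage of non-reference reads (pnr): < 10
reference, 25–75 heterozygous candidate, > 75 homozygous, indels ≥ 40;
variant alleles need ≥ 3 reads with MQ > 30; heterozygous candidates are
rejected above 3× the genome-wide median coverage (computed over covered
positions); SNVs within 10 bp (inclusive) of a called or candidate indel
are masked. The bands the rules leave open — pnr in [10, 25), or band
hits without high-quality support — are no-calls, and no-calls do not
confirm reference: in the three-genome cross-filter a variant is
strain-unique only when the other two genomes are *explicitly* called
reference at the position. This is the conservative reading; its cost is
sensitivity at poorly covered sites, its benefit that reference-genome
errors (sites non-reference in every genome) can never produce
strain-unique calls. The coverage cap applies to heterozygous candidates
only, matching the rule's stated purpose (repeat-collapse artifacts
masquerade as heterozygous sites). Heterozygous indels are not emitted:
in inbred strains an indel passing pnr ≥ 40 is treated as homozygous.
Indels are compared across call sets after left-aligned minimal
normalization.

## CNV segmentation

Both libraries are scaled to equal totals; per-bin log2 ratios use a
pseudocount of 0.5. Segmentation is recursive: within a segment the best
contiguous interval against the rest is found by the pooled two-sample t
statistic (a CBS-style scan; an interval touching a segment end is an
ordinary binary split), the scan runs over a dense grid of short interval
lengths plus a geometric grid (×1.25) up to 2,000 bins with exact local
refinement, and a split is accepted when t exceeds the alpha = 0.01
critical value Bonferroni-corrected over the candidates of that scan.
The per-scan Bonferroni correction is what keeps the genome-wide false
call rate at ≤ 1 call per 10 Mb of null track: an uncorrected
alpha-level threshold on the maximum of thousands of correlated t
statistics would fire constantly. Minimum segment length is 1,000 bp
(4 bins), consistent with the smallest CNVs worth reporting at 250-bp
resolution. Segment class: mean ratio < 0.4 deletion, > 1.6 duplication.
The "dynamic window" of the original depth-comparison tool is interpreted
as fixed 250-bp bins with the segmentation supplying the adaptivity; bin
width, thresholds, pseudocount, alpha and scan cap are all parameters.
Consensus between ambiguity settings and cross-strain removal both use
≥ 50% reciprocal overlap of same-class calls; consensus reports the
intersection span.

## Mate-pair SV rules

A library profile is the empirical median and 1%/99% insert-distance
quantiles of same-chromosome, expected-orientation pairs (≥ 1,000 pairs
required; expected orientation is a library parameter, default FR).
Classification is total: interchromosomal; everted order → duplication
support; one strand flipped → inversion support; expected orientation
beyond the upper/lower 1% tail → deletion/insertion support; otherwise
concordant. Clusters are connected components of pairwise interval
overlap; breakpoints are reported as the cluster's inner span (innermost
read ends). All SV types need ≥ 3 pairs. Deletions additionally require
(median(case) − median(control))/median(case) > 0.25 over all pairs
spanning the candidate midpoint (falling back to the control library
median when no control pair spans locally) and no control support;
duplications must span > 3,100 bp; inversions need both breakpoints
covered (≥ 1 pair on each strand side); insertions use the lower tail
mirrored from the deletion rule, with implied size = median shortfall,
and are only called when that shortfall exceeds 1.5× the library's
lower-tail spread — by construction 1% of perfectly normal pairs sit
below the empirical tail, and without a minimum implied size those
produce spurious three-pair clusters. Interchromosomal pairs are
classified but never called.

## Differential expression and the swap FDR

Counting is CDS-restricted and strand-aware (the library is stranded).
Normalization scales each sample by (mean coding total)/(sample total),
preserving count magnitude so the "expressed if strain mean > 10" rule is
meaningful. The DE test is a two-sided pooled-variance t-test on
log2(normalized + 1) — the log transform stabilizes variance for count
data; scale and sidedness are parameters since reasonable analysts
differ here. DE requires expressed, fold > 2 (either direction, fold =
ratio of strain means) and P < 0.05. The swap FDR enumerates balanced
relabelings of the six samples: 10 unordered partitions, the true one
excluded, 9 null relabelings (the test and |fold| are label-symmetric;
ordered enumeration is available as an option), applies the full DE rule
under each, and reports mean null positives / observed positives.

## Junction analysis

The reference enumerates ordered exon pairs of each gene (donor before
acceptor in transcription order, within 1 Mb, within-gene only), joining
flank_k terminal bases of each exon (default 45 = read length 50 − 5,
with 5-bp minimum overhang on both sides of the joint); identical
sequences are deduplicated. Reads must map uniquely with < 5 mismatches.
Junctions built from exon ends carrying a strain-unique SNV are excluded
(mapping bias). A = log2(strain1) − log2(strain2) on strain-summed
normalized counts with pseudocount 0.25 — chosen so that 4 reads versus 0
gives |A| = log2(4.25/0.25) ≈ 4.09, just above the threshold 4, making
the "at least 4 reads" side condition and the |A| > 4 rule consistent.
Calls are flagged annotated (adjacent exons) versus novel within-gene
combinations.

## Integration statistics

The consequence classifier evaluates CDS SNVs at codon level and indels
by length mod 3, flags the two intronic bases at each exon boundary as
essential splice sites, and assigns UTR5/UTR3, 5-kb-upstream
(strand-aware from the TSS), intronic and intergenic by interval. One
most-severe class per variant–gene pair under the fixed order stop_gain >
frameshift > stop_loss > essential_splice > missense > inframe_indel >
synonymous > UTR5/UTR3 > upstream > intronic > intergenic. This is a
deliberate simplification of a full effect predictor — adequate for the
synthetic annotation, and documented as such. The "stop variant" group
used in predictive-value summaries is stop_gain ∪ frameshift ∪
essential_splice. Predictive value of a class = DE fraction of the
expressed genes carrying it (null when none are expressed). Upstream
density compares per-gene 5-kb-upstream SNV and indel counts between DE
and non-DE genes with a two-tailed pooled t-test. Allele-specific
expression calls a site biallelic at coverage ≥ 8 with the minor allele
≥ 2 reads and ≥ 10% (thresholds are this package's choices; swapping
ref/alt labels cannot change the call). Deletions are flagged as
repeat-rich intronic when they lie entirely within one intron and
overlap > 2 kb of (merged) repeat annotation.

## Problem sizes used in the test suite

Simulation-recovery suites run at desk scale: the variant-caller recovery
check uses 1 Mb at 30× with 1% error; CNV recovery uses twenty 250-kb
tracks with one spiked ≥ 2-kb event each plus a 10-Mb null; mate-pair
recovery uses ten 2-Mb libraries at 10× physical coverage; DE calibration
uses ten 2,000-gene simulations; junction recovery thirty seeds of a
100-gene transcriptome. The thresholds asserted (≥ 95% / ≥ 90% recovery,
type-I 5% ± 2%, zero false calls) are the method's working claims at
those sizes.

## Known limitations

- The segmentation scan caps candidate interval lengths at 2,000 bins
  (500 kb); larger events are still found through their flanks but their
  boundaries derive from two separate splits.
- The swap FDR has only 9 null relabelings at 3 + 3, so its estimate is
  coarse (granularity of one relabeling ≈ 11% of a count unit).
- Total-count normalization is compositional: if differential expression
  is strongly mass-asymmetric between strains, null genes acquire an
  apparent fold shift. The generator's balanced realization of fold
  directions reflects the regime in which the published rule set is
  meaningful.
- The consequence classifier ignores transcript isoforms, start-loss,
  and splice-region (beyond ±2) effects.
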