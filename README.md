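# varxome

Toolkit for comparing the genomes and liver transcriptomes of two inbred
rat strains (the founders of a recombinant inbred panel, e.g. SHR and
BN-Lx) against a reference genome, and for asking which classes of genomic
variant actually predict expression changes. It reimplements, as a tested
and reusable pipeline, the analysis stages such a study needs:

- **Small variants** — a pileup-based SNV/indel caller driven by the
  percentage of non-reference reads (*pnr*): multi-mapped and clonal reads
  are discarded, variant alleles need ≥ 3 reads with mapping quality > 30,
  *pnr* < 10 is reference, 25–75 heterozygous (capped at 3× the median
  coverage), > 75 homozygous, indels need *pnr* ≥ 40, and SNVs within
  10 bp of an indel are masked. Calls are cross-filtered against two other
  genomes (a variant must be explicitly reference in both) and intersected
  with an independent second call set. A 100-kb window analysis quantifies
  clustering of heterozygous SNVs, with a uniform-placement simulation as
  its null model.
- **CNVs** — sample/reference read-depth ratios in 250-bp bins, segmented
  by recursive CBS-style binary segmentation; segments with ratio < 0.4
  are deletions and > 1.6 duplications; calls must survive two
  read-ambiguity settings (reciprocal 50% overlap) and strain-shared calls
  are removed.
- **SVs** — long mate-pair geometry: pairs beyond the empirical 1%
  insert-distance tails support deletions/insertions, everted pairs tandem
  duplications, single-strand-flipped pairs inversions. Calls need ≥ 3
  supporting pairs; duplications must exceed 3,100 bp; deletions pass
  (median(case) − median(control))/median(case) > 0.25 over spanning pairs
  and control subtraction.
- **Differential expression** — CDS strand-aware counting, normalization
  to coding-mapped totals, expressed if a strain mean > 10, DE if
  > two-fold with t-test P < 0.05, and a label-swap FDR: the DE rule is
  re-run under all 9 null balanced relabelings of the 3+3 samples and the
  mean null-positive count is divided by the observed DE count
  (e.g. 23/532 ≈ 4.3% < 5%).
- **Splicing** — a junction reference of all ordered same-gene exon-end
  combinations within 1 Mb; junction reads must map uniquely with < 5
  mismatches; SNV-biased exon ends are excluded; differential usage is
  |A| > 4 with ≥ 4 reads, where A = log2(strain1) − log2(strain2) on
  normalized strain-summed counts.
- **Integration** — a simplified consequence classifier (stop gain/loss,
  missense, synonymous, frameshift, essential splice site, UTRs, 5-kb
  upstream, intronic), SV–gene overlap (full/partial duplication and
  deletion), per-class predictive values (fraction of expressed
  variant-bearing genes that are DE), upstream variant density, per-site
  allele-specific expression and intronic repeat-rich deletions.

A first-class synthetic-data module generates every input with known
ground truth — genomes with multi-exon gene models, pileup site summaries,
binned coverage, mate-pair tables and negative-binomial RNA-seq counts —
so each stage is tested end to end against spiked truth without any
external data.

## Worked example

```bash
varxome simulate --seed 7 --outdir wk
varxome de --counts wk/gene_counts.tsv --out wk/de.tsv
varxome cnv --coverage wk/coverage.tsv --out wk/cnv.bed
varxome sv --case wk/matepairs_case.tsv --control wk/matepairs_control.tsv --out wk/sv.bed
varxome integrate --study wk --out wk/pv.tsv
```

prints

```
4 DE genes; swap FDR 0.0
1 CNV calls -> wk/cnv.bed
1 SV calls -> wk/sv.bed
variant_class  n_expressed  n_de  fraction
     intronic            1     1       1.0
  partial_dup            1     1       1.0
 stop_variant            0     0       NaN
  upstream5kb            3     3       1.0
```

The simulated study spikes a duplication at 20–30 kb (called
`chr1 20000 30000 DUP 1.774`: the coverage ratio estimate for a true copy
ratio of 2), a 10-kb deletion at 120–130 kb (called
`chr1 119806 130079 DEL` from 19 discordant mate pairs), one gene at a
true fold change of 8 (recovered among the DE genes, with the swap FDR
estimating how many of the DE calls relabeled data would produce), and an
exon-skipping event. The predictive-value table is the integration step:
for each variant class, how many genes carrying it are expressed and what
fraction of those are differentially expressed.

`varxome call-snv`, `varxome het-windows` and `varxome splice` cover the
remaining stages; every command is a thin wrapper over the library modules
(`varxome.small_variants`, `varxome.cnv_coverage`, `varxome.sv_matepair`,
`varxome.expression_de`, `varxome.splicing_junctions`,
`varxome.variant_impact`, `varxome.synthetic_data`).

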