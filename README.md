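# methylkin

Toolkit for intergenerational sperm DNA-methylome comparisons from RRBS-style
per-CpG bisulfite counts, with a synthetic-cohort generator for end-to-end
validation.

What it does:

- **Differential tiling** — fixed, non-overlapping 100 bp windows; a window
  is testable when it holds ≥ 2 CpGs covered at ≥ 10× in every sample of
  both groups; group difference tested per window (binomial logistic
  likelihood-ratio test, optional common-dispersion overdispersion
  correction, or pooled Fisher exact), BH-corrected jointly; DMT iff
  q < 0.01 and |difference| ≥ 10 percentage points.
- **DMC calling and merging** — per-CpG tests at ≥ 10× pooled coverage in
  both groups; same-direction DMCs within 100 bp (inclusive) merge
  transitively; clusters of ≥ 2 become DMRs, singletons are reported
  separately; size-class summaries at the ≤ 100 bp cut.
- **Overlap algebra** — exact tile intersections on the 100 bp grid,
  three-way intersections, and a region-pair nesting taxonomy
  (identical / nested either way / partial / disjoint) with
  best-overlap-partner classification.
- **Genomic context** — midpoint element annotation with fixed precedence
  (promoter > TTS > 5'UTR > 3'UTR > exon > intron > noncoding > intergenic,
  ±1 kb promoter/TTS windows), CpG-island shore (≤ 2 kb) / shelf (2–4 kb) /
  open-sea (> 4 kb) context, repeat-class composition and young-LINE-1
  subfamily enrichment (2×2 chi-square vs an all-sequenced background),
  expression-based KO-sensitive subfamily selection (> 5-fold) and ±1 kb
  flanked overlaps.
- **Developmental timing** — region × timepoint mean-methylation matrices
  against random 1 kb genome-bin backgrounds, early/late/ambiguous timing
  labels, RPKM from read-interval tracks, joint methylation–RPKM profiles
  and WT-vs-KO comparisons.
- **Synthetic cohorts** — annotation (genes, CpG islands, repeats with
  young LINE subfamilies), beta-binomial RRBS counts with negative-binomial
  coverage and planted hypomethylated regions (10–40 point effects,
  placement-biased, nested across cohorts with a tunable shared fraction),
  developmental tracks in which planted regions gain methylation only after
  the E16.5-analog timepoint, and enriched histone read tracks — all with
  ground truth and full determinism under a fixed seed.

## CLI

`methylkin` exposes one subcommand per stage (exit codes: 0 ok,
2 configuration error, 3 data error):

```sh
# generate a synthetic cohort run directory
methylkin simulate --seed 1 --n-planted 100 --out sim/

# call DMTs between groups (repeat --control/--mutant per sample file)
methylkin dmt --control c1.cov --control c2.cov \
              --mutant m1.cov --mutant m2.cov \
              --min-cov 10 --min-cpgs 2 --min-diff 10 --q 0.01 \
              --test logistic --out dmts.tsv

# DMCs -> merged DMRs (hypomethylated direction)
methylkin dmc-merge --control c1.cov --mutant m1.cov \
                    --gap 100 --direction hypo --out dmrs.bed

# cross-cohort overlap summary
methylkin overlap --a f1_dmrs.bed --b f2_dmrs.bed --mode regions --out ov.json

# context annotation and enrichment
methylkin annotate --regions dmrs.bed --genes genes.tsv --cgis cgis.bed \
                   --repeats repeats.tsv --background allseq.bed --out ann.json
methylkin enrich --expression folds.tsv --fold 5 --regions dmrs.bed \
                 --repeats repeats.tsv --chrom-sizes chrom.sizes --out enr.json

# developmental timing
methylkin timing --regions dmrs.bed \
                 --tracks E13.5=e13.cov,E16.5=e16.cov,P0=p0.cov,sperm=sp.cov \
                 --chrom-sizes chrom.sizes --out traj.tsv
methylkin chip-rpkm --regions dmrs.bed --reads chip.bed \
                    --library-size 1000000 --out rpkm.tsv
methylkin ko-compare --regions dmrs.bed --wt wt.cov --ko ko.cov --out ko.tsv

# full simulate -> analyse -> report pipeline on a toy cohort
methylkin run --seed 1 --out run/
methylkin report run/
```

Coverage-call files are whitespace-delimited `chrom pos strand meth cov`
with 1-based positions; all interval files are 0-based half-open BED-style.
Analysis defaults live in `methylkin.constants.DEFAULTS`.

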