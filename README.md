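# acetdiff

Differential H3K27ac analysis for two-condition CUT&RUN experiments —
built for the question of how the chromatin landscape of infarct
border-zone cardiomyocytes diverges from healthy left-ventricle
cardiomyocytes, and usable for any comparable paired design. The package
quantifies fragment signal in 500 bp genomic bins, subtracts a per-sample
background, quantile-normalizes across samples, calls differentially
acetylated bins with a moderated negative-binomial (NB) test, merges
adjacent significant bins into regions, relates promoter acetylation to
differential expression, partitions regions against directional ATAC peaks
(the six-way "Venn" classes), and tests class-specific transcription-factor
motif enrichment against a GC-matched background.

Because raw CUT&RUN and RNA data are large and external, the package ships a
first-class synthetic-data generator that reproduces the statistical
structure of such an experiment — NB bin counts (variance μ + αμ²) over a
uniform background plus enhancer-shaped peaks, a stable-peak backdrop,
condition-dependent fold changes, directional ATAC peaks, motif instances
planted in class-specific enhancers, and expression counts sign-coupled to
promoter acetylation — with full ground truth, so every stage can be
validated by recovery instead of by eyeballing.

## The model in brief

For bin *i*, sample *j* with condition *c(j)*, counts are modelled as

    K_ij ~ NB(mean = s_j (b + e_i f_i^{c(j)}),  variance = μ + α μ²)

where *b* is the background rate per bin, *e_i* the enhancer elevation,
*f_i* the condition fold change and *s_j* a library size factor. The
analysis chain is: midpoint binning → per-sample background subtraction
(mean count of bins with < 20 tags) → quantile normalization → per-bin
moderated NB Wald test of case vs control → Benjamini–Hochberg FDR
(q < 0.05) → merging of adjacent same-direction significant bins. Promoter
acetylation uses the identical chain on TSS ± 2000 bp windows. Motif calls
use a log-odds PWM scan (hit ≥ 80% of max score, both strands) and a
one-sided binomial test against GC-matched background windows, with
enrichment declared at p < 10⁻¹⁰.

## Worked example

```bash
acetdiff simulate demo/dataset --seed 1     # synthetic 3 vs 3 experiment
acetdiff all demo/dataset demo/work --seed 1
acetdiff evaluate demo/dataset demo/work
```

The `all` command prints (stderr carries per-stage logs):

```yaml
concordance:
  concordance_fraction: 1.0
  n_acetylation-unchanged: 22
  n_concordant: 39
  n_de_significant: 61
  n_discordant: 0
  n_not-tested: 0
  spearman_log2fc: 0.7993927125506073
n_enriched_motif_tests: 5
n_regions_down: 99
n_regions_up: 100
venn:
- acet_only: 58
  atac_only: 36
  both_acet: 41
  both_atac: 44
  direction: down
- ...
```

Reading: the pipeline called 100 gained and 99 lost acetylation regions; of
the lost regions, 41 overlap a (padded) lost-accessibility ATAC peak and 58
do not; 61 genes are differentially expressed, 39 of them with a
same-direction significant promoter acetylation change and none with an
opposite-direction change (concordance fraction 1.0). `evaluate` compares
the calls with the simulator's planted truth:

```yaml
n_called_regions: 199
n_planted: 199
region_fdr: 0.06030150753768844
region_sensitivity: 1.0
concordance_fraction: 1.0
motif_recovery_rate: 0.8333333333333334
```

Every planted differential region was recovered; 6% of called regions fall
outside planted truth (singleton false-positive bins, consistent with the
5% bin-level FDR target); five of the six planted class/motif pairs are
recovered at this small problem size.

Stages can also be run one at a time (`bin`, `normalize`, `diffacet`,
`promoters`, `diffexpr`, `concordance`, `integrate`, `motifs`) against the
same working directory, and everything is available as a library
(`acetdiff.binning_signal`, `acetdiff.differential`, …).

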