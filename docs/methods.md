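# Methods

## Signal quantification

Fragments arrive as BED records (one record = one tag; converters from
BAM/CRAM are standard tooling and out of scope). Each fragment is assigned
to exactly one bin of a fixed 500 bp tiling — the bin containing its
midpoint, `floor((start+end)/2)` — which makes counting insensitive to
fragments straddling bin edges and conserves the total fragment count.
Terminal partial bins are retained, so the tiling covers every base exactly
once. All coordinates are 0-based half-open throughout; gene annotations
(1-based GTF) are converted on read.

The per-sample background level is the mean count over bins with fewer than
20 tags; it is subtracted from every bin of that sample and the result is
floored at zero, since negative pseudo-counts have no meaning for the count
model downstream. If no bin falls below the threshold the background is 0
and a warning is raised. Promoter windows (TSS ± 2000 bp, strand-symmetric)
go through the identical subtract/normalize/test chain; with 4 kb windows
the sub-threshold rule often finds no qualifying window, which degrades
gracefully to no subtraction.

## Quantile normalization and ties

Quantile normalization maps each sample's order statistics onto the mean of
the per-sample order statistics. Tie handling is rank-stable by default:
tied values receive consecutive reference values in input order, so every
sample carries exactly the reference multiset and renormalizing is an exact
no-op — two invariants the pipeline's tests rely on. A tie-averaging
variant (`ties="average"`, each tied run receives the mean of the reference
values spanning its ranks) is provided for symmetry-sensitive uses; on tied
data it trades the two exact invariants for invariance to input order.
Integer counts are recovered after normalization by rounding half-to-even,
because the NB test consumes counts.

A structural point the simulator makes explicit: quantile normalization
preserves differential signal only *relative to a backdrop* of
non-differential signal. If every peak in a dataset changed in the same
direction, ranks would not shift and normalization would flatten the
effect entirely (we verified this degenerate case: zero regions are called
at any threshold). Real H3K27ac data contains tens of thousands of stable
peaks; the generator therefore plants a configurable set of stable "null"
peaks with log-normal amplitudes (default 200 peaks, median elevation 50
counts/bin, log-sd 1.0) alongside the differential ones. Conclusions from
recovery tests carry over to real data only insofar as differential regions
remain a minority of the acetylated landscape — the usual situation.

## Differential testing

Counts are modelled as NB with variance μ + αμ². Per feature, the
dispersion is estimated by method of moments from the pooled within-group
variance, α̂ = (v − m̄)/m̄² (exposed as `estimate_dispersion`, floored at
0.01). At three replicates per group this estimate has only d = n₁+n₂−2 = 4
residual degrees of freedom, and a Wald test that plugs it into a normal
reference is badly anti-conservative (measured ~10% of null p-values below
0.05). The test therefore moderates the dispersion toward an across-feature
prior — the 5%-trimmed mean of the raw moment estimates over features with
mean ≥ 10 (the trimmed mean, unlike the median, is nearly unbiased for the
skewed sampling distribution of α̂) — with prior weight d₀ = 12
pseudo-observations, floors the result at 0.01, and refers the Wald
statistic

    t = log2FC / SE,   log2FC = log2((m_case + 0.5)/(m_ctrl + 0.5)),
    SE = sqrt(Σ_g (1/(m_g + 0.5) + α̃)/n_g) / ln 2

to a Student t distribution with d + d₀ degrees of freedom, in the spirit
of limma's empirical-Bayes variance moderation. With these defaults the
measured null behaviour at 3 vs 3 is a p < 0.05 fraction of 0.037–0.047
with decile CDF deviations below 0.015, while 4-fold effects at ≥ 50
counts/bin are recovered with ≥ 0.95 sensitivity (see
`scripts/acceptance.py`). d₀ trades robustness against dispersion
heterogeneity for power and is exposed as `prior_df`; with strongly
feature-dependent dispersions a smaller value is the safer choice.

Size factors use DESeq2's median-of-ratios construction on raw counts
(expression arm). Quantile-normalized matrices already share one
distribution, so the bin/promoter arm runs with unit factors. Features with
zero counts in every sample are dropped before testing and before the
Benjamini–Hochberg adjustment fixes the number of tests. BH is the exact
step-up construction, validated against a brute-force implementation of the
definition. An independent cross-check against DESeq2 (pydeseq2) on planted
fold changes shows log2FC correlation > 0.95 with matching signs.

Adjacent significant bins (q < 0.05) merge into regions only when they
share a fold-change sign; a region mixing directions would have no defined
direction. Dropped all-zero bins break adjacency, as do chromosome
boundaries.

## ATAC integration and motif enrichment

Differential ATAC peaks are padded 500 bp on both sides (clipped at
chromosome bounds); any ≥ 1 bp overlap between a same-direction acetylation
region and a padded peak assigns both to the "both" class, with no
reciprocal-fraction requirement. Up- and down-direction analyses never mix.
Because overlaps can be many-to-many, the "both" tally is reported from
both sides (per acetylation region and per ATAC peak); each side's three
classes partition that side's elements exactly.

Motif scanning anchors on 200 bp windows: ATAC summit windows (peak centre
± 100 bp) for classes involving accessibility, acetylation-region centres
± 100 bp for the acetylation-only classes (the region centre is the best
available point estimate at 500 bp bin resolution). Scanning is a log-odds
scan of both strands against the PWM's background distribution; a position
is a hit at ≥ 80% of the matrix's maximum achievable score, and positions
containing N never match. Enrichment per (class, motif) compares the
fraction of target windows with ≥ 1 hit against GC-matched background
windows (two per target, |ΔGC| ≤ 0.02, drawn without replacement from a
non-differential pool) with a one-sided binomial tail using the
pseudocounted background rate p₀ = (k_bg + 1)/(n_bg + 2); a motif is called
enriched at p < 10⁻¹⁰. The built-in library holds sharp (0.97 consensus
probability) models of the four motif families the biology singles out:
AP-1 (TGASTCA), MEF2 (CTAWWWWTAG), a PPAR/RXR-like DR1 direct repeat
(AGGTCAAAGGTCA) and a KLF/SP GC-box (GGGGCGGGG). AP-1 and MEF2 are
effectively palindromic under their degenerate positions, so their
consensus hits both strands — expected behaviour, not a bug.

## Synthetic data: what it emulates and what it does not

The generator reproduces the design of the motivating experiment — 3 vs 3
CUT&RUN replicates, 3 vs 5 nuclear RNA replicates, GC 0.42, NB counts with
dispersion 0.05 and background 10 fragments/bin, 150 bp fragments — and
plants: six classes of 600 bp enhancers (gained/lost acetylation × with/
without accessibility change, fold 4 or 0.25, the low side of every change
at 50 counts/bin), stable null peaks, directional ATAC peaks equal to the
enhancer with a centred 200 bp summit, class-specific motif instances
sampled from the PWM and embedded at enhancer centres, and gene promoters
whose acetylation change is sign-coupled to the gene's expression change
for a configurable fraction of differential genes (default 0.65, matching
the proportion observed in border-zone cardiomyocytes). Placement shuffles
all elements across the genome with random gaps so class carries no
positional information. Every output is a pure function of the seed; each
operation draws from an independent seeded stream.

Not modelled: fragment-length distributions, duplicates, mappability or
GC bias, read-level error, spike-ins, and biological covariance between
neighbouring regions. The pipeline consumes bin counts, so these
realism gaps do not affect the statistical claims the tests make, but
absolute sensitivities measured here should not be quoted for real
libraries.

## Numerical and reproducibility choices

Probabilities in PWMs are floored at 1e-9 before taking logs; N positions
score −10⁹. The NB sampler uses the gamma–Poisson mixture and degrades to
Poisson at α = 0. Output tables are written with a fixed %.6g float format
and deterministic orderings, so identical configurations produce
byte-identical files (tested). Problem sizes in the reference studies —
10,000 bins for calibration, 20,000 bins / 200 enhancers / 5 seeds for
recovery, 200 windows per class / 5 seeds for motif recovery — keep the
whole reproduction under ~1 minute on one CPU while leaving the measured
characteristics stable across seeds.

## Known limitations

- The moderated t reference assumes roughly exchangeable dispersions across
  features; a strong mean–dispersion trend would call for a trended prior.
- Promoter windows overlapping multiple genes are counted independently per
  gene (a fragment may serve two genes); no attempt is made to deconvolve
  shared promoters.
- The acetylation-only motif anchor (region centre) is quantized to the bin
  grid and can sit up to ~250 bp from the causal element; with ≥ 200
  windows per class the enrichment call absorbs this, but per-window hit
  rates are diluted.
- Whether "tags" in the background rule mean reads or fragments is
  interpreted as: one BED record = one tag.
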