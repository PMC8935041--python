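# Methods

## The problem and the model

A mouse GV oocyte carries far more RNA than a typical somatic cell and
degrades roughly three quarters of it during meiotic maturation (GV → MII)
with transcription silenced. Two consequences drive the design of this
package:

1. **Cross-stage normalization must be anchored externally.** Any factor
   estimated from the genes themselves (total counts, all-gene
   median-of-ratios) equalizes the stages and hides the degradation. ERCC
   spike-ins, added in fixed amount per library, keep an absolute scale;
   where spikes are absent, maturation-stable endogenous genes
   (constGenes) substitute.
2. **GV is not one state.** Oocytes progress from NSN to SN chromatin
   configuration; single-oocyte libraries make this progression visible as
   a continuum, which the package models as a latent stage score
   t ∈ [0, 1] per oocyte.

Counts are modeled as negative binomial with mean m and variance
m + αm², the standard RNA-seq parameterization; α = 0 degenerates to
Poisson.

## Normalization

Size factors follow the classic median-of-ratios estimator: the reference
for feature i is the geometric mean of its counts across samples, computed
only over features positive in every sample (the log-mean is undefined
otherwise), restricted to the control set when one is given; s_j is the
median of k_ij / r_i (even-sized medians average the middle two). Factors
are not renormalized to product 1 — with spike or constGene controls they
are interpretable as absolute RNA-content scalings, which the dilution
readout relies on.

One exact property worth stating precisely: multiplying column j by c
multiplies every factor *ratio* s_j/s_l by exactly c; the raw factors pick
up a common c^(1/n) because the geometric-mean reference itself shifts.
Equivalently, normalized counts are recovered up to a common scalar. The
tests assert the ratio form, which is the exact invariance this estimator
has.

Two practical thresholds: features need ≥5 reads in ≥2 libraries to enter
any differential analysis (filtering happens before factor estimation;
config-reversible), and spike-anchored analyses require ≥500 spike reads
per library.

At low counts the geometric mean is biased downward relative to the mean,
which drags all-gene median-of-ratios factors for shallow, heavily
degraded libraries; the maturation normalization comparison therefore runs
on deep libraries (baseline ln-mean 6.5, median gene mean ≈ 650 counts),
where the all-gene medians sit near 0 as the estimator's construction
implies.

## Differential test

Per-gene dispersion is method-of-moments on normalized counts, pooled
within groups with degree-of-freedom weights and floored at 0. The Wald
statistic is lfc/se with lfc = log2 of the ratio of group means (a
half-minimum pseudocount replaces a zero group mean) and
se² = (1/ln2)² · Σ_g (1/m_g + α)/n_g. p-values are two-sided normal;
adjustment is Benjamini–Hochberg step-up (own implementation, tested
against an O(n²) oracle). No dispersion shrinkage, trend fitting or
independent filtering is applied: the estimator is deliberately
transparent, and its claims are validated by parameter recovery on
synthetic data, not by equivalence with any specific DE tool. At
moderate group sizes (n = 10) the normal approximation with
moment-estimated dispersion keeps the empirical false-positive fraction at
adjusted p < 0.01 well under 0.02 in the global-null simulation.

## Staging

PCA runs on log2(normalized count + 1) over the SN-featured gene set, with
genes centered and components taken from the SVD; the largest-|loading|
entry of each component is made positive so embeddings are deterministic.
log2(q+1) is a fixed, explicit transform chosen over variance-stabilizing
alternatives to keep the pipeline self-contained (config-switchable).
PC1 orientation is convention-dependent, so stage-axis correlations are
reported with sign but recovery criteria use |r|.

k-means is Lloyd's algorithm, best of 25 initializations (centers drawn
uniformly without replacement from the data points; run seeds derived from
the master seed by counter; WCSS is asserted non-increasing within each
run). Clusters are named by descending mean SN score — SN-High/SN-Low at
k = 2, SN-High2/SN-Mid/SN-Low at k = 3 — with ties broken by cluster index
(warned). The SN score is the mean (optionally sum) of normalized counts
over SN-featured genes.

Trajectory classification takes the two phase comparisons (Mid vs Low,
High2 vs Mid); genes significant in **at least one** comparison (adjusted
p < 0.01) are classed by their fold-change sign pair, the rest are
unclassified. Gating on one comparison rather than both is a genuine
choice — requiring both would empty the up-dn/dn-up classes of genes flat
in one phase; both gatings are available.

## rRNA 5′-ETS score

Coverage vectors span exactly the 13,403-base primary transcript (1-based;
bedGraph input is 0-based half-open and converted only in the reader).
Scores are the unit-normalized mass in the inclusive window 500–1,500
(1,001 positions) — window coordinates are transcript coordinates, the
5′-ETS beginning at position 1. The window, not any despiking filter, is
the defense against non-specific coverage spikes elsewhere in the 5′-ETS.
High/Low groups split at the mean score by default (an explicit threshold,
e.g. a previously published 0.00229, can be passed); ties go Low.

## constGenes

A gene is maturation-stable when |lfc| < log2(1.5) in both the poly(A) and
the RiboMinus GV-vs-MII comparison, each run with spike-anchored factors.
"Less than 50% change" is read symmetrically in log space (ratio within
(1/1.5, 1.5)); the asymmetric band (0.5, 1.5) is a config option. No
significance requirement is imposed — stability is an effect-size
statement, and requiring non-significance would favor noisy genes.

## Deduplication

Exact-match keys only: (sample, position, strand, UMI) for the UMI-aware
collapse, (sample, position, strand) for the coordinate-only collapse,
keeping the first read per key. No UMI error correction is attempted (a
hook exists for edit-distance collapse). "Alignment" is realized as
(position, strand) because the generator emits single-end records.

## The synthetic generator

`simulate_truth` draws, per configured cohort: log-normal baseline
expectations μ_i; a latent stage t_j (uniform on [0, 1] by default — the
real NSN→SN composition of a cohort is unknown, and uniform is the neutral
choice for a progression with intermediates); per-gene retention d_i with
MII expectation d_i·μ_i; true size factors s*_j (log-normal, sd 0.3);
spike concentrations (92 spikes, log-normal); and a 5′-ETS amplitude
e_j = a + b·t_j + noise (defaults a = 0.005, b = 0.010, noise sd = 0.001 =
0.1·b, which puts synthetic scores at the few-per-thousand scale real
residual-rRNA libraries show).

Structured genes: SN-featured genes scale as 1 + (fold−1)·t (2-fold at
t = 1 by default), NSN-featured genes mirror them; trajectory genes are
piecewise-linear in log2 space with the breakpoint at t = 0.5 and
±log2(fold) per phase — the simplest shape producing the four classes.
Retention-flat genes (the constGene truth; 15% of genes by default) have
log2 d ~ N(0, 0.2) truncated inside (−log2 1.5, log2 1.5); remaining genes
draw ln d ~ N(ln 0.15, 0.8) and are rescaled so that the mass-weighted
global retention Σd_iμ_i/Σμ_i equals the configured value **exactly**
(default 0.25, between the field's ~70% and ~80% degradation figures);
rescaled genes that would land inside the flat band are pinned just
outside it so the truth-flat set stays exact.

Counts are NB(s*_j·q_ij, α); spike means are s*_j·concentration·κ,
invariant to stage, fraction and degradation by construction. The dilution
series scales gene expectations by the fraction and leaves spikes alone
(spikes are added after dilution). Coverage profiles put baseline mass on
the mature 18S/5.8S/28S segments and a uniform 5′-ETS component of
relative mass e_j on positions 1–4,007 (the 5′-ETS length under the mouse
45S layout used here). Reads give each molecule a distinct
(position, strand, UMI) draw — UMIs uniform over 4⁸ — and emit it
D ~ 1 + Poisson(amplification−1) times, or a fixed D for the
uniform-amplification contrast. Every generator takes an explicit seed;
there is no global random state.

**What the generator does not emulate:** sequence-level artifacts (GC or
length bias, mapping ambiguity), batch structure between datasets beyond
independent sampling noise, zero-inflation beyond NB sampling, mate-pair
geometry, and real rRNA processing intermediates. Passing recovery tests
therefore demonstrates the estimators' correctness under the stated
stochastic model, not robustness to those real-data artifacts.

## Problem sizes and numerical choices

Desk-scale defaults: 2,000 genes, 92 spikes; 78 GV oocytes for staging
(dispersion 0.05); 10 + 10 GV/MII libraries for maturation and constGene
analyses (dispersion 0.01–0.02); 12 dilution libraries (4 fractions × 3
replicates, dispersion 0.01); 300 genes × 8 libraries for read-level
dedup simulations. These sizes keep every analysis and the full test suite
in seconds while leaving the recovery margins wide.

Tie-breaks and degenerate inputs are deterministic throughout: even-length
medians average the middle two; equal cluster scores warn and fall back to
cluster index; an all-zero coverage profile, an empty control set, a
sample missing from metadata, a zero column total and a p-value outside
[0, 1] are hard errors rather than silent fixes. Empty k-means clusters
re-seed at the worst-fit point.

## Known limitations

- The k = 2 staging ARI against the median split of t is structurally
  below 1 under a uniform stage distribution: the 2-means boundary on the
  log scale does not coincide with the t-median, so a few boundary oocytes
  differ between the two partitions and the ARI fluctuates with the seed.
- The NB Wald test is anti-conservative under strong dispersion
  misestimation at very small n; it is validated here for n ≥ 10 per
  group.
- Dataset-level correlations use log10(x + 1) on mean-normalized profiles;
  distances use log2(q + 1) — both are fixed explicit transforms, not
  variance-stabilized, and are documented non-equivalences with
  rlog-style pipelines.
- Real-data headline values from the literature (e.g. a 0.00229 5′-ETS
  threshold, 147 constGenes, 43% ± 15% UMI retention) depend on cohorts of
  100+ external libraries and are context, not desk-scale targets.
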