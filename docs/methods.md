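# Methods

This note records the modelling assumptions, parameter defaults, numerical
conventions and deliberately open design choices behind each stage of the
pipeline. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cosinor chronogram

**Model.** Per gene, ordinary least squares on
`Y(t) = M + β·cos(2πt/T) + γ·sin(2πt/T) + δ_batch + ε` with T = 8 cell
cycle bins, t ∈ {0..7}. The amplitude/acrophase parameterisation is
`A = √(β²+γ²)`, `φ = atan2(−γ, β)` mapped into [0, 2π). The design is
shared across genes, so all complete genes are fitted in one matrix least
squares; genes with missing samples are re-fitted individually on their
observed samples when the residual degrees of freedom permit, otherwise
skipped with a warning. A single harmonic at fixed period is deliberate:
the sampling design has one cycle and eight points, which cannot support
free-period or multi-harmonic fits.

**Batch coding.** Treatment contrasts with the lexicographically first
batch as reference; the reported mesor is the reference-batch baseline.
`batch_adjust` (for plotting/PCA only) removes per-gene batch means while
preserving each gene's grand mean; the inferential fit always keeps batch
as a covariate instead.

**Rhythmicity test.** `F = ((RSS_reduced − RSS_full)/2) /
(RSS_full/(n − p_full))` against the intercept+batch null, on
(2, n − p_full) df; BH adjustment is applied once jointly over all tested
genes (rhythmicity is a single hypothesis family). A perfectly fitted
gene (RSS_full = 0, possible only in noiseless synthetic data) gets
p = 0 with a `degenerate` flag rather than a spurious F ratio.

**Acrophase vs peak time.** The conventionally reported acrophase in bin
units is `acr = φT/(2π)`, but the fitted sinusoid is maximal at
`t* = (−φT/(2π)) mod T`. Binning by `acr` would mirror the phase axis, so
both are stored: `acr` as the reported quantity, `t*` for peak-bin
assignment. Peak bins own half-open unit intervals [k, k+1); genes peaking
in {M, eG1, lG1, G1/S, S1} are G1-centered, the rest G2-centered. A gene
with zero amplitude has no defined peak and gets missing labels.

**Circular Spearman.** Two phase vectors are each centred on their
circular mean (`atan2` of mean sine and mean cosine) and the Spearman
correlation of `sin(φ − φ̄)` is returned. This is invariant to rotating
either vector by any constant. A vector whose resultant length is
numerically zero (perfectly balanced phases) has no circular mean and is
rejected.

**Outlier handling.** Outlier-sample exclusion is left to the analyst
(drop columns before fitting); automating it would hide a judgement call.

## Imbalance screen

**Bins.** Five intervals with breaks (0, 3π/8, 7π/8, 7π/6, 13π/8, 2π),
half-open on the right, the last closed at 2π; phases are reduced mod 2π
first. Five bins trade statistical power against resolution for
conditions of a few hundred cells.

**Test.** The non-targeting proportions define the reference multinomial.
Per condition, 1e5 draws (default) at that condition's cell count give
add-one empirical tails `p = (k+1)/(N+1)`, so p-values are never 0 and the
observable floor at 1e5 draws is ≈1e-5. The observed count is counted in
both tails (ties included on both sides), hence
`p_greater + p_smaller ≥ 1 + 1/(N+1)`; a strict-inequality lower tail is
available behind a flag. `p_greater ≤ 0.05` is an accumulation,
`p_smaller ≤ 0.05` an attrition — i.e. the upper tail is the standard
empirical "simulated ≥ observed" fraction, which is the only reading under
which that interpretation is coherent. No multiplicity adjustment is
applied across bins or conditions by default (raw p ≤ 0.05 calls); BH is
available on the output table.

**Randomness.** Each condition's Monte-Carlo stream is derived from
(seed, SHA-256 of the condition label), so results are independent of the
order in which conditions are processed.

**Exported matrix.** The per-condition `delta_pct` vectors are exposed as
a plain conditions × bins matrix for external embedding; no embedding is
computed here.

## Repli-seq replication timing

**Smoothing.** Per chromosome and per fraction, the window profile is
edge-padded and convolved with a Gaussian of sd 1 window, truncated at
4 sd (the truncated kernel sees replicated edge values throughout; a
zero-padding variant exists behind a flag). Rows are then normalized to
percentages summing to 100; rows with zero smoothed mass are flagged
missing rather than forced to a value.

**RT index.** `RTi = log2((a·b + ε)/(u·v + ε))` with ε = 1e-9 guarding a
one-sided zero; rows with zero mass in both halves are missing. The late
dot product is evaluated against the reversed half so that a uniform row
yields bit-identical dot products and an RTi of exactly 0, and
fraction-order reversal flips the sign exactly.

**LU classification.** RTdiff = RTi_KO − RTi_WT is clustered with a
3-component 1-D Gaussian mixture fitted by explicit EM (k-means++
initialisation, 10 restarts, tolerance 1e-6 on the log-likelihood,
best-likelihood restart kept). The EM ascent property is asserted at
every iteration; restarts whose components collapse are discarded, and
input with no spread is rejected. Windows assigned (max posterior) to the
component whose mean is closest to zero AND with RTi_WT < 0 are
late-unchanged (LU) — the lateness condition is read as wild-type RTi < 0,
since a "KO − WT difference in WT" is not a defined quantity.

**EL shift classes.** Δlog2(E/L) (knockdown minus baseline two-fraction
log-ratio) below −1 is late-to-later (LtLr), above +1 late-to-earlier
(LtEr), the closed interval [−1, 1] unchanged. LU ∧ LtEr windows form
LU_K9LtEr (RIF1-insensitive, H3K9me3-dependent timing), LU ∧ LtLr form
LU_K9LtLr.

**Factor enrichment.** Per DNA-binding protein and category, a 2×2 of
[window in category] × [window overlaps ≥1 peak] over all windows
(overlap is binary, ≥1 bp), two-sided Fisher, BH jointly over all
(DBP, category) pairs. A putative timing factor is enriched (odds
ratio > 1, adj. p < 0.05) at LU_K9LtEr but not LU_K9LtLr.

## Promoter enrichment

**Promoters.** Per gene, TSS separated by less than 1 kb are
single-linkage clustered; the cluster span [min, max+1) is extended by
500 bp on both sides in genomic coordinates (symmetric extension makes
the strandedness question moot) and clipped at 0. One promoter per gene
survives ranking by decreasing H3K4me3 then H3K27ac signal. All
coordinates are BED-convention 0-based half-open.

**Fisher enrichment.** Per (DBP, phase), a 2×2 of [rhythmic and peaking
in the phase] × [promoter overlaps a peak] over the universe of all
rhythmicity-tested genes; two-sided Fisher p by the probability-mass
rule; BH jointly across all (DBP, phase) pairs by default, with a
within-DBP variant behind a flag (either family definition is
defensible). The reported odds ratio is the sample ratio a·d/(b·c), with
tables carrying no association (a·d = b·c, including empty margins)
reported as 1.

**Specificity.** Within each DBP, the 8 adjusted p-values are ranked
ascending (average ranks on ties); specificity = median(ranks)/rank.
With distinct p-values the median is 4.5, so a uniquely best phase scores
4.5 and a total tie scores 1 everywhere. The score depends only on ranks,
hence is invariant to monotone transforms of the p-values.

**H3K9me3 occupancy.** The 300-column binned promoter signal matrix
(10 bp bins; column-median scaling available as a helper, with a row-wise
variant behind a flag) is reordered by acrophase, padded by 7 columns on
each side by edge replication, and median-filtered with an even width of
4 — window offsets [−2, +1], even-length median = mean of the two central
values (a documented convention; alternatives shift values marginally).
In average mode the cutoff is the across-promoter mean of the smoothed
signal over scored columns 85..215 (0-based inclusive positions of the
padded matrix); in median mode a Gaussian filter (sd 7 columns) precedes
an across-promoter median cutoff. Fractions count columns strictly
exceeding the cutoff (ties are non-covered), making them invariant to
positive rescaling of the whole matrix.

## Signature scores

**Proliferation score.** log2(CPM+1) of the marker genes, z-scored per
cancer subtype (population sd), averaged per sample. Zero-variance genes
within a subtype are skipped there; with a single subtype the score
equals global z-scoring. Correlations with the score are Spearman per
cancer type, BH-adjusted jointly, significant at adj. p < 0.05.

**KRAB PSSM.** The deep-mutational-scan table (one wild-type row plus
every single substitution) is normalized to the wild-type construct as a
ratio (a difference mode exists behind a flag); wild-type residues score
exactly 1, and values below 1 mean loss of silencing. The wild-type
sequence may be supplied or inferred as the residue absent from each
position's 19 substitutions. Scoring an aligned domain looks up the
residue present at each reference position (gaps and unassayed entries
skipped, unknown residues rejected); the headline summary is the minimum
over positions — the worst predicted substitution — with the mean also
emitted because either summary is a defensible per-protein value; domains
of multi-KRAB proteins are averaged.

## Synthetic data

The generators are pure functions of parameters and seed, returning truth
tables alongside the data. Defaults: chronogram noise is Gaussian on the
log scale (the model lives there; raw counts are not simulated) with
sd 0.2, amplitude 1, mesor U(2, 10), acrophase U[0, 2π), per-gene batch
offsets N(0, 0.5²) against a zero reference batch; phases are uniform
within their bin (the binned test is blind to the within-bin density);
Repli-seq counts are Poisson at 100 reads/window/fraction over unimodal
fraction-weight profiles on 50-kb windows, with alternating early/late
domains of 20 windows; planted blocks come in three kinds — knockout
late-to-early (positive RTdiff), knockout late-to-later (negative RTdiff,
also anchoring the mixture's third component), and knockdown-responsive
late-unchanged blocks that shift only in the two-fraction table (the
LU∧LtEr truth); regulome binding is Bernoulli at baseline 0.1 with a 5×
planted rate; the cohort's planted Spearman uses the Gaussian-copula
conversion r = 2·sin(πρ/6).

What the generators do **not** emulate: read-level sequencing noise and
mappability, dropout and depth variation in single-cell data, spatial
autocorrelation of chromatin state beyond block structure, linkage between
stages (each generator is independent), and real gene/peak coordinate
distributions. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under its stated assumptions,
not robustness to artefacts of real data.

## Problem sizes

Simulation-based tests use 200–2,000 genes, 600 windows, 1,000 null
conditions at 2,000 Monte-Carlo draws and 3,000-point mixtures — sizes at
which every targeted property (calibration, recovery, power) is already
tight while the suite stays fast; the library itself is vectorised and
scales linearly in genes/windows/conditions.

## Known limitations

- Promoter-level only: distal regulatory elements are out of scope.
- The imbalance test conditions on the control proportions as if known;
  control sampling error is not propagated (controls are typically an
  order of magnitude larger than any condition).
- The GMM assumes exactly three RTdiff populations; data without a
  negative-shift mode can split the null mass across two components, which
  inflates or deflates the LU set. Inspect the fitted means.
- Even-width median filtering and the 0-based reading of the scored
  column range are conventions; results shift marginally under the
  alternatives.
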