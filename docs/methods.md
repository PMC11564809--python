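# Methods

## Reactivity model

Raw reactivity per nucleotide is the difference of two mean-normalized
log-count terms (treated minus α-weighted mock; see README for the
formula). Numerical conventions:

* α ∈ [0, 1] always; when the mock library has zero log-stop mass the
  mock term is defined as 0 and α recorded as 1, keeping the formula
  defined without division by zero. When the treated library has zero
  log-stop mass the profile is emitted all-missing with a warning.
* Both terms have transcript mean 1 by construction, so the *unclamped*
  raw profile has mean exactly 1 − α. This identity is the main
  regression oracle for the implementation and is asserted to 1e-9.
* Negative raw values are clamped to 0 by default (the common probing
  convention); a flag disables clamping. All cohort statistics in this
  package are computed on clamped profiles.
* DMS chemistry masks G/U positions: they are excluded from all sums and
  the transcript length is replaced by the unmasked count, both in the
  reactivity formula and in the coverage filter denominator.

Coverage filtering keeps a transcript iff **every** treated replicate of
**both** conditions has average coverage (RT stops per nucleotide, A/C
only in DMS mode) above the threshold (default 1). Replicate RT-stop
correlation excludes positions with more than 1e5 stops in either
replicate before pooling across transcripts.

The 2–8% normalization scale is computed **per transcript** from the WT
raw profile (top ceil(10%) of values, drop the top ceil(2%), average the
rest) and divides both conditions. Per-transcript scaling follows the
structure-probing pipeline lineage this formula comes from; a
per-library variant would only change a common factor within each
library. Transcripts with fewer than 50 unmasked positions are skipped —
a 2–8% band is meaningless on tiny n.

## Structure statistics

The Gini index uses the sorted-rank identity (equivalent to the
mean-absolute-difference double sum, which the tests run as an O(n²)
oracle), with no small-sample correction and a minimum of 10 valid
positions. Cohort contrasts report the ratio of cohort means of the
statistic (KO over WT) on transcripts present in both conditions, with a
paired Wilcoxon signed-rank test (normal approximation, tie correction);
all-zero difference vectors are reported as no-test (NA).

Metagene binning maps position *p* in a region of length ℓ to bin
⌊p·B/ℓ⌋ (clipped to B−1); default bins 5/10/5 for 5′UTR/CDS/3′UTR.
Per-bin deltas are per-transcript KO−WT means averaged across
transcripts with a paired-t 95% CI; zero-variance bins get a degenerate
CI equal to the point estimate.

Regression of per-site reactivity change uses z-scored response and
predictors (window GC, regional GC, ln region length) so coefficients
are comparable across strata (all sites and per region); pairwise
predictor correlations are emitted as the collinearity check.
Zero-variance predictors are dropped with a warning; strata with
n ≤ p+1 are skipped.

The random-site contrast draws, per real site, matched windows (same
length, same region, same transcript, uniform start) and compares
|mean Δreactivity| of real vs. random windows by a one-sided rank-sum
test per region.

## DRR caller

The caller is deliberately simple and self-contained; equivalence with
published differential-reactivity tools is a non-goal. Per position it
computes d_between (mean |KO_i − WT_j| over the four cross-replicate
pairs) and d_within (mean of |WT₁−WT₂| and |KO₁−KO₂|), scores sliding
11-nt windows by the mean of d_between − d_within, and compares every
window to a pooled empirical null. With two replicates per condition the
balanced relabeling space contains only two non-identity splits, so the
null is augmented with seeded circular shifts — applied to the
**within-condition difference track relative to the between-condition
track** under the relabeled splits. Shifting raw profiles instead would
misalign the position-specific reactivity baseline and grossly inflate
the null (verified during development); keeping both tracks
position-aligned preserves the null's comparability, at the cost of
assuming the noise scale varies slowly along the transcript. Window p
values get the +1 empirical correction, Benjamini–Hochberg across all
windows (q ≤ 0.25 by default, the conventional FDR for this analysis),
overlapping significant windows are merged, merged intervals are trimmed
at both ends to positions whose per-position contrast reaches at least a
quarter of the interval peak (window smearing otherwise overhangs the
true effect by up to window−1 nt per side), and intervals shorter than
5 nt are dropped. Direction is the sign of the interval's mean KO−WT:
negative = gain of structure.

Power at shallow depth is limited: with two replicates at ~20 stops/nt
the per-replicate reactivity noise dominates modest planted effects and
the caller returns few or no intervals — the FDR calibration test
confirms the null is controlled, and the planted-interval test (strong
contrast, low noise) confirms recovery with exact boundaries.

## rG4 scanning

Subtype definitions (canonical, long-loop, bulge, two-quartet, G40) are
this package's own, stated in `rg4.py`; the long-loop maximum of 21 nt
follows the common G4-prediction parameterization. Scanning is greedy
left-to-right over non-overlapping loci with precedence
canonical > long_loop > bulge > two_quartet > G40; at equal start the
higher-precedence class wins. The emitted stability ordinal (subtype
precedence, then shorter loops) is a proxy ranking, not a thermodynamic
score.

## Abundance and enrichment

Count normalization is median-of-ratios (genes with any zero excluded
from the median), fold change is the ratio of mean normalized counts
with a 0.5 pseudocount. pFC thresholds are inclusive (≥ 1.5, ≤ 1/1.5);
a strict flag exists because boundary genes are vanishingly rare in real
data. The pFC direction convention: chromatin FC exceeding whole-cell FC
means the transcript is lost post-transcriptionally in the KO (pDG).

The Monte Carlo test counts real 3′UTR windows containing ≥1 feature
anchor against 100 random sets matched in number, length and host
3′UTR; empirical p = (1 + #{null ≥ obs}) / (1 + n_sets), so p is never
0 and its floor at 100 sets is 1/101. When a 3′UTR cannot fit the
window the draw falls back to the whole transcript (logged). The
statistic is a discrete count: when feature density saturates the
windows, ties between observed and null counts make the test
conservative; calibration holds (≈5% of runs below p = 0.05) when the
per-window hit probability is mid-range.

Half-life degradation targets are genes whose replicate-averaged KO/WT
half-life ratio exceeds 1 (strict), matching the upstream convention;
with symmetric replicate noise genes near ratio 1 split either side, so
target recovery is exact only in the zero-noise limit (tested).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as the study conditions:

* **Transcripts** — mean region lengths 100/500/400 nt (5′UTR/CDS/3′UTR),
  lengths ~N(mean, 0.2·mean) floored at 20 nt; per-region GC 0.60 / 0.50
  / 0.40, the 3′UTR GC-poorest as in real mRNA.
* **Accessibility** — per position a ~ Beta(2,2) in WT (bounded, mildly
  concentrated at intermediate accessibility).
* **Knockout effect** — the default model is *multiplicative contrast
  compression*: a_KO = (1 − δ_global)·a_WT everywhere (δ_global = 0.3,
  the transcriptome-wide structure gain of the depleted condition), with
  an additional factor (1 − δ) (δ = 0.4) on affected intervals: binding
  windows plus a Bernoulli(spillover = 0.2) subset of the host 3′UTR.
  A subtractive model (a_KO = max(0, a_WT − δ) on affected intervals
  only) is available. The multiplicative default is deliberate: the
  reactivity formula renormalizes each transcript's treated term to
  mean 1, so a subtractive drop on a *subset* of positions inflates the
  remaining positions and raises the clamped cohort mean — the opposite
  of a structure-gain signature. Only a broad compression of the
  treated/mock contrast lowers cohort mean reactivity while raising the
  Gini, which is the behavior the pipeline is designed to detect.
* **RT stops** — mock ~ NegBin(mean = depth·b_i, dispersion 0.1) with a
  positional background b_i ~ Gamma(5, 0.2) (mean 1) shared between
  treatments; treated ~ NegBin(depth·b_i·(1 + k·a_i)), modification gain
  k = 5 (strong but not saturating); two replicates per condition; depth
  default 20 stops/nt; DMS mode zeroes the gain at G/U.
* **Sites** — binding anchors placed 15/25/60% across 5′UTR/CDS/3′UTR;
  m⁶A and reader anchors land in 3′UTRs with weight ρ (default 3) inside
  binding windows, 1 elsewhere.
* **Expression** — per-gene base expression ~ depth·LogNormal(0, 0.5)
  (depth 500), chromatin KO/WT FC ~ LogNormal(0, 0.1), whole-cell FC =
  chromatin FC / true pFC; planted classes 15% pDG (pFC 2.0), 15% pUG
  (pFC 0.5); NegBin dispersion 0.01 (tight replicates of a clonal cell
  line — by error propagation, log-pFC sd ≈ √(2·(1/μ + φ)) ≈ 0.16 at
  μ = 500, giving comfortable separation from the ln 1.5 threshold).
* **Half-lives** — WT ~ LogNormal(ln 4 h, 0.3); planted degradation
  targets (20%) have KO/WT ratio 1.5; multiplicative noise sd 0.05
  (0 for exact-recovery checks); three replicates.
* **RBNS** — input pool uniform over 4⁶ 6-mers; bound pools multinomial
  with probability ∝ target R.

What the generator does *not* emulate: sequence-dependent RT-stop bias,
coverage decay along the transcript, mappability gaps, isoform mixtures,
and batch effects between replicates. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
noise model, not robustness to every artifact of real libraries.

All randomness flows from one seed through spawned generators, so a
fixed config reproduces every output byte-for-byte.

## Problem sizes

Tests and the acceptance script use deliberately small cohorts —
200 transcripts for direction recovery, single 300-nt transcripts for
DRR oracles, 10-transcript worlds × 500 replications for Monte Carlo
calibration, 1000 genes for pFC recovery — sizes at which the planted
signals are comfortably detectable and the full suite runs in seconds.

## Known limitations

* The DRR null assumes slowly varying noise along the transcript; sharp
  heteroscedasticity would distort the shift-augmented null.
* The per-transcript 2–8% scale makes cross-transcript reactivity
  magnitudes comparable only up to each transcript's WT scale.
* rG4 subtype regexes are pattern definitions, not thermodynamics; the
  G40 class in particular is a permissive G-richness catch-all.
* The Monte Carlo test is conservative at saturating feature density
  (discrete ties).
* With two replicates the DRR permutation space is minimal; the shift
  augmentation widens the null but cannot substitute for more
  replicates.
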