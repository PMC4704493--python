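# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one defensible reading existed.

## Screen processing

**Normalization.** Raw per-well luminescence is divided by the median of
its plate row. This removes multiplicative row/position effects exactly
and, because any plate-level batch factor is constant within a row, batch
effects as well; after normalization every row has median 1. No edge-well
exclusion is applied. A row whose median is zero is rejected rather than
silently propagated.

**Aggregation and standardization.** Replicates are combined by mean and
sample SD (divisor n−1 everywhere in this package); a (mimic, line) cell
observed in a single replicate keeps its mean but its SD is flagged
missing, never fabricated. Z-scores standardize each cell line's
mean-viability column over all mimics screened in that line
(`scope="per_line"`, the default) — the choice that makes z-scores
comparable across lines; per-plate standardization is available via a
mimic→plate map for screens with strong plate-to-plate structure.

**Hit calling.** A hit is a cell with z at or below the threshold
(default −2). The boundary is **inclusive** (z = −2 is a hit) and
configurable. Hit calling is monotone in the threshold and bit-identical
across repeat runs.

**Variance profile.** Three SD distributions summarize screen quality:
per-mimic SD of mean viability across the panel (total phenotypic
variation), per-(seed family, line) SD over family members with ≥ 2
members (family coherence; the seed is mature positions 2–8 by default),
and the within-replicate SD (technical noise). Each gets a Gaussian KDE
with Silverman's bandwidth on a 512-point grid extended 4 bandwidths
beyond the data range; the 4-bandwidth margin keeps the truncated curve's
integral within 1e-3 of 1 even when a distribution is nearly degenerate.
Degenerate (all-equal) samples fall back to a narrow kernel so the mass
visibly concentrates at the common value.

## Affinity propagation

The clustering is implemented directly from the responsibility /
availability message-passing rules (see README for the update
equations), with:

- messages initialized at `a(i,k) = 0` and combined as
  `damping·old + (1−damping)·new`; defaults damping 0.9, max 1000
  iterations, convergence declared when a **non-empty** exemplar set is
  unchanged for 50 consecutive iterations. Counting only non-empty sets
  matters: with heavy damping the evidence grows slowly and the initial
  no-exemplar phase must not be mistaken for convergence.
- preference (the uniform diagonal of S) defaulting to the median
  off-diagonal similarity, so the number of clusters emerges from the
  data; quantile and explicit preferences are available.
- similarities: negative Euclidean distance, or Pearson correlation used
  directly as s(i,k). Both metrics are exposed for either orientation of
  the z-matrix (mimics over lines, or lines over mimics).
- deterministic tie-breaking. Exemplar-candidate symmetries (e.g. a
  two-point cluster whose members are equally good centres) make the
  evidence oscillate around zero indefinitely; the standard remedy is a
  tiny noise term on S. Here that term is a *deterministic* perturbation
  decreasing with candidate index, ~1e-9 of the similarity scale — far
  below any real margin — so ties break reproducibly toward the lowest
  index and repeated runs are bit-identical. A strict `> 0` exemplar rule
  is applied with a 1e-12 absolute tolerance; a fully symmetric input
  whose evidence is exactly zero converges to a message fixed point and
  yields a single lowest-index exemplar.
- after convergence, one clean assignment pass maps every item to its
  most similar exemplar (exemplars to themselves).

**Hierarchy.** Level 1 clusters all items; each further level re-clusters
the previous level's exemplars *using their original feature rows* (not
cluster means), stopping at a single exemplar or at a fixed point where
no merging occurs. Full-item membership at any level is the composition
of the per-level assignments. Exemplar counts strictly decrease across
recorded levels.

On well-separated instances (n ≤ 8, between-cluster gap ≥ 5× within
spread) the resulting partition equals the exhaustive maximization of net
similarity (sum of member-to-exemplar similarities plus exemplar
preferences), which the test suite checks by brute force; the
per-iteration messages at damping 0 match a literal triple-loop
transcription of the update rules to < 1e-12.

## Enrichment, context scores and phenocopy

**Overlap tests** use the exact hypergeometric upper tail
P(X ≥ k) computed by summing the pmf over the support — never a normal
approximation — one-sided because only enrichment is of interest. No
multiple-testing correction is applied inside these operations; a
Benjamini–Hochberg utility is provided but off by default.

**Context-score curves** bin expressed predicted targets by total context
score (default edges 0, −0.1, −0.2, −0.3, −0.4, −∞; scores above 0 are
clamped into the first bin) and report the fraction with log2 expression
ratio ≤ −log2(fold threshold), i.e. ≥ 2-fold down by default. Empty bins
are flagged undefined rather than reported as 0. A cumulative helper
reports P(down | score ≤ cut) with its denominator.

**Phenocopy nomination** is two-stage: (1) activity — the gene's siRNA
relative viability in the index (mimic-sensitive) line must be strictly
below 0.5; because the panel object carries only the two pool profiles,
this filter is evaluated on a configurable pool (default pool 1, the
primary screening reagent); (2) correlation — Pearson r between the
gene's profile and the mimic's toxicity profile must satisfy r > 0 *and*
r² > 0.35 (both strict) in both reagent pools independently.
"Positive correlation with r² above threshold" is deliberately read as a
sign constraint plus a variance-explained constraint: an anticorrelated
gene with large r² is not a phenocopy. Genes with constant profiles have
undefined correlation and are excluded with an explicit reason.

## Survival cutoff scan

Kaplan–Meier estimation and the two-sample log-rank test are delegated to
lifelines (events precede censorings at tied times; median survival is
the smallest observed time with S(t) ≤ 0.5, undefined if never reached).
The scan itself: the cohort is split into training (round(2n/3)) and
validation thirds by a seeded permutation; candidates are every integer
percentile in [25, 75] (step configurable); the cutpoint value is the
inclusive linear-interpolation quantile and the "high" arm is expression
*strictly above* it; candidates with an empty arm or no events carry an
undefined p. Selected cutoffs are those with training p < 0.05; all are
validated at the same absolute cutoff value, and the minimum-training-p
one is flagged primary. No multiplicity correction is applied inside the
training scan — the test suite quantifies the resulting inflation of the
training selection rate on null data and confirms that the held-out
validation rate stays at ~alpha.

## Feature preparation

Top-variance filtering keeps round(fraction · n_genes) genes (half-up
rounding) by sample variance on the scale provided — no internal log
transform; callers transform first — with boundary ties broken toward
the lexicographically smaller gene id. Copy-number calls are a pure
threshold rule on sample/reference read-depth ratios with **inclusive**
boundaries: gain at ≥ 1.5, loss at ≤ 0.5, neutral otherwise; upstream
depth computation is out of scope.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed) and return ground
truth sufficient to score every stage.

**Screen generator defaults** reproduce the study-scale conditions: 400
mimics × 16 lines × 3 replicates on 8×12 plates (one negative-control
well per row, so row-median normalization always has anchors);
multiplicative lognormal noise on luminescence with row-effect sigma
0.15, plate batch sigma 0.10 and per-well replicate sigma 0.05
(CellTiter-Glo-like positive, multiplicative noise; magnitudes chosen as
realistic plate-reader variability); 27% of mimics carry a planted
sensitivity, with responsive-line counts massed on one (0.55) or two
(0.25) lines and a decaying tail to nine; planted effects reduce
viability by 50–80%; ~8% of reagents duplicate another's mature sequence
(distinct reagent ids, one miRNA); seed families (positions 2–8) share a
latent phenotype with intra-family correlation 0.8; and the 16 lines
fall into 5 response groups through a per-(mimic, group) phenotype
component (sigma 0.08) over per-line noise (sigma 0.02).

What passing tests on this generator show: the normalization/z-score/hit
chain removes exactly the multiplicative artefacts it models and
separates planted effects of ≥ 50% viability reduction from noise; the
clustering recovers group structure that is genuinely present in the
z-matrix. What they do not show: robustness to artefacts the generator
omits — edge-well gradients, transfection-efficiency differences between
lines, non-multiplicative (additive or saturating) reader noise, missing
wells, or hit effects correlated within seed families. Real screens may
also violate the assumption that a plate row's median well is
phenotypically neutral (a row dense in toxic mimics would bias the row
median); with 11 library wells and one control per row this requires
more than five toxic mimics in one row, which the planted architecture
makes vanishingly rare.

**Survival generator**: exponential event times with the hazard
multiplied by the configured ratio above an expression-percentile
threshold (defaults: n=300, 30-month baseline median, threshold at the
60th percentile, hazard ratio 3, independent exponential censoring at
rate 0.01/month ≈ 13–30% censoring). It emulates a threshold effect
exactly, so cutoff-scan recovery results show location accuracy under
the model's own assumptions, not robustness to non-proportional hazards.

**Phenocopy generator**: standard-normal latent profiles mapped affinely
to relative viability (0.7 + 0.15z); the planted gene's pools are
r-correlated mixtures with the mimic profile; the mimic is strongly
toxic in the index line and the planted gene's index-line viability is
capped at 0.45 so stage 1 always passes (a one-line cap with negligible
effect on the 13-line correlation).

**Expression-response generator**: predicted targets receive uniform
context scores; the probability of a ≥ 2-fold decrease follows a
step function of score (0.41 at ≤ −0.2, 0.12 above; background 0.05 for
non-targets), so the context-score curve's estimate can be compared to a
known binomial rate.

## Problem sizes

Defaults used by the test suite and the acceptance script: the full
400×16×3 screen; 20 brute-force clustering instances at n ≤ 8;
hypergeometric enumeration over all configurations with N ≤ 12; 2000
null log-rank simulations at 100 per arm; 200 cutoff-scan replicates at
n=300; 200 phenocopy panels; ~500 strong-context-score targets. These
sizes give binomial standard errors small enough for the rate checks
(≤ ~0.5 percentage points for the type-I error; ~2 points for the
recovery rates) while keeping a full run to a few minutes.

## Known limitations

- The AP implementation is dense (O(n²) memory per message matrix);
  it is meant for panels and libraries up to a few thousand items, not
  for streaming or sparse similarity structures.
- The z-score scope of the original Excel-macro-based standardization
  that screens of this kind historically used is not recoverable from
  the procedure description; per-line scope is the default here because
  it is the only choice that justifies cross-line comparison of scores.
- Cutoff-scan results on real cohorts inherit the multiplicity caveat
  above: training-set p-values are exploratory by construction and only
  the validation p should be interpreted.
- The phenocopy correlation uses all panel lines symmetrically; it does
  not down-weight the index line, whose activity was used for stage-1
  selection.
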