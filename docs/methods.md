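# Methods

## Scope and model

`cofrac` treats a co-fractionation experiment on CSF lipoproteins as two
linked measurements over one separation: a continuous fluorescence elution
trace `y(v)` sampled against elution volume, and a discrete protein × fraction
intensity matrix from label-free quantification (LFQ) of 1-ml fractions.
The analyses are (i) decomposition of the trace into Gaussian particle
subpopulations, (ii) reduction of the LFQ table to a filtered, normalized
profile matrix, (iii) inference of co-elution networks over protein pairs,
(iv) extraction of maximal cliques of the method consensus as candidate
particle subspecies, and (v) functional-enrichment matrix clustering.

## Trace processing

Traces are strictly-increasing volume grids with finite signal. Replicate
averaging is pointwise, with the sample (n−1) SD as the uncertainty band; a
single replicate reports zero SD with a warning. Replicate grids that differ
by acquisition jitter may be linearly interpolated onto the first trace's
grid when explicitly enabled. Fraction binning integrates the trace by the
trapezoidal rule over half-open volume intervals `[start + k·v, start +
(k+1)·v)` with interpolated bin-edge values, so the binned total equals the
trace integral over the covered range to numerical precision; a sample
exactly on a boundary belongs to the later fraction. Per-fraction
quantification uses integration rather than midpoint sampling — the two
differ only at curvature scales below the fraction width, and integration is
conservation-exact. The signal-vs-phospholipid-mass calibration is ordinary
least squares on a dilution series.

## Gaussian curve peeling

The trace model is a constant baseline plus k Gaussians with independent
amplitudes, means, and widths; peak shape is fixed to Gaussian and no
width-sharing constraint is imposed. Fitting is bounded nonlinear least
squares (trust-region reflective, analytic Jacobian) with amplitudes ≥ 0,
means confined to the trace volume range ± 2 ml, and σ ∈ [0.2, 20] ml.
Initialization is deterministic residual peeling: the k-component start is
the refined (k−1)-fit plus a new component at the residual maximum; a small
seeded budget of multi-starts (default 3) jitters means (SD 0.35 ml) and
widths (log-SD 0.3) and keeps the lowest-SSE solution. Component count is
selected by BIC under a Gaussian error model (AIC available); a larger k
must improve BIC by more than Δ = 10 — a conventional strong-evidence bar —
otherwise the more parsimonious model is kept. Because an effectively exact
fit leaves residuals at solver precision rather than true zero, SS_res is
floored at 10⁻¹² of the total variance so that noiseless fits tie instead of
rewarding spurious components. Per-population quantification is the area
share `Aᵢσᵢ√2π / Σ Aⱼσⱼ√2π`, baseline excluded.

## Proteome filtering and normalization

The identification cascade keeps a protein group when (i) it has at least
three unique peptides and (ii) there exists at least one fraction in the
analyzed window where it is detected (intensity > 0) in every replicate;
decoy rows and contaminant rows are then removed, in that order, with
removal counts attributed disjointly in cascade order. Rule (ii) is read as
"some fraction detected in all replicates", not "identical detection sets".
Zero intensity means *not detected*, and zeros are included both in
replicate means and in downstream correlations: shared absence across
fractions is itself co-elution evidence. (A switch to exclude zeros from the
mean is deliberately not offered; excluding them would make a protein
detected once look as abundant as one detected consistently.) Profile
normalization divides each protein's averaged profile by its maximum, so
every row peaks at exactly 1; total abundance (for rankings and the
reference-overlap abundance share) is computed on the unnormalized matrix.
Reference-proteome comparison matches exact UniProt accessions with optional
isoform-suffix stripping.

## Co-elution networks

All three methods score every unordered pair of the filtered proteome
(n(n−1)/2 pairs; a flat, zero-variance profile has undefined correlation and
its pairs are skipped and counted). The uniform edge rule is score strictly
greater than 0.85 — interpreted as a cut on the coefficient itself, not a
p-value, since a p-threshold of 0.85 would be meaningless; an optional
p-value gate can be layered on in the pipeline config.

* **Global Pearson** over the full fraction window.
* **Local Spearman**: rank correlation (average ranks on ties) within each
  complete sliding window of 2·hw+1 fractions (hw = 2), giving F − 2·hw
  windows; the per-window networks are collapsed by edge union with the
  maximum window score and per-edge window provenance. The published
  local-S statistic is not spelled out beyond its window; windowed Spearman
  is our documented approximation.
* **Classifier (PrInCE-style)**: three per-pair features — Pearson r,
  Euclidean distance between normalized profiles, and co-apex offset in
  fractions — feed a Gaussian naive-Bayes model trained on reference-complex
  co-member pairs (positives) versus seeded random non-co-member pairs
  (negatives, 10 × positives; default seed 17). The edge score is the
  posterior interaction probability. This is a deliberate simplification of
  the published classifier, not a port; its validation surface is
  planted-complex recovery, not replication of the original edge count.

## Consensus, agreement, cliques

The consensus network is the edge-set intersection across methods (edge
score = minimum method score); Venn region counts over the edge union are
reported. Method agreement classifies every pair of the shared node universe
into a 2×2 table and applies a two-sided Fisher's exact test; association is
called at odds ratio > 1 and p < 0.05. The p-value is computed by exact
integer hypergeometric enumeration — within fixed margins all table
probabilities share the denominator C(N, c1), so "probability ≤ observed"
reduces to integer comparison of numerators, avoiding the floating-point tie
fragility of the usual two-sided definition. The reported odds ratio is the
sample a·d/(b·c), with a Haldane +0.5 on all cells when any cell is zero.
Maximal cliques are enumerated with Bron–Kerbosch with pivoting (own
implementation, cross-checked in tests against brute-force subset
enumeration and `networkx.find_cliques`) and reported in canonical order
(descending size, then lexicographic), with minimum size 2 since two-protein
cliques are biologically meaningful subspecies candidates.

## Enrichment matrix

Over-representation is a one-sided hypergeometric test of each GO-BP term
against a user-supplied annotation table (two-column TSV or GAF 2.2, aspect
P); the background defaults to all annotated proteins and terms with fewer
than two study proteins are not tested. Bonferroni correction multiplies by
the number of tested terms; significance is corrected p < 0.01. An optional
EASE-style penalty (one study success removed before the tail sum) is
available but off by default. The ±1 matrix marks annotated
(protein, term) pairs of the significant terms; proteins with no significant
term are dropped. Rows and columns are clustered independently with average
linkage on Jaccard distances between +1 indicator vectors — chosen because
grouping by shared membership is exactly what the matrix display is meant to
show — and each dendrogram is cut into exactly g = 10 groups. A functional
cluster is any of the g × g blocks whose fraction of +1 entries strictly
exceeds 0.5; exactly 50 % is not a call.

## Synthetic data

The generators are pure functions of their arguments including the seed.
`generate_cofractionation` emulates the statistical structure of the real
experiment: 120 proteins over fractions 23–50, ten planted complexes of 2–10
members sharing a Gaussian elution profile (member means jittered ≤ 0.2
fractions, σ between 0.8 and 1.6 fractions, amplitudes log-uniform over
10^6.5–10^8.5), independent single-peak background proteins, ~5 % scaffold
proteins with 2–3 peaks, three replicates with multiplicative lognormal
noise (CV 5 %), 5 % independent per-cell dropout, eight decoy and eight
contaminant rows, and low unique-peptide counts (~15 % of rows) drawn among
background proteins only — planted complexes emulate confidently identified
proteins, so the recovery benchmark measures the pipeline rather than random
attrition in the generator. A relative detection floor of 10⁻³ of each
protein's peak zeroes far Gaussian tails, matching the "0 = not detected"
convention. `generate_annotation` plants block-diagonal protein modules ×
term groups with per-cell flip noise, plus an optional wider background
universe annotated at a low uniform rate so over-representation is testable.
What the generators do *not* emulate: retention-time drift, peptide-level
identification, intensity-dependent missingness, correlated replicate error,
and the semantic structure of real GO. Passing closed-loop tests therefore
demonstrates algorithmic correctness under the stated statistical model, not
performance on real spectra.

## Problem sizes and numerics

Default benchmark sizes are chosen to exercise every code path at desk
scale: a 200-trace deconvolution suite (K ∈ 1..6, SNR 30–100, peak
separation ≥ 2σ_max), the 120-protein co-fractionation table, and a
100-protein/10-module annotation. The exhaustive Fisher validation covers
every 2×2 table with total ≤ 60 against an independent tail-enumeration
oracle. Key tolerances: binning conserves integrals to 10⁻⁶ relative;
fitted means on noiseless single-component input recover to 10⁻⁶;
area-fraction sums are exact to 10⁻⁹; Fisher p agreement is 10⁻¹⁰.

## Known limitations

The classifier stage is intentionally lightweight (three features, naive
Bayes) and its 0.85 posterior cut is not calibrated against the original
tool's precision-based threshold. Windowed Spearman on five points has a
coarse score distribution (ρ ∈ {…, 0.9, 1.0} for clean monotone profiles),
so the 0.85 threshold effectively demands near-perfect local rank agreement.
Hierarchical block calling inherits the usual dendrogram-cut instability for
matrices without clear block structure. GO graph propagation (ancestor
terms) and semantic-similarity reduction are out of scope; enrichment counts
depend on the supplied annotation snapshot.
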