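# Methods

## Problem setting

Two colon-polyp phenotypes — hyperplastic polyps (HP, benign) and sessile
serrated adenomas/polyps (SSA/P, premalignant) — are profiled on different
expression platforms: RNA-seq on the log2(1+FPKM) scale, microarrays on log2
intensity, and small qRT-PCR panels measured relative to 18S rRNA. The goal
is a gene signature trained on one platform that classifies samples from any
of the others. The package implements the full pipeline: DE/location
filtering, robust normalization, a cross-platform concordance test for
feature selection, a nearest shrunken centroid classifier, and a summary
metric with a distribution-free class probability.

## DE filtering and the location Venn partition

A gene is called DE when |log2FC| > 0.5 **and** BH-adjusted q < 0.05, both
strict. Because SSA/Ps arise mostly in the right colon and HPs in the left,
genes DE between control-right and control-left tissue (CR_CL) are
location-confounded; the three DE sets (CR_CL, HP_SSA/P, CR_SSA/P) are
partitioned into their seven exclusive Venn regions. Genes DE between SSA/P
and both HP and CR but *not* between CR and CL (`ssa_specific`) feed the
classifier; the triple intersection is excluded outright. The partition keeps
all seven regions (not just the five used downstream) so that disjointness
and exact reconstruction of the inputs hold as invariants.

The same-level criterion e = |CR − HP| / (CR + HP + 0.01) < 0.1 operates on
group *mean* log2(1+FPKM) expression (mean rather than median, matching how
FPKM levels are usually summarized). A non-positive denominator — possible
when mean log expressions are near zero — is flagged not-same-level with a
warning rather than propagating a sign flip silently.

## MAD normalization

Each gene row is transformed x → (x − median)/(c·MAD). Two deliberate
choices:

* **Raw MAD, c = 1 by default.** The MAD < 0.1 low-variability filter reads
  naturally on the raw-MAD scale, and nothing in the procedure depends on
  normal-consistency; `mad_constant` is configurable (1.4826 gives an
  SD-consistent scale) for sensitivity checks.
* **Center-and-scale, not subtraction.** Normalization must simultaneously
  center genes at zero and bring platforms to a common range; subtracting a
  scale estimate alone cannot do both, so the scaler divides by the MAD
  after subtracting the median.

Genes with MAD < 0.1 are removed *before* normalization (strict removal, so a
gene at exactly 0.1 is kept); consequently the zero-MAD error in the
normalizer is unreachable in the standard pipeline and exists only to catch
misuse.

## Concordance test

With n₁(m₁) phenotype-1 and n₂(m₂) phenotype-2 samples on platforms X(Y),
each iteration draws without replacement min(n₁,m₁) phenotype-1 and
min(n₂,m₂) phenotype-2 samples from each platform, concatenates them
phenotype-1-first, and records each gene's Pearson correlation across the
paired vectors (ρ_true). A second scheme draws the same totals ignoring
labels (ρ_random). Defaults: 10⁴ iterations, α = 0.05, offset multiplier 1.

Decisions worth recording:

* The within-draw pairing of samples is arbitrary by construction — only the
  phenotype blocking matters — so pairing in draw order is as good as any.
* An undefined correlation (a gene constant within a draw) is recorded as 0:
  draw counts stay balanced and uninformative genes are penalized.
* The test statistic is a **two-sample one-sided Mann–Whitney rank-sum**
  comparing ρ_true against ρ_random + offset, where
  offset = max over genes of SD(ρ_true ∪ ρ_random). The draws of the two
  schemes are not paired, which rules out the signed-rank variant. With
  thousands of iterations the rank-sum p-value saturates, so the offset is
  the effective selector; `n_iter` is configurable mainly so test suites can
  run at 300–500 iterations, where the behaviour is already stable.
* Concordance p-values are deliberately **not** multiplicity-adjusted; the
  conservative offset already controls the family-wise behaviour in
  practice (on null data the empirical call rate is ≈0).

## Shrunken centroid classifier

Standard nearest-shrunken-centroid formulas: pooled within-class SDs
s_i (ddof n−K), fudge s₀ = median(s_i), m_k = √(1/n_k − 1/n), standardized
deviations d_ik, soft-thresholding by Δ, discriminant score over surviving
genes, priors π_k = n_k/n. When every gene is shrunk away the score reduces
to −2 log π_k and classification falls back to the priors. Ties in
min_k δ_k go to the lowest class index; posteriors are computed as a
stabilized softmax of −δ/2 (shift-invariant, exact for equal scores).

Δ is selected on a **linear** grid of 30 points spanning [0, max|d_ik|]
(both ends included) by 3-fold stratified cross-validation repeated 100
times, iterations differing only in fold assignment. The selected Δ* is the
largest grid value attaining the minimum mean error — largest Δ means fewest
genes. Because the per-fold statistics do not depend on Δ, each fold is
fitted once and re-thresholded across the grid, which keeps the full
100-iteration search under a second at signature scale.

The AUC filter (symmetrized Mann–Whitney AUC, max(A, 1−A) > 0.8 strict) is
applied once on the full training set to the genes surviving the final fit;
this reading is deterministic. A stricter per-iteration mode
(`auc_per_iteration=True`) requires the threshold to be exceeded on every CV
training split. Signature directions are sign(mean_SSA/P − mean_HP), with a
zero difference mapped to +1 (it cannot occur on continuous data).

## Summary metric and class probabilities

SM = mean over signature genes of direction·x on MAD-normalized data;
SM > 0 → SSA/P, SM < 0 → HP, SM = 0 → uncertain (only strict inequalities
define the classes, so the measure-zero tie is left unassigned rather than
defaulted to HP).

The Cantelli bound P(X − μ ≤ a) ≥ 1 − σ²/(σ² + a²) gives a distribution-free
lower bound CLB = a²/(σ² + a²) on the assigned class's probability with
a = |SM|. A probability is reported **iff** CLB > 0.5, i.e. |SM| > σ;
otherwise the sample is in the uncertain zone. Defaults operate on the
standardized SM with σ = 1; a raw-scale σ (e.g. 0.14, appropriate for
15-gene-scale signatures) is accepted for unstandardized use. Empirical and
normal-CDF probabilities standardize SM by the mean/SD of SMs of many random
same-size signatures on a reference cohort, pooled across reference samples
(pooling, rather than per-sample distributions, gives a single stable null).
Random signatures receive uniformly random ± directions, since the direction
structure of an arbitrary gene set is unknowable. For small qRT-PCR panels
the SM distribution cannot be estimated, so only the sign label is emitted.

## qRT-PCR deployment

Raw panels (relative to 18S; larger value = lower expression) are normalized
in two steps: (1) per-sample centering by median (default; arithmetic or
geometric mean available — the geometric mean requires positive values) and
multiplication by −1, removing inter-sample shift biases exactly;
(2) gene-wise MAD normalization with medians/MADs estimated on the new
samples pooled with a stored raw reference cohort, because a handful of new
samples cannot estimate gene medians alone. The full pipeline is invariant
to per-sample additive bias by construction.

## Probe collapsing

When several microarray probes map to one gene, the probe with the largest
**absolute** Welch t-statistic between the two phenotype groups is kept
(ties: first in file order; probes without a mapping are dropped). Absolute
rather than signed t, because probe choice should reward separation in either
direction. Probe-to-gene mappings are supplied as files; no annotation
database is consulted. Gene identifiers are case-sensitive strings and
cross-platform joins are exact symbol matches.

## Synthetic data

`simulate_two_platform` emulates two platforms measuring the same genes on
independent cohorts, log2-scale Gaussian per gene: *concordant* genes have
phenotype means ±fc/2 (default fc = 1) with within-phenotype SD 0.25 on both
platforms; *discordant-DE* genes have the same means with SD 1 (fold change
drowned by variability); *background* genes are centred at 0 with SD 1.
The second distribution parameter is treated as an SD throughout; the
qualitative contrast (fold change above vs below within-phenotype spread)
holds under either reading. Optional per-gene platform offsets
(`platform_bias_sd`) and per-sample shifts (`sample_shift_sd`) model
systematic biases. `simulate_qpcr` generates direction-consistent latent
expression (class means at ±direction·effect/2, noise SD 1 — a realistic
strong-marker qRT-PCR regime), inverts the scale, adds a baseline and
per-sample shift biases.

What the generator does **not** emulate: count-level sequencing noise,
mean–variance coupling, probe saturation and batch structure beyond additive
shifts, correlated genes, FFPE degradation beyond sample bias. Passing tests
therefore demonstrate correctness of the algorithms and their advertised
behaviour under the stated Gaussian regimes, not clinical performance on
real cohorts.

## Problem sizes and numerics

The test-suite and acceptance-script runs use desk-scale sizes chosen to keep
the statistical claims meaningful: concordance at 500 resampling iterations
(call behaviour is already saturated relative to 10⁴), 200-gene matrices
with 20 planted concordant genes and 20 + 20 samples per platform, 20
cross-platform replicates, and the full 3-fold × 30-threshold × 100-iteration
CV. Correlations are clipped to [−1, 1] against floating-point drift; the
Mann–Whitney p-value uses the asymptotic (tie-corrected) normal
approximation, appropriate at hundreds of draws per group; equality of the
CV error minimum is taken within 1e−12 when picking the largest minimizing Δ.

## Known limitations

* Two phenotypes only in the deployed pipeline (the SCC formulas support
  more, but thresholds, directions and the SM are binary by design).
* No missing-value support — readers reject NaN; upstream pipelines are
  expected to produce complete matrices.
* The concordance test assumes both platforms have ≥2 samples per phenotype
  and at least 3 paired draws.
* Quantile normalization is intentionally absent (it underperformed MAD
  normalization for this task) as is any count-level DE engine — DE tables
  are consumed, not produced.
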