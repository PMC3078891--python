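# Methods

This note documents the statistical procedures implemented in `hibexpr`,
the assumptions behind them, the synthetic data they are tested on, and
the design choices made where the underlying analysis description left
the design open.

## Preprocessing model

Input is one spot table per array: `probe_id, signal_median, bg_median,
flag`. The pipeline assumes radiolabelled spotted arrays quantified by a
local-background segmentation, so the only usable per-spot quantities are
the signal median and the local background median.

* **Flags.** Spots with any flag are removed before everything else. If a
  whole array is flagged the array is rejected rather than silently
  emptied.
* **Background.** `corrected = signal_median − bg_median`. Non-positive
  corrected values cannot enter a division-based normalization; they are
  carried as missing (NaN) and excluded from the per-array median, from
  ANOVA and from fold changes. This is a deliberate reading — the
  alternative (clamping to a small positive value) biases low-intensity
  fold changes and is not offered.
* **Detection.** A spot is detected when `signal > 2 × bg_median`,
  strictly. "Above the level of two backgrounds" could also be read as
  background + 2·SD(background); the per-spot tables carry no background
  SD, so the 2× reading is the one implementable from the data, and the
  boundary convention (equality is *not* detected) is tested.
* **Normalization.** Each array's included corrected values are divided
  by their median, making the per-array median of included values exactly
  1. This removes per-array multiplicative scale (exposure time, label
  activity); the pipeline is invariant to rescaling any single array, and
  a test asserts it.
* **Probe → gene.** Probes map to gene symbols through an alignment-score
  table; the best-scoring hit wins, hits below 100 are dropped, and score
  ties break lexicographically (deterministic, warned). A gene with
  several probes is represented by its minimum-p probe *after* the
  per-probe statistics are computed — the ordering matters and is fixed.
* **Gene-level detection.** A gene has "significant signal" when at least
  one of its probes is detected in at least half the samples
  (configurable). This universe defines selection percentages and the
  enrichment background.

## Differential expression

ANOVA runs on log₂ normalized values — the variance-stabilized scale —
while the fold change is the ratio of *raw* group means,
log₂FC = log₂(mean_hib/mean_sum). These two conventions are reconciled
deliberately: the fold change definition follows the ratio-of-means
convention exactly, while testing on the log scale keeps the two-group
ANOVA equivalent to the pooled t-test (F = t², asserted to 1e-10).
Selection requires p < 0.01 **and** |log₂FC| > 0.5.

The experiment-level FDR is estimated by phenotype permutation:
rerun the entire selection under relabellings of the samples and report

    FDR = mean(permuted selection count) / observed selection count,

truncated to [0, 1]. For the 6-vs-5 design all C(11,5) = 462 distinct
relabellings (including the identity) are enumerated, removing Monte-Carlo
noise; above 10,000 distinct relabellings a seeded sample of 1,000 is
drawn. The estimator's orientation follows the standard permutation-FDR
convention (expected false positives over observed positives); the
reciprocal reading is available behind `literal=True` for comparison. With
zero observed selections the ratio is undefined and reported as NaN.

## Synthetic data: what it emulates and what it does not

`SyntheticDesign` defaults encode the study conditions the pipeline
targets: 6 hibernating vs 5 summer samples, 3,200 spots carrying 2,500
genes (10% with two probes), ~5% of genes truly changed with |log₂FC|
drawn uniformly from [1, 3], log-normal spot noise with σ = 0.35 on the
log₂ scale, local background ~10% of the median signal, 5% flagged spots,
and per-array scale factors log-uniform in [0.5, 2] (so that median
normalization is consequential). Flags are assigned independently of
intensity, as no flag-intensity model is available.

Two defaults deserve explanation:

* **Effect range [1, 3], not touching the 0.5 cutoff.** A gene whose true
  |log₂FC| sits exactly at the selection boundary is selected with
  probability ~½ regardless of implementation quality, so recovery of
  planted genes would be uninformative about correctness. The planted
  effects are kept clear of the boundary; boundary behaviour is tested
  directly on the selection gates instead.
* **Noise σ = 0.35.** Chosen so the default design reproduces the
  operating point this cutoff pair is known to produce in practice: a
  3–6% selected fraction at an experiment FDR near 10–13%. At this noise
  level ~97–99% of *measurable* planted genes are recovered. About 9% of
  planted genes fall below the 2×background detection floor — a
  consequence of the wide (σ = 2.5 in log₂) abundance distribution — and
  no analysis of the data can recover them; recovery is therefore
  reported over the genes with significant signal, with the overall rate
  reported alongside.

The generator does **not** model spatial artifacts, print-tip effects,
saturation, dye chemistry, or gene–gene expression correlation beyond the
planted group effects. Consequently, passing calibration tests show the
*estimators* behave correctly under the stated model; they do not certify
performance under correlated biological noise.

Annotations: a three-level DAG (root, parents, two leaves per parent)
with direct annotations on leaves only, so parent membership is exactly
the union of its children (the true-path rule by construction). Enriched
leaves receive 30% of their members from truly-DE genes of one direction,
matching the composition of genuinely enriched functional categories in
this kind of experiment (where 10–30% of a category's members change
coherently) — not categories made almost entirely of changed genes, which
real annotation sets never produce and which distort phenotype-permutation
nulls (the co-regulated members keep most of their coherence under any
relabelling, capping the attainable normalized score).

PCR panels: Ct = c₀ − log_E(abundance) + N(0, σ_Ct), with per-primer
efficiency E ∈ [1.85, 2] and a 4-point 10-fold dilution series per primer,
so the fitted slope recovers E through E = 10^(−1/slope) exactly in the
noise-free case.

## GO enrichment

The background N is the set of gene symbols with significant signal and at
least one annotation in the analysed namespace; K is the selected genes of
the analysed direction inside that background. Each term's one-sided
Fisher p is the upper hypergeometric tail P(X ≥ k); the enrichment ratio
is (k/n)/(K/N). Terms with k < 5 are omitted *before* testing. Up- and
down-regulated genes run separately. When a parent and a more specific
descendant are both significant with the identical changed-gene set, the
parent is pruned (transitively, so chains collapse to the deepest term).

The per-term FDR resamples K genes uniformly from the background (1,000
draws by default, seeded) and sets, for the term of rank r by observed p,

    FDR(r) = mean #{resampled term p ≤ observed p(r)} / r,

made monotone non-decreasing in p by a step-up pass and clipped to [0, 1].
The step-up granularity is a design choice; the resampling null ("changed
genes are a random subset of the background") is the estimator the
procedure is calibrated against, and a calibration test checks that
unstructured selections produce no small FDRs.

Note that ancestors of a genuinely enriched term are themselves enriched
under true-path propagation whenever their member sets differ from the
child's (so pruning does not remove them); in recovery experiments they
are counted with the planted terms, not as false flags.

## GSEA

Genes are ranked by the signal-to-noise ratio (μ₁ − μ₂)/(σ₁ + σ₂). Each
group's σ is floored at max(0.2·|μ|, 0.2) by default (the convention of
the reference implementation; policy `"none"` disables it). Walking the
ranked list, members of a set add |metric|^p / N_R (N_R = Σ|metric|^p over
members) and non-members subtract 1/(N − N_hits); ES is the signed maximum
deviation, with the first index winning ties. The weight exponent defaults
to p = 1; p = 0 gives the unweighted Kolmogorov–Smirnov-like walk whose
running sum telescopes to 0 (asserted to 1e-12). A set covering the whole
ranked list leaves the miss penalty undefined and is rejected.

Significance uses the same exhaustive 462 phenotype relabellings:
NES = ES / mean(|null ES| of the matching sign), and a set's FDR compares
the fraction of pooled null NES at least as extreme (same sign) with the
fraction of observed NES at least as extreme, clipped to [0, 1]. With
fewer than 50 distinct relabellings the FDR is unreliable: a warning is
emitted and the exact permutation p is reported with FDR = NaN. Ranking
ties break by gene symbol so results are deterministic across runs.

## RT-PCR quantification

Per primer set, a least-squares fit of Ct against log₁₀(input) over a
4-point 10-fold dilution series yields the efficiency E = 10^(−1/slope)
(E = 2 exactly when the slope is −1/log₁₀2 ≈ −3.32; a non-negative slope
is rejected). Per-sample relative expression is the efficiency-corrected
double ratio with the calibrator Ct taken as the summer-group mean, so
summer samples average ~1 and any constant Ct shift cancels. Groups are
compared by Student's t on log₂ ratios; the reported fold change is the
ratio of raw ratio means, matching the array convention. Reference genes
are screened by lowest coefficient of variation across samples.

A gene's array call is *confirmed* when the RT-PCR p < 0.05 with the same
fold-change sign; the panel-level correlation is the Pearson r of (RT-PCR,
array) log₂ fold-change pairs over the confirmed genes. Computing r on
log₂ rather than linear fold changes is a choice: the linear scale would
be dominated by the most extreme rows.

## Numerical and degenerate-input conventions

* Fisher p via the exact hypergeometric survival function; asserted
  against integer-arithmetic tail sums (|Δ| < 1e-12) across all margins
  with N ≤ 60.
* ANOVA with zero within-group variance everywhere: statistic undefined,
  gene excluded (NaN) rather than reported as infinitely significant.
* Fold change with a non-positive group mean: undefined, gene excluded.
* All randomness flows through explicit `numpy.random.Generator` seeds
  carried in the design/config objects; no global RNG state is touched,
  and a fixed seed regenerates byte-identical outputs end to end.
* Problem sizes in the calibration experiments (5,000 genes for the null
  design, 20 seeds for category recovery, exhaustive 462 permutations
  everywhere) are the sizes at which the relevant quantities stabilize;
  the category-recovery experiment verifies the GO-significant categories
  with GSEA, mirroring how the cutoff-free method is used as a
  cross-check.

## Known limitations

* The permutation FDR is an experiment-level (set-level) estimate, not a
  per-gene q-value; no moderated-variance (empirical Bayes) testing is
  offered.
* With 11 samples the permutation space (462) floors exact p-values at
  1/462 ≈ 0.0022 and limits FDR resolution.
* The GO background is explicit and configurable because published
  category tables generally do not pin down a single (K, N) pair; ratios
  computed under a different background are not comparable digit-for-digit.
* The generator's independence assumptions (noise, flags, term
  membership) make calibration results optimistic relative to data with
  correlated noise or annotation bias.
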