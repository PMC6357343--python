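# Methods

This note records the statistical model, the synthetic-data design, and
the numerical and design choices behind `lncolink`, at the level of
detail a maintainer or reviewer needs to judge what the tests do and do
not demonstrate.

## Positional classification

A transcript is a stranded set of non-overlapping exons on one
chromosome; 1-based fully closed coordinates (GTF convention) are used
everywhere, so an exon `[100, 200]` overlapping `[150, 400]` shares
51 bases. The transcript span runs from first exon start to last exon
end; gaps between exons are introns; the TSS is the 5' end (span start
on `+`, span end on `-`).

The six categories are decided in a fixed priority order
(most-specific overlap first):

1. `exon_sense_overlapping` — same strand, ≥ 1 bp of exon–exon overlap;
2. `intron_sense_overlapping` — same strand, spans overlap, no exon–exon
   overlap, and the lncRNA span reaches into an mRNA intron;
3. `intronic_antisense` — opposite strands, lncRNA span contained in a
   single mRNA intron;
4. `natural_antisense` — opposite strands, any span overlap not entirely
   intronic (so a lncRNA covering both exon and intron antisense is
   *natural*, not *intronic*: containment defines the intronic class);
5. `bidirectional` — disjoint spans, opposite strands, head-to-head
   (each TSS is the end facing the other transcript, i.e. both
   transcribe away from the shared gap), TSS-to-TSS distance
   `|tss_a − tss_b|` ≤ 1000 bp inclusive;
6. `intergenic` — everything else, including any cross-chromosome pair.

When one lncRNA qualifies against several mRNAs, the highest-priority
category wins; ties break by larger overlap, then smaller TSS distance,
then lexicographic mRNA id, making the map deterministic. The priority
order itself is a design choice: the source annotation emits a single
label per pair, and most-specific-first reproduces that behaviour.

The test suite checks the classifier against an independent brute-force
oracle that rasterises both transcripts into per-base occupancy masks
and applies the category definitions by set intersection — 16 004 grid
configurations (all four strand combinations × every offset in
±2000 bp for a 2-exon lncRNA against a 3-exon mRNA) with zero
disagreements, plus 100% label recovery on 600 generator-constructed
pairs.

One legacy display label, `sense overlap`, occurs once in the packaged
reference panel. It is not one of the six defined categories and has no
geometric definition; the fixture loader preserves it verbatim as
`sense_overlap`, and the classifier never emits it.

## Differential expression

Per feature, on the pooled tumor+normal sample vector:

* **Box-Cox**: `y(λ) = (x^λ − 1)/λ`, `ln x` at λ = 0 (implemented via
  `expm1` so small |λ| is stable). λ maximises the profile
  log-likelihood `(λ−1)Σ ln x − (n/2) ln Var[y(λ)]`, located by a grid
  search over [−3, 3] at step 0.01 and refined by bounded minimisation
  to 1e−5. One λ per feature, estimated on all samples pooled (not per
  group): the downstream test is per-feature, and per-variable
  estimation is the conventional use of a power transform before a mean
  comparison. A constant feature has no defined λ (flagged `nan`,
  identity transform). Features with non-positive values are shifted by
  `1 − min` and flagged.
* **Welch's t**: `t = (x̄ − ȳ)/√(s²ₓ/nₓ + s²ᵧ/nᵧ)` with
  Welch–Satterthwaite degrees of freedom and a two-sided Student-t
  p-value (delegated to `scipy.stats.ttest_ind(equal_var=False)`). A
  doubly degenerate comparison (zero variance both groups, equal means)
  returns t = 0, p = 1 with a warning.
* **Storey q-values**: π₀ is estimated as
  `π₀(l) = #{p > l}/(m(1−l))` on the grid l = 0.05 … 0.95, smoothed by
  a least-squares cubic in l evaluated at the grid maximum and clamped
  to (0, 1]; then `q(p₍ᵢ₎) = min_{j≥i} π₀ m p₍ⱼ₎/j`. With π₀ = 1 this
  is exactly Benjamini–Hochberg, which is asserted against statsmodels
  on random inputs. Families with fewer than 10 p-values fall back to
  π₀ = 1 with a warning. mRNA and lncRNA families are adjusted
  separately, since the selection rule thresholds each family on its
  own q-values.

Directions (`up` ⇔ transformed tumor mean > normal mean) are computed on
the transformed scale; the transform is monotone, so the sign agrees
with the raw scale.

## Selection

A biomarker record is any (mRNA probe, lncRNA) pair with a
non-intergenic relationship call and q below threshold (default 0.05) on
both members, sorted by mRNA q. "Coexpressed" is deliberately
implemented as *joint significance*, not direction concordance or a
correlation cutoff: the reference panel itself contains discordant pairs
(mRNA up with lncRNA down), so a concordance filter would contradict the
design being reproduced. Probe-level granularity is kept (one gene can
contribute several probe records); `collapse_to_genes` deduplicates to
gene symbols in order of first appearance for the validation stage.

## Validation

The classifier is an RBF-kernel SVM with C = 1 and γ = 1/n_features
(scikit-learn's `gamma="auto"`), fixed — no tuning, no feature selection
inside CV; the panel is frozen upstream. Three evaluations:

* **Five-fold CV** on the discovery cohort: stratified, shuffled with a
  recorded seed; metrics and AUC come from pooled out-of-fold
  predictions and decision scores (per-fold averaging is the other
  convention; pooling was chosen and is used consistently).
* **Split evaluation**: a seeded stratified split taking 8 samples per
  class for training on a 16-vs-16 cohort, the rest blind.
* **Cross-platform**: training expression is averaged probe→gene,
  min-max normalized per feature *within its own platform*
  (`y = (x−min)/(max−min)`; a constant feature maps to 0.5 with a
  warning), the SVM is fitted on all training samples, and applied once
  to the independently normalized RPKM test matrix. Per-feature rather
  than global scaling was chosen because a single global extreme value
  would otherwise dominate cross-platform transfer. The pipeline also
  min-max normalizes before the within-platform evaluations so RBF
  distances are O(1) regardless of the intensity scale.

Metrics are sensitivity tp/(tp+fn), specificity tn/(tn+fp), precision
tp/(tp+fp), accuracy (tp+tn)/total, each `None` when its denominator is
zero; AUC is the rank-based Mann–Whitney statistic with ties counted
half, asserted equal to trapezoidal ROC integration. Note that the
specificity formula sometimes circulates with tp+fp in the denominator;
that variant does not reproduce the reference confusion matrices'
printed values (e.g. 85.7% = 18/21 requires tn/(tn+fp)) and is not used.

## Synthetic data

The generator defines the study conditions the tests run under.

* **Geometry**: pairs are constructed per category (e.g. bidirectional =
  opposite strands, disjoint, TSS gap uniform in [1, 1000] bp;
  intronic = lncRNA placed inside an intron explicitly reserved to be
  large enough) and laid along one chromosome ≥ 10 kb apart, so no
  lncRNA can qualify against a foreign mRNA. Every pair therefore has a
  known true label, giving the generator-vs-classifier round-trip test
  its ground truth.
* **Discovery expression**: log-normal — normal on the log scale
  (defaults mean 6, sd 1, roughly array-intensity-like after
  exponentiation) — so the Box-Cox stage has a known optimum λ ≈ 0.
  Planted pairs (default 50, matching the discovery design of 16 tumor
  vs 16 normal) shift the tumor mean by `effect_size × baseline_sd` on
  the log scale before exponentiation, keeping `effect_size`
  interpretable as Cohen's d after a log-like transform. The lncRNA
  partner shifts concordantly with probability `concordant_fraction`
  (default 0.83 = 34/41, the concordant share of the reference panel).
* **Validation expression**: per-gene gamma draws (shape 4, so the
  coefficient of variation is RNA-seq-like at 0.5) around a baseline
  mean drawn log-uniform in [1, 100] RPKM; genes carrying signal have
  the tumor mean multiplied by `exp(±effect_size/2)` in the training
  direction.

Neither platform's real noise model is published for this design; the
log-normal and gamma families are explicit stand-ins. Consequences:
passing tests demonstrate that the pipeline recovers planted signal of
stated magnitude under well-behaved, independent-feature noise — they do
not demonstrate robustness to probe cross-hybridisation, batch effects,
correlated features, or heavy-tailed outliers, none of which the
generator emulates. The published real-data outcomes that depend on the
original cohorts (3543 DE mRNAs, the specific 41-probe panel, AUC
0.996/0.824) are not reproducible from synthetic data and are not
targets of the test suite; the packaged confusion matrices and panel
table are reproduced exactly instead.

## Problem sizes and determinism

Default test problem sizes: 120-pair genomes (20 per category) for
end-to-end runs, 600 pairs for classifier recovery, 10⁴ repetitions for
Welch calibration, n = 500 draws for Box-Cox recovery — sizes at which
every Monte-Carlo band in the suite is comfortably wide of its
threshold while the whole suite runs in well under a minute. All
randomness flows through `numpy.random.default_rng` seeded from an
explicit spec or config seed; pipeline stages derive fixed offsets from
the config seed, and a rerun with the same config is bit-identical
(asserted over output checksums).

The normal-draw Box-Cox recovery check uses N(50, 15²) truncated
positive (n = 500): λ is only weakly identified when the coefficient of
variation is small (the profile likelihood flattens, and λ̂ swings by
±2 across seeds at CV = 0.05), so the check uses a draw whose CV makes
λ ≈ 1 identifiable. The log-normal check uses exp N(0, 1), n = 500,
tolerance ±0.15 around 0.

## Known limitations

* Relationship calls are one-per-lncRNA (best mRNA partner); a lncRNA
  related to two genes contributes only its top-priority call.
* π₀ smoothing uses a cubic polynomial rather than a spline smoother;
  the two differ slightly for signal-rich p-value distributions (the
  BH-equivalence contract at π₀ = 1 is exact either way).
* The RPKM generator draws genes independently; no gene–gene
  correlation, length bias or library-size variation is modelled.
* GTF parsing accepts only `+`/`-` strands and requires exon features;
  transcripts are reconstructed from exons, not from `transcript` lines.
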