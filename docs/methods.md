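# Methods

This note documents the models, parameter choices and numerical conventions
behind `coelute`, and what the synthetic benchmark does and does not show.

## Profile matrices

An experiment is a proteins × fractions grid of non-negative numbers:
MS2 spectral counts (integers) or MS1 precursor intensities (reals).
Protein identifiers are gene-level — one protein per gene — which keeps
cross-species ortholog mapping unambiguous. Fractions are 0-based and
ordered by elution position. Conventions that matter downstream:

- **Missing cells are an error, not zeros.** A truncated file is
  distinguishable from genuine non-detection, which must be an explicit 0.
- **Identification requires evidence.** The MS1→MS2 filter keeps an MS1 row
  only when the protein's MS2 row has at least one nonzero count; an
  all-zero MS2 row is not an identification.
- **All-zero rows are retained by default.** The pre-scoring detection
  filter (`min_evidence_filter`) defaults to off, so dropping proteins is an
  explicit, logged decision.
- Zero counts between detections are treated as true zeros; no imputation
  is applied before correlation.

## Co-elution scores

Four features per pair per experiment; free parameters live in
`ScoreParams`.

**Poisson-noise Pearson** (MS2). Each of `noise_reps` R = 100 replicates
resamples every count as Poisson(count + p), p = 1.0, and the score is the
mean plain Pearson correlation over replicates. Count-valued noise matches
the sampling nature of spectral counts; the pseudocount injects variance
into empty fractions, deflating the spurious r = 1 that two sparse profiles
sharing a single detected fraction would otherwise get. R = 100 gives a
Monte-Carlo standard error of a few hundredths at desk-scale cost; R = 0
recovers the plain correlation exactly. Replicate draws come from a
substream keyed by (seed, canonical pair id), with the lexicographically
smaller protein consuming the first block — scores are therefore exactly
symmetric in the pair and bit-reproducible across runs.

**Weighted cross-correlation** (MS2). Pearson correlations at lags
−K..K, combined with weights 1/(1+|k|). K defaults to 2 fractions: real
complexes can peak one or two fractions apart through detector scheduling
and peak asymmetry, while larger shifts are usually genuine non-co-elution.
The weight law is a documented choice (monotone decay, lag 0 dominant); it
is configurable.

**Co-apex** (MS2). 1/(1 + |Δapex|), apex = earliest index attaining the
maximum. The reciprocal form retains ordering information beyond a
same-fraction boolean (which is recoverable by thresholding at 1.0). Ties
break to the earliest fraction; an all-zero profile has no apex and the
score is missing.

**Euclidean similarity** (MS1). Profiles are normalized to unit sum before
taking Euclidean distance, making the score scale-invariant: two proteins at
very different abundances but identical elution shape score 1.0. For
non-negative unit-sum vectors the distance is bounded by √2, so
1 − d/√2 maps it onto [0, 1]. Zero-sum profiles give a missing score.

Conventions: zero-variance profiles get Pearson r = 0.0 (logged, not NaN) —
a constant profile carries no co-elution information, and downstream
learners need total values. Pairs whose MS2 profiles are jointly nonzero in
fewer than `min_overlap` = 1 fractions are omitted entirely; within one
experiment, scores never mix information across experiments.

## Ortholog harmonization and projection

Many-to-many ortholog maps are handled by full expansion: a source pair
expands to every combination of reference co-orthologs, self-pairs are
dropped, and collisions keep the per-feature maximum — the strongest
co-elution evidence observed for that reference pair. The maximum (rather
than mean or abundance weighting, available as alternatives) is conservative
about evidence direction: it can only report a correlation some source pair
actually achieved. Unmapped genes are dropped so the reference table is
purely orthologous. Projection outward runs the same expansion through the
inverse map; through a bijective map, projection is exactly invertible.

## Supervision and classification

Reference complexes induce labels: positive pairs co-occur in at least one
complex; negative pairs appear in the gold standard but never together;
everything else is unlabeled. Features are kept per experiment (wide table)
so the learner can weight species and cell types differently; missing
features are encoded as sentinel 0 plus an observed-mask column per feature
column, because "not co-detected" is informative and distinct from
"uncorrelated".

The classifier is a gradient-boosted tree ensemble
(`GradientBoostingClassifier`), chosen for mixed, partially missing,
monotone-ish features. Defaults: 300 trees, learning rate 0.05, depth 2,
min 10 samples per leaf, 80% subsampling. The regularization matters beyond
accuracy: with deep, fast-learning trees the predicted probabilities
saturate at ~1 − 1e-8, and a precision threshold selected on held-out folds
then fails to transfer to the final model because the top of the score
scale is numerically meaningless. The shallow ensemble keeps scores spread
over (0, 1) and thresholds portable.

Cross-validation is **complex-held-out**: complexes, not pairs, are dealt
into k = 5 folds (seeded shuffle, round-robin), and a labeled pair enters a
fold only when every complex touching either protein lies in that fold;
fold-straddling pairs are excluded from CV entirely. This blocks the
standard leakage of pair-level splits, where a complex contributes training
and test pairs simultaneously. Held-out scores are pooled across folds and
summarized as average precision (AUPRC).

"High confidence" is operationalized as the lowest score at which
cumulative precision over the pooled held-out pairs reaches a target,
default 0.90. An unattainable target returns an explicit no-threshold
result rather than clamping. The final network is scored by a model trained
on all labeled pairs and thresholded at that held-out value.

## Clustering

Greedy seeded cohesiveness growth in the style of ClusterONE, since the
predicted modules may overlap. Cohesiveness of a node set S is
W_in/(W_in + W_bound + penalty·|S|) with penalty 2.0 modelling each
member's unobserved interactions. Seeds are edges in descending weight
order; an edge with both endpoints already inside accepted complexes is
skipped. Growth applies the best single-node addition or removal until a
local optimum (seed-edge nodes are anchored), acceptance requires
cohesiveness ≥ 0.3 and ≥ 3 members, and accepted sets with Jaccard ≥ 0.8
merge. All tie-breaks are explicit — higher weight first, then
lexicographic node id — so clustering is deterministic. Recovery against
reference complexes counts a predicted/reference pair as matched at member
Jaccard ≥ 0.25 and reports complex-level precision, recall and F1.

## The synthetic world

The simulator generates the study design the pipeline targets: a reference
proteome of complex members plus monomers, several species conserving each
reference gene with probability 0.9 (optionally duplicating it into
1-to-2 co-orthologs), and several fractionation experiments per species.

Defaults describe a desk-scale study: 2 species, 20 complexes of 3–6
members, 40 monomers, 2 experiments per species, 60 fractions. Per
experiment, each complex draws an apex uniform over fractions and a
Gaussian peak width σ uniform in 1–3 fractions (the standard
chromatographic peak model; apexes resample per experiment, emulating
different fractionation techniques). All members of a complex share apex
and width, so noise-free member profiles are exactly proportional —
perfect co-elution before noise; partial membership and substoichiometric
variants are deliberately out of the default design. Each protein draws a
log-normal amplitude (log-mean 3.0, log-sd 1.0: median peak height ~20
spectral counts, a typical mid-abundance protein), and peaks are truncated
beyond 4σ from the apex so profiles have finite support. MS2 counts are
Poisson(depth × expected) with depth 1.0; MS1 multiplies the expected
profile by per-cell log-normal noise (log-sd 0.2); whole-protein dropout
zeroes a profile with probability 0.1 per experiment. Every complex member
is guaranteed to survive in at least one species so the gold standard stays
realizable. Generation is fully deterministic given the seed, and a written
world's manifest regenerates it exactly.

**What the simulator does not emulate** — and what passing tests therefore
do not show about real data: peptide-level effects (shared peptides,
missed cleavages, unique-peptide filtering happens upstream), correlated
background proteins and chaperone smearing, substoichiometric or
condition-dependent complex membership, abundance-dependent identification
bias, retention-time drift between replicate experiments, and ortholog
misassignment. Recovery numbers on synthetic worlds are an upper bound on
what identical settings would achieve on real fractionation data.

## Problem sizes and numerics

The default benchmark (acceptance script and end-to-end tests) uses the
default world above: ~130 reference genes, ~4 × 2,000–2,500 scored pairs,
~450–600 labeled reference pairs, and runs in well under a minute. Across
seeds 1–7 it yields held-out AUPRC ≈ 0.94–0.99 and complex-level F1 ≈
0.67–1.0 at the precision-0.90 threshold.

Numerical conventions collected in one place: Pearson of a zero-variance
vector is 0.0; all correlation outputs are clipped to [−1, 1] against
floating-point overshoot; co-apex ties break to the earliest fraction;
probabilities are clipped to [0, 1] before network construction; PR curves
group tied scores into single points; cluster tie-breaks are
weight-then-lexicographic; and every random draw (noise replicates,
simulation, fold shuffles, subsampled boosting) flows from an explicit seed.
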