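# Methods

## The enhanced allele frequency statistic

For a biallelic SNP with allele frequencies `AF_1 .. AF_K` across K
reference ancestries, the enhanced allele frequency of ancestry *a* is
`EAF_a = AF_a − mean(AF_b : b ≠ a)`. Two algebraic identities follow
directly and are enforced as invariants: the K values of one variant sum
to zero (each value appears once positively and K−1 times inside the
other means with weight 1/(K−1)), and every value lies in [−1, 1]. The
default ancestry panel is the 17-group gnomAD v2.1.1 exome panel; any
panel of K ≥ 2 labeled groups with AC/AN/AF INFO triples works.

Records missing any panel ancestry (or with allele number 0 for one) are
dropped entirely rather than averaged over fewer populations — computing
the mean over a subset would silently break the zero-sum identity and
make EAF values incomparable across variants. Drops are tallied in a
skip log. Multiallelic sites are split per ALT allele, each with its own
AC/AF entries. Only pooled (not sex-stratified) fields are read.

Variant EAFs are filtered to the closed window [0.001, 1] per ancestry:
only positive enrichment qualifies (an absolute-value mode exists but is
off by default), the permissive lower bound avoids discarding disease
genes whose enrichment is real but modest, and bounds are inclusive.
Gene-level scores aggregate the surviving variants of a gene per
ancestry with a **max** rule by default — the strongest single-variant
enrichment is the signal of interest; a mean rule is available behind
the same interface.

## Network propagation

Functional-interaction networks are undirected gene graphs with edge
confidences in [0, 1] (HumanBase-style 3-column edge lists, optionally
translated from numeric ids to symbols; duplicate pairs keep the
maximum weight, self-loops are dropped). Neighborhood expansion returns
the seeds plus every gene reachable within `order` edges where *every*
edge on the path falls inside the confidence window — the alternative
reading (unrestricted paths, filtered terminal edges) would let a single
high-confidence hub bridge arbitrary low-confidence regions, which
defeats the point of the window. Defaults: order 2, window [0.2, 0.5].

The grid search utility scores (order, minimum-weight) combinations —
orders {1, 2, 3} against minimum weights {0.50, 0.55, …, 1.00} with an
open upper bound — by mean AUC over the supplied training batches, with
ties broken toward the smaller order and then the smaller minimum. The
grid convention (E as a floor) and the pipeline default (an explicit
[0.2, 0.5] window) are distinct conventions and both are exposed; the
pipeline does not attempt to reconcile them.

## Penalized fits

All fits operate on per-gene z-scores computed from the training data
only; the mean/sd statistics travel with the fitted model so scoring new
samples is self-contained and leakage-free. Zero-variance genes map to
all-zero columns and are flagged. Expression is assumed already
normalized/log-transformed upstream (TCGA-style matrices); only
z-scoring is applied internally.

- **Baseline**: L1-penalized logistic regression; the regularization
  strength is chosen by stratified cross-validated deviance (log-loss)
  over a fixed grid of 16 strengths spanning `C ∈ [10⁻², 10^1.5]`, with
  `min(5, minority-class count)` folds and a seeded shuffle. The
  baseline signature is the nonzero-coefficient genes. If the selected
  strength zeroes everything, the penalty is relaxed along the path
  until at least one gene activates.
- **Equitable selection**: network-neighborhood candidates with a
  gene-level EAF inside the window are re-ranked per ancestry by
  training-expression variance (computed on pre-z-score values, since
  post-z-score variance is uniformly 1) and the top `k_per_ancestry`
  (default 10) are taken; the deduplicated union is forced into the
  refit. Ties in variance break lexicographically by symbol.
- **Equitable refit**: ridge logistic regression on exactly the union of
  baseline and equitable genes, strength again by cross-validated
  deviance (`C ∈ [10⁻³, 10²]`). Restricting the design to the union *is*
  the forced-inclusion mechanism: ridge shrinks but never zeroes, so
  every union gene carries weight. Putting a zero penalty on forced
  genes inside a full-transcriptome fit would achieve the same end at
  far higher cost and is not what "retrains on the selected genes"
  suggests.
- **Benchmark**: the same LASSO implementation, size-matched to the
  paired equitable signature by taking the largest-|coefficient| genes
  at the cross-validated strength, relaxing the penalty along the path
  when fewer genes are active than required; ties break
  lexicographically. The benchmark model keeps the LASSO coefficients of
  the selected genes (no ridge refit), since it is defined as the
  LASSO-only counterpart.

Signature provenance records how each gene entered: `baseline` (nonzero
in the initial LASSO; takes precedence when a gene also qualifies as
equitable), `equitable` (forced through the network/EAF route), with a
`network` tag reserved for neighborhood genes carried without enrichment
filtering in degraded configurations.

## Batching

The ancestry-balanced batching scheme is driven by a base batch size
equal to the smallest ancestry group that can still train a model, where
"can train" is operationalized as ≥ 9 samples with ≥ 4 in each subtype.
Each viable ancestry group is split into `floor(n / base)` batches
(division is floor division — this is what reproduces the worked
examples 665 → 17 and 90 → 2 at base 38); each subtype is divided evenly
across the group's batches by floor, and the overflow is dealt
round-robin one sample per batch in a seeded shuffled order, so input
ordering cannot bias batch composition. Admixed samples are pooled into
a single group regardless of primary ancestry. A batch that would
violate the 9/4 floor aborts construction with an error rather than
silently re-planning. Mixed-composition batches draw each ancestry in
proportion to its cohort frequency via largest-remainder rounding,
without replacement within a batch; they are drawn from the full pool,
so overlap with single-ancestry batches is possible and left to the
caller to track.

## Evaluation

AUC is the rank-based Mann–Whitney estimator with midranks for ties —
exact, deterministic, and invariant under monotone score transforms; it
is undefined (returned as NaN with a warning) for single-class test
groups. Recall at threshold 0.5 (ties count positive) covers validation
sets that are positive by construction. Signature stability uses
pairwise Jaccard overlap by default, with `|A∩B|/min(|A|,|B|)` and
`|A∩B|/|A|` available because the overlap convention in comparable
analyses is ambiguous; published overlap percentages are therefore not
used as correctness oracles for this metric. Cancer-gene recovery
intersects signatures with a reference list and reports per-signature
counts, the union, and the fraction of union genes found in ≥ 2
signatures.

## Synthetic data

The generator emulates the statistical structure of the real inputs at
desk scale, with one spec and seed driving all four artifacts.

*Variants*: each variant's baseline AF is drawn once from Beta(0.5, 10)
(rare-skewed, as in exome panels) and shared across ancestries; allele
counts are Binomial(AN, AF) draws at AN = 100 000 per ancestry, and
AF = AC/AN exactly. Enrichment is planted additively: the designated
variant's target AF in the target ancestry is shifted by the target
gene-level EAF (hard error if that would exceed 1), so the EAF pipeline
recovers the target within binomial sampling error (±0.02 at this AN).
Because the baseline AF is shared across ancestries, null EAF noise is
purely binomial — small but nonzero, so a permissive 0.001 filter admits
many weak gene/ancestry entries, as it does on real population data.

*Network*: an Erdős–Rényi background (edge probability 0.04 over 150
genes) with Beta(1.5, 5) weights, plus a planted module: disease genes
chained together and each enriched gene attached to the two strongest
disease genes, all with weights uniform in [0.25, 0.45] — inside the
default expansion window.

*Expression*: for a sample of ancestry *a* with subtype `y ~
Bernoulli(0.45)`, `x = baseline_a + y·effect_a + N(0, 1)`, where
`baseline_a` is a per-gene ancestry shift (sd 0.3) and the effect
vectors are ancestry-specific. Admixed samples interpolate the two
reference ancestries' baselines and effects linearly by admixture
fraction. The conditional-shift direction (subtype drawn first,
expression shifted) is used rather than sampling labels from a logistic
model of expression; the two are equivalent up to reparameterization,
and this direction gives the closed-form single-gene check
`AUC = Φ(d/√2)` used in the generator self-tests.

*Default scenario (confounded)*: 120 EUR training samples and 40 AFR
held-out samples; subtype marker effects of 0.9–1.6 SD shared across
ancestries — the magnitude of strong transcriptomic subtype markers —
and one confounded gene at 0.4 SD in EUR but 2.0 SD in AFR, enriched at
gene-level EAF 0.35 in the African panel ancestry and wired into the
disease module, plus two enriched non-disease decoys (EAF 0.30/0.25).
The EUR group is split into 3 batches of 40 for stability estimates.
This is the structure the method is designed for: a gene the majority
ancestry's data cannot justify keeping, recoverable only through
population variant data plus the network.

## What the synthetic fixtures do and do not show

The generator has no linkage disequilibrium, no count-based noise model
(expression is continuous log-like by construction), independent genes
apart from the planted module, and ancestry effects that are simple mean
shifts. Passing tests therefore demonstrate that the pipeline's
machinery — EAF computation and filtering, windowed propagation, forced
ridge inclusion, size-matched benchmarking, batching — behaves as
specified and that the method recovers planted confounded structure; it
does not certify performance on real cohorts, where effect sizes,
correlation structure and ancestry confounding are harsher.

## Problem sizes and numerical notes

Test and benchmark runs use 150 genes, 450 variants, 160 samples and 20
seeds for the confounded comparison — small enough for a laptop-scale
run, large enough that the penalized fits select nontrivial gene sets.
Determinism: every random draw flows from an explicit seed (NumPy
`default_rng` with per-generator streams; seeded `StratifiedKFold`
shuffles; liblinear/lbfgs solvers with fixed `random_state`), and
repeated runs are byte-identical. VCF INFO floats are stored as 32-bit,
so allele frequencies round-trip to within 1e-6, which is the tolerance
used throughout. Degenerate inputs fail loudly: single-class labels,
empty gene-set unions, NaNs in expression, sub-floor training sets and
infeasible enrichment targets all raise errors naming the offender.

## Known limitations

- Indels/SVs and liftover are out of scope; only biallelic SNP rows are
  read.
- Patient ancestry inference is deliberately not performed anywhere.
- The mutation-seeded variant of network propagation (starting from most
  mutated genes rather than the baseline signature) is not implemented;
  the baseline-signature route is the operative description.
- Multiclass outcomes and survival endpoints are unsupported.
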