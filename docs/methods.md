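# Methods

## Model

Each gene-expression trait is treated as a quantitative phenotype explained
jointly by all available genomic feature types.  For gene *k* with centered
trait vector **y**_k over *N* samples, and standardized feature blocks
**X**^(m) (m ∈ {CNA, methylation, miRNA}, N × J^(m)), the integrative model
is

    y_i = β^(CNA)·x^(CNA)_i + β^(meth)·x^(meth)_i + β^(miRNA)·x^(miRNA)_i + ε_i,
    ε_i ~ N(0, σ²),

with no intercept (traits are centered per gene, features per column).  The
coefficients are estimated by an L1-penalized least-squares fit on the
concatenated design,

    min_β  Σ_i (y_i − x_i·β)²  +  λ ( ‖β^(CNA)‖₁ + ‖β^(meth)‖₁ + ‖β^(miRNA)‖₁ ),

i.e. a plain lasso over the stacked coefficient vector with a single
penalty, so the block concatenation order cannot change the optimum.  The
single-type baseline applies the same machinery to one block at a time.
An *association* is a (feature, gene) pair with a nonzero (and cleaned,
see below) coefficient; its *strength* is the coefficient magnitude, which
is comparable across feature types because all features are standardized.

The objective is kept on the raw residual-sum-of-squares scale (no 1/2N
factor), so the solution is identically zero for
λ ≥ λ_max = 2·max_j |x_jᵀy|, and on an orthonormal design with xᵀx = N the
coordinate solution is soft-threshold(x_jᵀy, λ/2)/N.  Features are
standardized with the population convention (denominator N) so that
x_jᵀx_j = N exactly, which keeps these identities sharp.  Expression
traits are centered but **not** variance-scaled: coefficient magnitudes
remain comparable across feature types while preserving each trait's
scale.

## Solver

Cyclic coordinate descent with warm starts along a descending geometric
λ grid, alternating one full sweep with active-set sweeps restricted to
the current support (convergence is always judged on a full sweep, so the
KKT conditions hold for every coordinate).  Numerical choices:

- grid: 60 points, geometric from λ_max down to 0.01·λ_max.  The screening
  half of a sample split often has J comparable to N; below ~0.01·λ_max
  the problem enters the interpolation regime where the solution is dense,
  the Gram matrix near-singular and convergence two orders of magnitude
  slower, while cross-validation never favors that regime.  The floor
  follows the n < p convention of reference lasso implementations.
- convergence: max coefficient change < tol · max(1, ‖β‖_∞) on a full
  sweep, tol = 1e-9 for reported fits (KKT residuals ≲ 1e-8 on the
  gradient scale) and 1e-4 inside cross-validation folds, where held-out
  MSE is insensitive to the last digits; at most 10,000 sweeps, with a
  `converged` flag on the returned solution.
- determinism: fixed cyclic order, no randomized heuristics; identical
  inputs give bit-identical solutions.

## Screen and Clean

Selection p-values come from a two-split Screen-and-Clean procedure:

1. **Split.** Samples are split 50/50 by a seeded permutation (one split
   per gene; the seed derives from the global seed and the gene index, so
   genes are independent and runs reproducible).
2. **Screen.** On the screen half, λ is tuned by 10-fold cross-validation
   and the lasso support at that λ becomes the candidate set.  The screen
   stage uses the one-standard-error rule (the largest λ whose mean CV
   error is within one SE of the minimum): screening only has to carry the
   true features forward, and every null candidate forwarded is a
   false-selection opportunity at level α in the clean stage, so the
   sparser 1-SE set directly lowers the false-positive load.  The raw CV
   minimizer is also exposed (`lambda_rule="min"`).
3. **Clean.** On the other half, ordinary least squares of the trait on
   the candidate columns yields two-sided t-tests; features with p ≤ α
   (default 0.05, no multiple-testing correction) are selected, and their
   clean-stage coefficients are the reported association strengths.
   Exactly collinear candidate columns are dropped (QR with pivoting) and
   recorded; candidate sets too large for the clean half are truncated to
   the largest-|β| candidates keeping ≥ 2 residual degrees of freedom.

Because the two halves are disjoint, clean-stage p-values of null
features are exactly uniform under Gaussian noise and the per-feature
false-selection rate is α — this calibration is verified by simulation in
the test suite.

## Prediction accuracy

Reported accuracy is the Pearson correlation between the observed trait
and pooled held-out predictions from 5-fold cross-validation in which the
entire selection pipeline (Screen-and-Clean, then discarding associations
with strength < ρ = 0.1, then an OLS refit on the survivors) is re-run
inside every training split.  An optimistic in-sample correlation is also
stored for comparison.  Two conventions worth noting:

- Predictions carry no fold-specific intercept.  Pearson correlation is
  translation-invariant, and a fold-varying training-mean offset
  anti-correlates with the held-out responses, biasing null-model
  accuracies visibly negative; a small residual negative bias from the
  training-estimated coefficients themselves remains and vanishes with N.
- Folds with no surviving feature predict a constant; if no fold produces
  a model, or the pooled predictions are constant, the accuracy is
  recorded as 0 with an explanatory flag.

## Preprocessing

Fixed order: variance filter (raw scale) → sample alignment → z-scoring.
The variance filter drops features whose raw variance falls strictly below
the given lower-quantile of per-feature variances; by default only
methylation, the largest feature set, is filtered (quantile 0.25).
Alignment restricts all matrices to the sorted intersection of sample ids
(deterministic; dropped samples reported).  Loaders reject non-finite
values, duplicate identifiers, and CNA calls outside {−2,−1,0,1,2}; CNA
categories are treated as numeric covariates and standardized like any
other feature.  A converter extracts a cytoband × sample call matrix from
GISTIC "all_lesions"-style tables (deletion calls negated).

## Synthetic data

The generator emulates the shapes and marginal families of tumor
multi-omics data at desk scale, with a known sparse ground truth:

| parameter | default | meaning |
|---|---|---|
| N | 200 | samples |
| J | 6 / 60 / 20 | CNA / methylation / miRNA features (real-data ordering CNA ≪ miRNA ≪ methylation) |
| genes | 40 | traits (20% null, 30% multi-type-driven, rest single-type) |
| s | 3 | true features per driven gene |
| effects | U[0.3, 1.0], random sign | standardized-scale coefficients |
| σ | 1.0 | trait noise sd |
| cross_type_rho | 0.7 | latent correlation inside the 5 correlation groups |

Marginals: CNA calls from a categorical distribution over {−2..2} with
mass 0.6 at 0; methylation as logit-normal values in (0,1) with a gentle
slope so the latent correlation survives the transform; miRNA as affine
Gaussian signals.  Cross-type correlation is induced by shared latent
Gaussian factors: each correlation group holds one feature per type
loading √ρ on a common factor, the minimal mechanism by which a
single-type analysis picks up another type's signal through a correlated
proxy.  Single-type-driven genes draw their causal features from these
groups (so decoys exist in the other types); multi-type genes use
independent features.  Trait archetypes tie expression structure to the
driving type: CNA-driven genes get a constant mean offset (high μ),
methylation-driven genes doubled effects (high σ), reproducing the
expected decile trends.  Traits are linear in the *z-scored* features, so
true and estimated coefficients live on the same scale.

What the generator does **not** emulate: genomic coordinates and linkage,
copy-number segment structure beyond cytoband calls, non-Gaussian trait
noise, batch effects, or cis-regulatory distance structure.  Passing
benchmarks therefore demonstrate the statistical mechanics of the method
(selection calibration, confounding via correlated features, prediction
pooling), not performance on any particular tumor dataset.

Benchmark presets: `default_benchmark_config()` (100 genes,
cross_type_rho 0.7) for the spurious-association comparison;
`strong_signal_config()` (N = 300, every gene driven, effects U[0.5,1],
no cross-type correlation — estimation quality isolated from confounding)
for support recovery; `prediction_superiority_config()` (all genes
multi-type-driven) for the integrative-vs-single accuracy comparison.
In the benchmark, a *false-type edge* is an edge whose feature type is not
among the gene's true driving types, and the *all-three* Venn class of the
single-type baseline is computed from the pooled edges of the three
separate single-type fits.

## Analytics

- **Edges** carry (feature, type, gene, strength, signed β, p); extraction
  thresholds at ρ (0.1 for prediction-oriented summaries, 0.3 for
  networks) and sorts by (strength desc, gene, feature) with stable
  tie-breaks.
- **Venn classes** partition genes with ≥ 1 edge into the 7 nonempty type
  combinations.
- **Deciles** rank genes by μ, σ, or μ/σ (ascending, ties by gene id) into
  equal bins, remainder to the lowest bins; per bin: mean CV accuracy over
  genes surviving the ρ filter and the count of such genes.
- **Top-K contribution** counts distinct (gene, type) pairs among the K
  strongest edges — one gene with several methylation edges counts once
  for methylation — so per-type proportions sum to 1; K clamps to the edge
  count.
- **Hubs** rank features by distinct-gene degree (ties by feature id) and
  export each hub's gene list for external enrichment tools.
- **Cis flags** mark methylation edges whose feature maps to its own gene
  (symbol identity by default; an explicit feature→gene map may be
  supplied); distance-based definitions are out of scope.

## Networks

The association network is strictly bipartite (feature ↔ gene), weighted
by strength, with node ids prefixed by type so a methylation feature and
its namesake gene stay distinct.  Because triangles cannot exist in a
bipartite graph, the reported clustering is the square-based bipartite
coefficient.  Modularity is Newman's Q under the partition found by
greedy (CNM) agglomeration on the unweighted graph; the communities are
returned with the summary.  Exports: SIF (relation = feature type;
attributes beyond the relation are not representable), GraphML and TSV
(lossless), all with byte-stable ordering.

## Problem sizes

All simulations run at the desk-scale defaults above; the heavier
benchmark suites use 30–50 replicates (spurious reduction / prediction
superiority), 50 replicates for support recovery, and 500 null replicates
for p-value calibration.  `scripts/acceptance.py` recomputes the same
quantities at moderately reduced replicate counts (10–20) so a full run
completes in a few minutes on one core.

## Known limitations

- Screening and cleaning each see only half the samples; with weak
  effects (standardized |β| ≲ 0.3 at N ≈ 200) recall drops before the
  type-I calibration does.
- λ is tuned per gene; no information is shared across traits.
- The flat α = 0.05 clean threshold performs no multiple-testing control
  across features or genes, by design.
- The greedy modularity partition is a heuristic; Q values are comparable
  between the integrative and single networks but are not global optima.
- CNA calls are treated as numeric dosages in a linear model; threshold
  effects of homozygous deletions are not modeled.
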