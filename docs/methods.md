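# Methods

## Model overview

`proteopath` analyzes sample × protein expression matrices (RPPA-style
proteomics) annotated by model system (`patient` or `cell_line`) and lineage
(tissue of origin). The analysis has four stages:

1. **Cancer-specific networks.** For each lineage × pathway slice, a
   node-wise Bayesian graphical regression with spike-and-slab selection.
2. **Sample-specific scores.** Each sample's proteins are compared with their
   posterior-predictive distribution under the fitted network, yielding
   per-protein and per-pathway (activated, neutral, suppressed) probability
   triples.
3. **Cross-system comparison and stratification.** Edge consistency across
   lineages, connectivity scores against a random-protein-set permutation
   null, avatar matching by Pearson correlation of aberration-score vectors,
   and complete-linkage clustering with a gap-statistic cluster count.
4. **Drug-sensitivity models.** Probit BART classifiers of binary drug
   response with the per-pathway aberration scores as predictors.

## Graphical regression

For a standardized slice `X` (mean 0, sd 1 per protein), each protein `i` is
regressed on all other pathway proteins:

    x_i = Σ_{k≠i} γ_ik β_ik x_k + ε_i,
    γ_ik ~ Bernoulli(π),   β_ik | σ² ~ N(0, τ² σ²),   σ²_i ~ IG(a, b),

with defaults π = 0.2, τ² = 1, a = 2, b = 1. Because the slab and noise
priors are conjugate, β and σ² integrate out analytically and the sampler is
a *collapsed* Gibbs chain over inclusion bitmasks: each flip compares the
closed-form marginal likelihoods of the two subsets. Marginal likelihoods are
memoised per visited subset, so the chain's stationary law is exactly the
enumerated posterior — which is what the `exact_posterior_oracle` computes by
full subset enumeration on ≤ 5-protein slices. Defaults are 20,000 sweeps
with 5,000 burn-in; at ≤ 12 proteins a fit takes milliseconds, and the
sampler is deterministic given its seed.

The posterior inclusion probability (PPI) of a directed pair is the
post-burn-in frequency of γ_ik = 1; the undirected edge PPI is by default the
maximum of the two directions (`mean` and `and` rules are available). Edges
are called at PPI strictly greater than 0.5.

## Deconvolution into sample scores

For sample `j` and protein `i`, let `z = (x_ij − μ_ij) / s_i` where `μ_ij` is
the fitted regression prediction from the sample's other proteins and `s_i`
the posterior-mean predictive standard deviation. With tail cutoff `c`
(default 1 predictive sd):

    p⁺ = Φ(z − c),   p⁻ = Φ(−z − c),   p⁰ = 1 − p⁺ − p⁻.

The triple is a partition of unity by construction. Pathway scores
`(k⁺, k⁰, k⁻)` average the protein triples; the pathway status is the argmax
with ties resolved to neutral. The **network aberration score** is
`k⁺ + k⁻ = 1 − k⁰`.

### Calibration convention (baseline vs case samples)

A mean shift applied coherently to the member proteins of a pathway is, in a
Gaussian model, indistinguishable from a rank-one factor: if shifted samples
are part of the network-fitting slice, the node-wise regressions absorb the
shift (each protein is predicted from co-shifted neighbours) and per-slice
centering absorbs any lineage-uniform component — the deconvolved scores then
read neutral regardless of the shift. Population networks and sample-level
aberration are therefore only jointly identifiable relative to a baseline
reference.

The package consequently supports an optional `role` annotation column
(`baseline` / `case`): when present, networks (and the centering/scale used
for scoring) are estimated on the baseline samples of each lineage, and all
downstream stages (scores, stratification, drug models) operate on the case
samples. Without a `role` column the whole lineage is used for both — valid
when per-sample aberrations are rare or weak, with the caveat above. The
synthetic generator always emits both cohorts.

## Synthetic data generator

The generator defines the study conditions for all tests:

- **Networks:** Erdős–Rényi support at a requested density; off-diagonal
  precision entries ±u with u ~ Uniform(0.3, 0.6); the diagonal is the
  absolute row sum plus 0.5 (floored at 1), which guarantees positive
  definiteness by Gershgorin while keeping implied partial correlations in a
  detectable range (≈ 0.15–0.5) and giving isolated proteins unit variance.
  A density so high that the dominance repair pushes more than 10% of edges
  below |partial correlation| = 0.05 is rejected.
- **Lineages:** zero-mean Gaussian draws from the implied covariance; an
  optional Student-t (df = 5) switch for heavy-tail robustness checks.
  Activated/suppressed samples receive ±shift on every pathway protein.
- **Reference bundle** (`default_config`): six disjoint 8-protein pathways;
  two patient and two cell-line lineages (100 baseline + 60/45 case samples
  each); shift 3. The planted avatar pair (PAT_A, cl_a) shares all networks
  and the status pattern — a dense (0.5) pw1 carrying the cross-signaling
  link and coherent activation of pw2/pw3 carrying the aberration signature.
  The planted non-match (PAT_B, cl_b) is generated independently with empty
  networks; PAT_B has its own suppression pattern (pw4/pw5) and cl_b a mixed
  pw2 activation that drives the example drug. Non-match lineages are
  structure-free because the generator draws pathways as independent blocks:
  any planted within-pathway structure would legitimately beat the pooled
  random-protein null and blur the planted/non-planted contrast.
- **Drug response:** latent = weights · aberration + N(0, noise_sd);
  sensitive iff the latent strictly exceeds the cohort median.

What the generator does **not** emulate: real antibody panels and their
marginal distributions, batch effects, overlapping pathway membership
(available only as a config switch), missingness mechanisms beyond random
blanks, and dose–response curves. Passing tests demonstrate internal
consistency and recovery under the stated Gaussian conditions, not
performance on any real cohort.

## Connectivity score and permutation null

CS = called edges / possible edges. The null (randomCS) refits the same
lineage slice on random same-size protein sets drawn from the pooled pathway
catalog (default 1,000 replicates; reduced replicate counts are used in
tests) and reports the fraction of null CS values **at or above** the
observed CS — ties count against significance. Null refits use shortened
chains (2,000 sweeps), a speed/accuracy trade-off validated against full
settings on fixtures. Two lineages are linked through a pathway when both
individually exceed the cutoff fraction of null values (0.9 and 0.8 are the
conventional choices), as strict exceedance.

Because CS is a discrete statistic and ties count against significance, the
null proportion is conservative rather than exactly uniform; the calibration
test verifies approximate uniformity (Kolmogorov–Smirnov) on background
lineages with generic pool-wide structure and no pathway-specific planting,
where the observed pathway draw is exchangeable with the null draws.

## Stratification

Avatar links: Pearson r between patient and cell-line aberration vectors
across pathways, per sample pair; a lineage pair is linked when the share of
defined pairs with |r| ≥ 0.9 strictly exceeds 75%. Constant vectors give an
undefined r and are excluded from the denominator (counts reported).

Clustering: complete linkage on correlation distance d = 1 − r between
sample aberration vectors (1 − |r| available); K chosen by the gap statistic
with uniform references over the data's bounding box (B = 50) and the
first-SE-max rule. Samples are processed in sorted-ID order, making labels
invariant to input row order; constant-vector samples are removed with a
warning. The alternative reading of clustering "on the correlations" — using
rows of the correlation matrix as features — is exposed as a flag, not the
default.

## Drug-sensitivity models

Binary response (continuous potency panels are binarized by a per-drug
median split; ties resistant) is modeled per lineage × drug for drugs with
≥ 10 profiles and both classes present. The classifier is an in-package
probit BART: Albert–Chib latent augmentation, grow/prune
Metropolis–Hastings tree moves under the depth prior
p_split(d) = 0.95·(1+d)⁻², conjugate Gaussian leaves with prior sd
3/(k√m), k = 2. Library defaults are 50 trees and 2,000 draws (500 burn-in);
the pipeline and tests use 20 trees and 500 draws (100 burn-in), which at
n ≈ 60 and 12 predictors gives indistinguishable AUC at a fraction of the
cost. Pathway importance is the posterior proportion of splitting rules using
each pathway (uniform when a draw contains no splits), normalized to sum
to 1. Evaluation is pooled out-of-fold AUC from seeded stratified 5-fold CV;
folds that lose a class are redrawn (max 10 attempts). Patient response is
predicted by applying a matched lineage's model to patient aberration
vectors; a responder is a posterior sensitivity probability strictly
above 0.5.

## Numerical and design choices

- Quadratic forms in the marginal likelihood are floored at 1e-12; logistic
  arguments clipped at ±35; latent probit draws clipped at ±6 sd.
- Per-stage seeds derive from the global seed by a fixed counter scheme
  (`seed·1000 + stage index`), so any stage can be reproduced in isolation.
- Float output uses `%.17g`, making write→read→write byte-stable.
- Missing expression: proteins over 20% missing within any lineage are
  dropped study-wide (keeping the matrix rectangular); the rest are imputed
  by the protein's lineage median.
- Problem sizes in tests and the acceptance script (3–5 fixture seeds,
  100–200 permutation replicates, 60–100 calibration draws, 10–20 drug
  fixtures, 2,000-sweep null refits) are chosen as the smallest sizes at
  which the measured properties are stable; the library defaults remain the
  full-scale settings quoted above.

## Known limitations

- Lineage-uniform pathway aberration is unidentifiable without baseline
  samples (see calibration convention); on studies lacking a `role` column,
  aberration scores describe within-lineage heterogeneity only.
- The graphical regression assumes approximately Gaussian, continuous
  expression after normalization; heavy-tailed data inflate tail scores.
- Grow/prune-only BART mixes more slowly than samplers with change/swap
  moves; chain lengths were chosen accordingly.
- The permutation null reuses the observed samples (conditional-on-data
  null); it does not account for uncertainty in the pathway catalog itself.
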