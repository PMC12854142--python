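# Methods

## The problem

Genomic selection ranks breeding candidates by genomic estimated breeding
values (GEBVs) predicted from a phenotyped training set. In hybrid breeding
the quantity of interest is the total genotypic value — additive plus
dominance — because heterosis acts through dominance. `hybridts` addresses
the *design* question: given genotypes for a candidate population of n_c
hybrids, which n_t of them should be phenotyped so that the fitted model
best identifies the k truly best hybrids?

## Marker coding and kinships

Calls are coded per locus as additive scores (AA → 1, AB → 0, BB → −1) and
dominance scores (AB → 1, homozygotes → 0), with AA the major-allele
homozygote. Each column is centered and scaled by its sample standard
deviation (n−1 denominator); this makes trace(XXᵀ)/p = n_c − 1 exact, a
property the tests assert. Columns with zero variance — common for
dominance scores when no sampled cross segregates at a locus — carry no
information and are dropped *per matrix*, and each kinship divides by its
own retained count (K_A = X_A X_Aᵀ/p_A, K_D = X_D X_Dᵀ/p_D), which keeps the
trace identity exact for both matrices. Inputs with missing genotypes are
rejected outright; imputation belongs upstream.

For the ridge criterion the merged matrix [X_A, X_D] is replaced by its
principal-component scores, keeping the smallest number of components whose
cumulative explained variance exceeds 0.99. The PC basis is computed once
from the full candidate population and training subsets are row subsets of
the same score matrix, so criterion values are comparable across subsets.

## Criteria

* **Ridge MSPE** (minimize): with X_c the candidate scores, X_t the
  training rows and A = X_tᵀ(X_t X_tᵀ + λI)⁻¹,
  `Tr[X_c A Aᵀ X_cᵀ] + Tr[(X_c − X_c A X_t)(X_c − X_c A X_t)ᵀ]`. This is an
  affine transform (n_c·(· − 1)) of the mean squared prediction error of a
  ridge predictor of every candidate's scores, and the tests verify that
  equivalence on random instances. λ defaults to 1; the robustness report
  shows subset rankings are essentially unchanged across λ ∈ [0.01, 100].
* **CDmean** (maximize): Σᵢ Aᵢ/Bᵢ with Aᵢ the i-th diagonal of
  G_ct(M_t G_t + I)⁻¹M_t G_ctᵀ and Bᵢ the i-th diagonal of
  α_A K_A + α_D K_D. Each term is the squared correlation between a
  candidate's true and BLUP-estimated genotypic value (the error variance
  cancels between numerator and denominator, so the criterion is computed
  in its cancelled form). Defaults α_A = α_D = 1. A candidate with
  essentially zero genomic variance (Bᵢ ≤ 1e-12) has no rankable signal;
  its term contributes 0 and a warning is logged rather than dividing by
  zero.
* **GVaverage**: score each candidate by its own genomic variance
  σ²_A K_A[i,i] + σ²_D K_D[i,i] and take the top n_t. Because the trace of
  any subset's kernel is the sum of its members' scores, sorting solves the
  subset-trace maximization exactly — no search. Rescaling (σ²_A, σ²_D) by
  a common positive factor rescales every score identically, so the ranking
  is exactly invariant; the acceptance script measures this.

## Exchange optimizer

The ridge and CD criteria are optimized by steepest-ascent exchange: from a
seeded uniform random subset, each round evaluates all n_t × (n_c − n_t)
single swaps and applies the best strictly improving one, stopping when no
swap improves (or after `max_rounds`, default 50). Evaluations are memoized
on the sorted index tuple. Ties are broken by evaluation order (ascending
member, ascending outsider), making runs fully deterministic given the
seed. The landscape is multimodal — on cross-structured kinships a single
run finds the exhaustive global optimum in only ~60–80% of starts at toy
sizes — so `n_restarts` is configurable (default 1 to mirror a single
optimization run); with 5 restarts the toy-size tests recover the
enumerated optimum in ≥ 90% of seeds. The search can never exceed the
exhaustive optimum, and the selected *criterion value*, not the identity of
the selected set, is the meaningful comparator between runs.

Training sets are selected once per (population, n_t) from genotypes only
and reused across all phenotype replicates: selection never sees
phenotypes.

## BLUP prediction

Under y_t = 1μ + g_t + e with Var(g) = σ²_e·G_t (G_t the α-weighted
training kernel, α = variance ratio to error), the BLUPs are

    ĝ_t = (M_t + G_t⁻¹)⁻¹ M_t y_t,
    ĝ_c = G_ct (M_t G_t + I)⁻¹ M_t y_t,

with M_t = I − J̄ the centering matrix that eliminates the fixed mean.
Both are algebraically identical to the genetic-effect solutions of
Henderson's mixed-model equations after absorbing the intercept; the test
suite checks this equivalence to 1e-8 on random instances, and the
candidate form against the conditional-expectation extension
ĝ_c = G_ct G_t⁻¹ ĝ_t.

Design choice: the simulation study predicts with the *true* variance
ratios α_A = σ²_A/σ²_e, α_D = σ²_D/σ²_e, which are known by construction.
This keeps prediction deterministic and desk-scale and isolates
training-set quality from variance-component estimation noise; a config
hook (`StudyGrid.alpha_override`, CLI `--alpha-a/--alpha-d`) accepts
user-supplied ratios for sensitivity runs. REML/Bayesian estimation of the
components is out of scope.

Numerical hygiene: explicit inverses are avoided in favor of linear solves;
(M_t G_t + I) is treated as a general nonsymmetric system. G_t⁻¹ appears
structurally in ĝ_t, so when G_t is ill-conditioned (condition number
> 1e12 — e.g. a training set containing near-duplicate hybrids, or the full
population, whose centered-score kernel annihilates the ones vector) a
diagonal jitter of 1e-8 × mean diagonal is added and logged.

## Ranking metrics

The candidates holding the k largest GEBVs are mapped to their ranks in the
true-breeding-value ordering, π₁…π_k (1 = best). Ties in either vector are
broken by ascending candidate index — simulated values are continuous, so
real ties have measure zero; the rule only pins down determinism.

* NDCG@k uses gain f(v) = v on the raw TBVs and discount d(i) =
  1/log₂(i+1). With μ = 100 the gains are positive in practice and the
  value lies in [0, 1]; negative gains void the range and trigger a warning
  rather than an error. Because the general mean is much larger than the
  genotypic spread, NDCG differences between methods are compressed — its
  replicate standard deviations are an order of magnitude smaller than the
  other metrics'.
* SRC@k is the Pearson correlation of the pairs (i, πᵢ), i.e. the Spearman
  correlation between predicted position and true rank of the selected
  top k (the denominator carries the square root that the correlation
  definition requires).
* RS_ratio@k = (Σᵢ i)/(Σᵢ πᵢ) ∈ (0, 1], equal to 1 exactly when the
  predicted and true top-k sets coincide.
* RIP = 100·(M̄_method − M̄_random)/M̄_random summarizes means over
  replicates against the random baseline. Because all methods share the
  same phenotype replicates within a scenario (common random numbers), the
  random method's RIP against itself is identically zero.

## Synthetic data

The genotype simulator emulates a factorial crossing design: per locus a
minor-allele frequency f ~ U(0.1, 0.5) is drawn, each fully homozygous
parent carries the minor allele with probability f, and a hybrid of a male
and a female parent is AA/AB/BB according to whether 0/1/2 of its parents
carry it. Defaults mirror a wheat-type design — 15 male × 120 female
parents, 500 crosses sampled uniformly without replacement from the 1800
possible, 2000 markers (MAF bound 0.1 matching the quality filter applied
to the real populations the simulator stands in for). Loci monomorphic
across the sampled hybrids are redrawn up to 10 times, then dropped.

What it does *not* emulate: linkage disequilibrium and genetic maps
(loci are independent), population structure beyond the two-parent-pool
cross design, genotyping error, or selection history. Passing tests
therefore demonstrate correctness of the machinery and the qualitative
behavior of the criteria under an idealized hybrid population, not
performance on any particular crop.

Phenotypes: g_A ~ MVN(0, σ²_A K_A), g_D ~ MVN(0, σ²_D K_D),
e ~ MVN(0, σ²_e I), TBV = μ + g_A + g_D, y = TBV + e. Defaults μ = 100,
σ²_A = 20, γ = σ²_D/σ²_A ∈ {0.5, 1, 2, 4}, broad-sense h² ∈ {0.3, 0.6}
with σ²_e = (1−h²)/h² · (σ²_A + σ²_D). Because the kinships have centered
scores (1ᵀK1 = 0) and trace n_c − 1, the expected sample variance of each
genetic component equals its σ² exactly — the identity behind the
simulator-recovery checks. Kinship square roots come from a symmetric
eigendecomposition with negative eigenvalues clipped at zero (the matrices
are rank-deficient by construction, so Cholesky is not assumed); an
eigenvalue below −1e-6 raises, as it indicates a corrupted matrix.

Reproducibility: replicate r draws from a dedicated substream
(`SeedSequence(seed, spawn_key=(r,))`), so a replicate is bit-identical
whether generated alone or inside a batch, and batches of different length
agree on their common prefix.

## Study orchestration and problem sizes

`run_study` wires the pipeline over a (method, n_t, γ, h²) grid and writes
tidy long-format summaries (mean, SD per metric) plus RIP tables and a
manifest (config hash, seeds, version). The default grid mirrors the full
study (n_t ∈ {50, 100, 150, 200}, all γ and h², k = 20) at 200 replicates
per scenario; `--full-scale` raises this to 2000. The package's own test
and acceptance runs use deliberately economical sizes — toy populations
(8–70 hybrids) for oracle equivalences and exhaustive-search comparisons,
and the 500-hybrid default population with 200–500 replicates and the fast
GVaverage/random methods for trend and recovery checks — chosen so the
whole suite runs in minutes while leaving every Monte-Carlo tolerance
conservative at those sizes.

## Known limitations

* SRC@k behaves non-monotonically under truncation: as the dominance ratio
  γ grows, identification genuinely degrades (NDCG and RS_ratio decline),
  but the true ranks of the selected top k scatter over a wider range, and
  the Pearson correlation of (i, πᵢ) can *increase* with that spread. On
  the synthetic populations this effect is systematic: SRC rises with γ
  while the other metrics fall. SRC@k comparisons across γ settings should
  therefore be read with care.
* The closed-form BLUP with known variance ratios is an upper bound on
  what an estimated model would achieve; method differences measured here
  exclude estimator noise by design.
* GVaverage can select highly related candidates (near-duplicate hybrids
  both carry large genomic variance), reducing training-set diversity at
  small n_t; the CD criterion is the safer choice there.
* The exchange search is a local optimizer; restarts mitigate but do not
  eliminate local optima.
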