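# Methods

## The question the package answers

Given an ultrametric phylogeny and replicated compositional fatty-acid (FA)
profiles of the same species, do related species resemble each other in FA
composition more than expected by chance — and is that resemblance
consistent with a Brownian-motion (BM) model of gradual trait evolution?
The package implements the full chain from raw percentage tables to a
per-trait signal decision.

## Model and statistics

**Phylogenetic covariance.** Under BM with rate σ², the trait vector at the
tips is multivariate normal with mean a·1 and covariance σ²C, where
C_ij is the shared root-to-MRCA path length of tips i and j and C_ii the
root-to-tip depth. C is built by a post-order sweep over the rooted tree;
taxa are ordered by sorted tip label everywhere a matrix meets a vector, so
misalignment cannot occur silently.

**Blomberg's K.** With â the GLS mean ( (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x ),

    K = (MSE0 / MSE) / E[MSE0/MSE | BM],
    MSE0 = (x−â1)ᵀ(x−â1)/(n−1),  MSE = (x−â1)ᵀC⁻¹(x−â1)/(n−1),
    E[MSE0/MSE | BM] = [tr C − n/(1ᵀC⁻¹1)] / (n−1).

K is invariant to affine transforms of the trait and to rescaling all branch
lengths. On an equal-depth star tree K = 1 identically. All solves use a
Cholesky factorization of C; explicit inverses appear only in test oracles.

**Measurement error.** Per-species standard errors of the trait mean enter
as an extra diagonal term: x ~ N(â1, σ²C + diag(se²)). σ² is profiled out
numerically — the likelihood is maximized by golden-section search on
log σ² over (0, r̂ᵀC⁻¹r̂/n], the upper end being the exact optimum when
se = 0 (adding diagonal error variance can only shrink the Brownian share) —
and K is then computed with the adjusted structure C′ = C + diag(se²)/σ̂².
With all-zero se this path reduces exactly to the plain K. Species with a
single measurement get se = 0, which degrades gracefully to the plain
treatment for those tips (flagged in the run log).

**Permutation null (H0: no signal).** The (x, se) pairs are shuffled over
tips; K is fully recomputed for each shuffle, including the σ² refit when
standard errors are present. The one-tailed add-one estimator
p = (1 + #{K_perm ≥ K_obs})/(n_perm + 1) avoids p = 0 and is mildly
conservative. The per-permutation σ² refit uses a 1e-3 relative tolerance
(the observed fit uses 1e-9): a 0.1% error in σ̂² perturbs K_perm far less
than permutation noise perturbs the null distribution.

**BM simulation null (H0: K = 1).** Traits are simulated under BM (σ² = 1;
K is rate-invariant) on the same tree and plain K computed for each. The
observed K is classified against the 2.5%/97.5% quantiles of log simulated
K; the two-sided p doubles the smaller tail of the empirical CDF. By
default simulated traits carry no measurement noise — they are generated
error-free — but a flag adds Gaussian noise at the observed se and analyses
each simulated trait with the error-adjusted K. The pipeline runs this test
only for traits whose unadjusted permutation p is below α, mirroring how
such tables are usually reported.

**Pagel's λ.** λ multiplies the off-diagonal entries of C. The profile
likelihood (â and σ² maximized analytically) is scanned on a 25-point grid
over [0, λ_max] and refined by bounded scalar search (tolerance 1e-8 on λ);
candidates at 0, the grid optimum, and λ_max guarantee logL ≥ logL0.
λ_max is the largest multiplier that still corresponds to a tree: tree
height divided by the depth of the deepest non-root internal node (≥ 1 on
ultrametric trees; 1 by convention on stars). Estimates at the ceiling are
flagged (`lambda_at_bound`), since a hard-bounded λ̂ is a qualitatively
different statement than an interior optimum. On star trees the likelihood
is constant in λ; the result then carries `flat_likelihood=True` and no
arbitrary estimate. The λ = 0 comparison uses a χ²(1) likelihood-ratio
test; the boundary mixture at λ = 0 is deliberately ignored to match common
practice, which makes the test slightly conservative there.

**Decision.** p-values are Benjamini–Hochberg-adjusted within each trait
family (PC scores; individual FAs; indices) separately for the permutation
and the likelihood-ratio families — matching how such reports present one
BH column per family — and signal is accepted only when both adjusted tests
fall strictly below α (default 0.05). A single global family is available
by running the signal functions directly.

## Compositional preprocessing

Percent-of-total profiles are filtered by two simultaneous rules evaluated
on the input table: an FA detected (> 0) in fewer than `min_occurrence`
measurements (default 2) is dropped, as is an FA whose mean proportion
across all measurements is below `min_pct` (default 1%). "Contributing less
than 1% of total" is read as the mean across measurements; the threshold
and rule are configurable. Survivors are re-closed to 100% per row
(idempotent), scaled to [0, 1], and logit-transformed; any column containing
an exact 0 or 1 is first remapped to eps + (1 − 2·eps)p with eps = 0.025,
the usual adjusted-logit convention. Species means and standard errors are
taken over all measurements irrespective of site and habitat.

Indices are computed per measurement on the renormalized profile and then
summarized per species: bacterial FA sum (a15:0, i15:0, 16:1w5, 16:1w7,
i16:0, i17:0, cy17:0, 18:1w7, cy19:0), plant:fungal, bacterial:fungal and
bacterial:plant marker ratios (18:1w9 plant-relative, 18:2w6,9
fungal-relative), the Unsaturation Index UI = Σ f_i·d_i on unit fractions
(f_i the proportion, d_i the double-bond count — recorded in output
metadata since scale conventions differ), saturation-class sums
(SFA/MUFA/PUFA, partitioning the composition), C20-PUFA sum, the
unsaturated:saturated ratio, and the count of detected FAs.
Methyl-branched (i/a), cyclopropane (cy) and hydroxylated FAs carry no
double bond and count as saturated; the classification table ships as
package data and is user-overridable. Ratios with zero denominators
propagate as explicit NaN markers; species with undefined values are
dropped for that trait only (covariance and tree are subset accordingly).

**Combined-dataset mode.** Own measurements are averaged per species at
each site and habitat; literature tables are taken as one data point per
species per treatment/site. Columns are restricted to the subset reliably
reported across sources (biomarker FAs, C20 unsaturated FAs, 16:0, 18:0);
FAs missing from a source are imputed as 0 on the assumption they were
present only in trace amounts. The pooled data points then pass through the
same rare-FA filter, closure, and logit path. Whether to test signal on a
tree pruned to the measured species or on a separately estimated subtree is
left to the caller — pruning is exposed, and the pipeline prunes when
`allow_prune` is set.

## PCA

Eigen-decomposition of the covariance matrix (divisor n−1) of the species ×
trait matrix of mean logit proportions. Eigenvector signs are fixed by
making each axis's largest-magnitude loading positive, so reports are
reproducible. Individual measurements are projected with the species-mean
center and the same eigenvectors to expose intraspecific score variation,
and the species-level standard errors of the PC scores feed the
measurement-error K. Axes are retained while their explained fraction
exceeds the broken-stick expectation b_k = (1/p)Σ_{i≥k}1/i, taken as the
leading consecutive run; a fixed axis count can be forced by configuration
(reports often discuss a fixed number of leading axes alongside the
broken-stick decision), and if no axis beats the stick the report keeps PC1
so the family is never empty. Trait–axis Pearson correlations are
Holm-adjusted across all (trait, axis) pairs.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any real organism's chemistry. A Yule (pure-birth) tree is drawn with
Exp(k·birth_rate) waiting times from two lineages up to n, plus a final
Exp(n·birth_rate) stretch so no terminal branch has zero length. Each FA
gets a latent logit-scale baseline N(0, 1); conserved FAs add a BM deviation
(λ_true = 1) with rate `bm_rate` per unit tree height, labile FAs an
i.i.d. deviation of matched variance (λ_true = 0). Replicates add
N(0, replicate_noise_sd²) on the latent scale, and rows are closed to 100%
by exponentiation and renormalization — so the BM assumption lives on the
latent (logit-like) scale the analysis actually tests, while every row is a
valid composition. Defaults (40 species, 21 FAs split 10 conserved / 11
labile, 3 replicates, bm_rate 1.0, replicate noise 0.5) mirror the scale of
the field study this pipeline is designed for.

What the generator does *not* emulate: softmax closure is not exactly the
inverse of the per-FA logit used in analysis, replicate noise is
homoscedastic, FA abundances have no realistic mean structure, and there is
no site/habitat effect. Passing recovery tests therefore show the
statistical machinery works under its own assumptions — they do not certify
field data behavior.

## Validation experiments and problem sizes

The calibration module re-derives the package's operating characteristics
from scratch (also runnable via `scripts/acceptance.py`):

- analytic exactness: K on equal-depth stars (50 random traits, 12 tips)
  and the closed-form broken stick at p = 3;
- oracle equivalence: 200 random trees (4–8 tips) × random traits, K, GLS
  mean, and the λ profile likelihood at 10 λ values against explicit
  dense-inverse oracles (tolerance 1e-10);
- BM calibration: 1,000 BM traits on a 50-tip Yule tree (median K; fraction
  outside the 2.5–97.5% band of an independent 2,000-trait null);
- type-I error: 1,000 white-noise traits, 500 permutations each, α = 0.05;
- λ recovery: 200 traits each at λ ∈ {0, 0.5, 1} on a 100-tip tree;
- end-to-end recovery: 100 generator seeds at the default synthetic scale,
  199 permutations and 199 BM simulations per trait — permutation counts
  chosen so the smallest attainable p (0.005) leaves clear headroom under
  BH at α = 0.05 while keeping the hundred-seed experiment a few minutes of
  compute; detection rates are pooled over seeds.

## Numerical choices and edge cases

- One integer seed determines everything: the pipeline spawns independent
  `SeedSequence` streams per trait family and per trait, so adding a trait
  does not shift another trait's null draws.
- Ultrametricity tolerance: relative 1e-6 of tree height, since chronogram
  exports lose digits.
- BM simulation factorizes C by symmetric eigendecomposition with negative
  eigenvalues clipped at zero, so degenerate (zero-height) trees simulate
  as constants rather than failing.
- Constant traits are rejected explicitly (K and λ are 0/0 undefined);
  all-zero profile rows are an error naming the sample.
- Newick I/O requires branch lengths on non-root edges, ignores internal
  labels/support values, and writes 17 significant digits so trees
  round-trip exactly. Tip labels are normalized (trim, underscores to
  spaces) before joining with table species names.

## Known limitations

- The likelihood-ratio test for λ ignores the boundary effect at λ = 0.
- The permutation test with measurement error refits σ² per permutation and
  is therefore O(n_perm) likelihood searches; at the default 10,000
  permutations and field-scale trees this is seconds, but it grows linearly.
- No OU or other non-BM models; no multivariate K; ratios are analysed as
  plain continuous traits.
- Combined-mode literature tables must already be compiled per species per
  context; the package does not parse heterogeneous source formats.
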