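# Methods

## The model

`nlhsim` tests, gene by gene, whether a *set* of genetic variants is
associated with a continuous phenotype, allowing the genotype–phenotype
relationship to be nonlinear (threshold effects, dominance-like codes,
cluster structure).  The pipeline has five stages:

1. **Screening (DC-SIS).**  Each candidate predictor (and covariate) is
   ranked by its sample distance correlation with the outcome; the top
   `d = ⌊n / log n⌋` columns are retained (natural logarithm, the DC-SIS
   convention; `d` is configurable, e.g. the top 10 000 in a genome-wide
   analysis).  Distance correlation is zero in population exactly under
   independence, so the screen is model-free.  Surviving covariates are
   carried forward as linear adjusters only and are never kernelized.

2. **Per-set kernel PCA.**  For each set the predictor block is
   standardized column-wise, a Gaussian kernel
   `K(x_i, x_j) = exp(−‖x_i − x_j‖² / 2σ²)` is built with the data-driven
   bandwidth `σ = sqrt(mean pairwise squared Euclidean distance)` (distinct
   pairs only: self-pairs are identically zero and would deflate σ; σ is
   deliberately not tuned by cross-validation), and the feature-space
   centered kernel `K_C = H K H` is eigendecomposed.  Above a configurable
   size threshold the kernel is replaced by the Nyström approximation
   `K̃ = C W⁺ Cᵀ` from `m = min(n, max(50, ⌈2√n⌉))` uniformly drawn
   landmarks, reducing the eigen-cost from O(n³) to O(nm²); the
   decomposition then runs on the m×m core and is lifted, never
   materializing n×n.  The landmark block is pseudo-inverted with singular
   values below `1e−10 · s_max` truncated, which keeps `K̃` positive
   semidefinite.  Eigenvector signs are fixed by making each vector's
   largest-magnitude loading positive so runs are reproducible across
   linear-algebra backends.

3. **Component retention** — two complementary strategies:
   * **A** (average eigenvalue): keep components with
     `λ_k > λ̄ = (1/n) Σ_{k=1}^n λ_k` (strict).  The mean runs over the
     *full* length-n spectrum including numerical zeros, so the rule
     depends on n; with a smooth kernel's long-tailed spectrum it is
     liberal (typically 25–35 components per 8-SNP set at n = 400) and
     suits cumulative weak-signal architectures.
   * **PA** (pre-image guided + refinement): a 10-fold cross-validated
     reconstruction error picks a coarse dimension
     `h_pre = argmin_h RE(h)`; the average-eigenvalue rule is then applied
     within the top `h_pre` components.  In fold i, KPCA runs on the
     training rows, the raw training feature mean `φ̄` is projected onto
     the top-h centered eigenvectors, the projection's pre-image `x̂` is
     computed with Mika's fixed-point iteration for Gaussian kernels, and
     `RE_i(h) = ‖μ_i − x̂‖²` against the held-out input-space mean;
     `RE(h)` averages the ten folds.  PA is parsimonious and suits
     dominating strong-signal architectures.
   Both strategies always return at least one component (leading-component
   fallback when a strict rule retains nothing).

4. **De-sparsified LASSO.**  The retained KPC scores of all sets are
   concatenated, standardized, joined with the covariates and regressed on
   the (centered) phenotype with an initial cross-validated LASSO.  A
   nodewise-regression bias correction
   `b̂ = β̂ + (1/n) Θ̂ Zᵀ(y − Zβ̂)` with the relaxed inverse
   `Θ̂ = T⁻² (I − Γᵀ)` (Γ the nodewise coefficients,
   `τ̂_j² = (1/n) z_jᵀ(z_j − Z_{−j}γ̂_j)`) yields asymptotically normal
   per-column estimators, standard errors
   `se_j = σ̂_ε sqrt((Θ̂ Σ̂ Θ̂ᵀ)_jj / n)` and two-sided normal p-values,
   valid even when the column count exceeds n.
   `σ̂_ε² = RSS / max(n − ŝ, n/2)` with ŝ the initial model's support size.

5. **Two-stage omnibus.**  Within each strategy, a set's per-KPC p-values
   are combined by MinP (Šidák-adjusted minimum: sparse, strong signals)
   and by an adaptive rank-truncated product, ART-A (dense, weak signals):
   `W_k = −Σ_{i≤k} log p_(i)` over the truncation grid
   `{1, ⌈L/4⌉, ⌈L/2⌉, ⌈3L/4⌉, L}`, each W_k calibrated by Monte Carlo
   under independent uniforms, and the minimum per-k p-value recalibrated
   against the same null draws so the adaptive selection over k is
   accounted for exactly at Monte-Carlo resolution.  Stage 1 merges MinP
   and ART-A with the Cauchy combination test
   (`T = Σ w_i tan((0.5 − p_i)π)`, valid under arbitrary dependence);
   stage 2 merges the two strategies' stage-1 p-values with another Cauchy
   aggregation into one omnibus p per set.  Benjamini–Hochberg FDR is
   applied across sets.

The **Linear-HSIM comparator** replaces stage 2–3 with per-set linear PCA
retaining the smallest leading block explaining over 85% of cumulative
variance; screening, inference and aggregation are identical.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `screening.top` | ⌊n/log n⌋ | DC-SIS retention count |
| `kernel.exact_threshold` | 2000 | exact kernel up to this n; Nyström above |
| `kernel.landmarks` | min(n, max(50, ⌈2√n⌉)) | landmark count m |
| `kpca.h_max` | 20 | candidate grid 1..h_max for RE(h) |
| `kpca.folds` | 10 | folds of the reconstruction CV |
| `kpca.preimage_tol` / `max_iter` | 1e−5 / 100 | fixed-point stopping |
| `inference.cv_folds` | 10 | initial and nodewise lasso CV folds |
| `inference.n_alphas`, `eps` | 20, 1e−3 | geometric penalty grid, floor as fraction of λ_max |
| `inference.nodewise` | `"cv"` | per-node CV; `"universal"` uses λ = √(2 log q / n) |
| `inference.penalize_covariates` | True | False leaves covariates out of the l1 penalty: y and KPCs are residualized on them (Frisch–Waugh) and covariates get classical OLS estimates |
| `omnibus.n_mc` | 5000 | ART-A Monte-Carlo draws (reporting floor 1/(n_mc+1)) |

Cauchy inputs are clipped to `[1e−15, 1 − 1e−15]`, a floor on reportable
significance.  Zero p-values entering ART-A are clipped to 1e−300 with a
warning.

## Numerical choices

* The bandwidth is computed in closed form from first and second moments
  (exactly the mean over distinct pairs), O(np) instead of O(n²p).
* All nodewise lasso problems share the design, so they are solved jointly
  by accelerated proximal gradient (FISTA) on the Gram matrix — one matrix
  recursion per penalty level for all q nodes — with per-node penalty
  grids anchored at each node's λ_max.  The objective per node is
  identical to scikit-learn's Lasso (verified against it in the tests).
  Under the universal-λ mode, nodes whose largest off-diagonal |Σ̂| entry
  is below λ are solved exactly by the KKT condition (γ = 0) and skipped.
* The pre-image fixed points for all candidate dimensions and folds of one
  set run as a single batched iteration (expansion coefficients
  zero-padded to the full row set).  A vanishing denominator triggers one
  restart from a perturbed mean; a second occurrence marks the point
  non-converged (flagged in the trace, not fatal).
* Negative eigenvalues of the centered kernel within −1e−8 are clamped to
  zero; numerical rank uses a 1e−10 relative cutoff.
* Ties in screening scores break by original column order; `argmin RE(h)`
  ties break to the smallest h (parsimony).

### Behavior of the reconstruction-error curve

With centered KPCA the centered training mean projects to zero on every
eigenvector, so the only non-degenerate truncated-mean target is the
projection of the *raw* feature mean onto the top-h centered
eigenvectors.  Under this algebra RE(h) is in practice non-increasing in
h — richer targets reconstruct the held-out mean at least as well — so
`h_pre` acts as a data-driven *cap* (typically 5–8 of a grid of 10 in the
study scenarios) rather than a sharp interior minimum, and the
average-eigenvalue refinement inside the cap does the actual trimming.
For small h on symmetric data the projection coefficients can be nearly
zero and the fixed point may wander; such points produce large RE and are
thereby excluded from the argmin, which is the intended effect.

## What the simulator emulates — and what it does not

Genotypes come from a latent Gaussian copula: block-exchangeable latent
correlation ρ within a set, zero between sets, thresholded at the
Hardy–Weinberg quantiles of a per-column MAF drawn uniformly from
`maf_range`, so marginals are Binomial(2, MAF).  Continuous predictors
return the latent normals.  Phenotypes are `y = signal + N(0, noise_sd²)`
with four architectures: CWSM (every predictor of a causal set gets a
Uniform(c1, c2) coefficient) and DSSM (exactly two predictors per causal
set get the fixed coefficients c1 and c2), each in a linear variant
(coefficients on standardized dosage) and a nonlinear variant
(coefficients on the threshold code I(x ≥ 1), configurable I(x = 2) for
genotypes; I(x ≥ median) for continuous predictors).  The code is used
raw, so a constant code contributes only an intercept.

Not emulated: realistic linkage disequilibrium from reference panels,
cross-set dependence, gene–environment interactions, missing genotypes or
genotyping error.  Passing tests therefore certify the statistical
machinery under idealized dependence, not performance on real LD
structure.

## Study scenarios (replicate harness)

* **Null calibration:** n = 400, twenty sets of 8 SNPs, ρ = 0.3,
  MAF ∈ (0.05, 0.5); per-set rejection pooled over sets and replicates.
* **Power scenarios:** two sets differing in dimension (4 and 8 SNPs),
  mirroring the small-scale two-group validation design.  The nonlinear
  variants use the **recessive** threshold I(x = 2) with
  MAF ∈ (0.1, 0.25): at common allele frequencies the dominant code is
  90–97% collinear with additive dosage (corr² = 2(1−f)/(2−f)), which
  makes a "nonlinear" scenario effectively linear, whereas the recessive
  code at low MAF (corr² = 2f/(1+f) ≈ 0.18–0.4) produces a genuinely
  nonlinear architecture.  DSSM uses (c1, c2) = (1, 3) with one causal
  set and noise_sd = 1.5; CWSM uses (c1, c2) = (0.1, 0.2) with both sets
  causal and noise_sd = 0.35.  Noise scales were fixed once, via a small
  pilot, so that the weaker method sits mid-power — the informative region
  of a power curve; they are not re-tuned.
* The harness runs the Nyström pathway (m = 50 landmarks by the default
  rule), h_max = 10 with fixed-point tolerance 1e−4 / 40 iterations,
  5-fold lasso CV over 10-point grids with floor 0.1·λ_max, the
  universal-λ nodewise mode, and ART-A with 2000 draws.  These desk-scale
  settings keep a full replicate under a second; replicate r uses seed
  `master_seed + r`.

## Known limitations

* Gaussian kernel only; no multi-kernel learning or bandwidth tuning.
* ART-A is Monte-Carlo calibrated; its p-values have resolution
  1/(n_mc + 1), so extremely small set-level p-values saturate.
* The recessive/dominant threshold dichotomy is the only nonlinearity the
  generator produces; epistasis is not simulated.
* MinP's Šidák adjustment is exact under independence and conservative
  under the positive dependence typical of KPC p-values.
* In the q > n regime the de-sparsified intervals inherit the usual
  sparsity assumptions; with dense strong signals the initial-lasso df
  correction can inflate σ̂_ε and the intervals become conservative.
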