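# Methods

## Model

`direqtl` treats each gene's cis region as a Bayesian linear regression of
standardized expression on standardized genotype dosages, with a hierarchical
prior that routes information from genomic annotations into the SNP effects.

Per gene *j* (n samples, m_j SNPs):

    y_j  = X_j b_j + eps_j,     eps_j ~ N(0, lambda_j^-1 I_n)
    b_ij ~ N( (omega' v_ij)(nu' f_ij), alpha_ij^-1 )

with hierarchical factors

    lambda_j ~ Gamma(lambda1, lambda2),       lambda2 ~ Gamma(rho1, rho2)
    omega    ~ N_s(0, diag(delta)^-1),        delta_i = prod_l upsilon^l_{d_i^l}
    upsilon^l_k ~ Gamma(chi1_l, chi2_l),      chi2_l  ~ Gamma(zeta1, zeta2)
    nu       ~ N_q(c, diag(p)^-1)
    alpha_ij ~ Gamma(gamma1, kappa_j * gamma_ij),  gamma_ij = prod_{k: C_ikj=1} a_k
    kappa_j  ~ Gamma(tau1, tau2),             tau2 ~ Gamma(xi1, xi2)
    a_k      ~ Gamma(phi1, phi2)

Interpretation of the moving parts:

* **omega** (length s) — signed effect of each directed annotation on SNP
  effect sizes. The grouping vectors `d^l` (one per meta-annotation, e.g. cell
  type and assay type) tie each annotation to one Gamma precision per
  meta-annotation; the product `delta_i` shrinks entire groups toward zero the
  way the group lasso does. `1/upsilon_k` is the group's *variance modifier* —
  the quantity reported (as square roots) when ranking assays or cell types.
  A partition with every annotation in its own singleton group gives the
  lasso-like setting.
* **nu** (length q) — weights of the undirected 0-1 annotations `F_j`
  (intercept plus nested upstream/downstream TSS distance windows). `F_j nu`
  multiplies the directed term per SNP, so it acts as a distance modifier; the
  intercept element is pinned near 1 by a high-precision prior so the scale of
  omega is identified.
* **alpha_ij** — per-SNP ARD precisions: integrating the Gamma prior out of
  the Gaussian gives t-distributed effects, hence sparse per-gene estimates.
  The 0-1 matrix `C_j` lets region annotations modify the prior precision
  multiplicatively through the shared `a_k` factors.

### Summary-statistics mode

With z_j = X'y/n and Sigma_j = X'X/n, and y'y = n by standardization, the
likelihood depends on the data only through (X'X, X'y, y'y) = (n Sigma, n z,
n). The engine therefore runs one code path on these sufficient statistics.
When z and Sigma derive from the same full-rank data this is *exactly* the
individual-level model, so the two modes produce identical fits. When Sigma is
approximated (low-rank, or from an external reference panel), z is no longer
consistent with Sigma and the residual reconstruction could turn negative;
the engine then switches to the proper summary likelihood
z ~ N_m(Sigma b, lambda^-1 Sigma / n), i.e. the same quadratic terms with the
constant n z' Sigma^-1 z and m Gaussian degrees of freedom. The switch is
automatic (it is keyed on the LD object being a low-rank factorization) and
preserves the ELBO guarantee because it is a well-defined model, not a patch.

LD matrices are replaced by trace-preserving low-rank surrogates: keep the top
eigenpairs until their eigenvalue sum reaches the target trace fraction
(0.99 for study LD, 0.95 for reference-panel LD by convention), then add
ridge * I restoring the remaining trace. The b-update inverts
(c A'A + D_alpha) with the Woodbury identity at O(m rank^2) cost.

## Inference

All factors are conjugate, so mean-field coordinate ascent (variational
message passing) has closed-form updates. Per sweep the engine updates, in a
fixed order: per-gene factors b_j, alpha_j, lambda_j, kappa_j (deterministic
gene order), then the global factors omega, nu, upsilon^l, chi2_l, a, tau2,
lambda2. The ELBO — including all normalization constants — is recorded after
every sweep; a decrease beyond 1e-6 relative aborts the fit with a diagnostic
message, and in testing the ELBO is validated against a Monte-Carlo estimate
of E_q[log p - log q] from the explicit joint density. Each update formula is
additionally checked at the converged fixed point against the variational
conditional renormalized by numerical integration on a grid.

Inference is deterministic: the seed only affects simulation and
bootstrapping. Initialization: omega = 0, nu = its prior mean, all Gamma
factors at unit mean, b_j at a unit-prior-variance ridge solution. The default
protocol is 300 fixed sweeps, with an optional early stop on relative ELBO
change (off by default).

### Hyperparameter defaults

All shape/rate pairs default to weakly informative Gamma(0.01, 0.01)-style
values (`Hyperparameters`), chosen once and guarded by the recovery tests
rather than tuned. "Pinned" factors (the nu intercept at 1; omega at 0 and a
at 1 in the annotation-uninformed mode; non-intercept nu at 0 in the
distance-modifier ablation) use prior precision 1e6 at the target value. The
prior mean of the non-intercept nu elements is 0 by default and exposed as a
single scalar (`FitConfig.nu_prior_mean`; 0.3 is the variant that favors
consistently positive distance-modifier signs on noisier data). The gene
inclusion filter takes the two-sided normal p-value of the top marginal
z-statistic (conventional thresholds 1e-10 or 1e-7); lambda2 (the prior rate
of the per-gene noise precisions) is shared across genes.

## Annotation preprocessing

Raw directed annotations from sequence-based epigenome predictors are dense
with mostly near-zero values. The pipeline soft-thresholds at 0.008
(|x| <= 0.008 -> 0, else x -> x - 0.008 sgn(x)), averages the two strand
predictions and re-applies the same shrinkage, then rescales all columns to a
common 2-norm equal to the mean of the unscaled norms. Zero-norm columns are
dropped (logged), and the realized zero fraction is logged, not asserted,
because it is data-dependent. Distance windows split each size into an
upstream and a downstream column; a SNP exactly at the TSS counts as
downstream, and sides are defined on the plus strand unless a gene strand is
supplied. Coordinates are 0-based half-open internally.

## Evaluation

* **Directed predictor.** eta_ij = (omega' v_ij)(nu' f_ij), mu_j = X_j eta_j,
  squared magnitude S_j = mu'mu. MSE^dir = ||y - mu||^2 / n, and in summary
  form MSE^dir = 1 - 2 eta'z + eta'Sigma eta (with z = X'y/n no additional
  1/n enters the cross term; the convention is fixed by requiring exact
  equality with the individual-level definition, asserted to 1e-10). Summary-
  mode S = n eta'Sigma eta. Windows and figures report S/n so MSE gains and
  predictor size share a scale; raw S is also stored.
* **Haseman–Elston regression.** Off-diagonal phenotype cross-products
  y_i y_k regressed on cis-GRM entries (XX'/m); the slope estimates the cis
  additive genetic variance fraction, with a leave-one-sample-out jackknife
  standard error. Unbiasedness at h2 in {0, 0.3} is asserted within 2
  Monte-Carlo standard errors over 500 replicates.
* **Selection metrics.** The product (omega'v)(nu'f) is invariant to
  reciprocal rescaling of omega and nu, so omega-hat is first put on the true
  nu scale: weight each nu element by its window's SNP coverage, sum, and take
  the estimate/truth ratio. Annotations with rescaled |omega-hat| > 0.01 are
  called positive; precision is 1 by convention when nothing is called.
* **Train/test protocol.** Chromosome split, defaults chr1-15 train vs
  chr16-22 test. Gene-level bootstrap (default 10,000 draws, seeded) gives
  95% CIs for sliding-window means (window 25% of genes, step 5%).

## Synthetic data

The simulator draws from the generative model itself, so parameter-recovery
tests are well-posed:

* **Genotypes** — two latent AR(1) Gaussian haplotypes per individual
  (default correlation 0.9) thresholded at MAF-matched cutpoints
  (MAF ~ U(0.05, 0.5)), summed to dosages, then standardized. This produces
  monotonically decaying LD but not coalescent-realistic haplotype structure.
* **Directed annotations** — Gaussian columns sharing a within-cell-type-group
  factor (default correlation 0.5), soft-thresholded to a target zero fraction
  (default 0.98, matching the sparsified output of epigenome predictors) and
  scaled to a common column norm on the gene-stacked matrix.
* **Truth** — n_causal annotations (default 9) with +-1 signs; *structured*
  supports are confined to at most two groups per meta-annotation,
  *unstructured* supports are uniform. The true nu is 1 at the intercept and
  0.25 per distance window (a TSS-peaked staircase). The variance budget is
  explicit: expression has unit variance, a `noise_h2` fraction (default 0.3)
  is genetic, and a `directed_fraction` (default 0.2) of the genetic variance
  comes from the annotation term; omega is first scaled to meet that budget
  and the annotation columns are then rescaled (leaving V omega invariant) so
  the true nonzero effects sit at `omega_scale` (default 0.2) — this pins the
  units in which the 0.01 selection threshold operates. Residual genetic
  effects use a two-point ARD mixture (5% of SNPs carry large variance).
* Expression is re-standardized per gene (y'y = n), and summary statistics
  z = X'y/n, Sigma = X'X/n are emitted alongside.

What passing tests on these data do *not* show: robustness to empirical LD
pathologies (long-range structure, rank-deficient blocks beyond the low-rank
surrogate), annotation measurement error, or confounding in real expression
data — the simulator has none of these by construction.

## Problem sizes used in the checks

The ELBO-monotonicity check runs the full protocol (400 genes, n = 300,
s = 200, 50 SNPs/gene, 300 sweeps). Null recovery uses 100 genes, s = 100
across 5 seeds; structured recovery (3 causal annotations in one group,
group-lasso) uses 200 genes, s = 60 across 5 seeds; mode equivalence 100
genes; the distance-modifier study 220 genes with a chromosome train/test
split. These sizes were fixed once as the package's standard desk-scale study
conditions; the acceptance script runs the same computations at 3 seeds per
stochastic quantity.

## Numerical choices and degenerate inputs

* Eigenvalues below 1e-10 of the top eigenvalue are treated as zero in the
  low-rank factorization; ties at the trace-fraction boundary are included
  (erring toward higher rank). A singular Woodbury inner matrix gets jitter
  1e-8 * trace/m added to the diagonal, logged.
* Missing dosages are mean-imputed before standardization; monomorphic or
  sub-MAF-floor (default 2.5%) SNPs are removed before LD computation.
* Gaussian covariances are symmetrized after inversion; argmax ties in SNP
  prioritization break toward the lowest index; a SNP exactly at the TSS is
  downstream.
* The SNP prioritization score E[b^2 | globals] uses the plug-in prior
  variance E[kappa] E[gamma] / gamma1 (the inverse prior-mean ARD precision),
  since the exact E[1/alpha] is undefined for shape <= 1.
* Strand-ambiguous variants (A/T, C/G) with MAF within 0.05 of 0.5 are
  dropped in summary mode; ref/alt swaps flip the z sign and are logged.

## Known limitations

Mean-field credibility intervals are unreliable and are deliberately not
reported; model assessment goes through the held-out directed MSE instead.
The AR(1) genotype model understates long-range LD. Group shrinkage assumes
the meta-annotation partition is meaningful; on unstructured truths the
group-lasso setting loses recall relative to the lasso setting, as expected.
Very small studies can drive whole annotation columns to zero during
sparsification; the simulator keeps each column's strongest entry alive and
the preprocessing pipeline drops such columns with a log entry.
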