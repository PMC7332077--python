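# direqtl

Variational-Bayes modeling of cis-eQTLs with **directed** and **undirected**
genomic annotations.

## The problem

Sequence-based predictors of epigenetic marks assign every common variant a
*signed* predicted effect on each assayed mark (a *directed annotation*): one
allele is predicted to increase DNase hypersensitivity, H3K27ac, TF binding,
and so on. If those marks causally shape transcription, the same signed
quantities should partially predict cis-eQTL effect sizes — and which marks
predict best is itself biologically informative. `direqtl` fits a hierarchical
regression that explains per-SNP expression effects through directed
annotations, weighted by TSS proximity, and scores how much expression
variance the annotation-derived component predicts on held-out genes.

## The model

For gene *j* with standardized genotypes `X_j` (n × m_j) and standardized
expression `y_j` (yᵀy = n):

```
y_j  = X_j b_j + ε_j,            ε_j  ~ N(0, λ_j⁻¹ I)
b_ij ~ N( (ωᵀ v_ij)(νᵀ f_ij),  α_ij⁻¹ )
```

* `v_ij` — row of the directed annotation matrix `V_j` (m_j × s), signed
  predicted epigenetic effects;
* `f_ij` — row of the 0–1 undirected matrix `F_j` (intercept + upstream /
  downstream TSS distance windows at 50/20/10/5/2/1/0.5/0.25 kb); `Fν` is the
  *distance modifier* that amplifies directed effects near the TSS;
* `ω ~ N(0, diag(δ)⁻¹)` with `δ_i = Π_l υ^l_{d_i^l}`: each meta-annotation
  partition (cell type, assay type) contributes a Gamma-distributed group
  precision, so whole annotation groups are shrunk to zero, group-lasso style;
  `υ_k⁻¹` is the group's *variance modifier*. Giving every annotation its own
  group yields a lasso-like setting;
* `α_ij ~ Γ(γ₁, κ_j γ_ij)` are ARD precisions — integrated out, effects are
  t-distributed, so per-gene estimates are sparse; `γ_ij` is modified by a
  second 0–1 annotation matrix `C_j`.

Inference is variational message passing (mean-field coordinate ascent, all
factors conjugate), monitored by the ELBO, which is guaranteed — and tested —
never to decrease. The model runs equally from **individual-level data** or
from **summary statistics** `z_j = Xᵀy/n` with an LD matrix `Σ_j = XᵀX/n`,
optionally replaced by a trace-preserving low-rank factorization whose
inversion uses the Woodbury identity.

Model fit is evaluated on genes never used in training: the *directed
predictor* `μ̂_j = X_j η̂_j` with `η̂_ij = (ω̂ᵀv_ij)(ν̂ᵀf_ij)` gives the
directed mean squared error `MSE^dir = ‖y − μ̂‖²/n` (1 = no predictive power),
comparable against the cis genetic variance estimated by Haseman–Elston
regression.

## Worked example

```python
import numpy as np
import direqtl as dq

# simulate a study: 120 genes, 300 samples, 40 SNPs per gene,
# 60 directed annotations in 6 cell-type x 5 assay groups, 3 causal
cfg = dq.SimulationConfig(
    n_genes=120, n_samples=300, snps_per_gene=40,
    n_annotations=60, n_groups=(6, 5), n_causal=3, seed=0,
)
study = dq.simulate_study(cfg)

genes = study.gene_data("individual")
train = [g for g in genes if g.chrom <= 15]
test = [g for g in genes if g.chrom >= 16]

state = dq.fit(
    train,
    config=dq.FitConfig(iterations=100, prior_setting="group_lasso"),
    partition=study.partition,
)

# which annotations carry signal?
top = np.argsort(-np.abs(state.omega_mean))[:3]
print("true causal annotations:", sorted(study.truth.causal_support))
for i in top:
    print(f"annotation {i}: omega_hat = {state.omega_mean[i]:+.3f}")

# held-out directed prediction
mses, sizes = [], []
for g in test:
    i = int(g.gene_id[4:])
    eta = dq.directed_mean(state.omega_mean, state.nu_mean, study.V[i], study.F[i].values)
    pred = dq.mse_dir_individual(study.y[i], study.genotypes[i], eta)
    mses.append(pred.mse_dir); sizes.append(pred.S_over_n)
print(f"held-out genes: {len(test)}")
print(f"mean MSE_dir:   {np.mean(mses):.4f}")
print(f"mean S/n:       {np.mean(sizes):.4f}")
```

Output:

```
true causal annotations: [6, 8, 36]
annotation 6: omega_hat = +0.207
annotation 36: omega_hat = +0.192
annotation 8: omega_hat = +0.173
held-out genes: 35
mean MSE_dir:   0.9612
mean S/n:       0.0327
```

The fit ranks exactly the three causal annotations on top with the right
signs. On genes it never saw, the annotation-derived predictor explains ~4%
of expression variance (MSE^dir 0.961 < 1), and the gain matches the mean
squared predictor magnitude S/n — the model is not overfitting.

The same workflow is available from the shell:

```bash
direqtl simulate --seed 0 --out study/
direqtl fit --study study/ --setting group-lasso --iterations 100 --out state.h5
direqtl predict --study study/ --state state.h5 --out pred.tsv
direqtl evaluate --predictions pred.tsv --out windows.tsv
```

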