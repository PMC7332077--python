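"""Synthetic cis-eQTL studies drawn from the model's own generative process.

The simulator emulates every input the fitting engine consumes: LD-structured
standardized genotypes, sparse within-group-correlated directed annotations
with a two-way meta-annotation partition (cell type x assay type), TSS
distance-window matrices, and expression generated from the hierarchical
effect model b_ij ~ N((omega^T v_ij)(nu^T f_ij), alpha_ij^-1).

Genotypes come from a latent AR(1) Gaussian per haplotype thresholded at
MAF-matched cutpoints, so adjacent SNPs carry realistic monotonically decaying
LD. Directed annotations are Gaussian with a shared within-group factor,
soft-thresholded to a target zero fraction and column-normalized, mimicking
the sparsified output of sequence-based epigenome predictors. Effect-size
units are pinned by rescaling the annotation columns (which leaves
eta = V omega invariant) so the true nonzero omega entries sit at a stated
magnitude; the variance budget (genetic fraction of expression, directed
fraction of genetic variance) is controlled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .annotations import (
    DEFAULT_WINDOW_SIZES,
    MetaAnnotationPartition,
    UndirectedAnnotationMatrix,
    build_distance_windows,
    scale_columns_to_common_norm,
)
from .engine import GeneData
from .ld import GenotypeBlock, SummaryStats, standardize_expression


@dataclass
class SimulationConfig:
    n_samples: int = 300
    n_genes: int = 400
    snps_per_gene: int = 50
    ld_decay: float = 0.9  # AR(1) correlation of the latent haplotype field
    n_annotations: int = 200
    n_groups: tuple[int, ...] = (10, 5)  # groups per meta-annotation (cell, assay)
    annotation_sparsity: float = 0.98  # fraction of zero entries in V
    annotation_correlation: float = 0.5  # within-cell-type-group column correlation
    n_causal: int = 9
    structured: bool = True
    omega_scale: float = 0.2  # magnitude of true nonzero directed effects
    nu_profile: str = "tss_peaked"  # or "flat"
    nu_window_value: float = 0.25  # true weight of each distance-window column
    noise_h2: float = 0.3  # genetic fraction of expression variance
    directed_fraction: float = 0.2  # directed share of the genetic variance
    p_causal_snp: float = 0.05  # ARD mixture: fraction of large-variance SNPs
    maf_range: tuple[float, float] = (0.05, 0.5)
    cis_window: int = 150_000
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_annotations:
            raise ValueError("n_causal cannot exceed n_annotations")
        for name in ("annotation_sparsity", "annotation_correlation", "noise_h2",
                     "directed_fraction", "p_causal_snp", "ld_decay"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimulatedTruth:
    omega_true: np.ndarray
    nu_true: np.ndarray
    b_true: list[np.ndarray]
    causal_support: set[int]
    genetic_variance: np.ndarray  # realized var(X b) / n per gene


@dataclass
class SimulatedStudy:
    """Everything a fit + evaluation needs, plus the generating truth."""

    config: SimulationConfig
    genotypes: list[GenotypeBlock]
    y: list[np.ndarray]
    V: list[np.ndarray]
    F: list[UndirectedAnnotationMatrix]
    partition: MetaAnnotationPartition
    positions: list[np.ndarray]
    tss: list[int]
    chroms: list[int]
    truth: SimulatedTruth
    summary: list[SummaryStats]

    def gene_data(self, mode: str = "individual") -> list[GeneData]:
        genes = []
        for i, block in enumerate(self.genotypes):
            gid = f"gene{i:04d}"
            if mode == "individual":
                g = GeneData.from_individual(
                    gid, block, self.y[i], self.V[i], self.F[i].values,
                    chrom=self.chroms[i], standardize=False,
                )
            elif mode == "summary":
                g = GeneData.from_summary(
                    gid, self.summary[i], self.V[i], self.F[i].values, chrom=self.chroms[i]
                )
            else:
                raise ValueError(f"unknown mode {mode!r}")
            genes.append(g)
        return genes

    @property
    def coverage(self) -> np.ndarray:
        """Per-column SNP coverage counts of F, pooled over genes."""
        return np.sum([f.values.sum(axis=0) for f in self.F], axis=0)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GenotypeBlock], list[np.ndarray], list[int], list[int]]:
    """Per-gene standardized dosages with AR(1) haplotype LD.

    Returns (blocks, SNP positions per gene, TSS per gene, chromosome per
    gene). Positions are uniform over the 2 x cis_window region with the TSS
    mid-region; genes cycle through autosomes 1..22.
    """
    rng = rng or np.random.default_rng(config.seed)
    n, m = config.n_samples, config.snps_per_gene
    rho = config.ld_decay
    blocks, positions, tsss, chroms = [], [], [], []
    tss0 = 1_000_000
    for gi in range(config.n_genes):
        maf = rng.uniform(*config.maf_range, size=m)
        cut = norm.ppf(maf)
        dosage = np.zeros((n, m))
        for _ in range(2):  # two haplotypes per individual
            h = np.empty((n, m))
            h[:, 0] = rng.standard_normal(n)
            innov = rng.standard_normal((n, m - 1)) * np.sqrt(1.0 - rho**2)
            for j in range(1, m):
                h[:, j] = rho * h[:, j - 1] + innov[:, j - 1]
            dosage += (h < cut).astype(float)
        sd = dosage.std(axis=0)
        for j in np.flatnonzero(sd == 0):  # monomorphic draws: flip one genotype
            dosage[0, j] = 1.0 if dosage[0, j] == 0 else dosage[0, j] - 1.0
        X = (dosage - dosage.mean(axis=0)) / dosage.std(axis=0)
        snp_ids = [f"g{gi}_snp{j}" for j in range(m)]
        blocks.append(GenotypeBlock(X, snp_ids, [f"s{k}" for k in range(n)]))
        tss = tss0 + gi * 10_000
        pos = np.sort(rng.integers(tss - config.cis_window, tss + config.cis_window + 1, size=m))
        positions.append(pos.astype(np.int64))
        tsss.append(tss)
        chroms.append(gi % 22 + 1)
    return blocks, positions, tsss, chroms


def default_partition(config: SimulationConfig) -> MetaAnnotationPartition:
    """Grid assignment of annotations to (cell-type, assay) groups."""
    s = config.n_annotations
    d, labels = [], []
    for l, h in enumerate(config.n_groups):
        if l == 0:
            dl = np.arange(s) % h + 1
        else:
            span = int(np.prod(config.n_groups[:l]))
            dl = (np.arange(s) // span) % h + 1
        d.append(dl)
        labels.append([f"meta{l}_g{k}" for k in range(1, h + 1)])
    return MetaAnnotationPartition(d=d, group_labels=labels)


def simulate_annotations(
    config: SimulationConfig,
    positions: list[np.ndarray],
    tss: list[int],
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], list[UndirectedAnnotationMatrix], MetaAnnotationPartition]:
    """Sparse correlated directed annotations plus distance-window matrices.

    Columns in the same cell-type group share a latent factor with weight
    sqrt(annotation_correlation); entries are soft-thresholded at the quantile
    matching ``annotation_sparsity`` and rescaled to a common column 2-norm
    (computed on the gene-stacked matrix so all genes share units).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    partition = default_partition(config)
    s = config.n_annotations
    rho = config.annotation_correlation
    group1 = partition.d[0] - 1
    raws = []
    for pos in positions:
        m = pos.shape[0]
        factors = rng.standard_normal((m, config.n_groups[0]))
        noise = rng.standard_normal((m, s))
        raws.append(np.sqrt(rho) * factors[:, group1] + np.sqrt(1.0 - rho) * noise)
    raw = np.concatenate(raws, axis=0)
    thr = np.quantile(np.abs(raw), config.annotation_sparsity)
    stacked = np.sign(raw) * np.maximum(np.abs(raw) - thr, 0.0)
    # keep every column alive: restore the strongest raw entry of any column
    # the global threshold wiped out (only matters for very small studies)
    for col in np.flatnonzero((stacked != 0).sum(axis=0) == 0):
        top = int(np.argmax(np.abs(raw[:, col])))
        stacked[top, col] = raw[top, col]
    scaled, kept = scale_columns_to_common_norm(stacked)
    assert len(kept) == s
    V_list, off = [], 0
    for pos in positions:
        V_list.append(scaled[off : off + pos.shape[0]])
        off += pos.shape[0]
    F_list = [
        build_distance_windows(pos, t, config.window_sizes, cis_window=config.cis_window)
        for pos, t in zip(positions, tss)
    ]
    return V_list, F_list, partition


def _draw_support(config: SimulationConfig, partition: MetaAnnotationPartition, rng) -> set[int]:
    s = config.n_annotations
    if not config.structured:
        return set(rng.choice(s, size=config.n_causal, replace=False).tolist())
    # concentrate the support in at most 2 groups per meta-annotation
    for n_pick in (1, 2):
        chosen = [
            set(rng.choice(h, size=min(n_pick, h), replace=False) + 1) for h in partition.h
        ]
        candidates = np.arange(s)
        for dl, groups in zip(partition.d, chosen):
            candidates = candidates[np.isin(dl[candidates], list(groups))]
        if candidates.size >= config.n_causal:
            return set(rng.choice(candidates, size=config.n_causal, replace=False).tolist())
    raise ValueError("partition groups too small for a structured support of this size")


def _nu_truth(config: SimulationConfig, q: int) -> np.ndarray:
    nu = np.zeros(q)
    nu[0] = 1.0
    if config.nu_profile == "tss_peaked":
        nu[1:] = config.nu_window_value
    elif config.nu_profile != "flat":
        raise ValueError(f"unknown nu_profile {config.nu_profile!r}")
    return nu


def simulate_expression(
    genotypes: list[GenotypeBlock],
    V_list: list[np.ndarray],
    F_list: list[UndirectedAnnotationMatrix],
    partition: MetaAnnotationPartition,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray], SimulatedTruth, list[SummaryStats]]:
    """Draw SNP effects and expression from the generative model.

    Returns (expression vectors, unit-rescaled V matrices, truth, summary
    statistics). Expression is standardized so y^T y = n; the genetic variance
    fraction targets ``noise_h2`` with a ``directed_fraction`` share coming
    from the annotation term.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    g_var = config.noise_h2
    dir_target = config.directed_fraction * g_var
    q = F_list[0].values.shape[1]
    nu_true = _nu_truth(config, q)

    if config.omega_scale > 0 and dir_target > 0:
        support = _draw_support(config, partition, rng)
        omega0 = np.zeros(config.n_annotations)
        idx = sorted(support)
        omega0[idx] = rng.choice([-1.0, 1.0], size=len(idx))
        eta0 = [
            (V @ omega0) * (F.values @ nu_true) for V, F in zip(V_list, F_list)
        ]
        var0 = np.mean([(x.X @ e) @ (x.X @ e) / x.n for x, e in zip(genotypes, eta0)])
        if var0 <= 0:
            raise RuntimeError("directed component has zero variance; annotations too sparse")
        kappa = np.sqrt(dir_target / var0)
        omega1 = kappa * omega0
        unit = np.mean(np.abs(omega1[idx])) / config.omega_scale
        V_list = [V * unit for V in V_list]
        omega_true = omega1 / unit
    else:
        support = set()
        omega_true = np.zeros(config.n_annotations)
        dir_target = 0.0

    resid_g = max(g_var - dir_target, 0.0)
    m = config.snps_per_gene
    sigma_c2 = resid_g / (m * (config.p_causal_snp + 1e-4 * (1 - config.p_causal_snp))) if resid_g > 0 else 0.0
    sigma_02 = 1e-4 * sigma_c2

    y_list, b_list, gvar, stats = [], [], [], []
    for x, V, F in zip(genotypes, V_list, F_list):
        eta = (V @ omega_true) * (F.values @ nu_true)
        is_big = rng.random(x.m) < config.p_causal_snp
        sd = np.sqrt(np.where(is_big, sigma_c2, sigma_02))
        b = eta + rng.standard_normal(x.m) * sd
        genetic = x.X @ b
        eps = rng.standard_normal(x.n) * np.sqrt(max(1.0 - g_var, 1e-12))
        y = standardize_expression(genetic + eps) if g_var > 0 else standardize_expression(eps)
        y_list.append(y)
        b_list.append(b)
        gvar.append(float(genetic @ genetic) / x.n)
        z = x.X.T @ y / x.n
        stats.append(SummaryStats(z=z, n=x.n, ld=x.X.T @ x.X / x.n, snp_ids=list(x.snp_ids)))
    truth = SimulatedTruth(
        omega_true=omega_true,
        nu_true=nu_true,
        b_true=b_list,
        causal_support=support,
        genetic_variance=np.array(gvar),
    )
    return y_list, V_list, truth, stats


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """End-to-end synthetic study: genotypes, annotations, expression, truth."""
    rng = np.random.default_rng(config.seed)
    genotypes, positions, tss, chroms = simulate_genotypes(config, rng)
    V_list, F_list, partition = simulate_annotations(config, positions, tss, rng)
    y_list, V_list, truth, stats = simulate_expression(
        genotypes, V_list, F_list, partition, config, rng
    )
    return SimulatedStudy(
        config=config,
        genotypes=genotypes,
        y=y_list,
        V=V_list,
        F=F_list,
        partition=partition,
        positions=positions,
        tss=tss,
        chroms=chroms,
        truth=truth,
        summary=stats,
    )
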