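"""File formats, per-gene dataset assembly, train/test protocol, prediction.

A study directory holds one row per gene in ``genes.tsv`` plus per-gene files:
``<gene>.snps.tsv`` (snp_id, chrom, pos, ref, alt, maf), ``<gene>.V.mtx``
(sparse directed annotations), and either ``<gene>.dosage.tsv`` (n x m
standardized dosages) or ``<gene>.summary.tsv`` (snp_id, zscore, n; zscore is
the conventional marginal z-statistic, i.e. sqrt(n) * X^T y / n). Annotation
columns and their meta-annotation grouping live in ``annotations.tsv`` /
``partition.tsv``. Distance-window matrices are rebuilt from positions, never
stored.

Coordinates are 0-based half-open internally; BED-style inputs pass through,
1-based position tables are converted on read by their readers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
from scipy.stats import norm

from . import evaluation as ev
from .annotations import (
    DEFAULT_WINDOW_SIZES,
    MetaAnnotationPartition,
    build_distance_windows,
    read_partition_table,
)
from .engine import FitConfig, GeneData, PosteriorState
from .ld import GenotypeBlock, SummaryStats, standardize_genotypes

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class RunConfig:
    """Validated top-level run description (paths + fit/simulation settings)."""

    study_dir: str
    fit: FitConfig
    simulation: "object | None" = None  # SimulationConfig when simulating
    hyper_overrides: dict | None = None
    threads: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.log_level.upper() not in {"DEBUG", "INFO", "WARNING", "ERROR"}:
            raise ValueError(f"unknown log level {self.log_level!r}")
        if self.hyper_overrides:
            from .engine import Hyperparameters

            valid = set(Hyperparameters.__dataclass_fields__)
            unknown = set(self.hyper_overrides) - valid
            if unknown:
                raise ValueError(f"unknown hyperparameter overrides: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        fit = FitConfig(**raw.pop("fit", {}))
        sim = raw.pop("simulation", None)
        if sim is not None:
            from .simulate import SimulationConfig

            if "n_groups" in sim:
                sim["n_groups"] = tuple(sim["n_groups"])
            sim = SimulationConfig(**sim)
        return cls(fit=fit, simulation=sim, **raw)


@dataclass
class GeneDataset:
    """Per-gene bundle: genotypes or summaries, annotations, positions."""

    gene_id: str
    chrom: int
    tss: int
    snps: pd.DataFrame  # snp_id, chrom, pos, ref, alt, maf
    V: np.ndarray
    F: np.ndarray
    genotypes: GenotypeBlock | None = None
    y: np.ndarray | None = None
    summary: SummaryStats | None = None
    C: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.genotypes is None) == (self.summary is None):
            raise ValueError("exactly one of genotypes/summary must be present")
        m = len(self.snps)
        for name, mat in (("V", self.V), ("F", self.F)):
            if mat.shape[0] != m:
                raise ValueError(f"{name} has {mat.shape[0]} rows for {m} SNPs")

    def to_gene_data(self) -> GeneData:
        if self.genotypes is not None:
            return GeneData.from_individual(
                self.gene_id, self.genotypes, self.y, self.V, self.F, self.C, chrom=self.chrom
            )
        return GeneData.from_summary(
            self.gene_id, self.summary, self.V, self.F, self.C, chrom=self.chrom
        )

    def top_pvalue(self) -> float:
        """Two-sided normal p-value of the strongest marginal association."""
        if self.summary is not None:
            zeta = np.abs(self.summary.z) * np.sqrt(self.summary.n)
        else:
            n = self.genotypes.n
            zeta = np.abs(self.genotypes.X.T @ self.y / n) * np.sqrt(n)
        return float(2.0 * norm.sf(np.max(zeta)))


# ---------------------------------------------------------------- genotypes

def read_dosage_tsv(path: str | Path) -> GenotypeBlock:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return GenotypeBlock(df.to_numpy(dtype=float), list(df.columns), list(df.index))


def read_plink(prefix: str | Path, maf_floor: float = 0.0) -> GenotypeBlock:
    """Read PLINK BED/BIM/FAM (SNP-major BED, 2-bit packed genotypes)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise ValueError("not a SNP-major PLINK BED file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:].reshape(m, bytes_per_snp)
    # unpack 2-bit codes: 0=hom a1, 2=het, 3=hom a2, 1=missing
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, -1)[:, :n].T.astype(float)
    lookup = np.array([2.0, np.nan, 1.0, 0.0])  # a1-allele dosage
    dosages = lookup[codes.astype(int)]
    return standardize_genotypes(dosages, list(bim["snp_id"]), list(fam["iid"]), maf_floor)


def read_vcf(path: str | Path, maf_floor: float = 0.0) -> GenotypeBlock:
    """Read dosages from a VCF (DS format field, or GT fallback) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    # cyvcf2 gt_types coding: 0=hom ref, 1=het, 3=hom alt, 2=unknown
    dosage_of = np.array([0.0, 1.0, np.nan, 2.0])
    ids, cols = [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            cols.append(np.asarray(ds, dtype=float).reshape(-1))
        else:
            cols.append(dosage_of[np.asarray(var.gt_types, dtype=int)])
    return standardize_genotypes(np.column_stack(cols), ids, samples, maf_floor)


# ------------------------------------------------------- summary statistics

def read_summary_tsv(path: str | Path) -> pd.DataFrame:
    """TSV with columns snp_id, zscore, n (conventional marginal z-scores)."""
    df = pd.read_csv(path, sep="\t")
    required = {"snp_id", "zscore", "n"}
    if not required.issubset(df.columns):
        raise ValueError(f"summary TSV needs columns {sorted(required)}")
    return df


def harmonize_summary(
    summary: pd.DataFrame,
    snps: pd.DataFrame,
    drop_ambiguous: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Align summary z-scores to the annotation SNP table's alleles.

    Match key is (chrom, pos, ref, alt); a ref/alt swap flips the z sign
    (logged); strand-ambiguous variants (A/T, C/G) with MAF near 0.5 are
    dropped. Returns (aligned summary, matching snp table, flip flags).
    """
    key = ["chrom", "pos"]
    merged = summary.merge(snps, on=key, suffixes=("_sum", ""))
    flips, keep = {}, []
    for idx, row in merged.iterrows():
        if drop_ambiguous and (row["ref"], row["alt"]) in AMBIGUOUS_PAIRS and abs(row["maf"] - 0.5) < 0.05:
            logger.info("dropping strand-ambiguous SNP %s (MAF near 0.5)", row["snp_id"])
            continue
        if (row["ref_sum"], row["alt_sum"]) == (row["ref"], row["alt"]):
            flips[row["snp_id"]] = 1
        elif (row["ref_sum"], row["alt_sum"]) == (row["alt"], row["ref"]):
            flips[row["snp_id"]] = -1
            logger.info("flipping z sign for swapped alleles at %s", row["snp_id"])
        else:
            logger.info("removing SNP %s with inconsistent alleles", row["snp_id"])
            continue
        keep.append(idx)
    merged = merged.loc[keep].copy()
    merged["zscore"] = merged["zscore"] * merged["snp_id"].map(flips)
    kept_snps = snps[snps["snp_id"].isin(merged["snp_id"])].reset_index(drop=True)
    return merged, kept_snps, flips


# ---------------------------------------------------------- study directory

def write_simulated(study, outdir: str | Path) -> None:
    """Write a simulated study in the same formats the loaders read."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    genes = []
    ann_ids = [f"ann{k}" for k in range(cfg.n_annotations)]
    pd.DataFrame({"annotation_id": ann_ids}).to_csv(out / "annotations.tsv", sep="\t", index=False)
    rows = []
    for l in range(study.partition.w):
        for a, grp in zip(ann_ids, study.partition.d[l]):
            rows.append((a, f"meta{l}", study.partition.group_labels[l][grp - 1]))
    pd.DataFrame(rows, columns=["annotation_id", "meta_annotation_name", "group_label"]).to_csv(
        out / "partition.tsv", sep="\t", index=False
    )
    for i, block in enumerate(study.genotypes):
        gid = f"gene{i:04d}"
        genes.append((gid, study.chroms[i], study.tss[i]))
        snps = pd.DataFrame(
            {
                "snp_id": block.snp_ids,
                "chrom": study.chroms[i],
                "pos": study.positions[i],
                "ref": "A",
                "alt": "G",
                "maf": 0.25,
            }
        )
        snps.to_csv(out / f"{gid}.snps.tsv", sep="\t", index=False)
        sio.mmwrite(out / f"{gid}.V.mtx", sp.csr_matrix(study.V[i]), precision=17)
        dos = pd.DataFrame(block.X, index=block.sample_ids, columns=block.snp_ids)
        dos.to_csv(out / f"{gid}.dosage.tsv", sep="\t", float_format="%.17g")
        np.savetxt(out / f"{gid}.expression.tsv", study.y[i], fmt="%.17g")
        st = study.summary[i]
        pd.DataFrame(
            {"snp_id": block.snp_ids, "zscore": st.z * np.sqrt(st.n), "n": st.n}
        ).to_csv(out / f"{gid}.summary.tsv", sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(genes, columns=["gene_id", "chrom", "tss"]).to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    truth = {
        "omega_true": study.truth.omega_true.tolist(),
        "nu_true": study.truth.nu_true.tolist(),
        "causal_support": sorted(study.truth.causal_support),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


def load_gene_datasets(
    directory: str | Path,
    mode: str = "individual",
    cis_window: int = 150_000,
    maf_floor: float = 0.0,
    gene_p_threshold: float | None = None,
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES,
) -> tuple[list[GeneDataset], MetaAnnotationPartition]:
    """Assemble per-gene datasets from a study directory.

    SNPs are restricted to the cis window and MAF floor; genes whose top
    marginal p-value exceeds ``gene_p_threshold`` are skipped (logged).
    """
    d = Path(directory)
    genes_tbl = pd.read_csv(d / "genes.tsv", sep="\t")
    ann_ids = list(pd.read_csv(d / "annotations.tsv", sep="\t")["annotation_id"])
    partition = read_partition_table(d / "partition.tsv", ann_ids)
    datasets = []
    kept = dropped_window = dropped_maf = dropped_p = 0
    for _, grow in genes_tbl.iterrows():
        gid, chrom, tss = grow["gene_id"], int(grow["chrom"]), int(grow["tss"])
        snps = pd.read_csv(d / f"{gid}.snps.tsv", sep="\t")
        V = np.asarray(sio.mmread(d / f"{gid}.V.mtx").todense())
        in_cis = (snps["pos"] - tss).abs() <= cis_window
        maf_ok = snps["maf"] >= maf_floor
        dropped_window += int((~in_cis).sum())
        dropped_maf += int((in_cis & ~maf_ok).sum())
        sel = np.flatnonzero(in_cis & maf_ok)
        if sel.size == 0:
            logger.warning("gene %s has no SNPs after filters; skipped", gid)
            continue
        snps = snps.iloc[sel].reset_index(drop=True)
        V = V[sel]
        F = build_distance_windows(snps["pos"].to_numpy(), tss, window_sizes).values
        if mode == "individual":
            dos = pd.read_csv(d / f"{gid}.dosage.tsv", sep="\t", index_col=0, float_precision="round_trip")
            block = GenotypeBlock(
                dos.to_numpy(dtype=float)[:, sel], list(snps["snp_id"]), list(dos.index)
            )
            y = np.loadtxt(d / f"{gid}.expression.tsv")
            ds = GeneDataset(gid, chrom, tss, snps, V, F, genotypes=block, y=y)
        else:
            summ = read_summary_tsv(d / f"{gid}.summary.tsv")
            summ = summ[summ["snp_id"].isin(snps["snp_id"])]
            summ = summ.set_index("snp_id").loc[snps["snp_id"]].reset_index()
            n = int(summ["n"].iloc[0])
            dos = pd.read_csv(d / f"{gid}.dosage.tsv", sep="\t", index_col=0, float_precision="round_trip")
            sigma = np.cov(dos.to_numpy(dtype=float)[:, sel], rowvar=False, bias=True)
            stats = SummaryStats(
                z=summ["zscore"].to_numpy() / np.sqrt(n),
                n=n,
                ld=np.atleast_2d(sigma),
                snp_ids=list(snps["snp_id"]),
            )
            ds = GeneDataset(gid, chrom, tss, snps, V, F, summary=stats)
        if gene_p_threshold is not None and ds.top_pvalue() > gene_p_threshold:
            dropped_p += 1
            logger.info("gene %s fails the top-p filter; skipped", gid)
            continue
        kept += 1
        datasets.append(ds)
    logger.info(
        "loaded %d genes (SNPs dropped: %d cis-window, %d MAF; genes dropped: %d top-p)",
        kept, dropped_window, dropped_maf, dropped_p,
    )
    return datasets, partition


def split_train_test(
    datasets: list[GeneDataset],
    train_chroms: set[int] = frozenset(range(1, 16)),
    test_chroms: set[int] = frozenset(range(16, 23)),
) -> tuple[list[GeneDataset], list[GeneDataset]]:
    """Chromosome-based train/test partition (defaults: 1-15 vs 16-22)."""
    train_chroms, test_chroms = set(train_chroms), set(test_chroms)
    if train_chroms & test_chroms:
        raise ValueError("train and test chromosome sets overlap")
    train = [d for d in datasets if d.chrom in train_chroms]
    test = [d for d in datasets if d.chrom in test_chroms]
    excluded = len(datasets) - len(train) - len(test)
    if excluded:
        logger.warning("%d genes on chromosomes outside both sets were excluded", excluded)
    if not test:
        raise ValueError("empty test set")
    logger.info("split: %d train genes, %d test genes", len(train), len(test))
    return train, test


def predict(
    state: PosteriorState | dict,
    test_datasets: list[GeneDataset],
    mode: str = "individual",
) -> pd.DataFrame:
    """Directed predictors and their MSE on held-out genes.

    ``state`` is a fitted posterior (or a dict with omega_mean / nu_mean).
    Returns one row per gene: S, S/n, MSE^dir, and y^T mu (sign score).
    """
    if isinstance(state, dict):
        omega, nu = np.asarray(state["omega_mean"]), np.asarray(state["nu_mean"])
    else:
        if not state.fitted:
            raise ValueError("state is not fitted")
        omega, nu = state.omega_mean, state.nu_mean
    rows = []
    for ds in test_datasets:
        if ds.V.shape[1] != omega.shape[0] or ds.F.shape[1] != nu.shape[0]:
            raise ValueError(f"annotation columns of gene {ds.gene_id} mismatch the fitted weights")
        eta = ev.directed_mean(omega, nu, ds.V, ds.F)
        if mode == "individual":
            from .ld import standardize_expression

            y = standardize_expression(ds.y)
            pred = ev.mse_dir_individual(y, ds.genotypes, eta)
            score = float(y @ pred.mu_hat)
        else:
            st = ds.summary
            pred = ev.mse_dir_summary(st.z, st.ld_dense(), eta, st.n)
            score = float(eta @ st.z) * st.n
        rows.append(
            {
                "gene_id": ds.gene_id,
                "chrom": ds.chrom,
                "S": pred.S,
                "S_over_n": pred.S_over_n,
                "mse_dir": pred.mse_dir,
                "sign_score": score,
            }
        )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- persistence

def save_state(state: PosteriorState, path: str | Path) -> None:
    """Persist the fitted global factors and per-gene effect means to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("omega_mean", data=state.omega_mean)
        f.create_dataset("omega_var", data=np.diag(state.omega_cov))
        f.create_dataset("nu_mean", data=state.nu_mean)
        f.create_dataset("nu_var", data=np.diag(state.nu_cov))
        f.create_dataset("elbo_trace", data=np.asarray(state.elbo_trace))
        f.create_dataset("b_mean", data=state.b_mean)
        f.create_dataset(
            "gene_ids", data=np.array([g.gene_id for g in state.genes], dtype="S")
        )
        f.create_dataset("offsets", data=np.array([s.start for s in state.slices] + [state.slices[-1].stop]))
        for l in range(len(state.ups_shape)):
            f.create_dataset(f"upsilon_shape_{l}", data=state.ups_shape[l])
            f.create_dataset(f"upsilon_rate_{l}", data=state.ups_rate[l])


def load_weights(path: str | Path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for key in ("omega_mean", "nu_mean", "elbo_trace", "b_mean", "offsets"):
            out[key] = f[key][()]
        out["gene_ids"] = [s.decode() for s in f["gene_ids"][()]]
    return out


def export_effect_sizes(
    state: PosteriorState, annotation_ids: list[str], path: str | Path, min_abs: float = 0.001
) -> pd.DataFrame:
    """TSV of directed effect sizes with |omega| above the reporting floor."""
    df = pd.DataFrame({"annotation_id": annotation_ids, "omega_hat": state.omega_mean})
    df = df[df["omega_hat"].abs() > min_abs]
    df.to_csv(path, sep="\t", index=False)
    return df


def default_fit_config(**overrides) -> FitConfig:
    return FitConfig(**overrides)
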