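"""Per-gene LD matrices: standardization, summary statistics, low-rank
approximation, and fast Woodbury inversion.

LD is defined on column-standardized dosages, ``Sigma = X^T X / n``. To keep
inference tractable on wide cis windows, ``Sigma`` is replaced by a
trace-preserving low-rank surrogate ``A^T A + ridge * I``: the top eigenpairs
are kept until their eigenvalue sum reaches a target fraction of the trace,
and a scaled identity restores the remaining trace mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Eigenvalues below this fraction of the top eigenvalue are treated as zero.
EIGENVALUE_FLOOR = 1e-10

#: Default minor-allele-frequency floor for LD computation.
DEFAULT_MAF_FLOOR = 0.025


@dataclass
class GenotypeBlock:
    """Column-standardized dosage matrix for one gene region (n x m_j)."""

    X: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]


@dataclass
class LowRankLD:
    """Factorized LD surrogate ``A^T A + ridge * I`` (A is rank x m)."""

    A: np.ndarray
    ridge: float
    trace_original: float
    snp_ids: list[str] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.A.shape[1]

    def dense(self) -> np.ndarray:
        return self.A.T @ self.A + self.ridge * np.eye(self.m)


@dataclass
class SummaryStats:
    """Marginal statistics z = X^T y / n with their LD matrix Sigma = X^T X / n."""

    z: np.ndarray
    n: int
    ld: LowRankLD | np.ndarray
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite z-scores")

    def ld_dense(self) -> np.ndarray:
        return self.ld.dense() if isinstance(self.ld, LowRankLD) else np.asarray(self.ld)


def standardize_genotypes(
    dosages: np.ndarray,
    snp_ids: list[str],
    sample_ids: list[str] | None = None,
    maf_floor: float = DEFAULT_MAF_FLOOR,
) -> GenotypeBlock:
    """Mean-impute missing dosages, drop low-MAF columns, and standardize.

    ``dosages`` holds 0/1/2 counts (or continuous dosages) with NaN for
    missing. Columns with MAF below ``maf_floor`` or zero variance are removed
    (logged); remaining columns are centered and scaled to unit variance.
    """
    X = np.asarray(dosages, dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_mean, nan_idx[1])
    freq = X.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    sd = X.std(axis=0)
    keep = (maf >= maf_floor) & (sd > 0)
    if not keep.all():
        dropped = [snp_ids[i] for i in np.flatnonzero(~keep)]
        logger.info("dropping %d SNPs below MAF %.3f or monomorphic", len(dropped), maf_floor)
    X = X[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    kept_ids = [snp_ids[i] for i in np.flatnonzero(keep)]
    return GenotypeBlock(X, kept_ids, sample_ids or [])


def standardize_expression(y: np.ndarray) -> np.ndarray:
    """Center y and scale so that y^T y = n (the evaluation convention)."""
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    ss = y @ y
    if ss == 0:
        raise ValueError("constant expression vector")
    return y * np.sqrt(len(y) / ss)


def compute_summary_stats(block: GenotypeBlock, y: np.ndarray) -> SummaryStats:
    """Marginal statistics z = X^T y / n and LD Sigma = X^T X / n.

    With standardized columns, z_i equals the per-SNP least-squares
    coefficient of y on SNP i.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != block.n:
        raise ValueError(f"length mismatch: y has {y.shape[0]} samples, X has {block.n}")
    n = block.n
    z = block.X.T @ y / n
    sigma = block.X.T @ block.X / n
    return SummaryStats(z=z, n=n, ld=sigma, snp_ids=list(block.snp_ids))


def lowrank_approximate(S: np.ndarray, trace_fraction: float) -> LowRankLD:
    """Trace-preserving low-rank approximation of a PSD matrix.

    Keeps the smallest number of top eigenpairs whose eigenvalue sum reaches
    ``trace_fraction`` of trace(S) (ties at the boundary err toward higher
    rank), then adds ridge = (trace(S) - kept sum) / m so the total trace is
    restored.
    """
    S = np.asarray(S, dtype=float)
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("input must be a symmetric matrix")
    if not 0 < trace_fraction <= 1:
        raise ValueError("trace_fraction must be in (0, 1]")
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    floor = EIGENVALUE_FLOOR * max(evals[0], 0.0)
    if evals[-1] < -1e-8 * max(evals[0], 1.0):
        raise ValueError(f"matrix is not PSD (min eigenvalue {evals[-1]:.3g})")
    evals = np.where(evals < floor, 0.0, evals)
    total = evals.sum()
    if total == 0:
        return LowRankLD(A=np.zeros((0, S.shape[0])), ridge=0.0, trace_original=0.0)
    cum = np.cumsum(evals)
    k = int(np.searchsorted(cum, trace_fraction * total - 1e-12) + 1)
    # include eigenvalues tied with the boundary one (err toward higher rank)
    while k < len(evals) and evals[k] > 0 and np.isclose(evals[k], evals[k - 1], rtol=1e-12):
        k += 1
    k = min(k, int(np.count_nonzero(evals)))
    A = (np.sqrt(evals[:k])[:, None] * evecs[:, :k].T)
    ridge = (total - evals[:k].sum()) / S.shape[0]
    return LowRankLD(A=A, ridge=float(ridge), trace_original=float(total))


def woodbury_inverse(
    D_diag: np.ndarray, A: np.ndarray, c: float, dense: bool = True
):
    """Invert ``c * A^T A + diag(D)`` via the Woodbury identity.

    Returns the dense inverse when ``dense`` is True, otherwise a function
    applying the inverse to a vector. Cost is O(m * rank^2) instead of O(m^3).
    A singular inner matrix signals ill-conditioned LD; a small jitter is added
    to D and logged.
    """
    D_diag = np.asarray(D_diag, dtype=float)
    if np.any(D_diag <= 0):
        raise ValueError("D_diag must be strictly positive")
    m = D_diag.shape[0]
    Dinv = 1.0 / D_diag
    if A.shape[0] == 0 or c == 0:
        if dense:
            return np.diag(Dinv)
        return lambda v: Dinv * v

    def _inner(Dinv):
        r = A.shape[0]
        return np.eye(r) / c + (A * Dinv) @ A.T

    inner = _inner(Dinv)
    try:
        inner_chol = np.linalg.cholesky(inner)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * (c * np.sum(A * A) / m + D_diag.mean())
        logger.warning("Woodbury inner matrix singular; adding jitter %.3g to D", jitter)
        Dinv = 1.0 / (D_diag + jitter)
        inner_chol = np.linalg.cholesky(_inner(Dinv))

    ADinv = A * Dinv  # rank x m

    def apply(v: np.ndarray) -> np.ndarray:
        t = ADinv @ v
        t = np.linalg.solve(inner_chol.T, np.linalg.solve(inner_chol, t))
        return Dinv * v - ADinv.T @ t

    if not dense:
        return apply
    t = np.linalg.solve(inner_chol.T, np.linalg.solve(inner_chol, ADinv))
    return np.diag(Dinv) - ADinv.T @ t


def reference_ld_from_panel(
    panel: GenotypeBlock,
    target_snps: list[str],
    panel_alleles: dict[str, tuple[str, str]] | None = None,
    target_alleles: dict[str, tuple[str, str]] | None = None,
    trace_fraction: float = 0.95,
) -> tuple[LowRankLD, dict[str, int]]:
    """LD for target SNPs from an external reference panel.

    SNPs absent from the panel are removed (logged). When allele tables are
    given, variants whose ref/alt are swapped relative to the target study get
    their genotype column sign-flipped and a -1 flag recorded so downstream
    z-scores can be harmonized; variants with inconsistent alleles are removed.
    Returns the low-rank LD (at ``trace_fraction`` trace retention) and a
    per-SNP flip flag (+1 kept, -1 flipped).
    """
    index = {sid: i for i, sid in enumerate(panel.snp_ids)}
    cols, kept, flips = [], [], {}
    for sid in target_snps:
        if sid not in index:
            logger.info("SNP %s absent from reference panel; removed", sid)
            continue
        col = panel.X[:, index[sid]]
        flip = 1
        if panel_alleles and target_alleles and sid in panel_alleles and sid in target_alleles:
            pa, ta = panel_alleles[sid], target_alleles[sid]
            if pa == ta:
                flip = 1
            elif pa == (ta[1], ta[0]):
                flip = -1
            else:
                logger.info("SNP %s has inconsistent alleles; removed", sid)
                continue
        cols.append(flip * col)
        kept.append(sid)
        flips[sid] = flip
    if not cols:
        raise ValueError("no target SNPs found in the reference panel")
    Xp = np.column_stack(cols)
    sigma = Xp.T @ Xp / Xp.shape[0]
    approx = lowrank_approximate(sigma, trace_fraction)
    approx.snp_ids = kept
    return approx, flips


def save_lowrank_h5(ld: LowRankLD, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=ld.A)
        f.attrs["ridge"] = ld.ridge
        f.attrs["trace_original"] = ld.trace_original
        f.create_dataset("snp_ids", data=np.array(ld.snp_ids, dtype="S"))


def load_lowrank_h5(path: str) -> LowRankLD:
    import h5py

    with h5py.File(path, "r") as f:
        return LowRankLD(
            A=f["A"][()],
            ridge=float(f.attrs["ridge"]),
            trace_original=float(f.attrs["trace_original"]),
            snp_ids=[s.decode() for s in f["snp_ids"][()]],
        )
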