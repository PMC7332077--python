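"""Directed-predictor evaluation, cis-heritability, and selection metrics.

The directed predictor for a test gene uses only the fitted global annotation
weights: eta_i = (omega^T v_i)(nu^T f_i) is the annotation-implied prior mean
of SNP i's effect, mu = X eta the implied expression prediction. With y
standardized so y^T y = n, MSE^dir = ||y - mu||^2 / n equals 1 for a useless
predictor, and its summary-statistics form is

    MSE^dir = 1 - 2 eta^T z + eta^T Sigma eta,    z = X^T y / n,

which agrees with the individual-level definition exactly when Sigma and z
come from the same data (this fixes the normalization: with z defined as
X^T y / n, no further 1/n enters the cross term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ld import GenotypeBlock, LowRankLD


@dataclass
class DirectedPredictor:
    """Per-gene directed prediction and its accuracy."""

    eta_hat: np.ndarray
    S: float  # squared magnitude mu^T mu
    mse_dir: float
    mu_hat: np.ndarray | None = None  # individual mode only

    @property
    def S_over_n(self) -> float:
        return self._s_over_n

    def __post_init__(self) -> None:
        self._s_over_n = np.nan


@dataclass
class HEResult:
    """Haseman-Elston estimate of additive genetic variance in cis."""

    sigma2_g_cis: float
    se: float


def directed_mean(omega_hat: np.ndarray, nu_hat: np.ndarray, V: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Annotation-implied prior mean shift eta_i = (omega^T v_i)(nu^T f_i)."""
    V = np.asarray(V, dtype=float)
    F = np.asarray(F, dtype=float)
    if V.shape[1] != len(omega_hat) or F.shape[1] != len(nu_hat) or V.shape[0] != F.shape[0]:
        raise ValueError("dimension mismatch between annotations and weights")
    return (V @ np.asarray(omega_hat)) * (F @ np.asarray(nu_hat))


def mse_dir_individual(y: np.ndarray, block: GenotypeBlock, eta_hat: np.ndarray) -> DirectedPredictor:
    """Directed MSE from individual-level data; y must satisfy y^T y = n."""
    y = np.asarray(y, dtype=float)
    n = block.n
    mu = block.X @ np.asarray(eta_hat, dtype=float)
    resid = y - mu
    pred = DirectedPredictor(
        eta_hat=np.asarray(eta_hat, dtype=float),
        S=float(mu @ mu),
        mse_dir=float(resid @ resid) / n,
        mu_hat=mu,
    )
    pred._s_over_n = pred.S / n
    return pred


def mse_dir_summary(
    z: np.ndarray, sigma: np.ndarray | LowRankLD, eta_hat: np.ndarray, n: int
) -> DirectedPredictor:
    """Directed MSE from summary statistics (z = X^T y / n, Sigma = X^T X / n).

    Assumes the source study standardized y so that y^T y = n. The summary-mode
    squared magnitude is S = n * eta^T Sigma eta.
    """
    eta = np.asarray(eta_hat, dtype=float)
    z = np.asarray(z, dtype=float)
    sig_eta = sigma.dense() @ eta if isinstance(sigma, LowRankLD) else np.asarray(sigma) @ eta
    quad = float(eta @ sig_eta)
    mse = 1.0 - 2.0 * float(eta @ z) + quad
    pred = DirectedPredictor(eta_hat=eta, S=float(n * quad), mse_dir=mse)
    pred._s_over_n = quad
    return pred


def he_cis_h2(y: np.ndarray, block: GenotypeBlock) -> HEResult:
    """Haseman-Elston regression estimate of cis genetic variance.

    Regresses off-diagonal phenotype cross-products y_i y_k on the cis GRM
    G = X X^T / m (X column-standardized, y variance-standardized). The slope
    is the additive genetic variance fraction; the standard error is a
    leave-one-sample-out jackknife.
    """
    y = np.asarray(y, dtype=float)
    n = block.n
    if n < 30:
        raise ValueError("need at least 30 samples for HE regression")
    y = y - y.mean()
    y = y / y.std()
    G = block.X @ block.X.T / block.m
    iu = np.triu_indices(n, k=1)
    g = G[iu]
    yy = (np.outer(y, y))[iu]
    denom = float(g @ g)
    if denom <= 0:
        raise ValueError("degenerate GRM")
    slope = float(g @ yy) / denom

    # delete-one-sample jackknife via downdating of the two sums
    num_total = float(g @ yy)
    den_total = denom
    Gy = (G * np.outer(y, y)).sum(axis=1)  # includes diagonal
    G2 = (G * G).sum(axis=1)
    diag_gy = np.diag(G) * y * y
    diag_g2 = np.diag(G) ** 2
    loo = np.empty(n)
    for i in range(n):
        num_i = num_total - (Gy[i] - diag_gy[i])
        den_i = den_total - (G2[i] - diag_g2[i])
        loo[i] = num_i / den_i
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    return HEResult(sigma2_g_cis=slope, se=max(se, np.finfo(float).tiny))


def sliding_window_summary(
    per_gene: list[tuple[float, float]],
    window_fraction: float = 0.25,
    step_fraction: float = 0.05,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean directed MSE within sliding windows of genes ranked by S.

    Genes are sorted by predictor size S; each window holds
    ``window_fraction`` of genes and advances by ``step_fraction``. Bootstrap
    95% confidence intervals resample genes within each window.
    """
    G = len(per_gene)
    w = int(np.floor(G * window_fraction))
    step = int(np.floor(G * step_fraction))
    if w < 1 or step < 1 or G < w:
        raise ValueError("too few genes for the requested window")
    arr = np.asarray(per_gene, dtype=float)
    order = np.argsort(arr[:, 0])
    arr = arr[order]
    rng = np.random.default_rng(seed)
    rows = []
    for start in range(0, G - w + 1, step):
        S_win = arr[start : start + w, 0]
        mse_win = arr[start : start + w, 1]
        boots = mse_win[rng.integers(0, w, size=(n_boot, w))].mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {
                "window_start": start,
                "mean_S": S_win.mean(),
                "mean_mse_dir": mse_win.mean(),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def rescale_omega(
    omega_hat: np.ndarray,
    nu_hat: np.ndarray,
    nu_true: np.ndarray,
    coverage: np.ndarray,
) -> np.ndarray:
    """Put fitted directed effects on the true nu scale.

    The product (omega^T v)(nu^T f) is invariant to reciprocal rescalings of
    omega and nu, so omega-hat is comparable to the truth only after fixing
    the nu scale: each nu element is weighted by the SNP coverage of its
    window column and summed, for the estimate and the truth; their ratio
    rescales omega-hat.
    """
    coverage = np.asarray(coverage, dtype=float)
    scale_hat = float(coverage @ np.asarray(nu_hat))
    scale_true = float(coverage @ np.asarray(nu_true))
    if scale_true == 0:
        raise ValueError("true nu scale is zero")
    return np.asarray(omega_hat) * (scale_hat / scale_true)


def selection_metrics(
    omega_hat: np.ndarray,
    nu_hat: np.ndarray,
    nu_true: np.ndarray,
    coverage: np.ndarray,
    true_support: set[int],
    threshold: float = 0.01,
) -> tuple[float, float]:
    """Precision and recall of annotation selection at a scaled-effect threshold.

    Positives are annotations whose rescaled |omega-hat| exceeds ``threshold``.
    With no positives, precision is 1 by convention; recall is 0 for nonempty
    truth.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    scaled = rescale_omega(omega_hat, nu_hat, nu_true, coverage)
    positives = set(np.flatnonzero(np.abs(scaled) > threshold).tolist())
    tp = len(positives & true_support)
    precision = tp / len(positives) if positives else 1.0
    recall = tp / len(true_support) if true_support else 1.0
    return precision, recall


def predictor_sign_agreement(
    scores: list[float], strata_S: list[float] | None = None, top_fraction: float | None = None
) -> float:
    """Fraction of genes whose prediction points the right way.

    ``scores`` holds y^T mu per gene (summary mode: eta^T z). When ``strata_S``
    and ``top_fraction`` are given, only genes in the top fraction by S count.
    """
    scores = np.asarray(scores, dtype=float)
    if strata_S is not None and top_fraction is not None:
        S = np.asarray(strata_S, dtype=float)
        cut = np.quantile(S, 1.0 - top_fraction)
        scores = scores[S >= cut]
    if scores.size == 0:
        raise ValueError("no genes in stratum")
    return float(np.mean(scores > 0))
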