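"""Variational message-passing inference for the hierarchical cis-eQTL model.

Model (per gene j with m_j SNPs, n samples):

    y_j   = X_j b_j + eps_j,            eps_j ~ N(0, lambda_j^-1 I)
    b_ij  ~ N((omega^T v_ij)(nu^T f_ij), alpha_ij^-1)
    omega ~ N(0, diag(delta)^-1),       delta_i = prod_l upsilon^l_{d^l_i}
    nu    ~ N(c, diag(p)^-1)            (intercept pinned near 1 via p, c)
    alpha_ij ~ Gamma(gamma1, kappa_j * gamma_ij),  gamma_ij = prod_{k: C_ik=1} a_k

with conjugate Gamma hyperpriors on lambda_j (rate lambda2), upsilon (rate
chi2l), kappa_j (rate tau2), and a_k; lambda2, chi2l, tau2 carry their own
Gamma priors. Directed-annotation effects omega get group-structured shrinkage
through the meta-annotation partition (group-lasso-like); giving every
annotation its own group recovers a lasso-like setting; per-SNP Gamma
precisions alpha implement automatic relevance determination (integrating
them out yields t-distributed, sparse effect estimates).

Inference is mean-field coordinate ascent. Every factor update is the exact
conjugate-exponential optimum, so the evidence lower bound (ELBO) is
non-decreasing across sweeps — the engine's core correctness invariant.

The engine operates on per-gene sufficient statistics X^T X (= n Sigma),
X^T y (= n z) and y^T y. Individual-level and summary-statistics inputs map
onto the same statistics (summary mode sets y^T y = n, the standardization
the evaluation assumes), so the two modes run identical updates whenever
Sigma and z derive from the same data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import digamma, gammaln

from .annotations import MetaAnnotationPartition
from .ld import GenotypeBlock, LowRankLD, SummaryStats, standardize_expression

logger = logging.getLogger(__name__)

#: Precision used to pin a factor "close to" a constrained value.
PIN_PRECISION = 1e6

#: An ELBO decrease larger than this (relative) aborts the fit.
ELBO_DIVERGENCE_TOL = 1e-6

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class Hyperparameters:
    """Fixed scalars of the hierarchical priors.

    Shape/rate pairs default to weakly informative Gamma(0.01, 0.01)-style
    values. ``p_intercept``/``c_intercept`` pin the distance-modifier
    intercept near 1; ``p_other`` is the prior precision of the remaining
    distance-window weights whose prior mean is ``c_other`` (0 by default,
    0.3 as the consistently-positive-sign variant).
    """

    lambda1: float = 0.01
    rho1: float = 0.01
    rho2: float = 0.01
    chi1: float = 0.01
    zeta1: float = 0.01
    zeta2: float = 0.01
    gamma1: float = 0.01
    tau1: float = 0.01
    xi1: float = 0.01
    xi2: float = 0.01
    phi1: float = 0.01
    phi2: float = 0.01
    p_intercept: float = PIN_PRECISION
    c_intercept: float = 1.0
    p_other: float = 1.0
    c_other: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda1", "rho1", "rho2", "chi1", "zeta1", "zeta2", "gamma1",
                     "tau1", "xi1", "xi2", "phi1", "phi2", "p_intercept", "p_other"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be strictly positive")

    def nu_prior(self, q: int, intercept_column: int = 0) -> tuple[np.ndarray, np.ndarray]:
        p = np.full(q, self.p_other)
        c = np.full(q, self.c_other)
        p[intercept_column] = self.p_intercept
        c[intercept_column] = self.c_intercept
        return p, c


@dataclass
class FitConfig:
    mode: Literal["individual", "summary"] = "individual"
    prior_setting: Literal["group_lasso", "lasso", "uninformed"] = "group_lasso"
    iterations: int = 300
    seed: int = 0
    cis_window: int = 150_000
    gene_p_threshold: float | None = None
    nu_prior_mean: float | None = None  # overrides hyper.c_other when set
    distance_modifier: bool = True  # False pins non-intercept nu at 0 (ablation)
    early_stop_tol: float | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class GeneData:
    """Per-gene sufficient statistics plus annotation matrices."""

    gene_id: str
    XtX: np.ndarray  # m x m, equals n * Sigma
    Xty: np.ndarray  # m, equals n * z
    yty: float
    n: int
    V: np.ndarray  # m x s directed annotations
    F: np.ndarray  # m x q undirected (mean) annotations
    C: np.ndarray | None = None  # m x t precision annotations
    chrom: int | str | None = None
    lowrank: LowRankLD | None = None  # when set, b-updates use Woodbury
    dof: int | None = None  # Gaussian dimension of the likelihood (defaults to n)

    def __post_init__(self) -> None:
        if self.dof is None:
            self.dof = self.n

    @property
    def m(self) -> int:
        return self.Xty.shape[0]

    @classmethod
    def from_individual(
        cls,
        gene_id: str,
        block: GenotypeBlock,
        y: np.ndarray,
        V: np.ndarray,
        F: np.ndarray,
        C: np.ndarray | None = None,
        chrom=None,
        standardize: bool = True,
    ) -> "GeneData":
        y = standardize_expression(y) if standardize else np.asarray(y, dtype=float)
        return cls(
            gene_id=gene_id,
            XtX=block.X.T @ block.X,
            Xty=block.X.T @ y,
            yty=float(y @ y),
            n=block.n,
            V=np.asarray(V, dtype=float),
            F=np.asarray(F, dtype=float),
            C=None if C is None else np.asarray(C, dtype=float),
            chrom=chrom,
        )

    @classmethod
    def from_summary(
        cls,
        gene_id: str,
        stats: SummaryStats,
        V: np.ndarray,
        F: np.ndarray,
        C: np.ndarray | None = None,
        chrom=None,
    ) -> "GeneData":
        n = stats.n
        lowrank = stats.ld if isinstance(stats.ld, LowRankLD) else None
        sigma = stats.ld_dense()
        m = stats.z.shape[0]
        if lowrank is None:
            # Study LD: z and Sigma are mutually consistent, so the residual
            # reconstruction with the y^T y = n standardization is exact.
            yty, dof = float(n), n
        else:
            # Approximated / external LD: z need not be consistent with Sigma,
            # so use the summary likelihood z ~ N(Sigma b, lambda^-1 Sigma / n)
            # directly; its quadratic constant is n z^T Sigma^-1 z with m
            # Gaussian degrees of freedom.
            from .ld import woodbury_inverse

            if lowrank.ridge > 0:
                apply_inv = woodbury_inverse(
                    np.full(m, lowrank.ridge), lowrank.A, 1.0, dense=False
                )
                yty = float(n * stats.z @ apply_inv(stats.z))
            else:
                yty = float(n * stats.z @ np.linalg.pinv(sigma) @ stats.z)
            dof = m
        return cls(
            gene_id=gene_id,
            XtX=n * sigma,
            Xty=n * stats.z,
            yty=yty,
            n=n,
            dof=dof,
            V=np.asarray(V, dtype=float),
            F=np.asarray(F, dtype=float),
            C=None if C is None else np.asarray(C, dtype=float),
            chrom=chrom,
            lowrank=lowrank,
        )


def _gamma_entropy(shape, rate):
    shape = np.asarray(shape, dtype=float)
    rate = np.asarray(rate, dtype=float)
    return shape - np.log(rate) + gammaln(shape) + (1.0 - shape) * digamma(shape)


def _gamma_cross(shape_p, rate_p_mean, rate_p_logmean, e_x, e_logx):
    """E[log Gamma(x; shape_p, rate_p)] with a (possibly random) rate.

    ``rate_p_mean``/``rate_p_logmean`` are E[rate] and E[log rate].
    """
    return (
        shape_p * rate_p_logmean
        - gammaln(shape_p)
        + (shape_p - 1.0) * e_logx
        - rate_p_mean * e_x
    )


@dataclass
class PosteriorState:
    """Variational moments of every factor plus the ELBO trace."""

    genes: list[GeneData]
    partition: MetaAnnotationPartition | None
    hyper: Hyperparameters
    config: FitConfig
    # per-SNP flat arrays (concatenated across genes)
    b_mean: np.ndarray = field(default=None)
    b_diag: np.ndarray = field(default=None)
    alpha_shape: float = 0.0
    alpha_rate: np.ndarray = field(default=None)
    # per-gene arrays
    lambda_shape: np.ndarray = field(default=None)
    lambda_rate: np.ndarray = field(default=None)
    kappa_shape: np.ndarray = field(default=None)
    kappa_rate: np.ndarray = field(default=None)
    # global factors
    omega_mean: np.ndarray = field(default=None)
    omega_cov: np.ndarray = field(default=None)
    nu_mean: np.ndarray = field(default=None)
    nu_cov: np.ndarray = field(default=None)
    ups_shape: list[np.ndarray] = field(default_factory=list)
    ups_rate: list[np.ndarray] = field(default_factory=list)
    chi2_shape: np.ndarray = field(default=None)
    chi2_rate: np.ndarray = field(default=None)
    lambda2_shape: float = 0.0
    lambda2_rate: float = 0.0
    tau2_shape: float = 0.0
    tau2_rate: float = 0.0
    a_shape: np.ndarray = field(default=None)
    a_rate: np.ndarray = field(default=None)
    iteration: int = 0
    elbo_trace: list[float] = field(default_factory=list)
    # bookkeeping
    slices: list[slice] = field(default_factory=list)
    fitted: bool = False

    # ----- expectations -----
    def e_lambda(self):
        return self.lambda_shape / self.lambda_rate

    def e_alpha(self):
        return self.alpha_shape / self.alpha_rate

    def e_kappa(self):
        return self.kappa_shape / self.kappa_rate

    def e_upsilon(self, l):
        return self.ups_shape[l] / self.ups_rate[l]

    def e_a(self):
        if self.a_shape is None:
            return None
        return self.a_shape / self.a_rate

    def gene_index(self, gene_id: str) -> int:
        for i, g in enumerate(self.genes):
            if g.gene_id == gene_id:
                return i
        raise KeyError(f"unknown gene {gene_id!r}")

    def gene_b_mean(self, gene_id: str) -> np.ndarray:
        i = self.gene_index(gene_id)
        return self.b_mean[self.slices[i]].copy()


class _Engine:
    """Owns the flat work arrays and implements one coordinate-ascent sweep."""

    def __init__(self, genes, partition, hyper, config):
        self.genes = genes
        self.hyper = hyper
        self.config = config
        self.G = len(genes)
        s = genes[0].V.shape[1]
        q = genes[0].F.shape[1]
        for g in genes:
            if g.V.shape[1] != s or g.F.shape[1] != q:
                raise ValueError("all genes must share the same annotation columns")
        self.s, self.q = s, q
        self.uninformed = config.prior_setting == "uninformed"
        if config.prior_setting == "lasso" or partition is None:
            partition = MetaAnnotationPartition(d=[np.arange(1, s + 1)])
        self.partition = partition

        # flatten SNP-level structures
        offs = np.cumsum([0] + [g.m for g in genes])
        self.slices = [slice(offs[i], offs[i + 1]) for i in range(self.G)]
        self.gene_of = np.concatenate([np.full(g.m, i) for i, g in enumerate(genes)])
        self.M = offs[-1]
        self.V = np.concatenate([g.V for g in genes], axis=0)
        self.F = np.concatenate([g.F for g in genes], axis=0)
        self.has_C = genes[0].C is not None and not self.uninformed
        if self.has_C:
            self.C = np.concatenate([g.C for g in genes], axis=0)
            self.t = self.C.shape[1]
        else:
            self.C = None
            self.t = 0

        h = hyper
        st = PosteriorState(genes=genes, partition=self.partition, hyper=h, config=config)
        st.slices = self.slices
        # --- initialization: omega = 0, nu = prior mean, Gammas at prior means,
        # b at a unit-prior-variance ridge solution ---
        st.omega_mean = np.zeros(s)
        st.omega_cov = np.eye(s)
        p_nu, c_nu = h.nu_prior(q)
        if config.nu_prior_mean is not None and q > 1:
            c_nu[1:] = config.nu_prior_mean
        if not config.distance_modifier and q > 1:
            p_nu[1:] = PIN_PRECISION
            c_nu[1:] = 0.0
        self.p_nu, self.c_nu = p_nu, c_nu
        st.nu_mean = c_nu.copy()
        st.nu_cov = np.diag(1.0 / p_nu)
        st.lambda2_shape, st.lambda2_rate = h.rho1, h.rho2
        st.tau2_shape, st.tau2_rate = h.xi1, h.xi2
        st.alpha_shape = h.gamma1 + 0.5
        st.alpha_rate = np.full(self.M, h.gamma1 + 0.5)  # E[alpha] = 1 at start
        st.lambda_shape = h.lambda1 + np.array([g.dof for g in genes]) / 2.0
        st.lambda_rate = st.lambda_shape.copy()  # E[lambda] = 1 at start
        st.kappa_shape = np.array([h.tau1 + g.m * h.gamma1 for g in genes])
        st.kappa_rate = st.kappa_shape.copy()
        if not self.uninformed:
            st.ups_shape = [np.full(hl, h.chi1) for hl in self.partition.h]
            st.ups_rate = [np.full(hl, h.chi1) for hl in self.partition.h]  # E[ups]=1
            st.chi2_shape = np.full(self.partition.w, h.zeta1)
            st.chi2_rate = np.full(self.partition.w, h.zeta1)  # E[chi2]=1
        if self.has_C:
            st.a_shape = np.full(self.t, h.phi1)
            st.a_rate = np.full(self.t, h.phi1)  # E[a]=1
        st.b_mean = np.zeros(self.M)
        st.b_diag = np.zeros(self.M)
        self.state = st
        self._stat_quad = np.zeros(self.G)  # m^T XtX m per gene
        self._stat_trace = np.zeros(self.G)  # tr(XtX S) per gene
        self._stat_logdetS = np.zeros(self.G)
        for i, g in enumerate(genes):
            P = g.XtX + np.eye(g.m)
            L = np.linalg.cholesky(P)
            S = np.linalg.inv(P)
            mean = S @ g.Xty
            sl = self.slices[i]
            st.b_mean[sl] = mean
            st.b_diag[sl] = np.diag(S)
            self._stat_quad[i] = mean @ g.XtX @ mean
            self._stat_trace[i] = float(np.sum(g.XtX * S))
            self._stat_logdetS[i] = -2.0 * np.sum(np.log(np.diag(L)))
        # annotation moment caches (refreshed each sweep)
        self._refresh_eta_caches()

    # ---- cached annotation moments under current q(omega), q(nu) ----
    def _refresh_eta_caches(self):
        st = self.state
        Eww = np.outer(st.omega_mean, st.omega_mean) + st.omega_cov
        Enn = np.outer(st.nu_mean, st.nu_mean) + st.nu_cov
        self.vbar = self.V @ st.omega_mean
        self.fbar = self.F @ st.nu_mean
        self.qv = np.einsum("ms,ms->m", self.V @ Eww, self.V)
        self.qf = np.einsum("mq,mq->m", self.F @ Enn, self.F)

    def e_delta(self):
        st = self.state
        if self.uninformed:
            return np.full(self.s, PIN_PRECISION), np.full(self.s, np.log(PIN_PRECISION))
        ed = np.ones(self.s)
        eld = np.zeros(self.s)
        for l, dl in enumerate(self.partition.d):
            eu = st.e_upsilon(l)
            elu = digamma(st.ups_shape[l]) - np.log(st.ups_rate[l])
            ed *= eu[dl - 1]
            eld += elu[dl - 1]
        return ed, eld

    def e_gamma(self):
        st = self.state
        if not self.has_C:
            return np.ones(self.M), np.zeros(self.M)
        ea = st.e_a()
        ela = digamma(st.a_shape) - np.log(st.a_rate)
        return np.exp(self.C @ np.log(ea)), self.C @ ela

    # ---- one full coordinate-ascent sweep ----
    def sweep(self):
        st, h = self.state, self.hyper
        e_lam = st.e_lambda()
        e_alpha = st.e_alpha()
        e_lambda2 = st.lambda2_shape / st.lambda2_rate
        e_tau2 = st.tau2_shape / st.tau2_rate
        e_gamma, _ = self.e_gamma()
        eta_bar = self.vbar * self.fbar

        # --- per-gene factors ---
        for i, g in enumerate(self.genes):
            sl = self.slices[i]
            alpha_g = e_alpha[sl]
            hvec = e_lam[i] * g.Xty + alpha_g * eta_bar[sl]
            if g.lowrank is not None:
                mean, diagS, trXtXS, logdetS = self._b_update_lowrank(g, e_lam[i], alpha_g, hvec)
            else:
                P = e_lam[i] * g.XtX + np.diag(alpha_g)
                L = np.linalg.cholesky(P)
                S = np.linalg.inv(P)
                S = (S + S.T) / 2.0
                mean = S @ hvec
                diagS = np.diag(S)
                trXtXS = float(np.sum(g.XtX * S))
                logdetS = -2.0 * float(np.sum(np.log(np.diag(L))))
            st.b_mean[sl] = mean
            st.b_diag[sl] = diagS
            self._stat_quad[i] = mean @ g.XtX @ mean
            self._stat_trace[i] = trXtXS
            self._stat_logdetS[i] = logdetS

        # alpha (flat across genes)
        e_kappa = st.e_kappa()
        eb2 = st.b_mean**2 + st.b_diag
        resid2 = eb2 - 2.0 * st.b_mean * eta_bar + self.qv * self.qf
        st.alpha_rate = e_kappa[self.gene_of] * e_gamma + 0.5 * resid2
        e_alpha = st.e_alpha()

        # lambda_j
        R = np.array(
            [
                g.yty - 2.0 * st.b_mean[self.slices[i]] @ g.Xty
                + self._stat_quad[i] + self._stat_trace[i]
                for i, g in enumerate(self.genes)
            ]
        )
        self._R = R
        st.lambda_rate = e_lambda2 + 0.5 * R
        e_lam = st.e_lambda()

        # kappa_j
        ga = e_gamma * e_alpha
        st.kappa_rate = e_tau2 + np.bincount(self.gene_of, weights=ga, minlength=self.G)
        e_kappa = st.e_kappa()

        # --- global factors ---
        # omega
        e_delta, _ = self.e_delta()
        coef = e_alpha * self.qf
        P_om = (self.V.T * coef) @ self.V
        P_om[np.diag_indices_from(P_om)] += e_delta
        h_om = self.V.T @ (e_alpha * st.b_mean * self.fbar)
        L = np.linalg.cholesky(P_om)
        st.omega_cov = np.linalg.inv(P_om)
        st.omega_cov = (st.omega_cov + st.omega_cov.T) / 2.0
        st.omega_mean = st.omega_cov @ h_om
        self._logdet_omega_cov = -2.0 * float(np.sum(np.log(np.diag(L))))

        # nu (with fresh omega moments)
        Eww = np.outer(st.omega_mean, st.omega_mean) + st.omega_cov
        self.vbar = self.V @ st.omega_mean
        self.qv = np.einsum("ms,ms->m", self.V @ Eww, self.V)
        coef = e_alpha * self.qv
        P_nu = (self.F.T * coef) @ self.F
        P_nu[np.diag_indices_from(P_nu)] += self.p_nu
        h_nu = self.p_nu * self.c_nu + self.F.T @ (e_alpha * st.b_mean * self.vbar)
        L = np.linalg.cholesky(P_nu)
        st.nu_cov = np.linalg.inv(P_nu)
        st.nu_cov = (st.nu_cov + st.nu_cov.T) / 2.0
        st.nu_mean = st.nu_cov @ h_nu
        self._logdet_nu_cov = -2.0 * float(np.sum(np.log(np.diag(L))))
        Enn = np.outer(st.nu_mean, st.nu_mean) + st.nu_cov
        self.fbar = self.F @ st.nu_mean
        self.qf = np.einsum("mq,mq->m", self.F @ Enn, self.F)

        # upsilon / chi2 per meta-annotation
        if not self.uninformed:
            eo2 = st.omega_mean**2 + np.diag(st.omega_cov)
            for l, dl in enumerate(self.partition.d):
                other = np.ones(self.s)
                for l2, dl2 in enumerate(self.partition.d):
                    if l2 != l:
                        other *= st.e_upsilon(l2)[dl2 - 1]
                hl = self.partition.h[l]
                cnt = np.bincount(dl - 1, minlength=hl)
                e_chi2 = st.chi2_shape[l] / st.chi2_rate[l]
                st.ups_shape[l] = h.chi1 + cnt / 2.0
                st.ups_rate[l] = e_chi2 + 0.5 * np.bincount(
                    dl - 1, weights=eo2 * other, minlength=hl
                )
                st.chi2_shape[l] = h.zeta1 + hl * h.chi1
                st.chi2_rate[l] = h.zeta2 + st.e_upsilon(l).sum()

        # a_k (precision annotations)
        if self.has_C:
            ek_snp = e_kappa[self.gene_of]
            for k in range(self.t):
                mask = self.C[:, k] == 1.0
                nk = float(mask.sum())
                ea = st.e_a()
                other = np.exp(self.C[mask] @ np.log(ea)) / ea[k]
                st.a_shape[k] = h.phi1 + h.gamma1 * nk
                st.a_rate[k] = h.phi2 + np.sum(ek_snp[mask] * e_alpha[mask] * other)

        # tau2, lambda2
        st.tau2_shape = h.xi1 + self.G * h.tau1
        st.tau2_rate = h.xi2 + e_kappa.sum()
        st.lambda2_shape = h.rho1 + self.G * h.lambda1
        st.lambda2_rate = h.rho2 + e_lam.sum()

        st.iteration += 1

    def _b_update_lowrank(self, g, elam, alpha_g, hvec):
        """Woodbury-based q(b) update for a gene with factorized LD.

        Precision = elam * n * (A^T A + ridge I) + diag(alpha)
                  = c A^T A + D with c = elam * n, D = diag(alpha + c * ridge).
        """
        from .ld import woodbury_inverse

        c = elam * g.n
        D = alpha_g + c * g.lowrank.ridge
        A = g.lowrank.A
        S = woodbury_inverse(D, A, c, dense=True)
        S = (S + S.T) / 2.0
        mean = S @ hvec
        trXtXS = float(np.sum(g.XtX * S))
        # log det via the matrix determinant lemma
        r = A.shape[0]
        inner = np.eye(r) + c * (A / D) @ A.T
        sign, logdet_inner = np.linalg.slogdet(inner)
        logdetP = float(np.sum(np.log(D)) + logdet_inner)
        return mean, np.diag(S), trXtXS, -logdetP

    # ---- evidence lower bound ----
    def elbo(self) -> float:
        st, h = self.state, self.hyper
        e_lam = st.e_lambda()
        el_lam = digamma(st.lambda_shape) - np.log(st.lambda_rate)
        e_alpha = st.e_alpha()
        el_alpha = digamma(st.alpha_shape) - np.log(st.alpha_rate)
        e_kappa = st.e_kappa()
        el_kappa = digamma(st.kappa_shape) - np.log(st.kappa_rate)
        e_lambda2 = st.lambda2_shape / st.lambda2_rate
        el_lambda2 = digamma(st.lambda2_shape) - np.log(st.lambda2_rate)
        e_tau2 = st.tau2_shape / st.tau2_rate
        el_tau2 = digamma(st.tau2_shape) - np.log(st.tau2_rate)
        e_gamma, el_gamma = self.e_gamma()
        e_delta, el_delta = self.e_delta()

        total = 0.0
        # 1. likelihood (Gaussian dimension = dof; n for individual data,
        # m for the summary formulation with approximated LD)
        ns = np.array([g.dof for g in self.genes], dtype=float)
        R = np.array(
            [
                g.yty - 2.0 * st.b_mean[self.slices[i]] @ g.Xty
                + self._stat_quad[i] + self._stat_trace[i]
                for i, g in enumerate(self.genes)
            ]
        )
        total += float(np.sum(0.5 * ns * el_lam - 0.5 * ns * LOG2PI - 0.5 * e_lam * R))
        # 2. p(b | omega, nu, alpha)
        eb2 = st.b_mean**2 + st.b_diag
        eta_bar = self.vbar * self.fbar
        resid2 = eb2 - 2.0 * st.b_mean * eta_bar + self.qv * self.qf
        total += float(np.sum(0.5 * el_alpha - 0.5 * LOG2PI - 0.5 * e_alpha * resid2))
        # 3. p(alpha | gamma1, kappa gamma)
        total += float(
            np.sum(
                h.gamma1 * (el_kappa[self.gene_of] + el_gamma)
                - gammaln(h.gamma1)
                + (h.gamma1 - 1.0) * el_alpha
                - e_kappa[self.gene_of] * e_gamma * e_alpha
            )
        )
        # 4-5. p(lambda_j | lambda2), p(lambda2)
        total += float(np.sum(_gamma_cross(h.lambda1, e_lambda2, el_lambda2, e_lam, el_lam)))
        total += float(_gamma_cross(h.rho1, h.rho2, np.log(h.rho2), e_lambda2, el_lambda2))
        # 6-7. p(kappa_j | tau2), p(tau2)
        total += float(np.sum(_gamma_cross(h.tau1, e_tau2, el_tau2, e_kappa, el_kappa)))
        total += float(_gamma_cross(h.xi1, h.xi2, np.log(h.xi2), e_tau2, el_tau2))
        # 8. p(a_k)
        if self.has_C:
            ea = st.e_a()
            ela = digamma(st.a_shape) - np.log(st.a_rate)
            total += float(np.sum(_gamma_cross(h.phi1, h.phi2, np.log(h.phi2), ea, ela)))
        # 9. p(omega | delta)
        eo2 = st.omega_mean**2 + np.diag(st.omega_cov)
        total += float(np.sum(0.5 * el_delta - 0.5 * LOG2PI - 0.5 * e_delta * eo2))
        # 10-11. p(upsilon | chi2), p(chi2)
        if not self.uninformed:
            for l in range(self.partition.w):
                eu = st.e_upsilon(l)
                elu = digamma(st.ups_shape[l]) - np.log(st.ups_rate[l])
                e_chi2 = st.chi2_shape[l] / st.chi2_rate[l]
                el_chi2 = digamma(st.chi2_shape[l]) - np.log(st.chi2_rate[l])
                total += float(np.sum(_gamma_cross(h.chi1, e_chi2, el_chi2, eu, elu)))
                total += float(_gamma_cross(h.zeta1, h.zeta2, np.log(h.zeta2), e_chi2, el_chi2))
        # 12. p(nu)
        en2 = st.nu_mean**2 + np.diag(st.nu_cov)
        total += float(
            np.sum(
                0.5 * np.log(self.p_nu)
                - 0.5 * LOG2PI
                - 0.5 * self.p_nu * (en2 - 2.0 * self.c_nu * st.nu_mean + self.c_nu**2)
            )
        )

        # entropies
        ms = np.array([g.m for g in self.genes], dtype=float)
        total += float(np.sum(0.5 * ms * (1.0 + LOG2PI) + 0.5 * self._stat_logdetS))
        total += 0.5 * self.s * (1.0 + LOG2PI) + 0.5 * self._logdet_omega_cov
        total += 0.5 * self.q * (1.0 + LOG2PI) + 0.5 * self._logdet_nu_cov
        total += float(np.sum(_gamma_entropy(st.alpha_shape, st.alpha_rate)))
        total += float(np.sum(_gamma_entropy(st.lambda_shape, st.lambda_rate)))
        total += float(np.sum(_gamma_entropy(st.kappa_shape, st.kappa_rate)))
        total += float(_gamma_entropy(st.lambda2_shape, st.lambda2_rate))
        total += float(_gamma_entropy(st.tau2_shape, st.tau2_rate))
        if self.has_C:
            total += float(np.sum(_gamma_entropy(st.a_shape, st.a_rate)))
        if not self.uninformed:
            for l in range(self.partition.w):
                total += float(np.sum(_gamma_entropy(st.ups_shape[l], st.ups_rate[l])))
                total += float(_gamma_entropy(st.chi2_shape[l], st.chi2_rate[l]))
        if not np.isfinite(total):
            raise FloatingPointError("non-finite ELBO")
        return total


def fit(
    genes: list[GeneData],
    hyper: Hyperparameters | None = None,
    config: FitConfig | None = None,
    partition: MetaAnnotationPartition | None = None,
) -> PosteriorState:
    """Run coordinate-ascent variational inference for ``config.iterations`` sweeps.

    Update order per sweep: per-gene factors (b_j, alpha_j, lambda_j, kappa_j)
    in a deterministic gene order, then the global factors
    (omega, nu, upsilon^l, chi2l, a, tau2, lambda2). The ELBO is recorded after
    every sweep; a decrease beyond tolerance aborts with a diagnostic dump.
    """
    hyper = hyper or Hyperparameters()
    config = config or FitConfig()
    if not genes:
        raise ValueError("no genes to fit")
    eng = _Engine(genes, partition, hyper, config)
    st = eng.state
    prev = -np.inf
    for it in range(config.iterations):
        eng.sweep()
        val = eng.elbo()
        st.elbo_trace.append(val)
        if np.isfinite(prev):
            scale = max(abs(prev), 1.0)
            if val < prev - ELBO_DIVERGENCE_TOL * scale:
                logger.error("ELBO decreased at sweep %d: %.10g -> %.10g", it, prev, val)
                raise FloatingPointError(
                    f"divergent ELBO at sweep {it}: {prev:.10g} -> {val:.10g}; "
                    f"state dumped at iteration {st.iteration}"
                )
            if config.early_stop_tol is not None and abs(val - prev) < config.early_stop_tol * scale:
                logger.info("early stop at sweep %d (relative ELBO change below tol)", it)
                break
        prev = val
    st.fitted = True
    return st


def prior_variance_modifiers(state: PosteriorState) -> list[np.ndarray]:
    """Posterior variance modifiers 1 / E[upsilon] per group per meta-annotation.

    Large modifiers mark annotation groups allowed large directed effects.
    Figures conventionally display their square roots.
    """
    if not state.fitted:
        raise ValueError("state is not fitted")
    if state.config.prior_setting == "uninformed" or not state.ups_shape:
        raise ValueError("no variance modifiers in uninformed mode")
    return [1.0 / state.e_upsilon(l) for l in range(len(state.ups_shape))]


def snp_prior_second_moment(state: PosteriorState, gene: GeneData) -> tuple[np.ndarray, int]:
    """Prior second moment of b_ij given the fitted global factors.

    E[b^2 | globals] = ((omega^T v)(nu^T f))^2 + plug-in prior variance
    E[kappa] E[gamma] / gamma1 (the inverse of the prior-mean ARD precision).
    Returns the per-SNP vector and the argmax index (ties -> lowest index).
    """
    if not state.fitted:
        raise ValueError("state is not fitted")
    if gene.V.shape[0] != gene.F.shape[0]:
        raise ValueError("annotation row count mismatch")
    eta = (gene.V @ state.omega_mean) * (gene.F @ state.nu_mean)
    e_kappa_prior = state.tau2_rate / state.tau2_shape * state.hyper.tau1  # hierarchy mean
    # plug-in E[1/alpha]: rate / shape of the prior at posterior-mean hyperparameters
    if gene.C is not None and state.a_shape is not None:
        e_gamma = np.exp(gene.C @ np.log(state.e_a()))
    else:
        e_gamma = np.ones(gene.m)
    var_term = e_kappa_prior * e_gamma / state.hyper.gamma1
    second = eta**2 + var_term
    return second, int(np.argmax(second))


def local_effect_estimates(state: PosteriorState, gene_id: str) -> np.ndarray:
    """Posterior-mean SNP effects b-hat for a training-set gene.

    Out-of-sample prediction is then ``X_new @ b_hat``.
    """
    if not state.fitted:
        raise ValueError("state is not fitted")
    return state.gene_b_mean(gene_id)


def elbo(state: PosteriorState) -> float:
    """Final recorded evidence lower bound."""
    if not state.elbo_trace:
        raise ValueError("no ELBO recorded; fit first")
    return state.elbo_trace[-1]
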