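"""Correctness of the variational engine.

The deepest checks work on a deliberately tiny model (two genes, one SNP
each, one directed annotation, intercept + one distance window, one precision
annotation) where every variational factor is low-dimensional:

* at convergence, each factor must be the optimal response to the others,
  verified against conditionals renormalized by numerical integration on a
  grid, with the required expectations estimated by Monte Carlo from the
  converged factors (independent of the engine's update algebra);
* the reported evidence lower bound must match a Monte Carlo estimate of
  E_q[log p] - E_q[log q] computed from the explicit joint density.
"""

import numpy as np
import pytest
from scipy import stats

import direqtl as dq
from direqtl.annotations import MetaAnnotationPartition
from direqtl.engine import GeneData, PIN_PRECISION


def _tiny_model():
    rng = np.random.default_rng(7)
    genes = []
    n = 40
    for gi in range(2):
        x = rng.standard_normal((n, 1))
        x = (x - x.mean()) / x.std()
        y = 0.4 * x[:, 0] * (1 if gi == 0 else -1) + rng.standard_normal(n)
        V = np.array([[0.8 if gi == 0 else -0.5]])
        F = np.array([[1.0, 1.0 if gi == 0 else 0.0]])
        C = np.array([[1.0 if gi == 0 else 0.0]])
        genes.append(
            GeneData.from_individual(f"g{gi}", dq.GenotypeBlock(x, ["s"]), y, V, F, C, chrom=gi + 1)
        )
    part = MetaAnnotationPartition(d=[np.array([1])])
    return genes, part


@pytest.fixture(scope="module")
def converged_tiny():
    genes, part = _tiny_model()
    hyper = dq.Hyperparameters()
    config = dq.FitConfig(iterations=4000, prior_setting="group_lasso")
    state = dq.fit(genes, hyper=hyper, config=config, partition=part)
    return genes, part, hyper, state


def _moments(state):
    """Factor expectations computed through scipy distributions only."""
    g = lambda a, b: stats.gamma(a, scale=1.0 / b)
    m = {
        "alpha": [g(state.alpha_shape, r) for r in state.alpha_rate],
        "lambda": [g(a, b) for a, b in zip(state.lambda_shape, state.lambda_rate)],
        "kappa": [g(a, b) for a, b in zip(state.kappa_shape, state.kappa_rate)],
        "ups": g(state.ups_shape[0][0], state.ups_rate[0][0]),
        "chi2": g(state.chi2_shape[0], state.chi2_rate[0]),
        "lambda2": g(state.lambda2_shape, state.lambda2_rate),
        "tau2": g(state.tau2_shape, state.tau2_rate),
        "a": g(state.a_shape[0], state.a_rate[0]),
        "omega": stats.norm(state.omega_mean[0], np.sqrt(state.omega_cov[0, 0])),
        "nu": stats.multivariate_normal(state.nu_mean, state.nu_cov, allow_singular=True),
    }
    return m


def _grid_gamma_mean(loggrid_fn, center):
    """Mean of an unnormalized density on a log-spaced grid."""
    x = center * np.logspace(-5, 2.5, 6000)
    lg = loggrid_fn(x)
    lg -= lg.max()
    w = np.exp(lg)
    Z = np.trapezoid(w, x)
    return np.trapezoid(w * x, x) / Z


N_MC = 400_000


@pytest.fixture(scope="module")
def samples(converged_tiny):
    genes, part, hyper, st = converged_tiny
    m = _moments(st)
    rng = np.random.default_rng(99)
    N = N_MC
    return {
        "b": np.column_stack(
            [rng.normal(st.b_mean[i], np.sqrt(st.b_diag[i]), N) for i in range(2)]
        ),
        "alpha": np.column_stack([m["alpha"][i].rvs(N, random_state=rng) for i in range(2)]),
        "lambda": np.column_stack([m["lambda"][i].rvs(N, random_state=rng) for i in range(2)]),
        "kappa": np.column_stack([m["kappa"][i].rvs(N, random_state=rng) for i in range(2)]),
        "ups": m["ups"].rvs(N, random_state=rng),
        "lambda2": m["lambda2"].rvs(N, random_state=rng),
        "tau2": m["tau2"].rvs(N, random_state=rng),
        "a": m["a"].rvs(N, random_state=rng),
        "omega": m["omega"].rvs(N, random_state=rng),
        "nu": m["nu"].rvs(N, random_state=rng),
    }


class TestFactorConditionals:
    """Each converged factor equals the variational conditional, renormalized
    numerically, with blanket expectations from Monte Carlo sampling."""

    N = N_MC

    def test_alpha_conditional(self, converged_tiny, samples):
        genes, part, hyper, st = converged_tiny
        for i, g in enumerate(genes):
            v, f = g.V[0, 0], g.F[0]
            eta_s = samples["omega"] * v * (samples["nu"] @ f)
            resid2 = np.mean((samples["b"][:, i] - eta_s) ** 2)
            gamma_i = samples["a"] if g.C[0, 0] == 1 else np.ones(self.N)
            rate_coef = np.mean(samples["kappa"][:, i] * gamma_i)
            mean = _grid_gamma_mean(
                lambda x: (hyper.gamma1 - 0.5) * np.log(x) - x * (rate_coef + resid2 / 2.0),
                st.alpha_shape / st.alpha_rate[i],
            )
            assert mean == pytest.approx(st.alpha_shape / st.alpha_rate[i], rel=2e-2)

    def test_lambda_conditional(self, converged_tiny, samples):
        genes, part, hyper, st = converged_tiny
        e_lambda2 = samples["lambda2"].mean()
        for i, g in enumerate(genes):
            b = samples["b"][:, i]
            rss = np.mean(g.yty - 2.0 * b * g.Xty[0] + b**2 * g.XtX[0, 0])
            mean = _grid_gamma_mean(
                lambda x: (g.n / 2.0 + hyper.lambda1 - 1.0) * np.log(x)
                - x * (e_lambda2 + rss / 2.0),
                st.lambda_shape[i] / st.lambda_rate[i],
            )
            assert mean == pytest.approx(st.lambda_shape[i] / st.lambda_rate[i], rel=2e-2)

    def test_upsilon_conditional(self, converged_tiny, samples):
        genes, part, hyper, st = converged_tiny
        e_omega2 = np.mean(samples["omega"] ** 2)
        e_chi2 = st.chi2_shape[0] / st.chi2_rate[0]
        mean = _grid_gamma_mean(
            lambda x: (0.5 + hyper.chi1 - 1.0) * np.log(x) - x * (e_chi2 + e_omega2 / 2.0),
            st.ups_shape[0][0] / st.ups_rate[0][0],
        )
        assert mean == pytest.approx(st.ups_shape[0][0] / st.ups_rate[0][0], rel=2e-2)

    def test_b_conditional(self, converged_tiny, samples):
        genes, part, hyper, st = converged_tiny
        for i, g in enumerate(genes):
            v, f = g.V[0, 0], g.F[0]
            e_lam = samples["lambda"][:, i].mean()
            e_alp = samples["alpha"][:, i].mean()
            e_eta = np.mean(samples["omega"] * v * (samples["nu"] @ f))
            grid = np.linspace(st.b_mean[i] - 1, st.b_mean[i] + 1, 8001)
            lg = (
                -0.5 * (e_lam * g.XtX[0, 0] + e_alp) * grid**2
                + (e_lam * g.Xty[0] + e_alp * e_eta) * grid
            )
            w = np.exp(lg - lg.max())
            mean = np.trapezoid(w * grid, grid) / np.trapezoid(w, grid)
            var = np.trapezoid(w * (grid - mean) ** 2, grid) / np.trapezoid(w, grid)
            assert mean == pytest.approx(st.b_mean[i], abs=5e-3)
            assert var == pytest.approx(st.b_diag[i], rel=2e-2)


class TestFixedPoint:
    """At convergence every factor is the exact optimal response (1e-4)."""

    def test_gamma_factor_fixed_points(self, converged_tiny):
        genes, part, hyper, st = converged_tiny
        e_alpha = st.e_alpha()
        e_kappa = st.e_kappa()
        e_lam = st.e_lambda()
        e_a = st.e_a()[0]
        e_ups = st.e_upsilon(0)[0]
        e_omega2 = st.omega_mean[0] ** 2 + st.omega_cov[0, 0]
        Enn = np.outer(st.nu_mean, st.nu_mean) + st.nu_cov
        for i, g in enumerate(genes):
            v, f = g.V[0, 0], g.F[0]
            e_gamma = e_a if g.C[0, 0] == 1 else 1.0
            eb2 = st.b_mean[i] ** 2 + st.b_diag[i]
            resid2 = (
                eb2
                - 2.0 * st.b_mean[i] * v * st.omega_mean[0] * (f @ st.nu_mean)
                + v**2 * e_omega2 * (f @ Enn @ f)
            )
            assert st.alpha_rate[i] == pytest.approx(
                e_kappa[i] * e_gamma + resid2 / 2.0, rel=1e-4
            )
            rss = g.yty - 2.0 * st.b_mean[i] * g.Xty[0] + eb2 * g.XtX[0, 0]
            assert st.lambda_rate[i] == pytest.approx(
                st.lambda2_shape / st.lambda2_rate + rss / 2.0, rel=1e-4
            )
            assert st.kappa_rate[i] == pytest.approx(
                st.tau2_shape / st.tau2_rate + e_gamma * e_alpha[i], rel=1e-4
            )
        # upsilon, chi2, a, tau2, lambda2
        assert st.ups_rate[0][0] == pytest.approx(
            st.chi2_shape[0] / st.chi2_rate[0] + e_omega2 / 2.0, rel=1e-4
        )
        assert st.chi2_rate[0] == pytest.approx(hyper.zeta2 + e_ups, rel=1e-4)
        assert st.a_rate[0] == pytest.approx(
            hyper.phi2 + e_kappa[0] * e_alpha[0], rel=1e-4
        )
        assert st.tau2_rate == pytest.approx(hyper.xi2 + e_kappa.sum(), rel=1e-4)
        assert st.lambda2_rate == pytest.approx(hyper.rho2 + e_lam.sum(), rel=1e-4)

    def test_gaussian_factor_fixed_points(self, converged_tiny):
        genes, part, hyper, st = converged_tiny
        e_alpha = st.e_alpha()
        e_lam = st.e_lambda()
        Enn = np.outer(st.nu_mean, st.nu_mean) + st.nu_cov
        e_omega2 = st.omega_mean[0] ** 2 + st.omega_cov[0, 0]
        # b_j
        for i, g in enumerate(genes):
            v, f = g.V[0, 0], g.F[0]
            prec = e_lam[i] * g.XtX[0, 0] + e_alpha[i]
            mean = (e_lam[i] * g.Xty[0] + e_alpha[i] * v * st.omega_mean[0] * (f @ st.nu_mean)) / prec
            assert st.b_mean[i] == pytest.approx(mean, rel=1e-4)
            assert st.b_diag[i] == pytest.approx(1.0 / prec, rel=1e-4)
        # omega
        prec = st.e_upsilon(0)[0] + sum(
            e_alpha[i] * (g.F[0] @ Enn @ g.F[0]) * g.V[0, 0] ** 2 for i, g in enumerate(genes)
        )
        mean = (
            sum(
                e_alpha[i] * st.b_mean[i] * g.V[0, 0] * (g.F[0] @ st.nu_mean)
                for i, g in enumerate(genes)
            )
            / prec
        )
        assert st.omega_mean[0] == pytest.approx(mean, rel=1e-4)
        assert st.omega_cov[0, 0] == pytest.approx(1.0 / prec, rel=1e-4)
        # nu
        p = np.array([PIN_PRECISION, hyper.p_other])
        c = np.array([hyper.c_intercept, hyper.c_other])
        P = np.diag(p).astype(float)
        h = p * c
        for i, g in enumerate(genes):
            f = g.F[0]
            P += e_alpha[i] * e_omega2 * g.V[0, 0] ** 2 * np.outer(f, f)
            h += e_alpha[i] * st.b_mean[i] * g.V[0, 0] * st.omega_mean[0] * f
        np.testing.assert_allclose(st.nu_mean, np.linalg.solve(P, h), rtol=1e-4)
        np.testing.assert_allclose(st.nu_cov, np.linalg.inv(P), rtol=1e-4)


class TestElbo:
    def test_elbo_matches_monte_carlo_estimate(self, converged_tiny):
        """E_q[log p - log q] sampled from the explicit joint density.

        Gamma factors with tiny shapes produce samples that underflow double
        precision, so sampling and all densities run in log space.
        """
        genes, part, hyper, st = converged_tiny
        from scipy.special import gammaln

        rng = np.random.default_rng(5)
        N = 200_000

        def draw_gamma(shape, rate):
            """Return (x, log x) for x ~ Gamma(shape, rate), stable in log space."""
            logx = stats.loggamma(shape).rvs(N, random_state=rng) - np.log(rate)
            return np.exp(logx), logx

        def glogpdf(x, logx, shape, lograte, rate_x):
            """log Gamma(x; shape, rate) from precomputed log x and rate * x."""
            return shape * lograte + (shape - 1.0) * logx - rate_x - gammaln(shape)

        b = np.column_stack([rng.normal(st.b_mean[i], np.sqrt(st.b_diag[i]), N) for i in range(2)])
        alpha, lalpha = zip(*[draw_gamma(st.alpha_shape, st.alpha_rate[i]) for i in range(2)])
        lam, llam = zip(*[draw_gamma(st.lambda_shape[i], st.lambda_rate[i]) for i in range(2)])
        kap, lkap = zip(*[draw_gamma(st.kappa_shape[i], st.kappa_rate[i]) for i in range(2)])
        ups, lups = draw_gamma(st.ups_shape[0][0], st.ups_rate[0][0])
        chi2, lchi2 = draw_gamma(st.chi2_shape[0], st.chi2_rate[0])
        lam2, llam2 = draw_gamma(st.lambda2_shape, st.lambda2_rate)
        tau2, ltau2 = draw_gamma(st.tau2_shape, st.tau2_rate)
        a, la = draw_gamma(st.a_shape[0], st.a_rate[0])
        om = stats.norm(st.omega_mean[0], np.sqrt(st.omega_cov[0, 0])).rvs(N, random_state=rng)
        nu_q = stats.multivariate_normal(st.nu_mean, st.nu_cov)
        nu = nu_q.rvs(N, random_state=rng)

        logp = np.zeros(N)
        logq = np.zeros(N)
        h = hyper
        l2pi = np.log(2 * np.pi)
        for i, g in enumerate(genes):
            rss = g.yty - 2.0 * b[:, i] * g.Xty[0] + b[:, i] ** 2 * g.XtX[0, 0]
            logp += 0.5 * g.n * (llam[i] - l2pi) - 0.5 * lam[i] * rss
            eta = om * g.V[0, 0] * (nu @ g.F[0])
            logp += 0.5 * lalpha[i] - 0.5 * l2pi - 0.5 * alpha[i] * (b[:, i] - eta) ** 2
            gam, lgam = (a, la) if g.C[0, 0] == 1 else (1.0, 0.0)
            logp += glogpdf(alpha[i], lalpha[i], h.gamma1, lkap[i] + lgam, kap[i] * gam * alpha[i])
            logp += glogpdf(lam[i], llam[i], h.lambda1, llam2, lam2 * lam[i])
            logp += glogpdf(kap[i], lkap[i], h.tau1, ltau2, tau2 * kap[i])
            logq += stats.norm.logpdf(b[:, i], st.b_mean[i], np.sqrt(st.b_diag[i]))
            logq += glogpdf(alpha[i], lalpha[i], st.alpha_shape, np.log(st.alpha_rate[i]), st.alpha_rate[i] * alpha[i])
            logq += glogpdf(lam[i], llam[i], st.lambda_shape[i], np.log(st.lambda_rate[i]), st.lambda_rate[i] * lam[i])
            logq += glogpdf(kap[i], lkap[i], st.kappa_shape[i], np.log(st.kappa_rate[i]), st.kappa_rate[i] * kap[i])
        logp += glogpdf(lam2, llam2, h.rho1, np.log(h.rho2), h.rho2 * lam2)
        logp += glogpdf(tau2, ltau2, h.xi1, np.log(h.xi2), h.xi2 * tau2)
        logp += glogpdf(a, la, h.phi1, np.log(h.phi2), h.phi2 * a)
        logp += 0.5 * lups - 0.5 * l2pi - 0.5 * ups * om**2
        logp += glogpdf(ups, lups, h.chi1, lchi2, chi2 * ups)
        logp += glogpdf(chi2, lchi2, h.zeta1, np.log(h.zeta2), h.zeta2 * chi2)
        p_nu = np.array([PIN_PRECISION, h.p_other])
        c_nu = np.array([h.c_intercept, h.c_other])
        logp += (0.5 * np.log(p_nu) - 0.5 * l2pi - 0.5 * p_nu * (nu - c_nu) ** 2).sum(axis=1)
        logq += glogpdf(lam2, llam2, st.lambda2_shape, np.log(st.lambda2_rate), st.lambda2_rate * lam2)
        logq += glogpdf(tau2, ltau2, st.tau2_shape, np.log(st.tau2_rate), st.tau2_rate * tau2)
        logq += glogpdf(a, la, st.a_shape[0], np.log(st.a_rate[0]), st.a_rate[0] * a)
        logq += glogpdf(ups, lups, st.ups_shape[0][0], np.log(st.ups_rate[0][0]), st.ups_rate[0][0] * ups)
        logq += glogpdf(chi2, lchi2, st.chi2_shape[0], np.log(st.chi2_rate[0]), st.chi2_rate[0] * chi2)
        logq += stats.norm.logpdf(om, st.omega_mean[0], np.sqrt(st.omega_cov[0, 0]))
        logq += nu_q.logpdf(nu)
        diff = logp - logq
        mc = diff.mean()
        se = diff.std() / np.sqrt(N)
        assert np.all(np.isfinite(diff))
        assert dq.elbo(st) == pytest.approx(mc, abs=max(6 * se, 2e-2))

    def test_elbo_non_decreasing(self, small_study):
        genes = small_study.gene_data()
        st = dq.fit(
            genes,
            config=dq.FitConfig(iterations=30, prior_setting="group_lasso"),
            partition=small_study.partition,
        )
        tr = np.array(st.elbo_trace)
        rel = np.diff(tr) / np.maximum(np.abs(tr[:-1]), 1.0)
        assert rel.min() > -1e-6

    def test_elbo_invariant_to_gene_order(self, small_study):
        genes = small_study.gene_data()
        cfg = dq.FitConfig(iterations=60, prior_setting="group_lasso", early_stop_tol=1e-12)
        st1 = dq.fit(genes, config=cfg, partition=small_study.partition)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(genes))
        st2 = dq.fit([genes[i] for i in perm], config=cfg, partition=small_study.partition)
        assert st2.elbo_trace[-1] == pytest.approx(st1.elbo_trace[-1], rel=1e-6)


class TestRecovery:
    def test_single_causal_annotation_sign_and_rank(self):
        """A single causal annotation at ~20% directed variance gets the
        largest |omega-hat| with the correct sign in most seeded replicates."""
        hits = 0
        reps = 8
        for seed in range(reps):
            cfg = dq.SimulationConfig(
                n_genes=80, n_samples=200, snps_per_gene=25, n_annotations=30,
                n_groups=(6, 5), n_causal=1, structured=True, seed=seed,
                directed_fraction=0.2,
            )
            study = dq.simulate_study(cfg)
            st = dq.fit(
                study.gene_data(),
                config=dq.FitConfig(iterations=60, prior_setting="group_lasso"),
                partition=study.partition,
            )
            (true_idx,) = study.truth.causal_support
            top = int(np.argmax(np.abs(st.omega_mean)))
            if top == true_idx and np.sign(st.omega_mean[top]) == np.sign(
                study.truth.omega_true[true_idx]
            ):
                hits += 1
        assert hits >= 0.95 * reps - 1e-9 or hits == reps

    def test_ard_gives_heavy_tailed_effects(self, small_study):
        """With many null SNPs the ARD posterior effect estimates have excess
        kurtosis relative to a Gaussian."""
        st = dq.fit(
            small_study.gene_data(),
            config=dq.FitConfig(iterations=60, prior_setting="group_lasso"),
            partition=small_study.partition,
        )
        assert stats.kurtosis(st.b_mean, fisher=True) > 0

    def test_divergent_iterations_rejected(self):
        with pytest.raises(ValueError, match="iterations"):
            dq.FitConfig(iterations=0)


class TestVarianceModifiers:
    def test_null_group_modifier_much_smaller_than_causal(self, small_study):
        st = dq.fit(
            small_study.gene_data(),
            config=dq.FitConfig(iterations=80, prior_setting="group_lasso"),
            partition=small_study.partition,
        )
        mods = dq.prior_variance_modifiers(st)
        truth = small_study.truth
        causal_groups = {
            small_study.partition.d[0][i] - 1 for i in truth.causal_support
        }
        null_groups = set(range(small_study.partition.h[0])) - causal_groups
        causal_max = max(mods[0][g] for g in causal_groups)
        for g in null_groups:
            assert mods[0][g] < 0.10 * causal_max

    def test_uninformed_state_has_no_modifiers(self, small_study):
        st = dq.fit(
            small_study.gene_data(),
            config=dq.FitConfig(iterations=10, prior_setting="uninformed"),
            partition=small_study.partition,
        )
        with pytest.raises(ValueError, match="uninformed"):
            dq.prior_variance_modifiers(st)

    def test_unfitted_state_rejected(self, small_study):
        from direqtl.engine import _Engine

        eng = _Engine(small_study.gene_data(), small_study.partition, dq.Hyperparameters(), dq.FitConfig())
        with pytest.raises(ValueError, match="not fitted"):
            dq.prior_variance_modifiers(eng.state)


class TestSnpPriorSecondMoment:
    def test_zero_omega_constant_vector_argmax_tie_lowest(self, small_study):
        genes = small_study.gene_data()
        st = dq.fit(
            genes,
            config=dq.FitConfig(iterations=10, prior_setting="uninformed"),
            partition=small_study.partition,
        )
        st.omega_mean = np.zeros_like(st.omega_mean)  # exactly-zero weights
        vec, top = dq.snp_prior_second_moment(st, genes[0])
        np.testing.assert_allclose(vec, vec[0], rtol=1e-12)
        assert top == 0

    def test_matches_term_by_term_oracle(self, small_study):
        genes = small_study.gene_data()
        st = dq.fit(
            genes,
            config=dq.FitConfig(iterations=40, prior_setting="group_lasso"),
            partition=small_study.partition,
        )
        g = genes[3]
        vec, top = dq.snp_prior_second_moment(st, g)
        expected = np.empty(g.m)
        var = st.hyper.tau1 / (st.tau2_shape / st.tau2_rate) / st.hyper.gamma1
        for i in range(g.m):
            mean_i = (st.omega_mean @ g.V[i]) * (st.nu_mean @ g.F[i])
            expected[i] = mean_i**2 + var
        np.testing.assert_allclose(vec, expected, rtol=1e-10)
        assert top == int(np.argmax(expected))

    def test_strong_annotation_snp_is_argmax(self, small_study):
        genes = small_study.gene_data()
        st = dq.fit(
            genes,
            config=dq.FitConfig(iterations=40, prior_setting="group_lasso"),
            partition=small_study.partition,
        )
        g = genes[0]
        V = np.zeros_like(g.V)
        V[5] = 10.0 * np.sign(st.omega_mean + (st.omega_mean == 0))
        g2 = GeneData(g.gene_id, g.XtX, g.Xty, g.yty, g.n, V, g.F, chrom=g.chrom)
        _, top = dq.snp_prior_second_moment(st, g2)
        assert top == 5


class TestLocalEffects:
    def test_heldout_prediction_tracks_heritability(self):
        """Strong single-eQTL genes: out-of-sample R^2 near the simulated h^2."""
        rng = np.random.default_rng(3)
        cfg = dq.SimulationConfig(
            n_genes=40, n_samples=500, snps_per_gene=20, n_annotations=20,
            n_groups=(4, 5), omega_scale=0.0, noise_h2=0.3, p_causal_snp=0.05, seed=8,
        )
        study = dq.simulate_study(cfg)
        genes = study.gene_data()
        st = dq.fit(
            genes,
            config=dq.FitConfig(iterations=60, prior_setting="uninformed"),
            partition=study.partition,
        )
        r2s, h2s = [], []
        for i, g in enumerate(genes):
            bhat = dq.local_effect_estimates(st, g.gene_id)
            # fresh samples with the same SNP effects
            Xn = rng.standard_normal((400, g.m))
            Xn = (Xn - Xn.mean(0)) / Xn.std(0)
            gen = Xn @ study.truth.b_true[i]
            yn = gen + rng.standard_normal(400) * np.sqrt(max(1 - cfg.noise_h2, 1e-9))
            pred = Xn @ bhat
            r2s.append(np.corrcoef(pred, yn)[0, 1] ** 2)
            h2s.append(np.var(gen) / np.var(yn))
        assert np.mean(r2s) == pytest.approx(np.mean(h2s), rel=0.2)

    def test_unknown_gene_rejected(self, small_study):
        st = dq.fit(
            small_study.gene_data(),
            config=dq.FitConfig(iterations=5, prior_setting="uninformed"),
            partition=small_study.partition,
        )
        with pytest.raises(KeyError):
            dq.local_effect_estimates(st, "nope")
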