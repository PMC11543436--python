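"""Coupling, conditioning, backpropagation and Bayes consistency."""
import networkx as nx
import numpy as np
import pytest
from scipy import stats

from tcrmeta import (
    ConvergenceError,
    InvalidConfigurationError,
    Observation,
    condition,
    couple,
    enumerate_dl_dep_posterior,
    likelihood_map,
    sample_dl_dep_posterior,
    sample_prior,
)
from tcrmeta.metamodel import VAR_NAMES, log_posterior


class TestCoupling:
    def test_graph_is_acyclic_with_unique_nodes(self, metamodel_fixture):
        g = metamodel_fixture.graph
        assert nx.is_directed_acyclic_graph(g)
        assert len(set(g.nodes)) == len(g.nodes) == len(VAR_NAMES)

    def test_mismatched_surrogates_rejected(self, surrogates):
        with pytest.raises(InvalidConfigurationError):
            couple(surrogates["LckA"], surrogates["KS"], surrogates["pTCR"])

    def test_default_coupling_noise_positive(self, metamodel_fixture):
        assert all(v > 0 for v in metamodel_fixture.sigma_c.values())

    def test_tight_coupling_forces_agreement(self, surrogates):
        """With coupling noise at 1e-6 of the variable scale, joint-model
        draws satisfy Dep^KS ~= Dep^pTCR to within 1e-3 of the scale."""
        mm = couple(
            surrogates["KS"], surrogates["LckA"], surrogates["pTCR"],
            sigma_c={"dep_c": 3e-4, "log10_dl_c": 2.4e-6, "phos_c": 1e-6, "rg_c": 1e-6},
        )
        draws = sample_prior(mm, n=5000, seed=3).draws
        gap = np.abs(draws["dep_ks"] - draws["dep_ptcr"])
        assert np.median(gap) < 0.3  # 1e-3 of the 300 nm Dep scale


class TestConditioning:
    def test_prior_marginals_match_root_priors(self, prior_samples):
        """Unconditioned sampling reproduces the root priors (here: the
        uniform time prior; KS test at alpha = 0.01)."""
        t = prior_samples.draws["t"]
        sub = t[:: max(1, len(t) // 500)]
        assert stats.kstest(sub, "uniform", args=(0, 100)).pvalue > 0.01

    def test_backpropagation_updates_upstream_parameters(self, posterior, prior_samples):
        """Information flows against the edge directions: conditioning on
        (Phos^C, Rg^C) shifts the LckA root marginals and sharpens the KS
        branch (its output variance shrinks; the single-realization spread
        of the depletion width, ~40 nm, keeps the t and R marginals close
        to their priors, so the KS branch is measured at its child)."""
        for var in ("log10_diff", "log10_p_off", "log10_dl_lcka"):
            a = posterior.draws[var][::100]
            b = prior_samples.draws[var][::100]
            assert stats.ks_2samp(a, b).pvalue < 0.01, var
        ratio = posterior.draws["dep_ks"].var() / prior_samples.draws["dep_ks"].var()
        assert ratio < 0.9

    def test_huge_observation_noise_recovers_prior(self, metamodel_fixture, prior_samples):
        """With uninformative observation noise the posterior matches the
        prior (draws thinned heavily so the two-sample test is not fooled
        by MCMC autocorrelation)."""
        obs = Observation(obs_noise={"phos": 1e3, "rg": 1e3})
        post = condition(metamodel_fixture, obs, seed=5, check_convergence=False)
        for var in ("t", "log10_diff"):
            a = post.draws[var][::400]
            b = prior_samples.draws[var][::400]
            assert stats.ks_2samp(a, b).pvalue > 0.01, var

    def test_convergence_guard_raises_on_short_chains(self, metamodel_fixture):
        with pytest.raises(ConvergenceError):
            condition(metamodel_fixture, Observation(), seed=6,
                      n_steps=60, burn=20, thin=1)

    def test_posterior_draws_within_supports(self, posterior):
        d = posterior.draws
        assert np.all((d["t"] >= 0) & (d["t"] <= 100))
        assert np.all((d["R"] >= 0) & (d["R"] <= 100))
        assert np.all(d["dep_ptcr"] >= 0)
        assert "r_hat" in posterior.diagnostics

    def test_vectorized_log_density_matches_scalar(self, metamodel_fixture):
        rng = np.random.default_rng(7)
        from tcrmeta.metamodel import _initial_walkers

        th = _initial_walkers(metamodel_fixture, 5, rng)
        obs = Observation()
        vec = log_posterior(metamodel_fixture, th, obs)
        for i in range(5):
            assert log_posterior(metamodel_fixture, th[i], obs) == pytest.approx(vec[i])


class TestBayesConsistency:
    def test_sampler_matches_enumeration_on_miniature(self, metamodel_fixture):
        """On a coarse (log10 DL, Dep) grid, MCMC conditioning matches the
        brute-force posterior ∝ likelihood x prior (TV distance < 0.05)."""
        mm = metamodel_fixture
        obs = Observation()
        le = np.linspace(mm.ptcr.axes["log10_dl"].min(),
                         mm.ptcr.axes["log10_dl"].max(), 13)
        de = np.linspace(mm.ptcr.axes["dep"].min(), mm.ptcr.axes["dep"].max(), 13)
        exact = enumerate_dl_dep_posterior(mm, obs, le, de)
        draws = sample_dl_dep_posterior(mm, obs, seed=8, n_steps=12000, burn=3000)
        h, _, _ = np.histogram2d(draws["log10_dl_ptcr"], draws["dep_ptcr"], bins=(le, de))
        h = h / h.sum()
        tv = 0.5 * np.abs(h - exact).sum()
        assert tv < 0.05


class TestLikelihoodMap:
    def test_diff_poff_ridge(self, metamodel_fixture):
        """The (p_off, diff) likelihood shows a proportionality ridge: both
        off-diagonal corners are well below the ridge maximum."""
        lpo = np.linspace(-1, 2, 7)
        ld = np.linspace(-2, 0, 7)
        L = likelihood_map(
            metamodel_fixture, Observation(), ("log10_p_off", "log10_diff"),
            (lpo, ld), n_mc=300, seed=9,
        )
        assert np.all(np.isfinite(L)) and np.all(L >= 0)
        ridge = L.max()
        corner_small_diff = L[-1, 0]  # high p_off, small diff: short range
        corner_large_diff = L[0, -1]  # low p_off, large diff: long range
        assert corner_small_diff < 0.5 * ridge
        assert corner_large_diff < 0.5 * ridge

    def test_unknown_pair_rejected(self, metamodel_fixture):
        with pytest.raises(InvalidConfigurationError):
            likelihood_map(metamodel_fixture, Observation(), ("t", "log10_diff"),
                           (np.arange(3), np.arange(3)))


class TestParameterRecovery:
    def test_credible_intervals_cover_known_truth(self, metamodel_fixture):
        """Generate (Phos, Rg) from the phosphorylation simulator at known
        (DL*, Dep*) and condition: the 90% credible intervals cover the
        truth in >= 80% of 20 repetitions."""
        from tcrmeta.ptcr_field import PhosConfig, assign_phosphorylation, lck_density
        from tcrmeta.surrogate import ptcr_scene

        mm = metamodel_fixture
        rng = np.random.default_rng(10)
        dl_true, dep_true = 80.0, 100.0
        tcr0, cd450 = ptcr_scene(100.0, 1234)
        beta_ref = 0.95 / float(lck_density(cd450, 70.0, tcr0).max())
        hits_dl = hits_dep = 0
        n_rep = 20
        for k in range(n_rep):
            tcr, cd45 = ptcr_scene(dep_true, int(rng.integers(2**31)))
            pat = assign_phosphorylation(
                tcr, cd45,
                PhosConfig(decay_length=dl_true, beta=beta_ref,
                           seed=int(rng.integers(2**31))),
            )
            obs = Observation(phos_obs=min(1.0, pat.phos), rg_obs=pat.rg_ratio)
            draws = sample_dl_dep_posterior(mm, obs, seed=100 + k,
                                            n_steps=4000, burn=1000)
            lo, hi = np.quantile(draws["log10_dl_ptcr"], [0.05, 0.95])
            hits_dl += lo <= np.log10(dl_true) <= hi
            lo, hi = np.quantile(draws["dep_ptcr"], [0.05, 0.95])
            hits_dep += lo <= dep_true <= hi
        assert hits_dl / n_rep >= 0.8
        assert hits_dep / n_rep >= 0.8
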