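"""Coupled Bayesian metamodel of early TCR signaling.

The three fitted surrogates are wired into one joint probabilistic model
through four coupling variables — Dep^C, DL^C, Phos^C and Rg^C — each a
noisy copy of the corresponding quantity in the model upstream of it:

    (t, R) -> Dep^KS -> Dep^C -> Dep^pTCR ─┐
    (diff, p_off) -> DL^LckA -> DL^C -> DL^pTCR ─┤-> Phos^pTCR -> Phos^C
                                               └-> Rg^pTCR   -> Rg^C

Conditioning the joint model on observed values of (Phos^C, Rg^C)
backpropagates the observation against the edge directions, updating the
posteriors of every upstream parameter (time from activation onset,
membrane rigidity, Lck diffusion coefficient and deactivation rate, decay
length and depletion width).  Decay-length variables live on the log10
scale throughout the joint model, matching the LckA and pTCR surrogates.

Sampling uses an affine-invariant ensemble MCMC with split-R-hat
convergence diagnostics; a discretized miniature of the model is solved by
brute-force enumeration in the tests to validate the sampler against
Bayes' theorem directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import emcee
import networkx as nx
import numpy as np

from .patterns import InvalidConfigurationError, TcrMetaError
from .surrogate import SurrogateModel

COUPLING_VARS = ("dep_c", "log10_dl_c", "phos_c", "rg_c")

# order of the free variables in the sampling vector
VAR_NAMES = (
    "t",
    "R",
    "dep_ks",
    "dep_c",
    "dep_ptcr",
    "log10_diff",
    "log10_p_off",
    "log10_dl_lcka",
    "log10_dl_c",
    "log10_dl_ptcr",
    "phos_ptcr",
    "phos_c",
    "rg_ptcr",
    "rg_c",
)


class ConvergenceError(TcrMetaError):
    pass


@dataclass
class Observation:
    """Observed coupling-variable values with observation noise.

    ``phos_obs`` is a fraction (the printed percentage divided by 100).
    """

    phos_obs: float = 0.22
    rg_obs: float = 1.31
    obs_noise: dict = field(default_factory=lambda: {"phos": 0.03, "rg": 0.1})

    def validate(self) -> None:
        if not (0.0 <= self.phos_obs <= 1.0):
            raise InvalidConfigurationError("phos_obs must be in [0, 1]")
        if self.rg_obs <= 0:
            raise InvalidConfigurationError("rg_obs must be > 0")
        if any(v <= 0 for v in self.obs_noise.values()):
            raise InvalidConfigurationError("obs_noise must be > 0")


@dataclass
class Metamodel:
    ks: SurrogateModel
    lcka: SurrogateModel
    ptcr: SurrogateModel
    sigma_c: dict  # coupling noise scale per coupling variable
    graph: nx.DiGraph

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise InvalidConfigurationError("metamodel graph must be acyclic")
        if any(s <= 0 for s in self.sigma_c.values()):
            raise InvalidConfigurationError("coupling noise must be > 0")


@dataclass
class PosteriorSamples:
    draws: dict  # variable name -> 1D array of posterior draws
    diagnostics: dict  # r_hat per variable, acceptance fraction, ess
    provenance: dict  # priors, sigma_c, obs, seeds

    def mode(self, var: str, grid_points: int = 201) -> float:
        """Posterior mode of a marginal via Gaussian KDE on a grid.

        For decay lengths prefer the mode of the model's native log10
        variable; ``dl_ptcr_nm``/``dl_lcka_nm`` are convenience copies on
        the nm scale whose KDE mode is biased by the skew of the
        exponentiated draws.
        """
        from scipy.stats import gaussian_kde

        x = self.draws[var]
        if np.std(x) < 1e-12:
            return float(np.mean(x))
        kde = gaussian_kde(x)
        grid = np.linspace(x.min(), x.max(), grid_points)
        return float(grid[np.argmax(kde(grid))])

    def credible_interval(self, var: str, level: float = 0.9) -> tuple:
        lo = (1.0 - level) / 2.0
        return (
            float(np.quantile(self.draws[var], lo)),
            float(np.quantile(self.draws[var], 1.0 - lo)),
        )


def couple(
    ks: SurrogateModel,
    lcka: SurrogateModel,
    ptcr: SurrogateModel,
    sigma_c: dict | None = None,
) -> Metamodel:
    """Assemble the joint model; coupling conditionals are normal with
    scale sigma_c (default 2 % of each variable's training-range span)."""
    for m, tag in ((ks, "KS"), (lcka, "LckA"), (ptcr, "pTCR")):
        if m.model_tag != tag:
            raise InvalidConfigurationError(
                f"expected a {tag} surrogate, got {m.model_tag}"
            )
    # spans of the coupled quantities from the training axes
    dep_span = float(ptcr.axes["dep"].max() - ptcr.axes["dep"].min())
    dl_span = float(ptcr.axes["log10_dl"].max() - ptcr.axes["log10_dl"].min())
    if sigma_c is None:
        sigma_c = {
            "dep_c": 0.02 * dep_span,
            "log10_dl_c": 0.02 * dl_span,
            "phos_c": 0.02 * 1.0,
            "rg_c": 0.02 * 1.0,
        }
    g = nx.DiGraph()
    edges = [
        ("t", "dep_ks"),
        ("R", "dep_ks"),
        ("dep_ks", "dep_c"),
        ("dep_c", "dep_ptcr"),
        ("log10_diff", "log10_dl_lcka"),
        ("log10_p_off", "log10_dl_lcka"),
        ("log10_dl_lcka", "log10_dl_c"),
        ("log10_dl_c", "log10_dl_ptcr"),
        ("log10_dl_ptcr", "phos_ptcr"),
        ("dep_ptcr", "phos_ptcr"),
        ("log10_dl_ptcr", "rg_ptcr"),
        ("dep_ptcr", "rg_ptcr"),
        ("phos_ptcr", "phos_c"),
        ("rg_ptcr", "rg_c"),
    ]
    g.add_edges_from(edges)
    mm = Metamodel(ks, lcka, ptcr, sigma_c, g)
    mm.validate()
    return mm


# ------------------------------------------------------------ log density

def _norm_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.9189385332046727


def log_posterior(
    mm: Metamodel, theta: np.ndarray, obs: Observation | None = None
) -> np.ndarray:
    """Vectorized joint log density over VAR_NAMES columns.

    ``theta`` is (n, 14).  With ``obs`` None this is the (unconditioned)
    joint prior density of the metamodel.
    """
    th = np.atleast_2d(theta)
    v = {name: th[:, i] for i, name in enumerate(VAR_NAMES)}
    lp = np.zeros(th.shape[0])

    # root priors
    pri = mm.ks.priors
    lp = np.where((v["t"] < pri["t"]["lo"]) | (v["t"] > pri["t"]["hi"]), -np.inf, lp)
    lp = np.where((v["R"] < pri["R"]["lo"]) | (v["R"] > pri["R"]["hi"]), -np.inf, lp)
    lpri = mm.lcka.priors
    lp = lp + _norm_logpdf(
        v["log10_diff"], lpri["log10_diff"]["mu"], lpri["log10_diff"]["sd"]
    )
    lp = lp + _norm_logpdf(
        v["log10_p_off"], lpri["log10_p_off"]["mu"], lpri["log10_p_off"]["sd"]
    )
    # keep the pTCR inputs inside the surrogate's validity domain
    dlo, dhi = mm.ptcr.axes["dep"].min(), mm.ptcr.axes["dep"].max()
    llo, lhi = mm.ptcr.axes["log10_dl"].min(), mm.ptcr.axes["log10_dl"].max()
    bad = (
        (v["dep_ptcr"] < dlo)
        | (v["dep_ptcr"] > dhi)
        | (v["log10_dl_ptcr"] < llo)
        | (v["log10_dl_ptcr"] > lhi)
        | (v["dep_ks"] < dlo)
        | (v["dep_ks"] > dhi)
    )
    lp = np.where(bad, -np.inf, lp)
    ok = np.isfinite(lp)
    if not ok.any():
        return lp if theta.ndim > 1 else lp[0]

    # surrogate conditionals
    mu, sd, _ = mm.ks.predict(np.column_stack([v["t"], v["R"]]), "dep")
    lp = lp + _norm_logpdf(v["dep_ks"], mu, sd)
    mu, sd, _ = mm.lcka.predict(
        np.column_stack([v["log10_p_off"], v["log10_diff"]]), "log10_dl"
    )
    lp = lp + _norm_logpdf(v["log10_dl_lcka"], mu, sd)
    X = np.column_stack([v["log10_dl_ptcr"], v["dep_ptcr"]])
    mu, sd, _ = mm.ptcr.predict(X, "phos")
    lp = lp + _norm_logpdf(v["phos_ptcr"], mu, sd)
    mu, sd, _ = mm.ptcr.predict(X, "rg")
    lp = lp + _norm_logpdf(v["rg_ptcr"], mu, sd)

    # coupling layer
    sc = mm.sigma_c
    lp = lp + _norm_logpdf(v["dep_c"], v["dep_ks"], sc["dep_c"])
    lp = lp + _norm_logpdf(v["dep_ptcr"], v["dep_c"], sc["dep_c"])
    lp = lp + _norm_logpdf(v["log10_dl_c"], v["log10_dl_lcka"], sc["log10_dl_c"])
    lp = lp + _norm_logpdf(v["log10_dl_ptcr"], v["log10_dl_c"], sc["log10_dl_c"])
    lp = lp + _norm_logpdf(v["phos_c"], v["phos_ptcr"], sc["phos_c"])
    lp = lp + _norm_logpdf(v["rg_c"], v["rg_ptcr"], sc["rg_c"])

    # observation layer
    if obs is not None:
        lp = lp + _norm_logpdf(obs.phos_obs, v["phos_c"], obs.obs_noise["phos"])
        lp = lp + _norm_logpdf(obs.rg_obs, v["rg_c"], obs.obs_noise["rg"])
    return lp if theta.ndim > 1 else lp[0]


def sample_prior(mm: Metamodel, n: int = 20000, seed: int = 0) -> PosteriorSamples:
    """Exact ancestral (forward) samples of the unconditioned joint model.

    The metamodel is a directed graphical model, so its prior is sampled
    exactly by drawing roots from their priors and each child from its
    conditional in topological order — no MCMC needed.
    """
    mm.validate()
    rng = np.random.default_rng(seed)
    pri = mm.ks.priors
    t = rng.uniform(pri["t"]["lo"], pri["t"]["hi"], n)
    R = rng.uniform(pri["R"]["lo"], pri["R"]["hi"], n)
    mu, sd, _ = mm.ks.predict(np.column_stack([t, R]), "dep")
    dep_ks = rng.normal(mu, sd)
    lpri = mm.lcka.priors
    ld = rng.normal(lpri["log10_diff"]["mu"], lpri["log10_diff"]["sd"], n)
    lpo = rng.normal(lpri["log10_p_off"]["mu"], lpri["log10_p_off"]["sd"], n)
    mu, sd, _ = mm.lcka.predict(np.column_stack([lpo, ld]), "log10_dl")
    dl_a = rng.normal(mu, sd)
    sc = mm.sigma_c
    dep_c = rng.normal(dep_ks, sc["dep_c"])
    dep_pt = rng.normal(dep_c, sc["dep_c"])
    dl_c = rng.normal(dl_a, sc["log10_dl_c"])
    dl_pt = rng.normal(dl_c, sc["log10_dl_c"])
    X = np.column_stack([dl_pt, dep_pt])
    mu, sd, _ = mm.ptcr.predict(X, "phos")
    phos_pt = rng.normal(mu, sd)
    mu, sd, _ = mm.ptcr.predict(X, "rg")
    rg_pt = rng.normal(mu, sd)
    draws = {
        "t": t, "R": R, "dep_ks": dep_ks, "dep_c": dep_c, "dep_ptcr": dep_pt,
        "log10_diff": ld, "log10_p_off": lpo, "log10_dl_lcka": dl_a,
        "log10_dl_c": dl_c, "log10_dl_ptcr": dl_pt,
        "phos_ptcr": phos_pt, "phos_c": rng.normal(phos_pt, sc["phos_c"]),
        "rg_ptcr": rg_pt, "rg_c": rng.normal(rg_pt, sc["rg_c"]),
    }
    draws["dl_ptcr_nm"] = 10.0 ** draws["log10_dl_ptcr"]
    draws["dl_lcka_nm"] = 10.0 ** draws["log10_dl_lcka"]
    return PosteriorSamples(
        draws, {"method": "ancestral"}, {"sigma_c": dict(sc), "obs": None, "seed": seed}
    )


def _initial_walkers(mm: Metamodel, n_walkers: int, rng: np.random.Generator):
    """Start walkers from a forward pass through the chain of conditionals."""
    t = rng.uniform(0, 100, n_walkers)
    R = rng.uniform(0, 100, n_walkers)
    dep_ks, _, _ = mm.ks.predict(np.column_stack([t, R]), "dep")
    dlo, dhi = mm.ptcr.axes["dep"].min(), mm.ptcr.axes["dep"].max()
    dep_ks = np.clip(dep_ks + rng.normal(0, 5, n_walkers), dlo + 1, dhi - 1)
    ld = rng.normal(-1, 0.5, n_walkers)
    lpo = rng.normal(1, 0.5, n_walkers)
    dl_a, _, _ = mm.lcka.predict(np.column_stack([lpo, ld]), "log10_dl")
    llo, lhi = mm.ptcr.axes["log10_dl"].min(), mm.ptcr.axes["log10_dl"].max()
    dl_a = np.clip(dl_a + rng.normal(0, 0.05, n_walkers), llo + 0.01, lhi - 0.01)
    X = np.column_stack([dl_a, dep_ks])
    phos, _, _ = mm.ptcr.predict(X, "phos")
    rg, _, _ = mm.ptcr.predict(X, "rg")
    jitter = lambda x, s: x + rng.normal(0, s, n_walkers)
    theta = np.column_stack(
        [
            t,
            R,
            dep_ks,
            jitter(dep_ks, 1.0),
            np.clip(jitter(dep_ks, 1.0), dlo + 0.5, dhi - 0.5),
            ld,
            lpo,
            dl_a,
            jitter(dl_a, 0.02),
            np.clip(jitter(dl_a, 0.02), llo + 0.005, lhi - 0.005),
            phos,
            jitter(phos, 0.01),
            rg,
            jitter(rg, 0.01),
        ]
    )
    return theta


def condition(
    mm: Metamodel,
    obs: Observation | None,
    seed: int = 0,
    n_walkers: int = 96,
    n_steps: int = 40000,
    burn: int = 20000,
    thin: int = 40,
    check_convergence: bool = True,
) -> PosteriorSamples:
    """Posterior (or prior when obs is None) samples of the joint model.

    Raises :class:`ConvergenceError` when the split-R-hat of any variable
    exceeds 1.05 (with ``check_convergence``).
    """
    if obs is not None:
        obs.validate()
    mm.validate()
    rng = np.random.default_rng(seed)
    p0 = _initial_walkers(mm, n_walkers, rng)
    lp0 = log_posterior(mm, p0, obs)
    # nudge any stuck starting points toward a finite-density walker
    good = np.isfinite(lp0)
    if not good.any():
        raise ConvergenceError("no valid starting point found")
    p0[~good] = p0[np.flatnonzero(good)[0]] + rng.normal(
        0, 1e-3, (int((~good).sum()), len(VAR_NAMES))
    )
    sampler = emcee.EnsembleSampler(
        n_walkers,
        len(VAR_NAMES),
        lambda th: log_posterior(mm, th, obs),
        vectorize=True,
        moves=[
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ],
    )
    sampler.random_state = np.random.RandomState(seed % 2**32).get_state()
    sampler.run_mcmc(p0, n_steps)
    chain = sampler.get_chain(discard=burn, thin=thin)  # (n, walkers, dim)

    diagnostics = {"acceptance_fraction": float(np.mean(sampler.acceptance_fraction))}
    rhat = {}
    for i, name in enumerate(VAR_NAMES):
        rhat[name] = _split_rhat(chain[:, :, i])
    diagnostics["r_hat"] = rhat
    if check_convergence and max(rhat.values()) > 1.05:
        worst = max(rhat, key=rhat.get)
        raise ConvergenceError(
            f"split-R-hat {rhat[worst]:.3f} > 1.05 for variable {worst!r}"
        )
    draws = {name: chain[:, :, i].ravel() for i, name in enumerate(VAR_NAMES)}
    # convenience: decay lengths on the nm scale
    draws["dl_ptcr_nm"] = 10.0 ** draws["log10_dl_ptcr"]
    draws["dl_lcka_nm"] = 10.0 ** draws["log10_dl_lcka"]
    provenance = {
        "sigma_c": dict(mm.sigma_c),
        "obs": None
        if obs is None
        else {"phos": obs.phos_obs, "rg": obs.rg_obs, "noise": dict(obs.obs_noise)},
        "seed": seed,
        "n_walkers": n_walkers,
        "n_steps": n_steps,
    }
    return PosteriorSamples(draws, diagnostics, provenance)


def _split_rhat(chain_2d: np.ndarray) -> float:
    """Split-chain potential-scale-reduction of a (steps, walkers) chain."""
    n, m = chain_2d.shape
    half = n // 2
    if half < 2:
        return float("nan")
    segs = np.concatenate([chain_2d[:half], chain_2d[half : 2 * half]], axis=1)
    means = segs.mean(axis=0)
    vars_ = segs.var(axis=0, ddof=1)
    W = vars_.mean()
    B = half * means.var(ddof=1)
    var_hat = (half - 1) / half * W + B / half
    if W <= 0:
        return float("nan")
    return float(np.sqrt(var_hat / W))


def likelihood_map(
    mm: Metamodel,
    obs: Observation,
    var_pair: tuple,
    grids: tuple,
    n_mc: int = 400,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo estimate of p(obs | var_pair) on a 2D grid.

    Supported pairs: ("t", "R"), ("log10_p_off", "log10_diff") and
    ("log10_dl_ptcr", "dep_ptcr"); the remaining root variables are
    marginalized by sampling from their priors, and all chain noises are
    folded in by sampling.
    """
    obs.validate()
    pairs = {("t", "R"), ("log10_p_off", "log10_diff"), ("log10_dl_ptcr", "dep_ptcr")}
    if tuple(var_pair) not in pairs:
        raise InvalidConfigurationError(f"unsupported variable pair {var_pair!r}")
    rng = np.random.default_rng(seed)
    g1, g2 = np.asarray(grids[0], float), np.asarray(grids[1], float)
    out = np.zeros((len(g1), len(g2)))
    sc = mm.sigma_c

    def dl_dep_loglik(ldl, dep):
        """log p(obs | DL^pTCR, Dep^pTCR) with pTCR + obs noises."""
        X = np.column_stack([ldl, dep])
        mp, sp, _ = mm.ptcr.predict(X, "phos")
        mr, sr, _ = mm.ptcr.predict(X, "rg")
        s_p = np.sqrt(sp**2 + sc["phos_c"] ** 2 + obs.obs_noise["phos"] ** 2)
        s_r = np.sqrt(sr**2 + sc["rg_c"] ** 2 + obs.obs_noise["rg"] ** 2)
        return _norm_logpdf(obs.phos_obs, mp, s_p) + _norm_logpdf(
            obs.rg_obs, mr, s_r
        )

    for i, a in enumerate(g1):
        for j, b in enumerate(g2):
            if tuple(var_pair) == ("log10_dl_ptcr", "dep_ptcr"):
                ll = dl_dep_loglik(np.full(1, a), np.full(1, b))
                out[i, j] = np.exp(ll[0])
                continue
            if tuple(var_pair) == ("t", "R"):
                mu, sd, _ = mm.ks.predict(np.array([[a, b]]), "dep")
                dep = rng.normal(
                    mu[0], np.sqrt(sd[0] ** 2 + 2 * sc["dep_c"] ** 2), n_mc
                )
                lpri = mm.lcka.priors
                ld = rng.normal(lpri["log10_diff"]["mu"], lpri["log10_diff"]["sd"], n_mc)
                lpo = rng.normal(
                    lpri["log10_p_off"]["mu"], lpri["log10_p_off"]["sd"], n_mc
                )
                mdl, sdl, _ = mm.lcka.predict(np.column_stack([lpo, ld]), "log10_dl")
                ldl = rng.normal(mdl, np.sqrt(sdl**2 + 2 * sc["log10_dl_c"] ** 2))
            else:  # (log10_p_off, log10_diff)
                mdl, sdl, _ = mm.lcka.predict(np.array([[a, b]]), "log10_dl")
                ldl = rng.normal(
                    mdl[0], np.sqrt(sdl[0] ** 2 + 2 * sc["log10_dl_c"] ** 2), n_mc
                )
                t = rng.uniform(mm.ks.priors["t"]["lo"], mm.ks.priors["t"]["hi"], n_mc)
                R = rng.uniform(mm.ks.priors["R"]["lo"], mm.ks.priors["R"]["hi"], n_mc)
                mu, sd, _ = mm.ks.predict(np.column_stack([t, R]), "dep")
                dep = rng.normal(mu, np.sqrt(sd**2 + 2 * sc["dep_c"] ** 2))
            dlo, dhi = mm.ptcr.axes["dep"].min(), mm.ptcr.axes["dep"].max()
            llo, lhi = mm.ptcr.axes["log10_dl"].min(), mm.ptcr.axes["log10_dl"].max()
            dep = np.clip(dep, dlo, dhi)
            ldl = np.clip(ldl, llo, lhi)
            ll = dl_dep_loglik(ldl, dep)
            out[i, j] = float(np.mean(np.exp(ll)))
    return out


# --------------------------------------------------- discretized miniature

def enumerate_dl_dep_posterior(
    mm: Metamodel,
    obs: Observation,
    ldl_edges: np.ndarray,
    dep_edges: np.ndarray,
    ldl_prior=None,
    refine: int = 7,
) -> np.ndarray:
    """Brute-force posterior over a coarse (log10 DL, Dep) cell grid for
    the pTCR slice of the metamodel: posterior ∝ likelihood × prior.  The
    continuous density is integrated over each cell (defined by the edge
    arrays) with a ``refine`` × ``refine`` midpoint rule, giving the exact
    cell mass that the sampler's histogram estimates.  Independent check
    of the sampler."""
    le, de = np.asarray(ldl_edges, float), np.asarray(dep_edges, float)
    sc = mm.sigma_c
    n1, n2 = len(le) - 1, len(de) - 1
    cell_ll = np.empty((n1, n2), dtype=object)
    gmax = -np.inf
    for i in range(n1):
        ls = le[i] + (np.arange(refine) + 0.5) / refine * (le[i + 1] - le[i])
        for j in range(n2):
            ds = de[j] + (np.arange(refine) + 0.5) / refine * (de[j + 1] - de[j])
            L, D = np.meshgrid(ls, ds, indexing="ij")
            X = np.column_stack([L.ravel(), D.ravel()])
            mp, sp, _ = mm.ptcr.predict(X, "phos")
            mr, sr, _ = mm.ptcr.predict(X, "rg")
            s_p = np.sqrt(sp**2 + sc["phos_c"] ** 2 + obs.obs_noise["phos"] ** 2)
            s_r = np.sqrt(sr**2 + sc["rg_c"] ** 2 + obs.obs_noise["rg"] ** 2)
            ll = _norm_logpdf(obs.phos_obs, mp, s_p) + _norm_logpdf(
                obs.rg_obs, mr, s_r
            )
            if ldl_prior is not None:
                ll = ll + ldl_prior(L.ravel())
            cell_ll[i, j] = ll
            gmax = max(gmax, float(ll.max()))
    out = np.zeros((n1, n2))
    for i in range(n1):
        for j in range(n2):
            # cell mass = mean density x cell area
            area = (le[i + 1] - le[i]) * (de[j + 1] - de[j])
            out[i, j] = np.mean(np.exp(cell_ll[i, j] - gmax)) * area
    return out / out.sum()


def sample_dl_dep_posterior(
    mm: Metamodel,
    obs: Observation,
    seed: int = 0,
    n_walkers: int = 32,
    n_steps: int = 4000,
    burn: int = 1000,
    ldl_prior=None,
) -> dict:
    """MCMC over the same reduced (log10 DL, Dep) density used by
    :func:`enumerate_dl_dep_posterior`."""
    sc = mm.sigma_c
    dlo, dhi = mm.ptcr.axes["dep"].min(), mm.ptcr.axes["dep"].max()
    llo, lhi = mm.ptcr.axes["log10_dl"].min(), mm.ptcr.axes["log10_dl"].max()

    def logp(th):
        th = np.atleast_2d(th)
        ldl, dep = th[:, 0], th[:, 1]
        lp = np.zeros(len(ldl))
        bad = (ldl < llo) | (ldl > lhi) | (dep < dlo) | (dep > dhi)
        lp[bad] = -np.inf
        if (~bad).any():
            X = np.column_stack([ldl, dep])
            mp, sp, _ = mm.ptcr.predict(X, "phos")
            mr, sr, _ = mm.ptcr.predict(X, "rg")
            s_p = np.sqrt(sp**2 + sc["phos_c"] ** 2 + obs.obs_noise["phos"] ** 2)
            s_r = np.sqrt(sr**2 + sc["rg_c"] ** 2 + obs.obs_noise["rg"] ** 2)
            contrib = _norm_logpdf(obs.phos_obs, mp, s_p) + _norm_logpdf(
                obs.rg_obs, mr, s_r
            )
            if ldl_prior is not None:
                contrib = contrib + ldl_prior(ldl)
            lp = np.where(bad, -np.inf, contrib)
        return lp

    rng = np.random.default_rng(seed)
    p0 = np.column_stack(
        [rng.uniform(llo, lhi, n_walkers), rng.uniform(dlo, dhi, n_walkers)]
    )
    sampler = emcee.EnsembleSampler(n_walkers, 2, logp, vectorize=True)
    sampler.random_state = np.random.RandomState(seed % 2**32).get_state()
    sampler.run_mcmc(p0, n_steps)
    chain = sampler.get_chain(discard=burn, thin=4).reshape(-1, 2)
    return {"log10_dl_ptcr": chain[:, 0], "dep_ptcr": chain[:, 1]}
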