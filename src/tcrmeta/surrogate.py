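"""Probabilistic surrogate models of the three partial models.

Each partial model (kinetic segregation, Lck activation, TCR
phosphorylation) is summarized by a training grid — its outputs evaluated
over a grid of its inputs with replicates — and converted into a directed
probabilistic model: a polynomial mean function of the parents plus
Gaussian observation noise, with a Bayesian posterior over the
coefficients.  Because the mean functions are linear in their
coefficients, the coefficient posterior is available exactly in conjugate
normal—inverse-gamma form; no approximate sampler is needed at this stage.

Surrogate structure per model:

* KS:   (t, R) -> Dep          depletion width, nm
* LckA: (log10 diff, log10 p_off) -> log10 DL, via the scaling basis
        u = (log10 diff - log10 p_off) / 2
* pTCR: (log10 DL, Dep) -> Phos and Rg ratio
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import lck_walk
from .ks_sim import KSConfig, depletion_width, run_ks
from .patterns import InvalidConfigurationError, TcrMetaError
from .ptcr_field import PhosConfig, assign_phosphorylation

MODEL_TAGS = ("KS", "LckA", "pTCR")


class FitDiagnosticsError(TcrMetaError):
    pass


# default sweep axes (documented ranges of the partial-model explorations)
DEFAULT_AXES = {
    "KS": {
        "t": np.array([0.0, 5.0, 10.0, 20.0, 50.0, 100.0]),
        "R": np.array([0.0, 5.0, 15.0, 40.0, 70.0, 100.0]),
    },
    "LckA": {
        "log10_p_off": np.linspace(-1.0, 2.0, 5),
        "log10_diff": np.linspace(-2.0, 0.0, 5),
    },
    "pTCR": {
        "log10_dl": np.linspace(np.log10(20.0), np.log10(5000.0), 10),
        "dep": np.array([0.0, 40.0, 80.0, 130.0, 200.0, 300.0]),
    },
}

# wide default priors for the root variables of each surrogate
DEFAULT_PRIORS = {
    "t": {"dist": "uniform", "lo": 0.0, "hi": 100.0, "unit": "s"},
    "R": {"dist": "uniform", "lo": 0.0, "hi": 100.0, "unit": "kT nm^2"},
    "log10_diff": {"dist": "normal", "mu": -1.0, "sd": 1.0, "unit": "log10 um^2/s"},
    "log10_p_off": {"dist": "normal", "mu": 1.0, "sd": 1.0, "unit": "log10 1/s"},
    "log10_dl": {"dist": "normal", "mu": 2.5, "sd": 0.6, "unit": "log10 nm"},
}


@dataclass
class TrainingGrid:
    model_tag: str
    axes: dict  # name -> strictly increasing 1D array (row axis first)
    outputs: dict  # name -> (n_row, n_col) replicate means
    output_sd: dict  # name -> replicate SDs
    n_replicates: int
    seed: int
    flagged: np.ndarray  # (n_row, n_col) bool, True where a cell failed

    def __post_init__(self) -> None:
        for name, ax in self.axes.items():
            if np.any(np.diff(ax) <= 0):
                raise InvalidConfigurationError(f"axis {name!r} must be increasing")
        if self.n_replicates < 1:
            raise InvalidConfigurationError("need >= 1 replicate per cell")

    @property
    def shape(self) -> tuple:
        a = list(self.axes.values())
        return len(a[0]), len(a[1])


def ptcr_scene(
    dep: float,
    seed: int,
    n_tcr: int = 200,
    n_cd45: int = 400,
    r_tcr: float = 250.0,
    tcr_sigma: float = 100.0,
    ring_width: float = 300.0,
):
    """Segregated geometry for the phosphorylation model.

    TCRs form a centrally concentrated cluster (2D Gaussian with scale
    ``tcr_sigma`` truncated at ``r_tcr``, mirroring the decay of TCR
    density away from the tight-contact centre), and CD45 occupies an
    annulus starting ``dep`` nm beyond the cluster edge."""
    rng = np.random.default_rng(seed)
    tcr = np.empty((0, 2))
    while tcr.shape[0] < n_tcr:
        cand = rng.normal(0.0, tcr_sigma, size=(2 * n_tcr + 16, 2))
        cand = cand[np.hypot(cand[:, 0], cand[:, 1]) <= r_tcr]
        tcr = np.vstack([tcr, cand])
    tcr = tcr[:n_tcr]
    r0, r1 = r_tcr + dep, r_tcr + dep + ring_width
    r = np.sqrt(r0**2 + (r1**2 - r0**2) * rng.random(n_cd45))
    th = rng.random(n_cd45) * 2 * np.pi
    cd45 = np.column_stack([r * np.cos(th), r * np.sin(th)])
    return tcr, cd45


def build_training_grid(
    model_tag: str,
    axes: dict | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    ks_config: KSConfig | None = None,
    lck_kwargs: dict | None = None,
) -> TrainingGrid:
    """Run the partial model over its input grid with replicates.

    A failing cell is flagged (not silently dropped); its mean is NaN.
    """
    if model_tag not in MODEL_TAGS:
        raise InvalidConfigurationError(f"unknown model tag {model_tag!r}")
    axes = axes or {k: v.copy() for k, v in DEFAULT_AXES[model_tag].items()}
    ss = np.random.SeedSequence([seed, MODEL_TAGS.index(model_tag)])

    if model_tag == "KS":
        t_ax, r_ax = axes["t"], axes["R"]
        if t_ax.min() < 0 or t_ax.max() > 100 or r_ax.min() < 0 or r_ax.max() > 100:
            raise InvalidConfigurationError("KS axes outside documented sweep range")
        dep = np.full((len(t_ax), len(r_ax), n_replicates), np.nan)
        seeds = ss.generate_state(len(r_ax) * n_replicates)
        k = 0
        base = ks_config or KSConfig()
        for j, R in enumerate(r_ax):
            for rep in range(n_replicates):
                cfg = replace(
                    base,
                    rigidity=float(R),
                    t_end=float(t_ax.max()),
                    sample_times=tuple(t_ax),
                    seed=int(seeds[k]) % 2**31,
                )
                k += 1
                try:
                    traj = run_ks(cfg)
                    for i, s in enumerate(traj.states):
                        dep[i, j, rep] = depletion_width(s).width
                except TcrMetaError:
                    pass
        outputs = {"dep": np.nanmean(dep, axis=2)}
        sds = {"dep": np.nanstd(dep, axis=2)}
        flagged = np.isnan(outputs["dep"])
    elif model_tag == "LckA":
        p_ax, d_ax = axes["log10_p_off"], axes["log10_diff"]
        vals = np.full((len(p_ax), len(d_ax), n_replicates), np.nan)
        seeds = ss.generate_state(n_replicates)
        kwargs = dict(n_walkers=1000, n_steps=1000)
        kwargs.update(lck_kwargs or {})
        for rep in range(n_replicates):
            g = lck_walk.decay_length_grid(
                10.0**d_ax, 10.0**p_ax, seed=int(seeds[rep]) % 2**31, **kwargs
            )
            vals[:, :, rep] = np.log10(g)
        outputs = {"log10_dl": np.nanmean(vals, axis=2)}
        sds = {"log10_dl": np.nanstd(vals, axis=2)}
        flagged = np.isnan(outputs["log10_dl"])
    else:  # pTCR
        from .ptcr_field import lck_density

        dl_ax, dep_ax = axes["log10_dl"], axes["dep"]
        phos = np.full((len(dl_ax), len(dep_ax), n_replicates), np.nan)
        rg = np.full_like(phos, np.nan)
        seeds = ss.generate_state(len(dl_ax) * len(dep_ax) * n_replicates * 2 + 1)
        # one probability scale for the whole sweep, anchored at the
        # canonical segregated geometry of the observations (70 nm decay
        # length, 100 nm depletion): the most exposed TCR there gets
        # p = 0.95.  A per-cell scale would normalize away the effect of
        # segregation on Phos.
        tcr0, cd450 = ptcr_scene(100.0, int(seeds[-1]) % 2**31)
        beta_ref = 0.95 / float(lck_density(cd450, 70.0, tcr0).max())
        k = 0
        for i, ldl in enumerate(dl_ax):
            for j, dep_v in enumerate(dep_ax):
                for rep in range(n_replicates):
                    tcr, cd45 = ptcr_scene(float(dep_v), int(seeds[k]) % 2**31)
                    cfg = PhosConfig(
                        decay_length=float(10.0**ldl),
                        beta=beta_ref,
                        seed=int(seeds[k + 1]) % 2**31,
                    )
                    k += 2
                    pat = assign_phosphorylation(tcr, cd45, cfg)
                    phos[i, j, rep] = pat.phos
                    if pat.rg_defined:
                        rg[i, j, rep] = pat.rg_ratio
        with warnings.catch_warnings():
            # cells where no TCR was phosphorylated have no Rg replicates
            warnings.simplefilter("ignore", RuntimeWarning)
            outputs = {"phos": np.nanmean(phos, axis=2), "rg": np.nanmean(rg, axis=2)}
            sds = {"phos": np.nanstd(phos, axis=2), "rg": np.nanstd(rg, axis=2)}
        flagged = np.isnan(outputs["phos"]) | np.isnan(outputs["rg"])
    return TrainingGrid(model_tag, axes, outputs, sds, n_replicates, seed, flagged)


# ------------------------------------------------------------------ fitting

def _features(model_tag: str, X: np.ndarray, degree: int = 2) -> np.ndarray:
    """Design matrix on standardized inputs.

    X columns follow the grid's axis order.  The LckA basis is
    u = (log10 diff - log10 p_off) / 2, reflecting the sqrt(diff/p_off)
    scaling of the decay length.  The pTCR basis augments the polynomial
    with fixed tanh ramps along log10 DL (and their interaction with Dep):
    the Phos surface saturates sharply in the decay length, which no
    low-order polynomial can express; with fixed ramp centres the model
    stays linear in its coefficients, keeping the conjugate posterior
    exact.
    """
    if model_tag == "LckA":
        u = 0.5 * (X[:, 1] - X[:, 0])  # (log10 diff - log10 p_off)/2
        cols = [np.ones_like(u), u]
        if degree >= 2:
            cols.append(u**2)
        return np.column_stack(cols)
    x1, x2 = X[:, 0], X[:, 1]
    cols = [np.ones_like(x1), x1, x2]
    if degree >= 2:
        cols += [x1**2, x1 * x2, x2**2]
    if degree >= 3:
        cols += [x1**3, x1**2 * x2, x1 * x2**2, x2**3]
    if model_tag == "pTCR":
        for c in (-1.0, -0.5, 0.0):
            ramp = np.tanh(3.0 * (x1 - c))
            cols += [ramp, ramp * x2]
    return np.column_stack(cols)


@dataclass
class ChildFit:
    """Conjugate normal—inverse-gamma posterior of one child variable."""

    name: str
    w_mean: np.ndarray
    w_cov_base: np.ndarray  # posterior cov = (b_n/a_n) * w_cov_base
    a_n: float
    b_n: float
    x_center: np.ndarray
    x_scale: np.ndarray
    degree: int
    r2: float

    @property
    def noise_sd(self) -> float:
        # posterior-mean noise variance of the inverse-gamma
        return float(np.sqrt(self.b_n / max(self.a_n - 1.0, 0.5)))


@dataclass
class SurrogateModel:
    model_tag: str
    parents: list  # ordered parent variable names
    children: dict  # name -> ChildFit
    priors: dict  # root variable name -> prior spec
    axes: dict  # training axes (defines the training hull)
    fit_diagnostics: dict = field(default_factory=dict)

    @property
    def edges(self) -> list:
        return [(p, c) for c in self.children for p in self.parents]

    def _design(self, X: np.ndarray, fit: ChildFit) -> np.ndarray:
        Xs = (X - fit.x_center) / fit.x_scale
        return _features(self.model_tag, Xs, fit.degree)

    def predict(self, inputs: np.ndarray, child: str | None = None):
        """Predictive mean and SD of a child at ``inputs`` (n, n_parents).

        Returns (mean, sd, extrapolated) for a single child, or a dict of
        such triples.  The predictive SD includes both coefficient
        uncertainty and observation noise; points outside the training
        hull are flagged.
        """
        X = np.atleast_2d(np.asarray(inputs, dtype=float))
        if X.shape[1] != len(self.parents):
            raise InvalidConfigurationError(
                f"expected {len(self.parents)} inputs {self.parents}"
            )
        lo = np.array([self.axes[p].min() for p in self.parents])
        hi = np.array([self.axes[p].max() for p in self.parents])
        extrap = np.any((X < lo) | (X > hi), axis=1)
        if child is None:
            return {c: self.predict(X, c) for c in self.children}
        fit = self.children[child]
        Phi = self._design(X, fit)
        mean = Phi @ fit.w_mean
        s2 = fit.b_n / fit.a_n
        var = s2 * (1.0 + np.einsum("ij,jk,ik->i", Phi, fit.w_cov_base, Phi))
        return mean, np.sqrt(var), extrap

    def sample_coefficients(self, child: str, n: int, seed: int = 0) -> np.ndarray:
        """Draw coefficient vectors from the exact posterior (t-like via
        inverse-gamma mixture over the noise variance)."""
        fit = self.children[child]
        rng = np.random.default_rng(seed)
        sigma2 = fit.b_n / rng.gamma(fit.a_n, 1.0, size=n)
        L = np.linalg.cholesky(fit.w_cov_base + 1e-12 * np.eye(len(fit.w_mean)))
        z = rng.standard_normal((n, len(fit.w_mean)))
        return fit.w_mean + np.sqrt(sigma2)[:, None] * (z @ L.T)

    # -------------------------------------------------------- serialization
    def to_json(self, path=None) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        payload = {
            "model_tag": self.model_tag,
            "parents": self.parents,
            "priors": self.priors,
            "axes": {k: v.tolist() for k, v in self.axes.items()},
            "fit_diagnostics": self.fit_diagnostics,
            "children": {
                c: {
                    "w_mean": f.w_mean.tolist(),
                    "w_cov_base": f.w_cov_base.tolist(),
                    "a_n": f.a_n,
                    "b_n": f.b_n,
                    "x_center": f.x_center.tolist(),
                    "x_scale": f.x_scale.tolist(),
                    "degree": f.degree,
                    "r2": f.r2,
                }
                for c, f in self.children.items()
            },
        }
        text = json.dumps(payload, default=enc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SurrogateModel":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        children = {
            c: ChildFit(
                name=c,
                w_mean=np.array(d["w_mean"]),
                w_cov_base=np.array(d["w_cov_base"]),
                a_n=d["a_n"],
                b_n=d["b_n"],
                x_center=np.array(d["x_center"]),
                x_scale=np.array(d["x_scale"]),
                degree=d["degree"],
                r2=d["r2"],
            )
            for c, d in payload["children"].items()
        }
        return cls(
            payload["model_tag"],
            payload["parents"],
            children,
            payload["priors"],
            {k: np.array(v) for k, v in payload["axes"].items()},
            payload.get("fit_diagnostics", {}),
        )


def fit_surrogate(
    grid: TrainingGrid, degree: int = 2, prior_scale: float = 100.0
) -> SurrogateModel:
    """Fit the conjugate Bayesian polynomial surrogate to a training grid.

    Requires >= 80 % of cells unflagged.  The coefficient prior is
    N(0, prior_scale^2) per (standardized) feature with a weak
    inverse-gamma prior on the noise variance.
    """
    frac_ok = 1.0 - grid.flagged.mean()
    if frac_ok < 0.8:
        raise FitDiagnosticsError(
            f"training grid only {frac_ok:.0%} complete (< 80%)"
        )
    names = list(grid.axes)
    A1, A2 = np.meshgrid(grid.axes[names[0]], grid.axes[names[1]], indexing="ij")
    X = np.column_stack([A1.ravel(), A2.ravel()])
    ok = ~grid.flagged.ravel()
    x_center = X[ok].mean(axis=0)
    x_scale = X[ok].std(axis=0)
    x_scale[x_scale == 0] = 1.0

    children = {}
    diagnostics = {}
    for child, Y in grid.outputs.items():
        y = Y.ravel()[ok]
        good = np.isfinite(y)
        Xs = (X[ok][good] - x_center) / x_scale
        Phi = _features(grid.model_tag, Xs, degree)
        yv = y[good]
        n, p = Phi.shape
        V0_inv = np.eye(p) / prior_scale**2
        Vn_inv = V0_inv + Phi.T @ Phi
        Vn = np.linalg.inv(Vn_inv)
        wn = Vn @ (Phi.T @ yv)
        a_n = 1e-3 + 0.5 * n
        b_n = float(1e-3 + 0.5 * (yv @ yv - wn @ Vn_inv @ wn))
        resid = yv - Phi @ wn
        ss_tot = float(((yv - yv.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
        children[child] = ChildFit(
            child, wn, Vn, a_n, b_n, x_center, x_scale, degree, r2
        )
        diagnostics[child] = {"r2": r2, "n_points": int(n)}
        if not np.all(np.isfinite(wn)):
            raise FitDiagnosticsError(f"non-finite coefficients for {child!r}")

    priors = {
        name: DEFAULT_PRIORS.get(name, {"dist": "uniform",
                                        "lo": float(grid.axes[name].min()),
                                        "hi": float(grid.axes[name].max())})
        for name in names
    }
    return SurrogateModel(
        grid.model_tag, names, children, priors,
        {k: np.asarray(v, dtype=float) for k, v in grid.axes.items()},
        diagnostics,
    )


def surrogate_predict(model: SurrogateModel, inputs, child: str | None = None):
    """Functional alias for :meth:`SurrogateModel.predict`."""
    return model.predict(inputs, child)


def loo_coverage(grid: TrainingGrid, child: str, degree: int = 2, level: float = 0.95) -> float:
    """Leave-one-cell-out predictive coverage of the surrogate at nominal
    ``level`` intervals."""
    from scipy import stats

    names = list(grid.axes)
    n1, n2 = grid.shape
    hits = 0
    total = 0
    cells = [(i, j) for i in range(n1) for j in range(n2) if not grid.flagged[i, j]]
    Y = grid.outputs[child]
    for (i, j) in cells:
        if not np.isfinite(Y[i, j]):
            continue
        mask = np.ones((n1, n2), dtype=bool)
        mask[i, j] = False
        g2 = TrainingGrid(
            grid.model_tag,
            grid.axes,
            {c: np.where(mask, v, np.nan) for c, v in grid.outputs.items()},
            grid.output_sd,
            grid.n_replicates,
            grid.seed,
            grid.flagged | ~mask,
        )
        m = fit_surrogate(g2, degree=degree)
        x = np.array([[grid.axes[names[0]][i], grid.axes[names[1]][j]]])
        mu, sd, _ = m.predict(x, child)
        zc = stats.norm.ppf(0.5 + level / 2.0)
        if abs(Y[i, j] - mu[0]) <= zc * sd[0]:
            hits += 1
        total += 1
    return hits / total if total else float("nan")
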