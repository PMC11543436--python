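"""Kinetic-segregation (KS) Monte-Carlo model of a T-cell membrane patch.

A 2 um x 2 um patch of T-cell plasma membrane faces an APC carrying a
cluster of pMHC.  The patch state is a height field z(x, y) (T-cell
membrane height above the APC surface, nm) on a square grid plus mobile
TCR and CD45 molecules.  Metropolis dynamics act on three move classes:

* height perturbations scored by a discretized bending energy
  R * sum (discrete Laplacian)^2, harmonic springs pulling bound-TCR nodes
  to the TCR-pMHC complex height, and a one-sided steric wall (with a
  shallow adhesion well) keeping CD45-occupied nodes near the CD45
  ectodomain height;
* lateral molecule hops calibrated so a free molecule's mean-square
  displacement per sweep is 4 * mol_diff * sweep_dt;
* TCR-pMHC bond toggling, gated on local height and a capture radius, with
  Kramers-type dissociation exp(-U_assoc + spring energy) at a molecular
  attempt frequency.

The ~37 nm height difference between the CD45 ectodomain (default 50 nm)
and the TCR-pMHC complex (default 13 nm) drives segregation: the stiffer
the membrane, the wider the annular depletion zone between the central TCR
cluster and the surrounding CD45.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from . import _ks_kernels as _k
from .patterns import (
    CD45,
    PMHC,
    TCR,
    InsufficientPatternError,
    InvalidConfigurationError,
    PointPattern,
    SimulationDivergedError,
)

NM2_PER_UM2 = 1.0e6


@dataclass
class KSConfig:
    """Configuration of the KS membrane simulation.

    Lengths nm, energies kT, times s.  ``rigidity`` is the bending-energy
    coefficient R (kT nm^2); ``u_assoc`` the TCR-pMHC binding energy;
    ``u_rep``/``u_adh`` the CD45 steric and adhesion coefficients.
    ``bond_attempt_rate`` is the molecular attempt frequency of the
    Kramers dissociation step (per second).
    """

    patch_size: float = 2000.0
    grid_spacing: float = 25.0
    n_tcr: int = 100
    n_cd45: int = 300
    n_pmhc: int = 150
    rigidity: float = 50.0
    h_tcr_bond: float = 13.0
    h_cd45: float = 50.0
    u_assoc: float = 50.0
    u_rep: float = 0.5
    u_adh: float = 2.0
    adh_width: float = 5.0
    k_bond: float = 0.5
    k_tcr_free: float = 0.005
    mol_diff: float = 0.05
    sweep_dt: float = 0.01
    t_end: float = 100.0
    sample_times: tuple = (0.0, 5.0, 10.0, 20.0, 50.0, 100.0)
    tcr_cluster_radius: float = 350.0
    pmhc_cluster_radius: float = 350.0
    cd45_exclusion_radius: float = 250.0  # tight-contact core free of CD45 at t=0
    init_separation: float = 15.0
    edge_height: float | None = None  # clamped edge value; None -> h_cd45
    capture_radius: float = 10.0
    bind_height_tol: float = 5.0
    bind_prob: float = 1.0
    bond_attempt_rate: float = 7.0e10
    bind_refractory: float = 2.0  # s a ruptured TCR waits before re-binding
    dz_step: float = 2.0
    z_max: float = 150.0
    separation_pressure: float = 0.05  # kT/nm per node below h_cd45
    seed: int = 0

    def validate(self) -> None:
        if self.patch_size <= 0:
            raise InvalidConfigurationError("patch_size must be > 0")
        n = self.patch_size / self.grid_spacing
        if abs(n - round(n)) > 1e-9 or round(n) < 4:
            raise InvalidConfigurationError(
                "grid_spacing must divide patch_size into >= 4 cells"
            )
        for name in ("n_tcr", "n_cd45", "n_pmhc"):
            if getattr(self, name) < 0:
                raise InvalidConfigurationError(f"{name} must be >= 0")
        if self.n_tcr + self.n_cd45 + self.n_pmhc > self.n_grid**2:
            raise InvalidConfigurationError("molecule counts exceed grid capacity")
        if self.rigidity < 0:
            raise InvalidConfigurationError("rigidity must be >= 0")
        if self.h_cd45 <= self.h_tcr_bond:
            raise InvalidConfigurationError("h_cd45 must exceed h_tcr_bond")
        if self.u_assoc < 0:
            raise InvalidConfigurationError("u_assoc must be >= 0")
        if self.sweep_dt <= 0 or self.t_end < 0:
            raise InvalidConfigurationError("sweep_dt and t_end must be positive")

    @property
    def n_grid(self) -> int:
        return int(round(self.patch_size / self.grid_spacing))

    @property
    def hop_sigma(self) -> float:
        """Per-axis hop std (nm): MSD per sweep = 4 * mol_diff * sweep_dt."""
        return float(np.sqrt(2.0 * self.mol_diff * NM2_PER_UM2 * self.sweep_dt))


@dataclass
class MembraneState:
    z: np.ndarray  # (n, n) height field, nm
    molecules: PointPattern  # TCR + CD45 (mobile, T-cell side)
    pmhc: PointPattern  # pMHC on the APC (static)
    bonds: np.ndarray  # per-TCR partner pMHC index, -1 if unbound
    t: float

    @property
    def n_bound(self) -> int:
        return int((self.bonds >= 0).sum())

    def copy(self) -> "MembraneState":
        return MembraneState(
            self.z.copy(),
            PointPattern(
                self.molecules.xy.copy(),
                self.molecules.species.copy(),
                {k: v.copy() for k, v in self.molecules.marks.items()},
            ),
            self.pmhc,
            self.bonds.copy(),
            self.t,
        )


@dataclass
class Trajectory:
    states: list
    config: KSConfig

    def __post_init__(self) -> None:
        ts = [s.t for s in self.states]
        if ts != sorted(ts):
            raise InvalidConfigurationError("trajectory states must be time-sorted")


@dataclass
class DepletionResult:
    width: float  # nm, max(0, cd45_inner_radius - tcr_outer_radius)
    tcr_outer_radius: float
    cd45_inner_radius: float
    radial_profiles: dict  # species -> (bin_edges, density per annulus area)


def _disk_points(rng, center, radius, n):
    r = radius * np.sqrt(rng.random(n))
    th = 2.0 * np.pi * rng.random(n)
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def init_state(config: KSConfig) -> MembraneState:
    """Initial condition: one central TCR cluster, CD45 scattered outside it,
    pMHC clustered on the APC opposite the TCR cluster, flat membrane at the
    initial separation, no bonds."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.patch_size
    c = (L / 2.0, L / 2.0)

    pmhc_xy = _disk_points(rng, c, config.pmhc_cluster_radius, config.n_pmhc)
    if config.n_pmhc >= config.n_tcr > 0:
        # the initial cluster is an engaged microcluster: TCRs sit opposite
        # pMHC sites (bonds still form dynamically in the first sweeps)
        sites = rng.choice(config.n_pmhc, size=config.n_tcr, replace=False)
        tcr_xy = pmhc_xy[sites] + rng.normal(0.0, 3.0, size=(config.n_tcr, 2))
    else:
        tcr_xy = _disk_points(rng, c, config.tcr_cluster_radius, config.n_tcr)
    # CD45 starts uniform outside the tight-contact core, overlapping the
    # outer part of the TCR cluster: the depletion zone proper develops
    # dynamically (and is ~0 by the quantile estimator at t=0)
    cd45 = np.empty((0, 2))
    while cd45.shape[0] < config.n_cd45:
        cand = rng.random((2 * config.n_cd45 + 16, 2)) * L
        d = np.hypot(cand[:, 0] - c[0], cand[:, 1] - c[1])
        cd45 = np.vstack([cd45, cand[d > config.cd45_exclusion_radius]])
    cd45 = cd45[: config.n_cd45]

    xy = np.vstack([tcr_xy, cd45]) % L
    species = np.array([TCR] * config.n_tcr + [CD45] * config.n_cd45, dtype=object)
    mols = PointPattern(xy, species, {"bound": np.zeros(len(xy), dtype=bool)})
    pmhc = PointPattern(
        pmhc_xy % L, np.array([PMHC] * config.n_pmhc, dtype=object)
    )
    n = config.n_grid
    edge = config.h_cd45 if config.edge_height is None else config.edge_height
    # the membranes start apposed at the initial separation everywhere;
    # the separation pressure lifts unbonded regions toward the CD45
    # resting height over the first seconds of the trajectory
    z = np.full((n, n), float(config.init_separation))
    z[0, :] = z[-1, :] = edge
    z[:, 0] = z[:, -1] = edge
    bonds = np.full(config.n_tcr, -1, dtype=np.int64)
    return MembraneState(z, mols, pmhc, bonds, 0.0)


class _Engine:
    """Mutable simulation state wrapping the numba kernel."""

    def __init__(self, config: KSConfig, state: MembraneState):
        self.config = config
        self.L = config.patch_size
        self.a = config.grid_spacing
        self.n = config.n_grid
        self.z = state.z.astype(float).copy()
        self.mol_x = state.molecules.xy[:, 0].copy()
        self.mol_y = state.molecules.xy[:, 1].copy()
        self.n_tcr = config.n_tcr
        self.bonds = state.bonds.astype(np.int64).copy()
        self.pmhc_x = state.pmhc.xy[:, 0].copy()
        self.pmhc_y = state.pmhc.xy[:, 1].copy()
        self.pmhc_taken = np.zeros(len(state.pmhc), dtype=np.int8)
        self.refract = np.zeros(config.n_tcr, dtype=np.int64)
        taken = self.bonds[self.bonds >= 0]
        self.pmhc_taken[taken] = 1
        self.t = state.t
        self._rebuild_counts()
        self._seedseq = np.random.SeedSequence(config.seed)
        self._chunk = 0

    def _rebuild_counts(self):
        n = self.n
        self.nb_bound = np.zeros((n, n), dtype=np.int64)
        self.nb_free = np.zeros((n, n), dtype=np.int64)
        self.nb_cd45 = np.zeros((n, n), dtype=np.int64)
        ii = np.minimum((self.mol_x / self.a).astype(int), n - 1)
        jj = np.minimum((self.mol_y / self.a).astype(int), n - 1)
        for m in range(len(self.mol_x)):
            if m < self.n_tcr:
                if self.bonds[m] >= 0:
                    self.nb_bound[ii[m], jj[m]] += 1
                else:
                    self.nb_free[ii[m], jj[m]] += 1
            else:
                self.nb_cd45[ii[m], jj[m]] += 1

    def advance(
        self,
        n_sweeps: int,
        freeze_height: bool = False,
        suspend_unbind: bool = False,
        clamp_mask: np.ndarray | None = None,
        clamp_k: float = 0.0,
        clamp_h: float = 0.0,
    ) -> None:
        if n_sweeps <= 0:
            return
        cfg = self.config
        if clamp_mask is None:
            clamp_mask = np.zeros((self.n, self.n), dtype=np.int8)
            clamp_k = 0.0
        self._chunk += 1
        seed = int(
            (int(self._seedseq.generate_state(1, np.uint32)[0]) ^ (self._chunk * 0x9E3779B1))
            % (2**32)
        )
        _k.run_sweeps(
            self.z,
            self.mol_x,
            self.mol_y,
            self.n_tcr,
            self.bonds,
            self.refract,
            self.pmhc_x,
            self.pmhc_y,
            self.pmhc_taken,
            self.nb_bound,
            self.nb_free,
            self.nb_cd45,
            n_sweeps,
            freeze_height,
            suspend_unbind,
            clamp_mask,
            clamp_k,
            clamp_h,
            self.L,
            self.a,
            cfg.rigidity,
            cfg.h_tcr_bond,
            cfg.h_cd45,
            cfg.u_rep,
            cfg.u_adh,
            cfg.adh_width,
            cfg.k_bond,
            cfg.k_tcr_free,
            cfg.u_assoc,
            cfg.bond_attempt_rate * cfg.sweep_dt,
            cfg.capture_radius,
            cfg.bind_height_tol,
            cfg.bind_prob,
            int(round(cfg.bind_refractory / cfg.sweep_dt)),
            cfg.hop_sigma,
            cfg.dz_step,
            cfg.z_max,
            cfg.separation_pressure,
            seed,
        )
        self.t += n_sweeps * cfg.sweep_dt
        e = _k.total_energy(
            self.z,
            self.nb_bound,
            self.nb_free,
            self.nb_cd45,
            cfg.rigidity,
            cfg.grid_spacing,
            cfg.h_tcr_bond,
            cfg.h_cd45,
            cfg.u_rep,
            cfg.u_adh,
            cfg.adh_width,
            cfg.k_bond,
            cfg.k_tcr_free,
        )
        if not np.isfinite(e):
            raise SimulationDivergedError(
                "non-finite total energy (bending/spring/steric sum) "
                f"at t={self.t:.2f} s"
            )

    def snapshot(self, pmhc: PointPattern) -> MembraneState:
        xy = np.column_stack([self.mol_x, self.mol_y])
        species = np.array(
            [TCR] * self.n_tcr + [CD45] * (len(self.mol_x) - self.n_tcr),
            dtype=object,
        )
        bound = np.zeros(len(self.mol_x), dtype=bool)
        bound[: self.n_tcr] = self.bonds >= 0
        return MembraneState(
            self.z.copy(),
            PointPattern(xy, species, {"bound": bound}),
            pmhc,
            self.bonds.copy(),
            self.t,
        )


def run_ks(config: KSConfig) -> Trajectory:
    """Run the KS simulation, recording states at ``config.sample_times``."""
    config.validate()
    state0 = init_state(config)
    engine = _Engine(config, state0)
    sample_times = sorted(set(float(t) for t in config.sample_times))
    states = []
    if sample_times and sample_times[0] == 0.0:
        states.append(engine.snapshot(state0.pmhc))
        sample_times = sample_times[1:]
    prev_sweep = 0
    for t in sample_times:
        if t > config.t_end + 1e-9:
            break
        target = int(round(t / config.sweep_dt))
        engine.advance(target - prev_sweep)
        prev_sweep = target
        states.append(engine.snapshot(state0.pmhc))
    return Trajectory(states, config)


def depletion_width(
    state: MembraneState,
    tcr_quantile: float = 0.95,
    cd45_quantile: float = 0.05,
    bin_width: float = 20.0,
) -> DepletionResult:
    """Depletion width of a state: the gap between the radius containing
    ``tcr_quantile`` of TCRs and the ``cd45_quantile`` radial quantile of
    CD45, measured about the TCR centre of mass (clamped at 0)."""
    tcr_xy = state.molecules.coords(TCR)
    cd45_xy = state.molecules.coords(CD45)
    if tcr_xy.shape[0] < 1 or cd45_xy.shape[0] < 1:
        raise InsufficientPatternError("depletion width needs >= 1 TCR and >= 1 CD45")
    com = tcr_xy.mean(axis=0)
    r_tcr = np.hypot(tcr_xy[:, 0] - com[0], tcr_xy[:, 1] - com[1])
    r_cd = np.hypot(cd45_xy[:, 0] - com[0], cd45_xy[:, 1] - com[1])
    tcr_outer = float(np.quantile(r_tcr, tcr_quantile))
    cd45_inner = float(np.quantile(r_cd, cd45_quantile))
    rmax = max(r_tcr.max(), r_cd.max()) + bin_width
    edges = np.arange(0.0, rmax + bin_width, bin_width)
    area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    profiles = {}
    for name, r in ((TCR, r_tcr), (CD45, r_cd)):
        counts, _ = np.histogram(r, bins=edges)
        profiles[name] = (edges, counts / area)
    return DepletionResult(
        max(0.0, cd45_inner - tcr_outer), tcr_outer, cd45_inner, profiles
    )


# ---------------------------------------------------------------- storage

def save_trajectory(path, traj: Trajectory) -> None:
    """Store a trajectory as HDF5: one group per sample time holding the
    height grid and molecule table."""
    with h5py.File(path, "w") as f:
        cfg = f.create_group("config")
        for k, v in vars(traj.config).items():
            if v is None:
                continue
            cfg.attrs[k] = v if not isinstance(v, tuple) else list(v)
        for i, s in enumerate(traj.states):
            g = f.create_group(f"state_{i:04d}")
            g.attrs["t"] = s.t
            g.create_dataset("z", data=s.z)
            g.create_dataset("mol_xy", data=s.molecules.xy)
            g.create_dataset(
                "species",
                data=np.array([str(x) for x in s.molecules.species], dtype="S8"),
            )
            g.create_dataset("bound", data=s.molecules.marks["bound"])
            g.create_dataset("bonds", data=s.bonds)
            g.create_dataset("pmhc_xy", data=s.pmhc.xy)


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        kwargs = {}
        for k, v in f["config"].attrs.items():
            if k == "sample_times":
                kwargs[k] = tuple(float(x) for x in v)
            else:
                kwargs[k] = v.item() if hasattr(v, "item") else v
        config = KSConfig(**kwargs)
        states = []
        for name in sorted(k for k in f.keys() if k.startswith("state_")):
            g = f[name]
            species = np.array([s.decode() for s in g["species"][...]], dtype=object)
            pmhc_xy = g["pmhc_xy"][...]
            states.append(
                MembraneState(
                    g["z"][...],
                    PointPattern(
                        g["mol_xy"][...], species, {"bound": g["bound"][...]}
                    ),
                    PointPattern(
                        pmhc_xy, np.array([PMHC] * len(pmhc_xy), dtype=object)
                    ),
                    g["bonds"][...],
                    float(g.attrs["t"]),
                )
            )
    return Trajectory(states, config)
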