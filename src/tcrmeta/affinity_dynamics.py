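"""TCR phosphorylation dynamics at varying pMHC:TCR association strengths.

The initial-contact scenario: the T-cell and APC membranes are constrained
next to each other for a clamp period (default 10 s) at a height allowing
TCR-pMHC binding, then released and left to evolve freely (default 90 s).
Contacts either persist (bound-TCR count stabilizes at a high plateau) or
detach completely, with a sharp boundary in the association energy
``U_assoc``.  At every sample time the bound TCRs are phosphorylated by the
pTCR model (snapshot mode, no memory between frames) for each decay length
of a grid, yielding per-decay-length pTCR time series.  A threshold rule
(at least ``n_min`` pTCRs sustained for at least ``tau`` seconds) converts
each series into an activation outcome, from which sensitivity and
specificity versus decay length are computed against the association-
strength ground-truth classes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ks_sim import KSConfig, _Engine, init_state
from .patterns import CD45, TCR, InvalidConfigurationError, TcrMetaError
from .ptcr_field import density_to_probability, lck_density


class UndefinedMetricError(TcrMetaError):
    pass


@dataclass
class ContactProtocol:
    """Initial-contact protocol and scan design.

    clamp_duration/free_duration in s; clamp_height nm (near the TCR-pMHC
    complex height so bonds can form); u_assoc_grid in kT; dl_grid in nm;
    sample cadence s.  ``phos_beta`` scales the exp-saturating density-to-
    probability map used for the per-frame phosphorylation snapshots.
    """

    clamp_duration: float = 10.0
    free_duration: float = 90.0
    clamp_height: float = 15.0
    clamp_margin: float = 100.0  # clamp disk radius = pMHC cluster radius + margin
    clamp_stiffness: float = 10.0  # kT/nm^2 per node while clamped
    u_assoc_grid: tuple = tuple(float(u) for u in range(5, 55, 5))
    dl_grid: tuple = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)
    n_replicates: int = 5
    cadence: float = 1.0
    phos_beta: float = 30.0
    sticky_phosphorylation: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.clamp_duration <= 0 or self.free_duration <= 0:
            raise InvalidConfigurationError("durations must be > 0")
        if any(u <= 0 for u in self.u_assoc_grid):
            raise InvalidConfigurationError("u_assoc values must be > 0")
        if self.cadence <= 0:
            raise InvalidConfigurationError("cadence must be > 0")


@dataclass
class ActivationRule:
    """T-cell activation proxy: at least ``n_min`` pTCRs sustained for at
    least ``tau`` seconds."""

    n_min: int = 5
    tau: float = 10.0

    def validate(self) -> None:
        if self.n_min < 1:
            raise InvalidConfigurationError("n_min must be >= 1")
        if self.tau <= 0:
            raise InvalidConfigurationError("tau must be > 0")


@dataclass
class BindingTimeSeries:
    t: np.ndarray  # s
    n_bound: np.ndarray  # bound TCRs per sample
    n_ptcr: dict  # decay length nm -> phosphorylated (bound) TCRs per sample
    u_assoc: float
    replicate: int
    n_tcr: int

    def validate_counts(self) -> None:
        for dl, series in self.n_ptcr.items():
            bad = (series < 0) | (series > self.n_bound) | (self.n_bound > self.n_tcr)
            if bad.any():
                raise InvalidConfigurationError(
                    f"count invariant 0 <= n_ptcr <= n_bound <= n_tcr violated at DL={dl}"
                )


def reduced_contact_config(**overrides) -> KSConfig:
    """Desk-scale KS configuration for the affinity scan (reduced molecule
    counts relative to the long-lived-contact default)."""
    base = dict(
        n_tcr=60,
        n_cd45=150,
        n_pmhc=80,
        tcr_cluster_radius=300.0,
        pmhc_cluster_radius=300.0,
        t_end=100.0,
    )
    base.update(overrides)
    return KSConfig(**base)


def run_contact(
    config: KSConfig, protocol: ContactProtocol, replicate_seed: int, u_assoc: float, replicate: int = 0
) -> BindingTimeSeries:
    """One initial-contact simulation at one association strength.

    The membrane is frozen at ``clamp_height`` for the clamp period, then
    released.  At each sample time the bound-TCR count is recorded and, for
    every decay length of the grid, phosphorylation is assigned to bound
    TCRs (snapshot mode) from the instantaneous CD45 pattern.
    """
    protocol.validate()
    cfg = replace(
        config,
        u_assoc=float(u_assoc),
        init_separation=protocol.clamp_height,
        t_end=protocol.clamp_duration + protocol.free_duration,
        seed=int(replicate_seed),
    )
    cfg.validate()
    state0 = init_state(cfg)
    # the clamp presses a finite contact disk to the binding distance; the
    # membrane outside the disk starts at the CD45 ectodomain height
    n = cfg.n_grid
    centers = (np.arange(n) + 0.5) * cfg.grid_spacing
    rr = np.hypot(
        centers[:, None] - cfg.patch_size / 2.0,
        centers[None, :] - cfg.patch_size / 2.0,
    )
    clamp_mask = (rr <= cfg.pmhc_cluster_radius + protocol.clamp_margin).astype(
        np.int8
    )
    state0.z[1:-1, 1:-1] = np.where(
        clamp_mask, protocol.clamp_height, cfg.h_cd45
    )[1:-1, 1:-1]
    engine = _Engine(cfg, state0)
    rng = np.random.default_rng(np.random.SeedSequence([int(replicate_seed), 7]))

    sweeps_per_sample = max(1, int(round(protocol.cadence / cfg.sweep_dt)))
    n_samples = int(round(cfg.t_end / protocol.cadence)) + 1
    t = np.arange(n_samples) * protocol.cadence
    n_bound = np.zeros(n_samples, dtype=int)
    n_ptcr = {float(dl): np.zeros(n_samples, dtype=int) for dl in protocol.dl_grid}
    sticky = {float(dl): np.zeros(cfg.n_tcr, dtype=bool) for dl in protocol.dl_grid}

    for i in range(n_samples):
        if i > 0:
            clamped = t[i] <= protocol.clamp_duration + 1e-9
            # while the membranes are pressed together, bond rupture is
            # immediately reversed (escape-limited kinetics): dissociation
            # only acts once the constraint is released
            engine.advance(
                sweeps_per_sample,
                suspend_unbind=clamped,
                clamp_mask=clamp_mask if clamped else None,
                clamp_k=protocol.clamp_stiffness if clamped else 0.0,
                clamp_h=protocol.clamp_height,
            )
        bound = engine.bonds >= 0
        n_bound[i] = int(bound.sum())
        if n_bound[i] == 0:
            continue
        tcr_xy = np.column_stack([engine.mol_x[: cfg.n_tcr], engine.mol_y[: cfg.n_tcr]])
        cd45_xy = np.column_stack([engine.mol_x[cfg.n_tcr :], engine.mol_y[cfg.n_tcr :]])
        bxy = tcr_xy[bound]
        for dl in n_ptcr:
            rho = lck_density(cd45_xy, dl, bxy)
            p = density_to_probability(rho, "exp-saturating", protocol.phos_beta)
            flags = rng.random(len(p)) < p
            if protocol.sticky_phosphorylation:
                s = sticky[dl]
                s[np.flatnonzero(bound)[flags]] = True
                s &= bound  # unbinding clears the mark
                n_ptcr[dl][i] = int(s.sum())
            else:
                n_ptcr[dl][i] = int(flags.sum())
    series = BindingTimeSeries(t, n_bound, n_ptcr, float(u_assoc), replicate, cfg.n_tcr)
    series.validate_counts()
    return series


def max_sustained_duration(
    n_ptcr: np.ndarray, t: np.ndarray, n_min: int
) -> float:
    """Length (s) of the longest contiguous interval with n_ptcr > n_min."""
    above = np.asarray(n_ptcr) > n_min
    if not above.any():
        return 0.0
    best = cur = 0
    for a in above:
        cur = cur + 1 if a else 0
        best = max(best, cur)
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
    return (best - 1) * dt


def activation_outcome(series: BindingTimeSeries, rule: ActivationRule, dl: float) -> bool:
    rule.validate()
    dur = max_sustained_duration(series.n_ptcr[float(dl)], series.t, rule.n_min)
    return dur >= rule.tau


def detachment_time(series: BindingTimeSeries) -> float:
    """First time at which the bound-TCR count reaches zero, or inf if the
    contact persists to the end."""
    idx = np.flatnonzero(series.n_bound == 0)
    # ignore the t=0 sample (no bonds formed yet at initialization)
    idx = idx[series.t[idx] > 0]
    return float(series.t[idx[0]]) if idx.size else float("inf")


def run_affinity_scan(
    config: KSConfig | None = None,
    protocol: ContactProtocol | None = None,
    seed: int = 0,
) -> list:
    """Full scan: every U_assoc x replicate combination."""
    config = config or reduced_contact_config()
    protocol = protocol or ContactProtocol()
    ss = np.random.SeedSequence([int(seed), 0xAF])
    seeds = ss.generate_state(len(protocol.u_assoc_grid) * protocol.n_replicates)
    out = []
    k = 0
    for u in protocol.u_assoc_grid:
        for rep in range(protocol.n_replicates):
            out.append(run_contact(config, protocol, int(seeds[k]) % 2**31, u, rep))
            k += 1
    return out


def classify_persistence(series: BindingTimeSeries) -> str:
    """'detached' if the contact fully detaches, else 'persistent'."""
    return "detached" if np.isfinite(detachment_time(series)) else "persistent"


def transition_u(scan: list) -> float:
    """Midpoint between the largest fully-detaching and the smallest
    persisting association strength (a run counts as detaching for a given
    U only if every replicate detaches)."""
    by_u = {}
    for s in scan:
        by_u.setdefault(s.u_assoc, []).append(classify_persistence(s))
    us = sorted(by_u)
    detaching = [u for u in us if all(c == "detached" for c in by_u[u])]
    persisting = [u for u in us if any(c == "persistent" for c in by_u[u])]
    if not detaching or not persisting:
        raise UndefinedMetricError("scan shows a single persistence class")
    return 0.5 * (max(detaching) + min(persisting))


def sensitivity_specificity(
    scan: list, rule: ActivationRule, truth_threshold: float = 25.0
) -> pd.DataFrame:
    """Per-decay-length sensitivity and specificity of the activation rule.

    Ground truth: positive if U_assoc > truth_threshold, negative otherwise.
    Sensitivity = fraction of positive runs activated; specificity =
    fraction of negative runs not activated.
    """
    us = {s.u_assoc for s in scan}
    if all(u > truth_threshold for u in us) or all(u <= truth_threshold for u in us):
        raise UndefinedMetricError("scan does not cover both truth classes")
    dls = sorted(scan[0].n_ptcr.keys())
    rows = []
    for dl in dls:
        tp = fn = tn = fp = 0
        for s in scan:
            act = activation_outcome(s, rule, dl)
            if s.u_assoc > truth_threshold:
                tp += act
                fn += not act
            else:
                tn += not act
                fp += act
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        rows.append(
            {
                "decay_length_nm": dl,
                "sensitivity": sens,
                "specificity": spec,
                "balanced_accuracy": 0.5 * (sens + spec),
            }
        )
    return pd.DataFrame(rows)


def optimal_decay_length(summary: pd.DataFrame) -> float:
    """Decay length maximizing balanced accuracy (ties -> smallest DL)."""
    i = int(np.argmax(summary["balanced_accuracy"].to_numpy()))
    return float(summary["decay_length_nm"].iloc[i])
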