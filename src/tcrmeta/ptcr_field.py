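"""TCR phosphorylation from the Lck* density field.

The Lck* density at a point is the sum of exponential kernels centred on
every CD45 molecule, with a single decay length.  Each TCR is phosphorylated
(all-or-none over its ITAMs) by a Bernoulli draw whose probability maps
monotonically to the local Lck* density.  The resulting pattern is
summarized by two statistics:

* ``phos`` - fraction of TCRs phosphorylated;
* ``rg_ratio`` - RMSD of the phosphorylated TCRs about the centre of mass
  of *all* TCRs, divided by the radius of gyration of all TCRs; values > 1
  indicate peripheral enrichment of pTCRs, 1 a like distribution, < 1
  central enrichment.

Segregated CD45 has no dephosphorylating action at a distance: the model
contains no dephosphorylation term (ITAM dephosphorylation requires direct
TCR-CD45 contact, which the depletion zone prevents).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patterns import (
    CD45,
    TCR,
    InsufficientPatternError,
    InvalidConfigurationError,
    PointPattern,
)

PROB_RULES = ("linear-capped", "normalize-by-max", "exp-saturating")


@dataclass
class PhosConfig:
    """Phosphorylation-assignment configuration.

    decay_length : nm, exponential decay of the Lck* kernel
    prob_rule : density-to-probability mapping; "linear-capped" uses
        p = min(1, beta*rho), "normalize-by-max" p = rho/max(rho),
        "exp-saturating" p = 1 - exp(-beta*rho)
    beta : scalar of the mapping; None (with "linear-capped") calibrates
        beta so the maximum density over the queried TCRs maps to 0.95
    only_bound : unbound TCRs get probability 0 (ligand-gated ITAM access)
    """

    decay_length: float = 70.0
    prob_rule: str = "linear-capped"
    beta: float | None = None
    only_bound: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.decay_length <= 0:
            raise InvalidConfigurationError("decay_length must be > 0")
        if self.prob_rule not in PROB_RULES:
            raise InvalidConfigurationError(f"unknown prob_rule {self.prob_rule!r}")
        if self.beta is not None and self.beta < 0:
            raise InvalidConfigurationError("beta must be >= 0")


@dataclass
class PhosPattern:
    flags: np.ndarray  # per-TCR phosphorylated boolean
    phos: float
    rg_ratio: float  # nan when undefined (no pTCR)
    rg_defined: bool
    densities: np.ndarray  # per-TCR Lck* density
    probabilities: np.ndarray
    no_cd45: bool = False


def lck_density(
    cd45_xy: np.ndarray, decay_length: float, query_xy: np.ndarray
) -> np.ndarray:
    """Summed exponential Lck* density at the query points.

    rho(x) = sum_j exp(-|x - c_j| / decay_length) over CD45 positions c_j.
    Returns zeros (the caller may warn) when there is no CD45.
    """
    if decay_length <= 0:
        raise InvalidConfigurationError("decay_length must be > 0")
    query_xy = np.asarray(query_xy, dtype=float).reshape(-1, 2)
    cd45_xy = np.asarray(cd45_xy, dtype=float).reshape(-1, 2)
    if cd45_xy.shape[0] == 0:
        return np.zeros(query_xy.shape[0])
    # chunk the query axis to bound the pairwise distance matrix
    out = np.empty(query_xy.shape[0])
    chunk = max(1, int(4e6) // max(cd45_xy.shape[0], 1))
    for s in range(0, query_xy.shape[0], chunk):
        q = query_xy[s : s + chunk]
        d = np.sqrt(
            ((q[:, None, :] - cd45_xy[None, :, :]) ** 2).sum(axis=2)
        )
        out[s : s + chunk] = np.exp(-d / decay_length).sum(axis=1)
    return out


def density_to_probability(
    rho: np.ndarray, rule: str = "linear-capped", beta: float | None = None
) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if rule == "normalize-by-max":
        m = rho.max() if rho.size else 0.0
        return rho / m if m > 0 else np.zeros_like(rho)
    if beta is None:
        m = rho.max() if rho.size else 0.0
        beta = 0.95 / m if m > 0 else 0.0
    if rule == "linear-capped":
        return np.minimum(1.0, beta * rho)
    if rule == "exp-saturating":
        return 1.0 - np.exp(-beta * rho)
    raise InvalidConfigurationError(f"unknown prob_rule {rule!r}")


def rg_ratio(all_tcr_xy: np.ndarray, ptcr_xy: np.ndarray) -> float:
    """RMSD of pTCRs about the COM of all TCRs over the Rg of all TCRs.

    The centre of mass and radius of gyration are computed over all TCRs,
    phosphorylated and non-phosphorylated alike.
    """
    all_tcr_xy = np.asarray(all_tcr_xy, dtype=float).reshape(-1, 2)
    ptcr_xy = np.asarray(ptcr_xy, dtype=float).reshape(-1, 2)
    if all_tcr_xy.shape[0] < 2:
        raise InsufficientPatternError("need >= 2 TCRs for a radius of gyration")
    if ptcr_xy.shape[0] < 1:
        raise InsufficientPatternError("undefined ratio: no phosphorylated TCR")
    com = all_tcr_xy.mean(axis=0)
    rg = np.sqrt(((all_tcr_xy - com) ** 2).sum(axis=1).mean())
    rmsd = np.sqrt(((ptcr_xy - com) ** 2).sum(axis=1).mean())
    if rg == 0:
        raise InsufficientPatternError("degenerate TCR pattern (zero Rg)")
    return float(rmsd / rg)


def assign_phosphorylation(
    tcr: PointPattern | np.ndarray,
    cd45: PointPattern | np.ndarray,
    config: PhosConfig,
    rng: np.random.Generator | None = None,
) -> PhosPattern:
    """Bernoulli phosphorylation of each TCR from the local Lck* density."""
    config.validate()
    if isinstance(tcr, PointPattern):
        tcr_xy = tcr.coords(TCR) if (tcr.species == TCR).any() else tcr.xy
        bound = tcr.marks.get("bound")
        if bound is not None and (tcr.species == TCR).any():
            bound = bound[tcr.species == TCR]
    else:
        tcr_xy = np.asarray(tcr, dtype=float).reshape(-1, 2)
        bound = None
    if isinstance(cd45, PointPattern):
        cd45_xy = cd45.coords(CD45) if (cd45.species == CD45).any() else cd45.xy
    else:
        cd45_xy = np.asarray(cd45, dtype=float).reshape(-1, 2)

    if tcr_xy.shape[0] < 1:
        raise InsufficientPatternError("need >= 1 TCR")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    rho = lck_density(cd45_xy, config.decay_length, tcr_xy)
    no_cd45 = cd45_xy.shape[0] == 0
    p = density_to_probability(rho, config.prob_rule, config.beta)
    if config.only_bound:
        if bound is None:
            raise InvalidConfigurationError(
                "only_bound requires a 'bound' mark on the TCR pattern"
            )
        p = np.where(bound, p, 0.0)
    flags = rng.random(tcr_xy.shape[0]) < p
    phos = float(flags.mean())
    if flags.any() and tcr_xy.shape[0] >= 2:
        ratio = rg_ratio(tcr_xy, tcr_xy[flags])
        defined = True
    else:
        ratio, defined = float("nan"), False
    return PhosPattern(flags, phos, ratio, defined, rho, p, no_cd45)


def apply_csk_inhibition(
    ptcr_pattern: PhosPattern,
    tcr: PointPattern | np.ndarray,
    csk_strength: float,
    query_xy: np.ndarray | None = None,
    densities: np.ndarray | None = None,
    csk_decay_length: float = 20.0,
) -> np.ndarray:
    """Attenuate an Lck* density field by Csk recruited to current pTCRs.

    Csk molecules are placed at the phosphorylated-TCR positions; their
    density sigma(x) uses the same exponential-kernel form with a short
    decay length (default 20 nm), and the field is multiplied by
    exp(-csk_strength * sigma(x)).  Intended for iterated re-assignment.
    """
    if csk_strength < 0:
        raise InvalidConfigurationError("csk_strength must be >= 0")
    tcr_xy = tcr.coords(TCR) if isinstance(tcr, PointPattern) else np.asarray(tcr)
    tcr_xy = tcr_xy.reshape(-1, 2)
    if query_xy is None:
        query_xy = tcr_xy
    if densities is None:
        densities = ptcr_pattern.densities
    densities = np.asarray(densities, dtype=float)
    csk_xy = tcr_xy[ptcr_pattern.flags]
    if csk_xy.shape[0] == 0 or csk_strength == 0:
        return densities.copy()
    sigma = lck_density(csk_xy, csk_decay_length, query_xy)
    return densities * np.exp(-csk_strength * sigma)
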