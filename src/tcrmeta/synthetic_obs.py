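"""Synthetic stand-ins for the measured inputs of the study.

The empirical anchors of the metamodel are two scalars estimated from
super-resolution imaging of early T-cell contacts: the fraction of
phosphorylated TCRs in a cluster (Phos_obs = 0.22) and the Rg ratio of
the phosphorylated subset (Rg_obs = 1.31).  No raw imaging data is
consumed here; instead this module generates synthetic scenes that
emulate the measured inputs — a smoothed membrane-topography height
field with a tight-contact depression, a TCR point pattern concentrated
at low membrane height (z < 10 nm), a CD45 pattern concentrated at
30-40 nm, and a pTCR proxy pattern enriched at the contact periphery —
and implements the estimation pipeline that turns a scene into
(phos_obs, rg_obs).  Default scene parameters are calibrated so the
estimates reproduce the printed anchors.

The scene contains exactly one TCR cluster, so no cluster-selection rule
is needed for the estimates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .patterns import (
    CD45,
    TCR,
    InsufficientPatternError,
    InvalidConfigurationError,
    PointPattern,
)
from .ptcr_field import rg_ratio


@dataclass
class SceneParams:
    """Generative parameters of a synthetic early-contact scene.

    Topography: radially symmetric smooth depression (minimum near 0 nm
    at the contact centre, far field at ``far_height``) plus correlated
    Gaussian surface noise (correlation length ``noise_corr_nm``).  The
    pTCR subset is drawn with a peripheral-annulus bias of strength set
    by ``ptcr_ring_radius``/``ptcr_ring_width`` (a zero-width, i.e.
    non-positive, bias makes the subset uniform).
    """

    patch_size: float = 2000.0
    grid_spacing: float = 10.0
    contact_radius: float = 300.0  # radius of the tight-contact depression
    rim_width: float = 120.0  # radial scale of the depression wall
    far_height: float = 60.0  # nm, membrane height away from the contact
    noise_sd: float = 2.0  # nm
    noise_corr_nm: float = 100.0
    n_tcr: int = 300
    n_cd45: int = 500
    tcr_z_scale: float = 10.0  # nm, TCR density ~ exp(-(z - z_min)/scale)
    cd45_band: tuple = (30.0, 40.0)  # nm, CD45 concentrates in this height band
    phos_fraction: float = 0.22
    ptcr_ring_radius: float = 280.0  # nm, peripheral bias centre
    ptcr_ring_width: float = 55.0  # nm, peripheral bias width (<= 0: no bias)
    seed: int = 0

    def validate(self) -> None:
        if self.contact_radius <= 0 or self.rim_width <= 0:
            raise InvalidConfigurationError("degenerate contact geometry")
        if not (0.0 < self.phos_fraction <= 1.0):
            raise InvalidConfigurationError("phos_fraction must be in (0, 1]")
        if self.tcr_z_scale <= 0:
            raise InvalidConfigurationError("tcr_z_scale must be > 0")


@dataclass
class SyntheticScene:
    topography: np.ndarray  # (n, n) heights, nm
    grid_spacing: float
    tcr_points: PointPattern
    cd45_points: PointPattern
    ptcr_indices: np.ndarray  # indices into tcr_points
    params: SceneParams

    @property
    def ptcr_xy(self) -> np.ndarray:
        return self.tcr_points.xy[self.ptcr_indices]


@dataclass
class ObsEstimates:
    phos_obs: float
    rg_obs: float
    n_tcr_used: int
    n_ptcr_used: int


def make_topography(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Smooth tight-contact depression with correlated surface noise."""
    n = int(round(params.patch_size / params.grid_spacing))
    c = params.patch_size / 2.0
    x = (np.arange(n) + 0.5) * params.grid_spacing
    rr = np.hypot(x[:, None] - c, x[None, :] - c)
    # sigmoidal bowl: ~0 inside the contact, far_height outside
    z = params.far_height / (1.0 + np.exp(-(rr - params.contact_radius) / params.rim_width))
    if params.noise_sd > 0:
        white = rng.standard_normal((n, n))
        sig = params.noise_corr_nm / params.grid_spacing
        smooth = ndimage.gaussian_filter(white, sig, mode="wrap")
        sd = smooth.std()
        if sd > 0:
            z = z + params.noise_sd * smooth / sd
    return np.clip(z, 0.0, None)


def sample_from_height_weights(
    topography: np.ndarray,
    weights: np.ndarray,
    n_points: int,
    grid_spacing: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample point coordinates with per-cell probability ``weights``,
    jittered uniformly within each cell."""
    p = weights.ravel() / weights.sum()
    idx = rng.choice(weights.size, size=n_points, p=p)
    ii, jj = np.unravel_index(idx, weights.shape)
    xy = np.column_stack([ii, jj]) * grid_spacing
    return xy + rng.random((n_points, 2)) * grid_spacing


def estimate_tcr_from_topography(
    topography: np.ndarray,
    n_points: int,
    z_scale: float = 10.0,
    seed: int = 0,
    grid_spacing: float = 10.0,
) -> PointPattern:
    """TCR positions inferred from membrane topography.

    Density ~ exp(-(z - z_min)/z_scale): TCRs concentrate where the
    membrane is within ~z_scale (default 10 nm) of the tightest contact.
    """
    if n_points <= 0:
        raise InvalidConfigurationError("n_points must be > 0")
    if z_scale <= 0:
        raise InvalidConfigurationError("z_scale must be > 0")
    topo = np.asarray(topography, dtype=float)
    if not np.all(np.isfinite(topo)):
        raise InvalidConfigurationError("topography must be finite")
    rng = np.random.default_rng(seed)
    w = np.exp(-(topo - topo.min()) / z_scale)
    xy = sample_from_height_weights(topo, w, n_points, grid_spacing, rng)
    return PointPattern(xy, np.array([TCR] * n_points, dtype=object))


def generate_scene(params: SceneParams | None = None, seed: int | None = None) -> SyntheticScene:
    """Generate a full synthetic scene (topography + point patterns)."""
    params = params or SceneParams()
    params.validate()
    if seed is not None:
        params = SceneParams(**{**vars(params), "seed": seed})
    rng = np.random.default_rng(params.seed)
    topo = make_topography(params, rng)

    tcr = estimate_tcr_from_topography(
        topo,
        params.n_tcr,
        params.tcr_z_scale,
        seed=int(rng.integers(2**31)),
        grid_spacing=params.grid_spacing,
    )
    # CD45 concentrated in its height band on the contact slopes
    lo, hi = params.cd45_band
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    w_cd45 = np.exp(-0.5 * ((topo - mid) / max(half, 1e-9)) ** 2)
    cd45_xy = sample_from_height_weights(
        topo, w_cd45, params.n_cd45, params.grid_spacing, rng
    )
    cd45 = PointPattern(cd45_xy, np.array([CD45] * params.n_cd45, dtype=object))

    # pTCR subset: a phos_fraction share of the cluster-member TCRs,
    # drawn with a peripheral-annulus bias
    c = params.patch_size / 2.0
    r = np.hypot(tcr.xy[:, 0] - c, tcr.xy[:, 1] - c)
    member = r <= params.contact_radius + params.rim_width
    m_idx = np.flatnonzero(member)
    if m_idx.size == 0:
        m_idx = np.arange(params.n_tcr)
    n_ptcr = max(1, int(round(params.phos_fraction * m_idx.size)))
    if params.ptcr_ring_width > 0:
        w = np.exp(
            -0.5
            * ((r[m_idx] - params.ptcr_ring_radius) / params.ptcr_ring_width) ** 2
        )
        w = w + 1e-12
    else:
        w = np.ones(m_idx.size)
    # weighted sampling without replacement (Efraimidis-Spirakis keys)
    keys = rng.random(m_idx.size) ** (1.0 / w)
    ptcr_idx = m_idx[np.argsort(keys)[-n_ptcr:]]
    phos_flags = np.zeros(params.n_tcr, dtype=bool)
    phos_flags[ptcr_idx] = True
    tcr.marks["phosphorylated"] = phos_flags
    return SyntheticScene(topo, params.grid_spacing, tcr, cd45, np.sort(ptcr_idx), params)


def estimate_obs(
    scene: SyntheticScene, cluster_radius: float | None = None
) -> ObsEstimates:
    """Empirical (Phos, Rg) estimates from a scene.

    The estimate is per TCR cluster: membership is a radial cut about the
    contact centre (default contact_radius + rim_width), excluding the
    sparse far-field TCRs outside the contact.  Phos is the counting
    fraction of phosphorylated members; Rg is the ratio of the pTCR RMSD
    to the cluster radius of gyration, both about the cluster COM.
    """
    p = scene.params
    if cluster_radius is None:
        cluster_radius = p.contact_radius + p.rim_width
    c = p.patch_size / 2.0
    xy = scene.tcr_points.xy
    member = np.hypot(xy[:, 0] - c, xy[:, 1] - c) <= cluster_radius
    phos_flags = np.zeros(len(xy), dtype=bool)
    phos_flags[scene.ptcr_indices] = True
    n_tcr = int(member.sum())
    n_ptcr = int((member & phos_flags).sum())
    if n_tcr < 2:
        raise InsufficientPatternError("need >= 2 TCRs in the cluster")
    if n_ptcr < 1:
        raise InsufficientPatternError("undefined estimate: no pTCR in cluster")
    phos = n_ptcr / n_tcr
    rg = rg_ratio(xy[member], xy[member & phos_flags])
    return ObsEstimates(phos, rg, n_tcr, n_ptcr)
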