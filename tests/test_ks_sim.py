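"""Kinetic-segregation simulator: initialization, dynamics, estimator."""
import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from tcrmeta import (
    CD45,
    TCR,
    InsufficientPatternError,
    InvalidConfigurationError,
    KSConfig,
    MembraneState,
    PointPattern,
    depletion_width,
    init_state,
    load_trajectory,
    run_ks,
    save_trajectory,
)


class TestInitState:
    def test_empty_tcr_species(self):
        s = init_state(KSConfig(n_tcr=0, n_pmhc=0, seed=1))
        assert len(s.molecules.select(TCR)) == 0
        assert s.bonds.size == 0

    def test_default_cluster_geometry(self):
        cfg = KSConfig(seed=2)
        s = init_state(cfg)
        tcr = s.molecules.coords(TCR)
        c = cfg.patch_size / 2
        r = np.hypot(tcr[:, 0] - c, tcr[:, 1] - c)
        # one central cluster: all TCRs inside the cluster disk (+jitter)
        assert np.all(r <= cfg.tcr_cluster_radius + 20)
        assert np.all((s.molecules.xy >= 0) & (s.molecules.xy <= cfg.patch_size))
        assert np.all(s.z >= 0)
        assert s.n_bound == 0

    def test_seeded_determinism_bit_exact(self):
        a, b = init_state(KSConfig(seed=3)), init_state(KSConfig(seed=3))
        np.testing.assert_array_equal(a.molecules.xy, b.molecules.xy)
        np.testing.assert_array_equal(a.z, b.z)

    def test_capacity_error(self):
        with pytest.raises(InvalidConfigurationError):
            init_state(KSConfig(n_cd45=10_000, seed=0))

    @pytest.mark.parametrize(
        "bad",
        [
            {"grid_spacing": 30.0},  # does not divide 2000
            {"h_cd45": 10.0},  # below the bond height
            {"u_assoc": -1.0},
            {"rigidity": -5.0},
        ],
    )
    def test_invalid_configurations(self, bad):
        with pytest.raises(InvalidConfigurationError):
            KSConfig(**bad).validate()


class TestDynamics:
    def test_noninteracting_distributions_are_stationary(self):
        """With all interaction coefficients and rigidity zero, the CD45
        radial distribution at t_end is indistinguishable from t=0."""
        cfg = KSConfig(
            rigidity=0.0, u_rep=0.0, u_adh=0.0, k_bond=0.0, k_tcr_free=0.0,
            u_assoc=0.0, separation_pressure=0.0, n_cd45=500, n_tcr=50,
            n_pmhc=60, cd45_exclusion_radius=0.0, t_end=100.0,
            sample_times=(0.0, 100.0), seed=11,
        )
        traj = run_ks(cfg)
        c = cfg.patch_size / 2
        r0 = np.hypot(*(traj.states[0].molecules.coords(CD45) - c).T)
        r1 = np.hypot(*(traj.states[-1].molecules.coords(CD45) - c).T)
        assert stats.ks_2samp(r0, r1).pvalue > 0.01

    def test_same_seed_trajectories_identical(self):
        cfg = KSConfig(t_end=5.0, sample_times=(0.0, 5.0), seed=21)
        a, b = run_ks(cfg), run_ks(cfg)
        np.testing.assert_array_equal(a.states[-1].molecules.xy, b.states[-1].molecules.xy)
        np.testing.assert_array_equal(a.states[-1].z, b.states[-1].z)
        np.testing.assert_array_equal(a.states[-1].bonds, b.states[-1].bonds)

    def test_bonds_conserved_at_high_association(self):
        """At U = 50 kT no bond ruptures over the trajectory: a TCR once
        bound keeps its partner in every later sample."""
        cfg = KSConfig(u_assoc=50.0, t_end=100.0, seed=31)
        traj = run_ks(cfg)
        prev = traj.states[0].bonds
        for s in traj.states[1:]:
            was_bound = prev >= 0
            assert np.all(s.bonds[was_bound] == prev[was_bound])
            prev = s.bonds

    def test_depletion_grows_with_cd45_ectodomain_height(self):
        """Longer CD45 isoforms (larger ectodomain) widen the depletion
        zone, all else fixed (replicate medians; the median is robust to
        occasional estimator collapses from transient strays)."""
        widths = {}
        for h in (40.0, 70.0):
            vals = []
            for seed in range(41, 47):
                cfg = KSConfig(h_cd45=h, rigidity=50.0, t_end=60.0,
                               sample_times=(60.0,), seed=seed)
                vals.append(depletion_width(run_ks(cfg).states[-1]).width)
            widths[h] = np.median(vals)
        assert widths[70.0] > widths[40.0]

    def test_depletion_monotone_in_rigidity(self, training_grids):
        """Final depletion width is non-decreasing in R within replicate
        standard error (training-grid means at t = 100 s)."""
        g = training_grids["KS"]
        dep = g.outputs["dep"][-1]  # t = 100 s row
        sd = g.output_sd["dep"][-1] / np.sqrt(g.n_replicates)
        for j in range(len(dep) - 1):
            assert dep[j + 1] >= dep[j] - (sd[j] + sd[j + 1])
        assert dep[-1] > dep[0] + 50  # overall growth well beyond noise


class TestDepletionEstimator:
    def test_constructed_disk_and_annulus(self):
        rng = np.random.default_rng(5)
        n = 4000
        r_t = 200 * np.sqrt(rng.random(n))
        th = 2 * np.pi * rng.random(n)
        tcr = np.column_stack([r_t * np.cos(th), r_t * np.sin(th)]) + 1000
        r_c = np.sqrt(300**2 + (500**2 - 300**2) * rng.random(n))
        th = 2 * np.pi * rng.random(n)
        cd45 = np.column_stack([r_c * np.cos(th), r_c * np.sin(th)]) + 1000
        state = _state_from_points(tcr, cd45)
        d = depletion_width(state)
        # closed-form quantile positions: TCR 95% radius = 200*sqrt(0.95),
        # CD45 5% radius = sqrt(300^2 + 0.05*(500^2-300^2)); the gap is the
        # ~100 nm construction gap plus the documented quantile bias
        expected = np.sqrt(300**2 + 0.05 * (500**2 - 300**2)) - 200 * np.sqrt(0.95)
        assert d.width == pytest.approx(expected, abs=8.0)
        assert d.width == pytest.approx(100.0, abs=25.0)

    def test_interleaved_species_give_zero(self):
        rng = np.random.default_rng(6)
        tcr = rng.random((2000, 2)) * 2000
        cd45 = rng.random((2000, 2)) * 2000
        assert depletion_width(_state_from_points(tcr, cd45)).width == 0.0

    def test_missing_species_raises(self):
        tcr = np.random.default_rng(7).random((10, 2)) * 2000
        with pytest.raises(InsufficientPatternError):
            depletion_width(_state_from_points(tcr, np.empty((0, 2))))


def _state_from_points(tcr_xy, cd45_xy):
    xy = np.vstack([tcr_xy, cd45_xy])
    species = np.array(
        [TCR] * len(tcr_xy) + [CD45] * len(cd45_xy), dtype=object
    )
    mols = PointPattern(xy, species, {"bound": np.zeros(len(xy), bool)})
    pmhc = PointPattern(np.empty((0, 2)), np.array([], dtype=object))
    return MembraneState(
        np.zeros((4, 4)), mols, pmhc, np.full(len(tcr_xy), -1, np.int64), 0.0
    )


def test_trajectory_roundtrip(tmp_path):
    cfg = KSConfig(t_end=5.0, sample_times=(0.0, 5.0), seed=51)
    traj = run_ks(cfg)
    path = tmp_path / "traj.h5"
    save_trajectory(path, traj)
    back = load_trajectory(path)
    assert len(back.states) == len(traj.states)
    np.testing.assert_allclose(back.states[-1].z, traj.states[-1].z)
    np.testing.assert_allclose(back.states[-1].molecules.xy, traj.states[-1].molecules.xy)
    np.testing.assert_array_equal(back.states[-1].bonds, traj.states[-1].bonds)
    assert back.config.rigidity == cfg.rigidity
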