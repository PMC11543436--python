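"""Lck* density field, phosphorylation assignment, Rg ratio, Csk."""
import numpy as np
import pytest

from tcrmeta import (
    InsufficientPatternError,
    InvalidConfigurationError,
    PhosConfig,
    PointPattern,
    apply_csk_inhibition,
    assign_phosphorylation,
    lck_density,
    rg_ratio,
)


class TestLckDensity:
    def test_exponential_kernel_identity(self):
        rho = lck_density(np.array([[0.0, 0.0]]), 70.0, np.array([[0, 0], [70, 0]]))
        assert rho[1] / rho[0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_additivity_of_coincident_sources(self):
        q = np.random.default_rng(0).normal(0, 300, (50, 2))
        one = lck_density(np.zeros((1, 2)), 50.0, q)
        two = lck_density(np.zeros((2, 2)), 50.0, q)
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)

    def test_infinite_decay_length_limit_is_uniform(self):
        cd45 = np.random.default_rng(1).random((100, 2)) * 2000
        q = np.random.default_rng(2).random((200, 2)) * 2000
        rho = lck_density(cd45, 1e7, q)
        assert rho.max() / rho.min() < 1.001

    def test_empty_cd45_gives_zero_field(self):
        rho = lck_density(np.empty((0, 2)), 70.0, np.zeros((5, 2)))
        assert np.all(rho == 0.0)


class TestRgRatio:
    def test_identical_sets_give_one(self):
        pts = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], float)
        assert rg_ratio(pts, pts) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # COM=(0.5,0), Rg=sqrt(3)/2, RMSD of {(2,0)}=1.5 -> ratio=sqrt(3)
        tcr = np.array([[0, 0], [0, 0], [0, 0], [2, 0]], float)
        assert rg_ratio(tcr, np.array([[2.0, 0.0]])) == pytest.approx(np.sqrt(3.0))

    def test_uniform_subsample_is_unbiased(self):
        """Half of a 10^4-point uniform disk has Rg ratio 1 +/- 0.02."""
        rng = np.random.default_rng(3)
        r = 500 * np.sqrt(rng.random(10_000))
        th = 2 * np.pi * rng.random(10_000)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        ratios = [
            rg_ratio(pts, pts[rng.random(10_000) < 0.5]) for _ in range(100)
        ]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)

    def test_empty_ptcr_is_an_error(self):
        with pytest.raises(InsufficientPatternError):
            rg_ratio(np.zeros((3, 2)), np.empty((0, 2)))


class TestAssignPhosphorylation:
    def test_no_cd45_means_no_phosphorylation(self):
        tcr = np.random.default_rng(0).random((50, 2)) * 1000
        pat = assign_phosphorylation(tcr, np.empty((0, 2)), PhosConfig(seed=1))
        assert pat.phos == 0.0
        assert not pat.rg_defined
        assert pat.no_cd45

    def test_saturating_density_phosphorylates_everything(self):
        tcr = np.random.default_rng(1).random((200, 2)) * 100
        cd45 = np.zeros((1, 2))
        cfg = PhosConfig(decay_length=1e7, beta=1e9, seed=2)
        pat = assign_phosphorylation(tcr, cd45, cfg)
        assert pat.phos == 1.0
        assert pat.rg_ratio == pytest.approx(1.0)

    def test_probabilities_bounded(self):
        tcr = np.random.default_rng(2).random((100, 2)) * 1000
        cd45 = np.random.default_rng(3).random((50, 2)) * 1000
        for rule in ("linear-capped", "normalize-by-max", "exp-saturating"):
            pat = assign_phosphorylation(
                tcr, cd45, PhosConfig(prob_rule=rule, beta=3.0, seed=4)
            )
            assert np.all(pat.probabilities >= 0) and np.all(pat.probabilities <= 1)

    def test_only_bound_gates_unbound_tcrs(self):
        rng = np.random.default_rng(5)
        xy = rng.random((60, 2)) * 200
        bound = np.zeros(60, bool)
        bound[:20] = True
        pat_in = PointPattern(xy, np.array(["TCR"] * 60, dtype=object), {"bound": bound})
        cfg = PhosConfig(decay_length=1e6, beta=1e9, only_bound=True, seed=6)
        pat = assign_phosphorylation(pat_in, np.zeros((1, 2)), cfg)
        assert pat.flags[:20].all()
        assert not pat.flags[20:].any()

    def test_peripheral_geometry_enriches_ptcr(self):
        """Central TCR disk + TCR ring near a CD45 ring: expected Rg ratio
        above 1 (peripheral phosphorylation)."""
        rng = np.random.default_rng(7)
        disk = rng.normal(0, 50, (100, 2))
        th = 2 * np.pi * rng.random(100)
        ring = np.column_stack([500 * np.cos(th), 500 * np.sin(th)])
        tcr = np.vstack([disk, ring])
        th = 2 * np.pi * rng.random(200)
        cd45 = np.column_stack([700 * np.cos(th), 700 * np.sin(th)])
        ratios = []
        for s in range(200):
            pat = assign_phosphorylation(tcr, cd45, PhosConfig(decay_length=70, seed=s))
            if pat.rg_defined:
                ratios.append(pat.rg_ratio)
        assert np.mean(ratios) > 1.0

    def test_phos_nondecreasing_in_decay_length(self):
        """Expected phosphorylated fraction grows with the decay length for
        a fixed segregated geometry (fixed probability scale)."""
        rng = np.random.default_rng(8)
        tcr = rng.normal(0, 100, (150, 2))
        th = 2 * np.pi * rng.random(300)
        r = rng.uniform(350, 600, 300)
        cd45 = np.column_stack([r * np.cos(th), r * np.sin(th)])
        means = []
        for dl in (30.0, 70.0, 200.0):
            vals = [
                assign_phosphorylation(
                    tcr, cd45, PhosConfig(decay_length=dl, beta=0.5, seed=s)
                ).phos
                for s in range(100)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestCsk:
    def _ring_pattern(self):
        rng = np.random.default_rng(9)
        disk = rng.normal(0, 60, (100, 2))
        th = 2 * np.pi * rng.random(80)
        ring = np.column_stack([300 * np.cos(th), 300 * np.sin(th)])
        tcr = np.vstack([disk, ring])
        cd45 = np.column_stack([450 * np.cos(th), 450 * np.sin(th)])
        pat = assign_phosphorylation(tcr, cd45, PhosConfig(decay_length=80, seed=10))
        return pat, tcr

    def test_zero_strength_is_identity(self):
        pat, tcr = self._ring_pattern()
        out = apply_csk_inhibition(pat, tcr, 0.0)
        np.testing.assert_array_equal(out, pat.densities)

    def test_attenuation_is_monotone_in_strength(self):
        pat, tcr = self._ring_pattern()
        d1 = apply_csk_inhibition(pat, tcr, 1.0)
        d2 = apply_csk_inhibition(pat, tcr, 2.0)
        assert np.all(d2 <= d1 + 1e-15)
        assert np.all(d1 <= pat.densities + 1e-15)

    def test_strong_csk_suppresses_interior_density(self):
        """With pTCRs on the ring, very strong Csk drives the residual Lck*
        density at the cluster interior below its no-Csk value."""
        pat, tcr = self._ring_pattern()
        interior = np.array([[0.0, 0.0], [30.0, 0.0]])
        base = np.ones(2)  # no-Csk interior density (arbitrary positive units)
        out = apply_csk_inhibition(
            pat, tcr, 1e9, query_xy=interior, densities=base
        )
        assert np.all(out < base)

    def test_negative_strength_rejected(self):
        pat, tcr = self._ring_pattern()
        with pytest.raises(InvalidConfigurationError):
            apply_csk_inhibition(pat, tcr, -1.0)
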