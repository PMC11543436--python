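# Methods

`tcrmeta` models the first tens of seconds of T-cell receptor (TCR)
signaling at a nascent immune-synapse contact. Three partial models —
kinetic segregation (KS), Lck activation (Lck-A), and TCR phosphorylation
(pTCR) — are simulated, summarized by probabilistic surrogates, coupled
into one Bayesian metamodel, and conditioned on two observed nanoscale
statistics. A separate scenario scans pMHC:TCR association strengths in an
initial contact and scores T-cell discrimination. This note records the
models, their assumptions, the numerical choices, and what the synthetic
data does and does not establish.

## Kinetic-segregation model (`ks_sim`)

A 2 µm × 2 µm patch of T-cell membrane faces an APC surface carrying a
cluster of pMHC. The state is a height field z(x, y) ≥ 0 (T-cell membrane
height above the APC, nm) on a square grid (default spacing 25 nm, edges
clamped at the CD45 resting height) plus mobile TCR and CD45 molecules
with continuous, periodically wrapped coordinates. Metropolis dynamics act
on three move classes per sweep:

* **Height moves** (±2 nm proposals per node, capped at z_max = 150 nm)
  scored by
  - a discretized bending energy `R/(2a²) · Σ (z_E+z_W+z_N+z_S−4z)²`,
    whose continuum limit is `(R/2)∫(∇²z)² dA` with the rigidity R in
    kT·nm² (default 50, swept 0–100);
  - harmonic bond springs `k_bond (z − h_tcr_bond)²` (k = 0.5 kT/nm²) at
    nodes holding pMHC-bound TCRs, pulling the membrane to the TCR–pMHC
    complex height (13 nm);
  - a one-sided harmonic steric wall `u_rep (h_cd45 − z)²` for z below the
    CD45 ectodomain height (50 nm; u_rep = 0.5 kT/nm²) at CD45-occupied
    nodes, with a shallow Gaussian adhesion well (depth 2 kT, width 5 nm)
    at h_cd45 representing weak CD45 attachment to the apposed surface;
  - a weak height preference `k_free (z − h_tcr_bond)²` (k = 0.005) for
    unbound TCRs (short ectodomain, crowding);
  - a separation pressure of 0.05 kT/nm per node for z < h_cd45,
    representing glycocalyx repulsion that drives unbonded membrane apart
    up to the CD45 resting distance. This term sets the ~10 s timescale on
    which a flat 15 nm contact relaxes and segregation becomes visible.

  The 50 − 13 = 37 nm height mismatch between the CD45 ectodomain and the
  TCR–pMHC complex is the driver of segregation.

* **Lateral hops**: Gaussian steps with per-axis σ = √(2·D·Δt) so that a
  free molecule's mean-square displacement per sweep equals 4·D·Δt
  (D = 0.05 µm²/s, Δt = 0.01 s per sweep). A bound TCR may not move
  beyond the capture radius (10 nm) of its pMHC partner.

* **Bond toggling**: binding is diffusion-limited — attempted once per
  sweep when a TCR is within the capture radius of a free pMHC and the
  local height is within ±5 nm of the complex height. Dissociation is a
  Kramers-type event at attempt frequency ν = 7×10¹⁰ s⁻¹ with acceptance
  `exp(−U_assoc + E_spring)`: the elastic energy stored in a stretched
  bond spring lowers the rupture barrier, which couples membrane lift to
  bond loss (peeling). A ruptured TCR is refractory for 2 s before it may
  re-engage (diffusional escape and conformational recovery of the
  complex; sub-second recrossings are considered part of the bound state).
  This bond move is kinetic, not strictly detailed-balanced: the on- and
  off-attempt bookkeeping differ, which is intentional — the quantities of
  interest are relaxation pathways and contact lifetimes, not equilibrium
  constants.

**Initial condition.** One engaged microcluster: pMHC scattered in a
central disk (radius 350 nm; 150 copies by default), TCRs placed opposite
pMHC sites with 3 nm jitter (bonds still form dynamically in the first
sweeps), CD45 (300 copies) uniform outside a 250 nm tight-contact core,
membrane flat at 15 nm. With this start the depletion zone develops from
≈0 over tens of seconds, faster and wider at higher rigidity.

**Depletion-width estimator.** About the TCR centre of mass, the gap
between the radius containing 95 % of TCRs and the 5 % radial quantile of
CD45, clamped at zero (quantiles configurable). At R = 0 the membrane
accommodates both species without bending cost and the estimator reads
≈0; the estimator also reads ≈0 at t = 0 by construction of the initial
condition.

**Calibration.** The kinetic constants that no published description
fixes (attempt frequency, bind probability, refractory time, wall and
spring stiffnesses, separation pressure) were chosen so the default
configuration reproduces the documented regime structure of the system:
no depletion at zero rigidity; depletion monotone in rigidity and in the
CD45 ectodomain height; a detached/persistent contact boundary near
25 kT with complete detachment of weak contacts within ~30 s; and pTCR
counts that saturate at the bound-TCR count for decay lengths beyond
~60–70 nm. They were then frozen; they are configuration fields, not
fitting parameters.

## Lck activation model (`lck_walk`)

Active Lck (Lck*) is created at a CD45 molecule and performs a 2D random
walk (Gaussian steps, per-axis σ = √(2·Diff·dt)) until deactivated with
probability P_off·dt per step (dt = 0.01 s, 1000 steps, 1000 walkers by
default). Deactivated walkers keep their deactivation position. The
radial histogram of end distances (20 nm bins) decays roughly
exponentially; its decay length is the activity range.

Estimators: the default fits log counts of nonempty bins from the
histogram mode outward (the small-r rise of the 2D radial measure is not
part of the decay); the `mle` method uses the exact first moment of the
2D killed-diffusion propagator, E[r] = (π/2)·λ, giving λ = (2/π)·mean(r).
For sweeps, only deactivated walkers are pooled — walkers still active
after the last step are still spreading and do not measure the activity
range. The histogram upper limit extends beyond half the nominal grid
when the 99th percentile of distances exceeds it (wide-λ cells would
otherwise be truncated).

Theory predicts λ ∝ √(Diff/P_off); both the ridge exponent of
Diff = C·P_off^α (α ≈ 1) and the collapse of log λ on
u = (log Diff − log P_off)/2 are checked against this.

## TCR phosphorylation model (`ptcr_field`)

The Lck* density at x is `ρ(x) = Σ_j exp(−|x − c_j|/DL)` over CD45
positions c_j. Each TCR is phosphorylated all-or-none by a Bernoulli draw
with probability mapped from ρ: `min(1, β·ρ)` (default), `ρ/max ρ`, or
`1 − exp(−β·ρ)`. When β is not given, the linear-capped rule calibrates
it so the maximum density over the queried TCRs maps to 0.95. With
`only_bound`, unbound TCRs get probability zero (ligand-gated ITAM
accessibility). There is no dephosphorylation term at any distance:
segregated CD45 requires direct contact to act on ITAMs, which the
depletion zone prevents.

Summaries: `phos`, the phosphorylated fraction; `rg_ratio`, the RMSD of
pTCRs about the centre of mass of **all** TCRs divided by the radius of
gyration of all TCRs (1 = like-distributed, >1 = peripheral). The ratio
is flagged undefined when nothing is phosphorylated.

The optional Csk extension places Csk at current pTCR positions (short
20 nm kernel) and attenuates the Lck* field by `exp(−strength·σ(x))` in a
single pass; it is not iterated to a fixed point by default.

## Surrogates (`surrogate`)

Each partial model is summarized by a training grid (replicate means/SDs
of its outputs over its input grid; failed cells are flagged, and ≥80 %
of cells must be valid to fit):

* KS: Dep over t ∈ {0, 5, 10, 20, 50, 100} s × R ∈ [0, 100] kT·nm²
  (each R×replicate is one trajectory sampled at all t).
* Lck-A: log₁₀ DL over a log grid of (P_off, Diff).
* pTCR: Phos and Rg over log₁₀ DL ∈ [20, 5000] nm × Dep ∈ [0, 300] nm,
  evaluated on a standard segregated geometry: a centrally concentrated
  TCR cluster (2D Gaussian, scale 100 nm, truncated at 250 nm — mirroring
  the decay of TCR density away from the tight-contact centre) with a
  CD45 annulus starting Dep beyond the cluster edge. One probability
  scale is used for the whole sweep, anchored so the most exposed TCR of
  the canonical geometry (70 nm decay length, 100 nm depletion) has
  p = 0.95; a per-cell scale would normalize away the effect of
  segregation on Phos.

The surrogate of each output is a polynomial mean function of the parents
(degree 2 by default; degree 3 for the saturating pTCR surfaces; the
Lck-A child uses the scaling basis u = (log₁₀ Diff − log₁₀ P_off)/2) plus
Gaussian noise. Because the mean is linear in its coefficients, the
posterior is exact conjugate normal–inverse-gamma (coefficient prior
N(0, 100²) on standardized features, Jeffreys-like inverse-gamma on the
noise); predictive means and SDs are analytic, and coefficient draws are
available for diagnostics. Leave-one-cell-out coverage at nominal 95 %
intervals is checked in the tests.

Root priors (wide, covering every training-axis value with positive
density): t ~ U[0, 100] s; R ~ U[0, 100] kT·nm²; log₁₀ Diff ~ N(−1, 1)
(µm²/s); log₁₀ P_off ~ N(1, 1) (s⁻¹); log₁₀ DL ~ N(2.5, 0.6) (nm,
spanning ~20–5000); the Dep prior is induced through the KS chain.

## Metamodel (`metamodel`)

Four coupling variables tie the same physical quantity across models:

    (t, R) → Dep^KS → Dep^C → Dep^pTCR ⟶ Phos^pTCR → Phos^C
    (Diff, P_off) → DL^LckA → DL^C → DL^pTCR ⟶ Rg^pTCR → Rg^C

Coupling conditionals are normal with scale σ_c, defaulting to 2 % of
each variable's training span; decay lengths live on the log₁₀ scale
throughout. Observations enter as Gaussian likelihoods on Phos^C
(0.22 ± 0.03) and Rg^C (1.31 ± 0.10); the printed 22 % is entered as the
fraction 0.22. The joint density is restricted to the pTCR surrogate's
training hull for (DL^pTCR, Dep^pTCR, Dep^KS) — polynomial surrogates are
not trusted to extrapolate.

Conditioning samples all 14 variables with an affine-invariant ensemble
sampler (96 walkers, 20 000 steps, half discarded, thinned; vectorized
log density). Convergence requires split-R̂ < 1.05 for every variable.
Posterior modes are KDE modes of the marginals, computed on each
variable's native scale (log₁₀ for decay lengths; the exponentiated copy
`dl_ptcr_nm` is provided for summaries but its KDE mode is skew-biased).
Correctness of the conditioning is validated against brute-force
enumeration of posterior ∝ likelihood × prior on a discretized miniature
of the (DL, Dep) slice (total-variation distance < 0.05), and by a
synthetic parameter-recovery experiment (90 % credible intervals cover
the generating values in ≥80 % of repetitions), run on the same reduced
slice to keep the suite fast.

`likelihood_map` estimates p(obs | pair) on a grid for the documented
pairs, marginalizing the remaining roots by Monte Carlo; the (Diff,
P_off) map shows the proportionality ridge expected from the scaling law.

## Affinity scan (`affinity_dynamics`)

The initial-contact protocol presses a finite contact disk (pMHC cluster
radius + 100 nm margin) to 15 nm for 10 s with a harmonic per-node clamp
(10 kT/nm²), then releases it for 90 s. While clamped, bond rupture is
suspended: with the membranes pressed together rupture is immediately
reversed (escape-limited kinetics), so dissociation acts once the
constraint is released, from a fully engaged cluster. Association
strengths U = 5–50 kT (step 5) with reduced molecule counts (60 TCR,
150 CD45, 80 pMHC) and 3 replicates are the desk-scale default (the full
design is 5 replicates); results at this scale are to be read as
scaled-down.

At 1 s cadence the bound count is recorded and bound TCRs are
phosphorylated per decay length of a grid (10–100 nm), in snapshot mode
(no memory between frames; a sticky mode that keeps marks while bound is
available but off by default). The dynamic scenario uses the
exp-saturating probability rule with β = 30, calibrated so the persistent
contact's pTCR count stays below the 5-count threshold at DL = 30 nm and
reaches the bound count beyond ~70 nm.

Derived quantities: the detached/persistent boundary (midpoint between
the largest fully detaching and smallest persisting U — a run counts as
detaching only if every replicate reaches zero bound TCRs); detachment
times (first zero-bound sample); the longest contiguous interval with
more than n_min pTCRs; the activation rule (duration ≥ τ); and per-DL
sensitivity (positives: U > 25 kT activated) and specificity (negatives:
U ≤ 25 kT not activated) with balanced accuracy.

## Synthetic observations (`synthetic_obs`)

The raw imaging behind the empirical anchors is not consumed. A scene
emulates it: a sigmoidal tight-contact depression (contact radius 300 nm,
rim 120 nm, far field 60 nm) plus correlated Gaussian surface noise
(100 nm correlation length); TCRs sampled with density
∝ exp(−(z − z_min)/10 nm) (concentrated where z < 10 nm); CD45 sampled
in the 30–40 nm height band on the slopes; and a pTCR subset (22 % of
cluster members) drawn with a peripheral-annulus bias (centre 280 nm,
width 55 nm). The estimate pipeline computes the counting fraction and
the Rg ratio over cluster members (a radial cut at contact radius + rim
width about the single cluster; the scene contains exactly one cluster so
no selection rule is needed beyond membership). The ring-bias defaults
are calibrated so the default scene reproduces the printed anchors
(0.22, ≈1.31); with the bias removed the Rg ratio is 1 within sampling
error, confirming the estimator is unbiased for like-distributed subsets.

## What the synthetic data shows — and does not

All tests run on synthetic inputs whose generative assumptions (radially
symmetric contacts, Poisson-like molecular placement, all-or-none ITAMs,
a single engaged microcluster, no localization error or drift) are
idealized. Passing them establishes internal consistency: the simulators
realize the documented qualitative physics, the surrogates faithfully
compress the simulators, conditioning obeys Bayes' theorem, and the
calibrated defaults reproduce the documented regime structure. They do
not establish that the inferred parameter values describe any particular
cell: real topographies are asymmetric, TCR clusters are multiple and
heterogeneous, PALM localizations carry uncertainty, and the
phosphorylation probability scale is a convention (results that depend on
it are checked for robustness, not taken as measurements).

## Problem sizes

Defaults are desk-scale: single KS trajectories take seconds (25 nm
grid, 100 s of dynamics); the affinity scan is 30 contact simulations;
surrogate training uses 6×6 (KS), 5×5 (Lck-A) and 10×6 (pTCR) grids with
3 replicates; conditioning uses ~96 000 post-burn-in draws. All
generators and samplers are fully seed-deterministic.

## Known limitations

No cytoskeleton, LFA-1/ICAM adhesion, co-receptors, SMAC-scale
organization, or serial pMHC engagement. The bond model trades strict
detailed balance for realistic contact lifetimes. The Csk extension is a
single-pass field attenuation and is not part of the metamodel. The KS
time axis is only as informative as the segregation timescale set by the
separation pressure; the surrogate treats the depletion width as a smooth
function of (t, R) although individual trajectories are noisy.
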