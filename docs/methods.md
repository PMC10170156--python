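# Methods

## Model

The simulator follows a single receptor on a two-dimensional periodic
square lattice. The state is (site, ligand flag, alive flag, time). One
timestep consists of a diffusion attempt, a binding check, then a removal
check; this fixed ordering matters only at O(rate·Δt) ≈ 10⁻⁶ and is chosen
for determinism.

*Diffusion.* The target site is drawn uniformly from the four nearest
neighbours (periodic wrap). If the move does not change compartment
membership it always succeeds; if it does, it succeeds with the Metropolis
probability exp(−ΔE/k_BT). A rejected move leaves the receptor in place;
time advances by Δt either way. Δt = Δx²/(4D) makes the walk's large-scale
statistics those of free diffusion at diffusivity D.

*Barriers.* The barrier for a membership-changing move is the sum of the
boundary terms the move crosses: leaving the origin compartment plus
entering the target compartment. Tetraspanin boundary terms apply only to
unliganded receptors (entry 11.5, exit 13 k_BT), clathrin terms only to
liganded receptors (entry 1, exit 4.5 k_BT); all other terms are zero.
For the dominant outside↔domain moves this reduces to the four configured
constants. The compositional rule also covers the rare case of two
domains' lattice sites being directly adjacent (discs never overlap, but
discrete sites of different discs can touch): a naive per-pair lookup that
treats unlisted pairs as barrier-free would let unliganded receptors slip
into tetraspanin domains through an adjacent clathrin site, violating
detailed balance for such placements. With the compositional rule the
unliganded equilibrium density ratio between tetraspanin domains and the
rest of the membrane is exactly exp(E_exit − E_entry) = e^1.5 for every
placement, which the long-run oracle test verifies.

*Reactions.* Binding and removal are per-step Bernoulli events with
probability rate·Δt (first-order kinetics discretized; both products are
≈ 10⁻⁶ at the defaults, so discretization error is negligible). Binding is
irreversible, allowed only while inside a tetraspanin domain, and takes
effect instantly: from the binding step onwards the liganded barrier set
applies. Removal is possible only while liganded inside a clathrin domain.

*Geometry.* Domain centres are continuous coordinates drawn uniformly over
the torus by rejection sampling (pairwise periodic centre distance
≥ 2·r_dom; bounded at 10⁵ attempts, ample at the ~5% default coverage).
Discs may straddle the periodic edge. A lattice site belongs to a domain
iff the site centre lies within r_dom of the domain centre under the torus
metric; a boundary crossing is any move whose origin and target sites
differ in membership. Every trajectory draws a fresh placement.

*Initial state and censoring.* Receptors start unliganded at a uniformly
chosen outside site. Trajectories end at removal or at the censoring
horizon T_max (default 1000 s; the reference horizon for never-removed
receptors is a free choice — the model itself never terminates an unbound
receptor). Censored trajectories enter ensemble averages with their
observed lifetime as weight, the same lifetime-weighting rule used for
removed receptors.

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| D | 0.2 | μm²/s | receptor diffusivity |
| dx | 0.002 | μm | lattice spacing |
| L | 0.2 | μm | membrane edge (periodic) |
| n_tet, n_cla | 10, 10 | – | domain counts |
| r_dom | 0.0056 | μm | domain radius (area ≈ 100 nm²) |
| E_entry_tet, E_exit_tet | 11.5, 13 | k_BT | tetraspanin barriers (unliganded) |
| E_entry_cla, E_exit_cla | 1, 4.5 | k_BT | clathrin barriers (liganded) |
| k_bind | swept | s⁻¹ | in-tetraspanin binding rate (∝ ligand dose) |
| k_remove | 0.05 | s⁻¹ | in-clathrin removal rate |
| T_max | 1000 | s | censoring horizon |

Derived: Δt = 5·10⁻⁶ s, lattice 100×100. `Δt` is always recomputed from
(dx, D) and never stored independently.

## Ensemble statistics

Per-trajectory compartment fractions are exact residence-time ratios
accumulated by the engine (the event-compressed interval log reproduces
them identically). Ensemble fractions are lifetime-weighted means,
Σ lifetimeᵢ·fᵢ / Σ lifetimeᵢ; standard errors come from a 1000-resample
bootstrap over trajectories. Two liganded metrics are reported separately,
because "confinement of the liganded pool" can reasonably mean either: the
post-binding time fraction in *any* nanodomain (`f_confined_liganded`) and
in *clathrin* domains only (`f_liganded_cla`); at the defaults they nearly
coincide since liganded receptors spend little time in tetraspanin
domains.

The binding-rate sweep (default grid: 9 log-spaced rates, 10⁻⁴–1 s⁻¹, 100
trajectories per rate) reuses the same per-trajectory seed stream at every
rate (common random numbers): trajectory *i* sees the same domain
placement and noise sequence at all rates and diverges only when a binding
event fires, so rate-to-rate differences estimate the rate effect itself
rather than resampling noise. This makes the monotone depletion of
tetraspanin occupancy and enrichment of clathrin occupancy resolvable at
100 trajectories per point. At the lowest rates the expected number of
binding events among 100 trajectories is below one, so the liganded
fractions there are flagged undefined (NaN) rather than extrapolated.

First-passage times into tetraspanin domains are computed with binding and
removal disabled; censored replicates are excluded from the mean and
reported. The diffusivity estimator fits the ensemble MSD linearly (with
an intercept that absorbs static localization noise) over the first 25% of
lags and returns slope/4.

## Ligand occupancy

Occupancy is a Kd-weighted sum of Langmuir isotherms over two site
classes, with free ligand approximated by total ligand (bulk stimulation;
no depletion) and ng/mL converted to nM via the 6045 Da mass of mature
human EGF (200 ng/mL ↔ 33 nM). No cooperativity or kinetics are modelled.

## Imaging analyses and synthetic data

Spot detection mirrors Gaussian-model detection of diffraction-limited
puncta: difference-of-Gaussian band-pass, local maxima above four robust
noise SDs, least-squares refinement of a pixel-integrated isotropic
Gaussian plus flat background in a 4σ half-width window (σ is a fixed
input, default 1.1 px — instrument-dependent), a one-sided amplitude
t-test against the fit residual variance at α = 0.05, and merging of
detections within 1 px (brighter wins). The 4σ candidate floor is what
keeps pure-noise false positives near zero; the t-test alone cannot,
because selecting local maxima biases fitted amplitudes upward.

Secondary-channel intensities at primary detections are fixed-position
amplitude+background fits (linear least squares). All randomization nulls
re-place object positions uniformly within the cell mask, preserving
counts and never resampling amplitudes (defaults: 10 randomizations for
intensity backgrounds, 100 for position nulls). Position colocalization
scores a primary object as colocalized when its nearest secondary
neighbour is within 3 px (Euclidean, no sub-pixel correction to the
radius); the conditional analysis splits reference objects by a condition
channel at the same radius. Intensity cohorts bin object amplitudes into
26 equal-width cohorts between the 5th and 95th percentiles with a
median high/low split. The structure-positivity threshold defaults to the
95th percentile of the randomized-position amplitude null.

Synthetic images render spots as pixel-integrated Gaussians (point
sampling is inaccurate at σ ≈ 1 px) with log-normal amplitudes, flat
background, Poisson shot noise and Gaussian read noise, inside an
elliptical cell mask; planted colocalization fractions and condition
structure are stored as ground truth. These fields emulate the statistical
structure of TIRF puncta images but not optical realism: no camera gain
maps, no drift or chromatic offsets, no varying PSF, no overlapping dense
clusters. Passing round-trip tests therefore demonstrates estimator
correctness on well-specified data, not robustness to every instrumental
artefact of real microscopy.

## Numerical and implementation choices

The trajectory loop is numba-compiled with an inline xorshift64*
generator (splitmix64 seeding; direction from the low output bits, the
Metropolis/reaction uniforms from 53 high bits) and a precomputed
neighbour table, reaching ~2·10⁸ steps/s on one core. The loop's empirical
acceptance rate is itself under test against exp(−ΔE) for all four default
barrier heights at 99% binomial confidence. Reference single-step
operations implement identical semantics on `numpy.random.Generator` for
direct unit testing. Per-trajectory seeds derive from one root seed via
`SeedSequence`, so ensembles are reproducible and order-invariant and can
be partitioned across workers without changing results.

Problem sizes used by the shipped checks: 100 replicates for the
first-entry mean (~1.7·10⁹ steps), a 9 × 100-trajectory sweep at a 450 s
horizon, 60 000 s of no-reaction time (12 runs × 5000 s) for the
equilibrium-enrichment oracle, and 1000 barrier-free tracks of 10⁴ steps
for the diffusivity round trip — chosen so each estimate's sampling error
is comfortably inside the tolerance it is tested at.

## Limitations

Single-receptor model: no receptor–receptor interactions, oligomerization,
ligand unbinding, recycling, or off-lattice diffusion. Domain positions
are frozen within a trajectory. The mean first-entry time at the default
barriers is 88.0 ± 2.3 s under this discretization (site-centre
membership, one attempt per Δt) — consistent with the ~83 ± 8 s the
barriers were tuned to produce, with the residual offset attributable to
boundary discretization of the 2.8-site-radius discs. A 100-replicate mean
of this quantity carries an SE of ~8 s.
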