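# Methods

## Lattice model

Chromosomes are two self-avoiding ring polymers of N = 80 monomers evolved
with the bond-fluctuation method (BFM) on a cubic lattice. A monomer at
integer position p occupies the 8 lattice sites of the unit cube p + {0,1}³;
no site may be claimed twice (excluded volume), and consecutive ring
monomers are joined by bonds from the standard 3D BFM set — all permutation
and sign images of (2,0,0), (2,1,0), (2,1,1), (2,2,1), (3,0,0), (3,1,0),
108 vectors with squared lengths {4, 5, 6, 9, 10}. This set guarantees that
single-site moves can never carry one bond through another, so ring topology
is conserved without explicit entanglement checks.

The confinement is a hard-walled 80 × 10 × 10 box (positions 0..L−1 per
axis; a cube may touch but not cross a wall). With N = 80 the equilibrium
radius of gyration of an *unconfined* ring is ≈ 10.6 lattice units, larger
than the lateral box size — the rings are genuinely confined, which is the
regime in which entropic repulsion between two rings is strong.

Kinetics: an elementary move displaces one random monomer by one lattice
unit along one of the 6 axial directions, accepted only if the monomer is
not tethered, the cube stays in the box, the four target sites are free,
and both ring bonds remain in the allowed set. One MCS = M attempted moves
(M = total monomers). Moves are proposed uniformly; all accepted moves are
symmetric, so detailed balance holds with respect to the uniform measure
over valid configurations. The test suite verifies this directly: visit
frequencies of a 4-ring in a 6×6×6 box are compared against the exactly
enumerated configuration set (4 579 392 labeled states, projected on the
monomer-0 position marginal for a well-powered χ² at 2 × 10⁴ thinned
samples).

An "entropy-off" switch disables only the cross-ring excluded volume;
each ring remains self-avoiding. This isolates the ratchet contribution
from the entropic one.

### Initialization

The t=0 state must be two intermixed rings whose axial centres of mass
(CMs) sit at mid-cell. We build a deterministic template — each ring a
Hamiltonian cycle on a spacing-2 grid (10×4×2 for N = 80), the two rings
stacked side by side along z, axially centred and therefore 100 %
axially overlapping — and then randomize it with 1000 seeded mixing sweeps
during which any x-move that would take either ring's axial CM more than
1.0 lattice unit from mid-cell is rejected. This replaces stochastic
growth-with-backtracking: it cannot fail, is bitwise reproducible per seed,
and satisfies the same t=0 contract (both |CM_x − Lx/2| ≤ 1, axial extent
overlap ≥ 50 % of the smaller extent). Left/right labels are assigned from
the sign of CM_x − Lx/2 after mixing (RNG tie-break). Because the initial
CM offsets are at most ~1 lattice unit (~0.0125 in relative units), these
labels carry little information about the final side — a point that matters
for how positioning precision is measured (below).

## Tethering (the Brownian ratchet)

Monomers whose cube lies within d_b lattice units of a *lateral* wall
(y or z; the pole caps carry no sites) may bind with probability p(x, t)
per MCS; bound monomers are immobilized for a geometric dwell time of mean
τ and then released. Field regimes:

- uniform: p = p_max everywhere;
- static gradient: p(x) = p_max (2|x/Lx − ½|)^s — zero at mid-cell,
  maximal at the poles, steepness s;
- oscillating gradient: the static profile restricted to one axial half,
  alternating every half-cycle T (idealized Min oscillation);
- MinD-profile-driven: p(x, t) = p_max · Î(x, t), where Î is a measured or
  synthetic axial fluorescence profile series, max-normalized per frame,
  linearly interpolated in x, nearest-frame (cyclic) in time.

### Parameter regime

Only *orderings* between regimes are physically constrained, not absolute
binding parameters, and the mechanism requires tethering to be weak and
transient: strong or long-lived binding immobilizes the chromosome
everywhere and *blocks* segregation. The controlling quantity is the
equilibrium bound fraction at the field maximum, p_max·τ/(1 + p_max·τ).
Defaults — p_max = 0.01 per MCS, τ = 100 MCS, d_b = 2, T = 5000 MCS —
put that occupancy at ½ at the poles and near zero at mid-cell, the
ratchet regime: poleward excursions are held, mid-cell motion stays free.
With p_max raised to 0.1 (bound fraction > 0.9) the same code reproduces
the failure mode instead: the gradient condition segregates *worse* than
no tethering at all, the behaviour the 10×-dwell control is designed to
show. The 10×-dwell condition multiplies τ to 1000 at fixed p_max.

The oscillating and MinD-profile conditions use p_max = 0.02, twice the
static default. Rationale: the oscillation redistributes a conserved
tether-site population (MinD molecules) rather than modulating it — when
the whole population occupies one pole, the local site density is double
its time-average. Doubling the peak keeps the time-averaged site number
matched to the static gradient, so the regimes are compared at equal
total tethering capacity.

The synthetic MinD profile generator emulates the measured pole-to-pole
oscillation: frames every 7 s, full period 56 s, a polar cap decaying
linearly to zero at mid-cell (decay exponent adjustable), the occupied pole
switching each half-period, optional multiplicative noise. Real profiles
additionally carry uneven illumination, cytoplasmic background and
frame-to-frame population noise; the max-per-frame normalization absorbs
much of that, but tests passing on synthetic profiles demonstrate the
pipeline, not robustness to arbitrary imaging artefacts. The default time
mapping puts one 56 s oscillation at 10⁴ MCS, matching the idealized
oscillating gradient (T = 5000 MCS) so the two can be compared one-to-one.

## Observables and statistics

Per ring we track the relative axial CM, cm_rel = (⟨x_center⟩ − Lx/2)/Lx.
The separation statistic is Δ = mean |cm_rel|. "Final" values are
trailing-window time-averages (last 10 recorded points = last 5 × 10⁴ MCS
at the default cadence): the standard steady-state estimator, which also
averages out the deliberate CM oscillation that the oscillating gradient
imprints (catch-and-release wobble at the Min period).

Positioning precision is quantified on the *per-polymer* |final cm_rel|
pooled across runs — the spread of the cross-run CM distribution about the
quarter positions. The signed CM of the initially-right-labelled polymer is
also reported, but its variance mostly measures side-assignment flips (the
t=0 labels are nearly uninformative, see Initialization) rather than
positioning precision, so precision comparisons use the unsigned statistic.
Note that in this model the precision contrast between gradient and
no-tether conditions is weak at accessible ensemble sizes: the hard 1:8
confinement already positions the entropic steady state tightly, and the
contrast develops only slowly with run length (the entropic plateau wanders
diffusively, so its cross-run variance grows with time while the gradient's
does not). The corresponding variance-ordering test is therefore
underpowered at desk scale and can fail; the Δ orderings are the robust
desk-scale signal.

Condition orderings are tested with one-sided Mann–Whitney rank tests on
per-run Δ values; variance orderings with a one-sided bootstrap on the
pooled per-polymer variances. The steepness sweep is asserted
statistically — no step down in s may significantly *increase* Δ, and the
shallowest gradient must still significantly beat no tethering — because
adjacent steepness values (s = 2 vs s = 1) produce statistically tied point
estimates at feasible ensemble sizes.

### Force–distance probe

An attractive inter-ring potential U = f·d (d = axial CM separation in
lattice units, energies in kT; kT ≡ 1) is imposed through a Metropolis
layer on top of all hard constraints; at f = 0 the layer consumes no
randomness, making the probe bitwise identical to the plain model. Each
replicate first segregates force-free to steady state, then re-equilibrates
under the force and samples d. The pre-segregation matters: the
gradient-plus-attraction system is bistable (a strong enough pull can drag
both rings to one pole, where the gradient then *holds* them together), and
the probe measures the force balance of the separated branch — the branch
the mechanism maintains in vivo. The entropic model's equilibrium distance
falls steadily with f, while the gradient model sustains clearly larger
separations at the same loads; equivalently, at matched large distances it
balances a larger force.

## Scales used by the tests and the acceptance script

Ensembles are run to the steady state of the mechanism, 5 × 10⁵ MCS
(2 × 10⁵ MCS for the uniform / 10×-dwell / entropy-off controls, whose
effects are larger and already stationary there), with 16–32 replicates
per condition (seeds = seed_base + replicate index). At 10⁵ MCS all
conditions are still in the shared entropic transient and the gradient
advantage has not yet developed; the orderings discussed above are
steady-state statements. Replicate counts were sized to the effect sizes
(standardized differences ≈ 1–3 for the main orderings).

## Known limitations

- Absolute tethering parameters are model choices (only orderings are
  constrained); MCS does not map to wall-clock seconds except through the
  Min-cycle convention above.
- The tether field is unsaturable (no site-count bookkeeping) and release
  is force-independent (no slip/catch-bond behaviour).
- Rings are fixed length: no replication, supercoiling, or loop extrusion.
- The MSD standard errors pool overlapping frame pairs and understate
  uncertainty at large lags; the short-lag fit used for D_app is
  insensitive to this.
- nucleoid_separation reports R = 0 exactly at the two-lobe unimodality
  threshold (lobe distance = 2σ for equal Gaussians): a profile without an
  interior valley is a single nucleoid by definition. The R formula
  1 − I_valley/mean(I_peaks) is a convention chosen for boundedness and
  unit invariance.
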