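# Methods

## Model and assumptions

The simulator evolves N point agents in an unbounded 2D plane. Each agent
carries a position and an oscillator phase; the pairwise interactions are
those written in the README: unit-vector attraction with a phase-dependent
weight A + J cos(Δθ − Q_ẋ), inverse-distance repulsion B/r along the same
axis, and Kuramoto phase coupling weighted by 1/r. The model is first
order (overdamped): velocities are prescribed, not integrated from forces.
Key structural assumptions:

* **Mean-field 1/N normalisation everywhere.** The 1/N prefactor is kept
  verbatim under local coupling, i.e. the sums are *not* renormalised by
  the number of agents inside the coupling radius σ. Consequently the net
  force on an agent with k neighbors scales like k/N, and short-range
  configurations (σ well below the collective extent) are weakly forced
  relative to the noise. This is a deliberate, literal reading of the
  model's local-coupling equations; the alternative neighbor-count
  normalisation produces visibly different short-range states (a stiffer
  lattice with pronounced C_θθ peaks at multiples of the lattice spacing,
  and continued expansion of its extent over time).
* **Strict Heaviside gate.** A pair interacts iff σ − r > 0; r = σ is
  excluded. σ = ∞ disables the gate entirely.
* **Phase offsets only under frequency coupling.** Q_ẋ and Q_θ̇ depend only
  on the *signs* of the two natural frequencies: (0, 0) for same-sign,
  (π, π/2) for opposite-sign pairs. They are precomputed once per run. The
  cosine offset enters the attraction term only; the repulsion term carries
  no phase dependence. With single-sign distributions (F1, F3) the offsets
  vanish identically, so frequency-coupled and plain runs coincide.
* **Embryonic variant.** Attraction kernel (A + J cos Δθ)/r, repulsion
  B/r³ (both along the pair axis), distance-independent and ungated phase
  coupling sin(Δθ − α) with a constant lag α, no inherent velocity in the
  presets. Noise enters as in the standard variant.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| A, B | attraction / repulsion coefficients | 1 | fixed throughout the study conditions |
| J | space–phase interaction | 0 | study range [−1, 1], enforced at the config layer |
| K | phase coupling | 0 | study range [−1, 2] |
| speed | inherent speed magnitude, 0 or 1 | 0 | sign of the motion lives on ω |
| σ | coupling radius | ∞ | distance units |
| d | noise strength | 0 | per √time by default (below) |
| Ω | frequency bound of F3/F4 | 3 | U(1, Ω); orbit radii then span [1/3, 1] |
| dt, T, N | Euler step, final time, agents | 0.1, 1000, 500 | reference protocol |
| L | initial box side | 4 | positions uniform on the centred L×L square |
| ε | pair-distance floor | 1e−6 | see numerical choices |

## Numerical choices

* **Forward Euler** with the reference step dt = 0.1 (dt = 0.25 for the
  correlation protocol). A refinement test in the suite confirms first-order
  convergence against the analytic two-agent equilibrium.
* **Noise scaling.** The distribution of the white-noise terms is not
  pinned down by the model statement; they are implemented as zero-mean
  Gaussians with Euler–Maruyama √dt scaling so that d has a dt-independent
  meaning. `ModelParams.noise_scaling = "per_step"` preserves the literal
  per-step reading (d·G added raw each step).
* **Singularity softening.** The B/r repulsion diverges as r → 0; pair
  distances are floored at ε = 1e−6 before any division. Equilibrium
  spacings are O(1), so the floor never activates in healthy runs; it only
  prevents overflow when the Euler step carries two agents nearly on top
  of each other.
* **Phase storage.** Phases are wrapped to (−π, π] for all coupling terms
  (every coupling is 2π-periodic); the integrator additionally maintains
  cumulative unwrapped phases and cumulative centroid-relative angles so
  the cycle fraction γ never depends on post-hoc unwrapping of subsampled
  frames. A lone agent is its own centroid, so its angle is advanced with
  its phase — exact for chiral motion, where phase *is* the angular
  position about the orbit.
* **Divergence guard.** Any coordinate exceeding 1e6 in magnitude aborts
  the run with the failing time in the message; scans record such cells as
  missing rather than failing.
* **Seeding.** Every run consumes a single integer seed; scans and
  ensembles derive independent per-cell/per-run seeds through
  `numpy.random.SeedSequence(base, indices...)`, so any cell can be re-run
  in isolation bit-identically.

## Order parameters and correlation conventions

* φ_j, the angular position about the collective centroid, is computed
  with the two-argument arctangent of centroid-relative coordinates
  (a plain y/x ratio would lose the quadrant and could not reach S = 1 on
  a phase wave). Agents exactly at the centroid are excluded from S with a
  warning. The centroid is recomputed per frame.
* The heat-map scalar per run is S averaged over frames in the final 10%
  of the run (configurable window); scans report the mean and sd over
  independent trials.
* γ counts agents whose unwrapped phase *and* unwrapped centroid angle
  both change by at least 2π over the post-transient window; the default
  transient is 20% of the run, by which time every catalogued steady state
  has formed.
* Delta functions in the correlation sums are resolved on a histogram grid
  of width 0.05 (≥40 bins across the features of interest). g(r) is the
  ordered-pair fraction per unit distance, normalised by N(N−1) and bin
  width with no shell-area factor, so value × width sums to 1. C_θθ(r) is
  the conditional mean of cos(θ_i − θ_j) over pairs at distance r (the
  joint-density reading could not plateau at 1 for a synchronised
  cluster); raw pair counts are stored so either convention is
  recoverable. C_vv uses finite-difference velocities over one recording
  interval — the model is first order, so instantaneous velocities are not
  part of the recorded state — averaged over agents, post-transient times
  (default: final half), and the ensemble. Ensemble averaging pools bin
  sums and counts, which makes it linear: count-weighted averaging of
  per-run curves equals the pooled computation.
* `support_radius` operationalises "the curve's domain": the right edge of
  the last bin above 1% of the maximum. `decay_radius` returns the
  smallest r beyond which |C| stays below a level (default 0.1); its value
  saturates at the grid edge when the curve never decays within range.
  `count_peaks` counts strict local maxima of a 3-bin moving-mean smoothed
  curve inside a window.

## Synthetic data and what passing tests show

All inputs are generated programmatically: uniform initial positions and
phases per the reference protocol, frequency draws per F1–F4 (plus an
evenly spaced k-group generalisation over [1, Ω] for multi-group states,
and explicit custom values), and hand-constructed analytic fixtures (rings,
crosses, force-balanced pairs, synthetic trajectories). The generator
emulates the study conditions exactly — sample sizes, box, noise, time
step — and nothing else: there are no boundaries, no hydrodynamics, no
contact mechanics, no heterogeneous per-agent coupling ranges. Passing
tests therefore certify the implementation of *this* model and its
statistics, not agreement of the model itself with any laboratory swarm.

## Scaled problem sizes

The suite and the acceptance script use desk-scale versions of the heavy
protocols, chosen as the package's own reproducible defaults: the
correlation ensembles average 20 independent runs per coupling radius
(N = 300, dt = 0.25, T = 500), and the reduced phase-diagram scan runs a
16×16 (K, J) grid with 3 trials at N = 150, T = 300. The full-scale
protocol (N = 500, t_f = 1000, 10 trials, finer grid) is available through
the same APIs and the `scan` CLI command.

## Known limitations and open points

* The correlation-protocol configuration (J = K = 1, d = 0.05, all ω = 1,
  L = 4 box) as printed produces a synchronised cluster of diameter
  ≈ 1.2 — the pair equilibrium B/(A + J) = 0.5 sets the scale — and, at
  σ = 3, clusters that remain mutually phase-correlated, because the
  side-4 initial box places every pair inside the coupling radius and the
  population synchronises before clusters separate. Short-range (σ = 0.5)
  states are diffuse rather than crystalline under the literal 1/N
  normalisation (see above). These regimes are sensitive to the initial
  spread relative to σ and to the normalisation convention; both switches
  are exposed (`init_box`, and the documented alternative readings) so the
  neighbouring conventions can be explored.
* Direct O(N²) pair sums are the contract; no cell lists. N ≲ 1000 is the
  intended regime.
* State auto-classification into the named catalog is out of scope; the
  presets encode best-effort parameter locations and flag approximate ones.
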