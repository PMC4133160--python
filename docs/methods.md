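# Methods

## Model

Each cortical minicolumn is a Wilson–Cowan pair of excitatory (E) and
inhibitory (I) population activities `u, v ∈ [0, 1]`:

    tau_e du/dt = -u + f(C_EE u - C_IE v + P + B ξ + I_net,E)
    tau_i dv/dt = -v + f(C_EI u - C_II v + Q + I_net,I)

with the logistic transfer `f(x) = 1 / (1 + exp(-a (x - θ)))`.  A sheet
couples 150 × 150 such units (macrocolumns of 10 × 10 units, minicolumn
pitch 50 μm) through three connection types:

* **local E→E** — each ordered pair within 510 μm connects independently
  with probability `exp(-d²/2σ²)`, σ = 170 μm (the cutoff is ≈ 3σ);
* **local E→I** — same sampler and parameters, independent realization;
* **remote patchy E→E** — every macrocolumn owns 3 circular patches
  (radius 5 units → 81 units) drawn within 2.5 mm of its center, one of
  them shared with a uniformly chosen direct neighbour; each minicolumn
  sends up to 20 connections drawn uniformly from its macrocolumn's
  patch pool.  Sharing can carry a patch beyond the 2.5 mm bound, which
  lengthens the remote-distance tail.

`W_IE` and `W_II` are diagonal (no long-range inhibition).  The diagonal
of `W_EE`/`W_EI` is the within-unit coupling, so an isolated sheet unit
is exactly the single-unit model.  Noise is one standard-normal draw per
macrocolumn per 2 ms step, shared by its 100 minicolumns and scaled by
B; it drives only the E population.  Integration is explicit fixed-step
Euler at dt = 2 ms (states remain in [0, 1] whenever dt does not exceed
the smallest time constant, since the update is a convex move toward a
value of `f`).  B is a per-step kick without √dt rescaling — a
convention tied to the default step; the default dt is therefore fixed
and a step-halving consistency check covers the deterministic part only.

## Parameter choice

The numeric working point was selected by a staged dynamical design
rather than transcription, with these requirements (in order):

1. the isolated unit has no limit cycle for **any** basal drive P (its
   repertoire is one or two stable fixed points);
2. the coupled sheet passes, as P rises, through monostable background →
   network-bistable (background coexists with collective oscillation) →
   monostable oscillatory, with the canonical ramp P: −3 → −1 crossing
   both transitions;
3. the collective rhythm lies in the EEG band (here ≈ 20 Hz, beta);
4. an oscillatory microdomain stays isolated in a monostable surround
   but recruits a bistable one;
5. a compact hyperactive cluster of 2250 units recruits almost none of a
   monostable surround, while the same units split into 25 random
   subclusters recruit most of it.

The searches behind (1)–(3) were run on the spatially homogeneous
mean-field reduction (effective couplings = within-unit + expected
network totals), then verified and refined on actual sheets.  Two
findings shaped the final set:

* Requirement (5) fails when the limit cycle rides on an elevated
  plateau: an oscillating domain then exports a large *constant* input
  lift to its halo and ignites traveling fronts regardless of phase
  structure.  The cycle must be burst-like (trough near the background
  level) so that recruitment depends on coherent, pulsed drive.
* A strong, *fast* feed-forward inhibitory veto (large local E→I weight,
  τ_i < τ_e, small within-unit E→I) pins single fronts in monostable
  tissue while still letting cooperative multi-source drive ignite the
  tissue between nearby subclusters — the mechanism that separates the
  compact from the subclustered arrangement.

Final values (the packaged `standard` preset): a = 2.5, θ = 1.15,
C_EE = 12 (within-unit) + 6 (local) + 2 (remote) = 20 total,
C_IE = 19.5, C_EI = 4 (within-unit) + 17.5 (local) = 21.5 total,
C_II = 0.5, Q = −7.85, τ_e = 30 ms, τ_i = 13.2 ms, B = 0.5, standard
interictal P = −3.  Weights per connection divide the network totals by
the expected in-degrees (≈ 70.9 local, ≈ 19.2 remote).  Local E→E and
local E→I carry **different** weights (0.0846 vs 0.2468); the sampler
parameters are identical.

At these values the sheet's pulse-sustained oscillatory band spans
P ≈ −2.3 … −1.3, spontaneous (noise-ignited) oscillation starts near
P ≈ −1.25, and the uniform-reset two-run classification yields
background ≤ −2.2, bistable −2.0 … −1.2, oscillatory ≥ −1.0 on the
30 × 30 fixture sheet.  The isolated unit is background/upper bistable
(never oscillatory), so a decoupled sheet classifies as
bistable-background-upper.

## Regime classification

`classify_regime` runs the sheet twice — from rest, and from a strongly
excited state (all E reset to 1) — and labels each run's post-transient
mean field oscillatory (peak-to-trough > 0.1 with dominant frequency in
1–30 Hz), upper (mean E > 0.8), or background.  The pairs map onto the
four regimes; inconsistent pairs are reported as `unresolved`, never
coerced.  The transient discard is 20% of the run.  Because a uniform
u = 1 state collapses synchronously, the uniform-reset probe detects a
slightly narrower bistable band than a localized-pulse probe
(−2.0 vs −2.3 at the lower edge); the scenario presets' bistable point
(−2.0) lies inside both.

## Recruitment detection

A unit is in the seizure core when a 1 s sliding window (stride 0.3 s,
the report cadence) shows at least 3 mean-crossing cycles, peak-to-
trough above 0.1, and mean phase coherence with its ≤ 3-unit
neighbourhood above 0.8 (phases from the analytic signal; the
neighbourhood reference is the circular mean).  The final recruited
percentage uses the last window; onset times use the first window a
unit qualifies in.  Both all-units and surround-only normalizations are
available (`RecruitmentReport.percent_of`); the microdomain experiments
report the surround share.

Wavefront speed is the inverse Theil–Sen slope of onset time against
distance-to-seed-region (Euclidean distance transform), robust to the
early "saltatory" onsets seeded through remote patches.  Degenerate
onset fields (near-simultaneous, or non-positive slope) return
"undefined" instead of a number.

## Scenario battery

Seven turn-key scenarios reproduce the onset-mechanism classes; each
checks its dynamical contract and fails loudly otherwise.  Working
points (all in the preset): bistable surround −2.0, scan surround −2.7,
microdomain drive −1.0.  Choices made where the design was open:

* **Class I heterogeneity** — "1.5× stronger feed-forward excitation" is
  realized as a 1.5× steeper drive increment during the global ramp, so
  the patch reaches the oscillatory threshold first.  Scaling only the
  (tiny) background network input produced sub-resolution leads.
* **Class IIIa subcluster count** — at reduced sheet sizes the
  subcluster count keeps the per-cluster size near the 90-unit patch
  scale; the full-scale experiment uses 2250 units in 17 or 25 clusters.
* **Counter-stimulation** — a negative input pulse (radius 20 units,
  600 ms, starting 300 ms after the trigger) covering the nascent core.
* **Microincision** — the enclosing cut is a rectangle of four segments
  overlapped past the corners, because chord/cut crossing is tested on
  open segments (touching an endpoint does not cut) and exact-corner
  chords would otherwise slip through.
* **Repeated random stimuli** (bistable-microdomain-network scenario) —
  the pulses reuse the class IIa footprint and amplitude.

## Headline numbers and their variability

The zero-flux 150 × 150 experiment ramps 2250 hyperactive units to the
oscillatory drive inside a monostable surround at P = −2.7 (0.4 input
units below the band edge, fixed at design time).  Averaged over five
noise-seed/placement replicates, one compact cluster recruits a few
percent of the surround (halo only) while 25 random subclusters recruit
about half or more of it through webs that grow between nearby
clusters.  Both numbers are strongly placement-dependent (compact runs
range from ≈ 1% to ≈ 25% when the cluster sits centrally; subcluster
runs from ≈ 15% to ≈ 90% with cluster density), an inherent feature of
percolation-like recruitment near its ignition boundary.  The
recruitment wavefront speed of a class IIb run is a few mm/s — the
product of the local connection reach (≈ 0.5 mm) and the burst rate
(≈ 20 Hz) bounds contiguous front speeds near 0.01 m/s, so
experimentally reported speeds above 0.1 m/s are not reproduced at this
working point; only remote-patch saltation exceeds the bound.

## What the synthetic fixtures do and do not show

`small_sheet` is a 30 × 30 sheet with the full generator at preset
parameters — small enough for second-scale tests while keeping all
three connection types (remote reach is clipped to the half-sheet).
`planted_wavefront` and `planted_oscillation` contain known ground
truth for the estimators and detectors.  Passing tests show the
machinery is correct at these scales; they do not show that the model's
parameters describe any particular patient's cortex, that the 2-D sheet
captures laminar structure, or that amplitude-thresholded oscillation
is an adequate seizure marker for clinical waveforms.

## Numerical details

* Fixed-point finding: sign-change cells on a grid (≥ 50²), polished
  with a hybrid Newton solver, deduplicated at 1e−6; eigenvalue
  real parts within 1e−8 of zero are flagged marginal; |Im λ| > 1e−8
  classifies a focus.  Unconverged candidates are reported, not dropped.
* Propagation delays (optional): off-diagonal contributions are binned
  by distance at one-pitch resolution and delayed by
  `round(d / (speed dt))` steps through ring buffers; infinite speed
  takes the undelayed code path exactly.
* The bisection threshold probe freezes the noise seed so the
  amplitude→response map is deterministic; ≤ 20 iterations, relative
  tolerance 1e−2; a bracket that does not straddle the criterion
  reports "no threshold in range".
* Simulations record E/I states as float32 at a 10 ms cadence by
  default in the experiment drivers (the integration step is always
  2 ms).

## Known limitations

* The quantitative working point is a designed parameter set, not a
  transcription; other sets satisfying the same qualitative constraints
  would shift the printed percentages.
* Recruitment percentages near the cooperative-ignition boundary have
  large placement-to-placement dispersion; means over few replicates
  move by several points.
* Contiguous-front speeds are orders of magnitude below the fastest
  experimentally reported propagation; see above.
* The regime probe's uniform reset cannot reach spatially structured
  attractors (e.g. the sparse asynchronous web states that exist below
  the pulse-ignition edge); regime labels are operational, tied to the
  stated protocol.
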