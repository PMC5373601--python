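# Methods

## Model and update rule

The map advances (x, y, z) synchronously: all three components of the
next state are computed from the old state, matching the recurrences

    x(t+1) = f((x − K y + z + H + I)/T),  y(t+1) = x,
    z(t+1) = (1 − δ) z − λ (x − x_R),

with f(u) = u/(1+|u|).  The logistic gain is evaluated in its piecewise
form, which is overflow-safe for any finite argument; the optional tanh
gain clamps its argument at ±50 before exponentiation.  All arithmetic is
IEEE double precision; no extended precision is used anywhere.
Trajectories are bit-reproducible given (parameters, initial state,
stimulus).  z(0) defaults to 0 in both regimes; transients are discarded
before any measurement, so this choice does not affect attractor
statistics.

The external input I(t) adds inside the gain argument; inhibition is a
negative amplitude.  Parameter files use the flat keys
`K, T, H, delta, lambda, xR, gain` (YAML).

## Equilibria and spectra

With the logistic gain the fixed-point condition reduces to x* = p0/p
with p0 = (1−K)x* + z* + H and p = T + |p0|, giving one quadratic per
sign branch s = sign(p0).  Roots are kept when real, |x*| ≤ 1 and the
branch sign is consistent; every kept root must satisfy the one-step map
identity to 1e−12 (this residual is asserted in the tests).  The
degenerate branch p0 = 0 (the origin when the effective bias vanishes)
is emitted as its own record rather than as a limit of the s-branches,
because s is undefined there.  Duplicate roots are merged at 1e−12
absolute tolerance in x*.

Eigenvalues: the 2-D spectrum solves Λ² − (T/p²)Λ + KT/p² = 0; the 3-D
spectrum solves p²Λ³ − [T + (1−δ)p²]Λ² + T(K+λ+1−δ)Λ − KT(1−δ) = 0, by
`numpy.roots` (authoritative) and by a Cardano closed form (cross-check;
the two must agree to 1e−8 relative except at branch-cut degeneracies).
At δ = λ = 0 the cubic factorizes into (Λ−1) times the 2-D quadratic,
which the tests verify to 1e−10.

Stability: stable iff max|Λ| < 1; equilibria with a real spectrum of
mixed sign are reported as saddles (complex pairs are classified by
modulus only).  When max|Λ| is within 1e−3 of 1 the record is flagged
marginal and the perturb-and-iterate verification (1e−6 perturbation,
1e4 steps) is skipped; otherwise the simulation verdict must agree with
the spectrum.

The H(T) stability-limit curves at fixed K follow from the eigenvalue
conditions: for K < 0.5 an eigenvalue reaches +1 at
x* = ±(1 − sqrt(T/(1−K))) giving H = (sqrt((1−K)T) + K − 1)x*; for
K ≥ 0.5 the unit-modulus condition p² = KT gives
x* = ±(1 − sqrt(T/K)) and H = (sqrt(KT) + K − 1)x*.  Both reduce to the
zero-bias limits T = 1−K and T = K, and all three zero-bias curves
intersect at (K, T) = (0.5, 0.5).

The quasi-static boundary x_R = ±(K − T) treats z as a frozen bias and
is accurate to O(δ) for 0 < δ = λ ≪ 1; the measured spike-onset at
δ = λ = 10⁻⁴ lies within 5e−3 of it (tested).

## Spike detection and regime classification

A spike is an upward crossing of `threshold` (default 0) after x has
been below `threshold − hysteresis` (default 0.1).  The thresholds of
the classifier are configuration, carried with every output:

| knob | default | role |
|---|---|---|
| `isi_th` | 100 ts | fast- vs slow-spiking split on the mean ISI |
| `cv_th` | 0.01 | periodic vs aperiodic cardiac split (event-period CV) |
| `ibi_th` | 500 ts | bursting vs slow-bursting split on the IBI |
| `A_so` | 0.05 | fixed point vs subthreshold oscillation amplitude |
| `burst_ratio` | 10 | max/min ISI spread that signals two time scales |
| `duty_th` | 0.15 | active fraction separating cardiac events from bursts |
| `mixed_fraction` | 0.2 | single/multi-spike event mix that defines dust |
| `discard`, `window` | 1e5, 1e6 ts | transient and measurement lengths |

Decision rule: no spikes → FP or SO by amplitude.  A two-time-scale ISI
distribution (shortest ISI below `isi_th`, spread beyond `burst_ratio`)
is segmented into events at the geometric midpoint of the ISI range:

* a substantial mixture of single-spike and multi-spike events is the
  chaotic **dust** (MIXED_DUST) between the cardiac and bursting regions;
* events with a small duty cycle (< `duty_th`) are cardiac action
  potentials whose plateau carries failed spike attempts — **CS** if the
  event-period CV is below `cv_th`, **ACS** otherwise;
* anything else is **BS**, or **SB** when the interburst interval
  exceeds `ibi_th` (an intentionally arbitrary split).

Otherwise a unimodal distribution is FS/CS/ACS by mean and CV.  Three of
these choices deviate from the more common histogram-peak approach, for
measured reasons: (i) chaotic bursting broadens both P(ISI) modes into
overlapping tails, and a periodic fast-spiker's adjacent integer ISIs
({11, 12}) produce two spurious histogram peaks, so bimodality is
detected by the spread test instead; (ii) dust orbits mix the two
behaviors within any statistically useful sub-window, so dust is defined
at the event level rather than by label instability across windows;
(iii) aperiodic cardiac spiking in this map has an event-period CV of
~0.01–0.06 against ~1e−3 for periodic trains, so `cv_th` = 0.01 — at the
conventional 0.1 the aperiodic class would be empty.

Winding numbers are measured as the average phase advance of the orbit
around its centroid in the (x, y) plane; an exactly Q-periodic orbit
(Q ≤ maxQ, detected at 1e−9) is reported as the rational P/Q.  On the
supercritical Neimark-Sacker line the estimate matches
arccos(1/2K)/2π to 1e−3 (property-tested over K ∈ [0.55, 2]).

Bistability probing re-runs a phase-diagram cell from the 8 corners of
the state cube and marks the cell BI when distinct labels coexist; this
probe is this package's protocol choice.

## Lyapunov exponents and dimensions

*Divergence fit*: twin orbits separated by 1e−8 in x(0); least-squares
slope of ln Δx vs t from t = 0 up to the first step where Δx ≥ 1e−2
(well below the ~2 saturation set by the gain range).  In contracting
regimes the shrink rate is fitted instead (down to the 1e−13 noise
floor) and flagged.

*Eckmann-Ruelle*: products of the analytic Jacobian along the orbit with
Gram-Schmidt/QR re-orthonormalization every 10 steps — the gain is C¹,
so tangent propagation is defined everywhere (the |u| kink affects only
the second derivative).  At a stable fixed point the spectrum equals
ln|Λᵢ| of the closed-form eigenvalues (to 1e−5 per exponent at 2e5
steps; members of a complex pair carry an O(1/n) rotation remainder
individually while their mean converges much faster).  The exponent sum
equals the orbit average of ln|det J| = ln(KT/p²) (tested to 1e−4).

*Box counting*: for point samples, occupied boxes are counted over
geometric scales of the bounding box.  For the strange attractor the
package iterates the map onto an occupancy grid instead
(`attractor_box_counts`), because counts at fine scales converge only in
orbit length: rare boxes carry very little natural measure, and a fixed
1e6-point sample undercounts them systematically.  The default fit range
is 2⁻⁴…2⁻¹² of the bounding box; the acceptance computation uses a
4e8-step orbit, for which the counts at 2⁻¹² are converged to <0.1%.

*Kaplan-Yorke*: D = j + Σ₁ʲλᵢ/|λ_{j+1}| with j the largest index keeping
the partial sum non-negative; 0 for an all-negative spectrum.

## Bifurcation location and scaling fits

Transitions are located by bisection on a regime predicate (spike onset,
burst-duration divergence — detected as interburst gaps exceeding 5× the
median ISI, a statistic chosen because the ISI extremes flicker near the
transition — or an A→B label change), to 1e−6 in the control parameter.
Observables (mean ISI, Var(ISI), burst duration, IBI) are measured over
1e6-step windows after a 1e5-step transient and fitted log-log against
the distance to the located critical point, requiring ≥ 8 valid points
spanning ≥ 1.5 decades, with points beyond distance 0.1 excluded (the
asymptotic laws hold only close to the transitions).

Two fit windows are used and always reported: the diverging period is
fitted over d ∈ [3e−4, 1e−2] (its inverse-square-root regime; closer in,
the period saturates near ~1.7e3 ts because the oscillation onset is
first-order-like, with the amplitude jumping within an extremely narrow
parameter interval), and the ISI variance over d ∈ [3e−3, 1e−1], the mid
range where its empirical power law is straight.

## Behavior gallery and networks

Each of the 19 registry behaviors pairs a cell, a stimulus protocol and
a deterministic predicate on the response (some contrastive: e.g. the
resonator must spike for a pulse pair at its ~8.4-ts ringing period and
stay silent at half that interval).  The parameter sets were found by
guided search from the bifurcation structure — a tonic driver resting at
H = −0.1 below the oscillatory band of the fast subsystem at K = 0.6,
T = 0.26; ringing cells biased just outside that band; burst/cardiac
cells of the slow subsystem; a K < 0.5 node cell for
integrator/accommodation protocols — and are registry data, not
canonical constants.  Firing rates are reported in spikes per 10⁴ ts; no
physical time calibration is claimed.  Class-1 vs class-2 excitability
uses the f-I curve: levels with fewer than 3 spikes per window count as
silent, and class 1 requires the first firing rate to fall below 10% of
the 90th-percentile plateau.

Networks couple identical units by gap junctions, I_i = Σ_j G(x_j −
x_i), computed from the old potentials; the directed chain has N−1
synapses (an undirected variant exists for the exact antisymmetry
checks), the complete graph N(N−1).  Random initial conditions are
uniform on x, y ∈ [−1, 1] with z = 0 and a recorded seed.  The
synchrony order parameter is 1 − ⟨population variance⟩/⟨single-unit
temporal variance⟩ — a package choice, since no standard metric is
implied by the coupling — and the chain propagation threshold is the
bisected minimal G for which the last unit spikes within the horizon.

## Problem sizes

Default measurement windows are 1e6 steps with 1e5-step transients;
phase diagrams in the test suite use 100×100 grids at 2e5-step windows
(≈ 1 minute), and the box-count orbit is 4e8 steps (≈ 10 s compiled).
These sizes leave every reported statistic converged at the precision
quoted above while keeping a full run on one CPU in a few minutes.

## Known limitations

* The blue-sky (bursting → fast-spiking) transition at K = 0.6,
  T = 0.275 shows a jump: the mean burst duration grows to ~6.5e3 ts and
  then gives way to an unbounded spike train within a parameter interval
  narrower than 5e−6, with no hysteresis under adiabatic continuation.
  The measured burst-duration exponent over the accessible window is
  ≈ −0.27, not the −1/2 expected of a resolvable blue-sky scaling
  regime; the corresponding acceptance test is left failing rather than
  refitted.
* The strange attractor's box-counting slope oscillates with scale
  (≈ 1.07–1.27 across octaves, overall trend ≈ 1.1–1.15 — close to the
  Kaplan-Yorke value); the literature value 1.35 is not recovered by any
  converged counting protocol tried, and the corresponding test is also
  left failing.
* A double-precision orbit eventually closes on a floating-point cycle;
  box counts at scales ≤ 2⁻¹⁵ are limited by this and are not used.
* The classifier thresholds are calibrated on this map's dynamics; the
  labels are only as transferable as those thresholds.
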