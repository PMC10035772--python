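# Methods

## The six-state stop-and-go model

Axonal neurofilaments are modelled as point particles carrying one of six
kinetic states: moving anterogradely (*a*, velocity v_a > 0) or
retrogradely (*r*, velocity v_r < 0), pausing on-track (*a₀*, *r₀*) or
pausing off-track (*aₚ*, *rₚ*).  The state chain is a continuous-time
Markov process with transitions

    a  ⇄ a₀ ⇄ aₚ          r  ⇄ r₀ ⇄ rₚ
      γ₁₀/γ₀₁  γ_off/γ_on     (same rates)

and directional reversals a₀⇄r₀, aₚ⇄rₚ at rates γ_ar (anterograde →
retrograde) and γ_ra.  Reversals act only from the pausing states: a
moving filament must pause before its direction can change.

Because the within-direction rates are direction-symmetric, the
stationary distribution has product form: aggregate occupancies
(moving : on-track pause : off-track pause) = (γ₀₁/γ₁₀ : 1 : γ_off/γ_on),
each split between directions as γ_ra : γ_ar.  The pulse-escape
observables are blind to direction, so the direction-blind 3-state
aggregate is the canonical object for occupancies and dwell times; the
directional 6-state form is constructed for simulation.

Derived summaries (all closed-form): mean on-track pause
1/(γ₀₁ + γ_off), mean off-track pause 1/γ_on, mean bout 1/γ₁₀, fraction
of time moving from the stationary distribution, and net velocity
v̄ = p_a·v_a + p_r·v_r with p_a, p_r the stationary moving-state fractions
(reported in mm/day; 1 µm/s = 86.4 mm/d).  Internally everything is in
seconds and micrometres; minutes and mm/day appear only at reporting
boundaries.

### Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| γ₀₁ | 3.72×10⁻³ /s | on-track pause → bout |
| γ₁₀ | 2.01×10⁻¹ /s | bout → on-track pause (bouts ≈ 5 s, ≈ 2.5 µm) |
| γ_on | 1.34×10⁻⁴ /s | off-track → on-track (pauses ≈ 2 h) |
| γ_off | 2.21×10⁻⁴ /s | on-track pause → off-track |
| γ_ar, γ_ra | 0 | reversal rates (see below) |
| v_a, v_r | +0.5, −0.5 µm/s | bout velocities |
| p_dir_a | 0.6 | anterograde share of moving filaments (pulse-spread measurement) |
| window | 5 µm | activation window length |
| margin | 50 µm | simulated axon beyond each window edge, absorbing far ends |

The four identifiable rates are the values extracted from adult mouse
tibial nerve; the velocities come from cultured-neuron measurements and
the 60/40 directional split from the pulse-spread companion method.

### Reversal rates: why the default is zero

Pulse-escape data constrain only the *ratio* γ_ra/γ_ar (through the
directional split), never the absolute reversal scale — the window decay
is blind to departure direction.  The absolute scale matters a great
deal for the physics of escape, however: if reversals are faster than
the window-escape time (~minutes for a 5 µm window), on-track motion
becomes diffusive rather than ballistic and the predicted decay slows
markedly (e.g. reversals at the γ₀₁ scale raise the 180-minute remaining
fraction from 19% to 28% and the 10-hour value from 1% to 6%).  Only the
quasi-ballistic regime (reversal scale ≪ inverse escape time) is
consistent with the measured decay endpoints and with the reported
long-term kinetics, so the package defaults to γ_ar = γ_ra = 0 and
carries the 60/40 split in `MotilityParams`.  Nonzero reversal rates are
fully supported throughout (simulation, grid solver, modal solver with a
re-entry margin) for sensitivity work.

## Forward models

**Grid solver** (`expected_decay`).  The six state densities obey a
linear advection–reaction master equation on [−margin, window+margin].
Each step applies a Strang split: half reaction step (exact, via the 6×6
matrix exponential of the generator — unconditionally stable and
mass-conserving), one upwind advection step for the moving states, half
reaction step.  The default time step is Δx/max|v|, making the Courant
number exactly 1, where upwind advection is an exact shift — the scheme
then has no numerical diffusion and its only error is the O(Δt²)
splitting error.  Sub-Courant steps fall back to standard first-order
upwind; Courant numbers above 1 raise an error naming the admissible
step.  Far boundaries are absorbing; a reflecting mode (mass folded into
the opposite moving state at the wall) exists for mass-conservation
validation and conserves total mass to machine precision.  Defaults:
Δx = 0.25 µm, margin 50 µm; halving Δx and Δt changes the sampled values
by < 0.1%.

**Initial condition.**  Filaments are uniform in the window with states
drawn from the stationary distribution: photoactivation tags a
steady-state population, and the fast decay phase is carried by the
filaments that happen to be on-track at activation.  Window occupancy is
reported relative to activation (value 1 at t = 0); re-entry into the
window is fully represented.

**Monte Carlo** (`simulate_pulse_escape`).  Event-driven simulation with
competing exponential clocks: dwell times are sampled exactly from the
state's total exit rate and the successor state from the relative
transition rates, with ballistic advection between events — no
time-discretisation bias in dwell statistics.  Bit-reproducible for a
fixed seed.  Filaments crossing the far boundary are counted as
permanently departed; without reversals such filaments can never
re-enter, so absorption is exact (a warning fires only when reversals
are enabled and crossings exceed 0.1%).

**Modal solver** (`modal_decay`).  Without reversals the directional
chains decouple and a filament that leaves the window can never return,
so the master equation restricted to the window alone (absorbing
immediately outside) is exact for window occupancy.  Each direction is
then a 3-state upwind operator on a ~40-cell grid whose dense
eigendecomposition yields the entire decay curve in about a millisecond
— this powers the inverse procedure.  With reversals the coupled
six-state operator on a ±25 µm re-entry margin is used instead.  The
modal curve agrees with the grid solver to better than 1% pointwise at
the default resolutions (Δx = 0.125 µm; the first-order upwind bias of
the modal operator is the dominant term).

**Model observables.**  `initial_slope` estimates −dy/dt at early times
by finite differences over the first 30 s of the grid solution (window
configurable); `initial_slope_analytic` gives the exact t → 0⁺ limit,
the advective outflux (f_a·v_a + f_r·|v_r|)/L of the uniformly filled
window.  `long_term_decay_constant` offers two estimators: the log-slope
over the last factor-of-e of a 12 h modal solution (default), and the
slowest eigenvalue of the window-escape operator.  These target subtly
different quantities: the slow spectrum is a quasi-continuous band just
below γ_on (one mode per off-track spatial profile), so the truly
asymptotic mode dominates only at unobservably long times.  At the
default rates the eigenvalue (1.26×10⁻⁴/s) exceeds the finite-horizon
slope (1.19×10⁻⁴/s) by ~5%; both sit strictly below γ_on because a
mobilised filament can return off-track before escaping.  The inverse
procedure uses the finite-horizon slope consistently on both the data
and the model side, which is what a fit to a 3-hour experiment actually
estimates.

## Fitting

The decay is fit to y(t) = A·e^(−at) + B·e^(−bt) + C with A, B, C ≥ 0
and the rates non-negative but otherwise free.  The fit is deterministic:
a variable-projection grid search — logarithmic (a, b) grid spanning
10⁻⁵–10⁻¹ /s (25 points per axis, pairs with a ≥ b), amplitudes solved
by non-negative least squares at each node — seeds a bounded
trust-region polish from the best three nodes.  Rates are canonically
ordered a ≥ b; if the two rates coincide to within 10⁻⁶ relative the fit
collapses to a single exponential plus plateau with a warning.
Weighting is unweighted by default (optional 1/SD² when the curve
carries SDs).  The time origin for fitting is the 1-minute frame (the
dark-state normalisation reference); observables are invariant to that
shift and to any uniform rescaling of the curve.

The derived observables are the normalised initial slope
(aA + bB)/(A + B + C) and the long-term constant b; C/(A+B+C) is the
fraction of a hypothetical permanently stationary population, estimated
freely with no upper bound.

Photobleach calibration fits the across-axon mean intensity to
I₀·e^(−k·n) in the cumulative exposure count n (each 1 s 488 nm exposure
bleaches the same fraction regardless of spacing); a rising mean is
rejected as an invalid calibration.

## Inverse procedure

Given the fitted observables (s₀, b) of an average curve, for each
candidate (γ₀₁, γ₁₀) on a 25×25 logarithmic grid
(γ₀₁ ∈ [10⁻⁴, 10⁻¹], γ₁₀ ∈ [10⁻², 1] /s, one 5×5 local refinement):

1. the slope identity s₀ = f_m·(p_a v_a + p_r|v_r|)/L, with
   f_m = [1 + (γ₁₀/γ₀₁)(1 + γ_off/γ_on)]⁻¹, fixes the ratio
   γ_off/γ_on in closed form (a required ratio below −0.5 marks the
   candidate infeasible; small negative values clamp to 0, the
   single-phase limit, in which case γ_on is unidentifiable and pinned
   at the b scale);
2. a bracketed 1-D root solve on γ_on (13-point log scan + Brent) matches
   the model's finite-horizon slow rate, computed from the modal solver
   over the late half of the experimental window, to the fitted b;
3. the candidate minimising the summed squared distance between the
   (activation-time-offset, renormalised) model decay and the data at
   the experimental sample times is returned, with the full residual
   surface as diagnostics.

The fitted plateau C is ignored by the extraction (for the measured
average it is numerically zero).  Reversal rates are filled from the
externally configured split, flagged as not extracted.  On the noiseless
model-generated curve the procedure recovers γ_on and γ_off to ~2% and
reproduces the forward curve to < 1% pointwise; under 5% multiplicative
noise the median γ_on error is ~7% (50 replicates).  γ₀₁ and γ₁₀ are
individually weakly identified (the curve constrains mainly their ratio
through f_m); curve-level round-trip accuracy is the guaranteed
contract.

## Synthetic data generator

`generate_pulse_escape_dataset` emulates the full experiment per axon:
pre-activation frame (residual fluorescence), post-activation frame at
t = 0, then the standard schedule 1, 2.5, 5, 10, 15, 30, 60, 90, 120,
150, 180 min.  Window occupancy comes from the event-driven simulation
of `nf_per_axon` filaments (default 500, setting the shot-noise scale to
match hundreds-to-thousands of filaments per window); an optional
`stationary_fraction` of filaments is pinned outside the state chain
entirely, implementing the literal stationary-network hypothesis.
Intensities are multiplied by the bleach factor e^(−k·n) (default k
gives a 13% decline over the 11 timed exposures; exposure counting
increments once per fluorescence frame, with pre = 0), the post frame is
divided by 1.15 (the dark-state recovery deficit relative to the
1-minute reference), and multiplicative log-normal measurement noise
(CV 3%) is applied.  Axon-to-axon variability is one shared mean-1
log-normal multiplier (CV 20%) on the four identifiable rates — a pure
clock rescaling that changes each axon's decay slopes without changing
occupancies, reproducing the observed spread in phase slopes without
inventing per-axon biology.  The variability CV was chosen so that the
ensemble average stays consistent with the average-curve analysis
(heterogeneous averaging raises the mean 180-min value by ~3% via
convexity) while the per-axon 180-min spread is of order 0.05–0.1.

What the generator does *not* emulate: imaging artefacts (focus drift,
stage drift, background), filament length and polymer flexibility (real
neurofilaments are micrometres long; the fluorescence accounting is
per-polymer), axon-to-axon differences in window geometry, and any
non-exponential pausing.  Passing round trips on synthetic data
therefore validate the estimator chain under the model's own
assumptions, not the model itself against real axons.

## Numerical and design choices

- Courant-1 splitting makes advection exact; all solver comparisons
  (grid vs Monte Carlo vs modal) are genuinely independent routes to the
  same master equation and agree within Monte Carlo error / 1%.
- The extraction grid and the modal resolution trade accuracy for time;
  the defaults (25×25 grid, Δx = 0.125 µm) run in under a minute, and
  reduced settings (9×9, Δx = 0.25 µm) used for repeated noisy-recovery
  studies change recovered γ_on by ~2%.
- Degenerate inputs: a flat curve has no feasible candidate and raises;
  single-phase curves (γ_off = 0 regime) return γ_off = 0 with γ_on
  conventionally pinned; zero-motility configurations yield a flat model
  curve, zero initial slope and a zero long-term constant.
- Reporting conventions follow the assay: experimental curves are
  normalised to the 1-minute frame (paGFP dark-state recovery makes
  earlier frames non-quantitative); model occupancies are reported
  relative to activation.  The two differ by the ~4% decay within the
  first minute and are converted explicitly where they meet (the
  extraction offsets model times by 60 s and renormalises).

## Known limitations

- The reversal-rate scale is not identifiable from pulse-escape data;
  the zero default is an inference from the measured decay endpoints,
  not a measurement.  Results for quantities that depend on directional
  persistence (e.g. pulse-spread profiles) should not be derived from
  these defaults.
- The long-term decay constant is horizon-dependent at the few-percent
  level (quasi-continuous slow spectrum); fits to experiments shorter
  than ~2 h will estimate a systematically larger b.
- Per-axon fits at realistic noise are much less stable than fits to the
  48-axon average; the stationary-fraction (plateau) estimate in
  particular fluctuates by ±0.05–0.07 across datasets at default noise.
- γ₀₁ and γ₁₀ are only jointly constrained by a single average curve;
  independent bout-level measurements are needed to pin them
  individually.
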