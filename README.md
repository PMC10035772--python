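# pulsescape

Kinetic analysis of fluorescence photoactivation **pulse-escape**
experiments on axonal neurofilament transport.

Neurofilaments are transported along axons in a stop-and-go fashion:
short bouts of rapid, bidirectional movement along microtubule tracks
separated by pauses lasting seconds to hours.  In a pulse-escape
experiment, photoactivatable GFP-tagged neurofilaments are switched on
inside a short axonal window (typically 5 µm) and the window fluorescence
is followed by time-lapse imaging: mobile filaments carry their
fluorescence out of the window, so the decay of the window intensity
encodes the pausing kinetics.  The central scientific question this assay
addresses is whether mature axons hold a large, permanently stationary
neurofilament network, or whether essentially all filaments cycle between
pausing and movement.

`pulsescape` implements the complete analysis chain for such experiments:

- **Six-state stop-and-go model** (`pulsescape.kinetics`, `pulsescape.params`)
  — filaments move anterogradely (*a*) or retrogradely (*r*), pause
  on-track (*a₀*, *r₀*) or off-track (*aₚ*, *rₚ*).  Transitions are
  governed by rate constants γ₀₁ (pause → move), γ₁₀ (move → pause),
  γ_on (off-track → on-track), γ_off (on-track → off-track), plus
  directional reversal rates γ_ar/γ_ra acting from the pausing states.
  Steady-state occupancies, mean pause/bout durations and the net
  transport velocity  v̄ = p_a·v_a + p_r·v_r  are available in closed form.
- **Forward models** (`pulsescape.forward`) — a deterministic solver for
  the spatial advection–reaction master equation of the six state
  densities (Strang splitting, exact matrix-exponential reactions, upwind
  advection at Courant number 1), an exact event-driven Monte Carlo
  simulation of individual filaments, and a modal (eigendecomposition)
  solver of the window-restricted operator for fast inverse work.
- **Curve fitting** (`pulsescape.fitting`) — constrained least-squares
  fits of the biphasic decay  y(t) = A·e^(−at) + B·e^(−bt) + C  with
  A, B, C ≥ 0, as scikit-learn-style estimators
  (`DoubleExponentialDecay`, `BleachCalibration`), plus the derived
  observables: initial slope (aA + bB)/(A+B+C) and long-term constant b.
- **Inverse procedure** (`pulsescape.extraction`) — `RateConstantExtractor`
  recovers (γ₀₁, γ₁₀, γ_on, γ_off) from a fitted average decay curve by
  matching the two observables and minimising the least-squares distance
  between the model decay and the data over a logarithmic candidate grid.
- **Preprocessing** (`pulsescape.preprocess`) — per-exposure photobleach
  correction, normalisation to the 1-minute frame (paGFP dark-state
  recovery), pointwise averaging across axons.
- **Synthetic data** (`pulsescape.synthetic`) — a generator that emulates
  the full experiment (biphasic escape, shot noise, photobleaching,
  dark-state recovery, axon-to-axon variability, optional stationary
  subpopulation), so the entire chain is testable without microscopy data.

## Worked example

The packaged defaults are the rate constants measured in myelinated axons
of adult mouse tibial nerve: γ₀₁ = 3.72×10⁻³, γ₁₀ = 2.01×10⁻¹,
γ_on = 1.34×10⁻⁴, γ_off = 2.21×10⁻⁴ s⁻¹, with bout velocities ±0.5 µm/s
split 60/40 anterograde/retrograde.

```python
import numpy as np
import pulsescape as ps

rates, motility, geom = ps.TIBIAL_NERVE_RATES, ps.DEFAULT_MOTILITY, ps.DEFAULT_GEOMETRY

ks = ps.kinetic_summary(rates, motility)
print(f"off-track {ks.pct_time_off_track:.0f}% of the time "
      f"(pauses of {ks.mean_off_track_pause:.0f} min), "
      f"moving {ks.pct_time_moving:.1f}%, net {ks.net_velocity:.2f} mm/d")
# off-track 62% of the time (pauses of 124 min), moving 0.7%, net 0.06 mm/d

schedule = tuple(60.0 * m for m in ps.PULSE_ESCAPE_SCHEDULE_MIN)
cfg = ps.SimulationConfig(sample_times=schedule, duration=schedule[-1], solver="grid")
curve = ps.expected_decay(rates, motility, geom, cfg)
print(f"{100 * curve.values[-1]:.1f}% of the fluorescence remains at 180 min")
# 19.4% of the fluorescence remains at 180 min

reference = ps.DecayCurve(np.array(schedule) - 60.0, curve.values / curve.values[0])
fit = ps.fit_double_exponential(reference)
result = ps.extract_rate_constants(fit, reference)
print(f"recovered gamma_on = {result.rates.gamma_on:.3e} /s")
# recovered gamma_on = 1.315e-04 /s
```

The same table is available from the shell:

```
$ pulsescape summary
| kinetic parameter       | value |
|-------------------------|-------|
| % of time off-track     | 62% |
| average off-track pause | 124 min |
| % of time on-track      | 38% |
| average on-track pause  | 4.2 min |
| % of time moving        | 0.7% |
| average bout duration   | 5 s |
| net average velocity    | 0.06 mm/d |
```

Reading: a filament spends 62% of its time in prolonged off-track pauses
(~2 h each) and only 0.7% of its time actually moving, yet the forward
model shows ~81% of the filaments leave a 5 µm window within 3 h — the
window fluorescence is predicted to decay essentially to zero (about 1%
left after 10 h), leaving no room for a substantial permanently
stationary population.

Other CLI commands: `synth` (write a synthetic dataset), `preprocess`
(bleach-correct/normalise/average raw traces), `fit`, `extract` and
`simulate` — see `pulsescape --help`.

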