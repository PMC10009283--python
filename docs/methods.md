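# Methods

## The model

`urgentrace` simulates urgent two-alternative saccadic choices with a
race-to-threshold architecture. Two scalar motor plans, `x_L` and `x_R`,
stand for the population activity of neurons promoting leftward and
rightward saccades. Both start at 0 when the go signal takes effect and
integrate by explicit Euler steps

```
x(t + Δt) = x(t) + b(t) Δt,          Δt = dt (default 1 ms),
```

racing to a fixed threshold (1000 activity units). The first plan to cross
triggers the saccade after a fixed efferent delay. The model is scale-free:
jointly rescaling the threshold and every rate/acceleration leaves behavior
bit-identical (this is a tested invariant), so the threshold is held fixed
and only rate-to-threshold ratios are meaningful.

A trial unfolds in phases:

1. **Pre-cue.** The race starts after a Gaussian afferent go delay
   (`aff_mean ± aff_sd`, clipped at 0) with constant initial rates
   `(b0_L, b0_R)` drawn from a bivariate Gaussian — common mean `mu_b`,
   common SD `sigma_b`, correlation `rho_b`. Negative draws are allowed
   (a plan may drift down); races that never cross by `t_max` are flagged
   invalid, as are RTs at or beyond the 450 ms task deadline. A crossing
   in this phase is an uninformed guess.
2. **Exogenous response interval (ERI).** The cue appears `gap` ms after
   the go signal and reaches the circuit one (independently drawn)
   afferent delay later. For the first `delta_eri` ms of the ERI both
   rates are attenuated to `g_eri · b0` (a halt/slowdown). On
   congruent/incongruent trials the remainder of the ERI accelerates the
   plan toward the *salient* stimulus — `b_S ← b_S + a_ex Δt` per step,
   starting from the attenuated rate — while the non-salient plan stays
   attenuated. On symmetric trials the whole (shorter) ERI is a
   symmetric halt. ERI durations are Gaussian (`mu_eri ± sigma_eri`,
   floored at `delta_eri`; symmetric: `eri_sym_mean ± eri_sym_sd`,
   floored at 0). A crossing inside the ERI is an exogenously captured
   saccade: correct when the salient item is the target, an error when
   it is the distracter.
3. **Post-ERI (endogenous).** Once the cue's color content is resolved,
   the rate modulation of the ERI — a transient, stimulus-driven
   perturbation — ends: plans revert to their intrinsic rates `b0`, the
   target plan thereafter accelerating by `a_end Δt` per step and the
   distracter plan decelerating by `d_end Δt` (which may drive its rate
   and activity negative). With probability `lapse`, decided by a single
   Bernoulli draw per trial, the endogenous terms are never applied and
   the race is settled by the intrinsic rates — lapse trials are coin
   flips with respect to the target, which caps asymptotic accuracy near
   `1 − lapse/2`. Positions accrued during the ERI always persist; only
   the *rates* revert.

Choice of the transient-reset convention: letting the exogenous rate boost
persist after the ERI makes every asymmetric trial systematically faster
than its symmetric counterpart (~25 ms at calibration strength), which
contradicts the empirical signature this task family is known for — large
tachometric differences with essentially superimposable chronometric
curves — and, for lapses, slows frozen attenuated plans so much that they
dominate long PTs and pull the plateau far below `1 − lapse/2`. The
transient reading preserves both signatures while leaving the capture
mechanism (position gains during the ERI) intact.

Numerical conventions: a step's rates are those in force at the step's
start; accumulators (`a_ex`, `a_end`, `d_end`) advance after the position
update, so the first step of a phase uses the phase's entry rate; crossing
is detected as `x ≥ threshold` at the end of a step and stamped `t + dt`
(RT resolution = `dt`); simultaneous crossings are resolved by a uniform
coin flip (a measure-zero tie in the continuum limit); sampled delays are
clipped at zero. The vectorised simulator is verified step-for-step, to
machine identity, against an independent scalar re-implementation.

## Default parameters

| parameter | value | units | meaning |
|---|---|---|---|
| `mu_b`, `sigma_b`, `rho_b` | 4.8, 1.0, −0.6 | units/ms, –, – | initial build-up rate distribution |
| `threshold` | 1000 | units | fixed trigger level (structural) |
| `dt` | 1 | ms | Euler step |
| `aff_mean`, `aff_sd` | 60, 8 | ms | afferent delay (go and cue) |
| `mu_eri`, `sigma_eri` | 25, 4 | ms | asymmetric ERI duration |
| `delta_eri` | 18 | ms | initial both-halt portion of the ERI |
| `eri_sym_mean`, `eri_sym_sd` | 19, 3 | ms | symmetric ERI duration (shorter) |
| `g_eri` | 0.35 | – | rate attenuation during the halt |
| `a_ex` | 4.5 | units/ms² | exogenous acceleration of the salient plan |
| `a_end`, `d_end` | 0.08, −0.25 | units/ms² | endogenous acceleration/deceleration |
| `lapse` | 0.02 | – | probability the cue is never applied |
| `eff_delay` | 20 | ms | fixed efferent delay |
| `rt_deadline`, `t_max` | 450, 1000 | ms | task deadline, simulation cap |

This set is a **calibration, not a fit**: values were chosen once so that
the simulated task shows the qualitative phenomenology — a chance floor
below PT ≈ 80 ms; exogenous capture concentrated in the 75–125 ms window
(accuracy well above chance for salient targets, well below for salient
distracters, symmetric in between); rise points ordered congruent <
symmetric < incongruent; a plateau near `1 − lapse/2`; mean RTs of
250–300 ms; and chronometric curves that nearly superimpose across trial
types (within ~10 ms, i.e. ≲ 0.2 RT SDs — invisible at the ±1 SD scale at
which such data are plotted). With `mu_b = 4.8` the typical uninformed
crossing takes ≈ 210 ms, which after the afferent and efferent delays puts
mean RT near 260 ms; `aff_mean + eff_delay = 80 ms` places the earliest
cue-driven effects at PT ≈ 80 ms and captured crossings at PT ≈ 95–125 ms.

## Statistics

- **Tachometric curve**: percent correct in 50 ms PT bins sliding every
  1 ms, bin membership `[c − 25, c + 25)` (half-open, centered; edge
  handling is a convention choice). The grid spans the populated PT range
  clipped to [−100, 400] ms. Bands are exact Clopper–Pearson 95% intervals
  (beta-quantile form, via `statsmodels`; tested exhaustively against an
  independent beta-quantile oracle for all n ≤ 50). Invalid trials
  (missed deadline, no crossing) are excluded unless requested otherwise;
  red- and green-target trials and sessions are pooled.
- **Capture-range accuracy**: pooled percent correct over the inclusive
  75 ≤ PT ≤ 125 ms range, with its binomial CI.
- **Rise point**: smallest grid PT at which the curve first reaches 75%
  correct, linearly interpolated between the bracketing grid points;
  undefined (NaN) when never reached. Grid points with fewer than
  `min_count` (default 25) trials are ignored: near-empty bins at the
  sparse edges of the PT distribution otherwise produce spurious ≥ 75%
  readings. "Reaches" is implemented as ≥; on continuous estimates the
  distinction from > is immaterial.
- **Rise-point CI**: percentile interval over case resamples of trials
  (not sessions — curves pool trials across sessions), seeded; flagged
  undefined when more than half the resamples lack a rise.
- **Chronometric curve**: mean ± SD of RT per distinct gap, pooled over
  sessions (population SD, ddof = 0).
- **Ensembles**: each run re-draws every non-structural parameter as
  `p (1 + rel_sd · ε)` with independent standard-normal `ε`
  (multiplicative, so each parameter's across-run SD is `rel_sd` of its
  magnitude; zero-valued parameters stay zero). Probabilities and gains
  are clipped to [0, 1], durations floored at 0, the correlation clipped
  to [−1, 1], `d_end` capped at 0, and `delta_eri ≤ mu_eri` re-imposed.
  `dt`, `threshold`, `rt_deadline`, `t_max` are structural and fixed —
  jittering the threshold would merely rescale all rates. Per run the
  capture-range accuracy and rise point are computed per trial type
  exactly as above; 2.5th/97.5th percentiles across runs give the 95%
  band, with undefined runs excluded and counted. The master seed spawns
  per-run child seeds through `numpy.random.SeedSequence.spawn`, so
  results are bit-reproducible.

## Synthetic data

`generate_dataset` emulates the *structure* of a multi-session monkey
dataset: randomly interleaved trial types (default 1/3 each), gaps uniform
on the {25, 50, …, 250} ms grid, target-color blocks of ~100 trials,
stimulus orientations drawn 33% near-horizontal / 15% near-vertical / 52%
near-diagonal, and eccentricities from a Beta(1.5, 2.0) shape scaled to
5–20° (median ≈ 11°, 90% range ≈ 6–17°). Outcomes come from the simulator
itself, so generated datasets are self-consistent: analyzing one
reproduces the generating model's tachometric curves within binomial
error (tested). What the generator does **not** emulate: session-to-session
drift, learning or fatigue, fixation breaks, reward-history effects, and
any dependence of behavior on color, orientation, or eccentricity — in
real data those are empirical questions; here they are independent labels.
Passing tests on generated data therefore validates the analysis pipeline
and the model's internal consistency, not the biology.

Synthetic eye traces are fixation noise plus a raised-sine velocity pulse
whose duration follows a main-sequence-like rule (≈ 2.2 ms/deg + 21 ms),
placed so the sampled speed first exceeds the 50 °/s detection threshold
exactly at the requested RT; `detect_saccade_onset` returns the first
sample *strictly above* threshold ("surpassed") and insists on uniform
1 kHz sampling. Amplitudes too small for the pulse to clear 50 °/s are
rejected rather than silently undetectable.

## Scales used in the shipped checks

The test suite runs the full-scale conditions where they are cheap
(40,000 trials per type for the headline properties) and a scaled-down
ensemble (50 runs × 10,000 trials rather than 500 × 40,000) for the
sensitivity bands; percentile bands at that scale are wider, so the
sign-structure assertions are conservative. The acceptance script uses
40,000 trials per condition throughout.

## Known limitations

- Two scalar plans; no neural-population realism, no fixation-break or
  reward bookkeeping, and no antisaccade variant (the architecture admits
  one as incongruent-with-vanishing-target, but it is not implemented).
- No parameter fitting: the defaults are a hand calibration against
  qualitative criteria; different calibrations satisfying the same
  criteria exist.
- The symmetric-ERI duration and the allocation of afferent delay between
  go and cue pathways are under-constrained by the phenomenology; both
  are surfaced as parameters rather than hard-coded.
- Euler integration at `dt = 1 ms` quantizes RTs to whole milliseconds;
  statistics that interpolate (rise points) are smooth, but trial-level
  RTs are grid-valued.
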