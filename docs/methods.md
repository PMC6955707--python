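# Methods

## The measurement model

A game session is a sequence of *T* tries (default 10) with a per-trial
time limit θ (default 60 s). Every try ends in exactly one of four ways —
correct, commission error, omission error, or a quit that forfeits the
rest of the session — and the scored tallies satisfy the conservation
identities *I = OE + CE* and *T = C + I + K* by construction. The session
measures are the ones standard in continuous-performance-test scoring:
mean and SD of correct response times, engagement (GF), inattention (IAF),
impulsivity (IMF), error (EF = IAF + IMF, computed as that sum so the
identity is bit-exact), the correct-response factor CRF = ΣCRT/(C·θ), and
the composite Performance Index PI = [((1−CRF) + (1−EF))/2]·GF.

Conventions for degenerate sessions are chosen so that "worse behaviour
never scores higher": when nothing was attempted (C + I = 0) all factors
are 0 and M is reported absent; when C = 0, CRF is 0. An
immediately-abandoned session therefore scores PI = 0, the floor.
Percentages round half away from zero to integer percent, matching the
usual table formatting.

Two deliberate readings of ambiguous conventions:

- The SD of correct response times is the **sample** standard deviation
  (divisor C − 1, with SD = 0 for C ≤ 1). A divisor of 1 − C would make
  the variance negative for C > 1, so it cannot be meant.
- PI uses (1 − CRF): slower correct responses lower the index. An elapsed
  time penalty via GT/ST is sometimes discussed for composite indices of
  this kind; it is exposed as an off-by-default three-term variant of
  `performance_index` (averaging in (1 − GT/ST)) but is not part of the
  standard two-term definition, which is the one the reference phase
  tables validate.
- CRF's denominator is C·θ, so commission-trial response times do not
  enter CRF; they enter only the elapsed-time tally GT, which charges a
  full θ for each omission (the timer ran out) and nothing for a quit.

## Summary-mode scoring

`score_summary` scores a session from printed tallies plus the mean CRT,
using ΣCRT = C·M. It returns exactly the factor and PI values that
`score_session` would return for any trial stream with the same tallies
and mean — a property the suite checks — while reporting SD and GT absent,
since neither is derivable from a summary.

## The behaviour simulator

The generative model behind the simulator is intentionally minimal, since
only outcome frequencies and response-time location are identified by the
session measures:

- Each attempted trial is an independent categorical draw: omission with
  probability `p_omit`, commission with `p_commit`, correct otherwise
  (`p_omit + p_commit ≤ 1`).
- Before every trial the patient quits with probability `p_quit`; a quit
  consumes no trial slot, so all remaining slots count toward K.
- Correct and commission response times are drawn from a normal
  distribution truncated to (`crt_floor`, θ], sampled by inverse CDF so a
  single uniform drives each draw. The location follows a linear
  improvement schedule μ(s, t) = max(floor, μ₀ − δ_session·s − δ_trial·t),
  emulating a patient growing familiar with the game; the default noise
  SD of 14 s reflects the high trial-to-trial variability typical of
  ADHD response times at a one-minute limit.

Defaults (μ₀ = 26 s, δ_session = 0.15 s, δ_trial = 0.05 s, floor 5 s,
`crt_floor` 0.5 s) give a mean CRT drifting from the mid-20s toward the
low-20s over a 20-session program, the regime the case-study phases
occupy. Every stochastic operation takes an explicit
`numpy.random.Generator`; identical seeds give bit-identical log streams.

`estimate_behavior` inverts the model by method of moments: pooled
omission/commission frequencies over attempted trials, quit frequency over
quit opportunities (one per reached trial), with binomial standard errors.
Recovery within 3 SE at 1,000 sessions is part of the test suite.

What the simulator does **not** emulate: within-session dependence
(fatigue, streaks), spatial behaviour, difficulty adaptation, or any
distributional shape information beyond a truncated normal. Passing tests
therefore show the scoring pipeline is correct and the simulator is
self-consistent — not that real patient telemetry follows this model.

## The two-part case study

Part 1 fixes full engagement (K = 0) and varies the error mix over three
phases ((C, OE, CE) = (3,3,4), (5,3,2), (8,1,1) with phase mean CRTs
25.13, 23.71, 21.81 s); part 2 zeroes the errors and varies engagement
over four phases ((C, K) = (3,7), (5,5), (7,3), (10,0); means 25.13,
23.93, 22.94, 21.62 s). Each phase spans 20 sessions with constant
per-session tallies. Three scoring modes:

- **Summary mode** scores the phase directly from its tallies and mean.
- **Curve mode** spreads the phase mean over a linear per-session
  improvement (default ±5 s around the mean, the start/end values being
  free as long as they average to the phase mean). PI is affine in the
  session mean CRT at fixed tallies, so the curve's mean equals the
  summary-mode PI to machine precision; the per-session values themselves
  are illustrative, not calibrated.
- **Generative mode** simulates the phase with a behaviour model whose
  outcome probabilities are the phase's error fractions. Engagement is
  realised deterministically — the session stops after C + I attempts —
  because the phase design holds K constant per session, which a
  stochastic quit cannot do. The truncated-normal location is solved
  numerically (Brent root-finding on the scipy `truncnorm` mean) so the
  *post-truncation* mean equals the phase mean CRT; without this
  correction the truncation at (0.5, 60] would bias the simulated mean
  CRT upward by about one second and the mean PI by about 0.008.

## Numerical choices

- CRF clips at 1 and tolerates ΣCRT ≤ C·θ·(1 + 1e-12) before rejecting a
  log as impossible, absorbing float accumulation.
- `calibrate_mu` brackets the root at ±(10·SD + range) around the target
  and solves to 1e-10; with zero noise it passes the target through.
- Response times serialise with three decimals (millisecond precision);
  round-tripping is exact at that precision.
- Trial indices are 0-based everywhere, including the JSONL/CSV schema.

## Problem sizes

The statistical suites use 10,000 trials for outcome-frequency checks,
1,000 sessions for parameter recovery, and 2,000 replicates for the
generative cross-check, each at 3-sigma (or 0.02 absolute for mean PI)
tolerances — sizes at which the checks are decisive in seconds on a
single core.

## Known limitations

- Printed SDs of phase CRTs cannot be reproduced exactly: the per-trial
  CRT schedule behind them is not specified anywhere, so SD correctness
  rests on the internal brute-force oracle.
- Multi-session aggregation is plain arithmetic averaging of PI; no
  clinical interpretation thresholds are provided.
- The game's spatial layer (player location, guidance effects) is carried
  as metadata only; no computation consumes it.
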