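# Methods

## The measurement problem

A two-dimensional sonification maps a point of a normalized data space
[-1, 1]² to a sound. Whether that mapping is usable is ultimately a
perceptual question: how small a change along each dimension can a listener
reliably hear (resolution), does audibility depend on the direction of the
change (hysteresis), and do simultaneous changes of both dimensions mask or
help each other (interference)? `sonijnd` answers these with a standardized
adaptive just-noticeable-difference (JND) experiment and turns the measured
JNDs into comparable scores.

## The experiment

**Mapping space.** Both dimensions are normalized to [-1, 1]; the space
splits into quadrants I–IV. The *standard* of each quadrant sits at its
center, (±0.5, ±0.5). A *variable* stimulus is offset from the standard by
a magnitude α along one of five directions: away from or toward the
coordinate origin in x, the same in y, or the positive diagonal (both
absolute values grow by α). "Plus" is defined relative to the origin —
larger absolute value — in every quadrant, which makes the direction
semantics consistent with how hysteresis is interpreted (approaching vs.
leaving the origin). Raw application data reaches the space through a
piecewise linear transfer anchored at a target value (→ 0) and clamped at
configurable bounds (→ ±1); any further pre-transforms (e.g. ion
concentration → pH) are the caller's responsibility.

**Trials.** Each trial is a two-alternative forced choice (2AFC): the
standard and a variable are played in randomized order and the listener
judges which lies further from the origin. Chance performance is 50%.

**Adaptive procedure.** Each (standard, direction) pair is one *track*. A
track maintains J candidate psychometric functions (*hypotheses*)

    psi(x; α_j, β, γ) = γ + (1 − γ) / (1 + exp(β (α_j − x)))

sharing slope β and chance level γ but differing in midpoint α_j. After
every trial the log-likelihood of each hypothesis is incremented by
log psi(Δ) for a correct answer or log(1 − psi(Δ)) for a wrong one. The
next stimulus is the *sweet point* of the currently winning hypothesis —
the inverse of its psychometric function at the target proportion correct —
rounded to the stimulus grid and clamped to its range. The first trial uses
a clearly audible offset so the listener starts with a success.

**Conventions (defaults of `MLPConventions`).** γ = 0.5 (2AFC chance),
β = 100 (dimensionless slope on the normalized offset scale), 100
hypothesis midpoints linearly spaced over α ∈ [0.001, 0.1] in steps of
0.001 (coinciding with the stimulus grid, so every selectable stimulus is
pre-renderable), p_target = 80.9% (the 2AFC placement that minimizes
threshold-estimate variance), 12 trials per track, initial offset 0.07.
Likelihoods are accumulated in natural log — the argmax is invariant to the
base — with base-10 values available for reporting. Likelihood ties break
toward the smallest midpoint, deterministically.

**JND readout.** Two conventions are implemented and always logged side by
side: `sweet_point` (default) reads the JND as the winning hypothesis's
inverse at p_target, clamped to the grid range; `midpoint` reads its α,
whose smallest reportable value is the grid floor 0.001. The published
wording of the procedure supports the former; the quoted score bounds
(0.001–0.1) match the latter, so neither is hidden: the session log stores
both and the report records which one fed the tables.

**Sessions.** A *full* session runs 5 directions × the quadrant mask
(20 tracks, 240 trials under defaults) in a seeded random order. A *light*
(design-stage) session instead measures the away-from-origin JND at axis
tick marks (default spacing 0.1; ticks whose offset grid would leave the
space are excluded) to check perceptual linearity of the parameter mapping
before any evaluation with end users. Tracks run sequentially in a seeded
random order by default; nothing in the model couples tracks, so
interleaving would not change the simulated results.

## Scores

With the five JNDs of a quadrant (readout mode recorded in the report):

* **Resolution** — the away-from-origin JNDs per dimension; 1/JND is the
  number of distinguishable steps (1000 at the grid floor, 10 at the
  ceiling).
* **Hysteresis** — h = 0.5·log10(JND(−d)/JND(+d)) per dimension, bounded in
  [−1, 1] on the grid; positive h means coarser resolution toward the
  origin.
* **Interference** — with JND_min/JND_max the smaller/larger single-
  dimension JND: T = 0.5·log10(JND_max/JND_min) ∈ [0, 1],
  δ = 0.5·log10(JND_diag/JND_min) ∈ [−1, 1], classified as positive
  (δ < 0), none (δ = 0), usual (0 < δ ≤ T) or negative (δ > T)
  interference.

Numerical choices: log-ratios are computed as differences of log10, so the
extreme grid values give exactly ±1; δ = 0 is measure-zero in floating
point, so `interference` takes an epsilon that widens the "none" band
(default 0, the literal rule). The linearity check passes an axis polarity
iff max/min JND across its ticks is ≤ 1.5 (a configurable default chosen as
"within half an octave of each other"; the criterion itself has no canonical
number). Multi-participant aggregation is deliberately out of scope: scores
are per session. Helpers accept any per-quadrant JND set, so a caller can
aggregate JNDs across listeners before scoring, or score per listener and
compare — neither is done silently.

## Stimuli

Test sounds must not leak cues a continuous sonification would not produce.
Each sound lasts 3–5 s (default 4 s, the band midpoint), is followed by a
silent pause of equal length — implemented between the two sounds of a pair
— and receives a short raised-cosine onset ramp (50 ms, against clicks) and
a long raised-cosine offset fade (500 ms), so listeners cannot compare the
pair by modulator phase at the note end. Both sounds of a pair are peak-
normalized by one common factor (0.9 of full scale over the joint peak), so
relative level cues survive but neither clips. The sonifier under test is a
user-supplied deterministic function (coordinate, duration, sample rate) →
mono buffer; modulators must start at a fixed phase. Output is uncompressed
16-bit PCM WAV at 44.1 kHz. The included reference sonifier (x → log
carrier frequency, one octave per unit around 440 Hz; y → amplitude-
modulation rate, 4 ± 3 Hz, modulator phase reset at onset) exists for tests
and demonstrations only — real evaluations plug in the design under test.

## The virtual observer

`VirtualObserver` answers trials from a known logistic psychometric
function with probability γ + (1 − γ − lapse)·logistic(Δ; α, β): the lapse
term lowers the ceiling symmetrically (a lapse is a random guess) while the
floor stays at chance. Answers depend only on the offset Δ, never on
presentation order, and the draw stream is reproducible under its seed.

It emulates a stationary, attentive listener. It does **not** emulate
learning or fatigue drift, inter-trial dependencies, order or interval
biases, or tick-dependent thresholds — so passing simulation tests shows
that the *procedure* recovers a stationary threshold, not that any real
sonification behaves this way. In particular the observer is perceptually
linear by construction, which is what makes it a positive control for the
light experiment's linearity check.

Simulation scale: parameter-recovery checks use 500 seeded tracks per
condition at 12 and at 100 trials, and the likelihood oracle is verified on
100 random tracks; these sizes put the median-estimate Monte-Carlo error
well below the tolerances being checked while the whole suite stays fast.
With 12-trial tracks the median sweet-point estimate lands within ±0.01 of
the observer's true sweet point; with 100 trials within ±0.003.

## Degenerate inputs and edge behavior

* A responder that errors mid-track aborts with the partial history
  preserved (`TrackAborted.state`).
* An all-correct history drives the estimate to the grid floor, an
  all-wrong one to the ceiling; the sweet point clamps to [α_min, α_max].
* Stimulus quantization rounds half away from zero to the 0.001 grid.
* A session log missing tracks for its mode fails scoring with an explicit
  listing; missing quadrants in a report are marked absent, never imputed.
* Simulated sessions carry no timestamps, so a replay from (config, seed)
  serializes to byte-identical JSON.

## Known limitations

The toolkit measures focused, unimodal, non-interactive listening with
static pairs; temporal resolution, training effects, shared attention, and
directions other than the five tested are outside the model. Interference
is probed only along the positive diagonal with equal changes in both
dimensions. Slope (β) is fixed, not estimated; Bayesian/staircase
alternatives and early stopping are out of scope. Hardware calibration,
loudspeaker spatialization, and survey-platform delivery are likewise not
part of the package.
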