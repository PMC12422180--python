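# Methods

This note records the generative model, the controller emulation, the
analysis conventions, and the design decisions taken where the published
procedure left room — in enough detail that every number the package
produces can be traced to an assumption.

## Synthetic kinematics

**Target sequences.** The task alternates strictly between a left and a
right target column; each side offers four target heights. Because the
start height of one movement is the end height of the previous one, a block
in which all 32 (start height × end height × direction) trajectory classes
occur equally often is an Eulerian circuit on the eight (side, height)
nodes with three parallel edges per directed pair; a seeded randomized
Hierholzer traversal generates one per 96-movement block. For movement
counts that are not multiples of 96, whole balanced blocks are generated
and truncated.

**Speed profiles.** Each reach uses the minimum-jerk speed bell
v(τ) = v_peak · 16 τ²(1−τ)², τ ∈ [0,1] — the standard unimodal profile for
point-to-point reaches and the simplest shape satisfying the online
detector's assumptions. Durations are N(0.812, 0.115²) s truncated at
0.25 s; sampling is a global 62-Hz clock; a 350-ms stationary dwell
separates movements and is assigned to the *following* trial (it is the
pre-movement rest period). Path length is v_peak·d/1.875, i.e. the profile
realizes the prescribed peak speed exactly; with the default parameters the
cursor travels ~780 px per reach and may stop short of the 1720-px target
separation. This is deliberate: every analysis in the chain consumes speed,
not end-point accuracy, and prescribing the peak-speed law is the contract
the tests audit. Additive position noise (default SD 2 px per sample)
models digitizer jitter.

**Bradykinetic decrement.** Expected peak speed decays geometrically,
v_i = v₀(1−r)^(i mod 96) with v₀ = 1800 px/s and r = 0.002 per movement
(≈ −17 % across a block). The exponent resets at block boundaries,
emulating the recovery provided by the between-block breaks in the
paradigm; without the reset a four-block session would decay 54 % and late
movements would fall below the 800.77 px/s movement threshold, which no
patient data shows. Multiplicative lognormal noise (CV 0.10, unit mean)
models trial-to-trial vigor fluctuations.

**Reinforcement.** When a protocol is supplied, the generator classifies
its own true peak speeds with the two-back rule, flags condition-matching
movements in stimulation blocks as stimulated, and multiplies the target
peak speed of the next same-direction movement (two ahead; targets
alternate) by 1+δ after fast- and 1−δ after slow-classified stimulated
movements, within the same block. The sign is taken from the
classification label rather than from the movement's position relative to
the decrement trend: the two differ for the ~1/8 of fast-classified
movements that lie below the trend line, and tying the sign to the label is
both the cleaner statement of "reinforcement of the stimulated state" and
the definition under which the injected effect is recoverable in sign and
approximate magnitude.

**What the generator does not model.** Reaction times, end-point errors,
secondary (corrective) sub-movements, fatigue beyond the geometric
decrement, learning, tremor, or any within-movement response to
stimulation. Passing tests therefore demonstrate correctness of the
*analysis machinery* under a clean unimodal-kinematics model, not
robustness to the full messiness of patient traces.

## Controller emulation

Instantaneous speed is the Euclidean step length divided by the elapsed
time; the controller's readout is the trailing mean of the most recent six
values (fewer at the stream head — a causal system must output
immediately). The three-decreasing peak detector counts consecutive strict
decreases; ties and increases reset the run, and the online peak is the
running maximum at the firing sample. The percentile-time variant reads
the running maximum out once the latency calibrated as the 80th percentile
of familiarization peak latencies (linear-interpolation percentile) has
elapsed since movement initiation.

The detector **arms** only once the smoothed speed crosses a movement
threshold (default: the 800.77 px/s offline constant). Without gating,
position-noise wiggles during the inter-trial dwell would satisfy three
consecutive decreases and freeze a near-zero "peak" long before the
movement starts; the deployed system must have used some onset criterion
for its reported accuracy to be attainable, and the offline movement
threshold is the natural choice.

The two-back comparison window resets at every block boundary, so the
first two movements of each block are unclassified and never stimulated;
this avoids cross-block leakage and matches per-block percentile
book-keeping. Movements without a detection contribute no reference peak.
Stimulation is a single event stream (the bilateral aspect, frequency,
amplitude and pulse width are metadata; no electrical model is attached).

**Accuracy metric.** `evaluate_controller` reports, by default, agreement
between the online label and the post-hoc label recomputed from the
*recorded* smoothed-speed trace — the definition a deployed system can
actually evaluate, and the one under which noiseless data give exactly
100 %. An audit against the generator's noise-free peak speeds is available
(`reference="truth"`); under the default noise it saturates near ~93 %
because sampling noise enters the online and the true peaks through
different paths, a ceiling no controller implementation can move.

## Offline behavior

Movement bounds are the contiguous above-threshold run containing the
peak — scanning outward from the peak to the last samples above
800.77 px/s — which makes the bounds robust to secondary sub-movements.
The per-movement outcome is the mean smoothed speed between onset and
offset. Block normalization subtracts and divides by the mean of the
block's first five (outlier-cleaned) averages; recovery blocks use the
first-five baseline of the preceding stimulation block; the first five
trials are excluded from the returned series; averages above 2413.35 px/s
become NaN and never contribute to any mean.

The post-stimulation shift computes, for each stimulated movement k, the
percent change of followers k+1 (opposite direction) and k+2 (same
direction), and subtracts the same changes after post-hoc-classified
fast/slow movements of the recovery block. Followers crossing a block
boundary are dropped. Cells without reference movements are NaN, never
zero. Cohort aggregation is one value per subject per cell, then
subject-level permutation tests.

**Recovery properties of the shift estimator.** Under the null the matched
subtraction is centred on zero (raw follower changes are ≈ −6 % after fast
and ≈ +7 % after slow movements — regression to the mean — and cancel).
With an injected δ = ±0.05 the estimator returns the correct sign, ≈ 0 for
opposite-direction followers, and a same-direction magnitude of ≈ 0.5·100δ
rather than 100δ. The attenuation has two sources, both inherent to a
self-consistent closed-loop emulation rather than to this implementation:
(i) the threshold-bounded average speed has elasticity ≈ 0.78 with respect
to a peak-speed multiplier (raising the peak widens the above-threshold
window into slower samples); (ii) roughly a third of stimulated movements
are themselves reinforced followers of earlier stimulation, and
classification bars inside the stimulation block include reinforced peaks,
while the recovery-block references are reinforcement-free — so the
control condition does not perfectly replicate the stimulated movements'
context. An exactly recoverable design would require the injected effect
to be invisible to the controller and to the stimulated movement's own
kinematics, which would contradict the closed loop being emulated. The
tests therefore audit sign, direction specificity and null behaviour
strictly, and document the attenuated magnitude.

## Permutation statistics

All tests are two-sided on mean-based statistics. Monte-Carlo p-values use
the add-one correction (b+1)/(n+1); when the permutation group is small
enough (2ⁿ sign patterns or C(n, n_a) assignments within the permutation
budget) the null is enumerated and the p-value is the exact tail fraction.
The cluster test forms clusters from pointwise Welch t values exceeding
the two-sided α = 0.05 critical value (Welch degrees of freedom per time
point), sums |t| within maximal contiguous same-sign runs, and compares
against the permutation distribution of the maximum cluster mass. Time
points excluded by the 15 % masking rule are removed before clustering and
clusters cannot bridge them. With 1,000 permutations the smallest
attainable cluster p is 1/1001.

## Spectral pipeline

The synthetic recording is 1/f background noise plus a 20–35 Hz narrowband
component (band-passed white noise) whose amplitude envelope carries a
peri-movement desynchronization and post-movement rebound around every
event; stimulated trials receive additional multiplicative window gains
(the injected effects) and damped 130-Hz transients at burst on/offset
(the artifacts). The synthetic sample rate is 1 kHz — beta-band analysis
gains nothing from the original 4-kHz acquisition rate and the lower rate
keeps the test suite fast.

Analysis conventions: epochs are −1…+1 s around the peak-speed time;
Morlet wavelets have 4 cycles (σ_t = 4/2πf), are truncated at ±5 σ_t, and
samples whose wavelet support leaves the epoch are masked; the default
frequency grid is 5–45 Hz in 1-Hz steps; z-scoring is per trial and
frequency against −400…−100 ms (zero-variance rows are masked rather than
divided); window membership uses closed intervals. Speed matching is
greedy nearest-neighbour without replacement, processing stimulated trials
in descending peak speed so extremes claim neighbours while the pool is
rich, with a permutation-test acceptance check and randomized-order
retries. Artifact masking NaNs ±65 ms around each on/offset per stimulated
trial. For cluster statistics, masked entries are replaced by the
cross-epoch median where the masked fraction is below 15 % and the time
point is excluded otherwise; window statistics are NaN-aware means and use
no replacement at all; linear interpolation across masked spans exists
solely for figures and is never an input to statistics.

## Problem sizes and seeds

The acceptance script simulates 1,000 decremented blocks for the
percentile placement, 50 four-block sessions (≈ 19,000 classified
movements) for the online/offline agreement, and 2,000 null cohorts of 24
subjects (1,000 permutations each) for the type-I error — sizes at which
each Monte-Carlo standard error is well below the quantity's tolerance
while the whole script completes in seconds. Every random draw in the
package flows through `numpy.random.default_rng` seeded from explicit
arguments; the acceptance script derives per-component seeds from the
single `--seed` via `SeedSequence`.

## Known limitations

- Single-channel spectral path only; no source modelling, connectivity or
  decoding.
- The generator's reinforcement acts instantaneously and only two
  movements ahead; longer-range or decaying after-effects are not modelled.
- Total block duration (and hence stimulation duty cycle) depends on
  unmodelled reaction times and is not a calibrated quantity.
- The null-cohort harness works at the level of per-movement average
  speeds (the decrement law times noise); it deliberately bypasses cursor
  synthesis, which the type-I-error question does not need.
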