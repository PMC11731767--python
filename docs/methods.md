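# Methods

This note documents the models and numerical choices behind `lmaze`: what the
synthetic-session generator emulates, how each analysis stage is defined, the
parameters that matter, and what the passing tests do and do not establish
about real recordings.

## Task model

The arena is treated as a 111-cm long axis tiled by six contiguous zones —
nest (0–19 cm), doorway (19–26), nest-side track (26–58), robot-side track
(58–82), robot (82–104) and feeder (104–111) — proportional to the published
arena dimensions; exact boundaries are unpublished, so all edges are
configurable (`ArenaGeometry`). The attack threshold is the nest-side /
robot-side boundary. On attack sessions every threshold crossing from lap 15
(1-based, inclusive) onward independently triggers an attack with probability
0.20; eligibility is inclusive of lap 15 because the published example animal
was attacked on lap 15. Laps are independent (no refractory period is
described, so none is modeled), and pellet counts are carried as inert
metadata.

## Synthetic sessions

`generate_session` splits one master seed into labeled per-component streams
(trajectory, theta, events, fields, spikes, LFP), so identical configurations
reproduce byte-identical sessions and any one component can be regenerated
without perturbing the others.

**Trajectory.** Position is scripted at 30 Hz as piecewise-linear segments:
runs at 35 cm/s, decelerating to 12 cm/s over the last 8 cm into either
feeder (so the feeder area is sampled during movement, as a real approach
would be), feeder dwells of 0.6–1.2 s, doorway staging dwells of 1.5–4 s, and
iid Gaussian tracking noise of 0.25 cm. Scripted events satisfy their
detection criteria with margin: outbound mid-track aborts (probability
0.15/lap) advance 12+ cm beyond the doorway for well over 0.5 s before
turning; inbound return-to-feeder aborts (0.05/lap) dip ≥ 8 cm below the
feeder threshold; pauses (0.30/journey) last 0.8–2.0 s; attack laps cross the
threshold, retreat to the nest at 60 cm/s, then complete. Ground truth
records every scripted event, lap boundary, movement interval and still nest
dwell.

**Theta schedule and LFP.** Movement epochs carry a phase-warped cosine:
each cycle runs peak → trough (descending) → next peak (ascending) with the
ascending:descending duration ratio set by `ThetaConfig.asymmetry_ratio`
(default 1.2, i.e. mildly longer ascent, with 0.2 Hz per-cycle frequency
jitter around 8 Hz). Stillness carries a 2.5 Hz delta oscillation (the LIA
proxy). Both regime gates are smoothed with a 20 ms Gaussian so state
transitions do not inject broadband steps into the ripple band. Channels
(default 4) share these components at slightly different gains over
independent 1/f² backgrounds (40 µV RMS) plus a small white floor. Ripple
bursts are flat-topped cosine-tapered (Tukey, α = 0.5) tones near 180 Hz
injected into SWR-flagged event windows, strongest on the designated channel;
their amplitude is calibrated against the pre-injection ripple-band envelope
so the peak sits near the configured z-score (default 6 SD).

**Place code.** Regular cells' Gaussian fields (SD 4–7 cm, peaks 8–16 Hz,
direction preference outbound/inbound/both at 0.4/0.4/0.2) evenly tile the
running span of the track from just beyond the doorway to the end wall.
During the descending theta phase a cell fires as an inhomogeneous Poisson
process at its field rate at the animal's position; during the ascending
phase the field is evaluated 7 cm ahead of the animal (signed by running
direction) — a fixed look-ahead standing in for forward theta sweeps. A
0.2 Hz ungated baseline applies throughout. Spikes are drawn per 1 ms bin
(Poisson counts, uniform jitter within the bin), so the expected in-field
count equals rate × occupancy exactly. A few tonic interneurons
(12–25 Hz, peak-to-valley ratio below 0.4) are added so the pyramidal
classifier has something to reject.

**Remapping.** A `remap_fraction` (default 0.3) of cells form the *threat
ensemble*: before the first attack they carry only a narrow, low-rate
(2–3 Hz) outbound field around the far feeder (reward-approach activity);
from the first attack onward they additionally express a sharp,
direction-unselective field in the robot-zone interior (peaks 8–16 Hz). The
representation thus trades feeder coding for threat coding, which is the
structure the pre/post cross-decoding analyses measure.

**Nest events.** Still nest dwells receive transient event windows
(0.6 per dwell-second, 75–120 ms), each flagged for ripple injection and/or
a population burst (probability 0.9 each, so the SWR/HSE overlap statistics
are non-trivial). Forty percent are *threat events*: their content is a
location in the robot-zone interior and they are expressed exclusively by the
threat ensemble (via its robot fields, in both epochs — the ensemble
rehearses the threat location even before it is expressed in behavior).
The rest are *ordinary replay*: content on the safe track or at the feeder
(reward replay with probability 0.2), expressed through all non-post
components, which includes the threat cells' reward-approach fields. Within
a window each participating cell fires at `hse_gain` (8) times its component
value at the content location — recruitment broadened by 3 cm — plus a 4 Hz
population term, giving bursts of roughly 40–70 spikes that stand far above
movement-theta firing. Content locations keep a 10 cm margin from zone
boundaries so the content category of an event is unambiguous.

This event structure is the generator's central modeling commitment: decoding
the same nest events against pre- vs post-attack tuning curves then *must*
shift posterior mass from the feeder zone to the robot zone, which is the
qualitative pattern the cross-decoding suite asserts for every seed. Real
recordings are under no such obligation; on real data the same pipeline would
measure the effect rather than confirm it.

## Analysis stages

**Behavior.** Tracking losses up to 0.5 s are bridged by linear
interpolation; longer gaps mark overlapping events uncertain. A track entry
begins when the animal leaves the nest+doorway region; entries reaching the
far-feeder threshold yield completed outbound and inbound journeys and
increment the lap count, others yield an incomplete outbound journey. MTAs
are incomplete entries with ≥ 0.5 s on the track and ≥ 5 cm beyond the
doorway, excluding journeys containing an attack; the event time is the first
sign change of the 2 Hz low-passed (zero-phase) velocity — a deterministic
proxy for the visually-scored head turn. Inbound aborts use the same
criteria on dips below the feeder threshold, without turn-time refinement.
Pauses are maximal intervals of a journey with < 1 cm of low-passed long-axis
displacement lasting > 0.5 s. Hesitations are nest+doorway occupancies
entered from and exited to the track; reported durations exclude samples
within 2 cm (Euclidean) of the nest feeder. Yoked splits permute the attack
sessions' first-attack laps over control sessions with a seeded RNG;
within-subject normalization uses the n−1 standard deviation.

**LFP state.** All spectral quantities come from non-overlapping Hann
spectrograms (1 s bins by default, 0.25 s for event-aligned use); a PSD is
the mean of the selected periodograms (Welch). The aperiodic component is a
Huber robust line in log-log coordinates over 80–400 Hz; residuals are
reported in linear power. State labels derive from the per-bin
log(theta/delta) band-power ratio z-scored over the session, theta iff
z ≥ 0.5; the ratio is invariant to overall gain, and the whole-session
normalization window realizes the within-subject normalization for a single
recording. Theta cycles take candidate extrema from the 6–10 Hz trace
(between zero crossings of the mean-subtracted signal) and refine each to
the extremum of the 6–40 Hz trace within the candidate's bracket (padded by
10% of the slowest narrow period). The broad filter is a second-order
Butterworth: steeper filters attenuate the in-band harmonics that carry
theta's sawtooth shape and shrink asymmetry estimates. The asymmetry index
is log2(ascending/descending duration) per cycle, summarized by the median;
the formula is isolated in one place so it can be swapped. Note a structural
ceiling: the extrema of a 2:1 sawtooth band-limited to 6–40 Hz sit at an
index of 0.835, not 1.0, so extremum-based estimates of strongly asymmetric
waveforms are conservative. Recordings above 2 kHz are decimated
(anti-aliased FIR) and 60 Hz line noise is notched before analysis.

**Transients.** SWRs: 150–250 Hz band-pass (zero-phase), Hilbert envelope,
z-normalized over the whole session including events (the literal reading;
an exclude-and-refit variant is deliberately not the default); candidate
supra-threshold (4 SD) intervals merge to fixpoint under both gap rules
(end→start < 5 ms, start→start < 20 ms — fixpoint makes the result
order-independent and idempotent) and events not exceeding 20 ms are
dropped. HSEs: pyramidal spike counts in 1 ms bins, 7 ms Gaussian kernel,
session-wide 3 SD threshold, keep 20 ms < duration < 750 ms (both bounds
exclusive). Channel selection integrates aperiodic-residual power over
120–250 Hz per channel, ties to the lowest id. Detection is session-wide;
analyses restrict by behavior afterwards. On attack sessions the
newly-expressed robot fields genuinely raise population synchrony during
post-attack robot-zone traversals, and the session-wide threshold flags some
of those passes; the in-nest restriction used by all decoding analyses
excludes them, and detector validation is therefore performed on control
sessions where injected events are the only bursts.

**Tuning.** Spikes and occupancy are both restricted to theta-state,
descending-phase samples inside the epoch (the matched-mask reading of the
occupancy normalization; an all-time-in-direction variant is available via
`occupancy_mode="direction_time"`). Direction is the 2 Hz low-passed
velocity with a ±5 cm/s stationary band. Spikes map to their nearest
position sample (a floor would lag the animal by half a sample). Counts and
occupancy are smoothed along position with a mass-preserving Gaussian kernel
(SD = 1 bin = 1.73 cm; each source bin's mass is renormalized within the
support, so Σ A·occupancy equals the included spike count exactly, smoothed
or not). Zero-occupancy bins propagate as NaN — never as zero rate — and are
excluded from averages and decoding. Shift maps take occupancy-weighted
direction marginals per cell, difference post − pre, require 10 included
spikes per epoch per cell, and collapse positional bins by zone.

**Decoding.** The posterior is evaluated in log space and normalized over
defined bins; defined bins where a cell's tuning is zero receive a 0.01 Hz
floor so one silent cell cannot annihilate a location. Ensembles below 10
putative pyramidal cells are refused. "Posterior probability of the robot's
(or feeder's) location" is the position-marginal mass over that zone's bins,
directions summed. HSE decoding uses τ = event duration and only events
whose midpoint lies in the nest (and in LIA bins when a state series is
supplied), partitioned at the first attack or yoked lap. Theta half-cycle
decoding uses τ = half-cycle duration, references the animal's interpolated
position at each half-cycle's own center, and reports signed-ahead offsets
(positive = ahead along the current run) plus re-centered average maps and
their descending − ascending difference. Matched controls share positional
bin, direction and epoch, avoid target event windows ± 1 s, and are sampled
without replacement up to 10 per target.

## Problem sizes used by the test suite

Round-trip checks run on 38–40-lap sessions (~8–9 min); parameter recovery
uses a 150-lap (~30 min) 50-cell session through the full LFP pathway
(per-cell tuning correlation, descending decode error, look-ahead recovery);
the cross-decoding pattern is checked on 20 seeds of attack sessions sized
as first-attack lap + 22 laps with the ground-truth theta schedule (the
LFP pathway adds nothing to that property but considerable runtime);
consistency is checked at 12/40/120 laps. The look-ahead estimator is the
median ascending-minus-descending signed center-of-mass offset over
mid-track passes (40–90 cm): the descending offset cancels shared reference
biases, and the track ends are excluded because the generative field bank
truncates there, which pulls posteriors inward.

## What passing tests do and do not show

The generator produces exactly the statistical structure the analyses
assume: Poisson spiking conditioned on known fields, binary theta/LIA
regimes, place fields aligned to scripted behavior, population bursts with a
single planted content location, and noise that is stationary and Gaussian.
Real recordings violate all of these to some degree — rate remapping is
graded rather than switched, replay content is sequential and mixed, theta
frequency and amplitude co-vary with speed, detectors face electromyographic
and reference artifacts, and tracking loss is structured. Passing tests
therefore certify that the implementation computes the stated quantities
correctly and recovers known ground truth under the model's assumptions;
they do not certify effect sizes or detector yields on animal data.

## Known limitations

* The LFP is phenomenological (warped cosine, gated delta, injected tones);
  it is not a biophysical simulation, and theta phase precession is reduced
  to a fixed ascending look-ahead offset.
* Asymmetry estimates from band-limited extrema are conservative for
  strongly sawtooth-shaped waveforms (ceiling ≈ 0.835 for a 2:1 sawtooth in
  6–40 Hz).
* Posterior masses from high-count events are nearly winner-take-all, so
  zone masses behave like win rates; with few events per epoch the 2 × 2
  cross-decoding summaries are lumpy.
* The diazepam pharmacology of the original study is out of scope beyond the
  exposed asymmetry/ripple knobs, as are spike sorting, video tracking and
  inferential statistics.
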