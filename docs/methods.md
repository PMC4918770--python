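# Methods

This note documents the models and procedures implemented in `cnswave`, the
choices made where the design was genuinely open, and what the synthetic
phantom does and does not establish about real recordings.

## Data model and foreground compression

Recordings are 4D `(x, y, z, t)` arrays with voxel spacing in micrometres
and a frame interval in seconds; x is the fastest-varying storage axis and
indices are 0-based.  Raw fluorescence is non-negative; the same container
carries ΔF/F, which is not.

The specimen geometry is modelled by thresholding the time-median
projection at 0.04 × its mean intensity (the median is robust to activity
transients), keeping the largest connected component, closing with a
2-voxel radius and dilating by a 3-voxel margin.  A truly empty mask (e.g.
an all-zero stack) raises; note that a *uniform positive* volume is
entirely above 4% of its own mean, so it yields a full single-component
mask rather than an empty one.  Per camera view, the detection path length
of a voxel is the cumulative tissue depth along the detection axis from the
first foreground voxel on that line of sight; it drives both view fusion
and attenuation in the phantom.

The compression container tiles the spatial axes into blocks (default
64 × 64 × 8; half-open 0-based ranges), skips blocks that do not intersect
the foreground, zeroes background voxels inside retained blocks, and
deflate-compresses each block (zlib, a dictionary-free lossless byte codec)
with a crc32 of the uncompressed bytes.  The lossless guarantee therefore
applies to foreground voxels — background decodes to 0 by design.  The
on-disk layout is: magic `CNSWBLK1`, version, 4D shape, block size, dtype
code, codec id, block count, voxel size, frame interval, view id, an index
table of `(bx, by, bz, offset, length, crc32)`, then the payload.

## Two-view preprocessing

The two cameras face each other across the detection axis, so view B is
mirrored before registration.  Translation is estimated by phase
correlation on the time-mean stacks with subpixel upsampling; an optional
in-plane rotation is recovered by a coarse-to-fine grid search.  Important
subtlety: because the two views carry *complementary* depth attenuation,
their intensities are anti-correlated inside the specimen; registration
quality is therefore scored by full-frame correlation (which the specimen
envelope against the dark background dominates), and if the aligned score
is worse than the unaligned one the identity-after-flip is returned with a
warning.

Fusion takes, per voxel, the value from the view with the shorter
detection path; exact ties, and voxels outside the foreground, are
averaged.  Drift correction registers every stack (translation-only) to
the stack at the temporal midpoint of the recording; integer shifts are
applied by exact rolling, fractional shifts by linear interpolation, and
all-zero stacks inherit the previous timepoint's shift.  Whether full
rigid or translation-only drift correction is more appropriate is an open
question for real data; translation-only is the default because global
specimen drift in an agarose mount is predominantly translational.

The baseline F0 is a per-voxel sliding-window percentile (25th percentile
for one-photon recordings, 10th for two-photon; 70-timepoint window;
linear interpolation between order statistics).  Windows shrink at the
recording edges so F0 is defined everywhere.  The percentile recovers the
resting level exactly only where activity occupies less than the
percentile's share of every window — a property the consistency tests
exploit and a caveat for recordings with near-continuous activity.
ΔF/F = (F − F0)/max(F0, ε) with ε = 1 raw count, making the measure
invariant to global detector gain and safe at dark voxels.

## Wave detection

The 16 hemisegment traces are processed in order: drop the first 120 s
(start-of-recording non-stationarity), z-score each trace (a zero-variance
trace maps to zeros), subtract the across-trace mean (removing the
CNS-wide activity envelope so relative segment timing dominates), average
left/right partners.  The SVD of the resulting 8 × T matrix gives the 2D
embedding; amplitude and phase are the polar coordinates of (v1_t, v2_t),
phase unwrapped by removing jumps larger than π.  These polar definitions
are the only reading consistent with waves being rotations away from and
back toward the origin of the embedding plane.

Detection: strict local maxima of the amplitude above 0.04, pruned
greedily by descending amplitude to a ≥ 3 s separation; the least-squares
phase slope over a 2 s window centred on each peak must exceed 0.125 rad/s
in magnitude (the slope threshold is interpreted in rad/s).  Component
signs of an SVD are arbitrary, so the slope-sign → direction mapping is
calibrated per recording: within each event the per-segment peak times are
regressed on segment index, posterior-leading order marks a forward
(anterior-progressing) wave, and the majority fixes the dictionary.
Thresholding precedes the separation rule.

Evaluation matches detections to annotations greedily one-to-one, same
direction, within a tolerance (default 3 s).  Because an annotation marks
a point inside an event that extends over many seconds while the detector
marks the amplitude peak (late in the wave under the phantom's recruitment
model), ground-truth evaluation on phantoms credits a detection that falls
within the wave's temporal extent (duration/2 + 3 s).  Wave duration is
defined as |A1 peak − A8 peak| of the left/right-averaged segment ΔF/F
inside a per-direction window around the event (±11.5 s forward, ±6.5 s
backward — wide enough for the longest waves of each direction, narrow
enough to exclude neighbouring events at the schedule's 20 s refractory
gap).

## Timing maps

For each voxel, windows of ΔF/F triggered on detected waves (forward
[−10, 10] s, backward [−6, 2] s, soma profiling [−8, 8] s; trigger frame
nearest the event time) are accumulated by Welford streaming into
per-offset mean μ_t and population variance v_t (divisor N, which makes
the least-squares error decomposition exact; with the paper-scale N the
difference from an N−1 divisor is negligible).  Events whose window runs
out of bounds, or overlaps a neighbouring selected event's window, are
discarded — both members of an overlapping pair, so retained windows are
disjoint.

The rectangular fit maximizes the (2r+1)-box-filtered μ_t over centres
where the window fits entirely inside [0, T−1] ('valid' convolution), with
ties broken toward the smallest index.  λ1/λ0 are the means inside/outside
the optimal window; when λ1 < λ0 (the best box is a dip) the voxel
collapses to the flat fit with zero gain — the statistic is meant to
reward activity increases, not dips — and τ\* takes the tie-rule value so
the result coincides with exhaustive constrained least squares.  Under the
λ0 ≤ λ1 constraint the box-filter argmax *is* the least-squares optimum:
for a fixed window sum the error is monotone in it on the feasible side,
and every infeasible centre collapses to the flat boundary.  The default
radius is one second's worth of frames (5 at 5 Hz); the gain map is
√E_flat − √E_time, non-negative because the rectangular family nests the
flat model.  Maps are written as HDF5 datasets `tau_s`, `gain`, `lambda0`,
`lambda1` with voxel-size metadata.

Region comparisons use the exact two-sided sign test (scipy's exact
binomial with the minimum-likelihood two-sided rule); ties are dropped and
an all-tie input returns NaN.

## Soma profiling

Somata are averaged over usable [−8, 8] s windows; the SEM uses the
population standard deviation over events divided by √N, so a single event
yields a zero SEM rather than an undefined one.  The propagation interval
per event runs from the leading to the trailing abdominal segment peak
(A8 → A1 forward, reversed backward); per-direction intervals are averaged
across events before classification, matching classification on the
event-averaged trace.  Class 4 requires two local maxima (prominence
≥ 5% of the trace range, to suppress noise peaks) whose intervening
minimum is at most (1 − dip_fraction) × each flanking peak, dip_fraction
0.5; otherwise the class is 1/2/3 by the position of the global maximum
relative to the interval.  Classification is invariant to positive
scaling, and lowering the required dip can only add class-4 calls.

## The phantom

The phantom is the package's ground-truthed stand-in for an isolated-CNS
recording; no real recordings ship with the package, so every quantitative
claim in the tests is a claim about this generator.

Geometry: a 160 × 64 × 32 grid (3 × 3 × 6 µm voxels) holding eight
bilateral segment blocks (A1 anterior … A8 posterior), two brain-lobe
spheres and an SOG block, joined by a neuropil core so the specimen is one
connected component (~10% of the volume); 16 scripted somata sit in
brain/SOG.  Two camera views are attenuated as exp(−path/60 µm) from
opposite sides, view B mirrored along the detection axis; resting
fluorescence is 100 counts inside the specimen and 0 outside.

Schedule: one renewal stream at the combined forward+backward rate
(defaults 9.5 and 15.5 mHz), inter-event gap = 20 s refractory (the
largest triggered-window span, so windows never overlap) plus an
exponential tail whose mean preserves the total rate; direction is drawn
by rate ratio.  Durations are normal (9.3 ± 3.7 s forward, 4.7 ± 1.1 s
backward), truncated at ±2 SD and ≥ 2 s — a crawl wave cannot sweep eight
segments in under a couple of seconds, and the symmetric truncation keeps
the mean.  Studies needing an exact event count use jittered even spacing
instead (`n_forward`/`n_backward`).

Waves: segment activation midpoints are spread linearly over the duration
between the A8 and A1 segment centres; the terminal segments activate as
units at the endpoints (the wave ignites in, and terminates by recruiting,
a whole segment), which makes the terminal ROI peaks land exactly on the
scheduled endpoints.  Each voxel's drive is a raised-cosine burst lasting
half the wave duration (adjacent segments co-active, as in recorded
average waves), convolved with a difference-of-exponentials indicator
kernel (rise 0.2 s, decay 1.8 s) and normalized to unit peak.  Drive
amplitude grows quadratically along the propagation path from a 0.2
relative floor ("progressive recruitment"), shorter waves are
proportionally stronger (vigour factor √((d + 4 s)/d)), and backward waves
carry a 1.35× amplitude factor — together these give the two wave modes
comparable energy in the population trajectory and make each wave a single
clean excursion ("petal") of the SVD embedding rather than a
constant-radius circle, which is what an amplitude-peak detector
presupposes.  These are properties of the
generator, chosen for realism of the embedding geometry; the z-scoring
step makes purely static per-segment gain profiles unobservable, so only
profiles that differ between the two directions survive into the data.

Noise is i.i.d. Gaussian per voxel and frame in ΔF/F units (default 0.1).
Trace-level simulation (`simulate_roi_traces`) draws the ROI-averaged
noise directly at SD noise_sd/√n_voxels — statistically identical to
rendering the noisy volume and spatially averaging, and verified against
full rendering in the tests.  `LazyDffSeries` materializes arbitrary frame
ranges on demand with noise seeded per absolute frame index, so
event-triggered accumulation over long recordings runs in bounded memory.

Ground-truth timing is expressed in *fluorescence* time: the expected
per-column peak offset replays the noise-free forward model (activation
midpoint + indicator response peak), optionally box-filtered at the
analysis radius, because the timing statistic measures when fluorescence
rises, not when the underlying drive starts.

### What the phantom does not show

Passing tests demonstrate correctness of the algorithms under the
generator's assumptions.  Real recordings additionally contain structured
noise (motion residuals, photobleaching, baseline wander), waves that
stall, merge, or change speed mid-cord, left/right asymmetries, activity
in thoracic and brain regions coupled to the waves, and optical blur —
none of which the phantom emulates.  Detection performance on the phantom
is therefore an upper bound, and wave density matters: at the paper-rate
hour-long schedule (~90 waves) the fixed 0.04 amplitude threshold sits
close to the embedding's energy budget (‖v1‖ = ‖v2‖ = 1 spreads over all
events), so the acceptance-scale runs use 40 scheduled waves, where the
threshold has clear margin.

## Problem sizes used by tests and the acceptance script

Detection: 160 × 64 × 32 grid, 1100 s at 5 Hz (5500 frames), 20 + 20
scheduled waves with a ≥ 20 s gap starting after the 120 s warm-up (40
waves cannot fit in 300 s without overlapping triggered windows, so the
recording is extended rather than the windows shrunk).  Timing-map
recovery: same grid, 30 forward waves over 800 s, lazily rendered, noise
0.1, box radius 5 frames.  Soma profiling: 12 + 12 waves over 560 s.  Wave
statistics: hour-long (3600 s) trace-level simulation at the default
renewal rates, triggered on the schedule.  Compression: a 96 × 48 × 24
phantom at ~24% foreground, uint16, 32 × 32 × 8 blocks.  Oracle
equivalence: 200 random instances with T ≤ 40, N ≤ 10, r ≤ 5.

## Known limitations

* Rotation search covers the in-plane (x–y) axis only; out-of-plane
  misalignment of the cameras is not modelled.
* Local (non-rigid) drift is out of scope; only global translation is
  corrected.
* The percentile baseline biases upward for voxels active most of the
  time (see above).
* The direction calibration needs at least one event with measurable
  segment peak order; a recording with a single ambiguous event falls
  back to the positive-slope = forward convention.
* The sign test treats events as exchangeable pairs; serial correlation
  between consecutive waves is ignored.
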