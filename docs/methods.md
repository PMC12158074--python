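# Methods

## Triangle separation of the shank clearance

Two distances are measured continuously between the actuator on one shank
(A0) and two sensors stacked on the other (S0 lower, S1 upper), a fixed
baseline d_a apart. Solving the triangle (law of cosines at S1) splits the
shank clearance into a component perpendicular to the sensor baseline,
Δy = d_c sin β, and a signed vertical shift, Δz = d_a/2 − d_c cos β. Δy is
reported non-negative: the sign of the mediolateral offset is not
recoverable from two scalar distances, and step width does not need it.
Because the sensor baseline is worn vertically, Δy actually measures the
distance of A0 from the S0–S1 *line*, i.e. it mixes the mediolateral and
anterior–posterior separation; sampling it at the pass-by instant, where
the anterior–posterior separation crosses zero, is what makes it a step
width estimate. This is why event timing matters as much as the geometry.

Numerics: the arccos argument is clamped to [−1, 1] when it lies within a
relative tolerance of 1e-6 outside (measurement noise routinely pushes
near-collinear triples marginally out of validity); beyond the tolerance
the triple is rejected as geometrically impossible and the event is
flagged and excluded with a logged count. Near the collinear limit the
solution is exact to roughly sqrt(machine epsilon) ≈ 1e-8 — inherent to
arccos, whose slope is unbounded at ±1 — and everywhere else to ~1e-15.

## Two-stage gait-event detection

Primary stage: the sample-wise channel average is low-pass filtered at
2 Hz (2nd-order Butterworth, applied forward and backward so the phase is
exactly zero and the magnitude response is squared) and scanned for strict
minima over a symmetric window of half-width N0 = round(0.5 s · fs).
Strictness plus the shared window guarantee events are at least N0 samples
apart. Windows truncate at the series ends by default (a config switch
discards boundary events instead); the two endpoint samples are never
candidates, since a minimum needs a descending and a rising flank.
Refinement stage: per-channel argmin on the unfiltered signals (full
tracking bandwidth) within half-width N1 = round(0.1 s · fs) of each
primary event, ties resolved toward the earlier sample. N0 and N1 are
half-widths of their windows.

Zero-phase filtering uses Gustafsson initial conditions rather than
reflection padding: the output is then exactly time-reversal equivariant
(filter∘reverse = reverse∘filter to machine precision), which keeps
detection symmetric near the record boundaries; away from the edges it
agrees with padded filtering to ~1e-6 of the signal scale.

Side classification compares the refined minimum values: the swinging
shank carries the actuator past the *upper* sensor more closely on a
right swing and past the *lower* sensor on a left swing. Sides must
alternate; when two consecutive events share a side the weaker minimum
(larger refined value) is dropped, and unknown-side events (exact ties)
are dropped before enforcement. Both counts are logged.

A minimum-prominence guard (default 1 cm: the window must rise at least
that far above the minimum) is applied at the pipeline level but is off in
the bare detection operation. During gait the low-pass signal swings tens
of centimetres per window, so the guard is inert; on quasi-constant
records (quiet standing) it suppresses the spurious minima that any
residual noise otherwise produces. Initial-contact detection uses the
same machinery on the heel height with a 5 mm guard, non-strict
comparison, and plateau collapsing (a flat stance maps to its centre
sample), with prominence evaluated over the plateau extent plus half a
window so long stance plateaus are not self-masking.

## Reference definitions

*Initial contact*: belt motion is compensated by adding belt_speed·t to
the forward coordinate; for two subsequent same-foot contacts P1, P2
bracketing exactly one contralateral contact Q, stride = |P2−P1| and
width = perpendicular distance from Q to the line P1P2 (a `simplified`
flag uses |y_Q − mean(y_P1, y_P2)| under a pure-forward line of
progression). Degenerate strides (< 1 mm) and pairs without exactly one
intermediate contact are skipped and counted. *Mid-swing*: the raw
treadmill-frame forward components of the two heels cross once per step
(stance drifts backward, swing advances); the crossing index is linearly
interpolated and the heel separation |y_L − y_R| sampled there. Crossings
are computed on raw, not belt-compensated, components — compensation
shifts both markers equally and would not move the intersections.
*Shank clearance*: distances between the device marker centroids run
through the identical magnetic pipeline; the device-level reference.

Surplus trailing steps are trimmed to equalise left/right counts,
implemented as the longest balanced prefix; a side sequence admitting no
balanced prefix reduces to an empty series with a warning.

## Error metrics

Signed error e = estimate − reference per matched step. bias = mean(e);
SD = sample standard deviation of e (n−1 denominator, also used for the
step-width variability itself); MAE = mean |e|; RMSE = sqrt(mean e²);
SCC = Spearman correlation with average ranks (undefined on a constant
series and then reported missing, not zero); MAE-VAR = |SD(est) −
SD(ref)|. Estimate and reference events are matched greedily by nearest
time within 250 ms, one-to-one; unmatched events are excluded and
counted. Cross-participant aggregation weights by step count and uses the
arithmetic mean for bias, MAE, SCC, MAE-VAR and the root mean square for
SD and RMSE. Tables render in cm (spatial) and ms (temporal); everything
internal is SI.

## The synthetic gait generator

`simulate_walk` emulates the validation protocol: 120 s at 0.5 m/s on a
treadmill, 100 Hz, step time 0.8 s (stride 1.6 s), swing occupying 40 %
of the cycle — a textbook value, configurable. During stance the heel
drifts backward at belt speed with zero height; during swing it advances
by a half-cosine profile that exactly regains the stance drift and lifts
by a half-sine bump (5 cm). Lateral placement is redrawn every step and
settles during the first half of swing, so the width realised at pass-by
is governed by the fresh draw; draws are scaled (sqrt(2) · step_width_sd
per half-placement) so that the standard deviation of the realised
pass-by widths equals `step_width_sd` (default 1.3 cm about a 10 cm
mean — the parameter is defined as an observed-width statistic, since
each realised width combines the two feet's half-placements). A 3 mm
sinusoidal trunk sway moves both feet in common mode and cancels in every
separation.

Devices ride rigidly on the shanks: S0 5 cm above the left heel marker,
S1 10 cm above it, A0 centred between those heights above the right heel.
Each mount is offset 2 cm outward of its heel line
(`device_lateral_offset`): shank-worn hardware cannot sit at the
anatomical reference point, and this offset is what produces the
near-constant ~4 cm proxy bias between shank-level and heel-level step
width that the validation exposes. Setting the offset to zero removes the
proxy bias entirely.

Per-step ground truth records the side, initial-contact time and
compensated position, the crossing (pass-by) time, the heel separation at
pass-by, and the true mid-swing event: the sample minimising the
noise-free channel average within the swing window, with the device-level
Δy and Δz at that sample.

`simulate_magnetic_distances` adds the measurement model to the true
device distances: (1) heteroscedastic Gaussian noise with SD
sigma0 · (d/d0)^3 (default 3 mm at d0 = 20 cm) — the transmitted dipole
field decays with 1/r³, so the channels are clean near mid-swing (~20 cm)
and noisy near initial contact (~40 cm, 8× the SD); (2) shock bursts at
each initial contact, zero-mean Gaussian noise under a Gaussian envelope
(SD = impact_duration/2, default 40 ms) drawn independently per channel;
(3) zero-phase band-limiting at the 25 Hz tracking bandwidth. With
`bandwidth=None` and zero noise the output equals the true distances
exactly — the `noise_free` scenario, used wherever sub-millimetre
agreement is asserted, because the sharp pass-by valley itself contains
energy above 25 Hz and band-limiting alone already displaces the minima
by a few tenths of a millimetre. One seed sequence drives everything,
split into walk and noise substreams (channel white noise lower then
upper, then impact draws lower then upper), so every scenario is
bit-reproducible.

The magnitudes of the magnetic channel noise are design choices: no
quantitative mid-swing versus initial-contact noise figures exist to
calibrate against, so sigma0 and impact_sigma are set to make the
resulting error scale plausible (error SD a few tenths of a centimetre)
rather than to match any measured value.

### What the simulator does and does not show

It reproduces the *structure* that the method must cope with —
gait-phase-dependent noise, impact bursts, the vertical swing component
that the triangle must remove, alternating sides, belt drift, and the
anatomical proxy bias. It does not model soft-tissue artefact, sensor
orientation error, magnetic field distortion from nearby metal, acoustic
resonance of the sensor cantilevers, calibration drift, or pathological
gait. Passing the recovery tests therefore demonstrates the correctness
and noise-robustness of the *processing chain*, not the field performance
of the hardware; real-data error levels are expected to be larger.

## Default problem sizes

Tests and the acceptance script run the generator at its native study
conditions (120 s, 150 steps) — small enough that the complete synthetic
study, including 20 calibrated-noise replicates, executes in seconds.

## Known limitations

Event times are reported on the sample grid (no sub-sample interpolation
of the distance minima); at 100 Hz this bounds timing resolution to 10 ms.
The side-classification rule assumes the two-sensor bar is on the left
shank and the actuator on the right; `actuator_side` in the config is
reserved for mirroring but the mirrored layout has no test coverage
against recorded data. The initial-contact reference locates stance
plateau centres rather than true touchdown instants, which is harmless
for widths (stance position is constant under belt compensation) but
makes its event times unsuitable for temporal validation.
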