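# Methods

This note documents the model implemented in `snntraj`, the synthetic
data it is evaluated on, and the numerical and design choices made
where the published description of this class of system leaves them
open. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Synthetic throw scenes

The pipeline was designed around camera recordings of a ball thrown
~2.3 m between two people, imaged at 128×120 px / 240 fps with the
camera perpendicular to the flight plane. Those recordings are not
distributed, so `snntraj.scenes` generates the study conditions
synthetically:

* **Kinematics** are closed-form ballistic motion,
  `x(t) = x0 + vx·t`, `y(t) = y0 + vy·t − ½g·t²`, in world meters,
  mapped to pixels by a fixed `pixel_pitch` (default 2.3 m across
  110 px). Per-frame ground truth (center, velocity, direction angle,
  speed) is exact, not estimated; the reception height is solved from
  the closed form at the reception-column crossing rather than read
  from a frame sample. An energy invariant
  (`v²/2 + g·y_world` constant to 1e−9 relative) guards the kinematics.
* **Conventions.** Pixel origin is top-left with y downward, so higher
  ball positions have smaller y. Direction angles are degrees
  clockwise from vertical-up: 0° up, 90° rightward, 180° down, 270°
  leftward; an ascending rightward throw sits near 45°.
* **Rendering** draws the ball as a hard-edged disk (no anti-aliasing,
  no motion blur) on a uniform background, with optional Gaussian pixel
  noise, an optional thrower-arm segment animated over the first
  ~0.15 s, and an optional persistent distractor (below).
* **Launch distribution.** The number of throws, speeds and angles of
  the original data set are known only coarsely ("multiple
  velocities", 297 throws, 70–30 split). Launches are drawn uniformly:
  speed 3–6 m/s, elevation 30–60° from vertical toward the throw
  direction, launch height 0.55–0.85 of the frame, alternating
  directions. The split is a seeded permutation with
  `round(n · split_fraction)` training items (297 → 208/89).

**What the generator does not emulate:** sensor noise beyond additive
Gaussian pixel noise, exposure/rolling-shutter effects, human
biomechanics, background clutter, lighting changes. Tests passing on
these scenes show the mechanisms work under clean, known kinematics;
they do not certify performance on real recordings.

## 2. Event-camera emulation

For each frame pair the difference image is convolved with a zero-mean
difference-of-Gaussians kernel (defaults σ_center = 1 px,
σ_surround = 2 px, 7×7 taps — the original filter sizes are
unpublished; all configurable). Pixels with `|R|` above a threshold
become ON/OFF events by the sign of `R`; magnitudes are min–max
normalized per frame (matching the per-frame magnitude sorting of the
hardware chain) and converted to latencies, strongest first, spread
over one frame period. Ties break in raster order (ascending y then
x), documented and stable. A frame with all-equal magnitudes (including
a single responding pixel) fires at the frame time.

The acquisition threshold was set manually on the original hardware.
`snntraj.frontend.tuned_config` reproduces that step: it picks the
threshold so a target fraction of pixels respond per frame
(default 0.3 %, consistent with the sparse regime such sensors run in;
the acceptance script measures ~0.3 % active pixels and ~10⁴ events/s
on the native-resolution synthetic scene).

## 3. Network

Three convolutional LIF layers with shared 5×5 kernels, stride 1,
valid convolution (each map shrinks by 4 px per side), no pooling.
Input events are duplicated onto three delay lines (defaults: 0, 1 and
2 frame periods; the published system used three delays of unstated
value), giving 6 input channels (ON/OFF × delay). The published
per-layer constants are the defaults:

| layer | w_max | τ_memb | N_f | τ_LTP | a_LTP | a_LTD | f_inst | f_long | T_thresh |
|---|---|---|---|---|---|---|---|---|---|
| 1 | 1.873 | 0.010 | 60 | 0.0754 | 0.00195 | 0.00050 | 3.00 | 2.89 | 0.031 |
| 2 | 0.813 | 0.052 | 80 | 0.0236 | 0.01310 | 0.00118 | 2.82 | 2.41 | 0.023 |
| 3 | 1.308 | 0.039 | 100 | 0.0368 | 0.00815 | 0.00198 | 3.46 | 1.90 | 0.051 |

All time constants are seconds. The simulation is event-driven: state
is touched only when a spike is delivered (leak → integrate → threshold
check → on spike: reset, STDP if that layer is learning, lateral
inhibition, penalty registration, propagation). Simultaneous events
process in (time, layer, raster (y, x), channel) order; within one
delivery, crossing neurons fire in raster order then filter order. A
dense clock-driven reference simulator (`snntraj.reference`, 0.01 ms
ticks, per-tick multiplicative decay, no event queue) reproduces the
event-driven spike sets exactly on random streams whose event times
lie on the tick grid; this equivalence is an acceptance test.

Numerical/design choices where the source description is open:

* **Base threshold.** The firing threshold's base value is
  unpublished; only the homeostatic *increase* is described. With
  `u_base = 1` and the published `w_max` values a single afferent event
  fires any neuron, which degenerates into layer-over-layer activity
  amplification. The default is `u_base = 8` potential units, chosen
  once so that several near-coincident afferents are required and
  per-layer spike counts decrease up the hierarchy (the sparse-coding
  regime the system is described to operate in). Configurable per
  layer; scaled experiments at other frame rates override it (16 for
  the 30 fps dot study below).
* **Homeostasis/inhibition signal.** `U_propinh` ("average of squared
  membrane potentials at the position") is computed over rectified
  potentials, `mean(max(u,0)²)`. Squaring sub-rest potentials makes
  instantaneous inhibition self-amplifying — each inhibition enlarges
  the mean square that scales the next one — and numerically divergent
  under dense input. Rectification bounds the signal; neurons pushed
  below rest carry no excitation and contribute zero. The membrane
  itself has no floor: inhibition may push it below rest, and the leak
  then decays it back.
* **Weight initialization** is independent uniform on [0.3, 0.7],
  seeded per layer.
* **LTD scope.** At a postsynaptic spike, every afferent of the
  receptive field whose last (delayed) presynaptic spike is absent or
  outside the LTP window is depressed; presynaptic spikes arriving
  after a postsynaptic spike trigger no update.
* **Silent gaps.** Trajectories are presented individually with a full
  state reset between them; at the published constants all state decays
  to baseline well within the 2 s inter-trajectory silence, so this is
  equivalent to simulating the gap. A strict mode
  (`train_network(..., strict_gaps=True)` / CLI `--strict-gaps`)
  concatenates the streams with literal 2 s gaps. The two are
  dynamically equivalent but not bit-identical: the stream time offset
  perturbs event times in the last float ulp, and a knife-edge
  threshold crossing can flip, after which learning trajectories
  diverge (the test compares them statistically).

## 4. Readout

Per output filter, ordinary least squares on the quadratic design
(1, x, y, x², y², xy) with the trajectory's reception height as target
for every spike; filters with fewer than six training spikes (the
coefficient count) are unusable and excluded. The per-spike score bump
is a Gaussian of width `max(RMSE_n, 1 px)` and height `1/RMSE_n`
(triangular available by option); the exact bump shape of the original
system is unpublished, and the choice matches its depiction as one
reliability-weighted bump per spiking neuron. The score leaks
exponentially with τ = 0.5 s (configurable, including off); scores are
kept on 1 px bins over the frame height. An empty score decodes to the
training-mean height — the same constant that defines the naive
baseline predictor. Direction is decoded independently of the
regression by majority vote over spiking filters' training labels,
ties to the most recent spike.

Visibility is a fraction of the clip duration; evaluation replays the
recorded output spikes up to each cutoff, so one network run per
trajectory serves all visibility levels.

## 5. Filter characterization

* **Direction tuning** bins spike-time ball directions at 1°
  resolution and divides by how often each direction occurred across
  the presented throws, making the curve invariant to the stimulus
  direction distribution (verified by a resampling test). The
  preferred direction is the peak after 5° boxcar smoothing (window
  unpublished; configurable), ties resolved by circular mean. The
  direction-selectivity index is
  `DSI = (R_pref − R_opp)/(R_pref + R_opp)` on the smoothed curve.
* **Speed selectivity** compares spike-triggered speeds against a
  direction-matched control resampled from the pooled ground truth.
  Control direction bins are drawn from the filter's tuning curve
  *times* the per-bin occurrence count — the expected spike-count
  profile. Weighting by the tuning curve alone mismatches the spike
  direction mixture whenever direction occupancy is non-uniform and
  inflates the false-positive rate (measured: 0.24 instead of 0.02 at
  α = 0.05). The decision rule — two-sample KS distance against a
  1000-permutation null at α = 0.05 — is this package's formalization;
  the original work asserted the difference visually.
* **Tracking** maps the ball center into layer k's retinotopic frame
  (minus 2 px per 5×5 valid-convolution stage) and computes each
  filter's mean spike-to-center distance D_n; filters strictly under a
  threshold are ball-coding. The full-scale threshold is 6 px at
  128×120; scaled scenes use `ball_radius + 3 px`, since event spikes
  sit on the moving edge and even a perfectly ball-locked filter has a
  distance floor of about one radius plus the kernel support.
* Ground truth at spike times uses nearest-frame lookup (≤ half a
  frame period of error).

## 6. Scaled-down experiment designs

`snntraj.experiments` freezes the study designs used by the acceptance
suite; each takes only a seed. Sizes were chosen once so the whole
suite runs in minutes on one core.

* **Moving-dot direction selectivity** — one layer, 8 filters,
  48×48 px, a 2 px dot crossing at 1 px/frame, 100 presentations per
  direction, delays {0, 1, 2} frame periods. The scene runs at 30 fps
  so that the frame period (33 ms) exceeds τ_memb (10 ms): delayed
  copies of past frames are then the only way to accumulate
  multi-frame motion evidence, which is the regime where delay lines
  matter. `u_base = 16` puts the layer in deep coincidence detection.
* **End-to-end prediction** — 64×48 px, 60 fps, 60 train / 20 test
  throws, layer sizes 16/20/24, one training epoch per layer (a second
  epoch was measurably worse: over-concentration of weights begins to
  erode filter diversity). The untrained control runs the identical
  pipeline with the seeded random kernels and a freshly fitted
  readout.
* **Tracking** — the end-to-end scene (ball radius 3) plus a
  horizontal bar bobbing vertically in the lower-center of the frame
  (period 0.6 s), orthogonal to the ball in both edge orientation and
  motion direction; one layer, 16 filters.
* **Speed-test calibration** — 200 synthetic null filters whose spikes
  are drawn by direction preference only (von Mises tuning over the
  pooled ballistic frames), plus one constructed filter restricted to
  the top decile of direction-matched speeds.

## 7. Known limitations

* **Delay ablation.** Zeroing the delay lines reduces mean DSI, but
  not by a large, seed-stable margin. This is a property of the
  simplified STDP rule: all afferents inside the (long) LTP window are
  potentiated equally, so the learned kernels pair recent positions
  with *all* delay channels — a structure that still contains
  synchronized arrival combinations for both directions — and frame
  differencing additionally provides a static direction cue
  (ON-leading/OFF-trailing polarity arrangement) that survives delay
  removal. Sharp delay *selection* (a thin diagonal in
  position × delay) would require depression of presynaptic spikes
  arriving after the postsynaptic spike, or a timing-graded window,
  neither of which is part of the rule. The corresponding acceptance
  assertion is left failing rather than weakened.
* Competitive specialization at desk scale (8–16 filters) is
  seed-sensitive: which filter claims which stimulus varies, and
  occasionally a split (e.g., ball vs distractor) is uneven. The
  acceptance experiments pin seeds; the acceptance script reports
  whatever the given seed produces.
* The event-driven simulator is exact but single-threaded pure
  Python/numpy; native-resolution multi-layer runs take seconds per
  trajectory. The clock-driven reference is intentionally simple and
  only supports one layer.
* Strict-gap and reset training are equivalent only statistically (see
  section 3).
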