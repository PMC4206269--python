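# Methods

This note documents the simulation model behind `activeecho`: what is
modelled, what is deliberately simplified, the parameters that matter, and
the numerical choices a user should know before trusting a result.

## Coordinate frame and units

Right-handed frame: `x` lateral (along the array), `e` elevational (out of
the imaging plane), `z` axial (depth, 0 at the probe face).  The imaging
mid-plane is `e = 0`, so "distance to the mid-plane" is simply `|e|`.
Everything internal is SI (m, s, Hz); scenario files may use explicit unit
suffixes (`4 cm`, `10 MHz`, `200 us`), normalized on load.

## Acoustic model

**Media** are ordered axial layer stacks `(thickness, c, attenuation)`;
the last layer may be unbounded.  Propagation is straight-ray: refraction
at layer boundaries is ignored, because the layered-medium phenomena of
interest (a fast plate making a target look shallow) are pure timing
effects.  One-way travel time to depth `z` is the sum of per-layer
`path/c`; the scanner converts round-trip time to displayed depth with its
*assumed* sound speed, which is exactly how the apparent-depth error
`L·(1 − c₁/c₂)` arises for an inclusion of thickness `L`.

**Attenuation** is a frequency-dependent amplitude factor
`10^(−α·f_MHz·path_cm/20)` per traversed layer, applied once per direction.
No dispersion.

**Transmit beams** are summarized by a separable Gaussian amplitude field
per scan line: lateral sigma, elevational sigma, and an on-axis peak.
Unfocused beams have constant lateral sigma `aperture_width/4`; focused
beams follow a hyperbolic waist with minimum `λ·z_f/aperture_width` at the
focus, opening back to the unfocused width at the probe face.  The peak
amplitude carries transmit power, aperture fraction and focusing gain
(amplitude ∝ 1/lateral width).  This is not a diffraction solver — it is
the simplest field that reproduces the orderings that matter here:
focused beams are narrower and hotter at the focus, larger apertures
deliver more power, beams overlap laterally so several lines can trigger
the element.

One consequence worth knowing: for *focused* beams a larger aperture also
narrows the waist (`∝ 1/aperture`), so at high peak-to-threshold ratios
the number of triggering lines can saturate or even dip even though the
delivered power rises.  The "larger aperture → more triggers" ordering is
guaranteed, and property-tested, in the unfocused regime, where width and
peak both grow with aperture.

**Echo timing uses axial depth only** (`t = 2·one_way_time(z)`); the
lateral/elevational beam pattern affects amplitude, not timing.  This
makes the axial position of any point target exact by construction, which
is the property the tracking method relies on.  RF lines are sums of
Gabor packets (Gaussian-windowed cosines, sigma = duration/6) placed with
fractional-sample accuracy, then band-pass filtered to the receive band
with a zero-phase Butterworth filter.  Zero-phase filtering keeps
envelope peaks where the physics puts them; it is also linear, so the
frame-subtraction identity `frame(on) − frame(off) = frame(AE alone)`
holds to floating-point precision — the basis of template acquisition.

Receive is one pre-beamformed line per transmit event; no per-element
channel data, no receive apodization.  AE pulses received by the probe are
not lateral-weighted: a firing during line `k`'s listen window appears on
line `k` at full amplitude.  The echo spot's lateral extent therefore
mirrors the trigger range, as on a real scanner (the spot widens at high
trigger counts; accurate localization comes from the trigger statistics,
not the spot).

## The device model

The AE element is a point receiver/emitter with:

| parameter | default | meaning |
| --- | --- | --- |
| `rx_gain_db` | 19 dB | front-end amplifier gain |
| `threshold` | 1.0 V | comparator level (sensitivity is an arbitrary scale; only the ratio matters) |
| `loop_delay` | 0.6 µs | trigger-to-fire electronics latency |
| `pulse_freq`, `pulse_cycles` | 9 MHz, 8 | emitted Gabor pulse; the long duration models the element's ringing tail and is what makes matched filtering discriminative |
| `drive_voltage` | 58 V | emission amplitude, ≤ 150 V, pulse ≥ 12.5 ns |
| `blink_period`, `blink_duty` | 0.5 s, 0.5 | time-modulation gate (off by default via `blink_enabled`) |

The front end applies a 0.1–20 MHz analog band-pass (upper cutoff clipped
below Nyquist) before the comparator.  The comparator acts on the
absolute value and latches per scan line: at most one trigger per line,
reset at the next line, so a frame can accumulate the multi-line trigger
counts that mid-plane detection needs.  Directivity is `cos²` of the
angle from broadside, floored at 0.05 — the element works at any tested
insertion angle once the gain is adjusted.

**Timing convention.**  The logged trigger time is the first comparator
crossing, as in hardware.  The *emission epoch*, however, is referenced to
the beacon envelope center plus `loop_delay`: a measured loop delay is the
interval between received and fired waveform features, so defining it this
way makes "zero delay ⇒ spot at the true element depth" hold exactly
instead of being off by the threshold-dependent lead of the first crossing.
(For reference, `c·0.6 µs/2` in water is 0.444 mm of axial offset.)

**Detected amplitude.**  The event amplitude is the packet's peak
amplitude estimated from its energy in a short window around the envelope
maximum, calibrated by the norm of the front-end-filtered unit-peak beacon
shape.  A raw sample maximum beats against the carrier phase at the
40 MHz sampling instants and jitters by several percent between positions;
the energy estimate is stable to ~0.2%, which the amplitude-based
mid-plane method needs to resolve sub-millimeter half-widths.

## Injection methods

`t = 2y/c − d/c` per pixel.  Method 1 (scanner sync available) computes
`d` per target line from geometry and places pixels at absolute image
coordinates.  Method 2 uses a reference trigger and the A-line period
estimated from beacon arrivals — the estimator divides successive trigger
differences by their nearest-integer line gaps (anchored at the smallest
difference), so skipped lines do not bias it; two isolated triggers are
fundamentally ambiguous and need an explicit gap.  With the exact period,
both methods produce identical fire times for element-relative pixels up
to the `(d_line − d_ref)/c` geometric term, which stays below one RF
sample for offsets of a few lines at centimeter depths.

Unreachable pixels (`2y < d`, i.e. the virtual spot is shallower than the
element can reach) are skipped with a logged warning rather than aborting:
a partial pattern is more useful than none.  Same-line firings closer than
one pulse duration merge with summed intensity — a single element cannot
overlap emissions.

The mid-plane bar indicator maps a trigger count to
`ceil(count/counts_per_bar)` element-relative bars, so an operator steering
toward more bars is steering toward the mid-plane.

## Imaging and metrics

Standard B-mode: per-line analytic-signal envelope, per-frame max
normalization, log compression over a 50 dB dynamic range to 0–255.  No
scan conversion (linear array).  M-mode stacks one line's envelope across
frames.

SNR/CNR use three quantities: `DiffSignal = on − off`, the background
(the echo-off frame), and a 50×50-pixel surrounding window.  The spot
region is where DiffSignal reaches half its maximum;
`SNR = mean(DiffSignal over spot)/std(background over window)` and
`CNR = |mean(on over spot) − mean(background over window)|/std(background
over window)`.  The CNR deliberately uses the raw on-image over the spot
(contrast between what is displayed and the background).

## Synthetic scenes

Phantoms are uniform random point scatterers at a configured density
(default bench scenes: 10–60 scatterers/cm³) with Rayleigh-distributed
reflectivities, optionally with bright spherical inclusions; identical
(spec, seed) is bit-reproducible.  This produces speckle-like clutter
with controllable statistics, which is what the blink and template methods
are tested against.  It does **not** reproduce real tissue speckle
statistics, aberration, reverberation, nonlinear propagation or probe
element noise — so passing tests demonstrate the *mechanisms* (timing,
counting, filtering, modulation) under controlled conditions, not
performance figures transferable to tissue.  Likewise the absolute SNR/CNR
and trigger-count values depend on the synthetic beam field and are
meaningful as orderings and trends, not as predictions of any particular
scanner's numbers.

## Numerical choices

- Sampling 40 MHz; packets are placed by evaluating the continuous Gabor
  at the sample grid (no nearest-sample rounding), so sub-sample timing
  survives into the RF.
- Butterworth order 4 (receive band) and 2 (device front end), applied
  with `sosfiltfilt`.
- Trigger traces are only synthesized for lines whose beacon peak could
  possibly cross the threshold (allowing an 8-sigma noise excursion);
  this is a pure speedup with no effect on noiseless results and a
  < 1e-15-per-sample effect with noise.
- Count-based localization centers the argmax on the plateau of tied
  maximal counts before parabolic refinement; integer counts otherwise
  bias a symmetric sweep by up to one grid step.
- Trigger counts above 40 per frame are flagged and excluded from derived
  fits — at that point the spot is wide and distorted and the count stops
  being informative.
- Degenerate inputs: all-zero frames compress to all-zero images (no
  log(0)); identical on/off frames raise instead of returning an empty
  template; a flat sweep has no maximum and raises.

## Default study conditions

128-element, 0.3 mm pitch probe; 256 lines/frame; 32-element transmit
aperture focused at 4 cm; 200 µs line period; imaging-mode presets
general (10 MHz Tx, 7–13 MHz Rx), resolution (10, 8.5–14.5), penetration
(6.6, 4–9) and harmonic (5 MHz Tx, 8–12 MHz Rx, tissue echoes at 2f₀
scaled by 0.1 — band bookkeeping only, no harmonic propagation physics).
Elevational beam sigma defaults to 3 mm, which with the default gain and
threshold gives a ±8 mm trigger range.  Line ordering and period are
declared defaults, not measurements.  Where a physical constant was
needed that no configuration states (e.g. soft-tissue attenuation for
deep-insertion scenes), a standard textbook value (0.5 dB/cm/MHz) is the
default and is a free parameter of the scenario.

## Known limitations

- No diffraction-accurate fields, elastic waves, or shear conversion in
  solid layers; the aluminum scenario is a timing model only.
- No receive beamforming, TGC, or scan conversion; phased and curved
  arrays, 3-D wobbler sweeps and multi-element AE tools are out of scope.
- The PZT element's own impulse response is not modelled; the emitted
  pulse is an ideal Gabor whose cycle count stands in for ringing.
- Pattern injection assumes the element is quasi-static over a frame;
  motion between plan construction and execution lags by one frame.
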