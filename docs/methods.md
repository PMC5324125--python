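# Methods

`ephysbench` generates annotated benchmark datasets for extracellular
multi-unit electrophysiology.  Every simulated electrode trace is the sum
of three components,

    s_e(n) = x_e(n) + w_e(n) + a_e(n),

where `x` is spike activity (resolvable spikes from nearby neurons plus
background noise from more distant ones), `w` is the non-stationary slow
oscillation (< 300 Hz) and `a` is the injected artefact component.  The
sum is exact and each component is stored, so the composition is
invertible and every event in the signal is annotated.

## Virtual tissue and probes

The preparation is an axis-aligned block of tissue, either a single cube
(default 1.5 mm³ at 300,000 neurons/mm³, hippocampus-like density) or a
stack of layer slabs along z (the `hippocampus_multilayer` preset models
stratum oriens / pyramidale / radiatum as 120 / 55 / 240 µm slabs at
11,300 / 272,400 / 1,900 neurons/mm³ over a 1 × 1 mm footprint).  Unit
counts are deterministic — `round(density × sub-volume)`, half away from
zero — and positions are i.i.d. uniform inside each slab.  Cell types are
assigned by exact proportional rounding (80% pyramidal by default) so the
ratio is testable without sampling error; which units get which label is
seeded-random.  Firing rates are drawn per unit from a configurable law:
uniform bounds (0.5–12 Hz awake, 0.5–5 Hz anaesthetised), generalised
Pareto, or logistic.  Interneurons draw from the same law with location
and scale multiplied by 5.  The logistic laws of the multilayer preset use
location = the layers' characteristic rates (0.6 / 0.4 / 0.2 Hz) and
scale = 0.1 × location, truncated at 0.01 Hz; the scale is a declared
stand-in because only the central rates are published.

Probes are site-coordinate lists in µm: a 25 µm tetrahedral tetrode, a
32-site polytrode (4 shanks at 200 µm pitch, 8 staggered sites at 20 µm
vertical pitch per shank, after the Buzsaki64-style layout), a 16-site
four-tetrode array used by the awake/anaesthetised presets, or arbitrary
user coordinates.  Presets are JSON files; the probe must fit inside the
tissue volume.

## Spike component

Each unit fires as a stationary renewal process with
ISI = refractory + Exp(1/rate − refractory), refractory 2 ms.  The ISI
mean is exactly 1/rate, so realized rates are unbiased, firing is
Poisson-irregular, and the dead time is hard.  Rates for which
refractory ≥ 1/rate are rejected as configuration errors.

Extracellular waveforms come from a parametric template bank: biphasic
shapes built from a negative trough Gaussian plus a delayed rebound,
peak-normalised, pinned to zero at both ends, ≤ 3 ms.  Interneuron
templates (trough sigma 0.04–0.07 ms) are strictly narrower than
pyramidal ones (0.10–0.16 ms).  Banks can be saved/loaded as NPZ
containers so waveforms extracted from real recordings can be swapped in.

Amplitude versus distance follows a clamped point-source law,
`scale(d) = A_ref · d_ref / max(d, d_min)` with A_ref = 50 µV at
d_ref = 50 µm and d_min = 10 µm.  This is a declared, monotone contract
standing in for compartmental/line-source simulation, which is out of
scope.  Rendering is a linear superposition: spike times are quantized to
the nearest sample and each template is added at its per-channel scale
(implemented as per-template impulse trains convolved once per channel,
so rendering is exactly linear in the spike trains).

Background noise is mechanistic, not added Gaussian noise: all active
units within `background_radius` (250 µm) of any site are rendered, but
only units within the attenuation model's `noise_radius` (100 µm) are
annotated as resolvable; the superposed low-amplitude spikes of the rest
form the background.  Units beyond 250 µm contribute < 10 µV individually
and are omitted; this cutoff is the main problem-size knob and is part of
the declared model.  A white-Gaussian surrogate (`gaussian_background`)
exists for quick tests.

## Slow-oscillation component

Extraction from a recording uses a 10th-order low-pass Butterworth at
300 Hz applied forward and backward (zero phase, SOS form).  The DC gain
is 1 and a sinusoid at the cutoff leaves at exactly half its amplitude
(two passes × −3 dB).  Edges are reflect-padded by
3 × order × ceil(fs/cutoff) samples: a sharp low cutoff rings for roughly
`order` periods of the cutoff frequency, so a pad proportional to the
order alone (the conventional 3 × order) leaves visible startup
transients at this fs/cutoff ratio.

The synthetic generator produces 1/f broadband noise (spectrum flattened
below a 1 Hz knee, mimicking AC-coupled front-ends) plus a
condition-specific oscillation — theta-band (8 ± 1 Hz) for `awake`,
slow (2 ± 0.8 Hz) for `anaesthetised` — with slow amplitude drift, shared
across channels (0.8 shared / 0.2 independent mixing plus small phase
jitter), low-passed at 300 Hz and scaled to a target RMS (100 µV awake,
200 µV anaesthetised; declared defaults).  `contamination_check` reports
the sub-300 Hz band power of the mean spike waveform relative to the slow
component (both via rectangular periodograms on a shared grid); the
presets pass at a 5% threshold with orders of magnitude to spare.

## Artefact component

Three parametric classes reproduce the documented statistics of artefact
libraries extracted from real recordings:

* **Mechanical shock** — 1142 µs waveform with a silent 285 µs
  pre-threshold segment; a Gabor-style damped package whose spectral peak
  frequency is drawn uniformly in 1000–2000 Hz (the carrier is
  fixed-point-corrected so the measured FFT peak lands on the drawn
  value; with < 1 carrier cycle inside the envelope the achievable peaks
  compress to ≈ 1230 Hz at the low edge, still inside the band).
  Peak-to-peak amplitude ~ Normal(136.1064, 62.0262) µV truncated above
  10 µV, which puts the expected mean at ≈ 139.3 µV (+2.3%).
* **Mastication** — sequences of Hann-enveloped noise bursts (100 ms,
  150 µV); cycle durations ~ Normal(162.5, 20) ms, sequence duration
  ~ Normal(3.3, 0.8) s, first onset at a uniform phase of the first cycle
  so the expected burst rate equals the reciprocal mean cycle (≈ 6.15/s
  against the printed 6.17/s).  Burst onsets are annotated.
* **Grooming** — broadband large-amplitude segments with log-uniform
  duration in 0.4–28 s (log-uniform is the declared reading of a
  "heterogeneous" range) split into an ordered, possibly incomplete chain
  of up to 4 movement phases with annotated onsets.
  `draw_grooming_durations` exposes the duration law without synthesizing
  tens-of-seconds waveforms.

The number of injected events is `round(a_rate × duration)` (a_rate 10/s
awake, 1/s anaesthetised).  Onsets are drawn uniformly over the feasible
range from a seeded Mersenne Twister and rejection-sampled to be disjoint
(up to 1000 attempts per event; failures raise a scheduling error
carrying the count placed).  Injection adds the template sample-wise on
the masked channels and inserts one transition sample before and after
it, each adding half the adjacent template boundary sample (a linear
interpolant anchored at the preceding composite sample) — exactly
invertible, verified by test.  With shocks only, the awake preset covers
1.15% of samples (100 × 23 samples at 20 kHz) and the anaesthetised one
0.115%, the printed ~1% / ~0.1% contamination levels; longer artefact
classes would not reproduce those figures at the printed rates, which is
why the presets inject shocks.

Detection mirrors the library-extraction criterion: an absolute-threshold
crossing on at least `ceil(0.8 × n_channels)` distinct channels inside a
300 µs window (rounded up to samples; 6 samples at 20 kHz), with
qualifying windows closer than one window width merged.  A shock can
legitimately produce more than one detection when separate oscillation
lobes cross threshold more than 300 µs apart; recall, not one-to-one
correspondence, is the guaranteed property.

## Composition, annotations and I/O

`compose` validates shapes and sampling rates and retains the three
component traces, so `s − compose(x, w, 0)` recovers `a` exactly.
`run_scenario` derives every stage seed from one master seed via fixed
offsets (multiplicative hash mod 2³¹), making stages independently
re-runnable and full runs bit-reproducible.  Ground truth stores, per
rendered unit: position, cell type, configured rate, layer, per-channel
peak scales, spike times and a `resolvable` flag; plus every artefact
event (class, onset, duration, channels, amplitude).  Datasets export to
a directory of interleaved int16 `.dat` files at a declared gain
(0.195 µV/bit default, with overflow detection), `annotations.json` and a
`config.yaml` snapshot; `load` inverts `export` up to the ±gain/2
quantization bound.  Bare int16 recordings can be read with
`read_raw_dat` for use as slow-oscillation sources.

## Validation statistics

`bartlett_psd` splits a trace into K = floor(duration/segment) 1 s
rectangular segments, computes per-segment periodograms with the
|DFT|²/(N·fs) density convention (one-sided; `sum(P)·df` equals the
segment mean square exactly) and averages them; the per-frequency SEM is
the segment standard deviation over √K.  No taper is applied — Bartlett's
method uses rectangular segments by construction.  `smooth_local` is
locally weighted least squares with tri-cube weights and a degree-2
polynomial over a 1%-of-bins window (nearest-neighbour windows at the
edges; the weight kernel is a declared choice, the method name fixes only
"weighted" and the polynomial degree, read as 2).  `compare_psd` reports
per-band means of log10(P_b/P_a) with SEM propagated per bin in
quadrature.  Averaging K segments reduces white-noise periodogram
variance by ≈ 1/K (tested at K = 10 within a factor of two).

## Test fixtures and problem sizes

`make_planted` builds Gaussian-noise recordings with suprathreshold
biphasic pulses planted on known channel subsets and time spreads; pulse
amplitude (120 µV) and noise RMS (5 µV) give ≥ 3× margins at the 60 µV
test threshold so detector tests are not flaky.  Fixtures are seeded and
bit-reproducible and make no claim to biological realism — passing tests
demonstrate the generator's declared contracts, not fidelity to any real
recording.

Default problem sizes: 10 s at 20 kHz, 16 channels, 450,000 placed units
of which ~6,000 are rendered and ~650 resolvable in the awake preset
(≈ 4 s per run).  The suite's end-to-end checks reuse one awake render;
statistics use 100 mastication sequences, 1000 shock templates and 1000
grooming draws, matching the sizes at which the class statistics are
specified.

## Known limitations

No bursting units, electrode drift, phase-amplitude coupling or
within-session state transitions; no compartmental waveforms (the
point-source law is a declared simplification); artefact injection in the
presets is limited to the shock class; int16 export clips rather than
rescales (by design, with an error); the spectral-peak distribution of
shocks does not reach the bottom of the 1000–2000 Hz band.
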