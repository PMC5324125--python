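"""Non-stationary slow-oscillation component w(n).

The slow component (< 300 Hz) of an extracellular recording arises from
synaptic currents.  It can either be extracted from a supplied multichannel
recording with a zero-phase (forward-backward) 10th-order low-pass
Butterworth filter, or synthesized: pink broadband noise with a low-
frequency knee plus a condition-specific oscillation (theta-band for the
awake preset, a 1-4 Hz slow oscillation for the anaesthetised one),
correlated across channels through a shared source.

``contamination_check`` quantifies how much spectral power the mean spike
waveform leaks into the slow band relative to the slow component itself,
so a user can verify the two components are spectrally separable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .spikes import RenderedSignal, SpikeTemplate, round_half_away


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification (zero-phase by default)."""

    order: int = 10
    cutoff: float = 300.0  # Hz
    zero_phase: bool = True

    def __post_init__(self):
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")

    def sos(self, fs: float) -> np.ndarray:
        if self.cutoff >= fs / 2:
            raise ValidationError("cutoff must be below the Nyquist frequency")
        return sps.butter(self.order, self.cutoff, btype="low", fs=fs, output="sos")


@dataclass
class SlowOscillation:
    """Per-channel slow-oscillation traces in uV."""

    traces: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    source: str  # "extracted" | "synthetic"

    def __post_init__(self):
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]


def _filt(spec: FilterSpec, fs: float, x: np.ndarray) -> np.ndarray:
    sos = spec.sos(fs)
    # reflect-pad by 3 x order x (fs / cutoff) samples: the ringing of a
    # sharp low cutoff lasts ~order periods of the cutoff frequency, so a
    # pad proportional to the order alone leaves startup transients
    padlen = min(int(3 * spec.order * np.ceil(fs / spec.cutoff)), x.shape[-1] - 1)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=padlen)
    return sps.sosfilt(sos, x, axis=-1)


def extract_slow(recording: RenderedSignal, spec: FilterSpec = FilterSpec()) -> SlowOscillation:
    """Zero-phase low-pass filter each channel of ``recording``.

    Forward-backward application doubles the attenuation: a sinusoid at the
    cutoff comes out at exactly half its input amplitude, and DC passes
    with unit gain and no phase shift.
    """
    fs = recording.sampling_rate
    if spec.cutoff >= fs / 2:
        raise ValidationError("cutoff must be below the Nyquist frequency")
    return SlowOscillation(_filt(spec, fs, recording.traces), fs, source="extracted")


_CONDITIONS = {
    # oscillation centre (Hz), half-jitter (Hz), default broadband RMS (uV)
    "awake": dict(f_osc=8.0, f_jitter=1.0, rms=100.0),
    "anaesthetised": dict(f_osc=2.0, f_jitter=0.8, rms=200.0),
}


def _pink(n: int, fs: float, rng: np.random.Generator, knee: float = 1.0) -> np.ndarray:
    """Unit-RMS pink noise with spectrum flattened below ``knee`` Hz
    (mimicking the AC coupling of real acquisition front-ends)."""
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(f, knee))
    amp[0] = 0.0
    phase = rng.uniform(0.0, 2.0 * np.pi, len(f))
    spec = amp * np.exp(1j * phase)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def synth_slow(
    condition: str,
    channels: int,
    fs: float,
    duration: float,
    seed: int = 0,
    rms: float | None = None,
    filter_spec: FilterSpec = FilterSpec(),
) -> SlowOscillation:
    """Synthesize a condition-specific slow oscillation.

    The trace is 1/f broadband noise plus a narrowband oscillation
    (theta for ``awake``, slow 1-4 Hz for ``anaesthetised``) with slow
    amplitude drift, shared across channels with per-channel jitter, then
    low-passed at the filter cutoff and scaled to the target RMS.
    """
    if duration <= 0:
        raise ValidationError("duration must be positive")
    if condition not in _CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}")
    cfg = _CONDITIONS[condition]
    target_rms = cfg["rms"] if rms is None else float(rms)
    n = round_half_away(duration * fs)
    if target_rms == 0.0:
        return SlowOscillation(np.zeros((channels, n)), fs, source="synthetic")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs

    f0 = cfg["f_osc"] + rng.uniform(-cfg["f_jitter"], cfg["f_jitter"])
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    drift = 1.0 + 0.3 * np.sin(2.0 * np.pi * 0.2 * t + rng.uniform(0.0, 2.0 * np.pi))
    shared_bb = _pink(n, fs, rng)
    osc = np.sqrt(2.0) * drift * np.sin(2.0 * np.pi * f0 * t + phase0)

    traces = np.empty((channels, n))
    for c in range(channels):
        own = _pink(n, fs, rng)
        bb = 0.8 * shared_bb + 0.2 * own
        ph_jit = rng.uniform(-0.1, 0.1)
        osc_c = np.sqrt(2.0) * drift * np.sin(2.0 * np.pi * f0 * t + phase0 + ph_jit)
        traces[c] = 0.6 * bb + osc_c
    traces = _filt(filter_spec, fs, traces)
    traces *= target_rms / traces.std(axis=1, keepdims=True)
    return SlowOscillation(traces, fs, source="synthetic")


def band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Integrated periodogram power of ``x`` in [lo, hi] Hz."""
    f, p = sps.periodogram(x, fs, window="boxcar", detrend=False)
    mask = (f >= lo) & (f <= hi)
    df = f[1] - f[0]
    return float(p[mask].sum() * df)


def contamination_check(
    mean_spike: SpikeTemplate | np.ndarray,
    slow: SlowOscillation,
    cutoff: float = 300.0,
) -> float:
    """Ratio of sub-cutoff band power of the mean spike waveform to that of
    the slow component (averaged over channels).

    The spike waveform is zero-padded to the slow-trace length so both
    periodograms share a frequency grid.  A small ratio (the presets use a
    5% threshold) means spike energy leaking below the cutoff is negligible
    relative to the slow oscillation itself.
    """
    fs = slow.sampling_rate
    if isinstance(mean_spike, SpikeTemplate):
        w = mean_spike.resampled(fs).waveform
    else:
        w = np.asarray(mean_spike, dtype=float)
    n = slow.n_samples
    if len(w) > n:
        raise ValidationError("mean spike waveform longer than the slow trace")
    padded = np.zeros(n)
    padded[: len(w)] = w
    num = band_power(padded, fs, 0.0, cutoff)
    den = float(np.mean([band_power(tr, fs, 0.0, cutoff) for tr in slow.traces]))
    if den == 0.0:
        raise ValidationError("slow component has zero power below the cutoff")
    return num / den
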