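"""Artefact synthesis, scheduling, injection and coincidence detection.

Real extracellular recordings are contaminated by three well-characterised
artefact classes:

* mechanical shocks — spike-like sharp transients, 1142 us long with a
  285 us pre-threshold segment, peak-to-peak amplitude ~ N(136.1064,
  62.0262) uV and spectral peak in the 1000-2000 Hz band;
* mastication — rhythmic noisy bursts at a mean rate of 6.17 bursts/s,
  mean cycle 162.5 ms, in sequences of ~3.3 s;
* grooming — large broadband segments lasting anywhere from 0.4 to 28 s,
  built from up to four ordered movement phases.

The number of injected events over a recording is ``round(a_rate x
duration)``.  Injection adds the template sample-wise and inserts one
linear-interpolation transition sample before and after the waveform so it
blends smoothly into the composite signal.  Detection mirrors the library
extraction criterion: a threshold crossing on at least 80% of channels
within a 300 us window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import SchedulingError, ValidationError
from .spikes import RenderedSignal, round_half_away

MECHANICAL_SHOCK = "mechanical_shock"
MASTICATION = "mastication"
GROOMING = "grooming"


# --------------------------------------------------------------------------
# Class parameters (printed library statistics as defaults)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ShockParams:
    p2p_mean: float = 136.1064  # uV
    p2p_sd: float = 62.0262  # uV
    peak_band: tuple[float, float] = (1000.0, 2000.0)  # Hz
    duration: float = 1142e-6  # s
    pre_threshold: float = 285e-6  # s
    min_p2p: float = 10.0  # uV, truncation of the amplitude law

    def __post_init__(self):
        if min(self.p2p_mean, self.duration, self.pre_threshold) <= 0 or self.p2p_sd < 0:
            raise ValidationError("shock parameters must be positive")
        if not 0 < self.peak_band[0] < self.peak_band[1]:
            raise ValidationError("peak band must be an increasing positive pair")


@dataclass(frozen=True)
class MasticationParams:
    burst_rate_mean: float = 6.17  # bursts/s
    sequence_duration_mean: float = 3.3  # s
    sequence_duration_sd: float = 0.8  # s
    cycle_mean: float = 0.1625  # s
    cycle_sd: float = 0.020  # s
    burst_duration: float = 0.100  # s
    amplitude: float = 150.0  # uV RMS inside a burst

    def __post_init__(self):
        if min(self.burst_rate_mean, self.sequence_duration_mean, self.cycle_mean,
               self.burst_duration, self.amplitude) <= 0:
            raise ValidationError("mastication parameters must be positive")
        if abs(self.cycle_mean * self.burst_rate_mean - 1.0) > 0.1:
            raise ValidationError("cycle_mean must be consistent with 1/burst_rate_mean")


@dataclass(frozen=True)
class GroomingParams:
    duration_range: tuple[float, float] = (0.4, 28.0)  # s
    amplitude: float = 250.0  # uV RMS
    n_phases: int = 4

    def __post_init__(self):
        lo, hi = self.duration_range
        if not 0 < lo <= hi:
            raise ValidationError("grooming duration range must be positive and ordered")
        if self.amplitude <= 0 or self.n_phases < 1:
            raise ValidationError("grooming parameters must be positive")


@dataclass(frozen=True)
class ArtefactClassParams:
    """Bundle of the per-class parameter sets."""

    shock: ShockParams = field(default_factory=ShockParams)
    mastication: MasticationParams = field(default_factory=MasticationParams)
    grooming: GroomingParams = field(default_factory=GroomingParams)


# --------------------------------------------------------------------------
# Templates and events
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ArtefactTemplate:
    """Single-channel artefact waveform with class tag and annotations.

    ``annotations`` holds burst onsets (mastication, s from template start)
    or phase labels/onsets (grooming) and class-specific metadata.
    """

    waveform: np.ndarray  # uV
    cls: str
    sampling_rate: float
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "waveform", np.asarray(self.waveform, dtype=float))
        if len(self.waveform) == 0:
            raise ValidationError("artefact template must be non-empty")

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.sampling_rate

    @property
    def p2p(self) -> float:
        return float(self.waveform.max() - self.waveform.min())


@dataclass(frozen=True)
class ArtefactEvent:
    """A scheduled injection: template start time and affected channels."""

    onset: float  # s, time of the first template sample
    template: ArtefactTemplate | None
    channel_mask: np.ndarray  # bool per channel, or channel indices
    a_rate: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "channel_mask", np.asarray(self.channel_mask))


@dataclass(frozen=True)
class DetectionRule:
    """Cross-channel coincidence rule used for artefact detection."""

    thresholds: np.ndarray | float  # uV per channel (scalar broadcasts)
    coincidence_fraction: float = 0.8
    window: float = 300e-6  # s

    def __post_init__(self):
        if not 0.0 < self.coincidence_fraction <= 1.0:
            raise ValidationError("coincidence_fraction must lie in (0, 1]")
        if self.window <= 0:
            raise ValidationError("window must be positive")


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def save_library(path: str, templates: Sequence[ArtefactTemplate]) -> None:
    """Write an artefact library to an NPZ container: per-set waveform
    arrays with class tags and JSON-encoded annotations, mirroring the
    drop-in layout of libraries extracted from real recordings."""
    import json as _json

    arrays = {f"waveform_{i}": t.waveform for i, t in enumerate(templates)}
    arrays["cls"] = np.asarray([t.cls for t in templates])
    arrays["sampling_rate"] = np.asarray([t.sampling_rate for t in templates])
    arrays["annotations"] = np.asarray(
        [
            _json.dumps(
                {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in t.annotations.items()}
            )
            for t in templates
        ]
    )
    np.savez(path, **arrays)


def load_library(path: str) -> list[ArtefactTemplate]:
    """Read an artefact library written by :func:`save_library`."""
    import json as _json

    with np.load(path, allow_pickle=False) as d:
        out = []
        for i in range(len(d["cls"])):
            ann = {
                k: (np.asarray(v) if isinstance(v, list) else v)
                for k, v in _json.loads(str(d["annotations"][i])).items()
            }
            out.append(
                ArtefactTemplate(
                    d[f"waveform_{i}"], str(d["cls"][i]),
                    float(d["sampling_rate"][i]), ann,
                )
            )
        return out


def count_artefacts(a_rate: float, duration: float) -> int:
    """Number of injected events: round(a_rate x duration)."""
    if a_rate < 0:
        raise ValidationError("artefact rate must be non-negative")
    if duration <= 0:
        raise ValidationError("duration must be positive")
    return round_half_away(a_rate * duration)


def gen_shock(params: ShockParams = ShockParams(), fs: float = 20000.0, seed: int = 0) -> ArtefactTemplate:
    """Synthesize one mechanical-shock template.

    A damped oscillation whose carrier frequency is drawn uniformly from
    the peak band and whose peak-to-peak amplitude follows the truncated
    normal amplitude law.  The waveform is silent over the pre-threshold
    segment and decays back towards zero by its end.
    """
    if fs <= 2.0 * params.peak_band[1]:
        raise ValidationError(
            f"fs = {fs} Hz cannot represent the {params.peak_band[1]} Hz band edge"
        )
    rng = np.random.default_rng(seed)
    n = round_half_away(params.duration * fs)
    pre = round_half_away(params.pre_threshold * fs)
    m = n - pre
    if m < 4:
        raise ValidationError("fs too low for the shock duration")
    f0 = rng.uniform(*params.peak_band)
    t = np.arange(m) / fs
    # Gabor-style damped package centred in the post-threshold segment
    t_c, sigma_t = 0.45e-3, 0.14e-3
    env = np.exp(-0.5 * ((t - t_c) / sigma_t) ** 2)

    def _build(fc: float) -> np.ndarray:
        w = np.zeros(n)
        w[pre:] = env * np.sin(2.0 * np.pi * fc * (t - t_c))
        w[pre] = w[-1] = 0.0
        return w

    def _peak_hz(w: np.ndarray) -> float:
        nfft = 1 << 14
        spec = np.abs(np.fft.rfft(w, nfft))
        return float(np.argmax(spec) * fs / nfft)

    # the short envelope biases the spectral peak above the carrier, so the
    # carrier is corrected (two fixed-point steps) until the peak sits at
    # the frequency drawn from the configured band
    fc = f0
    for _ in range(2):
        fc = max(fc - (_peak_hz(_build(fc)) - f0), 100.0)
    w = _build(fc)
    f0 = fc
    if params.p2p_sd == 0.0:
        p2p = params.p2p_mean
    else:
        p2p = rng.normal(params.p2p_mean, params.p2p_sd)
        while p2p <= params.min_p2p:
            p2p = rng.normal(params.p2p_mean, params.p2p_sd)
    w *= p2p / (w.max() - w.min())
    return ArtefactTemplate(
        w,
        MECHANICAL_SHOCK,
        fs,
        annotations={"carrier_hz": f0, "pre_threshold_samples": pre},
    )


def gen_mastication(
    params: MasticationParams = MasticationParams(), fs: float = 20000.0, seed: int = 0
) -> ArtefactTemplate:
    """Synthesize one chewing sequence of enveloped noise bursts.

    Burst onsets follow a renewal process with normally distributed cycle
    durations; the first onset is placed at a uniform phase of the first
    cycle so the expected burst rate equals the reciprocal mean cycle.
    """
    if fs <= 2000.0:
        raise ValidationError("fs must exceed 2 kHz for mastication synthesis")
    rng = np.random.default_rng(seed)
    if params.sequence_duration_sd == 0.0:
        dur = params.sequence_duration_mean
    else:
        dur = rng.normal(params.sequence_duration_mean, params.sequence_duration_sd)
        while dur < 0.5:
            dur = rng.normal(params.sequence_duration_mean, params.sequence_duration_sd)

    def draw_cycle() -> float:
        if params.cycle_sd == 0.0:
            return params.cycle_mean
        c = rng.normal(params.cycle_mean, params.cycle_sd)
        while c < 0.05:
            c = rng.normal(params.cycle_mean, params.cycle_sd)
        return c

    onsets = [rng.uniform(0.0, draw_cycle())]
    while True:
        nxt = onsets[-1] + draw_cycle()
        if nxt >= dur:
            break
        onsets.append(nxt)
    onsets_arr = np.asarray(onsets)

    n = round_half_away(dur * fs)
    w = np.zeros(n)
    bn = round_half_away(params.burst_duration * fs)
    envelope = np.hanning(bn)
    for o in onsets_arr:
        s = round_half_away(o * fs)
        seg = min(bn, n - s)
        if seg > 0:
            w[s : s + seg] += params.amplitude * envelope[:seg] * rng.normal(size=seg)
    return ArtefactTemplate(
        w, MASTICATION, fs, annotations={"burst_onsets": onsets_arr, "sequence_duration": dur}
    )


def draw_grooming_durations(
    params: GroomingParams, n: int, seed: int = 0
) -> np.ndarray:
    """Log-uniform grooming durations inside the configured range.

    Exposed separately so duration statistics can be studied without
    synthesizing the (potentially tens of seconds long) waveforms.
    """
    rng = np.random.default_rng(seed)
    lo, hi = params.duration_range
    if lo == hi:
        return np.full(n, lo)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), n))


def gen_grooming(
    params: GroomingParams = GroomingParams(), fs: float = 20000.0, seed: int = 0
) -> ArtefactTemplate:
    """Synthesize one grooming artefact: a large broadband segment whose
    duration is drawn log-uniformly in the configured range, split into an
    ordered (possibly incomplete) chain of movement phases."""
    if fs <= 2000.0:
        raise ValidationError("fs must exceed 2 kHz for grooming synthesis")
    rng = np.random.default_rng(seed)
    dur = float(draw_grooming_durations(params, 1, seed=rng.integers(2**31))[0])
    n = round_half_away(dur * fs)

    n_present = int(rng.integers(1, params.n_phases + 1))
    labels = np.sort(rng.choice(np.arange(1, params.n_phases + 1), n_present, replace=False))
    cuts = np.sort(rng.uniform(0.0, dur, n_present - 1)) if n_present > 1 else np.empty(0)
    phase_onsets = np.concatenate([[0.0], cuts])

    w = rng.normal(0.0, params.amplitude, n)
    bounds = np.concatenate([phase_onsets, [dur]])
    for i in range(n_present):
        s0 = round_half_away(bounds[i] * fs)
        s1 = round_half_away(bounds[i + 1] * fs)
        w[s0:s1] *= rng.uniform(0.7, 1.3)
    ramp = min(round_half_away(0.010 * fs), n // 2)
    if ramp > 0:
        edge = np.hanning(2 * ramp)
        w[:ramp] *= edge[:ramp]
        w[-ramp:] *= edge[ramp:]
    return ArtefactTemplate(
        w,
        GROOMING,
        fs,
        annotations={"phase_labels": labels, "phase_onsets": phase_onsets, "duration": dur},
    )


def schedule(
    n: int,
    duration: float,
    artefact_durations: Sequence[float] | float,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` non-overlapping onsets uniformly over the feasible range.

    Events are placed one at a time by rejection sampling (up to 1000
    attempts each) against the already-placed events; the uniform draws
    come from a seeded Mersenne Twister.  On infeasible packing a
    ``SchedulingError`` reports how many events were placed.
    """
    durs = np.broadcast_to(np.asarray(artefact_durations, dtype=float), (n,))
    if np.any(durs <= 0):
        raise ValidationError("artefact durations must be positive")
    if durs.sum() > duration + 1e-12:
        raise SchedulingError(
            f"total artefact time {durs.sum():.3f} s exceeds the recording", placed=0
        )
    rng = np.random.Generator(np.random.MT19937(seed))
    placed: list[tuple[float, float]] = []
    onsets = np.empty(n)
    for i, d in enumerate(durs):
        hi = duration - d
        ok = False
        for _ in range(1000):
            o = rng.uniform(0.0, hi) if hi > 0 else 0.0
            if all(o + d <= s or o >= s + sd for s, sd in placed):
                ok = True
                break
        if not ok:
            raise SchedulingError(
                f"could not place event {i} without overlap", placed=i
            )
        placed.append((o, d))
        onsets[i] = o
    return onsets


def inject(signal: RenderedSignal, event: ArtefactEvent) -> RenderedSignal:
    """Add an artefact template into a signal with boundary smoothing.

    The template is added sample-wise on the masked channels.  One
    transition sample is inserted immediately before the template and one
    immediately after it; each adds the linear interpolant between the
    (zero) baseline contribution and the template's first (resp. last)
    sample, anchored at the preceding composite sample — i.e. half the
    boundary sample value.  The operation is exactly invertible.
    """
    fs = signal.sampling_rate
    tmpl = event.template
    if tmpl is None:
        raise ValidationError("event carries no template to inject")
    if tmpl.sampling_rate != fs:
        raise ValidationError("template and signal sampling rates differ")
    w = tmpl.waveform
    start = round_half_away(event.onset * fs)
    n = signal.n_samples
    if start < 1 or start + len(w) + 1 > n:
        raise ValidationError("artefact event (with transition samples) exceeds signal bounds")
    mask = event.channel_mask
    if mask.dtype == bool:
        channels = np.flatnonzero(mask)
    else:
        channels = mask.astype(int)
    if len(channels) and channels.max() >= signal.n_channels:
        raise ValidationError("channel mask refers to a channel outside the signal")
    out = signal.traces.copy()
    for c in channels:
        out[c, start - 1] += w[0] / 2.0
        out[c, start : start + len(w)] += w
        out[c, start + len(w)] += w[-1] / 2.0
    return RenderedSignal(out, fs, signal.duration)


def detect(signal: RenderedSignal, rule: DetectionRule) -> list[ArtefactEvent]:
    """Detect artefacts by cross-channel threshold-crossing coincidence.

    An event is reported when at least ``ceil(fraction x n_channels)``
    distinct channels have a crossing of their absolute threshold within
    any window of the configured width (converted to samples by rounding
    up).  Qualifying windows closer than one window width are merged into
    one event.
    """
    n_ch = signal.n_channels
    thr = np.broadcast_to(np.asarray(rule.thresholds, dtype=float), (n_ch,))
    if signal.n_samples == 0:
        return []
    fs = signal.sampling_rate
    win = int(np.ceil(rule.window * fs))
    need = int(np.ceil(rule.coincidence_fraction * n_ch))

    x = np.abs(signal.traces)
    above = x >= thr[:, None]
    rising = above.copy()
    rising[:, 1:] &= ~above[:, :-1]
    ch_idx, samp_idx = np.nonzero(rising)
    if len(samp_idx) == 0:
        return []
    order = np.argsort(samp_idx, kind="stable")
    samp_idx, ch_idx = samp_idx[order], ch_idx[order]

    events: list[ArtefactEvent] = []
    i, m = 0, len(samp_idx)
    last_end = -win - 1
    while i < m:
        j = i
        seen = set()
        while j < m and samp_idx[j] - samp_idx[i] <= win:
            seen.add(int(ch_idx[j]))
            j += 1
        if len(seen) >= need and samp_idx[i] > last_end + win:
            mask = np.zeros(n_ch, dtype=bool)
            mask[list(seen)] = True
            events.append(ArtefactEvent(onset=samp_idx[i] / fs, template=None, channel_mask=mask))
            last_end = int(samp_idx[j - 1])
            i = j
        else:
            i += 1
    return events
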