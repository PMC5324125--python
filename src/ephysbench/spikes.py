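"""Spike trains, template banks and rendering of the spike component x(n).

Each unit fires as a stationary renewal process: inter-spike intervals are
``refractory + Exponential(1/rate - refractory)``, i.e. Poisson-like
irregular firing with a hard dead time.  Extracellular waveforms come from
a parametric template bank (peak-normalised biphasic shapes, interneurons
narrower than pyramidal cells) scaled by a point-source 1/d attenuation
law.  Units close to a site produce resolvable spikes; the superposition of
the many low-amplitude units farther away forms the physiological
background noise, so no Gaussian noise needs to be added (a Gaussian
surrogate is available for quick tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, ValidationError
from .tissue import INTERNEURON, PYRAMIDAL, NeuronPopulation, ProbeGeometry, round_half_away


@dataclass(frozen=True)
class SpikeTemplate:
    """Peak-normalised extracellular spike waveform.

    The waveform starts and ends at exactly zero, lasts at most 3 ms and
    has unit peak magnitude before any distance scaling is applied.
    """

    waveform: np.ndarray  # amplitude (dimensionless, |peak| = 1)
    sampling_rate: float  # Hz
    cell_type: str
    width: float  # trough FWHM, ms
    polarity: int = -1

    def __post_init__(self):
        w = np.asarray(self.waveform, dtype=float)
        object.__setattr__(self, "waveform", w)
        if len(w) / self.sampling_rate > 3.001e-3:
            raise ValidationError("spike template longer than 3 ms")
        if abs(w[0]) > 1e-12 or abs(w[-1]) > 1e-12:
            raise ValidationError("spike template must start and end at zero")

    def resampled(self, fs: float) -> "SpikeTemplate":
        if fs == self.sampling_rate:
            return self
        frac = Fraction(fs / self.sampling_rate).limit_denominator(1000)
        w = sps.resample_poly(self.waveform, frac.numerator, frac.denominator)
        w[0] = w[-1] = 0.0
        peak = np.abs(w).max()
        return SpikeTemplate(w / peak, fs, self.cell_type, self.width, self.polarity)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) of one unit."""

    unit_id: int
    times: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))


@dataclass(frozen=True)
class AttenuationModel:
    """Point-source amplitude attenuation with distance.

    The peak amplitude seen at distance d (um) is
    ``reference_amplitude * reference_distance / max(d, minimum_distance)``
    in uV per unit of normalised template peak.  Units beyond
    ``noise_radius`` are not annotated as resolvable; collectively their
    small superposed spikes form the background noise.
    """

    kind: str = "point_source"
    reference_distance: float = 50.0  # um
    reference_amplitude: float = 50.0  # uV
    minimum_distance: float = 10.0  # um
    noise_radius: float = 100.0  # um

    def __post_init__(self):
        if self.kind != "point_source":
            raise ConfigurationError(f"unknown attenuation kind {self.kind!r}")
        if min(self.reference_distance, self.reference_amplitude, self.minimum_distance) <= 0:
            raise ValidationError("attenuation parameters must be positive")

    def scale(self, distance) -> np.ndarray | float:
        d = np.maximum(np.asarray(distance, dtype=float), self.minimum_distance)
        return self.reference_amplitude * self.reference_distance / d


def attenuate(model: AttenuationModel, distance) -> np.ndarray | float:
    """Scale factor (uV per unit template peak) at ``distance`` um."""
    if np.any(np.asarray(distance) < 0):
        raise ValidationError("distance must be non-negative")
    return model.scale(distance)


@dataclass
class RenderedSignal:
    """Multichannel trace in uV."""

    traces: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    duration: float

    def __post_init__(self):
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        n_expected = round_half_away(self.duration * self.sampling_rate)
        if self.traces.shape[1] != n_expected:
            raise ValidationError(
                f"trace length {self.traces.shape[1]} != round(duration x fs) = {n_expected}"
            )

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @classmethod
    def zeros(cls, n_channels: int, fs: float, duration: float) -> "RenderedSignal":
        n = round_half_away(duration * fs)
        return cls(np.zeros((n_channels, n)), fs, duration)


# --------------------------------------------------------------------------
# Template bank
# --------------------------------------------------------------------------

# shape parameter ranges (ms); interneuron spikes are narrower throughout
_SHAPES = {
    PYRAMIDAL: dict(dur=2.4, trough=0.45, sigma1=(0.10, 0.16), rebound=(0.25, 0.45), s2_mult=2.0),
    INTERNEURON: dict(dur=1.2, trough=0.25, sigma1=(0.04, 0.07), rebound=(0.15, 0.30), s2_mult=1.5),
}


def _make_waveform(fs: float, cell_type: str, rng: np.random.Generator) -> SpikeTemplate:
    p = _SHAPES[cell_type]
    n = round_half_away(p["dur"] * 1e-3 * fs)
    t = np.arange(n) / fs * 1e3  # ms
    s1 = rng.uniform(*p["sigma1"])
    reb = rng.uniform(*p["rebound"])
    s2 = p["s2_mult"] * s1
    w = -np.exp(-0.5 * ((t - p["trough"]) / s1) ** 2)
    w += reb * np.exp(-0.5 * ((t - (p["trough"] + 3.0 * s1)) / s2) ** 2)
    w -= np.linspace(w[0], w[-1], n)  # pin both endpoints to exactly zero
    w /= np.abs(w).max()
    return SpikeTemplate(w, fs, cell_type, width=2.355 * s1, polarity=-1)


def synth_template_bank(
    n_templates: int,
    cell_type_mix: float = 0.8,
    seed: int = 0,
    fs: float = 20000.0,
) -> list[SpikeTemplate]:
    """Synthesize ``n_templates`` peak-normalised templates, a fraction
    ``cell_type_mix`` of them pyramidal (exact proportional rounding)."""
    if n_templates < 1:
        raise ValidationError("need at least one template")
    if not 0.0 <= cell_type_mix <= 1.0:
        raise ValidationError("cell_type_mix must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pyr = round_half_away(cell_type_mix * n_templates)
    bank = [_make_waveform(fs, PYRAMIDAL, rng) for _ in range(n_pyr)]
    bank += [_make_waveform(fs, INTERNEURON, rng) for _ in range(n_templates - n_pyr)]
    return bank


# --------------------------------------------------------------------------
# Spike trains
# --------------------------------------------------------------------------


def gen_spike_train(
    rate: float,
    duration: float,
    refractory: float = 0.002,
    seed: int = 0,
    unit_id: int = 0,
) -> SpikeTrain:
    """Renewal spike train: ISI = refractory + Exp(1/rate - refractory).

    The ISI mean is exactly 1/rate, so the realized rate matches the target
    up to sampling error while every interval respects the dead time.
    """
    if rate <= 0:
        raise ValidationError("rate must be positive")
    if refractory < 0:
        raise ValidationError("refractory must be non-negative")
    if refractory >= 1.0 / rate:
        raise ConfigurationError(
            f"rate {rate} Hz unattainable with refractory {refractory * 1e3:.1f} ms"
        )
    if duration <= 0:
        return SpikeTrain(unit_id, np.empty(0))
    rng = np.random.default_rng(seed)
    mean_exp = 1.0 / rate - refractory
    times: list[np.ndarray] = []
    t_last = 0.0
    while t_last < duration:
        k = max(int((duration - t_last) * rate * 1.5) + 16, 16)
        isi = refractory + rng.exponential(mean_exp, k)
        chunk = t_last + np.cumsum(isi)
        times.append(chunk)
        t_last = chunk[-1]
    all_times = np.concatenate(times)
    return SpikeTrain(unit_id, all_times[all_times < duration])


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def render(
    pop: NeuronPopulation,
    trains: Sequence[SpikeTrain],
    templates: Sequence[SpikeTemplate],
    probe: ProbeGeometry,
    atten: AttenuationModel,
    fs: float,
    duration: float,
) -> RenderedSignal:
    """Linear superposition of distance-scaled templates at spike times.

    Each unit uses one template of its cell type (deterministically, unit
    index modulo the per-type bank size); spike times are quantized to the
    nearest sample.  Rendering is linear in the trains, so disjoint unions
    of trains add sample-wise.
    """
    if fs <= 0:
        raise ValidationError("sampling rate must be positive")
    if len(trains) != pop.n:
        raise ValidationError("need exactly one spike train per unit")
    n = round_half_away(duration * fs)
    out = np.zeros((probe.n_sites, n))
    if pop.n == 0 or n == 0:
        return RenderedSignal(out, fs, duration)
    for tr in trains:
        if len(tr.times) and (tr.times.min() < 0 or tr.times.max() >= duration):
            raise ValidationError("spike train extends beyond the rendered duration")

    bank = [t.resampled(fs) for t in templates]
    by_type = {
        ct: [i for i, t in enumerate(bank) if t.cell_type == ct]
        for ct in (PYRAMIDAL, INTERNEURON)
    }
    # deterministic unit -> template mapping
    tmpl_of_unit = np.zeros(pop.n, dtype=int)
    for ct, idxs in by_type.items():
        units = np.flatnonzero(pop.cell_type == ct)
        if len(units) and not idxs:
            raise ConfigurationError(f"template bank has no {ct} templates")
        for j, u in enumerate(units):
            tmpl_of_unit[u] = idxs[j % len(idxs)]

    dist = np.linalg.norm(
        pop.positions[:, None, :] - probe.sites[None, :, :], axis=2
    )  # (units, channels)
    scales = atten.scale(dist)

    for g in np.unique(tmpl_of_unit):
        units = np.flatnonzero(tmpl_of_unit == g)
        units = units[[len(trains[u].times) > 0 for u in units]]
        if not len(units):
            continue
        samp = np.concatenate(
            [np.minimum(np.rint(trains[u].times * fs).astype(int), n - 1) for u in units]
        )
        uidx = np.concatenate(
            [np.full(len(trains[u].times), u, dtype=int) for u in units]
        )
        w = bank[g].waveform
        imp = np.empty((probe.n_sites, n))
        for c in range(probe.n_sites):
            imp[c] = np.bincount(samp, weights=scales[uidx, c], minlength=n)
        out += sps.oaconvolve(imp, w[None, :], mode="full", axes=1)[:, :n]
    return RenderedSignal(out, fs, duration)


def save_template_bank(path: str, bank: Sequence[SpikeTemplate]) -> None:
    """Write a template bank to an NPZ container (one waveform array per
    template plus metadata), so user-supplied banks extracted from real
    recordings can be swapped in."""
    arrays = {f"waveform_{i}": t.waveform for i, t in enumerate(bank)}
    arrays["cell_type"] = np.asarray([t.cell_type for t in bank])
    arrays["sampling_rate"] = np.asarray([t.sampling_rate for t in bank])
    arrays["width"] = np.asarray([t.width for t in bank])
    arrays["polarity"] = np.asarray([t.polarity for t in bank])
    np.savez(path, **arrays)


def load_template_bank(path: str) -> list[SpikeTemplate]:
    """Read a template bank written by :func:`save_template_bank`."""
    with np.load(path, allow_pickle=False) as d:
        n = len(d["cell_type"])
        return [
            SpikeTemplate(
                d[f"waveform_{i}"],
                float(d["sampling_rate"][i]),
                str(d["cell_type"][i]),
                float(d["width"][i]),
                int(d["polarity"][i]),
            )
            for i in range(n)
        ]


def gaussian_background(
    n_channels: int, fs: float, duration: float, rms: float, seed: int = 0
) -> RenderedSignal:
    """White Gaussian surrogate for the mechanistic background noise."""
    rng = np.random.default_rng(seed)
    n = round_half_away(duration * fs)
    return RenderedSignal(rng.normal(0.0, rms, (n_channels, n)), fs, duration)
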