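"""Synthetic planted recordings for exercising the artefact detector.

These fixtures make no attempt at biological realism: they are Gaussian
background noise with suprathreshold pulses planted on known channels at
known times, so detector behaviour (coincidence fraction, window width,
merging) can be verified against an exact truth list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .spikes import RenderedSignal, round_half_away


@dataclass(frozen=True)
class PlantSpec:
    """One planted event: a pulse on ``channels`` starting at ``onset`` s,
    with per-channel onsets spread uniformly over ``spread`` s."""

    onset: float
    channels: tuple[int, ...]
    amplitude: float = 120.0  # uV
    spread: float = 0.0  # s
    kind: str = "pulse"


@dataclass
class PlantedRecording:
    signal: RenderedSignal
    truth: list[dict]


_PULSE_MS = 0.5


def _pulse(fs: float, amplitude: float) -> np.ndarray:
    n = max(round_half_away(_PULSE_MS * 1e-3 * fs), 3)
    t = np.arange(n) / n
    return amplitude * np.sin(np.pi * t) * np.sin(2.0 * np.pi * t)


def make_planted(
    n_channels: int,
    fs: float,
    duration: float,
    events: Sequence[PlantSpec],
    seed: int = 0,
    noise_rms: float = 5.0,
) -> PlantedRecording:
    """Gaussian-noise recording with planted threshold-crossing pulses.

    Each event places a biphasic pulse of the stated peak amplitude on its
    channel subset; per-channel start times are jittered uniformly inside
    ``[onset, onset + spread]``.  The returned truth list is complete.
    """
    rng = np.random.default_rng(seed)
    n = round_half_away(duration * fs)
    traces = rng.normal(0.0, noise_rms, (n_channels, n)) if noise_rms > 0 else np.zeros((n_channels, n))
    truth = []
    for ev in events:
        if not ev.channels:
            raise ValidationError("planted event needs at least one channel")
        if min(ev.channels) < 0 or max(ev.channels) >= n_channels:
            raise ValidationError("planted event channel outside the probe")
        pulse = _pulse(fs, ev.amplitude)
        per_channel = {}
        for c in ev.channels:
            t_c = ev.onset + (rng.uniform(0.0, ev.spread) if ev.spread > 0 else 0.0)
            s = round_half_away(t_c * fs)
            if s < 0 or s + len(pulse) > n:
                raise ValidationError("planted event does not fit inside the recording")
            traces[c, s : s + len(pulse)] += pulse
            per_channel[int(c)] = t_c
        truth.append(
            dict(kind=ev.kind, onset=ev.onset, channels=list(ev.channels),
                 amplitude=ev.amplitude, per_channel_onsets=per_channel)
        )
    return PlantedRecording(RenderedSignal(traces, fs, duration), truth)
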