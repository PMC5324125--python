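"""Benchmark assembly: s_e(n) = x(n) + w(n) + a(n) with full ground truth.

``compose`` performs the exact sample-wise sum of the spike component, the
slow-oscillation component and the artefact component.  ``run_scenario``
drives the whole pipeline (tissue -> spikes -> lfp -> artefacts ->
compose) from a scenario configuration, deriving every stage seed from one
master seed through fixed documented offsets so stages are independently
reproducible.  ``export``/``load`` write and read the on-disk layout:
interleaved int16 ``.dat`` traces with a declared uV-per-bit gain, JSON
annotations and a YAML configuration snapshot.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import presets
from .artefacts import (
    ArtefactEvent,
    ShockParams,
    count_artefacts,
    gen_shock,
    inject,
    schedule,
)
from .errors import ConfigurationError, ExportError, ValidationError
from .lfp import SlowOscillation, synth_slow
from .spikes import (
    AttenuationModel,
    RenderedSignal,
    SpikeTrain,
    gen_spike_train,
    render,
    round_half_away,
    synth_template_bank,
)
from .tissue import (
    FiringRateModel,
    LayerSpec,
    ProbeGeometry,
    TissueVolume,
    assign_rates,
    assign_types,
    build_probe,
    place_neurons,
)

DEFAULT_GAIN = 0.195  # uV per int16 bit, common ephys acquisition convention

# master seed -> stage seed derivation: fixed documented offsets
_SEED_MOD = 2**31
_SEED_MULT = 2654435761  # Knuth multiplicative hash constant
_STAGE_OFFSETS = {
    "place": 11,
    "types": 12,
    "rates": 13,
    "templates": 14,
    "trains": 15,
    "lfp": 16,
    "artefact_waveforms": 17,
    "schedule": 18,
}


def stage_seed(master: int, stage: str) -> int:
    return (master * _SEED_MULT + _STAGE_OFFSETS[stage]) % _SEED_MOD


# --------------------------------------------------------------------------
# Ground truth containers
# --------------------------------------------------------------------------


@dataclass
class UnitAnnotation:
    unit_id: int
    position: np.ndarray  # (3,) um
    cell_type: str
    rate: float  # configured mean rate, Hz
    layer_id: int
    resolvable: bool  # within the attenuation model's noise radius
    peak_scales: np.ndarray  # (n_channels,) uV per unit template peak
    spike_times: np.ndarray  # s


@dataclass
class GroundTruth:
    units: list[UnitAnnotation] = field(default_factory=list)
    artefacts: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "units": [
                dict(
                    unit_id=u.unit_id,
                    position=np.asarray(u.position).tolist(),
                    cell_type=u.cell_type,
                    rate=float(u.rate),
                    layer_id=int(u.layer_id),
                    resolvable=bool(u.resolvable),
                    peak_scales=np.asarray(u.peak_scales).tolist(),
                    spike_times=np.asarray(u.spike_times).tolist(),
                )
                for u in self.units
            ],
            "artefacts": self.artefacts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        units = [
            UnitAnnotation(
                unit_id=u["unit_id"],
                position=np.asarray(u["position"]),
                cell_type=u["cell_type"],
                rate=u["rate"],
                layer_id=u["layer_id"],
                resolvable=u["resolvable"],
                peak_scales=np.asarray(u["peak_scales"]),
                spike_times=np.asarray(u["spike_times"]),
            )
            for u in d.get("units", [])
        ]
        return cls(units=units, artefacts=list(d.get("artefacts", [])))


@dataclass
class BenchmarkDataset:
    """Composite signal plus complete ground-truth annotations."""

    signal: np.ndarray  # (n_channels, n_samples) uV
    sampling_rate: float
    components: dict[str, np.ndarray] | None = None  # {"x","w","a"}
    ground_truth: GroundTruth = field(default_factory=GroundTruth)
    config: dict | None = None
    seeds: dict | None = None

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


# --------------------------------------------------------------------------
# Composition
# --------------------------------------------------------------------------


def _traces(obj) -> np.ndarray:
    if isinstance(obj, (RenderedSignal, SlowOscillation)):
        return obj.traces
    return np.atleast_2d(np.asarray(obj, dtype=float))


def compose(
    x, w, a, sampling_rate: float | None = None, keep_components: bool = True
) -> BenchmarkDataset:
    """Exact sample-wise sum s(n) = x(n) + w(n) + a(n)."""
    tx, tw, ta = _traces(x), _traces(w), _traces(a)
    if not (tx.shape == tw.shape == ta.shape):
        raise ValidationError(
            f"component shapes differ: {tx.shape}, {tw.shape}, {ta.shape}"
        )
    rates = {
        getattr(obj, "sampling_rate", None)
        for obj in (x, w, a)
        if getattr(obj, "sampling_rate", None) is not None
    }
    if sampling_rate is not None:
        rates.add(float(sampling_rate))
    if len(rates) > 1:
        raise ValidationError(f"component sampling rates differ: {sorted(rates)}")
    fs = rates.pop() if rates else 1.0
    ds = BenchmarkDataset(signal=tx + tw + ta, sampling_rate=fs)
    if keep_components:
        ds.components = {"x": tx.copy(), "w": tw.copy(), "a": ta.copy()}
    return ds


# --------------------------------------------------------------------------
# Scenario pipeline
# --------------------------------------------------------------------------


def _resolve_rate_model(d: dict) -> FiringRateModel:
    kind = d["kind"]
    if kind == "uniform_bounds":
        return FiringRateModel.uniform(d["min_rate_hz"], d["max_rate_hz"])
    if kind == "logistic":
        return FiringRateModel.logistic(
            d["loc_hz"], d["scale_hz"], d.get("min_rate_hz", 0.01)
        )
    if kind == "generalized_pareto":
        return FiringRateModel(
            "generalized_pareto",
            {"c": d["c"], "loc": d.get("loc_hz", 0.0), "scale": d["scale_hz"]},
        )
    raise ConfigurationError(f"unsupported rate model kind {kind!r}")


def _resolve_volume(cfg: dict) -> TissueVolume:
    t = cfg["tissue"]
    pyr = t.get("pyramidal_fraction", 0.8)
    if t["kind"] == "single":
        return TissueVolume.single_block(
            t["volume_mm3"],
            t["density_per_mm3"],
            t["active_fraction"],
            _resolve_rate_model(t["rate_model"]),
            pyr,
        )
    if t["kind"] == "layered":
        layers = [
            LayerSpec(
                l["name"],
                l["thickness_um"],
                l["density_per_mm3"],
                l["active_fraction"],
                _resolve_rate_model(l["rate_model"]),
                l.get("pyramidal_fraction", pyr),
            )
            for l in t["layers"]
        ]
        return TissueVolume.layered(tuple(t["footprint_um"]), layers)
    raise ConfigurationError(f"unsupported tissue kind {t['kind']!r}")


def _resolve_probe(cfg: dict, volume: TissueVolume) -> ProbeGeometry:
    p = cfg["probe"]
    if "coords" in p:
        probe = build_probe("custom", coords=p["coords"], name=p.get("name", "custom"))
    elif "file" in p:
        probe = presets.probe_preset(p["file"])
    elif "preset" in p:
        probe = build_probe(p["preset"])
    else:
        raise ConfigurationError("probe config needs 'coords', 'file' or 'preset'")
    center = p.get("center_um") or [d / 2.0 for d in volume.dimensions]
    probe = probe.translated(center)
    if not volume.contains_sites(probe):
        raise ConfigurationError("probe sites fall outside the tissue volume")
    return probe


def run_scenario(config: str | dict, seed: int = 0, overrides: dict | None = None,
                 keep_components: bool = True) -> BenchmarkDataset:
    """Run the full benchmark pipeline for a scenario.

    ``config`` is a shipped preset name (``awake``, ``anaesthetised``,
    ``hippocampus_multilayer``) or an equivalent dict; ``overrides`` are
    deep-merged on top.  All randomness derives from ``seed``; two calls
    with the same configuration and seed produce bit-identical datasets.
    """
    cfg = presets.scenario(config) if isinstance(config, str) else config
    cfg = presets.deep_merge(cfg, overrides)

    fs = float(cfg["sampling_rate_hz"])
    duration = float(cfg["duration_s"])
    refractory = float(cfg.get("refractory_s", 0.002))
    seeds = {stage: stage_seed(seed, stage) for stage in _STAGE_OFFSETS}

    def _stage(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:  # annotate which pipeline stage failed
            raise type(e)(f"[stage {stage}] {e}") from e

    # tissue ---------------------------------------------------------------
    volume = _stage("tissue", _resolve_volume, cfg)
    probe = _stage("tissue", _resolve_probe, cfg, volume)
    pop = _stage("tissue", place_neurons, volume, seeds["place"])
    pyr_frac = cfg["tissue"].get("pyramidal_fraction", 0.8)
    pop = _stage("tissue", assign_types, pop, pyr_frac, seeds["types"])
    if cfg["tissue"]["kind"] == "layered":
        models = {
            i: _resolve_rate_model(l["rate_model"])
            for i, l in enumerate(cfg["tissue"]["layers"])
        }
        model = models
    else:
        model = _resolve_rate_model(cfg["tissue"]["rate_model"])
    pop = _stage(
        "tissue",
        assign_rates,
        pop,
        model,
        cfg.get("interneuron_rate_factor", 5.0),
        seeds["rates"],
    )

    # spikes ---------------------------------------------------------------
    att_cfg = cfg.get("attenuation", {})
    atten = AttenuationModel(
        reference_distance=att_cfg.get("reference_distance_um", 50.0),
        reference_amplitude=att_cfg.get("reference_amplitude_uv", 50.0),
        minimum_distance=att_cfg.get("minimum_distance_um", 10.0),
        noise_radius=att_cfg.get("noise_radius_um", 100.0),
    )
    bg_radius = cfg.get("background_radius_um", 250.0)
    active_idx = np.flatnonzero(pop.active)
    diff = pop.positions[active_idx, None, :] - probe.sites[None, :, :]
    dist_active = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff)).min(axis=1)
    sel = active_idx[dist_active <= bg_radius]
    dist_sel = dist_active[dist_active <= bg_radius]
    sub = pop.subset(sel)

    tcfg = cfg.get("templates", {})
    bank = _stage(
        "spikes",
        synth_template_bank,
        tcfg.get("n", 20),
        tcfg.get("pyramidal_mix", 0.8),
        seeds["templates"],
        fs,
    )
    trains = [
        _stage(
            "spikes",
            gen_spike_train,
            sub.rate[i],
            duration,
            refractory,
            (seeds["trains"] + i) % _SEED_MOD,
            int(sel[i]),
        )
        for i in range(sub.n)
    ]
    x = _stage("spikes", render, sub, trains, bank, probe, atten, fs, duration)

    # lfp ------------------------------------------------------------------
    lcfg = cfg.get("lfp", {})
    w = _stage(
        "lfp",
        synth_slow,
        lcfg.get("condition", "awake"),
        probe.n_sites,
        fs,
        duration,
        seeds["lfp"],
        lcfg.get("rms_uv"),
    )

    # artefacts ------------------------------------------------------------
    acfg = cfg.get("artefacts", {})
    a = RenderedSignal.zeros(probe.n_sites, fs, duration)
    artefact_truth: list[dict] = []
    a_rate = acfg.get("rate_per_s", 0.0)
    n_events = count_artefacts(a_rate, duration) if a_rate > 0 else 0
    if n_events:
        if acfg.get("classes", ["mechanical_shock"]) != ["mechanical_shock"]:
            raise ConfigurationError(
                "scenario injection currently supports the mechanical_shock class"
            )
        shock_params = ShockParams()
        tmpls = [
            _stage(
                "artefacts",
                gen_shock,
                shock_params,
                fs,
                (seeds["artefact_waveforms"] + i) % _SEED_MOD,
            )
            for i in range(n_events)
        ]
        # footprint includes the two boundary transition samples
        footprints = [(len(t.waveform) + 2) / fs for t in tmpls]
        onsets = _stage("artefacts", schedule, n_events, duration, footprints, seeds["schedule"])
        mask = np.ones(probe.n_sites, dtype=bool)
        for t, o in zip(tmpls, onsets):
            ev = ArtefactEvent(onset=o + 1.0 / fs, template=t, channel_mask=mask)
            a = _stage("artefacts", inject, a, ev)
            artefact_truth.append(
                dict(
                    cls=t.cls,
                    onset=ev.onset,
                    duration=t.duration,
                    channels=list(range(probe.n_sites)),
                    p2p=t.p2p,
                    carrier_hz=t.annotations.get("carrier_hz"),
                )
            )

    # compose --------------------------------------------------------------
    ds = compose(x, w, a, keep_components=keep_components)

    scales = atten.scale(
        np.linalg.norm(sub.positions[:, None, :] - probe.sites[None, :, :], axis=2)
    )
    gt = GroundTruth(artefacts=artefact_truth)
    for i in range(sub.n):
        gt.units.append(
            UnitAnnotation(
                unit_id=int(sel[i]),
                position=sub.positions[i],
                cell_type=str(sub.cell_type[i]),
                rate=float(sub.rate[i]),
                layer_id=int(sub.layer_id[i]),
                resolvable=bool(dist_sel[i] <= atten.noise_radius),
                peak_scales=scales[i],
                spike_times=trains[i].times,
            )
        )
    ds.ground_truth = gt
    ds.config = presets.deep_merge(cfg, {"seed": seed})
    ds.seeds = seeds
    return ds


def artefact_sample_fraction(ds: BenchmarkDataset) -> float:
    """Fraction of samples inside annotated artefact events."""
    if ds.n_samples == 0:
        return 0.0
    covered = np.zeros(ds.n_samples, dtype=bool)
    fs = ds.sampling_rate
    for ev in ds.ground_truth.artefacts:
        s0 = round_half_away(ev["onset"] * fs)
        s1 = s0 + round_half_away(ev["duration"] * fs)
        covered[s0:s1] = True
    return float(covered.mean())


# --------------------------------------------------------------------------
# Export / load
# --------------------------------------------------------------------------


def _write_dat(path: str, traces: np.ndarray, gain: float) -> None:
    q = np.rint(traces / gain)
    if q.size and np.abs(q).max() > 32767:
        raise ExportError(
            f"signal exceeds int16 range at gain {gain} uV/bit; increase the gain"
        )
    q.T.astype("<i2").tofile(path)  # channel-major frames (sample interleaved)


def _read_dat(path: str, n_channels: int, gain: float) -> np.ndarray:
    raw = np.fromfile(path, dtype="<i2")
    if n_channels == 0:
        return np.zeros((0, 0))
    return raw.reshape(-1, n_channels).T.astype(float) * gain


def export(ds: BenchmarkDataset, path: str, gain: float = DEFAULT_GAIN) -> None:
    """Write a dataset directory: ``signal.dat`` (interleaved int16 at
    ``gain`` uV/bit), component ``.dat`` files when stored,
    ``annotations.json`` and ``config.yaml``."""
    os.makedirs(path, exist_ok=True)
    _write_dat(os.path.join(path, "signal.dat"), ds.signal, gain)
    comp_names = []
    if ds.components:
        for name, tr in ds.components.items():
            comp_names.append(name)
            _write_dat(os.path.join(path, f"{name}.dat"), tr, gain)
    meta = {
        "gain_uv_per_bit": gain,
        "sampling_rate_hz": ds.sampling_rate,
        "n_channels": ds.n_channels,
        "n_samples": ds.n_samples,
        "components": comp_names,
        "seeds": ds.seeds,
        "ground_truth": ds.ground_truth.to_dict(),
    }
    with open(os.path.join(path, "annotations.json"), "w") as fh:
        json.dump(meta, fh)
    with open(os.path.join(path, "config.yaml"), "w") as fh:
        yaml.safe_dump(ds.config or {}, fh)


def read_raw_dat(
    path: str, n_channels: int, sampling_rate: float, gain: float = DEFAULT_GAIN
) -> RenderedSignal:
    """Read a bare interleaved int16 ``.dat`` recording (e.g. a real
    session used as a slow-oscillation source) into a RenderedSignal."""
    traces = _read_dat(path, n_channels, gain)
    return RenderedSignal(traces, sampling_rate, traces.shape[1] / sampling_rate)


def load(path: str) -> BenchmarkDataset:
    """Inverse of :func:`export` up to int16 quantization."""
    with open(os.path.join(path, "annotations.json")) as fh:
        meta = json.load(fh)
    gain = meta["gain_uv_per_bit"]
    n_ch = meta["n_channels"]
    signal = _read_dat(os.path.join(path, "signal.dat"), n_ch, gain)
    components = None
    if meta.get("components"):
        components = {
            name: _read_dat(os.path.join(path, f"{name}.dat"), n_ch, gain)
            for name in meta["components"]
        }
    cfg_path = os.path.join(path, "config.yaml")
    config = None
    if os.path.exists(cfg_path):
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh)
    return BenchmarkDataset(
        signal=signal,
        sampling_rate=meta["sampling_rate_hz"],
        components=components,
        ground_truth=GroundTruth.from_dict(meta.get("ground_truth", {})),
        config=config,
        seeds=meta.get("seeds"),
    )
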