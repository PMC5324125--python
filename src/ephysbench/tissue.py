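"""Virtual tissue volumes, neuron placement, and recording-probe geometry.

The simulated preparation is a block of "virtual tissue" — by default a
1.5 mm^3 cube of hippocampus-like neuropil at 300,000 neurons/mm^3 with an
80/20 split of pyramidal cells and interneurons — in which neurons are
placed uniformly at random and a multi-site probe is embedded.  Layered
volumes (e.g. stratum oriens / pyramidale / radiatum) are modelled as slabs
stacked along the z axis, each with its own density, proportion of active
cells and firing-rate distribution.

Coordinates are in micrometres with the origin at a corner of the volume;
layer slabs are half-open intervals [z0, z0 + thickness) along z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ValidationError

PYRAMIDAL = "pyramidal"
INTERNEURON = "interneuron"

_UM3_PER_MM3 = 1e9


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


# --------------------------------------------------------------------------
# Firing-rate models
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FiringRateModel:
    """Distribution from which per-unit mean firing rates are drawn.

    ``kind`` is one of ``uniform_bounds`` (params ``min_rate``/``max_rate``
    in Hz), ``generalized_pareto`` (``c``, ``loc``, ``scale``), ``logistic``
    (``loc``, ``scale``, optional truncation ``min_rate``) or
    ``custom_table`` (``values`` with optional ``weights``).  Drawn rates
    are strictly positive by construction.
    """

    kind: str
    params: dict

    _KINDS = ("uniform_bounds", "generalized_pareto", "logistic", "custom_table")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ConfigurationError(f"unknown rate model kind {self.kind!r}")
        p = self.params
        if self.kind == "uniform_bounds":
            lo, hi = p["min_rate"], p["max_rate"]
            if not (0 < lo <= hi):
                raise ValidationError("uniform bounds require 0 < min_rate <= max_rate")
        elif self.kind == "generalized_pareto":
            if p["scale"] <= 0 or p.get("loc", 0.0) < 0:
                raise ValidationError("generalized Pareto needs scale > 0 and loc >= 0")
        elif self.kind == "logistic":
            if p["loc"] <= 0 or p["scale"] < 0:
                raise ValidationError("logistic rate model needs loc > 0 and scale >= 0")
        else:
            vals = np.asarray(p["values"], dtype=float)
            if vals.size == 0 or np.any(vals <= 0):
                raise ValidationError("custom_table values must be positive and non-empty")

    @classmethod
    def uniform(cls, min_rate: float, max_rate: float) -> "FiringRateModel":
        return cls("uniform_bounds", {"min_rate": float(min_rate), "max_rate": float(max_rate)})

    @classmethod
    def logistic(cls, loc: float, scale: float, min_rate: float = 0.01) -> "FiringRateModel":
        return cls("logistic", {"loc": float(loc), "scale": float(scale), "min_rate": float(min_rate)})

    def scaled(self, factor: float) -> "FiringRateModel":
        """Return a copy with the location/bounds scaled by ``factor``.

        Used to derive interneuron rates from the pyramidal model (factor 5
        by default in the scenario presets).
        """
        if factor <= 0:
            raise ValidationError("rate scale factor must be positive")
        p = dict(self.params)
        if self.kind == "uniform_bounds":
            p["min_rate"] *= factor
            p["max_rate"] *= factor
        elif self.kind == "generalized_pareto":
            p["loc"] = p.get("loc", 0.0) * factor
            p["scale"] *= factor
        elif self.kind == "logistic":
            p["loc"] *= factor
            p["scale"] *= factor
        else:
            p["values"] = [v * factor for v in p["values"]]
        return FiringRateModel(self.kind, p)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` strictly positive rates (Hz)."""
        if n == 0:
            return np.empty(0)
        if self.kind == "uniform_bounds":
            return rng.uniform(self.params["min_rate"], self.params["max_rate"], n)
        if self.kind == "generalized_pareto":
            out = stats.genpareto.rvs(
                self.params["c"],
                loc=self.params.get("loc", 0.0),
                scale=self.params["scale"],
                size=n,
                random_state=rng,
            )
            return np.maximum(out, 1e-3)
        if self.kind == "logistic":
            floor = self.params.get("min_rate", 0.01)
            out = rng.logistic(self.params["loc"], self.params["scale"], n)
            # resample sub-threshold draws (truncation keeps rates positive)
            bad = out < floor
            while np.any(bad):
                out[bad] = rng.logistic(self.params["loc"], self.params["scale"], int(bad.sum()))
                bad = out < floor
            return out
        vals = np.asarray(self.params["values"], dtype=float)
        w = self.params.get("weights")
        p = None if w is None else np.asarray(w, float) / np.sum(w)
        return rng.choice(vals, size=n, p=p)


# --------------------------------------------------------------------------
# Probe geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeGeometry:
    """Recording-site coordinates (um) and site diameter (um)."""

    sites: np.ndarray  # (n_sites, 3)
    site_diameter: float = 13.0
    name: str = "custom"

    def __post_init__(self):
        sites = np.atleast_2d(np.asarray(self.sites, dtype=float))
        if sites.ndim != 2 or sites.shape[1] != 3 or sites.shape[0] < 1:
            raise ValidationError("probe needs >= 1 site with (x, y, z) coordinates")
        if len(np.unique(sites, axis=0)) != len(sites):
            raise ValidationError("duplicate recording sites in probe geometry")
        object.__setattr__(self, "sites", sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def translated(self, offset: Sequence[float]) -> "ProbeGeometry":
        return replace(self, sites=self.sites + np.asarray(offset, dtype=float))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "name": self.name,
                    "site_diameter_um": self.site_diameter,
                    "sites": self.sites.tolist(),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ProbeGeometry":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["sites"], float), d.get("site_diameter_um", 13.0), d.get("name", "custom"))


def _tetrode_sites() -> np.ndarray:
    # regular tetrahedron, 25 um tip spacing, centred at the origin
    a = 25.0 / (2.0 * np.sqrt(2.0))
    return a * np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )


def _polytrode_8x4_sites() -> np.ndarray:
    # 4 shanks (200 um pitch) x 8 staggered sites (20 um vertical pitch),
    # after the Buzsaki64-style shank layout
    sites = []
    for shank in range(4):
        x = 200.0 * shank
        for k in range(8):
            y = 8.66 if k % 2 else -8.66
            sites.append((x, y, 20.0 * k))
    s = np.asarray(sites, dtype=float)
    return s - s.mean(axis=0)


def build_probe(
    preset: str,
    coords: Sequence[Sequence[float]] | None = None,
    site_diameter: float = 13.0,
    name: str | None = None,
) -> ProbeGeometry:
    """Build a probe from a preset (``tetrode``, ``polytrode_8x4``) or
    explicit ``custom`` coordinates (um)."""
    if preset == "tetrode":
        return ProbeGeometry(_tetrode_sites(), site_diameter, name or "tetrode")
    if preset == "polytrode_8x4":
        return ProbeGeometry(_polytrode_8x4_sites(), site_diameter, name or "polytrode_8x4")
    if preset == "custom":
        if coords is None:
            raise ConfigurationError("custom probe requires explicit site coordinates")
        return ProbeGeometry(np.asarray(coords, dtype=float), site_diameter, name or "custom")
    raise ConfigurationError(f"unknown probe preset {preset!r}")


# --------------------------------------------------------------------------
# Tissue volume
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerSpec:
    """One slab of tissue: thickness (um), neuron density (per mm^3),
    fraction of units firing, the firing-rate law, and pyramidal fraction."""

    name: str
    thickness: float
    density: float
    active_fraction: float
    rate_model: FiringRateModel
    pyramidal_fraction: float = 0.8

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValidationError(f"layer {self.name!r}: thickness must be > 0")
        if self.density < 0:
            raise ValidationError(f"layer {self.name!r}: density must be >= 0")
        for attr in ("active_fraction", "pyramidal_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"layer {self.name!r}: {attr} must lie in [0, 1]")


@dataclass(frozen=True)
class TissueVolume:
    """Axis-aligned tissue block with layers stacked along z."""

    dimensions: tuple[float, float, float]  # um
    layers: tuple[LayerSpec, ...]

    def __post_init__(self):
        dims = tuple(float(d) for d in self.dimensions)
        if any(d <= 0 for d in dims):
            raise ValidationError("tissue volume extents must be positive")
        object.__setattr__(self, "dimensions", dims)
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ValidationError("tissue volume needs at least one layer")
        if sum(l.thickness for l in self.layers) > dims[2] + 1e-9:
            raise ValidationError("layer thicknesses exceed the z extent of the volume")

    @classmethod
    def single_block(
        cls,
        volume_mm3: float,
        density: float,
        active_fraction: float,
        rate_model: FiringRateModel,
        pyramidal_fraction: float = 0.8,
        name: str = "block",
    ) -> "TissueVolume":
        """Cubic single-layer volume of the requested size in mm^3."""
        side = (volume_mm3 * _UM3_PER_MM3) ** (1.0 / 3.0)
        layer = LayerSpec(name, side, density, active_fraction, rate_model, pyramidal_fraction)
        return cls((side, side, side), (layer,))

    @classmethod
    def layered(
        cls, footprint: tuple[float, float], layers: Sequence[LayerSpec]
    ) -> "TissueVolume":
        """Stack of slabs sharing an x-y footprint (um)."""
        z = sum(l.thickness for l in layers)
        return cls((footprint[0], footprint[1], z), tuple(layers))

    def layer_bounds(self) -> list[tuple[float, float]]:
        """Half-open [z0, z1) interval of each layer."""
        out, z0 = [], 0.0
        for l in self.layers:
            out.append((z0, z0 + l.thickness))
            z0 += l.thickness
        return out

    def layer_volume_mm3(self, i: int) -> float:
        dx, dy, _ = self.dimensions
        return dx * dy * self.layers[i].thickness / _UM3_PER_MM3

    def contains_sites(self, probe: ProbeGeometry) -> bool:
        lo = np.zeros(3)
        hi = np.asarray(self.dimensions)
        return bool(np.all(probe.sites >= lo) and np.all(probe.sites <= hi))


# --------------------------------------------------------------------------
# Neuron population
# --------------------------------------------------------------------------


@dataclass
class NeuronPopulation:
    """Per-unit position, cell type, mean rate, active flag and layer id."""

    positions: np.ndarray  # (n, 3) um
    cell_type: np.ndarray  # (n,) str: "pyramidal" | "interneuron" | ""
    rate: np.ndarray  # (n,) Hz
    active: np.ndarray  # (n,) bool
    layer_id: np.ndarray  # (n,) int

    @property
    def n(self) -> int:
        return len(self.positions)

    def subset(self, idx) -> "NeuronPopulation":
        return NeuronPopulation(
            self.positions[idx],
            self.cell_type[idx],
            self.rate[idx],
            self.active[idx],
            self.layer_id[idx],
        )


def place_neurons(volume: TissueVolume, seed: int) -> NeuronPopulation:
    """Place ``round(density x sub-volume)`` units i.i.d. uniformly inside
    each layer slab and flag ``round(active_fraction x count)`` of them as
    active.  Reproducible for a fixed seed."""
    rng = np.random.default_rng(seed)
    dx, dy, _ = volume.dimensions
    if dx * dy <= 0:
        raise ValidationError("zero-area footprint yields zero-volume layers")
    pos, layer_ids, active = [], [], []
    for i, (layer, (z0, z1)) in enumerate(zip(volume.layers, volume.layer_bounds())):
        vol = volume.layer_volume_mm3(i)
        if vol <= 0:
            raise ValidationError(f"layer {layer.name!r} has zero volume")
        n_l = round_half_away(layer.density * vol)
        p = np.column_stack(
            [
                rng.uniform(0.0, dx, n_l),
                rng.uniform(0.0, dy, n_l),
                rng.uniform(z0, z1, n_l),
            ]
        )
        flag = np.zeros(n_l, dtype=bool)
        k = round_half_away(layer.active_fraction * n_l)
        flag[rng.permutation(n_l)[:k]] = True
        pos.append(p)
        layer_ids.append(np.full(n_l, i, dtype=np.int32))
        active.append(flag)
    positions = np.concatenate(pos) if pos else np.empty((0, 3))
    n = len(positions)
    return NeuronPopulation(
        positions=positions,
        cell_type=np.full(n, "", dtype="<U12"),
        rate=np.zeros(n),
        active=np.concatenate(active) if active else np.zeros(0, bool),
        layer_id=np.concatenate(layer_ids) if layer_ids else np.zeros(0, np.int32),
    )


def assign_types(
    pop: NeuronPopulation, pyramidal_fraction: float, seed: int
) -> NeuronPopulation:
    """Assign exactly ``round(fraction x n)`` pyramidal units per layer
    (which units is seeded-random; the count is deterministic)."""
    if not 0.0 <= pyramidal_fraction <= 1.0:
        raise ValidationError("pyramidal_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cell_type = np.full(pop.n, INTERNEURON, dtype="<U12")
    for lid in np.unique(pop.layer_id):
        idx = np.flatnonzero(pop.layer_id == lid)
        k = round_half_away(pyramidal_fraction * len(idx))
        chosen = idx[rng.permutation(len(idx))[:k]]
        cell_type[chosen] = PYRAMIDAL
    out = pop.subset(slice(None))
    out.cell_type = cell_type
    return out


def assign_rates(
    pop: NeuronPopulation,
    model: FiringRateModel | Mapping[int, FiringRateModel],
    interneuron_factor: float = 5.0,
    seed: int = 0,
) -> NeuronPopulation:
    """Draw pyramidal rates from ``model`` and interneuron rates from the
    same law with its location/bounds multiplied by ``interneuron_factor``
    (the presets use a factor of five)."""
    if interneuron_factor <= 0:
        raise ValidationError("interneuron_factor must be positive")
    rng = np.random.default_rng(seed)
    rate = np.zeros(pop.n)
    for lid in np.unique(pop.layer_id):
        m = model[int(lid)] if isinstance(model, Mapping) else model
        in_layer = pop.layer_id == lid
        pyr = in_layer & (pop.cell_type == PYRAMIDAL)
        inh = in_layer & (pop.cell_type == INTERNEURON)
        rate[pyr] = m.draw(int(pyr.sum()), rng)
        rate[inh] = m.scaled(interneuron_factor).draw(int(inh.sum()), rng)
    out = pop.subset(slice(None))
    out.rate = rate
    return out
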