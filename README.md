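# ephysbench

Bio-inspired benchmark generator for extracellular multi-unit recordings.

Spike sorters, artefact-removal methods and closed-loop neural devices
all need ground-truth data to be evaluated, but real extracellular
recordings never come with complete annotations.  `ephysbench` generates
fully annotated, parameterisable multichannel benchmarks in which every
electrode trace is the sum of three known components

    s_e(n) = x_e(n) + w_e(n) + a_e(n)

— spike activity `x` (resolvable spikes from nearby neurons plus
mechanistic background noise from distant ones, rendered from a template
bank through a point-source 1/d attenuation law), non-stationary slow
oscillations `w` (< 300 Hz, extracted from a real recording with a
zero-phase 10th-order Butterworth filter or synthesized), and artefacts
`a` (parametric mechanical-shock, mastication and grooming classes with
documented amplitude, rhythm and duration statistics, injected with
boundary-smoothing transition samples).  Every spike time, per-channel
peak amplitude and artefact interval is recorded in the ground truth, and
a Bartlett averaged-periodogram stack (with per-frequency SEM, local
polynomial smoothing and band-wise comparison) quantifies how
contamination reshapes the spectrum.

The default study conditions model rat hippocampal CA1: a 1.5 mm³ volume
at 300,000 neurons/mm³ with an 80/20 pyramidal/interneuron split,
interneurons firing 5× faster, a 2 ms refractory period, 20 kHz sampling
and 10 s sessions.  Shipped presets: `awake` (0.5–12 Hz rates, 10% active,
10 artefacts/s ≈ 1% of samples), `anaesthetised` (0.5–5 Hz, 4% active,
1 artefact/s ≈ 0.1%) and `hippocampus_multilayer` (stratum oriens /
pyramidale / radiatum slabs recorded by a 32-site polytrode).

## Worked example

```python
import ephysbench as eb

ds = eb.run_scenario("awake", seed=1)          # full pipeline, ~4 s
print(ds.n_channels, ds.n_samples)             # 16 200000
units = ds.ground_truth.units
print(len(units), sum(u.resolvable for u in units))   # 5918 667
print(len(ds.ground_truth.artefacts))          # 100
print(round(100 * eb.artefact_sample_fraction(ds), 2))  # 1.15
eb.export(ds, "awake_s1")                      # .dat + annotations.json + config.yaml
```

The run places 450,000 neurons, renders the ~5,900 active units within
250 µm of the 16-site four-tetrode array (667 of them close enough to be
annotated as resolvable), adds a theta-dominated slow oscillation, and
injects exactly `round(10 artefacts/s × 10 s) = 100` mechanical shocks
covering 1.15% of samples — the awake contamination condition.

The same from the command line, plus a spectral comparison:

```bash
ephysbench generate --scenario awake --seed 1 --out awake_s1
ephysbench inspect awake_s1
ephysbench validate-psd clean_dir dirty_dir
```

`validate-psd` prints per-band log10 power ratios; a contaminated
recording shows its excess power exactly where spikes live, e.g.
`band 1000-3000 Hz  log10_ratio 0.123` for a heavily contaminated
anaesthetised render against a clean one, and ~0 elsewhere.

Artefact classes can also be used standalone:

```python
shock = eb.gen_shock(fs=20000.0, seed=0)       # 1142 us, peak 1-2 kHz
chew  = eb.gen_mastication(fs=20000.0, seed=0) # ~3.3 s burst sequence
chew.annotations["burst_onsets"]               # annotated chewing cycle
```

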