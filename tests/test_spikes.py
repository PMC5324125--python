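import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ephysbench as eb
from ephysbench.errors import ConfigurationError, ValidationError
from ephysbench.tissue import INTERNEURON, PYRAMIDAL

from conftest import single_unit_population

FS = 20000.0


class TestTemplateBank:
    def test_normalization_and_zero_endpoints(self):
        bank = eb.synth_template_bank(10, 0.8, seed=0)
        for t in bank:
            assert np.abs(t.waveform).max() == pytest.approx(1.0)
            assert t.waveform[0] == 0.0 and t.waveform[-1] == 0.0
            assert len(t.waveform) / t.sampling_rate <= 3e-3 + 1e-9

    def test_cell_type_split(self):
        bank = eb.synth_template_bank(100, 0.8, seed=1)
        assert sum(t.cell_type == PYRAMIDAL for t in bank) == 80

    def test_single_pyramidal(self):
        bank = eb.synth_template_bank(1, 1.0, seed=2)
        assert len(bank) == 1 and bank[0].cell_type == PYRAMIDAL

    def test_interneurons_narrower(self):
        bank = eb.synth_template_bank(40, 0.5, seed=3)
        wp = [t.width for t in bank if t.cell_type == PYRAMIDAL]
        wi = [t.width for t in bank if t.cell_type == INTERNEURON]
        assert max(wi) < min(wp)

    def test_empty_bank_rejected(self):
        with pytest.raises(ValidationError):
            eb.synth_template_bank(0)


class TestSpikeTrains:
    def test_rate_and_refractory(self):
        tr = eb.gen_spike_train(5.0, 10.0, 0.002, seed=0)
        assert 25 <= len(tr.times) <= 80  # ~50 expected
        assert np.diff(tr.times).min() >= 0.002
        assert tr.times.min() >= 0.0 and tr.times.max() < 10.0

    def test_long_run_count_within_renewal_band(self):
        # independent oracle: brute-force renewal simulation of the same law
        rng = np.random.default_rng(12345)
        counts = []
        for _ in range(200):
            isis = 0.002 + rng.exponential(1.0 / 1.0 - 0.002, 1300)
            counts.append(int((np.cumsum(isis) < 1000.0).sum()))
        mu, sd = np.mean(counts), np.std(counts)
        n = len(eb.gen_spike_train(1.0, 1000.0, 0.002, seed=7).times)
        assert abs(n - mu) <= 3.0 * sd

    def test_zero_duration_empty(self):
        assert len(eb.gen_spike_train(5.0, 0.0, 0.002, seed=0).times) == 0

    def test_unattainable_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            eb.gen_spike_train(600.0, 1.0, 0.002, seed=0)


class TestAttenuation:
    def test_anchor_halving_and_clamp(self):
        m = eb.AttenuationModel()
        assert eb.attenuate(m, 50.0) == pytest.approx(50.0)
        assert eb.attenuate(m, 100.0) == pytest.approx(25.0)
        assert eb.attenuate(m, 5.0) == eb.attenuate(m, 10.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=10.0, max_value=1e4),
           st.floats(min_value=1.0, max_value=1e3))
    def test_strictly_decreasing_beyond_clamp(self, d, step):
        m = eb.AttenuationModel()
        assert eb.attenuate(m, d + step) < eb.attenuate(m, d)


class TestRender:
    def _render_single(self, pos, probe, times, seed=0):
        pop = single_unit_population(pos)
        bank = eb.synth_template_bank(1, 1.0, seed=seed)
        trains = [eb.SpikeTrain(0, np.asarray(times))]
        return eb.render(pop, trains, bank, probe, eb.AttenuationModel(), FS, 1.0), bank

    def test_single_event_is_scaled_template(self):
        probe = eb.build_probe("custom", coords=[[0.0, 0.0, 50.0]])
        sig, bank = self._render_single([0.0, 0.0, 0.0], probe, [0.1])
        w = bank[0].waveform
        s = round(0.1 * FS)
        scale = eb.attenuate(eb.AttenuationModel(), 50.0)
        assert np.allclose(sig.traces[0, s : s + len(w)], scale * w)
        mask = np.ones(sig.n_samples, bool)
        mask[s : s + len(w)] = False
        # FFT-based convolution leaves only float residue outside the event
        assert np.abs(sig.traces[0, mask]).max() < 1e-9

    def test_superposition_of_coincident_spikes(self):
        probe = eb.build_probe("custom", coords=[[0.0, 0.0, 50.0]])
        one, _ = self._render_single([0.0, 0.0, 0.0], probe, [0.1])
        two, _ = self._render_single([0.0, 0.0, 0.0], probe, [0.1, 0.1])
        assert np.allclose(two.traces, 2.0 * one.traces)

    def test_linearity_in_train_union(self):
        probe = eb.build_probe("tetrode").translated([0.0, 0.0, 100.0])
        pop = single_unit_population([0.0, 0.0, 0.0])
        bank = eb.synth_template_bank(1, 1.0, seed=0)
        atten = eb.AttenuationModel()
        t_a, t_b = [0.05, 0.30], [0.12, 0.70]
        r = lambda times: eb.render(
            pop, [eb.SpikeTrain(0, np.asarray(times))], bank, probe, atten, FS, 1.0
        ).traces
        assert np.allclose(r(sorted(t_a + t_b)), r(t_a) + r(t_b))

    def test_equidistant_tetrode_sites_identical_waveforms(self):
        probe = eb.build_probe("tetrode")  # tetrahedron centred at origin
        sig, _ = self._render_single([0.0, 0.0, 0.0], probe, [0.1])
        for c in range(1, 4):
            assert np.allclose(sig.traces[c], sig.traces[0])

    def test_channel_peaks_sorted_by_distance(self):
        probe = eb.build_probe("polytrode_8x4")
        pos = probe.sites[5] + np.asarray([30.0, 0.0, 0.0])
        sig, _ = self._render_single(pos, probe, [0.1])
        d = np.linalg.norm(probe.sites - pos, axis=1)
        peaks = np.abs(sig.traces).max(axis=1)
        order = np.argsort(d)
        assert np.all(np.diff(peaks[order]) <= 1e-9)

    def test_invalid_inputs(self):
        probe = eb.build_probe("custom", coords=[[0.0, 0.0, 50.0]])
        pop = single_unit_population([0.0, 0.0, 0.0])
        bank = eb.synth_template_bank(1, 1.0, seed=0)
        with pytest.raises(ValidationError):
            eb.render(pop, [eb.SpikeTrain(0, np.asarray([2.0]))], bank, probe,
                      eb.AttenuationModel(), FS, 1.0)
        with pytest.raises(ValidationError):
            eb.render(pop, [eb.SpikeTrain(0, np.asarray([0.1]))], bank, probe,
                      eb.AttenuationModel(), -1.0, 1.0)


class TestScenarioSpikes:
    def test_annotated_spikes_align_with_extrema(self, small_dataset):
        """Strong resolvable units leave a local trough within 0.5 ms of
        every annotated spike time on their best channel."""
        ds = small_dataset
        x = ds.components["x"]
        rms = x.std()
        fs = ds.sampling_rate
        half = int(0.5e-3 * fs)
        checked = 0
        for u in ds.ground_truth.units:
            if not u.resolvable or u.peak_scales.max() < 3.0 * rms:
                continue
            best = int(np.argmax(u.peak_scales))
            for t in u.spike_times:
                s = int(round(t * fs))
                seg = x[best, max(s - half, 0) : s + half]
                assert seg.min() <= -2.0 * rms
                checked += 1
        assert checked > 0


class TestTemplateBankIO:
    def test_npz_round_trip(self, tmp_path):
        bank = eb.synth_template_bank(6, 0.5, seed=4)
        p = str(tmp_path / "bank.npz")
        eb.save_template_bank(p, bank)
        back = eb.load_template_bank(p)
        assert len(back) == len(bank)
        for a, b in zip(bank, back):
            assert np.array_equal(a.waveform, b.waveform)
            assert a.cell_type == b.cell_type and a.width == b.width
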