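import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ephysbench as eb
from ephysbench.artefacts import MECHANICAL_SHOCK
from ephysbench.errors import SchedulingError, ValidationError

FS = 20000.0


class TestCounting:
    @pytest.mark.parametrize(
        "rate,duration,expected", [(1.0, 10.0, 10), (10.0, 10.0, 100), (0.0, 10.0, 0), (0.55, 10.0, 6)]
    )
    def test_round_rate_times_duration(self, rate, duration, expected):
        assert eb.count_artefacts(rate, duration) == expected

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            eb.count_artefacts(-1.0, 10.0)


class TestShocks:
    def test_duration_and_silent_pre_threshold(self):
        t = eb.gen_shock(fs=FS, seed=0)
        assert len(t.waveform) == round(1142e-6 * FS)
        pre = t.annotations["pre_threshold_samples"]
        assert pre == round(285e-6 * FS)
        assert np.all(t.waveform[:pre] == 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_spectral_peak_in_band(self, seed):
        t = eb.gen_shock(fs=FS, seed=seed)
        spec = np.abs(np.fft.rfft(t.waveform, 1 << 14))
        peak = np.argmax(spec) * FS / (1 << 14)
        assert 1000.0 <= peak <= 2000.0

    def test_p2p_statistics_recover_printed_mean(self):
        p2ps = [eb.gen_shock(fs=FS, seed=s).p2p for s in range(1000)]
        assert np.mean(p2ps) == pytest.approx(136.1064, rel=0.05)

    def test_degenerate_sd_exact_amplitude(self):
        params = eb.ShockParams(p2p_sd=0.0)
        for s in (0, 1):
            assert eb.gen_shock(params, FS, seed=s).p2p == pytest.approx(136.1064)

    def test_low_fs_rejected(self):
        with pytest.raises(ValidationError):
            eb.gen_shock(fs=3000.0, seed=0)


class TestMastication:
    def test_cycle_and_rate_statistics(self):
        cycles, rates = [], []
        for s in range(100):
            t = eb.gen_mastication(fs=FS, seed=s)
            onsets = t.annotations["burst_onsets"]
            cycles.extend(np.diff(onsets))
            rates.append(len(onsets) / t.annotations["sequence_duration"])
        assert np.mean(cycles) == pytest.approx(0.1625, rel=0.05)
        assert np.mean(rates) == pytest.approx(6.17, rel=0.05)

    def test_degenerate_jitter_exact_cycles(self):
        params = eb.MasticationParams(cycle_sd=0.0, sequence_duration_sd=0.0)
        t = eb.gen_mastication(params, FS, seed=0)
        d = np.diff(t.annotations["burst_onsets"])
        assert np.allclose(d, 0.1625)

    def test_annotated_onsets_inside_sequence(self):
        t = eb.gen_mastication(fs=FS, seed=5)
        onsets = t.annotations["burst_onsets"]
        assert onsets.min() >= 0.0
        assert onsets.max() < t.duration


class TestGrooming:
    def test_duration_bounds_over_many_draws(self):
        d = eb.draw_grooming_durations(eb.GroomingParams(), 1000, seed=1)
        assert d.min() >= 0.4 and d.max() <= 28.0

    def test_degenerate_range(self):
        d = eb.draw_grooming_durations(
            eb.GroomingParams(duration_range=(5.0, 5.0)), 100, seed=0
        )
        assert np.all(d == 5.0)

    def test_phases_ordered(self):
        for s in range(10):
            t = eb.gen_grooming(eb.GroomingParams(duration_range=(0.4, 2.0)), 4000.0, seed=s)
            labels = t.annotations["phase_labels"]
            onsets = t.annotations["phase_onsets"]
            assert np.all(np.diff(labels) > 0)  # nondecreasing chain, no repeats
            assert np.all(np.diff(onsets) >= 0)
            assert len(labels) == len(onsets)


class TestScheduling:
    def test_containment(self):
        onsets = eb.schedule(10, 10.0, 0.0012, seed=0)
        assert len(onsets) == 10
        assert onsets.min() >= 0.0
        assert (onsets + 0.0012).max() <= 10.0

    def test_forced_placement(self):
        assert eb.schedule(1, 2.0, 2.0, seed=0)[0] == 0.0

    def test_determinism(self):
        a = eb.schedule(20, 10.0, 0.01, seed=4)
        b = eb.schedule(20, 10.0, 0.01, seed=4)
        assert np.array_equal(a, b)

    def test_no_overlap(self):
        onsets = np.sort(eb.schedule(50, 2.0, 0.02, seed=1))
        assert np.all(np.diff(onsets) >= 0.02 - 1e-12)

    def test_infeasible_packing_reports_count(self):
        with pytest.raises(SchedulingError) as e:
            eb.schedule(3, 1.0, 0.5, seed=0)
        assert e.value.placed == 0


class TestInjection:
    def _template(self, values):
        return eb.ArtefactTemplate(np.asarray(values, float), MECHANICAL_SHOCK, FS)

    def test_interior_additivity_on_zero_signal(self):
        sig = eb.RenderedSignal.zeros(2, FS, 0.01)
        w = [-30.0, -60.0, 20.0, 10.0]
        ev = eb.ArtefactEvent(onset=50 / FS, template=self._template(w),
                              channel_mask=np.asarray([True, False]))
        out = eb.inject(sig, ev)
        assert np.allclose(out.traces[0, 50:54], w)
        assert np.all(out.traces[1] == 0.0)

    def test_transition_sample_is_midpoint(self):
        sig = eb.RenderedSignal.zeros(1, FS, 0.01)
        ev = eb.ArtefactEvent(onset=50 / FS, template=self._template([-30.0, 0.0]),
                              channel_mask=np.asarray([True]))
        out = eb.inject(sig, ev)
        assert out.traces[0, 49] == pytest.approx(-15.0)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_injection_invertible(self, seed):
        rng = np.random.default_rng(seed)
        sig = eb.RenderedSignal(rng.normal(size=(2, 200)), FS, 200 / FS)
        w = rng.normal(scale=50.0, size=8)
        ev = eb.ArtefactEvent(onset=100 / FS, template=self._template(w),
                              channel_mask=np.asarray([True, True]))
        out = eb.inject(sig, ev).traces.copy()
        out[:, 99] -= w[0] / 2.0
        out[:, 100:108] -= w
        out[:, 108] -= w[-1] / 2.0
        assert np.allclose(out, sig.traces)

    def test_out_of_bounds_rejected(self):
        sig = eb.RenderedSignal.zeros(1, FS, 0.001)
        ev = eb.ArtefactEvent(onset=18 / FS, template=self._template([-1.0] * 8),
                              channel_mask=np.asarray([True]))
        with pytest.raises(ValidationError):
            eb.inject(sig, ev)


class TestDetection:
    def _planted(self, k, spread=0.0, seed=0, n_events=1, gap=0.005):
        events = [
            eb.PlantSpec(onset=0.05 + i * gap, channels=tuple(range(k)), spread=spread)
            for i in range(n_events)
        ]
        return eb.make_planted(20, FS, 0.2, events, seed=seed)

    def test_eighty_percent_coincidence_detected(self):
        rec = self._planted(16, spread=250e-6)
        events = eb.detect(rec.signal, eb.DetectionRule(thresholds=60.0))
        assert len(events) == 1
        assert events[0].channel_mask.sum() >= 16

    def test_below_fraction_not_detected(self):
        rec = self._planted(15, spread=250e-6)
        assert eb.detect(rec.signal, eb.DetectionRule(thresholds=60.0)) == []

    def test_spread_beyond_window_not_detected(self):
        # crossings on 16 channels but spread over 1 ms exceeds the 300 us gap
        rec = self._planted(16, spread=1e-3, seed=3)
        assert eb.detect(rec.signal, eb.DetectionRule(thresholds=60.0)) == []

    def test_recall_on_injected_shocks(self):
        sig = eb.RenderedSignal.zeros(20, FS, 10.0)
        tmpls = [eb.gen_shock(fs=FS, seed=s) for s in range(10)]
        footprints = [(len(t.waveform) + 2) / FS for t in tmpls]
        onsets = eb.schedule(10, 10.0, footprints, seed=0)
        for t, o in zip(tmpls, onsets):
            sig = eb.inject(sig, eb.ArtefactEvent(onset=o + 1 / FS, template=t,
                                                  channel_mask=np.ones(20, bool)))
        thr = 0.5 * min(np.abs(t.waveform).max() for t in tmpls)
        events = eb.detect(sig, eb.DetectionRule(thresholds=thr))
        # 100% recall: every injected shock is covered by >= 1 detection
        found = np.asarray([e.onset for e in events])
        for t, o in zip(tmpls, onsets):
            assert np.any((found >= o - 300e-6) & (found <= o + t.duration))

    def test_no_false_positives_on_clean_render(self, awake_dataset):
        x = awake_dataset.components["x"]
        sig = eb.RenderedSignal(x, awake_dataset.sampling_rate, awake_dataset.duration)
        thr = 6.0 * x.std(axis=1)
        assert eb.detect(sig, eb.DetectionRule(thresholds=thr)) == []

    def test_empty_signal_empty_result(self):
        sig = eb.RenderedSignal(np.zeros((4, 0)), FS, 0.0)
        assert eb.detect(sig, eb.DetectionRule(thresholds=10.0)) == []


class TestLibraryIO:
    def test_npz_round_trip(self, tmp_path):
        tmpls = [eb.gen_shock(fs=FS, seed=0),
                 eb.gen_mastication(fs=FS, seed=1),
                 eb.gen_grooming(eb.GroomingParams(duration_range=(0.4, 1.0)), FS, seed=2)]
        p = str(tmp_path / "lib.npz")
        eb.save_library(p, tmpls)
        back = eb.load_library(p)
        assert [t.cls for t in back] == [t.cls for t in tmpls]
        for a, b in zip(tmpls, back):
            assert np.array_equal(a.waveform, b.waveform)
        assert np.allclose(back[1].annotations["burst_onsets"],
                           tmpls[1].annotations["burst_onsets"])
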