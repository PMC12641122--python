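import numpy as np
import pytest

from lfpei.events import (
    EventType,
    build_catalog,
    detect_swd,
    event_rate,
    isi_histogram,
    neo,
    neo_detect,
    classify_isolated,
    EventCatalog,
    SpikeEvent,
)
from lfpei.signal import ChannelMeta, Recording
from lfpei.synth import (
    GiantSpikeSpec,
    IsolatedSpikeSpec,
    SWDSpec,
    inject_events,
)

from conftest import FIVE_CHANNELS, make_pink_recording


class TestNeo:
    def test_pure_tone_energy_is_flat(self):
        fs = 1000.0
        t = np.arange(0, 2, 1 / fs)
        psi = neo(np.sin(2 * np.pi * 25 * t))
        mid = psi[100:-100]
        assert mid.max() / mid.min() < 1.05

    def test_delta_impulse_peak_is_height_squared(self):
        x = np.zeros(101)
        x[50] = 3.0
        psi = neo(x)
        assert psi[50] == pytest.approx(9.0)

    def test_linear_ramp_gives_unit_energy(self):
        psi = neo(np.arange(100, dtype=float))
        assert np.allclose(psi[1:-1], 1.0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            neo(np.array([1.0, 2.0]))


class TestNeoDetect:
    def test_zero_signal_no_candidates(self):
        assert neo_detect(np.zeros(10_000), 1000.0) == []

    def test_threshold_monotonicity(self):
        rec = make_pink_recording(seed=3, duration_s=120.0)
        x = rec.get("HC_L")
        inject_events(rec, isolated=[IsolatedSpikeSpec("HC_L", [20.0, 60.0, 100.0], 9.0)])
        n_lo = len(neo_detect(rec.get("HC_L"), rec.fs, k_thresh=8))
        n_hi = len(neo_detect(rec.get("HC_L"), rec.fs, k_thresh=16))
        assert n_hi <= n_lo

    def test_amplitude_rescaling_invariance(self):
        rec = make_pink_recording(seed=4, duration_s=120.0)
        inject_events(rec, isolated=[IsolatedSpikeSpec("HC_L", [30.0, 70.0], 10.0)])
        x = rec.get("HC_L")
        t1 = [round(e.time_s, 3) for e in neo_detect(x, rec.fs)]
        t2 = [round(e.time_s, 3) for e in neo_detect(500.0 * x, rec.fs)]
        assert t1 == t2


class TestSWD:
    def _pfc_recording(self, seed=5):
        return make_pink_recording(seed=seed, duration_s=300.0)

    def test_valid_train_detected_with_cycle_count(self):
        rec = self._pfc_recording()
        inject_events(rec, swds=[SWDSpec("PFC1", 100.0, 7.0, 8, 3.0)])
        eps = detect_swd(rec.get("PFC1"), rec.fs)
        assert len(eps) == 1
        ep = eps[0]
        assert ep.n_cycles == 8
        assert ep.duration_s >= 1.0
        assert ep.rate_hz >= 6.0
        assert ep.peak_to_peak_ratio > 2.0
        assert abs(ep.start_s - 100.0) < 0.3

    def test_two_cycle_burst_rejected(self):
        rec = self._pfc_recording(seed=6)
        inject_events(rec, swds=[SWDSpec("PFC1", 100.0, 7.0, 2, 3.0)])
        assert detect_swd(rec.get("PFC1"), rec.fs) == []

    def test_slow_train_rejected(self):
        rec = self._pfc_recording(seed=7)
        inject_events(rec, swds=[SWDSpec("PFC1", 100.0, 5.0, 8, 3.0)])
        eps = detect_swd(rec.get("PFC1"), rec.fs)
        assert all(ep.rate_hz >= 6.0 for ep in eps)
        assert not any(abs(ep.start_s - 100.0) < 1.0 and ep.n_cycles >= 8 for ep in eps)

    def test_swd_template_duration_rule(self):
        # 8 cycles at 7 Hz last 8/7 s >= the 1 s minimum by construction
        assert 8 / 7 >= 1.0

    def test_nearby_episodes_merged(self):
        rec = self._pfc_recording(seed=8)
        inject_events(rec, swds=[SWDSpec("PFC1", 100.0, 7.0, 8, 3.0),
                                 SWDSpec("PFC1", 101.8, 7.0, 8, 3.0)])
        eps = [e for e in detect_swd(rec.get("PFC1"), rec.fs)
               if 99 < e.start_s < 104]
        assert len(eps) == 1 and eps[0].n_cycles >= 14


class TestGiant:
    def test_injected_giant_classified(self):
        rec = make_pink_recording(seed=9)
        inject_events(rec, giants=GiantSpikeSpec([200.0, 320.0]))
        cat = build_catalog(rec)
        giants = cat.of_type(EventType.giant)
        assert sum(abs(g.time_s - t) < 0.05 for t in (200.0, 320.0)
                   for g in giants) == 2

    def test_event_missing_on_one_channel_not_giant(self):
        rec = make_pink_recording(seed=10)
        # inject the multi-channel giant, then erase it from one PTC channel
        before = rec.get("PTC_R").copy()
        inject_events(rec, giants=GiantSpikeSpec([200.0]))
        i = rec.channel_index("PTC_R")
        rec.data[i] = before
        cat = build_catalog(rec)
        assert not any(abs(g.time_s - 200.0) < 0.05
                       for g in cat.of_type(EventType.giant))

    def test_missing_positive_tail_not_giant(self):
        rec = make_pink_recording(seed=11)
        inject_events(rec, giants=GiantSpikeSpec([200.0]))
        # cancel the after-hyperpolarization on one channel
        fs = rec.fs
        i = rec.channel_index("PTC_L")
        sl = slice(int(200.05 * fs), int(200.45 * fs))
        rec.data[i, sl] -= rec.data[i, sl].mean() * 2
        cat = build_catalog(rec)
        assert not any(abs(g.time_s - 200.0) < 0.05
                       for g in cat.of_type(EventType.giant))


class TestIsolated:
    def _cands(self, **overrides):
        base = dict(time_s=10.0, channel="HC_L", polarity="negative",
                    width_ms=60.0, amplitude_sd=-9.0, type=EventType.candidate)
        base.update(overrides)
        return SpikeEvent(**base)

    META = {c.name: c for c in FIVE_CHANNELS}

    def test_lone_brief_negative_spike_is_isolated(self):
        cands = {"HC_L": [self._cands()], "HC_R": []}
        out = classify_isolated(cands, self.META)
        assert len(out) == 1 and out[0].type is EventType.isolated_hc

    def test_contralateral_partner_vetoes_both(self):
        cands = {"HC_L": [self._cands()],
                 "HC_R": [self._cands(time_s=10.05, channel="HC_R")]}
        out = classify_isolated(cands, self.META)
        assert out == []

    def test_wide_spike_rejected(self):
        cands = {"HC_L": [self._cands(width_ms=120.0)], "HC_R": []}
        assert classify_isolated(cands, self.META) == []

    def test_positive_spike_rejected(self):
        cands = {"HC_L": [self._cands(polarity="positive", amplitude_sd=9.0)],
                 "HC_R": []}
        assert classify_isolated(cands, self.META) == []

    def test_cortical_channels_use_same_rule(self):
        cands = {"PTC_L": [self._cands(channel="PTC_L")], "PTC_R": []}
        out = classify_isolated(cands, self.META)
        assert len(out) == 1 and out[0].type is EventType.isolated_ctx


class TestCatalogBookkeeping:
    def test_type_partition_complete(self):
        rec = make_pink_recording(seed=12)
        inject_events(rec,
                      isolated=[IsolatedSpikeSpec("HC_L", list(np.arange(20, 200, 20.0)), 10.0)],
                      giants=GiantSpikeSpec([300.0]))
        cat = build_catalog(rec)
        assert all(e.type is not EventType.candidate for e in cat.events)

    def test_event_rate_examples(self):
        events = [SpikeEvent(t, "HC_L", "negative", 50.0, -10.0, EventType.isolated_hc)
                  for t in np.linspace(10, 590, 12)]
        cat = EventCatalog(events, [], 600.0)
        assert event_rate(cat, EventType.isolated_hc) == pytest.approx(0.02)
        assert event_rate(cat, EventType.giant) == 0.0
        with pytest.raises(ValueError):
            event_rate(EventCatalog([], [], 0.0), EventType.giant)

    def test_rate_additivity_under_concatenation(self):
        ev1 = [SpikeEvent(t, "x", "negative", 50.0, -10.0, EventType.isolated_hc)
               for t in (1.0, 2.0)]
        ev2 = [SpikeEvent(t, "x", "negative", 50.0, -10.0, EventType.isolated_hc)
               for t in (1.0,)]
        merged = EventCatalog(ev1 + ev2, [], 300.0 + 100.0)
        assert event_rate(merged, EventType.isolated_hc) == pytest.approx(3 / 400)


class TestISIHistogram:
    def test_unit_intervals_fall_in_one_bin(self):
        h = isi_histogram(np.array([0.0, 1.0, 2.0, 3.0]))
        assert h.counts.sum() == 3
        assert (h.counts > 0).sum() == 1
        j = int(np.argmax(h.counts))
        assert h.bin_edges_s[j] <= 1.0 < h.bin_edges_s[j + 1]

    def test_count_conservation_any_input(self):
        rng = np.random.default_rng(13)
        times = np.cumsum(rng.exponential(5.0, 200))
        h = isi_histogram(times)
        assert h.counts.sum() == 199

    def test_out_of_range_intervals_clamped(self):
        h = isi_histogram(np.array([0.0, 0.001, 500.0]), range_s=(0.05, 200.0))
        assert h.counts.sum() == 2
        assert h.counts[0] == 1 and h.counts[-1] == 1

    def test_poisson_intervals_recover_mean(self):
        rng = np.random.default_rng(14)
        lam = 0.05
        means = []
        for _ in range(10):
            times = np.cumsum(rng.exponential(1 / lam, 400))
            h = isi_histogram(times, n_bins=40, range_s=(0.05, 500.0))
            centers = np.sqrt(h.bin_edges_s[:-1] * h.bin_edges_s[1:])
            means.append(np.sum(centers * h.counts) / h.counts.sum())
        assert np.mean(means) == pytest.approx(1 / lam, rel=0.2)

    def test_single_event_empty_histogram(self):
        h = isi_histogram(np.array([1.0]))
        assert h.counts.sum() == 0
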