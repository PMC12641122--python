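import numpy as np
import pytest
from scipy.signal import hilbert

from lfpei.bands import Band
from lfpei.pac import (
    Comodulogram,
    InsufficientDataError,
    amp_grid_bands,
    band_average,
    comodulogram,
    modulation_index,
    monthly_pac,
    phase_grid_bands,
    summarize,
)
from lfpei.signal import ChannelMeta, Recording, VigilanceTrack, bandpass
from lfpei.synth import gen_pac_signal


def brute_force_mi(phase, amplitude, n_bins=18):
    """Two-pass naive binning implementation."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (phase >= lo) & (phase < hi)
        if not sel.any():
            raise ValueError("empty bin")
        means.append(amplitude[sel].mean())
    p = np.array(means) / np.sum(means)
    kl = np.log(n_bins) + np.sum(p[p > 0] * np.log(p[p > 0]))
    return kl / np.log(n_bins)


def extract_phase_amp(x, fs, f_phase, f_amp, trim=3000):
    """Sharp filters (12 cycles of the low edge) so the modulator's
    sidebands at f_amp +- f_phase survive intact."""
    ph = np.angle(hilbert(bandpass(x, fs, Band(f_phase - 2, f_phase + 2), min_cycles=12)))
    am = np.abs(hilbert(bandpass(x, fs, Band(f_amp - 20, f_amp + 20), min_cycles=12)))
    return ph[trim:-trim], am[trim:-trim]


class TestModulationIndex:
    def test_uniform_amplitude_gives_zero(self):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, 60_000)
        mi = modulation_index(phase, np.ones_like(phase))
        assert mi == pytest.approx(0.0, abs=1e-12)

    def test_phase_independent_amplitude_near_zero(self):
        rng = np.random.default_rng(1)
        phase = rng.uniform(-np.pi, np.pi, 60_000)
        amp = rng.gamma(2.0, 1.0, phase.size)
        assert modulation_index(phase, amp) < 1e-3

    def test_single_bin_mass_gives_exactly_one(self):
        rng = np.random.default_rng(2)
        phase = rng.uniform(-np.pi, np.pi, 10_000)
        amp = np.where((phase >= 0) & (phase < np.pi / 9), 1.0, 0.0)
        assert modulation_index(phase, amp) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_binning(self):
        rng = np.random.default_rng(3)
        phase = rng.uniform(-np.pi, np.pi, 30_000)
        amp = 1 + 0.7 * np.cos(phase) + 0.05 * rng.standard_normal(phase.size)
        amp = np.abs(amp)
        assert modulation_index(phase, amp) == pytest.approx(
            brute_force_mi(phase, amp), abs=1e-12)

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(4)
        phase = rng.uniform(-np.pi, np.pi, 30_000)
        amp = np.abs(1 + 0.5 * np.cos(phase))
        assert modulation_index(phase, 1e4 * amp) == pytest.approx(
            modulation_index(phase, amp), abs=1e-12)

    def test_bin_width_phase_rotation_invariance(self):
        rng = np.random.default_rng(5)
        phase = rng.uniform(-np.pi, np.pi, 60_000)
        amp = np.abs(1 + 0.6 * np.cos(phase))
        rot = np.angle(np.exp(1j * (phase + 2 * np.pi / 18)))
        assert modulation_index(rot, amp) == pytest.approx(
            modulation_index(phase, amp), abs=1e-12)

    def test_empty_bin_raises(self):
        phase = np.linspace(0, np.pi / 2, 1000)  # covers a quarter turn only
        with pytest.raises(InsufficientDataError):
            modulation_index(phase, np.ones_like(phase))

    def test_mi_bounded_unit_interval(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            phase = rng.uniform(-np.pi, np.pi, 5000)
            amp = rng.gamma(rng.uniform(0.5, 5), 1.0, 5000)
            assert 0.0 <= modulation_index(phase, amp) <= 1.0


class TestPacRecovery:
    def test_uncoupled_signal_has_negligible_mi(self):
        x, _ = gen_pac_signal(6, 60, 0.0, 60, fs=1000.0, noise_sd=0.1, seed=0)
        ph, am = extract_phase_amp(x, 1000.0, 6, 60)
        assert modulation_index(ph, am) < 0.01

    def test_full_depth_matches_closed_form_modulator_oracle(self):
        x, gt = gen_pac_signal(6, 60, 1.0, 60, fs=1000.0, noise_sd=0.0, seed=7)
        ph, am = extract_phase_amp(x, 1000.0, 6, 60)
        mi = modulation_index(ph, am)
        trim = slice(3000, -3000)
        mi_oracle = modulation_index(gt["phase"][trim], gt["modulator"][trim])
        assert mi == pytest.approx(mi_oracle, abs=1e-3)

    def test_mi_strictly_increasing_in_chi(self):
        mis = []
        for chi in (0.0, 0.3, 0.6, 0.9):
            x, _ = gen_pac_signal(6, 60, chi, 60, fs=1000.0, noise_sd=0.05, seed=7)
            ph, am = extract_phase_amp(x, 1000.0, 6, 60)
            mis.append(modulation_index(ph, am))
        assert mis == sorted(mis) and len(set(mis)) == 4


class TestComodulogram:
    def test_cortical_grid_dimensions(self):
        phases = phase_grid_bands()
        amps = amp_grid_bands("PTC", fs=1000.0)
        assert [b.center for b in phases] == list(range(2, 15))
        assert len(amps) == 161 and amps[0].center == 40 and amps[-1].center == 200

    def test_hippocampal_grid_step_and_truncation(self):
        amps = amp_grid_bands("HC", fs=1000.0)
        centers = [b.center for b in amps]
        assert centers[0] == 40 and centers[1] == 42 and centers[-1] == 300
        truncated = amp_grid_bands("HC", fs=500.0)
        assert max(b.hi for b in truncated) < 250.0

    def test_coupling_localized_at_injected_frequencies(self):
        x, _ = gen_pac_signal(6, 60, 0.8, 90, fs=500.0, noise_sd=0.05, seed=1)
        com = comodulogram(
            x, 500.0,
            phase_bands=phase_grid_bands(4, 10, 2, 2),
            amp_bands=amp_grid_bands("PTC", fs=500.0, lo_c=45, hi_c=155, step=10, bw=10),
            region="PTC",
        )
        s = summarize(com, "PTC")
        assert s.theta_low_gamma > s.theta_high_gamma
        assert s.theta_total_gamma is None  # cortical channels skip total gamma
        i, j = np.unravel_index(np.nanargmax(com.mi), com.mi.shape)
        assert abs(com.phase_centers[i] - 6) <= 1
        assert abs(com.amp_centers[j] - 60) <= 10

    def test_uncoupled_grid_stays_below_threshold(self):
        x, _ = gen_pac_signal(6, 60, 0.0, 90, fs=500.0, noise_sd=0.05, seed=2)
        com = comodulogram(
            x, 500.0,
            phase_bands=phase_grid_bands(4, 10, 2, 2),
            amp_bands=amp_grid_bands("PTC", fs=500.0, lo_c=45, hi_c=95, step=10, bw=10),
            region="PTC",
        )
        assert np.nanmax(com.mi) < 0.01

    def test_band_average_of_constant_matrix_is_identity(self):
        com = Comodulogram(np.array([4.0, 6.0, 8.0]), np.array([50.0, 70.0]),
                           np.full((3, 2), 0.42))
        assert band_average(com, (4, 10), (40, 90)) == pytest.approx(0.42)
        with pytest.raises(ValueError):
            band_average(com, (20, 30), (40, 90))


class TestMonthlyPac:
    def _weekly(self, minutes, chi, seed, fs=500.0):
        duration = minutes * 60
        x, _ = gen_pac_signal(6, 60, chi, duration, fs=fs, noise_sd=0.05, seed=seed)
        rec = Recording(x[None, :], fs, [ChannelMeta("PTC_L", "PTC", None, "left")])
        ann = VigilanceTrack(["active_wake"] * int(duration // 5))
        return rec, ann

    def test_truncation_to_target_minutes(self):
        weekly = [self._weekly(3, 0.5, s) for s in range(4)]
        out = monthly_pac(weekly, "PTC_L", "PTC", target_minutes=10,
                          phase_bands=phase_grid_bands(4, 8, 2, 2),
                          amp_bands=[Band(50, 70, "60 Hz")])
        assert out.minutes_used == pytest.approx(10.0, abs=0.01)
        assert not out.shortfall

    def test_shortfall_flagged(self):
        weekly = [self._weekly(4, 0.5, 0)]
        out = monthly_pac(weekly, "PTC_L", "PTC", target_minutes=10,
                          phase_bands=phase_grid_bands(4, 8, 2, 2),
                          amp_bands=[Band(50, 70, "60 Hz")])
        assert out.shortfall and out.minutes_used == pytest.approx(4.0, abs=0.01)

    def test_monthly_mi_between_weekly_extremes(self):
        weekly = [self._weekly(3, chi, s) for s, chi in enumerate((0.9, 0.6, 0.3, 0.1))]
        pb = phase_grid_bands(5, 7, 2, 2)
        ab = [Band(50, 70, "60 Hz")]
        monthly = monthly_pac(weekly, "PTC_L", "PTC", target_minutes=12,
                              phase_bands=pb, amp_bands=ab)
        singles = [monthly_pac([w], "PTC_L", "PTC", target_minutes=3,
                               phase_bands=pb, amp_bands=ab).comodulogram.mi.max()
                   for w in weekly]
        m = monthly.comodulogram.mi.max()
        assert min(singles) <= m <= max(singles)

    def test_no_active_wake_is_excluded(self):
        rec, _ = self._weekly(2, 0.5, 0)
        ann = VigilanceTrack(["sleep"] * 24)
        out = monthly_pac([(rec, ann)], "PTC_L", "PTC")
        assert out.excluded
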