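"""Channel-relation and level oracles for every stimulus class."""

import numpy as np
import pytest
from scipy.signal import butter, filtfilt, hilbert

from hearlab.stimuli import (
    CHIRP_DIRECTIONS,
    CALIBRATION_TASKS,
    BmldChirpParams,
    CmrCondition,
    CmrParams,
    F0dlParams,
    GapParams,
    ToneSpec,
    erb_bandwidth,
    harmonic_complex,
    make_calibration_sound,
    synth_antiphase_triad,
    synth_bmld_chirp_trial,
    synth_cmr_trial,
    synth_f0dl_interval,
    synth_gap_trial,
    synth_ild_pair,
    synth_itd_pair,
)
from hearlab.waveform import Waveform, amp_to_db, rms


def db_ratio(a, b):
    return amp_to_db(rms(a)) - amp_to_db(rms(b))


def slow_envelope(x, sr, band=(5.0, 15.0)):
    """Hilbert envelope band-passed around the 10-Hz modulation rate."""
    env = np.abs(hilbert(x))
    b, a = butter(2, [band[0] / (sr / 2), band[1] / (sr / 2)], btype="band")
    return filtfilt(b, a, env)


# ---------------------------------------------------------------------------
# ERB
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "freq,expected",
    [(0.0, 24.7), (1000.0, 24.7 * (4.37 + 1)), (4000.0, 24.7 * (4.37 * 4 + 1))],
)
def test_erb_bandwidth_formula(freq, expected):
    assert erb_bandwidth(freq) == pytest.approx(expected, rel=1e-9)


def test_erb_rejects_negative_frequency():
    with pytest.raises(ValueError):
        erb_bandwidth(-1.0)


# ---------------------------------------------------------------------------
# Antiphase loudness triad
# ---------------------------------------------------------------------------


class TestAntiphaseTriad:
    def test_antiphase_foil_cancels_when_summed(self, fast_tone):
        waves, ans = synth_antiphase_triad(fast_tone, target_position=2)
        foil = waves[ans["antiphase_position"] - 1]
        mono_sum = foil.samples.sum(axis=1)
        assert db_ratio(mono_sum, foil.channel(0)) < -60

    def test_target_is_6db_below_each_foil_per_channel(self, fast_tone):
        waves, ans = synth_antiphase_triad(fast_tone, target_position=1)
        target = waves[0]
        for pos in (2, 3):
            for ch in range(2):
                diff = target.rms_db[ch] - waves[pos - 1].rms_db[ch]
                assert diff == pytest.approx(-6.0, abs=0.01)

    def test_target_softest_in_single_channel_playback(self, fast_tone):
        # the documented mono blind spot: per-channel the target still wins
        waves, ans = synth_antiphase_triad(fast_tone, target_position=3)
        for ch in range(2):
            levels = [rms(w.channel(ch)) for w in waves]
            assert int(np.argmin(levels)) + 1 == ans["target_position"]

    def test_exactly_one_foil_is_antiphase(self, fast_tone):
        waves, ans = synth_antiphase_triad(fast_tone, target_position=2)
        flipped = [
            i + 1
            for i, w in enumerate(waves)
            if np.allclose(w.channel(1), -w.channel(0)) and rms(w.channel(0)) > 0
        ]
        assert flipped == [ans["antiphase_position"]]
        assert ans["antiphase_position"] != ans["target_position"]

    def test_mono_request_rejected(self, fast_tone):
        with pytest.raises(ValueError):
            synth_antiphase_triad(fast_tone, target_position=1, n_channels=1)


# ---------------------------------------------------------------------------
# BMLD chirp (N0Spi)
# ---------------------------------------------------------------------------


class TestBmldChirp:
    def test_difference_channel_isolates_chirp(self, fast_bmld):
        wave, _, parts = synth_bmld_chirp_trial("rising", params=fast_bmld, return_components=True)
        recovered = (wave.channel(0) - wave.channel(1)) / 2
        c = parts["chirp"]
        corr = np.corrcoef(recovered, c)[0, 1]
        assert corr > 0.999

    def test_sum_channel_isolates_noise(self, fast_bmld):
        wave, _, parts = synth_bmld_chirp_trial("falling", params=fast_bmld, return_components=True)
        recovered = (wave.channel(0) + wave.channel(1)) / 2
        residual = recovered - parts["noise"]
        assert db_ratio(residual, parts["chirp"]) < -60

    def test_flat_trial_frequency_constant(self, fast_bmld):
        _, _, parts = synth_bmld_chirp_trial("flat", params=fast_bmld, return_components=True)
        sr = fast_bmld.sample_rate
        analytic = hilbert(parts["chirp"])
        inst = np.diff(np.unwrap(np.angle(analytic))) * sr / (2 * np.pi)
        mid = inst[len(inst) // 4 : -len(inst) // 4]
        assert np.std(mid) / np.mean(mid) < 0.01

    def test_invalid_direction_rejected(self, fast_bmld):
        with pytest.raises(ValueError):
            synth_bmld_chirp_trial("sideways", params=fast_bmld)

    def test_default_snr_from_params(self, fast_bmld):
        _, ans = synth_bmld_chirp_trial("rising", params=fast_bmld)
        assert ans["snr_db"] == fast_bmld.snr_db


# ---------------------------------------------------------------------------
# F0 discrimination intervals
# ---------------------------------------------------------------------------


def estimate_f0(segment, sr, f0_nominal, harmonic=10):
    """F0 via the frequency of a high harmonic (zero-padded FFT peak)."""
    n = len(segment)
    spec = np.abs(np.fft.rfft(segment * np.hanning(n), 16 * n))
    freqs = np.fft.rfftfreq(16 * n, 1 / sr)
    lo, hi = (harmonic - 0.5) * f0_nominal, (harmonic + 0.5) * f0_nominal
    band = (freqs > lo) & (freqs < hi)
    return freqs[band][np.argmax(spec[band])] / harmonic


class TestF0dlInterval:
    def _tone_slices(self, p):
        n_tone = int(round(p.tone_duration * p.sample_rate))
        n_gap = int(round(p.inter_tone_interval * p.sample_rate))
        return [slice(i * (n_tone + n_gap), i * (n_tone + n_gap) + n_tone) for i in range(4)]

    def test_foil_tones_all_at_base_f0(self, fast_f0dl):
        wave = synth_f0dl_interval(3.2, is_target=False, params=fast_f0dl)
        for sl in self._tone_slices(fast_f0dl):
            f0 = estimate_f0(wave.channel(0)[sl], fast_f0dl.sample_rate, 110.0)
            assert f0 == pytest.approx(110.0, abs=0.2)

    def test_zero_shift_target_equals_foil(self, fast_f0dl):
        a = synth_f0dl_interval(0.0, is_target=True, params=fast_f0dl)
        b = synth_f0dl_interval(0.0, is_target=False, params=fast_f0dl)
        assert np.array_equal(a.samples, b.samples)

    def test_target_shift_split_symmetrically(self, fast_f0dl):
        wave = synth_f0dl_interval(3.2, is_target=True, params=fast_f0dl)
        slices = self._tone_slices(fast_f0dl)
        f0s = [estimate_f0(wave.channel(0)[sl], fast_f0dl.sample_rate, 110.0) for sl in slices]
        assert f0s[0] == pytest.approx(111.6, abs=0.2)  # tone 1 shifted up
        assert f0s[2] == pytest.approx(108.4, abs=0.2)  # tone 3 shifted down
        assert f0s[1] == pytest.approx(110.0, abs=0.2)
        assert f0s[3] == pytest.approx(110.0, abs=0.2)

    def test_excessive_shift_rejected(self, fast_f0dl):
        with pytest.raises(ValueError):
            synth_f0dl_interval(2 * 110.0 + 1, is_target=True, params=fast_f0dl)

    def test_interval_is_diotic(self, fast_f0dl):
        wave = synth_f0dl_interval(1.0, is_target=True, params=fast_f0dl)
        assert np.array_equal(wave.channel(0), wave.channel(1))


# ---------------------------------------------------------------------------
# Gap detection
# ---------------------------------------------------------------------------


class TestGapTrial:
    def test_duration_is_additive_in_gap(self, fast_gap):
        sr = fast_gap.sample_rate
        for gap_ms in (0.0, 8.0, 32.0):
            wave = synth_gap_trial(gap_ms, fast_gap)
            expected = 0.05 + 0.125 + gap_ms / 1000 + 0.125 + 0.05
            assert wave.duration == pytest.approx(expected, abs=1.5 / sr)

    def test_noise_power_confined_to_band(self, fast_gap):
        _, parts = synth_gap_trial(8.0, fast_gap, return_components=True)
        sr = fast_gap.sample_rate
        spec = np.abs(np.fft.rfft(parts["noise"])) ** 2
        freqs = np.fft.rfftfreq(len(parts["noise"]), 1 / sr)
        band = (freqs >= 4000 * 2**-0.5) & (freqs <= 4000 * 2**0.5)
        assert spec[band].sum() / spec.sum() >= 0.99

    def test_tone_to_noise_ratio_is_10db(self, fast_gap):
        _, parts = synth_gap_trial(4.0, fast_gap, return_components=True)
        sr = fast_gap.sample_rate
        # steady portion of the first marker vs steady noise
        m0 = int(round(0.05 * sr)) + int(round(0.002 * sr))
        m1 = int(round(0.05 * sr)) + int(round(0.123 * sr))
        tone_rms = rms(parts["tone"][m0:m1])
        noise_rms = rms(parts["noise"][int(0.02 * sr) : -int(0.02 * sr)])
        assert amp_to_db(tone_rms) - amp_to_db(noise_rms) == pytest.approx(10.0, abs=0.3)

    def test_noise_is_continuous_through_gap(self, fast_gap):
        _, parts = synth_gap_trial(32.0, fast_gap, return_components=True)
        sr = fast_gap.sample_rate
        gap_start = int(round((0.05 + 0.125) * sr))
        gap_slice = parts["noise"][gap_start : gap_start + int(0.03 * sr)]
        assert rms(gap_slice) > 0.25 * rms(parts["noise"])

    def test_negative_gap_rejected(self, fast_gap):
        with pytest.raises(ValueError):
            synth_gap_trial(-1.0, fast_gap)


# ---------------------------------------------------------------------------
# ITD / ILD pairs
# ---------------------------------------------------------------------------


def xcorr_lag(left, right, sr, max_lag_s=5e-4):
    """Interaural lag of the cross-correlation peak, parabolic interpolation."""
    max_lag = int(round(max_lag_s * sr))
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.array([np.dot(left[max_lag:-max_lag], np.roll(right, k)[max_lag:-max_lag]) for k in lags])
    i = int(np.argmax(cc))
    if 0 < i < len(cc) - 1:
        denom = cc[i - 1] - 2 * cc[i] + cc[i + 1]
        i = i + 0.5 * (cc[i - 1] - cc[i + 1]) / denom if denom else i
    return (i - max_lag) / sr


class TestItdPair:
    def test_zero_itd_channels_identical(self, fast_itd):
        wave, _ = synth_itd_pair(0.0, "LR", fast_itd)
        assert np.array_equal(wave.channel(0), wave.channel(1))

    def test_carrier_phase_matches_formula(self, fast_itd):
        # 128 us at 500 Hz -> 2*pi*500*128e-6 = 0.402 rad
        wave, _ = synth_itd_pair(128.0, "LR", fast_itd)
        sr = fast_itd.sample_rate
        n = int(round(fast_itd.duration * sr))
        t = np.arange(n) / sr
        probe = np.exp(-2j * np.pi * 500.0 * t)
        seg = slice(int(0.05 * sr), int(0.25 * sr))
        phase = np.angle(np.vdot(probe[seg], wave.channel(0)[seg])) - np.angle(
            np.vdot(probe[seg], wave.channel(1)[seg])
        )
        assert abs(phase) == pytest.approx(2 * np.pi * 500 * 128e-6, abs=0.005)

    def test_lag_sign_flips_between_intervals(self, fast_itd):
        wave, _ = synth_itd_pair(128.0, "LR", fast_itd)
        sr = fast_itd.sample_rate
        n = int(round(fast_itd.duration * sr))
        gap = int(round(fast_itd.inter_stimulus_interval * sr))
        first = slice(0, n)
        second = slice(n + gap, 2 * n + gap)
        lag1 = xcorr_lag(wave.channel(0)[first], wave.channel(1)[first], sr)
        lag2 = xcorr_lag(wave.channel(0)[second], wave.channel(1)[second], sr)
        half_sample = 0.5 / sr
        assert abs(abs(lag1) - 128e-6) < half_sample
        assert abs(abs(lag2) - 128e-6) < half_sample
        assert np.sign(lag1) == -np.sign(lag2)

    def test_itd_beyond_pi_phase_rejected(self, fast_itd):
        with pytest.raises(ValueError):
            synth_itd_pair(1100.0, "LR", fast_itd)  # > half period of 500 Hz


class TestIldPair:
    def test_zero_ild_equal_rms(self, fast_ild):
        wave, _ = synth_ild_pair(0.0, "LR", fast_ild)
        assert wave.rms_db[0] == pytest.approx(wave.rms_db[1], abs=1e-9)

    def test_rms_ratio_matches_nominal_ild(self, fast_ild):
        wave, _ = synth_ild_pair(0.8, "LR", fast_ild)
        sr = fast_ild.sample_rate
        n = int(round(fast_ild.duration * sr))
        first = slice(0, n)
        ratio = rms(wave.channel(0)[first]) / rms(wave.channel(1)[first])
        assert ratio == pytest.approx(10 ** (0.8 / 20), rel=1e-6)

    def test_mean_level_preserved_within_interval(self, fast_ild):
        ref, _ = synth_ild_pair(0.0, "LR", fast_ild)
        wave, _ = synth_ild_pair(4.0, "LR", fast_ild)
        sr = fast_ild.sample_rate
        first = slice(0, int(round(fast_ild.duration * sr)))
        mean_db = np.mean(
            [amp_to_db(rms(wave.channel(ch)[first])) for ch in range(2)]
        )
        nominal = amp_to_db(rms(ref.channel(0)[first]))
        assert mean_db == pytest.approx(nominal, abs=0.01)

    def test_louder_ear_swaps_between_intervals(self, fast_ild):
        wave, _ = synth_ild_pair(4.0, "RL", fast_ild)
        sr = fast_ild.sample_rate
        n = int(round(fast_ild.duration * sr))
        gap = int(round(fast_ild.inter_stimulus_interval * sr))
        first, second = slice(0, n), slice(n + gap, 2 * n + gap)
        assert rms(wave.channel(1)[first]) > rms(wave.channel(0)[first])
        assert rms(wave.channel(0)[second]) > rms(wave.channel(1)[second])


# ---------------------------------------------------------------------------
# CMR
# ---------------------------------------------------------------------------


class TestCmrTrial:
    def _env_corr(self, parts, sr):
        on = slow_envelope(parts["on_band"], sr)
        out = []
        for key in ("lower_flanker", "upper_flanker"):
            fl = slow_envelope(parts[key], sr)
            trim = slice(int(0.1 * sr), -int(0.1 * sr))
            out.append(np.corrcoef(on[trim], fl[trim])[0, 1])
        return out

    def test_corr_flankers_share_the_modulator(self, fast_cmr):
        _, parts = synth_cmr_trial("CORR", -10.0, False, fast_cmr, return_components=True)
        for c in self._env_corr(parts, fast_cmr.sample_rate):
            assert c > 0.95

    def test_acorr_flankers_inverted_modulator(self, fast_cmr):
        _, parts = synth_cmr_trial("ACORR", -10.0, False, fast_cmr, return_components=True)
        for c in self._env_corr(parts, fast_cmr.sample_rate):
            assert c < -0.9

    def test_ref_has_no_energy_outside_on_band(self, fast_cmr):
        wave = synth_cmr_trial("REF", -10.0, False, fast_cmr)
        sr = fast_cmr.sample_rate
        x = wave.channel(0)
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(len(x), 1 / sr)
        erb = fast_cmr.erb
        inside = np.abs(freqs - 4000.0) <= 1.5 * erb  # on-band +/- 1 ERB margin
        out_db = 10 * np.log10(spec[~inside].sum() / spec[inside].sum())
        assert out_db < -40

    def test_tone_present_adds_4khz_line(self, fast_cmr):
        quiet = synth_cmr_trial("REF", 0.0, False, fast_cmr)
        loud = synth_cmr_trial("REF", 0.0, True, fast_cmr)
        sr = fast_cmr.sample_rate
        probe = np.exp(-2j * np.pi * 4000.0 * np.arange(quiet.n_samples) / sr)
        assert abs(np.vdot(probe, loud.channel(0))) > 3 * abs(np.vdot(probe, quiet.channel(0)))

    def test_flankers_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            synth_cmr_trial("CORR", -10.0, False, CmrParams(sample_rate=11_000))


# ---------------------------------------------------------------------------
# Calibration and global invariants
# ---------------------------------------------------------------------------


class TestCalibration:
    def test_calibration_duration_floor(self):
        cal, _ = make_calibration_sound("ild")
        assert cal.duration >= 3.0

    def test_headroom_rule_over_task_stimuli(self, fast_cmr):
        cal, ref = make_calibration_sound("cmr")
        for cond in CmrCondition:
            wave = synth_cmr_trial(cond, -10.0, True, CmrParams(seed=5))
            assert ref.admits(wave)

    def test_reproducible_under_seed(self):
        a, _ = make_calibration_sound("gap", seed=9)
        b, _ = make_calibration_sound("gap", seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_unknown_task_rejected(self):
        with pytest.raises(KeyError):
            make_calibration_sound("speech-in-quiet")

    def test_spectral_centroid_tracks_stimuli(self, fast_gap):
        cal, _ = make_calibration_sound("gap")

        def centroid(x, sr):
            spec = np.abs(np.fft.rfft(x)) ** 2
            freqs = np.fft.rfftfreq(len(x), 1 / sr)
            return np.sum(freqs * spec) / np.sum(spec)

        stim = synth_gap_trial(8.0, GapParams(seed=2))
        c_cal = centroid(cal.channel(0), cal.sample_rate)
        c_stim = centroid(stim.channel(0), stim.sample_rate)
        assert abs(np.log2(c_cal / c_stim)) < 1 / 3


def test_waveform_invariants_across_stimuli(fast_tone, fast_bmld, fast_gap, fast_cmr):
    waves = []
    triad, _ = synth_antiphase_triad(fast_tone, 1)
    waves += triad
    waves.append(synth_bmld_chirp_trial("rising", params=fast_bmld)[0])
    waves.append(synth_gap_trial(4.0, fast_gap))
    waves.append(synth_cmr_trial("ACORR", -12.0, True, fast_cmr))
    for w in waves:
        assert np.max(np.abs(w.samples)) <= 1.0
        w.validate()  # metadata within 0.01 dB of recomputed RMS


def test_synthesis_determinism(fast_bmld, fast_cmr):
    a, _ = synth_bmld_chirp_trial("rising", params=fast_bmld)
    b, _ = synth_bmld_chirp_trial("rising", params=fast_bmld)
    assert np.array_equal(a.samples, b.samples)
    c = synth_cmr_trial("CORR", -8.0, True, fast_cmr)
    d = synth_cmr_trial("CORR", -8.0, True, fast_cmr)
    assert np.array_equal(c.samples, d.samples)


def test_geometric_ladders_constant_ratio():
    from hearlab.tasks import TASK_REGISTRY

    for task, key, lo, hi in [
        ("f0dl", "delta_f0", 0.05, 3.2),
        ("gap", "gap_ms", 1.0, 32.0),
        ("itd", "itd_us", 2.0, 128.0),
    ]:
        levels = [c[key] for c in TASK_REGISTRY[task]["conditions"]]
        assert levels[0] == pytest.approx(lo)
        assert levels[-1] == pytest.approx(hi)
        ratios = np.diff(np.log(levels))
        assert np.allclose(ratios, ratios[0])
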