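"""Sample-accurate synthesis of the toolkit's psychoacoustic stimuli.

The stimuli cover the two headphone-use checks (antiphase loudness triad and
an N0Spi chirp-in-noise task exploiting the binaural masking level
difference), the four absolute-sensitivity tasks (F0 discrimination, gap
detection, ITD and ILD lateralization), and co-modulation masking release
(CMR) trials.  All levels are RMS dB re full scale; every task has a
calibration sound whose level bounds the task stimuli from above by 6 dB.

Conventions (documented in docs/methods.md):

* default sample rate 48 kHz;
* noise bands are synthesized in the frequency domain from seeded random
  phases, so identical seeds give bit-identical samples;
* ITDs for pure tones are realized as interaural carrier phase shifts
  ``phi = 2*pi*f*tau`` (exact for tones), split symmetrically across ears;
* ILDs are split as +/- ILD/2 so the across-ear mean level is preserved.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .waveform import (
    CalibrationReference,
    Waveform,
    amp_to_db,
    concatenate,
    db_to_amp,
    hann_taper,
    rms,
)

DEFAULT_SAMPLE_RATE = 48_000
#: Default stimulus level, RMS dB re full scale; leaves crest-factor headroom.
DEFAULT_LEVEL_DB = -26.0
#: Silence between intervals of a multi-interval trial, seconds.
INTER_STIMULUS_INTERVAL = 0.25


def erb_bandwidth(center_frequency: float) -> float:
    """Equivalent rectangular bandwidth of the auditory filter, in Hz.

    Uses the Glasberg & Moore formula ``24.7 * (4.37 * F_kHz + 1)``.
    """
    if center_frequency < 0:
        raise ValueError("frequency must be non-negative")
    return 24.7 * (4.37 * center_frequency / 1000.0 + 1.0)


# ---------------------------------------------------------------------------
# Parameter records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToneSpec:
    """Pure-tone (or harmonic-complex carrier) parameters."""

    frequency: float = 200.0
    duration: float = 1.0
    ramp_duration: float = 0.02
    level_db: float = DEFAULT_LEVEL_DB
    interaural_phase: float = 0.0
    itd: float = 0.0
    ild: float = 0.0
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self):
        if 2 * self.ramp_duration > self.duration:
            raise ValueError("ramps do not fit in the tone duration")


@dataclass(frozen=True)
class NoiseBandSpec:
    """Band-limited noise parameters (modulation_rate 0 means unmodulated)."""

    low_edge: float
    high_edge: float
    level_db: float = DEFAULT_LEVEL_DB
    modulation_rate: float = 0.0
    modulation_phase: float = 0.0
    seed: int = 0
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self):
        if not (0 < self.low_edge < self.high_edge < self.sample_rate / 2):
            raise ValueError("band edges must satisfy 0 < low < high < Nyquist")


class CmrCondition(str, enum.Enum):
    """Flanker configuration for a CMR trial."""

    REF = "REF"      # no flankers
    CORR = "CORR"    # flankers share the on-band modulator
    ACORR = "ACORR"  # flankers use the inverted modulator


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------


def _tone(frequency, duration, ramp, level_db, sample_rate, phase=0.0):
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.sin(2 * np.pi * frequency * t + phase)
    x *= hann_taper(n, int(round(ramp * sample_rate)))
    x *= db_to_amp(level_db) / rms(x)
    return x


def harmonic_complex(
    f0: float,
    duration: float,
    ramp: float,
    level_db: float,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    n_harmonics: int = 10,
) -> np.ndarray:
    """Equal-amplitude sine-phase harmonic complex, low-pass limited below Nyquist."""
    if f0 <= 0:
        raise ValueError("fundamental must be positive")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        if k * f0 >= sample_rate / 2:
            break
        x += np.sin(2 * np.pi * k * f0 * t)
    x *= hann_taper(n, int(round(ramp * sample_rate)))
    return x * db_to_amp(level_db) / rms(x)


def band_noise(spec: NoiseBandSpec, duration: float, rng: np.random.Generator | None = None) -> np.ndarray:
    """Gaussian noise restricted to [low_edge, high_edge), frequency-domain synthesis.

    Random phases (and Rayleigh magnitudes) come from ``rng`` or, when absent,
    from ``spec.seed`` — identical seeds give bit-identical noise.  The output
    is scaled to ``spec.level_db`` *after* any amplitude modulation.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = int(round(duration * spec.sample_rate))
    freqs = np.fft.rfftfreq(n, 1.0 / spec.sample_rate)
    in_band = (freqs >= spec.low_edge) & (freqs < spec.high_edge)
    spectrum = np.zeros(freqs.shape, dtype=complex)
    k = int(in_band.sum())
    mags = rng.rayleigh(scale=1.0, size=k)
    phases = rng.uniform(0.0, 2 * np.pi, size=k)
    spectrum[in_band] = mags * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n)
    if spec.modulation_rate > 0:
        t = np.arange(n) / spec.sample_rate
        x = x * raised_sine_modulator(t, spec.modulation_rate, spec.modulation_phase)
    x *= db_to_amp(spec.level_db) / rms(x)
    return x


def raised_sine_modulator(t: np.ndarray, rate: float, phase: float = 0.0) -> np.ndarray:
    """100%-depth raised-sine envelope in [0, 1]; zero at t=0 for phase 0."""
    return 0.5 * (1.0 - np.cos(2 * np.pi * rate * t + phase))


def _stereo(left: np.ndarray, right: np.ndarray, sample_rate: int) -> Waveform:
    return Waveform.from_samples(np.column_stack([left, right]), sample_rate)


def _diotic(x: np.ndarray, sample_rate: int) -> Waveform:
    return _stereo(x, x.copy(), sample_rate)


# ---------------------------------------------------------------------------
# Headphone-use screening stimuli
# ---------------------------------------------------------------------------


def synth_antiphase_triad(
    params: ToneSpec | None = None,
    target_position: int = 1,
    n_channels: int = 2,
):
    """Loudness-triad headphone check: three tones, target 6 dB softer.

    One foil is presented with opposite polarity in the two channels
    ("antiphase"), so that free-field playback attenuates it by acoustic
    cancellation; the target and the other foil are diotic.  Returns the
    three per-tone :class:`Waveform` objects and an answer key.  In either
    channel alone the target is still the softest tone — the documented mono
    blind spot that motivates the chirp check.
    """
    if n_channels != 2:
        raise ValueError("the antiphase triad is inherently two-channel")
    if target_position not in (1, 2, 3):
        raise ValueError("target_position must be 1, 2, or 3")
    p = params or ToneSpec()
    foils = [pos for pos in (1, 2, 3) if pos != target_position]
    antiphase_position = foils[0]
    waves = []
    for pos in (1, 2, 3):
        level = p.level_db - 6.0 if pos == target_position else p.level_db
        x = _tone(p.frequency, p.duration, p.ramp_duration, level, p.sample_rate)
        right = -x if pos == antiphase_position else x.copy()
        waves.append(_stereo(x, right, p.sample_rate))
    answer = {
        "target_position": target_position,
        "antiphase_position": antiphase_position,
        "correct_choice": str(target_position),
    }
    return waves, answer


@dataclass(frozen=True)
class BmldChirpParams:
    """N0Spi chirp-detection trial parameters.

    The noise band and the default per-channel SNR are package choices: the
    masker covers 100-500 Hz and the default SNR of -16 dB puts monaural
    detection near chance while the binaural masking level difference makes
    dichotic detection easy.
    """

    sweep_low: float = 150.0
    sweep_high: float = 400.0
    duration: float = 1.0
    ramp_duration: float = 0.02
    noise_low: float = 100.0
    noise_high: float = 500.0
    noise_level_db: float = DEFAULT_LEVEL_DB
    snr_db: float = -16.0
    sample_rate: int = DEFAULT_SAMPLE_RATE
    seed: int = 0


CHIRP_DIRECTIONS = ("rising", "falling", "flat")


def synth_bmld_chirp_trial(
    direction: str,
    snr_db: float | None = None,
    params: BmldChirpParams | None = None,
    return_components: bool = False,
):
    """One 3AFC chirp-direction trial in the N0Spi configuration.

    The noise is identical in both channels (N0); the chirp is added with
    opposite signs (Spi).  ``(L - R) / 2`` therefore reconstructs the chirp
    alone and ``(L + R) / 2`` the noise alone.
    """
    if direction not in CHIRP_DIRECTIONS:
        raise ValueError(f"direction must be one of {CHIRP_DIRECTIONS}")
    p = params or BmldChirpParams()
    snr = p.snr_db if snr_db is None else float(snr_db)
    n = int(round(p.duration * p.sample_rate))
    t = np.arange(n) / p.sample_rate
    f0, f1 = p.sweep_low, p.sweep_high
    if direction == "rising":
        inst = f0 + (f1 - f0) * t / p.duration
    elif direction == "falling":
        inst = f1 - (f1 - f0) * t / p.duration
    else:
        inst = np.full(n, math.sqrt(f0 * f1))
    phase = 2 * np.pi * np.cumsum(inst) / p.sample_rate
    chirp = np.sin(phase)
    chirp *= hann_taper(n, int(round(p.ramp_duration * p.sample_rate)))
    chirp *= db_to_amp(p.noise_level_db + snr) / rms(chirp)
    noise = band_noise(
        NoiseBandSpec(
            low_edge=p.noise_low,
            high_edge=p.noise_high,
            level_db=p.noise_level_db,
            seed=p.seed,
            sample_rate=p.sample_rate,
        ),
        p.duration,
    )
    wave = _stereo(noise + chirp, noise - chirp, p.sample_rate)
    answer = {"direction": direction, "snr_db": snr, "correct_choice": direction}
    if return_components:
        return wave, answer, {"chirp": chirp, "noise": noise}
    return wave, answer


# ---------------------------------------------------------------------------
# Diotic absolute-sensitivity stimuli
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class F0dlParams:
    """F0-discrimination interval parameters (3AFC, four-tone sequences)."""

    f0: float = 110.0
    n_harmonics: int = 10
    tone_duration: float = 0.2
    ramp_duration: float = 0.02
    inter_tone_interval: float = INTER_STIMULUS_INTERVAL
    level_db: float = DEFAULT_LEVEL_DB
    sample_rate: int = DEFAULT_SAMPLE_RATE


def synth_f0dl_interval(
    delta_f0: float,
    is_target: bool,
    params: F0dlParams | None = None,
) -> Waveform:
    """One interval of the F0-discrimination task.

    A foil interval is four identical harmonic complexes at the base F0.  In
    the target interval tones 1 and 3 carry a symmetric shift of total
    excursion ``delta_f0`` centred on the base F0: tone 1 at +delta/2, tone 3
    at -delta/2.  Diotic (both channels identical).
    """
    if delta_f0 < 0:
        raise ValueError("delta_f0 must be non-negative")
    p = params or F0dlParams()
    if is_target and p.f0 - delta_f0 / 2 <= 0:
        raise ValueError("delta_f0 drives the fundamental non-positive")
    f0s = [p.f0] * 4
    if is_target:
        f0s[0] = p.f0 + delta_f0 / 2
        f0s[2] = p.f0 - delta_f0 / 2
    tones = [
        harmonic_complex(
            f, p.tone_duration, p.ramp_duration, p.level_db, p.sample_rate, p.n_harmonics
        )
        for f in f0s
    ]
    gap = np.zeros(int(round(p.inter_tone_interval * p.sample_rate)))
    parts = []
    for i, x in enumerate(tones):
        if i:
            parts.append(gap)
        parts.append(x)
    return _diotic(np.concatenate(parts), p.sample_rate)


@dataclass(frozen=True)
class GapParams:
    """Gap-detection trial parameters: 4-kHz markers in band-limited noise."""

    tone_frequency: float = 4000.0
    marker_duration: float = 0.125
    marker_ramp: float = 0.001
    tone_level_db: float = DEFAULT_LEVEL_DB
    snr_db: float = 10.0          # tone level re noise level
    noise_lead: float = 0.05
    noise_tail: float = 0.05
    noise_taper: float = 0.01
    octave_halfwidth: float = 0.5
    sample_rate: int = DEFAULT_SAMPLE_RATE
    seed: int = 0

    @property
    def noise_low(self) -> float:
        return self.tone_frequency * 2.0 ** (-self.octave_halfwidth)

    @property
    def noise_high(self) -> float:
        return self.tone_frequency * 2.0 ** (self.octave_halfwidth)


def synth_gap_trial(
    gap_ms: float,
    params: GapParams | None = None,
    return_components: bool = False,
):
    """One interval of the gap-detection task.

    Two 125-ms 4-kHz markers (1-ms Hann ramps) separated by ``gap_ms`` of
    tonal silence; the 0-ms foil is the two ramped markers abutted.  Noise a
    half-octave either side of 4 kHz runs from 50 ms before the first marker
    to 50 ms after the second, 10 dB below the tone, with 10-ms edge tapers.
    The gap interrupts the tone only — the noise is continuous.
    """
    if gap_ms < 0:
        raise ValueError("gap must be non-negative")
    p = params or GapParams()
    sr = p.sample_rate
    gap_s = gap_ms / 1000.0
    marker = _tone(p.tone_frequency, p.marker_duration, p.marker_ramp, p.tone_level_db, sr)
    gap = np.zeros(int(round(gap_s * sr)))
    tone = np.concatenate([marker, gap, marker])
    lead = np.zeros(int(round(p.noise_lead * sr)))
    tail = np.zeros(int(round(p.noise_tail * sr)))
    tone_channel = np.concatenate([lead, tone, tail])
    total = len(tone_channel) / sr
    noise = band_noise(
        NoiseBandSpec(
            low_edge=p.noise_low,
            high_edge=p.noise_high,
            level_db=p.tone_level_db - p.snr_db,
            seed=p.seed,
            sample_rate=sr,
        ),
        total,
    )
    noise *= hann_taper(len(noise), int(round(p.noise_taper * sr)))
    mix = tone_channel + noise
    wave = _diotic(mix, sr)
    if return_components:
        return wave, {"tone": tone_channel, "noise": noise}
    return wave


# ---------------------------------------------------------------------------
# Interaural-difference stimuli
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItdParams:
    frequency: float = 500.0
    duration: float = 0.3
    ramp_duration: float = 0.02
    level_db: float = DEFAULT_LEVEL_DB
    inter_stimulus_interval: float = INTER_STIMULUS_INTERVAL
    sample_rate: int = DEFAULT_SAMPLE_RATE


def _phase_shift_pair(frequency, duration, ramp, level_db, sr, phi):
    """Tone pair with interaural phase +/- phi/2 (positive phi: left leads)."""
    left = _tone(frequency, duration, ramp, level_db, sr, phase=+phi / 2)
    right = _tone(frequency, duration, ramp, level_db, sr, phase=-phi / 2)
    return left, right


def synth_itd_pair(
    itd_us: float,
    order: str = "LR",
    params: ItdParams | None = None,
):
    """Two-interval ITD lateralization trial at 500 Hz.

    The ITD ``tau`` is realized as an interaural carrier phase shift
    ``phi = 2*pi*f*tau`` (exact for pure tones), split +/- phi/2 across ears.
    In the first interval of an ``"LR"`` trial the left ear leads; the
    leading ear swaps in the second interval.
    """
    if itd_us < 0:
        raise ValueError("itd must be non-negative")
    if order not in ("LR", "RL"):
        raise ValueError("order must be 'LR' or 'RL'")
    p = params or ItdParams()
    phi = 2 * np.pi * p.frequency * itd_us * 1e-6
    if phi > np.pi:
        raise ValueError(
            f"ITD of {itd_us} us implies interaural phase {phi:.3f} > pi at {p.frequency} Hz"
        )
    lead_first = +phi if order == "LR" else -phi
    intervals = []
    for sign in (lead_first, -lead_first):
        l, r = _phase_shift_pair(
            p.frequency, p.duration, p.ramp_duration, p.level_db, p.sample_rate, sign
        )
        intervals.append(_stereo(l, r, p.sample_rate))
    wave = concatenate(intervals, gap=p.inter_stimulus_interval)
    return wave, {"order": order, "itd_us": itd_us, "correct_choice": order}


@dataclass(frozen=True)
class IldParams:
    frequency: float = 4000.0
    duration: float = 0.3
    ramp_duration: float = 0.02
    level_db: float = DEFAULT_LEVEL_DB
    inter_stimulus_interval: float = INTER_STIMULUS_INTERVAL
    sample_rate: int = DEFAULT_SAMPLE_RATE


def synth_ild_pair(
    ild_db: float,
    order: str = "LR",
    params: IldParams | None = None,
):
    """Two-interval ILD lateralization trial at 4 kHz.

    Each interval applies +/- ild/2 dB to the two ears so the across-ear mean
    level equals the nominal level; the louder ear swaps between intervals
    (``"LR"``: left louder first).
    """
    if ild_db < 0:
        raise ValueError("ild must be non-negative")
    if order not in ("LR", "RL"):
        raise ValueError("order must be 'LR' or 'RL'")
    p = params or IldParams()
    louder_first = ild_db / 2 if order == "LR" else -ild_db / 2
    intervals = []
    for half in (louder_first, -louder_first):
        left = _tone(p.frequency, p.duration, p.ramp_duration, p.level_db + half, p.sample_rate)
        right = _tone(p.frequency, p.duration, p.ramp_duration, p.level_db - half, p.sample_rate)
        intervals.append(_stereo(left, right, p.sample_rate))
    wave = concatenate(intervals, gap=p.inter_stimulus_interval)
    return wave, {"order": order, "ild_db": ild_db, "correct_choice": order}


# ---------------------------------------------------------------------------
# Co-modulation masking release
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CmrParams:
    """CMR trial parameters: 1-ERB bands around 4 kHz, 10-Hz modulation.

    Flanker bands are 1 ERB wide with their near edges 2 ERB away from the
    on-band edges (one below, one above).
    """

    center_frequency: float = 4000.0
    duration: float = 0.5
    modulation_rate: float = 10.0
    modulation_phase: float = 0.0
    band_level_db: float = DEFAULT_LEVEL_DB
    tone_ramp: float = 0.02
    flanker_gap_erb: float = 2.0
    sample_rate: int = DEFAULT_SAMPLE_RATE
    seed: int = 0

    @property
    def erb(self) -> float:
        return erb_bandwidth(self.center_frequency)

    def band_edges(self):
        """(on-band, lower flanker, upper flanker) edge pairs in Hz."""
        half = self.erb / 2
        on = (self.center_frequency - half, self.center_frequency + half)
        gap = self.flanker_gap_erb * self.erb
        lower = (on[0] - gap - self.erb, on[0] - gap)
        upper = (on[1] + gap, on[1] + gap + self.erb)
        return on, lower, upper


def synth_cmr_trial(
    condition: CmrCondition | str,
    snr_db: float,
    tone_present: bool,
    params: CmrParams | None = None,
    return_components: bool = False,
):
    """One observation interval of a CMR tone-in-noise detection trial.

    The on-band masker is 1-ERB-wide noise centred at 4 kHz with 100%-depth
    10-Hz raised-sine amplitude modulation.  CORR flankers share the on-band
    modulator; ACORR flankers use the inverted (pi-shifted) modulator; REF
    has no flankers.  When ``tone_present`` a 4-kHz tone is added at
    ``snr_db`` re the on-band RMS level.
    """
    condition = CmrCondition(condition)
    p = params or CmrParams()
    on, lower, upper = p.band_edges()
    if upper[1] >= p.sample_rate / 2:
        raise ValueError("upper flanker extends beyond Nyquist")
    if lower[0] <= 0:
        raise ValueError("lower flanker extends below 0 Hz")

    def _band(edges, phase_offset, seed_offset):
        return band_noise(
            NoiseBandSpec(
                low_edge=edges[0],
                high_edge=edges[1],
                level_db=p.band_level_db,
                modulation_rate=p.modulation_rate,
                modulation_phase=p.modulation_phase + phase_offset,
                seed=p.seed + seed_offset,
                sample_rate=p.sample_rate,
            ),
            p.duration,
        )

    components = {"on_band": _band(on, 0.0, 0)}
    if condition is not CmrCondition.REF:
        offset = 0.0 if condition is CmrCondition.CORR else np.pi
        components["lower_flanker"] = _band(lower, offset, 1)
        components["upper_flanker"] = _band(upper, offset, 2)
    mix = sum(components.values())
    if tone_present:
        tone = _tone(
            p.center_frequency, p.duration, p.tone_ramp,
            p.band_level_db + snr_db, p.sample_rate,
        )
        components["tone"] = tone
        mix = mix + tone
    wave = _diotic(mix, p.sample_rate)
    if return_components:
        return wave, components
    return wave


# ---------------------------------------------------------------------------
# Calibration sounds
# ---------------------------------------------------------------------------

#: Tasks for which representative calibration material can be generated.
CALIBRATION_TASKS = ("triad", "bmld_chirp", "f0dl", "gap", "itd", "ild", "cmr")


def _representative_stimuli(task_id: str, seed: int) -> list:
    rng = np.random.default_rng(seed)
    if task_id == "triad":
        waves, _ = synth_antiphase_triad(target_position=int(rng.integers(1, 4)))
        return waves
    if task_id == "bmld_chirp":
        out = []
        for i, d in enumerate(CHIRP_DIRECTIONS):
            w, _ = synth_bmld_chirp_trial(d, params=BmldChirpParams(seed=seed + i))
            out.append(w)
        return out
    if task_id == "f0dl":
        return [synth_f0dl_interval(0.0, False), synth_f0dl_interval(3.2, True)]
    if task_id == "gap":
        return [
            synth_gap_trial(0.0, GapParams(seed=seed)),
            synth_gap_trial(32.0, GapParams(seed=seed + 1)),
        ]
    if task_id == "itd":
        return [synth_itd_pair(128.0, o)[0] for o in ("LR", "RL")] * 2
    if task_id == "ild":
        return [synth_ild_pair(2.0, o)[0] for o in ("LR", "RL")] * 2
    if task_id == "cmr":
        out = []
        for i, c in enumerate(CmrCondition):
            out.append(synth_cmr_trial(c, 0.0, True, CmrParams(seed=seed + i)))
        return out
    raise KeyError(f"unknown task {task_id!r}; known: {CALIBRATION_TASKS}")


def make_calibration_sound(
    task_id: str,
    seed: int = 0,
    min_duration: float = 3.0,
):
    """Calibration sound for a task: a long string of representative stimuli.

    Its overall RMS defines the :class:`CalibrationReference` against which
    all task stimuli are checked (headroom 6 dB).
    """
    stimuli = _representative_stimuli(task_id, seed)
    pieces = list(stimuli)
    k = 0
    while sum(w.duration for w in pieces) < min_duration:
        pieces.append(stimuli[k % len(stimuli)])
        k += 1
    cal = concatenate(pieces, gap=0.05)
    ref = CalibrationReference(rms_db=cal.overall_rms_db())
    return cal, ref
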