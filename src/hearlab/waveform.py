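"""Bounded multi-channel audio buffers with dB-re-full-scale level bookkeeping.

Every synthesized stimulus in this package lives in a :class:`Waveform`:
float samples in [-1, 1], a sample rate, and the measured per-channel RMS
level in dB re full scale (dBFS).  Levels are always RMS-based; a full-scale
sine therefore sits at about -3 dBFS.  The :class:`CalibrationReference`
captures the level of a task's calibration sound and enforces the rule that
no task stimulus may exceed it by more than 6 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

#: Floor used when a channel is digitally silent (RMS would be -inf dB).
SILENCE_DB = -200.0


def rms(x: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """Root-mean-square amplitude along ``axis``."""
    return np.sqrt(np.mean(np.square(x, dtype=float), axis=axis))


def amp_to_db(a) -> np.ndarray | float:
    """Amplitude ratio to dB, with silent input mapped to SILENCE_DB."""
    a = np.asarray(a, dtype=float)
    with np.errstate(divide="ignore"):
        out = 20.0 * np.log10(a)
    out = np.where(np.isfinite(out), out, SILENCE_DB)
    return out if out.ndim else float(out)


def db_to_amp(d) -> np.ndarray | float:
    """dB to amplitude ratio."""
    d = np.asarray(d, dtype=float)
    out = np.power(10.0, d / 20.0)
    return out if out.ndim else float(out)


def hann_taper(n_samples: int, n_ramp: int) -> np.ndarray:
    """Unit envelope with raised-cosine (Hann) on/off ramps of ``n_ramp`` samples."""
    if 2 * n_ramp > n_samples:
        raise ValueError("ramps longer than the signal")
    env = np.ones(n_samples)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


@dataclass
class Waveform:
    """Two-channel (or mono) bounded audio buffer.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Amplitudes in [-1, 1].
    sample_rate : int
        Sampling rate in Hz.
    rms_db : tuple of float
        Measured per-channel RMS level in dB re full scale.  Populated by
        :meth:`from_samples`; kept as metadata and re-checked by
        :meth:`validate`.
    """

    samples: np.ndarray
    sample_rate: int
    rms_db: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.ndim == 1:
            s = s[:, None]
        self.samples = s
        if self.rms_db is None:
            self.rms_db = tuple(amp_to_db(rms(s, axis=0)))
        else:
            self.rms_db = tuple(float(v) for v in self.rms_db)
        self.validate()

    @classmethod
    def from_samples(cls, samples: np.ndarray, sample_rate: int) -> "Waveform":
        return cls(samples=samples, sample_rate=int(sample_rate))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on violation."""
        if self.samples.ndim != 2 or self.n_channels not in (1, 2):
            raise ValueError("samples must be (n_samples, 1 or 2 channels)")
        if self.n_samples and np.max(np.abs(self.samples)) > 1.0 + 1e-12:
            raise ValueError("samples exceed full scale [-1, 1]")
        measured = np.atleast_1d(amp_to_db(rms(self.samples, axis=0)))
        if len(self.rms_db) != self.n_channels:
            raise ValueError("rms_db metadata has wrong channel count")
        for meta, meas in zip(self.rms_db, measured):
            if meta > SILENCE_DB and abs(meta - meas) > 0.01:
                raise ValueError(
                    f"rms_db metadata {meta:.3f} disagrees with measured {meas:.3f}"
                )

    def channel(self, i: int) -> np.ndarray:
        return self.samples[:, i]

    def overall_rms_db(self) -> float:
        """RMS over all samples of all channels, in dBFS."""
        return float(amp_to_db(rms(self.samples)))


def concatenate(waveforms: list, gap: float = 0.0) -> Waveform:
    """Concatenate waveforms in time, optionally separated by ``gap`` s of silence."""
    if not waveforms:
        raise ValueError("nothing to concatenate")
    sr = waveforms[0].sample_rate
    nch = waveforms[0].n_channels
    for w in waveforms:
        if w.sample_rate != sr or w.n_channels != nch:
            raise ValueError("waveforms differ in rate or channel count")
    silence = np.zeros((int(round(gap * sr)), nch))
    parts = []
    for i, w in enumerate(waveforms):
        if i:
            parts.append(silence)
        parts.append(w.samples)
    return Waveform.from_samples(np.concatenate(parts, axis=0), sr)


@dataclass(frozen=True)
class CalibrationReference:
    """Level anchor for a task: stimuli may not exceed it by more than 6 dB RMS."""

    rms_db: float
    max_headroom_db: float = 6.0

    def admits(self, waveform: Waveform) -> bool:
        """True when every channel of ``waveform`` respects the headroom rule."""
        loudest = max(waveform.rms_db)
        return loudest <= self.rms_db + self.max_headroom_db + 1e-9


def write_wav(path, waveform: Waveform) -> None:
    """Write a float32 RIFF WAV file."""
    wavfile.write(path, waveform.sample_rate, waveform.samples.astype(np.float32))


def read_wav(path) -> Waveform:
    """Read a WAV file into a :class:`Waveform` (PCM rescaled to [-1, 1])."""
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    return Waveform.from_samples(np.asarray(data, dtype=float), sr)
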