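"""Raw-EEG containers and time-frequency analysis.

The model pipeline consumes a single EEG channel (Pz in the original
protocol), notch-filtered at the power-line frequency and converted to a
time-frequency amplitude map with the Stockwell transform (S-transform):
a short-time Fourier analysis whose Gaussian window narrows with frequency
(sigma = 1/f seconds), giving multi-resolution amplitude estimates on an
integer-Hz frequency grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass
class EEGRecording:
    """A multichannel EEG recording, samples in microvolts.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
    rate_hz : float
        Sampling rate in Hz.
    channel_labels : list of str
    subject_id, session_id : str
    meta : dict
        Free-form provenance (simulators store ground-truth envelopes here).
    """

    samples: np.ndarray
    rate_hz: float
    channel_labels: list[str]
    subject_id: str = ""
    session_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def channel(self, label: str = "Pz") -> np.ndarray:
        """Return one channel as a 1-D array (falls back to the only channel)."""
        if label in self.channel_labels:
            return self.samples[self.channel_labels.index(label)]
        if self.samples.shape[0] == 1:
            return self.samples[0]
        raise KeyError(f"channel {label!r} not in {self.channel_labels}")


@dataclass
class TFMap:
    """Stockwell amplitude map: nonnegative (n_freqs, n_times) matrix."""

    freqs_hz: np.ndarray
    times_s: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.shape != (self.freqs_hz.size, self.times_s.size):
            raise ValueError("amplitude shape must be (n_freqs, n_times)")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be nonnegative")


def notch_filter(rec: EEGRecording, line_hz: float = 50.0) -> EEGRecording:
    """Remove power-line interference with a zero-phase IIR notch.

    A second-order notch at ``line_hz`` (-3 dB bandwidth 1 Hz) applied
    forward-backward, so the stopband attenuation is doubled and the
    passband stays within 1 dB beyond 2 Hz from the notch.
    """
    if line_hz >= rec.rate_hz / 2:
        raise ValueError("notch frequency must be below Nyquist")
    b, a = signal.iirnotch(line_hz, Q=line_hz / 1.0, fs=rec.rate_hz)
    filtered = signal.filtfilt(b, a, rec.samples, axis=1)
    return EEGRecording(
        samples=filtered,
        rate_hz=rec.rate_hz,
        channel_labels=list(rec.channel_labels),
        subject_id=rec.subject_id,
        session_id=rec.session_id,
        meta=dict(rec.meta),
    )


def _signed_bins(n: int) -> np.ndarray:
    """FFT bin indices in signed (centered) convention: 0, 1, ..., -1."""
    return ((np.arange(n) + n // 2) % n) - n // 2


def stockwell(
    x: np.ndarray | EEGRecording,
    rate_hz: float | None = None,
    fmin_hz: float = 1.0,
    fmax_hz: float = 40.0,
    channel: str = "Pz",
) -> TFMap:
    """Stockwell transform amplitude on an integer-Hz frequency grid.

    Computed with the standard frequency-domain formulation: for each voice
    frequency f the spectrum is shifted by f and multiplied by the Gaussian
    ``exp(-2 pi^2 nu^2 / f^2)`` (the Fourier transform of a time-domain
    Gaussian with sigma = 1/f scaled to unit area), then inverse-transformed.
    The time axis keeps the input rate; frequencies run from ``fmin_hz`` to
    ``fmax_hz`` in 1 Hz steps.  Each voice frequency must be resolvable on
    the record, i.e. f * duration must be an integer number of cycles.
    """
    if isinstance(x, EEGRecording):
        rate_hz = x.rate_hz
        x = x.channel(channel)
    if rate_hz is None:
        raise ValueError("rate_hz required for array input")
    x = np.asarray(x, dtype=float)
    n = x.size
    if fmin_hz < 1.0:
        raise ValueError("fmin_hz must be >= 1 Hz")
    if fmax_hz > rate_hz / 2:
        raise ValueError("fmax_hz must not exceed Nyquist")
    duration = n / rate_hz
    freqs = np.arange(np.ceil(fmin_hz), np.floor(fmax_hz) + 1.0)
    if 1.0 / freqs[0] > duration:
        raise ValueError("record shorter than the longest analysis window")

    X = np.fft.fft(x)
    k = _signed_bins(n)
    amp = np.empty((freqs.size, n))
    for i, f in enumerate(freqs):
        nf = f * duration
        if abs(nf - round(nf)) > 1e-9:
            raise ValueError(
                f"frequency {f} Hz is not resolvable on a {duration} s record"
            )
        nf = int(round(nf))
        voice = np.exp(-2.0 * np.pi**2 * k.astype(float) ** 2 / nf**2)
        shifted = X[(np.arange(n) + nf) % n]
        amp[i] = np.abs(np.fft.ifft(shifted * voice))
    times = np.arange(n) / rate_hz
    return TFMap(freqs_hz=freqs, times_s=times, amplitude=amp)
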