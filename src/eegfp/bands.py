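"""Frequency-band schemes and the 10-band x 4 Hz power representation.

The regression models do not see the full 1 Hz spectrum: Stockwell
amplitudes are averaged into 10 contiguous frequency bands chosen so that
each band carries an equal share of the area under the session-averaged
logarithmic mean spectrum, and the band-power time courses are resampled
to 4 Hz and normalized against rest-period statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .tf import TFMap

#: Analysis range used throughout: integer-Hz voices on [1, 41).
DEFAULT_FMIN = 1.0
DEFAULT_FMAX = 40.0
MODEL_RATE_HZ = 4.0
N_BANDS = 10
LOG_EPS = 1e-12


class Normalization(str, Enum):
    RAW = "raw"
    REFERENCE = "reference_normalized"


@dataclass(frozen=True)
class BandScheme:
    """Contiguous half-open frequency bands [low, high) on a 1 Hz grid."""

    edges_hz: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges_hz, dtype=float)
        if edges.ndim != 1 or edges.size < 3:
            raise ValueError("need at least two bands")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("band edges must be strictly increasing")
        object.__setattr__(self, "edges_hz", tuple(edges.tolist()))

    @property
    def n_bands(self) -> int:
        return len(self.edges_hz) - 1

    @property
    def fmin(self) -> float:
        return self.edges_hz[0]

    @property
    def fmax(self) -> float:
        return self.edges_hz[-1]

    def band_of(self, freq_hz: float) -> int:
        """Index of the band containing ``freq_hz`` ([low, high) convention)."""
        edges = np.asarray(self.edges_hz)
        if not (edges[0] <= freq_hz < edges[-1]):
            raise ValueError(f"{freq_hz} Hz outside scheme range")
        return int(np.searchsorted(edges, freq_hz, side="right") - 1)

    @classmethod
    def uniform(
        cls,
        fmin: float = DEFAULT_FMIN,
        fmax: float = DEFAULT_FMAX + 1.0,
        n_bands: int = N_BANDS,
    ) -> "BandScheme":
        return cls(tuple(np.linspace(fmin, fmax, n_bands + 1).tolist()))


@dataclass
class BandPowerSeries:
    """Band-power matrix (n_bands, n_times) at the 4 Hz model rate."""

    values: np.ndarray
    band_scheme: BandScheme
    rate_hz: float = MODEL_RATE_HZ
    normalization: Normalization = Normalization.RAW

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.rate_hz != MODEL_RATE_HZ:
            raise ValueError("band-power series must be at 4 Hz")
        if self.values.shape[0] != self.band_scheme.n_bands:
            raise ValueError("row count must match the band scheme")

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_times) / self.rate_hz


@dataclass(frozen=True)
class RestReference:
    """Per-band mean/sd computed on a rest recording, used for normalization."""

    mean_per_band: np.ndarray
    sd_per_band: np.ndarray
    source_session: str = ""

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean_per_band, dtype=float)
        sd = np.asarray(self.sd_per_band, dtype=float)
        if mean.shape != sd.shape or mean.ndim != 1:
            raise ValueError("mean and sd must be equal-length vectors")
        if np.any(sd <= 0):
            raise ValueError("reference sd must be positive in every band")
        object.__setattr__(self, "mean_per_band", mean)
        object.__setattr__(self, "sd_per_band", sd)


def log_mean_spectrum(tf: TFMap, eps: float = LOG_EPS) -> np.ndarray:
    """Time-average of log(amplitude + eps) per 1 Hz voice."""
    return np.log(tf.amplitude + eps).mean(axis=1)


def equal_area_bands(
    log_mean: np.ndarray,
    freqs_hz: np.ndarray | None = None,
    n_bands: int = N_BANDS,
) -> BandScheme:
    """Divide a log-mean spectrum into bands of (nearly) equal area.

    ``log_mean`` holds one value per 1 Hz bin; bin j covers
    [freqs[j], freqs[j] + 1).  Interior edges are placed on the 1 Hz grid at
    the cumulative-area points closest to k * total / n_bands, scanning left
    to right with strictly increasing edges, so each edge lands within half
    of one bin's area of its target whenever the spectrum permits.
    """
    spectrum = np.asarray(log_mean, dtype=float)
    if freqs_hz is None:
        freqs_hz = np.arange(DEFAULT_FMIN, DEFAULT_FMIN + spectrum.size)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if spectrum.size < n_bands:
        raise ValueError("fewer frequency bins than bands")
    if np.any(spectrum <= 0):
        raise ValueError(
            "log-mean spectrum must be strictly positive; rescale the input "
            "(amplitudes below 1 unit make the log negative)"
        )
    cum = np.concatenate([[0.0], np.cumsum(spectrum)])  # cum[i]: area of bins < i
    total = cum[-1]
    edges_idx = [0]
    for k in range(1, n_bands):
        target = total * k / n_bands
        lo = edges_idx[-1] + 1          # strictly increasing
        hi = spectrum.size - (n_bands - k)  # leave room for remaining edges
        if lo > hi:
            raise ValueError("spectrum too short for the requested bands")
        j = lo + int(np.argmin(np.abs(cum[lo : hi + 1] - target)))
        edges_idx.append(j)
    edges_idx.append(spectrum.size)
    edges = [freqs_hz[0] + i for i in edges_idx]
    return BandScheme(tuple(edges))


def band_areas(log_mean: np.ndarray, scheme: BandScheme,
               freqs_hz: np.ndarray | None = None) -> np.ndarray:
    """Area of the log-mean spectrum inside each band of ``scheme``."""
    spectrum = np.asarray(log_mean, dtype=float)
    if freqs_hz is None:
        freqs_hz = np.arange(DEFAULT_FMIN, DEFAULT_FMIN + spectrum.size)
    out = np.empty(scheme.n_bands)
    for b in range(scheme.n_bands):
        sel = (freqs_hz >= scheme.edges_hz[b]) & (freqs_hz < scheme.edges_hz[b + 1])
        out[b] = spectrum[sel].sum()
    return out


def collapse_to_bands(tf: TFMap, scheme: BandScheme) -> np.ndarray:
    """Average amplitude rows into bands; returns (n_bands, n_times).

    A voice at frequency f belongs to band b when
    edges[b] <= f < edges[b+1].  Every band must contain at least one voice.
    """
    if scheme.fmin < tf.freqs_hz[0] or scheme.fmax > tf.freqs_hz[-1] + 1:
        raise ValueError("band scheme outside the map's frequency range")
    out = np.empty((scheme.n_bands, tf.times_s.size))
    for b in range(scheme.n_bands):
        sel = (tf.freqs_hz >= scheme.edges_hz[b]) & (tf.freqs_hz < scheme.edges_hz[b + 1])
        if not sel.any():
            raise ValueError(f"band {b} contains no frequency rows")
        out[b] = tf.amplitude[sel].mean(axis=0)
    return out


def resample_to_4hz(values: np.ndarray, rate_hz: float) -> np.ndarray:
    """Resample a (rows, n) matrix (or vector) to the 4 Hz model grid.

    Rates above 4 Hz are reduced by averaging consecutive 250 ms blocks
    (block j covers sample indices [ceil(j*r), ceil((j+1)*r)) with
    r = rate/4; only complete blocks are kept), which suppresses aliasing
    of envelope fluctuations.  Rates below 4 Hz (e.g. BOLD at TR = 3 s)
    are linearly interpolated onto the 4 Hz grid, provided 4 Hz is an
    integer multiple of the source rate.
    """
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    squeeze = np.asarray(values).ndim == 1
    n = arr.shape[1]
    if rate_hz == MODEL_RATE_HZ:
        out = arr
    elif rate_hz > MODEL_RATE_HZ:
        r = rate_hz / MODEL_RATE_HZ
        n_blocks = int(np.floor(n / r))
        if n_blocks < 1:
            raise ValueError("series shorter than one 250 ms block")
        bounds = np.ceil(np.arange(n_blocks + 1) * r).astype(int)
        out = np.empty((arr.shape[0], n_blocks))
        for j in range(n_blocks):
            out[:, j] = arr[:, bounds[j] : bounds[j + 1]].mean(axis=1)
    else:
        ratio = MODEL_RATE_HZ / rate_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("4 Hz must be an integer multiple of the source rate")
        src_t = np.arange(n) / rate_hz
        dst_t = np.arange(0.0, src_t[-1] + 1e-12, 1.0 / MODEL_RATE_HZ)
        out = np.vstack([np.interp(dst_t, src_t, row) for row in arr])
    return out[0] if squeeze else out


def normalize(series: BandPowerSeries, ref: RestReference) -> BandPowerSeries:
    """Affine normalization per band: (value - ref mean) / ref sd."""
    if ref.mean_per_band.size != series.band_scheme.n_bands:
        raise ValueError("reference band count mismatch")
    vals = (series.values - ref.mean_per_band[:, None]) / ref.sd_per_band[:, None]
    return BandPowerSeries(
        values=vals,
        band_scheme=series.band_scheme,
        normalization=Normalization.REFERENCE,
    )


def denormalize(series: BandPowerSeries, ref: RestReference) -> BandPowerSeries:
    """Inverse of :func:`normalize` (exact, the transform is affine)."""
    vals = series.values * ref.sd_per_band[:, None] + ref.mean_per_band[:, None]
    return BandPowerSeries(values=vals, band_scheme=series.band_scheme)


def zscore(x: np.ndarray, axis: int = -1, ddof: int = 0) -> np.ndarray:
    """Z-score along an axis; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=axis, keepdims=True, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("cannot z-score a constant series")
    return (x - x.mean(axis=axis, keepdims=True)) / sd


def rest_reference_from_bands(values: np.ndarray, source: str = "") -> RestReference:
    """Reference statistics (mean, sd per band) from a raw band-power matrix."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    # a band whose power barely fluctuates relative to its level carries no
    # normalizable signal (e.g. a constant input leaving only filter ripple)
    if np.any(sd <= 1e-8 * (np.abs(mean) + np.finfo(float).tiny)):
        raise ValueError("degenerate rest segment: (near-)zero variance in a band")
    return RestReference(mean, sd, source_session=source)
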