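"""Paired EEG-band-power / BOLD session containers.

A :class:`SessionDataset` holds the two aligned time series the regression
consumes: the normalized 10-band power matrix at 4 Hz and the z-scored ROI
BOLD series on the same grid.  The BOLD series may start at a sample offset
into the band grid (simulated targets drop the first 47 samples, which lack
a full 12-s EEG history).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bands as bd
from . import tf as tfm

#: 12 s of history at 4 Hz: delays 0, 0.25, ..., 11.75 s.
N_DELAYS = 48
DELAY_GRID_S = np.arange(N_DELAYS) / bd.MODEL_RATE_HZ


@dataclass
class SessionDataset:
    """One session: normalized band powers plus a z-scored BOLD target.

    Parameters
    ----------
    bands : BandPowerSeries
        Normalized (n_bands, n) matrix at 4 Hz.
    bold : ndarray
        Z-scored BOLD at 4 Hz.  ``bold[i]`` is the target at band-grid
        sample ``bold_offset + i``.
    bold_offset : int
        Index into the band grid of the first BOLD sample.
    """

    bands: bd.BandPowerSeries
    bold: np.ndarray
    bold_offset: int = 0
    subject_id: str = ""
    session_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bold = np.asarray(self.bold, dtype=float)
        if self.bold.ndim != 1:
            raise ValueError("bold must be a 1-D series")
        if self.bold_offset < 0:
            raise ValueError("bold_offset must be nonnegative")
        if self.bold_offset + self.bold.size > self.bands.n_times:
            raise ValueError("BOLD series extends past the band-power grid")
        var = self.bold.var()
        if abs(var - 1.0) > 1e-6:
            raise ValueError(f"bold must be z-scored (variance {var:.3g})")

    @property
    def n_times(self) -> int:
        return self.bands.n_times

    @property
    def band_scheme(self) -> bd.BandScheme:
        return self.bands.band_scheme

    def bold_at(self, t_index: np.ndarray) -> np.ndarray:
        """BOLD values at band-grid sample indices (must be covered)."""
        idx = np.asarray(t_index) - self.bold_offset
        if np.any(idx < 0) or np.any(idx >= self.bold.size):
            raise IndexError("requested times not covered by the BOLD series")
        return self.bold[idx]

    @classmethod
    def from_arrays(
        cls,
        band_values: np.ndarray,
        bold: np.ndarray,
        scheme: bd.BandScheme,
        *,
        bold_offset: int = 0,
        normalize_bands: bool = True,
        zscore_bold: bool = True,
        subject_id: str = "",
        session_id: str = "",
        meta: dict | None = None,
    ) -> "SessionDataset":
        band_values = np.atleast_2d(np.asarray(band_values, dtype=float))
        if normalize_bands:
            band_values = bd.zscore(band_values, axis=1)
            norm = bd.Normalization.REFERENCE
        else:
            norm = bd.Normalization.RAW
        if zscore_bold:
            bold = bd.zscore(np.asarray(bold, dtype=float))
        series = bd.BandPowerSeries(band_values, scheme, normalization=norm)
        return cls(series, bold, bold_offset=bold_offset,
                   subject_id=subject_id, session_id=session_id,
                   meta=meta or {})

    @classmethod
    def from_recording(
        cls,
        rec: tfm.EEGRecording,
        bold: np.ndarray,
        tr_s: float = 3.0,
        scheme: bd.BandScheme | None = None,
        ref: bd.RestReference | None = None,
        *,
        channel: str = "Pz",
        line_hz: float = 50.0,
        fmin: float = bd.DEFAULT_FMIN,
        fmax: float = bd.DEFAULT_FMAX,
    ) -> "SessionDataset":
        """Featurize a raw recording and align it with a BOLD series at TR.

        Full offline pipeline: notch -> Stockwell -> band collapse ->
        4 Hz block means; the band scheme defaults to equal-area bands of
        this session's own log-mean spectrum; normalization uses ``ref``
        when given, otherwise the session's own statistics.  The BOLD
        series at TR is linearly interpolated to 4 Hz and z-scored; both
        series are trimmed to their common span.
        """
        filtered = tfm.notch_filter(rec, line_hz)
        tf = tfm.stockwell(filtered, fmin_hz=fmin, fmax_hz=fmax, channel=channel)
        if scheme is None:
            scheme = bd.equal_area_bands(bd.log_mean_spectrum(tf), tf.freqs_hz)
        powers = bd.resample_to_4hz(bd.collapse_to_bands(tf, scheme), rec.rate_hz)
        bold4 = bd.resample_to_4hz(np.asarray(bold, dtype=float), 1.0 / tr_s)
        n = min(powers.shape[1], bold4.size)
        powers, bold4 = powers[:, :n], bold4[:n]
        if ref is not None:
            series = bd.normalize(
                bd.BandPowerSeries(powers, scheme), ref)
            return cls(series, bd.zscore(bold4),
                       subject_id=rec.subject_id, session_id=rec.session_id)
        return cls.from_arrays(powers, bold4, scheme,
                               subject_id=rec.subject_id,
                               session_id=rec.session_id)
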