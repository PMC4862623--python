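"""File formats: EEG recordings, BOLD series, band-power archives, models.

EEG is read with MNE (EDF and BrainVision dialects).  A minimal EDF writer
is included for exporting simulated single-channel recordings (1-s data
records, 16-bit samples); no EDF-writing library ships with the package's
dependency set, and the writer covers exactly the subset the simulator
produces.  BOLD series travel as two-column CSV (``roi`` value, ``tr_s``);
band-power matrices and fitted models are NumPy archives with a JSON
metadata sidecar entry.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from . import bands as bd
from .regression import EFPModel
from .tf import EEGRecording


def read_eeg(path: str | Path) -> EEGRecording:
    """Read an EDF or BrainVision recording into microvolt samples."""
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG format: {path.suffix}")
    return EEGRecording(
        samples=raw.get_data() * 1e6,  # MNE uses volts internally
        rate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        session_id=path.stem,
    )


def write_edf(path: str | Path, rec: EEGRecording) -> None:
    """Write a recording as EDF (16-bit, 1-s data records).

    The sampling rate must be an integer; the trailing partial second, if
    any, is zero-padded.
    """
    rate = int(round(rec.rate_hz))
    if abs(rate - rec.rate_hz) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = rec.samples.shape[0]
    n_rec = int(np.ceil(rec.n_samples / rate))
    padded = np.zeros((n_ch, n_rec * rate))
    padded[:, : rec.n_samples] = rec.samples

    def fixed(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join([
        fixed("0", 8),
        fixed(f"X X X {rec.subject_id or 'X'}", 80),
        fixed(f"Startdate X X X {rec.session_id or 'X'}", 80),
        fixed("01.01.00", 8), fixed("00.00.00", 8),
        fixed(str(256 * (1 + n_ch)), 8),
        fixed("", 44),
        fixed(str(n_rec), 8),
        fixed("1", 8),
        fixed(str(n_ch), 4),
    ])
    phys_min = np.minimum(padded.min(axis=1), -1.0)
    phys_max = np.maximum(padded.max(axis=1), 1.0)
    sig_fields = [
        [fixed(lbl, 16) for lbl in rec.channel_labels],
        [fixed("AgAgCl electrode", 80)] * n_ch,
        [fixed("uV", 8)] * n_ch,
        [fixed(f"{v:.6g}", 8) for v in phys_min],
        [fixed(f"{v:.6g}", 8) for v in phys_max],
        [fixed("-32768", 8)] * n_ch,
        [fixed("32767", 8)] * n_ch,
        [fixed("", 80)] * n_ch,
        [fixed(str(rate), 8)] * n_ch,
        [fixed("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in sig_fields:
            fh.write(b"".join(group))
        scale = (phys_max - phys_min) / (32767.0 - (-32768.0))
        for r in range(n_rec):
            for ch in range(n_ch):
                block = padded[ch, r * rate : (r + 1) * rate]
                dig = np.round((block - phys_min[ch]) / scale[ch]) - 32768
                fh.write(struct.pack(f"<{rate}h",
                                     *dig.astype(np.int16).tolist()))


def write_bold_csv(path: str | Path, values: np.ndarray, tr_s: float = 3.0) -> None:
    """Write a ROI BOLD series as CSV with columns ``roi,tr_s``."""
    frame = pd.DataFrame({"roi": np.asarray(values, dtype=float),
                          "tr_s": tr_s})
    frame.to_csv(path, index=False)


def read_bold_csv(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a ROI BOLD series; returns (values, tr_s)."""
    frame = pd.read_csv(path)
    if "roi" not in frame.columns or "tr_s" not in frame.columns:
        raise ValueError("BOLD CSV must have columns 'roi' and 'tr_s'")
    tr = frame["tr_s"].unique()
    if tr.size != 1:
        raise ValueError("tr_s must be constant")
    return frame["roi"].to_numpy(dtype=float), float(tr[0])


def save_model(path: str | Path, model: EFPModel) -> None:
    """Serialize a fitted finger-print with its provenance."""
    np.savez(
        path,
        coeffs=model.coeffs,
        intercept=model.intercept,
        edges_hz=np.asarray(model.band_scheme.edges_hz),
        delay_grid_s=model.delay_grid_s,
        lam=model.lam,
        meta=json.dumps(model.fit_meta),
    )


def load_model(path: str | Path) -> EFPModel:
    with np.load(path, allow_pickle=False) as arc:
        return EFPModel(
            coeffs=arc["coeffs"],
            intercept=float(arc["intercept"]),
            band_scheme=bd.BandScheme(tuple(arc["edges_hz"].tolist())),
            lam=float(arc["lam"]),
            fit_meta=json.loads(str(arc["meta"])),
        )


def save_bandpower(path: str | Path, series: bd.BandPowerSeries,
                   meta: dict | None = None) -> None:
    """Band-power matrix archive with JSON metadata entry."""
    payload = {"edges_hz": list(series.band_scheme.edges_hz),
               "rate_hz": series.rate_hz,
               "normalization": series.normalization.value}
    payload.update(meta or {})
    np.savez(path, values=series.values, meta=json.dumps(payload))


def load_bandpower(path: str | Path) -> bd.BandPowerSeries:
    with np.load(path, allow_pickle=False) as arc:
        meta = json.loads(str(arc["meta"]))
        return bd.BandPowerSeries(
            values=arc["values"],
            band_scheme=bd.BandScheme(tuple(meta["edges_hz"])),
            normalization=bd.Normalization(meta["normalization"]),
        )
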