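"""Streaming neurofeedback engine (the "virtual machine").

Every 3-s EEG packet is appended to a rolling buffer (capacity 15 s: the
12-s multiplication window plus one packet, so the window clears the
buffer's leading Stockwell edge at steady state).  The buffer is
preprocessed exactly like the offline data — notch, Stockwell, collapse to
the model's bands, 4 Hz block means, rest-reference normalization — and
the last 48 4-Hz columns (12 s) are multiplied element-wise with the
common model's coefficient matrix to emit one predicted BOLD value per
packet.  Values are mapped to feedback loudness linearly around the
rest-period mean: 50 dB at the mean, 10 dB per rest sd, clipped to
[10, 90] dB, with the sd re-estimated after every feedback period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bands as bd
from . import tf as tfm
from .dataset import N_DELAYS
from .regression import EFPModel

#: Sentinel returned while fewer than 12 s of signal have been received.
WARMING_UP = None

CAPACITY_S = 15.0
PACKET_S = 3.0
WINDOW_S = N_DELAYS / bd.MODEL_RATE_HZ  # 12 s


def featurize_buffer(
    samples: np.ndarray,
    rate_hz: float,
    model: EFPModel,
    ref: bd.RestReference,
    line_hz: float = 50.0,
) -> np.ndarray:
    """Preprocess one raw buffer into normalized 4-Hz band-power columns."""
    rec = tfm.EEGRecording(samples[None, :], rate_hz, ["Pz"])
    filtered = tfm.notch_filter(rec, line_hz)
    tf = tfm.stockwell(filtered, fmin_hz=model.band_scheme.fmin,
                       fmax_hz=model.band_scheme.fmax)
    powers = bd.resample_to_4hz(bd.collapse_to_bands(tf, model.band_scheme),
                                rate_hz)
    series = bd.normalize(bd.BandPowerSeries(powers, model.band_scheme), ref)
    return series.values


def _window_value(feats: np.ndarray, model: EFPModel) -> float:
    """Multiply the last 12 s of feature columns by the coefficient matrix."""
    if feats.shape[1] < N_DELAYS:
        raise ValueError("buffer yields fewer than 48 feature columns")
    window = feats[:, ::-1][:, :N_DELAYS]  # column d = delay d * 0.25 s
    return model.apply_window(window)


@dataclass
class StreamState:
    """Rolling-buffer state of the real-time engine."""

    model: EFPModel
    ref: bd.RestReference
    rate_hz: float
    capacity_s: float = CAPACITY_S
    packet_s: float = PACKET_S
    line_hz: float = 50.0
    buffer: np.ndarray = field(default_factory=lambda: np.empty(0))
    received_s: float = 0.0
    emitted: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref is None:
            raise ValueError("a RestReference is required for streaming")

    @property
    def packet_samples(self) -> int:
        return int(round(self.packet_s * self.rate_hz))


def push_packet(state: StreamState, packet: np.ndarray):
    """Consume one 3-s packet; return the new cEFP value or WARMING_UP.

    The first value is emitted once 12 s of signal exist (the fourth 3-s
    packet); the buffer never grows beyond ``capacity_s``.
    """
    packet = np.asarray(packet, dtype=float).ravel()
    if packet.size != state.packet_samples:
        raise ValueError(
            f"packet must be {state.packet_samples} samples "
            f"({state.packet_s} s at {state.rate_hz} Hz), got {packet.size}")
    state.buffer = np.concatenate([state.buffer, packet])
    cap = int(round(state.capacity_s * state.rate_hz))
    if state.buffer.size > cap:
        state.buffer = state.buffer[-cap:]
    state.received_s += state.packet_s
    if state.received_s < WINDOW_S:
        return WARMING_UP
    feats = featurize_buffer(state.buffer, state.rate_hz, state.model,
                             state.ref, state.line_hz)
    value = _window_value(feats, state.model)
    t = state.received_s
    if state.emitted and t <= state.emitted[-1][0]:
        raise RuntimeError("emissions must be strictly time-ordered")
    state.emitted.append((t, value))
    return value


def replay(
    model: EFPModel,
    samples: np.ndarray,
    rate_hz: float,
    ref: bd.RestReference,
    packet_s: float = PACKET_S,
    capacity_s: float = CAPACITY_S,
    line_hz: float = 50.0,
) -> pd.DataFrame:
    """Stateless offline replay of the streaming computation.

    For every packet boundary the same buffer window the engine would hold
    is sliced from the full record and evaluated with the identical
    preprocessing; this is the batch-side oracle for streaming-batch
    equivalence (both paths window the Stockwell transform identically, so
    edge columns are treated the same).
    """
    samples = np.asarray(samples, dtype=float).ravel()
    ps = int(round(packet_s * rate_hz))
    cap = int(round(capacity_s * rate_hz))
    rows = []
    for end in range(ps, samples.size + 1, ps):
        t = end / rate_hz
        if t < WINDOW_S:
            continue
        buf = samples[max(0, end - cap) : end]
        feats = featurize_buffer(buf, rate_hz, model, ref, line_hz)
        rows.append({"t_s": t, "value": _window_value(feats, model)})
    return pd.DataFrame(rows)


def rest_calibration(
    samples: np.ndarray,
    rate_hz: float,
    model: EFPModel,
    line_hz: float = 50.0,
) -> tuple[bd.RestReference, float, float]:
    """Calibrate on a rest recording (>= 60 s).

    Returns the band-power reference statistics (mean/sd per band of the
    full rest record's raw band powers) plus the mean and sample sd of the
    cEFP values streamed over the rest period with that reference — the
    anchors of the feedback mapping.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size / rate_hz < 60:
        raise ValueError("rest period must be at least 60 s")
    rec = tfm.EEGRecording(samples[None, :], rate_hz, ["Pz"])
    filtered = tfm.notch_filter(rec, line_hz)
    tf = tfm.stockwell(filtered, fmin_hz=model.band_scheme.fmin,
                       fmax_hz=model.band_scheme.fmax)
    powers = bd.resample_to_4hz(bd.collapse_to_bands(tf, model.band_scheme),
                                rate_hz)
    ref = bd.rest_reference_from_bands(powers, source="rest")
    values = replay(model, samples, rate_hz, ref, line_hz=line_hz)["value"]
    if values.size < 2:
        raise ValueError("rest period too short to estimate cEFP statistics")
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate rest period: constant cEFP value")
    return ref, float(values.mean()), sd


@dataclass
class FeedbackState:
    """Linear loudness mapping state: 50 dB at rest mean, 10 dB per sd."""

    rest_mean: float
    current_sd: float
    db_min: float = 10.0
    db_mid: float = 50.0
    db_max: float = 90.0
    db_per_sd: float = 10.0
    period_values: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.current_sd <= 0:
            raise ValueError("current_sd must be positive")


def map_to_db(fb: FeedbackState, value: float) -> float:
    """Loudness for one cEFP value; the value is accumulated for the period."""
    db = fb.db_mid + fb.db_per_sd * (value - fb.rest_mean) / fb.current_sd
    fb.period_values.append(float(value))
    return float(np.clip(db, fb.db_min, fb.db_max))


def end_period(fb: FeedbackState) -> FeedbackState:
    """Reset the scaling sd to the sample sd of the period just finished."""
    if len(fb.period_values) < 2:
        warnings.warn("period ended with fewer than two values; sd unchanged")
        return fb
    fb.current_sd = float(np.std(fb.period_values, ddof=1))
    if fb.current_sd == 0:
        raise ValueError("degenerate period: constant cEFP values")
    fb.period_values = []
    return fb


def run_nf_session(
    model: EFPModel,
    samples: np.ndarray,
    rate_hz: float,
    rest_s: float,
    period_s: float = 420.0,
    packet_s: float = PACKET_S,
    line_hz: float = 50.0,
) -> pd.DataFrame:
    """Replay a full NF session: rest calibration then feedback periods.

    The first ``rest_s`` seconds calibrate the reference and the feedback
    anchors; the remainder is streamed in ``period_s`` feedback periods
    with the sd reset between periods.  Returns a log with columns
    packet_index, t_s, cefp_value, loudness_db, period_label.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    n_rest = int(round(rest_s * rate_hz))
    ref, rest_mean, rest_sd = rest_calibration(samples[:n_rest], rate_hz,
                                               model, line_hz)
    fb = FeedbackState(rest_mean=rest_mean, current_sd=rest_sd)
    state = StreamState(model=model, ref=ref, rate_hz=rate_hz,
                        packet_s=packet_s, line_hz=line_hz)
    ps = int(round(packet_s * rate_hz))
    rows = []
    period_len = int(round(period_s / packet_s))
    n_in_period = 0
    period = 1
    for i, start in enumerate(range(n_rest, samples.size - ps + 1, ps)):
        value = push_packet(state, samples[start : start + ps])
        if value is WARMING_UP:
            rows.append({"packet_index": i, "t_s": rest_s + (i + 1) * packet_s,
                         "cefp_value": np.nan, "loudness_db": np.nan,
                         "period_label": f"NF{period}"})
            continue
        db = map_to_db(fb, value)
        rows.append({"packet_index": i, "t_s": rest_s + (i + 1) * packet_s,
                     "cefp_value": value, "loudness_db": db,
                     "period_label": f"NF{period}"})
        n_in_period += 1
        if n_in_period >= period_len:
            end_period(fb)
            n_in_period = 0
            period += 1
    return pd.DataFrame(rows)
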