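"""Synthetic paired EEG/BOLD sessions with known ground truth.

The generator realizes the model class the finger-print estimates: ROI BOLD
is a linear function of delayed EEG band powers plus Gaussian noise.  Per
band, slowly varying log-normal envelopes (correlation time >= 2 s) are
drawn directly on the 4 Hz model grid, so the ground-truth band-power
matrix is known exactly at model resolution; raw EEG, when requested, is
synthesized by modulating band-pass-filtered white-noise carriers with
those envelopes.  A study is a majority of "positive" sessions sharing one
coefficient matrix plus a minority of outlier sessions with perturbed
matrices — the regime the one-class selection is built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter1d

from . import bands as bd
from .dataset import N_DELAYS, SessionDataset
from .tf import EEGRecording

#: Per-band carrier RMS in microvolts (scaled so even the quietest
#: Stockwell voice stays above 1 uV, keeping the log-mean spectrum
#: positive for equal-area banding).
CARRIER_RMS_UV = 40.0
#: Broadband pink background RMS in microvolts: fills the spectrum between
#: the oscillatory carriers, as in real EEG.
BACKGROUND_RMS_UV = 12.0
#: Envelope log-sd and correlation time.
ENV_LOG_SD = 0.4
ENV_CORR_S = 2.0
#: Fraction of envelope log-variance shared by all bands (a global
#: arousal-like component; empirical EEG band powers co-fluctuate).
AROUSAL_MIX = 0.75
#: Carrier amplitude grows as (f/20)**AMP_TILT, partly offsetting the
#: Stockwell voices' widening (hence stronger cross-band mixing) at high f.
AMP_TILT = 0.5
#: Default simulation band scheme: one carrier per band at an exact
#: multiple of 4 Hz (4, 8, ..., 40), edges halfway between carriers.
#: 4-Hz carrier spacing makes all beat frequencies integer multiples of
#: 4 Hz, which the 250-ms block means of the 4 Hz resampling cancel.
SIM_EDGES = (1.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0, 30.0, 34.0, 38.0, 41.0)


def simulation_scheme() -> bd.BandScheme:
    return bd.BandScheme(SIM_EDGES)


def carrier_frequencies(scheme: bd.BandScheme) -> np.ndarray:
    """One oscillatory carrier per band, at the band's central 4 Hz multiple
    for the default scheme (band midpoint rounded to the 1 Hz grid otherwise)."""
    if tuple(scheme.edges_hz) == SIM_EDGES:
        return np.arange(1, scheme.n_bands + 1) * 4.0
    edges = np.asarray(scheme.edges_hz)
    return np.round((edges[:-1] + edges[1:]) / 2.0)


class SessionGroup(str, Enum):
    POSITIVE = "positive"
    OUTLIER = "outlier"


@dataclass
class GroundTruth:
    """The true linear EEG->BOLD mapping planted in one session."""

    coeffs: np.ndarray
    band_scheme: bd.BandScheme
    noise_sd: float = 0.0
    session_group: SessionGroup = SessionGroup.POSITIVE

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.band_scheme.n_bands, N_DELAYS):
            raise ValueError(
                f"coeffs must be ({self.band_scheme.n_bands}, {N_DELAYS})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SimSpec:
    """Study-level simulation settings.

    snr is the variance ratio var(signal)/var(noise) of the BOLD target;
    outlier_perturbation scales the zero-mean Gaussian perturbation (in
    units of the positive matrix's RMS coefficient) applied to outlier
    sessions before renormalizing to equal Frobenius norm.
    """

    n_sessions: int = 15
    n_positive: int = 10
    duration_s: float = 300.0
    eeg_rate_hz: float = 250.0
    seed: int = 0
    outlier_perturbation: float = 3.0
    snr: float = 10.0
    band_scheme: bd.BandScheme = field(
        default_factory=lambda: bd.BandScheme(SIM_EDGES))
    band_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_positive > self.n_sessions:
            raise ValueError("n_positive cannot exceed n_sessions")
        if self.duration_s < 60:
            raise ValueError("sessions must be at least 60 s long")
        if self.eeg_rate_hz <= 2 * self.band_scheme.fmax:
            raise ValueError("EEG rate must exceed twice the top band edge")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.outlier_perturbation < 0:
            raise ValueError("outlier_perturbation must be nonnegative")

    @property
    def n_model_samples(self) -> int:
        return int(round(self.duration_s * bd.MODEL_RATE_HZ))


def _session_rng(spec: SimSpec, session_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed % 2**31, session_index, stream])


def band_envelopes(spec: SimSpec, session_index: int) -> np.ndarray:
    """Log-normal slow envelopes, (n_bands, n) on the 4 Hz grid, mean ~ 1.

    Each band's log-envelope mixes a shared arousal component (weight
    ``AROUSAL_MIX``) with an independent band-specific component; both are
    Gaussian with a >= 2 s correlation time.
    """
    rng = _session_rng(spec, session_index, 0)
    n = spec.n_model_samples
    sigma_samples = ENV_CORR_S * bd.MODEL_RATE_HZ

    def slow_noise(rows: int) -> np.ndarray:
        g = gaussian_filter1d(rng.standard_normal((rows, n)), sigma_samples,
                              axis=1, mode="reflect")
        return g / g.std(axis=1, keepdims=True)

    common = slow_noise(1)
    own = slow_noise(spec.band_scheme.n_bands)
    mix = AROUSAL_MIX * common + np.sqrt(1 - AROUSAL_MIX**2) * own
    env = np.exp(ENV_LOG_SD * mix - ENV_LOG_SD**2 / 2)
    if spec.band_scale is not None:
        env = env * np.asarray(spec.band_scale, dtype=float)[:, None]
    return env


def simulate_eeg(spec: SimSpec, session_index: int = 0) -> EEGRecording:
    """Synthesize one single-channel EEG recording (Pz) at ``eeg_rate_hz``.

    Each band of the scheme contributes one narrowband oscillatory
    carrier (a random-phase sinusoid at the band's central 4 Hz multiple)
    amplitude-modulated by that band's slow envelope (linearly upsampled
    from 4 Hz); carrier RMS is 10 uV at 20 Hz with a mild high-frequency
    tilt.  Deterministic-phase carriers keep the band power a faithful
    envelope readout: a stochastic (filtered-noise) carrier's Rayleigh
    fading would alias into the 4 Hz band-power estimate and swamp the
    envelope signal.  The 4 Hz envelopes are stored in
    ``meta['envelopes_4hz']`` as the oracle for time-frequency band power.
    """
    if spec.duration_s < 12:
        raise ValueError("duration too short for one 12-s window")
    env4 = band_envelopes(spec, session_index)
    rng = _session_rng(spec, session_index, 1)
    fs = spec.eeg_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    t4 = np.arange(env4.shape[1]) / bd.MODEL_RATE_HZ
    x = np.zeros(n)
    centers = carrier_frequencies(spec.band_scheme)
    for b in range(spec.band_scheme.n_bands):
        amp = CARRIER_RMS_UV * np.sqrt(2) * (centers[b] / 20.0) ** AMP_TILT
        carrier = amp * np.cos(2 * np.pi * centers[b] * t
                               + rng.uniform(0, 2 * np.pi))
        x += carrier * np.interp(t, t4, env4[b])
    x += _pink_noise(rng, n, fs) * BACKGROUND_RMS_UV
    return EEGRecording(
        samples=x[None, :],
        rate_hz=fs,
        channel_labels=["Pz"],
        subject_id=f"sub{session_index:02d}",
        session_id=f"S{session_index:02d}",
        meta={"envelopes_4hz": env4, "band_scheme": spec.band_scheme},
    )


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS noise with a 1/f amplitude spectrum (flat below 1 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec /= np.sqrt(np.maximum(freqs, 1.0))
    x = np.fft.irfft(spec, n)
    return x / np.sqrt(np.mean(x**2))


def simulate_bold(
    envelopes: np.ndarray,
    truth: GroundTruth,
    spec: SimSpec,
    session_index: int = 0,
) -> np.ndarray:
    """BOLD target from delayed band powers plus noise, z-scored.

    ``envelopes`` is the (n_bands, n) band-power matrix on the 4 Hz grid
    (in the normalization the model will see).  For every sample t with a
    full 12-s history (t >= 47) the signal is
    sum_{b,d} coeffs[b, d] * envelopes[b, t - d]; the first 47 samples are
    dropped.  Gaussian noise is scaled so that var(signal)/var(noise)
    equals ``spec.snr``; noiseless signals stay noiseless.
    """
    env = np.atleast_2d(np.asarray(envelopes, dtype=float))
    if env.shape[0] != truth.coeffs.shape[0]:
        raise ValueError("band count mismatch between envelopes and truth")
    if env.shape[1] < N_DELAYS:
        raise ValueError("envelopes must cover at least 12 s")
    sw = sliding_window_view(env, N_DELAYS, axis=1)[:, :, ::-1]
    y = np.einsum("bij,bj->i", sw, truth.coeffs)
    sig_var = y.var()
    if sig_var == 0:
        return y  # all-zero coefficients: constant-zero series
    if np.isfinite(spec.snr):
        rng = _session_rng(spec, session_index, 2)
        noise_sd = np.sqrt(sig_var / spec.snr)
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    return bd.zscore(y)


def positive_coeffs(
    scheme: bd.BandScheme, rng: np.random.Generator
) -> np.ndarray:
    """Draw a smooth ground-truth coefficient matrix.

    Each band's delay profile is a Gaussian bump (peak uniformly in
    4-8 s, width 1.5 s — a hemodynamic-response-like lag) with a standard
    normal amplitude, mimicking band-specific coupling at physiological
    delays.
    """
    delays = np.arange(N_DELAYS) / bd.MODEL_RATE_HZ
    coeffs = np.empty((scheme.n_bands, N_DELAYS))
    for b in range(scheme.n_bands):
        peak = rng.uniform(4.0, 8.0)
        amp = rng.standard_normal()
        coeffs[b] = amp * np.exp(-((delays - peak) ** 2) / (2 * 1.5**2))
    return coeffs


def perturb_coeffs(
    coeffs: np.ndarray, scale: float, rng: np.random.Generator,
    scheme: bd.BandScheme | None = None,
) -> np.ndarray:
    """Outlier matrix: add correlated Gaussian noise, renormalize to equal norm.

    The zero-mean perturbation is drawn from the same smooth
    delay-profile process as the positive matrix (an independent
    band-coupling pattern), scaled to ``scale`` times the positive
    matrix's Frobenius norm, then the sum is renormalized to the original
    norm.  Smooth (rather than white) noise is used so the planted
    cross-group separation survives ridge estimation, which filters
    delay-incoherent structure; the expected true-coefficient correlation
    between outlier and positive matrices is 1/sqrt(1 + scale^2).
    """
    if scale == 0:
        return coeffs.copy()
    if scheme is None:
        scheme = bd.BandScheme.uniform(n_bands=coeffs.shape[0])
    pert = positive_coeffs(scheme, rng)
    norm_c = np.linalg.norm(coeffs)
    pert *= norm_c / np.linalg.norm(pert)
    out = coeffs + scale * pert
    out *= norm_c / np.linalg.norm(out)
    return out


def simulate_study(
    spec: SimSpec,
) -> tuple[list[SessionDataset], list[GroundTruth]]:
    """Generate a study: positive sessions share coefficients, outliers don't.

    Sessions are built directly from the 4 Hz ground-truth envelopes
    (z-scored per band), so fitted coefficients are comparable to the
    planted ones up to the overall BOLD scale.  The first ``n_positive``
    session indices carry the shared positive matrix.
    """
    master = np.random.default_rng([spec.seed % 2**31, 999])
    base = positive_coeffs(spec.band_scheme, master)
    sessions, truths = [], []
    for i in range(spec.n_sessions):
        if i < spec.n_positive:
            coeffs, group = base, SessionGroup.POSITIVE
        else:
            coeffs = perturb_coeffs(base, spec.outlier_perturbation, master,
                                    spec.band_scheme)
            group = SessionGroup.OUTLIER
        env = band_envelopes(spec, i)
        bands_z = bd.zscore(env, axis=1)
        bold = simulate_bold(bands_z, GroundTruth(coeffs, spec.band_scheme),
                             spec, session_index=i)
        noise_sd = 0.0 if not np.isfinite(spec.snr) else 1.0 / np.sqrt(spec.snr)
        truths.append(GroundTruth(coeffs, spec.band_scheme,
                                  noise_sd=noise_sd, session_group=group))
        sessions.append(SessionDataset.from_arrays(
            bands_z, bold, spec.band_scheme, bold_offset=N_DELAYS - 1,
            subject_id=f"sub{i:02d}", session_id=f"S{i:02d}",
            meta={"group": group.value}))
    return sessions, truths


# ---------------------------------------------------------------------------
# Synthetic neurofeedback studies (for the evaluation statistics)

@dataclass
class NFStudySpec:
    """Planted-effect neurofeedback study.

    Defaults reproduce the published study conditions: 7 test + 6 sham
    subjects, five 7-min periods (one baseline + four feedback) sampled
    every 3 s, test-group down-regulation of -0.84 signal units on average
    (subject-to-subject sd 0.25), no planted sham effect, baseline
    subject means 0.01 +- 0.07, within-subject sample sd 0.5.
    """

    n_test: int = 7
    n_sham: int = 6
    period_s: float = 420.0
    step_s: float = 3.0
    n_nf_periods: int = 4
    baseline_mean: float = 0.01
    baseline_sd: float = 0.07
    effect_mean: float = -0.84
    effect_sd: float = 0.25
    sham_effect_mean: float = 0.0
    sample_sd: float = 0.5
    seed: int = 0


def simulate_nf_study(spec: NFStudySpec) -> list:
    """Generate per-subject NF session logs with planted group effects."""
    from .nfstats import NFSessionRecord  # avoid a circular import at load

    rng = np.random.default_rng(spec.seed % 2**31)
    n_per = int(round(spec.period_s / spec.step_s))
    records = []
    groups = ["test"] * spec.n_test + ["sham"] * spec.n_sham
    for i, group in enumerate(groups):
        mu = rng.normal(spec.baseline_mean, spec.baseline_sd)
        if group == "test":
            delta = rng.normal(spec.effect_mean, spec.effect_sd)
        else:
            delta = spec.sham_effect_mean
        values, labels = [], []
        values.append(rng.normal(mu, spec.sample_sd, n_per))
        labels += ["BL"] * n_per
        for p in range(spec.n_nf_periods):
            values.append(rng.normal(mu + delta, spec.sample_sd, n_per))
            labels += [f"NF{p + 1}"] * n_per
        records.append(NFSessionRecord(
            subject_id=f"{group}{i:02d}", group=group,
            values=np.concatenate(values), period_labels=labels))
    return records
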