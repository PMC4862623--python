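"""Common finger-print (cEFP) construction from the positive session pool.

The k selected sessions are validated leave-one-session-out: each fold
concatenates the other k-1 sessions (as a whole unit), picks the ridge
weight by inner block CV whose validation windows never span a session
boundary, and scores the fold model on the held-out session.  The final
common model refits on all k sessions with the modal fold lambda.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd

from . import bands as bd
from .dataset import N_DELAYS, SessionDataset
from .regression import (CVConfig, EFPModel, build_design_matrix,
                         evaluate_prediction, inner_cv_select, nmse,
                         ridge_fit)


def build_cefp_scheme(
    log_mean_spectra: list[np.ndarray],
    freqs_hz: np.ndarray | None = None,
    n_bands: int = bd.N_BANDS,
) -> bd.BandScheme:
    """Equal-area bands of the log-mean spectrum averaged across sessions.

    ``log_mean_spectra`` holds one per-session log-mean spectrum on the
    common 1 Hz grid (see :func:`eegfp.bands.log_mean_spectrum`).
    """
    if len(log_mean_spectra) < 2:
        raise ValueError("need spectra from at least two sessions")
    stacked = np.vstack([np.asarray(s, dtype=float) for s in log_mean_spectra])
    return bd.equal_area_bands(stacked.mean(axis=0), freqs_hz, n_bands)


def _concat_design(sessions: list[SessionDataset]):
    """Stack per-session design matrices, tracking session row bounds."""
    Xs, ys, bounds, pos = [], [], [], 0
    for ds in sessions:
        X, y, _ = build_design_matrix(ds)
        Xs.append(X)
        ys.append(y)
        bounds.append((pos, pos + X.shape[0]))
        pos += X.shape[0]
    return np.vstack(Xs), np.concatenate(ys), bounds


def fit_cefp(
    positive: list[SessionDataset], cfg: CVConfig | None = None
) -> tuple[EFPModel, pd.DataFrame]:
    """Leave-one-session-out common-model fit over the positive pool.

    Returns the final cEFP (refit on all sessions with the lambda most
    frequently selected across folds, ties toward larger lambda) and a
    per-fold report of the selected lambda and held-out Pearson r / NMSE.
    """
    cfg = cfg or CVConfig()
    # canonical session order, so fold results don't depend on input order
    positive = sorted(positive, key=lambda ds: ds.session_id)
    k = len(positive)
    if k < 3:
        raise ValueError("need at least three positive sessions")
    n_bands = positive[0].band_scheme.n_bands
    if any(ds.band_scheme.n_bands != n_bands for ds in positive):
        raise ValueError("all sessions must share the band count")
    rows = []
    for i, held in enumerate(positive):
        train = [ds for j, ds in enumerate(positive) if j != i]
        X, y, bounds = _concat_design(train)
        lam, _ = inner_cv_select(X, y, cfg, group_bounds=bounds)
        w, b = ridge_fit(X, y, lam)
        fold_model = EFPModel(w.reshape(n_bands, N_DELAYS), b,
                              held.band_scheme, lam)
        try:
            r = evaluate_prediction(fold_model, held)
            yhat, t_idx = fold_model.predict(held)
            fold_nmse = nmse(held.bold_at(t_idx), yhat)
        except ValueError as err:  # degenerate held-out target
            warnings.warn(f"fold {held.session_id}: skipped ({err})")
            r, fold_nmse = np.nan, np.nan
        rows.append({"session_id": held.session_id, "lambda": lam,
                     "r": r, "nmse": fold_nmse})
    report = pd.DataFrame(rows).sort_values("session_id").reset_index(drop=True)
    counts = Counter(report["lambda"])
    top = max(counts.values())
    final_lam = max(lam for lam, c in counts.items() if c == top)
    X, y, _ = _concat_design(positive)
    w, b = ridge_fit(X, y, final_lam)
    model = EFPModel(
        w.reshape(n_bands, N_DELAYS), b, positive[0].band_scheme, final_lam,
        fit_meta={"session_id": "cEFP",
                  "sessions": sorted(ds.session_id for ds in positive),
                  "loo_mean_r": float(report["r"].mean())})
    return model, report


def cross_apply(
    model: EFPModel, sessions: list[SessionDataset]
) -> pd.DataFrame:
    """Per-session prediction correlation of one model across sessions.

    The returned frame carries ``r`` per session plus mean/sd in
    ``frame.attrs``.
    """
    rows = [{"session_id": ds.session_id,
             "r": evaluate_prediction(model, ds)} for ds in sessions]
    frame = pd.DataFrame(rows)
    frame.attrs["mean_r"] = float(frame["r"].mean())
    frame.attrs["sd_r"] = float(frame["r"].std(ddof=1)) if len(frame) > 1 else 0.0
    return frame


class CommonEFP:
    """Common-model builder over a positive session pool (statsmodels-style)."""

    def __init__(self, sessions: list[SessionDataset]):
        self.sessions = sessions

    def fit(self, cv: CVConfig | None = None) -> "CommonEFPResults":
        model, report = fit_cefp(self.sessions, cv)
        return CommonEFPResults(self, model, report)


class CommonEFPResults:
    """Fitted cEFP with its leave-one-session-out validation report."""

    def __init__(self, builder: CommonEFP, model: EFPModel,
                 loo_report: pd.DataFrame):
        self.sessions = builder.sessions
        self.model = model
        self.loo_report = loo_report

    @property
    def coeffs(self) -> np.ndarray:
        return self.model.coeffs

    @property
    def lam(self) -> float:
        return self.model.lam

    def cross_apply(self, sessions: list[SessionDataset]) -> pd.DataFrame:
        return cross_apply(self.model, sessions)

    def summary(self) -> str:
        rep = self.loo_report
        lines = [
            "Common EFP (one-class ridge) results",
            "=" * 48,
            f"training sessions:     {len(self.sessions)}",
            f"final lambda (mode):   {self.model.lam:.4g}",
            f"LOO held-out r:        {rep['r'].mean():.3f} "
            f"+- {rep['r'].std(ddof=1):.3f}",
            f"LOO held-out NMSE:     {rep['nmse'].mean():.3f}",
            "-" * 48,
        ]
        for _, row in rep.iterrows():
            lines.append(f"  {row['session_id']:<12} lambda={row['lambda']:<10.4g}"
                         f" r={row['r']:.3f}")
        lines.append("=" * 48)
        return "\n".join(lines)
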