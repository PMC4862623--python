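"""Delay-embedded ridge regression: the EEG finger-print (EFP) model.

A BOLD value at time T is modelled as a linear function of the preceding
12 s of EEG band power: with 10 bands at 4 Hz that is a (10 x 48)
coefficient matrix over (frequency band, time delay) — the finger-print.
The regularization weight is chosen by repeated block cross-validation
(contiguous validation windows, respecting temporal autocorrelation),
minimizing normalized mean squared error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import bands as bd
from .dataset import DELAY_GRID_S, N_DELAYS, SessionDataset

_RANK_EPS = 1e-10


@dataclass
class CVConfig:
    """Inner cross-validation settings for regularization selection.

    n_inner_splits random contiguous validation windows of
    ``validation_fraction`` of the rows (block design); the lambda grid is
    log-spaced over the range of interest; ties in mean validation NMSE
    are broken toward the larger (more regularized) lambda.
    """

    n_inner_splits: int = 30
    validation_fraction: float = 0.2
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-2, 4, 25))
    seed: int = 0
    block_length_s: float = 0.25

    def __post_init__(self) -> None:
        self.lambda_grid = np.sort(np.asarray(self.lambda_grid, dtype=float))
        if self.lambda_grid.size == 0:
            raise ValueError("lambda grid must be nonempty")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class EFPModel:
    """A fitted finger-print: (n_bands x 48) ridge weights plus intercept."""

    coeffs: np.ndarray
    intercept: float
    band_scheme: bd.BandScheme
    lam: float
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 2 or self.coeffs.shape[1] != N_DELAYS:
            raise ValueError(f"coeffs must be (n_bands, {N_DELAYS})")
        if self.coeffs.shape[0] != self.band_scheme.n_bands:
            raise ValueError("coeffs row count must match the band scheme")

    @property
    def delay_grid_s(self) -> np.ndarray:
        return DELAY_GRID_S.copy()

    @property
    def weights(self) -> np.ndarray:
        """Flattened weights in design-matrix column order (band-major)."""
        return self.coeffs.ravel()

    def predict(self, ds: SessionDataset) -> tuple[np.ndarray, np.ndarray]:
        """Predicted BOLD on the session's valid rows -> (yhat, t_indices)."""
        X, _, t_idx = build_design_matrix(ds, require_bold=False)
        return X @ self.weights + self.intercept, t_idx

    def apply_window(self, window: np.ndarray) -> float:
        """One streamed value: element-wise product with a (bands x 48) window.

        ``window[:, j]`` is the band-power column at delay ``j * 0.25 s``
        before the prediction time (newest column first would be wrong:
        column 0 is delay 0).
        """
        if window.shape != self.coeffs.shape:
            raise ValueError("window shape must match the coefficient matrix")
        return float(np.sum(self.coeffs * window) + self.intercept)


def build_design_matrix(
    ds: SessionDataset, require_bold: bool = True
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Delay-embed a session into (X, y, t_indices).

    One row per band-grid sample t with a full 12-s history
    (t = 47 .. n-1); column (b * 48 + d) holds ``bands[b, t - d]``
    (band-major, delay ascending).  ``y`` is the BOLD value at the same
    samples (None when ``require_bold`` is False and coverage is partial).
    """
    vals = ds.bands.values
    n = vals.shape[1]
    if n < N_DELAYS:
        raise ValueError("session shorter than the 12-s delay window")
    # sw[b, i, j] = bands[b, i + j]; row t = i + 47, delay d -> j = 47 - d
    sw = sliding_window_view(vals, N_DELAYS, axis=1)
    X = sw[:, :, ::-1].transpose(1, 0, 2).reshape(n - N_DELAYS + 1, -1)
    t_idx = np.arange(N_DELAYS - 1, n)
    y = None
    if require_bold:
        y = ds.bold_at(t_idx)
    else:
        try:
            y = ds.bold_at(t_idx)
        except (IndexError, AttributeError):
            y = None
    return np.ascontiguousarray(X), y, t_idx


def ridge_fit(
    X: np.ndarray, y: np.ndarray, lam: float
) -> tuple[np.ndarray, float]:
    """Ridge solution on column-centered data; the intercept is unpenalized.

    Solves (Xc' Xc + lam I) w = Xc' yc with Xc, yc centered, then restores
    the intercept from the column means.  With lam = 0 on rank-deficient
    data the minimum-norm (pseudo-inverse) solution is returned and a
    warning is issued.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    if lam == 0:
        w, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
        if rank < X.shape[1]:
            warnings.warn("rank-deficient design with lambda=0; "
                          "returning the minimum-norm solution")
    else:
        G = Xc.T @ Xc + lam * np.eye(X.shape[1])
        w = np.linalg.solve(G, Xc.T @ yc)
    return w, float(y_mean - x_mean @ w)


def nmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared error normalized by the variance of the target."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("need equal-length series of length >= 2")
    var = y_true.var()
    if var == 0:
        raise ValueError("zero-variance target")
    return float(np.mean((y_true - y_pred) ** 2) / var)


def _moment_stats(X: np.ndarray, y: np.ndarray):
    """Sufficient statistics (gram, sums) for fast ridge downdating."""
    return X.T @ X, X.T @ y, X.sum(axis=0), y.sum(), X.shape[0]


def _ridge_from_moments(G, p, s, sy, n, lambdas):
    """Centered ridge solutions for all lambdas via one eigendecomposition.

    G = X'X, p = X'y, s = column sums, sy = sum(y), n = rows.  Eigenvalues
    below a relative floor are treated as null directions (pseudo-inverse
    behaviour at lambda ~ 0).
    """
    x_mean = s / n
    y_mean = sy / n
    Gc = G - np.outer(s, s) / n
    rhs = p - s * (sy / n)
    evals, evecs = np.linalg.eigh(Gc)
    proj = evecs.T @ rhs
    floor = _RANK_EPS * max(evals[-1], 1.0)
    out = []
    for lam in lambdas:
        denom = evals + lam
        scale = np.where(denom > floor, 1.0 / np.maximum(denom, floor), 0.0)
        w = evecs @ (proj * scale)
        out.append((w, float(y_mean - x_mean @ w)))
    return out


def _validation_windows(
    rng: np.random.Generator,
    group_bounds: list[tuple[int, int]],
    fraction: float,
) -> np.ndarray:
    """One contiguous validation window inside every group -> row mask."""
    mask = np.zeros(group_bounds[-1][1], dtype=bool)
    for lo, hi in group_bounds:
        m = hi - lo
        w = max(2, int(round(fraction * m)))
        start = lo + int(rng.integers(0, m - w + 1))
        mask[start : start + w] = True
    return mask


def inner_cv_select(
    X: np.ndarray,
    y: np.ndarray,
    cfg: CVConfig,
    group_bounds: list[tuple[int, int]] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose lambda by repeated contiguous-block validation splits.

    Each of ``cfg.n_inner_splits`` seeded splits holds out one uniformly
    placed contiguous window of ~20% of the rows (one window per session
    when ``group_bounds`` delimits concatenated sessions, so no window
    spans a session boundary); every lambda is fitted on the remaining rows
    and scored by validation NMSE.  Returns the lambda minimizing the mean
    NMSE across splits (ties toward larger lambda) and the full
    (split x lambda) NMSE table.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if group_bounds is None:
        group_bounds = [(0, n)]
    if group_bounds[-1][1] != n:
        raise ValueError("group bounds must cover all rows")
    rng = np.random.default_rng(cfg.seed)
    lambdas = cfg.lambda_grid
    G_full, p_full, s_full, sy_full, _ = _moment_stats(X, y)
    table = np.empty((cfg.n_inner_splits, lambdas.size))
    for split in range(cfg.n_inner_splits):
        val = _validation_windows(rng, group_bounds, cfg.validation_fraction)
        Xv, yv = X[val], y[val]
        Gv, pv, sv, syv, nv = _moment_stats(Xv, yv)
        n_tr = n - nv
        sols = _ridge_from_moments(
            G_full - Gv, p_full - pv, s_full - sv, sy_full - syv, n_tr, lambdas)
        for j, (w, b) in enumerate(sols):
            table[split, j] = nmse(yv, Xv @ w + b)
    mean_nmse = table.mean(axis=0)
    # ties toward larger lambda: last index on the ascending grid
    best = int(np.flatnonzero(mean_nmse == mean_nmse.min())[-1])
    cv_table = pd.DataFrame(table, columns=lambdas)
    cv_table.index.name = "split"
    return float(lambdas[best]), cv_table


def fit_individual_efp(ds: SessionDataset, cfg: CVConfig | None = None) -> EFPModel:
    """Fit one session's EFP: inner-CV lambda choice, then a full refit."""
    cfg = cfg or CVConfig()
    X, y, _ = build_design_matrix(ds)
    lam, cv_table = inner_cv_select(X, y, cfg)
    w, b = ridge_fit(X, y, lam)
    coeffs = w.reshape(ds.band_scheme.n_bands, N_DELAYS)
    return EFPModel(
        coeffs, b, ds.band_scheme, lam,
        fit_meta={
            "subject_id": ds.subject_id,
            "session_id": ds.session_id,
            "n_rows": X.shape[0],
            "cv_mean_nmse": cv_table.mean(axis=0).to_dict(),
        },
    )


def evaluate_prediction(model: EFPModel, ds: SessionDataset) -> float:
    """Pearson r between predicted and observed BOLD on the valid rows.

    A constant prediction (e.g. an all-zero model) has undefined
    correlation; by convention it scores 0 and a warning is issued.
    """
    if model.band_scheme.n_bands != ds.band_scheme.n_bands:
        raise ValueError("band count mismatch between model and session")
    yhat, t_idx = model.predict(ds)
    y = ds.bold_at(t_idx)
    if np.std(yhat) == 0:
        warnings.warn("constant prediction; correlation reported as 0")
        return 0.0
    return float(np.corrcoef(y, yhat)[0, 1])


class EFPRegression:
    """Single-session EFP model builder (statsmodels-style).

    Parameters
    ----------
    session : SessionDataset
        Normalized band powers plus z-scored BOLD.

    Examples
    --------
    >>> res = EFPRegression(session).fit()        # doctest: +SKIP
    >>> res.coeffs.shape
    (10, 48)
    """

    def __init__(self, session: SessionDataset):
        self.session = session
        self.exog, self.endog, self.t_indices = build_design_matrix(session)

    def fit(self, cv: CVConfig | None = None) -> "EFPResults":
        cv = cv or CVConfig()
        lam, cv_table = inner_cv_select(self.exog, self.endog, cv)
        w, b = ridge_fit(self.exog, self.endog, lam)
        model = EFPModel(
            w.reshape(self.session.band_scheme.n_bands, N_DELAYS),
            b, self.session.band_scheme, lam,
            fit_meta={"subject_id": self.session.subject_id,
                      "session_id": self.session.session_id,
                      "n_rows": self.exog.shape[0]},
        )
        return EFPResults(self, model, cv_table)


class EFPResults:
    """Fitted single-session EFP with CV diagnostics."""

    def __init__(self, model_builder: EFPRegression, model: EFPModel,
                 cv_table: pd.DataFrame):
        self.session = model_builder.session
        self.model = model
        self.cv_table = cv_table
        yhat = model_builder.exog @ model.weights + model.intercept
        self.fittedvalues = yhat
        self.rsquared_insample = float(
            np.corrcoef(model_builder.endog, yhat)[0, 1] ** 2)
        self.nmse_insample = nmse(model_builder.endog, yhat)

    @property
    def coeffs(self) -> np.ndarray:
        return self.model.coeffs

    @property
    def lam(self) -> float:
        return self.model.lam

    def evaluate(self, ds: SessionDataset) -> float:
        return evaluate_prediction(self.model, ds)

    def coeff_frame(self) -> pd.DataFrame:
        """Coefficients as a DataFrame (band interval x delay seconds)."""
        edges = self.model.band_scheme.edges_hz
        idx = [f"[{lo:g},{hi:g}) Hz" for lo, hi in zip(edges[:-1], edges[1:])]
        return pd.DataFrame(self.model.coeffs, index=idx,
                            columns=DELAY_GRID_S)

    def summary(self) -> str:
        mean_nmse = self.cv_table.mean(axis=0)
        lines = [
            "EFP ridge regression results",
            "=" * 44,
            f"session:          {self.session.session_id or '-'}",
            f"subject:          {self.session.subject_id or '-'}",
            f"rows (12-s hist): {self.fittedvalues.size}",
            f"bands x delays:   {self.model.coeffs.shape[0]} x "
            f"{self.model.coeffs.shape[1]}",
            f"lambda (CV):      {self.model.lam:.4g}",
            f"CV mean NMSE:     {mean_nmse.loc[self.model.lam]:.4f}",
            f"in-sample NMSE:   {self.nmse_insample:.4f}",
            f"in-sample R^2:    {self.rsquared_insample:.4f}",
            "=" * 44,
        ]
        return "\n".join(lines)

    def plot_fingerprint(self, ax=None):
        """Heatmap of the coefficient matrix (band x delay)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        m = np.abs(self.model.coeffs).max() or 1.0
        im = ax.imshow(self.model.coeffs, aspect="auto", origin="lower",
                       extent=[0, 12, 0, self.model.coeffs.shape[0]],
                       cmap="RdBu_r", vmin=-m, vmax=m)
        ax.set_xlabel("delay (s)")
        ax.set_ylabel("frequency band")
        ax.figure.colorbar(im, ax=ax, label="weight")
        return ax
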