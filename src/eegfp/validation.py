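"""Simulation-based validation harnesses.

Each function runs one of the package's end-to-end checks on synthetic
studies with known ground truth and returns the measured quantities:
ridge-solver agreement with a dense oracle, planted-coefficient recovery,
one-class selection accuracy, common-model superiority over single-session
models, streaming-batch agreement, equal-area banding quality, and the
feedback-mapping anchors.  The problem sizes are chosen so a full battery
runs on a laptop in minutes; docs/methods.md discusses what they do and do
not establish about real recordings.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import bands as bd
from . import oneclass as oc
from . import realtime as rt
from .cefp import cross_apply, fit_cefp
from .dataset import N_DELAYS
from .regression import (CVConfig, EFPModel, evaluate_prediction,
                         fit_individual_efp, ridge_fit)
from .simulate import SimSpec, simulate_eeg, simulate_study

#: Coarser CV used by the heavier batteries (fewer splits, smaller grid);
#: model defaults stay at the 30-split, 25-point configuration.
FAST_CV = dict(n_inner_splits=10, lambda_grid=np.logspace(-1, 4, 8))


def _seed(base: int, offset: int) -> int:
    return int((base + 7919 * offset) % 2**31)


def ridge_oracle_check(seed: int, n_instances: int = 100) -> float:
    """Max |w - w_oracle| over random dense normal-equation instances."""
    rng = np.random.default_rng(seed % 2**31)
    worst = 0.0
    for _ in range(n_instances):
        n, p = int(rng.integers(20, 80)), int(rng.integers(3, 15))
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        lam = float(10 ** rng.uniform(-2, 3))
        w, b = ridge_fit(X, y, lam)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w_ref = np.linalg.inv(Xc.T @ Xc + lam * np.eye(p)) @ (Xc.T @ yc)
        worst = max(worst, float(np.max(np.abs(w - w_ref))))
    return worst


def parameter_recovery(
    seed: int,
    n_sessions: int = 10,
    duration_s: float = 300.0,
    snr: float = 10.0,
    holdout_fraction: float = 0.25,
) -> dict:
    """Fit planted sessions; report recovery and held-out prediction r.

    Each session is split in time: the model is fitted on the leading
    1 - holdout_fraction of the band-power grid and evaluated on the
    trailing segment.
    """
    recovery, heldout = [], []
    for i in range(n_sessions):
        spec = SimSpec(n_sessions=1, n_positive=1, duration_s=duration_s,
                       seed=_seed(seed, i), snr=snr)
        [session], [truth] = simulate_study(spec)
        n = session.n_times
        cut = int(round(n * (1 - holdout_fraction)))
        train = _slice_session(session, 0, cut)
        test = _slice_session(session, cut - (N_DELAYS - 1), n)
        model = fit_individual_efp(train, CVConfig(seed=_seed(seed, 1000 + i)))
        recovery.append(float(np.corrcoef(model.coeffs.ravel(),
                                          truth.coeffs.ravel())[0, 1]))
        heldout.append(evaluate_prediction(model, test))
    return {
        "recovery_r": np.asarray(recovery),
        "heldout_r": np.asarray(heldout),
        "median_recovery_r": float(np.median(recovery)),
        "median_heldout_r": float(np.median(heldout)),
    }


def _slice_session(session, start: int, stop: int):
    """A contiguous sub-session on band-grid samples [start, stop)."""
    from .dataset import SessionDataset

    vals = session.bands.values[:, start:stop]
    lo = max(start + N_DELAYS - 1, session.bold_offset)
    bold = session.bold_at(np.arange(lo, stop))
    return SessionDataset.from_arrays(
        vals, bold, session.band_scheme, bold_offset=lo - start,
        normalize_bands=False, zscore_bold=True,
        subject_id=session.subject_id, session_id=session.session_id)


def oneclass_recovery(
    seed: int,
    n_studies: int = 20,
    n_positive: int = 10,
    n_outliers: int = 5,
    duration_s: float = 240.0,
    outlier_perturbation: float = 3.0,
) -> dict:
    """Planted-label recovery of the full cluster-and-select pipeline."""
    uniform = bd.BandScheme.uniform()
    n_sessions = n_positive + n_outliers
    hits, ratios = [], []
    for s in range(n_studies):
        spec = SimSpec(n_sessions=n_sessions, n_positive=n_positive,
                       duration_s=duration_s, seed=_seed(seed, s),
                       outlier_perturbation=outlier_perturbation)
        sessions, _ = simulate_study(spec)
        cfg = CVConfig(seed=_seed(seed, 2000 + s), **FAST_CV)
        models = [fit_individual_efp(ds, cfg) for ds in sessions]
        vecs = [oc.rebin_efp(m, uniform) for m in models]
        within = [oc.efp_distance(vecs[a], vecs[b])
                  for a in range(n_positive) for b in range(a + 1, n_positive)]
        cross = [oc.efp_distance(vecs[a], vecs[b])
                 for a in range(n_positive) for b in range(n_positive, n_sessions)]
        ratios.append(float(np.mean(cross) / np.mean(within)))
        full = oc.cluster_efps(vecs, 1)
        stop_k = max(2, oc.knee_stop(full.merge_distances(), n_sessions))
        tree = oc.cluster_efps(vecs, stop_k)
        planted = {ds.session_id for ds in sessions[:n_positive]}
        try:
            selected = set(oc.select_positive(tree, n_positive))
        except ValueError:
            selected = set(tree.largest_cluster())
        hits.append(len(planted & selected))
    hits = np.asarray(hits)
    return {
        "hits": hits,
        "separation_ratios": np.asarray(ratios),
        "fraction_recovered": float(np.mean(hits >= n_positive - 1)),
    }


def cefp_superiority(
    seed: int,
    n_replicates: int = 20,
    n_train: int = 6,
    n_new: int = 4,
    duration_s: float = 180.0,
    include_contaminated: bool = False,
    n_contaminating: int = 3,
) -> dict:
    """Common model vs single-session model on fresh positive sessions.

    Every replicate simulates ``n_train`` positive training sessions plus
    ``n_new`` fresh sessions sharing the same planted coefficients, fits
    the common model (leave-one-session-out) and one single-session EFP,
    and compares their mean prediction r on the fresh sessions.  With
    ``include_contaminated`` a third model trained on the positives plus
    perturbed outlier sessions is evaluated as well.  One-sided sign-test
    p-values ask whether the common model wins more often than chance.
    """
    cefp_r, efp_r, contaminated_r = [], [], []
    for rep in range(n_replicates):
        total = n_train + n_new + (n_contaminating if include_contaminated else 0)
        spec = SimSpec(
            n_sessions=total, n_positive=n_train + n_new,
            duration_s=duration_s, seed=_seed(seed, 100 + rep))
        sessions, _ = simulate_study(spec)
        train = sessions[:n_train]
        new = sessions[n_train : n_train + n_new]
        cfg = CVConfig(seed=_seed(seed, 3000 + rep), **FAST_CV)
        cmodel, _ = fit_cefp(train, cfg)
        cefp_r.append(cross_apply(cmodel, new).attrs["mean_r"])
        single = fit_individual_efp(train[0], cfg)
        efp_r.append(cross_apply(single, new).attrs["mean_r"])
        if include_contaminated:
            pool = train + sessions[n_train + n_new :]
            dirty, _ = fit_cefp(pool, cfg)
            contaminated_r.append(cross_apply(dirty, new).attrs["mean_r"])
    cefp_r = np.asarray(cefp_r)
    efp_r = np.asarray(efp_r)
    out = {
        "cefp_r": cefp_r,
        "efp_r": efp_r,
        "mean_cefp_r": float(cefp_r.mean()),
        "mean_efp_r": float(efp_r.mean()),
        "wins_vs_efp": int(np.sum(cefp_r > efp_r)),
        "sign_p_vs_efp": _sign_test(cefp_r, efp_r),
    }
    if include_contaminated:
        contaminated_r = np.asarray(contaminated_r)
        out["contaminated_r"] = contaminated_r
        out["wins_vs_contaminated"] = int(np.sum(cefp_r > contaminated_r))
        out["sign_p_vs_contaminated"] = _sign_test(cefp_r, contaminated_r)
    return out


def _sign_test(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided sign test for median(a - b) > 0 (ties dropped)."""
    diff = a - b
    n = int(np.sum(diff != 0))
    wins = int(np.sum(diff > 0))
    return float(stats.binomtest(wins, n, 0.5, alternative="greater").pvalue)


def streaming_equivalence(
    seed: int, duration_s: float = 300.0, rate_hz: float = 250.0
) -> dict:
    """Max |streamed - replayed| cEFP value on one synthetic stream."""
    spec = SimSpec(n_sessions=1, n_positive=1, duration_s=duration_s,
                   seed=seed % 2**31, eeg_rate_hz=rate_hz)
    rec = simulate_eeg(spec, 0)
    x = rec.channel("Pz")
    rng = np.random.default_rng(seed % 2**31)
    model = EFPModel(
        rng.standard_normal((spec.band_scheme.n_bands, N_DELAYS)), 0.1,
        spec.band_scheme, 1.0)
    n_rest = int(60 * rate_hz)
    ref, _, _ = rt.rest_calibration(x[:n_rest], rate_hz, model)
    offline = rt.replay(model, x, rate_hz, ref)
    state = rt.StreamState(model=model, ref=ref, rate_hz=rate_hz)
    streamed = []
    ps = state.packet_samples
    for start in range(0, x.size - ps + 1, ps):
        v = rt.push_packet(state, x[start : start + ps])
        if v is not rt.WARMING_UP:
            streamed.append(v)
    streamed = np.asarray(streamed)
    offline_v = offline["value"].to_numpy()
    return {
        "n_emissions": streamed.size,
        "max_abs_diff": float(np.max(np.abs(streamed - offline_v))),
    }


def banding_quality(seed: int, n_spectra: int = 50) -> dict:
    """Equal-area banding on random positive spectra plus the flat case.

    For each spectrum the maximum deviation of a band's area from
    total/n_bands is reported in units of the largest single-bin area.
    """
    rng = np.random.default_rng(seed % 2**31)
    worst = 0.0
    freqs = np.arange(1.0, 41.0)
    for _ in range(n_spectra):
        spectrum = rng.uniform(0.2, 3.0, freqs.size)
        spectrum *= np.exp(-freqs / rng.uniform(5, 50))
        spectrum += 0.05
        scheme = bd.equal_area_bands(spectrum, freqs)
        areas = bd.band_areas(spectrum, scheme, freqs)
        dev = np.max(np.abs(areas - spectrum.sum() / bd.N_BANDS))
        worst = max(worst, float(dev / spectrum.max()))
    flat = bd.equal_area_bands(np.ones(40), freqs)
    flat_uniform = np.allclose(np.diff(flat.edges_hz), 4.0)
    return {"max_area_deviation_bins": worst, "flat_is_uniform": bool(flat_uniform)}


def feedback_mapping_check() -> dict:
    """Anchor values of the dB mapping and the per-period sd rescaling."""
    fb = rt.FeedbackState(rest_mean=0.2, current_sd=0.5)
    at_mean = rt.map_to_db(fb, 0.2)
    up_one = rt.map_to_db(fb, 0.7)
    down_ten = rt.map_to_db(fb, 0.2 - 10 * 0.5)
    fb.period_values = [0.0, 2.0]
    rt.end_period(fb)
    return {
        "db_at_rest_mean": at_mean,
        "db_at_plus_one_sd": up_one,
        "db_at_minus_ten_sd": down_ten,
        "sd_after_period_reset": fb.current_sd,
    }
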