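"""Latent-variable chemometrics: NIPALS PLS1 regression with LOOCV,
VIP-based band selection, and PCA.

The PLS implementation is a hand-rolled NIPALS PLS1 with X-deflation on
mean-centered data (no variance scaling by default, the usual choice for
derivative spectra).  Variable importance in projection (VIP) follows the
standard Wold definition, whose squared scores average to exactly one
across channels; VIP >= 1 is the conventional selection threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class PLSModel:
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # W, channels x LV (unit columns)
    x_loadings: np.ndarray  # P, channels x LV
    y_loadings: np.ndarray  # q, LV
    scores: np.ndarray  # T, samples x LV
    regression_vector: np.ndarray  # b, channels
    fitted: np.ndarray  # training-set predictions

    @property
    def n_channels(self) -> int:
        return self.x_mean.size


@dataclass
class CVResult:
    rmse: float
    r_squared: float
    rpd: float
    predictions: np.ndarray
    scheme: str  # "loocv" | "auto"
    r_squared_corr: float = float("nan")  # squared Pearson, for transparency


@dataclass
class VIPResult:
    scores: np.ndarray
    threshold: float
    selected_bands: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_pct: np.ndarray


def pls_fit(X: np.ndarray, y: np.ndarray, n_lv: int = 10) -> PLSModel:
    """NIPALS PLS1 on mean-centered X and y.

    Each component takes the weight direction w = X'y / ||X'y||, scores
    t = Xw, loadings p = X't / t't and q = y't / t't, then deflates X by
    t p'.  The regression vector b = W (P'W)^-1 q reproduces the fitted
    values as (X - x_mean) b + y_mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if n < 3:
        raise ValueError("PLS requires at least 3 samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    max_lv = min(n - 1, p)
    if not (1 <= n_lv <= max_lv):
        raise ValueError(f"n_lv must be in [1, {max_lv}] for this data")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; nothing to regress on")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    scale = np.linalg.norm(E) * max(np.linalg.norm(f), 1.0)

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    for a in range(n_lv):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(scale, 1.0):
            raise ValueError(
                f"X exhausted after {a} components; reduce n_lv to at most {a}"
            )
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt <= 1e-24 * max(scale, 1.0) ** 2:
            raise ValueError(
                f"degenerate score on component {a + 1}; reduce n_lv to at most {a}"
            )
        pvec = (E.T @ t) / tt
        qa = float(f @ t) / tt
        E = E - np.outer(t, pvec)
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t

    b = W @ np.linalg.solve(P.T @ W, q)
    fitted = (X - x_mean) @ b + y_mean
    return PLSModel(
        n_lv=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        regression_vector=b,
        fitted=fitted,
    )


def pls_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_channels:
        raise ValueError(
            f"X_new has {X_new.shape[1]} channels, model expects {model.n_channels}"
        )
    return (X_new - model.x_mean) @ model.regression_vector + model.y_mean


def _metrics(observed: np.ndarray, predicted: np.ndarray, scheme: str) -> CVResult:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    resid = observed - predicted
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    sd = float(observed.std(ddof=1))
    rpd = sd / rmse if rmse > 0 else float("inf")
    if np.ptp(predicted) > 0 and np.ptp(observed) > 0:
        r2c = float(np.corrcoef(observed, predicted)[0, 1] ** 2)
    else:
        r2c = float("nan")
    return CVResult(
        rmse=rmse,
        r_squared=r2,
        rpd=rpd,
        predictions=predicted,
        scheme=scheme,
        r_squared_corr=r2c,
    )


def loocv(X: np.ndarray, y: np.ndarray, n_lv: int = 10) -> CVResult:
    """Leave-one-out cross-validation with a full refit per held-out sample."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < n_lv + 2:
        raise ValueError(f"LOOCV needs at least n_lv + 2 = {n_lv + 2} samples, got {n}")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            model = pls_fit(X[mask], y[mask], n_lv)
        except ValueError as exc:
            raise ValueError(f"LOOCV fit failed with sample {i} held out: {exc}") from exc
        preds[i] = pls_predict(model, X[i : i + 1])[0]
    return _metrics(y, preds, "loocv")


def auto_predict(X: np.ndarray, y: np.ndarray, n_lv: int = 10) -> CVResult:
    """Fit on all samples and evaluate on the same samples (optimistic)."""
    model = pls_fit(X, y, n_lv)
    return _metrics(np.asarray(y, dtype=float).ravel(), model.fitted, "auto")


def vip_scores(model: PLSModel, threshold: float = 1.0) -> VIPResult:
    """Wold VIP per channel.

    VIP_j = sqrt( p * sum_a[ SSY_a * (w_ja / ||w_a||)^2 ] / sum_a SSY_a )
    with SSY_a = q_a^2 * t_a' t_a; the mean of the squared scores is 1.
    """
    W, T, q = model.weights, model.scores, model.y_loadings
    p = W.shape[0]
    tt = np.einsum("ij,ij->j", T, T)
    ssy = q**2 * tt
    keep = ssy > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} degenerate PLS component(s) from VIP",
            stacklevel=2,
        )
    if not np.any(keep):
        raise ValueError("no non-degenerate components; VIP undefined")
    Wn = W[:, keep] / np.linalg.norm(W[:, keep], axis=0)
    scores = np.sqrt(p * (Wn**2 @ ssy[keep]) / ssy[keep].sum())
    return VIPResult(scores=scores, threshold=threshold)


def select_bands(vip: VIPResult, wavenumbers: np.ndarray) -> list[tuple[float, float]]:
    """Maximal runs of consecutive channels with VIP >= threshold,
    reported as (low, high) cm^-1 intervals in descending-wavenumber
    order (the reporting convention for mid-IR)."""
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if wavenumbers.size != vip.scores.size:
        raise ValueError("wavenumber grid does not match VIP score count")
    above = vip.scores >= vip.threshold
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(wavenumbers[start]), float(wavenumbers[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(wavenumbers[start]), float(wavenumbers[-1])))
    intervals.sort(key=lambda iv: -iv[1])
    vip.selected_bands = intervals
    return intervals


def pca(X: np.ndarray, n_components: int) -> PCAResult:
    """Mean-centered SVD; explained percentages from squared singular values."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if not (1 <= n_components <= max_comp):
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    pct = 100.0 * s[:n_components] ** 2 / total if total > 0 else np.zeros(n_components)
    return PCAResult(
        scores=U[:, :n_components] * s[:n_components],
        loadings=Vt[:n_components].T,
        explained_variance_pct=pct,
    )


def flag_outliers(cv: CVResult, observed: np.ndarray, n_mad: float = 3.0) -> np.ndarray:
    """Indices of samples whose CV residual exceeds ``n_mad`` times the
    robust residual scale (MAD * 1.4826).  Flagging only — callers decide
    whether to drop."""
    resid = np.asarray(observed, dtype=float) - cv.predictions
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad
    if scale == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(np.abs(resid - np.median(resid)) > n_mad * scale)


def suggest_n_lv(X: np.ndarray, y: np.ndarray, max_lv: int = 15) -> int:
    """Latent-variable count minimising RMSECV (ties to the smaller)."""
    n = np.asarray(y).ravel().size
    upper = min(max_lv, n - 2, np.asarray(X).shape[1])
    best_lv, best_rmse = 1, float("inf")
    for lv in range(1, upper + 1):
        rmse = loocv(X, y, lv).rmse
        if rmse < best_rmse:
            best_lv, best_rmse = lv, rmse
    return best_lv
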