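"""HRF-deconvolved conditional Granger causality (CGC).

Raw BOLD mixes neural dynamics with regionally variable hemodynamic
delays, so lag-based causality on BOLD can invert the true temporal
precedence.  The pipeline here therefore (1) estimates a per-ROI HRF by
regressing the ROI series on task-input basis regressors, (2) inverts it
by Wiener deconvolution to a pseudo-neural series, (3) selects a VAR
order by information criterion, and (4) computes, for every ordered ROI
pair (i -> j), the conditional Granger causality

    F(i -> j | rest) = ln( RSS_reduced / RSS_full )

where the full model regresses j on the lags of all ROIs and the
reduced model omits i's lags.  Conditioning on the remaining ROIs
removes indirect (pseudo-causal) routes that bivariate GC would report.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sp_signal

from .hrf import CANONICAL, HRFSpec
from .paradigm import TASK, BlockParadigm
from .synthetic import SubjectDataset


# ---------------------------------------------------------------------------
# HRF estimation from the task structure
# ---------------------------------------------------------------------------

@dataclass
class HRFEstimate:
    kernel: np.ndarray  # sampled at TR, unit peak
    basis_weights: np.ndarray
    time_to_peak_s: float
    fit_residual: float  # residual variance of the basis regression
    basis: str = "canonical+derivatives"
    tr_s: float = 3.0


def _canonical_basis(tr_s: float, hrf: HRFSpec = CANONICAL) -> np.ndarray:
    """Canonical kernel plus its latency derivative (rows).

    The latency derivative is d h(t; offset) / d offset at offset 0, so a
    fit y = a*h + b*D estimates a response shifted by roughly b/a seconds.
    """
    h = hrf.sample(tr_s, normalize="none")
    dt = 0.1
    h_shift = hrf.with_latency_offset(dt).sample(tr_s, normalize="none")
    latency_deriv = (h_shift - h) / dt
    return np.vstack([h, latency_deriv])


def _fir_basis(tr_s: float, duration_s: float = 24.0) -> np.ndarray:
    k = int(round(duration_s / tr_s))
    return np.eye(k)


def estimate_hrf(
    roi_series: np.ndarray,
    paradigm: BlockParadigm,
    basis: str = "canonical+derivatives",
    reference_hrf: HRFSpec = CANONICAL,
) -> HRFEstimate:
    """Estimate the ROI's HRF by modelling signal dynamics with the task
    inputs: regress the series on task-boxcar-convolved basis kernels
    (plus intercept and linear drift) and rebuild the kernel from the
    fitted weights, normalized to unit positive peak."""
    y = np.asarray(roi_series, float)
    if y.ndim != 1 or y.size != paradigm.n_volumes:
        raise ValueError("series length must equal paradigm n_volumes")
    if basis == "canonical+derivatives":
        B = _canonical_basis(paradigm.tr_s, reference_hrf)
    elif basis == "fir":
        B = _fir_basis(paradigm.tr_s)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    u = paradigm.boxcar(TASK)
    T = paradigm.n_volumes
    regs = np.vstack([np.convolve(u, b)[:T] for b in B])
    X = np.column_stack(
        [regs.T, np.ones(T), np.linspace(-1, 1, T)]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular HRF basis regression (collinear regressors)")
    w, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    nb = B.shape[0]
    resid = y - X @ w
    if basis == "canonical+derivatives":
        # reconstruct as a latency-shifted canonical kernel: the raw
        # weighted basis sum can be wild when the evoked signal is weak,
        # whereas a shift-constrained kernel is always physiological
        a, b = w[0], w[1]
        offset = 0.0 if a <= 0 else float(np.clip(b / a, -4.0, 4.0))
        spec = reference_hrf.with_latency_offset(offset)
        kernel = spec.sample(paradigm.tr_s)  # unit peak
        ttp = spec.time_to_peak_s
    else:
        kernel = w[:nb] @ B
        peak_ix = int(np.argmax(np.abs(kernel)))
        peak = kernel[peak_ix]
        if peak != 0:
            kernel = kernel / peak
        ttp = float(peak_ix * paradigm.tr_s)
    return HRFEstimate(
        kernel=kernel,
        basis_weights=w[:nb],
        time_to_peak_s=ttp,
        fit_residual=float(np.var(resid)),
        basis=basis,
        tr_s=paradigm.tr_s,
    )


# ---------------------------------------------------------------------------
# Wiener deconvolution
# ---------------------------------------------------------------------------

@dataclass
class DeconvolvedSeries:
    values: np.ndarray
    regularization: float
    hrf_used: Optional[HRFEstimate] = None


def default_regularization(
    series: np.ndarray, kernel: np.ndarray, factor: float = 0.1
) -> float:
    """Regularization scaled to a noise-floor estimate from the
    high-frequency tail of the series spectrum, relative to the kernel's
    peak spectral power."""
    y = np.asarray(series, float)
    Y = np.abs(np.fft.rfft(y - y.mean())) ** 2
    tail = Y[int(0.75 * len(Y)):]
    noise = float(np.median(tail)) if tail.size else float(np.median(Y))
    total = float(np.mean(Y)) + 1e-300
    H = np.abs(np.fft.rfft(kernel, n=max(len(y), len(kernel)))) ** 2
    return factor * (noise / total) * float(np.max(H))


def deconvolve(
    roi_series: np.ndarray,
    hrf: HRFEstimate,
    reg: Optional[float] = None,
) -> DeconvolvedSeries:
    """Frequency-domain Wiener inversion of one ROI series.

    X(w) = conj(H(w)) Y(w) / (|H(w)|^2 + reg), computed on a zero-padded
    grid to avoid circular wrap-around; the output is mean-centered.
    """
    y = np.asarray(roi_series, float)
    h = np.asarray(hrf.kernel, float)
    if not np.any(h):
        raise ValueError("HRF kernel is identically zero")
    if reg is None:
        reg = default_regularization(y, h)
    if reg <= 0:
        raise ValueError("regularization must be positive (reg > 0)")
    n = sp_fft.next_fast_len(len(y) + len(h))
    Y = np.fft.rfft(y, n)
    H = np.fft.rfft(h, n)
    X = np.conj(H) * Y / (np.abs(H) ** 2 + reg)
    x = np.fft.irfft(X, n)[: len(y)]
    return DeconvolvedSeries(
        values=x - x.mean(), regularization=float(reg), hrf_used=hrf
    )


# ---------------------------------------------------------------------------
# VAR machinery
# ---------------------------------------------------------------------------

@dataclass
class VARModel:
    order: int
    coefficients: np.ndarray  # (n, n, p): target, source, lag
    intercept: np.ndarray
    residual_cov: np.ndarray
    residuals: np.ndarray  # (T_eff, n)
    criterion_trace: dict = field(default_factory=dict)


def _lag_design(series: np.ndarray, order: int, offset: Optional[int] = None):
    """Targets Y (T_eff, n) and lagged design X (T_eff, 1 + n*order).

    Column 0 is the intercept; column 1 + (k-1)*n + j is region j at lag k.
    Rows start at ``offset`` (default ``order``) so alternative orders can
    share a common sample window.
    """
    s = np.asarray(series, float)
    n, T = s.shape
    offset = order if offset is None else offset
    if offset < order or T - offset < 2:
        raise ValueError("series too short for the requested lag order")
    rows = T - offset
    X = np.empty((rows, 1 + n * order))
    X[:, 0] = 1.0
    for k in range(1, order + 1):
        X[:, 1 + (k - 1) * n: 1 + k * n] = s[:, offset - k: T - k].T
    Y = s[:, offset:].T
    return Y, X


def _rss(X: np.ndarray, Y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.sum(resid**2, axis=0), beta, resid


def select_order(
    series: np.ndarray,
    max_order: int = 5,
    criterion: str = "bic",
) -> int:
    """Order in 1..max_order minimizing AIC/BIC on a common sample window."""
    s = np.asarray(series, float)
    n, T = s.shape
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if max_order >= T / 3:
        raise ValueError(
            f"max_order {max_order} too large for T = {T} (need < T/3)"
        )
    crit = criterion.lower()
    if crit not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    scores = {}
    for p in range(1, max_order + 1):
        Y, X = _lag_design(s, p, offset=max_order)
        rows = Y.shape[0]
        _, _, resid = _rss(X, Y)
        sigma = resid.T @ resid / rows
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            logdet = -np.inf
        k = p * n * n
        penalty = (2.0 if crit == "aic" else np.log(rows)) * k / rows
        scores[p] = float(logdet + penalty)
    return min(scores, key=scores.get)


def fit_var(series: np.ndarray, order: int) -> VARModel:
    """Per-equation least-squares VAR fit with intercept."""
    s = np.asarray(series, float)
    n, T = s.shape
    if T <= order * n + 1:
        raise ValueError(
            f"T = {T} too short to fit VAR({order}) on {n} regions"
        )
    Y, X = _lag_design(s, order)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear lagged regressors; VAR fit is singular")
    _, beta, resid = _rss(X, Y)
    rows = Y.shape[0]
    dof = rows - X.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    coeffs = np.empty((n, n, order))
    for k in range(order):
        coeffs[:, :, k] = beta[1 + k * n: 1 + (k + 1) * n, :].T
    return VARModel(
        order=order,
        coefficients=coeffs,
        intercept=beta[0, :].copy(),
        residual_cov=resid.T @ resid / dof,
        residuals=resid,
    )


# ---------------------------------------------------------------------------
# conditional Granger causality
# ---------------------------------------------------------------------------

GC_FLOOR = -1e-10


def conditional_gc(
    series: np.ndarray,
    source: int,
    target: int,
    conditioning: Optional[Sequence[int]] = None,
    order: int = 1,
) -> float:
    """F(source -> target | conditioning) for one ordered pair.

    The full model regresses the target on the lags of {target, source,
    conditioning}; the reduced model omits the source's lags.  Both use
    the same sample, so the raw log RSS ratio is non-negative up to
    numerical tolerance.
    """
    s = np.asarray(series, float)
    if source == target:
        raise ValueError("source and target must differ")
    cond = [] if conditioning is None else list(conditioning)
    keep = sorted({target, source, *cond})
    sub = s[keep]
    src_ix = keep.index(source)
    tgt_ix = keep.index(target)
    F = cgc_matrix(sub, order=order)
    return float(F[src_ix, tgt_ix])


def cgc_matrix(series: np.ndarray, order: int = 1) -> np.ndarray:
    """Conditional GC for every ordered pair, conditioned on all others.

    Entry [i, j] is F(i -> j | rest); the diagonal is NaN.  Values below
    the -1e-10 numerical floor raise, as the nested least-squares fits
    share one sample and cannot legitimately produce them.
    """
    s = np.asarray(series, float)
    n, T = s.shape
    Y, X = _lag_design(s, order)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear lagged regressors; CGC fit is singular")
    rss_full, _, _ = _rss(X, Y)
    if np.any(rss_full <= 0):
        bad = int(np.argmin(rss_full))
        raise ValueError(
            f"degenerate full-model fit (zero residual variance) for region "
            f"{bad}"
        )
    F = np.full((n, n), np.nan)
    all_cols = np.arange(X.shape[1])
    for src in range(n):
        drop = 1 + src + n * np.arange(order)
        keep_cols = np.setdiff1d(all_cols, drop)
        rss_red, _, _ = _rss(X[:, keep_cols], Y)
        with np.errstate(divide="ignore"):
            F[src, :] = np.log(rss_red / rss_full)
    np.fill_diagonal(F, np.nan)
    off = ~np.eye(n, dtype=bool)
    if np.any(F[off] < GC_FLOOR):
        raise FloatingPointError("conditional GC fell below the -1e-10 floor")
    return F


def pairwise_gc_matrix(series: np.ndarray, order: int = 1) -> np.ndarray:
    """Unconditional bivariate GC for every ordered pair (no conditioning)."""
    s = np.asarray(series, float)
    n = s.shape[0]
    F = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            sub = s[[i, j]] if i < j else s[[j, i]]
            G = cgc_matrix(sub, order=order)
            F[i, j] = G[0, 1] if i < j else G[1, 0]
    return F


# ---------------------------------------------------------------------------
# subject-level pipeline
# ---------------------------------------------------------------------------

@dataclass
class CGCMatrix:
    f_values: np.ndarray
    region_names: list
    order: int
    metadata: dict = field(default_factory=dict)
    #: the preprocessed series the CGC was computed on (deconvolved when
    #: deconvolution was enabled) — the series the bootstrap null must use
    analyzed_series: Optional[np.ndarray] = None

    def value(self, source: str, target: str) -> float:
        i = self.region_names.index(source)
        j = self.region_names.index(target)
        return float(self.f_values[i, j])


def preprocess_series(series: np.ndarray) -> np.ndarray:
    """Mean-center and linearly detrend each region series."""
    return sp_signal.detrend(np.asarray(series, float), axis=1, type="linear")


def remove_task_evoked(
    series: np.ndarray, paradigm: BlockParadigm, n_lags: int = 5
) -> np.ndarray:
    """Project out the task-locked component from each region series.

    Every region of a task experiment carries a copy of the (possibly
    lag-shifted) condition input; this deterministic common component is
    not causal coupling, and the autoregressive bootstrap null contains
    no counterpart for it, so it must not reach the VAR stage.  Each row
    is residualized against the task boxcar at lags 0..n_lags plus an
    intercept.
    """
    s = np.atleast_2d(np.asarray(series, float))
    T = s.shape[1]
    if T != paradigm.n_volumes:
        raise ValueError("series length must equal paradigm n_volumes")
    u = paradigm.boxcar(TASK)
    cols = [np.ones(T)]
    for k in range(n_lags + 1):
        shifted = np.zeros(T)
        shifted[k:] = u[: T - k]
        cols.append(shifted)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, s.T, rcond=None)
    return s - (X @ beta).T


def cgc_pipeline(
    subject: SubjectDataset,
    rois: Optional[list] = None,
    basis: str = "canonical+derivatives",
    deconvolve_bold: bool = True,
    reg: Optional[float] = None,
    max_order: int = 5,
    criterion: str = "aic",
    order: Optional[int] = None,
    remove_evoked: bool = True,
    evoked_lags: int = 5,
) -> CGCMatrix:
    """Full per-subject path: ROI series -> HRF estimate -> deconvolution
    -> task-evoked removal -> order selection -> conditional GC for every
    ordered pair.

    ``rois`` (list of :class:`~hemiflow.activation.ROIDefinition`)
    selects voxel-derived mean series; otherwise the subject's region
    series are used directly.  ``remove_evoked`` residualizes the series
    against lagged task boxcars before the VAR stage (see
    :func:`remove_task_evoked`); disable it only for methodological
    experiments on the evoked confound itself.
    """
    from .activation import extract_roi_series  # local to avoid cycle

    if rois is not None:
        if subject.voxel_data is None:
            raise ValueError("[roi-extraction] subject has no voxel data")
        series = np.vstack(
            [extract_roi_series(subject.voxel_data, r) for r in rois]
        )
        names = [r.name for r in rois]
    else:
        series = subject.roi_bold
        names = list(subject.region_names)
    if series.shape[0] < 3:
        raise ValueError(
            "[setup] conditional GC needs at least 3 ROIs "
            f"(got {series.shape[0]})"
        )
    hrfs = []
    if deconvolve_bold:
        rows = []
        for i in range(series.shape[0]):
            try:
                est = estimate_hrf(series[i], subject.paradigm, basis=basis)
                dec = deconvolve(series[i], est, reg=reg)
            except ValueError as e:
                raise ValueError(f"[hrf/deconvolution] ROI {names[i]}: {e}")
            hrfs.append(est)
            rows.append(dec.values)
        neural = np.vstack(rows)
    else:
        neural = series
    if remove_evoked:
        neural = remove_task_evoked(neural, subject.paradigm, evoked_lags)
    neural = preprocess_series(neural)
    try:
        p = order if order is not None else select_order(
            neural, max_order=max_order, criterion=criterion
        )
        F = cgc_matrix(neural, order=p)
    except ValueError as e:
        raise ValueError(f"[var/cgc] {e}")
    return CGCMatrix(
        f_values=F,
        region_names=names,
        order=p,
        analyzed_series=neural,
        metadata={
            "deconvolved": deconvolve_bold,
            "basis": basis if deconvolve_bold else None,
            "order_criterion": criterion if order is None else "fixed",
            "hrf_time_to_peak_s": [h.time_to_peak_s for h in hrfs],
            "seed": subject.seed,
        },
    )
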