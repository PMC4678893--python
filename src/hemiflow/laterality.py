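"""Threshold-free lateralization index (LI).

Activated-voxel counts in the left and right territory are traced over
an ascending grid of t cutoffs; a decay model fitted to each hemisphere's
count-versus-threshold curve provides a constant term per side, and

    LI = (c_left - c_right) / (c_left + c_right)

so the index does not hinge on any single statistical threshold.
Positive LI marks left-hemisphere dominance.  Categories use inclusive
boundaries: left-lateralized when LI >= 0.2, right-lateralized when
LI <= -0.2, non-lateralized otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import LEFT, RIGHT

LEFT_LATERALIZED = "left-lateralized"
RIGHT_LATERALIZED = "right-lateralized"
NON_LATERALIZED = "non-lateralized"

LI_BOUNDARY = 0.2

#: log-domain fitting ignores thresholds with fewer than this many voxels
SMALL_COUNT_FLOOR = 5


@dataclass
class LICurve:
    thresholds: np.ndarray
    n_left: np.ndarray
    n_right: np.ndarray

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, float)
        self.n_left = np.asarray(self.n_left)
        self.n_right = np.asarray(self.n_right)
        if not (len(self.thresholds) == len(self.n_left) == len(self.n_right)):
            raise ValueError("curve arrays must share length")


@dataclass
class LIFit:
    model_form: str
    c_left: float
    c_right: float
    decay_left: float
    decay_right: float
    goodness: float  # mean squared residual on log counts


@dataclass
class LIResult:
    li: float
    category: str
    territory: str = "all"


def default_threshold_grid(tmap: np.ndarray, n_steps: int = 40) -> np.ndarray:
    """t cutoffs from 0 to the map's 99.9th percentile in equal steps."""
    hi = float(np.percentile(np.asarray(tmap), 99.9))
    if hi <= 0:
        hi = float(max(np.max(tmap), 1e-6))
    return np.linspace(0.0, hi, n_steps)


def count_curve(
    tmap: np.ndarray,
    hemisphere_mask: np.ndarray,
    thresholds: np.ndarray,
    territory: Optional[np.ndarray] = None,
    territory_name: str = "all",
) -> LICurve:
    """Count activated voxels per hemisphere at each cutoff.

    ``hemisphere_mask`` holds 'L' / 'R' / 'midline' per voxel;
    ``territory`` optionally restricts counting to a voxel subset (e.g.
    the cerebral or cerebellar label set).  Midline voxels count for
    neither side.
    """
    t = np.asarray(tmap, float).ravel()
    hemi = np.asarray(hemisphere_mask).ravel()
    thresholds = np.asarray(thresholds, float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly ascending")
    sel = np.ones(t.shape, dtype=bool)
    if territory is not None:
        sel = np.asarray(territory).ravel().astype(bool)
    left = sel & (hemi == LEFT)
    right = sel & (hemi == RIGHT)
    if not np.any(left) or not np.any(right):
        raise ValueError(
            f"territory {territory_name!r} is empty in one hemisphere; "
            "LI is undefined"
        )
    tl, tr_ = t[left], t[right]
    n_left = np.array([(tl >= thr).sum() for thr in thresholds])
    n_right = np.array([(tr_ >= thr).sum() for thr in thresholds])
    return LICurve(thresholds, n_left, n_right)


def _fit_side(thr: np.ndarray, counts: np.ndarray) -> tuple:
    """Fit N(t) = c * exp(-lam * t) to one hemisphere's curve.

    Ordinary least squares on log counts; small-count points (N < 5) are
    excluded — zero counts have no log, and the log of a handful of
    voxels is so noisy that keeping such points makes the fit drift with
    the threshold-grid density.  If fewer than 4 usable points remain
    the tail is too sparse for the log fit, and we fall back to
    nonlinear least squares on the raw counts.
    """
    counts = np.asarray(counts, float)
    if np.all(counts == 0):
        return 0.0, np.nan, 0.0
    pos = counts >= SMALL_COUNT_FLOOR
    if pos.sum() >= 4:
        x, y = thr[pos], np.log(counts[pos])
        w = np.ones(int(pos.sum()))
        W = w / w.sum()
        xm, ym = np.sum(W * x), np.sum(W * y)
        sxx = np.sum(W * (x - xm) ** 2)
        slope = 0.0 if sxx == 0 else np.sum(W * (x - xm) * (y - ym)) / sxx
        intercept = ym - slope * xm
        resid = y - (intercept + slope * x)
        return float(np.exp(intercept)), float(-slope), float(np.mean(resid**2))
    # sparse tail: nonlinear fit on raw counts
    c0 = max(counts.max(), 1.0)

    def model(t, c, lam):
        return c * np.exp(-lam * t)

    try:
        (c, lam), _ = curve_fit(
            model, thr, counts, p0=(c0, 0.5),
            bounds=((0, 0), (np.inf, np.inf)), maxfev=10000,
        )
    except RuntimeError:
        return float(c0), np.nan, np.inf
    resid = counts - model(thr, c, lam)
    return float(c), float(lam), float(np.mean(resid**2))


def fit_curve(curve: LICurve) -> LIFit:
    """Fit the per-hemisphere exponential decay model to a count curve."""
    if len(curve.thresholds) < 4:
        raise ValueError("need at least 4 thresholds to fit the decay model")
    if np.all(curve.n_left == 0) and np.all(curve.n_right == 0):
        raise ValueError("all counts are zero on both sides; nothing to fit")
    cl, ll, gl = _fit_side(curve.thresholds, curve.n_left)
    cr, lr, gr = _fit_side(curve.thresholds, curve.n_right)
    return LIFit(
        model_form="exponential-decay",
        c_left=cl, c_right=cr, decay_left=ll, decay_right=lr,
        goodness=float(np.nanmean([gl, gr])),
    )


def compute_li(fit: LIFit, territory: str = "all") -> LIResult:
    """Normalized left-right difference of the fitted constants."""
    total = fit.c_left + fit.c_right
    if total <= 0:
        raise ValueError("both fitted constants are zero; LI undefined")
    li = (fit.c_left - fit.c_right) / total
    return LIResult(li=float(li), category=categorize_li(li), territory=territory)


def categorize_li(li: float) -> str:
    if not -1.0 - 1e-12 <= li <= 1.0 + 1e-12:
        raise ValueError("|LI| must not exceed 1")
    if li >= LI_BOUNDARY:
        return LEFT_LATERALIZED
    if li <= -LI_BOUNDARY:
        return RIGHT_LATERALIZED
    return NON_LATERALIZED


def li_for_tmap(
    tmap: np.ndarray,
    hemisphere_mask: np.ndarray,
    territory: Optional[np.ndarray] = None,
    territory_name: str = "all",
    thresholds: Optional[np.ndarray] = None,
    n_steps: int = 40,
) -> tuple:
    """Convenience wrapper: counts -> fit -> LI for one t map.

    Returns ``(LIResult, LIFit, LICurve)``.
    """
    if thresholds is None:
        sel = (
            np.ones(np.asarray(tmap).shape, bool)
            if territory is None
            else np.asarray(territory, bool)
        )
        thresholds = default_threshold_grid(np.asarray(tmap)[sel], n_steps)
    curve = count_curve(
        tmap, hemisphere_mask, thresholds, territory, territory_name
    )
    fit = fit_curve(curve)
    return compute_li(fit, territory_name), fit, curve
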