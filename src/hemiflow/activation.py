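"""Voxelwise GLM activation mapping for a two-condition block design.

The task-versus-control contrast is estimated per voxel by ordinary
least squares on a design of HRF-convolved condition boxcars plus
polynomial drift terms; voxelwise one-sided t maps are thresholded by
Benjamini–Hochberg FDR, filtered by cluster extent, and combined across
groups by minimum-statistic conjunction.  Functional ROIs are defined by
masking the conjoint map with a parcellation, and task amplitude is
summarized as percent signal change relative to the ROI baseline.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence
import warnings

import numpy as np
from numpy.polynomial import legendre
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .hrf import CANONICAL, HRFSpec
from .paradigm import CONTROL, TASK, BlockParadigm
from .synthetic import Parcellation

T_CAP = 1e6  # reported t for an exact (zero-residual) fit


@dataclass
class DesignMatrix:
    """Named volume x regressor matrix for the block-design GLM."""

    names: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be (n_volumes, n_regressors)")
        rank = np.linalg.matrix_rank(self.values)
        if rank < len(self.names):
            raise ValueError(
                f"design is rank deficient (rank {rank} < {len(self.names)} "
                f"columns {self.names})"
            )

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def contrast_vector(self, weights: dict) -> np.ndarray:
        c = np.zeros(len(self.names))
        for name, w in weights.items():
            c[self.names.index(name)] = w
        return c


@dataclass
class GLMResult:
    beta: np.ndarray  # (n_regressors, n_voxels)
    contrast_t: np.ndarray  # (n_voxels,)
    df: int
    p: np.ndarray  # one-sided (contrast > 0)
    contrast_estimate: np.ndarray  # c'beta per voxel
    shape: Optional[tuple] = None  # spatial shape if input was 4-D

    def t_volume(self) -> np.ndarray:
        if self.shape is None:
            raise ValueError("result was fitted on a flat voxel matrix")
        return self.contrast_t.reshape(self.shape)


@dataclass
class ActivationMask:
    mask: np.ndarray  # boolean, flat or 3-D
    threshold_meta: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(np.sum(self.mask))


def build_design(
    paradigm: BlockParadigm,
    reference_hrf: HRFSpec = CANONICAL,
    drift_order: int = 1,
) -> DesignMatrix:
    """One HRF-convolved boxcar per condition, Legendre drift columns up
    to ``drift_order``, and an intercept."""
    kernel = reference_hrf.sample(paradigm.tr_s)
    cols, names = [], []
    for cond in (TASK, CONTROL):
        box = paradigm.boxcar(cond)
        if not np.any(box):
            raise ValueError(
                f"condition {cond!r} has no volumes; design would be rank "
                "deficient"
            )
        cols.append(np.convolve(box, kernel)[: paradigm.n_volumes])
        names.append(cond)
    t = np.linspace(-1, 1, paradigm.n_volumes)
    for k in range(1, drift_order + 1):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        cols.append(legendre.legval(t, coef))
        names.append(f"drift{k}")
    cols.append(np.ones(paradigm.n_volumes))
    names.append("intercept")
    return DesignMatrix(names, np.column_stack(cols))


def fit_glm(
    voxels: np.ndarray,
    design: DesignMatrix,
    contrast: Sequence[float],
) -> GLMResult:
    """Per-voxel OLS with a one-sided t test on ``contrast``.

    ``voxels`` may be (n_voxels, n_volumes) or a 4-D (x, y, z, time)
    volume; 4-D input is flattened and the spatial shape recorded.
    """
    voxels = np.asarray(voxels, float)
    shape = None
    if voxels.ndim == 4:
        shape = voxels.shape[:3]
        voxels = voxels.reshape(-1, voxels.shape[3])
    elif voxels.ndim == 1:
        voxels = voxels[None, :]
    X = design.values
    T, k = X.shape
    if voxels.shape[1] != T:
        raise ValueError("voxel time length does not match the design")
    if T <= k:
        raise ValueError(f"{T} volumes cannot identify {k} regressors")
    c = np.asarray(contrast, float)
    if c.shape != (k,):
        raise ValueError("contrast length must equal the regressor count")
    Y = voxels.T  # (T, V)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # (k, V)
    resid = Y - X @ beta
    df = T - k
    sigma2 = np.sum(resid**2, axis=0) / df
    denom2 = sigma2 * float(c @ xtx_inv @ c)
    est = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = est / np.sqrt(denom2)
    exact = denom2 <= np.finfo(float).tiny * 1e3
    tval = np.where(exact, np.sign(est) * T_CAP, tval)
    tval = np.clip(tval, -T_CAP, T_CAP)
    p = stats.t.sf(tval, df)
    return GLMResult(
        beta=beta, contrast_t=tval, df=df, p=p, contrast_estimate=est,
        shape=shape,
    )


def group_tmap(contrast_maps: np.ndarray):
    """Second-level one-sample t across subjects' contrast maps.

    ``contrast_maps`` is (n_subjects, ...); returns ``(t, p)`` arrays of
    the spatial shape, with one-sided p (mean contrast > 0).
    """
    maps = np.asarray(contrast_maps, float)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("group t-map needs at least 2 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.sign(mean) * T_CAP, t)
    p = stats.t.sf(t, n - 1)
    return t, p


def fdr_threshold(p_values: np.ndarray, q: float = 0.01) -> ActivationMask:
    """Benjamini–Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return ActivationMask(
        mask=reject.reshape(p.shape),
        threshold_meta={"method": "fdr_bh", "q": q},
    )


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def cluster_filter(
    mask: ActivationMask,
    min_voxels: int = 10,
    connectivity: int = 26,
    rule: str = ">",
) -> ActivationMask:
    """Remove connected components whose size fails the extent rule.

    ``rule=">"`` keeps clusters strictly larger than ``min_voxels`` (the
    operative map filter here); ``rule=">="`` keeps clusters of at least
    that size.
    """
    m = np.asarray(mask.mask)
    if m.ndim != 3:
        raise ValueError(
            "cluster filtering needs a 3-D mask; ROI-matrix input has no "
            "spatial geometry"
        )
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    if rule not in (">", ">="):
        raise ValueError("rule must be '>' or '>='")
    structure = ndimage.generate_binary_structure(
        3, _CONNECTIVITY_RANK[connectivity]
    )
    labelled, n = ndimage.label(m, structure=structure)
    keep = np.zeros_like(m)
    if n:
        sizes = np.bincount(labelled.ravel())[1:]
        ok = sizes > min_voxels if rule == ">" else sizes >= min_voxels
        keep = np.isin(labelled, np.nonzero(ok)[0] + 1)
    meta = dict(mask.threshold_meta)
    meta.update(
        {"min_voxels": min_voxels, "connectivity": connectivity, "rule": rule}
    )
    return ActivationMask(mask=keep, threshold_meta=meta)


def default_threshold_rule(
    q: float = 0.01, min_voxels: int = 10, connectivity: int = 26
) -> Callable:
    """The map-thresholding recipe: BH-FDR at ``q`` then cluster extent."""

    def rule(t: np.ndarray, p: np.ndarray) -> ActivationMask:
        m = fdr_threshold(p, q)
        if np.asarray(t).ndim == 3:
            m = cluster_filter(m, min_voxels=min_voxels, connectivity=connectivity)
        return m

    return rule


def conjunction(
    tmaps: Sequence[np.ndarray],
    pmaps: Sequence[np.ndarray],
    threshold_rule: Optional[Callable] = None,
) -> ActivationMask:
    """Minimum-statistic conjunction across group maps.

    A voxel survives only if it survives the thresholding rule in every
    group (the conjunction-null reading: min statistic over groups above
    every per-map threshold).
    """
    if len(tmaps) != len(pmaps) or not tmaps:
        raise ValueError("need matching, nonempty t and p map lists")
    shapes = {np.asarray(t).shape for t in tmaps}
    if len(shapes) != 1:
        raise ValueError(f"group maps disagree on geometry: {shapes}")
    rule = threshold_rule or default_threshold_rule()
    masks = [rule(np.asarray(t), np.asarray(p)) for t, p in zip(tmaps, pmaps)]
    out = masks[0].mask
    for m in masks[1:]:
        out = out & m.mask
    return ActivationMask(
        mask=out,
        threshold_meta={
            "conjunction": "minimum-statistic",
            "n_groups": len(tmaps),
            "per_map": masks[0].threshold_meta,
        },
    )


@dataclass
class ROIDefinition:
    name: str
    voxel_ids: np.ndarray  # (n, 3) voxel indices
    hemisphere: str

    def __post_init__(self):
        self.voxel_ids = np.asarray(self.voxel_ids)
        if self.voxel_ids.size == 0:
            raise ValueError(f"ROI {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return self.voxel_ids.shape[0]

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxel_ids.T)] = True
        return m


def define_rois(
    conjoint: ActivationMask, parcellation: Parcellation
) -> list:
    """One ROI per parcellation label intersecting the conjoint mask."""
    mask = np.asarray(conjoint.mask)
    if mask.shape != parcellation.labels.shape:
        raise ValueError("mask and parcellation geometry differ")
    rois = []
    for i, name in enumerate(parcellation.region_names):
        inter = mask & (parcellation.labels == i + 1)
        if not np.any(inter):
            continue
        rois.append(
            ROIDefinition(
                name=name,
                voxel_ids=np.argwhere(inter),
                hemisphere=parcellation.region_hemisphere[i],
            )
        )
    if not rois:
        warnings.warn(
            "conjoint mask does not intersect any parcel; no ROIs defined",
            stacklevel=2,
        )
    return rois


def extract_roi_series(voxels: np.ndarray, roi: ROIDefinition) -> np.ndarray:
    """Unweighted mean time series across the ROI's member voxels."""
    v = np.asarray(voxels, float)
    if v.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, time) volume")
    return v[tuple(roi.voxel_ids.T)].mean(axis=0)


def percent_signal_change(
    roi_series: np.ndarray,
    design: DesignMatrix,
    contrast: Sequence[float],
) -> float:
    """Task-contrast amplitude as percent of the ROI baseline.

    The contrast estimate is scaled by the peak height of the
    contrast-combined condition regressor (so a unit beta on a unit-peak
    regressor is one signal unit) and normalized by the intercept
    estimate — the usual toolbox convention for block designs.
    """
    res = fit_glm(np.asarray(roi_series, float)[None, :], design, contrast)
    c = np.asarray(contrast, float)
    cond_idx = [
        i for i, n in enumerate(design.names) if n in (TASK, CONTROL)
    ]
    combined = design.values[:, cond_idx] @ c[cond_idx]
    peak = float(np.max(np.abs(combined))) if np.any(combined) else 1.0
    baseline = float(res.beta[design.names.index("intercept"), 0])
    if baseline <= 0:
        raise ValueError(
            f"non-positive baseline estimate ({baseline:.3g}); percent "
            "signal change undefined"
        )
    return 100.0 * float(res.contrast_estimate[0]) * peak / baseline
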