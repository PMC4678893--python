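"""Significance thresholding and group analysis of directed CGC networks.

A nonparametric bootstrap sets the significance cutoff for conditional
GC values: the fitted VAR with all cross-region coefficients zeroed
(autocorrelation preserved, coupling destroyed) is re-simulated with
resampled residuals, CGC is recomputed per replicate, and the empirical
(1 - alpha) quantile of the pooled null edge values becomes the
threshold.  Thresholded digraphs are summarized by In-Out degrees (in
minus out; negative marks causal sources, positive causal targets) and
by inter-/intra-hemispheric connection counts, and groups are compared
edgewise (one-tailed Welch t with Bonferroni FWE control) and countwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cgc import CGCMatrix, VARModel, cgc_matrix, fit_var
from .synthetic import LEFT, MIDLINE, RIGHT, hemisphere_of


# ---------------------------------------------------------------------------
# bootstrap null
# ---------------------------------------------------------------------------

@dataclass
class BootstrapNull:
    n_reps: int
    null_values: np.ndarray  # (n_reps, n, n) off-diagonal null CGC values
    alpha: float
    threshold: float
    scheme: str = "zeroed-cross-VAR residual bootstrap"
    seed: Optional[int] = None
    #: optional matching null for unconditional (bivariate) GC values
    pairwise_null_values: Optional[np.ndarray] = None
    pairwise_threshold: Optional[float] = None

    def pooled(self) -> np.ndarray:
        n = self.null_values.shape[1]
        off = ~np.eye(n, dtype=bool)
        return self.null_values[:, off].ravel()


def _decoupled_coefficients(var_fit: VARModel) -> np.ndarray:
    """Zero every cross-region coefficient, keeping self-lags; shrink the
    self-lags if that (rarely) leaves an unstable univariate AR."""
    a = var_fit.coefficients.copy()
    n = a.shape[0]
    mask = np.eye(n, dtype=bool)
    for k in range(a.shape[2]):
        a[:, :, k] = np.where(mask, a[:, :, k], 0.0)
    for i in range(n):
        # univariate stability: companion roots of the self-lag polynomial
        guard = 0
        while guard < 50:
            poly = np.r_[1.0, -a[i, i, :]]
            roots = np.roots(poly)
            if len(roots) == 0 or np.max(np.abs(roots)) < 0.999:
                break
            a[i, i, :] *= 0.95
            guard += 1
    return a


def _simulate_null(
    a: np.ndarray,
    residuals: np.ndarray,
    T: int,
    rng: np.random.Generator,
    burn_in: int = 100,
) -> np.ndarray:
    n, _, p = a.shape
    idx = rng.integers(0, residuals.shape[0], size=burn_in + T)
    e = residuals[idx].T  # (n, burn_in+T), rows resampled jointly
    x = np.zeros((n, burn_in + T))
    for t in range(burn_in + T):
        acc = e[:, t].copy()
        for k in range(1, p + 1):
            if t - k >= 0:
                acc += a[:, :, k - 1] @ x[:, t - k]
        x[:, t] = acc
    return x[:, burn_in:]


def bootstrap_threshold(
    series: np.ndarray,
    var_fit: Optional[VARModel] = None,
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    order: Optional[int] = None,
    include_pairwise: bool = False,
) -> BootstrapNull:
    """Bootstrap significance threshold for CGC values of one subject.

    With ``include_pairwise`` the same null replicates also yield a
    threshold for unconditional bivariate GC, so conditional and
    pairwise statistics can be compared against matched null bands.
    """
    s = np.asarray(series, float)
    if var_fit is None:
        var_fit = fit_var(s, order or 1)
    if n_reps < 100:
        raise ValueError("n_reps < 100 makes the null quantile unstable")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    a = _decoupled_coefficients(var_fit)
    n = s.shape[0]
    T = s.shape[1]
    p = var_fit.order
    nulls = np.empty((n_reps, n, n))
    pw = np.empty((n_reps, n, n)) if include_pairwise else None
    resid = var_fit.residuals - var_fit.residuals.mean(axis=0)
    from .cgc import pairwise_gc_matrix, preprocess_series

    for r in range(n_reps):
        # the null replicate walks the same measurement path as the data
        x = preprocess_series(_simulate_null(a, resid, T, rng))
        nulls[r] = cgc_matrix(x, order=p)
        if include_pairwise:
            pw[r] = pairwise_gc_matrix(x, order=p)
    off = ~np.eye(n, dtype=bool)
    pooled = nulls[:, off].ravel()
    threshold = float(np.quantile(pooled, 1.0 - alpha))
    return BootstrapNull(
        n_reps=n_reps, null_values=nulls, alpha=alpha,
        threshold=threshold, seed=seed,
        pairwise_null_values=pw,
        pairwise_threshold=(
            float(np.quantile(pw[:, off].ravel(), 1.0 - alpha))
            if include_pairwise else None
        ),
    )


# ---------------------------------------------------------------------------
# significant network
# ---------------------------------------------------------------------------

@dataclass
class SignificantNetwork:
    adjacency: np.ndarray  # boolean (source, target)
    region_names: list
    node_hemisphere: list
    threshold_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, bool)
        np.fill_diagonal(self.adjacency, False)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def edges(self) -> list:
        return [
            (self.region_names[i], self.region_names[j])
            for i, j in np.argwhere(self.adjacency)
        ]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for name, hemi in zip(self.region_names, self.node_hemisphere):
            g.add_node(name, hemisphere=hemi)
        g.add_edges_from(self.edges())
        return g


def build_network(
    cgc: CGCMatrix,
    null: BootstrapNull,
    hemispheres: Optional[list] = None,
) -> SignificantNetwork:
    """Edge (i, j) present iff f_values[i, j] > the bootstrap threshold."""
    f = cgc.f_values
    if null.null_values.shape[1:] != f.shape:
        raise ValueError("null and CGC matrices disagree on ROI count")
    hemi = hemispheres or [hemisphere_of(r) for r in cgc.region_names]
    adj = np.zeros_like(f, dtype=bool)
    off = ~np.eye(f.shape[0], dtype=bool)
    adj[off] = f[off] > null.threshold
    return SignificantNetwork(
        adjacency=adj,
        region_names=list(cgc.region_names),
        node_hemisphere=list(hemi),
        threshold_meta={
            "alpha": null.alpha,
            "threshold": null.threshold,
            "n_reps": null.n_reps,
            "scheme": null.scheme,
        },
    )


def group_network(
    cgc_list: Sequence[CGCMatrix],
    null_list: Sequence[BootstrapNull],
    alpha_group: float = 0.01,
    method: str = "exceedance",
    hemispheres: Optional[list] = None,
) -> SignificantNetwork:
    """Aggregate subject-level networks into one group digraph.

    ``exceedance`` (default): an edge enters the group network when the
    count of subjects whose CGC exceeds their own bootstrap threshold is
    larger than chance (one-sample binomial test against the per-subject
    alpha, one-sided, at ``alpha_group``).  ``majority``: more than half
    the subjects carry the edge.
    """
    if len(cgc_list) != len(null_list) or not cgc_list:
        raise ValueError("need one bootstrap null per CGC matrix")
    names = list(cgc_list[0].region_names)
    n = len(names)
    exceed = np.zeros((n, n), dtype=int)
    for cgc, null in zip(cgc_list, null_list):
        if list(cgc.region_names) != names:
            raise ValueError("subjects disagree on ROI order")
        exceed += (cgc.f_values > null.threshold).astype(int)
    S = len(cgc_list)
    alpha0 = null_list[0].alpha
    if method == "exceedance":
        # P(X >= k) under Binomial(S, alpha0)
        pvals = stats.binom.sf(exceed - 1, S, alpha0)
        adj = pvals < alpha_group
    elif method == "majority":
        adj = exceed > S / 2
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    hemi = hemispheres or [hemisphere_of(r) for r in names]
    return SignificantNetwork(
        adjacency=adj,
        region_names=names,
        node_hemisphere=list(hemi),
        threshold_meta={
            "aggregation": method,
            "alpha_group": alpha_group,
            "per_subject_alpha": alpha0,
            "n_subjects": S,
        },
    )


# ---------------------------------------------------------------------------
# degrees and hemispheric counts
# ---------------------------------------------------------------------------

def in_out_degrees(net: SignificantNetwork) -> pd.DataFrame:
    """Degree table sorted by ascending In-Out degree (in minus out).

    Ties are broken by descending Out-degree when the tied In-Out degree
    is negative (stronger sources first) and by ascending In-degree when
    it is non-negative.
    """
    adj = net.adjacency
    out_deg = adj.sum(axis=1)
    in_deg = adj.sum(axis=0)
    in_out = in_deg - out_deg
    rows = [
        {
            "node": net.region_names[i],
            "hemisphere": net.node_hemisphere[i],
            "in_degree": int(in_deg[i]),
            "out_degree": int(out_deg[i]),
            "in_out": int(in_out[i]),
        }
        for i in range(len(net.region_names))
    ]

    def key(row):
        tie = -row["out_degree"] if row["in_out"] < 0 else row["in_degree"]
        return (row["in_out"], tie, row["node"])

    rows.sort(key=key)
    df = pd.DataFrame(rows)
    df.index = range(len(df))
    return df


@dataclass
class HemisphericCounts:
    inter_directional: int
    inter_bidirectional: int
    intra_left: int
    intra_right: int

    def as_dict(self) -> dict:
        return {
            "inter_directional": self.inter_directional,
            "inter_bidirectional": self.inter_bidirectional,
            "intra_left": self.intra_left,
            "intra_right": self.intra_right,
        }


def hemispheric_counts(net: SignificantNetwork) -> HemisphericCounts:
    """Count inter- and intra-hemispheric connections.

    A midline node contributes to neither intra count; a midline-lateral
    edge counts as inter-hemispheric.  A bidirectional inter connection
    is an unordered cross-hemisphere pair significant in both directions.
    """
    hemi = net.node_hemisphere
    adj = net.adjacency
    n = len(hemi)
    inter_dir = inter_bi = intra_l = intra_r = 0
    for i in range(n):
        for j in range(n):
            if i == j or not adj[i, j]:
                continue
            hi, hj = hemi[i], hemi[j]
            if hi == hj and hi == LEFT:
                intra_l += 1
            elif hi == hj and hi == RIGHT:
                intra_r += 1
            elif hi != hj or hi == MIDLINE:
                # differing hemispheres, or midline-midline (counts inter
                # only when one endpoint is lateralized)
                if hi == MIDLINE and hj == MIDLINE:
                    continue
                inter_dir += 1
                if j < i and adj[j, i]:
                    inter_bi += 1
    return HemisphericCounts(inter_dir, inter_bi, intra_l, intra_r)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def compare_edge_groups(
    group_a: Sequence[CGCMatrix],
    group_b: Sequence[CGCMatrix],
    direction: str = "greater",
    alpha_fwe: float = 0.01,
) -> pd.DataFrame:
    """One-tailed Welch two-sample t per ordered ROI pair, Bonferroni FWE.

    ``direction='greater'`` tests mean(A) > mean(B).  The corrected
    significance flag applies Bonferroni over the n*(n-1) ordered pairs
    at ``alpha_fwe``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    names = list(group_a[0].region_names)
    for m in list(group_a) + list(group_b):
        if list(m.region_names) != names:
            raise ValueError("groups disagree on ROI sets or order")
    A = np.stack([m.f_values for m in group_a])
    B = np.stack([m.f_values for m in group_b])
    n = len(names)
    m_tests = n * (n - 1)
    rows = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            t, p = stats.ttest_ind(
                A[:, i, j], B[:, i, j], equal_var=False, alternative=direction
            )
            rows.append(
                {
                    "source": names[i],
                    "target": names[j],
                    "t": float(t),
                    "p": float(p),
                    "significant": bool(p < alpha_fwe / m_tests),
                    "direction": "A>B" if t > 0 else "A<B",
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["correction"] = {
        "method": "bonferroni",
        "alpha_fwe": alpha_fwe,
        "n_tests": m_tests,
        "alternative": direction,
    }
    return df


#: the four hemispheric-count hypotheses, (field, alternative)
COUNT_HYPOTHESES = (
    ("inter_directional", "greater"),
    ("inter_bidirectional", "greater"),
    ("intra_left", "two-sided"),
    ("intra_right", "two-sided"),
)


def compare_count_groups(
    counts_a: Sequence[HemisphericCounts],
    counts_b: Sequence[HemisphericCounts],
    alpha: float = 0.01,
    hypotheses=COUNT_HYPOTHESES,
) -> pd.DataFrame:
    """Two-sample t tests on per-subject hemispheric connection counts.

    One-sided ("are there MORE in group A?") for the two inter-hemisphere
    hypotheses, two-sided ("is the number DIFFERENT?") for the two
    intra-hemisphere ones, each at the stated ``alpha``.
    """
    if len(counts_a) < 2 or len(counts_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    rows = []
    for fieldname, alternative in hypotheses:
        a = np.array([getattr(c, fieldname) for c in counts_a], float)
        b = np.array([getattr(c, fieldname) for c in counts_b], float)
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        rows.append(
            {
                "count": fieldname,
                "alternative": alternative,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "t": float(t),
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["alpha"] = alpha
    return df
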