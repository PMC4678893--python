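"""Ground-truth simulator for block-design BOLD with known causal structure.

Latent neural signals for a set of named brain regions follow a
vector-autoregressive (VAR) process driven by the task boxcar; each
region's BOLD is its latent signal convolved with a region-specific
double-gamma HRF plus Gaussian measurement noise.  Optionally the region
signals are broadcast to a small 3-D voxel lattice split into left and
right hemispheres, with a controllable left:right ratio of truly active
voxels, so activation mapping, lateralization and connectivity stages
can all be validated against known ground truth.

Two groups of simulated subjects ("LH-like" and "RH-like", after the
left- and right-handed cohorts such designs compare) differ in their
hemispheric asymmetry and in a small set of coupling edges.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .hrf import CANONICAL, HRFSpec
from .paradigm import CONTROL, TASK, BlockParadigm

LEFT, RIGHT, MIDLINE = "L", "R", "midline"

#: samples discarded before the paradigm window so initial-condition
#: transients never reach the outputs
DEFAULT_BURN_IN = 200


def hemisphere_of(name: str) -> str:
    if name.endswith("_L"):
        return LEFT
    if name.endswith("_R"):
        return RIGHT
    return MIDLINE


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def companion_spectral_radius(adjacency: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix of ``adjacency`` (n,n,p)."""
    a = np.asarray(adjacency, float)
    if a.ndim == 2:
        a = a[:, :, None]
    n, _, p = a.shape
    comp = np.zeros((n * p, n * p))
    for k in range(p):
        comp[:n, k * n:(k + 1) * n] = a[:, :, k]
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class GroundTruthNetwork:
    """Directed weighted coupling among simulated regions.

    ``adjacency[i, j, k]`` is the influence of region ``j`` at lag
    ``k+1`` on region ``i`` (rows receive, columns send) — the
    convention of the VAR update ``x_t = sum_k A_k x_{t-k} + ...``.
    """

    region_names: list
    adjacency: np.ndarray  # (n, n, p)
    noise_sd: np.ndarray  # per-region innovation SD
    hrf_specs: list  # per-region HRFSpec
    hemisphere: list = None

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, float)
        if self.adjacency.ndim == 2:
            self.adjacency = self.adjacency[:, :, None]
        n = len(self.region_names)
        if self.adjacency.shape[:2] != (n, n):
            raise ValueError("adjacency shape does not match region count")
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, float), (n,)
        ).copy()
        if len(self.hrf_specs) != n:
            raise ValueError("one HRFSpec per region required")
        if self.hemisphere is None:
            self.hemisphere = [hemisphere_of(r) for r in self.region_names]

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def order(self) -> int:
        return self.adjacency.shape[2]

    @property
    def spectral_radius(self) -> float:
        return companion_spectral_radius(self.adjacency)

    def is_stationary(self, tol: float = 1.0) -> bool:
        return self.spectral_radius < tol

    def edges(self, tol: float = 0.0) -> set:
        """Directed (source, target) pairs with |coupling| > tol at any lag."""
        out = set()
        strength = np.max(np.abs(self.adjacency), axis=2)
        n = self.n_regions
        for tgt in range(n):
            for src in range(n):
                if src != tgt and strength[tgt, src] > tol:
                    out.add((self.region_names[src], self.region_names[tgt]))
        return out

    def edge_matrix(self, tol: float = 0.0) -> np.ndarray:
        """Boolean (source, target) matrix of true edges, diagonal False."""
        strength = np.max(np.abs(self.adjacency), axis=2).T  # -> (src, tgt)
        m = strength > tol
        np.fill_diagonal(m, False)
        return m


def demo_network(
    coupling: float = 0.35,
    self_coupling: float = 0.3,
    noise_sd: float = 1.0,
    latency_offsets: Optional[dict] = None,
) -> GroundTruthNetwork:
    """An 8-region network loosely following the visual-to-frontal routes
    reported for semantic tasks (occipital -> insula -> precentral ->
    middle frontal, with right cerebellar crus1 as a target)."""
    names = [
        "IOG_L", "MOG_L", "MOG_R", "INS_L",
        "INS_R", "PreCG_L", "MFG_L", "CRB_crus1_R",
    ]
    idx = {r: i for i, r in enumerate(names)}
    edges = [
        ("IOG_L", "INS_L"),
        ("MOG_L", "INS_L"),
        ("MOG_R", "INS_R"),
        ("INS_L", "PreCG_L"),
        ("PreCG_L", "MFG_L"),
        ("MFG_L", "CRB_crus1_R"),
        ("IOG_L", "CRB_crus1_R"),
    ]
    n = len(names)
    a = np.zeros((n, n, 1))
    for i in range(n):
        a[i, i, 0] = self_coupling
    for src, tgt in edges:
        a[idx[tgt], idx[src], 0] = coupling
    offsets = latency_offsets or {}
    hrfs = [CANONICAL.with_latency_offset(offsets.get(r, 0.0)) for r in names]
    net = GroundTruthNetwork(names, a, noise_sd, hrfs)
    if not net.is_stationary():
        raise ValueError("demo network parameters yield a non-stationary VAR")
    return net


# ---------------------------------------------------------------------------
# latent neural dynamics
# ---------------------------------------------------------------------------

def _input_matrix(paradigm: BlockParadigm) -> np.ndarray:
    """(2, T) stacked boxcars, rows = (task, control)."""
    return np.vstack([paradigm.boxcar(TASK), paradigm.boxcar(CONTROL)])


def _as_gain(input_gain, n_regions: int) -> np.ndarray:
    """Normalize the per-region, per-condition input gain to shape (n, 2).

    A scalar drives the task condition only (control gain 0); a length-n
    vector likewise; a full (n, 2) array is used as given.
    """
    g = np.asarray(input_gain, float)
    if g.ndim == 0:
        out = np.zeros((n_regions, 2))
        out[:, 0] = g
        return out
    if g.ndim == 1:
        if g.shape[0] != n_regions:
            raise ValueError("gain vector length must equal region count")
        out = np.zeros((n_regions, 2))
        out[:, 0] = g
        return out
    if g.shape != (n_regions, 2):
        raise ValueError("gain must be scalar, (n,) or (n, 2)")
    return g


def simulate_neural_signals(
    network: GroundTruthNetwork,
    paradigm: BlockParadigm,
    input_gain=1.0,
    seed: int = 0,
    burn_in: int = DEFAULT_BURN_IN,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate latent region signals x_t = sum_k A_k x_{t-k} + g u_t + e_t.

    ``u_t`` is the (task, control) boxcar pair (zero during burn-in),
    ``e_t`` independent Gaussian innovations with the network's per-region
    SD.  The ``burn_in`` leading samples are discarded, so the returned
    matrix is (n_regions, paradigm.n_volumes).
    """
    if not network.is_stationary():
        raise ValueError(
            f"network is non-stationary (spectral radius "
            f"{network.spectral_radius:.3f} >= 1); refusing to simulate"
        )
    g = _as_gain(input_gain, network.n_regions)
    if not np.all(np.isfinite(g)):
        raise ValueError("input gains must be finite")
    rng = np.random.default_rng(seed) if rng is None else rng
    n, p = network.n_regions, network.order
    T = paradigm.n_volumes
    u = np.zeros((2, burn_in + T))
    u[:, burn_in:] = _input_matrix(paradigm)
    drive = g @ u  # (n, burn_in+T)
    e = rng.standard_normal((n, burn_in + T)) * network.noise_sd[:, None]
    x = np.zeros((n, burn_in + T))
    A = network.adjacency
    for t in range(burn_in + T):
        acc = drive[:, t] + e[:, t]
        for k in range(1, p + 1):
            if t - k >= 0:
                acc = acc + A[:, :, k - 1] @ x[:, t - k]
        x[:, t] = acc
    return x[:, burn_in:]


def convolve_and_sample(
    latent: np.ndarray,
    hrf_specs: Sequence[HRFSpec],
    tr_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Convolve each latent row with its own TR-sampled HRF kernel,
    truncate to the input length, and add Gaussian measurement noise."""
    latent = np.atleast_2d(np.asarray(latent, float))
    n, T = latent.shape
    if len(hrf_specs) != n:
        raise ValueError("one HRFSpec per latent row required")
    rng = np.random.default_rng(seed) if rng is None else rng
    out = np.empty_like(latent)
    for i, spec in enumerate(hrf_specs):
        kernel = spec.sample(tr_s)
        if kernel.size > T:
            raise ValueError(
                f"HRF kernel ({kernel.size} samples) longer than series ({T})"
            )
        out[i] = np.convolve(latent[i], kernel)[:T]
    if noise_sd > 0:
        out = out + rng.standard_normal(out.shape) * noise_sd
    return out


# ---------------------------------------------------------------------------
# voxel geometry
# ---------------------------------------------------------------------------

@dataclass
class Parcellation:
    """Integer-labelled voxel lattice with an affine mapping to world mm.

    Label 0 is background; label ``i+1`` is ``region_names[i]``.
    Hemisphere membership of a voxel is decided in world coordinates:
    x < 0 is left, x > 0 right, x == 0 midline.
    """

    labels: np.ndarray  # 3-D int array
    region_names: list
    affine: np.ndarray
    region_hemisphere: list = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integers")
        if self.region_hemisphere is None:
            self.region_hemisphere = [hemisphere_of(r) for r in self.region_names]

    @property
    def shape(self):
        return self.labels.shape

    def world_x(self) -> np.ndarray:
        """World x coordinate of every voxel (same shape as labels)."""
        ii = np.indices(self.labels.shape)
        coords = np.stack(
            [ii[0], ii[1], ii[2], np.ones_like(ii[0])], axis=-1
        ) @ self.affine.T
        return coords[..., 0]

    def hemisphere_mask(self) -> np.ndarray:
        """Per-voxel hemisphere label array of 'L' / 'R' / 'midline'."""
        x = self.world_x()
        out = np.full(self.labels.shape, MIDLINE, dtype=object)
        out[x < 0] = LEFT
        out[x > 0] = RIGHT
        return out

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == (self.region_names.index(name) + 1)


def build_parcellation(
    region_names: Sequence[str],
    shape=(20, 20, 10),
    voxel_mm: float = 3.0,
) -> Parcellation:
    """Block-shaped regions on a lattice mirrored across the x midline.

    Left-hemisphere regions occupy x-slabs strictly left of the midline
    plane, right-hemisphere regions mirror them on the right, midline
    regions straddle it.  Regions within a hemisphere are stacked along
    y; z occupies a central band.  The affine is diagonal ``voxel_mm``
    with the origin placed so the midline plane x = 0 bisects the
    lattice (no voxel centre lies exactly at x = 0 for even nx).
    """
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int32)
    half = nx // 2
    lefts = [r for r in region_names if hemisphere_of(r) == LEFT]
    rights = [r for r in region_names if hemisphere_of(r) == RIGHT]
    mids = [r for r in region_names if hemisphere_of(r) == MIDLINE]
    zlo, zhi = max(0, nz // 5), nz - max(0, nz // 5)

    def strips(m):
        edges = np.linspace(0, ny, m + 1).astype(int)
        return [(edges[i], edges[i + 1]) for i in range(m)]

    for names, (x0, x1) in (
        (lefts, (1, half - 1)),
        (rights, (half + 1, nx - 1)),
    ):
        if not names:
            continue
        for r, (y0, y1) in zip(names, strips(len(names))):
            labels[x0:x1, y0:y1, zlo:zhi] = region_names.index(r) + 1
    if mids:
        qw = max(1, nx // 10)
        for r, (y0, y1) in zip(mids, strips(len(mids))):
            labels[half - qw:half + qw, y0:y1, zlo:zhi] = (
                region_names.index(r) + 1
            )
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    # centre the midline plane between voxels half-1 and half
    affine[0, 3] = -voxel_mm * (nx / 2 - 0.5)
    affine[1, 3] = -voxel_mm * (ny - 1) / 2.0
    affine[2, 3] = -voxel_mm * (nz - 1) / 2.0
    return Parcellation(labels, list(region_names), affine)


# ---------------------------------------------------------------------------
# subjects and groups
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """Study-condition description of one simulated cohort."""

    n_subjects: int = 28
    asymmetry_ratio: float = 1.0  # expected L:R truly-active voxel count ratio
    edge_deltas: list = field(default_factory=list)  # (source, target, offset)
    between_subject_sd: float = 0.05  # coupling-weight jitter across subjects
    label: str = "LH"

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("a group needs at least 2 subjects")
        if self.asymmetry_ratio <= 0:
            raise ValueError("asymmetry ratio must be positive")


@dataclass
class SubjectDataset:
    """One simulated subject: region series, optional voxel volume, truth."""

    roi_bold: np.ndarray  # (n_regions, T)
    paradigm: BlockParadigm
    region_names: list
    seed: int
    group_label: str
    coupling: np.ndarray  # subject-level adjacency actually used
    voxel_data: Optional[np.ndarray] = None  # (x, y, z, T)
    parcellation: Optional[Parcellation] = None
    active_mask: Optional[np.ndarray] = None  # ground-truth active voxels
    hemisphere: list = None

    def __post_init__(self):
        if self.roi_bold.shape[1] != self.paradigm.n_volumes:
            raise ValueError("roi_bold length must equal paradigm n_volumes")
        if self.hemisphere is None:
            self.hemisphere = [hemisphere_of(r) for r in self.region_names]


def _subject_coupling(
    network: GroundTruthNetwork,
    group: GroupSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Base adjacency + group edge offsets + subject jitter, kept stationary."""
    idx = {r: i for i, r in enumerate(network.region_names)}
    a = network.adjacency.copy()
    for src, tgt, delta in group.edge_deltas:
        a[idx[tgt], idx[src], 0] += delta
    if group.between_subject_sd > 0:
        jitter = rng.standard_normal(a.shape) * group.between_subject_sd
        jitter[np.abs(a) == 0] = 0.0  # only perturb existing couplings
        a = a + jitter
    # shrink cross-couplings until stationary (jitter can push over the edge)
    guard = 0
    while companion_spectral_radius(a) >= 0.98 and guard < 50:
        off = ~np.eye(a.shape[0], dtype=bool)
        a[off, :] *= 0.95
        guard += 1
    return a


def _active_probabilities(
    parcellation: Parcellation,
    asymmetry_ratio: float,
    p_base: float,
) -> np.ndarray:
    """Per-voxel probability of being truly task-active, calibrated so the
    expected L:R active count ratio equals ``asymmetry_ratio`` exactly."""
    hemi = parcellation.hemisphere_mask()
    labelled = parcellation.labels > 0
    n_l = int(np.sum(labelled & (hemi == LEFT)))
    n_r = int(np.sum(labelled & (hemi == RIGHT)))
    if asymmetry_ratio != 1.0 and (n_l == 0 or n_r == 0):
        raise ValueError(
            "asymmetry requested but the parcellation lacks voxels in one "
            "hemisphere"
        )
    total = p_base * (n_l + n_r)
    r = asymmetry_ratio
    p = np.zeros(parcellation.labels.shape)
    if n_l:
        p[labelled & (hemi == LEFT)] = min(1.0, total * r / ((1 + r) * n_l))
    if n_r:
        p[labelled & (hemi == RIGHT)] = min(1.0, total / ((1 + r) * n_r))
    p[labelled & (hemi == MIDLINE)] = p_base
    return p


def simulate_subject(
    network: GroundTruthNetwork,
    paradigm: BlockParadigm,
    group: GroupSpec,
    make_voxels: bool = False,
    seed: int = 0,
    parcellation: Optional[Parcellation] = None,
    input_gain=1.0,
    bold_noise_sd: float = 0.5,
    voxel_noise_sd: float = 1.0,
    baseline: float = 100.0,
    effect_scale: float = 1.0,
    p_active: float = 0.5,
    active_mask: Optional[np.ndarray] = None,
) -> SubjectDataset:
    """Simulate one subject of ``group``.

    The subject's coupling is the network adjacency plus the group's edge
    offsets plus subject-level jitter.  With ``make_voxels`` the region
    BOLD is broadcast to that region's voxels: a voxel carries the
    (mean-removed) region signal scaled by ``effect_scale`` if it was
    drawn truly active — active-draw probabilities are calibrated to the
    group's left:right ``asymmetry_ratio`` — on top of ``baseline``, plus
    independent voxel noise.  ``active_mask`` overrides the draw (used by
    :func:`simulate_group` to share one functional anatomy across a
    cohort's subjects).
    """
    rng = np.random.default_rng(seed)
    coupling = _subject_coupling(network, group, rng)
    subj_net = replace(network)
    subj_net = GroundTruthNetwork(
        network.region_names,
        coupling,
        network.noise_sd,
        network.hrf_specs,
        list(network.hemisphere),
    )
    latent = simulate_neural_signals(
        subj_net, paradigm, input_gain=input_gain, rng=rng
    )
    roi_bold = convolve_and_sample(
        latent, network.hrf_specs, paradigm.tr_s, noise_sd=bold_noise_sd, rng=rng
    )
    voxel_data = active = parc = None
    if make_voxels:
        parc = parcellation or build_parcellation(network.region_names)
        if active_mask is not None:
            active = np.asarray(active_mask, bool)
        else:
            p = _active_probabilities(parc, group.asymmetry_ratio, p_active)
            active = rng.random(parc.labels.shape) < p
        T = paradigm.n_volumes
        voxel_data = np.full(parc.labels.shape + (T,), baseline, dtype=float)
        centred = roi_bold - roi_bold.mean(axis=1, keepdims=True)
        for i in range(network.n_regions):
            region = parc.labels == i + 1
            vox = region & active
            voxel_data[vox, :] += effect_scale * centred[i]
        voxel_data += rng.standard_normal(voxel_data.shape) * voxel_noise_sd
    return SubjectDataset(
        roi_bold=roi_bold,
        paradigm=paradigm,
        region_names=list(network.region_names),
        seed=seed,
        group_label=group.label,
        coupling=coupling,
        voxel_data=voxel_data,
        parcellation=parc,
        active_mask=active,
    )


def subject_seeds(master_seed: int, n: int) -> list:
    """Deterministic per-subject seeds derived from a master seed."""
    return [int((master_seed * 100003 + 7919 * i + 1) % (2**31 - 1)) for i in range(n)]


def simulate_group(
    network: GroundTruthNetwork,
    paradigm: BlockParadigm,
    group: GroupSpec,
    seed: int = 0,
    **subject_kwargs,
) -> list:
    """Simulate all subjects of a group with deterministically derived seeds.

    When voxel data is requested, the group's truly-active voxel mask is
    drawn once from the master seed and shared by every subject — the
    cohort has one functional anatomy; subjects differ in noise
    realizations and coupling jitter.
    """
    if subject_kwargs.get("make_voxels") and "active_mask" not in subject_kwargs:
        parc = subject_kwargs.get("parcellation") or build_parcellation(
            network.region_names
        )
        subject_kwargs["parcellation"] = parc
        p = _active_probabilities(
            parc, group.asymmetry_ratio, subject_kwargs.get("p_active", 0.5)
        )
        rng = np.random.default_rng(seed)
        subject_kwargs["active_mask"] = rng.random(parc.labels.shape) < p
    return [
        simulate_subject(network, paradigm, group, seed=s, **subject_kwargs)
        for s in subject_seeds(seed, group.n_subjects)
    ]


# ---------------------------------------------------------------------------
# simple activation-level volume (no VAR dynamics)
# ---------------------------------------------------------------------------

def simulate_activation_volume(
    paradigm: BlockParadigm,
    parcellation: Parcellation,
    amplitude_pct: float = 1.5,
    asymmetry_ratio: float = 1.0,
    baseline: float = 100.0,
    noise_sd: float = 1.0,
    hrf: HRFSpec = CANONICAL,
    p_active: float = 0.5,
    seed: int = 0,
):
    """A purely activation-level voxel volume with a programmed percent
    signal change, for validating GLM / signal-change / laterality code
    without autoregressive dynamics.

    Active voxels carry ``baseline * (1 + amplitude_pct/100 * r(t))``
    where r(t) is the task boxcar convolved with ``hrf`` and scaled to
    unit peak, so ``amplitude_pct`` is the task-versus-control signal
    difference in percent of baseline.  Returns ``(volume, active_mask)``.
    """
    rng = np.random.default_rng(seed)
    kernel = hrf.sample(paradigm.tr_s)
    reg = np.convolve(paradigm.boxcar(TASK), kernel)[: paradigm.n_volumes]
    reg = reg / np.max(np.abs(reg))
    p = _active_probabilities(parcellation, asymmetry_ratio, p_active)
    active = rng.random(parcellation.labels.shape) < p
    T = paradigm.n_volumes
    vol = np.full(parcellation.labels.shape + (T,), baseline, dtype=float)
    vol[active, :] += baseline * amplitude_pct / 100.0 * reg
    vol += rng.standard_normal(vol.shape) * noise_sd
    return vol, active
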