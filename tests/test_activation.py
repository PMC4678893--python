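from collections import deque

import numpy as np
import pytest

from hemiflow import (
    ActivationMask,
    build_paradigm,
    build_parcellation,
    build_design,
    cluster_filter,
    conjunction,
    define_rois,
    extract_roi_series,
    fdr_threshold,
    fit_glm,
    group_tmap,
    percent_signal_change,
    simulate_activation_volume,
)
from hemiflow.activation import ROIDefinition, default_threshold_rule
from hemiflow.hrf import HRFSpec
from hemiflow.paradigm import CONTROL, TASK


class TestDesign:
    def test_columns_without_drift(self, paradigm80):
        d = build_design(paradigm80, drift_order=0)
        assert d.names == [TASK, CONTROL, "intercept"]
        assert d.values.shape == (80, 3)

    def test_condition_columns_are_convolved_boxcars(self, paradigm80):
        from hemiflow.hrf import CANONICAL

        d = build_design(paradigm80, drift_order=0)
        kernel = CANONICAL.sample(paradigm80.tr_s)
        for cond in (TASK, CONTROL):
            expected = np.convolve(paradigm80.boxcar(cond), kernel)[:80]
            assert np.allclose(d.column(cond), expected)

    def test_empty_condition_rejected(self):
        # a paradigm cannot be built without both conditions; simulate the
        # degenerate design directly through the DesignMatrix rank check
        from hemiflow.activation import DesignMatrix

        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix(
                ["task", "control", "intercept"],
                np.column_stack(
                    [np.zeros(20), np.ones(20), np.ones(20)]
                ),
            )


class TestGLM:
    def test_perfect_fit_t_capped_and_p_zero(self, paradigm80):
        d = build_design(paradigm80, drift_order=0)
        voxel = d.column(TASK)[None, :]
        res = fit_glm(voxel, d, [1.0, -1.0, 0.0])
        assert res.contrast_t[0] >= 1e5
        assert res.p[0] == pytest.approx(0.0, abs=1e-12)

    def test_null_voxels_have_uniform_p(self, paradigm80, rng):
        d = build_design(paradigm80, drift_order=1)
        voxels = rng.standard_normal((10_000, 80))
        res = fit_glm(voxels, d, d.contrast_vector({TASK: 1, CONTROL: -1}))
        frac = np.mean(res.p < 0.05)
        # binomial CI around 0.05 at n = 10,000
        assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 10_000)

    def test_t_matches_statsmodels_ols(self, paradigm80, rng):
        import statsmodels.api as sm

        d = build_design(paradigm80, drift_order=1)
        y = rng.standard_normal(80) + 0.5 * d.column(TASK)
        res = fit_glm(y[None, :], d, d.contrast_vector({TASK: 1, CONTROL: -1}))
        fit = sm.OLS(y, d.values).fit()
        c = d.contrast_vector({TASK: 1, CONTROL: -1})
        tt = fit.t_test(c)
        assert res.contrast_t[0] == pytest.approx(
            float(np.squeeze(tt.tvalue)), abs=1e-10
        )
        assert res.df == int(fit.df_resid)

    def test_too_few_volumes_rejected(self):
        from hemiflow.activation import DesignMatrix

        d = DesignMatrix(["task", "control", "d1", "intercept"], np.eye(4))
        with pytest.raises(ValueError, match="volumes"):
            fit_glm(np.zeros((1, 4)), d, [1, -1, 0, 0])


class TestFDR:
    def test_hand_computed_step_up(self):
        # BH at q=0.05 on (0.001, 0.004, 0.03, 0.2): thresholds are
        # 0.0125, 0.025, 0.0375, 0.05 -> largest k with p_(k) <= k q/m is 3
        mask = fdr_threshold(np.array([0.001, 0.004, 0.03, 0.2]), q=0.05)
        assert mask.mask.sum() == 3
        assert not mask.mask[3]

    def test_all_ones_rejects_none_and_all_zeros_rejects_all(self):
        assert fdr_threshold(np.ones(50), 0.05).mask.sum() == 0
        assert fdr_threshold(np.zeros(50), 0.05).mask.sum() == 50

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fdr_threshold(np.array([]), 0.05)


def _flood_fill_sizes(mask, neighbours):
    """Pure-python BFS connected components, the independent oracle."""
    seen = np.zeros_like(mask, dtype=bool)
    sizes = {}
    comp = np.zeros(mask.shape, dtype=int)
    label = 0
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if seen[idx]:
            continue
        label += 1
        q = deque([idx])
        seen[idx] = True
        size = 0
        while q:
            cur = q.popleft()
            comp[cur] = label
            size += 1
            for off in neighbours:
                nxt = tuple(np.add(cur, off))
                if any(c < 0 or c >= s for c, s in zip(nxt, mask.shape)):
                    continue
                if mask[nxt] and not seen[nxt]:
                    seen[nxt] = True
                    q.append(nxt)
        sizes[label] = size
    return comp, sizes


def _neighbour_offsets(connectivity):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                manhattan = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


class TestClusterFilter:
    def test_extent_rule_on_known_components(self):
        m = np.zeros((10, 10, 4), dtype=bool)
        m[0:3, 0:4, 0] = True       # 12 voxels
        m[6:9, 6:9, 3] = True       # 9 voxels
        out = cluster_filter(ActivationMask(m), min_voxels=10)
        assert out.mask.sum() == 12

    def test_empty_mask_stays_empty(self):
        out = cluster_filter(ActivationMask(np.zeros((4, 4, 4), bool)), 10)
        assert out.mask.sum() == 0

    def test_cross_survives_under_6_and_26_connectivity(self):
        m = np.zeros((7, 7, 7), dtype=bool)
        m[3, 3, :] = True
        m[3, :, 3] = True  # 3-D cross, 13 voxels, one face-connected blob
        for conn in (6, 26):
            out = cluster_filter(ActivationMask(m), min_voxels=10,
                                 connectivity=conn)
            assert np.array_equal(out.mask, m)

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for trial in range(25):
            m = rng.random((12, 12, 6)) < 0.25
            conn = (6, 18, 26)[trial % 3]
            out = cluster_filter(ActivationMask(m), min_voxels=4,
                                 connectivity=conn, rule=">")
            comp, sizes = _flood_fill_sizes(m, _neighbour_offsets(conn))
            keep = np.isin(comp, [k for k, v in sizes.items() if v > 4])
            assert np.array_equal(out.mask, keep)

    def test_idempotent_and_monotone(self, rng):
        m = rng.random((12, 12, 6)) < 0.3
        once = cluster_filter(ActivationMask(m), 5)
        twice = cluster_filter(once, 5)
        assert np.array_equal(once.mask, twice.mask)
        bigger = cluster_filter(ActivationMask(m), 10)
        assert np.all(bigger.mask <= once.mask)

    def test_flat_input_rejected(self):
        with pytest.raises(ValueError, match="3-D"):
            cluster_filter(ActivationMask(np.zeros(100, bool)), 10)


class TestConjunction:
    def _maps(self, rng, k=2, shape=(10, 10, 5)):
        t = rng.standard_normal(shape) + 3.0 * (rng.random(shape) < 0.1)
        from scipy import stats

        p = stats.norm.sf(t)
        return t, p

    def test_identical_maps_idempotent(self, rng):
        t, p = self._maps(rng)
        single = default_threshold_rule(0.05, 0)(t, p)
        conj = conjunction([t, t], [p, p], default_threshold_rule(0.05, 0))
        assert np.array_equal(conj.mask, single.mask)

    def test_disjoint_activations_empty(self):
        t1 = np.zeros((6, 6, 3))
        t2 = np.zeros((6, 6, 3))
        t1[0, 0, 0] = 10
        t2[5, 5, 2] = 10
        from scipy import stats

        conj = conjunction(
            [t1, t2], [stats.norm.sf(t1), stats.norm.sf(t2)],
            default_threshold_rule(0.05, 0),
        )
        assert conj.mask.sum() == 0

    def test_subset_of_per_group_masks(self, rng):
        rule = default_threshold_rule(0.05, 2)
        ts, ps = zip(*(self._maps(rng) for _ in range(3)))
        conj = conjunction(list(ts), list(ps), rule)
        inter = np.ones_like(conj.mask)
        for t, p in zip(ts, ps):
            inter &= rule(t, p).mask
        assert np.array_equal(conj.mask, inter)
        # monotonicity: adding a group never adds voxels
        conj2 = conjunction(list(ts[:2]), list(ps[:2]), rule)
        assert np.all(conj.mask <= conj2.mask)

    def test_geometry_mismatch_rejected(self, rng):
        t1, p1 = self._maps(rng)
        t2, p2 = self._maps(rng, shape=(8, 8, 4))
        with pytest.raises(ValueError, match="geometry"):
            conjunction([t1, t2], [p1, p2])


class TestROIs:
    def test_mask_covering_two_parcels(self, small_parcellation):
        parc = small_parcellation
        mask = (parc.labels == 1) | (parc.labels == 2)
        rois = define_rois(ActivationMask(mask), parc)
        assert [r.name for r in rois] == ["A_L", "B_L"]
        assert rois[0].n_voxels == int(np.sum(parc.labels == 1))
        assert {r.hemisphere for r in rois} == {"L"}

    def test_mask_inside_one_parcel(self, small_parcellation):
        parc = small_parcellation
        mask = np.zeros(parc.shape, bool)
        vox = np.argwhere(parc.labels == 3)[:5]
        mask[tuple(vox.T)] = True
        rois = define_rois(ActivationMask(mask), parc)
        assert len(rois) == 1 and rois[0].n_voxels == 5

    def test_disjoint_mask_warns_and_returns_empty(self, small_parcellation):
        mask = np.zeros(small_parcellation.shape, bool)
        with pytest.warns(UserWarning, match="no ROIs"):
            assert define_rois(ActivationMask(mask), small_parcellation) == []

    def test_extract_series_mean_and_variance(self, rng):
        vol = np.zeros((4, 4, 1, 10))
        vol[0, 0, 0, :] = 1.0
        vol[0, 1, 0, :] = 3.0
        roi = ROIDefinition("x", np.array([[0, 0, 0], [0, 1, 0]]), "L")
        assert np.allclose(extract_roi_series(vol, roi), 2.0)
        # variance of the mean ~ sigma^2 / n for independent unit voxels
        n = 50
        vol = rng.standard_normal((n, 1, 1, 4000))
        roi = ROIDefinition(
            "y", np.array([[i, 0, 0] for i in range(n)]), "L"
        )
        v = np.var(extract_roi_series(vol, roi))
        assert v == pytest.approx(1.0 / n, rel=0.2)


class TestSignalChange:
    def test_programmed_two_percent(self, paradigm80):
        d = build_design(paradigm80, drift_order=0)
        reg = d.column(TASK) / d.column(TASK).max()
        series = 100.0 + 2.0 * reg
        c = d.contrast_vector({TASK: 1.0})
        assert percent_signal_change(series, d, c) == pytest.approx(2.0, abs=1e-8)

    def test_zero_effect_zero_percent(self, paradigm80):
        d = build_design(paradigm80, drift_order=0)
        series = np.full(80, 50.0)
        c = d.contrast_vector({TASK: 1.0, CONTROL: -1.0})
        assert percent_signal_change(series, d, c) == pytest.approx(0.0, abs=1e-10)

    def test_nonpositive_baseline_rejected(self, paradigm80):
        d = build_design(paradigm80, drift_order=0)
        series = np.zeros(80) - 5.0
        with pytest.raises(ValueError, match="baseline"):
            percent_signal_change(series, d, d.contrast_vector({TASK: 1.0}))

    def test_recovery_of_programmed_amplitude(self, paradigm80):
        # generator ground truth: 1.5% programmed amplitude
        parc = build_parcellation(["A_L", "A_R"], shape=(10, 8, 4))
        d = build_design(paradigm80, drift_order=1)
        c = d.contrast_vector({TASK: 1.0, CONTROL: -1.0})
        estimates = []
        for s in range(50):
            vol, active = simulate_activation_volume(
                paradigm80, parc, amplitude_pct=1.5, noise_sd=0.3, seed=s,
                p_active=1.0,
            )
            roi = ROIDefinition("A_L", np.argwhere(parc.labels == 1), "L")
            series = extract_roi_series(vol, roi)
            estimates.append(percent_signal_change(series, d, c))
        assert np.mean(estimates) == pytest.approx(1.5, abs=0.2)


def test_group_tmap_one_sample_t(rng):
    maps = rng.standard_normal((8, 5, 5, 2)) + 1.0
    t, p = group_tmap(maps)
    from scipy import stats

    t_ref, p_ref = stats.ttest_1samp(maps, 0.0, axis=0, alternative="greater")
    assert np.allclose(t, t_ref)
    assert np.allclose(p, p_ref)
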