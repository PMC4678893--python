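import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemiflow import (
    BootstrapNull,
    HemisphericCounts,
    SignificantNetwork,
    bootstrap_threshold,
    build_network,
    compare_count_groups,
    compare_edge_groups,
    fit_var,
    group_network,
    hemispheric_counts,
    in_out_degrees,
)
from hemiflow.cgc import CGCMatrix, preprocess_series


def _ar1(n, T, rng, a=0.3):
    e = rng.standard_normal((n, T + 50))
    x = np.zeros((n, T + 50))
    for t in range(1, T + 50):
        x[:, t] = a * x[:, t - 1] + e[:, t]
    return preprocess_series(x[:, 50:])


def _net(adj, hemi=None):
    adj = np.asarray(adj, bool)
    n = adj.shape[0]
    names = [f"N{i}" for i in range(n)]
    hemi = hemi or ["L"] * n
    return SignificantNetwork(adj, names, hemi)


class TestBootstrap:
    def test_threshold_monotone_in_alpha(self, rng):
        x = _ar1(3, 120, rng)
        fit = fit_var(x, 1)
        t1 = bootstrap_threshold(x, fit, n_reps=150, alpha=0.01, seed=0)
        t2 = bootstrap_threshold(x, fit, n_reps=150, alpha=0.10, seed=0)
        assert t1.threshold >= t2.threshold
        assert t1.threshold == np.quantile(t1.pooled(), 0.99)

    def test_same_seed_identical_threshold(self, rng):
        x = _ar1(3, 120, rng)
        fit = fit_var(x, 1)
        a = bootstrap_threshold(x, fit, n_reps=120, alpha=0.05, seed=9)
        b = bootstrap_threshold(x, fit, n_reps=120, alpha=0.05, seed=9)
        assert a.threshold == b.threshold

    def test_too_few_reps_rejected(self, rng):
        x = _ar1(3, 120, rng)
        with pytest.raises(ValueError, match="n_reps"):
            bootstrap_threshold(x, fit_var(x, 1), n_reps=50)

    def test_null_false_edge_rate_calibrated(self):
        # modest version of the calibration study (full size in acceptance)
        false = total = 0
        for s in range(40):
            x = _ar1(3, 80, np.random.default_rng(3000 + s))
            from hemiflow import cgc_matrix

            F = cgc_matrix(x, order=1)
            fit = fit_var(x, 1)
            null = bootstrap_threshold(x, fit, n_reps=150, alpha=0.05, seed=s)
            off = ~np.eye(3, dtype=bool)
            false += int(np.sum(F[off] > null.threshold))
            total += int(off.sum())
        rate = false / total
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total) + 0.01


class TestBuildNetwork:
    def _cgc(self, f):
        f = np.asarray(f, float)
        return CGCMatrix(f, [f"N{i}" for i in range(f.shape[0])], 1)

    def _null(self, thr, n):
        return BootstrapNull(
            n_reps=100, null_values=np.zeros((100, n, n)), alpha=0.05,
            threshold=thr,
        )

    def test_all_below_threshold_empty(self):
        f = np.full((3, 3), 0.01)
        net = build_network(self._cgc(f), self._null(0.5, 3))
        assert net.n_edges == 0

    def test_zero_threshold_complete_digraph(self):
        f = np.full((3, 3), 0.2)
        net = build_network(self._cgc(f), self._null(-1e-9, 3))
        assert net.n_edges == 6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ROI count"):
            build_network(self._cgc(np.zeros((3, 3))), self._null(0.1, 4))


class TestDegrees:
    def test_chain_degrees_and_order(self):
        adj = np.zeros((3, 3), bool)
        adj[0, 1] = adj[1, 2] = True  # A->B->C
        net = SignificantNetwork(adj, ["A", "B", "C"], ["L"] * 3)
        df = in_out_degrees(net)
        assert list(df.node) == ["A", "B", "C"]
        assert list(df.in_out) == [-1, 0, 1]

    def test_tie_break_sources_by_descending_out_degree(self):
        # two pure sources, out-degrees 3 and 1 -> same in_out sign class
        adj = np.zeros((6, 6), bool)
        adj[0, 2] = adj[0, 3] = adj[0, 4] = True  # big source, out 3
        adj[1, 5] = True                           # small source, out 1
        names = ["big", "small", "t1", "t2", "t3", "t4"]
        net = SignificantNetwork(adj, names, ["L"] * 6)
        df = in_out_degrees(net)
        assert list(df.node[:2]) == ["big", "small"]

    def test_nonnegative_ties_by_ascending_in_degree(self):
        adj = np.zeros((4, 4), bool)
        # two pure targets with in-degrees 1 and 2; in_out +1 vs +2 differ,
        # so craft equal in_out: n2 has in 1/out 0, n3 has in 2/out 1
        adj[0, 2] = True
        adj[0, 3] = adj[1, 3] = True
        adj[3, 1] = True
        names = ["s1", "s2", "t_small", "t_big"]
        net = SignificantNetwork(adj, names, ["L"] * 4)
        df = in_out_degrees(net)
        ones = df[df.in_out == 1]
        assert list(ones.node) == ["t_small", "t_big"]

    def test_brute_force_oracle_on_random_digraphs(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 11))
            adj = rng.random((n, n)) < 0.3
            np.fill_diagonal(adj, False)
            net = _net(adj)
            df = in_out_degrees(net).set_index("node")
            for i in range(n):
                out_d = sum(bool(adj[i, j]) for j in range(n) if j != i)
                in_d = sum(bool(adj[j, i]) for j in range(n) if j != i)
                row = df.loc[f"N{i}"]
                assert row.out_degree == out_d
                assert row.in_degree == in_d
                assert row.in_out == in_d - out_d
            assert df.in_degree.sum() == df.out_degree.sum() == adj.sum()
            assert df.in_out.sum() == 0
            assert list(df.in_out) == sorted(df.in_out)


class TestHemisphericCounts:
    def test_bidirectional_pair_counts(self):
        adj = np.zeros((2, 2), bool)
        adj[0, 1] = adj[1, 0] = True
        net = _net(adj, hemi=["L", "R"])
        c = hemispheric_counts(net)
        assert c.inter_directional == 2
        assert c.inter_bidirectional == 1
        assert c.intra_left == c.intra_right == 0

    def test_all_left_network(self):
        adj = np.zeros((3, 3), bool)
        adj[0, 1] = adj[1, 2] = adj[2, 0] = True
        c = hemispheric_counts(_net(adj, hemi=["L"] * 3))
        assert c.intra_left == 3
        assert c.inter_directional == c.inter_bidirectional == 0
        assert c.intra_right == 0

    def test_midline_edges_count_as_inter_only_with_lateral_partner(self):
        adj = np.zeros((3, 3), bool)
        adj[0, 1] = True  # midline -> L: inter
        adj[1, 2] = True  # L -> midline: inter
        adj[0, 0] = True  # ignored (self)
        net = _net(adj, hemi=["midline", "L", "midline"])
        c = hemispheric_counts(net)
        assert c.inter_directional == 2
        assert c.intra_left == 0

    def test_brute_force_oracle_random_labelled_digraphs(self, rng):
        hemis = np.array(["L", "R", "midline"])
        for _ in range(300):
            n = int(rng.integers(2, 9))
            adj = rng.random((n, n)) < 0.35
            np.fill_diagonal(adj, False)
            hemi = list(hemis[rng.integers(0, 3, n)])
            c = hemispheric_counts(_net(adj, hemi=hemi))
            inter = intra_l = intra_r = bi = 0
            for i in range(n):
                for j in range(n):
                    if i == j or not adj[i, j]:
                        continue
                    hi, hj = hemi[i], hemi[j]
                    if hi == "L" and hj == "L":
                        intra_l += 1
                    elif hi == "R" and hj == "R":
                        intra_r += 1
                    elif hi == "midline" and hj == "midline":
                        pass
                    else:
                        inter += 1
            for i in range(n):
                for j in range(i + 1, n):
                    if adj[i, j] and adj[j, i]:
                        hi, hj = hemi[i], hemi[j]
                        if hi != hj and "midline" not in (hi, hj):
                            bi += 1
                        elif "midline" in (hi, hj) and hi != hj:
                            bi += 1
            assert c.inter_directional == inter
            assert c.intra_left == intra_l
            assert c.intra_right == intra_r
            assert c.inter_bidirectional == bi
            assert c.inter_directional >= 2 * c.inter_bidirectional


class TestGroupNetwork:
    def _subject(self, f, thr):
        n = f.shape[0]
        return (
            CGCMatrix(f, [f"N{i}" for i in range(n)], 1),
            BootstrapNull(100, np.zeros((100, n, n)), 0.05, thr),
        )

    def test_exceedance_aggregation(self):
        f_hi = np.full((3, 3), 0.5)
        f_lo = np.full((3, 3), 0.0)
        subs = [self._subject(f_hi, 0.1) for _ in range(10)]
        cgcs, nulls = zip(*subs)
        net = group_network(list(cgcs), list(nulls), alpha_group=0.01)
        assert net.n_edges == 6
        subs = [self._subject(f_lo, 0.1) for _ in range(10)]
        cgcs, nulls = zip(*subs)
        net = group_network(list(cgcs), list(nulls), alpha_group=0.01)
        assert net.n_edges == 0

    def test_majority_aggregation(self):
        f_hi = np.full((3, 3), 0.5)
        f_lo = np.full((3, 3), 0.0)
        subs = [self._subject(f_hi if i < 6 else f_lo, 0.1)
                for i in range(10)]
        cgcs, nulls = zip(*subs)
        net = group_network(list(cgcs), list(nulls), method="majority")
        assert net.n_edges == 6


class TestEdgeComparison:
    def _group(self, rng, n_sub, bump=None, n=4):
        out = []
        for _ in range(n_sub):
            f = np.abs(rng.standard_normal((n, n))) * 0.05 + 0.1
            np.fill_diagonal(f, np.nan)
            if bump:
                f[bump] += 0.3
            out.append(CGCMatrix(f, [f"N{i}" for i in range(n)], 1))
        return out

    def test_identical_groups_not_significant(self, rng):
        a = self._group(rng, 12)
        b = self._group(rng, 12)
        df = compare_edge_groups(a, b, alpha_fwe=0.05)
        assert not df.significant.any()

    def test_programmed_edge_flagged_one_sided(self, rng):
        a = self._group(rng, 20, bump=(0, 1))
        b = self._group(rng, 20)
        df = compare_edge_groups(a, b, direction="greater", alpha_fwe=0.01)
        sig = df[df.significant]
        assert len(sig) == 1
        assert (sig.iloc[0].source, sig.iloc[0].target) == ("N0", "N1")
        # the opposite sidedness must not flag it
        df_less = compare_edge_groups(a, b, direction="less", alpha_fwe=0.01)
        assert not df_less.significant.any()

    def test_swapping_groups_flips_t(self, rng):
        a = self._group(rng, 8)
        b = self._group(rng, 8)
        ab = compare_edge_groups(a, b)
        ba = compare_edge_groups(b, a)
        assert np.allclose(ab.t.to_numpy(), -ba.t.to_numpy())

    def test_mismatched_roi_sets_rejected(self, rng):
        a = self._group(rng, 4)
        b = self._group(rng, 4, n=5)
        with pytest.raises(ValueError, match="ROI"):
            compare_edge_groups(a, b)

    def test_single_subject_group_rejected(self, rng):
        a = self._group(rng, 1)
        b = self._group(rng, 5)
        with pytest.raises(ValueError, match="2 subjects"):
            compare_edge_groups(a, b)


class TestCountComparison:
    def _counts(self, rng, n, base=5, inter_shift=0):
        out = []
        for _ in range(n):
            inter = max(0, int(base + inter_shift + rng.integers(-2, 3)))
            bi = int(rng.integers(0, inter // 2 + 1))
            out.append(
                HemisphericCounts(inter, bi, int(rng.integers(0, 5)),
                                  int(rng.integers(0, 5)))
            )
        return out

    def test_identical_generators_not_significant(self, rng):
        a = self._counts(rng, 20)
        b = self._counts(rng, 20)
        df = compare_count_groups(a, b, alpha=0.01)
        assert not df.significant.any()

    def test_programmed_inter_difference_detected(self, rng):
        a = self._counts(rng, 28, inter_shift=4)
        b = self._counts(rng, 28)
        df = compare_count_groups(a, b, alpha=0.01)
        row = df[df["count"] == "inter_directional"].iloc[0]
        assert row.significant and row.t > 0

    def test_swapping_groups_flips_every_t(self, rng):
        a = self._counts(rng, 10)
        b = self._counts(rng, 10, inter_shift=1)
        ab = compare_count_groups(a, b)
        ba = compare_count_groups(b, a)
        assert np.allclose(ab.t.to_numpy(), -ba.t.to_numpy())

    def test_sidedness_as_specified(self, rng):
        df = compare_count_groups(self._counts(rng, 6), self._counts(rng, 6))
        alt = dict(zip(df["count"], df["alternative"]))
        assert alt["inter_directional"] == "greater"
        assert alt["inter_bidirectional"] == "greater"
        assert alt["intra_left"] == "two-sided"
        assert alt["intra_right"] == "two-sided"


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_degree_conservation_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 12))
    adj = rng.random((n, n)) < 0.4
    np.fill_diagonal(adj, False)
    df = in_out_degrees(_net(adj))
    assert df.in_degree.sum() == df.out_degree.sum() == int(adj.sum())
    assert df.in_out.sum() == 0
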