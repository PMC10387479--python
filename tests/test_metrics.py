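"""Graph-metric oracle equivalence, depth profiles, effect sizes, mixed model."""

import logging

import numpy as np
import pandas as pd
import pytest

from calnet import CalnetError
from calnet.connectivity import FunctionalNetwork
from calnet.metrics import (
    clustering_coefficient,
    cohens_d,
    compare_groups_over_time,
    degree_assortativity,
    depth_degree_profile,
    depth_profile_group_test,
    global_efficiency,
    interlayer_contrast,
    network_metric_rows,
    node_degrees,
)

import _oracles as bf


def _net(adj, depths=None, label="w"):
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    if depths is None:
        depths = np.linspace(0.05, 0.95, n)
    iu = np.triu_indices(n, k=1)
    rho = {(int(i), int(j)): 0.5 for i, j in zip(*iu) if adj[i, j]}
    return FunctionalNetwork(adj, np.asarray(depths, dtype=float), label, rho)


def _random_net(n, p, seed):
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.uniform(size=(n, n)) < p, k=1)
    return _net(upper | upper.T)


def _triangle():
    adj = np.zeros((3, 3), bool)
    adj[0, 1] = adj[1, 2] = adj[0, 2] = True
    return _net(adj | adj.T)


def _star(n=5):
    adj = np.zeros((n, n), bool)
    adj[0, 1:] = adj[1:, 0] = True
    return _net(adj)


def _path(n):
    adj = np.zeros((n, n), bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return _net(adj)


def _cycle(n):
    adj = np.zeros((n, n), bool)
    for i in range(n):
        adj[i, (i + 1) % n] = adj[(i + 1) % n, i] = True
    return _net(adj)


def _complete(n):
    return _net(~np.eye(n, dtype=bool))


class TestNodeDegrees:
    def test_triangle_all_two(self):
        assert node_degrees(_triangle()).tolist() == [2, 2, 2]

    def test_star_hub_and_leaves(self):
        assert node_degrees(_star(5)).tolist() == [4, 1, 1, 1, 1]

    def test_matches_bruteforce_on_random_graph(self):
        net = _random_net(20, 0.3, seed=0)
        assert node_degrees(net).tolist() == bf.degrees(net.adjacency)


class TestClustering:
    def test_complete_graph_is_one(self):
        assert clustering_coefficient(_complete(4)) == pytest.approx(1.0)

    def test_path_has_no_triangles(self):
        assert clustering_coefficient(_path(4)) == 0.0

    def test_matches_triangle_enumeration(self):
        net = _random_net(15, 0.4, seed=1)
        assert clustering_coefficient(net) == pytest.approx(
            bf.mean_clustering(net.adjacency), abs=1e-12
        )


class TestGlobalEfficiency:
    def test_complete_graph_is_one(self):
        assert global_efficiency(_complete(5)) == pytest.approx(1.0)

    def test_path_three_closed_form(self):
        assert global_efficiency(_path(3)) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_edgeless_graph_is_zero(self):
        assert global_efficiency(_net(np.zeros((4, 4), bool))) == 0.0

    def test_matches_bfs_enumeration(self):
        for seed in (2, 3):
            net = _random_net(18, 0.15, seed=seed)
            assert global_efficiency(net) == pytest.approx(
                bf.global_efficiency(net.adjacency), abs=1e-10
            )

    def test_adding_edge_never_decreases_efficiency(self):
        rng = np.random.default_rng(4)
        net = _random_net(12, 0.2, seed=5)
        adj = net.adjacency.copy()
        before = global_efficiency(net)
        absent = [
            (i, j)
            for i in range(12)
            for j in range(i + 1, 12)
            if not adj[i, j]
        ]
        i, j = absent[rng.integers(len(absent))]
        adj[i, j] = adj[j, i] = True
        assert global_efficiency(_net(adj)) >= before - 1e-12

    def test_invariant_under_relabeling(self):
        net = _random_net(10, 0.3, seed=6)
        perm = np.random.default_rng(7).permutation(10)
        relabeled = _net(net.adjacency[np.ix_(perm, perm)])
        assert global_efficiency(relabeled) == pytest.approx(
            global_efficiency(net), abs=1e-12
        )
        assert clustering_coefficient(relabeled) == pytest.approx(
            clustering_coefficient(net), abs=1e-12
        )


class TestAssortativity:
    def test_star_is_minus_one(self):
        assert degree_assortativity(_star(5)) == pytest.approx(-1.0)

    def test_cycle_is_undefined(self):
        assert np.isnan(degree_assortativity(_cycle(6)))

    def test_matches_edge_list_pearson(self):
        net = _random_net(30, 0.2, seed=8)
        assert degree_assortativity(net) == pytest.approx(
            bf.degree_assortativity(net.adjacency), abs=1e-10
        )

    def test_edgeless_graph_rejected(self):
        with pytest.raises(CalnetError):
            degree_assortativity(_net(np.zeros((3, 3), bool)))


class TestDepthDegreeProfile:
    def test_identical_to_basal_gives_zero_relative(self):
        net = _random_net(30, 0.2, seed=9)
        prof = depth_degree_profile(net, net)
        assert np.allclose(prof["rel_degree"].dropna(), 0.0)
        assert len(prof) == 10

    def test_single_occupied_bin_leaves_nine_missing(self):
        adj = np.zeros((5, 5), bool)
        net = _net(adj, depths=np.full(5, 0.55))
        prof = depth_degree_profile(net, net)
        assert int(prof["n"].gt(0).sum()) == 1
        assert prof["mean_degree"].isna().sum() == 9

    def test_superficial_heavy_connectivity_ranks_bins(self):
        # dense coupling among superficial neurons, deep neurons isolated
        rng = np.random.default_rng(10)
        depths = np.r_[rng.uniform(0.8, 1.0, 15), rng.uniform(0.0, 0.2, 15)]
        adj = np.zeros((30, 30), bool)
        sup = np.arange(15)
        for i in sup:
            for j in sup:
                if i < j and rng.uniform() < 0.6:
                    adj[i, j] = adj[j, i] = True
        basal = _net(np.zeros((30, 30), bool), depths=depths)
        net = _net(adj, depths=depths)
        prof = depth_degree_profile(net, basal)
        top = prof[prof["bin_lo"] >= 0.8]["mean_degree"].dropna().mean()
        bottom = prof[prof["bin_hi"] <= 0.2]["mean_degree"].dropna().mean()
        assert top > bottom

    def test_group_test_shapes(self):
        nets = [_random_net(20, 0.3, seed=s) for s in range(4)]
        basal = _random_net(20, 0.1, seed=99)
        profs = [depth_degree_profile(n, basal) for n in nets]
        out = depth_profile_group_test(profs[:2], profs[2:])
        assert {"t", "p", "cohens_d"} <= set(out.columns)
        assert len(out) == 10


class TestInterlayerContrast:
    def test_identical_groups_show_no_effect(self):
        nets_a = [_random_net(40, 0.15, seed=s) for s in range(6)]
        nets_b = [_random_net(40, 0.15, seed=s + 50) for s in range(6)]
        out = interlayer_contrast(nets_a, nets_b)
        sig = out["p"].dropna() < 0.05
        assert sig.mean() < 0.15  # at most alpha-level plus noise
        assert out["cohens_d"].abs().dropna().median() < 1.0

    def test_planted_interband_deficit_detected(self):
        rng = np.random.default_rng(11)

        def make(p_cross, seed):
            r = np.random.default_rng(seed)
            depths = np.r_[r.uniform(0.0, 0.1, 20), r.uniform(0.9, 1.0, 20)]
            adj = np.zeros((40, 40), bool)
            for i in range(20):
                for j in range(20, 40):
                    if r.uniform() < p_cross:
                        adj[i, j] = adj[j, i] = True
            return _net(adj, depths=depths)

        group_a = [make(0.4, s) for s in range(5)]
        group_b = [make(0.05, s + 10) for s in range(5)]
        out = interlayer_contrast(group_a, group_b)
        cross = out[(out["bin_i"] == 0.0) & (out["bin_j"] == 0.9)].iloc[0]
        assert cross["p"] < 0.05
        assert cross["cohens_d"] > 0  # deficit in group B

    def test_single_occupied_bin_yields_one_row(self):
        net = _net(np.zeros((4, 4), bool), depths=np.full(4, 0.35))
        out = interlayer_contrast([net, net], [net, net])
        assert len(out) == 1


class TestCohensD:
    def test_identical_samples_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d(x, x.copy()) == 0.0

    def test_unit_shift_recovered_at_large_n(self):
        rng = np.random.default_rng(12)
        x = rng.normal(1, 1, 10000)
        y = rng.normal(0, 1, 10000)
        assert cohens_d(x, y) == pytest.approx(1.0, abs=0.05)

    def test_zero_pooled_sd_undefined(self):
        assert np.isnan(cohens_d(np.array([1.0, 1.0]), np.array([1.0, 1.0])))

    def test_too_few_values_rejected(self):
        with pytest.raises(CalnetError):
            cohens_d(np.array([1.0]), np.array([1.0, 2.0]))


def _metric_table(rng, shift=0.0, n_sub=6, sigma_b=1.0, sigma_e=1.0):
    rows = []
    for gi, g in enumerate(("control", "treated")):
        for s in range(n_sub):
            intercept = rng.normal(0, sigma_b) + (shift if gi else 0.0)
            for w in range(5):
                rows.append(
                    {
                        "subject": f"{g}{s}",
                        "group": g,
                        "window": f"w{w}",
                        "value": intercept + rng.normal(0, sigma_e),
                    }
                )
    return pd.DataFrame(rows)


class TestCompareGroupsOverTime:
    def test_planted_group_shift_detected(self):
        rng = np.random.default_rng(13)
        res = compare_groups_over_time(_metric_table(rng, shift=3.0), "value", "group")
        assert res.effect == "group"
        assert res.df == 1
        assert res.pvalue < 0.01

    def test_time_effect_testable(self):
        rng = np.random.default_rng(14)
        df = _metric_table(rng)
        df["value"] += df["window"].str[-1].astype(int) * 2.0
        res = compare_groups_over_time(df, "value", "window")
        assert res.df == 4
        assert res.pvalue < 0.01

    def test_single_subject_per_group_rejected(self):
        rng = np.random.default_rng(15)
        df = _metric_table(rng, n_sub=1)
        with pytest.raises(CalnetError):
            compare_groups_over_time(df, "value", "group")

    def test_missing_values_dropped_not_fatal(self):
        rng = np.random.default_rng(16)
        df = _metric_table(rng)
        df.loc[df.index[:3], "value"] = np.nan
        res = compare_groups_over_time(df, "value", "group")
        assert np.isfinite(res.pvalue)


class TestNetworkMetricRows:
    def test_tidy_table_per_window(self):
        nets = {
            "before": _random_net(15, 0.3, seed=17),
            "window 1": _random_net(15, 0.4, seed=18),
        }
        df = network_metric_rows(nets, subject="s1", group="control")
        assert list(df["window"]) == ["before", "window 1"]
        assert df["clustering"].between(0, 1).all()
        assert df["efficiency"].between(0, 1).all()

    def test_degenerate_assortativity_is_missing_not_zero(self):
        nets = {"before": _cycle(6)}
        df = network_metric_rows(nets, subject="s1", group="control")
        assert np.isnan(df["assortativity"].iloc[0])
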