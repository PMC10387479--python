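"""Windowing, Spearman oracle equivalence, surrogate contracts, FDR behavior."""

import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr

from calnet import CalnetError, StimulusProtocol
from calnet.connectivity import (
    build_adjacency,
    build_phase_pool,
    fdr_refine,
    make_surrogates,
    pair_significance,
    segment_windows,
    spearman_matrix,
    window_connectivity,
)

from _oracles import spearman as spearman_bf


class TestSegmentWindows:
    def test_full_recording_five_windows(self):
        w = segment_windows(2475, fs=3.3)
        assert len(w) == 5
        assert all(b - a == 495 for a, b in w.boundaries)
        assert w.labels == ("before", "window 1", "window 2", "window 3", "window 4")

    def test_trailing_frames_dropped(self):
        w = segment_windows(int(round(751 * 3.3)), fs=3.3)
        assert len(w) == 5
        assert w.boundaries[-1] == (1980, 2475)

    def test_too_short_recording_reports_requirement(self):
        with pytest.raises(CalnetError, match="2475"):
            segment_windows(int(round(300 * 3.3)), fs=3.3)

    def test_windows_contiguous_nonoverlapping(self):
        w = segment_windows(2475, fs=3.3)
        for (a0, b0), (a1, b1) in zip(w.boundaries, w.boundaries[1:]):
            assert b0 == a1


class TestSpearmanMatrix:
    def test_monotone_pair_is_one(self):
        x = np.linspace(1, 5, 30)
        rho = spearman_matrix(np.vstack([x, x**2]))
        assert rho[0, 1] == pytest.approx(1.0)

    def test_antitone_pair_is_minus_one(self):
        x = np.linspace(1, 5, 30)
        rho = spearman_matrix(np.vstack([x, -x]))
        assert rho[0, 1] == pytest.approx(-1.0)

    def test_matches_bruteforce_oracle(self, rng):
        X = rng.normal(size=(20, 50))
        X[3, :10] = X[3, 10:20]  # introduce ties
        rho = spearman_matrix(X)
        for i in range(20):
            for j in range(i + 1, 20):
                assert rho[i, j] == pytest.approx(
                    spearman_bf(X[i], X[j]), abs=1e-12
                )
        ref = spearmanr(X, axis=1).statistic
        assert np.allclose(rho, ref, atol=1e-12)

    def test_zero_variance_row_gives_nan_pairs(self, rng):
        X = rng.normal(size=(4, 30))
        X[2] = 7.0
        rho = spearman_matrix(X)
        assert np.isnan(rho[2, 0]) and np.isnan(rho[1, 2])
        assert rho[2, 2] == 1.0
        assert np.isfinite(rho[0, 1])


class TestMakeSurrogates:
    @pytest.fixture()
    def window_traces(self, rng):
        return rng.normal(size=(6, 495)) + np.sin(
            2 * np.pi * 0.1 * np.arange(495) / 3.3
        )

    def test_amplitude_spectrum_preserved(self, window_traces):
        pool = build_phase_pool(window_traces)
        s = make_surrogates(window_traces[0], pool, n=50, seed=0)
        ref = np.abs(np.fft.rfft(window_traces[0]))
        for row in s:
            assert np.allclose(np.abs(np.fft.rfft(row)), ref, atol=1e-9)

    def test_variance_preserved(self, window_traces):
        pool = build_phase_pool(window_traces)
        s = make_surrogates(window_traces[0], pool, n=50, seed=0)
        assert np.allclose(s.var(axis=1), window_traces[0].var(), atol=1e-9)

    def test_deterministic_under_seed(self, window_traces):
        pool = build_phase_pool(window_traces)
        a = make_surrogates(window_traces[0], pool, n=10, seed=42)
        b = make_surrogates(window_traces[0], pool, n=10, seed=42)
        assert np.array_equal(a, b)

    def test_empty_pool_falls_back_to_uniform_phases(self, window_traces, caplog):
        with caplog.at_level("WARNING", logger="calnet.connectivity"):
            s = make_surrogates(window_traces[0], None, n=5, seed=1)
        assert "empty phase pool" in caplog.text
        ref = np.abs(np.fft.rfft(window_traces[0]))
        assert np.allclose(np.abs(np.fft.rfft(s[0])), ref, atol=1e-9)

    def test_surrogate_pairs_of_independent_traces_uncorrelated(self, rng):
        # phases pooled over a study-like population; tiny pools would add a
        # ~1/N_pool correlation bias between surrogate pairs by construction
        population = rng.normal(size=(40, 495))
        x, y = population[0], population[1]
        pool = build_phase_pool(population)
        sx = make_surrogates(x, pool, n=1000, seed=2)
        sy = make_surrogates(y, pool, n=1000, seed=3)
        rx = rankdata(sx, axis=1)
        ry = rankdata(sy, axis=1)
        rx = (rx - rx.mean(1, keepdims=True)) / rx.std(1, keepdims=True)
        ry = (ry - ry.mean(1, keepdims=True)) / ry.std(1, keepdims=True)
        rhos = (rx * ry).mean(axis=1)
        assert -0.05 < rhos.mean() < 0.05


class TestPairSignificance:
    def test_rho_at_null_mean_not_flagged(self):
        null = np.random.default_rng(0).normal(0, 0.1, 1000)
        flag, p = pair_significance(null.mean(), null.mean(), null.std(), null)
        assert not flag
        assert p == pytest.approx(1.0)

    def test_three_sigma_flagged(self):
        flag, _ = pair_significance(0.3, 0.0, 0.1)
        assert flag

    def test_zero_sd_uses_strict_inequality(self):
        flag0, _ = pair_significance(0.5, 0.5, 0.0, np.full(200, 0.5))
        flag1, p1 = pair_significance(0.6, 0.5, 0.0, np.full(200, 0.5))
        assert not flag0
        assert flag1
        assert p1 == pytest.approx(1 / 201)

    def test_gaussian_null_calibration(self):
        # under a Gaussian null the two-sided 2-SD rule fires ~4.55% of the time
        rng = np.random.default_rng(5)
        hits = 0
        n_trials = 4000
        for _ in range(n_trials):
            mu, sd = 0.0, 0.08
            rho = rng.normal(mu, sd)
            flag, _ = pair_significance(rho, mu, sd, None, k_sd=2.0)
            hits += flag
        assert 0.031 < hits / n_trials < 0.061


class TestFdrRefine:
    def test_small_p_set_fully_selected(self):
        mask = fdr_refine(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert mask.all()

    def test_all_ones_select_nothing(self):
        assert not fdr_refine(np.ones(10), q=0.05).any()

    def test_mask_subset_of_raw_flags(self):
        p = np.array([0.001, 0.5, 0.002, 0.9])
        raw = np.array([True, True, False, False])
        mask = fdr_refine(p, q=0.05, raw_flags=raw)
        assert mask.tolist() == [True, False, False, False]

    def test_global_null_false_discovery_rate_controlled(self):
        rng = np.random.default_rng(6)
        reps = 200
        fdp = []
        for _ in range(reps):
            p = rng.uniform(size=1000)
            sel = fdr_refine(p, q=0.05)
            # every discovery is false under the global null
            fdp.append(1.0 if sel.any() else 0.0)
        fdp = np.array(fdp)
        se = fdp.std(ddof=1) / np.sqrt(reps)
        assert fdp.mean() <= 0.05 + 3 * se

    def test_invalid_q_rejected(self):
        with pytest.raises(CalnetError):
            fdr_refine(np.array([0.1]), q=1.5)


@pytest.fixture(scope="module")
def small_wc():
    rng = np.random.default_rng(7)
    traces = rng.normal(size=(8, 495))
    traces[1] += traces[0]  # one strongly coupled pair
    return window_connectivity(traces, n_surrogates=200, seed=8)


class TestWindowConnectivity:
    def test_fdr_mask_subset_of_raw(self, small_wc):
        assert np.all(~small_wc.fdr_mask | small_wc.raw_mask)

    def test_masks_symmetric_hollow(self, small_wc):
        for m in (small_wc.raw_mask, small_wc.fdr_mask):
            assert np.array_equal(m, m.T)
            assert not np.diag(m).any()

    def test_coupled_pair_detected(self, small_wc):
        assert small_wc.fdr_mask[0, 1]

    def test_bit_identical_under_seed(self):
        rng = np.random.default_rng(9)
        traces = rng.normal(size=(5, 300))
        a = window_connectivity(traces, n_surrogates=150, seed=10)
        b = window_connectivity(traces, n_surrogates=150, seed=10)
        assert np.array_equal(a.fdr_mask, b.fdr_mask)
        assert np.array_equal(a.null_mean, b.null_mean, equal_nan=True)
        assert np.array_equal(a.pvals, b.pvals, equal_nan=True)

    def test_pooled_null_mode(self):
        rng = np.random.default_rng(11)
        traces = rng.normal(size=(6, 300))
        wc = window_connectivity(traces, n_surrogates=150, seed=12, null_mode="pooled")
        assert wc.null_mode == "pooled"
        off = ~np.eye(6, dtype=bool)
        assert np.unique(wc.null_mean[off]).size == 1

    def test_empirical_p_mode_available(self):
        rng = np.random.default_rng(13)
        traces = rng.normal(size=(5, 300))
        wc = window_connectivity(traces, n_surrogates=150, seed=14, p_mode="empirical")
        iu = np.triu_indices(5, k=1)
        assert np.array_equal(wc.pvals[iu], wc.empirical_pvals[iu])
        assert np.nanmin(wc.pvals[iu]) >= 1 / 151

    def test_surrogate_null_stats_accessible_per_pair(self, small_wc):
        null = small_wc.null_for(0, 1)
        assert null.n_surrogates == 200
        assert 0 < null.empirical_p <= 1
        assert null.null_sd >= 0


class TestBuildAdjacency:
    def _wc_with_mask(self, n, mask):
        rng = np.random.default_rng(15)
        traces = rng.normal(size=(n, 200))
        wc = window_connectivity(traces, n_surrogates=100, seed=16)
        wc.fdr_mask = mask
        return wc

    def test_empty_mask_gives_edgeless_network(self):
        wc = self._wc_with_mask(4, np.zeros((4, 4), dtype=bool))
        net = build_adjacency(wc, np.linspace(0, 1, 4))
        assert net.n_edges == 0
        assert np.all(net.adjacency.sum(axis=1) == 0)

    def test_complete_mask_gives_full_degrees(self):
        mask = ~np.eye(4, dtype=bool)
        wc = self._wc_with_mask(4, mask)
        net = build_adjacency(wc, np.linspace(0, 1, 4))
        assert np.all(net.adjacency.sum(axis=1) == 3)
        assert len(net.edge_rho) == 6

    def test_edge_count_equals_half_degree_sum(self):
        rng = np.random.default_rng(17)
        mask = rng.uniform(size=(6, 6)) < 0.4
        mask = np.triu(mask, 1)
        mask = mask | mask.T
        wc = self._wc_with_mask(6, mask)
        net = build_adjacency(wc, np.linspace(0, 1, 6))
        assert net.n_edges == net.adjacency.sum() // 2
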