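"""Window contrasts, cluster permutation, phase bins, sine fit, ANOVA."""

import numpy as np
import pytest
from scipy import sparse
from scipy import stats as sps

from entraineeg.montage import CHANNELS_8, CHANNELS_63, adjacency_matrix
from entraineeg.spectral import TFMap
from entraineeg.stats import (
    WINDOWS,
    assign_phase_bins,
    cluster_permutation,
    correlate_iaf_itpc,
    phase_bin_itpc,
    phase_bins,
    rm_anova_bins,
    sine_regression,
    window_contrast,
)


class TestWindows:
    def test_planned_windows_are_contiguous_100ms(self):
        bounds = list(WINDOWS.values())
        assert bounds[0] == (5.0, 105.0)
        for (s0, e0), (s1, _) in zip(bounds, bounds[1:]):
            assert e0 == s1
        assert all(e - s == 100.0 for s, e in bounds)


class TestWindowContrast:
    def test_identical_inputs(self):
        a = np.array([0.4, 0.5, 0.6, 0.55])
        t, p = window_contrast(a, a)
        assert t == 0.0 and p == 1.0

    def test_constant_shift_matches_one_sample_t(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0.5, 0.1, 10)
        a = b + rng.normal(0.0, 0.05, 10)
        delta = 0.03
        t_paired, p_paired = window_contrast(a + delta, b)
        t_one, p_one = sps.ttest_1samp(a - b + delta, 0.0)
        assert t_paired == pytest.approx(float(t_one))
        assert p_paired == pytest.approx(float(p_one))

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            window_contrast(np.array([1.0, 2.0]), np.array([1.5, 2.5]))


@pytest.fixture(scope="module")
def adj63():
    return adjacency_matrix(CHANNELS_63)


class TestClusterPermutation:
    def test_identical_topographies_no_clusters(self, adj63):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((10, 63))
        res = cluster_permutation(a, a.copy(), adj63, n_perm=200, seed=0)
        assert len(res.clusters) == 0 and not res.any_significant

    def test_p_value_range_and_cluster_connectivity(self, adj63):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((10, 63)) + 0.3
        b = rng.standard_normal((10, 63))
        res = cluster_permutation(a, b, adj63, n_perm=500, seed=3)
        assert ((res.p_values >= 1 / 501) & (res.p_values <= 1.0)).all()
        for comp in res.clusters:
            if comp.size > 1:  # every member reaches another via the graph
                sub = adj63[np.ix_(comp, comp)]
                assert (sub.sum(axis=1) > 0).all()

    def test_null_false_positive_rate_controlled(self, adj63):
        rng = np.random.default_rng(4)
        hits = 0
        reps = 120
        for _ in range(reps):
            a = rng.standard_normal((10, 63))
            b = rng.standard_normal((10, 63))
            res = cluster_permutation(a, b, adj63, n_perm=250, seed=rng)
            hits += res.any_significant
        assert hits / reps <= 0.10  # nominal 0.05 plus binomial slack

    def test_planted_occipital_effect_detected(self, adj63):
        rng = np.random.default_rng(5)
        patch = [CHANNELS_63.index(c) for c in ("O2", "PO4", "PO8")]
        contain = 0
        reps = 40
        for _ in range(reps):
            a = rng.standard_normal((10, 63))
            b = rng.standard_normal((10, 63))
            a[:, patch] += 2.0  # 2 SD of a single topography (sqrt(2) SD of diff)
            res = cluster_permutation(a, b, adj63, n_perm=500, seed=rng)
            contain += any(
                set(patch) <= set(c.tolist()) for c in res.significant()
            )
        assert contain / reps >= 0.8

    def test_matches_mne_reference_implementation(self, adj63):
        from mne.stats import permutation_cluster_1samp_test

        rng = np.random.default_rng(6)
        patch = [CHANNELS_63.index(c) for c in ("O2", "PO4", "PO8")]
        a = rng.standard_normal((10, 63))
        b = rng.standard_normal((10, 63))
        a[:, patch] += 1.2
        res = cluster_permutation(a, b, adj63, n_perm=2000, tail="one", seed=0)
        thr = sps.t.ppf(0.95, 9)
        t_ref, clusters_ref, p_ref, _ = permutation_cluster_1samp_test(
            a - b, threshold=thr, n_permutations=2000, tail=1,
            adjacency=sparse.coo_matrix(adj63), seed=0, out_type="indices",
            verbose=False,
        )
        assert np.allclose(res.t_obs, t_ref)
        mine = sorted(tuple(c.tolist()) for c in res.clusters)
        theirs = sorted(tuple(sorted(c[0].tolist())) for c in clusters_ref)
        assert mine == theirs
        order = np.argsort([c[0] for c in res.clusters])
        order_ref = np.argsort([sorted(c[0])[0] for c in clusters_ref])
        assert np.allclose(
            res.p_values[order], np.asarray(p_ref)[order_ref], atol=0.02
        )

    def test_input_validation(self, adj63):
        a = np.zeros((10, 63))
        with pytest.raises(ValueError):
            cluster_permutation(a, a[:, :5], adj63, seed=0)
        with pytest.raises(ValueError):
            cluster_permutation(a, a, adj63, tail="both", seed=0)


class TestPhaseBins:
    def test_six_bins_partition_the_circle(self):
        edges = phase_bins(6)
        assert np.allclose(np.diff(edges), np.pi / 3)
        assert edges[0] == -np.pi and edges[-1] == np.pi

    def test_every_phase_assigned_exactly_once(self):
        rng = np.random.default_rng(7)
        ph = rng.uniform(-np.pi, np.pi, 1000)
        idx = assign_phase_bins(ph)
        assert idx.min() >= 0 and idx.max() <= 5
        edges = phase_bins(6)
        for b in range(6):
            sel = idx == b
            assert (ph[sel] >= edges[b]).all() and (ph[sel] < edges[b + 1]).all()

    def test_itpc_binning_shapes_and_missing_bins(self):
        rng = np.random.default_rng(8)
        n_trials, n_times = 60, 120
        times = -300.0 + np.arange(n_times) * 10.0
        coefs = np.exp(
            1j * rng.uniform(0, 2 * np.pi, (n_trials, 2, 1, n_times))
        )
        tf = TFMap(coefs, np.array([10.0]), times, ("O2", "PO4"), "coefficients")
        phases = rng.uniform(-np.pi, -np.pi / 3, n_trials)  # only bins 0-1
        out, t_sel, counts = phase_bin_itpc(phases, tf, (205.0, 705.0), 10.0)
        assert out.shape == (6, 51) and t_sel.size == 51
        assert t_sel[0] == 200.0 and t_sel[-1] == 700.0
        assert counts[2:].sum() == 0
        assert np.isnan(out[2:]).all() and not np.isnan(out[:2]).any()

    def test_uniform_phases_give_flat_bins(self):
        rng = np.random.default_rng(9)
        n_trials, n_times = 240, 120
        times = -300.0 + np.arange(n_times) * 10.0
        tables = []
        for _ in range(8):  # simulated participants, no phase dependence
            coefs = np.exp(
                1j * rng.uniform(0, 2 * np.pi, (n_trials, 2, 1, n_times))
            )
            tf = TFMap(coefs, np.array([10.0]), times, ("O2", "PO4"),
                       "coefficients")
            phases = rng.uniform(-np.pi, np.pi, n_trials)
            out, _, _ = phase_bin_itpc(phases, tf)
            tables.append(out.mean(axis=1))
        _, _, p = rm_anova_bins(np.array(tables))
        assert p > 0.05


class TestSineRegression:
    def test_exact_unit_sine(self):
        fit = sine_regression(np.sin(np.arange(1, 7) * np.pi / 3))
        assert fit.a == pytest.approx(1.0, abs=1e-9)
        assert fit.f == pytest.approx(1.0, abs=1e-9)
        assert fit.phi == pytest.approx(0.0, abs=1e-9)
        assert fit.c == pytest.approx(0.0, abs=1e-9)
        assert fit.sse < 1e-20

    def test_noiseless_parameter_recovery(self):
        x = np.arange(1, 7)
        y = 0.05 * np.sin(x * np.pi / 3 + np.pi / 4) + 0.4
        fit = sine_regression(y)
        assert abs(fit.a - 0.05) < 1e-6
        assert abs(fit.f - 1.0) < 1e-6
        assert abs(fit.phi - np.pi / 4) < 1e-6
        assert abs(fit.c - 0.4) < 1e-6

    def test_flat_input_flagged(self):
        fit = sine_regression(np.full(6, 0.3))
        assert fit.flat and fit.a == 0.0 and fit.c == pytest.approx(0.3)

    def test_canonicalization_idempotent(self):
        x = np.arange(1, 7)
        y = 0.2 * np.sin(x * np.pi / 3 + 5.1) + 0.6
        fit1 = sine_regression(y)
        fit2 = sine_regression(fit1.predict(x))
        assert fit1.a == pytest.approx(fit2.a, abs=1e-8)
        assert fit1.phi == pytest.approx(fit2.phi, abs=1e-7)
        assert 0.0 <= fit1.phi < 2 * np.pi and fit1.a >= 0.0


class TestRmAnova:
    def test_flat_participants(self):
        table = np.tile(np.array([[0.2], [0.5], [0.4]]), (1, 6))
        f_stat, dof, p = rm_anova_bins(table)
        assert f_stat == 0.0 and p == 1.0

    def test_dof_for_six_bins_ten_participants(self):
        rng = np.random.default_rng(10)
        _, dof, _ = rm_anova_bins(rng.normal(size=(10, 6)))
        assert dof == (5, 45)

    def test_matches_statsmodels(self):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(11)
        table = rng.normal(0, 1, (10, 6)) + 0.8 * np.sin(np.arange(6))
        long = pd.DataFrame(
            [
                {"s": s, "b": b, "y": table[s, b]}
                for s in range(10)
                for b in range(6)
            ]
        )
        ref = AnovaRM(long, "y", "s", within=["b"]).fit().anova_table
        f_stat, _, p = rm_anova_bins(table)
        assert f_stat == pytest.approx(float(ref["F Value"].iloc[0]))
        assert p == pytest.approx(float(ref["Pr > F"].iloc[0]))

    def test_power_against_planted_sinusoidal_effect(self):
        rng = np.random.default_rng(12)
        effect = np.sin(np.arange(1, 7) * np.pi / 3)  # 1 SD amplitude
        hits = 0
        for _ in range(100):
            table = rng.normal(0, 1, (10, 6)) + effect
            _, _, p = rm_anova_bins(table)
            hits += p < 0.01
        assert hits >= 90

    def test_missing_cells_rejected(self):
        table = np.ones((5, 6))
        table[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_bins(table)


class TestIafCorrelation:
    def test_perfect_linear_relation(self):
        iaf = np.linspace(8, 12, 10)
        out = correlate_iaf_itpc(iaf, 0.1 * iaf - 0.3)
        assert out["iaf"][0] == pytest.approx(1.0)

    def test_null_critical_value(self):
        # |r| exceeds 0.632 (two-tailed critical at n=10) in ~5% of nulls
        rng = np.random.default_rng(13)
        exceed = sum(
            abs(sps.pearsonr(rng.standard_normal(10),
                             rng.standard_normal(10))[0]) >= 0.632
            for _ in range(1000)
        )
        assert 0.02 <= exceed / 1000 <= 0.08
        out = correlate_iaf_itpc(rng.standard_normal(10) + 10.0,
                                 rng.standard_normal(10))
        assert abs(out["iaf"][0]) <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_iaf_itpc(np.full(5, 10.0), np.arange(5.0))
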