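"""Profile-RSS grid inference: analytic p0, g evaluation, recovery, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import neandsel as ns
from neandsel.genome import build_windows
from neandsel.inference import GEngine, _refined_grid
from neandsel.model import ModelParams
from neandsel.synthetic import SyntheticGenomeConfig, generate_dataset

F_A_LINKED = 0.7318316036619834


class TestP0Analytic:
    def test_exact_linear_fit(self):
        g = np.linspace(0.8, 1.0, 50)
        assert ns.p0_analytic(g, 0.03 * g) == pytest.approx(0.03, abs=1e-15)

    def test_single_snp(self):
        assert ns.p0_analytic([0.9], [0.027]) == pytest.approx(0.03)

    def test_matches_numeric_minimizer(self):
        rng = np.random.default_rng(5)
        g = rng.uniform(0.7, 1.0, 100)
        p_n = np.clip(0.034 * g + rng.normal(0, 0.01, 100), 0, 1)
        analytic = ns.p0_analytic(g, p_n)
        numeric = minimize_scalar(
            lambda p0: ns.rss(p_n, g, p0), bounds=(0, 1), method="bounded",
            options={"xatol": 1e-12},
        ).x
        assert analytic == pytest.approx(numeric, abs=1e-10)

    def test_clamped_to_unit_interval(self):
        assert ns.p0_analytic([0.5], [1.0]) == 1.0

    def test_empty_input(self):
        with pytest.raises(ValueError):
            ns.p0_analytic([], [])


class TestRSS:
    def test_hand_cases(self):
        assert ns.rss([0.1, 0.2], [1.0, 1.0], 0.15) == pytest.approx(0.005)
        assert ns.rss([0.1, 0.2], [1.0, 1.0], 0.0) == pytest.approx(0.05)
        g = np.array([0.9, 1.0])
        assert ns.rss(0.03 * g, g, 0.03) == 0.0


class TestGVector:
    def test_mu_zero_gives_ones(self, toy_genome):
        gmap, exons, calls, _ = toy_genome
        g = ns.g_vector(calls, exons, gmap, s=4e-4, t=2000, mu=0.0)
        assert np.all(g == 1.0)

    def test_single_exon_worked_example(self):
        gmap = ns.GeneticMap({"1": (np.array([0.0, 2e7]), np.array([0.0, 20.0]))})
        exons = ns.ExonAnnotation(
            {"1": (np.array([10_100_000 - 500]), np.array([10_100_000 + 500]))}
        )
        calls = ns.CallTable(pd.DataFrame({"chrom": ["1"], "pos": [10_000_000], "p": [0.03]}))
        g = ns.g_vector(calls, exons, gmap, s=4e-4, t=2000, mu=1e-4)
        assert g[0] == pytest.approx(0.1 * F_A_LINKED + 0.9, rel=1e-6)

    def test_wider_window_weakly_decreases_g(self, toy_genome):
        gmap, exons, calls, _ = toy_genome
        g1 = ns.g_vector(calls, exons, gmap, s=4e-4, t=2000, mu=1e-4, window_cm=1.0)
        g10 = ns.g_vector(calls, exons, gmap, s=4e-4, t=2000, mu=1e-4, window_cm=10.0)
        assert np.all(g10 <= g1 + 1e-9)
        assert np.all(g1 > 0) and np.all(g1 <= 1.0)

    def test_kernel_matches_float64_reference(self, toy_genome):
        gmap, exons, calls, _ = toy_genome
        windows = build_windows(calls, exons, gmap, 1.0)
        engine = GEngine(windows, 2000)
        for s, mu in [(4e-4, 8.1e-5), (1e-5, 1e-3), (3.9e-3, 1e-6)]:
            assert engine.g(s, mu) == pytest.approx(engine.g_reference(s, mu), abs=1e-6)

    def test_x_mode_scales_recombination(self, toy_genome):
        gmap, exons, calls, _ = toy_genome
        g_a = ns.g_vector(calls, exons, gmap, s=4e-4, t=2000, mu=1e-4, mode="autosome")
        g_x = ns.g_vector(calls, exons, gmap, s=4e-4, t=2000, mu=1e-4, mode="X")
        # weaker effective recombination on X -> stronger linked loss
        assert np.all(g_x <= g_a + 1e-12)


class TestGridFit:
    def test_zero_noise_truth_on_grid_is_recovered_exactly(self, toy_genome):
        gmap, exons, calls, truth = toy_genome
        s_grid = np.geomspace(1e-5, 4e-3, 13)
        s_grid[6] = truth.s
        mu_grid = np.geomspace(1e-6, 1e-3, 13)
        mu_grid[6] = truth.mu
        model = ns.LinkedSelectionModel(s_grid=s_grid, mu_grid=mu_grid).fit(
            calls, exons, gmap
        )
        assert model.s_ == truth.s and model.mu_ == truth.mu
        assert model.p0_ == pytest.approx(truth.p0, abs=1e-6)
        assert model.rss_ <= 1e-18

    def test_constant_calls_select_mu_zero_row(self, toy_genome):
        gmap, exons, calls, _ = toy_genome
        const = ns.CallTable(calls.df.assign(p=0.03))
        mu_grid = np.concatenate([[0.0], np.geomspace(1e-6, 1e-4, 5)])
        model = ns.LinkedSelectionModel(
            s_grid=np.geomspace(1e-5, 1e-3, 5), mu_grid=mu_grid, refine=False
        ).fit(const, exons, gmap)
        assert model.mu_ == 0.0
        assert model.p0_ == pytest.approx(0.03, abs=1e-12)
        assert model.rss_ <= 1e-12

    def test_scaled_surface_is_nonpositive_with_zero_at_best(self, toy_genome):
        gmap, exons, calls, _ = toy_genome
        model = ns.LinkedSelectionModel(coarse_size=6, refine=False).fit(
            calls, exons, gmap
        )
        scaled = model.grid_.scaled
        assert scaled.max() == 0.0
        i, j = model.grid_.best_index
        assert scaled[i, j] == 0.0

    def test_invariant_to_snp_order(self, toy_genome):
        gmap, exons, calls, _ = toy_genome
        rng = np.random.default_rng(0)
        shuffled = ns.CallTable(
            calls.df.sample(frac=1.0, random_state=rng.integers(1 << 16)).reset_index(
                drop=True
            )
        )
        m1 = ns.LinkedSelectionModel(coarse_size=6, refine=False).fit(calls, exons, gmap)
        m2 = ns.LinkedSelectionModel(coarse_size=6, refine=False).fit(shuffled, exons, gmap)
        assert (m1.s_, m1.mu_) == (m2.s_, m2.mu_)
        assert m1.p0_ == pytest.approx(m2.p0_, rel=1e-12)

    def test_profile_surface_has_mus_ridge(self, toy_genome):
        """RSS varies far less along curves of constant mu*s than across them."""
        gmap, exons, calls, truth = toy_genome
        factors = np.array([0.5, 1.0, 2.0])
        # along the ridge: (s*k, mu/k); across: (s*k, mu*k)
        along, across = [], []
        windows = build_windows(calls, exons, gmap, 1.0)
        engine = GEngine(windows, 2000)
        p_n = calls.p
        for k in factors:
            for target, s, mu in (
                (along, truth.s * k, truth.mu / k),
                (across, truth.s * k, truth.mu * k),
            ):
                g = engine.g(s, mu)
                target.append(ns.rss(p_n, g, ns.p0_analytic(g, p_n)))
        assert np.ptp(along) < 0.2 * np.ptp(across)

    def test_refined_grid_contains_center(self):
        vals = np.geomspace(1e-5, 1e-3, 9)
        for i in (0, 4, 8):
            fine = _refined_grid(vals, i, 26)
            assert np.any(fine == vals[i])
            assert fine.size <= 26
            assert np.all(np.diff(fine) > 0)

    def test_estimator_follows_sklearn_conventions(self, toy_genome):
        gmap, exons, calls, _ = toy_genome
        model = ns.LinkedSelectionModel(coarse_size=5, refine=False)
        params = model.get_params()
        assert params["t"] == 2000 and params["mode"] == "autosome"
        model.set_params(window_cm=1.0)
        with pytest.raises(RuntimeError):
            model.predict()
        model.fit(calls, exons, gmap)
        pred = model.predict()
        assert pred.shape == (len(calls),)
        assert model.score(calls) == pytest.approx(-model.rss_, rel=1e-6)

    def test_empty_call_table_rejected(self, toy_genome):
        gmap, exons, _, _ = toy_genome
        empty = ns.CallTable(pd.DataFrame({"chrom": [], "pos": [], "p": []}))
        with pytest.raises(ValueError):
            ns.LinkedSelectionModel().fit(empty, exons, gmap)


class TestParameterRecovery:
    def test_median_errors_and_mus_rank_correlation(self, recovery_batch):
        """Across 50 drift-noise genomes with truths near the published
        estimates: p0 is tightly recovered, s within a factor ~2, and the
        compound mu*s tracks the truth in rank (mu and s individually are
        confounded along the RSS ridge)."""
        from scipy.stats import spearmanr

        rel_s = [abs(r.s_hat - r.truth.s) / r.truth.s for r in recovery_batch]
        rel_p0 = [abs(r.p0_hat - r.truth.p0) / r.truth.p0 for r in recovery_batch]
        assert np.median(rel_s) <= 0.5
        assert np.median(rel_p0) <= 0.1
        true_mus = [r.truth.s * r.truth.mu for r in recovery_batch]
        est_mus = [r.mus_hat for r in recovery_batch]
        assert spearmanr(true_mus, est_mus).statistic > 0


class TestExonDensityDiagnostic:
    def test_zero_noise_observed_equals_predicted(self, toy_genome):
        gmap, exons, calls, _ = toy_genome
        model = ns.LinkedSelectionModel(coarse_size=6).fit(calls, exons, gmap)
        diag = ns.exon_density_diagnostic(calls, exons, gmap, model)
        assert diag.table["observed"].to_numpy() == pytest.approx(
            diag.table["predicted"].to_numpy(), abs=1e-4
        )
        assert diag.pearson_r > 0.99

    def test_prediction_decreases_with_exon_density(self, toy_genome):
        gmap, exons, calls, _ = toy_genome
        model = ns.LinkedSelectionModel(coarse_size=6).fit(calls, exons, gmap)
        diag = ns.exon_density_diagnostic(calls, exons, gmap, model, n_bins=5)
        pred = diag.table.sort_values("mean_exonic_bases")["predicted"].to_numpy()
        assert np.all(np.diff(pred) <= 1e-6)

    def test_toy_two_bin_means(self):
        """Four 1-cM segments, two bins: means computed by hand."""
        gmap = ns.GeneticMap({"1": (np.array([0.0, 4e6]), np.array([0.0, 4.0]))})
        exons = ns.ExonAnnotation(
            {"1": (np.array([2_500_000, 3_500_000]), np.array([2_500_600, 3_500_100]))}
        )
        pos = np.array([0.5e6, 1.5e6, 2.5e6, 3.5e6], dtype=int)
        p_obs = np.array([0.04, 0.03, 0.02, 0.01])
        calls = ns.CallTable(pd.DataFrame({"chrom": "1", "pos": pos, "p": p_obs}))
        model = ns.LinkedSelectionModel(
            s_grid=[4e-4], mu_grid=[1e-4], refine=False
        ).fit(calls, exons, gmap)
        diag = ns.exon_density_diagnostic(calls, exons, gmap, model, n_bins=2)
        # zero-exon segments (first two) collapse into the low-density bin
        low = diag.table.iloc[0]
        high = diag.table.iloc[1]
        assert low["observed"] == pytest.approx(0.035)
        assert high["observed"] == pytest.approx(0.015)

    def test_fewer_segments_than_bins_warns(self, toy_genome):
        gmap, exons, calls, _ = toy_genome
        model = ns.LinkedSelectionModel(coarse_size=4, refine=False).fit(
            calls, exons, gmap
        )
        with pytest.warns(RuntimeWarning):
            ns.exon_density_diagnostic(calls, exons, gmap, model, segment_cm=2.0, n_bins=1000)
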