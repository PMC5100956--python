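"""Closed-form retention factors, their recursion oracles, and the
nearest-exon mixture."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neandsel as ns
from neandsel.model import LinkedExonContext, ModelParams

# frozen oracle values: recursion_oracle(r=0.001, s=4e-4, t=2000) iterated in
# exact arithmetic equals the closed form to ~1e-14
F_A_LINKED = 0.7318316036619834
F_X_LINKED = 0.6695266256093529


class TestAutosomalRetention:
    @pytest.mark.parametrize(
        "r,s,t,expected,tol",
        [
            (0.0, 0.0004, 2000, (1 - 0.0004) ** 2000, 1e-12),  # unlinked: (1-s)^t
            (0.3, 0.0, 5000, 1.0, 1e-12),  # no selection, no loss
            (0.001, 0.0004, 2000, F_A_LINKED, 1e-8),
        ],
    )
    def test_point_values(self, r, s, t, expected, tol):
        assert ns.f_autosome(r, s, t) == pytest.approx(expected, abs=tol)

    def test_agrees_with_recursion_over_published_grid(self):
        """Closed form vs iterated haplotype recursion over the 26x26 grid of
        (r, s) combinations used for the simulation validation."""
        r = np.geomspace(1e-5, 1e-2, 26)[:, None]
        s = np.geomspace(1e-5, 4e-4, 26)[None, :]
        closed = ns.f_autosome(r, s, 2000)
        iterated = ns.recursion_oracle(r, s, 2000, p0=1.0, mode="autosome")
        assert np.abs(closed - iterated).max() <= 1e-8

    def test_equilibrium_values_and_limit(self):
        assert ns.f_autosome_equilibrium(0.001, 0.0004) == pytest.approx(
            0.001 / 0.0013996, rel=1e-6
        )
        assert ns.f_autosome_equilibrium(0.5, 0.0) == 1.0
        assert ns.f_autosome_equilibrium(0.01, 1e-5) == pytest.approx(0.99901, abs=5e-6)
        # long-time convergence to the gene flow factor
        r = np.geomspace(1e-5, 1e-2, 26)[:, None]
        s = np.geomspace(1e-5, 4e-4, 26)[None, :]
        rel = np.abs(ns.f_autosome(r, s, 10**7) - ns.f_autosome_equilibrium(r, s))
        rel /= ns.f_autosome_equilibrium(r, s)
        assert rel.max() <= 1e-6

    def test_equilibrium_degenerate_input(self):
        with pytest.raises(ValueError):
            ns.f_autosome_equilibrium(0.0, 0.0)

    def test_t_inf_sentinel_routes_to_equilibrium(self):
        assert ns.f_autosome(0.001, 0.0004, math.inf) == ns.f_autosome_equilibrium(
            0.001, 0.0004
        )

    @pytest.mark.parametrize("bad", [(-0.1, 0.1), (0.6, 0.1), (0.1, -0.2), (0.1, 1.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            ns.f_autosome(bad[0], bad[1], 100)

    @given(
        r=st.floats(0.0, 0.5),
        s=st.floats(0.0, 0.99),
        t=st.integers(0, 100000),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_in_unit_interval(self, r, s, t):
        f = ns.f_autosome(r, s, t)
        assert -1e-12 <= f <= 1 + 1e-12

    def test_monotonicity_on_grid(self):
        """f is non-decreasing in r, non-increasing in s and in t."""
        r = np.linspace(0, 0.5, 26)[:, None]
        s = np.linspace(0, 0.99, 26)[None, :]
        prev = None
        for t in (0, 10, 100, 2000, 100000):
            f = ns.f_autosome(r, s, t)
            assert np.all(np.diff(f, axis=0) >= -1e-12)
            assert np.all(np.diff(f, axis=1) <= 1e-12)
            if prev is not None:
                assert np.all(f <= prev + 1e-12)
            prev = f


class TestXRetention:
    @pytest.mark.parametrize(
        "r,s,t,expected,tol",
        [
            (0.0, 0.0004, 2000, (1 - 0.0004) ** 2000, 1e-12),
            (0.2, 0.0, 1000, 1.0, 1e-12),
            (0.001, 0.0004, 2000, F_X_LINKED, 1e-8),
        ],
    )
    def test_point_values(self, r, s, t, expected, tol):
        assert ns.f_xchr(r, s, t) == pytest.approx(expected, abs=tol)

    def test_matches_effective_transmission_recursion(self):
        """The X closed form is the exact solution of the single-pool
        transmission recursion with effective recombination (2/3) r."""
        r = np.geomspace(1e-5, 1e-2, 26)[:, None]
        s = np.geomspace(1e-5, 4e-4, 26)[None, :]
        closed = ns.f_xchr(r, s, 2000)
        iterated = ns.recursion_oracle(2.0 / 3.0 * r, s, 2000, p0=1.0, mode="autosome")
        assert np.abs(closed - iterated).max() <= 1e-8

    def test_two_sex_recursion_cross_check(self):
        """The explicit female/male pool recursion deviates from the
        2/3-time-averaged closed form only at O(r^2) per generation; over the
        published grid at t=2000 the deviation stays below 1e-3."""
        r = np.geomspace(1e-5, 1e-2, 26)[:, None]
        s = np.geomspace(1e-5, 4e-4, 26)[None, :]
        closed = ns.f_xchr(r, s, 2000)
        two_sex = ns.recursion_oracle(r, s, 2000, p0=1.0, mode="X")
        assert np.abs(closed - two_sex).max() <= 1e-3


class TestRecursionOracle:
    def test_fully_neutral_is_conserved(self):
        assert ns.recursion_oracle(0.0, 0.0, 100, p0=0.04, mode="autosome") == 0.04
        assert ns.recursion_oracle(0.0, 0.0, 100, p0=0.04, mode="X") == pytest.approx(
            0.04, abs=1e-15
        )

    @pytest.mark.parametrize("mode", ["autosome", "X"])
    def test_non_increasing_in_time(self, mode):
        vals = [
            ns.recursion_oracle(0.5, 0.9, t, p0=0.5, mode=mode) for t in (0, 1, 5, 20, 100)
        ]
        assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            ns.recursion_oracle(0.1, 0.1, 10, mode="Y")


class TestNearestExonWeights:
    def test_two_equal_exons(self):
        ctx = LinkedExonContext(np.array([0.001, 0.002]), np.array([1000.0, 1000.0]))
        w = ns.nearest_exon_weights(ctx, 1e-4)
        assert w == pytest.approx([0.1, 0.09, 0.81], abs=1e-15)

    def test_mu_zero_and_empty_window(self):
        ctx = LinkedExonContext(np.array([0.001]), np.array([500.0]))
        assert ns.nearest_exon_weights(ctx, 0.0) == pytest.approx([0.0, 1.0])
        empty = LinkedExonContext(np.empty(0), np.empty(0))
        assert ns.nearest_exon_weights(empty, 1e-4) == pytest.approx([1.0])

    def test_saturated_exon_clamps_with_warning(self):
        ctx = LinkedExonContext(np.array([0.001, 0.002]), np.array([2e4, 1e3]))
        with pytest.warns(RuntimeWarning):
            w = ns.nearest_exon_weights(ctx, 1e-3)
        assert w[0] == pytest.approx(1.0)
        assert w[1:] == pytest.approx([0.0, 0.0], abs=1e-15)

    @given(
        mu=st.floats(0.0, 1e-3),
        lengths=st.lists(st.floats(1.0, 5e3), min_size=0, max_size=30),
    )
    @settings(max_examples=200, deadline=None)
    def test_weights_always_sum_to_one(self, mu, lengths):
        import warnings as _warnings

        n = len(lengths)
        ctx = LinkedExonContext(np.linspace(0.0, 0.01, n), np.asarray(lengths))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # mu*l may saturate
            w = ns.nearest_exon_weights(ctx, mu)
        assert abs(w.sum() - 1.0) <= 1e-12


class TestExpectedFrequency:
    def test_single_exon_composition(self):
        """p0 * (mu*l * f + (1 - mu*l)) for one 1-kb exon at r=0.001."""
        ctx = LinkedExonContext(np.array([0.001]), np.array([1000.0]))
        params = ModelParams(p0=0.034, s=4e-4, t=2000, mu=1e-4)
        expected = 0.034 * (0.1 * F_A_LINKED + 0.9)
        assert ns.expected_frequency(ctx, params) == pytest.approx(expected, rel=1e-8)

    def test_neutral_cases_return_p0(self):
        ctx = LinkedExonContext(np.array([0.001]), np.array([1000.0]))
        assert ns.expected_frequency(ctx, ModelParams(0.034, 0.1, 100, 0.0)) == 0.034
        empty = LinkedExonContext(np.empty(0), np.empty(0))
        assert ns.expected_frequency(empty, ModelParams(0.034, 0.1, 100, 1e-4)) == 0.034

    def test_non_increasing_in_mu_and_s(self):
        ctx = LinkedExonContext(np.array([0.0005, 0.002]), np.array([800.0, 1500.0]))
        base = ns.expected_frequency(ctx, ModelParams(0.034, 4e-4, 2000, 1e-4))
        more_mu = ns.expected_frequency(ctx, ModelParams(0.034, 4e-4, 2000, 5e-4))
        more_s = ns.expected_frequency(ctx, ModelParams(0.034, 4e-3, 2000, 1e-4))
        assert more_mu <= base and more_s <= base

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ModelParams(p0=1.5, s=0.1, t=10, mu=0.0)
        with pytest.raises(ValueError):
            ModelParams(p0=0.5, s=1.0, t=10, mu=0.0)
        with pytest.raises(ValueError):
            ModelParams(p0=0.5, s=0.1, t=-1, mu=0.0)
        with pytest.raises(ValueError):
            ModelParams(p0=0.5, s=0.1, t=10, mu=0.0, mode="Y")
        assert ModelParams(p0=0.5, s=0.1, t=math.inf, mu=0.0).is_equilibrium
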