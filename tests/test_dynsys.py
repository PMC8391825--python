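"""Chaotic maps, Lyapunov estimation, flows and maxima extraction."""

import itertools
import math

import numpy as np
import pytest

from ordinoise.dynsys import (
    FlowDivergenceError,
    integrate_flow,
    iterate_map,
    lyapunov_1d,
    maxima_series,
)
from ordinoise.ordinal import OrdinalConfig, ordinal_distribution


class TestMaps:
    @pytest.mark.parametrize("family,param", [("logistic", 4.0), ("beta_x", 2.7), ("schuster", 1.5)])
    def test_orbit_stays_in_unit_interval(self, family, param):
        x = iterate_map(family, param, 5000).values
        assert x.min() >= 0.0 and x.max() <= 1.0

    def test_integer_beta_orbit_does_not_collapse(self):
        # the float64 doubling map collapses to 0; the exact path must not
        for beta in (2, 4, 8):
            x = iterate_map("beta_x", beta, 5000).values
            assert np.unique(np.round(x, 6)).size > 4000

    def test_reproducible_without_seed_and_seedable(self):
        a = iterate_map("beta_x", 2, 500).values
        b = iterate_map("beta_x", 2, 500).values
        c = iterate_map("beta_x", 2, 500, seed=9).values
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_explicit_x0_controls_orbit(self):
        a = iterate_map("logistic", 3.9, 100, x0=0.2, burn_in=0).values
        assert a[0] == 0.2

    @pytest.mark.parametrize(
        "family,param", [("logistic", 4.5), ("logistic", 0.0), ("beta_x", -1.0), ("schuster", 0.0)]
    )
    def test_out_of_range_parameters_rejected(self, family, param):
        with pytest.raises(ValueError):
            iterate_map(family, param, 100)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown map family"):
            iterate_map("tent", 2.0, 100)

    def test_schuster_intermittency_grows_with_z(self):
        # laminar phases near 0 lengthen as the reinjection exponent grows
        def longest_laminar(z):
            x = iterate_map("schuster", z, 2**14).values < 0.05
            runs = [len(list(g)) for k, g in itertools.groupby(x) if k]
            return max(runs) if runs else 0

        assert longest_laminar(2.0) > 50 * max(longest_laminar(0.5), 1)

    def test_beta2_indistinguishable_from_uniform_by_histogram(self):
        x = iterate_map("beta_x", 2, 2**14).values
        hist, _ = np.histogram(x, bins=10, range=(0, 1))
        assert hist.min() > 0.9 * len(x) / 10


class TestLyapunov:
    @pytest.mark.parametrize("beta", [2.0, 3.0, 10.0])
    def test_beta_map_closed_form(self, beta):
        assert abs(lyapunov_1d("beta_x", beta, n_terms=10**6) - math.log(beta)) <= 1e-3

    def test_logistic_fully_chaotic_closed_form(self):
        # r=4 conjugates to the tent map: lambda = ln 2
        assert abs(lyapunov_1d("logistic", 4.0, n_terms=200_000) - math.log(2)) <= 5e-3

    def test_logistic_periodic_window_negative(self):
        assert lyapunov_1d("logistic", 3.83, n_terms=100_000) < 0.0
        assert lyapunov_1d("logistic", 4.0, n_terms=100_000) > 0.0


class TestFlows:
    def test_lorenz_bounded_and_aperiodic(self):
        tr = integrate_flow("lorenz", t_total=100.0)
        x = tr.column("x")
        assert np.all(np.isfinite(tr.values))
        assert 20 < np.abs(x).max() < 100
        m = maxima_series(tr, "x").values
        assert np.std(m) > 1.0  # successive maxima vary: not a limit cycle

    def test_step_halving_preserves_maxima_statistics(self):
        a = maxima_series(integrate_flow("lorenz", t_total=120.0, dt=0.01), "x").values
        b = maxima_series(integrate_flow("lorenz", t_total=120.0, dt=0.005), "x").values
        assert abs(len(a) - len(b)) <= 5
        assert abs(a.mean() - b.mean()) < 1.0
        assert abs(a.std() - b.std()) < 1.5

    def test_three_waves_amplitude_observable(self):
        tr = integrate_flow("three_waves", t_total=150.0)
        c1 = tr.column("abs_C1")
        assert (c1 > 0).all()
        assert c1.std() > 0.1 * c1.mean()  # visibly fluctuating amplitude

    def test_hindmarsh_rose_bursting(self):
        tr = integrate_flow("hindmarsh_rose", t_total=2000.0)
        x = tr.column("x")
        # bursts of spikes above 1 separated by quiescent phases below -1
        assert x.max() > 1.0 and x.min() < -1.0
        assert np.mean(x < -0.9) > 0.3  # substantial quiescent fraction
        pk = (x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])
        isi = np.diff(tr.times[1:-1][pk])
        assert isi.max() > 2.5 * np.median(isi)  # inter-burst gaps dwarf intra-burst ones

    def test_divergence_reported_with_time(self):
        with pytest.raises(FlowDivergenceError, match="diverged at t"):
            integrate_flow("lorenz", t_total=50.0, dt=1.0)

    def test_unknown_parameters_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            integrate_flow("lorenz", t_total=10.0, params={"sigma": 16.0, "rho": 1.0})

    def test_rossler_maxima_count(self):
        tr = integrate_flow("rossler", t_total=500.0)
        m = maxima_series(tr, "x")
        assert 50 < len(m) < 120  # roughly one maximum per ~6 time units


class TestMaximaSeries:
    def test_sinusoid_constant_maxima_single_pattern(self):
        from ordinoise.dynsys import Trajectory

        t = np.arange(0.0, 200.0, 0.1)
        y = np.sin(2.0 * np.pi * t / 10.0)  # period exactly 100 samples
        tr = Trajectory("synthetic", t, np.column_stack([y] * 3), ("x", "y", "z"), 0.1)
        m = maxima_series(tr, "x")
        d = ordinal_distribution(m, OrdinalConfig(D=3))
        assert (d.counts > 0).sum() == 1  # ties collapse to one pattern

    def test_monotone_segment_has_no_maxima(self):
        from ordinoise.dynsys import Trajectory

        t = np.arange(100.0)
        tr = Trajectory("synthetic", t, np.column_stack([t, t, t]), ("x", "y", "z"), 1.0)
        with pytest.raises(ValueError, match="only 0 local maxima"):
            maxima_series(tr, "x", min_count=6)

    def test_unknown_variable_rejected(self):
        tr = integrate_flow("lorenz", t_total=10.0)
        with pytest.raises(KeyError):
            maxima_series(tr, "w")
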