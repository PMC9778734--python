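import math

import numpy as np
import pytest

from glycopmf import (
    CVSeries,
    NumericalError,
    PotentialSpec,
    UmbrellaWindow,
    ValidationError,
    conformation_weights,
    convergence_check,
    direct_projection,
    equilibration_discard,
    generate_umbrella_set,
    pool_windows,
    profile_deviation,
    reweighted_projection,
    simulate_langevin,
    tst_convert,
    wham_solve,
)
from glycopmf.constants import KB_KCAL, KB_SI, PLANCK_SI

from conftest import UMBRELLA_RANGE
from helpers_oracles import wham_fixed_point_oracle

KT310 = KB_KCAL * 310.0


def series_from_values(values, labels=None, temperature=310.0):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return CVSeries(times=np.arange(1, n + 1, dtype=float), values=values,
                    labels=labels, temperature=temperature)


class TestDirectProjection:
    def test_uniform_occupancy_is_flat_zero(self):
        series = series_from_values(np.repeat([0.5, 1.5, 2.5, 3.5], 25))
        profile = direct_projection(series, n_bins=4, bin_range=[(0, 4)])
        assert np.allclose(profile.delta_g, 0.0)

    def test_two_bin_closed_form(self):
        # counts 100 vs 10 at 310 K: dG = -kT ln(0.1) = 1.4185 kcal/mol
        series = series_from_values(np.concatenate([np.full(100, 0.5), np.full(10, 1.5)]))
        profile = direct_projection(series, n_bins=2, bin_range=[(0, 2)])
        assert profile.delta_g[0] == 0.0
        assert profile.delta_g[1] == pytest.approx(-KT310 * math.log(0.1), abs=1e-12)
        assert profile.delta_g[1] == pytest.approx(1.4185, abs=5e-4)

    def test_empty_bin_is_inf_not_zero(self):
        series = series_from_values(np.concatenate([np.full(10, 0.5), np.full(10, 2.5)]))
        profile = direct_projection(series, n_bins=3, bin_range=[(0, 3)])
        assert np.isinf(profile.delta_g[1])
        assert profile.mass[1] == 0.0

    def test_auto_bins_sqrt_n(self):
        series = series_from_values(np.linspace(0, 1, 100))
        profile = direct_projection(series, n_bins="auto")
        assert profile.delta_g.size == 10  # ceil(sqrt(100))

    def test_temperature_scaling_linear(self):
        values = np.concatenate([np.full(100, 0.5), np.full(10, 1.5)])
        p1 = direct_projection(series_from_values(values), n_bins=2, bin_range=[(0, 2)])
        p2 = direct_projection(series_from_values(values, temperature=620.0),
                               n_bins=2, bin_range=[(0, 2)])
        assert p2.delta_g[1] == pytest.approx(2 * p1.delta_g[1])

    def test_2d_projection_shape_and_anchor(self):
        rng = np.random.default_rng(0)
        series = series_from_values(rng.normal(size=(500, 2)), labels=["a", "b"])
        profile = direct_projection(series, axes=["a", "b"], n_bins=8)
        assert profile.delta_g.shape == (8, 8)
        assert np.nanmin(profile.delta_g[profile.occupied]) == 0.0

    def test_monotone_occupancy_monotone_energy(self):
        counts = [80, 40, 20, 10]
        values = np.concatenate([np.full(c, 0.5 + i) for i, c in enumerate(counts)])
        profile = direct_projection(series_from_values(values), n_bins=4, bin_range=[(0, 4)])
        assert np.all(np.diff(profile.delta_g) > 0)


class TestEquilibrationDiscard:
    def window(self, n=100, dt=0.1):
        series = CVSeries(times=dt * np.arange(1, n + 1), values=np.zeros(n),
                          temperature=310.0)
        return UmbrellaWindow(center=0.0, force_constant=100.0, series=series)

    def test_default_two_ps(self):
        w = self.window(n=100, dt=0.1)  # 10 ps window
        out = equilibration_discard(w)
        assert out.series.times[0] >= 2.0
        assert len(out.series) == 81  # 8 ps retained at 0.1 ps spacing, inclusive

    def test_zero_is_identity(self):
        w = self.window()
        assert equilibration_discard(w, 0.0) is w

    def test_discard_everything_raises(self):
        with pytest.raises(ValidationError):
            equilibration_discard(self.window(), t_eq=1000.0)


class TestWhamZeroBias:
    def test_null_bias_reduces_to_pooled_histogram(self):
        pot = PotentialSpec("harmonic", {"stiffness": 5.0}, domain=(-3, 3))
        windows = generate_umbrella_set(pot, [0.0], force_constant=0.0,
                                        steps_per_window=5000, seed=2, dt=1e-3)
        solution, pmf = wham_solve(windows, n_bins=30, bin_range=(-1.5, 1.5))
        pooled = pool_windows(windows)
        direct = direct_projection(pooled, n_bins=30, bin_range=[(-1.5, 1.5)])
        np.testing.assert_array_equal(pmf.counts, direct.counts)  # bitwise
        both = pmf.occupied & direct.occupied
        assert np.max(np.abs(pmf.delta_g[both] - direct.delta_g[both])) <= 1e-9
        assert solution.converged
        np.testing.assert_allclose(solution.f, 0.0, atol=1e-12)

    def test_uniform_weights_one_window(self):
        pot = PotentialSpec("harmonic", {"stiffness": 5.0}, domain=(-3, 3))
        windows = generate_umbrella_set(pot, [0.0], force_constant=0.0,
                                        steps_per_window=1000, seed=2, dt=1e-3)
        solution, _ = wham_solve(windows, n_bins=20)
        np.testing.assert_allclose(solution.sample_weights, 1.0 / 1000, rtol=1e-12)

    def test_uniform_weights_two_windows(self):
        pot = PotentialSpec("harmonic", {"stiffness": 5.0}, domain=(-3, 3))
        windows = generate_umbrella_set(pot, [-0.05, 0.05], force_constant=0.0,
                                        steps_per_window=700, seed=3, dt=1e-3)
        solution, _ = wham_solve(windows, n_bins=20)
        np.testing.assert_allclose(solution.sample_weights, 1.0 / 1400, rtol=1e-12)


class TestWhamOracle:
    @pytest.mark.parametrize("n_win,n_bins,seed", [(1, 5, 0), (2, 8, 1), (3, 10, 2)])
    def test_matches_bruteforce_fixed_point(self, n_win, n_bins, seed):
        rng = np.random.default_rng(seed)
        centers = np.linspace(-0.3, 0.3, n_win)
        ks = np.full(n_win, 20.0)
        samples = [rng.normal(c, 0.35, size=40) for c in centers]
        edges = np.linspace(-1.0, 1.0, n_bins + 1)
        windows = [
            UmbrellaWindow(center=float(c), force_constant=float(k),
                           series=series_from_values(x))
            for c, k, x in zip(centers, ks, samples)
        ]
        solution, pmf = wham_solve(windows, n_bins=n_bins, bin_range=(-1.0, 1.0),
                                   tolerance=1e-13, max_iter=500000)
        f_ref, p_ref = wham_fixed_point_oracle(samples, centers, ks, edges, 310.0)
        np.testing.assert_allclose(solution.f, f_ref, atol=1e-8)
        np.testing.assert_allclose(pmf.mass, p_ref, atol=1e-8)

    def test_harmonic_curvature_recovery(self):
        kappa = 5.0
        pot = PotentialSpec("harmonic", {"stiffness": kappa, "center": 0.0},
                            domain=(-3, 3))
        centers = np.round(np.arange(-1.0, 1.001, 0.1), 10)
        windows = generate_umbrella_set(pot, centers, force_constant=100.0,
                                        steps_per_window=4000, seed=12, dt=5e-4)
        _, pmf = wham_solve(windows, n_bins=60, bin_range=(-1.0, 1.0))
        c = pmf.centers[0][pmf.occupied]
        g = pmf.delta_g[pmf.occupied]
        coeffs = np.polyfit(c, g, 2)
        assert 2 * coeffs[0] == pytest.approx(kappa, rel=0.10)

    def test_disconnected_windows_flagged(self):
        far = [series_from_values(np.full(50, -2.0) + 0.01 * np.arange(50) % 0.05),
               series_from_values(np.full(50, 2.0) + 0.01 * np.arange(50) % 0.05)]
        windows = [UmbrellaWindow(center=c, force_constant=50.0, series=s)
                   for c, s in zip([-2.0, 2.0], far)]
        with pytest.warns(UserWarning, match="disconnected"):
            solution, _ = wham_solve(windows, n_bins=40)
        assert not solution.connected


class TestConformationWeights:
    def test_weights_reproduce_binned_density(self, umbrella_windows, wham_result):
        solution, pmf = wham_result
        weights = conformation_weights(umbrella_windows, solution)
        edges = solution.edges
        pooled_x = np.concatenate([w.x for w in umbrella_windows])
        inside = (pooled_x >= edges[0]) & (pooled_x <= edges[-1])
        acc = np.zeros(len(edges) - 1)
        idx = np.clip(np.searchsorted(edges, pooled_x[inside], side="right") - 1,
                      0, len(edges) - 2)
        np.add.at(acc, idx, weights[inside])
        acc_norm = acc / acc.sum()
        np.testing.assert_allclose(acc_norm, pmf.mass, atol=1e-6)
        assert weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(weights > 0)

    def test_window_mismatch_rejected(self, umbrella_windows, wham_result):
        solution, _ = wham_result
        with pytest.raises(ValidationError):
            conformation_weights(umbrella_windows[:-1], solution)


class TestReweightedProjection:
    def test_uniform_weights_equal_direct(self):
        rng = np.random.default_rng(1)
        series = series_from_values(rng.normal(size=400))
        direct = direct_projection(series, n_bins=15, bin_range=[(-3, 3)])
        n = len(series)
        rw = reweighted_projection(series, np.full(n, 1.0 / n), n_bins=15,
                                   bin_range=[(-3, 3)])
        both = direct.occupied
        assert np.array_equal(direct.occupied, rw.occupied)
        assert np.max(np.abs(direct.delta_g[both] - rw.delta_g[both])) <= 1e-12

    def test_all_mass_in_one_bin(self):
        series = series_from_values(np.array([0.5, 1.5, 2.5]))
        w = np.array([1.0, 0.0, 0.0])
        with np.errstate(all="ignore"):
            profile = reweighted_projection(series, w, n_bins=3, bin_range=[(0, 3)])
        assert profile.delta_g[0] == 0.0
        assert np.isinf(profile.delta_g[1]) and np.isinf(profile.delta_g[2])

    def test_reproduces_wham_pmf_on_biased_coordinate(self, umbrella_windows, wham_result):
        solution, pmf = wham_result
        pooled = pool_windows(umbrella_windows)
        rw = reweighted_projection(pooled, solution.sample_weights, n_bins=100,
                                   bin_range=[UMBRELLA_RANGE])
        assert profile_deviation(rw, pmf) < 0.05

    def test_unnormalized_weights_rejected(self):
        series = series_from_values(np.array([0.5, 1.5]))
        with pytest.raises(ValidationError):
            reweighted_projection(series, np.array([1.0, 1.0]), n_bins=2)


class TestConvergenceCheck:
    def test_well_sampled_set_converges(self, umbrella_windows):
        for scheme in ("direct", "reverse"):
            report = convergence_check(umbrella_windows, scheme=scheme, n_blocks=5,
                                       n_bins=200, bin_range=(-1.25, 1.25))
            assert report.converged
            assert max(report.deviations) < 1.0

    def test_duplicated_blocks_have_zero_deviation(self):
        x = np.tile(np.linspace(-0.2, 0.2, 50), 4)
        series = series_from_values(x)
        window = UmbrellaWindow(center=0.0, force_constant=0.0, series=series)
        report = convergence_check([window], n_blocks=4, n_bins=5,
                                   bin_range=(-0.25, 0.25))
        assert report.deviations[-1] == 0.0

    def test_truncated_set_flagged_unconverged(self, umbrella_windows):
        starved = []
        for w in umbrella_windows:
            n = max(1, int(0.05 * len(w.series)))
            starved.append(UmbrellaWindow(center=w.center, force_constant=w.force_constant,
                                          series=w.series.select(slice(0, n))))
        report = convergence_check(starved, scheme="direct", n_blocks=5, n_bins=200,
                                   bin_range=(-1.25, 1.25))
        assert not report.converged

    def test_scheme_validated(self, umbrella_windows):
        with pytest.raises(ValidationError):
            convergence_check(umbrella_windows, scheme="sideways")


class TestTstConvert:
    def test_zero_barrier_gives_prefactor(self):
        rate = tst_convert(0.0, "barrier_to_rate", temperature=310.0)
        assert rate == pytest.approx(KB_SI * 310.0 / PLANCK_SI, rel=1e-12)
        assert rate == pytest.approx(6.46e12, rel=1e-3)

    def test_round_trip_identity(self):
        barrier = 14.4
        rate = tst_convert(barrier, "barrier_to_rate", temperature=310.0)
        assert tst_convert(rate, "rate_to_barrier", temperature=310.0) == \
            pytest.approx(barrier, abs=1e-10)

    def test_monotone_decreasing_in_barrier(self):
        rates = [tst_convert(b, "barrier_to_rate") for b in (1.0, 5.0, 10.0, 14.0)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValidationError):
            tst_convert(0.0, "rate_to_barrier")


class TestProfileDeviation:
    def test_no_shared_bins_raises(self):
        a = direct_projection(series_from_values(np.full(10, 0.5)), n_bins=2,
                              bin_range=[(0, 2)])
        b = direct_projection(series_from_values(np.full(10, 1.5)), n_bins=2,
                              bin_range=[(0, 2)])
        with pytest.raises(NumericalError):
            profile_deviation(a, b)
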