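"""Mosaic statistics: histograms, Gaussian fits, Poisson reference, RI, DRP."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from retmosaic import (
    POISSON_NND_RI,
    NNDHistogram,
    SimConfig,
    compare_histogram_to_reference,
    density_recovery_profile,
    fit_gaussian,
    nearest_neighbor_distances,
    nnd_histogram,
    poisson_nnd_pdf,
    regularity_index,
    simulate_field,
)

#: intensity of the printed dense central field: 292 cells / 246.03² μm²
LAMBDA_CENTRAL = 292 / 246.03**2


class TestNNDHistogram:
    def test_single_bin(self):
        h = nnd_histogram([5.0, 5.0], bin_width=1.0)
        assert h.counts[5] == 2
        assert h.counts.sum() == 2
        assert h.bin_left_edges[5] == 5.0

    def test_rejects_bad_bin_width(self):
        with pytest.raises(ValueError, match="bin_width"):
            nnd_histogram([1.0], bin_width=0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 100.0), min_size=1, max_size=200),
        st.sampled_from([0.25, 0.5, 1.0, 2.0]),
    )
    def test_counts_conserved(self, values, bin_width):
        h = nnd_histogram(values, bin_width)
        assert h.counts.sum() == len(values)

    def test_sampling_mean_recovered(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(11.0, 2.5, 1000)
        draws = draws[draws > 0]
        h = nnd_histogram(draws, 0.25)
        est = (h.bin_centers * h.counts).sum() / h.counts.sum()
        assert est == pytest.approx(draws.mean(), abs=3 * 2.5 / np.sqrt(len(draws)))


class TestGaussianFit:
    @staticmethod
    def _noiseless_histogram(x0=11.0, sd=2.5, A=40.0, bin_width=0.25, upper=25.0):
        edges = np.arange(0.0, upper, bin_width)
        centers = edges + bin_width / 2
        counts = A * np.exp(-(((centers - x0) / (np.sqrt(2) * sd)) ** 2))
        return NNDHistogram(bin_width, edges, counts, n=int(counts.sum()))

    def test_recovers_noiseless_parameters(self):
        fit = fit_gaussian(self._noiseless_histogram())
        assert fit.x0 == pytest.approx(11.0, abs=0.05)
        assert fit.sd == pytest.approx(2.5, abs=0.05)
        assert fit.amplitude_A == pytest.approx(40.0, rel=1e-3)
        assert fit.r_squared > 0.999

    def test_three_significant_figures(self):
        fit = fit_gaussian(self._noiseless_histogram(x0=9.87, sd=1.23, A=55.5))
        assert fit.x0 == pytest.approx(9.87, rel=1e-3)
        assert fit.sd == pytest.approx(1.23, rel=1e-3)
        assert fit.amplitude_A == pytest.approx(55.5, rel=1e-3)

    def test_symmetric_histogram_centered(self):
        edges = np.arange(0.0, 20.0, 1.0)
        centers = edges + 0.5
        counts = np.exp(-np.abs(centers - 10.0))  # symmetric about 10, non-Gaussian
        h = NNDHistogram(1.0, edges, counts * 30, n=30)
        fit = fit_gaussian(h)
        assert fit.x0 == pytest.approx(10.0, abs=1e-6)

    def test_baseline_fixed_at_zero(self):
        fit = fit_gaussian(self._noiseless_histogram())
        assert fit.y0 == 0.0
        assert fit.sd == pytest.approx(fit.w / np.sqrt(2))

    def test_too_few_bins(self):
        h = NNDHistogram(1.0, np.arange(3.0), np.array([0.0, 5.0, 1.0]), n=6)
        with pytest.raises(ValueError, match="non-empty bins"):
            fit_gaussian(h)


class TestPoissonReference:
    def test_zero_at_origin_and_normalized(self):
        r = np.linspace(0.0, 60.0, 20_001)
        ref = poisson_nnd_pdf(LAMBDA_CENTRAL, r, n=292)
        assert ref.pdf[0] == 0.0
        assert np.trapezoid(ref.pdf, r) == pytest.approx(1.0, abs=1e-6)
        assert np.trapezoid(ref.scaled, r) == pytest.approx(292.0, abs=1e-3)

    def test_mode_location(self):
        # dP/dr = 0 at r* = 1/sqrt(2πλ); λ from 292 cells in the 246.03² window
        r = np.linspace(0.0, 30.0, 300_001)
        ref = poisson_nnd_pdf(LAMBDA_CENTRAL, r, n=292)
        r_star = r[np.argmax(ref.pdf)]
        assert r_star == pytest.approx(1 / np.sqrt(2 * np.pi * LAMBDA_CENTRAL), abs=1e-3)
        assert r_star == pytest.approx(5.744, abs=5e-3)

    def test_mean_closed_form(self):
        r = np.linspace(0.0, 80.0, 80_001)
        ref = poisson_nnd_pdf(LAMBDA_CENTRAL, r, n=292)
        mean = np.trapezoid(r * ref.pdf, r)
        assert mean == pytest.approx(1 / (2 * np.sqrt(LAMBDA_CENTRAL)), rel=1e-5)

    def test_rejects_nonpositive_lambda(self):
        with pytest.raises(ValueError, match="lambda"):
            poisson_nnd_pdf(0.0, np.linspace(0, 1, 10), 5)

    def test_matches_point_pattern_simulations(self):
        # pooled NNDs of unconstrained point placements follow the analytic
        # CDF F(r) = 1 − exp(−λπr²)
        cfg = SimConfig(n_cells=1000, point_mode=True)
        nnds = np.concatenate(
            [nearest_neighbor_distances(simulate_field(cfg, s)) for s in range(5)]
        )
        lam = 1000 / cfg.window.area
        ks = kstest(nnds, lambda r: 1 - np.exp(-lam * np.pi * r**2)).statistic
        assert ks < 0.05


class TestRegularityIndex:
    def test_hand_arithmetic(self):
        res = regularity_index([1.0, 2.0, 3.0])
        assert res.mean == 2.0
        assert res.sd == 1.0
        assert res.regularity_index == 2.0

    def test_degenerate_distribution_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            regularity_index([4.0, 4.0, 4.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.01, 1000.0), st.integers(0, 100))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(1.0, 10.0, 50)
        base = regularity_index(vals).regularity_index
        scaled = regularity_index(c * vals).regularity_index
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_poisson_limit(self):
        # RI of an unconstrained random pattern approaches sqrt(pi/(4-pi))
        f = simulate_field(SimConfig(n_cells=10_000, point_mode=True), trial_seed=5)
        ri = regularity_index(nearest_neighbor_distances(f)).regularity_index
        assert ri == pytest.approx(POISSON_NND_RI, abs=0.05)


class TestDensityRecoveryProfile:
    def test_two_cells_single_annulus(self):
        from retmosaic import MosaicField, Window

        f = MosaicField(x=[100.0, 110.0], y=[100.0, 100.0], window=Window())
        drp = density_recovery_profile(f, annulus_width=1.0, max_radius=20.0)
        hot = np.flatnonzero(drp.density_estimate)
        assert hot.tolist() == [10]  # all pair mass in the [10, 11) annulus
        assert drp.radii[10] == pytest.approx(10.5)

    def test_flat_for_poisson_pattern(self):
        # the autocorrelation of a Poisson process is λ everywhere
        cfg = SimConfig(n_cells=400, point_mode=True)
        profiles = []
        for s in range(20):
            f = simulate_field(cfg, trial_seed=s)
            profiles.append(
                density_recovery_profile(f, annulus_width=5.0, max_radius=60.0).density_estimate
            )
        profiles = np.array(profiles)
        lam_mm2 = 400 / cfg.window.area_mm2
        mean = profiles.mean(axis=0)
        se = profiles.std(axis=0, ddof=1) / np.sqrt(len(profiles))
        assert np.all(np.abs(mean - lam_mm2) < 3 * se + 1e-9)

    def test_exclusion_zone_for_hardcore_pattern(self, hardcore_field):
        drp = density_recovery_profile(hardcore_field, annulus_width=1.0, max_radius=50.0)
        # annuli fully below the contact distance are empty
        assert np.all(drp.density_estimate[:8] == 0.0)
        assert drp.effective_radius > 5.0

    def test_max_radius_guard(self, hardcore_field):
        with pytest.raises(ValueError, match="half the shorter window side"):
            density_recovery_profile(hardcore_field, annulus_width=1.0, max_radius=200.0)


class TestCompareHistogramToReference:
    def test_identity_gives_zero(self):
        r = np.linspace(0.0, 40.0, 4001)
        ref = poisson_nnd_pdf(LAMBDA_CENTRAL, r, n=292)
        edges = np.arange(0.0, 30.0, 0.25)
        counts = np.interp(edges + 0.125, r, ref.scaled)
        h = NNDHistogram(0.25, edges, counts, n=292, scale_mode="per_micrometer")
        rec = compare_histogram_to_reference(h, ref)
        assert rec.max_abs_deviation == pytest.approx(0.0, abs=1e-9)
        assert rec.integrated_abs_deviation == pytest.approx(0.0, abs=1e-9)

    def test_deviations_nonnegative(self, hardcore_field):
        nnd = nearest_neighbor_distances(hardcore_field)
        h = nnd_histogram(nnd, 1.0)
        r = np.linspace(0.0, 60.0, 6001)
        ref = poisson_nnd_pdf(LAMBDA_CENTRAL, r, n=292)
        rec = compare_histogram_to_reference(h, ref)
        assert rec.max_abs_deviation > 0
        assert rec.integrated_abs_deviation >= rec.max_abs_deviation * h.bin_width

    def test_incompatible_support_errors(self, hardcore_field):
        nnd = nearest_neighbor_distances(hardcore_field)
        h = nnd_histogram(nnd, 1.0)
        short = poisson_nnd_pdf(LAMBDA_CENTRAL, np.linspace(0, 2.0, 10), n=292)
        with pytest.raises(ValueError, match="incompatible"):
            compare_histogram_to_reference(h, short)
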