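"""DVH representation, conversions, interpolated queries, grid histograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from planbio.dvh import (
    DVH,
    DoseGrid,
    DVHValidationError,
    dvh_from_grid,
    to_cumulative,
    to_differential,
    uniform_dvh,
)

from conftest import matched_grid, random_dvh


def _sort_oracle_bounds(q, n, sorted_desc):
    """Admissible [lo, hi] for D_q from a descending voxel sort.

    For non-integer q*n the quantile is pinned to the hottest-ceil(q*n)
    voxel.  When q*n is an integer the cumulative curve sits exactly at q
    across the gap between voxels q*n and q*n+1, so any dose in that
    interval is a valid tie resolution.
    """
    qn = q * n
    if abs(qn - round(qn)) < 1e-9:
        hi = sorted_desc[max(int(round(qn)) - 1, 0)]
        lo = sorted_desc[min(int(round(qn)), n - 1)]
        return lo, hi
    v = sorted_desc[max(int(np.ceil(qn)) - 1, 0)]
    return v, v


class TestConversions:
    def test_single_bin_cumulative(self):
        d = DVH("t", np.array([0.0, 69.0, 71.0]), np.array([0.0, 1.0]))
        c = to_cumulative(d)
        assert c.kind == "cumulative"
        np.testing.assert_allclose(c.volume, [1.0, 1.0, 0.0])

    def test_two_equal_bins_cumulative_midpoint(self, two_bin_dvh):
        assert two_bin_dvh.volume_fraction_at_dose(65.0) == pytest.approx(0.5)

    def test_round_trip_identity(self, rng):
        for _ in range(20):
            d = random_dvh(rng)
            back = to_differential(to_cumulative(d))
            np.testing.assert_allclose(back.volume, d.volume, atol=1e-12)
            np.testing.assert_array_equal(back.bin_edges, d.bin_edges)

    def test_cumulative_finite_differences(self):
        c = DVH("t", np.array([0.0, 60.0, 70.0]), np.array([1.0, 0.5, 0.0]),
                kind="cumulative")
        d = to_differential(c)
        np.testing.assert_allclose(d.volume, [0.5, 0.5])

    def test_constant_then_drop(self):
        c = DVH("t", np.array([0.0, 70.0, 70.5]), np.array([1.0, 1.0, 0.0]),
                kind="cumulative")
        d = to_differential(c)
        np.testing.assert_allclose(d.volume, [0.0, 1.0])

    def test_tiny_nonmonotone_dip_clipped(self):
        c = DVH("t", np.array([0.0, 50.0, 60.0, 70.0]),
                np.array([1.0, 0.5, 0.5 + 2e-9, 0.0]), kind="cumulative")
        d = to_differential(c)
        assert np.all(d.volume >= 0)
        assert d.volume.sum() == pytest.approx(1.0, abs=1e-9)

    def test_large_increase_rejected(self):
        with pytest.raises(DVHValidationError):
            DVH("t", np.array([0.0, 50.0, 70.0]), np.array([1.0, 0.4, 0.6]),
                kind="cumulative")

    def test_unnormalised_differential_rejected(self):
        with pytest.raises(DVHValidationError):
            DVH("t", np.array([0.0, 70.0]), np.array([0.7]))


class TestQueries:
    def test_uniform_dose_quantiles(self):
        d = uniform_dvh(70.0, width=1e-6)
        assert d.dose_at_volume_fraction(0.02) == pytest.approx(70.0, abs=1e-5)
        assert d.dose_at_volume_fraction(0.98) == pytest.approx(70.0, abs=1e-5)

    def test_linear_cumulative_interpolation(self):
        c = DVH("t", np.array([60.0, 70.0]), np.array([1.0, 0.0]),
                kind="cumulative")
        assert c.dose_at_volume_fraction(0.5) == pytest.approx(65.0)
        assert c.volume_fraction_at_dose(65.0) == pytest.approx(0.5)

    def test_q_bounds_conventions(self):
        d = DVH("t", np.array([0.0, 69.0, 71.0]), np.array([0.0, 1.0]))
        assert d.dose_at_volume_fraction(0.0) == pytest.approx(71.0)  # max dose
        assert d.dose_at_volume_fraction(1.0) == pytest.approx(69.0)  # min dose

    def test_q_out_of_range(self, two_bin_dvh):
        with pytest.raises(ValueError):
            two_bin_dvh.dose_at_volume_fraction(1.5)

    def test_volume_fraction_trivials(self, two_bin_dvh):
        assert uniform_dvh(70.0).volume_fraction_at_dose(40.0) == 1.0
        assert two_bin_dvh.volume_fraction_at_dose(65.0) == pytest.approx(0.5)
        assert two_bin_dvh.volume_fraction_at_dose(90.0) == 0.0

    def test_quantile_matches_voxel_sort_oracle(self, rng):
        """D_q from the DVH agrees with a sorted-voxel quantile within a bin."""
        d = random_dvh(rng, n_bins=3)
        grid, exact = matched_grid(d)
        bw = np.diff(exact.bin_edges).max()
        doses = np.sort(grid.masked_doses)[::-1]
        for q in (0.02, 0.5, 0.98):
            lo, hi = _sort_oracle_bounds(q, doses.size, doses)
            got = exact.dose_at_volume_fraction(q)
            assert lo - bw - 1e-9 <= got <= hi + bw + 1e-9

    def test_quasi_inverse_on_strict_segment(self, rng):
        for _ in range(20):
            d = random_dvh(rng)
            e, c = d._cumulative_curve()
            # probe strictly inside a strictly-decreasing segment
            j = int(np.argmax(-np.diff(c)))
            if c[j] - c[j + 1] < 1e-6:
                continue
            q = 0.5 * (c[j] + c[j + 1])
            dose = d.dose_at_volume_fraction(q)
            assert d.volume_fraction_at_dose(dose) == pytest.approx(q, abs=1e-9)
            assert d.dose_at_volume_fraction(
                d.volume_fraction_at_dose(dose)) == pytest.approx(dose, abs=1e-9)


class TestDoseGrid:
    def test_four_voxels(self):
        grid = DoseGrid(np.array([[[60.0, 60.0], [70.0, 70.0]]]),
                        np.ones((1, 2, 2), bool))
        d = dvh_from_grid(grid, bin_width=0.5)
        assert d.volume_fraction_at_dose(65.0) == pytest.approx(0.5)
        assert d.abs_volume_cc == pytest.approx(4 * 0.001)

    def test_single_voxel(self):
        grid = DoseGrid(np.full((1, 1, 1), 54.0), np.ones((1, 1, 1), bool))
        d = dvh_from_grid(grid, bin_width=0.1)
        occupied = d.bin_edges[:-1][d.volume > 0]
        assert occupied.size == 1
        assert occupied[0] <= 54.0 <= occupied[0] + 0.1

    def test_empty_mask_errors(self):
        grid = DoseGrid(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError):
            dvh_from_grid(grid)

    def test_mean_dose_matches_grid_mean(self, rng):
        dose = rng.gamma(8.0, 5.0, size=(10, 10, 10))
        grid = DoseGrid(dose, np.ones_like(dose, bool))
        d = dvh_from_grid(grid, bin_width=0.1)
        assert abs(d.mean_dose() - dose.mean()) <= 0.05

    def test_grid_quantiles_match_sort_oracle(self, rng):
        """100 random grids: DVH quantiles within one bin width of sorting."""
        bw = 0.25
        for _ in range(100):
            dose = rng.uniform(0, 80, size=int(rng.integers(50, 400)))
            grid = DoseGrid(dose.reshape(1, 1, -1),
                            np.ones((1, 1, dose.size), bool))
            d = dvh_from_grid(grid, bin_width=bw)
            sorted_desc = np.sort(dose)[::-1]
            for q in (0.01, 0.02, 0.05, 0.5, 0.98):
                lo, hi = _sort_oracle_bounds(q, dose.size, sorted_desc)
                got = d.dose_at_volume_fraction(q)
                assert lo - bw - 1e-9 <= got <= hi + bw + 1e-9


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(1, 30), st.integers(0, 2**32 - 1))
def test_generated_dvh_invariants(n_bins, seed):
    """Normalisation, monotone cumulative and round-trip hold for random DVHs."""
    d = random_dvh(np.random.default_rng(seed), n_bins=n_bins)
    assert d.volume.sum() == pytest.approx(1.0, abs=1e-9)
    c = d.as_cumulative()
    assert np.all(np.diff(c.volume) <= 1e-12)
    assert c.volume[0] == 1.0
    back = c.as_differential()
    np.testing.assert_allclose(back.volume, d.volume, atol=1e-12)
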