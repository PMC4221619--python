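"""Dose-response models: EQD2, Poisson sigmoid, TCP, NTCP, gEUD, P+."""

import math

import numpy as np
import pytest

from planbio.dvh import DVH, uniform_dvh
from planbio.radbio import (
    DoseResponseParams,
    FractionationScheme,
    ParamLibrary,
    eqd2,
    geud,
    invert_uniform_response,
    ntcp_relative_seriality,
    p_plus,
    poisson_response,
    tcp_poisson,
)

from conftest import matched_grid, random_dvh

FX35 = FractionationScheme(35)
FX33 = FractionationScheme(33)


def narrow(dose):
    return uniform_dvh(dose, width=1e-8)


class TestEqd2:
    def test_two_gray_fixed_point(self):
        assert eqd2(70.0, FX35, 10.0) == pytest.approx(70.0)

    def test_hand_evaluated_33_fractions(self):
        # 70 * (70/33 + 10) / 12
        assert eqd2(70.0, FX33, 10.0) == pytest.approx(70.7071, abs=1e-4)

    def test_zero_dose(self):
        assert eqd2(0.0, FX33, 3.0) == 0.0

    def test_invalid_alpha_beta(self):
        with pytest.raises(ValueError):
            eqd2(70.0, FX35, 0.0)


class TestPoissonResponse:
    def test_half_response_at_d50(self):
        p = DoseResponseParams(65.10, 2.4, 3.0)
        assert poisson_response(65.10, p) == pytest.approx(0.5, abs=1e-15)

    def test_underflow_at_zero_dose(self):
        p = DoseResponseParams(57.4, 6.3, 10.0)
        assert poisson_response(0.0, p) < 1e-300

    def test_closed_form_value(self):
        p = DoseResponseParams(50.0, 1.8, 3.0)
        # 2^(-exp(e*1.8*(1-1.2))) evaluated independently
        expected = 2.0 ** (-math.exp(math.e * 1.8 * (1 - 1.2)))
        assert poisson_response(60.0, p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.7706, abs=1e-4)

    def test_strictly_increasing(self):
        p = DoseResponseParams(57.4, 6.3, 10.0)
        d = np.linspace(40, 120, 200)  # below ~35 Gy the response underflows to 0
        assert np.all(np.diff(poisson_response(d, p)) > 0)

    def test_normalised_gradient_at_d50(self):
        """D50 * dP/dD at D50 equals (e*ln2/2)*gamma to 1e-4 relative."""
        for gamma in (1.2, 2.4, 6.3):
            p = DoseResponseParams(60.0, gamma, 3.0)
            h = 1e-4
            slope = (poisson_response(60.0 + h, p)
                     - poisson_response(60.0 - h, p)) / (2 * h)
            expected = math.e * math.log(2.0) / 2.0 * gamma / 60.0
            assert slope == pytest.approx(expected, rel=1e-4)


class TestTcp:
    def test_uniform_at_d50(self):
        p = DoseResponseParams(57.4, 6.3, 10.0)
        assert tcp_poisson(narrow(57.4), p, use_eqd2=False) == pytest.approx(0.5, abs=1e-9)

    def test_two_bin_half_saturated(self):
        p = DoseResponseParams(57.4, 6.3, 10.0)
        d = DVH("t", np.array([57.4 - 5e-9, 57.4 + 5e-9, 200.0, 200.1]),
                np.array([0.5, 0.0, 0.5]))
        assert tcp_poisson(d, p, use_eqd2=False) == pytest.approx(
            math.sqrt(0.5), abs=1e-6)

    def test_matches_voxel_product_oracle(self, rng):
        p = DoseResponseParams(57.4, 6.3, 10.0)
        for _ in range(20):
            d = random_dvh(rng, n_bins=5)
            grid, exact = matched_grid(d)
            doses = np.asarray(eqd2(grid.masked_doses, FX35, p.alpha_beta))
            # per-voxel log response from the closed form, no underflow
            log_probs = -math.log(2) * np.exp(math.e * p.gamma * (1 - doses / p.d50))
            mean_log = log_probs.mean()
            oracle = math.exp(mean_log) if mean_log > -745 else 0.0
            assert tcp_poisson(exact, p, FX35) == pytest.approx(oracle, abs=1e-10)

    def test_uniform_collapse_equals_sigmoid(self):
        p = DoseResponseParams(60.2, 4.2, 10.0)
        for dose in (40.0, 60.2, 75.0):
            assert tcp_poisson(narrow(dose), p, use_eqd2=False) == pytest.approx(
                poisson_response(dose, p), abs=1e-12)


class TestNtcp:
    def test_uniform_at_d50_any_seriality(self):
        for s in (0.25, 1.0, 4.0):
            p = DoseResponseParams(65.1, 2.4, 3.0, seriality=s)
            assert ntcp_relative_seriality(narrow(65.1), p, use_eqd2=False) == \
                pytest.approx(0.5, abs=1e-9)

    def test_seriality_one_closed_form(self):
        p = DoseResponseParams(46.0, 1.8, 3.0, seriality=1.0)
        d_zero = 1.0
        d_two = invert_dose(p, 0.2)
        dvh = DVH("o", np.array([d_zero - 0.5, d_zero + 0.5,
                                 d_two - 5e-10, d_two + 5e-10]),
                  np.array([0.5, 0.0, 0.5]))
        p_low = poisson_response(d_zero, p)   # effectively 0
        expected = 1 - ((1 - p_low) ** 0.5) * (0.8 ** 0.5)
        got = ntcp_relative_seriality(dvh, p, use_eqd2=False)
        assert got == pytest.approx(expected, abs=1e-6)
        assert got == pytest.approx(0.1056, abs=1e-3)

    def test_seriality_four_closed_form(self):
        p = DoseResponseParams(46.0, 1.8, 3.0, seriality=4.0)
        d_two = invert_dose(p, 0.2)
        dvh = DVH("o", np.array([0.5, 1.5, d_two - 5e-10, d_two + 5e-10]),
                  np.array([0.5, 0.0, 0.5]))
        p1 = poisson_response(1.0, p)
        p2 = 0.2
        expected = (1 - (1 - p1 ** 4) ** 0.5 * (1 - p2 ** 4) ** 0.5) ** 0.25
        assert ntcp_relative_seriality(dvh, p, use_eqd2=False) == \
            pytest.approx(expected, abs=1e-6)

    def test_seriality_one_equals_independent_product(self, rng):
        p = DoseResponseParams(46.0, 1.8, 3.0, seriality=1.0)
        for _ in range(10):
            d = random_dvh(rng, n_bins=8)
            probs = poisson_response(d.midpoints, p)
            expected = 1 - np.prod((1 - probs) ** d.volume)
            assert ntcp_relative_seriality(d, p, use_eqd2=False) == \
                pytest.approx(expected, abs=1e-12)

    def test_monotone_in_seriality(self, rng):
        base = DoseResponseParams(46.0, 1.8, 3.0)
        for _ in range(10):
            d = random_dvh(rng, n_bins=10)
            vals = [ntcp_relative_seriality(
                d, DoseResponseParams(base.d50, base.gamma, base.alpha_beta,
                                      seriality=s), use_eqd2=False)
                for s in (0.25, 0.5, 1.0, 2.0, 4.0)]
            assert np.all(np.diff(vals) >= -1e-12)

    def test_monotone_under_uniform_scaling(self):
        p = DoseResponseParams(68.6, 1.9, 3.0, seriality=4.0)
        d = DVH("o", np.array([20.0, 30.0, 40.0, 50.0]),
                np.array([0.5, 0.3, 0.2]))
        vals = []
        for scale in (1.0, 1.1, 1.25, 1.5):
            scaled = DVH("o", d.bin_edges * scale, d.volume)
            vals.append(ntcp_relative_seriality(scaled, p, use_eqd2=False))
        assert np.all(np.diff(vals) >= 0)

    def test_missing_seriality_errors(self):
        p = DoseResponseParams(65.0, 2.3, 3.0)
        with pytest.raises(ValueError):
            ntcp_relative_seriality(narrow(50.0), p, use_eqd2=False)

    def test_matches_voxel_oracle(self, rng):
        p = DoseResponseParams(46.0, 1.8, 3.0, seriality=2.5)
        for _ in range(20):
            d = random_dvh(rng, n_bins=5)
            grid, exact = matched_grid(d)
            doses = np.asarray(eqd2(grid.masked_doses, FX33, p.alpha_beta))
            log_probs = -math.log(2) * np.exp(math.e * p.gamma * (1 - doses / p.d50))
            inner = np.prod((1 - np.exp(p.seriality * log_probs))
                            ** (1.0 / doses.size))
            oracle = (1 - inner) ** (1.0 / p.seriality)
            assert ntcp_relative_seriality(exact, p, FX33) == \
                pytest.approx(oracle, abs=1e-10)


def invert_dose(params, prob):
    """Uniform dose at which the sigmoid equals prob (helper)."""
    from scipy.optimize import brentq

    return brentq(lambda d: poisson_response(d, params) - prob,
                  1e-6, 5 * params.d50, xtol=1e-12)


class TestGeud:
    def test_a_one_is_mean(self, two_bin_dvh):
        assert geud(two_bin_dvh, 1.0) == pytest.approx(65.0)

    def test_uniform_fixed_point(self):
        for a in (-10.0, 0.5, 1.0, 20.0):
            assert geud(uniform_dvh(54.0, 1e-9), a) == pytest.approx(54.0)

    def test_power_mean_hand_value(self, two_bin_dvh):
        # (0.5*60^20 + 0.5*70^20)^(1/20)
        assert geud(two_bin_dvh, 20.0) == pytest.approx(67.77, abs=0.01)

    def test_a_zero_rejected(self, two_bin_dvh):
        with pytest.raises(ValueError):
            geud(two_bin_dvh, 0.0)

    def test_monotone_in_a_and_bounded(self, rng):
        for _ in range(10):
            d = random_dvh(rng, n_bins=12)
            vals = [geud(d, a) for a in (-5.0, -1.0, 0.5, 1.0, 2.0, 10.0)]
            assert np.all(np.diff(vals) >= -1e-9)
            mids = d.midpoints[d.volume > 0]
            assert mids.min() - 1e-9 <= vals[0] and vals[-1] <= mids.max() + 1e-9


class TestPPlus:
    def test_arithmetic(self):
        assert p_plus(0.9, [0.1, 0.05]) == pytest.approx(0.7695)

    def test_empty_ntcp_list(self):
        assert p_plus(0.73) == 0.73

    def test_certain_complication(self):
        assert p_plus(0.99, [0.2, 1.0]) == 0.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            p_plus(1.2, [0.1])


class TestInversion:
    def test_recovers_d50_both_models(self):
        tcp_p = DoseResponseParams(57.4, 6.3, 10.0)
        ntcp_p = DoseResponseParams(68.6, 1.9, 3.0, seriality=4.0)
        assert invert_uniform_response(0.5, tcp_p, "tcp") == \
            pytest.approx(57.40, abs=1e-5)
        assert invert_uniform_response(0.5, ntcp_p, "ntcp") == \
            pytest.approx(68.60, abs=1e-5)

    def test_monotone(self):
        p = DoseResponseParams(46.0, 1.8, 3.0, seriality=1.0)
        assert invert_uniform_response(0.8, p, "ntcp") > \
            invert_uniform_response(0.5, p, "ntcp")

    def test_invalid_target(self):
        p = DoseResponseParams(46.0, 1.8, 3.0)
        with pytest.raises(ValueError):
            invert_uniform_response(0.0, p)


class TestParamLibrary:
    def test_default_rows_complete(self):
        lib = ParamLibrary.default()
        assert set(lib.tcp_stages) == {"early", "t3", "stage4"}
        assert set(lib.ntcp_structures) == {
            "brain_stem", "spinal_cord", "optic_chiasma", "optic_nerve",
            "eye_retina", "lens", "parotid"}
        assert lib.tcp("early").d50 == 57.40
        assert lib.ntcp("spinal_cord").seriality == 4.0
        assert lib.ntcp("parotid").endpoint == "xerostomia"

    def test_probability_outputs_bounded(self, rng):
        lib = ParamLibrary.default()
        for _ in range(20):
            d = random_dvh(rng)
            tcp = tcp_poisson(d, lib.tcp("early"), FX35)
            ntcp = ntcp_relative_seriality(d, lib.ntcp("parotid"), FX33)
            assert 0.0 <= tcp <= 1.0
            assert 0.0 <= ntcp <= 1.0
            assert 0.0 <= p_plus(tcp, [ntcp]) <= 1.0
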