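"""GHK algebra, dilution/biionic inversion, Kimizuka–Koketsu P_Na."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from tjpatch.permeability import (
    activity_coefficient_nacl,
    biionic_conditions,
    biionic_px_over_pna,
    ghk_vrev,
    hbss,
    invert_ghk_dilution,
    kimizuka_koketsu_pna,
)
from tjpatch.units import FARADAY, R_GAS, T_BODY

DILUTED = hbss(apical_nacl_mm=13.5)  # 90% apical dilution


class TestActivity:
    @pytest.mark.parametrize("c,g", [(135.0, 0.755), (67.5, 0.812), (13.5, 0.882)])
    def test_anchor_points(self, c, g):
        assert activity_coefficient_nacl(c) == pytest.approx(g)

    def test_interpolation_monotone_decreasing(self):
        grid = np.linspace(13.5, 135.0, 50)
        vals = [activity_coefficient_nacl(c) for c in grid]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestForwardGHK:
    def test_symmetric_compartments_zero(self):
        for ratio in (0.5, 1.0, 7.4, 9.5):
            assert ghk_vrev(hbss(), ratio) == 0.0

    def test_equal_permeabilities_cancel_under_dilution(self):
        # symmetric salt: Na and Cl gradients cancel exactly at PNa=PCl
        assert ghk_vrev(DILUTED, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_nernst_limit_for_impermeant_chloride(self):
        a_baso = 135.0 * 0.755
        a_api = 13.5 * 0.882
        nernst = 1000.0 * R_GAS * T_BODY / FARADAY * np.log(a_baso / a_api)
        assert nernst == pytest.approx(57.4, abs=0.1)
        assert ghk_vrev(DILUTED, 1e15) == pytest.approx(nernst, rel=1e-6)

    def test_antisymmetric_under_compartment_swap(self):
        for ratio in (0.2, 1.0, 9.5, 40.0):
            assert ghk_vrev(DILUTED, ratio) == pytest.approx(
                -ghk_vrev(DILUTED.swapped(), ratio), abs=1e-12
            )

    def test_monotone_in_permeability_ratio(self):
        ratios = np.logspace(-1, 2, 30)
        v = [ghk_vrev(DILUTED, r) for r in ratios]
        assert all(a < b for a, b in zip(v, v[1:]))


class TestInversion:
    def test_zero_vrev_gives_unity_ratio(self):
        assert invert_ghk_dilution(0.0, DILUTED) == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_at_reported_global_ratio(self):
        v = ghk_vrev(DILUTED, 9.5)
        assert invert_ghk_dilution(v, DILUTED) == pytest.approx(9.5, abs=1e-6)

    @given(st.floats(0.1, 100.0))
    def test_round_trip_identity(self, ratio):
        v = ghk_vrev(DILUTED, ratio)
        assert invert_ghk_dilution(v, DILUTED) == pytest.approx(ratio, rel=1e-6)

    def test_near_limit_large_but_finite(self):
        v_limit = ghk_vrev(DILUTED, 1e15)
        ratio = invert_ghk_dilution(v_limit - 0.01, DILUTED)
        assert 100.0 < ratio < np.inf

    def test_beyond_nernst_limit_rejected(self):
        v_limit = ghk_vrev(DILUTED, 1e15)
        with pytest.raises(ValueError):
            invert_ghk_dilution(v_limit + 1.0, DILUTED)

    def test_symmetric_conditions_rejected(self):
        with pytest.raises(ValueError):
            invert_ghk_dilution(0.0, hbss())


class TestBiionic:
    def test_identical_cation_gives_unity(self):
        bc = biionic_conditions("X")  # X has Na-like activity
        assert biionic_px_over_pna(0.0, bc, "X", 9.5) == pytest.approx(1.0, abs=1e-12)

    def test_methylamine_near_zero_vrev_is_near_unity(self):
        bc = biionic_conditions("MA")
        p = biionic_px_over_pna(0.5, bc, "MA", 9.5)
        assert 0.8 < p < 1.2

    def test_round_trip_low_permeability_cation(self):
        bc = biionic_conditions("TMA")
        v = ghk_vrev(bc, {"Na": 1.0, "TMA": 0.1, "Cl": 1.0 / 9.5})
        assert v < -10.0  # large negative shift for a poorly permeant cation
        assert biionic_px_over_pna(v, bc, "TMA", 9.5) == pytest.approx(0.1, rel=1e-9)


class TestKimizukaKoketsu:
    def test_hand_computed_reference_value(self):
        # independent arithmetic of (RT/F^2) * G * r/(1+r) / a_Na
        expected = (
            (8.314462618 * 310.15 / 96485.33212**2)
            * (1.0 / 100.0)
            * (9.5 / 10.5)
            / (135.0 * 0.755 * 1e-6)
        )
        got = kimizuka_koketsu_pna(100.0, 9.5)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(2.4589e-5, rel=1e-4)  # cm/s

    def test_linear_in_conductance(self):
        assert kimizuka_koketsu_pna(50.0, 9.5) == pytest.approx(
            2 * kimizuka_koketsu_pna(100.0, 9.5), rel=1e-12
        )

    def test_perfectly_cation_selective_limit(self):
        limit = kimizuka_koketsu_pna(100.0, np.inf)
        assert kimizuka_koketsu_pna(100.0, 1e12) == pytest.approx(limit, rel=1e-6)
        assert limit == pytest.approx(
            (R_GAS * T_BODY / FARADAY**2) / 100.0 / (135.0 * 0.755 * 1e-6), rel=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            kimizuka_koketsu_pna(0.0, 9.5)
        with pytest.raises(ValueError):
            kimizuka_koketsu_pna(100.0, -1.0)
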