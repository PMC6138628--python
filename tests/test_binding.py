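"""Binding isotherms, partition coefficients and Stern-Volmer quenching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepmem import (
    Spectrum,
    TitrationSeries,
    blue_shift,
    bound_fraction,
    build_isotherm,
    dilution_correct,
    estimate_f_inf,
    inverse_bound_fraction,
    partition_coefficient,
    stern_volmer_fit,
)
from pepmem.errors import (
    DegenerateInputError,
    ExtrapolationError,
    FitError,
    InsufficientDataError,
)
from pepmem.synthetic_data import gen_trp_titration


def _trp_spectrum(center_nm: float) -> Spectrum:
    wl = np.linspace(300.0, 400.0, 501)  # 0.2 nm grid
    return Spectrum(
        wavelengths_nm=wl, values=np.exp(-((wl - center_nm) ** 2) / (2 * 25.0**2))
    )


class TestBlueShift:
    def test_identical_spectra_give_zero(self):
        assert blue_shift(_trp_spectrum(350.0), _trp_spectrum(350.0)) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_six_nm_blue_shift_recovered_subgrid(self):
        assert blue_shift(_trp_spectrum(350.0), _trp_spectrum(344.0)) == pytest.approx(
            6.0, abs=0.1
        )

    def test_subgrid_resolution_below_sampling_step(self):
        # 0.2 nm grid, 0.05 nm true shift: parabolic refinement resolves it
        assert blue_shift(_trp_spectrum(350.0), _trp_spectrum(349.95)) == pytest.approx(
            0.05, abs=0.01
        )

    def test_flat_spectrum_raises(self):
        flat = Spectrum(
            wavelengths_nm=np.linspace(300, 400, 11), values=np.ones(11)
        )
        with pytest.raises(DegenerateInputError):
            blue_shift(flat, _trp_spectrum(350.0))


class TestDilutionCorrect:
    def test_no_addition_is_identity(self):
        assert dilution_correct(100.0, 1000.0, 0.0) == 100.0

    def test_ten_percent_dilution(self):
        assert dilution_correct(100.0, 1000.0, 100.0) == pytest.approx(110.0)

    def test_zero_initial_volume_rejected(self):
        with pytest.raises(ValueError):
            dilution_correct(100.0, 0.0, 10.0)


def _finf_grid_search_oracle(L, F, outer, candidates):
    """Brute-force oracle: the F_inf whose double-reciprocal line fits best.

    For each candidate F_inf the reciprocal intercept is fixed at 1/F_inf
    and only the slope is fitted; the candidate minimizing the residual sum
    of squares wins.  Independent of the production estimator's algebra.
    """
    x = 1.0 / (outer * np.asarray(L))
    y = 1.0 / np.asarray(F)
    best, best_sse = None, np.inf
    for cand in candidates:
        icpt = 1.0 / cand
        slope = np.sum(x * (y - icpt)) / np.sum(x * x)
        sse = float(np.sum((y - icpt - slope * x) ** 2))
        if sse < best_sse:
            best, best_sse = cand, sse
    return best


class TestEstimateFInf:
    def test_hyperbolic_saturation_recovered_and_matches_oracle(self):
        # F = F_inf * L' / (K + L'): its double reciprocal is exactly linear
        outer, f_inf, K = 0.6, 300.0, 2e-4
        L = np.geomspace(1e-5, 5e-3, 10)
        Lp = outer * L
        F = f_inf * Lp / (K + Lp)
        est = estimate_f_inf(L, F, outer)
        assert est == pytest.approx(f_inf, rel=1e-3)
        oracle = _finf_grid_search_oracle(
            L, F, outer, np.arange(250.0, 350.0, 0.05)
        )
        assert est == pytest.approx(oracle, rel=1e-3)

    def test_constant_fluorescence_returns_that_constant(self):
        L = np.array([1e-4, 2e-4, 4e-4, 8e-4])
        est = estimate_f_inf(L, np.full(4, 120.0), 0.6)
        assert est == pytest.approx(120.0, rel=1e-9)

    def test_decreasing_fluorescence_warns(self):
        L = np.array([1e-4, 2e-4, 4e-4])
        with pytest.warns(UserWarning, match="decreases"):
            estimate_f_inf(L, np.array([300.0, 200.0, 150.0]), 0.6)

    def test_negative_intercept_raises_extrapolation_failure(self):
        # construct 1/F = -0.01 + 1.0 * (1/L'), an unphysical extrapolation
        outer = 1.0
        x = np.array([0.02, 0.05, 0.1])
        L = 1.0 / x
        F = 1.0 / (-0.01 + x)
        with pytest.raises(ExtrapolationError):
            estimate_f_inf(L, F, outer)

    def test_weighted_equals_unweighted_on_noiseless_data(self):
        outer, f_inf, K = 0.6, 300.0, 2e-4
        L = np.geomspace(1e-5, 5e-3, 10)
        F = f_inf * (outer * L) / (K + outer * L)
        a = estimate_f_inf(L, F, outer)
        b = estimate_f_inf(L, F, outer, weights="response")
        assert a == pytest.approx(b, rel=1e-9)

    def test_delta_mode_is_exact_with_baseline(self):
        # hyperbola on top of baseline F0: delta double-reciprocal is linear
        outer, f0, f_inf, K = 0.6, 100.0, 300.0, 2e-4
        L = np.geomspace(1e-5, 5e-3, 10)
        Lp = outer * L
        F = f0 + (f_inf - f0) * Lp / (K + Lp)
        est = estimate_f_inf(L, F, outer, mode="delta", f0=f0)
        assert est == pytest.approx(f_inf, rel=1e-9)


class TestBoundFraction:
    def test_endpoints_and_interior(self):
        assert bound_fraction(50.0, 50.0, 250.0) == 0.0
        assert bound_fraction(250.0, 50.0, 250.0) == 1.0
        assert bound_fraction(100.0, 50.0, 250.0) == pytest.approx(0.25)

    def test_degenerate_scale_raises(self):
        with pytest.raises(DegenerateInputError):
            bound_fraction(1.0, 2.0, 2.0)

    @given(fb=st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_inverse_composition_is_identity(self, fb):
        f = inverse_bound_fraction(fb, 100.0, 300.0)
        assert bound_fraction(f, 100.0, 300.0) == pytest.approx(fb, abs=1e-12)


class TestBuildIsotherm:
    def test_single_point_worked_example(self):
        # L/P = 200: peptide 4 uM, lipid 0.8 mM, half bound
        s = TitrationSeries(x=[8e-4], y=[200.0], x_kind="lipid_conc")
        iso = build_isotherm(s, 4e-6, f0=100.0, f_inf=300.0, outer_fraction=0.6)
        assert iso.f_b[0] == pytest.approx(0.5)
        assert iso.c_f[0] == pytest.approx(2e-6)
        assert iso.x_b[0] == pytest.approx(2.5e-3)
        assert iso.x_b_star[0] == pytest.approx(4.1667e-3, rel=1e-4)

    def test_no_binding_gives_zero_isotherm(self):
        s = TitrationSeries(
            x=[1e-4, 2e-4, 4e-4], y=[100.0] * 3, x_kind="lipid_conc"
        )
        iso = build_isotherm(s, 4e-6, f0=100.0, f_inf=300.0)
        np.testing.assert_allclose(iso.x_b_star, 0.0)
        np.testing.assert_allclose(iso.c_f, 4e-6)

    def test_outer_fraction_one_leaves_xb_unchanged(self):
        s = TitrationSeries(x=[8e-4], y=[200.0], x_kind="lipid_conc")
        iso = build_isotherm(s, 4e-6, f0=100.0, f_inf=300.0, outer_fraction=1.0)
        assert iso.x_b_star[0] == iso.x_b[0]


def _linear_isotherm(kp, n=8, peptide=4e-6):
    """Exact points on X_b* = kp * C_f via the synthetic titration at zero noise."""
    series, _ = gen_trp_titration(kp, peptide_total=peptide)
    return build_isotherm(series, peptide, f0=100.0, f_inf=300.0)


class TestPartitionCoefficient:
    @pytest.mark.parametrize("kp", [4.24e4, 1.55e3])
    def test_exact_linear_isotherm_recovers_slope(self, kp):
        fit = partition_coefficient(_linear_isotherm(kp))
        assert fit.kp == pytest.approx(kp, rel=1e-6)

    def test_matches_direct_slope_formula_oracle(self):
        iso = _linear_isotherm(4.24e4)
        fit = partition_coefficient(iso)
        sel = np.argsort(iso.c_f)[:4]  # the fallback initial-region points
        direct = np.sum(iso.c_f[sel] * iso.x_b_star[sel]) / np.sum(
            iso.c_f[sel] ** 2
        )
        assert fit.kp == pytest.approx(direct, rel=1e-12)

    def test_zero_isotherm_fails_with_zero_slope(self):
        s = TitrationSeries(
            x=[1e-4, 2e-4, 4e-4], y=[100.0] * 3, x_kind="lipid_conc"
        )
        iso = build_isotherm(s, 4e-6, f0=100.0, f_inf=300.0)
        with pytest.raises(FitError, match="slope"):
            partition_coefficient(iso)

    def test_too_few_distinct_points_rejected(self):
        s = TitrationSeries(x=[8e-4, 9e-4], y=[200.0, 210.0], x_kind="lipid_conc")
        iso = build_isotherm(s, 4e-6, f0=100.0, f_inf=300.0)
        with pytest.raises(InsufficientDataError):
            partition_coefficient(iso)

    def test_initial_slope_insensitive_to_surface_self_association(self):
        """Only the low-C_f region enters the fit, so an upward-curving
        isotherm (membrane-surface aggregation above a critical C_f) leaves
        the recovered K_p within 5% of the plain partition value."""
        kp = 4.24e4
        fits = []
        for coop in (0.0, 5.0, 20.0):
            series, _ = gen_trp_titration(kp, cooperativity=coop)
            iso = build_isotherm(series, 4e-6, f0=100.0, f_inf=300.0)
            fits.append(partition_coefficient(iso).kp)
        for f in fits[1:]:
            assert f == pytest.approx(fits[0], rel=0.05)


class TestSternVolmer:
    @staticmethod
    def _series(ksv, f0=100.0, n=9):
        q = np.linspace(0.0, 0.2, n)
        return TitrationSeries(x=q, y=f0 / (1 + ksv * q), x_kind="quencher_conc")

    @pytest.mark.parametrize("ksv", [10.21, 2.05, 3.04])
    def test_noiseless_recovery_is_exact(self, ksv):
        fit = stern_volmer_fit(self._series(ksv), f0=100.0)
        assert fit.ksv == pytest.approx(ksv, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_slope_formula_oracle(self):
        s = self._series(10.21)
        fit = stern_volmer_fit(s, f0=100.0)
        y = 100.0 / s.y - 1.0
        direct = float(np.sum(s.x * y) / np.sum(s.x * s.x))
        assert fit.ksv == pytest.approx(direct, rel=1e-12)

    def test_constant_fluorescence_gives_zero_ksv(self):
        s = TitrationSeries(
            x=np.linspace(0, 0.2, 5), y=np.full(5, 100.0), x_kind="quencher_conc"
        )
        assert stern_volmer_fit(s).ksv == 0.0

    def test_f0_taken_from_zero_quencher_point(self):
        fit = stern_volmer_fit(self._series(5.0))
        assert fit.ksv == pytest.approx(5.0, rel=1e-9)

    def test_nonpositive_fluorescence_rejected(self):
        s = TitrationSeries(
            x=[0.0, 0.1, 0.2], y=[100.0, 0.0, 50.0], x_kind="quencher_conc"
        )
        with pytest.raises(ValueError):
            stern_volmer_fit(s)

    def test_quencher_above_configured_max_warns(self):
        q = np.linspace(0.0, 0.5, 6)
        s = TitrationSeries(x=q, y=100.0 / (1 + 3 * q), x_kind="quencher_conc")
        with pytest.warns(UserWarning, match="maximum"):
            stern_volmer_fit(s, f0=100.0)
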