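"""Higuchi–Connors model, speciation, K fitting and A_N breakpoint detection."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gelsolv as g
from gelsolv.errors import InsufficientDataError, ValidationError

conc = st.floats(1e-4, 50.0, allow_nan=False)


class TestPredictTotalSolubility:
    def test_no_complexation_returns_intrinsic(self):
        assert g.predict_total_solubility(0.0, 0.033, 10.0) == pytest.approx(0.033)

    def test_closed_form_hand_value(self):
        # S0 + (K S0/(1+K S0)) L = 0.05 + (0.1/1.1)*1.0
        assert g.predict_total_solubility(2.0, 0.05, 1.0) == pytest.approx(
            0.14090909090909, abs=1e-12
        )

    def test_intercept_exact_and_monotone(self):
        assert g.predict_total_solubility(1.5, 0.04, 0.0) == 0.04
        lt = np.linspace(0, 25, 11)
        st_ = g.predict_total_solubility(1.5, 0.04, lt)
        assert np.all(np.diff(st_) > 0)

    @given(K=st.floats(1e-6, 1e3), S0=st.floats(1e-6, 10.0))
    def test_slope_strictly_between_zero_and_one(self, K, S0):
        slope = (g.predict_total_solubility(K, S0, 1.0) - S0) / 1.0
        assert 0.0 < slope < 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            g.predict_total_solubility(-1.0, 0.04, 1.0)
        with pytest.raises(ValidationError):
            g.predict_total_solubility(1.0, 0.04, -1.0)


class TestSpeciation:
    def test_no_binding(self):
        s = g.solve_speciation(0.0, 1.2, 3.4)
        assert s.complex_conc == 0.0
        assert s.free_drug == 1.2 and s.free_ligand == 3.4

    def test_stoichiometric_limit(self):
        s = g.solve_speciation(1e9, 1.0, 2.0)
        assert s.complex_conc == pytest.approx(1.0, rel=1e-6)
        assert s.free_drug == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_unit_case(self):
        # K=1, D=L=1: C^2 - 3C + 1 = 0 -> C = (3 - sqrt(5))/2
        s = g.solve_speciation(1.0, 1.0, 1.0)
        assert s.complex_conc == pytest.approx((3 - math.sqrt(5)) / 2, abs=1e-12)
        residual = 1.0 * s.free_drug * s.free_ligand - s.complex_conc
        assert abs(residual) < 1e-12

    # K capped at 1e3/mM (far above any physical 1:1 constant): beyond
    # that, free-drug cancellation hits double-precision conditioning.
    @given(K=st.floats(1e-6, 1e3), D=conc, L=conc)
    def test_mass_balance_and_equilibrium_residuals(self, K, D, L):
        s = g.solve_speciation(K, D, L)
        assert s.free_drug + s.complex_conc == pytest.approx(D, rel=1e-9)
        assert s.free_ligand + s.complex_conc == pytest.approx(L, rel=1e-9)
        assert K * s.free_drug * s.free_ligand == pytest.approx(
            s.complex_conc, rel=1e-9, abs=1e-12
        )
        assert 0 <= s.complex_conc <= min(D, L)


class TestAggregationModel:
    def test_beta_zero_reduces_to_linear(self):
        lt = np.linspace(0, 25, 17)
        np.testing.assert_allclose(
            g.predict_with_aggregation(1.5, 0.04, 0.0, lt),
            g.predict_total_solubility(1.5, 0.04, lt),
            rtol=0,
        )

    @given(beta=st.floats(1e-3, 5.0), L=st.floats(1e-3, 25.0))
    def test_aggregation_lowers_solubility(self, beta, L):
        low = g.predict_with_aggregation(1.5, 0.04, beta, L)
        assert low < g.predict_total_solubility(1.5, 0.04, L)

    def test_concavity_on_equispaced_grid(self):
        lt = np.linspace(0.0, 25.0, 50)
        s = g.predict_with_aggregation(1.5, 0.04, 0.2, lt)
        assert np.all(np.diff(s, 2) <= 1e-15)


class TestFitK11:
    def test_noiseless_recovery_exact(self):
        lt = 6.25 / 2.0 ** np.arange(7, -1, -1)
        data = g.PhaseSolubilityDataset(
            lt, g.predict_total_solubility(1.5, 0.04, lt), intrinsic_solubility=0.04
        )
        fit = g.fit_K11(data, linear_range=(float(lt[0]), float(lt[-1])))
        assert fit.K11 == pytest.approx(1.5, rel=1e-6)
        assert fit.r_squared > 1 - 1e-12
        assert fit.diagram_class == "A_L"

    def test_hand_inversion_of_half_slope(self):
        lt = np.array([1.0, 2.0, 3.0, 4.0])
        data = g.PhaseSolubilityDataset(lt, 1.0 + 0.5 * lt, intrinsic_solubility=1.0)
        fit = g.fit_K11(data)
        assert fit.slope == pytest.approx(0.5, rel=1e-12)
        assert fit.K11 == pytest.approx(1.0, rel=1e-9)

    def test_restricted_fit_on_curved_diagram(self):
        # smooth A_N curvature: restricting the fit to the detected onset
        # keeps the within-range fit essentially linear
        grid = g.default_ligand_grid()
        data, _ = g.gen_phase_solubility(
            g.PhaseSolSimConfig(beta=0.2, noise_cv=0.0)
        )
        fit = g.fit_K11(data)  # default range: up to the detected breakpoint
        assert fit.r_squared > 0.99
        assert fit.diagram_class == "A_N"
        lo, hi = fit.linear_range
        assert grid[0] <= lo <= hi <= grid[-1]
        assert hi < grid[-1]

    def test_s0_from_intercept_flag(self):
        lt = np.array([1.0, 2.0, 3.0, 4.0])
        data = g.PhaseSolubilityDataset(lt, 2.0 + 0.5 * lt, intrinsic_solubility=1.0)
        by_intercept = g.fit_K11(data, s0_from_intercept=True)
        assert by_intercept.K11 == pytest.approx(0.5 / (2.0 * 0.5), rel=1e-9)

    def test_flat_and_steep_slopes_rejected(self):
        lt = np.array([1.0, 2.0, 3.0, 4.0])
        flat = g.PhaseSolubilityDataset(lt, np.full(4, 0.5), intrinsic_solubility=0.5)
        with pytest.raises(ValidationError, match="no solubilization trend"):
            g.fit_K11(flat)
        steep = g.PhaseSolubilityDataset(lt, 0.1 + 1.2 * lt, intrinsic_solubility=0.1)
        with pytest.raises(ValidationError, match="inconsistent with 1:1"):
            g.fit_K11(steep)


class TestDetectBreakpoint:
    def test_linear_data_classified_a_l(self, linear_dataset):
        bp, cls = g.detect_breakpoint(linear_dataset)
        assert cls == "A_L"
        assert bp == float(linear_dataset.ligand_total[-1])

    def test_noiseless_aggregation_onset(self):
        data, truth = g.gen_phase_solubility(
            g.PhaseSolSimConfig(beta=0.2, noise_cv=0.0)
        )
        bp, cls = g.detect_breakpoint(data)
        assert cls == "A_N"
        assert bp == truth.breakpoint

    def test_breakpoint_always_on_observed_grid(self):
        for seed in range(20):
            data, _ = g.gen_phase_solubility(
                g.PhaseSolSimConfig(beta=0.3, noise_cv=0.05, seed=seed)
            )
            bp, _ = g.detect_breakpoint(data)
            assert bp in data.ligand_total

    def test_decreasing_tail_warns_b_type(self):
        lt = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
        dt = np.array([0.14, 0.18, 0.26, 0.42, 0.30, 0.20])
        data = g.PhaseSolubilityDataset(lt, dt, intrinsic_solubility=0.1)
        with pytest.warns(UserWarning, match="B-type"):
            bp, cls = g.detect_breakpoint(data)
        assert cls == "A_N"

    def test_too_few_points(self):
        lt = np.array([1.0, 2.0, 3.0, 4.0])
        data = g.PhaseSolubilityDataset(lt, 0.1 + 0.05 * lt, intrinsic_solubility=0.1)
        with pytest.raises(InsufficientDataError):
            g.detect_breakpoint(data)
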