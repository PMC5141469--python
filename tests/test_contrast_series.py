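"""Contrast-variation line, match-point decomposition, oligomeric state."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import guinier_points
from tricontrast.constants import AVOGADRO
from tricontrast.contrast_series import (
    ContrastPoint,
    WaterCalibration,
    concentration_from_absorbance,
    fit_cv_line,
    lipid_count,
    oligomeric_state,
    scattering_length_from_I0,
    solve_volume_fractions,
    subtract_protein,
)
from tricontrast.guinier import GuinierResult
from tricontrast.sld_core import mixture_match_point
from tricontrast.synthetic_data import make_fixture_suite, true_rhoV


def _point(f_d2o, I0, I0_err, c=2.0, scale="absolute"):
    g = GuinierResult(
        I0=I0, I0_err=I0_err, Rg=50.0, Rg_err=1.0,
        q_window=(0.003, 0.02), n_points=20, qRg_max=1.0, valid=True,
    )
    return ContrastPoint(f_d2o, g, c, 0.7, 0.1, intensity_scale=scale)


class TestScatteringLengthFromI0:
    def test_concentration_normalisation(self):
        """Doubling c at fixed per-particle rhoV doubles I(0); the
        operation returns the same rhoV."""
        M = 2.5e5
        rhoV = 1.5e-8  # cm
        for c in (1.0, 2.0):
            I0 = (c * 1e-3 * AVOGADRO / M) * rhoV**2
            got, _ = scattering_length_from_I0(_point(0.0, I0, 0.01 * I0, c=c), M)
            assert got == pytest.approx(rhoV, rel=1e-12)

    def test_zero_forward_intensity_gives_zero(self):
        got, _ = scattering_length_from_I0(_point(0.0, 0.0, 1e-4), 2.5e5)
        assert got == 0.0

    def test_simulator_roundtrip_absolute(self, htl_bundle_clean):
        b = htl_bundle_clean
        pts = guinier_points(b)
        M = b.manifest["reference_molar_mass"]
        for p in pts:
            truth = abs(true_rhoV(b.model, p.f_d2o, b.config.exchange))
            got, err = scattering_length_from_I0(p, M)
            assert got == pytest.approx(truth, rel=0.02)

    def test_simulator_roundtrip_water_ratio(self):
        """Curves emitted as water-normalised ratios recover the same
        rhoV once the calibration bracket is applied."""
        import dataclasses

        b_abs = make_fixture_suite("htl_native_like", seed=5, noise_rel_I0=0.0)
        cfg_ratio = dataclasses.replace(b_abs.config, intensity_scale="water_ratio")
        from tricontrast.synthetic_data import simulate_series

        curves = simulate_series(b_abs.model, cfg_ratio)
        M = b_abs.manifest["reference_molar_mass"]
        from tricontrast.guinier import guinier_fit

        c = curves[0]
        res = guinier_fit(c)
        p = ContrastPoint(
            c.metadata["f_d2o"], res, c.metadata["concentration_mg_ml"],
            cfg_ratio.transmission, cfg_ratio.path_length,
            intensity_scale="water_ratio",
        )
        truth = abs(true_rhoV(b_abs.model, p.f_d2o, cfg_ratio.exchange))
        got, _ = scattering_length_from_I0(p, M)
        assert got == pytest.approx(truth, rel=0.02)


class TestFitCVLine:
    def test_exact_line_root_at_24(self):
        """Points generated exactly on a line with root 24% D2O."""
        M, c = 2.5e5, 2.0
        root, slope = 24.0, -1.0e-10  # cm per %D2O
        pts = []
        for f_pct in (0.0, 10.0, 20.0, 30.0, 50.0, 70.0):
            rhoV = slope * (f_pct - root)
            I0 = (c * 1e-3 * AVOGADRO / M) * rhoV**2
            pts.append(_point(f_pct / 100.0, I0, 1e-4 * I0 + 1e-12, c=c))
        line = fit_cv_line(pts, M)
        assert line.cmp_total == pytest.approx(24.0, abs=1e-6)
        assert line.chi2_dof < 1e-6

    def test_sign_assignment_splits_at_root(self):
        M, c = 2.5e5, 2.0
        root, slope = 24.0, -1.0e-10
        pts = []
        for f_pct in (0.0, 10.0, 20.0, 30.0, 50.0, 70.0):
            rhoV = slope * (f_pct - root)
            I0 = (c * 1e-3 * AVOGADRO / M) * rhoV**2
            pts.append(_point(f_pct / 100.0, I0, 1e-4 * I0 + 1e-12, c=c))
        line = fit_cv_line(pts, M)
        assert np.all(line.rhoV[line.f_pct < 24.0] > 0)
        assert np.all(line.rhoV[line.f_pct > 24.0] < 0)

    def test_two_point_minimal_input(self):
        M, c = 2.5e5, 2.0
        pts = []
        for f_pct, rhoV in ((0.0, 2.0e-9), (50.0, -2.0e-9)):
            I0 = (c * 1e-3 * AVOGADRO / M) * rhoV**2
            pts.append(_point(f_pct / 100.0, I0, 1e-3 * I0, c=c))
        line = fit_cv_line(pts, M)
        assert line.cmp_total == pytest.approx(25.0, abs=1e-6)
        assert "no_degrees_of_freedom" in line.flags

    def test_htl_like_series_recovers_mixture_cmp(self, htl_bundle):
        b = htl_bundle
        line = fit_cv_line(guinier_points(b), b.manifest["reference_molar_mass"])
        truth = b.manifest["cmp_total_pct"]
        assert line.cmp_total == pytest.approx(truth, abs=1.0)
        # and the generating truth is itself the volume-weighted mixture CMP
        fr = b.manifest["fractions"]
        oracle = mixture_match_point(
            [
                (b.manifest["cmp_protein_pct"], fr["protein"]),
                (b.manifest["cmp_lipid_pct"], fr["lipid"]),
                (b.manifest["cmp_detergent_pct"], fr["detergent"]),
            ]
        )
        assert truth == pytest.approx(oracle, abs=1e-9)


class TestOligomericState:
    def test_single_copy_recovered(self, htl_bundle, protein):
        b = htl_bundle
        line = fit_cv_line(guinier_points(b), b.manifest["reference_molar_mass"])
        n, err = oligomeric_state(line, protein, b.manifest["cmp_nonprotein_pct"])
        assert n == pytest.approx(1.0, abs=max(0.15, 3 * err))

    def test_doubling_copies_doubles_estimate(self, protein):
        b2 = make_fixture_suite("htl_native_like", seed=7, noise_rel_I0=0.0, n_copies=2)
        # analysis still normalises by the one-copy molar mass
        line = fit_cv_line(guinier_points(b2), protein.molar_mass)
        n, _ = oligomeric_state(line, protein, b2.manifest["cmp_nonprotein_pct"])
        assert n == pytest.approx(2.0, rel=0.1)

    def test_protein_free_particle_estimates_zero(self, protein, lipid_mix):
        from tricontrast.synthetic_data import (
            ParticleModel,
            Region,
            SimulationConfig,
            simulate_series,
        )

        model = ParticleModel([Region(lipid_mix, 3.0e5)], name="micelle")
        cfg = SimulationConfig(seed=1, noise_rel_I0=0.0)
        curves = simulate_series(model, cfg)

        class B:  # minimal bundle shim for guinier_points
            pass

        b = B()
        b.curves = curves
        line = fit_cv_line(guinier_points(b), protein.molar_mass)
        lipid_cmp = 13.2
        n, err = oligomeric_state(line, protein, lipid_cmp)
        assert abs(n) < max(0.05, 3 * err)


class TestSubtractProtein:
    def test_residual_root_matches_nonprotein_cmp(self, htl_bundle, protein):
        b = htl_bundle
        line = fit_cv_line(guinier_points(b), b.manifest["reference_molar_mass"])
        residual, band = subtract_protein(line, protein, 1.0)
        assert band.value == pytest.approx(b.manifest["cmp_nonprotein_pct"], abs=1.0)

    def test_pure_protein_residual_rejected(self, protein):
        b = make_fixture_suite("protein_only", seed=2, noise_rel_I0=0.0)
        line = fit_cv_line(guinier_points(b), b.manifest["reference_molar_mass"])
        with pytest.raises(ValueError, match="no non-protein"):
            subtract_protein(line, protein, 1.0)

    def test_zero_copies_is_identity(self, htl_bundle, protein):
        b = htl_bundle
        line = fit_cv_line(guinier_points(b), b.manifest["reference_molar_mass"])
        residual, band = subtract_protein(line, protein, 0.0)
        assert np.allclose(residual.rhoV, line.rhoV)
        assert band.value == pytest.approx(line.cmp_total, abs=1e-9)


class TestSolveVolumeFractions:
    def test_published_native_protein_fraction(self, protein):
        d = solve_volume_fractions(
            24.0, 16.5, protein, cmp_protein=39.0,
            cmp_lipid=13.1, cmp_detergent=21.7,
        )
        assert d.v_P == pytest.approx(0.333, abs=0.005)

    def test_published_crosslinked_lipid_fraction(self, protein):
        """Non-protein CMP 18 with lipid/DDM CMPs 13.1/21.7 and a 59%
        non-protein particle puts ~25% of the whole volume in lipid."""
        d = solve_volume_fractions(
            # total CMP that yields v_P = 0.41 with cmp_nonprotein = 18
            18.0 + 0.41 * (39.0 - 18.0), 18.0, protein,
            cmp_protein=39.0, cmp_lipid=13.1, cmp_detergent=21.7,
        )
        assert d.v_P == pytest.approx(0.41, abs=0.005)
        assert d.v_L == pytest.approx(0.254, abs=0.01)

    def test_pure_protein_limit(self, protein):
        d = solve_volume_fractions(
            39.0, 16.5, protein, cmp_protein=39.0,
            cmp_lipid=13.1, cmp_detergent=21.7,
        )
        assert d.v_P == pytest.approx(1.0)
        assert d.v_L == pytest.approx(0.0)
        assert d.v_D == pytest.approx(0.0)

    def test_fractions_sum_to_one(self, protein):
        d = solve_volume_fractions(
            24.0, 16.5, protein, cmp_protein=39.0,
            cmp_lipid=13.1, cmp_detergent=21.7,
        )
        assert d.v_P + d.v_L + d.v_D == pytest.approx(1.0)

    def test_degenerate_cmps_singular(self, protein):
        with pytest.raises(ZeroDivisionError):
            solve_volume_fractions(
                24.0, 24.0, protein, cmp_protein=24.0,
                cmp_lipid=13.1, cmp_detergent=21.7,
            )

    def test_cmp_total_between_components(self, protein):
        d = solve_volume_fractions(
            24.0, 16.5, protein, cmp_protein=39.0,
            cmp_lipid=13.1, cmp_detergent=21.7,
        )
        assert 16.5 < d.cmp_total < 39.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        v_p=st.floats(0.1, 0.9),
        f_lip=st.floats(0.05, 0.95),
    )
    def test_mixture_then_solve_recovers_fractions(self, protein, v_p, f_lip):
        """Composing the mixing law with its inverse is the identity on
        noise-free CMPs (machine precision)."""
        cmp_p, cmp_l, cmp_d = 39.0, 13.1, 21.7
        v_np = 1 - v_p
        v_l, v_d = v_np * f_lip, v_np * (1 - f_lip)
        cmp_np = mixture_match_point([(cmp_l, v_l), (cmp_d, v_d)])
        cmp_tot = mixture_match_point([(cmp_p, v_p), (cmp_np, v_np)])
        d = solve_volume_fractions(
            cmp_tot, cmp_np, protein, cmp_protein=cmp_p,
            cmp_lipid=cmp_l, cmp_detergent=cmp_d,
        )
        assert d.v_P == pytest.approx(v_p, abs=1e-9)
        assert d.v_L == pytest.approx(v_l, abs=1e-9)
        assert d.v_D == pytest.approx(v_d, abs=1e-9)


class TestLipidCount:
    def test_zero_lipid_volume(self, protein):
        d = solve_volume_fractions(
            39.0, 16.5, protein, cmp_protein=39.0,
            cmp_lipid=13.1, cmp_detergent=21.7,
        )
        lo, hi = lipid_count(d, 1200.0)
        assert lo == hi == 0.0

    def test_exact_volume_ratio(self, protein):
        d = solve_volume_fractions(
            24.0, 16.5, protein, cmp_protein=39.0,
            cmp_lipid=13.1, cmp_detergent=21.7,
        )
        d.v_L_err = 0.0
        lo, hi = lipid_count(d, d.V_L / 2.0)
        assert lo == pytest.approx(2.0)
        assert hi == pytest.approx(2.0)

    def test_native_like_count_in_low_hundreds(self, protein):
        """Hand oracle: V_P = M·vbar/N_A, V_total = V_P/v_P, V_L = v_L·V_total."""
        d = solve_volume_fractions(
            24.0, 16.5, protein, cmp_protein=39.0,
            cmp_lipid=13.1, cmp_detergent=21.7,
        )
        V_P = protein.dry_volume
        V_total = V_P / d.v_P
        V_L = d.v_L * V_total
        assert d.V_L == pytest.approx(V_L, rel=1e-12)
        lo, hi = lipid_count(d, (1100.0, 1250.0))
        assert 200 < lo < hi < 500


class TestConcentrationFromAbsorbance:
    def test_htl_preset_factor(self):
        assert concentration_from_absorbance(1.0) == pytest.approx(0.5)
        assert concentration_from_absorbance(0.0) == 0.0

    def test_general_preset_matches_htl_factor(self):
        got = concentration_from_absorbance(1.0, epsilon=497_000.0, M_W=250_000.0)
        assert got == pytest.approx(0.5, abs=0.01)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            concentration_from_absorbance(-0.1)
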