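"""Stuhrmann plot and parallel-axis decomposition of R_g vs contrast."""

import math

import numpy as np
import pytest

from tricontrast.constants import COHERENT_B_FM, FM_PER_ANGSTROM
from tricontrast.guinier import guinier_fit
from tricontrast.sld_core import AtomicComposition, Component, ExchangeModel, match_point, solvent_sld
from tricontrast.stuhrmann import (
    ContrastRgPoint,
    UnderdeterminedError,
    contrast_fraction_X,
    mean_particle_contrast,
    parallel_axis_fit,
    shell_rg,
    sphere_rg,
    stuhrmann_fit,
    two_phase_rg2,
)
from tricontrast.synthetic_data import ParticleModel, Region, SimulationConfig, simulate_series


def const_sld_component(name, sld, volume=1.0e5, role="other"):
    """Component with a constant (exchange-free) SLD in Å⁻²."""
    n_c = sld * volume / (COHERENT_B_FM["C"] * FM_PER_ANGSTROM)
    return Component(name, AtomicComposition({"C": n_c}), volume, 1.0e4, role=role)


def core_shell_points(rho_core, rho_shell, R1=30.0, R2=50.0, f_grid=None):
    """Exact (closed-form) Stuhrmann points for concentric spheres."""
    V1 = 4 / 3 * math.pi * R1**3
    V2 = 4 / 3 * math.pi * (R2**3 - R1**3)
    rg2_core = sphere_rg(R1) ** 2
    rg2_shell = shell_rg(R1, R2) ** 2
    if f_grid is None:
        f_grid = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
    pts = []
    for f in f_grid:
        rho_s = solvent_sld(f)
        d1, d2 = rho_core - rho_s, rho_shell - rho_s
        tot = d1 * V1 + d2 * V2
        if abs(tot) < 1e-12 * (abs(d1 * V1) + abs(d2 * V2)):
            continue
        rg2 = two_phase_rg2(rg2_core, d1, V1, rg2_shell, d2, V2)
        drho_mean = tot / (V1 + V2)
        pts.append(ContrastRgPoint(f, math.sqrt(abs(rg2)), 0.01, drho_mean, 0.0))
    return pts, (V1, V2, rg2_core, rg2_shell)


class TestContrastFractionX:
    def setup_method(self):
        self.prot = const_sld_component("p", 3.0e-6, role="protein")
        self.lip = const_sld_component("l", 1.0e-7, role="lipid")

    def _f_at_sld(self, sld):
        from tricontrast.constants import SLD_D2O, SLD_H2O

        return (sld - SLD_H2O) / (SLD_D2O - SLD_H2O)

    def test_x_is_one_when_nonprotein_matched(self):
        f = self._f_at_sld(1.0e-7)
        X = contrast_fraction_X([self.prot, self.lip], [1e5, 1e5], f)
        assert X == pytest.approx(1.0, abs=1e-9)

    def test_x_is_zero_when_protein_matched(self):
        f = self._f_at_sld(3.0e-6)
        X = contrast_fraction_X([self.prot, self.lip], [1e5, 1e5], f)
        assert X == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_toy_direct_arithmetic(self):
        """Solvent at the SLD midpoint of two equal-volume components:
        equal and opposite contrast weights, X = Δρ_P·V/(Δρ_P·V + Δρ_L·V)
        diverges from 0.5 only through the sign — hand arithmetic gives
        Δρ_P = -Δρ_L so the denominator vanishes; slightly off-midpoint
        X follows the direct Δρ·V ratio."""
        f = self._f_at_sld(0.5 * (3.0e-6 + 1.0e-7) + 2.0e-7)
        rho_s = solvent_sld(f)
        dp, dl = 3.0e-6 - rho_s, 1.0e-7 - rho_s
        expect = dp * 1e5 / (dp * 1e5 + dl * 1e5)
        X = contrast_fraction_X([self.prot, self.lip], [1e5, 1e5], f)
        assert X == pytest.approx(expect, rel=1e-9)

    def test_undefined_at_particle_match_point(self):
        f = self._f_at_sld(0.5 * (3.0e-6 + 1.0e-7))
        with pytest.raises(ZeroDivisionError):
            contrast_fraction_X([self.prot, self.lip], [1e5, 1e5], f)


class TestStuhrmannFit:
    def test_homogeneous_particle_alpha_zero(self):
        """Uniform density: R_g is contrast-independent, α = β = 0."""
        pts = []
        for f in (0.0, 0.1, 0.2, 0.6, 0.8, 1.0):
            drho = 2.0e-6 - solvent_sld(f)
            pts.append(ContrastRgPoint(f, 40.0, 0.01, drho, 0.0))
        res = stuhrmann_fit(pts)
        x_span = max(abs(1 / p.delta_rho) for p in pts)
        assert abs(res.alpha) * x_span < 1e-6 * 40.0**2
        assert res.beta == 0.0
        assert res.Rc2 == pytest.approx(1600.0, rel=1e-9)
        assert res.model == "linear"

    def test_low_sld_core_gives_positive_alpha_and_rc2(self):
        """High-SLD shell around a low-SLD core: positive slope, and the
        infinite-contrast radius equals the volume-weighted two-phase value."""
        pts, (V1, V2, rg2_c, rg2_s) = core_shell_points(5.0e-7, 3.0e-6)
        res = stuhrmann_fit(pts, model_policy="linear")
        assert res.alpha > 0
        rc2_oracle = (V1 * rg2_c + V2 * rg2_s) / (V1 + V2)
        assert res.Rc2 == pytest.approx(rc2_oracle, rel=1e-6)

    def test_swapped_slds_flip_alpha_sign(self):
        pts_lo, _ = core_shell_points(5.0e-7, 3.0e-6)
        pts_hi, _ = core_shell_points(3.0e-6, 5.0e-7)
        a_lo = stuhrmann_fit(pts_lo, model_policy="linear").alpha
        a_hi = stuhrmann_fit(pts_hi, model_policy="linear").alpha
        assert a_lo > 0 > a_hi
        assert abs(a_lo) == pytest.approx(abs(a_hi), rel=1e-6)

    def test_underdetermined_rejected(self):
        pts = [ContrastRgPoint(0.0, 40.0, 0.1, 2e-6, 0.0)] * 2
        with pytest.raises(UnderdeterminedError):
            stuhrmann_fit(pts)

    def test_low_contrast_points_excluded(self):
        pts, _ = core_shell_points(5.0e-7, 3.0e-6)
        # add a pathological near-match-point observation
        pts.append(ContrastRgPoint(0.36, 500.0, 0.01, 1e-9, 0.0))
        res = stuhrmann_fit(pts, model_policy="linear")
        assert res.n_points == len(pts) - 1


class TestParallelAxisFit:
    def test_exact_model_recovered_to_machine_precision(self):
        """Points generated from R_P = 52 Å, R_L = 22 Å, D = 0."""
        R_P, R_L = 52.0, 22.0
        pts = [
            ContrastRgPoint(
                0.0, math.sqrt(X * R_P**2 + (1 - X) * R_L**2), 0.01, 1e-6, 0.0, X
            )
            for X in (0.05, 0.2, 0.4, 0.6, 0.8, 0.95)
        ]
        res = parallel_axis_fit(pts)
        assert res.Rg_P == pytest.approx(R_P, rel=1e-9)
        assert res.Rg_L == pytest.approx(R_L, rel=1e-9)

    def test_concentric_sphere_simulation_intercepts(self, protein, lipid_mix):
        """Simulated core-shell particle (R1=30, R2=50): the X = 1 and
        X = 0 intercepts match the analytic shell and core radii within
        5% at zero noise."""
        R1, R2 = 30.0, 50.0
        V_core = 4 / 3 * math.pi * R1**3
        V_shell = 4 / 3 * math.pi * (R2**3 - R1**3)
        model = ParticleModel(
            [Region(lipid_mix, V_core), Region(protein, V_shell)], name="cs"
        )
        cfg = SimulationConfig(
            seed=0, noise_rel_I0=0.0,
            f_d2o_grid=(0.0, 0.08, 0.132, 0.20, 0.50, 0.70, 1.0),
        )
        curves = simulate_series(model, cfg)
        comps = [protein, lipid_mix]
        vols = [V_shell, V_core]
        pts = []
        for c in curves:
            f = c.metadata["f_d2o"]
            res = guinier_fit(c)
            drho = mean_particle_contrast(comps, vols, f)
            try:
                X = contrast_fraction_X(comps, vols, f)
            except ZeroDivisionError:
                continue
            pts.append(ContrastRgPoint(f, res.Rg, max(res.Rg_err, 1e-3), drho.value, drho.err, X))
        pa = parallel_axis_fit(pts)
        assert pa.Rg_P == pytest.approx(shell_rg(R1, R2), rel=0.05)
        assert pa.Rg_L == pytest.approx(sphere_rg(R1), rel=0.05)

    def test_displaced_spheres_recover_centre_distance(self):
        """Two displaced phases: the quadratic X(1−X)·D² term recovers D
        (well within 10% on noise-free points)."""
        R_P, R_L, D = 45.0, 30.0, 60.0
        rg2p, rg2l = sphere_rg(R_P) ** 2, sphere_rg(R_L) ** 2
        pts = []
        for X in (0.1, 0.25, 0.4, 0.55, 0.7, 0.85, 0.95):
            rg2 = X * rg2p + (1 - X) * rg2l + X * (1 - X) * D**2
            pts.append(ContrastRgPoint(0.0, math.sqrt(rg2), 0.01, 1e-6, 0.0, X))
        res = parallel_axis_fit(pts, include_D=True)
        assert res.D == pytest.approx(D, rel=0.10)
        assert res.model == "quadratic"

    def test_narrow_x_range_warned(self):
        pts = [
            ContrastRgPoint(0.0, 40.0 + 0.1 * i, 0.01, 1e-6, 0.0, 0.5 + 0.01 * i)
            for i in range(5)
        ]
        res = parallel_axis_fit(pts)
        assert "narrow_X_range" in res.flags


class TestStuhrmannParallelAxisEquivalence:
    def test_same_component_radius_from_both_plots(self):
        """On a noise-free two-phase series with coincident centres the
        Stuhrmann line evaluated at the solvent that matches the core
        equals the parallel-axis X = 1 intercept."""
        rho_core, rho_shell = 5.0e-7, 3.0e-6
        pts, (V1, V2, rg2_c, rg2_s) = core_shell_points(rho_core, rho_shell)
        # attach X to each point
        for p in pts:
            rho_s = solvent_sld(p.f_d2o)
            d1, d2 = rho_core - rho_s, rho_shell - rho_s
            p.X = d2 * V2 / (d1 * V1 + d2 * V2)
        stu = stuhrmann_fit(pts, model_policy="linear")
        pa = parallel_axis_fit(pts)
        # solvent matching the core: Δρ̄ there is the shell-only mean contrast
        from tricontrast.constants import SLD_D2O, SLD_H2O

        f_core = (rho_core - SLD_H2O) / (SLD_D2O - SLD_H2O)
        drho_at_core_match = (rho_shell - rho_core) * V2 / (V1 + V2)
        rg2_p_stuhrmann = stu.Rc2 + stu.alpha / drho_at_core_match
        assert math.sqrt(rg2_p_stuhrmann) == pytest.approx(pa.Rg_P, rel=1e-6)
        assert pa.Rg_P == pytest.approx(math.sqrt(rg2_s), rel=1e-6)

    def test_beta_zero_selected_for_coincident_centres(self):
        pts, _ = core_shell_points(5.0e-7, 3.0e-6)
        res = stuhrmann_fit(pts, model_policy="auto")
        assert res.model == "linear"
        assert res.beta == 0.0
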