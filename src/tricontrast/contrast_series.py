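"""Contrast-match-point decomposition of a protein/lipid/detergent particle.

On absolute scale, the forward intensity of a monodisperse solution is
I(0) = n·(Δρ·V)², with n the particle number density.  √(I(0)/c) is
therefore proportional to the particle's excess scattering length ρV,
which is linear in the solvent D₂O fraction.  Fitting the signed ρV
against %D₂O (the contrast-variation line) gives the complex match point;
subtracting the theoretical protein contribution yields the non-protein
(lipid + detergent) match point; and the volume-weighted mixing algebra
then dissects the particle into protein, lipid and detergent volume
fractions, an absolute particle volume, a lipid copy number, and the
oligomeric state of the protein.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import AVOGADRO, FM_TO_CM
from .guinier import GuinierResult
from .sld_core import (
    Banded,
    Component,
    ExchangeModel,
    component_scattering_length,
    match_point,
    solvent_sld,
    solve_mixing_fraction,
)


class SignAmbiguityError(ValueError):
    """Neither sign assignment of √I(0) yields a stable line fit."""


@dataclass(frozen=True)
class WaterCalibration:
    """Absolute-scale calibration via the incoherent scattering of water.

    T_water: transmission of the water standard; f_lambda: wavelength-
    dependent correction of the water cross-section (0.8 at 6 Å);
    t_water: path length of the water cell, cm.
    """

    T_water: float = 0.53
    f_lambda: float = 0.8
    t_water: float = 0.1

    def absolute_factor(self, transmission: float, path_length: float) -> float:
        """Factor converting a water-ratio intensity I_s/I_w into cm⁻¹."""
        dsigma_water = (1.0 - self.T_water) * self.f_lambda / (4.0 * math.pi * self.t_water)
        return dsigma_water * (self.T_water * self.t_water) / (transmission * path_length)


@dataclass
class ContrastPoint:
    """One contrast condition: Guinier result plus sample metadata."""

    f_d2o: float
    guinier: GuinierResult
    concentration: float  # protein mass concentration, mg/ml
    transmission: float = 1.0
    path_length: float = 0.1  # cm
    wavelength: float = 6.0  # Å
    calibration: WaterCalibration = field(default_factory=WaterCalibration)
    intensity_scale: str = "absolute"  # or "water_ratio"

    def __post_init__(self):
        if not 0.0 < self.transmission <= 1.0:
            raise ValueError("transmission must be in (0, 1]")
        if self.concentration <= 0 or self.path_length <= 0:
            raise ValueError("concentration and path length must be positive")


@dataclass
class CVLine:
    """Fitted contrast-variation line: signed ρV (cm) vs % D₂O."""

    f_pct: np.ndarray
    rhoV: np.ndarray  # signed, cm per particle
    rhoV_err: np.ndarray
    slope: float
    intercept: float
    cov: np.ndarray  # covariance of (intercept, slope)
    cmp_total: float  # % D₂O
    cmp_total_err: float
    chi2_dof: float
    flags: list[str] = field(default_factory=list)

    def eval(self, f_pct: float) -> tuple[float, float]:
        """Line value and 1σ error at f_pct % D₂O."""
        v = self.intercept + self.slope * f_pct
        var = (
            self.cov[0, 0]
            + f_pct**2 * self.cov[1, 1]
            + 2.0 * f_pct * self.cov[0, 1]
        )
        return v, math.sqrt(max(var, 0.0))

    def as_dict(self) -> dict:
        return {
            "f_pct": self.f_pct.tolist(),
            "rhoV_cm": self.rhoV.tolist(),
            "rhoV_err_cm": self.rhoV_err.tolist(),
            "slope_cm_per_pct": self.slope,
            "intercept_cm": self.intercept,
            "cmp_total_pctD2O": self.cmp_total,
            "cmp_total_err_pctD2O": self.cmp_total_err,
            "chi2_dof": self.chi2_dof,
            "flags": self.flags,
        }


@dataclass
class Decomposition:
    """Volume-fraction dissection of the particle with propagated errors."""

    v_P: float
    v_L: float
    v_D: float
    v_P_err: float
    v_L_err: float
    v_D_err: float
    V_total: float  # Å³
    V_P: float
    V_L: float
    V_D: float
    cmp_total: float
    cmp_nonprotein: Banded
    cmp_nonprotein_err: float
    n_copies: float
    n_copies_err: float
    lipid_count: tuple[float, float] = (0.0, 0.0)

    def as_dict(self) -> dict:
        return {
            "volume_fractions": {
                "protein": [self.v_P, self.v_P_err],
                "lipid": [self.v_L, self.v_L_err],
                "detergent": [self.v_D, self.v_D_err],
            },
            "volumes_A3": {
                "total": self.V_total,
                "protein": self.V_P,
                "lipid": self.V_L,
                "detergent": self.V_D,
            },
            "cmp_total_pctD2O": self.cmp_total,
            "cmp_nonprotein_pctD2O": [
                self.cmp_nonprotein.value,
                self.cmp_nonprotein_err,
            ],
            "cmp_nonprotein_band_pctD2O": [
                self.cmp_nonprotein.low,
                self.cmp_nonprotein.high,
            ],
            "oligomeric_state": [self.n_copies, self.n_copies_err],
            "lipid_count_range": list(self.lipid_count),
        }


def protein_excess_scattering_length(
    protein: Component,
    f_d2o: float,
    xm: ExchangeModel = ExchangeModel(),
    n_copies: float = 1.0,
) -> Banded:
    """Theoretical excess scattering length of the protein component, cm:
    n_copies · (b_P(f) − ρ_solv(f)·V_P)."""
    b = component_scattering_length(protein, f_d2o, xm)
    rho_s = solvent_sld(f_d2o)
    sub = rho_s * protein.dry_volume * 1e-8  # Å⁻²·Å³ = Å → cm
    vals = [n_copies * (x * FM_TO_CM - sub) for x in (b.value, b.low, b.high)]
    return Banded(vals[0], min(vals[1:]), max(vals[1:]))


def scattering_length_from_I0(p: ContrastPoint, M_W: float) -> tuple[float, float]:
    """|ρV| per particle in cm from an absolute-scale I(0).

    I(0) [cm⁻¹] = n·(ρV)² with n = c·N_A/M_W (c in g/cm³), hence
    |ρV| = √(I(0)·M_W/(c·N_A)).  Water-ratio intensities are first
    converted to absolute scale with the water calibration bracket.
    Returns (value, error) with the error propagated from I(0).
    """
    I0, I0_err = p.guinier.I0, p.guinier.I0_err
    if p.intensity_scale == "water_ratio":
        k = p.calibration.absolute_factor(p.transmission, p.path_length)
        I0, I0_err = I0 * k, I0_err * k
    elif p.intensity_scale != "absolute":
        raise ValueError(f"unknown intensity scale {p.intensity_scale!r}")
    c_gcm3 = p.concentration * 1e-3
    scale = M_W / (c_gcm3 * AVOGADRO)
    if I0 <= 0:
        return 0.0, math.sqrt(max(I0_err, 0.0) * scale) if I0_err > 0 else 0.0
    rhoV = math.sqrt(I0 * scale)
    err = 0.5 * I0_err / I0 * rhoV
    return rhoV, err


def _weighted_line(x: np.ndarray, y: np.ndarray, sig: np.ndarray):
    w = 1.0 / sig**2
    W, Wx, Wxx = np.sum(w), np.sum(w * x), np.sum(w * x * x)
    det = W * Wxx - Wx * Wx
    Wy, Wxy = np.sum(w * y), np.sum(w * x * y)
    a = (Wxx * Wy - Wx * Wxy) / det
    b = (W * Wxy - Wx * Wy) / det
    cov = np.array([[Wxx, -Wx], [-Wx, W]]) / det
    chi2 = float(np.sum(w * (y - a - b * x) ** 2))
    return a, b, cov, chi2


def _root_and_err(a: float, b: float, cov: np.ndarray) -> tuple[float, float]:
    root = -a / b
    var = (cov[0, 0] + root**2 * cov[1, 1] + 2 * root * cov[0, 1]) / b**2
    return root, math.sqrt(max(var, 0.0))


def fit_cv_line(points: list[ContrastPoint], M_W: float) -> CVLine:
    """Fit the contrast-variation line of signed ρV against % D₂O.

    √I(0) loses the sign of the contrast; the sign change is located by
    scanning every candidate break between consecutive contrast points
    (plus the all-positive/all-negative assignments) and keeping the
    weighted line fit with the smallest χ².  The line is normalised to be
    positive at 0% D₂O (protein-rich particles scatter above solvent in
    H₂O).  cmp_total is the fitted root.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 contrast points")
    pts = sorted(points, key=lambda p: p.f_d2o)
    f = np.array([100.0 * p.f_d2o for p in pts])
    mag = np.empty(len(pts))
    err = np.empty(len(pts))
    for i, p in enumerate(pts):
        mag[i], err[i] = scattering_length_from_I0(p, M_W)
    err = np.where(err > 0, err, max(1e-3 * np.max(mag), 1e-30))

    candidates = [-np.inf] + [0.5 * (f[i] + f[i + 1]) for i in range(len(f) - 1)] + [np.inf]
    best = None
    for c in candidates:
        signs = np.where(f < c, 1.0, -1.0)
        a, b, cov, chi2 = _weighted_line(f, signs * mag, err)
        if best is None or chi2 < best[0]:
            best = (chi2, a, b, cov, signs)
    chi2, a, b, cov, signs = best

    flags: list[str] = []
    others = sorted(
        c[0] for c in (
            (_weighted_line(f, np.where(f < cc, 1.0, -1.0) * mag, err)[3], cc)
            for cc in candidates
        )
    )
    if len(others) > 1 and others[0] > 0 and others[1] / max(others[0], 1e-30) < 1.5:
        flags.append("sign_assignment_ambiguous")

    if a < 0:  # normalise polarity: positive below the match point
        a, b, signs = -a, -b, -signs
    if abs(b) < 1e-30:
        raise SignAmbiguityError("contrast line has zero slope; no match point")
    root, root_err = _root_and_err(a, b, cov)
    dof = len(pts) - 2
    if dof <= 0:
        flags.append("no_degrees_of_freedom")
    chi2_dof = chi2 / dof if dof > 0 else float("nan")
    if dof > 0 and chi2_dof > 5.0:
        flags.append("poor_linearity")  # polydispersity or composition change
    return CVLine(
        f_pct=f, rhoV=signs * mag, rhoV_err=err, slope=b, intercept=a, cov=cov,
        cmp_total=root, cmp_total_err=root_err, chi2_dof=chi2_dof, flags=flags,
    )


def oligomeric_state(
    line: CVLine,
    protein: Component,
    cmp_nonprotein: float,
    xm: ExchangeModel = ExchangeModel(),
) -> tuple[float, float]:
    """Copies of the monomeric protein set in the particle.

    At the non-protein match point only the protein scatters; the line
    value there, extrapolated to 0% D₂O along a line rooted at the protein
    match point, gives the protein-only excess scattering length in H₂O.
    Its square over the theoretical one-copy value squared is the apparent
    over sequence molar mass, i.e. the copy number.
    """
    cmp_p = match_point(protein, xm)
    span = np.ptp(line.f_pct)
    if abs(cmp_nonprotein - np.median(line.f_pct)) > 1.5 * span:
        warnings.warn("non-protein CMP far outside measured contrast span", stacklevel=2)
    val, val_err = line.eval(cmp_nonprotein)

    def estimate(cmp_p_val: float, exch: float) -> float:
        if abs(cmp_p_val - cmp_nonprotein) < 1e-12:
            return float("nan")
        at_zero = val * cmp_p_val / (cmp_p_val - cmp_nonprotein)
        b_theory = protein_excess_scattering_length(
            protein, 0.0, ExchangeModel(exch, exch, exch)
        ).value
        return (at_zero / b_theory) ** 2

    n = estimate(cmp_p.value, xm.fraction)
    n_lo = estimate(cmp_p.low, xm.low)
    n_hi = estimate(cmp_p.high, xm.high)
    stat_err = abs(n) * 2.0 * val_err / abs(val) if val != 0 else 0.0
    band_err = 0.5 * abs(n_hi - n_lo)
    return n, math.hypot(stat_err, band_err)


def subtract_protein(
    line: CVLine,
    protein: Component,
    n_copies: float = 1.0,
    xm: ExchangeModel = ExchangeModel(),
) -> tuple[CVLine, Banded]:
    """Subtract the theoretical protein line from the complex CV line.

    Returns the residual (non-protein) line and its root, the non-protein
    match point, as a Banded value whose band propagates the exchange
    band of the protein scattering length.
    """
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")

    def residual_fit(exch_model: ExchangeModel):
        resid = np.array([
            line.rhoV[i]
            - protein_excess_scattering_length(
                protein, f / 100.0, exch_model, n_copies
            ).value
            for i, f in enumerate(line.f_pct)
        ])
        a, b, cov, chi2 = _weighted_line(line.f_pct, resid, line.rhoV_err)
        return resid, a, b, cov, chi2

    resid, a, b, cov, chi2 = residual_fit(xm)
    scale = max(np.max(np.abs(line.rhoV)), 1e-30)
    if np.max(np.abs(resid)) < 0.05 * scale or np.all(
        np.abs(resid) < 3.0 * line.rhoV_err
    ):
        raise ValueError("residual indistinguishable from zero: no non-protein component")
    root, root_err = _root_and_err(a, b, cov)
    roots = [root]
    for exch in (xm.low, xm.high):
        _, a2, b2, cov2, _ = residual_fit(ExchangeModel(exch, exch, exch))
        if abs(b2) > 1e-30:
            roots.append(-a2 / b2)
    dof = len(line.f_pct) - 2
    residual_line = CVLine(
        f_pct=line.f_pct, rhoV=resid, rhoV_err=line.rhoV_err, slope=b, intercept=a,
        cov=cov, cmp_total=root, cmp_total_err=root_err,
        chi2_dof=chi2 / dof if dof > 0 else float("nan"),
    )
    return residual_line, Banded(root, min(roots), max(roots))


def solve_volume_fractions(
    cmp_total: float,
    cmp_nonprotein: float,
    protein: Component,
    n_copies: float = 1.0,
    cmp_lipid: float = 13.1,
    cmp_detergent: float = 21.7,
    cmp_protein: float | None = None,
    xm: ExchangeModel = ExchangeModel(),
    cmp_total_err: float = 0.0,
    cmp_nonprotein_err: float = 0.0,
    cmp_nonprotein_band: Banded | None = None,
) -> Decomposition:
    """Dissect the particle into protein/lipid/detergent volume fractions.

    The protein fraction follows from inverse mixing of the total and
    non-protein match points; the absolute protein volume (sequence ×
    copies) anchors the total particle volume; the lipid:detergent split
    follows from inverse mixing of the non-protein match point between
    the lipid and detergent match points.  First-order error propagation
    throughout, including the exchange band on the non-protein CMP.
    """
    cmp_p = cmp_protein if cmp_protein is not None else match_point(protein, xm).value
    if abs(cmp_p - cmp_nonprotein) < 1e-12:
        raise ZeroDivisionError("protein and non-protein CMPs coincide")
    v_P = solve_mixing_fraction(cmp_total, cmp_p, cmp_nonprotein)
    denom = cmp_p - cmp_nonprotein
    dvP_dtot = 1.0 / denom
    dvP_dnp = (cmp_total - cmp_p) / denom**2
    v_P_err = math.hypot(dvP_dtot * cmp_total_err, dvP_dnp * cmp_nonprotein_err)

    if abs(cmp_lipid - cmp_detergent) < 1e-12:
        raise ZeroDivisionError("lipid and detergent CMPs coincide")
    band = cmp_nonprotein_band or Banded(
        cmp_nonprotein, cmp_nonprotein, cmp_nonprotein
    )
    f_lip = solve_mixing_fraction(cmp_nonprotein, cmp_lipid, cmp_detergent)
    f_lip_err = math.hypot(
        cmp_nonprotein_err / abs(cmp_lipid - cmp_detergent),
        0.5
        * abs(
            (band.high - band.low) / (cmp_lipid - cmp_detergent)
        ),
    )

    v_NP = 1.0 - v_P
    v_L = v_NP * f_lip
    v_D = v_NP * (1.0 - f_lip)
    v_L_err = math.hypot(f_lip * v_P_err, v_NP * f_lip_err)
    v_D_err = math.hypot((1 - f_lip) * v_P_err, v_NP * f_lip_err)

    V_P = protein.dry_volume * n_copies
    if v_P <= 0:
        raise ValueError("protein fraction non-positive: cannot anchor total volume")
    V_total = V_P / v_P
    return Decomposition(
        v_P=v_P, v_L=v_L, v_D=v_D,
        v_P_err=v_P_err, v_L_err=v_L_err, v_D_err=v_D_err,
        V_total=V_total, V_P=V_P, V_L=v_L * V_total, V_D=v_D * V_total,
        cmp_total=cmp_total, cmp_nonprotein=band,
        cmp_nonprotein_err=cmp_nonprotein_err,
        n_copies=n_copies, n_copies_err=0.0,
    )


def lipid_count(
    d: Decomposition, lipid_mol_volume: float | tuple[float, float] = (1100.0, 1250.0)
) -> tuple[float, float]:
    """Number of lipid molecules in the particle, as a (low, high) range.

    The range spans the propagated error on the lipid volume and the
    configured molecular-volume range (default brackets typical
    phospholipid volumes around the E. coli blend's ~1180 Å³).
    """
    if isinstance(lipid_mol_volume, (int, float)):
        vols = (float(lipid_mol_volume), float(lipid_mol_volume))
    else:
        vols = (float(lipid_mol_volume[0]), float(lipid_mol_volume[1]))
    if vols[0] <= 0:
        raise ValueError("lipid molecular volume must be positive")
    rel_err = d.v_L_err / d.v_L if d.v_L > 0 else 0.0
    V_L_low = d.V_L * max(1.0 - rel_err, 0.0)
    V_L_high = d.V_L * (1.0 + rel_err)
    return (V_L_low / vols[1], V_L_high / vols[0])


def concentration_from_absorbance(
    A280: float,
    epsilon: float | None = None,
    M_W: float | None = None,
    factor: float = 0.5,
) -> float:
    """Protein concentration in mg/ml from absorbance at 280 nm (1 cm path).

    With no extinction data the holo-translocon calibration c = 0.5·A is
    used; given ε (1/M/cm) and M_W (g/mol) the general Beer–Lambert factor
    M_W/ε replaces it.
    """
    if A280 < 0:
        raise ValueError("negative absorbance")
    if epsilon is not None and M_W is not None:
        return A280 * M_W / epsilon
    return factor * A280
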