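"""Stuhrmann and parallel-axis decomposition of R_g versus contrast.

For a two-density particle the observed radius of gyration depends on the
mean contrast Δρ̄ as

    R_g² = R_c² + α/Δρ̄ − β/Δρ̄²,

where R_c is the radius of gyration at infinite contrast, α carries the
radial distribution of scattering density (α > 0: high-SLD material
peripheral) and β the separation of the component centres of mass.  The
equivalent parallel-axis form in the protein contrast share
X = Δρ_P·V_P / (Δρ_P·V_P + Δρ_L·V_L) is

    R_g² = X·R_P² + (1−X)·R_L² + X(1−X)·D²,

whose X = 1 and X = 0 intercepts are the protein and non-protein component
radii of gyration and D the distance between their centres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sld_core import Banded, Component, ExchangeModel, component_sld, solvent_sld


class UnderdeterminedError(ValueError):
    """Fewer usable contrast points than fit parameters."""


@dataclass
class ContrastRgPoint:
    """One (contrast, R_g) observation for the Stuhrmann analysis."""

    f_d2o: float
    Rg: float
    Rg_err: float
    delta_rho: float  # mean particle contrast, Å⁻²
    delta_rho_err: float = 0.0  # exchange-band half-width
    X: float = float("nan")  # protein share of total contrast
    X_err: float = 0.0


@dataclass
class StuhrmannResult:
    Rc2: float
    Rc2_err: float
    alpha: float
    alpha_err: float
    beta: float
    beta_err: float
    model: str  # "linear" | "parabolic"
    chi2_dof: float
    n_points: int
    linear: dict = field(default_factory=dict)
    parabolic: dict = field(default_factory=dict)

    @property
    def Rc(self) -> float:
        return math.sqrt(self.Rc2) if self.Rc2 > 0 else float("nan")

    def as_dict(self) -> dict:
        return {
            "Rc2_A2": [self.Rc2, self.Rc2_err],
            "alpha": [self.alpha, self.alpha_err],
            "beta": [self.beta, self.beta_err],
            "model": self.model,
            "chi2_dof": self.chi2_dof,
            "n_points": self.n_points,
            "linear_fit": self.linear,
            "parabolic_fit": self.parabolic,
        }


@dataclass
class ParallelAxisResult:
    Rg_P: float
    Rg_P_err: float
    Rg_L: float
    Rg_L_err: float
    D: float
    D_err: float
    model: str
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "Rg_protein_A": [self.Rg_P, self.Rg_P_err],
            "Rg_nonprotein_A": [self.Rg_L, self.Rg_L_err],
            "D_A": [self.D, self.D_err],
            "model": self.model,
            "flags": self.flags,
        }


def mean_particle_contrast(
    components: list[Component],
    volume_fractions: list[float],
    f_d2o: float,
    xm: ExchangeModel = ExchangeModel(),
) -> Banded:
    """Volume-weighted mean particle SLD minus solvent SLD, Å⁻²."""
    if len(components) != len(volume_fractions):
        raise ValueError("components and fractions differ in length")
    total = sum(volume_fractions)
    rho_s = solvent_sld(f_d2o)
    vals = []
    for pick in ("value", "low", "high"):
        mean = (
            sum(
                getattr(component_sld(c, f_d2o, xm), pick) * v
                for c, v in zip(components, volume_fractions)
            )
            / total
        )
        vals.append(mean - rho_s)
    return Banded(vals[0], min(vals[1:]), max(vals[1:]))


def contrast_fraction_X(
    components: list[Component],
    volume_fractions: list[float],
    f_d2o: float,
    xm: ExchangeModel = ExchangeModel(),
) -> float:
    """Protein share of the total contrast-weighted scattering length:
    X = Δρ_P·V_P / (Δρ_P·V_P + Δρ_L·V_L).

    Protein components are identified by role; everything else counts as
    the non-protein phase.  Undefined at the particle match point.
    """
    rho_s = solvent_sld(f_d2o)
    num = 0.0
    tot = 0.0
    mag = 0.0
    for c, v in zip(components, volume_fractions):
        term = (component_sld(c, f_d2o, xm).value - rho_s) * v
        tot += term
        mag += abs(term)
        if c.role == "protein":
            num += term
    if abs(tot) < 1e-9 * max(mag, 1e-30):
        raise ZeroDivisionError("total contrast vanishes: X undefined at the match point")
    return num / tot


def _wpolyfit(x: np.ndarray, y: np.ndarray, sig: np.ndarray, order: int):
    """Weighted polynomial LS in powers of x; returns coeffs (ascending),
    covariance and chi²."""
    A = np.vander(x, order + 1, increasing=True)
    w = 1.0 / sig
    Aw = A * w[:, None]
    yw = y * w
    coef, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    cov = np.linalg.inv(Aw.T @ Aw)
    chi2 = float(np.sum((yw - Aw @ coef) ** 2))
    return coef, cov, chi2


def filter_low_contrast(
    points: list[ContrastRgPoint], min_fraction: float = 0.10
) -> list[ContrastRgPoint]:
    """Drop points whose |Δρ̄| falls below min_fraction of the series
    maximum — near the particle match point R_g is unreliable."""
    max_c = max(abs(p.delta_rho) for p in points)
    return [p for p in points if abs(p.delta_rho) >= min_fraction * max_c]


def stuhrmann_fit(
    points: list[ContrastRgPoint],
    model_policy: str = "auto",
    low_contrast_fraction: float = 0.10,
    f_test_p: float = 0.05,
) -> StuhrmannResult:
    """Weighted fit of R_g² against 1/Δρ̄ (and 1/Δρ̄² for the parabolic model).

    Effective-variance weighting folds the exchange-band x-errors into the
    y-variance using the current slope (two passes).  model_policy:
    'linear', 'parabolic', or 'auto' (parabolic only if an F-test on the
    extra term is significant at f_test_p).
    """
    usable = filter_low_contrast(points, low_contrast_fraction)
    usable = [p for p in usable if np.isfinite(p.Rg) and p.Rg_err >= 0]
    n = len(usable)
    if n < 3:
        raise UnderdeterminedError(f"only {n} usable contrast points")
    x = np.array([1.0 / p.delta_rho for p in usable])
    y = np.array([p.Rg**2 for p in usable])
    sig_y = np.array([max(2.0 * p.Rg * p.Rg_err, 1e-12) for p in usable])
    sig_x = np.array([p.delta_rho_err / p.delta_rho**2 for p in usable])

    def fit(order: int):
        sig = sig_y.copy()
        coef = cov = None
        chi2 = np.inf
        for _ in range(2):  # effective-variance iteration
            coef, cov, chi2 = _wpolyfit(x, y, sig, order)
            slope = coef[1]
            sig = np.sqrt(sig_y**2 + (slope * sig_x) ** 2)
        return coef, cov, chi2

    lin_coef, lin_cov, lin_chi2 = fit(1)
    linear = {
        "Rc2": lin_coef[0], "alpha": lin_coef[1],
        "chi2_dof": lin_chi2 / (n - 2) if n > 2 else float("nan"),
    }
    parabolic = {}
    par_ok = n >= 4
    if par_ok:
        par_coef, par_cov, par_chi2 = fit(2)
        parabolic = {
            "Rc2": par_coef[0], "alpha": par_coef[1], "beta": -par_coef[2],
            "chi2_dof": par_chi2 / (n - 3) if n > 3 else float("nan"),
        }

    if model_policy == "linear" or not par_ok:
        model = "linear"
    elif model_policy == "parabolic":
        model = "parabolic"
    elif model_policy == "auto":
        if par_chi2 <= 0 or n <= 3:
            model = "linear"
        else:
            F = (lin_chi2 - par_chi2) / (par_chi2 / (n - 3))
            p_val = 1.0 - stats.f.cdf(F, 1, n - 3) if F > 0 else 1.0
            model = "parabolic" if p_val < f_test_p else "linear"
    else:
        raise ValueError(f"unknown model_policy {model_policy!r}")

    if model == "linear":
        coef, cov, chi2 = lin_coef, lin_cov, lin_chi2
        beta, beta_err = 0.0, 0.0
        dof = n - 2
    else:
        coef, cov, chi2 = par_coef, par_cov, par_chi2
        beta, beta_err = -coef[2], math.sqrt(max(cov[2, 2], 0.0))
        dof = n - 3
    return StuhrmannResult(
        Rc2=coef[0], Rc2_err=math.sqrt(max(cov[0, 0], 0.0)),
        alpha=coef[1], alpha_err=math.sqrt(max(cov[1, 1], 0.0)),
        beta=beta, beta_err=beta_err, model=model,
        chi2_dof=chi2 / dof if dof > 0 else float("nan"),
        n_points=n, linear=linear, parabolic=parabolic,
    )


def parallel_axis_fit(
    points: list[ContrastRgPoint],
    include_D: bool = False,
    low_contrast_fraction: float = 0.10,
    min_X_span: float = 0.2,
) -> ParallelAxisResult:
    """Weighted fit of R_g² against the protein contrast share X.

    Linear model (D = 0): intercepts at X = 1 and X = 0 give R_P² and
    R_L².  With include_D the X(1−X)·D² cross term is added.  Negative
    fitted squares are flagged 'imaginary_*', not silently clipped.
    """
    usable = filter_low_contrast(points, low_contrast_fraction)
    usable = [p for p in usable if np.isfinite(p.X) and np.isfinite(p.Rg)]
    n = len(usable)
    n_par = 3 if include_D else 2
    if n < n_par:
        raise UnderdeterminedError(f"{n} points for {n_par} parameters")
    X = np.array([p.X for p in usable])
    y = np.array([p.Rg**2 for p in usable])
    sig = np.array([max(2.0 * p.Rg * p.Rg_err, 1e-12) for p in usable])

    flags: list[str] = []
    if np.ptp(X) < min_X_span:
        flags.append("narrow_X_range")

    cols = [X, 1.0 - X]
    if include_D:
        cols.append(X * (1.0 - X))
    A = np.column_stack(cols)
    w = 1.0 / sig
    Aw = A * w[:, None]
    coef, *_ = np.linalg.lstsq(Aw, y * w, rcond=None)
    cov = np.linalg.inv(Aw.T @ Aw)

    def sqrt_flagged(val: float, var: float, label: str):
        err_sq = math.sqrt(max(var, 0.0))
        if val < 0:
            flags.append(f"imaginary_{label}")
            r = math.sqrt(-val)
            return r, err_sq / (2 * r) if r > 0 else float("inf")
        r = math.sqrt(val)
        return r, err_sq / (2 * r) if r > 0 else float("inf")

    Rg_P, Rg_P_err = sqrt_flagged(coef[0], cov[0, 0], "Rg_P")
    Rg_L, Rg_L_err = sqrt_flagged(coef[1], cov[1, 1], "Rg_L")
    if include_D:
        D, D_err = sqrt_flagged(coef[2], cov[2, 2], "D")
        model = "quadratic"
    else:
        D, D_err, model = 0.0, 0.0, "linear"
    return ParallelAxisResult(
        Rg_P=Rg_P, Rg_P_err=Rg_P_err, Rg_L=Rg_L, Rg_L_err=Rg_L_err,
        D=D, D_err=D_err, model=model, flags=flags,
    )


# ---------------------------------------------------------------------------
# Closed-form oracles for two-phase spherical geometries
# ---------------------------------------------------------------------------

def sphere_rg(R: float) -> float:
    """R_g of a homogeneous sphere: √(3/5)·R."""
    return math.sqrt(3.0 / 5.0) * R


def shell_rg(R_inner: float, R_outer: float) -> float:
    """R_g of a homogeneous spherical shell."""
    num = R_outer**5 - R_inner**5
    den = R_outer**3 - R_inner**3
    return math.sqrt(3.0 / 5.0 * num / den)


def two_phase_rg2(
    rg2_a: float, rho_a: float, V_a: float,
    rg2_b: float, rho_b: float, V_b: float,
    D: float = 0.0,
) -> float:
    """Contrast-weighted R_g² of two phases with centre separation D
    (parallel-axis theorem)."""
    wa = rho_a * V_a
    wb = rho_b * V_b
    tot = wa + wb
    if tot == 0:
        raise ZeroDivisionError("zero total contrast")
    Xa = wa / tot
    return Xa * rg2_a + (1 - Xa) * rg2_b + Xa * (1 - Xa) * D**2
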