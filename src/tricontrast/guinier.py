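"""Guinier analysis of reduced 1D scattering curves.

At low angle, I(q) ≈ I(0)·exp(−q²R_g²/3), so a weighted straight-line fit
of ln I against q² yields the forward intensity and radius of gyration.
The fit window is chosen self-consistently: the upper edge is pushed out
until q·R_g at the edge reaches the validity limit (default 1.3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class GuinierError(ValueError):
    """Guinier fit impossible on the supplied curve."""


@dataclass
class ScatteringCurve:
    """One reduced 1D SANS measurement on absolute scale.

    q in Å⁻¹ (strictly increasing), I and sigma_I in cm⁻¹, optional dq in
    Å⁻¹ carried through but not used (no smearing model).
    """

    q: np.ndarray
    I: np.ndarray
    sigma_I: np.ndarray
    dq: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma_I = np.asarray(self.sigma_I, dtype=float)
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)
        n = len(self.q)
        if not (len(self.I) == len(self.sigma_I) == n) or (
            self.dq is not None and len(self.dq) != n
        ):
            raise ValueError("column length mismatch")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")

    def __len__(self) -> int:
        return len(self.q)

    def scaled(self, factor: float) -> "ScatteringCurve":
        return ScatteringCurve(
            self.q, self.I * factor, self.sigma_I * factor,
            None if self.dq is None else self.dq.copy(), dict(self.metadata),
        )


@dataclass
class GuinierResult:
    I0: float
    I0_err: float
    Rg: float
    Rg_err: float
    q_window: tuple[float, float]
    n_points: int
    qRg_max: float
    valid: bool
    flags: list[str] = field(default_factory=list)
    residual_runs_z: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "I0_cm^-1": self.I0,
            "I0_err": self.I0_err,
            "Rg_A": self.Rg,
            "Rg_err": self.Rg_err,
            "q_window_A^-1": list(self.q_window),
            "n_points": self.n_points,
            "qRg_max": self.qRg_max,
            "valid": self.valid,
            "flags": self.flags,
            "residual_runs_z": self.residual_runs_z,
        }


def _weighted_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted LS fit y = a + b x; returns a, b and covariance matrix."""
    W = np.sum(w)
    Wx = np.sum(w * x)
    Wxx = np.sum(w * x * x)
    det = W * Wxx - Wx * Wx
    if det <= 0:
        raise GuinierError("degenerate fit window")
    Wy = np.sum(w * y)
    Wxy = np.sum(w * x * y)
    a = (Wxx * Wy - Wx * Wxy) / det
    b = (W * Wxy - Wx * Wy) / det
    cov = np.array([[Wxx, -Wx], [-Wx, W]]) / det
    return a, b, cov


def _runs_z(residuals: np.ndarray) -> float:
    """Wald–Wolfowitz runs-test z statistic on residual signs; large
    negative values indicate systematic curvature."""
    signs = residuals >= 0
    n1 = int(np.sum(signs))
    n2 = len(signs) - n1
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2 * n1 * n2 / (n1 + n2) + 1
    var = 2 * n1 * n2 * (2 * n1 * n2 - n1 - n2) / ((n1 + n2) ** 2 * (n1 + n2 - 1))
    if var <= 0:
        return 0.0
    return (runs - mu) / math.sqrt(var)


def guinier_fit(
    curve: ScatteringCurve,
    qrg_limit: float = 1.3,
    window_policy: str = "auto",
    q_window: tuple[float, float] | None = None,
    min_points: int = 5,
) -> GuinierResult:
    """Fit ln I vs q² on a low-q window, weighted by 1/σ_lnI².

    window_policy 'auto' iterates the upper window edge to satisfy
    q_max·R_g ≤ qrg_limit self-consistently; 'fixed' uses q_window as
    given.  Points with I ≤ 0 are excluded, never clipped.
    """
    usable = curve.I > 0
    if int(np.sum(usable)) < min_points:
        raise GuinierError("fewer than %d points with positive intensity" % min_points)
    q = curve.q[usable]
    I = curve.I[usable]
    sig = curve.sigma_I[usable]
    sig = np.where(sig > 0, sig, np.min(sig[sig > 0]) if np.any(sig > 0) else 1.0)

    x_all = q**2
    y_all = np.log(I)
    w_all = (I / sig) ** 2  # σ_lnI = σI/I

    flags: list[str] = []

    def fit_slice(sel: np.ndarray):
        a, b, cov = _weighted_line(x_all[sel], y_all[sel], w_all[sel])
        return a, b, cov

    if window_policy == "fixed":
        if q_window is None:
            raise ValueError("fixed window policy requires q_window")
        sel = (q >= q_window[0]) & (q <= q_window[1])
    elif window_policy == "auto":
        qmax = q[min(len(q) - 1, max(min_points, len(q) // 3))]
        if q_window is not None:
            qmax = q_window[1]
        sel = q <= qmax
        for _ in range(60):
            if int(np.sum(sel)) < min_points:
                sel = q <= q[min_points - 1]
            a, b, _ = fit_slice(sel)
            if b >= 0:
                break
            rg = math.sqrt(-3.0 * b)
            new_qmax = qrg_limit / rg if rg > 0 else q[-1]
            new_sel = q <= new_qmax
            if int(np.sum(new_sel)) < min_points:
                new_sel = q <= q[min_points - 1]
            if np.array_equal(new_sel, sel):
                break
            sel = new_sel
    else:
        raise ValueError(f"unknown window_policy {window_policy!r}")

    if window_policy == "auto":
        # shrink the window while the residuals show a systematic run —
        # curvature beyond the Guinier regime that the qRg cap alone
        # cannot detect on low-noise data
        while int(np.sum(sel)) > min_points:
            a, b, _ = fit_slice(sel)
            resid = (y_all[sel] - (a + b * x_all[sel])) * np.sqrt(w_all[sel])
            if _runs_z(resid) >= -2.5:
                break
            idx = np.where(sel)[0]
            k = max(1, int(0.1 * len(idx)))
            sel = sel.copy()
            sel[idx[-k:]] = False

    if int(np.sum(sel)) < min_points:
        raise GuinierError("fit window holds fewer than %d points" % min_points)

    a, b, cov = fit_slice(sel)
    I0 = math.exp(a)
    I0_err = I0 * math.sqrt(max(cov[0, 0], 0.0))
    if b < 0:
        Rg = math.sqrt(-3.0 * b)
        Rg_err = 1.5 * math.sqrt(max(cov[1, 1], 0.0)) / Rg if Rg > 0 else float("inf")
        valid = True
    else:
        Rg, Rg_err, valid = float("nan"), float("nan"), False
        flags.append("positive_slope")

    resid = (y_all[sel] - (a + b * x_all[sel])) * np.sqrt(w_all[sel])
    z = _runs_z(resid)
    if z < -2.5:
        flags.append("systematic_residuals")

    q_used = q[sel]
    qrg_max = q_used[-1] * Rg if valid else float("nan")
    if valid and qrg_max > qrg_limit * 1.05:
        flags.append("qRg_exceeds_limit")
    return GuinierResult(
        I0=I0, I0_err=I0_err, Rg=Rg, Rg_err=Rg_err,
        q_window=(float(q_used[0]), float(q_used[-1])),
        n_points=int(np.sum(sel)), qRg_max=float(qrg_max), valid=valid,
        flags=flags, residual_runs_z=float(z),
    )


def contrast_series_guinier(
    curves: list[ScatteringCurve],
    qrg_limit: float = 1.3,
    match_points_pct: list[float] | None = None,
    low_contrast_window_pct: float = 3.0,
    **kwargs,
) -> list[GuinierResult]:
    """Guinier-fit every curve of a contrast series.

    Each curve must carry 'f_d2o' (fraction) in its metadata; curves whose
    solvent lies within low_contrast_window_pct of any supplied component
    match point are flagged 'near_match_point' (inflated errors expected).
    """
    results = []
    for curve in curves:
        if "f_d2o" not in curve.metadata:
            raise KeyError("curve metadata missing 'f_d2o'")
        res = guinier_fit(curve, qrg_limit=qrg_limit, **kwargs)
        f_pct = 100.0 * float(curve.metadata["f_d2o"])
        if match_points_pct and any(
            abs(f_pct - mp) <= low_contrast_window_pct for mp in match_points_pct
        ):
            res.flags.append("near_match_point")
        if res.I0_err > 0.3 * abs(res.I0):
            res.flags.append("low_signal")
        results.append(res)
    return results
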