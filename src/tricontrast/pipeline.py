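"""End-to-end contrast-variation analysis.

Chains the stages: per-curve Guinier fits → contrast-variation line →
oligomeric state → protein subtraction → volume fractions and lipid
count → Stuhrmann / parallel-axis R_g decomposition, and gathers
everything into a serialisable AnalysisReport with provenance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .contrast_series import (
    ContrastPoint,
    fit_cv_line,
    lipid_count,
    oligomeric_state,
    solve_volume_fractions,
    subtract_protein,
)
from .guinier import ScatteringCurve, contrast_series_guinier
from .sld_core import Component, ExchangeModel, match_point
from .stuhrmann import (
    ContrastRgPoint,
    contrast_fraction_X,
    mean_particle_contrast,
    parallel_axis_fit,
    stuhrmann_fit,
)


@dataclass
class AnalysisConfig:
    """Every policy knob of the pipeline, echoed into report provenance."""

    qrg_limit: float = 1.3
    window_policy: str = "auto"
    model_policy: str = "auto"  # Stuhrmann model selection
    low_contrast_fraction: float = 0.10
    include_D_term: bool = False
    lipid_mol_volume: tuple[float, float] = (1100.0, 1250.0)
    cmp_lipid: float | None = None  # None → from lipid component
    cmp_detergent: float | None = None
    round_copies: bool = False
    seed: int = 0

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["lipid_mol_volume"] = list(self.lipid_mol_volume)
        return d


@dataclass
class AnalysisReport:
    """Per-stage results plus provenance; JSON-serialisable."""

    guinier_table: list[dict]
    cv_line: dict
    decomposition: dict
    stuhrmann: dict
    parallel_axis: dict
    provenance: dict
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "guinier": self.guinier_table,
            "cv_line": self.cv_line,
            "decomposition": self.decomposition,
            "stuhrmann": self.stuhrmann,
            "parallel_axis": self.parallel_axis,
            "provenance": self.provenance,
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.as_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary_tsv(self, path: str | Path | None = None) -> str:
        """Human-readable key-number summary (TSV)."""
        d = self.decomposition
        rows = [("quantity", "value", "error", "units")]
        rows.append(("cmp_total", f"{self.cv_line['cmp_total_pctD2O']:.2f}",
                     f"{self.cv_line['cmp_total_err_pctD2O']:.2f}", "%D2O"))
        rows.append(("cmp_nonprotein", f"{d['cmp_nonprotein_pctD2O'][0]:.2f}",
                     f"{d['cmp_nonprotein_pctD2O'][1]:.2f}", "%D2O"))
        for key in ("protein", "lipid", "detergent"):
            v, e = d["volume_fractions"][key]
            rows.append((f"v_{key}", f"{100 * v:.1f}", f"{100 * e:.1f}", "%v/v"))
        rows.append(("oligomeric_state", f"{d['oligomeric_state'][0]:.2f}",
                     f"{d['oligomeric_state'][1]:.2f}", "copies"))
        lo, hi = d["lipid_count_range"]
        rows.append(("lipid_count", f"{lo:.0f}-{hi:.0f}", "", "molecules"))
        if self.parallel_axis:
            pa = self.parallel_axis
            rows.append(("Rg_protein", f"{pa['Rg_protein_A'][0]:.1f}",
                         f"{pa['Rg_protein_A'][1]:.1f}", "A"))
            rows.append(("Rg_nonprotein", f"{pa['Rg_nonprotein_A'][0]:.1f}",
                         f"{pa['Rg_nonprotein_A'][1]:.1f}", "A"))
        if self.stuhrmann:
            rows.append(("stuhrmann_alpha", f"{self.stuhrmann['alpha'][0]:.3e}",
                         f"{self.stuhrmann['alpha'][1]:.3e}", "unitless"))
        text = "\n".join("\t".join(r) for r in rows) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def run_full(
    curves: list[ScatteringCurve],
    protein: Component,
    lipid: Component,
    detergent: Component,
    exchange: ExchangeModel = ExchangeModel(),
    config: AnalysisConfig = None,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Run the whole analysis on an in-memory contrast series.

    Every curve must carry f_d2o, concentration_mg_ml, transmission,
    path_length_cm (and optionally intensity_scale) in its metadata.
    """
    cfg = config or AnalysisConfig()
    warn: list[str] = []
    if len(curves) < 3:
        raise ValueError("need at least 3 contrast points")

    xm = exchange
    cmp_p = match_point(protein, xm)
    cmp_l = cfg.cmp_lipid if cfg.cmp_lipid is not None else match_point(lipid, xm).value
    cmp_d = (
        cfg.cmp_detergent
        if cfg.cmp_detergent is not None
        else match_point(detergent, xm).value
    )

    # --- Guinier stage -----------------------------------------------------
    gres = contrast_series_guinier(
        curves,
        qrg_limit=cfg.qrg_limit,
        match_points_pct=[cmp_p.value, cmp_l, cmp_d],
        window_policy=cfg.window_policy,
    )
    points = []
    for curve, res in zip(curves, gres):
        md = curve.metadata
        for key in ("concentration_mg_ml", "transmission", "path_length_cm"):
            if key not in md:
                raise KeyError(f"curve metadata missing {key!r}")
        points.append(
            ContrastPoint(
                f_d2o=float(md["f_d2o"]),
                guinier=res,
                concentration=float(md["concentration_mg_ml"]),
                transmission=float(md["transmission"]),
                path_length=float(md["path_length_cm"]),
                wavelength=float(md.get("wavelength_A", 6.0)),
                intensity_scale=str(md.get("intensity_scale", "absolute")),
            )
        )
        for f in res.flags:
            warn.append(f"guinier f_d2o={md['f_d2o']}: {f}")

    # --- contrast-variation line ------------------------------------------
    M_W = protein.molar_mass
    line = fit_cv_line(points, M_W)
    warn += [f"cv_line: {f}" for f in line.flags]

    # --- oligomeric state, iterated once with the measured residual root ---
    # first pass with a provisional non-protein CMP from one-copy subtraction
    try:
        resid0, band0 = subtract_protein(line, protein, 1.0, xm)
    except ValueError as e:
        resid0 = band0 = None
        warn.append(f"subtract_protein: {e}")
    if band0 is not None:
        n_copies, n_err = oligomeric_state(line, protein, band0.value, xm)
        copies_used = round(n_copies) if cfg.round_copies else n_copies
        if copies_used <= 0:
            warn.append("oligomeric state non-positive; using 1 copy for subtraction")
            copies_used = 1.0
        residual, band = subtract_protein(line, protein, copies_used, xm)

        # --- volume fractions ----------------------------------------------
        decomp = solve_volume_fractions(
            line.cmp_total,
            band.value,
            protein,
            n_copies=copies_used,
            cmp_lipid=cmp_l,
            cmp_detergent=cmp_d,
            cmp_protein=cmp_p.value,
            xm=xm,
            cmp_total_err=line.cmp_total_err,
            cmp_nonprotein_err=residual.cmp_total_err,
            cmp_nonprotein_band=band,
        )
    else:
        # particle is protein within measurement error
        from .contrast_series import Decomposition, protein_excess_scattering_length
        from .sld_core import Banded

        b_theory = protein_excess_scattering_length(protein, 0.0, xm).value
        v0, v0_err = line.eval(0.0)
        n_copies = (v0 / b_theory) ** 2
        n_err = abs(n_copies) * 2.0 * v0_err / abs(v0) if v0 else 0.0
        copies_used = max(n_copies, 1.0)
        V_P = protein.dry_volume * copies_used
        decomp = Decomposition(
            v_P=1.0, v_L=0.0, v_D=0.0, v_P_err=0.0, v_L_err=0.0, v_D_err=0.0,
            V_total=V_P, V_P=V_P, V_L=0.0, V_D=0.0,
            cmp_total=line.cmp_total,
            cmp_nonprotein=Banded(line.cmp_total, line.cmp_total, line.cmp_total),
            cmp_nonprotein_err=float("nan"), n_copies=n_copies, n_copies_err=n_err,
        )
    decomp.n_copies = n_copies
    decomp.n_copies_err = n_err
    decomp.lipid_count = lipid_count(decomp, cfg.lipid_mol_volume)

    # --- Stuhrmann / parallel axis ----------------------------------------
    comps = [protein, lipid, detergent]
    vols = [decomp.V_P, decomp.V_L, decomp.V_D]
    rg_points = []
    for p, res in zip(points, gres):
        if not res.valid or not np.isfinite(res.Rg):
            continue
        drho = mean_particle_contrast(comps, vols, p.f_d2o, xm)
        try:
            X = contrast_fraction_X(comps, vols, p.f_d2o, xm)
        except ZeroDivisionError:
            X = float("nan")
        rg_points.append(
            ContrastRgPoint(p.f_d2o, res.Rg, res.Rg_err, drho.value, drho.err, X)
        )
    stu = pa = None
    try:
        stu = stuhrmann_fit(
            rg_points,
            model_policy=cfg.model_policy,
            low_contrast_fraction=cfg.low_contrast_fraction,
        )
    except Exception as e:  # noqa: BLE001 - stage failure is a report warning
        warn.append(f"stuhrmann: {e}")
    try:
        pa = parallel_axis_fit(
            rg_points,
            include_D=cfg.include_D_term,
            low_contrast_fraction=cfg.low_contrast_fraction,
        )
        warn += [f"parallel_axis: {f}" for f in pa.flags]
    except Exception as e:  # noqa: BLE001
        warn.append(f"parallel_axis: {e}")

    prov = {
        "version": __version__,
        "config": cfg.as_dict(),
        "exchange": {"fraction": xm.fraction, "low": xm.low, "high": xm.high},
        "component_cmps_pctD2O": {
            "protein": [cmp_p.value, cmp_p.low, cmp_p.high],
            "lipid": cmp_l,
            "detergent": cmp_d,
        },
        "protein_molar_mass": M_W,
        "n_contrast_points": len(points),
    }
    if provenance:
        prov.update(provenance)
    return AnalysisReport(
        guinier_table=[
            {"f_d2o": p.f_d2o, **res.as_dict()} for p, res in zip(points, gres)
        ],
        cv_line=line.as_dict(),
        decomposition=decomp.as_dict(),
        stuhrmann=stu.as_dict() if stu else {},
        parallel_axis=pa.as_dict() if pa else {},
        provenance=prov,
        warnings=warn,
    )


def run_full_from_files(
    samples_path: str | Path,
    components_path: str | Path,
    config: AnalysisConfig = None,
) -> AnalysisReport:
    """File-based entry point: TSV sample sheet + component YAML/JSON."""
    from .io import file_sha256, read_components, read_curve, read_sample_sheet

    samples_path = Path(samples_path)
    sheet = read_sample_sheet(samples_path)
    comps = read_components(components_path)
    for need in ("protein", "lipid", "detergent"):
        if need not in comps:
            raise KeyError(f"component file missing {need!r}")
    curves = []
    for _, row in sheet.iterrows():
        cpath = samples_path.parent / str(row["file"])
        curve = read_curve(cpath)
        curve.metadata.update(
            {
                "f_d2o": float(row["pct_d2o"]) / 100.0,
                "concentration_mg_ml": float(row["concentration_mg_ml"]),
                "transmission": float(row["transmission"]),
                "path_length_cm": float(row["path_length_cm"]),
                "wavelength_A": float(row["wavelength_A"]),
            }
        )
        curves.append(curve)
    prov = {
        "samples_sheet": str(samples_path),
        "input_hashes": {
            str(samples_path.name): file_sha256(samples_path),
            str(Path(components_path).name): file_sha256(components_path),
        },
    }
    return run_full(
        curves,
        comps["protein"],
        comps["lipid"],
        comps["detergent"],
        exchange=comps["exchange"],
        config=config,
        provenance=prov,
    )
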