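"""Reading and writing the pipeline's file formats.

Curves are plain ASCII (3 or 4 whitespace/comma-separated numeric columns:
q, I, σI[, Δq]) with '#' or free-text headers; sample sheets are TSV with
one row per contrast point; component definitions are YAML/JSON; reports
and manifests are JSON.  All formats are text — nothing binary.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contrast_series import WaterCalibration
from .guinier import ScatteringCurve
from .sld_core import Component, ExchangeModel, preset

SAMPLE_SHEET_COLUMNS = [
    "file",
    "pct_d2o",
    "concentration_mg_ml",
    "transmission",
    "path_length_cm",
    "wavelength_A",
]


class CurveFormatError(ValueError):
    """Malformed reduced-curve file; message names the offending row."""


def read_curve(path: str | Path) -> ScatteringCurve:
    """Read a reduced 1D curve from ASCII columns.

    Header lines (starting with '#' or containing no parseable numbers)
    are skipped; once data rows begin, any malformed row is an error
    reported with its 1-based line number.  Requires ≥ 5 data rows and
    strictly increasing q.
    """
    path = Path(path)
    rows: list[list[float]] = []
    ncols = None
    in_data = False
    meta: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*([\w.]+)\s*[:=]\s*(.+)$", line)
                if m:
                    key, val = m.group(1), m.group(2).strip()
                    try:
                        meta[key] = float(val)
                    except ValueError:
                        meta[key] = val
                continue
            parts = re.split(r"[,\s]+", line)
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                if in_data:
                    raise CurveFormatError(
                        f"{path.name}: malformed data row at line {lineno}: {line!r}"
                    ) from None
                continue  # free-text header
            if len(vals) not in (3, 4):
                raise CurveFormatError(
                    f"{path.name}: expected 3 or 4 columns at line {lineno}, got {len(vals)}"
                )
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise CurveFormatError(
                    f"{path.name}: inconsistent column count at line {lineno}"
                )
            in_data = True
            rows.append(vals)
    if len(rows) < 5:
        raise CurveFormatError(f"{path.name}: fewer than 5 data rows")
    arr = np.array(rows)
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise CurveFormatError(f"{path.name}: q column not strictly increasing")
    dq = arr[:, 3] if arr.shape[1] == 4 else None
    return ScatteringCurve(arr[:, 0], arr[:, 1], arr[:, 2], dq=dq, metadata=meta)


def write_curve(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve with a self-describing header; roundtrips through
    read_curve to full printed precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# reduced 1D SANS curve\n")
        fh.write("# columns: q[1/A] I[1/cm] sigma_I[1/cm]")
        fh.write(" dq[1/A]\n" if curve.dq is not None else "\n")
        for key, val in curve.metadata.items():
            fh.write(f"# {key}: {val}\n")
        cols = [curve.q, curve.I, curve.sigma_I]
        if curve.dq is not None:
            cols.append(curve.dq)
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.10e}" for v in row) + "\n")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample sheet; raises naming any missing column."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"sample sheet missing column(s): {', '.join(missing)}")
    return df


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def build_component(spec: dict, name: str) -> Component:
    """Build a Component from a config mapping.

    Accepts {'preset': name}, {'sequences': [...]} (protein), or
    {'formula': str, 'n_exchangeable_H': int, 'vbar'|'dry_volume': float}.
    """
    if "preset" in spec:
        return preset(spec["preset"])
    if "sequences" in spec:
        return Component.protein_from_sequences(
            spec.get("name", name),
            list(spec["sequences"]),
            n_copies=int(spec.get("n_copies", 1)),
            vbar=spec.get("vbar"),
        )
    if "formula" in spec:
        return Component.from_formula(
            spec.get("name", name),
            spec["formula"],
            float(spec.get("n_exchangeable_H", 0)),
            vbar=spec.get("vbar"),
            dry_volume=spec.get("dry_volume"),
            role=spec.get("role", name if name in ("protein", "lipid", "detergent") else "other"),
        )
    raise KeyError(f"component {name!r} needs 'preset', 'sequences' or 'formula'")


def read_components(path: str | Path) -> dict:
    """Read a component-definition file (YAML or JSON).

    Returns {'protein': Component, 'lipid': Component, 'detergent':
    Component, 'exchange': ExchangeModel, 'calibration': WaterCalibration,
    'raw': original mapping}.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    out: dict = {"raw": raw}
    for name in ("protein", "lipid", "detergent"):
        if name in raw:
            out[name] = build_component(raw[name], name)
    xs = raw.get("exchange", {})
    out["exchange"] = ExchangeModel(
        xs.get("fraction", 0.80), xs.get("low", 0.70), xs.get("high", 0.90)
    )
    cal = raw.get("calibration", {})
    out["calibration"] = WaterCalibration(
        cal.get("T_water", 0.53), cal.get("f_lambda", 0.8), cal.get("t_water", 0.1)
    )
    return out


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_suite(bundle, outdir: str | Path) -> dict:
    """Write a simulated FixtureBundle to disk: one .dat per curve, a
    sample sheet, a component YAML and a ground-truth manifest.  Returns
    the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, curve in enumerate(bundle.curves):
        fname = f"{bundle.scenario}_{i:02d}_{100 * curve.metadata['f_d2o']:.0f}pct.dat"
        write_curve(curve, outdir / fname)
        rows.append(
            {
                "file": fname,
                "pct_d2o": 100.0 * curve.metadata["f_d2o"],
                "concentration_mg_ml": curve.metadata["concentration_mg_ml"],
                "transmission": curve.metadata["transmission"],
                "path_length_cm": curve.metadata["path_length_cm"],
                "wavelength_A": curve.metadata["wavelength_A"],
            }
        )
    sheet = outdir / "samples.tsv"
    write_sample_sheet(pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS), sheet)
    comp_path = outdir / "components.yaml"
    with open(comp_path, "w") as fh:
        yaml.safe_dump(bundle.components, fh)
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    return {
        "samples": sheet,
        "components": comp_path,
        "manifest": manifest_path,
        "outdir": outdir,
    }
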