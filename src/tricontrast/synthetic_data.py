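"""Forward simulation of absolute-scale SANS contrast series.

Generates reduced 1D curves for core–shell (and displaced two-sphere)
particles built from real chemical components, across a grid of D₂O
fractions, with counting noise — the statistical structure a contrast-
variation experiment on a detergent-solubilised membrane-protein complex
produces.  Every scenario carries a ground-truth manifest so the whole
analysis pipeline can be verified end to end without external data.

Scattering model: monodisperse particles, I(q) = n·A(q)² with
A(q) = Σ_regions Δρ_i·[V(R_i)F(qR_i) − V(R_{i−1})F(qR_{i−1})] and the
sphere amplitude F(x) = 3(sin x − x·cos x)/x³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import AVOGADRO
from .contrast_series import WaterCalibration
from .guinier import ScatteringCurve
from .sld_core import (
    AtomicComposition,
    Component,
    ExchangeModel,
    component_sld,
    match_point,
    mixture_match_point,
    solvent_sld,
)
from .stuhrmann import shell_rg, sphere_rg, two_phase_rg2

# Repeating 50-residue unit with a membrane-protein-like composition
# (hydrophobic-rich); 45 repeats give a ~247 kDa pseudo-protein standing in
# for a large multi-subunit membrane complex.
_MEMBRANE_UNIT = "LAGVFILVAGLSTFAWLIPGMVLYSDKQERHTNAILGVFAGTLSMEKDRC"
HTL_LIKE_SEQUENCE = _MEMBRANE_UNIT * 45


def mix_components(parts: list[tuple[Component, float]], name: str = "mixture") -> Component:
    """Volume-weighted pseudo-component.

    parts: (component, volume_fraction).  The average formula unit is the
    mole-weighted combination whose per-unit volumes reproduce the target
    volume ratio.
    """
    if not parts:
        raise ValueError("empty mixture")
    total_v = sum(v for _, v in parts)
    counts: dict[str, float] = {}
    n_exch = 0.0
    mass = 0.0
    vol = 0.0
    for c, v in parts:
        moles = (v / total_v) / c.dry_volume  # formula units per unit volume
        for el, n in c.composition.element_counts.items():
            counts[el] = counts.get(el, 0.0) + moles * n
        n_exch += moles * c.composition.n_exchangeable_H
        mass += moles * c.molar_mass
        vol += moles * c.dry_volume
    return Component(
        name,
        AtomicComposition(counts, n_exch),
        vol,
        mass,
        role="other",
    )


@dataclass
class Region:
    """One radial region of the particle, bound to a chemical component."""

    component: Component
    volume: float  # Å³
    center_offset: float = 0.0  # Å, along a common axis

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("region volume must be positive")


@dataclass
class ParticleModel:
    """Concentric (or centre-offset) spherical regions, innermost first.

    reference_molar_mass is the molar mass the analysis divides by — the
    protein mass per particle when protein is present (that is what the
    sample sheet's mg/ml concentration refers to), else the total mass.
    """

    regions: list[Region]
    n_copies: float = 1.0
    name: str = "particle"

    @property
    def total_volume(self) -> float:
        return sum(r.volume for r in self.regions)

    @property
    def protein_molar_mass(self) -> float:
        m = sum(
            r.component.molar_mass / r.component.dry_volume * r.volume
            for r in self.regions
            if r.component.role == "protein"
        )
        return m

    @property
    def reference_molar_mass(self) -> float:
        m = self.protein_molar_mass
        if m > 0:
            return m
        return sum(
            r.component.molar_mass / r.component.dry_volume * r.volume
            for r in self.regions
        )

    def concentric(self) -> bool:
        return all(r.center_offset == 0.0 for r in self.regions)


@dataclass
class SimulationConfig:
    """Contrast grid, q grid, concentration and noise model."""

    f_d2o_grid: tuple[float, ...] = (0.0, 0.10, 0.20, 0.30, 0.45, 0.60, 0.80, 1.00)
    q_min: float = 0.003  # Å⁻¹
    q_max: float = 0.06
    n_q: int = 120
    concentration: float = 2.0  # mg/ml of the reference (protein) component
    noise_rel_I0: float = 0.05  # relative σ at q = 0
    noise_floor: float = 1e-5  # cm⁻¹
    seed: int = 0
    transmission: float = 0.7
    path_length: float = 0.1  # cm
    wavelength: float = 6.0  # Å
    calibration: WaterCalibration = field(default_factory=WaterCalibration)
    intensity_scale: str = "absolute"  # or "water_ratio"
    exchange: ExchangeModel = field(default_factory=ExchangeModel)

    @property
    def q(self) -> np.ndarray:
        return np.linspace(self.q_min, self.q_max, self.n_q)


def _sphere_amplitude(qR: np.ndarray) -> np.ndarray:
    """3(sin x − x cos x)/x³, with the x→0 limit handled."""
    out = np.ones_like(qR)
    small = np.abs(qR) < 1e-6
    x = qR[~small]
    out[~small] = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    return out


def _region_amplitudes(model: ParticleModel, f_d2o: float, q: np.ndarray, xm: ExchangeModel):
    """Per-region excess amplitudes Δρ_i·V_i·F_i(q) in cm, plus offsets."""
    rho_s = solvent_sld(f_d2o)
    amps = []
    offsets = []
    if model.concentric():
        cum_v = 0.0
        prev_term = np.zeros_like(q)
        prev_R = 0.0
        for r in model.regions:
            cum_v += r.volume
            R = (3.0 * cum_v / (4.0 * math.pi)) ** (1.0 / 3.0)
            term = cum_v * _sphere_amplitude(q * R)
            drho = component_sld(r.component, f_d2o, xm).value - rho_s
            # Δρ·V [Å⁻²·Å³ = Å] → cm
            amps.append(drho * (term - prev_term) * 1e-8)
            offsets.append(0.0)
            prev_term = term
            prev_R = R
    else:
        for r in model.regions:
            R = (3.0 * r.volume / (4.0 * math.pi)) ** (1.0 / 3.0)
            drho = component_sld(r.component, f_d2o, xm).value - rho_s
            amps.append(drho * r.volume * _sphere_amplitude(q * R) * 1e-8)
            offsets.append(r.center_offset)
    return amps, offsets


def forward_intensity_zero(model: ParticleModel, f_d2o: float, cfg: SimulationConfig) -> float:
    """Noise-free I(0) in cm⁻¹ — direct Σ Δρ_i V_i arithmetic."""
    amps, _ = _region_amplitudes(model, f_d2o, np.zeros(1), cfg.exchange)
    total = sum(float(a[0]) for a in amps)
    n_density = cfg.concentration * 1e-3 * AVOGADRO / model.reference_molar_mass
    return n_density * total**2


def true_rhoV(model: ParticleModel, f_d2o: float, xm: ExchangeModel) -> float:
    """Signed per-particle excess scattering length Σ Δρ_i V_i, cm."""
    amps, _ = _region_amplitudes(model, f_d2o, np.zeros(1), xm)
    return sum(float(a[0]) for a in amps)


def true_rg(model: ParticleModel, f_d2o: float, xm: ExchangeModel) -> float:
    """Contrast-weighted R_g of the particle at one solvent, Å (closed form,
    concentric or two offset regions)."""
    rho_s = solvent_sld(f_d2o)
    if model.concentric():
        cum = 0.0
        radii = []
        for r in model.regions:
            cum += r.volume
            radii.append((3.0 * cum / (4.0 * math.pi)) ** (1.0 / 3.0))
        num = 0.0
        den = 0.0
        prev_R = 0.0
        for r, R in zip(model.regions, radii):
            drho = component_sld(r.component, f_d2o, xm).value - rho_s
            rg2 = shell_rg(prev_R, R) ** 2
            num += drho * r.volume * rg2
            den += drho * r.volume
            prev_R = R
        return math.sqrt(num / den) if num / den > 0 else float("nan")
    if len(model.regions) == 2:
        a, b = model.regions
        Ra = (3.0 * a.volume / (4.0 * math.pi)) ** (1.0 / 3.0)
        Rb = (3.0 * b.volume / (4.0 * math.pi)) ** (1.0 / 3.0)
        da = component_sld(a.component, f_d2o, xm).value - rho_s
        db = component_sld(b.component, f_d2o, xm).value - rho_s
        D = abs(b.center_offset - a.center_offset)
        rg2 = two_phase_rg2(
            sphere_rg(Ra) ** 2, da, a.volume, sphere_rg(Rb) ** 2, db, b.volume, D
        )
        return math.sqrt(rg2) if rg2 > 0 else float("nan")
    raise NotImplementedError("closed-form Rg only for concentric or two offset regions")


def simulate_curve(
    model: ParticleModel,
    f_d2o: float,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ScatteringCurve:
    """Simulate one reduced curve at a single D₂O fraction.

    Noise: σ(q) = max(noise_rel_I0·√(I(0)·I(q)), floor) — counting noise
    that is noise_rel_I0 relative at q = 0 and scales with √I.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    q = cfg.q
    amps, offsets = _region_amplitudes(model, f_d2o, q, cfg.exchange)
    I = np.zeros_like(q)
    for i, Ai in enumerate(amps):
        for j, Aj in enumerate(amps):
            d = abs(offsets[i] - offsets[j])
            cross = np.sinc(q * d / math.pi) if d > 0 else 1.0
            I += Ai * Aj * cross
    n_density = cfg.concentration * 1e-3 * AVOGADRO / model.reference_molar_mass
    I = n_density * I
    I0 = float(forward_intensity_zero(model, f_d2o, cfg))
    sigma = np.maximum(
        cfg.noise_rel_I0 * np.sqrt(np.maximum(abs(I0) * np.abs(I), 0.0)),
        cfg.noise_floor,
    )
    if cfg.noise_rel_I0 > 0:
        I = I + rng.normal(0.0, 1.0, size=len(q)) * sigma
    if cfg.intensity_scale == "water_ratio":
        k = cfg.calibration.absolute_factor(cfg.transmission, cfg.path_length)
        I, sigma = I / k, sigma / k
    meta = {
        "f_d2o": f_d2o,
        "concentration_mg_ml": cfg.concentration,
        "transmission": cfg.transmission,
        "path_length_cm": cfg.path_length,
        "wavelength_A": cfg.wavelength,
        "intensity_scale": cfg.intensity_scale,
    }
    return ScatteringCurve(q, I, sigma, metadata=meta)


def simulate_series(
    model: ParticleModel, cfg: SimulationConfig
) -> list[ScatteringCurve]:
    """One curve per D₂O fraction in the grid; a single seeded RNG drives
    the whole series, so a fixed seed gives byte-identical output."""
    rng = np.random.default_rng(cfg.seed)
    return [simulate_curve(model, f, cfg, rng) for f in cfg.f_d2o_grid]


# ---------------------------------------------------------------------------
# Scenario fixtures
# ---------------------------------------------------------------------------

SCENARIOS = (
    "htl_native_like",
    "htl_crosslinked_like",
    "homogeneous",
    "displaced_centres",
    "protein_only",
)


@dataclass
class FixtureBundle:
    """Curves + component definitions + ground-truth manifest."""

    scenario: str
    model: ParticleModel
    config: SimulationConfig
    curves: list[ScatteringCurve]
    components: dict
    manifest: dict


def _three_component_model(
    v_P: float, v_L: float, v_D: float, protein: Component,
    lipid: Component, detergent: Component, n_copies: float = 1.0,
) -> ParticleModel:
    """Core–shell particle: mixed lipid/detergent core, protein shell,
    with region volumes set by the target v/v fractions and the absolute
    protein volume."""
    V_P = protein.dry_volume * n_copies
    V_total = V_P / v_P
    core = mix_components(
        [(lipid, v_L), (detergent, v_D)], name="lipid_detergent_core"
    )
    V_core = V_total - V_P
    return ParticleModel(
        regions=[Region(core, V_core), Region(protein, V_P)],
        n_copies=n_copies,
        name="core_shell",
    )


def make_fixture_suite(
    scenario: str,
    seed: int = 0,
    noise_rel_I0: float = 0.05,
    f_d2o_grid: tuple[float, ...] | None = None,
    n_copies: float = 1.0,
) -> FixtureBundle:
    """Build a named scenario with its ground-truth manifest.

    Scenarios: htl_native_like (33/41/26 v/v protein/lipid/detergent),
    htl_crosslinked_like (41/25/33), homogeneous, displaced_centres,
    protein_only.
    """
    from .sld_core import preset  # local to keep import graph flat

    if scenario not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario!r}")
    xm = ExchangeModel()
    protein = Component.protein_from_sequences("htl_like_protein", [HTL_LIKE_SEQUENCE])
    lipid = preset("ecoli_inner_membrane_lipid")
    detergent = preset("ddm")
    cfg = SimulationConfig(seed=seed, noise_rel_I0=noise_rel_I0)
    if f_d2o_grid is not None:
        cfg = replace(cfg, f_d2o_grid=tuple(f_d2o_grid))

    fractions = None
    if scenario in ("htl_native_like", "htl_crosslinked_like"):
        fractions = (
            (0.33, 0.41, 0.26) if scenario == "htl_native_like" else (0.41, 0.25, 0.33)
        )
        v_P, v_L, v_D = fractions
        if n_copies != 1.0:
            protein_n = Component.protein_from_sequences(
                "htl_like_protein", [HTL_LIKE_SEQUENCE], n_copies=int(n_copies)
            )
        else:
            protein_n = protein
        model = _three_component_model(v_P, v_L, v_D, protein_n, lipid, detergent)
    elif scenario == "homogeneous":
        model = ParticleModel([Region(protein, protein.dry_volume)], name="homogeneous")
    elif scenario == "protein_only":
        model = ParticleModel([Region(protein, protein.dry_volume)], name="protein_only")
    elif scenario == "displaced_centres":
        model = ParticleModel(
            [
                Region(lipid, 2.0e5, center_offset=0.0),
                Region(protein, protein.dry_volume, center_offset=60.0),
            ],
            name="displaced",
        )

    curves = simulate_series(model, cfg)

    cmp_p = match_point(protein, xm).value
    cmp_l = match_point(lipid, xm).value
    cmp_d = match_point(detergent, xm).value
    manifest: dict = {
        "scenario": scenario,
        "seed": seed,
        "n_copies": n_copies,
        "cmp_protein_pct": cmp_p,
        "cmp_lipid_pct": cmp_l,
        "cmp_detergent_pct": cmp_d,
        "protein_molar_mass": protein.molar_mass * n_copies,
        "reference_molar_mass": model.reference_molar_mass,
        "total_volume_A3": model.total_volume,
        "rg_by_f_d2o": {
            str(f): true_rg(model, f, xm) for f in cfg.f_d2o_grid
        },
    }
    if fractions is not None:
        v_P, v_L, v_D = fractions
        manifest.update(
            {
                "fractions": {"protein": v_P, "lipid": v_L, "detergent": v_D},
                "cmp_nonprotein_pct": mixture_match_point(
                    [(cmp_l, v_L), (cmp_d, v_D)]
                ),
                "cmp_total_pct": mixture_match_point(
                    [(cmp_p, v_P), (cmp_l, v_L), (cmp_d, v_D)]
                ),
                "rg_protein_shell_A": shell_rg(
                    (3 * model.regions[0].volume / (4 * math.pi)) ** (1 / 3),
                    (3 * model.total_volume / (4 * math.pi)) ** (1 / 3),
                ),
                "rg_core_A": sphere_rg(
                    (3 * model.regions[0].volume / (4 * math.pi)) ** (1 / 3)
                ),
            }
        )
    elif scenario in ("homogeneous", "protein_only"):
        manifest["fractions"] = {"protein": 1.0, "lipid": 0.0, "detergent": 0.0}
        manifest["cmp_total_pct"] = cmp_p
        R = (3 * model.total_volume / (4 * math.pi)) ** (1 / 3)
        manifest["rg_A"] = sphere_rg(R)
    else:  # displaced_centres
        manifest["centre_separation_A"] = 60.0

    components = {
        "protein": {
            "name": "htl_like_protein",
            "sequences": [HTL_LIKE_SEQUENCE],
            "n_copies": n_copies,
        },
        "lipid": {"preset": "ecoli_inner_membrane_lipid"},
        "detergent": {"preset": "ddm"},
        "exchange": {"fraction": xm.fraction, "low": xm.low, "high": xm.high},
    }
    return FixtureBundle(scenario, model, cfg, curves, components, manifest)
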