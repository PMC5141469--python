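"""Neutron scattering lengths, SLDs and contrast match points.

The contrast-variation experiment rests on one piece of arithmetic: every
chemical species has a coherent scattering length that varies *linearly*
with the solvent D₂O fraction, because the only f_D₂O-dependent term is the
exchange of labile hydrogens for deuterium.  The solvent scattering-length
density is likewise linear in f_D₂O.  The contrast match point (CMP) of a
component is the intersection of these two lines, and the CMP of any
volume-weighted mixture is the volume-weighted mean of the component CMPs.

This module provides the component model (atomic compositions, protein
sequences, presets for DDM and an E. coli inner-membrane lipid blend), the
labile-hydrogen exchange model with its uncertainty band, and the match
point / mixing algebra used by the decomposition stage.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

from .constants import (
    ATOMIC_MASS,
    AVOGADRO,
    B_EXCHANGE_FM,
    COHERENT_B_FM,
    DDM_VBAR,
    FM_PER_ANGSTROM,
    PROTEIN_VBAR_FALLBACK,
    RESIDUES,
    SLD_D2O,
    SLD_H2O,
)


class UnknownElementError(KeyError):
    """Element symbol absent from the scattering-length table."""


class UnknownResidueError(ValueError):
    """Amino-acid one-letter code not in the residue table."""


class NoMatchPointError(ValueError):
    """Component and solvent SLD lines are parallel: no crossing exists."""


@dataclass(frozen=True)
class Banded:
    """A value with an asymmetric uncertainty band [low, high].

    Used wherever the labile-hydrogen exchange band (rather than counting
    statistics) dominates the uncertainty.
    """

    value: float
    low: float
    high: float

    def __post_init__(self):
        if not (min(self.low, self.high) <= self.value <= max(self.low, self.high)):
            object.__setattr__(self, "low", min(self.low, self.value))
            object.__setattr__(self, "high", max(self.high, self.value))

    @property
    def err(self) -> float:
        """Symmetrised half-width of the band."""
        return 0.5 * abs(self.high - self.low)


@dataclass(frozen=True)
class ExchangeModel:
    """Fraction of labile hydrogens exchanged for D at f_D2O = 1.

    Membrane-protein complexes never reach complete exchange on experimental
    timescales; the default central value 0.80 with a 0.70–0.90 band is the
    conventional range for solvent-exposed biomolecules.
    """

    fraction: float = 0.80
    low: float = 0.70
    high: float = 0.90

    def __post_init__(self):
        if not (0.0 <= self.low <= self.fraction <= self.high <= 1.0):
            raise ValueError(
                f"require 0 <= low <= fraction <= high <= 1, got "
                f"{self.low}/{self.fraction}/{self.high}"
            )


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse a Hill-style formula string ("C24H46O11") into element counts."""
    counts: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        pos = m.end()
        el, n = m.group(1), m.group(2)
        if el not in ATOMIC_MASS:
            raise UnknownElementError(el)
        counts[el] = counts.get(el, 0.0) + (float(n) if n else 1.0)
    if pos != len(formula) or not counts:
        raise ValueError(f"malformed formula {formula!r}")
    return counts


@dataclass(frozen=True)
class AtomicComposition:
    """Element counts of one formula unit plus its labile-hydrogen count.

    Counts may be fractional (average compositions of mixtures).
    """

    element_counts: dict[str, float]
    n_exchangeable_H: float = 0.0

    def __post_init__(self):
        if any(v < 0 for v in self.element_counts.values()):
            raise ValueError("negative element count")
        if self.n_exchangeable_H < 0:
            raise ValueError("negative exchangeable-H count")
        n_h = self.element_counts.get("H", 0.0)
        if self.n_exchangeable_H > n_h + 1e-9:
            raise ValueError("more exchangeable H than total H")

    @classmethod
    def from_formula(cls, formula: str, n_exchangeable_H: float = 0.0) -> "AtomicComposition":
        return cls(parse_formula(formula), n_exchangeable_H)

    @property
    def molar_mass(self) -> float:
        """Formula mass, g/mol."""
        return sum(n * ATOMIC_MASS[el] for el, n in self.element_counts.items())

    def scattering_length_fm(self) -> float:
        """Sum of coherent scattering lengths (all H protiated), fm."""
        try:
            return sum(n * COHERENT_B_FM[el] for el, n in self.element_counts.items())
        except KeyError as e:  # pragma: no cover - mapping shared with masses
            raise UnknownElementError(str(e)) from e

    def combine(self, other: "AtomicComposition", w_self: float, w_other: float) -> "AtomicComposition":
        """Weighted sum of two compositions (weights in formula units)."""
        counts: dict[str, float] = {}
        for src, w in ((self, w_self), (other, w_other)):
            for el, n in src.element_counts.items():
                counts[el] = counts.get(el, 0.0) + w * n
        return AtomicComposition(
            counts, w_self * self.n_exchangeable_H + w_other * other.n_exchangeable_H
        )


@dataclass(frozen=True)
class Component:
    """A chemical species taking part in the particle.

    dry_volume is the solvent-excluded volume of one formula unit in Å³;
    for proteins it comes from the residue-volume table, for detergents and
    lipids from molar mass × partial specific volume.
    """

    name: str
    composition: AtomicComposition
    dry_volume: float
    molar_mass: float
    role: str = "other"

    def __post_init__(self):
        if self.dry_volume <= 0:
            raise ValueError("dry_volume must be positive")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        if self.role not in ("protein", "lipid", "detergent", "other"):
            raise ValueError(f"unknown role {self.role!r}")

    @classmethod
    def from_formula(
        cls,
        name: str,
        formula: str,
        n_exchangeable_H: float = 0.0,
        *,
        vbar: float | None = None,
        dry_volume: float | None = None,
        role: str = "other",
    ) -> "Component":
        comp = AtomicComposition.from_formula(formula, n_exchangeable_H)
        m = comp.molar_mass
        if dry_volume is None:
            if vbar is None:
                raise ValueError("need vbar or dry_volume")
            dry_volume = m * vbar / AVOGADRO * 1e24  # ml/mol -> Å³ per unit
        return cls(name, comp, dry_volume, m, role)

    @classmethod
    def protein_from_sequences(
        cls, name: str, sequences: list[str], *, n_copies: int = 1, vbar: float | None = None
    ) -> "Component":
        """Protein component from one-letter sequences (one per chain).

        The dry volume defaults to the summed residue-table volumes; passing
        vbar overrides with molar mass × vbar.
        """
        comp = protein_composition_from_sequence(sequences)
        if n_copies != 1:
            comp = AtomicComposition(
                {el: n * n_copies for el, n in comp.element_counts.items()},
                comp.n_exchangeable_H * n_copies,
            )
        m = comp.molar_mass
        if vbar is not None:
            vol = m * vbar / AVOGADRO * 1e24
        else:
            vol = n_copies * protein_volume_from_sequence(sequences)
        return cls(name, comp, vol, m, role="protein")


def solvent_sld(f_d2o: float) -> float:
    """Solvent SLD in Å⁻² for a H₂O/D₂O mixture of D₂O volume fraction f.

    Linear between the pure-water endpoints; raises for f outside [0, 1].
    """
    if not 0.0 <= f_d2o <= 1.0:
        raise ValueError(f"f_d2o must be in [0, 1], got {f_d2o}")
    return SLD_H2O + f_d2o * (SLD_D2O - SLD_H2O)


def solvent_zero_sld_fraction() -> float:
    """D₂O fraction at which the solvent SLD crosses zero (≈ 8% D₂O)."""
    return -SLD_H2O / (SLD_D2O - SLD_H2O)


def component_scattering_length(
    c: Component, f_d2o: float, xm: ExchangeModel = ExchangeModel()
) -> Banded:
    """Coherent scattering length of one formula unit at f_D₂O, in fm.

    b(f) = Σ n_el·b_el + n_exch · exchange_fraction · f · (b_D − b_H).
    The band covers the exchange-model low/high fractions.
    """
    if not c.composition.element_counts:
        raise ValueError("empty composition")
    b0 = c.composition.scattering_length_fm()
    n_ex = c.composition.n_exchangeable_H

    def at(frac: float) -> float:
        return b0 + n_ex * frac * f_d2o * B_EXCHANGE_FM

    return Banded(at(xm.fraction), at(xm.low), at(xm.high))


def component_sld_line(
    c: Component, xm: ExchangeModel = ExchangeModel(), exchange_fraction: float | None = None
) -> tuple[float, float]:
    """(intercept, slope) of the component SLD in Å⁻² as a function of f_D₂O."""
    frac = xm.fraction if exchange_fraction is None else exchange_fraction
    b0 = c.composition.scattering_length_fm()
    intercept = b0 * FM_PER_ANGSTROM / c.dry_volume
    slope = (
        c.composition.n_exchangeable_H * frac * B_EXCHANGE_FM * FM_PER_ANGSTROM / c.dry_volume
    )
    return intercept, slope


def component_sld(c: Component, f_d2o: float, xm: ExchangeModel = ExchangeModel()) -> Banded:
    """Component SLD at f_D₂O, Å⁻², with exchange band."""
    b = component_scattering_length(c, f_d2o, xm)
    k = FM_PER_ANGSTROM / c.dry_volume
    return Banded(b.value * k, b.low * k, b.high * k)


def match_point(c: Component, xm: ExchangeModel = ExchangeModel()) -> Banded:
    """Contrast match point of a component, in % D₂O.

    Solves component SLD(f) = solvent SLD(f); both sides are linear in f.
    Values outside [0, 100] are returned with a warning (the lines cross
    outside the physical solvent range).
    """

    def root(frac: float) -> float:
        a, b = component_sld_line(c, xm, exchange_fraction=frac)
        s0, s1 = SLD_H2O, SLD_D2O - SLD_H2O
        denom = b - s1
        if abs(denom) < 1e-9 * abs(s1):
            raise NoMatchPointError(c.name)
        return 100.0 * (s0 - a) / denom

    res = Banded(root(xm.fraction), root(xm.low), root(xm.high))
    if not 0.0 <= res.value <= 100.0:
        warnings.warn(
            f"match point of {c.name} ({res.value:.1f}% D2O) lies outside 0-100%",
            stacklevel=2,
        )
    return res


def protein_composition_from_sequence(sequences: list[str] | str) -> AtomicComposition:
    """Atomic composition of a (multi-chain) protein from 1-letter sequences.

    Residue-table summation; each chain gains one water for its free
    termini, and three additional labile hydrogens (N-terminal amine plus
    C-terminal hydroxyl).
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    counts: dict[str, float] = {}
    n_exch = 0.0
    for seq in sequences:
        seq = seq.strip().upper()
        if not seq:
            raise UnknownResidueError("empty sequence")
        for aa in seq:
            try:
                entry = RESIDUES[aa]
            except KeyError:
                raise UnknownResidueError(f"unknown residue code {aa!r}") from None
            for el, n in entry["formula"].items():
                counts[el] = counts.get(el, 0.0) + n
            n_exch += entry["n_exch"]
        # free termini: + H2O per chain, 2 amine H + 1 hydroxyl H labile
        counts["H"] = counts.get("H", 0.0) + 2
        counts["O"] = counts.get("O", 0.0) + 1
        n_exch += 3
    return AtomicComposition(counts, n_exch)


def protein_volume_from_sequence(sequences: list[str] | str) -> float:
    """Dry protein volume, Å³, from the residue-volume table (+ one water
    volume per chain for the termini)."""
    if isinstance(sequences, str):
        sequences = [sequences]
    vol = 0.0
    for seq in sequences:
        seq = seq.strip().upper()
        for aa in seq:
            try:
                vol += RESIDUES[aa]["volume"]
            except KeyError:
                raise UnknownResidueError(f"unknown residue code {aa!r}") from None
        vol += 29.9  # one water per chain termini
    return vol


def protein_vbar_from_sequence(sequences: list[str] | str) -> float:
    """Partial specific volume, ml/g, implied by the residue volume table."""
    comp = protein_composition_from_sequence(sequences)
    vol = protein_volume_from_sequence(sequences)
    return vol * AVOGADRO * 1e-24 / comp.molar_mass


def mixture_match_point(parts: list[tuple]) -> float:
    """Volume-weighted mean CMP of a mixture, % D₂O.

    parts: (component_or_cmp, volume_fraction) pairs.  Components are
    converted with their default exchange model; plain numbers are taken as
    CMPs in % D₂O.  Fractions are renormalised to sum to 1.
    """
    if not parts:
        raise ValueError("empty mixture")
    cmps, weights = [], []
    for item, w in parts:
        if w < 0:
            raise ValueError("negative volume fraction")
        cmps.append(match_point(item).value if isinstance(item, Component) else float(item))
        weights.append(float(w))
    total = sum(weights)
    if total <= 0:
        raise ValueError("volume fractions sum to zero")
    return sum(c * w for c, w in zip(cmps, weights)) / total


def solve_mixing_fraction(cmp_total: float, cmp_a: float, cmp_b: float) -> float:
    """Volume fraction of component a in a two-component mixture whose
    volume-weighted CMP is cmp_total.  Clamped to [0, 1] with a warning if
    the inputs are inconsistent."""
    if cmp_a == cmp_b:
        raise ZeroDivisionError("component CMPs are equal: mixture is degenerate")
    f = (cmp_total - cmp_b) / (cmp_a - cmp_b)
    if not 0.0 <= f <= 1.0:
        warnings.warn(f"mixing fraction {f:.3f} outside [0, 1]; clamped", stacklevel=2)
        f = min(1.0, max(0.0, f))
    return f


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# E. coli inner-membrane lipid blend, % by weight.  Headgroup composition
# of the inner membrane is dominated by PE with PG and cardiolipin;
# representative molecular species carry palmitoyl/oleoyl (and for CL
# tetra-oleoyl) acyl chains.
_ECOLI_LIPID_MIX = [
    # (name, formula, exchangeable H, vbar ml/g, weight %)
    ("POPE", "C39H76NO8P", 3, 0.965, 75.0),
    ("POPG", "C40H77O10P", 2, 0.960, 20.0),
    ("TOCL", "C81H142O17P2", 1, 0.920, 5.0),
]


def _average_lipid() -> Component:
    mole = []
    for name, formula, nex, vbar, wt in _ECOLI_LIPID_MIX:
        comp = AtomicComposition.from_formula(formula, nex)
        m = comp.molar_mass
        mole.append((comp, m, vbar, wt / m))
    x_total = sum(x for *_, x in mole)
    counts: dict[str, float] = {}
    n_exch = 0.0
    mass = 0.0
    vol = 0.0
    for comp, m, vbar, x in mole:
        w = x / x_total
        for el, n in comp.element_counts.items():
            counts[el] = counts.get(el, 0.0) + w * n
        n_exch += w * comp.n_exchangeable_H
        mass += w * m
        vol += w * m * vbar / AVOGADRO * 1e24
    return Component(
        "ecoli_inner_membrane_lipid",
        AtomicComposition(counts, n_exch),
        vol,
        mass,
        role="lipid",
    )


def preset(name: str) -> Component:
    """Named component presets: 'ddm', 'ecoli_inner_membrane_lipid'."""
    key = name.strip().lower()
    if key == "ddm":
        # n-dodecyl-β-D-maltoside: 7 hydroxyls on the maltoside headgroup
        return Component.from_formula(
            "DDM", "C24H46O11", 7, vbar=DDM_VBAR, role="detergent"
        )
    if key in ("ecoli_inner_membrane_lipid", "ecoli_lipid", "lipid"):
        return _average_lipid()
    raise KeyError(f"unknown preset {name!r}")
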