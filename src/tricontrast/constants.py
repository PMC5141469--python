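"""Physical constants and lookup tables for neutron contrast calculations.

Units policy (package-wide): lengths in Å, scattering lengths in fm
(1 fm = 1e-13 cm = 1e-5 Å), scattering-length densities (SLD) in Å⁻²,
volumes in Å³, intensities in cm⁻¹ (absolute scale), concentrations in
mg/ml, D₂O content as a 0–1 volume fraction internally and 0–100 % in all
user-facing I/O.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # 1/mol (exact, SI 2019)

# Conversion: scattering length in fm over volume in Å³ → SLD in Å⁻².
FM_PER_ANGSTROM = 1.0e-5
FM_TO_CM = 1.0e-13

# Bound coherent neutron scattering lengths, fm.
# Values from the standard neutron data compilation (Sears, Neutron News 3,
# 26 (1992)); natural isotopic abundance except D.
COHERENT_B_FM: dict[str, float] = {
    "H": -3.7390,
    "D": 6.6710,
    "C": 6.6460,
    "N": 9.3600,
    "O": 5.8030,
    "P": 5.1300,
    "S": 2.8470,
    "Na": 3.6300,
    "Cl": 9.5770,
    "K": 3.6700,
    "Mg": 5.3750,
    "Ca": 4.7000,
    "Fe": 9.4500,
    "Zn": 5.6800,
    "Se": 7.9700,
}

# Standard atomic weights, g/mol (IUPAC 2021, abridged).
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.060,
    "Na": 22.990,
    "Cl": 35.450,
    "K": 39.098,
    "Mg": 24.305,
    "Ca": 40.078,
    "Fe": 55.845,
    "Zn": 65.380,
    "Se": 78.971,
}

# Change in scattering length when a labile H is replaced by D, fm.
B_EXCHANGE_FM = COHERENT_B_FM["D"] - COHERENT_B_FM["H"]

# Solvent SLD endpoints, Å⁻².  Standard literature values for light and
# heavy water at ambient conditions; the solvent SLD is linear in the D₂O
# volume fraction between them.
SLD_H2O = -0.560e-6
SLD_D2O = 6.370e-6

# Amino-acid residue table: chain residues (free amino acid minus one
# water).  Formula as element counts; n_exch counts labile hydrogens per
# residue in H₂O at neutral pH (backbone amide NH, absent for proline,
# plus side-chain N–H/O–H/S–H; ionised Asp/Glu carboxylates contribute
# none).  Volumes are the Zamyatnin consensus residue volumes, Å³.
RESIDUES: dict[str, dict] = {
    "A": {"formula": {"C": 3, "H": 5, "N": 1, "O": 1}, "n_exch": 1, "volume": 88.6},
    "R": {"formula": {"C": 6, "H": 12, "N": 4, "O": 1}, "n_exch": 6, "volume": 173.4},
    "N": {"formula": {"C": 4, "H": 6, "N": 2, "O": 2}, "n_exch": 3, "volume": 114.1},
    "D": {"formula": {"C": 4, "H": 5, "N": 1, "O": 3}, "n_exch": 1, "volume": 111.1},
    "C": {"formula": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1}, "n_exch": 2, "volume": 108.5},
    "E": {"formula": {"C": 5, "H": 7, "N": 1, "O": 3}, "n_exch": 1, "volume": 138.4},
    "Q": {"formula": {"C": 5, "H": 8, "N": 2, "O": 2}, "n_exch": 3, "volume": 143.8},
    "G": {"formula": {"C": 2, "H": 3, "N": 1, "O": 1}, "n_exch": 1, "volume": 60.1},
    "H": {"formula": {"C": 6, "H": 7, "N": 3, "O": 1}, "n_exch": 2, "volume": 153.2},
    "I": {"formula": {"C": 6, "H": 11, "N": 1, "O": 1}, "n_exch": 1, "volume": 166.7},
    "L": {"formula": {"C": 6, "H": 11, "N": 1, "O": 1}, "n_exch": 1, "volume": 166.7},
    "K": {"formula": {"C": 6, "H": 12, "N": 2, "O": 1}, "n_exch": 4, "volume": 168.6},
    "M": {"formula": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1}, "n_exch": 1, "volume": 162.9},
    "F": {"formula": {"C": 9, "H": 9, "N": 1, "O": 1}, "n_exch": 1, "volume": 189.9},
    "P": {"formula": {"C": 5, "H": 7, "N": 1, "O": 1}, "n_exch": 0, "volume": 112.7},
    "S": {"formula": {"C": 3, "H": 5, "N": 1, "O": 2}, "n_exch": 2, "volume": 89.0},
    "T": {"formula": {"C": 4, "H": 7, "N": 1, "O": 2}, "n_exch": 2, "volume": 116.1},
    "W": {"formula": {"C": 11, "H": 10, "N": 2, "O": 1}, "n_exch": 2, "volume": 227.8},
    "Y": {"formula": {"C": 9, "H": 9, "N": 1, "O": 2}, "n_exch": 2, "volume": 193.6},
    "V": {"formula": {"C": 5, "H": 9, "N": 1, "O": 1}, "n_exch": 1, "volume": 140.0},
}

# Fallback protein partial specific volume, ml/g, when no residue volumes
# are available (e.g. formula-defined proteins).
PROTEIN_VBAR_FALLBACK = 0.73

# DDM (n-dodecyl-β-D-maltoside) specific volume, ml/g.
DDM_VBAR = 0.82
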