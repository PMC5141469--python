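# Methods

## Physical model

A particle of total volume V composed of phases i with SLDs ρᵢ(f) in a
solvent of SLD ρ_s(f), f the D₂O volume fraction, has per-particle excess
scattering length

    ρV(f) = Σᵢ (ρᵢ(f) − ρ_s(f))·Vᵢ .

Every ρᵢ(f) is affine in f: the only f-dependent term is the replacement of
labile hydrogens by deuterium, b(f) = Σ b_atom + n_exch·x·f·(b_D − b_H),
with x the exchanged fraction of labile H. The solvent SLD is linear
between the pure-water endpoints. Consequently ρV(f) is a straight line
whose root is the particle's contrast match point, and the match point of a
volume-weighted mixture is the volume-weighted mean of the component match
points. That single algebraic fact drives the whole decomposition: measure
the total match point, subtract the theoretically known protein line,
invert the mixing relation twice (protein vs non-protein, then lipid vs
detergent within the non-protein part).

Absolute scale connects I(0) to ρV: I(0) = c·N_A/M_W · (ρV)², with c the
protein mass concentration and M_W the protein molar mass per particle.
Because √I(0) loses the sign of the contrast, the sign change is located by
scanning every candidate break between consecutive contrast points and
keeping the weighted line fit with the smallest χ²; the line is normalised
positive at 0% D₂O. The χ²/dof of this line is a monodispersity /
constant-composition diagnostic.

The oligomeric state is defined as (ρV_protein-only at 0% D₂O over the
one-copy theoretical value)² — the ratio of apparent to sequence molar
mass, linear in copy number. The protein-only value is obtained by
evaluating the fitted line at the non-protein match point (where only
protein scatters) and extrapolating to 0% D₂O along a line rooted at the
protein match point. At 0% D₂O no exchange has occurred, which makes this
estimate nearly independent of the exchange fraction.

## Constants and component models

- Solvent SLD endpoints: H₂O −0.560×10⁻⁶ Å⁻², D₂O +6.370×10⁻⁶ Å⁻²
  (standard literature values; `constants.py`).
- Coherent scattering lengths from the Sears compilation.
- Proteins: residue-table summation (formula, labile-H count, Zamyatnin
  residue volume) with one water and three labile H per chain for the
  termini; ionised Asp/Glu carboxylates contribute no labile H. The
  residue volumes imply a partial specific volume of ≈ 0.73–0.75 ml/g; a
  vbar override is accepted.
- DDM: C₂₄H₄₆O₁₁ with 7 hydroxyl hydrogens, specific volume 0.82 ml/g →
  CMP 21.3% D₂O at 80% exchange (measured literature value 21.7%).
- *E. coli* inner-membrane lipid: PE:PG:CL 75:20:5 by weight with
  palmitoyl/oleoyl (tetra-oleoyl for CL) chains → CMP 13.2% D₂O
  (literature calculated value 13.1%). The blend is data, overridable.
- Labile-hydrogen exchange: default fraction 0.80 with band 0.70–0.90.
  The band is propagated as an asymmetric low/high envelope on every SLD,
  match point and derived fraction rather than folded into a Gaussian.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `qrg_limit` | 1.3 | upper Guinier window edge, q·R_g units |
| `window_policy` | auto | self-consistent window + runs-test shrinkage |
| exchange fraction | 0.80 (0.70–0.90) | labile H exchanged at 100% D₂O |
| `low_contrast_fraction` | 0.10 | drop Stuhrmann points with \|Δρ̄\| below this fraction of the series maximum |
| `model_policy` | auto | Stuhrmann linear vs parabolic, F-test at p < 0.05 |
| `lipid_mol_volume` | 1100–1250 Å³ | molecular-volume range for the lipid count |

## Numerical choices

- **Guinier fits** are weighted linear least squares of ln I vs q² with
  σ_lnI = σ_I/I; points with I ≤ 0 are excluded, never clipped. The window
  is iterated so that q_max·R_g ≤ `qrg_limit`, then shrunk from the top
  while a Wald–Wolfowitz runs test on the weighted residuals signals a
  systematic run (z < −2.5). On low-noise curved data (e.g. an exact
  sphere curve) this removes the form-factor truncation bias — a plain
  qR_g ≤ 1 window on a sphere overestimates R_g by ≈ 1%; with the
  shrinkage the error is ≈ 0.1%. On realistically noisy data the runs test
  stays quiet and the full window is used.
- **Line fits** (CV line, protein-subtracted residual, Stuhrmann,
  parallel axis) are weighted linear least squares with closed-form
  covariance; roots carry first-order propagated errors. Stuhrmann x-errors
  (exchange band on Δρ̄) are folded in by effective-variance weighting
  (two passes). Negative fitted squares in the parallel-axis intercepts are
  reported flagged as imaginary, never silently clipped.
- **Model selection**: the Stuhrmann fit is linear (β = 0) unless an
  F-test on the 1/Δρ̄² term is significant at p < 0.05; both fits are
  always reported. A linear choice with coincident centres is exact for
  any two-phase particle.
- **Degenerate inputs**: equal component CMPs raise a singular error;
  mixing fractions outside [0, 1] are clamped with a warning; curves near
  a component match point are flagged low-contrast; a residual line
  indistinguishable from zero (max |residual| < 5% of the signal or within
  3σ everywhere) is reported as "no non-protein component" and the
  pipeline falls back to a pure-protein decomposition.

## Synthetic data: what it emulates and what it does not

The simulator produces monodisperse concentric-sphere (or two offset
sphere) particles built from the same chemical components the analysis
uses, on absolute scale, with counting noise σ(q) = r·√(I(0)·I(q)) (r = 5%
by default) and a small absolute floor. The default contrast grid is
8 D₂O fractions (0–100%), 120 q points over 0.003–0.06 Å⁻¹, 2 mg/ml.
The native-like scenario is a ~250 kDa membrane-protein-like pseudo-
sequence (CMP 38.8% D₂O) as a shell around a mixed lipid/DDM core at
33/41/26 v/v; the cross-linked-like scenario uses 41/25/33.

Deliberately **not** modelled: instrumental smearing, incoherent/flat
background, buffer-subtraction artefacts, interparticle structure factor,
polydispersity, shape anisotropy beyond the two-phase radial profile, and
exchange kinetics (exchange is applied identically in simulation and
analysis, so roundtrips isolate the analysis itself; a mismatch can be
probed by passing different ExchangeModels to the two sides). Passing
tests therefore demonstrate the correctness and noise behaviour of the
analysis chain, not robustness to every artefact of real reduced data.

## Accuracy observed on the default conditions

On the native-like fixture at 5% noise the pipeline recovers the total
match point to ≈ 0.6% D₂O, the non-protein match point to ≈ 0.2% D₂O,
volume fractions to ≈ 2–3 percentage points and the oligomeric state to
≈ 0.01. The residual biases are systematic, not statistical: Guinier
truncation on a core-shell form factor under- or over-estimates I(0) by a
contrast-dependent fraction of a percent, which the CV-line root inherits.
Problem sizes throughout (8 curves × 120 points) are the package's default
study conditions; all tests and the acceptance script run in seconds.

## Known limitations

- Smearing (Δq) is carried through file I/O but ignored in fitting.
- The lipid copy number depends on the assumed lipid molecular volume;
  it is reported as a range over a configurable volume window.
- The parallel-axis D (centre separation) is only identifiable with the
  quadratic term enabled and a wide X range; with the default linear
  policy it is reported as 0 when the Stuhrmann fit selects β ≈ 0.
- X-ray SLDs, per-atom displaced volumes and P(r)/shape reconstruction
  are out of scope.
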