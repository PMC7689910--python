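# fuzzynmr

Analysis toolkit for **fuzzy complexes of intrinsically disordered proteins
(IDPs)** characterized by solution NMR and conformational ensembles.

Many IDP-partner complexes never settle into a single structure: the
disordered chain binds through a few anchor residues and transiently formed
helices while large segments stay mobile. Classical structure calculation
fails for such systems, but a set of per-residue NMR observables — chemical-
shift perturbations, secondary structure propensities, amide temperature
coefficients, and ¹⁵N relaxation — combined with statistics over simulated
or modelled conformational ensembles still yields a coherent structural and
dynamical picture. `fuzzynmr` implements that entire workflow as a tested
library with a thin CLI, shaped around the canonical example of this class:
the ~60-residue p53 transactivation domain (p53TAD¹⁻⁶⁰) bound to the
EF-hand homodimer S100A4.

## What it computes

- **Chemical-shift perturbation (CSP) mapping** (`fuzzynmr.csp`):
  cumulative amide shift change Δδ = √(Δδ²_H + (α·Δδ_N)²) with α = 0.14,
  classification against a 0.15 ppm limit, detection of residues broadened
  below the detection limit, contiguous binding regions, ¹H line widths by
  Lorentzian fitting, titration peak tracking, and partner-side peak-doubling
  counts (homodimer asymmetry).
- **Secondary structure propensity (SSP)** (`fuzzynmr.secondary_structure`):
  secondary shifts Δδ = δ_obs − δ_coil from sequence-corrected random-coil
  references; SSP score per residue from Hα/Cα/Cβ over a 5-residue window,
  normalised so full helix → +1 and full strand → −1; amide ¹H temperature
  coefficients (ppb/K) with the −4.5 / −9 ppb/K hydrogen-bond / fast-exchange
  classification.
- **¹⁵N relaxation and reduced spectral density mapping**
  (`fuzzynmr.relaxation`): R₁/R₂ from single-exponential decay fits on the
  standard delay schedules, steady-state hetNOE, inversion to J(0), J(ω_N),
  J(0.87 ω_H), the single-motion curve (2/5)τ vs (2/5)τ/(1+(ω_N τ)²),
  mobility groups I–IV by J(0), and exchange-suspect flagging.
- **Ensemble statistics** (`fuzzynmr.ensemble`): Kabsch superposition,
  GROMOS-style (Daura) RMSD-cutoff clustering with mid-structures, B-factors
  B = (8π²/3)⟨|r−⟨r⟩|²⟩, φ/ψ helix assignment, hydrogen bonds, inter-chain
  contact/anchor maps, and NOE upper-bound checks under r⁻⁶ averaging.
- **Synthetic ground truth** (`fuzzynmr.synthetic_data`): a model-free
  (Lipari–Szabo) relaxation generator, shift-table/titration/temperature
  series generators, and a φ/ψ backbone builder, all deterministic under a
  seed — every analysis stage has a parameter-recovery test with known truth.
- **Pipeline** (`fuzzynmr.pipeline`): one YAML config → a per-residue
  summary joining all stages.

## Worked example

Generate a complete synthetic input set for a p53TAD-like IDP (mobile
termini 1–13/56–60, bound-state helices 18–29/36–47/50–55, binding regions
20–29/39–44/48–55 with 48–55 exchange-broadened, anchors L26/M40/W53) and
run every stage:

```bash
fuzzynmr simulate --preset p53tad_like --seed 7 --out sim/
fuzzynmr run --config run.yaml --out out/
```

The pipeline log reports the recovered binding map:

```
INFO fuzzynmr.pipeline: csp: 50 residues, perturbed regions [(20, 29), (39, 44), (48, 55)]
summary with 60 residues -> out
```

i.e. the three ground-truth binding regions are recovered exactly, with the
48–55 stretch flagged as broadened (asterisk class). `out/summary.tsv` holds
one row per residue: Δδ_cum, perturbed/broadened flags, SSP (free and
bound), temperature-coefficient class, R₁/R₂/hetNOE, J(0)/J(ω_N) with
mobility group, ensemble helix fraction, B-factor, and the anchor flag from
partner contact frequencies (≥ 0.5 at residues 26, 40 and 53).

Library-level example — frequency referencing and the construct mass:

```python
>>> from fuzzynmr import larmor_frequencies, average_mass
>>> from fuzzynmr.core_io import P53TAD_1_60
>>> larmor_frequencies(700.17)   # MHz: (13C, 15N)
(176.05741742009997, 70.94760855006)
>>> round(average_mass(P53TAD_1_60) / 1000)   # kDa
7
```

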