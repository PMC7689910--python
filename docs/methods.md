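# Methods

This note records the models, conventions, parameter choices and known
limitations behind `fuzzynmr`, in the order the pipeline runs them.

## Chemical-shift perturbation mapping

The cumulative amide perturbation is Δδ_cum = √(Δδ_H² + (α Δδ_N)²). The
nitrogen weight α defaults to 0.14 — the common scaling that brings ¹⁵N
shift ranges onto the ¹H scale — and is configurable; no residue-type
specific weights are used. A residue whose amide is observed in the free
state but absent within the matching gate in the bound state is *broadened*
(intermediate exchange); broadened residues have no Δδ_cum but are always
counted as perturbed, since in this system they concentrate in the binding
regions. The perturbation class switches at Δδ_cum ≥ 0.15 ppm (closed
boundary: exactly 0.15 is perturbed). Contiguous binding regions are maximal
runs of perturbed/broadened residues; a single-residue gap is bridged only
when that residue carries no data at all (prolines have no amide probe), so
an observed-but-unperturbed residue always splits a region.

Line widths come from a Lorentzian least-squares fit (amplitude, centre,
FWHM, baseline) rather than half-height interpolation; a flat or monotone
window is a hard error, not a silent NaN. Titration tracking matches peaks
between consecutive points by nearest neighbour in the (1, α)-scaled ppm
metric under a maximum-jump gate (default 0.05 scaled ppm); a lost peak ends
the trajectory as broadened, and two trajectories claiming one target are
both flagged ambiguous rather than merged. Peak-doubling detection counts
peaks within the same gate around each reference position of one homodimer
chain; a count of 2 marks chain asymmetry.

The threshold 0.15 applies at the titration endpoint (the bound-state
table), not at intermediate points.

## Secondary shifts and SSP

Secondary shifts are δ_obs − δ_coil with sequence-corrected random-coil
references. The shipped coil table covers Cα/Cβ/Hα (plus amide H/N and C′
for the generators) for all twenty residue types at 298 K; the sequence
correction implements the dominant neighbour effect, the residue preceding
proline (Cα −1.9, C′ −1.5, Cβ −0.2, Hα +0.05, N +0.5 ppm at i+1-Pro). Any
complete substitute table is accepted through the `RandomCoilTable`
constructor.

The SSP score of residue i sums, over a 5-residue window (i−2…i+2) and the
available nuclei, the secondary shifts weighted by the *sign* of the
full-helix reference shift for that nucleus (+ for Cα, − for Cβ and Hα),
then divides by the summed magnitudes of the full helix (if the sum is
positive) or full strand (if negative) reference shifts. This makes an
ideal helix score exactly +1, coil 0, ideal strand −1, and the statistic
linear in partial helicity. Note the sign weighting follows from the
reference table itself: Hα moves upfield in helix just as Cβ does, so both
are inverted. The full secondary-shift magnitudes are per-nucleus averages
(helix: Cα +3.1, Cβ −0.38, Hα −0.39 ppm; strand: −1.5, +2.16, +0.37)
replicated across residue types; uniform weighting, no variance weighting.
Hα participates whenever present; with carbons only the statistic is
unchanged in form.

Amide temperature coefficients are least-squares slopes of the ¹H shift
(ppb) versus temperature (K), fit per residue across ≥ 3 temperatures
spanning ≥ 10 K; positions are taken from tracked peak lists, not
re-assignment. Classes: slope > −4.5 ppb/K → hydrogen-bonded; slope < −9
ppb/K → fast solvent exchange; the boundaries themselves fall in the
intermediate class.

## Relaxation and reduced spectral density mapping

R₁ and R₂ come from nonlinear least-squares fits of I(t) = I₀ e^(−Rt) on
the standard schedules (T₁: 10 delays in 0.01–2 s; T₂: 11 delays in
0.03–1.36 s; one delay duplicated as a reproducibility check — a repeat
discrepancy beyond 3× the fit-residual noise flags the residue). Rates from
non-decaying series are refused (flagged unfittable), never reported
negative. hetNOE is the saturated/unsaturated intensity ratio; an
unsaturated intensity at the noise floor makes the ratio undefined.

The reduced mapping inverts (R₁, R₂, NOE) to three spectral-density values:

    σ_NH      = R₁ (NOE − 1) γ_N/γ_H
    J(0.87ω_H) = 4σ_NH / (5d²)
    J(ω_N)    = [R₁ − (7d²/4) J(0.87ω_H)] / (3d²/4 + c²)
    J(0)      = [R₂ − (3d²/8 + c²/2) J(ω_N) − (13d²/8) J(0.87ω_H)]
                / (d²/2 + 2c²/3)

with d the N–H dipolar coupling constant from r_NH = 1.02 Å and
c² = (ω_N Δσ_N)²/3 with Δσ_N = −160 ppm; γ_N/γ_H = −0.10136. These are the
standard ¹⁵N backbone values and are exposed in the module constants. Two
conventions matter numerically:

- ω_N is **negative**; the sum frequency ω_H + ω_N therefore lies at
  0.899 ω_H, and the combination 6J(ω_H+ω_N) − J(ω_H−ω_N) that defines σ_NH
  is sampled effectively at 0.87 ω_H. Treating ω_N as positive misplaces
  the high-frequency point at 1.16 ω_H.
- Exchange is deliberately **not** separated: R_ex feeds straight into the
  apparent J(0). An inflated J(0) relative to the single-motion curve
  (factor ≥ 2 by default, configurable) flags the residue exchange-suspect;
  this mirrors how elevated J(0) is read as possible conformational
  exchange.

Against rates generated from a model-free spectral density the inversion is
accurate to < 1 % over S² ∈ [0.2, 0.95], τ_c ∈ [2, 10] ns at 700.17 MHz;
the 5 % acceptance band absorbs the approximation error of the single
high-frequency point. Uncertainties propagate by Monte-Carlo resampling
(200 draws from the fit sigmas) because closed-form propagation is brittle
near NOE ≈ 1.

Mobility groups I–IV partition residues by increasing J(0) using either
user-supplied boundaries or deterministic 1-D k-means (k = 4, quantile
initialisation — no random restarts, so reruns are identical). Fewer than
four residues fall back to a single group with a warning.

## Ensemble statistics

Superposition is least-squares (Kabsch) on a selection mask, onto a chosen
snapshot or iteratively onto the ensemble mean. GROMOS (Daura-style)
clustering repeatedly takes the snapshot with the most neighbours within
the RMSD cutoff (1.0 Å default on the IDP main chain) as a cluster
mid-structure, removes the cluster, and recounts; ties break to the lowest
snapshot index, making the partition deterministic, and the implementation
is property-tested against an exhaustive neighbour-count oracle. B-factors
are (8π²/3)⟨|r − ⟨r⟩|²⟩ per atom on the aligned ensemble, averaged over
main-chain atoms (N, Cα, C′, O) per residue; a single snapshot is an error.

Helix assignment uses φ/ψ windows (φ ∈ [−100°, −30°], ψ ∈ [−80°, 0°], runs
of ≥ 4) instead of DSSP hydrogen-bond patterns, so it needs no hydrogen
placement; chain-terminal residues lacking a dihedral are unassigned, which
trims one residue from each end of an ideal helical stretch. Hydrogen bonds
require donor–acceptor heavy-atom distance ≤ 3.5 Å and a D–H⋯A angle within
30° of linear; missing amide protons are reconstructed on the
C′(i−1)/Cα bisector at 1.02 Å and marked inferred. Inter-chain contacts use
a 4.5 Å heavy-atom minimum-distance criterion; a residue is an anchor when
its maximum contact frequency with the partner reaches 0.5. NOE upper
bounds are checked against ⟨r⁻⁶⟩^(−1/6) over snapshots (NOE intensities
average as r⁻⁶, so transient close approaches dominate); per-snapshot
checking is available, and a constraint naming an absent atom is reported
unresolvable rather than dropped.

## Synthetic ground truth

The generator fixes per residue: helical fraction (free and bound), S²,
exchange R_ex, endpoint amide shift changes, broadening flags, and
temperature coefficients, plus a global τ_c and local τ_e. Observables
follow from the model: relaxation from the full dipolar+CSA expressions
over the model-free J; shift tables as coil + f·(full-helix shift) + noise;
titrations as linear fast-exchange peak movement with broadened peaks
fading past 50 % saturation; ensembles from φ/ψ sampling (helices tight
around (−57°, −47°), linkers broad) built with ideal backbone geometry and
Cβ-only side chains. Amide peak positions carry a fixed per-residue
dispersion offset (σ 0.08 ppm ¹H / 1.2 ppm ¹⁵N) shared by all generators —
without it every residue of one type would stack on a single HSQC
coordinate, which no real spectrum does; because free and bound states
share the offset it cancels from all differences.

The `p53tad_like` preset encodes the study conditions: 60 residues
(UniProt P04637 1–60), mobile termini 1–13 and 56–60 (S² ≈ 0.25), helices
18–29/36–47/50–55 (S² ≈ 0.85, helicity 0.9), anchors 26/40/53 with the
largest endpoint shifts, binding regions 20–29/39–44/48–55 with 48–55
broadened, R_ex = 4 s⁻¹ at residues 23/24/32/51, τ_c = 6 ns (the bound
chain tumbles with the 31 kDa complex but stays locally flexible),
τ_e = 50 ps, 1 % intensity noise, and a smooth ±0.05 residue-to-residue S²
variation (flat plateaus are unphysical and would make rank statistics
degenerate). Partner pocket atoms ride just outside the anchor Cβ in every
snapshot, emulating persistent burial.

What the generator does **not** emulate — hence what passing tests do not
show about real data: no intermediate-exchange lineshapes (broadening is a
binary dropout), no anisotropic tumbling, no titration-point-dependent
assignment errors, no side chains beyond Cβ, and the partner is a set of
pocket pseudo-atoms rather than a folded dimer, so partner-side analyses
(peak doubling, H-bond networks to specific partner residues) are exercised
on constructed geometries only.

## Recovery statistics and problem sizes

The acceptance script runs every stage at sizes that keep the whole suite
in tens of seconds on one CPU: the reduced-mapping grid is 6 × 5 parameter
points, fit-bias and classification-recovery loops use 100 replicates,
the clustering oracle 200 random ensembles of ≤ 50 snapshots, B-factor
checks 2000 snapshots, and end-to-end runs use 20-snapshot ensembles of
the 60-residue preset. The J(0)–S² rank correlation is evaluated over
residues with zero ground-truth R_ex: the mapping folds exchange into J(0)
on purpose, so at the four R_ex-bearing residues J(0) measures exchange,
not order, and including them caps the attainable correlation (~0.92
noise-free) for reasons unrelated to recovery fidelity.

## Known limitations

- The coil and full-secondary-shift tables are compiled averages; SSP
  values on real data shift slightly with the chosen compilation (the
  tables are injectable).
- Reduced mapping assumes a single ¹⁵N CSA (−160 ppm) and rigid N–H bond
  length; site-to-site CSA variation (±20 ppm) maps to a few percent in
  J(ω_N)/J(0).
- The GROMOS clustering is O(n²) in snapshots with a full RMSD matrix in
  memory — intended for NMR-scale ensembles (≤ a few thousand snapshots),
  not raw MD trajectories; subsample first.
- Titration tracking is nearest-neighbour with a gate: in crowded IDP
  spectra with large steps it terminates trajectories (flagged, never
  silently reassigned), as it should.
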