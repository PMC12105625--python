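# Methods

## Model and assumptions

The package computes one-electron oxidation potentials of dissociating
molecules (nucleobases and their epigenetic derivatives) from
solution-phase free energies, under the following physical picture:

1. **Thermodynamic cycle.** The solution ionization free energy of a
   pathway is `ΔG_IE^sol = ΔG_IE^gas + ΔG^solv(oxidized) −
   ΔG^solv(reduced)`; the standard potential of that pathway is
   `E° = ΔG_IE^sol/nF − E_ref`. Gas-phase ionization uses the adiabatic
   convention (both end points at their own optimized geometry). With
   energies expressed in eV per electron the division by F is implicit.

2. **Redox square.** A molecule RH with an acidic proton has two
   oxidation pathways — neutral (RH → RH⁺•) and deprotonated
   (R⁻ → R•) — linked by the acidity constants K_a(0)r (of RH) and
   K_a(+1)o (of RH⁺•). Because the radical cation is at least as acidic
   as its parent, the deprotonated pathway never costs more;
   `RedoxCouple` enforces `ΔG_IE(−1)r ≤ ΔG_IE(0)r` (equality is the
   degenerate case in which all prototropic corrections vanish).

3. **Speciation.** The observable potential at a given pH mixes the
   pathways. M2 weights the two pathway potentials by
   Henderson–Hasselbalch mole fractions; because the free-energy →
   potential map is affine, weighting potentials equals weighting free
   energies. M3 adds the Nernst correction
   `(RT/F) ln[(10^−pH + K_a(0)r)/(10^−pH + K_a(+1)o)]` to one pathway's
   E°; M4 additionally activates R• and R⁻ as oxidant/reductant, which
   contributes the neutralization term `(RT/F) ln[K_a(+1)o/K_a(0)r]`
   (positive in the usual ordering) and doubles the pH/Ka term. M4 − M3
   equals the sum of those two terms identically; tests assert this to
   1e-12 V.

4. **Ensembles.** A species' G^sol is a Boltzmann combination over its
   conformers and tautomers. The default functional form is the
   population-weighted mean Σ wᵢGᵢ; the partition-function free energy
   −RT ln Σ exp(−Gᵢ/RT) is also implemented (`mode="partition_sum"`)
   because the conventional phrase "Boltzmann-averaged free energy" is
   ambiguous between the two. Both reduce to the single member's G for a
   singleton; the weighted mean lies within [min G, max G] while the
   partition form lies at or below min G.

## Parameters, units, defaults

| Parameter | Default | Why |
|---|---|---|
| R | 8.31446 J mol⁻¹ K⁻¹ | CODATA, as used in the source tables |
| T | 298.15 K | standard conditions; threaded through every formula so the effective temperature of the acidity terms stays testable |
| F | 96485.3 C mol⁻¹ | CODATA |
| E_ref | SHE +4.281 V (water), SCE +4.429 V (acetonitrile) | absolute electrode potentials of the conventional references |
| 1 atm → 1 M correction | +7.91 kJ/mol literal | reproduces the source arithmetic; `use_literal_standard_state=False` recomputes RT ln(24.46) ≈ 7.93 kJ/mol |
| pKa → ΔG | ln(10)·RT = 5.708 kJ/mol per unit at 298.15 K | exact ln 10 rather than the rounded 2.303 prefactor |
| dedup energy threshold | 1e-7 hartree | conformer-search individuality criterion |
| contribution filter | 2 % Boltzmann weight | population screening before expensive refinement; the lowest-G member is always retained |
| CBS exponent | 3 (on cardinals 3/4) | inverse-cubic two-point extrapolation, the standard form for the cc-pVTZ/cc-pVQZ pair; exposed as a parameter |
| pH grid | 0–14, step 0.1 | titration-curve convention |

Raw energies are carried in hartree, assembled free energies in kJ/mol,
pathway ionization energies in eV, potentials in V; all conversions pass
through one frozen constants table (1 Ha = 27.2114 eV = 2625.50 kJ/mol),
so unit round trips are identities to 1e-12.

## Numerical choices

* Boltzmann weights subtract min G before exponentiating: overflow-safe
  and shift-invariant by construction.
* Deduplication keeps the lowest-G member of a duplicate group, ties
  broken lexicographically by conformer id; geometry descriptors
  (atom-to-centroid distances) are sorted before element-wise
  comparison, making the criterion independent of atom ordering. A
  missing descriptor never blocks a merge. Processing records in
  ascending G order makes the operation idempotent.
* Acidity constants are stored as literal Ka values so that
  "non-acidic" (Ka = 0) is representable; `AcidBaseSpec.from_pka`
  covers the usual convention. M4 refuses Ka(0)r = 0 (its first term
  diverges) and directs the caller to M3 or the deprotonated pathway;
  the pipeline falls back to M1 with a logged notice when a compound has
  no acidic proton, mirroring how a xanthine without acidic protons
  (e.g. caffeine) is handled.
* Pathway selection: M3/M4 start from the M1 value of the pathway whose
  reduced species dominates at the run's pH (deprotonated iff
  x_R⁻ > 0.5, ties to neutral); `force_neutral_pathway` overrides. This
  reproduces both the generic workflow and the treatment of strongly
  acidic 5-carboxy compounds (pKa ≈ 4.3, fully ionized at pH 7).
* Display rounding is half-away-from-zero at 2 d.p., matching printed
  tables; all table-reproduction comparisons are made at that precision,
  with ±0.01 V slack for quantities recomposed from inputs that are
  themselves printed rounded to 0.01 V.
* MSE is signed as theoretical − experimental (positive = computed value
  too high); R² is the squared Pearson correlation of the OLS fit of
  experimental on theoretical. Censored experimental entries (lower
  bounds such as ">2.15") default to resolution at the bound; a `drop`
  policy removes them.
* The linear adjustment derives its intercept from the anchor compound
  (`intercept = E_exp(anchor) − slope·E_raw(anchor)`) and then sets the
  anchor's adjusted value to the experimental value exactly, avoiding a
  last-ulp float discrepancy. The shipped construction uses the
  benchmark slope 0.60 with cytosine (1.44 V) anchoring the cytosine
  family and uracil (1.34 V) the uracil family.

## Synthetic data

`SyntheticSystemSpec` describes a redox square with known ground truth:
a prescribed standard potential, a non-decreasing pKa ladder of the
reduced species, and a `radical_acidity_shift` = pKa(0)r − pKa(+1)o ≥ 0
placing the radical cation's acidity (default 5 pKa units, a typical
magnitude for nucleobase radical cations; 0 gives the degenerate couple
where M3 = M4 = M1). The four corner free energies are mutually
consistent — the neutral ionization gap equals (E°_true + E_ref) per
electron and each deprotonation costs its ladder free energy — so any
route around the square closes, and the noiseless pipeline returns
E°_true exactly (tests assert 1e-10 V). Conformer ensembles add
exponential-like offsets (scale spread/3, clipped at the spread) above
each corner's base so the low-energy region is denser, as in relaxed
conformer searches; Gaussian noise of width `noise_sd` models residual
method error. Each (seed, corner) pair uses a named NumPy substream: runs
are bit-reproducible and corners are independent.

What the generator does *not* emulate: real tautomer energetics,
geometry-dependent solvation, correlated errors between redox states,
and explicit-water placement. Passing tests therefore demonstrate the
correctness of the post-processing arithmetic and statistics, not the
accuracy of any electronic-structure method.

The packaged reference tables (`table1` … `table6` with JSON sidecars)
transcribe the published benchmark and prediction tables at printed
precision, preserving censored entries (">2.15") and footnote mole
fractions. Known internal inconsistencies of the source are transcribed
as printed and documented in the sidecars (uracil's experimental AIE
appears as 8.68 eV in one table and 9.32 eV in another; the gas-phase
regression metrics recompute only under the latter).

## Design choices

* The analysis is organised as numbered drivers over a library: every
  computation lives in `src/redoxph/` where tests import it; the
  `analysis/` scripts only narrate and write tables.
* Problem sizes: the Monte-Carlo recovery check uses 500 replicates at
  3 kJ/mol noise (SEM ≈ 1.5 mV, comfortably resolving any bias of
  interest); property tests run 50–100 random cases each. The whole
  suite completes in a few seconds.
* Regression membership per printed metrics row is data, not code: the
  aqueous benchmark's metric rows do not recompute from any obvious row
  subset of the printed columns, so only quantities that do recompute
  (the acetonitrile regression, the M4 R² = 0.93 column, the M2
  recompositions, the adjusted-table construction) are asserted; the
  rest are reported as informational by the analysis drivers.

## Limitations

* No electronic-structure computation: inputs are tabulated or synthetic
  free energies; the package cannot improve on the solvation model
  deficiencies that dominate absolute errors in water.
* The linear adjustment transfers a benchmark slope to chemically
  similar compounds; it is a family-wise calibration, not an
  uncertainty-quantified prediction.
* Multi-site acids are reduced to their lowest-pKa first deprotonation;
  microstate-resolved speciation is out of scope.
* Potentials are thermodynamic (midpoint) values; electrode kinetics,
  scan-rate effects and activity coefficients beyond the prototropic
  terms are not modeled.
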