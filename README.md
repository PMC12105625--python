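# redoxph

pH-dependent one-electron oxidation potentials of nucleobase derivatives
from thermodynamic-cycle free energies.

## The problem

One-electron oxidation (RH → RH⁺• + e⁻) is the first step of oxidative
DNA damage, and the epigenetic cytosine marks (5mC, 5hmC, 5fC, 5caC and
the formyl hydrate 5dhmC) shift how easily that electron leaves. Quantum
chemistry delivers solution free energies of the species involved; this
package does everything that comes *after* the electronic-structure
step:

* assemble solution free energies `G^sol` from single-point energies,
  ZPE, thermal corrections, the 1 atm → 1 M standard-state term and
  implicit-solvation free energies, with two-point CBS extrapolation of
  TZ/QZ basis pairs;
* Boltzmann-average conformer/tautomer ensembles (with duplicate-structure
  removal and a 2 % population screening filter);
* convert pathway ionization free energies into potentials through a
  hierarchy of models:
  * **M1** — standard potential of one pathway,
    `E° = ΔG_IE^sol/nF − E_ref` (SHE +4.281 V in water, SCE +4.429 V in
    acetonitrile);
  * **M2** — Henderson–Hasselbalch mole-fraction average over the
    neutral (RH → RH⁺•) and deprotonated (R⁻ → R•) pathways,
    `x_RH = 1/(1 + 10^(pH−pKa))`;
  * **M3** — Nernst prototropic correction for one pathway,
    `E = E° + (RT/F) ln[(10^−pH + K_a(0)r)/(10^−pH + K_a(+1)o)]`;
  * **M4** — both protonation levels active on each side,
    `E = E° + (RT/F) ln[K_a(+1)o/K_a(0)r] + 2(RT/F) ln[(10^−pH + K_a(0)r)/(10^−pH + K_a(+1)o)]`;
* calibrate theory against experiment (OLS slope/intercept/R², MSE, MUE,
  RMSE, censored-value handling) and apply the *linear adjustment*:
  rescale computed potentials by the benchmark slope and anchor the
  intercept at a reference compound's experimental value.

Synthetic generators (`redoxph.synthetic`) build conformer ensembles and
redox couples with known ground truth, so every stage is testable with
no quantum-chemistry runs; the published benchmark and prediction tables
ship as packaged CSV fixtures (`load_fixture("table1")` …
`"table6"`).

## Worked example

```python
from redoxph import (AcidBaseSpec, RedoxCouple, m1_potential, m2_potential,
                     m4_potential, mole_fractions, PhysicalConstants)

she = PhysicalConstants(reference="SHE")

# xanthine-like couple: pKa(0)r = 7.5, pathway standard potentials
# 1.89 V (neutral) and 0.92 V (deprotonated)
couple = RedoxCouple(
    dg_ie_neutral_ev=1.89 + she.ref_potential,
    dg_ie_deprotonated_ev=0.92 + she.ref_potential,
    acid_base=AcidBaseSpec.from_pka(pka_reduced_0=7.5),
)
x = mole_fractions(ph=7.0, pka=7.5)
print(f"x_RH = {x.x_rh:.2f}")                      # x_RH = 0.76
print(f"E(M2) = {m2_potential(couple, 7.0).E:.2f} V")   # E(M2) = 1.66 V
```

At pH 7 the molecule is 76 % neutral, and the mole-fraction-averaged
potential (1.66 V vs SHE) sits between the two pathway potentials —
matching the published Henderson–Hasselbalch averaged value.

The analysis drivers under `analysis/` retrace the full study on the
packaged tables and synthetic data, writing their outputs to `results/`:

```bash
python analysis/01_benchmark_gas_acetonitrile.py   # benchmark regressions
python analysis/02_aqueous_m1_m2.py                # water: M1 fails, M2 recomposes
python analysis/03_ph_models_m3_m4.py              # prototropic models, R² = 0.93
python analysis/04_linear_adjustment_trends.py     # adjusted potentials + trend
python analysis/05_synthetic_validation.py         # ground-truth recovery
```

`analysis/04` prints the headline ordering of the cytosine marks at pH 7:
`d_5caC < 5mC < 5caC < 5hmC < C < 5dhmC < 5fC` (5mC/5caC tie at printed
precision).

A `redoxph` console command exposes the same machinery
(`compute`, `calibrate`, `speciate`, `simulate`, `fixtures`,
`verify-tables`); `redoxph verify-tables` recomputes the packaged
reference tables from their own printed inputs and reports any mismatch.

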