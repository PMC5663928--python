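# alchemtraj

Post-simulation thermodynamic analysis for relative binding free-energy
studies of ligand linker isosteres (e.g. replacing a charged phosphodiester
linker with a neutral carbamate or 1,2,3-triazole in enzyme inhibitors):
alchemical free-energy estimation, thermodynamic-cycle closure,
two-temperature enthalpy–entropy decomposition, quasi-harmonic
configurational entropy, hydrogen-bond / water-bridge / hydrophobic
occupancy analysis, and RMSD-threshold conformational clustering — with a
synthetic-data layer that gives every stage an analytic ground truth, so the
whole pipeline is testable without a simulation engine.

It is aimed at computational chemists who already have trajectories and
per-window energy differences (or want to validate analysis code before
trusting it on real data).

## The core quantities

**Per-window free energy** (Zwanzig exponential averaging, overflow-safe):

    ΔΔG_i = −k_B T ln ⟨ exp(−(H(λ_{i+1}) − H(λ_i)) / k_B T) ⟩_{λ_i}

summed over a validated λ chain (default 21 points, 0.0, 0.05, …, 1.0), with
midpoint-outward bidirectional windows (`0.0 ← 0.05 → 0.1`) sign-mapped onto
the forward axis, and block-averaged SEMs.

**Cycle closure**: three transformations between three ligand states close a
thermodynamic cycle; the signed ΔΔG sum is the convergence diagnostic.

**Enthalpy–entropy decomposition** from two temperatures:

    ΔΔS = −(ΔΔG(T₂) − ΔΔG(T₁)) / (T₂ − T₁),   ΔΔH = ΔΔG(T₂) + T₂·ΔΔS

so ΔΔH − T₂·ΔΔS = ΔΔG(T₂) exactly, with linear SEM propagation.

**Quasi-harmonic entropy**: eigenvalues λ of the mass-weighted covariance of
aligned ligand heavy-atom coordinates define mode frequencies
ω = √(k_B T/λ) and the quantum-oscillator entropy
S = k_B Σ [x/(eˣ−1) − ln(1−e⁻ˣ)], x = ħω/k_B T; binding entropy is
ΔS_conf = S(complex) − S(free) over triplicates.

**Interactions**: H-bond = D–H···A angle ≥ 120° and D···A ≤ 3 Å; hydrophobic
contact ≤ 4 Å between flagged atoms; water bridge = one water H-bonded to
ligand and protein in the same frame; all reported as per-frame occupancies.

**Clustering**: radius-driven k-means under RMSD with a 1.6 Å
member-to-centroid guarantee.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Run the all-synthetic demo pipeline (three compounds — a flexible
phosphodiester-like ligand and two stiffer isosteres — with transformation
free energies planted at their reported two-temperature values):

```sh
alchemtraj run-all --seed 0 --out demo_out
```

`demo_out/cycle_closure.json` — the three estimated transformations close
the cycle near the planted arithmetic (−1.5 and −0.8 kcal/mol):

```json
"T1": {"closure_kcal_mol": -1.5376, "sem_kcal_mol": 0.0653, "temperature_K": 288.15}
"T2": {"closure_kcal_mol": -0.7405, "sem_kcal_mol": 0.0686, "temperature_K": 298.15}
```

`demo_out/decomposition_table.tsv` — each transformation's estimated ΔΔG at
both temperatures and its decomposition (raw and report-rounded):

```
transformation  ddG_T1  ddG_T2  ddH_rounded  minus_T_ddS_rounded   ddH_raw  minus_T_ddS_raw
    phos->carb    -1.1    -1.7           10                  -20 14.903766       -16.573314
    phos->tria    -0.3    -1.4           30                  -30 32.314793       -33.726647
    carb->tria    -0.7    -0.5          -10                   10 -7.095340         6.612522
```

Replacing the flexible linker is enthalpically unfavourable (ΔΔH > 0) but
entropically compensated (−TΔΔS < 0) — the decomposition recovers the
planted enthalpy–entropy compensation pattern.

`demo_out/entropy_table.tsv` — quasi-harmonic binding-entropy penalties
(kcal/mol at 298.15 K, mean ± SEM over synthetic triplicates); the flexible
compound pays the largest configurational-entropy price on binding:

```
compound  minus_T_delta_S_kcal_mol  minus_T_delta_S_sem
    phos                  8.819070             0.050420
    carb                  4.478123             0.003102
    tria                  3.835399             0.016184
```

`demo_out/occupancy.tsv` ranks detected interactions by occupancy (an
always-present planted H-bond at 1.0, a half-present one at 0.5, …), and
`demo_out/cluster_populations.tsv` reports the two planted conformer
clusters at populations 0.5/0.5.  `manifest.json` records the seed, config
hash and per-stage counts; reruns with the same seed are byte-identical.

Library use mirrors the CLI:

```python
from alchemtraj.fep import SoftCoreParams, run_toy_fep, toy_alchemical_reference

params = SoftCoreParams()          # soft-core LJ toy, alpha = 4.0 A^2
truth = toy_alchemical_reference(params)       # quadrature: -0.0990 kcal/mol
est = run_toy_fep(params, n_per_window=100_000, seed=1)
print(est.total_ddG, "+-", est.total_sem)      # -0.0985 +- 0.0006
```

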