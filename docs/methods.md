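# Methods

`alchemtraj` re-implements, as a tested reusable pipeline, the complete
post-simulation analysis used in relative binding free-energy studies of
linker isosteres: alchemical free-energy estimation with thermodynamic-cycle
closure, two-temperature enthalpy–entropy decomposition, quasi-harmonic
configurational entropy, geometric interaction-occupancy analysis, and
RMSD-threshold conformational clustering.  Because the machinery is meant to
be validated without running molecular dynamics, every stage is exercised on
synthetic inputs with analytic ground truth; this note records the models,
the defaults and why they were chosen, and what the synthetic data does and
does not emulate.

## Free-energy estimation

For one coupling subinterval `λ_i → λ_{i+1}` the free-energy difference is
the Zwanzig exponential average

    ΔΔG_i = −k_B T ln ⟨ exp(−ΔH / k_B T) ⟩_{λ_i},   ΔH = H(λ_{i+1}) − H(λ_i),

computed with log-sum-exp so that arbitrarily large sample magnitudes only
shift the result by the identity `ΔΔG(x + c) = ΔΔG(x) + c` (tested as a
property).  A transformation total is the signed sum over a connected λ
chain covering [0, 1].  The default schedule is the 21-point uniform grid
0.0, 0.05, …, 1.0 (20 windows); the validator rejects schedules with gaps or
overlaps, naming the missing interval.

The midpoint-outward bidirectional scheme samples at the odd grid points
(0.05, 0.15, …, 0.95) and perturbs each toward both neighbours
(`0.0 ← 0.05 → 0.1`).  Reverse-direction windows are mapped onto the forward
axis with negated sign and summed; an averaging of forward/reverse halves is
not applied.  Plain exponential averaging (not BAR/MBAR) is used throughout
because it is the estimator under test; BAR is deliberately out of scope.

Window SEMs come from block averaging: consecutive sample segments (one
block per "nanosecond" of synthetic sampling by default) each yield their
own estimate, and the SEM is their standard deviation over √n_blocks.  The
transformation SEM assumes independent windows (quadrature sum) — a known
simplification, adequate for block-independent synthetic samples.

### Soft-core toy system

End-to-end validation uses one Lennard-Jones particle coupled to a fixed
particle through the separation-shifted soft-core form

    U(r, λ) = 4 ε λ [ (σ²/(α(1−λ) + r²))⁶ − (σ²/(α(1−λ) + r²))³ ],  α = 4.0 Å²

(for an appearing particle; a disappearing particle mirrors λ and 1−λ).
The configuration space is the sphere of radius `box_length/2` around the
fixed particle, so the coupling free energy has an *independent* 1-D
quadrature ground truth, and Monte-Carlo samples are drawn from the same
space by inverse-CDF on a dense radial grid (trapezoid cumulative density,
20,001 points).

Defaults ε = 0.5 kcal/mol, σ = 2.5 Å, box 10 Å were chosen once for
phase-space overlap: with the α = 4 Å² soft core fixed, substantially larger
ε or σ leaves the `0.05 → 0.0` deletion window unable to see the core region
that the decoupled state occupies, which biases exponential averaging — the
standard endpoint-overlap pathology, here avoided by construction rather
than corrected.

### Gaussian-window oracle

For Gaussian energy differences `ΔH ~ N(μ, σ²)` the exponential average has
the exact second-cumulant value `ΔG = μ − σ²/(2 k_B T)`.  The synthetic FEP
generator uses this identity both to test the estimator and, in the demo
pipeline, to plant two-temperature transformation targets whose analytic
totals equal the study's reported table values.

## Cycle closure and enthalpy–entropy decomposition

Three transformations between the three linker states form a closed cycle;
the signed sum of their ΔΔG (orientation ±1 per leg) is the closure error,
with quadrature SEM.  The loop validator requires every state to be entered
exactly as often as it is left.

Running a transformation at T₁ = 288.15 K and T₂ = 298.15 K allows the
finite-temperature-difference (van't Hoff) decomposition

    ΔΔS = −(ΔΔG(T₂) − ΔΔG(T₁)) / (T₂ − T₁),   ΔΔH = ΔΔG(T₂) + T₂·ΔΔS,

anchored at T₂ so that `ΔΔH − T₂·ΔΔS = ΔΔG(T₂)` holds exactly (asserted on
every decomposition).  SEMs propagate linearly treating the two temperature
legs as independent; the empirical 1-SEM coverage of the propagated ΔΔS
interval is verified at ≈68 % over 1,000 seeded repeats.  Report-precision
helpers round ΔΔG to one decimal and ΔΔH / −TΔΔS to the nearest 10 (the
table convention of the source analysis); raw values are always retained in
machine-readable output.

## Quasi-harmonic configurational entropy

Each frame is superposed (Kabsch) onto a reference over the ligand heavy
atoms to remove overall rotation and translation; the mass-weighted
covariance `σ = M^{1/2} C M^{1/2}` (amu·Å²) of the aligned coordinates is
eigen-decomposed; each retained eigenvalue λ maps to a harmonic mode with
`ω = √(k_B T / λ)`; and the entropy is the quantum-oscillator sum

    S = k_B Σ_i [ x_i/(e^{x_i} − 1) − ln(1 − e^{−x_i}) ],   x_i = ħω_i / k_B T,

in kcal/mol/K with k_B = 1.987204×10⁻³ kcal/mol/K.  The classical
Karplus–Kushick form `k_B (1 − ln x)` is available by flag and agrees with
the quantum form within 1 % in the high-temperature limit (tested).  The
quantum form is the default because the CHARMM quasi-harmonic lineage this
analysis follows reports it.

Alignment leaves ≥ 6 near-zero rigid-body modes; modes with
λ < 10⁻⁸ amu·Å² are discarded and counted in the result.  Hydrogens are
excluded by the default heavy-atom selection; both the eigenvalue floor and
the selection are configurable, since neither is uniquely fixed by the
method's description.

The binding entropy change is `ΔS_conf = S(complex) − S(free)`, paired per
replicate; the reported error is the SEM across replicate values (matching
the triplicate convention of the source tables), not an error propagated
within one trajectory.  `−TΔS_conf` is exactly `−T` times the mean.
Convergence is monitored by recomputing S on sub-windows of the trajectory
(e.g. first/second half) — for a stationary process the halves agree within
sampling error.

### Span and frame-count conventions

Sampling schedules use ordinal nanosecond labels: "11–100 ns" denotes the
11th through 100th nanosecond, i.e. time (10 ns, 100 ns] — 90 ns — and
"1–20 ns" denotes (0, 20].  Frames sit at `t = start + k·interval`
(start-exclusive, end-inclusive), so 10-ps sampling of triplicate runs
yields 27,000 structures for the complexed span and 6,000 for the
ligand-only span.  This is the only convention consistent with those counts,
and it makes the convergence windows 11–55 / 56–100 ns tile the full span
exactly.

## Interaction detection and occupancy

Geometric criteria (all configurable, defaults from the source analysis):

- hydrogen bond: donor–hydrogen–acceptor angle ≥ 120° **and**
  donor-heavy-atom to acceptor-heavy-atom distance ≤ 3.0 Å ("heavy-atom
  distance" is read literally as D···A, not H···A; the alternative is a
  configuration switch);
- hydrophobic contact: two flagged atoms of different molecules within
  4.0 Å;
- water bridge: a *single* water H-bonded (either donor/acceptor role) to a
  ligand atom and a protein atom in the same frame; two-water chains are
  deliberately not reported.

Donor/acceptor/hydrophobic flags are explicit topology annotations, with a
derivable default (donor = N/O with bonded H; acceptor = N/O; hydrophobic =
C/S bonded only to C/S/H) the user can override — "hydrophobic atom" has no
universal definition, so explicitness keeps detections exactly reproducible.
Occupancy is the fraction of frames in which an interaction is present,
reported per atom pair or merged per residue pair (presence bitmaps OR'd).
No occupancy threshold defines "conserved"; the full table is emitted and
rows with occupancy ≥ 0.5 are annotated.

## Conformational clustering

Clustering is radius-driven k-means under RMSD distance: after each
converged assignment/update pass, every cluster whose farthest member
exceeds the radius threshold (default 1.6 Å, ligand heavy atoms) seeds a new
centroid at that member — widest cluster first — and the pass repeats until
`max(member-to-centroid RMSD) ≤ threshold`, which is asserted on every
converged model.  Splitting all violating clusters per round (rather than
only the widest, one per round) changes neither the radius contract nor the
determinism, and converges in O(log k) rounds instead of O(k).

Initialisation is deterministic: first structure, then farthest-point
seeding.  By default all structures are superposed once onto the first
structure and distances are plain Euclidean-form RMSDs ("global" mode); a
"pairwise" mode re-superposes per distance evaluation.  Ties in assignment
break to the lowest cluster index; population reports sort descending with
index tie-break, and each cluster's representative is its centroid-nearest
member.

## Synthetic data: what it emulates, and what it does not

The generators stand in for MD/FEP engine output:

- **Gaussian trajectories** — multivariate-normal coordinate fluctuations
  about a mean structure with a prescribed 3N×3N covariance, optionally
  composed with random rigid-body motions (which alignment must remove) and
  optional AR(1) frame correlation (marginal-variance preserving, for block
  tests).  Frames are i.i.d. by default: real MD is autocorrelated,
  anharmonic and multimodal, so passing entropy tests demonstrates correct
  estimation of a *harmonic* reference, not of a real ligand's entropy.
- **FEP samples** — i.i.d. Gaussians per window with exact cumulant ground
  truth; real ΔH distributions are skewed and time-correlated, so the block
  SEM's independence assumption is exact here but approximate in practice.
- **Planted complexes** — minimal protein/ligand/water sites placed ≥ 25 Å
  apart, each satisfying (or violating, for negatives) a detection criterion
  by a construction margin of ≥ 0.1 Å / 5°; waters are ideal 3-site (O,H,H)
  molecules.  Precision = recall = 1 on these fixtures shows the geometry
  tests are implemented exactly, not that real-trajectory occupancy is
  noise-free.
- **Linear ΔG(T) series** — exact `ΔG = ΔH − TΔS`, making decomposition an
  inverse-function test.

Problem sizes used by the test suite and acceptance script — 10⁵ frames for
entropy-oracle convergence, 2×10⁵ samples for the Gaussian Zwanzig check,
10⁵ samples/window × 20 windows for the toy FEP, 1,000 repeats for SEM
coverage, 5,000 structures for the flexibility comparison — were chosen as
the package's own balance between Monte-Carlo tightness (3-SE / 2 %
tolerances) and a desk-scale run.

## Numerical choices

- Kabsch superposition with the reflection (negative-determinant) branch;
  selections of < 3 non-collinear atoms leave the rotation under-determined
  and warn, but the minimised RMSD is still unique and returned (two-atom
  fits are legitimate).
- Covariance generation uses the symmetric eigendecomposition square root;
  matrices with eigenvalues below −10⁻¹⁰·max are rejected as indefinite.
- The Zwanzig estimator never forms raw exponentials (log-sum-exp).
- Quadrature for the toy reference uses adaptive integration to 10⁻¹⁰
  relative tolerance and fails loudly if not met.
- All physical constants live in one module (`alchemtraj.constants`);
  decomposition identities are therefore bit-consistent across modules.

## Known limitations

- SEMs of combined transformations assume inter-window independence.
- Entropy is configurational-only, single-trajectory quasi-harmonic: no
  anharmonic/multimodal corrections, no protein or solvent entropy.
- The interaction module detects geometry only (no π-stacking, salt-bridge
  or energetic scoring).
- I/O supports PDB/XYZ/DCD plus the documented TSV/YAML sidecars; PSF or
  PRMTOP topologies are out of scope.
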