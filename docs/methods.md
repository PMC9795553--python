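# Methods

This note documents the models, conventions and numerical choices behind
`bpbreathe`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under which assumptions, and
where the package's own design decisions lie.

## Scientific setting

A DNA adenine·thymine pair can pair in the canonical Watson–Crick (WC)
geometry, with the adenine *anti* about its glycosidic bond and an
N1(A)–N3(T) hydrogen bond, or in the Hoogsteen (HG) geometry, with the
adenine flipped ~180° to *syn*, an N7(A)–N3(T) hydrogen bond and a
shorter C1′–C1′ helix diameter. Transient WC→HG excursions ("base-pair
breathing") are rare on molecular-dynamics timescales, so studying them
combines equilibrium trajectory analysis (fluctuations, entropy,
interaction energies) with enhanced sampling on collective variables
(CVs) and free-energy-surface post-processing. This package implements
that analysis machinery and replaces the all-atom trajectories with
synthetic ensembles of known ground truth, so every stage can be
validated quantitatively on a desk.

## Collective variables and state assignment

* **χ (glycosidic angle)**: dihedral O4′–C1′–N9–C4 of the purine.
  Dihedral sign convention: `atan2((n1×n2)·û2, n1·n2)` with
  n1 = b1×b2, n2 = b2×b3 — 0° is cis, the range is (−180°, 180°], and
  the sign flips under mirror reflection. WC sits near χ ≈ −110°
  (*anti*), HG near χ ≈ +45…60° (*syn*).
* **Θ (flip pseudodihedral)**: the dihedral of the geometric
  (mass-unweighted) centres of four configurable atom groups,
  quantifying flipping toward the major (Θ > 0) or minor (Θ < 0)
  groove. The literature defers the exact group definition to earlier
  work; here the groups are supplied by the caller and the default
  convention (flipping base ring / its sugar / flanking-pair rings) is a
  documented package convention, not a claim about any particular
  original implementation.
* **State labels**: WC and HG are identified from the two donor–acceptor
  distances, which separate the states unambiguously where χ–Θ does
  not. With `bond_max` = 3.5 Å and `open_min` = 4.5 Å (configurable):
  WC ⇔ d(N1–N3) ≤ 3.5 Å and d(N7–N3) ≥ 4.5 Å; HG is the mirror
  condition; OPEN means both distances ≥ 4.5 Å; anything else is
  UNASSIGNED. The thresholds sit in the gap between the ~3 Å bonded and
  ~6 Å unbonded populations of the reference geometries; the WC and HG
  conditions are mutually exclusive whenever `bond_max < open_min`. No
  hysteresis is applied — the label is a pure function of one frame's
  geometry; callers can smooth the label series downstream.

## Quasi-harmonic entropy and RMSF

Frames are least-squares superposed (Kabsch, proper rotations enforced)
before any fluctuation statistic. The coordinate covariance
σ′_ij = ⟨(x_i−⟨x_i⟩)(x_j−⟨x_j⟩)⟩ (population normalisation, 1/n) is
mass-weighted, σ = M^{1/2} σ′ M^{1/2}, and each eigenvalue λ_i (amu·Å²)
is mapped to a harmonic-oscillator frequency ω_i = √(k_B T / λ_i). The
entropy is the exact quantum-oscillator sum

S = R Σ_i [ α_i/(e^{α_i}−1) − ln(1−e^{−α_i}) ],  α_i = ħω_i/(k_B T),

reported per mole (R = 1.98720 cal·mol⁻¹·K⁻¹; ħ, k_B CODATA 2018). A
single mode with α = 1 gives S ≈ 2.068 cal·mol⁻¹·K⁻¹, a convenient
closed-form anchor. Numerical choices:

* Rather than discarding exactly six rigid-body modes, eigenvalues
  below 10⁻⁸ amu·Å² are dropped; after superposition the rigid-body
  modes are numerically near-zero and this is robust to modes that
  split across the threshold.
* Hydrogens are excluded by selection in practice (their fast modes
  contribute little entropy and would dominate the spectrum's stiff
  end); the readers retain them and selection filters them.
* Windowed analysis follows the overlapping-segment scheme: 50 ns
  windows every 10 ns starting at 10 ns give the five segments
  10–60 … 50–100 ns on a 100 ns trajectory. Each window is superposed
  to its own mean structure (one alignment pass to the first frame, a
  second pass to the resulting mean). The window mean ± 95% CI uses the
  t interval t_{0.975,n−1}·s/√n (normal interval available by option);
  the interval construction on five points is a package choice.

RMSF is the per-atom root of the time-mean squared deviation from the
time-mean position (3-D norm), after superposition. The HG/WC RMSF
ratio is elementwise, with optional residue-level averaging of atom
RMSFs before division; zero denominators yield NaN, never infinity.

## Nonbonded energetics

Interaction energies between two disjoint atom selections are direct
sums over cross pairs of Coulomb (C·q_a q_b/r, C = 332.0636
kcal·Å·mol⁻¹·e⁻²) plus 12-6 Lennard-Jones
ε_ab[(R_ab/r)¹² − 2(R_ab/r)⁶] with Lorentz–Berthelot combination
(ε_ab geometric, R_ab = Rmin/2_a + Rmin/2_b). Two cutoff schemes mirror
the two force-field families' production settings: a CHARMM-style
cubic switch S(r) = (c²−r²)²(c²+2r²−3s²)/(c²−s²)³ between 10 and 12 Å,
and a hard truncation at 9 Å. The switch multiplies both components
(energy switching); whether the original post-processing switched
electrostatics and vdW separately is not documented, so the single
multiplicative switch is this package's stated simplification. No
periodic images, no Ewald, no 1-2/1-3/1-4 exclusions: the contract is
the direct selection–selection energy used in trajectory
post-processing (base–base, base-pair–duplex, stacking), and
overlapping selections are rejected outright. Parameter tables are
plain CSV of (residue_name, atom_name, charge, ε, Rmin/2); shipped
fixtures carry toy values, not real force-field parameters.

## Free-energy landscapes

PMF grids are 1-D/2-D arrays of free energies (kcal/mol) at bin
centres; angular axes wrap periodically, distance axes do not; NaN
marks unvisited bins, which are impassable to path searches and
excluded from convergence statistics. Grids are anchored so the lowest
visited value is 0. The text format is a colvars-style dialect: a
dimension line, one header line per axis (name, lower edge, bin width,
bin count, periodic flag), then one value per line in row-major order;
floats are written at repr precision so the round trip is exact.

* **ΔG between basins** is min-to-min over rectangular CV regions —
  appropriate for sharply peaked basins; it is not a basin integral.
* **Minimum free-energy paths** use the watershed (minimax) criterion:
  among simple 8-neighbour paths (periodic wrap where flagged), choose
  the one minimising the highest node energy. The node-by-node search
  this mirrors is barrier-oriented; minimax is its well-defined
  formalisation. Implementation: widest-path Dijkstra fixes the optimal
  barrier; a second, additive Dijkstra restricted to nodes at or below
  that barrier breaks ties by smaller cumulative node energy, then
  fewer nodes (cumulative energy measured after shifting the grid
  minimum to zero so edge weights are non-negative — the tie-break
  convention is this package's). A cumulative-sum path mode is the same
  second phase without the barrier restriction.
* **Reweighting** onto new CVs: each biased-trajectory sample carries
  the converged free energy A(ξ) along the biased CVs. Because the
  bias is a function of ξ only, the orthogonal degrees of freedom are
  Boltzmann-distributed conditional on ξ, so the exact unbiased weight
  is exp(−A(ξ)/k_BT)/ρ̂(ξ), with ρ̂ the empirical sampling density of
  the sample's biased-CV bin. When the sampling is assumed flat (a
  converged adaptive-bias run) the density factor drops and
  w ∝ exp(−A(ξ)/k_BT). The weighted histogram over the new CVs becomes
  −k_BT ln(density), anchored. Validation is against synthetic ground
  truth only (samples drawn from a known biased ring density recover
  the unbiased potential to ≈0.01 kcal/mol RMS at 10⁶ samples).
* **Convergence** is the RMS difference between consecutive anchored
  grids over commonly visited bins.

## Toy meta-eABF sampler

Langevin dynamics (BAOAB splitting) on analytic periodic model
potentials, with the meta-eABF bias acting on a fictitious particle
harmonically coupled to the CV. Units: kcal/mol, degrees, ps. Defaults:

| parameter | default | note |
|---|---|---|
| temperature | 298 K | k_BT = 0.5925 kcal/mol |
| friction γ | 5 ps⁻¹ | BAOAB O-step |
| timestep | 0.02 ps | ≥50 steps per spring period |
| particle mass | 10⁻³ kcal·mol⁻¹·ps²·deg⁻² | sets velocity scale |
| fictitious mass | 2×10⁻² (same units) | slow extended dynamics |
| coupling κ | 100 kcal·mol⁻¹·rad⁻² | ≈0.0305 per deg² |
| hill height | 0.06 kcal/mol | production setting |
| hill width w | 15° | Gaussian h·e^{−Δ²/2w²} |
| deposit interval | 100 steps (2 ps) | production setting |
| ABF bin | 5° | production setting |
| ABF activation | 1000 samples/bin | hard threshold |

The coupling is quoted per radian²: per degree² the spring would be
~3000× stiffer than the potential curvature and the thermal spring
width meaninglessly small. At κ = 100 kcal/mol/rad² the width
√(k_BT/κ) ≈ 4.4° is commensurate with the 5° bin, and the implied
Gaussian smoothing attenuates a 3 kcal/mol cosine barrier by ~1%.

Each step deposits one ABF sample in the fictitious coordinate's bin:
the instantaneous spring force on the fictitious particle,
κ·minimage(x−λ). Conditional on λ, x is Boltzmann-distributed under
U(x) + κ(x−λ)²/2 *regardless of any λ-only bias* (hills and ABF act on
λ alone), so the per-bin mean of this sample is an unbiased estimator
of −dA/dλ of the spring-smoothed free energy. Consequences:

* The applied ABF force, −(force sum)/count once the bin holds its
  threshold samples, cancels the mean force; metadynamics hills
  (accumulated on a 0.5° grid for speed; the public `meta_bias` sums
  hills directly) flatten what remains and accelerate early
  exploration before bins activate.
* The PMF estimate is the trapezoidal integral of the negated per-bin
  mean force, with the profile's mean gradient removed on a ring (the
  true gradient integrates to zero around a cycle; the removal
  suppresses integration drift), anchored to zero. No hill-sum term
  enters the estimator: because the conditional mean-force identity
  holds exactly under λ-only biases, adding the hill potential would
  double-count the bias. More elaborate estimators (CZAR, umbrella
  integration) are out of scope.

On a 3 kcal/mol periodic cosine double well, 5×10⁶ steps recover the
PMF with RMSE ≈ 0.03–0.08 kcal/mol and every 5° bin holds ≳5×10⁴
samples. The unbiased sampler's ring histogram is checked against
exp(−U/k_BT) by chi-square; since chi-square assumes independent
counts and the slow observable is well occupancy, the check strides
samples past the well-exchange correlation time (control conditions:
1 kcal/mol barrier, γ = 1 ps⁻¹, every 10⁴th step; the empirical
p-value distribution under these conditions was verified to be
consistent with uniform across seeds).

## Synthetic data: what it emulates, what it does not

* **Base-pair templates** place only the atoms the CVs and classifier
  need (adenine C1′, O4′, N9, C4, N1, N7; thymine N3, C1′) on an
  idealised adenine base frame, solving for O4′ (target χ), thymine N3
  (in-plane circle intersection for the two donor–acceptor distances)
  and thymine C1′ (helix diameter). They reproduce the reference mean
  geometries of all four force-field models exactly but are geometric
  scaffolds, not chemically complete nucleotides.
* **Gaussian ensembles** add exactly specified correlated displacements
  to a template, giving closed-form covariance spectra, entropies and
  RMSFs. Real trajectories are neither Gaussian nor harmonic, and their
  covariance converges far more slowly; passing these tests validates
  the estimator algebra, not force-field entropies.
* **CV transition series** switch a two-state Markov chain between WC
  and HG and emit distances/χ as Gaussians around the reference means
  with the reference SDs. With the CHARMM27 HG spread (3.12 ± 0.30 Å),
  ~10% of genuine HG frames drift past the 3.5 Å bond cutoff and are
  labelled UNASSIGNED — the honest behaviour of a hard threshold; the
  assigned labels are >99% correct.
* **Toy PMFs** are sums of periodic Gaussian wells with ground-truth
  minima, ΔG, and a watershed barrier computed by threshold-connectivity
  flood fill — an algorithm independent of the Dijkstra path search it
  validates.
* **Charged clusters** are random non-overlapping (≥1.5 Å) charged LJ
  atoms with toy parameters for O(N²) energy oracles.

All generators are pure functions of their parameters and a mandatory
seed.

## Problem sizes used in validation

Entropy/RMSF ensembles use 5×10⁴ frames (sampling error well inside the
2% comparisons); reweighting uses 10⁶ samples on a 72-bin ring; the
path-search cross-check enumerates all simple paths on 200 random 4×4
grids; the sampler validation runs 5×10⁶ steps (the numba-compiled
inner loop makes this a few seconds). These sizes are the package's
documented validation conditions.

## Known limitations

* No PSF/prmtop parsing, no solvent, no periodic-image wrapping of
  coordinates; parameters come from plain CSV tables.
* Energies are direct nonbonded sums — no PME/Ewald, no polarisation;
  quantum π-stacking is out of scope (distinct from the classical
  stacking energies computed here).
* Entropy is quasi-harmonic only: no Schlitter variant, no solvent
  entropy, no mutual-information corrections; it upper-bounds
  configurational entropy under the harmonic-mode assumption.
* ΔG between basins is min-to-min, not a Boltzmann basin integral.
* The sampler supports 1-D periodic CVs in the fast path; it is a
  model-potential tool and makes no claim of equivalence to any
  production enhanced-sampling engine's extended-system settings.
* PMF error bars by block analysis are not computed; convergence is
  reported as consecutive-grid RMS only.
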