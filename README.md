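# bpbreathe

Analysis machinery for DNA base-pair breathing: the transition of an
A·T pair between Watson–Crick (WC) pairing — purine *anti*, N1(A)–N3(T)
hydrogen bond — and Hoogsteen (HG) pairing — purine flipped ~180° to
*syn*, N7(A)–N3(T) bond, shorter C1′–C1′ helix diameter. The package
provides, as a tested library plus a thin CLI, the pieces such a study
needs:

* **Collective variables & state assignment** — glycosidic angle
  χ = ∠(O4′–C1′–N9–C4), flip pseudodihedral Θ of four group centres,
  donor–acceptor distances, and a WC/HG/OPEN classifier on
  d(N1–N3)/d(N7–N3) with thresholds 3.5/4.5 Å.
* **Fluctuations** — Kabsch superposition, mass-weighted covariance,
  quasi-harmonic entropy
  S = R Σᵢ[αᵢ/(e^{αᵢ}−1) − ln(1−e^{−αᵢ})], αᵢ = ħωᵢ/k_BT,
  ωᵢ = √(k_BT/λᵢ), per-atom RMSF and HG/WC RMSF ratios, overlapping
  50 ns windows with t-based 95% confidence intervals.
* **Nonbonded energetics** — Coulomb + 12-6 Lennard-Jones
  selection–selection sums with CHARMM-style switching (10/12 Å) or
  truncation (9 Å), including base-stacking energies.
* **Free-energy landscapes** — colvars-dialect PMF grid I/O, basin ΔG,
  minimax (watershed) minimum-free-energy paths with periodic wrap,
  reweighting of biased samples onto new CVs, convergence diagnostics.
* **Toy meta-eABF sampler** — BAOAB Langevin dynamics on analytic
  periodic potentials with metadynamics hills (0.06 kcal/mol, 15°)
  plus extended-system ABF (5° bins, 1000-sample activation) on a
  harmonically coupled fictitious particle; numba-compiled inner loop.
* **Synthetic data** — WC/HG base-pair templates reproducing the
  reference mean geometries of four nucleic-acid force fields
  (CHARMM27/36, AMBER bsc0/bsc1), Gaussian ensembles with closed-form
  entropy, Markov CV series with ground-truth labels, analytic
  multi-well PMFs, charged LJ clusters.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

```python
import numpy as np
from bpbreathe import synthetic, cvs, fluctuations as fl, classify_state

# an idealised Hoogsteen A·T fragment and its observables
hg = synthetic.build_basepair_template("HG", "CHARMM27")
g = cvs.basepair_geometry(hg, adenine_id=1, thymine_id=2)
print(f"chi={g.chi:.1f}  dN1N3={g.d_N1N3:.2f}  dN7N3={g.d_N7N3:.2f}  "
      f"dC1C1={g.d_C1C1:.2f}  state={classify_state(g).value}")

# quasi-harmonic entropy of a Gaussian ensemble with known covariance
rng = np.random.default_rng(7)
n3 = 3 * hg.n_atoms
a = rng.standard_normal((n3, n3)) * 0.1
cov = a @ a.T + 0.05 * np.eye(n3)
ens = synthetic.gaussian_ensemble(hg, cov, n_frames=50_000, seed=11)
s = fl.quasiharmonic_entropy(fl.mass_weighted_covariance(ens), temperature=298.0)
sm = np.sqrt(np.repeat(hg.masses(), 3))
s_exact = fl.entropy_from_eigenvalues(
    np.linalg.eigvalsh(cov * np.outer(sm, sm)), 298.0)
print(f"S = {s:.2f} cal/mol/K  (closed form {s_exact:.2f})")
```

prints

```
chi=46.7  dN1N3=5.90  dN7N3=3.12  dC1C1=8.88  state=HG
S = 112.19 cal/mol/K  (closed form 112.21)
```

— the fragment reproduces the HG reference geometry and is labelled HG
by the donor–acceptor rule, and the entropy estimated from 50,000
frames agrees with the closed form evaluated on the specified
mass-weighted spectrum to ~0.02 cal/mol/K.

Recovering a free-energy profile with the biased sampler:

```python
from bpbreathe import sampler as sp
pot = sp.cosine_double_well(3.0)   # wells at 0/±180°, 3 kcal/mol barrier
cfg = sp.MetaEABFConfig(langevin=sp.LangevinParams(n_steps=5_000_000, seed=3), seed=3)
res = sp.run_meta_eabf(pot, cfg)   # PMFGrid + CV trajectory + bias state
```

The estimated PMF matches the analytic double well with RMSE
≈ 0.03 kcal/mol.

The same operations are available from the shell, e.g.

```bash
bpbreathe generate --kind basepair --state HG --out hg
bpbreathe --seed 3 generate --kind gaussian --n 1000 --out ens
bpbreathe cvs --structure hg.pdb --trajectory ens.dcd --out cvs.csv
bpbreathe --seed 2 sample --steps 1000000 --out run   # PMF + CV + hill logs
```

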