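# thermogal

Structural thermostability profiling and galactan degradation analysis for
GH53 endo-β-1,4-galactanases.

GH53 galactanases hydrolyse internal β-1,4 bonds of galactan. Family members
range from mesophilic fungal and bacterial enzymes to a hyperthermostable
archaeal one, which makes the family a natural testbed for asking *which
structural features track thermal adaptation* and *how subsite architecture
shapes the oligosaccharide product profile*. `thermogal` packages the
computational side of that analysis:

* **Interaction profiling** — detects salt bridges (side-chain N⁺⋯carboxylate
  O⁻ ≤ 4.0 Å), hydrogen bonds (heavy-atom donor–acceptor ≤ 3.5 Å), π–π
  stacking (aromatic ring-centroid distance ≤ 7.2 Å), cation–π contacts
  (Lys NZ / Arg CZ within 6.0 Å of a ring centroid and ≤ 60° off the ring
  normal), disulfides (SG–SG ≤ 2.5 Å) and metal (Ca²⁺) coordination
  (O/N ≤ 3.0 Å) in PDB-format structures.
* **Helix-dipole and composition metrics** — charged residues in the first /
  last three helix residues stabilize or destabilize the helix dipole
  (positive at the C-terminus stabilizes, negative destabilizes; vice versa
  at the N-terminus); plus the Pro/Gly ratio.
* **Compactness** — Shrake–Rupley SASA (deterministic golden-spiral points),
  grid-integrated van der Waals and solvent-excluded envelope volumes,
  packing density, surface/volume ratio.
* **Phenotype correlation** — per-structure feature table with temperature
  optima (°C) and the Pearson r of every feature against the optimum, with
  and without an exclusion set.
* **Degradation profiles** — degree of hydrolysis
  DoH = reducing ends / (load / 162.14 g mol⁻¹), mass-balance estimation of
  oligosaccharides longer than G5, small-integer endpoint product ratios,
  and Michaelis–Menten fits (Km, kcat, kcat/Km with 95 % CIs).
* **Trajectory RMSF** — Kabsch superposition of every frame onto the first,
  then per-residue root-mean-square fluctuation.
* **Synthetic data** — generators for planted-interaction structures with an
  exact ground-truth manifest, a Gillespie endo-hydrolysis digest simulator
  built on a subsite occupancy model (bond k of a chain of length L cleaves
  with weight `min(k, n₋)·min(L−k, n₊)`, chains ≤ the inert length are never
  cut), jittered trajectories with optional side-chain flips, and noisy
  kinetics tables.

## Worked example

Simulate a digest with an archaeal-like enzyme (inert length 3: galactotriose
is bound non-productively, never cut), then quantify it:

```python
import numpy as np
from thermogal import synthetic_data as syn, degradation as dg

spec = syn.DigestSpec(n_chains=50, chain_length=12, archetype="iagal_like",
                      sampling_times=[0.01, 0.1, 1.0, 10.0], seed=1)
series = syn.simulate_endo_hydrolysis(spec)
for tp in series:
    print(f"t={tp.time:<6g} DoH={dg.compute_doh(tp.sample):6.2f}%  "
          f"G>5={dg.estimate_g_gt5(tp.sample):.3f} mM")
```

```
t=0.01   DoH= 12.17%  G>5=1.028 mM
t=0.1    DoH= 33.83%  G>5=0.267 mM
t=1      DoH= 45.50%  G>5=0.000 mM
t=10     DoH= 45.50%  G>5=0.000 mM
```

DoH climbs as bonds are cut and plateaus when only inert chains (length ≤ 3)
remain; the G>5 pool (chains longer than galactopentaose, estimated as
reducing ends minus the quantified G1..G5) is consumed on the way — the same
qualitative shape seen in real digests of lupin galactan. Fitting synthetic
Michaelis–Menten data generated with Km = 0.47 mg ml⁻¹ and kcat = 34 s⁻¹:

```python
s, v = syn.generate_kinetics(0.47, 34.0, 1e-3, 45000.0,
                             np.geomspace(0.05, 5, 10), noise_cv=0.02, seed=1)
fit = dg.fit_michaelis_menten(s, v, enzyme_conc=1e-3, enzyme_mw=45000.0)
print(f"Km = {fit.km:.3f} mg/ml, kcat = {fit.kcat:.1f} /s, "
      f"kcat/Km = {fit.efficiency:.1f} ml/mg/s")
# Km = 0.475 mg/ml, kcat = 34.3 /s, kcat/Km = 72.2 ml/mg/s
```

A command-line interface mirrors the library:

```sh
thermogal simulate digest --seed 1 -o out/
thermogal digest --input out/digest.tsv -o out/profile.tsv
thermogal features --pdb-dir structures/ --phenotypes topt.tsv -o features.tsv
thermogal correlate --features features.tsv --exclude 6GP5 -o cc.tsv
thermogal rmsf --traj frames.pdb -o rmsf.tsv
```

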