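# Methods

This note documents the models behind `thermogal`, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
known limitations. Nothing here states a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate model and PDB I/O

Structures are parsed from fixed-column PDB text (ATOM/HETATM/HELIX; first
MODEL only) into a small chain → residue → atom hierarchy. Alternate
locations are resolved to the highest-occupancy copy, ties broken by the
lexicographically smallest altloc character — deterministic and in line with
common practice. Residue identity is (chain, author seq number, insertion
code). Hydrogens are retained when present but ignored by every detector
(the reference crystal structures are X-ray without hydrogens). Non-standard
residues are hetero unless added to a configurable polymer whitelist.
Writing emits fixed-column text; write∘parse preserves coordinates to the
PDB's three decimals (≤ 0.5 mÅ per axis).

## Interaction detectors

All criteria are geometric, on heavy atoms, with one record per unordered
residue pair carrying the minimum qualifying distance:

* **Salt bridges** — basic side-chain N (Arg NH1/NH2/NE, Lys NZ, His
  ND1/NE2) to carboxylate O (Glu OE1/OE2, Asp OD1/OD2), cutoff 4.0 Å.
* **Hydrogen bonds** — distance-only heavy-atom criterion, cutoff 3.5 Å,
  with an explicit donor/acceptor dictionary (backbone N/O plus the polar
  side-chain atoms; see `interactions.HBOND_DONORS/ACCEPTORS`, configurable
  per call). Intra-residue pairs and backbone–backbone pairs of sequence
  neighbours (|i−j| < 2) are excluded: those contacts are covalently
  constrained, not hydrogen bonds. A distance-only rule without angles is a
  deliberate, reproducible approximation for hydrogen-free crystal
  structures; it over-counts relative to angle-aware assignments (e.g. an
  ideal α-helix shows i→i+2..i+4 backbone pairs within 3.5 Å, not only the
  canonical i→i+4), uniformly across structures, which is what a
  cross-structure correlation needs.
* **π–π** — ring centroids of Phe, Tyr, His (one ring) and Trp (both
  rings), cutoff 7.2 Å on the closest centroid pair; sequence-adjacent
  aromatic pairs are excluded. Manual visual pruning of spurious stacks is
  not reproducible; the deterministic one-record-per-pair rule plus the
  adjacency exclusion replaces it (documented divergence).
* **Cation–π** — Lys NZ or Arg CZ within 6.0 Å of a ring centroid and
  within 60° of the ring normal (sign-insensitive). This geometric criterion
  replaces force-field energy scoring; His rings count as π partners but His
  is not treated as a cation, matching the aromatic set used for π–π.
  Thresholds configurable.
* **Disulfides** — Cys SG–SG ≤ 2.5 Å.
* **Metal coordination** — every O/N (protein or water) within 3.0 Å of a
  metal atom; bidentate carboxylates contribute one ligand per oxygen, which
  is what lets a bidentate glutamate site reach coordination number 7 where
  a monodentate one reaches 6.

Ring normals come from the least-squares plane (smallest-singular-vector of
the centred ring coordinates). No occupancy or B-factor weighting anywhere.

## Helix dipole and composition

Helices come from HELIX records when present, otherwise from backbone
dihedrals: maximal runs of ≥ 4 residues with φ ∈ [−100°, −30°] and
ψ ∈ [−80°, −5°]; chain-terminal residues with only one defined angle are
judged on that angle so an ideal helix spans its full length. Scoring
inspects exactly the first and last three helix residues: positive residues
(Lys, Arg, His) stabilize at the C-terminus and destabilize at the
N-terminus; negative residues (Glu, Asp) the reverse. A helix is
"stabilized" when stabilizing effects outnumber destabilizing ones. For
helices shorter than six residues the windows overlap and a residue counts
once per window (with a warning). Both per-helix counts and per-structure
totals are exposed, since either aggregate is a defensible summary. The
score is a pure function of sequence and helix bounds.

## Compactness

SASA is Shrake–Rupley with 960 deterministic golden-section-spiral points
per atom and probe 1.4 Å; Bondi radii (C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20, P 1.80 Å; unknown elements fall back to 1.70 Å with a warning).
Determinism makes runs exactly reproducible; 960 points put a single-atom
sphere within 1 % of 4π(r+1.4)².

Volumes are grid integrals at 0.5 Å spacing: the van der Waals volume is the
measure of cells whose centres lie in the union of vdW spheres; the total
(solvent-excluded envelope) volume inflates every sphere by the probe and
then erodes the occupied grid by a probe-radius ball
(`scipy.ndimage.binary_erosion`). The rasterized erosion ball uses a
half-cell radius compensation — without it the eroded boundary sits
systematically inside the true one and the volume converges only linearly in
the spacing; with it, halving the spacing moves the envelope volume of a
40-atom cluster by < 1 %. The envelope is forced to contain the vdW union on
the grid, so packing density = vdW/total ≤ 1 by construction. A probe-radius
convergence series (as used by dedicated volume tools) is replaced by this
single fixed grid; the approximation is documented rather than hidden.

## Feature table and correlation

One row per structure: salt_bridges, hbonds, pi_pi, cation_pi, disulfides,
stabilized_helices, dipole_net, pro_gly_ratio, sasa, total_volume,
packing_density, surface_to_volume, plus the phenotype t_opt in °C. Default
temperature optima for the seven structurally characterized GH53 enzymes are
shipped (7OSK 95 — reported as "at least 95", 1R8L 40, 6GP5 37 — an
assumption from the organism's gut niche, 1FOB 50, 4BF7 49, 1HJQ 65,
1HJS 65) and are configurable. Correlation is the plain Pearson
product-moment r per feature, reported with and without an exclusion set
(conventionally the niche-assumed structure); no p-values or
multiple-testing correction, since single raw coefficients over ≤ 7
structures carry no defensible inferential weight. Which chain of a
multi-chain entry is analysed is a flag, defaulting to the first chain.

## Degradation quantification

The theoretical maximum of reducing ends uses the anhydrogalactose residue
mass 162.14 g mol⁻¹ (the mass of a galactose unit *inside* a chain), not
free galactose (180.16): hydrolysis adds water, so the monomer count of a
load of polymer is load/162.14. The convention is configurable. DoH =
100 × reducing ends / maximum; up to 5 % assay excess clips to 100 % with a
warning, more raises. G>5 = reducing ends − Σ(G1..G5) in chain-molar
(reducing-end-equivalent) mM — every chain has exactly one reducing end —
with negative noise clipped to zero; multiplying by the mean length of the
pool would give monomer-equivalents, and the chain-molar convention is the
one consistent with the subtraction definition. Endpoint ratios search
integer tuples over denominators ≤ 10; candidates whose worst relative error
is within 5 % (the assay-noise scale) of the best are ties, resolved to the
smallest integer sum, so (1.48, 1.02, 2.97) mM still reads 3:2:6 rather than
a noise-fit 10:7:20.

Michaelis–Menten fits use `scipy.optimize.curve_fit` on v = Vmax·s/(Km+s)
with data-driven starts and restarts; kcat = Vmax/[E] with [E] from the
enzyme mass concentration and molar mass (rates in mM s⁻¹). 95 % CIs come
from the linearized covariance with t(n−2) quantiles; a profile-likelihood
CI (F-threshold on the residual sum of squares) is available behind
`ci_method="profile"`. Fits with non-finite covariance, non-positive
estimates, or a Km CI half-width more than ten times the estimate raise as
unidentifiable — a rate table flat in s (pure zero-order regime) fails
rather than returning a meaningless Km.

## Trajectory RMSF

Every frame is superposed onto frame 0 by the Kabsch algorithm (SVD
closed form, proper rotation enforced so mirror images keep a positive
residual; collinear point sets are rejected). Alignment defaults to Cα
atoms; RMSF is computed on all heavy atoms and aggregated per residue as the
root mean square of the per-atom values, so side-chain motions — e.g. a
subsite tryptophan alternating between conformers — remain visible.
Deviations are measured from frame 0 (the simulation's starting structure),
not from the time-averaged structure; this is a documented divergence from
the more common mean-reference convention and yields slightly larger values.
Input formats: multi-MODEL PDB or whitespace xyz frames; no binary
trajectory formats.

## Synthetic generators

* **Planted structures.** Idealized residue templates (anchor atom or ring
  centroid at a local origin, body extending away) are placed pairwise on a
  30 Å lattice — far beyond every cutoff — so each planted pair realises
  exactly one interaction at its target distance and nothing else; decoys
  sit ≥ 0.2 Å outside their cutoff (or inside the distance cutoff but at 90°
  for angle-rejected cation–π decoys). Planted distance windows are chosen
  so every pair belongs to exactly one interaction class (e.g. salt bridges
  at 3.6–3.95 Å, above the 3.5 Å hydrogen-bond window, since an N⁺⋯O⁻
  contact below 3.5 Å would legitimately register as both); this keeps the
  ground-truth manifest unambiguous. A seeded random rigid motion of the
  whole structure exercises rotation invariance without changing any
  distance. What this does **not** emulate: real packing density, crowded
  environments where interactions overlap and compete, missing atoms,
  alternate conformers. Passing the detector–oracle equivalence on these
  fixtures shows the geometry and bookkeeping are right, not that cutoffs
  are biologically optimal.
* **Digest simulator.** Chains are integer lengths; bond k of a chain of
  length L > inert_length cleaves with weight min(k, n₋)·min(L−k, n₊) — the
  number of sugar-binding subsites occupied on each side of the catalytic
  centre — via an exact Gillespie algorithm (exponential waiting times,
  integer census bookkeeping, mass conservation exact by construction).
  Archetypes: fungal (2, 2, inert 2 — degrades G3, accumulates G1/G2),
  iagal_like (3, 2, inert 3 — binds G3 non-productively), blgal_like
  (4, 2, inert 3 — the extra negative subsite does not block G4 cleavage).
  The subsite counts and inert lengths are interpretive choices encoding the
  observed product floors; the rate law is a minimal occupancy model — no
  rate law is published, and any law monotone in occupancy preserves every
  property the tests assert (conservation, monotone DoH, absorbing states).
  Transglycosylation and polymer branching (arabinan side chains) are not
  simulated.
* **Trajectories.** A helical Cα trace (radius 8 Å, rise 1.5 Å per residue;
  well-spread in all three directions so alignment is well conditioned) with
  five atoms per residue; frame 0 is the noise-free reference and later
  frames add isotropic Gaussian jitter of σ per axis, so the expected
  per-atom RMSF is σ√3. An optional two-state flip displaces one residue's
  side-chain atom from a switch frame onward; an optional global rigid
  motion per frame must be removed by alignment.
* **Kinetics.** v = Vmax·s/(Km+s) with multiplicative Gaussian noise of a
  given CV, seeded.

All generators are deterministic given (spec, seed).

## Problem sizes and numerical defaults

The shipped tests and acceptance script use: 100 fuzzed planted structures
(≤ 500 atoms each); digests of 25–60 chains of length 4–25; 5000-frame /
30-residue trajectories for the jitter expectation (Monte-Carlo error well
under the 3 % check); 100 Monte-Carlo seeds for CI coverage; 0.5 Å volume
grids on ≤ 40-atom clusters. These sizes give stable statistics while
keeping a full run in seconds; all are parameters, not limits.

## Known limitations

* Hydrogen bonds and cation–π use geometric stand-ins for angle- and
  energy-aware criteria; absolute counts are not comparable to other tools,
  only internally consistent across structures.
* The π–π visual-pruning step of manual analyses is replaced by a
  deterministic rule; per-structure counts can differ from manually curated
  ones even when the cross-structure trend is preserved.
* Grid volumes and spiral-point SASA are approximations with stated
  convergence behaviour, not analytic alpha-shape values.
* The digest simulator's rate law is phenomenological; it reproduces
  endpoint compositions and conservation laws, not absolute time scales.
* mmCIF, assemblies, anisotropic B-factors and binary trajectory formats
  are out of scope.
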