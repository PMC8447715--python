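"""Synthetic inputs with known ground truth for every analysis stage.

Four generator families:

* planted-interaction structures: idealized residue templates placed on a
  widely spaced lattice so that each planted pair realises exactly one
  interaction at a chosen distance, with decoys strictly outside the
  cutoffs; the whole structure then receives one random rigid motion,
* a stochastic endo-hydrolysis (Gillespie) digest simulator over galactan
  chains with a subsite occupancy rate law, with exact integer bookkeeping,
* trajectories with Gaussian positional jitter and an optional two-state
  side-chain flip (emulating a subsite tryptophan alternating between two
  conformers), and
* Michaelis-Menten rate tables with multiplicative Gaussian noise.

All generators are deterministic for a given (spec, seed).

Subsite archetypes for the digest simulator: the enzyme groove is modelled
as ``n_minus`` galactose-binding subsites on the non-reducing side of the
catalytic centre and ``n_plus`` on the reducing side. A chain of length L
can be cut at bond k (between units k and k+1) with rate weight
``min(k, n_minus) * min(L-k, n_plus)`` -- the number of occupied subsites on
each side -- and chains no longer than ``inert_length`` are never cut
(non-productive binding). The presets encode the observed product floors:
fungal-type enzymes degrade galactotriose (inert length 2, final products
G1/G2); an IaGal-like archaeal enzyme binds G3 non-productively (inert
length 3); a BlGal-like bacterial enzyme degrades G4 but not G3 despite its
extra negative subsite (inert length 3).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .degradation import ANHYDRO_GALACTOSE_MASS, DigestSample
from .structure_io import AtomRecord, Residue, StructureModel
from .trajectory import Trajectory

__all__ = [
    "PlantSpec",
    "DigestSpec",
    "DigestTimePoint",
    "GroundTruth",
    "ARCHETYPES",
    "generate_planted_structure",
    "random_plant_spec",
    "generate_calcium_site",
    "simulate_endo_hydrolysis",
    "generate_trajectory",
    "generate_kinetics",
]

# ---------------------------------------------------------------------------
# planted-interaction structures
# ---------------------------------------------------------------------------

# Idealized side-chain templates. Convention: the "anchor" atom (or ring
# centroid) sits at the origin and the rest of the residue extends towards
# negative x, so that two residues facing each other realise their planted
# distance only between the intended groups.
# Each entry: residue name -> list of (atom_name, element, (x, y, z)).
_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "LYS": [
        ("NZ", "N", (0.0, 0.0, 0.0)),
        ("CE", "C", (-1.48, 0.0, 0.0)),
        ("CD", "C", (-2.20, 1.20, 0.0)),
        ("CG", "C", (-3.70, 1.20, 0.0)),
        ("CB", "C", (-4.40, 2.40, 0.0)),
        ("CA", "C", (-5.90, 2.40, 0.0)),
        ("N", "N", (-6.50, 3.60, 0.50)),
        ("C", "C", (-6.60, 1.20, -0.30)),
        ("O", "O", (-7.80, 1.20, -0.30)),
    ],
    "GLU": [
        ("OE1", "O", (0.0, 0.0, 0.0)),
        ("CD", "C", (-0.85, 0.90, 0.0)),
        ("OE2", "O", (-0.50, 2.10, 0.0)),
        ("CG", "C", (-2.35, 0.90, 0.0)),
        ("CB", "C", (-3.05, 2.10, 0.20)),
        ("CA", "C", (-4.55, 2.10, 0.20)),
        ("N", "N", (-5.15, 3.30, 0.50)),
        ("C", "C", (-5.25, 0.90, 0.0)),
        ("O", "O", (-6.45, 0.90, 0.0)),
    ],
    "ASP": [
        ("OD1", "O", (0.0, 0.0, 0.0)),
        ("CG", "C", (-0.85, 0.90, 0.0)),
        ("OD2", "O", (-0.50, 2.10, 0.0)),
        ("CB", "C", (-2.35, 0.90, 0.0)),
        ("CA", "C", (-3.05, 2.10, 0.20)),
        ("N", "N", (-2.55, 3.30, 0.50)),
        ("C", "C", (-4.55, 2.10, 0.20)),
        ("O", "O", (-5.25, 3.10, 0.20)),
    ],
    "SER": [
        ("OG", "O", (0.0, 0.0, 0.0)),
        ("CB", "C", (-1.42, 0.0, 0.0)),
        ("CA", "C", (-2.10, 1.30, 0.0)),
        ("N", "N", (-1.60, 2.50, 0.40)),
        ("C", "C", (-3.60, 1.30, 0.0)),
        ("O", "O", (-4.30, 2.30, 0.0)),
    ],
    "GLN": [
        ("OE1", "O", (0.0, 0.0, 0.0)),
        ("CD", "C", (-0.85, 0.90, 0.0)),
        ("NE2", "N", (-0.50, 2.15, 0.0)),
        ("CG", "C", (-2.35, 0.90, 0.0)),
        ("CB", "C", (-3.05, 2.10, 0.20)),
        ("CA", "C", (-4.55, 2.10, 0.20)),
        ("N", "N", (-5.15, 3.30, 0.50)),
        ("C", "C", (-5.25, 0.90, 0.0)),
        ("O", "O", (-6.45, 0.90, 0.0)),
    ],
    "CYS": [
        ("SG", "S", (0.0, 0.0, 0.0)),
        ("CB", "C", (-1.80, 0.0, 0.0)),
        ("CA", "C", (-2.50, 1.30, 0.0)),
        ("N", "N", (-2.00, 2.50, 0.40)),
        ("C", "C", (-4.00, 1.30, 0.0)),
        ("O", "O", (-4.70, 2.30, 0.0)),
    ],
    # Aromatic templates: the (first) ring lies in the z = 0 plane with its
    # centroid at the origin; the ring normal is +z.
    "PHE": [
        ("CG", "C", (-1.39, 0.0, 0.0)),
        ("CD1", "C", (-0.695, 1.204, 0.0)),
        ("CD2", "C", (-0.695, -1.204, 0.0)),
        ("CE1", "C", (0.695, 1.204, 0.0)),
        ("CE2", "C", (0.695, -1.204, 0.0)),
        ("CZ", "C", (1.39, 0.0, 0.0)),
        ("CB", "C", (-2.90, 0.0, 0.0)),
        ("CA", "C", (-3.60, 1.30, 0.0)),
        ("N", "N", (-3.10, 2.50, 0.40)),
        ("C", "C", (-5.10, 1.30, 0.0)),
        ("O", "O", (-5.80, 2.35, 0.0)),
    ],
    "HIS": [
        ("CG", "C", (-1.17, 0.0, 0.0)),
        ("ND1", "N", (-0.36, 1.11, 0.0)),
        ("CE1", "C", (0.95, 0.69, 0.0)),
        ("NE2", "N", (0.95, -0.69, 0.0)),
        ("CD2", "C", (-0.36, -1.11, 0.0)),
        ("CB", "C", (-2.67, 0.0, 0.0)),
        ("CA", "C", (-3.37, 1.30, 0.0)),
        ("N", "N", (-2.87, 2.50, 0.40)),
        ("C", "C", (-4.87, 1.30, 0.0)),
        ("O", "O", (-5.57, 2.30, 0.0)),
    ],
    "TRP": [
        # 6-ring (benzene moiety), centroid at the origin
        ("CE2", "C", (0.0, 1.39, 0.0)),
        ("CZ2", "C", (1.204, 0.695, 0.0)),
        ("CH2", "C", (1.204, -0.695, 0.0)),
        ("CZ3", "C", (0.0, -1.39, 0.0)),
        ("CE3", "C", (-1.204, -0.695, 0.0)),
        ("CD2", "C", (-1.204, 0.695, 0.0)),
        # fused 5-ring
        ("NE1", "N", (-0.75, 2.85, 0.0)),
        ("CD1", "C", (-2.00, 2.70, 0.0)),
        ("CG", "C", (-2.25, 1.35, 0.0)),
        ("CB", "C", (-3.50, 1.00, 0.0)),
        ("CA", "C", (-4.20, 2.30, 0.0)),
        ("N", "N", (-3.70, 3.50, 0.40)),
        ("C", "C", (-5.70, 2.30, 0.0)),
        ("O", "O", (-6.40, 3.30, 0.0)),
    ],
    "ALA": [
        ("N", "N", (0.0, 1.40, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("CB", "C", (1.00, -0.70, 1.00)),
        ("C", "C", (-1.20, -0.80, 0.0)),
        ("O", "O", (-2.30, -0.30, 0.0)),
    ],
    "GLY": [
        ("N", "N", (0.0, 1.40, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (-1.20, -0.80, 0.0)),
        ("O", "O", (-2.30, -0.30, 0.0)),
    ],
}

AROMATIC_CHOICES = ("PHE", "TYR", "TRP", "HIS")
# Tyr is Phe plus a hydroxyl para to CB.
_TEMPLATES["TYR"] = _TEMPLATES["PHE"] + [("OH", "O", (2.76, 0.0, 0.0))]

#: Distance windows for planted interactions. Windows keep every planted
#: pair inside its own cutoff with margin, outside every other class, and
#: geometrically collision-free; decoy windows sit >= 0.2 A above cutoff.
PLANT_DISTANCES: dict[str, tuple[float, float]] = {
    "salt_bridge": (3.60, 3.95),  # above the 3.5 A h-bond window (distinct class)
    "hbond": (2.60, 3.40),
    "pi_pi": (4.50, 7.15),
    "cation_pi": (3.50, 5.90),
    "disulfide": (2.00, 2.45),
}
DECOY_DISTANCES: dict[str, tuple[float, float]] = {
    "salt_bridge": (4.20, 5.80),
    "hbond": (3.70, 4.80),
    "pi_pi": (7.40, 9.50),
    "cation_pi": (6.20, 7.80),
    "disulfide": (2.70, 3.40),
}

_CELL_SPACING = 30.0  # A between planted groups: far beyond every cutoff


@dataclass(frozen=True)
class GroundTruth:
    """One planted interaction the detectors must find."""

    kind: str
    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    distance: float


@dataclass
class PlantSpec:
    """Plan for a planted-interaction structure.

    ``planted``/``decoys`` are lists of (kind, distance, variant) /
    (kind, distance) tuples; ``variant`` selects geometry details (e.g. the
    aromatic residue pairing for pi-pi, ``"equatorial"`` for an in-plane
    cation decoy). ``n_filler`` alanine/glycine residues are placed far from
    every planted group.
    """

    planted: list[tuple] = field(default_factory=list)
    decoys: list[tuple] = field(default_factory=list)
    n_filler: int = 5
    seed: int = 0

    def validate(self) -> None:
        for kind, distance, *_ in self.planted:
            lo, hi = PLANT_DISTANCES[kind]
            if not lo <= distance <= hi:
                raise ValueError(
                    f"planted {kind} distance {distance} outside the safe window [{lo}, {hi}]"
                )
        for entry in self.decoys:
            kind, distance = entry[0], entry[1]
            variant = entry[2] if len(entry) > 2 else ""
            if variant == "equatorial":
                continue  # inside the distance cutoff, rejected by the angle
            lo, hi = DECOY_DISTANCES[kind]
            if not lo <= distance <= hi:
                raise ValueError(
                    f"decoy {kind} distance {distance} outside the safe window [{lo}, {hi}]"
                )


def _instantiate(
    res_name: str,
    chain_id: str,
    seq_number: int,
    offset: np.ndarray,
    mirror: bool = False,
    lift: float = 0.0,
) -> Residue:
    """Place a template: optional 180-degree flip about z, then translate."""
    atoms = []
    for name, element, xyz in _TEMPLATES[res_name]:
        x, y, z = xyz
        if mirror:
            x, y = -x, -y
        atoms.append(
            AtomRecord(
                name=name,
                element=element,
                coord=np.array([x, y, z + lift]) + offset,
            )
        )
    return Residue(
        chain_id=chain_id,
        seq_number=seq_number,
        insertion_code="",
        res_name=res_name,
        atoms=atoms,
    )


_PAIR_RESIDUES: dict[str, tuple[str, str]] = {
    "salt_bridge": ("LYS", "GLU"),
    "hbond": ("SER", "GLN"),
    "disulfide": ("CYS", "CYS"),
}


def _place_pair(
    kind: str, distance: float, variant: str, cell: np.ndarray, seq: int
) -> tuple[list[Residue], tuple]:
    """Residues for one planted/decoy pair; returns (residues, key pair)."""
    if kind in _PAIR_RESIDUES:
        name_a, name_b = _PAIR_RESIDUES[kind]
        if kind == "salt_bridge" and variant == "asp":
            name_b = "ASP"
        res_a = _instantiate(name_a, "A", seq, cell)
        res_b = _instantiate(name_b, "A", seq + 2, cell + np.array([distance, 0.0, 0.0]), mirror=True)
        return [res_a, res_b], (res_a.key, res_b.key)
    if kind == "pi_pi":
        name_a, name_b = (variant.split("-") if "-" in variant else ("PHE", "PHE"))
        # face-to-face stack: second ring directly above the first
        res_a = _instantiate(name_a, "A", seq, cell)
        res_b = _instantiate(name_b, "A", seq + 2, cell + np.array([0.0, 0.0, distance]))
        return [res_a, res_b], (res_a.key, res_b.key)
    if kind == "cation_pi":
        cation = "ARG" if variant == "arg" else "LYS"
        res_a = _instantiate("PHE", "A", seq, cell)
        if variant == "equatorial":
            # in the ring plane: inside the distance cutoff, angle 90 degrees
            res_b = _instantiate(
                cation, "A", seq + 2, cell + np.array([distance, 0.0, 0.0]), mirror=True
            )
        else:
            # axial: on the ring normal, angle 0
            res_b = _instantiate(
                cation, "A", seq + 2, cell + np.array([0.0, 0.0, distance]), mirror=True
            )
        return [res_a, res_b], (res_a.key, res_b.key)
    raise ValueError(f"unknown interaction kind {kind!r}")


# ARG needs a template for the cation-pi "arg" variant.
_TEMPLATES["ARG"] = [
    ("CZ", "C", (0.0, 0.0, 0.0)),
    ("NH1", "N", (0.65, 1.15, 0.0)),
    ("NH2", "N", (0.65, -1.15, 0.0)),
    ("NE", "N", (-1.35, 0.0, 0.0)),
    ("CD", "C", (-2.10, 1.20, 0.0)),
    ("CG", "C", (-3.60, 1.20, 0.0)),
    ("CB", "C", (-4.30, 2.40, 0.0)),
    ("CA", "C", (-5.80, 2.40, 0.0)),
    ("N", "N", (-6.40, 3.60, 0.40)),
    ("C", "C", (-6.50, 1.20, -0.20)),
    ("O", "O", (-7.70, 1.20, -0.20)),
]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def generate_planted_structure(spec: PlantSpec) -> tuple[StructureModel, list[GroundTruth]]:
    """Build a structure realising exactly the planted interactions.

    Every planted or decoy pair occupies its own lattice cell (30 A apart,
    far beyond every cutoff), so cross-pair contacts cannot arise; filler
    residues are likewise isolated. A seeded random rigid motion is applied
    to the whole structure, which preserves all distances exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    model = StructureModel(structure_id=f"planted-{spec.seed}")
    truth: list[GroundTruth] = []

    residues: list[Residue] = []
    cell_idx = 0

    def next_cell() -> np.ndarray:
        nonlocal cell_idx
        side = 6  # 6x6xN lattice
        i, rem = divmod(cell_idx, side * side)
        j, k = divmod(rem, side)
        cell_idx += 1
        return _CELL_SPACING * np.array([float(i), float(j), float(k)])

    seq = 1
    for entry in spec.planted:
        kind, distance = entry[0], entry[1]
        variant = entry[2] if len(entry) > 2 else ""
        pair, keys = _place_pair(kind, distance, variant, next_cell(), seq)
        residues.extend(pair)
        truth.append(GroundTruth(kind=kind, residue_a=keys[0], residue_b=keys[1], distance=distance))
        seq += 10
    for entry in spec.decoys:
        kind, distance = entry[0], entry[1]
        variant = entry[2] if len(entry) > 2 else ""
        pair, _ = _place_pair(kind, distance, variant, next_cell(), seq)
        residues.extend(pair)
        seq += 10
    for _ in range(spec.n_filler):
        name = "ALA" if rng.random() < 0.7 else "GLY"
        residues.append(_instantiate(name, "A", seq, next_cell()))
        seq += 10

    rotation = _random_rotation(rng)
    translation = rng.uniform(-20.0, 20.0, size=3)
    for res in residues:
        for atom in res.atoms:
            atom.coord = rotation @ atom.coord + translation
    model.chains["A"] = residues
    model.validate()
    return model, truth


def random_plant_spec(seed: int, max_per_kind: int = 3) -> PlantSpec:
    """A fuzzed plan: random counts, distances and variants per kind."""
    rng = np.random.default_rng(seed)
    planted: list[tuple] = []
    decoys: list[tuple] = []
    for kind, (lo, hi) in PLANT_DISTANCES.items():
        for _ in range(int(rng.integers(0, max_per_kind + 1))):
            variant = ""
            if kind == "pi_pi":
                variant = "-".join(rng.choice(AROMATIC_CHOICES, size=2))
            elif kind == "cation_pi":
                variant = str(rng.choice(["", "arg"]))
            elif kind == "salt_bridge":
                variant = str(rng.choice(["", "asp"]))
            planted.append((kind, float(rng.uniform(lo, hi)), variant))
        dlo, dhi = DECOY_DISTANCES[kind]
        for _ in range(int(rng.integers(0, 2 + 1))):
            decoys.append((kind, float(rng.uniform(dlo, dhi)), ""))
    if rng.random() < 0.5:
        # angle-rejected decoy: cation inside the distance cutoff but in-plane
        decoys.append(("cation_pi", float(rng.uniform(4.0, 5.8)), "equatorial"))
    return PlantSpec(planted=planted, decoys=decoys, n_filler=int(rng.integers(2, 7)), seed=seed)


def generate_calcium_site(
    n_waters: int = 3,
    n_backbone_o: int = 2,
    bidentate_glu: bool = True,
    n_outside: int = 1,
    seed: int = 0,
) -> tuple[StructureModel, int]:
    """A synthetic calcium-binding site with a known coordination number.

    Ligand oxygens are placed on well-separated directions at 2.3-2.6 A from
    the ion; a bidentate glutamate contributes both carboxylate oxygens
    (mimicking the archaeal-enzyme site that reaches coordination number 7);
    ``n_outside`` extra waters sit beyond the 3.0 A cutoff. Returns the model
    and the expected coordination number.
    """
    rng = np.random.default_rng(seed)
    n_dirs = n_waters + n_backbone_o + 1 + n_outside
    # golden-spiral directions are guaranteed well separated
    from .compactness import sphere_points

    dirs = sphere_points(max(n_dirs, 6))
    center = rng.uniform(-5.0, 5.0, size=3)
    residues: list[Residue] = []
    seq = 1
    d = 0

    # bidentate (or monodentate) carboxylate of a glutamate
    u = dirs[d]
    d += 1
    perp = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(u, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    oe1 = center + 2.35 * u
    if bidentate_glu:
        oe2 = center + 2.55 * (np.cos(0.45) * u + np.sin(0.45) * perp)
    else:
        oe2 = center + 3.60 * (np.cos(0.8) * u + np.sin(0.8) * perp)
    cd = center + 3.30 * (np.cos(0.22) * u + np.sin(0.22) * perp)
    glu_atoms = [
        AtomRecord(name="OE1", element="O", coord=oe1),
        AtomRecord(name="OE2", element="O", coord=oe2),
        AtomRecord(name="CD", element="C", coord=cd),
        AtomRecord(name="CG", element="C", coord=center + 4.8 * u),
        AtomRecord(name="CB", element="C", coord=center + 6.2 * u),
        AtomRecord(name="CA", element="C", coord=center + 7.6 * u),
        AtomRecord(name="N", element="N", coord=center + 8.6 * u + perp),
        AtomRecord(name="C", element="C", coord=center + 8.8 * u - perp),
        AtomRecord(name="O", element="O", coord=center + 10.0 * u - perp),
    ]
    residues.append(
        Residue(chain_id="A", seq_number=seq, insertion_code="", res_name="GLU", atoms=glu_atoms)
    )
    seq += 1
    expected = 2 if bidentate_glu else 1

    for _ in range(n_backbone_o):
        u = dirs[d]
        d += 1
        o = center + 2.30 * u
        atoms = [
            AtomRecord(name="O", element="O", coord=o),
            AtomRecord(name="C", element="C", coord=center + 3.55 * u),
            AtomRecord(name="CA", element="C", coord=center + 5.0 * u),
            AtomRecord(name="N", element="N", coord=center + 6.4 * u),
            AtomRecord(name="CB", element="C", coord=center + 5.2 * u + perp),
        ]
        residues.append(
            Residue(chain_id="A", seq_number=seq, insertion_code="", res_name="ALA", atoms=atoms)
        )
        seq += 1
        expected += 1

    hetero_res: list[Residue] = []
    wseq = 501
    for _ in range(n_waters):
        u = dirs[d]
        d += 1
        hetero_res.append(
            Residue(
                chain_id="A",
                seq_number=wseq,
                insertion_code="",
                res_name="HOH",
                atoms=[AtomRecord(name="O", element="O", coord=center + 2.40 * u, is_hetero=True)],
            )
        )
        wseq += 1
        expected += 1
    for _ in range(n_outside):
        u = dirs[d]
        d += 1
        hetero_res.append(
            Residue(
                chain_id="A",
                seq_number=wseq,
                insertion_code="",
                res_name="HOH",
                atoms=[AtomRecord(name="O", element="O", coord=center + 3.40 * u, is_hetero=True)],
            )
        )
        wseq += 1

    ca_res = Residue(
        chain_id="A",
        seq_number=499,
        insertion_code="",
        res_name="CA",
        atoms=[AtomRecord(name="CA", element="CA", coord=center, is_hetero=True)],
    )
    model = StructureModel(structure_id=f"casite-{seed}")
    model.chains["A"] = residues + [ca_res] + hetero_res
    model.validate()
    return model, expected


# ---------------------------------------------------------------------------
# stochastic endo-hydrolysis digest simulator
# ---------------------------------------------------------------------------

#: (n_minus, n_plus, inert_length) per enzyme archetype.
ARCHETYPES: dict[str, tuple[int, int, int]] = {
    "fungal": (2, 2, 2),
    "iagal_like": (3, 2, 3),
    "blgal_like": (4, 2, 3),
}


@dataclass
class DigestSpec:
    """Plan for a simulated galactan digest."""

    n_chains: int = 100
    chain_length: int | tuple[str, float] = 30  # fixed L, or ("geometric", mean)
    archetype: str | tuple[int, int, int] = "iagal_like"
    sampling_times: list[float] | None = None  # None -> initial + exhaustion
    substrate_load: float = 2.0  # mg/ml
    enzyme_id: str = "enzyme"
    seed: int = 0

    @property
    def subsites(self) -> tuple[int, int, int]:
        if isinstance(self.archetype, str):
            try:
                return ARCHETYPES[self.archetype]
            except KeyError:
                raise ValueError(
                    f"unknown archetype {self.archetype!r}; options: {sorted(ARCHETYPES)}"
                ) from None
        n_minus, n_plus, inert = self.archetype
        if n_minus < 1 or n_plus < 1 or inert < 1:
            raise ValueError("n_minus, n_plus and inert_length must all be >= 1")
        return (n_minus, n_plus, inert)


@dataclass
class DigestTimePoint:
    """Census (chain length -> count) and derived sample at one time."""

    time: float
    census: dict[int, int]
    sample: DigestSample

    def monomer_units(self) -> int:
        return sum(length * count for length, count in self.census.items())

    def g_gt5_true_mM(self, scale: float) -> float:
        return scale * sum(count for length, count in self.census.items() if length > 5)


def _bond_weights(length: int, n_minus: int, n_plus: int) -> np.ndarray:
    k = np.arange(1, length)
    return np.minimum(k, n_minus) * np.minimum(length - k, n_plus)


def census_to_sample(
    census: Counter,
    substrate_load: float,
    enzyme_id: str,
    sample_id: str,
) -> tuple[DigestSample, float]:
    """Map an integer chain census to concentrations (mM).

    Normalization: the total monomer pool corresponds to the substrate load,
    so one chain contributes ``scale = load / 162.14 * 1000 / total_units``
    mM. Returns the sample and the scale (mM per chain count).
    """
    total_units = sum(length * count for length, count in census.items())
    total_mM = substrate_load / ANHYDRO_GALACTOSE_MASS * 1000.0
    scale = total_mM / total_units
    analytes = {f"G{i}": census.get(i, 0) * scale for i in range(1, 6)}
    reducing_ends = sum(census.values()) * scale
    return (
        DigestSample(
            sample_id=sample_id,
            enzyme_id=enzyme_id,
            substrate_load=substrate_load,
            analytes=analytes,
            reducing_ends=reducing_ends,
        ),
        scale,
    )


def simulate_endo_hydrolysis(spec: DigestSpec) -> list[DigestTimePoint]:
    """Gillespie simulation of stochastic endo-cleavage of galactan chains.

    Bonds of a chain of length L (> inert_length) are cut with rate weight
    ``min(k, n_minus) * min(L - k, n_plus)`` at position k; waiting times are
    exponential in the total weight. The census is recorded at the requested
    sampling times (state just before the first event after each time), or at
    t=0 and exhaustion when ``sampling_times`` is None. Monomer bookkeeping
    is exact integers.
    """
    n_minus, n_plus, inert = spec.subsites
    rng = np.random.default_rng(spec.seed)

    census: Counter = Counter()
    if isinstance(spec.chain_length, tuple):
        kind, mean = spec.chain_length
        if kind != "geometric":
            raise ValueError(f"unknown chain length distribution {kind!r}")
        lengths = rng.geometric(1.0 / mean, size=spec.n_chains)
        census.update(int(v) for v in lengths)
    else:
        census[int(spec.chain_length)] = spec.n_chains

    rate_cache: dict[int, float] = {}
    weight_cache: dict[int, np.ndarray] = {}

    def chain_rate(length: int) -> float:
        if length <= inert:
            return 0.0
        if length not in rate_cache:
            w = _bond_weights(length, n_minus, n_plus).astype(float)
            weight_cache[length] = w
            rate_cache[length] = float(w.sum())
        return rate_cache[length]

    times = sorted(spec.sampling_times) if spec.sampling_times else None
    out: list[DigestTimePoint] = []
    t = 0.0
    next_sample = 0

    def record(at_time: float) -> None:
        sample, _ = census_to_sample(
            census, spec.substrate_load, spec.enzyme_id, f"t{at_time:g}"
        )
        out.append(DigestTimePoint(time=at_time, census=dict(census), sample=sample))

    if times is None:
        record(0.0)

    while True:
        active = [(length, count) for length, count in census.items() if count > 0 and chain_rate(length) > 0]
        total_rate = sum(count * chain_rate(length) for length, count in active)
        if total_rate == 0.0:
            if times is not None:
                while next_sample < len(times):
                    record(times[next_sample])
                    next_sample += 1
            else:
                record(t)
            break
        dt = rng.exponential(1.0 / total_rate)
        t_new = t + dt
        if times is not None:
            while next_sample < len(times) and times[next_sample] <= t_new:
                record(times[next_sample])
                next_sample += 1
            if next_sample >= len(times):
                break
        # choose a chain length, then a bond within it
        probs = np.array([count * chain_rate(length) for length, count in active]) / total_rate
        idx = rng.choice(len(active), p=probs)
        length = active[idx][0]
        w = weight_cache[length]
        k = int(rng.choice(np.arange(1, length), p=w / w.sum()))
        census[length] -= 1
        if census[length] == 0:
            del census[length]
        census[k] += 1
        census[length - k] += 1
        t = t_new
    return out


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

_TRAJ_ATOM_OFFSETS = [
    ("N", (-1.20, 0.80, 0.0)),
    ("CA", (0.0, 0.0, 0.0)),
    ("C", (1.20, 0.80, 0.0)),
    ("O", (1.90, 1.80, 0.0)),
    ("CB", (0.0, -1.50, 0.80)),
]


def generate_trajectory(
    n_res: int = 30,
    n_frames: int = 100,
    jitter_sigma: float = 0.5,
    flip: tuple[int, float, int] | None = None,
    seed: int = 0,
    global_motion: bool = False,
) -> Trajectory:
    """Synthetic trajectory: ideal chain + Gaussian jitter (+ optional flip).

    Frame 0 is the noise-free reference structure; frames 1..n-1 add
    isotropic per-atom Gaussian jitter of the given sigma per axis. ``flip``
    = (residue_index, displacement_A, switch_frame) displaces that residue's
    side-chain (CB) atom along +z from ``switch_frame`` onward, emulating a
    two-state side-chain flip. ``global_motion`` additionally applies a
    random rigid motion to every frame past 0 (which alignment must remove).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    base = []
    atom_names: list[str] = []
    residue_ids: list[tuple[str, int]] = []
    for i in range(n_res):
        # helical C-alpha trace: well-spread in all three directions, so the
        # frame-alignment rotation is well determined
        angle = 2.0 * np.pi * i / 10.0
        ca = np.array([8.0 * np.cos(angle), 8.0 * np.sin(angle), 1.5 * i])
        for name, off in _TRAJ_ATOM_OFFSETS:
            base.append(ca + np.array(off))
            atom_names.append(name)
            residue_ids.append(("A", i + 1))
    base = np.array(base)
    n_atoms = len(base)

    coords = np.empty((n_frames, n_atoms, 3))
    coords[0] = base
    if n_frames > 1:
        coords[1:] = base[None] + rng.normal(0.0, jitter_sigma, size=(n_frames - 1, n_atoms, 3))

    if flip is not None:
        res_idx, displacement, switch_frame = flip
        if not 1 <= switch_frame < n_frames:
            raise ValueError("switch_frame must be in [1, n_frames)")
        cb = [
            j
            for j, (name, rid) in enumerate(zip(atom_names, residue_ids))
            if name == "CB" and rid[1] == res_idx
        ]
        if not cb:
            raise ValueError(f"no CB atom for residue {res_idx}")
        coords[switch_frame:, cb[0], 2] += displacement

    if global_motion:
        for f in range(1, n_frames):
            rot = _random_rotation(rng)
            trans = rng.uniform(-10.0, 10.0, size=3)
            coords[f] = coords[f] @ rot.T + trans

    return Trajectory(coords=coords, atom_names=atom_names, residue_ids=residue_ids)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def generate_kinetics(
    km: float,
    kcat: float,
    enzyme_conc: float,
    enzyme_mw: float,
    s_levels,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Michaelis-Menten rates with multiplicative Gaussian noise.

    Km in mg ml^-1, kcat in s^-1, enzyme concentration in mg ml^-1 and molar
    mass in g mol^-1; returned rates are mM s^-1 so that fitting with
    :func:`thermogal.degradation.fit_michaelis_menten` recovers kcat.
    """
    s = np.asarray(s_levels, dtype=float)
    if np.any(s <= 0):
        raise ValueError("substrate levels must be positive")
    rng = np.random.default_rng(seed)
    vmax = kcat * (enzyme_conc / enzyme_mw) * 1e3  # mM/s
    v = vmax * s / (km + s)
    if noise_cv > 0:
        v = v * (1.0 + rng.normal(0.0, noise_cv, size=s.shape))
    return s, v
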