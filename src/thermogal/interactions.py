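"""Intramolecular interaction detectors.

Detects the interaction classes used to profile thermostability across GH53
galactanase structures: salt bridges, hydrogen bonds, pi-pi stacking,
cation-pi contacts, disulfide bridges and metal (typically Ca2+)
coordination. All criteria are purely geometric, computed on heavy atoms of
the altloc-resolved model; each detector emits at most one record per
unordered residue pair, carrying the minimum qualifying distance.

Default cutoffs: salt bridges 4.0 A (basic side-chain N to carboxylate O),
hydrogen bonds 3.5 A (heavy-atom donor-acceptor dictionary), pi-pi 7.2 A
(ring centroid to ring centroid), cation-pi 6.0 A with the cation within 60
degrees of the ring normal, disulfides 2.5 A (SG-SG), metal coordination
3.0 A (metal to O/N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .structure_io import Residue, StructureModel

__all__ = [
    "InteractionKind",
    "InteractionRecord",
    "RingDescriptor",
    "CoordinationSite",
    "detect_salt_bridges",
    "detect_hydrogen_bonds",
    "compute_ring_descriptors",
    "detect_pi_pi",
    "detect_cation_pi",
    "detect_disulfides",
    "metal_coordination",
    "records_to_frame",
]


class InteractionKind(str, Enum):
    SALT_BRIDGE = "salt_bridge"
    HBOND = "hbond"
    PI_PI = "pi_pi"
    CATION_PI = "cation_pi"
    DISULFIDE = "disulfide"
    METAL_COORDINATION = "metal_coordination"


ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class InteractionRecord:
    """One detected interaction between two residues.

    ``residue_a``/``residue_b`` are (chain_id, seq_number, insertion_code)
    keys ordered so that a pair is reported exactly once. ``atom_a``/``atom_b``
    name the closest qualifying atoms (or ring labels for centroid-based
    kinds); ``angle`` is set for cation-pi records (degrees between the ring
    normal and the centroid-to-cation vector).
    """

    kind: InteractionKind
    residue_a: ResidueKey
    residue_b: ResidueKey
    res_name_a: str
    res_name_b: str
    atom_a: str
    atom_b: str
    distance: float
    angle: float | None = None

    @property
    def pair(self) -> frozenset[ResidueKey]:
        return frozenset((self.residue_a, self.residue_b))


@dataclass
class RingDescriptor:
    """Aromatic ring of a residue: member atoms, centroid and unit normal."""

    residue: ResidueKey
    res_name: str
    ring_label: str  # PHE6, TYR6, TRP5, TRP6, HIS5
    ring_atom_names: list[str]
    centroid: np.ndarray
    normal: np.ndarray


@dataclass
class CoordinationSite:
    """One metal site: the metal atom and every O/N ligand within the cutoff."""

    metal_residue: ResidueKey
    metal_res_name: str
    metal_atom: str
    ligands: list[tuple[ResidueKey, str, str, float]] = field(default_factory=list)

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)


# --- residue chemistry dictionaries (heavy atoms only) -----------------------

BASIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
ACIDIC_ATOMS: dict[str, tuple[str, ...]] = {
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
}

# Donor/acceptor dictionary for the distance-only hydrogen-bond criterion
# (the crystal structures carry no hydrogens). Configurable at call time.
HBOND_DONORS: dict[str, tuple[str, ...]] = {
    "*": ("N",),  # backbone amide of every residue
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "TRP": ("NE1",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}
HBOND_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "*": ("O",),  # backbone carbonyl
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

RING_DEFINITIONS: dict[str, list[tuple[str, tuple[str, ...]]]] = {
    "PHE": [("PHE6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "TYR": [("TYR6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "HIS": [("HIS5", ("CG", "ND1", "CD2", "CE1", "NE2"))],
    "TRP": [
        ("TRP5", ("CG", "CD1", "CD2", "NE1", "CE2")),
        ("TRP6", ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
    ],
}

CATION_ATOMS: dict[str, tuple[str, ...]] = {"LYS": ("NZ",), "ARG": ("CZ",)}


def _ordered(a: Residue, b: Residue) -> tuple[Residue, Residue]:
    return (a, b) if a.key <= b.key else (b, a)


def _min_dist_record(
    kind: InteractionKind,
    res_a: Residue,
    res_b: Residue,
    atoms_a: list[str],
    atoms_b: list[str],
    cutoff: float,
) -> InteractionRecord | None:
    """Record at the minimum distance over qualifying atom pairs, or None."""
    best: tuple[float, str, str] | None = None
    for na in atoms_a:
        aa = res_a.atom(na)
        if aa is None:
            continue
        for nb in atoms_b:
            ab = res_b.atom(nb)
            if ab is None:
                continue
            d = float(np.linalg.norm(aa.coord - ab.coord))
            if d <= cutoff and (best is None or d < best[0]):
                best = (d, na, nb)
    if best is None:
        return None
    d, na, nb = best
    ra, rb = res_a, res_b
    if rb.key < ra.key:
        ra, rb, na, nb = rb, ra, nb, na
    return InteractionRecord(
        kind=kind,
        residue_a=ra.key,
        residue_b=rb.key,
        res_name_a=ra.res_name,
        res_name_b=rb.res_name,
        atom_a=na,
        atom_b=nb,
        distance=d,
    )


def detect_salt_bridges(model: StructureModel, cutoff: float = 4.0) -> list[InteractionRecord]:
    """Salt bridges: basic side-chain N within ``cutoff`` of a carboxylate O.

    Basic atoms: Arg NH1/NH2/NE, Lys NZ, His ND1/NE2. Acidic atoms:
    Glu OE1/OE2, Asp OD1/OD2. One record per (basic, acidic) residue pair at
    the minimum qualifying N-O distance. Residues missing their side-chain
    atoms are skipped with a warning.
    """
    polymer = model.polymer_residues()
    basic = [r for r in polymer if r.res_name in BASIC_ATOMS]
    acidic = [r for r in polymer if r.res_name in ACIDIC_ATOMS]
    records: list[InteractionRecord] = []
    for rb in basic:
        names_b = [n for n in BASIC_ATOMS[rb.res_name] if rb.atom(n) is not None]
        if not names_b:
            warnings.warn(f"{rb.label}: missing basic side-chain atoms; skipped", stacklevel=2)
            continue
        for ra in acidic:
            names_a = [n for n in ACIDIC_ATOMS[ra.res_name] if ra.atom(n) is not None]
            if not names_a:
                continue
            rec = _min_dist_record(InteractionKind.SALT_BRIDGE, rb, ra, names_b, names_a, cutoff)
            if rec is not None:
                records.append(rec)
    return records


def _donor_atoms(res: Residue, donors: dict[str, tuple[str, ...]]) -> list[str]:
    names = list(donors.get("*", ())) + list(donors.get(res.res_name, ()))
    return [n for n in names if res.atom(n) is not None]


def _acceptor_atoms(res: Residue, acceptors: dict[str, tuple[str, ...]]) -> list[str]:
    names = list(acceptors.get("*", ())) + list(acceptors.get(res.res_name, ()))
    return [n for n in names if res.atom(n) is not None]


def detect_hydrogen_bonds(
    model: StructureModel,
    cutoff: float = 3.5,
    donors: dict[str, tuple[str, ...]] = HBOND_DONORS,
    acceptors: dict[str, tuple[str, ...]] = HBOND_ACCEPTORS,
) -> list[InteractionRecord]:
    """Hydrogen bonds by the heavy-atom donor-acceptor distance criterion.

    Intra-residue pairs are excluded, as are backbone-backbone pairs between
    sequence neighbours (|i - j| < 2 on the same chain), which are covalently
    constrained rather than hydrogen bonded. One record per residue pair at
    the minimum qualifying donor-acceptor distance.
    """
    polymer = model.polymer_residues()
    best: dict[frozenset[ResidueKey], InteractionRecord] = {}
    for i, res_i in enumerate(polymer):
        for j in range(len(polymer)):
            if i == j:
                continue
            res_j = polymer[j]
            d_names = _donor_atoms(res_i, donors)
            a_names = _acceptor_atoms(res_j, acceptors)
            if not d_names or not a_names:
                continue
            neighbours = (
                res_i.chain_id == res_j.chain_id
                and abs(res_i.seq_number - res_j.seq_number) < 2
            )
            for nd in d_names:
                ad = res_i.atom(nd)
                for na in a_names:
                    if neighbours and nd in BACKBONE_ATOMS and na in BACKBONE_ATOMS:
                        continue
                    aa = res_j.atom(na)
                    d = float(np.linalg.norm(ad.coord - aa.coord))
                    if d > cutoff:
                        continue
                    ra, rb = _ordered(res_i, res_j)
                    atom_a, atom_b = (nd, na) if ra is res_i else (na, nd)
                    rec = InteractionRecord(
                        kind=InteractionKind.HBOND,
                        residue_a=ra.key,
                        residue_b=rb.key,
                        res_name_a=ra.res_name,
                        res_name_b=rb.res_name,
                        atom_a=atom_a,
                        atom_b=atom_b,
                        distance=d,
                    )
                    key = rec.pair
                    if key not in best or d < best[key].distance:
                        best[key] = rec
    return sorted(best.values(), key=lambda r: (r.residue_a, r.residue_b))


def compute_ring_descriptors(residue: Residue) -> list[RingDescriptor]:
    """Aromatic ring centroid(s) and least-squares plane normal(s).

    Phe/Tyr yield one six-membered ring, His one five-membered ring and Trp
    both its five- and six-membered rings. Incomplete rings yield an empty
    list with a warning.
    """
    defs = RING_DEFINITIONS.get(residue.res_name)
    if defs is None:
        return []
    out: list[RingDescriptor] = []
    for label, names in defs:
        coords = residue.coords(list(names))
        if coords.shape[0] != len(names):
            warnings.warn(f"{residue.label}: incomplete {label} ring; skipped", stacklevel=2)
            continue
        centroid = coords.mean(axis=0)
        centered = coords - centroid
        # normal = singular vector of the smallest singular value
        _, _, vt = np.linalg.svd(centered)
        normal = vt[-1]
        normal = normal / np.linalg.norm(normal)
        out.append(
            RingDescriptor(
                residue=residue.key,
                res_name=residue.res_name,
                ring_label=label,
                ring_atom_names=list(names),
                centroid=centroid,
                normal=normal,
            )
        )
    return out


def _all_ring_descriptors(model: StructureModel) -> dict[ResidueKey, list[RingDescriptor]]:
    out: dict[ResidueKey, list[RingDescriptor]] = {}
    for res in model.polymer_residues():
        if res.res_name in RING_DEFINITIONS:
            rings = compute_ring_descriptors(res)
            if rings:
                out[res.key] = rings
    return out


def detect_pi_pi(model: StructureModel, cutoff: float = 7.2) -> list[InteractionRecord]:
    """Pi-pi stacking: ring-centroid distance between aromatic residues.

    For every pair of aromatic residues (Phe, Tyr, Trp, His) all ring-centroid
    pairs are considered; if any distance is within the cutoff a single record
    is emitted for the residue pair at the minimum centroid distance.
    Sequence-adjacent aromatic pairs (|i - j| = 1 on one chain) are excluded.
    """
    polymer = {r.key: r for r in model.polymer_residues()}
    rings = _all_ring_descriptors(model)
    keys = sorted(rings)
    records: list[InteractionRecord] = []
    for ii, key_a in enumerate(keys):
        for key_b in keys[ii + 1 :]:
            res_a, res_b = polymer[key_a], polymer[key_b]
            if (
                res_a.chain_id == res_b.chain_id
                and abs(res_a.seq_number - res_b.seq_number) == 1
            ):
                continue
            best: tuple[float, str, str] | None = None
            for da in rings[key_a]:
                for db in rings[key_b]:
                    d = float(np.linalg.norm(da.centroid - db.centroid))
                    if d <= cutoff and (best is None or d < best[0]):
                        best = (d, da.ring_label, db.ring_label)
            if best is not None:
                d, la, lb = best
                records.append(
                    InteractionRecord(
                        kind=InteractionKind.PI_PI,
                        residue_a=key_a,
                        residue_b=key_b,
                        res_name_a=res_a.res_name,
                        res_name_b=res_b.res_name,
                        atom_a=la,
                        atom_b=lb,
                        distance=d,
                    )
                )
    return records


def detect_cation_pi(
    model: StructureModel, dist_cutoff: float = 6.0, angle_cutoff: float = 60.0
) -> list[InteractionRecord]:
    """Cation-pi contacts by a geometric (distance + axial angle) criterion.

    Cation points are Lys NZ and Arg CZ (guanidinium centre). A contact
    requires the cation within ``dist_cutoff`` of a ring centroid and within
    ``angle_cutoff`` degrees of the ring normal (measured from the centroid;
    the normal's sign is immaterial). His rings count as aromatic partners but
    His is not treated as a cation. One record per (cation, aromatic) residue
    pair at the minimum qualifying distance.
    """
    polymer = {r.key: r for r in model.polymer_residues()}
    rings = _all_ring_descriptors(model)
    cations = [r for r in polymer.values() if r.res_name in CATION_ATOMS]
    best: dict[frozenset[ResidueKey], InteractionRecord] = {}
    for rc in cations:
        for atom_name in CATION_ATOMS[rc.res_name]:
            atom = rc.atom(atom_name)
            if atom is None:
                continue
            for key_r, descriptors in rings.items():
                if key_r == rc.key:
                    continue
                for desc in descriptors:
                    v = atom.coord - desc.centroid
                    d = float(np.linalg.norm(v))
                    if d == 0.0 or d > dist_cutoff:
                        continue
                    cos = abs(float(np.dot(v / d, desc.normal)))
                    angle = float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
                    if angle > angle_cutoff:
                        continue
                    res_r = polymer[key_r]
                    ra, rb = _ordered(rc, res_r)
                    atom_a, atom_b = (
                        (atom_name, desc.ring_label) if ra is rc else (desc.ring_label, atom_name)
                    )
                    rec = InteractionRecord(
                        kind=InteractionKind.CATION_PI,
                        residue_a=ra.key,
                        residue_b=rb.key,
                        res_name_a=ra.res_name,
                        res_name_b=rb.res_name,
                        atom_a=atom_a,
                        atom_b=atom_b,
                        distance=d,
                        angle=angle,
                    )
                    key = rec.pair
                    if key not in best or d < best[key].distance:
                        best[key] = rec
    return sorted(best.values(), key=lambda r: (r.residue_a, r.residue_b))


def detect_disulfides(model: StructureModel, cutoff: float = 2.5) -> list[InteractionRecord]:
    """Disulfide bridges: Cys SG-SG pairs within the cutoff."""
    cys = [r for r in model.polymer_residues() if r.res_name == "CYS" and r.atom("SG")]
    records: list[InteractionRecord] = []
    for i, ra in enumerate(cys):
        for rb in cys[i + 1 :]:
            rec = _min_dist_record(InteractionKind.DISULFIDE, ra, rb, ["SG"], ["SG"], cutoff)
            if rec is not None:
                records.append(rec)
    return records


def metal_coordination(
    model: StructureModel, metal_element: str = "CA", cutoff: float = 3.0
) -> list[CoordinationSite]:
    """Coordination report for every metal atom of the given element.

    For each metal (matched by element symbol on hetero atoms) every protein
    or water O/N atom within the cutoff is listed as a ligand; the
    coordination number is the ligand count. Bidentate carboxylates therefore
    contribute one ligand per coordinating oxygen. Returns an empty list when
    no such metal is present.
    """
    target = metal_element.upper()
    metals: list[tuple[Residue, str, np.ndarray]] = []
    for res in model.residues():
        for atom in res.atoms:
            if atom.is_hetero and atom.element.upper() == target:
                metals.append((res, atom.name, atom.coord))
    sites: list[CoordinationSite] = []
    for metal_res, metal_atom, pos in metals:
        site = CoordinationSite(
            metal_residue=metal_res.key, metal_res_name=metal_res.res_name, metal_atom=metal_atom
        )
        for res in model.residues():
            for atom in res.atoms:
                if res.key == metal_res.key and atom.name == metal_atom:
                    continue
                if atom.element.upper() not in ("O", "N"):
                    continue
                d = float(np.linalg.norm(atom.coord - pos))
                if d <= cutoff:
                    site.ligands.append((res.key, res.res_name, atom.name, d))
        site.ligands.sort(key=lambda t: t[3])
        sites.append(site)
    return sites


def records_to_frame(records: list[InteractionRecord], structure_id: str = "") -> pd.DataFrame:
    """Tabulate interaction records for TSV export."""

    def fmt(key: ResidueKey, name: str) -> str:
        chain, seq, icode = key
        return f"{chain}/{name}{seq}{icode}".rstrip()

    rows = [
        {
            "structure_id": structure_id,
            "kind": r.kind.value,
            "res_a": fmt(r.residue_a, r.res_name_a),
            "res_b": fmt(r.residue_b, r.res_name_b),
            "atom_a": r.atom_a,
            "atom_b": r.atom_b,
            "distance_A": round(r.distance, 3),
            "angle_deg": round(r.angle, 2) if r.angle is not None else "",
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "structure_id",
            "kind",
            "res_a",
            "res_b",
            "atom_a",
            "atom_b",
            "distance_A",
            "angle_deg",
        ],
    )
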