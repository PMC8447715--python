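"""Shared test utilities: backbone construction from dihedrals (NERF)."""

from __future__ import annotations

import numpy as np

from thermogal.structure_io import AtomRecord, Residue, StructureModel

# idealized backbone internal coordinates (Angstrom / degrees)
B_N_CA, B_CA_C, B_C_N = 1.458, 1.525, 1.329
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NERF: place the next atom given three predecessors + internals."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(
    phi_psi: list[tuple[float, float]],
    res_names: list[str] | None = None,
    chain_id: str = "A",
) -> StructureModel:
    """Poly-peptide backbone (N, CA, C per residue) with given phi/psi."""
    n_res = len(phi_psi)
    names = res_names or ["ALA"] * n_res
    coords: list[np.ndarray] = [
        np.array([0.0, 0.0, 0.0]),  # N1
        np.array([B_N_CA, 0.0, 0.0]),  # CA1
    ]
    # C1 at the N-CA-C angle in the xy-plane
    ang = np.radians(A_N_CA_C)
    coords.append(coords[1] + B_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0]))
    for i in range(n_res - 1):
        phi_next = phi_psi[i + 1][0]
        psi = phi_psi[i][1]
        n_at = coords[3 * i]
        ca_at = coords[3 * i + 1]
        c_at = coords[3 * i + 2]
        n_next = _place(n_at, ca_at, c_at, B_C_N, A_CA_C_N, psi)
        ca_next = _place(ca_at, c_at, n_next, B_N_CA, A_C_N_CA, 180.0)  # omega trans
        c_next = _place(c_at, n_next, ca_next, B_CA_C, A_N_CA_C, phi_next)
        coords.extend([n_next, ca_next, c_next])

    model = StructureModel(structure_id="backbone")
    residues = []
    for i in range(n_res):
        # carbonyl oxygen in the peptide plane, opposite the next amide N
        o_at = _place(
            coords[3 * i], coords[3 * i + 1], coords[3 * i + 2],
            1.231, 120.5, phi_psi[i][1] + 180.0,
        )
        atoms = [
            AtomRecord(name="N", element="N", coord=coords[3 * i]),
            AtomRecord(name="CA", element="C", coord=coords[3 * i + 1]),
            AtomRecord(name="C", element="C", coord=coords[3 * i + 2]),
            AtomRecord(name="O", element="O", coord=o_at),
        ]
        residues.append(
            Residue(chain_id=chain_id, seq_number=i + 1, insertion_code="",
                    res_name=names[i], atoms=atoms)
        )
    model.chains[chain_id] = residues
    return model


def single_atom_model(element: str = "C", coord=(0.0, 0.0, 0.0)) -> StructureModel:
    model = StructureModel(structure_id="atom")
    model.chains["A"] = [
        Residue(chain_id="A", seq_number=1, insertion_code="", res_name="ALA",
                atoms=[AtomRecord(name="CA", element=element, coord=np.asarray(coord, float))])
    ]
    return model


def atom_cluster_model(coords: np.ndarray, element: str = "C") -> StructureModel:
    """All atoms in one residue (element uniform) for geometry tests."""
    atoms = [
        AtomRecord(name=f"C{i+1}", element=element, coord=c) for i, c in enumerate(coords)
    ]
    model = StructureModel(structure_id="cluster")
    model.chains["A"] = [
        Residue(chain_id="A", seq_number=1, insertion_code="", res_name="ALA", atoms=atoms)
    ]
    return model


def random_rotation(rng: np.random.Generator) -> np.ndarray:
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


def transform_model(model: StructureModel, rotation: np.ndarray, translation: np.ndarray):
    """Return a rigid-motion copy of a structure model."""
    import copy

    out = copy.deepcopy(model)
    for res in out.residues():
        for atom in res.atoms:
            atom.coord = rotation @ atom.coord + translation
    return out
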