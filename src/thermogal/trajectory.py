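"""Trajectory superposition and per-residue RMSF.

Frames are superposed onto the first frame by the Kabsch algorithm
(closed-form least-squares rigid alignment via SVD, proper rotation
enforced). RMSF is then the root-mean-square deviation of each atom from its
frame-0 position averaged over time, aggregated per residue over the
selected atoms. Measuring deviations from the first frame (rather than the
time-averaged structure) matches the convention used for assessing sugar-
binding-subsite stability in galactanase simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import parse_structure

__all__ = [
    "Trajectory",
    "RmsfProfile",
    "kabsch_superpose",
    "compute_rmsf",
    "read_multiframe_pdb",
    "read_xyz_frames",
]


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinate series (Angstrom) with atom metadata."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    atom_names: list[str]
    residue_ids: list[tuple[str, int]]  # (chain_id, seq_number) per atom
    residue_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n_atoms = self.coords.shape[1]
        if len(self.atom_names) != n_atoms or len(self.residue_ids) != n_atoms:
            raise ValueError("atom metadata length does not match coordinate array")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_mask(self, selection: str | list[str] | None) -> np.ndarray:
        """Boolean mask over atoms. ``"CA"``/name list, ``"heavy"`` or None (all)."""
        if selection is None or selection == "all":
            return np.ones(self.n_atoms, dtype=bool)
        if selection == "heavy":
            return np.array([not n.startswith("H") for n in self.atom_names])
        names = [selection] if isinstance(selection, str) else list(selection)
        return np.array([n in names for n in self.atom_names])


@dataclass
class RmsfProfile:
    """Per-residue RMSF (Angstrom) and the atom selection it was computed on."""

    residue_ids: list[tuple[str, int]]
    rmsf: np.ndarray
    selection: str
    atom_rmsf: pd.DataFrame | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain_id": [c for c, _ in self.residue_ids],
                "seq_number": [s for _, s in self.residue_ids],
                "rmsf_A": self.rmsf,
            }
        )


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the (weighted) RMSD to
    ``reference``. The rotation is proper (det = +1); mirror images therefore
    retain a positive residual. Degenerate (collinear or coincident) point
    sets raise.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()

    mu_m = (w[:, None] * mobile).sum(axis=0)
    mu_r = (w[:, None] * reference).sum(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    if np.linalg.matrix_rank(y * np.sqrt(w)[:, None], tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) reference point set")

    h = (w[:, None] * x).T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = mu_r - rotation @ mu_m
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt((w * ((moved - reference) ** 2).sum(axis=1)).sum()))
    return rotation, translation, rmsd


def compute_rmsf(
    traj: Trajectory,
    selection: str | list[str] | None = "heavy",
    align_selection: str | list[str] | None = "CA",
    per_residue: bool = True,
) -> RmsfProfile:
    """Per-residue RMSF after aligning every frame to frame 0.

    Alignment uses the ``align_selection`` atoms (default C-alpha); the RMSF
    itself is computed over ``selection`` (default all heavy atoms, so that
    side-chain motions such as subsite tryptophan flips are visible) and
    aggregated per residue as the root mean square over the residue's
    selected atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    sel_mask = traj.atom_mask(selection)
    if not sel_mask.any():
        raise ValueError("empty RMSF atom selection")
    align_mask = traj.atom_mask(align_selection)
    if not align_mask.any():
        raise ValueError("empty alignment atom selection")

    ref_align = traj.coords[0][align_mask]
    aligned = np.empty_like(traj.coords)
    aligned[0] = traj.coords[0]
    for f in range(1, traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.coords[f][align_mask], ref_align)
        aligned[f] = traj.coords[f] @ rot.T + trans

    dev2 = ((aligned - aligned[0]) ** 2).sum(axis=2)  # frames x atoms
    atom_rmsf = np.sqrt(dev2.mean(axis=0))

    sel_idx = np.flatnonzero(sel_mask)
    atom_frame = pd.DataFrame(
        {
            "chain_id": [traj.residue_ids[i][0] for i in sel_idx],
            "seq_number": [traj.residue_ids[i][1] for i in sel_idx],
            "atom_name": [traj.atom_names[i] for i in sel_idx],
            "rmsf_A": atom_rmsf[sel_idx],
        }
    )
    sel_label = selection if isinstance(selection, str) else ",".join(selection or [])
    if not per_residue:
        ids = [(traj.residue_ids[i][0], traj.residue_ids[i][1]) for i in sel_idx]
        return RmsfProfile(
            residue_ids=ids, rmsf=atom_rmsf[sel_idx], selection=sel_label or "all",
            atom_rmsf=atom_frame,
        )
    grouped = atom_frame.groupby(["chain_id", "seq_number"], sort=False)["rmsf_A"].apply(
        lambda v: float(np.sqrt(np.mean(np.square(v))))
    )
    ids = list(grouped.index)
    return RmsfProfile(
        residue_ids=ids,
        rmsf=grouped.to_numpy(),
        selection=sel_label or "all",
        atom_rmsf=atom_frame,
    )


def read_multiframe_pdb(text: str) -> Trajectory:
    """Load a multi-MODEL PDB file as a trajectory (identical atom order)."""
    blocks: list[str] = []
    current: list[str] = []
    in_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model = True
            current = []
        elif rec == "ENDMDL":
            blocks.append("\n".join(current) + "\nEND\n")
            in_model = False
        elif in_model:
            current.append(line)
    if not blocks:
        blocks = [text]
    frames = []
    meta = None
    for block in blocks:
        model = parse_structure(block)
        atoms, names, rids, rnames = [], [], [], []
        for res in model.residues():
            for atom in res.atoms:
                atoms.append(atom.coord)
                names.append(atom.name)
                rids.append((res.chain_id, res.seq_number))
                rnames.append(res.res_name)
        frames.append(np.array(atoms))
        if meta is None:
            meta = (names, rids, rnames)
        elif names != meta[0]:
            raise ValueError("frames differ in atom names/order")
    coords = np.stack(frames)
    return Trajectory(
        coords=coords, atom_names=meta[0], residue_ids=meta[1], residue_names=meta[2]
    )


def read_xyz_frames(
    text: str, atom_names: list[str], residue_ids: list[tuple[str, int]]
) -> Trajectory:
    """Whitespace-delimited frames: one row per atom (x y z), frames separated
    by blank lines."""
    frames = []
    current: list[list[float]] = []
    for line in text.splitlines():
        if not line.strip():
            if current:
                frames.append(current)
                current = []
            continue
        current.append([float(tok) for tok in line.split()[:3]])
    if current:
        frames.append(current)
    coords = np.array(frames, dtype=float)
    return Trajectory(coords=coords, atom_names=atom_names, residue_ids=residue_ids)
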