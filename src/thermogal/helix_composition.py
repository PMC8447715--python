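"""Alpha-helix assignment, helix-dipole stabilization scoring, composition.

The helix dipole carries a partial positive charge at the N-terminus and a
partial negative charge at the C-terminus. Charged side chains in the first
or last three helix residues therefore either stabilize or destabilize it:
a positive residue (Lys, Arg, His) stabilizes at the C-terminus and
destabilizes at the N-terminus; a negative residue (Glu, Asp) does the
opposite. A helix counts as "stabilized" when its stabilizing effects
outnumber its destabilizing ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Residue, StructureModel

__all__ = [
    "HelixAnnotation",
    "HelixDipole",
    "DipoleScore",
    "assign_helices",
    "score_helix_dipoles",
    "pro_gly_ratio",
]

POSITIVE_RESIDUES = frozenset({"LYS", "ARG", "HIS"})
NEGATIVE_RESIDUES = frozenset({"GLU", "ASP"})

# Dihedral windows for the fallback helix assignment (degrees).
PHI_RANGE = (-100.0, -30.0)
PSI_RANGE = (-80.0, -5.0)
MIN_HELIX_LENGTH = 4
TERMINAL_WINDOW = 3


@dataclass(frozen=True)
class HelixAnnotation:
    chain_id: str
    start: int  # seq_number of the first residue
    end: int  # seq_number of the last residue
    length: int


@dataclass
class HelixDipole:
    """Per-helix terminal-charge counts. ``net`` = stabilizing - destabilizing."""

    helix: HelixAnnotation
    n_term_stabilizing: int = 0
    n_term_destabilizing: int = 0
    c_term_stabilizing: int = 0
    c_term_destabilizing: int = 0

    @property
    def net(self) -> int:
        return (
            self.n_term_stabilizing
            + self.c_term_stabilizing
            - self.n_term_destabilizing
            - self.c_term_destabilizing
        )

    @property
    def stabilized(self) -> bool:
        return (self.n_term_stabilizing + self.c_term_stabilizing) > (
            self.n_term_destabilizing + self.c_term_destabilizing
        )


@dataclass
class DipoleScore:
    """Structure-level aggregate of per-helix dipole counts."""

    helices: list[HelixDipole] = field(default_factory=list)

    @property
    def total_stabilizing(self) -> int:
        return sum(h.n_term_stabilizing + h.c_term_stabilizing for h in self.helices)

    @property
    def total_destabilizing(self) -> int:
        return sum(h.n_term_destabilizing + h.c_term_destabilizing for h in self.helices)

    @property
    def net(self) -> int:
        return self.total_stabilizing - self.total_destabilizing

    @property
    def n_stabilized_helices(self) -> int:
        return sum(1 for h in self.helices if h.stabilized)


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Dihedral angle (degrees, signed) of four points."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _chain_backbone(residues: list[Residue]):
    for res in residues:
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        yield res, (n.coord if n else None, ca.coord if ca else None, c.coord if c else None)


def _dihedral_helices(model: StructureModel) -> list[HelixAnnotation]:
    annotations: list[HelixAnnotation] = []
    for chain_id, residues in model.chains.items():
        polymer = [r for r in residues if model.is_polymer(r)]
        bb = list(_chain_backbone(polymer))
        helical = []
        for i, (res, (n, ca, c)) in enumerate(bb):
            phi = psi = None
            # dihedrals are only defined across an actual peptide bond
            if i > 0 and n is not None and ca is not None and c is not None:
                prev_c = bb[i - 1][1][2]
                if prev_c is not None and np.linalg.norm(n - prev_c) < 2.0:
                    phi = _dihedral(prev_c, n, ca, c)
            if i < len(bb) - 1 and n is not None and ca is not None and c is not None:
                next_n = bb[i + 1][1][0]
                if next_n is not None and np.linalg.norm(next_n - c) < 2.0:
                    psi = _dihedral(n, ca, c, next_n)
            # chain-terminal residues have one undefined angle: judge them on
            # the angle that exists, so an ideal helix spans its full length
            phi_ok = phi is None or PHI_RANGE[0] <= phi <= PHI_RANGE[1]
            psi_ok = psi is None or PSI_RANGE[0] <= psi <= PSI_RANGE[1]
            ok = phi_ok and psi_ok and not (phi is None and psi is None)
            helical.append(ok)
        # maximal runs of >= MIN_HELIX_LENGTH consecutive helical residues
        i = 0
        while i < len(helical):
            if helical[i]:
                j = i
                while j < len(helical) and helical[j]:
                    j += 1
                if j - i >= MIN_HELIX_LENGTH:
                    annotations.append(
                        HelixAnnotation(
                            chain_id=chain_id,
                            start=polymer[i].seq_number,
                            end=polymer[j - 1].seq_number,
                            length=j - i,
                        )
                    )
                i = j
            else:
                i += 1
    return annotations


def assign_helices(model: StructureModel, source: str = "records") -> list[HelixAnnotation]:
    """Return helix annotations from HELIX records or backbone dihedrals.

    ``source="records"`` reads the file's HELIX annotations (erroring with a
    pointer to dihedral mode when none exist); ``source="dihedral"`` returns
    maximal runs of at least four consecutive residues with phi in
    [-100, -30] and psi in [-80, -5] degrees.
    """
    if source == "records":
        if not model.helix_annotations:
            raise ValueError(
                "no HELIX records in this structure; use assign_helices(..., source='dihedral')"
            )
        out = []
        for chain_id, start, end in model.helix_annotations:
            residues = [
                r
                for r in model.chains.get(chain_id, [])
                if start <= r.seq_number <= end and model.is_polymer(r)
            ]
            out.append(HelixAnnotation(chain_id=chain_id, start=start, end=end, length=len(residues)))
        return out
    if source == "dihedral":
        return _dihedral_helices(model)
    raise ValueError(f"unknown helix source {source!r}; expected 'records' or 'dihedral'")


def _helix_residues(model: StructureModel, helix: HelixAnnotation) -> list[Residue]:
    return [
        r
        for r in model.chains.get(helix.chain_id, [])
        if helix.start <= r.seq_number <= helix.end and model.is_polymer(r)
    ]


def score_helix_dipoles(
    model: StructureModel, helices: list[HelixAnnotation]
) -> DipoleScore:
    """Score dipole stabilization over the first/last three residues per helix.

    A residue falling in both terminal windows of a short helix is counted
    once per window (with a warning), matching the literal three-residue-
    window rule.
    """
    score = DipoleScore()
    for helix in helices:
        residues = _helix_residues(model, helix)
        if not residues:
            continue
        dip = HelixDipole(helix=helix)
        if len(residues) < 2 * TERMINAL_WINDOW:
            warnings.warn(
                f"helix {helix.chain_id}:{helix.start}-{helix.end} shorter than "
                f"{2 * TERMINAL_WINDOW} residues; terminal windows overlap",
                stacklevel=2,
            )
        n_window = residues[:TERMINAL_WINDOW]
        c_window = residues[-TERMINAL_WINDOW:]
        for res in n_window:
            if res.res_name in NEGATIVE_RESIDUES:
                dip.n_term_stabilizing += 1
            elif res.res_name in POSITIVE_RESIDUES:
                dip.n_term_destabilizing += 1
        for res in c_window:
            if res.res_name in POSITIVE_RESIDUES:
                dip.c_term_stabilizing += 1
            elif res.res_name in NEGATIVE_RESIDUES:
                dip.c_term_destabilizing += 1
        score.helices.append(dip)
    return score


def pro_gly_ratio(model: StructureModel) -> float:
    """Proline count divided by glycine count over polymer residues.

    Returns NaN (flagged undefined) when the structure contains no glycine.
    """
    polymer = model.polymer_residues()
    n_pro = sum(1 for r in polymer if r.res_name == "PRO")
    n_gly = sum(1 for r in polymer if r.res_name == "GLY")
    if n_gly == 0:
        warnings.warn("no glycine residues; Pro/Gly ratio undefined", stacklevel=2)
        return float("nan")
    return n_pro / n_gly
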