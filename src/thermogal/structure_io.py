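"""Coordinate data model and PDB-format I/O.

A deliberately small hierarchical model (structure -> chains -> residues ->
atoms) carrying exactly what the interaction detectors, helix analysis and
compactness metrics need: atom names, element symbols, Cartesian coordinates
in Angstrom, hetero flags and HELIX annotations. Parsing is delegated to
gemmi; on top of it this module resolves alternate locations, keeps only the
first MODEL and enforces the error contract. Writing produces fixed-column
PDB text that round-trips through :func:`parse_structure` with coordinates
preserved to three decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "PDBParseError",
    "PDBWriteError",
    "parse_structure",
    "select_polymer",
    "write_structure",
    "STANDARD_AMINO_ACIDS",
]

#: Three-letter codes treated as polymer (protein) residues by default.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Water residue names.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class PDBParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


class PDBWriteError(ValueError):
    """Raised when a model cannot be serialized as PDB."""


@dataclass
class AtomRecord:
    """A single atom: name, element, position (Angstrom) and bookkeeping."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False
    serial: int = 0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """One residue: identity triple plus its atoms (altloc-resolved)."""

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        """Unique residue identifier (chain_id, seq_number, insertion_code)."""
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain_id}/{self.res_name}{self.seq_number}{icode}"

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, names: list[str] | None = None) -> np.ndarray:
        if names is None:
            return np.array([a.coord for a in self.atoms], dtype=float)
        return np.array([a.coord for a in self.atoms if a.name in names], dtype=float)


@dataclass
class StructureModel:
    """Parsed structure: ordered chains of residues plus HELIX annotations.

    ``chains`` maps chain_id to the ordered residue list (insertion order of
    the file). ``helix_annotations`` holds ``(chain_id, start_seq, end_seq)``
    triples from HELIX records when present.
    """

    structure_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    helix_annotations: list[tuple[str, int, int]] = field(default_factory=list)
    polymer_whitelist: frozenset[str] = STANDARD_AMINO_ACIDS

    def residues(self) -> list[Residue]:
        return [r for residues in self.chains.values() for r in residues]

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues() if self.is_polymer(r)]

    def hetero_residues(self) -> list[Residue]:
        return [r for r in self.residues() if not self.is_polymer(r)]

    def is_polymer(self, residue: Residue) -> bool:
        return residue.res_name in self.polymer_whitelist and not any(
            a.is_hetero for a in residue.atoms
        )

    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues() for a in r.atoms]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for res in self.residues():
            if res.key in seen:
                raise ValueError(f"duplicate residue identifier {res.key}")
            seen.add(res.key)
            names = [a.name for a in res.atoms]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate atom names in residue {res.label}")


def _resolve_altlocs(raw_atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one location per atom name: highest occupancy, tie -> smallest altloc."""
    by_name: dict[str, list[AtomRecord]] = {}
    for a in raw_atoms:
        by_name.setdefault(a.name, []).append(a)
    resolved = []
    for name, group in by_name.items():
        best = min(group, key=lambda a: (-a.occupancy, a.altloc or "~"))
        resolved.append(best)
    resolved.sort(key=lambda a: a.serial)
    return resolved


def _prevalidate(pdb_text: str) -> None:
    n_coord_lines = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        n_coord_lines += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated {rec} record ({len(line)} columns)")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: unparseable {what} coordinate field {line[lo:hi]!r}"
                ) from None
    if n_coord_lines == 0:
        raise PDBParseError("no ATOM or HETATM records found")


def parse_structure(
    pdb_text: str,
    structure_id: str = "",
    polymer_whitelist: frozenset[str] = STANDARD_AMINO_ACIDS,
) -> StructureModel:
    """Parse PDB text into a :class:`StructureModel`.

    Only the first MODEL is used (a warning is issued if more are present).
    Alternate locations are resolved to the highest-occupancy copy
    (ties broken by the lexicographically smallest altloc character).
    Waters and hetero groups are retained with ``is_hetero=True``.
    """
    if not pdb_text or not pdb_text.strip():
        raise PDBParseError("empty PDB input")
    _prevalidate(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line in its message
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError("no models in PDB input")
    if len(st) > 1:
        warnings.warn(
            f"{len(st)} MODELs present; using the first only", stacklevel=2
        )
    gmodel = st[0]

    model = StructureModel(
        structure_id=structure_id or (st.name or "").strip(),
        polymer_whitelist=polymer_whitelist,
    )
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            hetero = gres.het_flag == "H"
            raw = [
                AtomRecord(
                    name=ga.name,
                    element=ga.element.name.upper(),
                    coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    altloc="" if ga.altloc == "\0" else ga.altloc,
                    is_hetero=hetero,
                    serial=ga.serial,
                )
                for ga in gres
            ]
            icode = gres.seqid.icode.strip()
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_number=gres.seqid.num,
                    insertion_code=icode,
                    res_name=gres.name,
                    atoms=_resolve_altlocs(raw),
                )
            )
        if residues:
            model.chains.setdefault(gchain.name, []).extend(residues)

    for helix in st.helices:
        model.helix_annotations.append(
            (helix.start.chain_name, helix.start.res_id.seqid.num, helix.end.res_id.seqid.num)
        )
    model.validate()
    return model


def select_polymer(model: StructureModel, chain_id: str) -> StructureModel:
    """Restrict a model to one chain, keeping its hetero groups and waters.

    The polymer/hetero distinction is preserved so metal-coordination analysis
    still sees ions and waters of the selected chain.
    """
    if chain_id not in model.chains:
        available = ", ".join(sorted(model.chains)) or "(none)"
        raise KeyError(f"chain {chain_id!r} not found; available chains: {available}")
    sub = StructureModel(
        structure_id=model.structure_id,
        chains={chain_id: list(model.chains[chain_id])},
        helix_annotations=[h for h in model.helix_annotations if h[0] == chain_id],
        polymer_whitelist=model.polymer_whitelist,
    )
    return sub


def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise PDBWriteError(f"atom name {name!r} longer than 4 characters")
    # Standard PDB convention: 1-letter elements start in column 14.
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(model: StructureModel) -> str:
    """Serialize a model as fixed-column PDB text (ATOM/HETATM/HELIX/TER/END)."""
    if model.n_atoms() == 0:
        raise PDBWriteError("model contains no atoms")
    lines: list[str] = []
    for idx, (chain_id, start, end) in enumerate(model.helix_annotations, start=1):
        length = end - start + 1
        lines.append(
            f"HELIX  {idx:>3d} {idx:>3d} UNK {chain_id:1s} {start:>4d}  "
            f"UNK {chain_id:1s} {end:>4d}  1{'':30s}{length:>6d}"
        )
    serial = 0
    for chain_id, residues in model.chains.items():
        last_polymer: Residue | None = None
        for res in residues:
            for atom in res.atoms:
                serial += 1
                record = "HETATM" if atom.is_hetero else "ATOM  "
                name = _format_atom_name(atom.name, atom.element)
                x, y, z = atom.coord
                lines.append(
                    f"{record}{serial:>5d} {name}{atom.altloc or ' '}"
                    f"{res.res_name:>3s} {chain_id:1s}{res.seq_number:>4d}"
                    f"{res.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
            if model.is_polymer(res):
                last_polymer = res
        if last_polymer is not None:
            serial += 1
            lines.append(
                f"TER   {serial:>5d}      {last_polymer.res_name:>3s} "
                f"{chain_id:1s}{last_polymer.seq_number:>4d}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"
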