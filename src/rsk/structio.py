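"""Structure data model, PDB coordinate I/O and geometry primitives.

The data model is deliberately small: a :class:`Structure` holds one or
more models, each an ordered list of :class:`Residue` objects addressed
by ``(chain_id, residue_number, insertion_code)``.  Coordinates are in Å
in the frame of the source file; residue numbering is taken verbatim
from the file.  Alternate locations are resolved at parse time to the
highest-occupancy conformer (ties broken by file order); hydrogens are
parsed but excluded from heavy-atom selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .chem import CANONICAL_AAS, element_of


class PDBParseError(ValueError):
    """Malformed coordinate file; carries the offending line number."""


class PDBWriteError(ValueError):
    pass


class SelectionError(KeyError):
    pass


class DegeneracyError(ValueError):
    pass


@dataclass
class AtomRecord:
    atom_name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"bad coordinates for atom {self.atom_name!r}")
        if not self.atom_name.strip():
            raise ValueError("empty atom name")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    chain_id: str
    residue_number: int
    identity: str
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: str = ""
    is_hetero: bool = False
    phi: float | None = None
    psi: float | None = None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def is_amino_acid(self) -> bool:
        return self.identity in CANONICAL_AAS

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        raise SelectionError(
            f"atom {name!r} not in {self.identity} "
            f"{self.chain_id}{self.residue_number}{self.insertion_code}")

    def has_atom(self, name: str) -> bool:
        return any(a.atom_name == name for a in self.atoms)

    def heavy_coords(self, names: list[str] | None = None) -> np.ndarray:
        atoms = self.atoms if names is None else [self.atom(n) for n in names]
        sel = [a.coords for a in atoms if a.is_heavy]
        return np.array(sel).reshape(-1, 3)

    def sidechain_heavy_atoms(self) -> list[AtomRecord]:
        backbone = {"N", "CA", "C", "O", "OXT"}
        return [a for a in self.atoms
                if a.is_heavy and a.atom_name not in backbone]


@dataclass
class Model:
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self):
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, chain_id: str, residue_number: int,
                insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain_id, residue_number, insertion_code):
                return r
        raise SelectionError(
            f"residue {chain_id}:{residue_number}{insertion_code} not found")

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def ca_coords(self) -> np.ndarray:
        sel = [r.atom("CA").coords for r in self.residues
               if r.is_amino_acid and r.has_atom("CA")]
        return np.array(sel).reshape(-1, 3)

    def heavy_coords(self) -> np.ndarray:
        sel = [a.coords for r in self.residues for a in r.atoms if a.is_heavy]
        return np.array(sel).reshape(-1, 3)


@dataclass
class Structure:
    models: list[Model] = field(default_factory=list)
    header_metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.models:
            self.models = [Model()]

    @property
    def first_model(self) -> Model:
        return self.models[0]

    def copy(self) -> "Structure":
        models = [
            Model([replace(r, atoms=[replace(a, coords=a.coords.copy())
                                     for a in r.atoms])
                   for r in m.residues])
            for m in self.models
        ]
        return Structure(models, dict(self.header_metadata))


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# --- PDB I/O --------------------------------------------------------------

_SUPPORTED_DIALECTS = ("pdb",)


def parse_structure(text: str, dialect: str = "pdb") -> Structure:
    """Parse PDB-format coordinate text into a :class:`Structure`.

    Multi-MODEL files yield one model each; alternate locations are
    resolved to the highest-occupancy conformer (tie → first in file);
    insertion codes are preserved.
    """
    if dialect not in _SUPPORTED_DIALECTS:
        raise ValueError(f"unsupported dialect {dialect!r}")
    if not text.strip():
        raise PDBParseError("empty coordinate text")

    models: list[Model] = []
    current = Model()
    seen_any_atom = False
    # altloc bookkeeping per model: (res key, atom name) → (occupancy, index)
    alt_seen: dict[tuple, tuple[float, int]] = {}

    def flush() -> None:
        nonlocal current, alt_seen
        if current.residues:
            models.append(current)
        current = Model()
        alt_seen = {}

    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6]
        if record == "MODEL ":
            flush()
        elif record == "ENDMDL":
            flush()
        elif record in ("ATOM  ", "HETATM"):
            seen_any_atom = True
            try:
                atom_name = line[12:16].strip()
                altloc = line[16].strip()
                identity = line[17:20].strip()
                chain_id = line[21].strip()
                residue_number = int(line[22:26])
                icode = line[26].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ_text = line[54:60].strip()
                occupancy = float(occ_text) if occ_text else 1.0
                b_text = line[60:66].strip()
                b_factor = float(b_text) if b_text else 0.0
                element = line[76:78].strip() or element_of(atom_name)
            except (ValueError, IndexError) as exc:
                raise PDBParseError(
                    f"malformed {record.strip()} record at line {lineno}: "
                    f"{exc}") from exc
            atom = AtomRecord(atom_name, element, np.array([x, y, z]),
                              min(max(occupancy, 0.0), 1.0), b_factor)
            res_key = (chain_id, residue_number, icode)
            res = None
            for r in reversed(current.residues):
                if r.key == res_key and r.identity == identity:
                    res = r
                    break
            if res is None:
                res = Residue(chain_id, residue_number, identity,
                              insertion_code=icode,
                              is_hetero=(record == "HETATM"))
                current.residues.append(res)
            slot = (res_key, identity, atom_name)
            if altloc:
                prev = alt_seen.get(slot)
                if prev is not None:
                    prev_occ, prev_idx = prev
                    if occupancy > prev_occ:
                        res.atoms[prev_idx] = atom
                        alt_seen[slot] = (occupancy, prev_idx)
                    continue
                alt_seen[slot] = (occupancy, len(res.atoms))
            res.atoms.append(atom)
    flush()
    if not seen_any_atom:
        raise PDBParseError("no ATOM/HETATM records found")
    return Structure(models)


def write_structure(s: Structure, dialect: str = "pdb") -> str:
    """Serialize to PDB text; round-trips coordinates to 1e-3 Å."""
    if dialect not in _SUPPORTED_DIALECTS:
        raise ValueError(f"unsupported dialect {dialect!r}")
    lines: list[str] = []
    multi = len(s.models) > 1
    serial = 1
    for imodel, model in enumerate(s.models, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:4d}")
            serial = 1
        for res in model.residues:
            record = "HETATM" if res.is_hetero else "ATOM  "
            for a in res.atoms:
                x, y, z = a.coords
                for v in (x, y, z):
                    if not -999.999 <= v <= 9999.999:
                        raise PDBWriteError(
                            f"coordinate {v:.3f} exceeds PDB field width")
                name = a.atom_name
                fname = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"{record}{serial % 100000:5d} {fname:<4s}"
                    f"{res.identity:>4s} {res.chain_id or 'A':1s}"
                    f"{res.residue_number:4d}{res.insertion_code or ' ':1s}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}"
                    f"{a.b_factor:6.2f}          {a.element:>2s}")
                serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# --- geometry -------------------------------------------------------------

def superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch; proper rotations only).

    Returns the transform minimizing the RMSD of ``mobile`` onto
    ``target`` over ordered point correspondences.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(
            f"shape mismatch: {mobile.shape} vs {target.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    p = mobile - mc
    q = target - tc
    if (np.linalg.matrix_rank(p, tol=1e-8) < 2
            or np.linalg.matrix_rank(q, tol=1e-8) < 2):
        raise DegeneracyError("point cloud is collinear or degenerate")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tc - rot @ mc
    moved = mobile @ rot.T + trans
    value = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=value)


def rmsd(a: np.ndarray, b: np.ndarray, presuperpose: bool = False) -> float:
    """Root-mean-square deviation between ordered point sets (Å)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty selection")
    if presuperpose:
        return superpose(a, b).rmsd
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def neighbor_count(points_a: np.ndarray, points_b: np.ndarray,
                   cutoff: float) -> int:
    """Number of points in ``a`` with any point of ``b`` within ``cutoff``.

    The boundary is inclusive (d ≤ cutoff).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    points_a = np.asarray(points_a, dtype=float).reshape(-1, 3)
    points_b = np.asarray(points_b, dtype=float).reshape(-1, 3)
    if len(points_a) == 0 or len(points_b) == 0:
        return 0
    tree = cKDTree(points_b)
    dist, _ = tree.query(points_a, k=1)
    return int(np.sum(dist <= cutoff + 1e-12))


def assign_backbone_dihedrals(s: Structure) -> None:
    """Set phi/psi on every amino-acid residue (termini stay undefined)."""
    from .chem import dihedral as _dihedral

    for model in s.models:
        by_chain: dict[str, list[Residue]] = {}
        for r in model.residues:
            if r.is_amino_acid:
                by_chain.setdefault(r.chain_id, []).append(r)
        for chain_res in by_chain.values():
            for i, r in enumerate(chain_res):
                try:
                    n, ca, c = (r.atom("N").coords, r.atom("CA").coords,
                                r.atom("C").coords)
                except SelectionError:
                    continue
                if i > 0 and chain_res[i - 1].has_atom("C"):
                    r.phi = _dihedral(chain_res[i - 1].atom("C").coords,
                                      n, ca, c)
                if i + 1 < len(chain_res) and chain_res[i + 1].has_atom("N"):
                    r.psi = _dihedral(n, ca, c,
                                      chain_res[i + 1].atom("N").coords)
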