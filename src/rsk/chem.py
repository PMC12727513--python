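"""Chemical reference data and internal-coordinate machinery.

Provides element properties, canonical amino-acid tables (chi dihedral
definitions, hydrophobicity, reference sidechain SASA), and the
internal-coordinate (z-matrix) templates used to build sidechains from
chi angles.  Template bond lengths, angles and fixed torsions are
measured once per identity from CCD ideal residue geometry (via
biotite) and cached.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

# --- element data ---------------------------------------------------------

#: van der Waals radii (Å) used by the default clash criterion.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
}

#: atomic masses (u) for mass-weighted descriptors (radius of gyration).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
CANONICAL_AAS = frozenset(THREE_TO_ONE)
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: standard chi dihedral definitions (atom-name quadruples, chi1..chi4).
CHI_DEFINITIONS: dict[str, list[tuple[str, str, str, str]]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
}

#: identities with at least one chi dihedral.
CHI_BEARING = tuple(sorted(k for k, v in CHI_DEFINITIONS.items() if v))

#: Black & Mould (1991) relative hydrophobicity, 0–1 normalized.
BLACK_MOULD_HYDROPHOBICITY: dict[str, float] = {
    "ALA": 0.616, "ARG": 0.000, "ASN": 0.236, "ASP": 0.028, "CYS": 0.680,
    "GLN": 0.251, "GLU": 0.043, "GLY": 0.501, "HIS": 0.165, "ILE": 0.943,
    "LEU": 0.943, "LYS": 0.283, "MET": 0.738, "PHE": 1.000, "PRO": 0.711,
    "SER": 0.359, "THR": 0.450, "TRP": 0.878, "TYR": 0.880, "VAL": 0.825,
}


def hydrophobicity(identity: str) -> float:
    """Black–Mould hydrophobicity shifted so that glycine scores zero."""
    return BLACK_MOULD_HYDROPHOBICITY[identity] - BLACK_MOULD_HYDROPHOBICITY["GLY"]


#: fully exposed sidechain reference SASA (Å², Tien et al. 2013 theoretical).
SIDECHAIN_REF_SASA: dict[str, float] = {
    "ALA": 67.0, "ARG": 196.0, "ASN": 113.0, "ASP": 106.0, "CYS": 104.0,
    "GLN": 144.0, "GLU": 138.0, "GLY": 25.0, "HIS": 118.0, "ILE": 140.0,
    "LEU": 137.0, "LYS": 162.0, "MET": 160.0, "PHE": 175.0, "PRO": 105.0,
    "SER": 80.0, "THR": 102.0, "TRP": 217.0, "TYR": 187.0, "VAL": 117.0,
}


def element_of(atom_name: str) -> str:
    """Guess an element symbol from a PDB atom name (heavy-atom oriented)."""
    stripped = atom_name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    for two in ("CL", "BR"):
        if stripped.upper().startswith(two):
            return two
    return stripped[0].upper()


# --- geometry primitives --------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else float(ang)


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    v1 = p0 - p1
    v2 = p2 - p1
    c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position X with |c-X| = bond, ∠(b,c,X) = angle and
    dihedral a-b-c-X = torsion (degrees)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        -bond * np.sin(ang) * np.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.stack([bc, np.cross(n, bc), n], axis=1)
    return c + m @ d


# --- sidechain z-matrix templates ----------------------------------------

@dataclass(frozen=True)
class ZMatrixRow:
    """One internal-coordinate row: place `atom` from refs (d, a, b)."""
    atom: str
    ref_d: str
    ref_a: str
    ref_b: str
    bond: float
    angle: float
    torsion: float | None  # None → variable (chi)
    chi_index: int | None  # 0-based chi index when variable


@dataclass(frozen=True)
class ResidueTemplate:
    identity: str
    rows: tuple[ZMatrixRow, ...]
    n_chi: int
    sidechain_atoms: tuple[str, ...]


def _ideal_residue_graph(identity: str):
    import biotite.structure.info as _info

    res = _info.residue(identity)
    mask = (res.element != "H") & (res.atom_name != "OXT")
    res = res[mask]
    names = list(res.atom_name)
    coords = {n: res.coord[i].astype(float) for i, n in enumerate(names)}
    adjacency: dict[str, set[str]] = {n: set() for n in names}
    for i, j, _ in res.bonds.as_array():
        if i < len(names) and j < len(names):
            adjacency[names[i]].add(names[j])
            adjacency[names[j]].add(names[i])
    return names, coords, adjacency


@lru_cache(maxsize=None)
def residue_template(identity: str) -> ResidueTemplate:
    """Internal-coordinate template for one canonical identity.

    Sidechain atoms are ordered breadth-first from CA; the torsion of the
    first atom on each chi path is variable, all other torsions are fixed
    at the CCD ideal value.  Reference atoms for the torsion of a branch
    atom are the earliest-placed sibling, which keeps every chi a true
    free variable.
    """
    if identity not in CANONICAL_AAS:
        raise KeyError(f"not a canonical amino acid: {identity!r}")
    names, coords, adjacency = _ideal_residue_graph(identity)
    chi_quads = CHI_DEFINITIONS[identity]
    chi_fourth = {q[3]: k for k, q in enumerate(chi_quads)}

    parent: dict[str, str] = {"CA": "N", "N": "C"}
    placed = ["N", "CA", "C"]
    placed_set = set(placed)
    rows: list[ZMatrixRow] = []
    # BFS from CA into the sidechain; chi-path atoms visited first.
    queue = ["CA"]
    while queue:
        p = queue.pop(0)
        children = [n for n in sorted(adjacency[p])
                    if n not in placed_set and n not in ("N", "C", "O")]
        children.sort(key=lambda n: (n not in chi_fourth, n))
        first_child_of_p: str | None = None
        for child in children:
            g = parent[p]
            if first_child_of_p is not None:
                ref_d = first_child_of_p
            elif p == "CA":
                ref_d = "C"  # improper C-N-CA-CB fixes L-chirality
            else:
                ref_d = parent[g]
            bond = float(np.linalg.norm(coords[child] - coords[p]))
            angle = bond_angle(coords[g], coords[p], coords[child])
            tor = dihedral(coords[ref_d], coords[g], coords[p], coords[child])
            chi_k = None
            if (child in chi_fourth
                    and chi_quads[chi_fourth[child]] == (ref_d, g, p, child)):
                chi_k = chi_fourth[child]
            rows.append(ZMatrixRow(child, ref_d, g, p, bond, angle,
                                   None if chi_k is not None else tor,
                                   chi_k))
            parent[child] = p
            placed.append(child)
            placed_set.add(child)
            if first_child_of_p is None:
                first_child_of_p = child
            queue.append(child)
    return ResidueTemplate(
        identity=identity,
        rows=tuple(rows),
        n_chi=len(chi_quads),
        sidechain_atoms=tuple(r.atom for r in rows),
    )


def build_sidechain_atoms(identity: str, frame: np.ndarray,
                          chi: tuple[float, ...] | list[float]) -> dict[str, np.ndarray]:
    """Build sidechain heavy-atom coordinates onto a backbone frame.

    Parameters
    ----------
    identity : three-letter amino-acid code
    frame : (3, 3) array of N, CA, C coordinates (Å, in that order)
    chi : chi dihedrals in degrees; length must match the identity

    Returns a name → coordinate map for the sidechain atoms (CB outward).
    """
    template = residue_template(identity)
    chi = tuple(float(c) for c in chi)
    if len(chi) != template.n_chi:
        raise ValueError(
            f"{identity} takes {template.n_chi} chi angles, got {len(chi)}")
    pos: dict[str, np.ndarray] = {
        "N": np.asarray(frame[0], dtype=float),
        "CA": np.asarray(frame[1], dtype=float),
        "C": np.asarray(frame[2], dtype=float),
    }
    for row in template.rows:
        torsion = chi[row.chi_index] if row.torsion is None else row.torsion
        pos[row.atom] = place_atom(pos[row.ref_d], pos[row.ref_a],
                                   pos[row.ref_b], row.bond, row.angle,
                                   torsion)
    return {name: pos[name] for name in template.sidechain_atoms}


def canonical_backbone_frame() -> np.ndarray:
    """Ideal N/CA/C coordinates with CA near the origin (Å)."""
    n_ca, ca_c, n_ca_c = 1.458, 1.525, 111.2
    n = np.array([-n_ca, 0.0, 0.0])
    ca = np.zeros(3)
    ang = np.radians(180.0 - n_ca_c)
    c = np.array([ca_c * np.cos(ang), ca_c * np.sin(ang), 0.0])
    return np.stack([n, ca, c])
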