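"""Artificial motif-library construction from catalytic arrays.

Pipeline: for every catalytic residue, select rotamers compatible with
the phi/psi of each helical-fragment anchor position, *invert* each
rotamer (functional-group atoms stay fixed in space, the backbone frame
is solved from the chi angles), rigidly place the fragment onto the
solved backbone, enumerate all mutually clash-free fragment
combinations, rank them by rotamer probability and fragment abundance,
and aggregate the result into a serializable library.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from . import structio
from .chem import (
    CHI_DEFINITIONS,
    VDW_RADII,
    build_sidechain_atoms,
    canonical_backbone_frame,
    element_of,
)
from .structio import (
    AtomRecord,
    DegeneracyError,
    Model,
    Residue,
    Structure,
    superpose,
)


class LookupError_(KeyError):
    pass


class CombinationCapError(RuntimeError):
    pass


# --- domain types ---------------------------------------------------------

@dataclass
class CatalyticResidue:
    """A catalytic-array member: identity + fixed functional-group atoms."""

    identity: str
    functional_atoms: dict[str, np.ndarray]
    source_label: str = ""

    def __post_init__(self) -> None:
        self.functional_atoms = {
            k: np.asarray(v, dtype=float) for k, v in self.functional_atoms.items()
        }
        if len(self.functional_atoms) < 3:
            raise ValueError(
                f"{self.identity} needs ≥3 functional atoms to fix a frame")

    @property
    def chi_definitions(self) -> list[tuple[str, str, str, str]]:
        return CHI_DEFINITIONS[self.identity]

    def functional_coords(self) -> np.ndarray:
        return np.stack(list(self.functional_atoms.values()))


@dataclass
class CatalyticArray:
    residues: list[CatalyticResidue]
    ligand: Residue | None = None
    name: str = "array"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("catalytic array needs at least one residue")


@dataclass(frozen=True)
class Rotamer:
    chi: tuple[float, ...]
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 < self.probability <= 1.0:
            raise ValueError(f"rotamer probability {self.probability} not in (0, 1]")


class RotamerLibrary:
    """Backbone-dependent rotamer table with square phi/psi bins."""

    def __init__(self, bin_width: float = 10.0):
        if not 0 < bin_width <= 360:
            raise ValueError("bin width must be in (0, 360]")
        self.bin_width = float(bin_width)
        self.entries: dict[tuple[str, int, int], list[Rotamer]] = {}

    def bin_index(self, angle: float) -> int:
        wrapped = ((float(angle) + 180.0) % 360.0) - 180.0
        idx = int(math.floor((wrapped + 180.0) / self.bin_width))
        return min(idx, int(360.0 / self.bin_width) - 1)

    def add(self, identity: str, phi: float, psi: float, rotamer: Rotamer) -> None:
        key = (identity, self.bin_index(phi), self.bin_index(psi))
        self.entries.setdefault(key, []).append(rotamer)

    def identities(self) -> set[str]:
        return {k[0] for k in self.entries}

    def lookup(self, identity: str, phi: float, psi: float) -> list[Rotamer]:
        if identity not in self.identities():
            raise LookupError_(f"identity {identity!r} absent from rotamer library")
        key = (identity, self.bin_index(phi), self.bin_index(psi))
        return list(self.entries.get(key, []))

    # TSV schema: identity  phi_bin_center  psi_bin_center  probability  chi1..chi4
    def to_tsv(self) -> str:
        rows = []
        for (identity, bi, bj), rotamers in sorted(self.entries.items()):
            phi_c = -180.0 + (bi + 0.5) * self.bin_width
            psi_c = -180.0 + (bj + 0.5) * self.bin_width
            for rot in rotamers:
                chis = list(rot.chi) + [math.nan] * (4 - len(rot.chi))
                rows.append([identity, phi_c, psi_c, rot.probability, *chis])
        df = pd.DataFrame(
            rows, columns=["identity", "phi", "psi", "probability",
                           "chi1", "chi2", "chi3", "chi4"])
        return df.to_csv(sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, text: str, bin_width: float = 10.0) -> "RotamerLibrary":
        df = pd.read_csv(StringIO(text), sep="\t")
        lib = cls(bin_width=bin_width)
        for row in df.itertuples(index=False):
            n_chi = len(CHI_DEFINITIONS[row.identity])
            chi = tuple(float(getattr(row, f"chi{k + 1}")) for k in range(n_chi))
            lib.add(row.identity, float(row.phi), float(row.psi),
                    Rotamer(chi=chi, probability=float(row.probability)))
        return lib


@dataclass
class HelicalFragment:
    """A short helical backbone in a canonical frame with an anchor slot."""

    backbone: list[dict[str, np.ndarray]]  # per residue: N/CA/C/O
    phi_psi: list[tuple[float, float]]
    anchor_index: int
    abundance: float = 0.0
    fragment_id: str = "frag"

    def __post_init__(self) -> None:
        if len(self.backbone) < 3:
            raise ValueError("fragment needs ≥3 residues")
        if not 0 < self.anchor_index < len(self.backbone) - 1:
            raise ValueError("anchor must be interior to the fragment")
        for i in range(len(self.backbone) - 1):
            d = np.linalg.norm(self.backbone[i + 1]["CA"] - self.backbone[i]["CA"])
            if not 3.3 <= d <= 4.3:
                raise ValueError(
                    f"CA(i)-CA(i+1) distance {d:.2f} Å outside 3.8 ± 0.5 Å")

    @property
    def length(self) -> int:
        return len(self.backbone)

    def anchor_phi_psi(self) -> tuple[float, float]:
        return self.phi_psi[self.anchor_index]

    def anchor_frame(self) -> np.ndarray:
        bb = self.backbone[self.anchor_index]
        return np.stack([bb["N"], bb["CA"], bb["C"]])

    def all_coords(self) -> np.ndarray:
        return np.array([bb[a] for bb in self.backbone
                         for a in ("N", "CA", "C", "O") if a in bb])


def fragments_to_tsv(fragments: list[HelicalFragment]) -> str:
    """Serialize a fragment set (one row per backbone atom)."""
    rows = []
    for frag in fragments:
        for i, bb in enumerate(frag.backbone):
            phi, psi = frag.phi_psi[i]
            for atom in ("N", "CA", "C", "O"):
                if atom not in bb:
                    continue
                x, y, z = bb[atom]
                rows.append([frag.fragment_id, i, atom, x, y, z, phi, psi,
                             frag.anchor_index, frag.abundance])
    df = pd.DataFrame(rows, columns=[
        "fragment_id", "residue_index", "atom_name", "x", "y", "z",
        "phi", "psi", "anchor_index", "abundance"])
    return df.to_csv(sep="\t", index=False, float_format="%.6f")


def fragments_from_tsv(text: str) -> list[HelicalFragment]:
    df = pd.read_csv(StringIO(text), sep="\t")
    fragments = []
    for frag_id, group in df.groupby("fragment_id", sort=False):
        backbone: list[dict[str, np.ndarray]] = []
        phi_psi: list[tuple[float, float]] = []
        for _, res in group.groupby("residue_index", sort=True):
            backbone.append({
                r.atom_name: np.array([r.x, r.y, r.z])
                for r in res.itertuples(index=False)})
            first = res.iloc[0]
            phi_psi.append((float(first.phi), float(first.psi)))
        first = group.iloc[0]
        fragments.append(HelicalFragment(
            backbone=backbone, phi_psi=phi_psi,
            anchor_index=int(first.anchor_index),
            abundance=float(first.abundance), fragment_id=str(frag_id)))
    return fragments


@dataclass
class FragmentPlacement:
    fragment: HelicalFragment
    rotation: np.ndarray
    translation: np.ndarray
    rotamer: Rotamer
    identity: str
    residue_index: int  # index of the catalytic residue this realizes

    def transformed_backbone(self) -> list[dict[str, np.ndarray]]:
        return [
            {a: c @ self.rotation.T + self.translation for a, c in bb.items()}
            for bb in self.fragment.backbone
        ]

    def anchor_frame(self) -> np.ndarray:
        return self.fragment.anchor_frame() @ self.rotation.T + self.translation

    def rebuilt_residue(self) -> Residue:
        """Full-atom catalytic residue realized on the anchor position."""
        frame = self.anchor_frame()
        side = build_sidechain_atoms(self.identity, frame, self.rotamer.chi)
        bb = self.transformed_backbone()[self.fragment.anchor_index]
        atoms = [AtomRecord(n, element_of(n), bb[n])
                 for n in ("N", "CA", "C", "O") if n in bb]
        atoms += [AtomRecord(n, element_of(n), c) for n, c in side.items()]
        return Residue("X", self.residue_index + 1, self.identity, atoms)

    def heavy_atoms(self) -> list[tuple[str, np.ndarray]]:
        """Fragment backbone + rebuilt sidechain heavy atoms (for clashes)."""
        out = [(a, c) for bb in self.transformed_backbone()
               for a, c in bb.items()]
        side = build_sidechain_atoms(
            self.identity, self.anchor_frame(), self.rotamer.chi)
        out += list(side.items())
        return out


@dataclass
class ClashParams:
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    tolerance_factor: float = 0.75
    exempt_pairs: frozenset[frozenset[str]] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 < self.tolerance_factor <= 1.0:
            raise ValueError("tolerance factor must be in (0, 1]")
        if any(r <= 0 for r in self.vdw_radii.values()):
            raise ValueError("vdW radii must be positive")

    def radius(self, element: str) -> float:
        try:
            return self.vdw_radii[element.upper()]
        except KeyError as exc:
            raise ValueError(f"no vdW radius configured for element "
                             f"{element!r}") from exc


@dataclass
class ClashReport:
    count: int
    pairs: list[tuple[str, str, float]]

    def __bool__(self) -> bool:
        return self.count > 0


@dataclass
class MotifAssembly:
    placements: list[FragmentPlacement]
    ligand: Residue | None = None
    score: float = 0.0
    clash_free: bool = True

    def functional_atom_coords(self, array: CatalyticArray) -> float:
        """Max deviation of rebuilt functional atoms from the array (Å)."""
        worst = 0.0
        for placement, cat in zip(self.placements, array.residues):
            res = placement.rebuilt_residue()
            for name, target in cat.functional_atoms.items():
                worst = max(worst, float(np.linalg.norm(
                    res.atom(name).coords - target)))
        return worst


@dataclass
class MotifLibrary:
    assemblies: list[MotifAssembly]
    provenance: dict = field(default_factory=dict)
    diagnostic: dict | None = None


# --- operations -----------------------------------------------------------

def build_sidechain_forward(identity: str, backbone_frame: np.ndarray,
                            chi: tuple[float, ...]) -> Residue:
    """Build a full-atom residue (backbone N/CA/C + ideal sidechain)."""
    frame = np.asarray(backbone_frame, dtype=float)
    side = build_sidechain_atoms(identity, frame, chi)
    atoms = [AtomRecord("N", "N", frame[0]),
             AtomRecord("CA", "C", frame[1]),
             AtomRecord("C", "C", frame[2])]
    atoms += [AtomRecord(n, element_of(n), c) for n, c in side.items()]
    return Residue("A", 1, identity, atoms)


def invert_rotamer(residue: CatalyticResidue,
                   chi: tuple[float, ...]) -> np.ndarray:
    """Solve the backbone N/CA/C frame realizing fixed functional atoms.

    The sidechain is forward-built in a canonical frame with the given
    chi angles; the rigid transform mapping its functional atoms onto
    the array's fixed coordinates is then applied to the backbone.  The
    functional-group atoms themselves never move.
    """
    canonical = canonical_backbone_frame()
    built = build_sidechain_forward(residue.identity, canonical, chi)
    names = list(residue.functional_atoms)
    mobile = np.stack([built.atom(n).coords for n in names])
    target = np.stack([residue.functional_atoms[n] for n in names])
    try:
        sup = superpose(mobile, target)
    except DegeneracyError as exc:
        raise DegeneracyError(
            f"functional atoms of {residue.identity} "
            f"({residue.source_label}) do not fix a frame") from exc
    return sup.apply(canonical)


def compatible_rotamers(identity: str, phi: float, psi: float,
                        lib: RotamerLibrary,
                        min_prob: float = 0.0) -> list[Rotamer]:
    """Rotamers of the (phi, psi) bin with probability ≥ ``min_prob``,
    sorted by descending probability (stable)."""
    rotamers = lib.lookup(identity, phi, psi)
    kept = [r for r in rotamers if r.probability >= min_prob]
    return sorted(kept, key=lambda r: -r.probability)


def place_fragment(fragment: HelicalFragment, anchor_frame: np.ndarray,
                   rotamer: Rotamer, identity: str,
                   residue_index: int = 0) -> FragmentPlacement:
    """Rigidly place a fragment so its anchor N/CA/C meet ``anchor_frame``."""
    sup = superpose(fragment.anchor_frame(), np.asarray(anchor_frame, float))
    return FragmentPlacement(
        fragment=fragment, rotation=sup.rotation, translation=sup.translation,
        rotamer=rotamer, identity=identity, residue_index=residue_index)


def _atom_list(obj) -> list[tuple[str, np.ndarray]]:
    if hasattr(obj, "heavy_atoms"):
        return obj.heavy_atoms()
    if isinstance(obj, Residue):
        return [(a.atom_name, a.coords) for a in obj.atoms if a.is_heavy]
    return list(obj)


def clash_check(a, b, params: ClashParams | None = None) -> ClashReport:
    """Count heavy-atom pairs with d < γ·(r_i + r_j) between two groups."""
    params = params or ClashParams()
    atoms_a = _atom_list(a)
    atoms_b = _atom_list(b)
    pairs: list[tuple[str, str, float]] = []
    if atoms_a and atoms_b:
        coords_a = np.stack([c for _, c in atoms_a])
        coords_b = np.stack([c for _, c in atoms_b])
        rad_a = np.array([params.radius(element_of(n)) for n, _ in atoms_a])
        rad_b = np.array([params.radius(element_of(n)) for n, _ in atoms_b])
        dmat = np.linalg.norm(
            coords_a[:, None, :] - coords_b[None, :, :], axis=-1)
        thresh = params.tolerance_factor * (rad_a[:, None] + rad_b[None, :])
        for i, j in zip(*np.nonzero(dmat < thresh)):
            name_a, name_b = atoms_a[i][0], atoms_b[j][0]
            if frozenset((name_a, name_b)) in params.exempt_pairs:
                continue
            pairs.append((name_a, name_b, float(dmat[i, j])))
    return ClashReport(count=len(pairs), pairs=pairs)


def score_assembly(a: MotifAssembly,
                   weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """w_rot · mean(log p_i) + w_abund · mean(log(abundance_i + 1))."""
    w_rot, w_abund = weights
    probs = [p.rotamer.probability for p in a.placements]
    abunds = [p.fragment.abundance for p in a.placements]
    if any(p <= 0 for p in probs) or any(x < 0 for x in abunds):
        raise ValueError("probabilities must be > 0 and abundances ≥ 0")
    return (w_rot * float(np.mean(np.log(probs)))
            + w_abund * float(np.mean(np.log1p(abunds))))


def enumerate_assemblies(candidates: list[list[FragmentPlacement]],
                         ligand: Residue | None = None,
                         params: ClashParams | None = None,
                         max_out: int = 100,
                         weights: tuple[float, float] = (1.0, 1.0),
                         combination_cap: int = 10 ** 6,
                         ) -> tuple[list[MotifAssembly], dict]:
    """Depth-first enumeration of all clash-free placement combinations.

    Takes one placement per catalytic residue; prunes on the first
    pairwise clash, so the surviving set equals brute-force filtering of
    the Cartesian product.  Returns (ranked assemblies, diagnostics).
    """
    params = params or ClashParams()
    diagnostics: dict = {"n_candidates": [len(c) for c in candidates]}
    if not candidates or any(len(c) == 0 for c in candidates):
        diagnostics["reason"] = "empty candidate list"
        return [], diagnostics

    n_total = math.prod(len(c) for c in candidates)
    if n_total > combination_cap:
        raise CombinationCapError(
            f"{n_total} combinations exceed the cap of {combination_cap}")

    atom_cache = [[_atom_list(p) for p in col] for col in candidates]
    ligand_atoms = _atom_list(ligand) if ligand is not None else None
    tightest: list[float] = [math.inf]

    def pair_ok(atoms_a, atoms_b) -> bool:
        report = clash_check(atoms_a, atoms_b, params)
        if report.count:
            tightest[0] = min(tightest[0],
                              min(d for _, _, d in report.pairs))
            return False
        return True

    ligand_ok = [
        [ligand_atoms is None or pair_ok(atoms, ligand_atoms)
         for atoms in col]
        for col in atom_cache
    ]

    results: list[tuple[float, int, MotifAssembly]] = []
    order_counter = [0]

    def recurse(level: int, chosen: list[int]) -> None:
        if level == len(candidates):
            placements = [candidates[k][i] for k, i in enumerate(chosen)]
            assembly = MotifAssembly(placements=list(placements),
                                     ligand=ligand, clash_free=True)
            assembly.score = score_assembly(assembly, weights)
            results.append((assembly.score, order_counter[0], assembly))
            order_counter[0] += 1
            return
        for i in range(len(candidates[level])):
            if not ligand_ok[level][i]:
                continue
            if all(pair_ok(atom_cache[k][chosen[k]], atom_cache[level][i])
                   for k in range(level)):
                recurse(level + 1, chosen + [i])

    recurse(0, [])
    results.sort(key=lambda t: (-t[0], t[1]))
    assemblies = [a for _, _, a in results[:max_out]]
    diagnostics["n_clash_free"] = len(results)
    if not results and math.isfinite(tightest[0]):
        diagnostics["reason"] = "all combinations clash"
        diagnostics["tightest_clash_distance"] = tightest[0]
    return assemblies, diagnostics


@dataclass
class MotifLibraryConfig:
    min_rotamer_prob: float = 0.0
    score_weights: tuple[float, float] = (1.0, 1.0)
    max_out: int = 100
    combination_cap: int = 10 ** 6
    clash_tolerance: float = 0.75
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "min_rotamer_prob": self.min_rotamer_prob,
            "score_weights": list(self.score_weights),
            "max_out": self.max_out,
            "combination_cap": self.combination_cap,
            "clash_tolerance": self.clash_tolerance,
            "seed": self.seed,
        }


def build_motif_library(array: CatalyticArray, lib: RotamerLibrary,
                        fragments: list[HelicalFragment],
                        config: MotifLibraryConfig | None = None,
                        ) -> MotifLibrary:
    """Full pipeline: rotamer inversion → fragment placement → clash-free
    enumeration → ranking.  Deterministic for identical config."""
    config = config or MotifLibraryConfig()
    params = ClashParams(tolerance_factor=config.clash_tolerance)
    candidates: list[list[FragmentPlacement]] = []
    for idx, cat in enumerate(array.residues):
        column: list[FragmentPlacement] = []
        for fragment in fragments:
            phi, psi = fragment.anchor_phi_psi()
            for rotamer in compatible_rotamers(
                    cat.identity, phi, psi, lib, config.min_rotamer_prob):
                frame = invert_rotamer(cat, rotamer.chi)
                column.append(place_fragment(fragment, frame, rotamer,
                                             cat.identity, idx))
        candidates.append(column)
    assemblies, diagnostics = enumerate_assemblies(
        candidates, ligand=array.ligand, params=params,
        max_out=config.max_out, weights=config.score_weights,
        combination_cap=config.combination_cap)
    provenance = {"array": array.name, "config": config.to_dict(),
                  "n_fragments": len(fragments)}
    return MotifLibrary(assemblies=assemblies, provenance=provenance,
                        diagnostic=None if assemblies else diagnostics)


# --- serialization --------------------------------------------------------

def library_to_structure(library: MotifLibrary) -> Structure:
    """Multi-model structure: one MODEL per assembly (fragments on chains
    B, C, …; catalytic residues carried on the fragment anchors; ligand
    on chain Z)."""
    models = []
    for assembly in library.assemblies:
        residues: list[Residue] = []
        for k, placement in enumerate(assembly.placements):
            chain = chr(ord("B") + k)
            rebuilt = placement.rebuilt_residue()
            for i, bb in enumerate(placement.transformed_backbone()):
                number = i + 1
                if i == placement.fragment.anchor_index:
                    atoms = [AtomRecord(a.atom_name, a.element,
                                        a.coords.copy())
                             for a in rebuilt.atoms]
                    residues.append(Residue(chain, number,
                                            placement.identity, atoms))
                else:
                    atoms = [AtomRecord(n, element_of(n), bb[n].copy())
                             for n in ("N", "CA", "C", "O") if n in bb]
                    residues.append(Residue(chain, number, "ALA", atoms))
        if assembly.ligand is not None:
            lig = assembly.ligand
            residues.append(Residue(
                "Z", lig.residue_number, lig.identity,
                [AtomRecord(a.atom_name, a.element, a.coords.copy(),
                            a.occupancy, a.b_factor) for a in lig.atoms],
                is_hetero=True))
        models.append(Model(residues))
    return Structure(models or [Model()])


def library_sidecar_json(library: MotifLibrary) -> str:
    payload = {
        "provenance": library.provenance,
        "diagnostic": library.diagnostic,
        "assemblies": [
            {
                "rank": i,
                "score": a.score,
                "clash_free": a.clash_free,
                "rotamer_probabilities": [p.rotamer.probability
                                          for p in a.placements],
                "abundances": [p.fragment.abundance for p in a.placements],
                "fragment_ids": [p.fragment.fragment_id
                                 for p in a.placements],
            }
            for i, a in enumerate(library.assemblies)
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def serialize_library(library: MotifLibrary) -> tuple[str, str]:
    """(multi-model PDB text, sidecar JSON text)."""
    return (structio.write_structure(library_to_structure(library)),
            library_sidecar_json(library))


__all__ = [
    "CatalyticResidue", "CatalyticArray", "Rotamer", "RotamerLibrary",
    "HelicalFragment", "FragmentPlacement", "ClashParams", "ClashReport",
    "MotifAssembly", "MotifLibrary", "MotifLibraryConfig",
    "build_sidechain_forward", "invert_rotamer", "compatible_rotamers",
    "place_fragment", "clash_check", "score_assembly",
    "enumerate_assemblies", "build_motif_library", "library_to_structure",
    "serialize_library", "fragments_to_tsv", "fragments_from_tsv",
]
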