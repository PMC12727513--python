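"""Binding-pocket enforcement geometry and metrics.

Places the entry-channel placeholder helix, evaluates the flat-bottom
pocket potential (with analytic gradients, usable as a per-step guiding
potential callback by an external backbone-diffusion wrapper), computes
ligand burial and backbone–ligand clash metrics, and strips the
placeholder chain afterwards.

The potential is a reconstruction: a flat-bottom quadratic
``E = w · Σ max(0, d_i − r0)²`` of all backbone-atom distances to a
centre point on the placeholder helix.  ``r0`` and ``w`` are
configuration, defaults r0 = 12 Å, w = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixtures import helix_axis, make_ideal_helix
from .motiflib import ClashParams, ClashReport, MotifAssembly, clash_check
from .structio import Residue, SelectionError, Structure, neighbor_count


class PlacementError(RuntimeError):
    pass


@dataclass
class ChannelHelix:
    """Ideal placeholder helix with its axis and reserved chain label."""

    backbone: list[dict[str, np.ndarray]]
    axis: np.ndarray
    chain_id: str = "P"

    @property
    def length(self) -> int:
        return len(self.backbone)

    def ca_coords(self) -> np.ndarray:
        return np.array([bb["CA"] for bb in self.backbone])

    def atoms(self) -> list[tuple[str, np.ndarray]]:
        return [(name, coords) for bb in self.backbone
                for name, coords in bb.items()]

    def to_residues(self) -> list[Residue]:
        from .structio import AtomRecord
        from .chem import element_of

        out = []
        for i, bb in enumerate(self.backbone):
            atoms = [AtomRecord(n, element_of(n), bb[n].copy())
                     for n in ("N", "CA", "C", "O") if n in bb]
            out.append(Residue(self.chain_id, i + 1, "ALA", atoms))
        return out


@dataclass
class PocketPotentialParams:
    center: np.ndarray
    flat_radius: float = 12.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.flat_radius <= 0:
            raise ValueError("flat radius must be positive")
        if self.weight < 0:
            raise ValueError("weight must be ≥ 0")


@dataclass
class BurialReport:
    n_calpha_within_cutoff: int
    n_ligand_heavy: int
    cutoff: float
    burial: float


def _assembly_atoms(assembly: MotifAssembly) -> list[tuple[str, np.ndarray]]:
    return [pair for p in assembly.placements for pair in p.heavy_atoms()]


def place_channel_helix(assembly: MotifAssembly, ligand: Residue,
                        helix_length: int = 9,
                        standoff: float = 3.0,
                        params: ClashParams | None = None) -> ChannelHelix:
    """Place the entry-channel placeholder helix.

    The helix axis points from the catalytic functional-atom centroid
    through the ligand heavy-atom centroid; the near end starts
    ``standoff`` Å beyond the ligand centroid.  A deterministic grid of
    axial rotations (30° steps) and extra offsets (1 Å steps up to 5 Å)
    is searched for a clash-free pose.
    """
    if not assembly.placements:
        raise ValueError("assembly has no placements")
    lig_heavy = np.array([a.coords for a in ligand.atoms if a.is_heavy])
    if len(lig_heavy) == 0:
        raise ValueError("ligand has no heavy atoms")
    params = params or ClashParams()

    func_centroid = np.mean(
        [bb["CA"] for p in assembly.placements
         for bb in [p.transformed_backbone()[p.fragment.anchor_index]]],
        axis=0)
    lig_centroid = lig_heavy.mean(axis=0)
    axis = lig_centroid - func_centroid
    norm = np.linalg.norm(axis)
    if norm < 1e-6:
        raise PlacementError("ligand and motif centroids coincide")
    axis = axis / norm

    template = make_ideal_helix(helix_length)
    t_ca = np.array([bb["CA"] for bb in template.backbone])
    t_centroid, t_axis = helix_axis(t_ca)

    from .fixtures import _axis_rotation, _rotation_from_to

    align = _rotation_from_to(t_axis, axis)
    motif_atoms = _assembly_atoms(assembly)
    ligand_atoms = [(a.atom_name, a.coords) for a in ligand.atoms if a.is_heavy]

    start_along = float(np.min((t_ca - t_centroid) @ t_axis))
    for extra in range(0, 6):
        for spin in range(0, 360, 30):
            rot = align @ _axis_rotation(t_axis, float(spin))
            # near end of the helix sits standoff+extra Å past the ligand
            near_target = lig_centroid + (standoff + extra) * axis
            offset = near_target - rot @ (t_centroid + start_along * t_axis)
            backbone = [
                {n: rot @ c + offset for n, c in bb.items()}
                for bb in template.backbone
            ]
            helix = ChannelHelix(backbone=backbone, axis=axis)
            if clash_check(helix.atoms(), motif_atoms, params).count:
                continue
            if clash_check(helix.atoms(), ligand_atoms, params).count:
                continue
            return helix
    raise PlacementError(
        "no clash-free placeholder-helix pose within the search budget "
        f"(length={helix_length}, standoff={standoff})")


def pocket_center(helix: ChannelHelix, fraction: float = 0.5) -> np.ndarray:
    """Point on the helix axis at fractional position ``fraction``."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    ca = helix.ca_coords()
    centroid, axis = helix_axis(ca)
    proj = (ca - centroid) @ axis
    p0 = centroid + proj.min() * axis
    p1 = centroid + proj.max() * axis
    return p0 + fraction * (p1 - p0)


def pocket_potential(backbone_coords: np.ndarray,
                     params: PocketPotentialParams,
                     ) -> tuple[float, np.ndarray]:
    """Flat-bottom quadratic distance restraint with analytic gradient.

    E = w · Σ_i max(0, d_i − r0)²  with d_i = |x_i − center|.  Atoms at
    the centre (d = 0) contribute zero gradient by convention.
    """
    coords = np.asarray(backbone_coords, dtype=float).reshape(-1, 3)
    if len(coords) == 0:
        raise ValueError("no backbone atoms")
    delta = coords - params.center
    d = np.linalg.norm(delta, axis=1)
    excess = np.maximum(0.0, d - params.flat_radius)
    energy = params.weight * float(np.sum(excess ** 2))
    grad = np.zeros_like(coords)
    outside = (excess > 0) & (d > 1e-12)
    grad[outside] = (2.0 * params.weight
                     * (excess[outside] / d[outside])[:, None]
                     * delta[outside])
    return energy, grad


def _select_ligand(s: Structure, ligand_selection: tuple[str, int]) -> Residue:
    chain, number = ligand_selection
    try:
        return s.first_model.residue(chain, number)
    except SelectionError as exc:
        raise SelectionError(
            f"ligand {chain}:{number} not found") from exc


def burial_score(s: Structure, ligand_selection: tuple[str, int],
                 cutoff: float = 8.0) -> BurialReport:
    """CA count within ``cutoff`` of any ligand heavy atom, normalized by
    the number of ligand heavy atoms (inclusive boundary)."""
    ligand = _select_ligand(s, ligand_selection)
    lig_heavy = np.array([a.coords for a in ligand.atoms if a.is_heavy])
    if len(lig_heavy) == 0:
        raise SelectionError("ligand has no heavy atoms")
    ca = np.array([
        r.atom("CA").coords for r in s.first_model.residues
        if r.is_amino_acid and r.has_atom("CA") and r.key != ligand.key])
    count = (neighbor_count(ca, lig_heavy, cutoff) if len(ca) else 0)
    return BurialReport(
        n_calpha_within_cutoff=count,
        n_ligand_heavy=len(lig_heavy),
        cutoff=cutoff,
        burial=count / len(lig_heavy),
    )


def ligand_clash_count(s: Structure, ligand_selection: tuple[str, int],
                       params: ClashParams | None = None) -> ClashReport:
    """Clashes between protein backbone heavy atoms and ligand heavy atoms."""
    ligand = _select_ligand(s, ligand_selection)
    backbone_atoms = [
        (a.atom_name, a.coords)
        for r in s.first_model.residues
        if r.is_amino_acid and r.key != ligand.key
        for a in r.atoms
        if a.is_heavy and a.atom_name in ("N", "CA", "C", "O")
    ]
    ligand_atoms = [(a.atom_name, a.coords) for a in ligand.atoms if a.is_heavy]
    if not ligand_atoms:
        raise SelectionError("ligand has no heavy atoms")
    return clash_check(backbone_atoms, ligand_atoms, params or ClashParams())


def strip_placeholder(s: Structure, chain_id: str) -> Structure:
    """Remove all residues of the placeholder chain (no renumbering)."""
    if chain_id not in {r.chain_id for m in s.models for r in m.residues}:
        raise SelectionError(f"chain {chain_id!r} not present")
    out = s.copy()
    for model in out.models:
        model.residues = [r for r in model.residues if r.chain_id != chain_id]
    return out
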