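"""Seeded synthetic-data generators.

Everything here is a pure function of its :class:`FixtureConfig`:
identical seeds produce byte-identical artifacts.  The generators stand
in for the external inputs of the real workflow — a backbone-dependent
rotamer library, a PDB-mined helical fragment set, catalytic arrays,
trajectory ensembles and measured metric/kinetics tables — so the whole
package builds and tests offline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chem import place_atom
from .motiflib import (
    CatalyticArray,
    CatalyticResidue,
    HelicalFragment,
    Rotamer,
    RotamerLibrary,
    build_sidechain_forward,
)
from .structio import AtomRecord, Model, Residue, Structure


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_rotamers: int = 3
    fragment_length: int = 7
    n_frames: int = 50
    n_designs: int = 24
    noise_sigma: float = 0.0


# ideal backbone geometry shared with the sidechain templates
_BOND_N_CA, _BOND_CA_C, _BOND_C_N, _BOND_C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.5


def make_ideal_helix(length: int, phi: float = -57.0, psi: float = -47.0,
                     omega: float = 180.0,
                     config: FixtureConfig | None = None) -> HelicalFragment:
    """Ideal α-helical fragment (N/CA/C/O per residue, canonical frame)."""
    if length < 3:
        raise ValueError("helix needs ≥3 residues")
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _ANG_N_CA_C)
    c = ca + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    backbone = [{"N": n, "CA": ca, "C": c}]
    for _ in range(1, length):
        n_next = place_atom(backbone[-1]["N"], backbone[-1]["CA"],
                            backbone[-1]["C"], _BOND_C_N, _ANG_CA_C_N, psi)
        ca_next = place_atom(backbone[-1]["CA"], backbone[-1]["C"], n_next,
                             _BOND_N_CA, _ANG_C_N_CA, omega)
        c_next = place_atom(backbone[-1]["C"], n_next, ca_next,
                            _BOND_CA_C, _ANG_N_CA_C, phi)
        backbone.append({"N": n_next, "CA": ca_next, "C": c_next})
    for i, bb in enumerate(backbone):
        # carbonyl O trans to the following amide N
        bb["O"] = place_atom(bb["N"], bb["CA"], bb["C"],
                             _BOND_C_O, _ANG_CA_C_O, psi + 180.0)
    return HelicalFragment(
        backbone=backbone,
        phi_psi=[(phi, psi)] * length,
        anchor_index=length // 2,
        abundance=1.0,
        fragment_id=f"helix{length}",
    )


def helix_axis(ca_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(point on axis, unit direction N→C terminus) of a helical CA trace.

    Direction: normalized sum of cross products of successive CA
    second-difference vectors, which point radially and so have an
    axis-parallel cross product (exact for an ideal helix).  Axis
    position: algebraic circle fit of the CAs projected onto the
    perpendicular plane.
    """
    ca = np.asarray(ca_coords, dtype=float)
    centroid = ca.mean(axis=0)
    diffs = np.diff(ca, n=2, axis=0)
    axis = np.sum(np.cross(diffs[:-1], diffs[1:]), axis=0)
    norm = np.linalg.norm(axis)
    if norm < 1e-8:  # degenerate (e.g. collinear trace): fall back to SVD
        _, _, vt = np.linalg.svd(ca - centroid)
        axis = vt[0]
    else:
        axis = axis / norm
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    # orthonormal in-plane basis
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    uv = (ca - centroid) @ np.stack([e1, e2], axis=1)
    # Kåsa circle fit: minimize |u² + v² − 2au − 2bv − c|
    a_mat = np.column_stack([2 * uv, np.ones(len(uv))])
    rhs = np.sum(uv ** 2, axis=1)
    sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    center = centroid + sol[0] * e1 + sol[1] * e2
    return center, axis


#: canonical rotamer chi means per fixture identity (degrees).
_FIXTURE_CHI: dict[str, list[tuple[float, ...]]] = {
    "LYS": [(-60.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, 180.0),
            (-60.0, 180.0, -65.0, 180.0), (-60.0, 180.0, 180.0, 60.0)],
    "TYR": [(-65.0, 95.0), (180.0, 75.0), (-177.0, 80.0)],
    "ASN": [(-65.0, -20.0), (180.0, 30.0), (-65.0, 120.0)],
    "HIS": [(-65.0, -70.0), (180.0, 60.0), (-177.0, -100.0)],
    "GLU": [(-65.0, 180.0, -5.0), (180.0, 180.0, 0.0), (180.0, -65.0, -20.0)],
    "ARG": [(-65.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, 180.0),
            (-60.0, 180.0, -65.0, 180.0)],
    "SER": [(60.0,), (-60.0,), (180.0,)],
}


def make_toy_rotamer_library(config: FixtureConfig | None = None,
                             bin_width: float = 10.0) -> RotamerLibrary:
    """Small backbone-dependent rotamer table.

    Covers Lys/Tyr/Asn/His/Glu/Arg/Ser with ≥2 rotamers in the helical
    (−57, −47) bin and in the eight surrounding bins; per-bin
    probabilities are seeded and normalized to sum to 1.
    """
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    lib = RotamerLibrary(bin_width=bin_width)
    centers = [(-57.0 + di * bin_width, -47.0 + dj * bin_width)
               for di in (-1, 0, 1) for dj in (-1, 0, 1)]
    for identity, chi_sets in sorted(_FIXTURE_CHI.items()):
        n = max(2, min(config.n_rotamers, len(chi_sets)))
        for phi, psi in centers:
            raw = rng.uniform(0.5, 1.0, size=n)
            probs = raw / raw.sum()
            for chi, p in zip(chi_sets[:n], probs):
                lib.add(identity, phi, psi, Rotamer(chi=chi,
                                                    probability=float(p)))
    return lib


def _rotation_from_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_rotation(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = np.radians(degrees)
    vx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                   [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * vx + (1 - np.cos(t)) * vx @ vx


#: functional-atom sets: rigid groups sufficient to fix a frame.
FUNCTIONAL_ATOM_SETS: dict[str, tuple[str, ...]] = {
    "LYS": ("CD", "CE", "NZ"),
    "TYR": ("CE1", "CE2", "CZ", "OH"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "GLU": ("CG", "CD", "OE1", "OE2"),
    "ARG": ("CD", "NE", "CZ", "NH1", "NH2"),
}

#: key H-bonding atom of each functional set.
KEY_FUNCTIONAL_ATOM: dict[str, str] = {
    "LYS": "NZ", "TYR": "OH", "ASN": "ND2", "HIS": "NE2",
    "GLU": "OE2", "ARG": "NH1",
}

# key atom's bonded neighbor, used to orient the sidechain outward
_KEY_NEIGHBOR: dict[str, str] = {
    "LYS": "CE", "TYR": "CZ", "ASN": "CG", "HIS": "CD2",
    "GLU": "CD", "ARG": "CZ",
}


def _place_catalytic_residue(identity: str, chi: tuple[float, ...],
                             key_target: np.ndarray, outward: np.ndarray,
                             twist: float, label: str) -> CatalyticResidue:
    """Forward-build a residue, then rigidly pose it so its key
    functional atom sits at ``key_target`` with the sidechain extending
    along ``outward``."""
    from .chem import canonical_backbone_frame

    built = build_sidechain_forward(identity, canonical_backbone_frame(), chi)
    key = built.atom(KEY_FUNCTIONAL_ATOM[identity]).coords
    neighbor = built.atom(_KEY_NEIGHBOR[identity]).coords
    rot = _axis_rotation(outward, twist) @ _rotation_from_to(
        neighbor - key, outward)
    trans = key_target - rot @ key
    functional = {
        name: rot @ built.atom(name).coords + trans
        for name in FUNCTIONAL_ATOM_SETS[identity]
    }
    return CatalyticResidue(identity=identity, functional_atoms=functional,
                            source_label=label)


def _ligand_residue(name: str, atoms: list[tuple[str, str, np.ndarray]],
                    number: int = 500) -> Residue:
    return Residue("Z", number, name,
                   [AtomRecord(n, el, c) for n, el, c in atoms],
                   is_hetero=True)


def make_toy_catalytic_array(kind: str = "ra_tetrad",
                             config: FixtureConfig | None = None,
                             ) -> CatalyticArray:
    """Constructed catalytic arrays with H-bond-range functional contacts.

    ``ra_tetrad``: Lys/Tyr/Asn/Tyr around a small two-ring placeholder
    ligand.  ``mbh_triad``: His/Glu/Arg around a two-part ligand.  All
    geometry is built from ideal internal coordinates.
    """
    config = config or FixtureConfig()
    if kind == "ra_tetrad":
        ligand = _ligand_residue("LIG", [
            ("C1", "C", np.array([0.0, 0.0, 0.0])),
            ("O1", "O", np.array([1.23, 0.0, 0.4])),
            ("C2", "C", np.array([-0.8, 1.2, -0.3])),
            ("O2", "O", np.array([-0.5, 2.4, 0.3])),
            ("C3", "C", np.array([-2.3, 1.0, -0.2])),
            ("C4", "C", np.array([-3.1, 2.1, -0.6])),
        ])
        specs = [
            ("LYS", (-60.0, 180.0, 180.0, 180.0), "O1", 310.0, 120.0),
            ("TYR", (-65.0, 95.0), "O2", 120.0, 90.0),
            ("ASN", (-65.0, -20.0), "O1", 270.0, 0.0),
            ("TYR", (180.0, 75.0), "O2", 0.0, 330.0),
        ]
        elevations = [30.0, -10.0, -20.0, 20.0]
    elif kind == "mbh_triad":
        ligand = _ligand_residue("MBL", [
            ("C1", "C", np.array([0.0, 0.0, 0.0])),
            ("O1", "O", np.array([0.9, 0.0, 0.9])),
            ("C2", "C", np.array([-1.4, 0.3, -0.2])),
            ("C3", "C", np.array([-2.3, -0.7, -0.6])),
            ("C5", "C", np.array([3.4, 0.5, -0.6])),
            ("O3", "O", np.array([4.3, 1.3, -0.2])),
            ("C6", "C", np.array([3.9, -0.8, -1.1])),
        ])
        specs = [
            ("HIS", (-65.0, -70.0), "C1", 260.0, 210.0),
            ("GLU", (-65.0, 180.0, -5.0), "O1", 70.0, 60.0),
            ("ARG", (-65.0, 180.0, 180.0, 180.0), "O3", 330.0, 30.0),
        ]
        elevations = [40.0, 30.0, -30.0]
    else:
        raise ValueError(f"unknown array kind {kind!r}")

    residues = []
    for i, ((identity, chi, partner, azimuth, twist), elev) in enumerate(
            zip(specs, elevations)):
        theta = np.radians(azimuth)
        phi_el = np.radians(elev)
        outward = np.array([
            np.cos(phi_el) * np.cos(theta),
            np.cos(phi_el) * np.sin(theta),
            np.sin(phi_el),
        ])
        partner_xyz = ligand.atom(partner).coords
        key_target = partner_xyz + 2.9 * outward
        residues.append(_place_catalytic_residue(
            identity, chi, key_target, outward, twist,
            label=f"{kind}:{identity}{i + 1}"))
    return CatalyticArray(residues=residues, ligand=ligand, name=kind)


def make_ensemble(base: Structure, n_frames: int, sigma: float,
                  config: FixtureConfig | None = None) -> Structure:
    """Multi-model copy of ``base`` with seeded isotropic Gaussian jitter."""
    if sigma < 0:
        raise ValueError("sigma must be ≥ 0")
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    ref = base.first_model
    models = []
    for _ in range(n_frames):
        residues = []
        for r in ref.residues:
            atoms = [
                AtomRecord(a.atom_name, a.element,
                           a.coords + rng.normal(0.0, sigma, 3)
                           if sigma > 0 else a.coords.copy(),
                           a.occupancy, a.b_factor)
                for a in r.atoms
            ]
            residues.append(replace(r, atoms=atoms))
        models.append(Model(residues))
    return Structure(models)


def make_synthetic_tables(kind: str, truth: dict | None = None,
                          noise_sigma: float = 0.0,
                          config: FixtureConfig | None = None,
                          ) -> tuple[pd.DataFrame, dict]:
    """Seeded (table, ground-truth) pairs for parameter-recovery tests."""
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    truth = dict(truth or {})

    if kind == "stability":
        truth.setdefault("coefficients", {
            "energy_total": -0.01, "plddt_avg": 0.05,
            "sap_total": -0.02, "core_contacts": 0.15})
        truth.setdefault("intercept", 1.0)
        n = config.n_designs
        table = pd.DataFrame({
            "energy_total": rng.uniform(-400.0, -150.0, n),
            "plddt_avg": rng.uniform(70.0, 95.0, n),
            "sap_total": rng.uniform(10.0, 60.0, n),
            "core_contacts": rng.uniform(8.0, 20.0, n),
        })
        midpoint = truth["intercept"] + sum(
            coef * table[col] for col, coef in truth["coefficients"].items())
        table["midpoint"] = midpoint + rng.normal(0.0, noise_sigma, n)
        return table, truth

    if kind == "mm":
        truth.setdefault("kcat", 3.6e-2)
        truth.setdefault("km", 1e-4)
        conc = truth.get("concentrations",
                         np.geomspace(truth["km"] / 20, truth["km"] * 50, 10))
        v = truth["kcat"] * conc / (truth["km"] + conc)
        if noise_sigma > 0:
            v = v * (1.0 + rng.normal(0.0, noise_sigma, len(conc)))
        return pd.DataFrame({"concentration": conc, "rate": v}), truth

    if kind == "two_pka":
        truth.setdefault("pka1", 7.5)
        truth.setdefault("pka2", 10.0)
        truth.setdefault("rate_max", 1.0)
        ph = truth.get("ph", np.arange(4.0, 13.01, 0.5))
        rate = truth["rate_max"] / (
            1.0 + 10.0 ** (truth["pka1"] - ph) + 10.0 ** (ph - truth["pka2"]))
        if noise_sigma > 0:
            rate = rate * (1.0 + rng.normal(0.0, noise_sigma, len(ph)))
        return pd.DataFrame({"ph": ph, "rate": rate}), truth

    if kind == "design_metrics":
        n = config.n_designs
        table = pd.DataFrame({
            "design_id": [f"d{i:03d}" for i in range(n)],
            "plddt_avg": rng.uniform(60.0, 95.0, n),
            "energy_total": rng.uniform(-400.0, -100.0, n),
            "sap_total": rng.uniform(5.0, 80.0, n),
            "core_contacts": rng.uniform(5.0, 25.0, n),
            "motif_backbone_rmsd": rng.uniform(0.2, 3.0, n),
            "sidechain_rmsd": rng.uniform(0.3, 4.0, n),
        })
        return table, truth

    raise ValueError(f"unknown table kind {kind!r}")
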