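"""Per-design structural metrics and the stability regression.

Conventions documented here once:

* motif RMSDs — for the ``backbone`` selection the model is globally
  superposed on the reference Cα atoms of the mapped residues and the
  Cα RMSD is reported; for ``sidechain-heavy`` and ``functional-group``
  selections superposition is on the mapped residues' backbone N/CA/C
  and the RMSD runs over the selection, with symmetric sidechain naming
  (Tyr/Phe ring flips, Asp/Glu/Arg equivalent atoms) resolved by the
  permutation minimizing the RMSD.
* core contacts — for each residue, the number of heavy atoms of other
  residues within ``neighbor_cutoff`` Å of its Cα; the reported density
  is the mean of those counts over all residues (equivalently, the
  total count normalized by residue count).  With ``core_threshold``
  set, the fraction of residues at or above the threshold is returned
  instead.
* SAP — Shrake–Rupley SASA (probe 1.4 Å, 960 sphere points); per
  sidechain heavy atom, (atom SASA / fully exposed sidechain reference
  SASA) × Black–Mould hydrophobicity (glycine-normalized); the
  per-residue value sums atom contributions within ``radius`` Å of the
  residue Cα, and the total sums positive per-residue values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from ..chem import SIDECHAIN_REF_SASA, VDW_RADII, hydrophobicity
from ..structio import (
    Residue,
    SelectionError,
    Structure,
    rmsd as _rmsd,
    superpose,
)

AtomRef = tuple[str, int, str]  # (chain, residue number, atom name)
ResidueRef = tuple[str, int]


@dataclass
class DesignMetrics:
    plddt_avg: float = 0.0
    energy_total: float = 0.0
    sap_total: float = 0.0
    core_contacts: float = 0.0
    motif_backbone_rmsd: float = 0.0
    sidechain_rmsd: float = 0.0
    burial: float = 0.0
    composite_site: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.plddt_avg <= 100.0:
            raise ValueError("plddt_avg must be in [0, 100]")
        if self.motif_backbone_rmsd < 0 or self.sidechain_rmsd < 0:
            raise ValueError("RMSDs must be ≥ 0")

    def to_dict(self) -> dict[str, float]:
        return dict(vars(self))


#: equivalent heavy-atom label swaps for symmetric sidechains
SYMMETRIC_SWAPS: dict[str, list[tuple[str, str]]] = {
    "TYR": [("CD1", "CD2"), ("CE1", "CE2")],
    "PHE": [("CD1", "CD2"), ("CE1", "CE2")],
    "ASP": [("OD1", "OD2")],
    "GLU": [("OE1", "OE2")],
    "ARG": [("NH1", "NH2")],
}


def auto_mapping(model: Structure, reference: Structure,
                 ) -> list[tuple[ResidueRef, ResidueRef]]:
    """Pair residues sharing (chain, number, identity) in both structures."""
    ref_keys = {(r.chain_id, r.residue_number): r.identity
                for r in reference.first_model.residues if r.is_amino_acid}
    mapping = []
    for r in model.first_model.residues:
        if not r.is_amino_acid:
            continue
        key = (r.chain_id, r.residue_number)
        if ref_keys.get(key) == r.identity:
            mapping.append((key, key))
    return mapping


def _resolve(s: Structure, ref: ResidueRef) -> Residue:
    return s.first_model.residue(ref[0], ref[1])


def _sidechain_pairs(res_m: Residue, res_r: Residue,
                     model_coords_map: dict[str, np.ndarray],
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Matched sidechain heavy-atom coords with minimum-RMSD symmetric
    relabelling of the model residue."""
    names = sorted(
        {a.atom_name for a in res_r.sidechain_heavy_atoms()}
        & {a.atom_name for a in res_m.sidechain_heavy_atoms()})
    if not names:
        return np.empty((0, 3)), np.empty((0, 3))
    ref = np.stack([res_r.atom(n).coords for n in names])
    swaps = SYMMETRIC_SWAPS.get(res_r.identity, [])
    best = None
    # try all 2^k swap subsets (k ≤ 2)
    for mask in range(1 << len(swaps)):
        relabel = {}
        for bit, (a, b) in enumerate(swaps):
            if mask >> bit & 1:
                relabel[a], relabel[b] = b, a
        mdl = np.stack([model_coords_map[relabel.get(n, n)] for n in names])
        ss = float(np.sum((mdl - ref) ** 2))
        if best is None or ss < best[0]:
            best = (ss, mdl)
    return best[1], ref


def motif_rmsd(model: Structure, reference, mapping=None,
               selection: str = "backbone",
               functional_atoms: dict[ResidueRef, list[str]] | None = None,
               ) -> float:
    """Motif RMSD between a model and a reference structure/assembly.

    ``mapping`` is an explicit list of ((model chain, resnum),
    (reference chain, resnum)) pairs; defaults to :func:`auto_mapping`.
    ``selection`` is one of ``backbone`` (Cα RMSD after global Cα
    superposition), ``sidechain-heavy`` or ``functional-group`` (RMSD
    after superposition on mapped backbone N/CA/C).
    """
    from ..motiflib import MotifAssembly
    from ..motiflib import library_to_structure, MotifLibrary

    if isinstance(reference, MotifAssembly):
        reference = library_to_structure(
            MotifLibrary(assemblies=[reference]))
    if mapping is None:
        mapping = auto_mapping(model, reference)
    if not mapping:
        raise SelectionError("empty residue mapping")
    pairs = [(_resolve(model, m), _resolve(reference, r))
             for m, r in mapping]

    if selection == "backbone":
        ca_m = np.stack([p.atom("CA").coords for p, _ in pairs])
        ca_r = np.stack([q.atom("CA").coords for _, q in pairs])
        return _rmsd(ca_m, ca_r, presuperpose=True)

    bb_m = np.concatenate([
        np.stack([p.atom(n).coords for n in ("N", "CA", "C")])
        for p, _ in pairs])
    bb_r = np.concatenate([
        np.stack([q.atom(n).coords for n in ("N", "CA", "C")])
        for _, q in pairs])
    sup = superpose(bb_m, bb_r)

    total_ss = 0.0
    total_n = 0
    for (m_ref, r_ref), (res_m, res_r) in zip(mapping, pairs):
        moved = {a.atom_name: sup.apply(a.coords[None])[0]
                 for a in res_m.atoms}
        if selection == "sidechain-heavy":
            mdl, ref = _sidechain_pairs(res_m, res_r, moved)
        elif selection == "functional-group":
            if not functional_atoms or r_ref not in functional_atoms:
                raise SelectionError(
                    f"no functional atoms given for residue {r_ref}")
            names = functional_atoms[r_ref]
            mdl = np.stack([moved[n] for n in names])
            ref = np.stack([res_r.atom(n).coords for n in names])
        else:
            raise ValueError(f"unknown selection {selection!r}")
        total_ss += float(np.sum((mdl - ref) ** 2))
        total_n += len(mdl)
    if total_n == 0:
        raise SelectionError("selection matched no atoms")
    return float(np.sqrt(total_ss / total_n))


# --- SASA and SAP ---------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def shrake_rupley_sasa(coords: np.ndarray, elements: list[str],
                       probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å², heavy atoms)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.array([VDW_RADII[e.upper()] for e in elements]) + probe
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    sasa = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i],
                                                      radii[i] + max_r)
                     if j != i]
        if neighbors:
            nb_coords = coords[neighbors]
            nb_radii = radii[np.array(neighbors)]
            d2 = np.sum((pts[:, None, :] - nb_coords[None, :, :]) ** 2,
                        axis=-1)
            buried = np.any(d2 < nb_radii[None, :] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        sasa[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return sasa


def sap_score(s: Structure, radius: float = 5.0,
              probe: float = 1.4, n_points: int = 960,
              ) -> tuple[dict[ResidueRef, float], float]:
    """Spatial aggregation propensity (per-residue map, total)."""
    residues = [r for r in s.first_model.residues if r.is_amino_acid]
    atoms = []
    for r in residues:
        for a in r.atoms:
            if a.is_heavy:
                atoms.append((r, a))
    if not atoms:
        raise ValueError("no heavy atoms present")
    coords = np.stack([a.coords for _, a in atoms])
    elements = [a.element for _, a in atoms]
    sasa = shrake_rupley_sasa(coords, elements, probe, n_points)

    backbone = {"N", "CA", "C", "O", "OXT"}
    contrib = np.zeros(len(atoms))
    for i, (r, a) in enumerate(atoms):
        if a.atom_name in backbone:
            continue
        try:
            ref = SIDECHAIN_REF_SASA[r.identity]
        except KeyError as exc:
            raise ValueError(
                f"no reference SASA for identity {r.identity!r}") from exc
        contrib[i] = sasa[i] / ref * hydrophobicity(r.identity)

    tree = cKDTree(coords)
    per_residue: dict[ResidueRef, float] = {}
    for r in residues:
        if not r.has_atom("CA"):
            continue
        within = tree.query_ball_point(r.atom("CA").coords, radius)
        per_residue[(r.chain_id, r.residue_number)] = float(
            np.sum(contrib[within]))
    total = float(sum(v for v in per_residue.values() if v > 0))
    return per_residue, total


def core_contacts(s: Structure, neighbor_cutoff: float = 10.0,
                  core_threshold: int | None = None) -> float:
    """Mean per-residue heavy-atom contact density (see module notes)."""
    residues = [r for r in s.first_model.residues
                if r.is_amino_acid and r.has_atom("CA")]
    if len(residues) < 2:
        raise ValueError("need at least two residues")
    atoms = [(ri, a.coords) for ri, r in enumerate(residues)
             for a in r.atoms if a.is_heavy]
    owners = np.array([ri for ri, _ in atoms])
    coords = np.stack([c for _, c in atoms])
    tree = cKDTree(coords)
    counts = np.zeros(len(residues))
    for ri, r in enumerate(residues):
        within = tree.query_ball_point(r.atom("CA").coords, neighbor_cutoff)
        counts[ri] = np.sum(owners[within] != ri)
    if core_threshold is not None:
        return float(np.mean(counts >= core_threshold))
    return float(counts.mean())


# --- stability regression -------------------------------------------------

STABILITY_PREDICTORS = ("energy_total", "plddt_avg", "sap_total",
                        "core_contacts")


@dataclass
class StabilityModel:
    coefficients: dict[str, float]
    intercept: float
    fit_r: float
    predictors: tuple[str, ...] = STABILITY_PREDICTORS

    def predict(self, table) -> np.ndarray:
        out = np.full(len(table), self.intercept)
        for name, coef in self.coefficients.items():
            out = out + coef * np.asarray(table[name], dtype=float)
        return out


def fit_stability_model(table, predictors=STABILITY_PREDICTORS,
                        response: str = "midpoint") -> StabilityModel:
    """OLS of denaturation midpoints on the design metrics; reports the
    Pearson correlation of fitted vs observed values."""
    x = np.column_stack([np.asarray(table[p], dtype=float)
                         for p in predictors])
    y = np.asarray(table[response], dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in stability table")
    if len(y) < len(predictors) + 2:
        raise ValueError(
            f"need ≥ {len(predictors) + 2} rows for {len(predictors)} "
            "predictors")
    design = np.column_stack([np.ones(len(y)), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the collinear columns for the error message
        bad = []
        for i, p in enumerate(predictors):
            others = np.delete(design, i + 1, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(design):
                bad.append(p)
        raise ValueError(f"rank-deficient design matrix; collinear "
                         f"columns: {bad or list(predictors)}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    r = float(stats.pearsonr(fitted, y).statistic) if np.std(fitted) > 0 else 0.0
    return StabilityModel(
        coefficients={p: float(b) for p, b in zip(predictors, beta[1:])},
        intercept=float(beta[0]),
        fit_r=r,
        predictors=tuple(predictors),
    )


# --- composite active-site metric ----------------------------------------

@dataclass
class ActiveSiteGeometry:
    """H-bond pairs measured in the intermediate complex plus the
    nucleophilic-attack pair measured in the substrate complex."""

    hbond_pairs: list[tuple[AtomRef, AtomRef, float]] = field(
        default_factory=list)
    attack_pair: tuple[AtomRef, AtomRef, float] | None = None

    def __post_init__(self) -> None:
        for *_, ideal in self.hbond_pairs:
            if not 2.0 < ideal < 5.0:
                raise ValueError(f"ideal distance {ideal} outside (2, 5) Å")
        if self.attack_pair is not None and not 2.0 < self.attack_pair[2] < 5.0:
            raise ValueError("ideal attack distance outside (2, 5) Å")


def _atom_coords(s: Structure, ref: AtomRef) -> np.ndarray:
    chain, number, atom = ref
    try:
        return s.first_model.residue(chain, number).atom(atom).coords
    except SelectionError as exc:
        raise SelectionError(f"cannot resolve atom {ref}") from exc


def composite_site_metric(substrate_complex: Structure,
                          intermediate_complex: Structure,
                          geometry: ActiveSiteGeometry) -> float:
    """Σ |measured − ideal| over H-bond pairs (intermediate complex) and
    the attack pair (substrate complex); lower is better, 0 at ideal."""
    score = 0.0
    for ref_a, ref_b, ideal in geometry.hbond_pairs:
        d = float(np.linalg.norm(
            _atom_coords(intermediate_complex, ref_a)
            - _atom_coords(intermediate_complex, ref_b)))
        score += abs(d - ideal)
    if geometry.attack_pair is not None:
        ref_a, ref_b, ideal = geometry.attack_pair
        d = float(np.linalg.norm(
            _atom_coords(substrate_complex, ref_a)
            - _atom_coords(substrate_complex, ref_b)))
        score += abs(d - ideal)
    return score
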