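"""Flexibility metrics over multi-model coordinate ensembles.

Per frame the whole protein is superposed on the first frame's Cα
trace before any per-residue statistic is taken; functional-group
displacement instead superposes each frame's catalytic backbone onto
the reference backbone, matching how positioning deviations are
measured against a fixed catalytic geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..structio import SelectionError, Structure, superpose

ResidueRef = tuple[str, int]
AtomRef = tuple[str, int, str]


@dataclass
class EnsembleMetrics:
    rmsf_per_residue: dict[ResidueRef, float]
    hb_distance_deviation: list[float]
    fg_displacement: float


def _atom(model, ref: AtomRef, frame_index: int) -> np.ndarray:
    chain, number, name = ref
    try:
        return model.residue(chain, number).atom(name).coords
    except SelectionError as exc:
        raise SelectionError(
            f"atom {ref} missing in frame {frame_index}") from exc


def ensemble_metrics(ensemble: Structure,
                     catalytic_selection: list[ResidueRef],
                     reference: Structure,
                     hbond_pairs: list[tuple[AtomRef, AtomRef]] | None = None,
                     functional_atoms: dict[ResidueRef, list[str]] | None = None,
                     ) -> EnsembleMetrics:
    """RMSF of catalytic sidechains, H-bond distance deviations vs the
    reference, and functional-group displacement after backbone
    superposition on the reference.

    ``reference`` must contain the catalytic residues under the same
    (chain, residue number) keys as the ensemble.
    """
    if len(ensemble.models) < 2:
        raise ValueError("ensemble needs ≥2 frames")
    hbond_pairs = hbond_pairs or []
    functional_atoms = functional_atoms or {}

    # global Cα superposition of every frame onto frame 0
    ref_ca = ensemble.models[0]
    ca_names = [(r.chain_id, r.residue_number) for r in ref_ca.residues
                if r.is_amino_acid and r.has_atom("CA")]
    ca0 = np.stack([ref_ca.residue(c, n).atom("CA").coords
                    for c, n in ca_names])
    aligned_frames = []
    for fi, model in enumerate(ensemble.models):
        ca = np.stack([_atom(model, (c, n, "CA"), fi) for c, n in ca_names])
        sup = superpose(ca, ca0)
        aligned_frames.append(sup)

    # RMSF over sidechain heavy atoms of each catalytic residue
    rmsf: dict[ResidueRef, float] = {}
    for chain, number in catalytic_selection:
        res0 = ensemble.models[0].residue(chain, number)
        names = [a.atom_name for a in res0.sidechain_heavy_atoms()]
        if not names:
            names = ["CA"]
        per_frame = []
        for fi, (model, sup) in enumerate(zip(ensemble.models,
                                              aligned_frames)):
            coords = np.stack([_atom(model, (chain, number, n), fi)
                               for n in names])
            per_frame.append(sup.apply(coords))
        stack = np.stack(per_frame)  # (frames, atoms, 3)
        mean_pos = stack.mean(axis=0)
        sq = np.sum((stack - mean_pos) ** 2, axis=-1)  # (frames, atoms)
        rmsf[(chain, number)] = float(np.sqrt(sq.mean()))

    # H-bond distance deviation vs the reference geometry
    hb_dev: list[float] = []
    for ref_a, ref_b in hbond_pairs:
        d_ref = float(np.linalg.norm(
            _atom(reference.first_model, ref_a, -1)
            - _atom(reference.first_model, ref_b, -1)))
        devs = []
        for fi, model in enumerate(ensemble.models):
            d = float(np.linalg.norm(_atom(model, ref_a, fi)
                                     - _atom(model, ref_b, fi)))
            devs.append(abs(d - d_ref))
        hb_dev.append(float(np.mean(devs)))

    # functional-group displacement after superposition on the
    # reference catalytic backbone N/CA/C
    fg_values: list[float] = []
    if functional_atoms:
        bb_refs = [(c, n, a) for c, n in catalytic_selection
                   for a in ("N", "CA", "C")]
        bb_target = np.stack([_atom(reference.first_model, r, -1)
                              for r in bb_refs])
        fg_refs = [(c, n, a) for (c, n), names in functional_atoms.items()
                   for a in names]
        fg_target = np.stack([_atom(reference.first_model, r, -1)
                              for r in fg_refs])
        for fi, model in enumerate(ensemble.models):
            bb = np.stack([_atom(model, r, fi) for r in bb_refs])
            sup = superpose(bb, bb_target)
            fg = sup.apply(np.stack([_atom(model, r, fi) for r in fg_refs]))
            fg_values.append(float(np.mean(
                np.linalg.norm(fg - fg_target, axis=1))))
    return EnsembleMetrics(
        rmsf_per_residue=rmsf,
        hb_distance_deviation=hb_dev,
        fg_displacement=float(np.mean(fg_values)) if fg_values else 0.0,
    )
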