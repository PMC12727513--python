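"""Deterministic skeleton of the iterative design-refinement loop.

The external sequence-design / relax / structure-prediction stages are
pluggable :class:`StageAdapter` contracts.  Shipped stubs (identity and
seeded coordinate jitter) keep the loop and its selection logic fully
testable offline.  Motif coordinates are emitted as harmonic
coordinate-constraint records with a lossless text serialization
(one record per line: chain, residue number, atom name, x, y, z, sd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .motiflib import MotifAssembly
from .structio import SelectionError, Structure


class ContractError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


# --- coordinate constraints ----------------------------------------------

@dataclass(frozen=True)
class ConstraintRecord:
    chain: str
    residue_number: int
    atom_name: str
    target: tuple[float, float, float]
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ContractError("constraint sd must be positive")


_SELECTIONS = ("backbone", "backbone+functional", "all-heavy")


def make_coordinate_constraints(assembly: MotifAssembly, sd: float = 0.5,
                                selection: str = "backbone",
                                ) -> list[ConstraintRecord]:
    """One harmonic record per selected motif atom (target = motif coord)."""
    if selection not in _SELECTIONS:
        raise ContractError(f"unknown selection {selection!r}")
    records: list[ConstraintRecord] = []
    for placement in assembly.placements:
        residue = placement.rebuilt_residue()
        chain = chr(ord("B") + placement.residue_index)
        number = placement.fragment.anchor_index + 1
        backbone = [a for a in residue.atoms
                    if a.atom_name in ("N", "CA", "C", "O")]
        if selection == "backbone":
            chosen = backbone
        elif selection == "all-heavy":
            chosen = [a for a in residue.atoms if a.is_heavy]
        else:
            functional = residue.sidechain_heavy_atoms()
            chosen = backbone + functional
        for atom in chosen:
            records.append(ConstraintRecord(
                chain=chain, residue_number=number, atom_name=atom.atom_name,
                target=tuple(round(float(v), 6) for v in atom.coords),
                sd=sd))
    return records


def serialize_constraints(records: list[ConstraintRecord]) -> str:
    lines = ["# chain resnum atom x y z sd"]
    for r in records:
        x, y, z = r.target
        lines.append(f"{r.chain} {r.residue_number} {r.atom_name} "
                     f"{x:.6f} {y:.6f} {z:.6f} {r.sd:.6f}")
    return "\n".join(lines) + "\n"


def parse_constraints(text: str) -> list[ConstraintRecord]:
    records = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chain, num, atom, x, y, z, sd = line.split()
        records.append(ConstraintRecord(
            chain=chain, residue_number=int(num), atom_name=atom,
            target=(float(x), float(y), float(z)), sd=float(sd)))
    return records


# --- adapters -------------------------------------------------------------

@dataclass
class StageAdapter:
    """Callable contract for an external pipeline stage.

    ``fn(structure, options) -> (structure, metrics)``; adapters must not
    mutate their input structure.
    """

    stage: str  # sequence_design | relax | predict
    fn: Callable[[Structure, dict], tuple[Structure, dict[str, float]]]
    deterministic: bool = True

    def __call__(self, s: Structure,
                 options: dict | None = None) -> tuple[Structure, dict]:
        return self.fn(s, options or {})


def identity_stub(stage: str) -> StageAdapter:
    """Adapter that returns its input unchanged with empty metrics."""

    def fn(s: Structure, options: dict) -> tuple[Structure, dict]:
        return s.copy(), {}

    return StageAdapter(stage=stage, fn=fn)


def jitter_stub(stage: str, sigma: float = 0.1, seed: int = 0) -> StageAdapter:
    """Adapter adding seeded Gaussian coordinate noise; emits the noise
    magnitude as a per-design metric so selection is exercisable."""
    rng = np.random.default_rng(seed)

    def fn(s: Structure, options: dict) -> tuple[Structure, dict]:
        out = s.copy()
        total = 0.0
        n = 0
        for model in out.models:
            for res in model.residues:
                for atom in res.atoms:
                    noise = rng.normal(0.0, sigma, 3)
                    atom.coords = atom.coords + noise
                    total += float(noise @ noise)
                    n += 1
        metric = math.sqrt(total / max(n, 1))
        return out, {f"{stage}_jitter_rms": metric}

    return StageAdapter(stage=stage, fn=fn, deterministic=True)


# --- design records and selection ----------------------------------------

@dataclass
class DesignRecord:
    pose: Structure
    sequence: str
    metrics: dict[str, float] = field(default_factory=dict)
    cycle: int = 0
    lineage: str = "root"
    failed: bool = False
    failure: str | None = None


@dataclass
class RefinementConfig:
    n_cycles: int = 3
    keep_fraction: float = 0.5
    ranking_weights: dict[str, float] = field(default_factory=lambda: {
        "sidechain_rmsd": -2.0, "motif_backbone_rmsd": -1.0,
        "plddt_avg": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ContractError("n_cycles must be ≥ 1")
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ContractError("keep_fraction must be in (0, 1]")


def select_top(designs: list[DesignRecord], weights: dict[str, float],
               k: int) -> list[DesignRecord]:
    """Top-k by z-score-weighted composite (signs encode direction:
    negative weight → lower raw metric is better).  Ties break on
    lineage id, deterministically."""
    if not designs:
        return []
    for metric in weights:
        for d in designs:
            if metric not in d.metrics:
                raise ContractError(
                    f"design {d.lineage!r} missing metric {metric!r}")
    scores = []
    for metric, weight in weights.items():
        values = np.array([d.metrics[metric] for d in designs], dtype=float)
        sd = values.std()
        z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
        scores.append(weight * z)
    composite = np.sum(scores, axis=0) if scores else np.zeros(len(designs))
    order = sorted(range(len(designs)),
                   key=lambda i: (-composite[i], designs[i].lineage))
    return [designs[i] for i in order[:k]]


def composite_scores(designs: list[DesignRecord],
                     weights: dict[str, float]) -> list[float]:
    """Z-score-weighted composite in the input order."""
    total = np.zeros(len(designs))
    for metric, weight in weights.items():
        arr = np.array([d.metrics[metric] for d in designs], dtype=float)
        sd = arr.std()
        if sd > 0:
            total = total + weight * (arr - arr.mean()) / sd
    return [float(v) for v in total]


def run_refinement_cycle(designs: list[DesignRecord],
                         adapters: dict[str, StageAdapter],
                         constraints: list[ConstraintRecord],
                         config: RefinementConfig,
                         cycle: int = 1) -> list[DesignRecord]:
    """One cycle: sequence design → constrained relax → sequence redesign
    → structure prediction, then keep ceil(keep_fraction·n) designs."""
    for stage in ("sequence_design", "relax", "predict"):
        if stage not in adapters:
            raise ContractError(f"missing adapter for stage {stage!r}")
    options = {"constraints": constraints, "seed": config.seed,
               "cycle": cycle}
    processed: list[DesignRecord] = []
    for i, design in enumerate(designs):
        try:
            pose, metrics = adapters["sequence_design"](design.pose, options)
            pose, m2 = adapters["relax"](pose, options)
            metrics.update(m2)
            pose, m3 = adapters["sequence_design"](pose, options)
            metrics.update(m3)
            pose, m4 = adapters["predict"](pose, options)
            metrics.update(m4)
        except Exception as exc:  # adapter failure → record, continue
            processed.append(replace(
                design, cycle=cycle, failed=True, failure=str(exc)))
            continue
        merged = dict(design.metrics)
        merged.update(metrics)
        processed.append(DesignRecord(
            pose=pose, sequence=design.sequence, metrics=merged,
            cycle=cycle, lineage=f"{design.lineage}/c{cycle}.{i}"))
    survivors = [d for d in processed if not d.failed]
    if not survivors:
        raise PipelineError("all designs failed in this cycle")
    k = math.ceil(config.keep_fraction * len(survivors))
    return select_top(survivors, config.ranking_weights, k)


def run_refinement(designs: list[DesignRecord],
                   adapters: dict[str, StageAdapter],
                   constraints: list[ConstraintRecord],
                   config: RefinementConfig) -> list[DesignRecord]:
    """Run ``config.n_cycles`` refinement cycles."""
    current = designs
    for cycle in range(1, config.n_cycles + 1):
        current = run_refinement_cycle(current, adapters, constraints,
                                       config, cycle=cycle)
    return current
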