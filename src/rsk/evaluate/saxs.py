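"""Model-side small-angle scattering descriptors."""

from __future__ import annotations

import numpy as np

from ..chem import ATOMIC_MASSES
from ..structio import Structure


def radius_of_gyration(s: Structure) -> float:
    """Mass-weighted radius of gyration of the first model's heavy atoms:
    Rg = √(Σ m_i |r_i − r̄|² / Σ m_i) (Å)."""
    coords = []
    masses = []
    for r in s.first_model.residues:
        for a in r.atoms:
            if a.is_heavy:
                coords.append(a.coords)
                masses.append(ATOMIC_MASSES.get(a.element.upper(), 12.011))
    if not coords:
        raise ValueError("no heavy atoms present")
    coords = np.stack(coords)
    masses = np.asarray(masses)
    center = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - center) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def kratky_dimensionless(q, intensity, rg: float, i0: float,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless Kratky transform: (qRg, (qRg)²·I(q)/I(0))."""
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if q.size == 0 or intensity.size == 0:
        raise ValueError("empty scattering curve")
    if q.shape != intensity.shape:
        raise ValueError("q and I must have the same length")
    if i0 <= 0:
        raise ValueError("I(0) must be positive")
    x = q * rg
    return x, x ** 2 * intensity / i0
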