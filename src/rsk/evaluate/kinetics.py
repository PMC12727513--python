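"""Enzyme-kinetics analysis: Michaelis–Menten and two-pKa fits, rate
accelerations, and kinetic-resolution selectivity relations.

Units: rates are stored in s⁻¹ and concentrations in mol·L⁻¹; every
interface that accepts a rate takes an explicit unit tag (``"per_s"``
or ``"per_min"``).  The default uncatalysed reference rate constant is
3.9 × 10⁻⁷ min⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

#: default uncatalysed background rate constant, min⁻¹
DEFAULT_KUNCAT_PER_MIN = 3.9e-7

_UNIT_FACTORS = {"per_s": 1.0, "per_min": 1.0 / 60.0}


class FitError(RuntimeError):
    pass


def _to_per_second(value: float, unit: str) -> float:
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"rate unit must be one of {sorted(_UNIT_FACTORS)}, "
                         f"got {unit!r}")
    if value <= 0:
        raise ValueError("rate constants must be positive")
    return value * _UNIT_FACTORS[unit]


@dataclass
class KineticsRecord:
    kcat: float  # s⁻¹
    km: float    # mol·L⁻¹
    kuncat: float = DEFAULT_KUNCAT_PER_MIN / 60.0  # s⁻¹

    def __post_init__(self) -> None:
        if min(self.kcat, self.km, self.kuncat) <= 0:
            raise ValueError("kinetic constants must be positive")

    @property
    def efficiency(self) -> float:
        """kcat/KM in M⁻¹ s⁻¹."""
        return self.kcat / self.km

    @property
    def rate_acceleration(self) -> float:
        return self.kcat / self.kuncat


@dataclass
class SelectivityRecord:
    e_value: float
    ee_product: float
    ee_substrate: float
    conversion: float

    def __post_init__(self) -> None:
        if self.e_value < 1:
            raise ValueError("E-value must be ≥ 1")
        for name in ("ee_product", "ee_substrate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.conversion < 1.0:
            raise ValueError("conversion must be in [0, 1)")


@dataclass
class TwoPkaFit:
    pka1: float
    pka2: float
    rate_max: float

    def __post_init__(self) -> None:
        if not self.pka1 < self.pka2:
            raise ValueError("pKa1 must be below pKa2")

    def predict(self, ph: np.ndarray) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        return self.rate_max / (1.0 + 10.0 ** (self.pka1 - ph)
                                + 10.0 ** (ph - self.pka2))


# --- Michaelis–Menten -----------------------------------------------------

def michaelis_menten(s, kcat: float, km: float):
    s = np.asarray(s, dtype=float)
    return kcat * s / (km + s)


def fit_michaelis_menten(concentrations, rates,
                         ) -> tuple[float, float, np.ndarray]:
    """Nonlinear least squares of v = kcat·[S]/(KM + [S]).

    Deterministic initialization: kcat₀ = max(v), KM₀ = median([S]).
    Returns (kcat, KM, covariance).
    """
    s = np.asarray(concentrations, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(np.unique(s)) < 3:
        raise ValueError("need ≥3 distinct substrate concentrations")
    if np.any(s <= 0) or np.any(v <= 0):
        raise ValueError("concentrations and rates must be positive")
    p0 = (float(v.max()), float(np.median(s)))
    try:
        popt, pcov = curve_fit(michaelis_menten, s, v, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    kcat, km = (float(popt[0]), float(popt[1]))
    if kcat <= 0 or km <= 0:
        raise FitError(f"non-physical fit: kcat={kcat}, km={km}")
    return kcat, km, pcov


def rate_acceleration(kcat: float, kuncat: float = DEFAULT_KUNCAT_PER_MIN,
                      kcat_unit: str = "per_s",
                      kuncat_unit: str = "per_min") -> float:
    """kcat/k_uncat after normalizing both rates to s⁻¹."""
    return _to_per_second(kcat, kcat_unit) / _to_per_second(kuncat,
                                                            kuncat_unit)


def fold_change(kcat_a: float, kcat_b: float, unit_a: str = "per_min",
                unit_b: str = "per_min") -> float:
    """Activity ratio kcat_a / kcat_b; units must match."""
    if unit_a != unit_b:
        raise ValueError(f"unit mismatch: {unit_a!r} vs {unit_b!r}")
    if kcat_a <= 0 or kcat_b <= 0:
        raise ValueError("rate constants must be positive")
    return kcat_a / kcat_b


# --- kinetic resolution ---------------------------------------------------

def ee_product_low_conversion(e_value: float) -> float:
    """Product ee of a racemate resolution in the limit c → 0: (E−1)/(E+1)."""
    if e_value < 1:
        raise ValueError("E-value must be ≥ 1")
    return (e_value - 1.0) / (e_value + 1.0)


def e_from_ee_substrate(conversion: float, ee_s: float) -> float:
    """E = ln[(1−c)(1−ee_s)] / ln[(1−c)(1+ee_s)]."""
    return (np.log((1 - conversion) * (1 - ee_s))
            / np.log((1 - conversion) * (1 + ee_s)))


def e_from_ee_product(conversion: float, ee_p: float) -> float:
    """E = ln[1−c(1+ee_p)] / ln[1−c(1−ee_p)]."""
    return (np.log(1 - conversion * (1 + ee_p))
            / np.log(1 - conversion * (1 - ee_p)))


def selectivity_relations(e_value: float,
                          conversion: float = 0.0) -> SelectivityRecord:
    """Solve the irreversible kinetic-resolution relations on a racemate.

    At ``conversion == 0`` the low-conversion limits are returned
    (ee_substrate = 0, ee_product = (E−1)/(E+1)); otherwise ee values
    are obtained by bracketed root finding to 1e-10.
    """
    if e_value < 1:
        raise ValueError("E-value must be ≥ 1")
    if not 0.0 <= conversion < 1.0:
        raise ValueError("conversion must be in [0, 1)")
    if conversion == 0.0 or e_value == 1.0:
        return SelectivityRecord(
            e_value=e_value,
            ee_product=ee_product_low_conversion(e_value),
            ee_substrate=0.0,
            conversion=conversion)

    c = conversion

    def f_sub(ee_s: float) -> float:
        return e_from_ee_substrate(c, ee_s) - e_value

    hi = min(1.0 - 1e-13, c / (1.0 - c))  # mass balance: ee_s ≤ c/(1−c)
    ee_s = (hi if f_sub(hi - 1e-13) < 0
            else float(brentq(f_sub, 1e-13, hi - 1e-13, xtol=1e-12)))

    def f_prod(ee_p: float) -> float:
        return e_from_ee_product(c, ee_p) - e_value

    # domain: 1 − c(1+ee_p) > 0 and mass balance ee_p ≤ (1−c)/c
    hi_p = min(1.0 - 1e-13, (1.0 - c) / c - 1e-13, 1.0 / c - 1.0 - 1e-13)
    if hi_p <= 1e-12 or f_prod(hi_p) < 0:
        ee_p = hi_p
    else:
        ee_p = float(brentq(f_prod, 1e-13, hi_p, xtol=1e-12))
    return SelectivityRecord(e_value=e_value, ee_product=min(ee_p, 1.0),
                             ee_substrate=min(ee_s, 1.0),
                             conversion=conversion)


# --- pH profile -----------------------------------------------------------

def two_pka_model(ph, rate_max: float, pka1: float, pka2: float):
    ph = np.asarray(ph, dtype=float)
    return rate_max / (1.0 + 10.0 ** (pka1 - ph) + 10.0 ** (ph - pka2))


def fit_two_pka(ph_values, rates) -> TwoPkaFit:
    """Least-squares fit of the bell-shaped two-pKa rate profile.

    Initialization is deterministic, from the curve maximum and the
    half-maximum crossings.  Single-limb data (no descending limb)
    produce a warning and an unbounded (infinite) pKa2.
    """
    ph = np.asarray(ph_values, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(ph) < 5:
        raise ValueError("need ≥5 pH points")
    order = np.argsort(ph)
    ph, v = ph[order], v[order]
    imax = int(np.argmax(v))
    vmax = float(v[imax])
    half = vmax / 2.0
    rising = np.nonzero(v[: imax + 1] >= half)[0]
    pka1_0 = float(ph[rising[0]]) if len(rising) else float(ph[0])
    falling = np.nonzero(v[imax:] <= half)[0]
    single_limb = imax >= len(ph) - 1 or len(falling) == 0
    if single_limb:
        warnings.warn("no descending limb in pH profile; pKa2 is unbounded",
                      stacklevel=2)

        def one_pka(p, rate_max, pka1):
            return rate_max / (1.0 + 10.0 ** (pka1 - np.asarray(p)))

        popt, _ = curve_fit(one_pka, ph, v, p0=(vmax, pka1_0), maxfev=10000)
        return TwoPkaFit(pka1=float(popt[1]), pka2=np.inf,
                         rate_max=float(popt[0]))
    pka2_0 = float(ph[imax + falling[0]])
    try:
        popt, _ = curve_fit(two_pka_model, ph, v,
                            p0=(vmax, pka1_0, pka2_0), maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"two-pKa fit did not converge: {exc}") from exc
    rate_max, pka1, pka2 = map(float, popt)
    if pka1 > pka2:
        pka1, pka2 = pka2, pka1
    return TwoPkaFit(pka1=pka1, pka2=pka2, rate_max=rate_max)
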