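"""Molecular formulas, ion m/z, mass error and isotope patterns.

This module grounds every mass-based QC rule in the curation workflow:
a feature is only accepted if its measured m/z lies within a ppm gate of the
m/z expected for the candidate ion species, and if its observed M+1/M
abundance ratio matches the ratio predicted from the molecular formula
(the 13C isotopic-distribution check).

Only singly charged species are handled: protonated ([M+H]+), sodiated
([M+Na]+), deprotonated ([M-H]-) and radical cations ([M]+, written
[M]•+ in the field).  Electron mass is accounted for in all ion m/z
values so the ppm gate is unbiased at low mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .isotopes import ELECTRON_MASS, ISOTOPES, MONOISOTOPIC_MASS, SUPPORTED_ELEMENTS

__all__ = [
    "FormulaError",
    "ElementalFormula",
    "IsotopePattern",
    "IsotopeTolerance",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "normalize_ion_type",
    "ion_charge",
    "ion_polarity",
    "ion_mz",
    "ppm_error",
    "isotope_pattern",
    "predicted_m1_ratio",
    "isotope_check",
    "ION_TYPES",
    "MODES",
    "MODE_POLARITY",
]


class FormulaError(ValueError):
    """Raised for unparseable formulas or unsupported elements/ion types."""


#: map element->count; plain dict keeps the type lightweight and hashable via items
ElementalFormula = dict[str, int]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_GRAMMAR = re.compile(r"(?:[A-Z][a-z]?\d*)+")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style molecular formula string into element counts.

    Repeated element tokens are summed.  No charge, isotope or group
    markers are accepted.

    >>> parse_formula("C10H7N3S")
    {'C': 10, 'H': 7, 'N': 3, 'S': 1}
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    if not _GRAMMAR.fullmatch(text):
        raise FormulaError(f"formula {text!r} does not match element+count grammar")
    counts: ElementalFormula = {}
    for sym, num in _TOKEN.findall(text):
        if sym not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unknown element {sym!r} in formula {text!r}")
        n = int(num) if num else 1
        if n < 1:
            raise FormulaError(f"element {sym!r} has count {n} in formula {text!r}")
        counts[sym] = counts.get(sym, 0) + n
    return counts


def formula_to_string(f: ElementalFormula) -> str:
    """Canonical Hill-order writer: C, H, then other elements alphabetically.

    Without carbon, all elements (including H) are written alphabetically.
    ``parse_formula`` round-trips through this writer.
    """
    if not f:
        raise FormulaError("empty formula")
    parts: list[str] = []
    if "C" in f:
        order = ["C"] + (["H"] if "H" in f else [])
        order += sorted(el for el in f if el not in ("C", "H"))
    else:
        order = sorted(f)
    for el in order:
        n = f[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass in Da: sum of count x lightest-stable-isotope mass."""
    if not f:
        raise FormulaError("empty formula")
    mass = 0.0
    for el, n in f.items():
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element {el!r}")
        if n < 0:
            raise FormulaError(f"negative count for element {el!r}")
        mass += n * MONOISOTOPIC_MASS[el]
    return mass


# ion type -> (summed mass of added/removed atoms in Da, charge z)
_M_H = MONOISOTOPIC_MASS["H"]
_M_NA = MONOISOTOPIC_MASS["Na"]
ION_TYPES: dict[str, tuple[float, int]] = {
    "[M+H]+": (+_M_H, +1),
    "[M+Na]+": (+_M_NA, +1),
    "[M-H]-": (-_M_H, -1),
    "[M]+": (0.0, +1),
}

MODES = ("ESI+", "ESI-", "APCI+")
MODE_POLARITY = {"ESI+": +1, "ESI-": -1, "APCI+": +1}

_ION_ALIASES = {
    "[M]•+": "[M]+",
    "[M].+": "[M]+",
    "[M]*+": "[M]+",
}


def normalize_ion_type(token: str) -> str:
    """Map an ion-type token (incl. unicode minus/bullet variants) to canonical form."""
    t = str(token).strip().replace("−", "-").replace("–", "-")
    t = _ION_ALIASES.get(t, t)
    if t not in ION_TYPES:
        raise FormulaError(f"unknown ion type token {token!r}")
    return t


def ion_charge(ion_type: str) -> int:
    return ION_TYPES[normalize_ion_type(ion_type)][1]


def ion_polarity(ion_type: str) -> int:
    """Sign of the charge: +1 or -1 (polarity is derived from z)."""
    return 1 if ion_charge(ion_type) > 0 else -1


def ion_mz(f: ElementalFormula, ion_type: str) -> float:
    """Theoretical m/z (Th) for a singly charged ion of the given type.

    m/z = (M + delta_atoms - z*m_e) / |z|, where delta_atoms is the summed
    monoisotopic mass of added/removed atoms and m_e the electron mass.
    """
    t = normalize_ion_type(ion_type)
    delta, z = ION_TYPES[t]
    m = monoisotopic_mass(f)
    return (m + delta - z * ELECTRON_MASS) / abs(z)


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed mass error in parts per million relative to the theoretical value."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (measured - theoretical) / theoretical


@dataclass(frozen=True)
class IsotopePattern:
    """Coarse isotope pattern aggregated on nominal mass offsets.

    ``peaks`` holds (offset, abundance relative to the base peak) with
    offsets 0, 1, 2, ...; the base (most abundant) peak has abundance 1.
    """

    peaks: tuple[tuple[int, float], ...]

    @property
    def m1_ratio(self) -> float:
        """Abundance ratio of the M+1 peak to the monoisotopic M peak."""
        a0 = self.peaks[0][1]
        a1 = self.peaks[1][1] if len(self.peaks) > 1 else 0.0
        return a1 / a0


@dataclass(frozen=True)
class IsotopeTolerance:
    """Tolerance for the M+1/M ratio gate.

    ``rel_tol`` is a fraction of the predicted ratio; ``abs_floor`` keeps the
    gate meaningful for low-carbon formulas whose predicted ratio is tiny.
    Comparisons are inclusive at the boundary.
    """

    rel_tol: float = 0.20
    abs_floor: float = 0.005


def _element_offset_dist(el: str) -> np.ndarray:
    isos = ISOTOPES[el]
    base = isos[0][0]
    size = round(isos[-1][0] - base) + 1
    arr = np.zeros(size)
    for m, ab in isos:
        arr[round(m - base)] += ab
    return arr


def _convolve_power(dist: np.ndarray, n: int) -> np.ndarray:
    """dist ** n under convolution, by exponentiation-by-squaring."""
    result = np.array([1.0])
    acc = dist
    while n > 0:
        if n & 1:
            result = np.convolve(result, acc)
        n >>= 1
        if n:
            acc = np.convolve(acc, acc)
    return result


@lru_cache(maxsize=4096)
def _pattern_cached(items: tuple[tuple[str, int], ...]) -> np.ndarray:
    arr = np.array([1.0])
    for el, n in items:
        if el not in ISOTOPES:
            raise FormulaError(f"unsupported element {el!r}")
        arr = np.convolve(arr, _convolve_power(_element_offset_dist(el), n))
    return arr


def isotope_pattern(f: ElementalFormula, n_peaks: int = 3) -> IsotopePattern:
    """Predict relative abundances of M, M+1, ... for a molecular formula.

    Per-element isotope distributions (on nominal mass offsets from the
    monoisotopic species) are convolved together; the result is normalized
    to the most abundant peak.
    """
    if n_peaks < 2:
        raise ValueError("n_peaks must be >= 2")
    if not f:
        raise FormulaError("empty formula")
    arr = _pattern_cached(tuple(sorted(f.items())))
    base = arr.max()
    peaks = tuple(
        (k, float(arr[k] / base) if k < len(arr) else 0.0) for k in range(n_peaks)
    )
    return IsotopePattern(peaks=peaks)


def predicted_m1_ratio(f: ElementalFormula) -> float:
    """Predicted M+1/M abundance ratio (the 13C-dominated first isotope peak)."""
    return isotope_pattern(f, n_peaks=2).m1_ratio


def isotope_check(
    observed_ratio: float,
    f: ElementalFormula,
    tol: IsotopeTolerance | None = None,
) -> bool:
    """Gate an observed M+1/M ratio against the formula's predicted ratio.

    Passes iff |observed - predicted| <= max(rel_tol * predicted, abs_floor);
    the boundary is inclusive.
    """
    if observed_ratio < 0:
        raise ValueError("observed ratio must be >= 0")
    tol = tol or IsotopeTolerance()
    predicted = predicted_m1_ratio(f)
    band = max(tol.rel_tol * predicted, tol.abs_floor)
    return abs(observed_ratio - predicted) <= band
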