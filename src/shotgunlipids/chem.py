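"""Elemental compositions, monoisotopic masses and isotope envelopes.

Lipid molecules in this package are built from C/H/N/O/P only, which covers
glycerolipids, glycerophospholipids, sphingolipids and sterol esters.  Two
isotope-envelope models are provided:

``binomial``
    carbon-only binomial with a single :sup:`13`\\ C abundance parameter.
    Cheap, and exactly self-consistent between the spectrum simulator and
    the correction step.
``composition``
    full multi-element convolution over the aggregated (nominal-mass)
    isotope distributions of C, H, N, O and P.  This is what vendor-style
    "correction for isotope distribution" actually computes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

# CODATA / IUPAC monoisotopic atomic masses (u)
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857991
NEUTRON_SPACING = 1.003355  # average isotopologue m/z spacing used for peaks

#: default natural abundance of 13C
C13_ABUNDANCE = 0.0107

#: aggregated isotope abundances per element, indexed by extra nominal mass
#: (A, A+1, A+2).  Values are natural abundances; rows need not sum to 1
#: exactly because rarer isotopes are dropped.
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0,),
}

_ELEMENTS = ("C", "H", "N", "O", "P")


@dataclass(frozen=True)
class ElementalComposition:
    """Counts of C, H, N, O and P atoms.

    Supports element-wise addition/subtraction and integer scaling so that
    molecules can be assembled from head group + backbone + chains minus
    condensation water.
    """

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            self.C + other.C, self.H + other.H, self.N + other.N,
            self.O + other.O, self.P + other.P,
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            self.C - other.C, self.H - other.H, self.N - other.N,
            self.O - other.O, self.P - other.P,
        )

    def __mul__(self, n: int) -> "ElementalComposition":
        return ElementalComposition(self.C * n, self.H * n, self.N * n,
                                    self.O * n, self.P * n)

    __rmul__ = __mul__

    def as_dict(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in _ELEMENTS if getattr(self, el)}

    @property
    def is_valid(self) -> bool:
        return all(getattr(self, el) >= 0 for el in _ELEMENTS)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * getattr(self, el) for el in _ELEMENTS)

    @property
    def hill_formula(self) -> str:
        """Hill-order formula string, e.g. ``C42H82NO8P``."""
        parts = []
        for el in _ELEMENTS:
            n = getattr(self, el)
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)


WATER = ElementalComposition(H=2, O=1)

# singly-charged adduct mass shifts (Th) relative to the neutral species
ADDUCT_MASS_SHIFT: dict[str, float] = {
    "[M+H]+": PROTON_MASS,
    "[M+NH4]+": (MONOISOTOPIC_MASS["N"] + 4 * MONOISOTOPIC_MASS["H"]
                 - ELECTRON_MASS),
    "[M-H]-": -PROTON_MASS,
}


def binomial_envelope(n_carbons: int, p13: float = C13_ABUNDANCE,
                      n_peaks: int = 5) -> np.ndarray:
    """Carbon-only isotopologue fractions M0..M+(n_peaks-1).

    Fraction of molecules with exactly k heavy carbons; other elements are
    treated as monoisotopic.
    """
    if n_carbons < 0:
        raise ValueError("carbon count must be non-negative")
    k = np.arange(n_peaks)
    return binom.pmf(k, n_carbons, p13)


def composition_envelope(composition: ElementalComposition,
                         n_peaks: int = 5) -> np.ndarray:
    """Aggregated isotope distribution of a molecule by nominal extra mass.

    Convolves per-element distributions; returns fractions M0..M+(n_peaks-1).
    """
    dist = np.array([1.0])
    for el in _ELEMENTS:
        n = getattr(composition, el)
        if n == 0:
            continue
        base = np.asarray(ISOTOPE_ABUNDANCES[el], dtype=float)
        base = base / base.sum()
        elem = np.array([1.0])
        # exponentiation by squaring on the convolution monoid
        power = base
        m = n
        while m:
            if m & 1:
                elem = np.convolve(elem, power)[: n_peaks + 8]
            power = np.convolve(power, power)[: n_peaks + 8]
            m >>= 1
        dist = np.convolve(dist, elem)[: n_peaks + 8]
    out = np.zeros(n_peaks)
    upto = min(n_peaks, dist.size)
    out[:upto] = dist[:upto]
    return out


def envelope_for(composition: ElementalComposition, model: str = "binomial",
                 p13: float = C13_ABUNDANCE, n_peaks: int = 5) -> np.ndarray:
    """Isotopologue fractions for a species under the chosen envelope model."""
    if model == "binomial":
        return binomial_envelope(composition.C, p13=p13, n_peaks=n_peaks)
    if model == "composition":
        return composition_envelope(composition, n_peaks=n_peaks)
    raise ValueError(f"unknown envelope model: {model!r}")
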