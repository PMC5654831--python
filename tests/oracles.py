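"""Independent oracle computations used by the test suite.

Everything here is deliberately written without reference to the package
implementation: plain-Python atom summation for masses, a direct
polynomial-product convolution for isotope envelopes, and textbook
sum-of-squares formulas for the ANOVA/LSD statistics.
"""

from __future__ import annotations

import math

# independent copy of standard monoisotopic atomic masses (IUPAC)
ATOM_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}

# aggregated isotope abundances by extra nominal mass units
ATOM_ISOTOPES = {
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "P": [1.0],
}


def mass_by_atom_summation(counts: dict[str, int]) -> float:
    """Brute-force monoisotopic mass: sum atom masses one by one."""
    total = 0.0
    for element, n in counts.items():
        for _ in range(n):
            total += ATOM_MASS[element]
    return total


def full_convolution_envelope(counts: dict[str, int], n_peaks: int = 6
                              ) -> list[float]:
    """Multi-element aggregated isotope distribution by naive convolution.

    Multiplies out one polynomial factor per atom — O(atoms x peaks), no
    squaring tricks — and returns fractions for M0..M+(n_peaks-1).
    """
    dist = [1.0]
    for element, n in counts.items():
        base = ATOM_ISOTOPES[element]
        norm = sum(base)
        base = [b / norm for b in base]
        for _ in range(n):
            new = [0.0] * min(len(dist) + len(base) - 1, n_peaks + 4)
            for i, d in enumerate(dist):
                for j, b in enumerate(base):
                    if i + j < len(new):
                        new[i + j] += d * b
            dist = new
    return (dist + [0.0] * n_peaks)[:n_peaks]


def carbon_binomial_envelope(n_carbons: int, p13: float = 0.0107,
                             n_peaks: int = 6) -> list[float]:
    """Carbon-only binomial fractions, written out with factorials."""
    out = []
    for k in range(n_peaks):
        if k > n_carbons:
            out.append(0.0)
            continue
        comb = math.comb(n_carbons, k)
        out.append(comb * p13 ** k * (1 - p13) ** (n_carbons - k))
    return out


def anova_by_hand(groups: list[list[float]]) -> tuple[float, float, int, int]:
    """Textbook one-way ANOVA: (F, MSE, df_between, df_within)."""
    all_values = [v for g in groups for v in g]
    grand = sum(all_values) / len(all_values)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = 0.0
    for g in groups:
        mean = sum(g) / len(g)
        ss_within += sum((v - mean) ** 2 for v in g)
    df_between = len(groups) - 1
    df_within = len(all_values) - len(groups)
    mse = ss_within / df_within
    f = (ss_between / df_between) / mse
    return f, mse, df_between, df_within


def lsd_t_by_hand(group_a: list[float], group_b: list[float],
                  mse: float) -> float:
    """LSD t statistic for a pair of cells with the pooled ANOVA error."""
    mean_a = sum(group_a) / len(group_a)
    mean_b = sum(group_b) / len(group_b)
    se = math.sqrt(mse * (1 / len(group_a) + 1 / len(group_b)))
    return (mean_a - mean_b) / se
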