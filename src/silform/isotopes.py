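"""Exact isotopologue-distribution generation.

For each element the distribution of extra-neutron counts over ``n``
atoms is an exact multinomial: the probability of a configuration with
k_i atoms of isotope i is n!/(prod k_i!) * prod p_i^k_i, and the
configurations are aggregated by their total neutron offset.  No
Gaussian or polynomial approximation is used.  The six per-element
vectors are then convolved to give the molecular isotopologue
distribution.

Two binning modes are provided.  Unit binning aggregates by integer
neutron offset (M0, M1, M2, ...), matching what unit-resolution
instruments observe and what the M1/M0, M2/M0 ratio analysis needs.
A fine mass-axis mode bins configurations on a fixed-width mass grid
instead, resolving e.g. the 13C vs 15N substitution masses.

``ratio_tables``/``batch_ratios`` expose exact closed forms for M1/M0
and M2/M0 derived from the same per-element distributions, used to
score thousands of candidate formulae at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .chemspace import (
    DEFAULT_ISOTOPE_TABLE,
    ELEMENTS,
    ChemicalFormula,
    IsotopeTable,
    monoisotopic_mass,
)

#: Probabilities below this floor are dropped from truncated patterns.
PROBABILITY_FLOOR = 1e-12

#: Default truncation: offsets above M5 are discarded.  For CHNOPS
#: molecules below ~2000 Da this keeps M0..M2 exact to well under 1e-9.
DEFAULT_MAX_OFFSET = 5


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue peak probabilities for one molecular formula.

    ``probabilities[d]`` is the probability of the isotopologue class
    with ``d`` extra neutrons (absolute normalization: the entries sum
    to at most 1, approaching 1 as the truncation offset grows).  In
    ``relative_to_M0`` normalization every entry is divided by M0.
    The optional fine-binning fields carry a mass axis instead of
    integer offsets.
    """

    probabilities: tuple[float, ...]
    max_offset: int
    normalization: str = "absolute"  # "absolute" | "relative_to_M0"
    mass_bin_centers: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.normalization not in ("absolute", "relative_to_M0"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if any(p < 0 for p in self.probabilities):
            raise ValueError("probabilities must be non-negative")

    def probability(self, offset: int) -> float:
        if self.mass_bin_centers is not None:
            raise ValueError("fine-binned pattern has no integer offsets")
        if 0 <= offset < len(self.probabilities):
            return self.probabilities[offset]
        return 0.0

    def relative_to_m0(self) -> "IsotopePattern":
        m0 = self.probabilities[0]
        if m0 <= 0:
            raise ValueError("cannot normalize: M0 probability is zero")
        return IsotopePattern(
            probabilities=tuple(p / m0 for p in self.probabilities),
            max_offset=self.max_offset,
            normalization="relative_to_M0",
            mass_bin_centers=self.mass_bin_centers,
        )

    def total(self) -> float:
        return float(sum(self.probabilities))


@lru_cache(maxsize=4096)
def _element_configs(
    table: IsotopeTable, element: str, atom_count: int, max_offset: int
) -> tuple[tuple[float, int, float], ...]:
    """Exact (mass, offset, probability) per isotope configuration.

    Enumerates every way to distribute ``atom_count`` atoms over the
    element's isotopes with total neutron offset <= ``max_offset``; the
    remainder sits in the lightest isotope.  Multinomial coefficients
    are evaluated in exact integer arithmetic before the float product.
    """
    isotopes = table[element]
    heavy = isotopes[1:]
    base = isotopes[0]
    configs: list[tuple[float, int, float]] = []

    def recurse(idx: int, remaining: int, offset: int, counts: tuple[int, ...]):
        if idx == len(heavy):
            k_base = remaining
            coeff = math.factorial(atom_count)
            for k in counts:
                coeff //= math.factorial(k)
            coeff //= math.factorial(k_base)
            prob = float(coeff) * base.abundance**k_base
            mass = k_base * base.mass
            for k, iso in zip(counts, heavy):
                prob *= iso.abundance**k
                mass += k * iso.mass
            if prob > 0.0:
                configs.append((mass, offset, prob))
            return
        iso = heavy[idx]
        max_k = remaining if iso.neutron_offset == 0 else min(
            remaining, (max_offset - offset) // iso.neutron_offset
        )
        for k in range(max_k + 1):
            recurse(idx + 1, remaining - k, offset + k * iso.neutron_offset, counts + (k,))

    recurse(0, atom_count, 0, ())
    return tuple(configs)


def element_distribution(
    element: str,
    atom_count: int,
    table: IsotopeTable = DEFAULT_ISOTOPE_TABLE,
    max_offset: int = DEFAULT_MAX_OFFSET,
) -> IsotopePattern:
    """Multinomial neutron-offset distribution for ``atom_count`` atoms.

    Offsets above ``max_offset`` are truncated; probabilities below the
    floor are dropped.  An unknown element symbol raises ``KeyError``.
    """
    if atom_count < 0:
        raise ValueError(f"atom count must be non-negative, got {atom_count}")
    if max_offset < 0:
        raise ValueError(f"max offset must be non-negative, got {max_offset}")
    table[element]  # raises KeyError for unknown symbols
    probs = np.zeros(max_offset + 1)
    for _mass, offset, prob in _element_configs(table, element, atom_count, max_offset):
        probs[offset] += prob
    probs[probs < PROBABILITY_FLOOR] = 0.0
    return IsotopePattern(probabilities=tuple(probs), max_offset=max_offset)


def molecular_pattern(
    formula: ChemicalFormula,
    table: IsotopeTable = DEFAULT_ISOTOPE_TABLE,
    max_offset: int = DEFAULT_MAX_OFFSET,
    bin_width: float | str = "unit",
) -> IsotopePattern:
    """Convolve the six element distributions into the molecular pattern.

    With ``bin_width="unit"`` peaks are aggregated by integer neutron
    offset; a float bin width instead bins configurations on a fixed
    mass grid anchored at the monoisotopic mass (fine structure mode).
    Absolute normalization in both cases.
    """
    if max_offset < 2:
        raise ValueError("max_offset must be >= 2 so M1 and M2 exist")
    if bin_width == "unit":
        pattern = np.zeros(1)
        pattern[0] = 1.0
        for element, count in zip(ELEMENTS, formula.counts()):
            if count == 0:
                continue
            elem = element_distribution(element, count, table, max_offset)
            pattern = np.convolve(pattern, np.asarray(elem.probabilities))[
                : max_offset + 1
            ]
        probs = np.zeros(max_offset + 1)
        probs[: len(pattern)] = pattern
        probs[probs < PROBABILITY_FLOOR] = 0.0
        return IsotopePattern(probabilities=tuple(probs), max_offset=max_offset)

    width = float(bin_width)
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    # Fine mode: convolve (mass, prob) point masses across elements, then bin.
    points: list[tuple[float, float]] = [(0.0, 1.0)]
    for element, count in zip(ELEMENTS, formula.counts()):
        if count == 0:
            continue
        configs = _element_configs(table, element, count, max_offset)
        merged: dict[float, float] = {}
        for mass0, prob0 in points:
            for mass1, offset, prob1 in configs:
                key = mass0 + mass1
                merged[key] = merged.get(key, 0.0) + prob0 * prob1
        points = [(m, p) for m, p in merged.items() if p >= PROBABILITY_FLOOR]
    mono = monoisotopic_mass(formula, table)
    # Bin index relative to the monoisotopic peak (always bin 0).
    binned: dict[int, float] = {}
    base_mass = min(m for m, _ in points)
    for mass, prob in points:
        idx = int(round((mass - base_mass) / width))
        binned[idx] = binned.get(idx, 0.0) + prob
    n_bins = max(binned) + 1
    probs_arr = np.zeros(n_bins)
    for idx, prob in binned.items():
        probs_arr[idx] = prob
    centers = tuple(mono + i * width for i in range(n_bins))
    return IsotopePattern(
        probabilities=tuple(probs_arr),
        max_offset=max_offset,
        mass_bin_centers=centers,
    )


def relative_ratios(pattern: IsotopePattern) -> tuple[float, float]:
    """(M1/M0, M2/M0) from a unit-binned pattern, any normalization."""
    if pattern.mass_bin_centers is not None:
        raise ValueError("relative ratios require a unit-binned pattern")
    if len(pattern.probabilities) < 3:
        raise ValueError("pattern must contain offsets 0, 1 and 2")
    m0 = pattern.probabilities[0]
    if m0 <= 0:
        raise ValueError("cannot form ratios: M0 probability is zero")
    return (pattern.probabilities[1] / m0, pattern.probabilities[2] / m0)


def formula_ratios(
    formula: ChemicalFormula,
    table: IsotopeTable = DEFAULT_ISOTOPE_TABLE,
) -> tuple[float, float]:
    """Theoretical (M1/M0, M2/M0) for one formula."""
    return relative_ratios(molecular_pattern(formula, table))


@lru_cache(maxsize=16)
def ratio_tables(
    table: IsotopeTable, max_count: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element lookup tables R1[e][n] = A1/A0 and R2[e][n] = A2/A0.

    ``A_d`` is the element's multinomial probability of offset ``d`` over
    ``n`` atoms.  Shapes are (6, max_count + 1) in C,H,N,O,S,P order.
    """
    r1 = np.zeros((len(ELEMENTS), max_count + 1))
    r2 = np.zeros((len(ELEMENTS), max_count + 1))
    for i, element in enumerate(ELEMENTS):
        for n in range(max_count + 1):
            dist = element_distribution(element, n, table, max_offset=2)
            a0, a1, a2 = dist.probabilities[:3]
            r1[i, n] = a1 / a0
            r2[i, n] = a2 / a0
    return r1, r2


def batch_ratios(
    count_matrix: np.ndarray,
    table: IsotopeTable = DEFAULT_ISOTOPE_TABLE,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact (M1/M0, M2/M0) for many formulae at once.

    ``count_matrix`` is (n, 6) in C,H,N,O,S,P order.  Uses the identities

        M1/M0 = sum_e A1_e/A0_e
        M2/M0 = sum_e A2_e/A0_e + sum_{e<f} (A1_e/A0_e)(A1_f/A0_f)

    which are exact because an offset-1 molecular peak is a single +1
    substitution in exactly one element, and an offset-2 peak is either
    one +2 substitution pattern within an element or +1 substitutions in
    two distinct elements.  Agrees with ``molecular_pattern`` to float
    precision (property-tested).
    """
    counts = np.asarray(count_matrix, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[1] != len(ELEMENTS):
        raise ValueError("count matrix must have shape (n, 6)")
    if counts.size == 0:
        return np.zeros(0), np.zeros(0)
    r1_tab, r2_tab = ratio_tables(table, int(counts.max()))
    cols = np.arange(len(ELEMENTS))
    r1_elem = r1_tab[cols, counts]  # (n, 6)
    r2_elem = r2_tab[cols, counts]
    m1 = r1_elem.sum(axis=1)
    sum_sq = (r1_elem**2).sum(axis=1)
    cross = (m1**2 - sum_sq) / 2.0
    m2 = r2_elem.sum(axis=1) + cross
    return m1, m2
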