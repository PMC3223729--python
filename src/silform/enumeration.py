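"""Exhaustive CHNOPS formula generation within a mass window.

``enumerate_brute_force`` returns every count combination inside the
element ranges whose monoisotopic mass falls in the window — the
contract is set equality with a naive six-nested-loop enumeration.
The implementation avoids iterating the full space (288,120,000 points
under the default ranges) by looping over the heteroatom combinations
(N, O, S, P — at most 7 x 21 x 7 x 7 = 7203 under the defaults) and
solving the residual one-dimensional integer problem for the hydrogen
count at each carbon count with vectorized arithmetic.

``enumerate_filtered`` additionally applies configurable heuristic
plausibility filters (element-ratio bounds and a ring/double-bond
equivalent floor) in the style of heuristic formula generators such as
HR2 / the Seven Golden Rules.  The filters are a pure subset operation:
disabling them always reproduces the brute-force set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .chemspace import (
    DEFAULT_ISOTOPE_TABLE,
    ELEMENTS,
    ChemicalFormula,
    ElementRanges,
    IsotopeTable,
    MassWindow,
    error_ppm,
)

#: Element-ratio "common range" bounds used by heuristic formula
#: generators (Seven Golden Rules).  Note the O/C ceiling of 1.2 is
#: known to exclude real metabolites such as ATP (O/C = 1.3), taurine
#: (O/C = 1.5) and malate (O/C = 1.25); the bounds are configuration,
#: not truth.
COMMON_RATIO_BOUNDS: dict[str, tuple[float, float]] = {
    "H/C": (0.2, 3.1),
    "N/C": (0.0, 1.3),
    "O/C": (0.0, 1.2),
    "P/C": (0.0, 0.3),
    "S/C": (0.0, 0.8),
}


def rdbe(formula: ChemicalFormula) -> float:
    """Ring/double-bond equivalents: c - h/2 + n/2 + p/2 + 1."""
    return formula.c - formula.h / 2 + formula.n / 2 + formula.p / 2 + 1


@dataclass(frozen=True)
class HeuristicFilterConfig:
    """Configurable chemical-plausibility filters for candidate formulae.

    With ``enabled=False`` no candidate is ever rejected.  Ratio bounds
    are inclusive and only applied to formulae with at least one carbon;
    carbon-free formulae (possible when the carbon range allows zero)
    pass the ratio checks vacuously.  ``require_integer_rdbe`` demands an
    integer ring/double-bond equivalent (even h + n + p), the parity form
    of the nitrogen rule for even-electron neutral molecules.
    """

    enabled: bool = True
    ratio_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(COMMON_RATIO_BOUNDS)
    )
    rdbe_min: float | None = 0.0
    require_integer_rdbe: bool = False

    def accepts(self, formula: ChemicalFormula) -> bool:
        if not self.enabled:
            return True
        if formula.c > 0:
            ratios = {
                "H/C": formula.h / formula.c,
                "N/C": formula.n / formula.c,
                "O/C": formula.o / formula.c,
                "P/C": formula.p / formula.c,
                "S/C": formula.s / formula.c,
            }
            for name, (lo, hi) in self.ratio_bounds.items():
                if not (lo <= ratios[name] <= hi):
                    return False
        value = rdbe(formula)
        if self.rdbe_min is not None and value < self.rdbe_min:
            return False
        if self.require_integer_rdbe and (formula.h + formula.n + formula.p) % 2 != 0:
            return False
        return True


#: A convenience disabled config (identity filter).
NO_FILTER = HeuristicFilterConfig(enabled=False)


@dataclass(frozen=True)
class Candidate:
    """One formula hit inside a window, with its signed ppm error."""

    formula: ChemicalFormula
    mass: float
    error_ppm: float


@dataclass(frozen=True)
class CandidateSet:
    """All candidate formulae for one mass window.

    Candidates are unique and sorted by absolute ppm error, ties broken
    lexicographically on the (C, H, N, O, S, P) count tuple, so output
    is deterministic and diff-friendly.
    """

    window: MassWindow
    candidates: tuple[Candidate, ...]
    ranges: ElementRanges
    filter_config: HeuristicFilterConfig = NO_FILTER

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def formulae(self) -> list[ChemicalFormula]:
        return [c.formula for c in self.candidates]

    def count_matrix(self) -> np.ndarray:
        """(n_candidates, 6) integer array of counts in C,H,N,O,S,P order."""
        if not self.candidates:
            return np.empty((0, 6), dtype=np.int64)
        return np.array([c.formula.counts() for c in self.candidates], dtype=np.int64)

    def contains(self, formula: ChemicalFormula) -> bool:
        return any(c.formula == formula for c in self.candidates)

    def replace(self, candidates) -> "CandidateSet":
        """New set over the same window/ranges with a candidate subset."""
        return CandidateSet(
            window=self.window,
            candidates=tuple(candidates),
            ranges=self.ranges,
            filter_config=self.filter_config,
        )

    def to_frame(self):
        """Candidates as a pandas DataFrame (formula, mass_da, error_ppm)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "formula": str(c.formula),
                    "mass_da": c.mass,
                    "error_ppm": c.error_ppm,
                }
                for c in self.candidates
            ],
            columns=["formula", "mass_da", "error_ppm"],
        )


def search_space_size(ranges: ElementRanges) -> int:
    """Number of count combinations in the 6-D space: prod(max - min + 1)."""
    return math.prod(hi - lo + 1 for lo, hi in ranges.bounds())


def _sort_candidates(candidates: list[Candidate]) -> tuple[Candidate, ...]:
    return tuple(
        sorted(candidates, key=lambda c: (abs(c.error_ppm), c.formula.counts()))
    )


def enumerate_brute_force(
    window: MassWindow,
    ranges: ElementRanges | None = None,
    table: IsotopeTable = DEFAULT_ISOTOPE_TABLE,
) -> CandidateSet:
    """Every in-range formula whose monoisotopic mass lies in the window.

    Equivalent, as a set, to iterating all six nested count loops and
    keeping in-window masses; a window above the maximum achievable mass
    simply yields an empty set.
    """
    if ranges is None:
        ranges = ElementRanges()
    masses = {e: table.lightest_mass(e) for e in ELEMENTS}
    (c_lo, c_hi), (h_lo_rng, h_hi_rng) = ranges.bounds()[0], ranges.bounds()[1]
    het_bounds = ranges.bounds()[2:]  # N, O, S, P

    # Heteroatom grid: masses of every (n, o, s, p) combination.
    het_axes = [np.arange(lo, hi + 1, dtype=np.int64) for lo, hi in het_bounds]
    n_g, o_g, s_g, p_g = np.meshgrid(*het_axes, indexing="ij")
    het_counts = np.stack(
        [n_g.ravel(), o_g.ravel(), s_g.ravel(), p_g.ravel()], axis=1
    )
    het_mass = (
        het_counts[:, 0] * masses["N"]
        + het_counts[:, 1] * masses["O"]
        + het_counts[:, 2] * masses["S"]
        + het_counts[:, 3] * masses["P"]
    )

    # Sound carbon bounds: a candidate in the window must satisfy
    # c*mC <= high - min(het mass) - h_min*mH (and symmetrically below),
    # so carbons outside these bounds cannot appear in any hit.
    m_c = masses["C"]
    c_cap = math.floor(
        (window.high - float(het_mass.min()) - h_lo_rng * masses["H"]) / m_c
    )
    c_floor = math.ceil(
        (window.low - float(het_mass.max()) - h_hi_rng * masses["H"]) / m_c
    )
    c_lo = max(c_lo, c_floor)
    c_hi = min(c_hi, c_cap)
    if c_hi < c_lo:
        return CandidateSet(
            window=window, candidates=(), ranges=ranges, filter_config=NO_FILTER
        )
    c_vals = np.arange(c_lo, c_hi + 1, dtype=np.int64)
    # base[i, j] = mass of heteroatom combo i plus j carbons
    base = het_mass[:, None] + c_vals[None, :] * masses["C"]

    m_h = masses["H"]
    # Integer hydrogen counts h with low <= base + h*m_h <= high.  The
    # bounds are widened by one to absorb float rounding in ceil/floor;
    # every emitted candidate is re-checked against the exact window.
    h_min = np.ceil((window.low - base) / m_h).astype(np.int64) - 1
    h_max = np.floor((window.high - base) / m_h).astype(np.int64) + 1
    np.clip(h_min, h_lo_rng, None, out=h_min)
    np.clip(h_max, None, h_hi_rng, out=h_max)

    candidates: list[Candidate] = []
    span = h_max - h_min
    feasible = span >= 0
    if feasible.any():
        max_span = int(span[feasible].max())
        for offset in range(max_span + 1):
            h_try = h_min + offset
            mask = feasible & (h_try <= h_max)
            if not mask.any():
                continue
            het_idx, c_idx = np.nonzero(mask)
            h_sel = h_try[mask]
            mass_sel = base[mask] + h_sel * m_h
            in_window = (window.low <= mass_sel) & (mass_sel <= window.high)
            for k in np.nonzero(in_window)[0]:
                n, o, s, p = het_counts[het_idx[k]]
                formula = ChemicalFormula(
                    int(c_vals[c_idx[k]]), int(h_sel[k]), int(n), int(o), int(s), int(p)
                )
                candidates.append(
                    Candidate(
                        formula=formula,
                        mass=float(mass_sel[k]),
                        error_ppm=error_ppm(float(mass_sel[k]), window.target_mass),
                    )
                )
    return CandidateSet(
        window=window,
        candidates=_sort_candidates(candidates),
        ranges=ranges,
        filter_config=NO_FILTER,
    )


def enumerate_filtered(
    window: MassWindow,
    ranges: ElementRanges | None = None,
    filter_config: HeuristicFilterConfig | None = None,
    table: IsotopeTable = DEFAULT_ISOTOPE_TABLE,
) -> CandidateSet:
    """Brute-force enumeration minus candidates failing any enabled heuristic."""
    if filter_config is None:
        filter_config = HeuristicFilterConfig()
    full = enumerate_brute_force(window, ranges, table)
    kept = tuple(c for c in full.candidates if filter_config.accepts(c.formula))
    return CandidateSet(
        window=full.window,
        candidates=kept,
        ranges=full.ranges,
        filter_config=filter_config,
    )


def degeneracy(
    candidate_set: CandidateSet, true_formula: ChemicalFormula | None = None
) -> int:
    """Number of formulae indistinguishable from the truth by mass alone.

    With a known true formula this is the count of *other* candidates
    (set size minus one); without one it is the full set size.
    """
    if true_formula is None:
        return len(candidate_set)
    if not candidate_set.contains(true_formula):
        raise ValueError(
            f"true formula {true_formula} not in the candidate set for its own window"
        )
    return len(candidate_set) - 1


def enumerate_naive(
    window: MassWindow,
    ranges: ElementRanges,
    table: IsotopeTable = DEFAULT_ISOTOPE_TABLE,
) -> set[ChemicalFormula]:
    """Reference six-nested-loop enumeration (for tiny ranges only).

    Kept in the library as the executable statement of the brute-force
    contract; tests compare the optimized enumerator against it.
    """
    masses = [table.lightest_mass(e) for e in ELEMENTS]
    hits: set[ChemicalFormula] = set()
    bounds = ranges.bounds()
    for counts in itertools.product(*(range(lo, hi + 1) for lo, hi in bounds)):
        if sum(counts) < 1:
            continue
        mass = sum(k * m for k, m in zip(counts, masses))
        if window.low <= mass <= window.high:
            hits.add(ChemicalFormula(*counts))
    return hits
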