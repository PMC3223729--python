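"""Core domain types for CHNOPS chemical space.

Formulae are restricted to the six biologically dominant elements
C, H, N, O, S and P.  All masses are neutral monoisotopic masses in
daltons; no adducts, charges or electron-mass corrections are applied
anywhere in the package.

The isotope table is a pinned, versioned constant (masses and natural
abundances from the NIST/CODATA compilation); it is never fetched at
run time, so every mass and isotope-pattern computation in the package
is bit-reproducible.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterator

logger = logging.getLogger(__name__)

#: Canonical element order used for count tuples throughout the package.
ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "S", "P")


class FormulaError(ValueError):
    """Raised for malformed or non-CHNOPS formula strings."""


@dataclass(frozen=True)
class Isotope:
    """One stable isotope of an element."""

    mass: float  # exact atomic mass, Da
    abundance: float  # natural abundance, fraction in [0, 1]
    neutron_offset: int  # extra neutrons relative to the lightest isotope


@dataclass(frozen=True, eq=False)
class IsotopeTable:
    """Pinned table of stable isotopes per element.

    Invariants: abundances per element sum to 1 within 1e-9, masses
    strictly increase with neutron offset, and the lightest isotope has
    neutron offset 0.  Tables compare and hash by identity (they are
    module-level constants), which lets per-table caches key on them.
    """

    version: str
    isotopes: dict[str, tuple[Isotope, ...]]

    def __post_init__(self) -> None:
        for symbol, isos in self.isotopes.items():
            total = sum(i.abundance for i in isos)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"abundances for {symbol} sum to {total!r}, expected 1"
                )
            offsets = [i.neutron_offset for i in isos]
            masses = [i.mass for i in isos]
            if offsets[0] != 0:
                raise ValueError(f"lightest isotope of {symbol} must have offset 0")
            if sorted(offsets) != offsets or sorted(masses) != masses:
                raise ValueError(f"isotopes of {symbol} must be sorted by mass")

    def __getitem__(self, symbol: str) -> tuple[Isotope, ...]:
        try:
            return self.isotopes[symbol]
        except KeyError:
            raise KeyError(f"unknown element {symbol!r}") from None

    def lightest_mass(self, symbol: str) -> float:
        return self[symbol][0].mass


#: NIST atomic weights and isotopic compositions (2018 compilation),
#: rounded to 7 decimals in mass and at most 6 in abundance.
DEFAULT_ISOTOPE_TABLE = IsotopeTable(
    version="NIST-2018",
    isotopes={
        "C": (
            Isotope(12.0, 0.9893, 0),
            Isotope(13.0033548, 0.0107, 1),
        ),
        "H": (
            Isotope(1.0078250, 0.999885, 0),
            Isotope(2.0141018, 0.000115, 1),
        ),
        "N": (
            Isotope(14.0030740, 0.99636, 0),
            Isotope(15.0001089, 0.00364, 1),
        ),
        "O": (
            Isotope(15.9949146, 0.99757, 0),
            Isotope(16.9991316, 0.00038, 1),
            Isotope(17.9991596, 0.00205, 2),
        ),
        "S": (
            Isotope(31.9720707, 0.9499, 0),
            Isotope(32.9714589, 0.0075, 1),
            Isotope(33.9678670, 0.0425, 2),
            Isotope(35.9670809, 0.0001, 4),
        ),
        "P": (Isotope(30.9737615, 1.0, 0),),
    },
)


@dataclass(frozen=True, order=True)
class ChemicalFormula:
    """Integer CHNOPS atom counts C_a H_b N_c O_x S_y P_z.

    All counts are non-negative and at least one must be positive.
    Equality and ordering are defined on the six-count tuple.
    """

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        counts = self.counts()
        if any(int(v) != v for v in counts):
            raise FormulaError(f"atom counts must be integers, got {counts}")
        if any(v < 0 for v in counts):
            raise FormulaError(f"atom counts must be non-negative, got {counts}")
        if sum(counts) < 1:
            raise FormulaError("formula must contain at least one atom")

    def counts(self) -> tuple[int, int, int, int, int, int]:
        """Counts in canonical (C, H, N, O, S, P) order."""
        return (self.c, self.h, self.n, self.o, self.s, self.p)

    def count(self, symbol: str) -> int:
        return self.counts()[ELEMENTS.index(symbol)]

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        return ChemicalFormula(
            *(a + b for a, b in zip(self.counts(), other.counts()))
        )

    def __str__(self) -> str:
        return format_formula(self)


@dataclass(frozen=True)
class ElementRanges:
    """Per-element [min, max] atom-count bounds defining the search space.

    The default bounds — C and H in [1, 200], N, S and P in [0, 6],
    O in [0, 20] — cover the vast majority of small-molecule metabolites
    while keeping the six-dimensional space finite (288,120,000 points).
    """

    c: tuple[int, int] = (1, 200)
    h: tuple[int, int] = (1, 200)
    n: tuple[int, int] = (0, 6)
    o: tuple[int, int] = (0, 20)
    s: tuple[int, int] = (0, 6)
    p: tuple[int, int] = (0, 6)

    def __post_init__(self) -> None:
        for symbol, (lo, hi) in zip(ELEMENTS, self.bounds()):
            if not (0 <= lo <= hi):
                raise ValueError(
                    f"range for {symbol} must satisfy 0 <= min <= max, got {lo}:{hi}"
                )

    def bounds(self) -> tuple[tuple[int, int], ...]:
        """Bounds in canonical (C, H, N, O, S, P) order."""
        return (self.c, self.h, self.n, self.o, self.s, self.p)

    def contains(self, formula: ChemicalFormula) -> bool:
        return all(
            lo <= v <= hi for v, (lo, hi) in zip(formula.counts(), self.bounds())
        )

    def iter_formulae(self) -> Iterator[ChemicalFormula]:
        """Exhaustive generator over the full space (use only for tiny ranges)."""
        (c0, c1), (h0, h1), (n0, n1), (o0, o1), (s0, s1), (p0, p1) = self.bounds()
        for c in range(c0, c1 + 1):
            for h in range(h0, h1 + 1):
                for n in range(n0, n1 + 1):
                    for o in range(o0, o1 + 1):
                        for s in range(s0, s1 + 1):
                            for p in range(p0, p1 + 1):
                                if c + h + n + o + s + p >= 1:
                                    yield ChemicalFormula(c, h, n, o, s, p)


@dataclass(frozen=True)
class MassWindow:
    """Symmetric relative mass window around a target mass.

    low = target * (1 - ppm * 1e-6), high = target * (1 + ppm * 1e-6).
    """

    target_mass: float
    tolerance_ppm: float
    low: float = field(init=False)
    high: float = field(init=False)

    def __post_init__(self) -> None:
        if self.target_mass <= 0:
            raise ValueError(f"target mass must be positive, got {self.target_mass}")
        if self.tolerance_ppm < 0:
            raise ValueError(
                f"ppm tolerance must be non-negative, got {self.tolerance_ppm}"
            )
        object.__setattr__(
            self, "low", self.target_mass * (1.0 - self.tolerance_ppm * 1e-6)
        )
        object.__setattr__(
            self, "high", self.target_mass * (1.0 + self.tolerance_ppm * 1e-6)
        )

    def contains(self, mass: float) -> bool:
        return self.low <= mass <= self.high


def ppm_window(target_mass: float, tolerance_ppm: float) -> MassWindow:
    """Build the symmetric ppm window around ``target_mass``."""
    return MassWindow(target_mass, tolerance_ppm)


def monoisotopic_mass(
    formula: ChemicalFormula, table: IsotopeTable = DEFAULT_ISOTOPE_TABLE
) -> float:
    """Neutral monoisotopic mass: sum of lightest-isotope masses times counts."""
    return sum(
        count * table.lightest_mass(symbol)
        for symbol, count in zip(ELEMENTS, formula.counts())
    )


def error_ppm(candidate_mass: float, target_mass: float) -> float:
    """Signed relative mass error of a candidate versus the target, in ppm."""
    return (candidate_mass - target_mass) / target_mass * 1e6


_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ChemicalFormula:
    """Parse Hill-like notation restricted to C, H, N, O, S, P.

    An omitted element means count 0; an omitted count means 1
    (``"CH4"`` -> CH4).  Repeated element symbols accumulate.

    Raises
    ------
    FormulaError
        On empty input, unknown element symbols, or malformed tokens.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts = dict.fromkeys(ELEMENTS, 0)
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {text[pos:]!r}"
            )
        symbol, digits = match.groups()
        if symbol not in counts:
            raise FormulaError(
                f"non-CHNOPS element {symbol!r} in formula {text!r}"
            )
        counts[symbol] += int(digits) if digits else 1
        pos = match.end()
    return ChemicalFormula(*(counts[e] for e in ELEMENTS))


def format_formula(formula: ChemicalFormula) -> str:
    """Format in Hill order (C, H, then N, O, P, S alphabetically).

    Elements with count 0 are omitted; count 1 is written without a digit.
    """
    parts: list[str] = []
    for symbol in ("C", "H", "N", "O", "P", "S"):
        count = formula.count(symbol)
        if count == 1:
            parts.append(symbol)
        elif count > 1:
            parts.append(f"{symbol}{count}")
    return "".join(parts)


def read_compound_table(path, table: IsotopeTable = DEFAULT_ISOTOPE_TABLE):
    """Read a TSV compound table with columns (id, formula, monoisotopic_mass).

    The mass column is recomputed from the formula; a discrepancy larger
    than 1e-3 Da triggers a warning (the recomputed mass is kept).
    Returns a pandas DataFrame with columns id, formula, monoisotopic_mass.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str, "formula": str})
    required = {"id", "formula"}
    if not required.issubset(df.columns):
        raise ValueError(f"compound table must have columns {sorted(required)}")
    recomputed = [
        monoisotopic_mass(parse_formula(f), table) for f in df["formula"]
    ]
    if "monoisotopic_mass" in df.columns:
        for row_id, stated, fresh in zip(df["id"], df["monoisotopic_mass"], recomputed):
            if abs(float(stated) - fresh) > 1e-3:
                logger.warning(
                    "compound %s: stated mass %.4f differs from recomputed %.4f Da",
                    row_id,
                    float(stated),
                    fresh,
                )
    df["monoisotopic_mass"] = recomputed
    return df


def write_compound_table(path, formulae, table: IsotopeTable = DEFAULT_ISOTOPE_TABLE):
    """Write a TSV compound table (id, formula, monoisotopic_mass)."""
    import pandas as pd

    rows = [
        {
            "id": f"cpd{i:06d}",
            "formula": format_formula(f),
            "monoisotopic_mass": monoisotopic_mass(f, table),
        }
        for i, f in enumerate(formulae)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
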