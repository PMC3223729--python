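import numpy as np
import pytest

from silform import ChemicalFormula, ElementRanges, parse_formula


@pytest.fixture(scope="session")
def folate() -> ChemicalFormula:
    return parse_formula("C19H19N7O6")


@pytest.fixture(scope="session")
def folate_ranges() -> ElementRanges:
    """Default element ranges widened to N <= 7 so folate is in-range."""
    return ElementRanges(n=(0, 7))


@pytest.fixture(scope="session")
def reduced_ranges() -> ElementRanges:
    """Small search space where the naive six-loop oracle is affordable."""
    return ElementRanges(
        c=(1, 30), h=(1, 30), n=(0, 3), o=(0, 3), s=(0, 3), p=(0, 3)
    )


def random_formulae(rng: np.random.Generator, n: int, small: bool = True):
    """Draw n random valid CHNOPS formulae (no mass constraint)."""
    out = []
    hi = (30, 40, 4, 8, 2, 2) if small else (120, 160, 6, 20, 6, 6)
    while len(out) < n:
        counts = tuple(int(rng.integers(0, h + 1)) for h in hi)
        if sum(counts) < 1:
            continue
        out.append(ChemicalFormula(*counts))
    return out
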