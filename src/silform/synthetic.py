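"""Seeded generators for synthetic study inputs.

These stand in for the large public resources the analysis is normally
run against: a compound library with unique CHNOPS formulae (the role a
chemical-structure database snapshot plays), a pathway database with
controlled compound sharing and planted ground truth (the role a
curated metabolic-pathway database plays), and noisy measured features
(the role of real mass-spectral observations).

All generators are deterministic in their seed.  Element counts are
sampled uniformly per element and rejection-filtered to the requested
mass band; no attempt is made to match the empirical formula
distribution of any real database — the claims tested against these
libraries are structural (subset, monotonicity, directional), not
distributional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemspace import (
    DEFAULT_ISOTOPE_TABLE,
    ELEMENTS,
    ChemicalFormula,
    ElementRanges,
    IsotopeTable,
    format_formula,
    monoisotopic_mass,
)
from .constraints import MeasuredFeature
from .isotopes import formula_ratios
from .pathways import PathwayDB


@dataclass(frozen=True)
class LibrarySpec:
    """Recipe for a synthetic compound library.

    ``require_unique_masses_at_ppm`` additionally guarantees no two
    library masses lie within that ppm tolerance of each other, so every
    library entry is its own nearest formula in mass.
    """

    n_formulae: int
    ranges: ElementRanges = field(default_factory=ElementRanges)
    mass_min: float = 50.0
    mass_max: float = 2000.0
    require_unique_formulae: bool = True
    require_unique_masses_at_ppm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_formulae < 1:
            raise ValueError("n_formulae must be positive")
        if not (0 < self.mass_min <= self.mass_max):
            raise ValueError("need 0 < mass_min <= mass_max")


class InfeasibleSpecError(RuntimeError):
    """Raised when a generator cannot satisfy its spec within its budget."""


def generate_library(
    spec: LibrarySpec, table: IsotopeTable = DEFAULT_ISOTOPE_TABLE
) -> list[ChemicalFormula]:
    """Sample distinct CHNOPS formulae uniformly over in-range counts.

    Counts are drawn uniformly per element within the ranges,
    rejection-filtered to the mass band, de-duplicated (and optionally
    mass-separated).  Same seed, same library; a spec that cannot be
    filled within a bounded number of rejection rounds raises
    ``InfeasibleSpecError``.
    """
    rng = np.random.default_rng(spec.seed)
    bounds = spec.ranges.bounds()
    lows = np.array([lo for lo, _ in bounds], dtype=np.int64)
    highs = np.array([hi for _, hi in bounds], dtype=np.int64)
    masses_per_atom = np.array([table.lightest_mass(e) for e in ELEMENTS])

    accepted: list[ChemicalFormula] = []
    accepted_masses: list[float] = []
    seen: set[tuple[int, ...]] = set()
    ppm = spec.require_unique_masses_at_ppm
    batch = max(4 * spec.n_formulae, 1024)
    for _ in range(200):
        counts = rng.integers(lows, highs + 1, size=(batch, len(ELEMENTS)))
        masses = counts @ masses_per_atom
        ok = (
            (masses >= spec.mass_min)
            & (masses <= spec.mass_max)
            & (counts.sum(axis=1) >= 1)
        )
        for row, mass in zip(counts[ok], masses[ok]):
            key = tuple(int(v) for v in row)
            if spec.require_unique_formulae and key in seen:
                continue
            if ppm is not None and any(
                abs(mass - m) <= ppm * 1e-6 * max(mass, m) for m in accepted_masses
            ):
                continue
            seen.add(key)
            accepted.append(ChemicalFormula(*key))
            accepted_masses.append(float(mass))
            if len(accepted) == spec.n_formulae:
                return accepted
    raise InfeasibleSpecError(
        f"could not draw {spec.n_formulae} formulae satisfying the spec "
        f"(got {len(accepted)}) — mass band or uniqueness constraints too tight"
    )


@dataclass(frozen=True)
class PathwayDBSpec:
    """Recipe for a synthetic pathway database with planted ground truth.

    Each pathway gets ``reactions_per_pathway`` reactions of
    ``compounds_per_reaction`` compounds.  A fraction of compound slots
    is filled from a pool shared across pathways; the rest are private
    compounds.  Exactly ``planted_unique_formula_pathways`` pathways
    carry a private compound with a formula found nowhere else (the
    recoverable ground truth); private formulae of the remaining
    pathways are deliberately duplicated elsewhere so they are never
    formula-unique.  Optionally a fraction of extra non-CHNOPS filler
    compounds and super-pathway aggregates are added.
    """

    n_pathways: int
    reactions_per_pathway: int = 3
    compounds_per_reaction: int = 3
    shared_compound_fraction: float = 0.3
    planted_unique_formula_pathways: int = 0
    non_chnops_fraction: float = 0.0
    super_pathway_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("need at least one pathway")
        if self.reactions_per_pathway < 1 or self.compounds_per_reaction < 1:
            raise ValueError("reactions and compounds per pathway must be >= 1")
        if not (0.0 <= self.shared_compound_fraction <= 1.0):
            raise ValueError("shared_compound_fraction must be in [0, 1]")
        if not (0.0 <= self.non_chnops_fraction <= 1.0):
            raise ValueError("non_chnops_fraction must be in [0, 1]")
        if not (0.0 <= self.super_pathway_fraction <= 1.0):
            raise ValueError("super_pathway_fraction must be in [0, 1]")
        if self.planted_unique_formula_pathways > self.n_pathways:
            raise ValueError(
                "cannot plant more unique-formula pathways than pathways"
            )


def _distinct_formula_stream(rng: np.random.Generator):
    """Endless stream of distinct small CHNOPS formulae."""
    seen: set[tuple[int, ...]] = set()
    while True:
        counts = (
            int(rng.integers(1, 40)),
            int(rng.integers(1, 60)),
            int(rng.integers(0, 7)),
            int(rng.integers(0, 15)),
            int(rng.integers(0, 4)),
            int(rng.integers(0, 4)),
        )
        if counts in seen:
            continue
        seen.add(counts)
        yield ChemicalFormula(*counts)


def generate_pathway_db(spec: PathwayDBSpec) -> tuple[PathwayDB, dict]:
    """Build a synthetic pathway database plus its planted ground truth.

    Returns ``(db, ground_truth)`` where ``ground_truth`` records the
    pathway ids planted as formula-unique, the planted compound/formula
    per pathway, and the number of non-CHNOPS filler compounds added.
    The planting is exact: after CHNOPS restriction and super-pathway
    removal, the uniqueness analysis finds exactly the planted pathways
    as formula-unique.
    """
    rng = np.random.default_rng(spec.seed)
    formula_stream = _distinct_formula_stream(rng)

    # Super-pathway aggregates are carved out of n_pathways, so a
    # fraction of 1 leaves no pathways after they are dropped.
    n_super = int(round(spec.super_pathway_fraction * spec.n_pathways))
    n_regular = spec.n_pathways - n_super
    n_planted = spec.planted_unique_formula_pathways
    if n_planted > n_regular:
        raise InfeasibleSpecError(
            f"cannot plant {n_planted} unique-formula pathways with only "
            f"{n_regular} non-super pathways"
        )
    n_plain = n_regular - n_planted
    if n_plain >= 1 and n_regular == 1:
        raise InfeasibleSpecError(
            "a lone unplanted pathway is always formula-unique; "
            "use >= 2 pathways or plant it"
        )
    if n_plain == 1 and spec.shared_compound_fraction == 0.0:
        raise InfeasibleSpecError(
            "cannot make a single unplanted pathway formula-non-unique "
            "without shared compounds"
        )

    compounds: dict[str, ChemicalFormula | None] = {}
    reactions: dict[str, set[str]] = {}
    pathways: dict[str, set[str]] = {}
    flags: dict[str, bool] = {}

    def new_compound(formula: ChemicalFormula | None) -> str:
        cid = f"cpd{len(compounds):05d}"
        compounds[cid] = formula
        return cid

    # Shared pool: compounds reused across at least two pathways.
    slots_per_pathway = spec.reactions_per_pathway * spec.compounds_per_reaction
    n_shared_slots = int(round(spec.shared_compound_fraction * slots_per_pathway))
    n_shared_slots = min(n_shared_slots, slots_per_pathway - 1)  # keep >=1 private slot
    pool_size = max(2, n_regular * max(n_shared_slots, 1) // 2) if n_shared_slots else 0
    shared_pool = [new_compound(next(formula_stream)) for _ in range(pool_size)]

    planted_ids = [f"pwy{i:04d}" for i in range(n_planted)]
    plain_ids = [f"pwy{i:04d}" for i in range(n_planted, n_regular)]
    ground_planted: dict[str, dict] = {}

    plain_private: list[str] = []  # private compounds of unplanted pathways
    by_pathway: dict[str, str] = {}  # private compound -> owning pathway
    for pwy_idx, pwy_id in enumerate(planted_ids + plain_ids):
        rxn_ids = []
        private_slots = []
        shared_slot_budget = n_shared_slots
        for r in range(spec.reactions_per_pathway):
            rxn_id = f"{pwy_id}_rxn{r}"
            members: set[str] = set()
            for _slot in range(spec.compounds_per_reaction):
                if shared_slot_budget > 0 and shared_pool:
                    members.add(shared_pool[int(rng.integers(len(shared_pool)))])
                    shared_slot_budget -= 1
                else:
                    cid = new_compound(next(formula_stream))
                    members.add(cid)
                    private_slots.append(cid)
            reactions[rxn_id] = members
            rxn_ids.append(rxn_id)
        pathways[pwy_id] = set(rxn_ids)
        flags[pwy_id] = False
        if pwy_id in planted_ids:
            # First private compound is the planted fingerprint; its
            # formula occurs nowhere else by the distinct-stream design.
            planted_cpd = private_slots[0]
            ground_planted[pwy_id] = {
                "compound": planted_cpd,
                "formula": format_formula(compounds[planted_cpd]),
            }
        else:
            plain_private.extend(private_slots)
            for cid in private_slots:
                by_pathway[cid] = pwy_id

    # Destroy formula-uniqueness of every unplanted private compound by
    # duplicating its formula onto a compound in a different pathway,
    # or onto a shared-pool compound when no partner pathway exists.
    # Interleave privates round-robin by pathway so adjacent list
    # entries come from different pathways wherever possible.
    groups = [
        [c for c in plain_private if by_pathway[c] == pwy]
        for pwy in plain_ids
    ]
    interleaved: list[str] = []
    while any(groups):
        for g in groups:
            if g:
                interleaved.append(g.pop(0))
    leftovers: list[str] = []
    i = 0
    while i + 1 < len(interleaved):
        a, b = interleaved[i], interleaved[i + 1]
        if by_pathway[a] != by_pathway[b]:
            compounds[b] = compounds[a]
            i += 2
        else:
            leftovers.append(a)
            i += 1
    leftovers.extend(interleaved[i:])
    for cid in leftovers:
        donor = next(
            (c for c in plain_private if by_pathway[c] != by_pathway[cid]), None
        )
        if donor is not None:
            compounds[cid] = compounds[donor]
        elif shared_pool:
            donor = shared_pool[int(rng.integers(len(shared_pool)))]
            compounds[cid] = compounds[donor]
        else:
            raise InfeasibleSpecError(
                "cannot deduplicate private formulae of unplanted pathways"
            )

    # A shared-pool compound drawn by only one pathway would be an
    # accidental unique fingerprint there; force every used pool
    # compound into at least two pathways.
    if shared_pool and n_regular >= 2:
        regular = planted_ids + plain_ids
        usage: dict[str, set[str]] = {c: set() for c in shared_pool}
        for pwy_id in regular:
            for rxn_id in pathways[pwy_id]:
                for cid in reactions[rxn_id]:
                    if cid in usage:
                        usage[cid].add(pwy_id)
        for cid, users in usage.items():
            if len(users) == 1:
                owner = next(iter(users))
                other = next(p for p in regular if p != owner)
                target_rxn = sorted(pathways[other])[0]
                reactions[target_rxn].add(cid)

    # Non-CHNOPS filler compounds appended to existing reactions.
    n_total_cpds = len(compounds)
    n_non_chnops = int(round(spec.non_chnops_fraction * n_total_cpds))
    rxn_keys = sorted(reactions)
    for _ in range(n_non_chnops):
        cid = new_compound(None)
        reactions[rxn_keys[int(rng.integers(len(rxn_keys)))]].add(cid)

    # Super-pathway aggregates: union of two regular pathways' reactions
    # when possible, otherwise standalone flagged pathways.
    regular_ids = planted_ids + plain_ids
    for i in range(n_super):
        sp_id = f"super{i:04d}"
        if len(regular_ids) >= 2:
            members = rng.choice(len(regular_ids), size=2, replace=False)
            pathways[sp_id] = set().union(
                *(pathways[regular_ids[j]] for j in members)
            )
        else:
            rxn_id = f"{sp_id}_rxn0"
            reactions[rxn_id] = {new_compound(next(formula_stream))}
            pathways[sp_id] = {rxn_id}
        flags[sp_id] = True

    db = PathwayDB(
        compounds,
        {k: frozenset(v) for k, v in reactions.items()},
        {k: frozenset(v) for k, v in pathways.items()},
        flags,
    )
    ground_truth = {
        "formula_unique_pathways": sorted(ground_planted),
        "planted": ground_planted,
        "n_non_chnops": n_non_chnops,
        "n_super_pathways": n_super,
    }
    return db, ground_truth


def generate_noisy_feature(
    true_formula: ChemicalFormula,
    rel_error: float = 0.0,
    tolerance_ppm: float = 5.0,
    label_mode: str = "none",
    seed: int = 0,
    table: IsotopeTable = DEFAULT_ISOTOPE_TABLE,
    noise: str = "uniform",
) -> MeasuredFeature:
    """Simulate one measured feature from a known true formula.

    The mass is perturbed uniformly within the ppm tolerance; the
    isotope ratios are the theoretical values times (1 + eps) with eps
    drawn independently per ratio — uniform on [-rel_error, +rel_error]
    by default (matching the bounded-deviation acceptance band of the
    ratio filter), or Gaussian with sigma = rel_error when
    ``noise="gaussian"``.  SIL atom counts are attached exactly per
    ``label_mode`` in {"none", "c_count", "n_count", "both"}: labeling
    counts atoms without error.
    """
    if rel_error < 0:
        raise ValueError("rel_error must be non-negative")
    if label_mode not in ("none", "c_count", "n_count", "both"):
        raise ValueError(f"unknown label_mode {label_mode!r}")
    if noise not in ("uniform", "gaussian"):
        raise ValueError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    true_mass = monoisotopic_mass(true_formula, table)
    mass = true_mass * (1.0 + rng.uniform(-tolerance_ppm, tolerance_ppm) * 1e-6)
    m1, m2 = formula_ratios(true_formula, table)
    if noise == "uniform":
        eps = rng.uniform(-rel_error, rel_error, size=2)
    else:
        eps = rng.normal(0.0, rel_error, size=2)
    return MeasuredFeature(
        mass=mass,
        tolerance_ppm=tolerance_ppm,
        c_count=true_formula.c if label_mode in ("c_count", "both") else None,
        n_count=true_formula.n if label_mode in ("n_count", "both") else None,
        m1_over_m0=max(m1 * (1.0 + float(eps[0])), 0.0),
        m2_over_m0=max(m2 * (1.0 + float(eps[1])), 0.0),
        ratio_rel_uncertainty=rel_error,
    )
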