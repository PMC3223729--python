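"""Pathway-uniqueness analysis over a compounds/reactions/pathways graph.

A metabolite whose every occurrence maps to a single metabolic pathway
— and that never appears in a reaction unlinked to any pathway — is a
fingerprint for that pathway: detecting it (or even just its chemical
formula, if the formula is equally exclusive) in an untargeted
metabolomics experiment is evidence that the pathway is active, which
can support or extend a genome annotation.

The database model is deliberately generic (flat maps of compounds,
reactions and pathways) rather than tied to any specific curated
database's flat-file dialect; ingest accepts a small JSON document or
three TSV tables.  Aggregate "super-pathways" are flagged so they can
be dropped before uniqueness is computed, since a compound shared
between a pathway and its aggregate is not genuinely ambiguous.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chemspace import ChemicalFormula, FormulaError, format_formula, parse_formula

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayDB:
    """Compounds, reactions and pathways as flat maps.

    ``compounds`` maps a compound id to its CHNOPS formula, or ``None``
    when the compound's formula contains other elements or could not be
    parsed (flagged on ingest, removed by ``restrict_to_chnops``).
    Reactions reference compound ids; pathways reference reaction ids.
    """

    compounds: dict[str, ChemicalFormula | None]
    reactions: dict[str, frozenset[str]]
    pathways: dict[str, frozenset[str]]
    super_pathway_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rxn_id, cpds in self.reactions.items():
            missing = cpds - self.compounds.keys()
            if missing:
                raise ValueError(
                    f"reaction {rxn_id} references unknown compounds {sorted(missing)}"
                )
        for pwy_id, rxns in self.pathways.items():
            missing = rxns - self.reactions.keys()
            if missing:
                raise ValueError(
                    f"pathway {pwy_id} references unknown reactions {sorted(missing)}"
                )

    def is_super(self, pathway_id: str) -> bool:
        return bool(self.super_pathway_flags.get(pathway_id, False))


def restrict_to_chnops(db: PathwayDB) -> PathwayDB:
    """Drop non-CHNOPS compounds and prune now-empty reactions/pathways.

    Compounds flagged on ingest as non-CHNOPS (formula ``None``) are
    removed; reactions left with no compounds and pathways left with no
    reactions are pruned.  Removal counts are logged.
    """
    kept_compounds = {k: v for k, v in db.compounds.items() if v is not None}
    n_dropped = len(db.compounds) - len(kept_compounds)
    reactions = {}
    for rxn_id, cpds in db.reactions.items():
        remaining = frozenset(c for c in cpds if c in kept_compounds)
        if remaining:
            reactions[rxn_id] = remaining
    pathways = {}
    for pwy_id, rxns in db.pathways.items():
        remaining = frozenset(r for r in rxns if r in reactions)
        if remaining:
            pathways[pwy_id] = remaining
    logger.info(
        "CHNOPS restriction removed %d/%d compounds, %d reactions, %d pathways",
        n_dropped,
        len(db.compounds),
        len(db.reactions) - len(reactions),
        len(db.pathways) - len(pathways),
    )
    flags = {p: db.is_super(p) for p in pathways}
    return PathwayDB(kept_compounds, reactions, pathways, flags)


def drop_super_pathways(db: PathwayDB) -> PathwayDB:
    """Remove pathways flagged as aggregates; reactions/compounds stay."""
    pathways = {p: r for p, r in db.pathways.items() if not db.is_super(p)}
    flags = {p: False for p in pathways}
    return PathwayDB(dict(db.compounds), dict(db.reactions), pathways, flags)


@dataclass(frozen=True)
class UniquenessReport:
    """Result of the pathway-uniqueness analysis.

    ``compound_occurrence`` has one row per CHNOPS compound appearing in
    at least one reaction, with its distinct-reaction and
    distinct-pathway occurrence counts and orphan-reaction flag.
    ``unique_metabolites``/``unique_formulae`` map pathway ids to the
    compound ids / formula strings exclusive to that pathway.
    """

    compound_occurrence: pd.DataFrame
    unique_metabolites: dict[str, frozenset[str]]
    unique_formulae: dict[str, frozenset[str]]

    def n_pathways_with_unique_metabolite(self) -> int:
        return sum(1 for v in self.unique_metabolites.values() if v)

    def n_pathways_with_unique_formula(self) -> int:
        return sum(1 for v in self.unique_formulae.values() if v)

    def metabolite_reaction_histogram(self) -> Counter:
        """#compounds present in exactly k distinct reactions, keyed by k."""
        return Counter(self.compound_occurrence["n_reactions"].tolist())

    def metabolite_pathway_histogram(self) -> Counter:
        """#compounds present in exactly k distinct pathways, keyed by k.

        Compounds appearing in orphan (pathway-unlinked) reactions are
        left out of this histogram entirely, mirroring the convention
        that the pathway panel ignores them.
        """
        df = self.compound_occurrence
        eligible = df[(~df["in_orphan_reaction"]) & (df["n_pathways"] > 0)]
        return Counter(eligible["n_pathways"].tolist())

    def formula_pathway_histogram(self) -> Counter:
        """#distinct formulae whose compounds span exactly k pathways."""
        df = self.compound_occurrence
        eligible = df[(~df["in_orphan_reaction"]) & (df["n_pathways"] > 0)]
        spans: dict[str, set[str]] = {}
        for _, row in eligible.iterrows():
            spans.setdefault(row["formula"], set()).update(row["pathway_ids"])
        return Counter(len(v) for v in spans.values())

    def to_frame(self) -> pd.DataFrame:
        """Per-pathway summary: unique metabolite/formula counts and lists."""
        pathway_ids = sorted(
            set(self.unique_metabolites) | set(self.unique_formulae)
        )
        rows = []
        for pwy in pathway_ids:
            mets = sorted(self.unique_metabolites.get(pwy, frozenset()))
            formulae = sorted(self.unique_formulae.get(pwy, frozenset()))
            rows.append(
                {
                    "pathway_id": pwy,
                    "n_unique_metabolites": len(mets),
                    "n_unique_formulae": len(formulae),
                    "unique_metabolites": ";".join(mets),
                    "unique_formulae": ";".join(formulae),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "pathway_id",
                "n_unique_metabolites",
                "n_unique_formulae",
                "unique_metabolites",
                "unique_formulae",
            ],
        )


def uniqueness_analysis(db: PathwayDB) -> UniquenessReport:
    """Find pathway-exclusive metabolites and chemical formulae.

    A metabolite is unique to a pathway iff it occurs in exactly one
    pathway and in no reaction unlinked to any pathway.  A formula is
    unique to a pathway iff every compound bearing it is unique to that
    same pathway.  The input should already be CHNOPS-restricted and
    free of super-pathway aggregates.  With an empty pathway map the
    occurrence table still reports reaction-level counts (useful for
    reaction-only databases).
    """
    reaction_pathways: dict[str, set[str]] = {r: set() for r in db.reactions}
    for pwy_id, rxns in db.pathways.items():
        for rxn_id in rxns:
            reaction_pathways[rxn_id].add(pwy_id)

    compound_reactions: dict[str, set[str]] = {}
    for rxn_id, cpds in db.reactions.items():
        for cpd in cpds:
            compound_reactions.setdefault(cpd, set()).add(rxn_id)

    rows = []
    compound_pathway: dict[str, set[str]] = {}
    in_orphan: dict[str, bool] = {}
    for cpd in sorted(compound_reactions):
        formula = db.compounds[cpd]
        if formula is None:
            continue
        rxns = compound_reactions[cpd]
        pwys: set[str] = set()
        orphan = False
        for rxn_id in rxns:
            linked = reaction_pathways[rxn_id]
            if linked:
                pwys.update(linked)
            else:
                orphan = True
        compound_pathway[cpd] = pwys
        in_orphan[cpd] = orphan
        rows.append(
            {
                "compound_id": cpd,
                "formula": format_formula(formula),
                "n_reactions": len(rxns),
                "n_pathways": len(pwys),
                "in_orphan_reaction": orphan,
                "pathway_ids": tuple(sorted(pwys)),
            }
        )
    occurrence = pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "formula",
            "n_reactions",
            "n_pathways",
            "in_orphan_reaction",
            "pathway_ids",
        ],
    )

    unique_metabolites: dict[str, set[str]] = {p: set() for p in db.pathways}
    for cpd, pwys in compound_pathway.items():
        if len(pwys) == 1 and not in_orphan[cpd]:
            unique_metabolites[next(iter(pwys))].add(cpd)

    # Formula-level: all compounds bearing the formula (anywhere in the
    # reaction network) must be unique to the same single pathway.
    formula_compounds: dict[str, set[str]] = {}
    for cpd in compound_pathway:
        formula_compounds.setdefault(
            format_formula(db.compounds[cpd]), set()
        ).add(cpd)
    unique_formulae: dict[str, set[str]] = {p: set() for p in db.pathways}
    unique_lookup = {
        cpd: pwy for pwy, cpds in unique_metabolites.items() for cpd in cpds
    }
    for formula_str, cpds in formula_compounds.items():
        owners = {unique_lookup.get(cpd) for cpd in cpds}
        if len(owners) == 1:
            owner = next(iter(owners))
            if owner is not None:
                unique_formulae[owner].add(formula_str)

    return UniquenessReport(
        compound_occurrence=occurrence,
        unique_metabolites={p: frozenset(v) for p, v in unique_metabolites.items()},
        unique_formulae={p: frozenset(v) for p, v in unique_formulae.items()},
    )


def _parse_compound_formula(text: str | None) -> ChemicalFormula | None:
    if text is None or not str(text).strip():
        return None
    try:
        return parse_formula(str(text))
    except FormulaError:
        return None


def load_pathway_db_json(path) -> PathwayDB:
    """Load a PathwayDB from a JSON document.

    Schema: ``{"compounds": {id: formula_string}, "reactions":
    {id: [compound ids]}, "pathways": {id: [reaction ids]},
    "super_pathways": [pathway ids]}``.  Formulae that are empty or
    contain non-CHNOPS elements load as flagged (``None``) compounds.
    """
    with open(path) as fh:
        doc = json.load(fh)
    compounds = {
        str(k): _parse_compound_formula(v) for k, v in doc.get("compounds", {}).items()
    }
    reactions = {
        str(k): frozenset(map(str, v)) for k, v in doc.get("reactions", {}).items()
    }
    pathways = {
        str(k): frozenset(map(str, v)) for k, v in doc.get("pathways", {}).items()
    }
    supers = set(map(str, doc.get("super_pathways", [])))
    flags = {p: p in supers for p in pathways}
    return PathwayDB(compounds, reactions, pathways, flags)


def save_pathway_db_json(db: PathwayDB, path) -> None:
    doc = {
        "compounds": {
            k: (format_formula(v) if v is not None else "")
            for k, v in sorted(db.compounds.items())
        },
        "reactions": {k: sorted(v) for k, v in sorted(db.reactions.items())},
        "pathways": {k: sorted(v) for k, v in sorted(db.pathways.items())},
        "super_pathways": sorted(p for p in db.pathways if db.is_super(p)),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_pathway_db_tsv(compounds_path, reactions_path, pathways_path) -> PathwayDB:
    """Load a PathwayDB from three TSV tables.

    ``compounds.tsv``: columns id, formula.  ``reactions.tsv``: columns
    reaction_id, compound_id (one row per membership).  ``pathways.tsv``:
    columns pathway_id, reaction_id, is_super (0/1).
    """
    cpd_df = pd.read_csv(compounds_path, sep="\t", dtype=str)
    rxn_df = pd.read_csv(reactions_path, sep="\t", dtype=str)
    pwy_df = pd.read_csv(pathways_path, sep="\t", dtype={"is_super": int}, converters=None)
    compounds = {
        str(row["id"]): _parse_compound_formula(row.get("formula"))
        for _, row in cpd_df.iterrows()
    }
    reactions: dict[str, set[str]] = {}
    for _, row in rxn_df.iterrows():
        reactions.setdefault(str(row["reaction_id"]), set()).add(str(row["compound_id"]))
    pathways: dict[str, set[str]] = {}
    flags: dict[str, bool] = {}
    for _, row in pwy_df.iterrows():
        pwy = str(row["pathway_id"])
        pathways.setdefault(pwy, set()).add(str(row["reaction_id"]))
        flags[pwy] = flags.get(pwy, False) or bool(int(row["is_super"]))
    return PathwayDB(
        compounds,
        {k: frozenset(v) for k, v in reactions.items()},
        {k: frozenset(v) for k, v in pathways.items()},
        flags,
    )
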