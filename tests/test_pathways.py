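"""Pathway-uniqueness analysis: definitions, invariants, planted recovery."""

import pytest

from silform import (
    PathwayDB,
    drop_super_pathways,
    load_pathway_db_json,
    load_pathway_db_tsv,
    parse_formula,
    restrict_to_chnops,
    uniqueness_analysis,
)
from silform.pathways import save_pathway_db_json
from silform.synthetic import PathwayDBSpec, generate_pathway_db


def make_db(compounds, reactions, pathways, supers=()):
    return PathwayDB(
        compounds={k: (parse_formula(v) if v else None) for k, v in compounds.items()},
        reactions={k: frozenset(v) for k, v in reactions.items()},
        pathways={k: frozenset(v) for k, v in pathways.items()},
        super_pathway_flags={p: p in supers for p in pathways},
    )


@pytest.fixture
def shared_compound_db():
    """Two pathways sharing X, each with one private compound."""
    return make_db(
        compounds={"X": "C6H12O6", "A": "C5H5N5", "B": "C3H7NO2"},
        reactions={"r1": ["X", "A"], "r2": ["X", "B"]},
        pathways={"p1": ["r1"], "p2": ["r2"]},
    )


class TestRestrictToChnops:
    def test_pure_chnops_unchanged(self, shared_compound_db):
        out = restrict_to_chnops(shared_compound_db)
        assert out.compounds.keys() == shared_compound_db.compounds.keys()
        assert out.reactions == shared_compound_db.reactions

    def test_flagged_compounds_removed(self):
        db = make_db(
            compounds={"A": "C2H6O", "B": "", "C": "CH4"},
            reactions={"r1": ["A", "B"], "r2": ["B"], "r3": ["C"]},
            pathways={"p1": ["r1", "r2"], "p2": ["r3"]},
        )
        out = restrict_to_chnops(db)
        assert set(out.compounds) == {"A", "C"}
        # r2 contained only the flagged compound and is pruned
        assert set(out.reactions) == {"r1", "r3"}
        assert set(out.pathways) == {"p1", "p2"}

    def test_generator_fraction_bookkeeping(self):
        spec = PathwayDBSpec(
            n_pathways=8, non_chnops_fraction=0.12, seed=5,
            planted_unique_formula_pathways=2,
        )
        db, truth = generate_pathway_db(spec)
        out = restrict_to_chnops(db)
        assert len(db.compounds) - len(out.compounds) == truth["n_non_chnops"]
        n_expected = round(0.12 * (len(db.compounds) - truth["n_non_chnops"]))
        assert truth["n_non_chnops"] == n_expected


class TestDropSuperPathways:
    def test_no_flags_unchanged(self, shared_compound_db):
        out = drop_super_pathways(shared_compound_db)
        assert out.pathways == shared_compound_db.pathways

    def test_all_flagged_removes_all(self):
        db = make_db(
            compounds={"A": "CH4"},
            reactions={"r1": ["A"]},
            pathways={"p1": ["r1"], "p2": ["r1"]},
            supers=("p1", "p2"),
        )
        assert len(drop_super_pathways(db).pathways) == 0

    def test_mixed_drops_exactly_flagged(self):
        spec = PathwayDBSpec(n_pathways=10, super_pathway_fraction=0.4, seed=6)
        db, truth = generate_pathway_db(spec)
        out = drop_super_pathways(db)
        assert len(db.pathways) - len(out.pathways) == truth["n_super_pathways"]


class TestUniquenessAnalysis:
    def test_private_compounds_are_unique(self, shared_compound_db):
        report = uniqueness_analysis(shared_compound_db)
        assert report.unique_metabolites["p1"] == frozenset({"A"})
        assert report.unique_metabolites["p2"] == frozenset({"B"})
        # shared X is unique to neither
        assert "X" not in report.unique_metabolites["p1"]

    def test_same_formula_in_two_pathways_blocks_formula_uniqueness(self):
        """Distinct private compounds sharing one formula: metabolite-unique
        each, but the formula fingerprints neither pathway."""
        db = make_db(
            compounds={"A": "C5H5N5", "B": "C5H5N5", "S": "C6H12O6"},
            reactions={"r1": ["A", "S"], "r2": ["B", "S"]},
            pathways={"p1": ["r1"], "p2": ["r2"]},
        )
        report = uniqueness_analysis(db)
        assert report.unique_metabolites["p1"] == frozenset({"A"})
        assert report.unique_metabolites["p2"] == frozenset({"B"})
        assert report.unique_formulae["p1"] == frozenset()
        assert report.unique_formulae["p2"] == frozenset()

    def test_orphan_reaction_disqualifies(self):
        """A compound also present in a pathway-unlinked reaction is not unique."""
        db = make_db(
            compounds={"A": "C5H5N5", "B": "C3H7NO2"},
            reactions={"r1": ["A", "B"], "orphan": ["A"]},
            pathways={"p1": ["r1"]},
        )
        report = uniqueness_analysis(db)
        assert "A" not in report.unique_metabolites["p1"]
        assert report.unique_metabolites["p1"] == frozenset({"B"})

    def test_orphan_only_compound_excluded_from_pathway_histogram(self):
        db = make_db(
            compounds={"A": "C5H5N5", "Z": "CH4"},
            reactions={"r1": ["A"], "orphan": ["Z"]},
            pathways={"p1": ["r1"]},
        )
        report = uniqueness_analysis(db)
        histogram = report.metabolite_pathway_histogram()
        assert sum(histogram.values()) == 1  # only A counted
        # but Z still appears in the reaction-level histogram
        assert sum(report.metabolite_reaction_histogram().values()) == 2

    def test_formula_unique_implies_metabolite_unique(self, shared_compound_db):
        report = uniqueness_analysis(shared_compound_db)
        for pwy, formulae in report.unique_formulae.items():
            if formulae:
                assert report.unique_metabolites[pwy]

    def test_histogram_conservation(self):
        spec = PathwayDBSpec(
            n_pathways=12, shared_compound_fraction=0.3,
            planted_unique_formula_pathways=3, seed=8,
        )
        db, _ = generate_pathway_db(spec)
        clean = drop_super_pathways(restrict_to_chnops(db))
        report = uniqueness_analysis(clean)
        histogram = report.metabolite_reaction_histogram()
        assert sum(histogram.values()) == len(report.compound_occurrence)

    def test_reaction_only_database(self):
        """With no pathways the occurrence table still works (reaction mode)."""
        db = make_db(
            compounds={"A": "C5H5N5", "B": "C3H7NO2"},
            reactions={"r1": ["A", "B"], "r2": ["A"]},
            pathways={},
        )
        report = uniqueness_analysis(db)
        occ = report.compound_occurrence.set_index("compound_id")
        assert occ.loc["A", "n_reactions"] == 2
        assert occ.loc["B", "n_reactions"] == 1

    def test_deterministic_under_iteration_order(self, shared_compound_db):
        reversed_db = PathwayDB(
            compounds=dict(reversed(list(shared_compound_db.compounds.items()))),
            reactions=dict(reversed(list(shared_compound_db.reactions.items()))),
            pathways=dict(reversed(list(shared_compound_db.pathways.items()))),
            super_pathway_flags=dict(shared_compound_db.super_pathway_flags),
        )
        a = uniqueness_analysis(shared_compound_db)
        b = uniqueness_analysis(reversed_db)
        assert a.unique_metabolites == b.unique_metabolites
        assert a.unique_formulae == b.unique_formulae
        assert a.compound_occurrence.equals(b.compound_occurrence)


class TestPlantedRecovery:
    @pytest.mark.parametrize("k", [0, 1, 5])
    def test_recovers_exactly_planted_pathways(self, k):
        spec = PathwayDBSpec(
            n_pathways=10,
            shared_compound_fraction=0.3,
            planted_unique_formula_pathways=k,
            non_chnops_fraction=0.1,
            super_pathway_fraction=0.2,
            seed=13 + k,
        )
        db, truth = generate_pathway_db(spec)
        clean = drop_super_pathways(restrict_to_chnops(db))
        report = uniqueness_analysis(clean)
        found = sorted(
            p for p, formulae in report.unique_formulae.items() if formulae
        )
        assert found == truth["formula_unique_pathways"]
        assert len(found) == k

    def test_formula_unique_at_most_metabolite_unique(self):
        for seed in range(5):
            spec = PathwayDBSpec(
                n_pathways=9,
                shared_compound_fraction=0.4,
                planted_unique_formula_pathways=2,
                seed=seed,
            )
            db, _ = generate_pathway_db(spec)
            report = uniqueness_analysis(drop_super_pathways(restrict_to_chnops(db)))
            assert (
                report.n_pathways_with_unique_formula()
                <= report.n_pathways_with_unique_metabolite()
            )


class TestValidationAndIO:
    def test_dangling_references_rejected(self):
        with pytest.raises(ValueError):
            make_db(
                compounds={"A": "CH4"},
                reactions={"r1": ["A", "MISSING"]},
                pathways={},
            )
        with pytest.raises(ValueError):
            make_db(
                compounds={"A": "CH4"},
                reactions={"r1": ["A"]},
                pathways={"p1": ["ghost"]},
            )

    def test_json_round_trip(self, tmp_path, shared_compound_db):
        path = tmp_path / "db.json"
        save_pathway_db_json(shared_compound_db, path)
        loaded = load_pathway_db_json(path)
        assert loaded.compounds == shared_compound_db.compounds
        assert loaded.reactions == shared_compound_db.reactions
        assert loaded.pathways == shared_compound_db.pathways

    def test_tsv_ingest(self, tmp_path):
        (tmp_path / "compounds.tsv").write_text(
            "id\tformula\nA\tC5H5N5\nB\tC2H6OFe\n"
        )
        (tmp_path / "reactions.tsv").write_text(
            "reaction_id\tcompound_id\nr1\tA\nr1\tB\n"
        )
        (tmp_path / "pathways.tsv").write_text(
            "pathway_id\treaction_id\tis_super\np1\tr1\t0\n"
        )
        db = load_pathway_db_tsv(
            tmp_path / "compounds.tsv",
            tmp_path / "reactions.tsv",
            tmp_path / "pathways.tsv",
        )
        assert db.compounds["A"] == parse_formula("C5H5N5")
        assert db.compounds["B"] is None  # iron-bearing, flagged on ingest
        assert not db.is_super("p1")
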