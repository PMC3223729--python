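"""Isotopologue distributions: exact multinomials, convolution, ratios."""

import math

import numpy as np
import pytest

from silform import (
    DEFAULT_ISOTOPE_TABLE,
    ChemicalFormula,
    batch_ratios,
    element_distribution,
    molecular_pattern,
    parse_formula,
    relative_ratios,
)
from silform.isotopes import IsotopePattern, formula_ratios

from conftest import random_formulae

TABLE = DEFAULT_ISOTOPE_TABLE
P13 = TABLE["C"][1].abundance
P12 = TABLE["C"][0].abundance


def per_atom_plus1_ratio(symbol: str) -> float:
    isos = TABLE[symbol]
    plus1 = next((i for i in isos if i.neutron_offset == 1), None)
    return 0.0 if plus1 is None else plus1.abundance / isos[0].abundance


class TestElementDistribution:
    def test_phosphorus_monoisotopic(self):
        dist = element_distribution("P", 5, max_offset=5)
        assert dist.probabilities[0] == pytest.approx(1.0, abs=1e-12)
        assert sum(dist.probabilities[1:]) == 0.0

    def test_single_carbon_is_abundance_vector(self):
        dist = element_distribution("C", 1, max_offset=2)
        assert dist.probabilities[0] == pytest.approx(P12)
        assert dist.probabilities[1] == pytest.approx(P13)

    def test_ten_carbons_binomial_closed_form(self):
        dist = element_distribution("C", 10, max_offset=2)
        assert dist.probabilities[1] == pytest.approx(
            10 * P13 * P12**9, rel=1e-12
        )
        assert dist.probabilities[2] == pytest.approx(
            math.comb(10, 2) * P13**2 * P12**8, rel=1e-12
        )

    def test_sulfur_mixed_offsets(self):
        # offset 2 for S mixes one 34S against two 33S
        isos = {i.neutron_offset: i.abundance for i in TABLE["S"]}
        dist = element_distribution("S", 3, max_offset=2)
        expected_2 = 3 * isos[2] * isos[0] ** 2 + 3 * isos[1] ** 2 * isos[0]
        assert dist.probabilities[2] == pytest.approx(expected_2, rel=1e-12)

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            element_distribution("Fe", 2)

    def test_zero_atoms_is_identity(self):
        dist = element_distribution("O", 0, max_offset=3)
        assert dist.probabilities[0] == 1.0
        assert sum(dist.probabilities[1:]) == 0.0


class TestMolecularPattern:
    def test_single_carbon_ratio(self):
        m1, m2 = relative_ratios(molecular_pattern(ChemicalFormula(c=1, h=0)))
        assert m1 == pytest.approx(P13 / P12, rel=1e-12)
        assert m2 == pytest.approx(0.0, abs=1e-12)

    def test_m0_is_all_lightest_product(self):
        rng = np.random.default_rng(23)
        for f in random_formulae(rng, 20):
            pattern = molecular_pattern(f)
            expected = math.prod(
                TABLE[e][0].abundance ** k for e, k in zip("CHNOSP", f.counts())
            )
            assert pattern.probabilities[0] == pytest.approx(expected, rel=1e-12)

    def test_m1_single_substitution_closed_form(self):
        """Convolved M1/M0 equals sum of per-element count * (p+1 / p0)."""
        f = parse_formula("C4H4N4O4S4P4")
        m1, _ = relative_ratios(molecular_pattern(f))
        expected = sum(
            k * per_atom_plus1_ratio(e) for e, k in zip("CHNOSP", f.counts())
        )
        assert m1 == pytest.approx(expected, abs=1e-9)

    def test_m1_closed_form_random(self):
        rng = np.random.default_rng(29)
        for f in random_formulae(rng, 100):
            m1, _ = relative_ratios(molecular_pattern(f))
            expected = sum(
                k * per_atom_plus1_ratio(e) for e, k in zip("CHNOSP", f.counts())
            )
            assert m1 == pytest.approx(expected, abs=1e-9)

    def test_conservation_small_molecules(self):
        rng = np.random.default_rng(31)
        for f in random_formulae(rng, 10):
            total = molecular_pattern(f, max_offset=20).total()
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_convolution_is_commutative(self):
        # the same multiset of atoms split across two formula orderings
        f = parse_formula("C10H13N5O4S2")
        a = molecular_pattern(f)
        parts = [ChemicalFormula(c=10), ChemicalFormula(h=13), ChemicalFormula(n=5),
                 ChemicalFormula(o=4), ChemicalFormula(s=2)]
        probs = np.zeros(6)
        probs[0] = 1.0
        for part in reversed(parts):
            pattern = np.asarray(molecular_pattern(part).probabilities)
            probs = np.convolve(probs, pattern)[:6]
        assert np.abs(np.asarray(a.probabilities) - probs).max() < 1e-12

    def test_oracle_agreement_pyteomics(self):
        """Full patterns match an independent isotopologue enumerator."""
        pmass = pytest.importorskip("pyteomics.mass")
        light = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32, "P": 31}
        rng = np.random.default_rng(37)
        caps = (20, 30, 3, 6, 2, 1)
        formulae = []
        while len(formulae) < 20:
            counts = tuple(int(rng.integers(0, c + 1)) for c in caps)
            if sum(counts) >= 1:
                formulae.append(ChemicalFormula(*counts))
        for f in formulae:
            agg = np.zeros(6)
            composition = {
                e: k for e, k in zip("CHNOSP", f.counts()) if k > 0
            }
            for comp, ab in pmass.isotopologues(
                composition,
                report_abundance=True,
                overall_threshold=1e-8,
                isotope_threshold=1e-8,
            ):
                off = sum(
                    (int(key.split("[")[1][:-1]) - light[key.split("[")[0]]) * cnt
                    for key, cnt in comp.items()
                )
                if off < 6:
                    agg[off] += ab
            mine = np.asarray(molecular_pattern(f).probabilities)
            assert np.abs(mine - agg).max() < 1e-4

    def test_max_offset_must_allow_m2(self):
        with pytest.raises(ValueError):
            molecular_pattern(parse_formula("CH4"), max_offset=1)

    def test_fine_binning_preserves_mass_and_probability(self):
        f = parse_formula("C6H12O6")
        fine = molecular_pattern(f, bin_width=0.001)
        unit = molecular_pattern(f)
        assert fine.mass_bin_centers is not None
        # fine mode keeps cross-element terms the stepwise unit-mode
        # truncation drops, so its total is never smaller
        assert fine.total() >= unit.total() - 1e-12
        assert fine.total() == pytest.approx(1.0, abs=1e-6)
        # the M1 cluster (13C vs 2H vs 15N substitutions) splits in fine mode
        n_fine_peaks = sum(1 for p in fine.probabilities if p > 1e-10)
        assert n_fine_peaks > len([p for p in unit.probabilities if p > 1e-10])


class TestRelativeRatios:
    def test_monoisotopic_only(self):
        m1, m2 = relative_ratios(molecular_pattern(ChemicalFormula(p=1)))
        assert (m1, m2) == (0.0, 0.0)

    def test_plain_arithmetic(self):
        pattern = IsotopePattern(probabilities=(1.0, 0.1, 0.02), max_offset=2)
        assert relative_ratios(pattern) == (pytest.approx(0.1), pytest.approx(0.02))

    def test_independent_of_normalization(self):
        f = parse_formula("C5H5N5")
        pattern = molecular_pattern(f)
        assert relative_ratios(pattern) == relative_ratios(pattern.relative_to_m0())

    def test_zero_m0_is_an_error(self):
        with pytest.raises(ValueError):
            relative_ratios(
                IsotopePattern(probabilities=(0.0, 0.1, 0.0), max_offset=2)
            )


class TestBatchRatios:
    def test_matches_convolution(self):
        rng = np.random.default_rng(41)
        formulae = random_formulae(rng, 50)
        counts = np.array([f.counts() for f in formulae])
        m1_batch, m2_batch = batch_ratios(counts)
        for i, f in enumerate(formulae):
            m1, m2 = formula_ratios(f)
            assert m1_batch[i] == pytest.approx(m1, rel=1e-9, abs=1e-12)
            assert m2_batch[i] == pytest.approx(m2, rel=1e-9, abs=1e-12)

    def test_empty_input(self):
        m1, m2 = batch_ratios(np.empty((0, 6), dtype=int))
        assert len(m1) == 0 and len(m2) == 0
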