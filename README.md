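# silform

Chemical-formula degeneracy analysis for untargeted metabolomics.

## The problem

Untargeted mass-spectrometry metabolomics measures accurate masses of
unknown compounds. Assigning a chemical formula to a measured mass is the
first step toward identifying the metabolite — and, because many
metabolites (or even just their formulae) occur in a single metabolic
pathway, toward using metabolomics as evidence for genome annotation.
But mass is a one-dimensional projection of a six-dimensional chemical
space: restricting to the biologically dominant elements, every candidate
is a formula C<sub>a</sub>H<sub>b</sub>N<sub>c</sub>O<sub>x</sub>S<sub>y</sub>P<sub>z</sub>,
and under typical per-element bounds (C, H ∈ [1, 200], N, S, P ∈ [0, 6],
O ∈ [0, 20]) the space holds 288,120,000 formulae. Within a ±5 ppm
instrument window a single mass is usually *degenerate*: many distinct
formulae fit.

`silform` quantifies that degeneracy and compares three ways of resolving

1. **mass only** — enumerate every in-range formula whose neutral
   monoisotopic mass falls in the ppm window;
2. **mass + isotope ratios** — additionally require a candidate's
   predicted natural-abundance M1/M0 and M2/M0 isotopologue intensity
   ratios to match the measured ones within a relative uncertainty;
3. **mass + SIL** — stable-isotope labeling: growing cultures on
   uniformly ¹³C- or ¹⁵N-enriched media shifts each feature by one mass
   unit per C (or N) atom, so the C and N atom counts are known exactly
   and candidates must match both.

It also analyses a pathway database (compounds → reactions → pathways)
to find metabolites and formulae unique to a single pathway — usable as
pathway fingerprints.

## What is inside

| module | contents |
| --- | --- |
| `silform.chemspace` | `ChemicalFormula`, `ElementRanges`, pinned isotope table, monoisotopic masses, ppm windows, formula parsing |
| `silform.enumeration` | brute-force and heuristic-filtered formula enumeration in a mass window, search-space sizing, degeneracy counts |
| `silform.isotopes` | exact multinomial isotopologue distributions per element, convolved molecular patterns, M1/M0 & M2/M0 ratios |
| `silform.constraints` | SIL (C/N-count) and isotope-ratio candidate filters; the three-regime comparison |
| `silform.pathways` | pathway-uniqueness analysis over a generic compounds/reactions/pathways schema |
| `silform.synthetic` | seeded generators for compound libraries, pathway databases with planted ground truth, and noisy features |
| `silform.cli`, `silform.reporting` | `silform` command line and the end-to-end report bundle |

## Worked example: folate

```python
from silform import (parse_formula, monoisotopic_mass, ppm_window,
                     enumerate_brute_force, ElementRanges, degeneracy,
                     filter_by_cn, filter_by_ratios)
from silform.isotopes import formula_ratios

folate = parse_formula("C19H19N7O6")
mass = monoisotopic_mass(folate)          # 441.1397 Da
cset = enumerate_brute_force(ppm_window(mass, 5), ElementRanges(n=(0, 7)))
print(len(cset), degeneracy(cset, folate))
# 261 260   -> 260 other formulae share folate's mass within 5 ppm

print(len(filter_by_cn(cset, c_count=19, n_count=7)))
# 1         -> knowing "19 C and 7 N" (SIL) leaves only folate itself

print(len(filter_by_ratios(cset, formula_ratios(folate), 0.10)))
# 2         -> matching M1/M0 and M2/M0 within 10% leaves 2 candidates
```

So accurate mass alone leaves 260 impostors; exact C/N counts collapse
the set to the single true formula, while isotope-ratio matching at a
realistic 10% intensity uncertainty still leaves ambiguity. (The
nitrogen bound is widened to 7 here because folate itself has seven
nitrogen atoms, one above the standard library bound.)

On a synthetic library of formulae heavier than 500 Da the same
comparison, run over every library member, shows the SIL regime
producing a strictly smaller candidate set than the ratio regime for the
large majority of masses at 10% ratio uncertainty — while at 0%
uncertainty the ratios alone are essentially always unique.

## Command line

```sh
silform enumerate --mass 441.1397 --ppm 5 --out candidates.csv
silform isotopes --formula C19H19N7O6
silform simulate library --seed 42 --out lib.tsv
silform degeneracy --library lib.tsv --ppm 5 --ratio-tol 0.10 --seed 1 --out summary.csv
silform pathways --db db.json --out report.tsv
silform full --seed 42 --out-dir run/
```

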