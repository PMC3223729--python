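# Methods

## Chemical space and masses

A formula is a vector of six non-negative integer atom counts
(C, H, N, O, S, P); at least one count must be positive. The search
space is a box of per-element bounds; the default box
(C, H ∈ [1, 200], N ∈ [0, 6], O ∈ [0, 20], S ∈ [0, 6], P ∈ [0, 6])
contains 288,120,000 count vectors and is meant to cover small-molecule
metabolites. All masses are neutral monoisotopic masses: the sum of
each element's lightest-isotope mass times its count. No adducts,
charge states or electron-mass corrections are modeled anywhere; users
must deconvolute ions to neutral masses upstream.

Isotope masses and natural abundances are pinned as a versioned
constant (`DEFAULT_ISOTOPE_TABLE`, tag `NIST-2018`), with masses to 7
decimals and abundances as published by NIST (e.g. ¹³C abundance
0.0107, ³⁴S 0.0425). Nothing is fetched at run time, so all computed
masses and patterns are bit-reproducible. Fourth-decimal abundance
differences between published tables exist; they shift M1/M0 ratios by
well under the 10% uncertainty band used in the analysis.

A mass window is symmetric and relative to the *target* mass:
[m·(1 − ppm·10⁻⁶), m·(1 + ppm·10⁻⁶)]. The tolerance is a half-width
(±5 ppm means a window of width 10 ppm), the usual instrument
convention.

## Formula enumeration

`enumerate_brute_force` is contractually equal to the naive six-nested
loop over the element box, keeping formulae whose mass lies in the
window. The implementation instead iterates the heteroatom
combinations (N, O, S, P — at most 7·21·7·7 = 7203 under the default
box), adds each candidate carbon count, and solves the remaining
one-dimensional problem for integer hydrogen counts with vectorized
arithmetic. Two numerical guards keep this exactly equivalent to the
naive loop: the integer bounds derived with `ceil`/`floor` are widened
by one count and every emitted candidate is re-tested against the
exact window with the same mass function and comparisons the naive
loop uses; and the carbon range is only ever narrowed by *sound*
bounds (a candidate in the window cannot carry more carbon mass than
the window top minus the minimal heteroatom and hydrogen mass).
Equivalence is enforced in the test suite against a materialized
full-grid enumeration over reduced ranges on 120 random windows.

Candidates are ordered by absolute ppm error with ties broken
lexicographically on the count tuple, so outputs diff cleanly.

Degeneracy of a candidate set built around a known formula is the
number of *other* candidates (set size minus one): "one degeneracy"
means one impostor exists.

### Heuristic filters

`enumerate_filtered` applies optional plausibility heuristics of the
kind used by restricted formula generators: inclusive element-ratio
bounds (defaults are the "common range" values H/C 0.2–3.1, N/C 0–1.3,
O/C 0–1.2, P/C 0–0.3, S/C 0–0.8), a ring/double-bond-equivalent floor
(RDBE = c − h/2 + n/2 + p/2 + 1 ≥ 0 by default), and optionally an
integer-RDBE parity requirement. The defaults are deliberately
configuration, not truth: the stock O/C ceiling of 1.2 excludes real
metabolites such as ATP (O/C 1.3), taurine (1.5) and malate (1.25).
Ratio checks are skipped for carbon-free formulae (no ratio is
defined); disabling the config reproduces the brute-force set exactly.
When a filter rejects the true formula during the regime comparison the
event is counted and surfaced as a warning rather than silently
producing an empty result.

## Isotopologue patterns

For one element with isotope abundances p_i and neutron offsets d_i,
the distribution of total extra neutrons over n atoms is the exact
multinomial: P(offset = d) = Σ over count vectors k (Σk_i = n,
Σk_i·d_i = d) of n!/(Πk_i!)·Πp_i^{k_i}. Configurations are enumerated
exactly (integer multinomial coefficients, no normal or polynomial
approximation); per-element results are cached. The molecular pattern
is the discrete convolution of the six element vectors.

Binning is by integer neutron offset by default (M0, M1, M2, …),
matching unit-resolution instruments and the M1/M0, M2/M0 analysis; a
fine mode bins exact configuration masses on a fixed-width mass axis
instead and resolves e.g. the ¹³C vs ¹⁵N substitution splitting.
Truncation keeps offsets ≤ 5 by default with a 10⁻¹² per-bin floor;
for CHNOPS molecules under ~2000 Da this leaves M0–M2 exact to well
below 10⁻⁹, and with the truncation raised to 20 the full pattern of a
small molecule sums to 1 within 10⁻⁹ (tested). Note the stepwise
truncation during unit-mode convolution discards cross-element terms
beyond the cutoff, so the retained total is a lower bound on the true
cumulative probability.

Candidate scoring uses exact closed forms derived from the same
per-element vectors: M1/M0 = Σ_e A1_e/A0_e and
M2/M0 = Σ_e A2_e/A0_e + Σ_{e<f} (A1_e/A0_e)(A1_f/A0_f), where A_d is
the element's offset-d probability over its atom count. These are
identities (an offset-1 molecular peak is exactly one +1 substitution;
an offset-2 peak is one within-element offset-2 pattern or two +1
substitutions in distinct elements) and agree with the convolution to
float precision (property-tested); they let thousands of candidates be
scored with table lookups.

## Constraint regimes

* **SIL filter**: retain candidates whose C and N counts equal the
  measured ones. Labeling is modeled as error-free atom counting; the
  mass shift between labeled and unlabeled cultures counts atoms
  discretely, so fractional errors do not accumulate the way intensity
  errors do. Partial labeling efficiency and isotope effects are out of
  scope.
* **Ratio filter**: retain candidates with
  |predicted_k − observed_k| ≤ u·observed_k for both k ∈ {M1/M0, M2/M0}
  jointly (AND). The uncertainty u is an acceptance band, not a noise
  draw. When an observed ratio is exactly zero the candidate's
  prediction must fall below an absolute floor of 10⁻⁹. A relative
  float-equality guard of 10⁻⁹ is added to the band so that a
  zero-width (u = 0) filter accepts a prediction equal to the
  observation up to rounding — predictions may come from the
  convolution or the closed-form route, which agree to ~1 ulp, while
  distinct formulae in one window differ in M1/M0 by several orders of
  magnitude more than that.

`compare_regimes` samples formulae from a library, enumerates each
one's 5 ppm window, and counts survivors under each regime, taking the
true formula's own noise-free theoretical ratios as the observation.
Winners (strictly fewer survivors for SIL, for ratios, or a tie) are
reported as three disjoint fractions and stratified into 100 Da mass
bins over 50–2000 Da; the 0/1/≥2-degeneracy stratification per regime
is reported alongside. An optional noisy mode (via
`generate_noisy_feature`) exists for robustness studies but is not part
of the headline comparison.

## Pathway uniqueness

The database model is three flat maps: compound → formula,
reaction → compound set, pathway → reaction set, plus a super-pathway
flag for aggregate pathways. Ingest accepts JSON or three TSVs;
formulae containing elements outside CHNOPS (or unparseable ones) are
flagged on load and removed by `restrict_to_chnops`, which then prunes
empty reactions and pathways and logs every removal. Native flat-file
dialects of specific curated databases are deliberately not parsed —
the analysis is database-agnostic and the dialects drift between
releases.

A metabolite is unique to a pathway iff it occurs in exactly one
pathway and in no reaction unlinked to any pathway. A formula is
unique to a pathway iff every compound bearing it is unique to that
same pathway ("same formula" is the identity of the count vector). A
pathway with a unique formula therefore always has a unique
metabolite, and the number of formula-unique pathways can never exceed
the number of metabolite-unique pathways — asserted as an invariant on
every synthetic database. Occurrence histograms (compounds present in
exactly k reactions / k pathways) are reported; compounds appearing
only in pathway-unlinked reactions are excluded from the pathway
histogram but kept in the reaction histogram. With an empty pathway
map the same operation yields reaction-level occurrence counts, which
covers reaction-only databases.

## Synthetic data

The generators define the study conditions:

* **Library**: element counts drawn uniformly per element inside the
  box, rejection-filtered to a mass band (default 50–2000 Da),
  de-duplicated; optionally a minimum pairwise mass separation in ppm
  is enforced. The headline comparison uses 320 formulae in
  500–2000 Da under the default box. Uniform count sampling does not
  match the empirical formula-frequency distribution of real compound
  databases (it over-weights heteroatom-rich corners); the claims
  tested on these libraries are structural — subset relations,
  monotonicity, directional dominance — not distributional, and the
  directional result is seed-robust in practice.
* **Pathway DB**: a configurable number of pathways, reactions per
  pathway and compounds per reaction; a fraction of compound slots is
  filled from a pool shared across ≥2 pathways; exactly k chosen
  pathways are planted with a private compound whose formula occurs
  nowhere else, and the private formulae of all other pathways are
  deliberately duplicated across pathways so they cannot be
  formula-unique — making the planted ground truth exactly
  recoverable. Optional non-CHNOPS filler compounds and super-pathway
  aggregates (carved out of the pathway count, so a fraction of 1
  leaves nothing after dropping them) exercise the ingest filters.
* **Features**: measured mass uniform within ±ppm of truth; ratios
  multiplied by (1 + ε) with ε uniform on [−r, +r] per ratio — a
  bounded multiplicative model chosen to mirror the filter's
  bounded-deviation acceptance band (a Gaussian option exists for
  sensitivity studies); SIL counts attached exactly.

All generators are deterministic functions of their seed.

## Problem sizes and determinism

The shipped analyses run at desk scale: 320-formula libraries for the
regime comparison, 120 random windows for the enumerator-equivalence
check over reduced ranges (C, H ≤ 30; N, O, S, P ≤ 3), 100 random
formulae for the closed-form M1 identity, 20 for the external-oracle
pattern comparison, and 12-pathway synthetic databases. Every script
and test seeds its generators explicitly; the acceptance script derives
all randomness from its `--seed` argument.

## Known limitations

* Neutral masses only: adduct and charge handling, retention time and
  fragmentation evidence are out of scope.
* Isotopic fine structure is available only through the fine binning
  mode; the headline analysis is unit-resolution by construction.
* The SIL model assumes complete, uniform labeling; real labeling
  efficiency below 100% would blur the C/N counts.
* The default nitrogen bound (≤ 6) excludes some real metabolites —
  folate itself carries 7 nitrogens, which is why the worked example
  widens that bound; bounds are parameters, not facts.
* Synthetic libraries are structurally, not distributionally,
  realistic (see above); absolute percentages measured on them are not
  estimates of any real database's values, only the directional
  comparisons are.
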