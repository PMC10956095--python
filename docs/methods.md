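# Methods

This note documents the models implemented in flavokit, the conventions and
thresholds they use, what the synthetic-data generators emulate, and the
design choices made where the design was genuinely open.

## Conceptual-DFT reactivity descriptors

All global descriptors derive from a vertical ionization potential *I* and
electron affinity *A* in eV:

| quantity | formula | units |
|---|---|---|
| electronegativity χ | (I+A)/2 | eV |
| chemical potential μ | −χ | eV |
| global hardness η | (I−A)/2 | eV |
| HOMO–LUMO gap ΔE | E_HOMO − E_LUMO (= −(I−A) under Koopmans) | eV |
| electrophilicity ω | μ²/2η | eV |
| global softness s | 1/2η | eV⁻¹ |
| nucleophilicity ε | μ·η | eV² |

Conventions worth spelling out:

* **Softness.** Both 1/η and 1/(2η) circulate in the literature. The
  packaged reference table is only internally consistent with 1/(2η)
  (e.g. s = 16.67 for η = 0.03 eV), so that is the default;
  `softness_convention="inverse_eta"` selects the other.
* **Nucleophilicity.** There is no universally agreed closed form; ε = μ·η
  is the relation that reproduces every tabulated reference value and is
  documented as inferred, not derived.
* **Input precedence.** When a record carries both orbital energies and a
  printed (I, A) pair, the printed pair wins. Some literature rows tabulate
  (I, A) values that are not the Koopmans negatives of the same row's
  orbital energies (ΔSCF-style values, or transcription artefacts); treating
  the printed pair as authoritative is the only reading that keeps those
  rows self-consistent. The reported gap is E_HOMO − E_LUMO when the
  Koopmans path is taken (or the printed pair is Koopmans-consistent) and
  −(I−A) otherwise, so gap and hardness never disagree.
* **Rounding.** All intermediates are full-precision floats; rounding
  happens once, at the report boundary, to 2 decimals with ties away from
  zero. Because floats store exact decimal ties inexactly (3.535 is stored
  as 3.53499…97), values are first quantised at 9 decimals. Several
  reference values (η = 3.54, ε = −0.36) are reproducible only with
  unrounded intermediates.
* **Degenerate hardness.** I = A makes ω, s and ε undefined; this raises a
  dedicated error rather than returning infinities.
* **Ranking.** `rank_by_gap` sorts by |ΔE| descending (hard/least-reactive
  first) with a deterministic alphabetical tie-break.

## Flavonoid perception and the RSA QSAR

Scaffold perception is substructure matching (RDKit) against the flavanone
(2-phenylchroman-4-one) and flavone (2-phenylchromen-4-one) templates;
flavonol = flavone + 3-OH. Locants follow standard flavonoid numbering.
The pendant B ring maps onto the template two ways; the mapping whose
substituent locant list sorts first is reported (so a 3′,4′-catechol is
never reported as 4′,5′), while symmetry-dependent flags are evaluated over
all mappings. Substituents recognised on scaffold carbons: OH, OMe, =O,
other-OR, other. Dihydroflavonols (taxifolin) match the flavanone template
and are reported as flavanones with `has_3_OH=True`; the flavonol class is
reserved for the unsaturated scaffold, matching how the indicator variable
uses the flags.

The RSA regression is the reduced indicator form RSA = intercept +
slope·I. Only its value at I = 1 (88.403 %) is anchored by a
machine-readable source — the full regression was published as an image —
so the coefficient split is a transcription input constrained by
intercept + slope = 88.403, enforced at config load. Defaults are
(0.0, 88.403); a transcribed intercept/slope pair can be substituted in
config without code change. The original Amić-type equation contains terms
beyond the indicator; this package implements the two-coefficient reduced
form only and flags it as such.

Rule of five: the oxygen-count variant (MW < 500 g/mol, MLOGP ≤ 4.15,
O atoms < 10, NH+OH hydrogens < 5) is the default because it is the form
used in the flavonoid pharmacokinetics narrative this package reproduces;
`variant="canonical"` switches the third rule to the usual N+O acceptor
count. MLOGP is always an external input (the Moriguchi model is out of
scope); when absent the rule reports "not evaluated", never a violation.
Molecular weights use standard atomic weights (C 12.011, H 1.008, N 14.007,
O 15.999) over all atoms including implicit hydrogens.

## Vibrational scaling and Fermi-resonance search

Two-region scaling: factor 0.967 below the 1800 cm⁻¹ boundary, 0.955
at/above, rounded to integer cm⁻¹ with ties away from zero. The boundary
case is unobservable in the packaged reference spectrum (no mode between
1744 and 2997 cm⁻¹); the `< boundary` convention is documented rather than
empirically fixed. Half-away rounding is likewise a convention choice: the
reference column never exercises an exact .5.

Peak assignment (`match_peaks`) maximises the number of within-tolerance
computed↔experimental pairs, then minimises the total |Δ| (solved as a
rectangular linear assignment problem with forbidden cells). Equal-total
optima are common — swapping two pairs on the same side of their peaks
leaves the total unchanged — so a vanishing secondary objective (squared
index offset) deterministically prefers the non-crossing assignment. The
default tolerance of 15 cm⁻¹ reflects the largest scaled-vs-observed gap in
well-matched reference rows; it is configurable.

The Fermi search enumerates combination pairs (b_i + b_j, i ≤ j,
repetition allowed) and overtones (n·b, 2 ≤ n ≤ max order) within a
tolerance of the target band, sorted by deviation. No intensity model is
applied (none is available from the inputs): the search reports candidates,
not assignments. For the packaged blumeatin band list the observed
fundamentals at 528 and 1089 cm⁻¹ sum to 1617 cm⁻¹, within 2 cm⁻¹ of the
split 1615 cm⁻¹ carbonyl band, while no order-2/3 overtone lands within
5 cm⁻¹ — the combination-band reading of the splitting. Note the search is
exhaustive, so other arithmetically valid pairs from the same band list
(e.g. 499 + 1118 = 1617) are reported alongside; selecting among candidates
requires intensity or symmetry information outside this package's scope.
The packaged band list is the assignment table's experimental column plus
five observed bands not listed there (1089, the 1603/1635 satellites, 3189,
3367), kept separable via `include_extra=False`.

`estimate_scale_factor` is the least-squares slope through the origin,
Σce/Σc²; under Gaussian noise its standard error is sd/√Σc², which the
parameter-recovery tests check as a calibration property over fixed seeds.

## Protein–ligand contacts

Hydrogen bonds are heavy-atom N/O···N/O pairs across the ligand–protein
interface with donor–acceptor distance in [2.0, 4.1] Å — no hydrogen
positions are required, matching docking outputs that lack them. Strength
bins: < 2.2 very strong (almost covalent), [2.2, 2.5) strong, [2.5, 3.2)
moderate, [3.2, 4.1] weak. The weak bin's upper edge is 4.1 Å rather than
the textbook 4.0 so that reference contacts printed at 4.04 Å classify as
weak; sub-2.2 Å contacts are labelled very strong following the language
used for a reference 2.03 Å contact. Hydrophobic contacts are
carbon–carbon pairs within 5.5 Å (covering printed π-alkyl distances up to
5.22 Å), reported once per residue at the minimal distance. Typed aromatic
interactions (π–π, π–σ, π-alkyl, amide-π, π-sulfur) require ring-plane
perception and are deliberately not detected; reports carry an explicit
scope note. Residue identity is (chain, number, name); insertion codes and
altlocs other than blank/'A' are ignored; waters are dropped; non-ligand
heteroatoms are treated as receptor atoms with a warning.

## Geometry

Dihedrals use the standard two-normal atan2 construction, degrees in
(−180, 180], IUPAC sign. The signed dihedral is symmetric under reversing
the atom order and antisymmetric under mirror reflection — both are tested,
alongside rigid-motion invariance and an independent library cross-check.
Planarity: coplanar iff the angle is within a threshold (default 20°) of 0
or 180°. Literature usage of "twisted" is inconsistent around ~16°, so the
threshold is prominently configurable and reports always carry the raw
angle.

## ADME/Tox interpretation

All rules are listed in the module docstring; the non-obvious choices:

* Solubility bins are closed on the moderate side (−4 ≤ logS ≤ −3) so a
  value of exactly −3 or −4 stays "moderately soluble".
* The Caco-2 value is compared unit-free against the 0.90 threshold, as the
  source narrative does (predictors report log Papp; the units of the
  printed threshold are unstated).
* VDss bins are applied as stated (low < −0.15, high > 0.45, else
  intermediate). Cited interpretations sometimes call intermediate-band
  values "high"; intermediate calls therefore carry a divergence note so
  both readings stay visible. This is the one deliberate divergence from
  the reference narrative.
* The oral rat LD50 has no threshold rule in the sources interpreted here;
  it is carried as an informational call.

## Synthetic data: what it does and does not emulate

The generators produce inputs with the *structure* each stage assumes, not
physically realistic chemistry:

* `gen_orbital_table` guarantees E_HOMO < E_LUMO (η > 0) with uniform
  energies — no correlation structure between compounds.
* `gen_spectrum` draws computed wavenumbers uniformly on [400, 1800] cm⁻¹
  and applies experimental = factor·computed + Gaussian noise — a single
  global factor, no mode-dependent anharmonicity, no missing peaks.
* `gen_complex` writes minimal PDB records (one polar ligand oxygen, two
  ligand carbons, one contact atom per planted residue, far decoys) laid
  out in the z = 0 plane so the 3-decimal coordinate grid keeps each
  realised distance within 0.001 Å of the request. There is no protein
  geometry, sterics or secondary structure.

Passing round-trip tests therefore demonstrates correctness of the
*detection and classification logic* under the stated geometric
definitions, not performance on real crystal structures or docking poses.

Problem sizes used by the test suite and acceptance script — an 11-row
descriptor table, a 102-mode spectrum, band lists of ~60 entries,
complexes with ≤ 6 planted contacts, oracle sweeps of 200–1000 random
instances — were chosen as the natural scale of the reference data and run
in seconds on one CPU.

## Known limitations

* Electronic structure, docking and ADMET prediction are out of scope by
  design: the package consumes their outputs (orbital energies, pose
  affinities, property panels) and never recomputes them.
* The flavonoid perceiver handles the three scaffold classes above;
  chalcones, aurones, isoflavones and glycosylated flavonoids fall back to
  "non-flavonoid" or annotate only the aglycone-like core if it matches.
* The 3′,4′-catechol flag tests for adjacent B-ring hydroxyls at the 3′/4′
  positions under some template mapping; exotic substitution patterns
  (2′,3′-diOH) would need the full locant list rather than the flag.
* PED text in mode tables is carried verbatim as annotation and never
  parsed into computation.
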