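# flavokit

A desk-scale cheminformatics toolkit for profiling flavonoid antioxidants
and xanthine-oxidase (XO) inhibitor candidates. It bundles the five
computations that recur in this kind of structure–activity study — each one
cheap, deterministic and reproducible from printed inputs:

1. **Conceptual-DFT reactivity descriptors** (`flavokit.reactivity`).
   From a compound's vertical ionization potential *I* and electron
   affinity *A* (or via Koopmans' approximation *I* = −*E*<sub>HOMO</sub>,
   *A* = −*E*<sub>LUMO</sub>):

   χ = (I+A)/2, μ = −χ, η = (I−A)/2, ω = μ²/2η, s = 1/2η, ε = μ·η

   plus the HOMO–LUMO gap ΔE and a |ΔE|-descending reactivity ranking.
   Printed (I, A) pairs take precedence over Koopmans values when a source
   supplies both.

2. **Flavonoid scaffold perception and an indicator-variable RSA QSAR**
   (`flavokit.chem_graph`). SMILES are parsed (RDKit), matched against
   2-phenylchroman-4-one / 2-phenylchromen-4-one templates, and substituents
   are assigned standard flavonoid locants (C ring 2–4, A ring 5–8, B ring
   2′–6′). The binary indicator *I* = 1 iff the molecule carries a
   3′,4′-catechol, a 3-OH, a 5-OH or the C2=C3 double bond; the reduced
   Amić-type regression RSA = intercept + slope·*I* predicts radical
   scavenging activity in percent. A Lipinski rule-of-five screen (the
   oxygen-count variant: MW < 500 g/mol, MLOGP ≤ 4.15, O < 10, NH+OH < 5)
   is included.

3. **Vibrational wavenumber scaling and Fermi-resonance search**
   (`flavokit.vibrational`). Two-region multiplicative scaling of DFT
   harmonic wavenumbers (0.967 below 1800 cm⁻¹, 0.955 at/above), optimal
   computed↔experimental peak assignment, and enumeration of overtone
   (n·ν) and combination (ν<sub>i</sub>+ν<sub>j</sub>) candidates that can
   split a fundamental by Fermi resonance.

4. **Protein–ligand contact classification** (`flavokit.interactions`).
   Heavy-atom N/O···N/O hydrogen bonds from PDB complexes, binned by
   donor–acceptor distance (very strong < 2.2 Å ≤ strong < 2.5 Å ≤
   moderate < 3.2 Å ≤ weak ≤ 4.1 Å), carbon–carbon hydrophobic contacts,
   residue-set comparison between ligands, and docking-pose ranking.

5. **ADME/Tox threshold interpretation** (`flavokit.admet`). Categorical
   calls (solubility, Caco-2, HIA, VDss, fraction unbound, CYP inhibition,
   clearance, AMES, MRTD, hERG, …) from externally predicted pkCSM /
   SwissADME panels. Nothing is predicted from structure — the module
   interprets predictor outputs against documented thresholds.

A seeded synthetic-data module (`flavokit.synthetic_data`) generates every
input the stages consume — orbital tables with positive hardness, spectra
with a known scale factor, PDB complexes with contacts planted at exact
distances, and hand-verified flavonoid fixtures — so the entire pipeline is
testable offline.

## Worked example

Blumeatin (5,3′,5′-trihydroxy-7-methoxyflavanone, a flavonoid from
*Blumea balsamifera*) from its SMILES:

```bash
$ flavokit rsa "COC1=CC(=C2C(=O)CC(OC2=C1)C3=CC(=CC(=C3)O)O)O"
{
  "indicator_variable": 1,
  "rsa_percent": 88.403
}
```

The scaffold perceiver finds a flavanone with OH at 5, 3′ and 5′ and OMe
at 7; the 5-OH alone sets the QSAR indicator to 1, and the regression
anchored at 88.403 % predicts high radical scavenging activity.

```bash
$ flavokit ro5 "COC1=CC(=C2C(=O)CC(OC2=C1)C3=CC(=CC(=C3)O)O)O"
{
  "mlogp": null,
  "mw": 302.28,
  "nh_oh_count": 3,
  "not_evaluated": [
    "MLOGP>4.15"
  ],
  "oxygen_count": 6,
  "passes": true,
  "violations": []
}
```

302.28 g/mol, six oxygens and three hydroxyls: no rule-of-five violation
(the MLOGP rule is reported "not evaluated" because no external prediction
was supplied). Other subcommands follow the same pattern — `descriptors`
(reactivity table + gap ranking), `scale-spectrum`, `match-peaks`,
`fermi-search` (e.g. `--blumeatin` finds the 528 + 1089 = 1617 cm⁻¹
combination pair behind the split 1615 cm⁻¹ carbonyl band),
`complex-analyze`, `compare-residues`, `rank-poses`, `admet-interpret`,
`torsion`, `simulate` and the combined `profile` report. From Python, the
same functionality lives in the modules listed above.

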