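import pytest

from flavokit import chem_graph, reactivity


@pytest.fixture(scope="session")
def blumeatin_mol():
    return chem_graph.parse_smiles(chem_graph.BLUMEATIN_SMILES)


@pytest.fixture(scope="session")
def reference_records():
    """The packaged 11-row frontier-orbital comparison table (both quercetin
    literature rows included)."""
    return reactivity.reference_orbital_records(quercetin_source=None)


#: printed descriptor table (2-dp report values) for the 11 reference rows,
#: keyed by (compound, source)
PRINTED_TABLE1 = {
    ("blumeatin", "this work"): dict(gap=-4.84, chi=3.90, eta=2.42, mu=-3.90,
                                     omega=3.14, nucleophilicity=-9.44, softness=0.21),
    ("quercetin", "ref77"): dict(gap=-2.54, chi=3.76, eta=1.27, mu=-3.76,
                                 omega=5.57, nucleophilicity=-4.78, softness=0.39),
    ("quercetin", "ref78"): dict(gap=-3.78, chi=3.99, eta=1.89, mu=-3.99,
                                 omega=4.21, nucleophilicity=-7.54, softness=0.26),
    ("taxifolin", "ref78"): dict(gap=-2.98, chi=3.95, eta=1.49, mu=-3.95,
                                 omega=5.24, nucleophilicity=-5.89, softness=0.34),
    ("luteolin", "ref79"): dict(gap=-4.26, chi=3.80, eta=2.13, mu=-3.80,
                                omega=3.39, nucleophilicity=-8.09, softness=0.23),
    ("gallic acid", "ref80"): dict(gap=-1.47, chi=0.50, eta=0.74, mu=-0.50,
                                   omega=0.17, nucleophilicity=-0.36, softness=0.68),
    ("betulinic acid", "ref80"): dict(gap=-6.64, chi=3.15, eta=3.32, mu=-3.15,
                                      omega=1.49, nucleophilicity=-10.46, softness=0.15),
    ("lupeol", "ref80"): dict(gap=-7.07, chi=2.78, eta=3.54, mu=-2.78,
                              omega=1.09, nucleophilicity=-9.81, softness=0.14),
    ("procyanidin", "ref80"): dict(gap=-0.06, chi=0.01, eta=0.03, mu=-0.01,
                                   omega=0.00, nucleophilicity=0.00, softness=16.67),
    ("foeniculin", "ref80"): dict(gap=-0.18, chi=0.25, eta=0.09, mu=-0.25,
                                  omega=0.35, nucleophilicity=-0.02, softness=5.56),
    ("morin", "ref81"): dict(gap=-0.49, chi=6.93, eta=0.25, mu=-6.93,
                             omega=97.87, nucleophilicity=-1.70, softness=2.04),
}

#: the published decreasing-|gap| compound ordering (ten compounds, the
#: ref-78 quercetin row)
GAP_ORDERING = [
    "lupeol", "betulinic acid", "blumeatin", "luteolin", "quercetin",
    "taxifolin", "gallic acid", "morin", "foeniculin", "procyanidin",
]

#: the eight reported conventional hydrogen-bond distances (A) and the bin
#: classes the documented bins give them
HBOND_DISTANCES = [2.70, 3.26, 2.93, 2.97, 3.08, 2.03, 4.04, 3.58]
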