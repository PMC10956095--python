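"""Protein-ligand contact detection, classification and pose ranking."""

import numpy as np
import pytest

from conftest import HBOND_DISTANCES
from flavokit import interactions
from flavokit.errors import FlavokitError, PdbParseError
from flavokit.interactions import (
    HBondStrength,
    PoseAffinity,
    classify_hbond_strength,
    detect_hbonds,
    hydrophobic_contacts,
    parse_pdb,
    rank_poses,
    reference_mutual_residues,
    reference_pose_affinities,
    reference_residue_sets,
    residue_overlap,
)
from flavokit.synthetic_data import gen_complex


class TestStrengthBins:
    @pytest.mark.parametrize(
        "distance, expected",
        [
            (2.03, HBondStrength.VERY_STRONG),
            (2.70, HBondStrength.MODERATE),
            (5.0, HBondStrength.NONE),
            (2.2, HBondStrength.STRONG),     # lower edges are inclusive
            (2.5, HBondStrength.MODERATE),
            (3.2, HBondStrength.WEAK),
            (4.1, HBondStrength.WEAK),       # widened upper edge admits 4.04
            (4.11, HBondStrength.NONE),
        ],
    )
    def test_bin_membership(self, distance, expected):
        assert classify_hbond_strength(distance) == expected

    def test_non_positive_distance_rejected(self):
        with pytest.raises(FlavokitError):
            classify_hbond_strength(0.0)

    def test_bins_partition_without_gaps_or_overlaps(self):
        """Over a fine grid of (0, 4.1] every distance lands in exactly one
        class and the class sequence is monotone in distance."""
        order = [HBondStrength.VERY_STRONG, HBondStrength.STRONG,
                 HBondStrength.MODERATE, HBondStrength.WEAK]
        grid = np.arange(0.01, 4.1001, 0.001)
        ranks = [order.index(classify_hbond_strength(float(d))) for d in grid]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))
        assert set(ranks) == {0, 1, 2, 3}

    def test_reported_distance_set_classification(self):
        """The eight reported H-bond distances classify as 1 very strong,
        0 strong, 4 moderate, 3 weak under the documented bins."""
        classes = [classify_hbond_strength(d) for d in HBOND_DISTANCES]
        counts = {cls: classes.count(cls) for cls in HBondStrength}
        assert counts[HBondStrength.VERY_STRONG] == 1
        assert counts[HBondStrength.STRONG] == 0
        assert counts[HBondStrength.MODERATE] == 4
        assert counts[HBondStrength.WEAK] == 3


class TestParsePdb:
    def test_round_trip_partition(self):
        text = gen_complex([("Thr1010", "hbond", 2.70)], seed=1)
        cx = parse_pdb(text)
        assert cx.ligand_resname == "LIG"
        assert {a.name for a in cx.ligand_atoms} == {"O1", "C1", "C2"}
        assert all(a.resname in {"THR", "GLY"} for a in cx.protein_atoms)

    def test_waters_and_altlocs_dropped(self):
        text = (
            "ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00  0.00           N\n"
            "ATOM      2  CA BALA A   1      11.000  10.000  10.000  1.00  0.00           C\n"
            "HETATM    3  O   HOH A 100       1.000   1.000   1.000  1.00  0.00           O\n"
            "HETATM    4  O1  LIG L   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        cx = parse_pdb(text)
        assert [a.name for a in cx.ligand_atoms] == ["O1"]
        assert [a.name for a in cx.protein_atoms] == ["N"]  # altloc B dropped

    def test_only_waters_is_an_error(self):
        text = ("HETATM    1  O   HOH A   1       0.000   0.000   0.000"
                "  1.00  0.00           O\nEND\n")
        with pytest.raises(PdbParseError):
            parse_pdb(text)

    def test_empty_input_is_an_error(self):
        with pytest.raises(PdbParseError):
            parse_pdb("")


class TestDetectHbonds:
    def test_planted_distances_and_classes(self):
        text = gen_complex(
            [("Thr1010", "hbond", 2.03), ("Val1011", "hbond", 2.70),
             ("Arg880", "hbond", 3.58)],
            seed=42,
        )
        cx = parse_pdb(text)
        contacts = detect_hbonds(cx.ligand_atoms, cx.protein_atoms)
        by_res = {c.residue: c for c in contacts}
        assert set(by_res) == {"Thr1010", "Val1011", "Arg880"}
        assert by_res["Thr1010"].strength_class == HBondStrength.VERY_STRONG
        assert by_res["Val1011"].strength_class == HBondStrength.MODERATE
        assert by_res["Arg880"].strength_class == HBondStrength.WEAK
        for planted, c in [(2.03, by_res["Thr1010"]), (2.70, by_res["Val1011"]),
                           (3.58, by_res["Arg880"])]:
            assert c.distance == pytest.approx(planted, abs=1e-3)

    def test_pair_outside_window_not_reported(self):
        text = gen_complex([("Thr1010", "hbond", 4.5)], seed=0)
        cx = parse_pdb(text)
        assert detect_hbonds(cx.ligand_atoms, cx.protein_atoms) == []

    def test_apolar_complex_yields_nothing(self):
        text = gen_complex([("Leu648", "hydrophobic", 4.0)], seed=0)
        cx = parse_pdb(text)
        lig_carbons = [a for a in cx.ligand_atoms if a.element == "C"]
        assert detect_hbonds(lig_carbons, cx.protein_atoms) == []

    def test_planted_contact_recovery_over_seeds(self):
        """Round trip across 200 random planted layouts: detection recovers
        exactly the planted residues, distances (to 0.001 A) and classes."""
        rng = np.random.default_rng(3145)
        residues = ["Thr1010", "Val1011", "Arg880", "Phe914", "Ala1078",
                    "Leu1014", "Ser876", "Glu802"]

        def edge_safe(d):
            # the PDB coordinate grid realises distances to ~0.001 A; keep
            # planted values clear of the class-bin edges so the expected
            # class is unambiguous
            for edge in (2.2, 2.5, 3.2):
                if abs(d - edge) < 0.005:
                    return d + 0.01
            return d

        for seed in range(200):
            n_hb = int(rng.integers(1, 5))
            n_hp = int(rng.integers(0, 3))
            chosen = rng.choice(residues, size=n_hb + n_hp, replace=False)
            planted = [(str(chosen[k]), "hbond",
                        edge_safe(float(np.round(rng.uniform(2.0, 4.09), 2))))
                       for k in range(n_hb)]
            planted += [(str(chosen[n_hb + k]), "hydrophobic",
                         float(np.round(rng.uniform(3.5, 5.45), 2)))
                        for k in range(n_hp)]
            cx = parse_pdb(gen_complex(planted, seed=seed))
            hbonds = detect_hbonds(cx.ligand_atoms, cx.protein_atoms)
            hydro = hydrophobic_contacts(cx.ligand_atoms, cx.protein_atoms)
            got_hb = {c.residue: c for c in hbonds}
            want_hb = {r: d for r, kind, d in planted if kind == "hbond"}
            assert set(got_hb) == set(want_hb), seed
            for res, d in want_hb.items():
                assert got_hb[res].distance == pytest.approx(d, abs=1e-3)
                assert got_hb[res].strength_class == classify_hbond_strength(d)
            want_hp = {r: d for r, kind, d in planted if kind == "hydrophobic"}
            got_hp = {c.residue: c.distance for c in hydro}
            assert set(got_hp) == set(want_hp), seed
            for res, d in want_hp.items():
                assert got_hp[res] == pytest.approx(d, abs=1e-3)


class TestHydrophobicContacts:
    def test_contact_inside_cutoff_reported(self):
        cx = parse_pdb(gen_complex([("Leu648", "hydrophobic", 5.05)], seed=9))
        (contact,) = hydrophobic_contacts(cx.ligand_atoms, cx.protein_atoms)
        assert contact.residue == "Leu648"
        assert contact.distance == pytest.approx(5.05, abs=1e-3)
        assert contact.strength_class is None

    def test_contact_beyond_cutoff_dropped(self):
        cx = parse_pdb(gen_complex([("Leu648", "hydrophobic", 6.0)], seed=9))
        assert hydrophobic_contacts(cx.ligand_atoms, cx.protein_atoms) == []

    def test_carbon_free_ligand_yields_nothing(self):
        cx = parse_pdb(gen_complex([("Leu648", "hydrophobic", 4.0)], seed=2))
        polar_only = [a for a in cx.ligand_atoms if a.element != "C"]
        assert hydrophobic_contacts(polar_only, cx.protein_atoms) == []


class TestResidueOverlap:
    def test_reference_tables_mutual_residues(self):
        """The blumeatin vs quercetin residue comparison recovers every
        residue highlighted as mutual in the reference table."""
        ref_b = reference_residue_sets("blumeatin")
        ref_q = reference_residue_sets("quercetin")
        mutual, only_b, only_q = residue_overlap(
            ref_b["typed"] + ref_b["vdw"], ref_q["typed"] + ref_q["vdw"]
        )
        assert set(reference_mutual_residues()) <= set(mutual)
        assert "Ala910" in only_b  # blumeatin-only pi-alkyl contact
        assert "Pro1076" in only_q

    def test_identical_and_disjoint(self):
        assert residue_overlap(["A", "B"], ["B", "A"]) == (["A", "B"], [], [])
        assert residue_overlap(["A"], ["B"]) == ([], ["A"], ["B"])

    def test_partition_laws(self):
        rng = np.random.default_rng(7)
        pool = [f"Res{i}" for i in range(30)]
        for _ in range(50):
            a = set(rng.choice(pool, size=int(rng.integers(0, 20)), replace=False))
            b = set(rng.choice(pool, size=int(rng.integers(0, 20)), replace=False))
            mutual, only_a, only_b = residue_overlap(a, b)
            assert set(mutual) | set(only_a) == a
            assert set(mutual) & set(only_a) == set()
            assert set(mutual) | set(only_b) == b


class TestRankPoses:
    def test_reference_affinities(self):
        ranked = rank_poses(reference_pose_affinities())
        assert ranked[0].pose == 1 and ranked[0].affinity == -9.6
        assert ranked[-1].pose == 9 and ranked[-1].affinity == -8.7

    def test_stability_on_ties(self):
        poses = [PoseAffinity("a", -9.0), PoseAffinity("b", -9.2),
                 PoseAffinity("c", -9.0)]
        assert [p.pose for p in rank_poses(poses)] == ["b", "a", "c"]

    def test_single_and_invalid(self):
        only = PoseAffinity(1, -5.0)
        assert rank_poses([only]) == [only]
        with pytest.raises(FlavokitError):
            rank_poses([PoseAffinity(1, float("nan"))])
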