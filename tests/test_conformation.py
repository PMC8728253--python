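import numpy as np
import pytest

from kinconf.conformation import (
    CentroidEntry,
    CentroidTable,
    assign_dihedral_label,
    chelix_label,
    classify_chain,
    diagnostic_distances,
    load_centroid_table,
    spatial_label,
)
from kinconf.fixtures import (
    MODAL_CHI1,
    SPATIAL_TARGETS,
    FixtureSpec,
    build_peptide,
    fixture_for_state,
    place_pseudo_anchors,
    random_rotation,
    transform_chain,
)
from kinconf.geometry import chi1_bin, compute_dihedral_vector, rama_region
from kinconf.model import DihedralVector


class TestSpatialLabel:
    @pytest.mark.parametrize("d1,d2,expected", [
        (10.0, 12.0, "DFGin"),
        (12.0, 13.0, "DFGout"),
        (10.0, 10.0, "DFGinter"),
        (12.0, 15.0, None),          # outlier
        (11.0, 11.0, "DFGin"),       # shared boundary: first clause wins
        (None, 12.0, None),
        (10.0, None, None),
    ])
    def test_examples(self, d1, d2, expected):
        assert spatial_label(d1, d2) == expected

    def test_grid_agrees_with_clause_order_oracle(self):
        """Exactly one outcome per (d1, d2); equals first-true-clause."""
        for d1 in np.arange(5.0, 18.01, 0.25):
            for d2 in np.arange(5.0, 18.01, 0.25):
                clauses = [
                    ("DFGin", d1 <= 11.0 and d2 >= 11.0),
                    ("DFGout", d1 > 11.0 and d2 <= 14.0),
                    ("DFGinter", d1 <= 11.0 and d2 <= 11.0),
                ]
                expected = next((name for name, ok in clauses if ok), None)
                assert spatial_label(float(d1), float(d2)) == expected


class TestChelixLabel:
    @pytest.mark.parametrize("dist,expected", [
        (9.0, "in"), (10.0, "in"), (10.5, "out"), (None, "unknown"),
    ])
    def test_examples(self, dist, expected):
        assert chelix_label(dist) == expected

    def test_missing_cb_gives_unknown(self):
        """A Gly-like anchor without CB cannot support the salt-bridge proxy."""
        chain, anchors = fixture_for_state("BLAminus")
        lys = chain.residues[anchors.b3_lys]
        lys.atoms = [a for a in lys.atoms if a.name != "CB"]
        _, _, salt = diagnostic_distances(chain, anchors)
        assert salt is None
        assert chelix_label(salt) == "unknown"

    def test_ca_variant_uses_chelix_glu(self):
        chain, anchors = fixture_for_state("BLAminus")
        _, _, salt_cb = diagnostic_distances(chain, anchors, chelix_atoms="cb")
        _, _, salt_ca = diagnostic_distances(chain, anchors, chelix_atoms="ca")
        assert salt_ca is not None and salt_ca != salt_cb


class TestDiagnosticDistances:
    @pytest.mark.parametrize("d1,d2", [(10.0, 12.0), (13.0, 9.0), (8.0, 8.0)])
    def test_constructed_targets_recovered(self, d1, d2):
        chain, anchors = fixture_for_state("BLAminus")
        place_pseudo_anchors(chain, anchors, d1, d2, 9.0)
        got1, got2, _ = diagnostic_distances(chain, anchors)
        assert got1 == pytest.approx(d1, abs=0.01)
        assert got2 == pytest.approx(d2, abs=0.01)

    def test_missing_phe_ring_gives_missing_distances(self):
        chain, anchors = fixture_for_state("BLAminus")
        phe = chain.residues[anchors.dfg_phe]
        phe.atoms = [a for a in phe.atoms if a.name not in ("CG", "CZ")]
        d1, d2, salt = diagnostic_distances(chain, anchors)
        assert d1 is None and d2 is None
        assert salt is not None     # independent of the Phe ring

    def test_rigid_invariance(self):
        chain, anchors = fixture_for_state("BLAminus")
        ref = diagnostic_distances(chain, anchors)
        rng = np.random.default_rng(2)
        moved = transform_chain(chain, random_rotation(rng), rng.normal(size=3) * 30)
        got = diagnostic_distances(moved, anchors)
        assert got == pytest.approx(ref, abs=1e-9)


class TestDihedralLabel:
    def test_centroid_self_assignment(self, centroid_table):
        for state, entry in centroid_table.entries.items():
            vec = DihedralVector(*entry.angles, chi1_f=MODAL_CHI1[entry.rotamer])
            got, dist = assign_dihedral_label(vec, entry.spatial, centroid_table)
            assert got == state
            assert dist == pytest.approx(0.0, abs=1e-12)

    def test_uniform_50_degree_offset_unassigned(self, centroid_table):
        entry = centroid_table.entries["BLAminus"]
        vec = DihedralVector(*(a + 50.0 for a in entry.angles), chi1_f=-60.0)
        got, dist = assign_dihedral_label(vec, "DFGin", centroid_table)
        assert got is None
        assert dist == pytest.approx(2.0 * (1.0 - np.cos(np.radians(50.0))), abs=1e-6)

    def test_incomplete_vector_unassigned(self, centroid_table):
        vec = DihedralVector(-129, 179, 61, 81, -97, None, chi1_f=-60.0)
        assert assign_dihedral_label(vec, "DFGin", centroid_table) == (None, None)

    def test_spatial_none_unassigned(self, centroid_table):
        entry = centroid_table.entries["BLAminus"]
        vec = DihedralVector(*entry.angles, chi1_f=-60.0)
        assert assign_dihedral_label(vec, None, centroid_table) == (None, None)

    def test_no_candidates_for_dfgout_plus(self, centroid_table):
        entry = centroid_table.entries["BBAminus"]
        vec = DihedralVector(*entry.angles, chi1_f=60.0)   # plus rotamer
        assert assign_dihedral_label(vec, "DFGout", centroid_table) == (None, None)

    def test_label_never_conflicts_with_rotamer_or_group(self, centroid_table):
        rng = np.random.default_rng(9)
        for _ in range(500):
            vec = DihedralVector(*rng.uniform(-180, 180, 7))
            spatial = rng.choice(["DFGin", "DFGinter", "DFGout"])
            state, _ = assign_dihedral_label(vec, spatial, centroid_table)
            if state is None:
                continue
            entry = centroid_table.entries[state]
            assert entry.spatial == spatial
            assert entry.rotamer == chi1_bin(vec.chi1_f)


class TestCentroidTable:
    def test_shipped_table_self_consistent(self, centroid_table):
        assert len(centroid_table.entries) == 8
        for state, e in centroid_table.entries.items():
            letters = "".join(
                rama_region(e.angles[i], e.angles[i + 1]) for i in (0, 2, 4)
            )
            assert state == letters + e.rotamer

    def test_mislabelled_centroid_rejected(self):
        good = load_centroid_table()
        entries = []
        for e in good.entries.values():
            if e.state == "BLAminus":
                # break the X-DFG letter: make phi positive (-> 'L')
                e = CentroidEntry(e.state, e.spatial, e.rotamer,
                                  (120.0,) + e.angles[1:])
            entries.append(e)
        with pytest.raises(ValueError, match="Ramachandran"):
            CentroidTable(entries)

    def test_incomplete_state_set_rejected(self):
        good = list(load_centroid_table().entries.values())
        with pytest.raises(ValueError, match="exactly"):
            CentroidTable(good[:-1])


class TestClassifyChain:
    def test_round_trip_all_eight_states(self, centroid_table, state_fixtures):
        for state, (chain, anchors) in state_fixtures.items():
            res = classify_chain(chain, anchors, centroid_table)
            assert res.dihedral == state
            assert res.spatial == centroid_table.entries[state].spatial
            assert res.min_centroid_distance == pytest.approx(0.0, abs=1e-9)

    def test_deleted_dfg_degrades_to_none(self, centroid_table):
        chain, anchors = fixture_for_state("BLAminus")
        from dataclasses import replace
        anchors = replace(anchors, x_dfg=None, dfg_asp=None, dfg_phe=None,
                          dfg_gly=None)
        res = classify_chain(chain, anchors, centroid_table)
        assert res.spatial is None and res.dihedral is None
        assert res.chelix in ("in", "out")    # salt bridge still measurable

    def test_rigid_invariance(self, centroid_table):
        chain, anchors = fixture_for_state("BLBplus")
        ref = classify_chain(chain, anchors, centroid_table)
        rng = np.random.default_rng(4)
        for _ in range(10):
            moved = transform_chain(chain, random_rotation(rng),
                                    rng.normal(size=3) * 50)
            got = classify_chain(moved, anchors, centroid_table)
            assert (got.spatial, got.dihedral, got.chelix) == \
                (ref.spatial, ref.dihedral, ref.chelix)
            assert got.d1 == pytest.approx(ref.d1, abs=1e-9)

    def test_atom_order_permutation_invariance(self, centroid_table):
        chain, anchors = fixture_for_state("ABAminus")
        ref = classify_chain(chain, anchors, centroid_table)
        rng = np.random.default_rng(8)
        for res in chain.residues:
            rng.shuffle(res.atoms)
        got = classify_chain(chain, anchors, centroid_table)
        assert (got.spatial, got.dihedral, got.chelix) == \
            (ref.spatial, ref.dihedral, ref.chelix)

    def test_dihedral_cutoff_is_configurable(self, centroid_table):
        entry = centroid_table.entries["BLAminus"]
        dih = [(-120.0, 130.0)] * 10
        a = entry.angles
        dih[3] = (a[0] + 30, a[1] + 30)
        dih[4] = (a[2] + 30, a[3] + 30)
        dih[5] = (a[4] + 30, a[5] + 30)
        d1, d2 = SPATIAL_TARGETS["DFGin"]
        chain, anchors = build_peptide(FixtureSpec(
            backbone_dihedrals=dih, chi1_f=-60.0, d1_target=d1, d2_target=d2))
        # 2(1-cos30) ~ 0.268 < 0.45 -> assigned; tighter cutoff -> None
        assert classify_chain(chain, anchors, centroid_table).dihedral == "BLAminus"
        res = classify_chain(chain, anchors, centroid_table, dihedral_cutoff=0.2)
        assert res.dihedral is None
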