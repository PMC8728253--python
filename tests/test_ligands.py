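import itertools
import math

import numpy as np
import pytest

from kinconf.fixtures import (
    fixture_for_state,
    place_ligand,
    place_ligand_equidistant,
    random_rotation,
    transform_chain,
)
from kinconf.ligands import (
    assign_ligand_type,
    candidate_ligands,
    classify_ligands,
    contact_profile,
)
from kinconf.model import Atom, ContactProfile, KinaseChain, Residue

from conftest import oracle_region_counts


def _profile(n_hinge=0, n_back=0, n_type2only=0, n_chelix_nterm=0,
             min_hinge=math.inf, min_glu4=math.inf):
    return ContactProfile(
        ligand_id="LIG:1", n_hinge=n_hinge, n_back=n_back,
        n_type2only=n_type2only, n_chelix_nterm=n_chelix_nterm,
        min_hinge_dist=min_hinge, min_glu4_dist=min_glu4,
        min_any_dist=min(min_hinge, min_glu4),
    )


class TestTypeRules:
    @pytest.mark.parametrize("profile,expected", [
        # ATP-site binder: hinge contacts only
        (_profile(n_hinge=3, min_hinge=3.1, min_glu4=7.0), "Type1"),
        # back pocket + Type-2-only pocket
        (_profile(n_hinge=2, n_back=4, n_type2only=1, min_hinge=3.5,
                  min_glu4=3.8), "Type2"),
        # back pocket, far from hinge
        (_profile(n_back=3, min_hinge=7.0, min_glu4=5.0), "Type3"),
        # back pocket + C-helix N-terminal contact
        (_profile(n_hinge=1, n_back=3, n_chelix_nterm=1, min_hinge=3.5,
                  min_glu4=3.9), "Type1.5_front"),
        # back pocket, no C-helix N-terminal contact
        (_profile(n_hinge=1, n_back=3, min_hinge=3.5, min_glu4=3.9),
         "Type1.5_back"),
        # far from both hinge and Glu(+4)
        (_profile(min_hinge=8.0, min_glu4=8.0), "Allosteric"),
        # boundary: exactly 6.5 A is NOT beyond the allosteric screen
        (_profile(min_hinge=6.5, min_glu4=6.5), "Type1"),
        # boundary: exactly 6 A from hinge is NOT Type 3
        (_profile(n_back=3, min_hinge=6.0, min_glu4=5.0), "Type1.5_back"),
        # two back contacts are not enough for any back-pocket type
        (_profile(n_hinge=1, n_back=2, min_hinge=3.5, min_glu4=5.0), "Type1"),
    ])
    def test_rule_examples(self, profile, expected):
        assert assign_ligand_type(profile).type == expected

    def test_assignment_total_and_single_valued_on_lattice(self):
        """Every reachable contact profile gets exactly one of the six types."""
        seen = set()
        for n_back, n_t2, n_nterm, mh, mg in itertools.product(
            (0, 1, 2, 3, 4), (0, 1), (0, 1),
            (3.0, 6.0, 6.25, 6.5, 6.75, 8.0), (3.0, 6.5, 6.75, 8.0),
        ):
            p = _profile(n_back=n_back, n_type2only=n_t2, n_chelix_nterm=n_nterm,
                         min_hinge=mh, min_glu4=mg)
            label = assign_ligand_type(p).type
            assert label in {"Type1", "Type1.5_front", "Type1.5_back", "Type2",
                             "Type3", "Allosteric"}
            seen.add(label)
        assert len(seen) == 6    # lattice reaches every type

    def test_adding_type2_contact_promotes_15back_to_type2(self):
        base = _profile(n_hinge=1, n_back=3, min_hinge=3.5, min_glu4=3.9)
        assert assign_ligand_type(base).type == "Type1.5_back"
        promoted = _profile(n_hinge=1, n_back=3, n_type2only=1, min_hinge=3.5,
                            min_glu4=3.9)
        assert assign_ligand_type(promoted).type == "Type2"

    def test_removing_back_contacts_from_type3(self):
        t3 = _profile(n_back=3, min_hinge=7.0, min_glu4=5.0)
        assert assign_ligand_type(t3).type == "Type3"
        # near Glu(+4): falls through to Type1
        assert assign_ligand_type(
            _profile(min_hinge=7.0, min_glu4=5.0)).type == "Type1"
        # far from both: Allosteric
        assert assign_ligand_type(
            _profile(min_hinge=7.0, min_glu4=7.0)).type == "Allosteric"


class TestCandidateScreen:
    def test_nearby_ligand_is_candidate(self):
        chain, anchors = fixture_for_state("BLAminus")
        place_ligand(chain, anchors, "hinge", 3.0, 1)
        assert len(candidate_ligands([chain], chain)) == 1

    def test_excluded_additive_not_candidate(self):
        chain, anchors = fixture_for_state("BLAminus")
        lig = place_ligand(chain, anchors, "hinge", 3.0, 1)
        lig.name = "GOL"
        assert candidate_ligands([chain], chain) == []

    def test_far_ligand_not_candidate(self):
        chain, anchors = fixture_for_state("BLAminus")
        place_ligand(chain, anchors, "remote", 12.0, 1)
        assert candidate_ligands([chain], chain) == []

    def test_ligand_on_other_chain_screened_per_chain(self):
        chain_a, anchors = fixture_for_state("BLAminus")
        lig = place_ligand(chain_a, anchors, "hinge", 4.0, 1)
        # move the hetero record to a different author chain
        chain_b = KinaseChain(entry_id=chain_a.entry_id, chain_id="B",
                              residues=[], hetero=[lig])
        chain_a.hetero = []
        assert candidate_ligands([chain_a, chain_b], chain_a) == [lig]


class TestContactProfile:
    def test_boundary_contact_at_4A(self):
        for d, expect in ((3.9, 1), (4.0, 1), (4.1, 0)):
            chain, anchors = fixture_for_state("BLAminus")
            lig = place_ligand(chain, anchors, "hinge", d, 1)
            p = contact_profile(lig, chain, anchors)
            assert p.n_hinge >= expect if expect else p.n_hinge == 0

    def test_hydrogens_never_count(self):
        chain, anchors = fixture_for_state("BLAminus")
        hinge_atom = chain.residues[sorted(anchors.hinge_set)[0]].atoms[0]
        lig = Residue("LIG", 901, is_polymer=False, atoms=[
            Atom("H1", "H", hinge_atom.position + np.array([2.0, 0, 0])),
            Atom("C1", "C", hinge_atom.position + np.array([0, 0, 9.0])),
        ])
        chain.hetero.append(lig)
        p = contact_profile(lig, chain, anchors)
        assert p.n_hinge == 0
        assert p.min_hinge_dist == pytest.approx(9.0)

    def test_counts_match_brute_force_oracle(self):
        chain, anchors = fixture_for_state("BBAminus")
        lig = place_ligand(chain, anchors, "back_pocket", 3.5, 3)
        p = contact_profile(lig, chain, anchors)
        n_back, min_back = oracle_region_counts(lig, chain, anchors.back_pocket_set)
        n_hinge, min_hinge = oracle_region_counts(lig, chain, anchors.hinge_set)
        assert p.n_back == n_back >= 3
        assert p.n_hinge == n_hinge
        assert p.min_hinge_dist == pytest.approx(min_hinge, abs=1e-12)

    def test_residue_counting_variant(self):
        chain, anchors = fixture_for_state("BLAminus")
        lig = place_ligand(chain, anchors, "hinge", 3.0, 1)
        pairs = contact_profile(lig, chain, anchors).n_hinge
        residues = contact_profile(lig, chain, anchors, count_residues=True).n_hinge
        assert residues <= pairs
        assert residues >= 1

    def test_rigid_invariance(self):
        chain, anchors = fixture_for_state("BLAminus")
        lig = place_ligand(chain, anchors, "hinge", 3.5, 2)
        ref = contact_profile(lig, chain, anchors)
        rng = np.random.default_rng(6)
        moved = transform_chain(chain, random_rotation(rng), rng.normal(size=3) * 20)
        got = contact_profile(moved.hetero[0], moved, anchors)
        assert (got.n_hinge, got.n_back, got.n_type2only, got.n_chelix_nterm) == \
            (ref.n_hinge, ref.n_back, ref.n_type2only, ref.n_chelix_nterm)
        assert got.min_hinge_dist == pytest.approx(ref.min_hinge_dist, abs=1e-9)


class TestEndToEnd:
    def test_hinge_binder_is_type1(self):
        chain, anchors = fixture_for_state("BLAminus")
        place_ligand(chain, anchors, "hinge", 3.5, 1)
        (result,) = classify_ligands([chain], chain, anchors)
        assert result.type == "Type1"

    def test_equidistant_allosteric_boundary(self):
        for d, expected in ((6.5, "Type1"), (6.51, "Allosteric")):
            chain, anchors = fixture_for_state("BLAminus")
            lig = place_ligand_equidistant(chain, anchors, d)
            p = contact_profile(lig, chain, anchors)
            assert assign_ligand_type(p).type == expected
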