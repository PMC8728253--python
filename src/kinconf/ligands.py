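"""Ligand identification, pocket contact profiling and inhibitor typing.

Pockets are defined by functional residues of the kinase domain (hinge,
back pocket, Type-2-only pocket, N-terminal half of the C-helix).  A contact
is a heavy-atom pair (ligand atom, pocket-residue atom) at distance
<= 4.0 A; hydrogens never count.  The type rules, evaluated most-specific
first so that a Type 2 profile is never shadowed by the weaker Type 1.5
criteria:

    Allosteric:   min distance to the hinge > 6.5 A and to
                  C-helix-Glu(+4) > 6.5 A
    Type 2:       >= 3 back-pocket contacts and >= 1 Type-2-only contact
    Type 3:       min hinge distance > 6 A and >= 3 back-pocket contacts
    Type1.5_front: >= 3 back-pocket contacts and >= 1 contact with the
                  N-terminal region of the C-helix
    Type1.5_back: >= 3 back-pocket contacts, no C-helix N-terminal contact
    Type 1:       everything else
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .model import EPS, AnchorMap, ContactProfile, KinaseChain, LigandTypeResult, Residue

__all__ = [
    "candidate_ligands",
    "contact_profile",
    "assign_ligand_type",
    "classify_ligands",
    "CONTACT_CUTOFF",
    "SCREEN_RADIUS",
    "ALLOSTERIC_CUTOFF",
    "HINGE_FAR_CUTOFF",
    "DEFAULT_EXCLUDED",
]

CONTACT_CUTOFF = 4.0       # A, inclusive
SCREEN_RADIUS = 5.0        # A, candidate-ligand binding screen
ALLOSTERIC_CUTOFF = 6.5    # A, strict 'beyond' for the allosteric rule
HINGE_FAR_CUTOFF = 6.0     # A, strict 'beyond' for the Type 3 rule
MIN_BACK_CONTACTS = 3

# Crystallisation additives, buffer components, ions and other hetero
# species that are never treated as candidate inhibitors.
DEFAULT_EXCLUDED = frozenset({
    "HOH", "DOD", "WAT",
    "GOL", "EDO", "PEG", "PGE", "PG4", "1PE", "MPD", "DMS", "ACT", "FMT",
    "SO4", "PO4", "NO3", "NH4", "TRS", "MES", "EPE", "BME", "ACE", "NME",
    "CIT", "TLA", "IMD", "BOG", "UNX",
    "NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "CO", "NI", "CU", "CD",
    "IOD", "BR", "F", "CS", "LI", "SR", "BA", "AL", "HG",
})


def _heavy_coords(residue: Residue) -> np.ndarray:
    pts = [a.position for a in residue.heavy_atoms()]
    return np.vstack(pts) if pts else np.empty((0, 3))


def _set_coords(chain: KinaseChain, indices: Iterable[int]) -> np.ndarray:
    pts = []
    for i in indices:
        if 0 <= i < len(chain.residues):
            arr = _heavy_coords(chain.residues[i])
            if arr.size:
                pts.append(arr)
    return np.vstack(pts) if pts else np.empty((0, 3))


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if a.size == 0 or b.size == 0:
        return float("inf")
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def _n_pairs_within(a: np.ndarray, b: np.ndarray, cutoff: float) -> int:
    if a.size == 0 or b.size == 0:
        return 0
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return int(np.count_nonzero(d <= cutoff + EPS))


def candidate_ligands(
    chains: Iterable[KinaseChain],
    target: KinaseChain,
    screen_radius: float = SCREEN_RADIUS,
    excluded: frozenset[str] = DEFAULT_EXCLUDED,
) -> list[Residue]:
    """Hetero residues anywhere in the asymmetric unit that can bind ``target``.

    Any non-water, non-excluded small molecule whose minimum heavy-atom
    distance to the target chain polymer is <= ``screen_radius`` is a
    candidate, regardless of which author chain it was deposited with.
    """
    target_xyz = _set_coords(target, range(len(target.residues)))
    seen: set[int] = set()
    out: list[Residue] = []
    for ch in chains:
        for het in ch.hetero:
            if id(het) in seen:
                continue
            seen.add(id(het))
            if het.is_water or het.name.upper() in excluded:
                continue
            if _min_dist(_heavy_coords(het), target_xyz) <= screen_radius + EPS:
                out.append(het)
    return out


def contact_profile(
    ligand: Residue,
    chain: KinaseChain,
    anchors: AnchorMap,
    cutoff: float = CONTACT_CUTOFF,
    count_residues: bool = False,
) -> ContactProfile:
    """Count pocket contacts and measure minimum distances for one ligand.

    Contacts are aggregated per region as heavy-atom pairs by default; with
    ``count_residues`` each contacting pocket residue counts once instead
    (sensitivity-check variant).
    """
    lig = _heavy_coords(ligand)

    def region_count(indices: Iterable[int]) -> int:
        indices = list(indices)
        if count_residues:
            n = 0
            for i in indices:
                if 0 <= i < len(chain.residues):
                    if _min_dist(lig, _heavy_coords(chain.residues[i])) <= cutoff + EPS:
                        n += 1
            return n
        return _n_pairs_within(lig, _set_coords(chain, indices), cutoff)

    glu4 = (
        [anchors.chelix_glu_plus4] if anchors.chelix_glu_plus4 is not None else []
    )
    all_xyz = _set_coords(chain, range(len(chain.residues)))
    return ContactProfile(
        ligand_id=f"{ligand.name}:{ligand.author_number}{ligand.insertion_code}",
        n_hinge=region_count(anchors.hinge_set),
        n_back=region_count(anchors.back_pocket_set),
        n_type2only=region_count(anchors.type2_only_set),
        n_chelix_nterm=region_count(anchors.chelix_nterm_set),
        min_hinge_dist=_min_dist(lig, _set_coords(chain, anchors.hinge_set)),
        min_glu4_dist=_min_dist(lig, _set_coords(chain, glu4)),
        min_any_dist=_min_dist(lig, all_xyz),
    )


def assign_ligand_type(
    profile: ContactProfile,
    allosteric_cutoff: float = ALLOSTERIC_CUTOFF,
    hinge_far_cutoff: float = HINGE_FAR_CUTOFF,
    min_back: int = MIN_BACK_CONTACTS,
) -> LigandTypeResult:
    """Apply the type rules in most-specific-first order (total assignment)."""
    p = profile
    if p.min_hinge_dist > allosteric_cutoff + EPS and p.min_glu4_dist > allosteric_cutoff + EPS:
        label = "Allosteric"
    elif p.n_back >= min_back and p.n_type2only >= 1:
        label = "Type2"
    elif p.min_hinge_dist > hinge_far_cutoff + EPS and p.n_back >= min_back:
        label = "Type3"
    elif p.n_back >= min_back and p.n_chelix_nterm >= 1:
        label = "Type1.5_front"
    elif p.n_back >= min_back:
        label = "Type1.5_back"
    else:
        label = "Type1"
    return LigandTypeResult(profile=p, type=label)


def classify_ligands(
    chains: Iterable[KinaseChain],
    target: KinaseChain,
    anchors: AnchorMap,
    contact_cutoff: float = CONTACT_CUTOFF,
    screen_radius: float = SCREEN_RADIUS,
    excluded: frozenset[str] = DEFAULT_EXCLUDED,
) -> list[LigandTypeResult]:
    """Candidate screen + profile + typing for every ligand near ``target``."""
    results = []
    for lig in candidate_ligands(chains, target, screen_radius, excluded):
        prof = contact_profile(lig, target, anchors, cutoff=contact_cutoff)
        results.append(assign_ligand_type(prof))
    return results
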