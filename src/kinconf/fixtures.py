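"""Synthetic kinase-like structures with prescribed geometry.

Real kinase domains cannot be bundled with the package, so every
classification rule is exercised on synthetic chains built here from
internal coordinates: a short peptide containing the X-DFG motif realises
prescribed phi/psi/chi1 dihedrals exactly (NeRF chain construction with
ideal bond lengths and angles), pseudo-anchor residues (beta3-Lys,
C-helix-Glu, C-helix-Glu(+4)) are placed to realise prescribed D1/D2 and
salt-bridge distances, and dummy ligands are placed at prescribed minimum
distances from named pocket regions.  No attempt is made at a globally
realistic kinase fold; a fixture satisfies exactly the predicates the
classifiers measure.

These chains are synthetic stand-ins for experimental structures: what they
demonstrate is the correctness of the decision rules, not performance on
deposited PDB entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .conformation import CentroidTable, load_centroid_table
from .model import AnchorMap, Atom, KinaseChain, Residue

__all__ = [
    "FixtureSpec",
    "FixtureError",
    "build_peptide",
    "place_ligand",
    "place_ligand_equidistant",
    "place_pseudo_anchors",
    "fixture_for_state",
    "transform_chain",
    "random_rotation",
    "MODAL_CHI1",
]

# ideal backbone geometry (A, degrees); exact values immaterial to labels
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
BOND_CB_CG = 1.520
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_C_CA_CB = 110.1
ANGLE_CA_CB_CG = 113.8
IMPROPER_N_C_CA_CB = -122.6   # L-amino-acid branch
RING_CG_CZ = 2.87             # para carbon along the CB->CG axis

MODAL_CHI1 = {"plus": 60.0, "minus": -60.0, "trans": 180.0}

#: default diagnostic-distance targets per spatial group (A)
SPATIAL_TARGETS = {
    "DFGin": (9.5, 13.5),
    "DFGinter": (9.5, 9.5),
    "DFGout": (13.0, 10.0),
}


class FixtureError(ValueError):
    """An infeasible geometric request (e.g. triangle-inequality violation)."""


@dataclass
class FixtureSpec:
    """Recipe for one synthetic chain.

    ``backbone_dihedrals`` gives (phi, psi) per peptide residue; the phi of
    the first and psi of the last residue are unrealisable (chain termini)
    and ignored.  ``ligand_placements`` is a list of
    (region, min distance A, atom count) requests executed after the chain
    is built.
    """

    sequence: str = "AAAADFGAAA"
    x_dfg_pos: int = 3                       # index of X-DFG within sequence
    backbone_dihedrals: Optional[Sequence[tuple[float, float]]] = None
    chi1_f: Optional[float] = -60.0
    d1_target: float = 9.5
    d2_target: float = 13.5
    salt_bridge_target: float = 9.0
    ligand_placements: list[tuple[str, float, int]] = field(default_factory=list)
    seed: int = 0
    entry_id: str = "FIXT"
    chain_id: str = "A"

    def __post_init__(self) -> None:
        d = self.x_dfg_pos + 1
        if self.sequence[d:d + 3] != "DFG":
            raise FixtureError("sequence must carry D-F-G after the X-DFG position")
        for t in (self.d1_target, self.d2_target, self.salt_bridge_target):
            if t <= 0:
                raise FixtureError("distance targets must be positive")


# ---------------------------------------------------------------- NeRF core

def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place point d given a-b-c with |cd|=bond, angle(b,c,d), torsion(a,b,c,d)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------- pseudo-residue layout
# chain layout: indices 0-11 are single-atom pseudo residues carrying the
# pocket regions and anchors; the NeRF peptide starts at index 12.  The
# order follows the common residue numbering so that fixtures written in
# the common scheme are consistent with the shipped anchor table.
IDX_B3_LYS = 0
IDX_BACK_EXTRA = (1, 2)
IDX_NTERM = (3, 4)
IDX_CHELIX_GLU = 5
IDX_GLU4 = 6
IDX_HINGE = (7, 8, 9)
IDX_TYPE2 = (10, 11)
PEPTIDE_START = 12
#: common numbers of the pseudo residues, matching the anchor table roles
PSEUDO_COMMON = (1226, 1230, 1231, 1240, 1241, 1245, 1249, 1275, 1276, 1277,
                 1311, 1318)


def _pseudo(name: str, number: int) -> Residue:
    return Residue(name=name, author_number=number, atoms=[], is_polymer=True)


def _default_dihedrals(n: int, x_pos: int, chi_state=None) -> list[tuple[float, float]]:
    return [(-120.0, 130.0)] * n


def build_peptide(spec: FixtureSpec) -> tuple[KinaseChain, AnchorMap]:
    """Construct the synthetic chain and its (bypass) anchor map.

    The returned anchor map indexes directly into ``chain.residues``; the
    profile-alignment stage is deliberately bypassed so geometry and
    classification are testable on their own.
    """
    seq = spec.sequence
    n = len(seq)
    dih = list(spec.backbone_dihedrals or _default_dihedrals(n, spec.x_dfg_pos))
    if len(dih) != n:
        raise FixtureError("backbone_dihedrals length must match sequence length")

    # backbone via NeRF
    N = [None] * n
    CA = [None] * n
    C = [None] * n
    N[0] = np.zeros(3)
    CA[0] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(n - 1):
        psi_i = dih[i][1]
        N[i + 1] = _nerf(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi_i)
        CA[i + 1] = _nerf(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, 180.0)
        C[i + 1] = _nerf(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C,
                         dih[i + 1][0])

    three = {"A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
             "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
             "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
             "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL"}
    pep_residues: list[Residue] = []
    f_pos = spec.x_dfg_pos + 2
    for i, letter in enumerate(seq):
        res = Residue(name=three.get(letter, "ALA"),
                      author_number=PEPTIDE_START + i + 1)
        res.atoms.append(Atom("N", "N", N[i]))
        res.atoms.append(Atom("CA", "C", CA[i]))
        res.atoms.append(Atom("C", "C", C[i]))
        if i < n - 1:
            res.atoms.append(Atom("O", "O", _nerf(N[i], CA[i], C[i], BOND_C_O,
                                                  ANGLE_CA_C_O, dih[i][1] + 180.0)))
        if letter != "G":
            cb = _nerf(N[i], C[i], CA[i], BOND_CA_CB, ANGLE_C_CA_CB,
                       IMPROPER_N_C_CA_CB)
            res.atoms.append(Atom("CB", "C", cb))
            if i == f_pos:
                # with chi1 unspecified the CG atom is omitted (chi1 becomes
                # unmeasurable) but the ring CZ is still placed so the
                # diagnostic distances stay defined
                cg = _nerf(N[i], CA[i], cb, BOND_CB_CG, ANGLE_CA_CB_CG,
                           spec.chi1_f if spec.chi1_f is not None else -60.0)
                if spec.chi1_f is not None:
                    res.atoms.append(Atom("CG", "C", cg))
                axis = cg - cb
                axis /= np.linalg.norm(axis)
                res.atoms.append(Atom("CZ", "C", cg + RING_CG_CZ * axis))
        pep_residues.append(res)

    chain = KinaseChain(entry_id=spec.entry_id, chain_id=spec.chain_id)
    chain.residues = [
        _pseudo("LYS", 1),                             # beta3 Lys
        _pseudo("ALA", 2), _pseudo("ALA", 3),          # extra back-pocket
        _pseudo("ALA", 4), _pseudo("ALA", 5),          # C-helix N-term region
        _pseudo("GLU", 6),                             # C-helix Glu
        _pseudo("GLN", 7),                             # C-helix Glu(+4)
        _pseudo("ALA", 8), _pseudo("ALA", 9), _pseudo("ALA", 10),  # hinge
        _pseudo("ALA", 11), _pseudo("ALA", 12),        # Type-2-only pocket
    ] + pep_residues

    x_idx = PEPTIDE_START + spec.x_dfg_pos
    anchors = AnchorMap(
        x_dfg=x_idx,
        dfg_asp=x_idx + 1,
        dfg_phe=x_idx + 2,
        dfg_gly=x_idx + 3,
        b3_lys=IDX_B3_LYS,
        chelix_glu=IDX_CHELIX_GLU,
        chelix_glu_plus4=IDX_GLU4,
        hinge_set=frozenset(IDX_HINGE),
        back_pocket_set=frozenset(IDX_BACK_EXTRA) | {x_idx, x_idx + 1, x_idx + 2},
        type2_only_set=frozenset(IDX_TYPE2),
        chelix_nterm_set=frozenset(IDX_NTERM),
        group=None,
        alignment_score=float("nan"),
    )
    place_pseudo_anchors(chain, anchors, spec.d1_target, spec.d2_target,
                         spec.salt_bridge_target)
    # common numbering per the anchor table; DFG-Asp lands at common 1338
    asp_idx = x_idx + 1
    for i, res in enumerate(chain.residues):
        res.uniprot_number = 100 + i
        if i < PEPTIDE_START:
            res.common_number = PSEUDO_COMMON[i]
        else:
            res.common_number = 1338 + (i - asp_idx)
    for region, dist, n_atoms in spec.ligand_placements:
        place_ligand(chain, anchors, region, dist, n_atoms)
    return chain, anchors


def _frame(chain: KinaseChain, anchors: AnchorMap) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Phe-CZ-centred orthonormal frame pointing away from the peptide."""
    cz = chain.residues[anchors.dfg_phe].coord("CZ")
    if cz is None:
        raise FixtureError("fixture Phe has no CZ; cannot place pseudo-anchors")
    pts = [a.position for r in chain.residues[PEPTIDE_START:] for a in r.atoms]
    centroid = np.mean(np.vstack(pts), axis=0)
    e1 = cz - centroid
    nrm = np.linalg.norm(e1)
    e1 = np.array([1.0, 0.0, 0.0]) if nrm < 1e-6 else e1 / nrm
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, e1)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, ref)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return cz, e1, e2, e3


def place_pseudo_anchors(
    chain: KinaseChain,
    anchors: AnchorMap,
    d1: float,
    d2: float,
    salt: float,
) -> None:
    """(Re)place the Lys/Glu pseudo-anchor atoms to hit the distance targets.

    D1 and D2 are realised exactly by construction; the salt-bridge CB-CB
    distance is realised by choosing the CA-CA separation and the CB offset
    geometry (perpendicular, inward or outward), whichever is feasible.
    Raises :class:`FixtureError` when no arrangement satisfies the triangle
    inequality.
    """
    cz, e1, e2, e3 = _frame(chain, anchors)
    margin = 0.05
    arrangements = (
        ("perp", salt),
        ("inward", salt + 2 * BOND_CA_CB),
        ("outward", salt - 2 * BOND_CA_CB),
    )
    for mode, d_caca in arrangements:
        if d_caca <= 0:
            continue
        if not (abs(d1 - d2) + margin <= d_caca <= d1 + d2 - margin):
            continue
        cos_t = (d1 * d1 + d2 * d2 - d_caca * d_caca) / (2.0 * d1 * d2)
        half = 0.5 * math.acos(max(-1.0, min(1.0, cos_t)))
        u1 = math.cos(half) * e1 + math.sin(half) * e2
        u2 = math.cos(half) * e1 - math.sin(half) * e2
        glu_ca = cz + d1 * u1
        lys_ca = cz + d2 * u2
        axis = lys_ca - glu_ca
        axis /= np.linalg.norm(axis)
        if mode == "perp":
            p = np.cross(axis, e3)
            if np.linalg.norm(p) < 1e-6:
                p = np.cross(axis, e2)
            p /= np.linalg.norm(p)
            glu_cb = glu_ca + BOND_CA_CB * p
            lys_cb = lys_ca + BOND_CA_CB * p
        elif mode == "inward":
            glu_cb = glu_ca + BOND_CA_CB * axis
            lys_cb = lys_ca - BOND_CA_CB * axis
        else:
            glu_cb = glu_ca - BOND_CA_CB * axis
            lys_cb = lys_ca + BOND_CA_CB * axis
        break
    else:
        raise FixtureError(
            f"no feasible anchor arrangement for d1={d1}, d2={d2}, salt={salt}"
        )

    def set_atoms(idx: int, coords: dict[str, np.ndarray]) -> None:
        chain.residues[idx].atoms = [Atom(n, "C" if n != "N" else "N", p)
                                     for n, p in coords.items()]

    set_atoms(IDX_GLU4, {"CA": glu_ca, "CB": glu_cb})
    set_atoms(IDX_B3_LYS, {"CA": lys_ca, "CB": lys_cb})
    glu_pos = glu_ca + 3.0 * e3
    set_atoms(IDX_CHELIX_GLU, {"CA": glu_pos})
    set_atoms(IDX_NTERM[0], {"CA": glu_pos + 2.0 * e3 + 1.9 * e2})
    set_atoms(IDX_NTERM[1], {"CA": glu_pos + 2.0 * e3 - 1.9 * e2})
    # hinge triplet 8 A from the Glu(+4) CB, opposite side from the N-term set
    hinge_mid = glu_cb - 8.0 * e3
    for k, idx in enumerate(IDX_HINGE):
        set_atoms(idx, {"CA": hinge_mid + (k - 1) * 3.8 * e2})
    # extra back-pocket and Type-2-only atoms near the DFG region
    set_atoms(IDX_BACK_EXTRA[0], {"CA": cz + 3.0 * e3})
    set_atoms(IDX_BACK_EXTRA[1], {"CA": cz + 3.0 * e3 + 2.5 * e2})
    set_atoms(IDX_TYPE2[0], {"CA": cz - 6.0 * e3 - 7.0 * e2})
    set_atoms(IDX_TYPE2[1], {"CA": cz - 6.0 * e3 - 9.5 * e2})


# ------------------------------------------------------------ ligand placement

REGIONS = ("hinge", "back_pocket", "type2_only", "chelix_nterm", "glu4", "remote")


def _region_coords(chain: KinaseChain, anchors: AnchorMap, region: str) -> np.ndarray:
    if region == "hinge":
        idx = anchors.hinge_set
    elif region == "back_pocket":
        idx = anchors.back_pocket_set
    elif region == "type2_only":
        idx = anchors.type2_only_set
    elif region == "chelix_nterm":
        idx = anchors.chelix_nterm_set
    elif region == "glu4":
        idx = {anchors.chelix_glu_plus4} if anchors.chelix_glu_plus4 is not None else set()
    elif region == "remote":
        idx = set(range(len(chain.residues)))
    else:
        raise FixtureError(f"unknown region {region!r}")
    pts = [a.position for i in sorted(idx) for a in chain.residues[i].heavy_atoms()]
    if not pts:
        raise FixtureError(f"region {region!r} has no atoms")
    return np.vstack(pts)


def _fibonacci_sphere(n: int = 400) -> np.ndarray:
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ])


def _min_dist(p: np.ndarray, pts: np.ndarray) -> float:
    return float(np.linalg.norm(pts - p, axis=1).min())


def _new_ligand(chain: KinaseChain, coords: list[np.ndarray]) -> Residue:
    lig = Residue(
        name="LIG",
        author_number=900 + len(chain.hetero) + 1,
        atoms=[Atom(f"C{i+1}", "C", p) for i, p in enumerate(coords)],
        is_polymer=False,
    )
    chain.hetero.append(lig)
    return lig


def place_ligand(
    chain: KinaseChain,
    anchors: AnchorMap,
    region: str,
    distance: float,
    n_atoms: int = 1,
    clearance: float = 4.0,
) -> Residue:
    """Add a dummy ligand whose minimum distance to ``region`` equals
    ``distance`` (each atom sits exactly ``distance`` from a region atom)
    while staying strictly beyond ``clearance`` from every other region.

    Raises :class:`FixtureError` when no direction satisfies the request.
    """
    if region == "remote":
        return _place_remote(chain, distance, n_atoms)
    target = _region_coords(chain, anchors, region)
    others = [
        _region_coords(chain, anchors, r)
        for r in ("hinge", "back_pocket", "type2_only", "chelix_nterm", "glu4")
        if r != region
    ]
    order = np.lexsort((target[:, 2], target[:, 1], target[:, 0]))
    dirs = _fibonacci_sphere()
    placed: list[np.ndarray] = []
    for k in range(n_atoms):
        t = target[order[k % len(order)]]
        best, best_score = None, -math.inf
        for v in dirs:
            p = t + distance * v
            if _min_dist(p, target) < distance - 1e-9:
                continue
            score = min((_min_dist(p, o) for o in others), default=math.inf)
            if score <= clearance + 1e-9:
                continue
            if placed and _min_dist(p, np.vstack(placed)) < 1.2:
                continue
            if score > best_score:
                best, best_score = p, score
        if best is None:
            raise FixtureError(
                f"cannot place atom {k+1}/{n_atoms} at {distance} A from {region}"
            )
        placed.append(best)
    return _new_ligand(chain, placed)


def _place_remote(chain: KinaseChain, distance: float, n_atoms: int) -> Residue:
    all_pts = np.vstack([
        a.position for r in chain.residues for a in r.heavy_atoms()
    ])
    dirs = _fibonacci_sphere()
    placed: list[np.ndarray] = []
    for k in range(n_atoms):
        ok = None
        for v in dirs:
            t = all_pts[np.argmax(all_pts @ v)]   # extremal atom along v
            p = t + distance * v
            if _min_dist(p, all_pts) < distance - 1e-9:
                continue
            if placed and _min_dist(p, np.vstack(placed)) < 1.2:
                continue
            ok = p
            break
        if ok is None:
            raise FixtureError(f"cannot place remote atom at {distance} A")
        placed.append(ok)
    return _new_ligand(chain, placed)


def place_ligand_equidistant(
    chain: KinaseChain,
    anchors: AnchorMap,
    distance: float,
    clearance: float = 4.0,
) -> Residue:
    """One-atom ligand with equal minimum distance to the hinge set and to
    C-helix-Glu(+4), and beyond ``clearance`` from the remaining regions.

    Used to probe the allosteric screen, whose rule compares exactly these
    two minimum distances.
    """
    hinge = _region_coords(chain, anchors, "hinge")
    glu4 = _region_coords(chain, anchors, "glu4")
    # nearest pair of (hinge atom, glu4 atom)
    d = np.linalg.norm(hinge[:, None, :] - glu4[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    h, g = hinge[i], glu4[j]
    sep = float(np.linalg.norm(h - g))
    if 2.0 * distance < sep:
        raise FixtureError(
            f"equidistant placement needs distance >= {sep/2:.2f} A"
        )
    mid = 0.5 * (h + g)
    axis = (g - h) / sep
    height = math.sqrt(max(distance * distance - (sep / 2.0) ** 2, 0.0))
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    b1 = np.cross(axis, ref)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(axis, b1)
    others = [
        _region_coords(chain, anchors, r)
        for r in ("back_pocket", "type2_only", "chelix_nterm")
    ]
    for ang in np.linspace(0.0, 2.0 * math.pi, 360, endpoint=False):
        p = mid + height * (math.cos(ang) * b1 + math.sin(ang) * b2)
        if abs(_min_dist(p, hinge) - distance) > 1e-6:
            continue
        if abs(_min_dist(p, glu4) - distance) > 1e-6:
            continue
        if min(_min_dist(p, o) for o in others) <= clearance + 1e-9:
            continue
        return _new_ligand(chain, [p])
    raise FixtureError(f"no equidistant placement at {distance} A")


# ------------------------------------------------------------ helpers

def fixture_for_state(
    state: str,
    table: Optional[CentroidTable] = None,
    salt: float = 9.0,
    **kwargs,
) -> tuple[KinaseChain, AnchorMap]:
    """Build a fixture whose motif sits exactly at a shipped centroid state."""
    table = table or load_centroid_table()
    entry = table.entries[state]
    n = len(FixtureSpec.sequence)
    dih = _default_dihedrals(n, FixtureSpec.x_dfg_pos)
    x = FixtureSpec.x_dfg_pos
    a = entry.angles
    dih[x] = (a[0], a[1])
    dih[x + 1] = (a[2], a[3])
    dih[x + 2] = (a[4], a[5])
    d1, d2 = SPATIAL_TARGETS[entry.spatial]
    spec = FixtureSpec(
        backbone_dihedrals=dih,
        chi1_f=MODAL_CHI1[entry.rotamer],
        d1_target=d1,
        d2_target=d2,
        salt_bridge_target=salt,
        **kwargs,
    )
    return build_peptide(spec)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transform_chain(chain: KinaseChain, rotation: np.ndarray,
                    translation: np.ndarray) -> KinaseChain:
    """Rigid-body copy of a chain (hetero included)."""
    import copy

    out = copy.deepcopy(chain)
    for res in list(out.residues) + list(out.hetero):
        for atom in res.atoms:
            atom.position = rotation @ atom.position + np.asarray(translation, float)
    return out
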