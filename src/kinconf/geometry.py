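"""Torsion angles, rotamer bins, Ramachandran regions and the dihedral metric.

The dihedral distance between two conformations is the mean over the six
backbone torsions (phi/psi of X-DFG, DFG-Asp, DFG-Phe) of

    d(theta1, theta2) = 2 * (1 - cos(theta1 - theta2))

which is 0 for identical angles and 4 for angles 180 degrees apart; the
classification cutoff of 0.45 corresponds to a uniform offset of about
40 degrees on every angle.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .model import AnchorMap, DihedralVector, KinaseChain

__all__ = [
    "dihedral",
    "compute_dihedral_vector",
    "chi1_bin",
    "rama_region",
    "dihedral_distance",
    "DegenerateGeometryError",
    "IncompleteVectorError",
]


class DegenerateGeometryError(ValueError):
    """Raised when a torsion is undefined (coincident or collinear points)."""


class IncompleteVectorError(ValueError):
    """Raised when the dihedral distance is requested for incomplete vectors."""


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    The angle is measured looking down the p2->p3 bond; clockwise rotation of
    the far bond relative to the near bond is positive.  Result in
    (-180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b1) < 1e-9 or np.linalg.norm(b2) < 1e-9 or np.linalg.norm(b3) < 1e-9:
        raise DegenerateGeometryError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError("collinear consecutive points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = -np.degrees(np.arctan2(y, x))
    # normalise to (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def _res_coord(chain: KinaseChain, idx: Optional[int], atom: str):
    if idx is None or idx < 0 or idx >= len(chain.residues):
        return None
    return chain.residues[idx].coord(atom)


def _safe_dihedral(*points) -> Optional[float]:
    if any(p is None for p in points):
        return None
    try:
        return dihedral(*points)
    except DegenerateGeometryError:
        return None


def compute_dihedral_vector(chain: KinaseChain, anchors: AnchorMap) -> DihedralVector:
    """Measure the seven motif dihedrals from backbone N/CA/C atoms.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
    chi1 of the Phe = N-CA-CB-CG.  Any dihedral whose atoms are missing
    (unresolved residue, absent atom, chain terminus) is left as None.
    """
    vec = DihedralVector()
    triples = (("x", anchors.x_dfg), ("d", anchors.dfg_asp), ("f", anchors.dfg_phe))
    for tag, idx in triples:
        if idx is None:
            continue
        n = _res_coord(chain, idx, "N")
        ca = _res_coord(chain, idx, "CA")
        c = _res_coord(chain, idx, "C")
        c_prev = _res_coord(chain, idx - 1, "C")
        n_next = _res_coord(chain, idx + 1, "N")
        setattr(vec, f"phi_{tag}", _safe_dihedral(c_prev, n, ca, c))
        setattr(vec, f"psi_{tag}", _safe_dihedral(n, ca, c, n_next))
    if anchors.dfg_phe is not None:
        n = _res_coord(chain, anchors.dfg_phe, "N")
        ca = _res_coord(chain, anchors.dfg_phe, "CA")
        cb = _res_coord(chain, anchors.dfg_phe, "CB")
        cg = _res_coord(chain, anchors.dfg_phe, "CG")
        vec.chi1_f = _safe_dihedral(n, ca, cb, cg)
    return vec


def chi1_bin(chi1: Optional[float]) -> str:
    """Bin a chi1 angle into the sp3 rotamer wells.

    [0, 120) -> 'plus' (gauche+, modal +60); (-120, 0) -> 'minus'
    (gauche-, modal -60); the remaining third of the circle, boundaries
    included -> 'trans' (modal 180).  Missing chi1 -> 'none'.
    """
    if chi1 is None:
        return "none"
    a = float(chi1) % 360.0
    if a >= 180.0:
        a -= 360.0  # a in (-180, 180]
    if 0.0 <= a < 120.0:
        return "plus"
    if -120.0 < a < 0.0:
        return "minus"
    return "trans"


def rama_region(phi: Optional[float], psi: Optional[float]) -> str:
    """Letter for the Ramachandran region: B (beta), A (alpha), L (left-handed).

    phi >= 0 -> L; otherwise psi in [-120, 50) -> A (helical band), the rest
    of the psi circle -> B (sheet/PPII band).  Missing angle -> 'none'.
    """
    if phi is None or psi is None:
        return "none"
    phi = _wrap(phi)
    psi = _wrap(psi)
    if phi >= 0.0:
        return "L"
    if -120.0 <= psi < 50.0:
        return "A"
    return "B"


def _wrap(angle: float) -> float:
    a = float(angle) % 360.0
    if a > 180.0:
        a -= 360.0
    return a


def _elem_dist(a: float, b: float) -> float:
    return 2.0 * (1.0 - np.cos(np.radians(a - b)))


def dihedral_distance(v1: DihedralVector, v2: DihedralVector) -> float:
    """Mean angular distance over the six backbone dihedrals; range [0, 4]."""
    b1, b2 = v1.backbone(), v2.backbone()
    if any(a is None for a in b1) or any(a is None for a in b2):
        raise IncompleteVectorError("both vectors must have all six backbone angles")
    return float(np.mean([_elem_dist(a, b) for a, b in zip(b1, b2)]))
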