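"""Spatial, dihedral and C-helix labels for a kinase chain.

The spatial label places the DFG-Phe ring relative to the N-lobe using two
distances measured to the Phe zeta carbon:

    D1 = C-helix-Glu(+4) CA  ->  DFG-Phe CZ
    D2 = beta3-Lys CA        ->  DFG-Phe CZ

    DFGin:    D1 <= 11 and D2 >= 11
    DFGout:   D1 > 11  and D2 <= 14
    DFGinter: D1 <= 11 and D2 <= 11

evaluated in that order (at the shared D1 <= 11, D2 = 11 boundary the DFGin
clause wins).  Anything else is an outlier (label None).

The dihedral label is the nearest cluster centroid with the same spatial
group and chi1 rotamer bin, accepted only when the mean angular distance is
strictly below the cutoff (default 0.45, about a 40-degree uniform offset).

The C-helix disposition proxies the conserved Lys-Glu salt bridge: the
beta3-Lys CB to C-helix-Glu(+4) CB distance <= 10 A is 'in', > 10 A 'out'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .geometry import (
    chi1_bin,
    compute_dihedral_vector,
    dihedral_distance,
    rama_region,
)
from .model import EPS, AnchorMap, ConformationResult, DihedralVector, KinaseChain

__all__ = [
    "CentroidTable",
    "load_centroid_table",
    "diagnostic_distances",
    "spatial_label",
    "assign_dihedral_label",
    "chelix_label",
    "classify_chain",
    "DIHEDRAL_CUTOFF",
    "CHELIX_CUTOFF",
]

DIHEDRAL_CUTOFF = 0.45   # mean-of-six angular distance, strict inequality
CHELIX_CUTOFF = 10.0     # A, inclusive for 'in'

SPATIAL_STATES = ("DFGin", "DFGinter", "DFGout")


@dataclass(frozen=True)
class CentroidEntry:
    state: str
    spatial: str
    rotamer: str
    angles: tuple[float, float, float, float, float, float]

    def as_vector(self) -> DihedralVector:
        return DihedralVector(*self.angles)


class CentroidTable:
    """The 8 shipped cluster centroids, keyed by state name."""

    def __init__(self, entries: list[CentroidEntry], provenance: str = ""):
        self.entries = {e.state: e for e in entries}
        self.provenance = provenance
        self._audit()

    def _audit(self) -> None:
        """State names must agree with the centroid's own Ramachandran letters
        and rotamer bin; exactly the eight canonical states must be present."""
        expected = {
            "BLAminus", "BLAplus", "ABAminus", "BLBminus", "BLBplus",
            "BLBtrans", "BABtrans", "BBAminus",
        }
        if set(self.entries) != expected:
            raise ValueError(f"centroid table must contain exactly {sorted(expected)}")
        for e in self.entries.values():
            letters = e.state[:3]
            rotamer = e.state[3:]
            got = "".join(
                rama_region(e.angles[i], e.angles[i + 1]) for i in (0, 2, 4)
            )
            if got != letters:
                raise ValueError(
                    f"centroid {e.state}: Ramachandran letters {got} disagree with name"
                )
            if rotamer != e.rotamer:
                raise ValueError(f"centroid {e.state}: rotamer field {e.rotamer!r}")
            if e.spatial not in SPATIAL_STATES:
                raise ValueError(f"centroid {e.state}: bad spatial group {e.spatial!r}")

    def candidates(self, spatial: str, rotamer: str) -> list[CentroidEntry]:
        return [
            e for e in self.entries.values()
            if e.spatial == spatial and e.rotamer == rotamer
        ]


def load_centroid_table(path: Optional[Path] = None) -> CentroidTable:
    """Load a centroid table from TSV (default: the shipped table)."""
    if path is None:
        text = (resources.files("kinconf") / "data" / "centroids.tsv").read_text()
    else:
        text = Path(path).read_text()
    provenance_lines, entries = [], []
    header: Optional[list[str]] = None
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            provenance_lines.append(line.lstrip("# "))
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        entries.append(
            CentroidEntry(
                state=row["state"],
                spatial=row["spatial"],
                rotamer=row["rotamer"],
                angles=tuple(
                    float(row[k])
                    for k in ("phi_x", "psi_x", "phi_d", "psi_d", "phi_f", "psi_f")
                ),
            )
        )
    return CentroidTable(entries, provenance="\n".join(provenance_lines))


def _dist(a: Optional[np.ndarray], b: Optional[np.ndarray]) -> Optional[float]:
    if a is None or b is None:
        return None
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def diagnostic_distances(
    chain: KinaseChain, anchors: AnchorMap, chelix_atoms: str = "cb"
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(D1, D2, salt-bridge distance) in Angstroms; None where atoms are absent.

    ``chelix_atoms`` selects the salt-bridge proxy: "cb" (default) measures
    beta3-Lys CB to C-helix-Glu(+4) CB; "ca" measures beta3-Lys CA to
    C-helix-Glu CA.
    """

    def coord(idx: Optional[int], atom: str) -> Optional[np.ndarray]:
        if idx is None or idx < 0 or idx >= len(chain.residues):
            return None
        return chain.residues[idx].coord(atom)

    cz = coord(anchors.dfg_phe, "CZ")
    d1 = _dist(coord(anchors.chelix_glu_plus4, "CA"), cz)
    d2 = _dist(coord(anchors.b3_lys, "CA"), cz)
    if chelix_atoms == "cb":
        salt = _dist(coord(anchors.b3_lys, "CB"), coord(anchors.chelix_glu_plus4, "CB"))
    elif chelix_atoms == "ca":
        salt = _dist(coord(anchors.b3_lys, "CA"), coord(anchors.chelix_glu, "CA"))
    else:
        raise ValueError("chelix_atoms must be 'cb' or 'ca'")
    return d1, d2, salt


def spatial_label(d1: Optional[float], d2: Optional[float]) -> Optional[str]:
    """Assign DFGin / DFGout / DFGinter from the two diagnostic distances."""
    if d1 is None or d2 is None:
        return None
    if d1 <= 11.0 + EPS and d2 >= 11.0 - EPS:
        return "DFGin"
    if d1 > 11.0 + EPS and d2 <= 14.0 + EPS:
        return "DFGout"
    if d1 <= 11.0 + EPS and d2 <= 11.0 + EPS:
        return "DFGinter"
    return None


def assign_dihedral_label(
    vec: DihedralVector,
    spatial: Optional[str],
    table: CentroidTable,
    cutoff: float = DIHEDRAL_CUTOFF,
) -> tuple[Optional[str], Optional[float]]:
    """Nearest same-group, same-rotamer centroid if strictly below cutoff.

    Returns (state, minimum centroid distance); the distance is reported
    even when no state is assigned, and is None when the backbone vector is
    incomplete or the spatial label is None.
    """
    if spatial is None or not vec.complete:
        return None, None
    rotamer = chi1_bin(vec.chi1_f)
    if rotamer == "none":
        return None, None
    candidates = table.candidates(spatial, rotamer)
    if not candidates:
        return None, None
    best_state, best_d = None, math.inf
    for entry in sorted(candidates, key=lambda e: e.state):
        d = dihedral_distance(vec, entry.as_vector())
        if d < best_d:
            best_state, best_d = entry.state, d
    if best_d < cutoff - EPS:
        return best_state, best_d
    return None, best_d


def chelix_label(salt_bridge_distance: Optional[float],
                 cutoff: float = CHELIX_CUTOFF) -> str:
    """'in' when the salt-bridge proxy distance is <= cutoff, 'out' above,
    'unknown' when the distance could not be measured."""
    if salt_bridge_distance is None:
        return "unknown"
    return "in" if salt_bridge_distance <= cutoff + EPS else "out"


def classify_chain(
    chain: KinaseChain,
    anchors: AnchorMap,
    table: Optional[CentroidTable] = None,
    dihedral_cutoff: float = DIHEDRAL_CUTOFF,
    chelix_cutoff: float = CHELIX_CUTOFF,
    chelix_atoms: str = "cb",
) -> ConformationResult:
    """Full conformational classification; never raises on missing data."""
    if table is None:
        table = load_centroid_table()
    d1, d2, salt = diagnostic_distances(chain, anchors, chelix_atoms=chelix_atoms)
    spatial = spatial_label(d1, d2)
    vec = compute_dihedral_vector(chain, anchors)
    state, min_d = assign_dihedral_label(vec, spatial, table, cutoff=dihedral_cutoff)
    return ConformationResult(
        spatial=spatial,
        dihedral=state,
        chelix=chelix_label(salt, cutoff=chelix_cutoff),
        d1=d1,
        d2=d2,
        salt_bridge_distance=salt,
        min_centroid_distance=min_d,
        dihedrals=vec,
        group=anchors.group,
    )
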