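"""Core domain types shared by all modules.

A structure is decomposed into :class:`KinaseChain` objects (one per polymer
chain in the asymmetric unit).  Functional residues of the kinase domain are
located by an :class:`AnchorMap`, either resolved from a profile alignment
(:mod:`kinconf.profiles`) or supplied directly (synthetic fixtures).  The
classification layers consume only these types, so they are testable without
any real structure file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: residue names treated as water and dropped from hetero lists
WATER_NAMES = frozenset({"HOH", "DOD", "WAT"})

#: numeric tolerance for decision-rule comparisons: distances constructed to
#: sit exactly on a threshold carry O(1e-15) rounding, far below the 0.01 A
#: precision at which the thresholds are stated
EPS = 1e-9

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


def three_to_one(name: str) -> str:
    """1-letter code for a 3-letter residue name ('X' for non-standard)."""
    return _THREE_TO_ONE.get(name.upper(), "X")


@dataclass
class Atom:
    """A heavy atom or hydrogen with PDB-convention name and position (Å)."""

    name: str
    element: str
    position: np.ndarray  # shape (3,)
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if self.element.upper() in ("H", "D"):
            self.is_hydrogen = True


@dataclass
class Residue:
    """One residue with up to three parallel numbering schemes.

    ``author_number``/``insertion_code`` reproduce the deposited numbering;
    ``uniprot_number`` and ``common_number`` are filled in by renumbering
    (the common scheme is the alignment-column scheme in which the DFG motif
    is always 1338-1340).
    """

    name: str
    author_number: int
    insertion_code: str = ""
    uniprot_number: Optional[int] = None
    common_number: Optional[int] = None
    atoms: list[Atom] = field(default_factory=list)
    is_polymer: bool = True
    is_water: bool = False

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> Optional[np.ndarray]:
        a = self.atom(name)
        return None if a is None else a.position

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def one_letter(self) -> str:
        return three_to_one(self.name)


@dataclass
class KinaseChain:
    """One polymer chain plus the hetero residues deposited with it."""

    entry_id: str
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    hetero: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue_by_author(self, number: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.author_number == number and r.insertion_code == icode:
                return r
        return None

    def residue_by_common(self, number: int) -> Optional[Residue]:
        for r in self.residues:
            if r.common_number == number:
                return r
        return None


@dataclass
class AnchorMap:
    """Positions (indices into ``chain.residues``) of the functional residues.

    Every anchor is either a valid index / non-empty set or ``None`` / empty,
    meaning the anchor could not be resolved; downstream labels degrade to
    None rather than raising.
    """

    x_dfg: Optional[int] = None
    dfg_asp: Optional[int] = None
    dfg_phe: Optional[int] = None
    dfg_gly: Optional[int] = None
    b3_lys: Optional[int] = None
    chelix_glu: Optional[int] = None
    chelix_glu_plus4: Optional[int] = None
    hinge_set: frozenset[int] = frozenset()
    back_pocket_set: frozenset[int] = frozenset()
    type2_only_set: frozenset[int] = frozenset()
    chelix_nterm_set: frozenset[int] = frozenset()
    group: Optional[str] = None
    alignment_score: float = float("nan")

    def missing_anchors(self) -> list[str]:
        out = []
        for key in ("x_dfg", "dfg_asp", "dfg_phe", "dfg_gly", "b3_lys",
                    "chelix_glu", "chelix_glu_plus4"):
            if getattr(self, key) is None:
                out.append(key)
        return out


@dataclass
class DihedralVector:
    """The seven dihedrals that define a DFG-motif conformation (degrees).

    phi/psi of the residue before the motif (X-DFG), of DFG-Asp and of
    DFG-Phe, plus chi1 of the Phe side chain.  Angles live in (-180, 180];
    ``None`` marks a dihedral whose atoms were unresolved.
    """

    phi_x: Optional[float] = None
    psi_x: Optional[float] = None
    phi_d: Optional[float] = None
    psi_d: Optional[float] = None
    phi_f: Optional[float] = None
    psi_f: Optional[float] = None
    chi1_f: Optional[float] = None

    BACKBONE_FIELDS = ("phi_x", "psi_x", "phi_d", "psi_d", "phi_f", "psi_f")

    def backbone(self) -> tuple[Optional[float], ...]:
        return tuple(getattr(self, f) for f in self.BACKBONE_FIELDS)

    @property
    def complete(self) -> bool:
        """True when all six backbone dihedrals are present."""
        return all(v is not None for v in self.backbone())


@dataclass
class ConformationResult:
    """Labels plus the diagnostic quantities that produced them."""

    spatial: Optional[str]            # DFGin / DFGinter / DFGout / None
    dihedral: Optional[str]           # e.g. BLAminus, or None
    chelix: str                       # in / out / unknown
    d1: Optional[float]
    d2: Optional[float]
    salt_bridge_distance: Optional[float]
    min_centroid_distance: Optional[float]
    dihedrals: DihedralVector
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.spatial is None and self.dihedral is not None:
            raise ValueError("dihedral label requires a spatial label")


@dataclass
class ContactProfile:
    """Per-(chain, ligand) contact counts and minimum distances (Å).

    Contacts are heavy-atom pairs at most the contact cutoff apart; counts
    aggregate pairs per pocket region.  Minimum distances are over all
    heavy-atom pairs to the named set and are +inf when the set is empty.
    """

    ligand_id: str
    n_hinge: int = 0
    n_back: int = 0
    n_type2only: int = 0
    n_chelix_nterm: int = 0
    min_hinge_dist: float = float("inf")
    min_glu4_dist: float = float("inf")
    min_any_dist: float = float("inf")


@dataclass
class LigandTypeResult:
    profile: ContactProfile
    type: str  # Type1 / Type1.5_front / Type1.5_back / Type2 / Type3 / Allosteric / NotBound


def chain_coordinates(chain: KinaseChain, include_hetero: bool = False) -> np.ndarray:
    """All atom positions of a chain as an (n, 3) array (polymer first)."""
    pts: list[np.ndarray] = []
    for r in chain.residues:
        pts.extend(a.position for a in r.atoms)
    if include_hetero:
        for r in chain.hetero:
            pts.extend(a.position for a in r.atoms)
    if not pts:
        return np.empty((0, 3))
    return np.vstack(pts)
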