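"""Reading and writing structures and reports.

Parsing is delegated to gemmi (PDB, mmCIF, optionally gzip-compressed);
only the first model of multi-model files is used, and for alternate
conformations the highest-occupancy altloc is kept (ties broken toward
altloc 'A').  Output coordinate files are mmCIF with a selectable residue
numbering scheme; reports are plain TSV.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import pandas as pd

from .model import Atom, ConformationResult, KinaseChain, LigandTypeResult, Residue, WATER_NAMES

__all__ = [
    "parse_structure",
    "write_renumbered",
    "write_report",
    "read_report",
    "ParseError",
    "EmptyStructureError",
    "REPORT_COLUMNS",
]


class ParseError(ValueError):
    """The file could not be parsed as PDB or mmCIF."""


class EmptyStructureError(ValueError):
    """The file parsed but contains no polymer chain."""


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None:
        return info.is_amino_acid() or info.is_nucleic_acid()
    return False


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per atom name: highest occupancy, ties toward altloc 'A'."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            continue
        key_new = (-atom.occ, atom.altloc or "A")
        key_old = (-prev.occ, prev.altloc or "A")
        if key_new < key_old:
            best[atom.name] = atom
    return list(best.values())


def _convert_residue(res: gemmi.Residue, is_polymer: bool) -> Residue:
    atoms = [
        Atom(
            name=a.name,
            element=a.element.name,
            position=(a.pos.x, a.pos.y, a.pos.z),
        )
        for a in _pick_altlocs(res)
    ]
    icode = res.seqid.icode.strip()
    return Residue(
        name=res.name,
        author_number=res.seqid.num,
        insertion_code=icode,
        atoms=atoms,
        is_polymer=is_polymer,
        is_water=res.name.upper() in WATER_NAMES or res.is_water(),
    )


def parse_structure(path, format_hint: Optional[str] = None) -> list[KinaseChain]:
    """Parse a PDB/mmCIF file into one :class:`KinaseChain` per polymer chain.

    ``format_hint`` may be "pdb" or "cif"; by default the format is inferred
    from the extension/content.  Hetero residues (waters excluded) are
    attached to the chain with the same author chain id; hetero residues on
    a chain with no polymer are attached to the first polymer chain so they
    remain visible to the asymmetric-unit ligand screen.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        if format_hint == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        elif format_hint == "cif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path.name}: no models")
    model = st[0]  # first model only

    chains: dict[str, KinaseChain] = {}
    orphans: list[Residue] = []
    for gch in model:
        kc = chains.setdefault(
            gch.name, KinaseChain(entry_id=st.name or path.stem, chain_id=gch.name)
        )
        for res in gch:
            if _is_polymer_residue(res):
                kc.residues.append(_convert_residue(res, is_polymer=True))
            else:
                conv = _convert_residue(res, is_polymer=False)
                if not conv.is_water:
                    kc.hetero.append(conv)
    polymer = [c for c in chains.values() if c.residues]
    if not polymer:
        raise EmptyStructureError(f"{path.name}: no polymer chains")
    # re-home hetero residues that sit on ligand-only author chains
    for c in chains.values():
        if not c.residues and c.hetero:
            polymer[0].hetero.extend(c.hetero)
    return polymer


_SCHEMES = ("author", "uniprot", "common")


def write_renumbered(chain: KinaseChain, scheme: str, path) -> None:
    """Write one chain as mmCIF with the selected numbering scheme.

    ``scheme`` is "author", "uniprot" or "common"; the latter two must be
    populated on every polymer residue (run the renumbering first).
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"scheme must be one of {_SCHEMES}")
    if scheme != "author":
        attr = f"{scheme}_number"
        missing = [r.author_number for r in chain.residues if getattr(r, attr) is None]
        if missing:
            raise ValueError(
                f"{scheme} numbering not populated for residues {missing[:5]}..."
            )
    st = gemmi.Structure()
    st.name = chain.entry_id
    model = gemmi.Model("1")
    gch = gemmi.Chain(chain.chain_id)

    def add(res: Residue, number: int, icode: str, het: bool) -> None:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(number, icode or " ")
        gres.het_flag = "H" if het else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.position)
            ga.occ = 1.0
            gres.add_atom(ga)
        gch.add_residue(gres)

    for res in chain.residues:
        if scheme == "author":
            add(res, res.author_number, res.insertion_code, het=False)
        else:
            # insertion codes are flattened out of uniprot/common numbering
            add(res, getattr(res, f"{scheme}_number"), "", het=False)
    for het in chain.hetero:
        add(het, het.author_number, het.insertion_code, het=True)
    model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))


REPORT_COLUMNS = [
    "entry", "chain", "group", "gene", "spatial", "dihedral", "chelix",
    "d1", "d2", "salt_bridge", "min_centroid_distance", "ligand", "ligand_type",
]


def _fmt(value: Optional[float], ndigits: int) -> str:
    if value is None or (isinstance(value, float) and not math.isfinite(value)):
        return "-"
    return f"{value:.{ndigits}f}"


def report_rows(
    entry: str,
    chain_id: str,
    conf: ConformationResult,
    ligands: Sequence[LigandTypeResult] = (),
    gene: Optional[str] = None,
) -> list[dict]:
    """One report row per ligand, or a single ligand-free row for apo chains."""
    base = {
        "entry": entry,
        "chain": chain_id,
        "group": conf.group or "-",
        "gene": gene or "-",
        "spatial": conf.spatial or "None",
        "dihedral": conf.dihedral or "None",
        "chelix": conf.chelix,
        "d1": _fmt(conf.d1, 2),
        "d2": _fmt(conf.d2, 2),
        "salt_bridge": _fmt(conf.salt_bridge_distance, 2),
        "min_centroid_distance": _fmt(conf.min_centroid_distance, 3),
    }
    if not ligands:
        return [{**base, "ligand": "-", "ligand_type": "-"}]
    return [
        {**base, "ligand": lr.profile.ligand_id, "ligand_type": lr.type}
        for lr in ligands
    ]


def write_report(rows: Iterable[dict], path) -> None:
    """Write report rows as TSV with a fixed, versioned column order."""
    df = pd.DataFrame(list(rows), columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
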