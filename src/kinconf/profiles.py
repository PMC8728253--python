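"""Kinase-domain detection and anchor resolution via group profiles.

Ten profile HMMs — one per kinase phylogenetic group (AGC, CAMK, CK1, CMGC,
NEK, RGC, STE, TKL, TYR, OTHER) — are built at load time from the shipped
per-group seed alignments.  A query sequence is searched against all ten;
the best-scoring profile (ties broken alphabetically and logged) yields the
group and a residue-to-column alignment.  Profile columns carry the common
residue numbering in which the DFG motif is 1338-1340, so the alignment
immediately resolves every anchor and pocket residue.

The shipped seed library is synthetic (see its header and
``scripts/build_seed_library.py``): it pins the universally conserved kinase
motifs at the reference columns and separates groups by deterministic
signature substitutions.  Real, externally built seed alignments in the same
FASTA convention can be substituted via ``load_profile_library(path)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pyhmmer

from .model import AnchorMap, KinaseChain

__all__ = [
    "GroupProfile",
    "AnchorDefinitions",
    "DomainHit",
    "NotAKinaseError",
    "load_profile_library",
    "load_anchor_definitions",
    "detect_domain",
    "build_anchor_map",
    "detect_and_map",
    "SCORE_THRESHOLD",
    "MIN_SEQUENCE_LENGTH",
    "COMMON_OFFSET",
]

logger = logging.getLogger(__name__)

#: bit-score threshold below which a chain is not considered a kinase domain.
#: Profile members score in the hundreds of bits; shuffled or unrelated
#: sequences score near or below zero.
SCORE_THRESHOLD = 50.0
MIN_SEQUENCE_LENGTH = 50

#: common number of profile column 1 (column i -> common number 1190 + i,
#: placing the DFG-Asp column, 148, at 1338)
COMMON_OFFSET = 1190

_ALPHABET = pyhmmer.easel.Alphabet.amino()


class NotAKinaseError(ValueError):
    """No group profile matches the sequence above the score threshold."""


@dataclass
class GroupProfile:
    group_name: str
    hmm: pyhmmer.plan7.HMM
    column_map: dict[int, int]  # profile column (1-based) -> common number


@dataclass
class DomainHit:
    group: str
    score: float
    residue_to_common: dict[int, int]  # 0-based residue index -> common number


@dataclass(frozen=True)
class AnchorDefinitions:
    """Functional-residue roles in common-number space (shipped as data)."""

    x_dfg: int
    dfg_asp: int
    dfg_phe: int
    dfg_gly: int
    b3_lys: int
    chelix_glu: int
    chelix_glu_plus4: int
    hinge: frozenset[int]
    back_pocket: frozenset[int]
    type2_only: frozenset[int]
    chelix: frozenset[int]
    chelix_nterm: frozenset[int]


def _parse_number_spec(spec: str) -> frozenset[int]:
    out: set[int] = set()
    for part in spec.split(","):
        part = part.strip()
        if "-" in part[1:]:
            lo, hi = part.split("-")
            out.update(range(int(lo), int(hi) + 1))
        elif part:
            out.add(int(part))
    return frozenset(out)


def load_anchor_definitions(path: Optional[Path] = None) -> AnchorDefinitions:
    if path is None:
        text = (resources.files("kinconf") / "data" / "anchors.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, frozenset[int]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("role\t"):
            continue
        role, numbers = line.split("\t")
        table[role] = _parse_number_spec(numbers)

    def single(role: str) -> int:
        (value,) = table[role]
        return value

    return AnchorDefinitions(
        x_dfg=single("x_dfg"),
        dfg_asp=single("dfg_asp"),
        dfg_phe=single("dfg_phe"),
        dfg_gly=single("dfg_gly"),
        b3_lys=single("b3_lys"),
        chelix_glu=single("chelix_glu"),
        chelix_glu_plus4=single("chelix_glu_plus4"),
        hinge=table["hinge"],
        back_pocket=table["back_pocket"],
        type2_only=table["type2_only"],
        chelix=table["chelix"],
        chelix_nterm=table["chelix_nterm"],
    )


def _read_seed_fasta(text: str) -> dict[str, list[tuple[str, str]]]:
    groups: dict[str, list[tuple[str, str]]] = {}
    name, buf = None, []
    for line in text.splitlines() + [">end|"]:
        if line.startswith(">"):
            if name is not None:
                group = name.split("|")[0]
                groups.setdefault(group, []).append((name, "".join(buf)))
            name, buf = line[1:].strip(), []
        else:
            buf.append(line.strip())
    groups.pop("end", None)
    return groups


def load_profile_library(path: Optional[Path] = None) -> list[GroupProfile]:
    """Build the ten group HMMs from a seed-alignment FASTA.

    Seed headers are ``>GROUP|seedname``; sequences within a group must be
    aligned (equal length; here, ungapped), so profile column k maps to
    common number ``COMMON_OFFSET + k``.
    """
    if path is None:
        text = (
            resources.files("kinconf") / "data" / "seed_alignments_synthetic.fasta"
        ).read_text()
    else:
        text = Path(path).read_text()
    groups = _read_seed_fasta(text)
    builder = pyhmmer.plan7.Builder(_ALPHABET)
    background = pyhmmer.plan7.Background(_ALPHABET)
    library = []
    for group in sorted(groups):
        seqs = [
            pyhmmer.easel.TextSequence(name=n.encode(), sequence=s)
            for n, s in groups[group]
        ]
        lengths = {len(s.sequence) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"group {group}: seed sequences are not aligned")
        msa = pyhmmer.easel.TextMSA(name=group.encode(), sequences=seqs)
        hmm, _, _ = builder.build_msa(msa.digitize(_ALPHABET), background)
        ncols = lengths.pop()
        column_map = {k: COMMON_OFFSET + k for k in range(1, ncols + 1)}
        library.append(GroupProfile(group, hmm, column_map))
    return library


_DEFAULT_LIBRARY: Optional[list[GroupProfile]] = None


def default_library() -> list[GroupProfile]:
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = load_profile_library()
    return _DEFAULT_LIBRARY


def _alignment_map(alignment, column_map: dict[int, int]) -> dict[int, int]:
    """0-based target residue index -> common number, match columns only."""
    out: dict[int, int] = {}
    hmm_pos = alignment.hmm_from          # 1-based
    target_pos = alignment.target_from    # 1-based
    for hc, tc in zip(alignment.hmm_sequence, alignment.target_sequence):
        hmm_gap = hc == "."
        target_gap = tc == "-"
        if not hmm_gap and not target_gap:
            common = column_map.get(hmm_pos)
            if common is not None:
                out[target_pos - 1] = common
        if not hmm_gap:
            hmm_pos += 1
        if not target_gap:
            target_pos += 1
    return out


def detect_domain(
    sequence: str,
    library: Optional[list[GroupProfile]] = None,
    threshold: float = SCORE_THRESHOLD,
) -> DomainHit:
    """Find the best-matching group profile for a protein sequence.

    Raises ``ValueError`` for sequences shorter than the minimum and
    :class:`NotAKinaseError` when no profile scores above ``threshold``.
    """
    if len(sequence) < MIN_SEQUENCE_LENGTH:
        raise ValueError(
            f"sequence length {len(sequence)} below minimum {MIN_SEQUENCE_LENGTH}"
        )
    if library is None:
        library = default_library()
    background = pyhmmer.plan7.Background(_ALPHABET)
    query = pyhmmer.easel.TextSequence(name=b"query", sequence=sequence)
    block = pyhmmer.easel.DigitalSequenceBlock(_ALPHABET, [query.digitize(_ALPHABET)])
    best: Optional[tuple[str, float, object]] = None
    tie = False
    for profile in sorted(library, key=lambda p: p.group_name):
        pipeline = pyhmmer.plan7.Pipeline(_ALPHABET, background=background)
        hits = pipeline.search_hmm(profile.hmm, block)
        if not hits:
            continue
        score = hits[0].score
        if best is not None and score == best[1]:
            tie = True
        if best is None or score > best[1]:
            domain = max(hits[0].domains, key=lambda d: d.score)
            best = (profile.group_name, score, (domain.alignment, profile.column_map))
    if best is None or best[1] < threshold:
        got = f"best score {best[1]:.1f}" if best else "no hits"
        raise NotAKinaseError(f"no kinase-domain match ({got}, threshold {threshold})")
    if tie:
        logger.warning("profile score tie; keeping alphabetically first group %s", best[0])
    alignment, column_map = best[2]
    return DomainHit(
        group=best[0],
        score=best[1],
        residue_to_common=_alignment_map(alignment, column_map),
    )


def build_anchor_map(
    chain: KinaseChain,
    hit: DomainHit,
    definitions: Optional[AnchorDefinitions] = None,
) -> AnchorMap:
    """Resolve anchors and pocket sets on a chain from its profile alignment.

    Side effect: writes ``common_number`` (and, lacking an external
    residue-level mapping, ``uniprot_number`` as the author-number
    approximation) onto the aligned residues.  Anchors whose columns are
    unaligned are left missing; the map is always returned.
    """
    defs = definitions or load_anchor_definitions()
    common_to_idx: dict[int, int] = {}
    for idx, res in enumerate(chain.residues):
        common = hit.residue_to_common.get(idx)
        res.common_number = common
        if res.uniprot_number is None:
            res.uniprot_number = res.author_number
        if common is not None:
            common_to_idx[common] = idx

    def lookup(common: int) -> Optional[int]:
        return common_to_idx.get(common)

    def lookup_set(commons: frozenset[int]) -> frozenset[int]:
        return frozenset(
            i for c in commons if (i := common_to_idx.get(c)) is not None
        )

    return AnchorMap(
        x_dfg=lookup(defs.x_dfg),
        dfg_asp=lookup(defs.dfg_asp),
        dfg_phe=lookup(defs.dfg_phe),
        dfg_gly=lookup(defs.dfg_gly),
        b3_lys=lookup(defs.b3_lys),
        chelix_glu=lookup(defs.chelix_glu),
        chelix_glu_plus4=lookup(defs.chelix_glu_plus4),
        hinge_set=lookup_set(defs.hinge),
        back_pocket_set=lookup_set(defs.back_pocket),
        type2_only_set=lookup_set(defs.type2_only),
        chelix_nterm_set=lookup_set(defs.chelix_nterm),
        group=hit.group,
        alignment_score=hit.score,
    )


def anchor_map_from_common_numbering(
    chain: KinaseChain,
    definitions: Optional[AnchorDefinitions] = None,
) -> AnchorMap:
    """Resolve anchors on a chain whose residue numbers ARE common numbers.

    Used for structures already renumbered to the alignment-column scheme
    (e.g. files this package wrote with scheme="common"); no profile search
    is performed.
    """
    defs = definitions or load_anchor_definitions()
    hit = DomainHit(
        group=None,
        score=float("nan"),
        residue_to_common={
            i: r.author_number for i, r in enumerate(chain.residues)
        },
    )
    return build_anchor_map(chain, hit, definitions=defs)


def detect_and_map(
    chain: KinaseChain,
    library: Optional[list[GroupProfile]] = None,
    definitions: Optional[AnchorDefinitions] = None,
    threshold: float = SCORE_THRESHOLD,
) -> AnchorMap:
    """Detect the kinase domain in a chain and resolve its anchor map."""
    hit = detect_domain(chain.sequence, library=library, threshold=threshold)
    return build_anchor_map(chain, hit, definitions=definitions)


def consensus_sequence(profile: GroupProfile) -> str:
    """Majority-rule consensus emission of a group profile."""
    return profile.hmm.consensus.upper()
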