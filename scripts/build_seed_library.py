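"""Regenerate the synthetic per-group seed alignments shipped with kinconf.

The library is a stand-in for profile models built from a real structure-based
kinase alignment, which cannot be redistributed here.  Each phylogenetic group
gets four synthetic kinase-like sequences sharing one 262-column scaffold
(matching the common-numbering frame: scaffold column i corresponds to common
number 1190 + i) with the universally conserved kinase motifs pinned at their
reference columns:

    glycine-rich loop  GKGKFG   columns 15-20
    beta3 lysine       AMK      columns 34-36   (K = common 1226)
    C-helix glutamate  E        column  55      (common 1245)
    catalytic loop     HRD      columns 128-130
    DFG motif          DFG      columns 148-150 (common 1338-1340)
    APE motif          APE      columns 171-173

Group identity is carried by a deterministic 25% substitution signature on
non-motif columns; the four seeds per group add a further 8% within-group
variation.  Running this script rewrites
src/kinconf/data/seed_alignments_synthetic.fasta byte-identically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

GROUPS = ["AGC", "CAMK", "CK1", "CMGC", "NEK", "OTHER", "RGC", "STE", "TKL", "TYR"]
LENGTH = 262
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
MASTER_SEED = 12345
N_SEEDS = 4

MOTIFS: dict[int, str] = {}          # 1-based column -> residue
for start, motif in ((15, "GKGKFG"), (34, "AMK"), (128, "HRD"),
                     (148, "DFG"), (171, "APE")):
    for k, ch in enumerate(motif):
        MOTIFS[start + k] = ch
MOTIFS[55] = "E"


def _scaffold() -> list[str]:
    rng = np.random.default_rng(MASTER_SEED)
    seq = [ALPHABET[i] for i in rng.integers(0, len(ALPHABET), LENGTH)]
    for col, ch in MOTIFS.items():
        seq[col - 1] = ch
    return seq


def _mutate(seq: list[str], rng: np.random.Generator, rate: float) -> list[str]:
    out = list(seq)
    for i in range(LENGTH):
        if (i + 1) in MOTIFS:
            continue
        if rng.random() < rate:
            out[i] = ALPHABET[int(rng.integers(0, len(ALPHABET)))]
    return out


def generate() -> dict[str, list[str]]:
    scaffold = _scaffold()
    library: dict[str, list[str]] = {}
    for gi, group in enumerate(GROUPS):
        g_rng = np.random.default_rng([MASTER_SEED, gi])
        signature = _mutate(scaffold, g_rng, 0.25)
        seeds = []
        for si in range(N_SEEDS):
            s_rng = np.random.default_rng([MASTER_SEED, gi, si])
            seeds.append("".join(_mutate(signature, s_rng, 0.08)))
        library[group] = seeds
    return library


def main() -> None:
    out = Path(__file__).resolve().parents[1] / "src" / "kinconf" / "data" / \
        "seed_alignments_synthetic.fasta"
    lines = []
    for group, seeds in generate().items():
        for si, seq in enumerate(seeds, 1):
            lines.append(f">{group}|seed{si}")
            lines.append(seq)
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
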