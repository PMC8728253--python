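# kinconf

Conformational-state and inhibitor-type classification of protein kinase
structures.

Protein kinases share one fold but occupy many functional states, and the
geometry of the Asp-Phe-Gly (DFG) motif at the start of the activation loop
is the most informative single descriptor of that state: the active enzyme,
the "SRC-inactive" and "CDK-inactive" states, and the DFG-out state targeted
by type 2 inhibitors such as imatinib all differ in where the DFG-Phe side
chain sits and which backbone torsions put it there.  `kinconf` takes a
structure file (PDB or mmCIF, optionally gzipped), finds the kinase domain in
each chain, and assigns:

* a **spatial DFG label** — DFGin, DFGinter, DFGout or None — from two
  diagnostic distances to the DFG-Phe ζ-carbon,

  ```
  D1 = d(αC-Glu(+4) Cα, DFG-Phe Cζ)      D2 = d(β3-Lys Cα, DFG-Phe Cζ)

  DFGin:    D1 ≤ 11 Å and D2 ≥ 11 Å
  DFGout:   D1 > 11 Å and D2 ≤ 14 Å
  DFGinter: D1 ≤ 11 Å and D2 ≤ 11 Å      (anything else → None)
  ```

* a **dihedral label** — one of BLAminus, BLAplus, ABAminus, BLBminus,
  BLBplus, BLBtrans (DFGin), BABtrans (DFGinter), BBAminus (DFGout), or
  None.  The name encodes the Ramachandran region (B/A/L) of the X-DFG,
  DFG-Asp and DFG-Phe residues plus the Phe χ₁ rotamer (plus/minus/trans).
  A chain is assigned to the nearest cluster centroid with matching spatial
  group and rotamer, under the mean angular distance over the six backbone
  torsions φ,ψ of X-DFG, Asp, Phe:

  ```
  D(i,j) = (1/6) Σ 2·(1 − cos(θᵢ − θⱼ)),    assigned iff D < 0.45 (≈ 40°)
  ```

* the **C-helix disposition** — `in` if the β3-Lys Cβ to C-helix-Glu(+4) Cβ
  distance (a proxy for the conserved Lys–Glu salt bridge) is ≤ 10 Å,
  otherwise `out`,

* an **inhibitor type** for every bound small molecule — Type 1 (ATP site),
  Type 1.5_front / 1.5_back (ATP site + back pocket, with/without contact to
  the C-helix N-terminal region), Type 2 (back pocket + DFGout-only pocket),
  Type 3 (back pocket without the ATP site), or Allosteric (> 6.5 Å from
  both the hinge and C-helix-Glu(+4)) — from heavy-atom contacts at ≤ 4.0 Å
  with pocket residues defined in a kinase-wide common numbering
  (DFG = 1338–1340).

Domain detection aligns each chain against ten per-group profile HMMs
(AGC, CAMK, CK1, CMGC, NEK, RGC, STE, TKL, TYR, OTHER); the best-scoring
profile supplies the phylogenetic group and the residue-to-common-number
mapping that resolves all anchors.  See `docs/methods.md` for the model
details, defaults and limitations.

## Worked example

The package ships a synthetic-structure builder (`kinconf.fixtures`) that
realises prescribed motif dihedrals and anchor distances exactly, so every
rule can be demonstrated without downloading structures:

```python
from kinconf.fixtures import fixture_for_state, place_ligand
from kinconf.conformation import classify_chain
from kinconf.ligands import classify_ligands

chain, anchors = fixture_for_state("BLAminus")   # active-state geometry
place_ligand(chain, anchors, "hinge", 3.5, 1)    # one atom 3.5 A from the hinge

result = classify_chain(chain, anchors)
print(f"spatial={result.spatial}  dihedral={result.dihedral}  chelix={result.chelix}")
print(f"D1={result.d1:.2f} A  D2={result.d2:.2f} A  salt bridge={result.salt_bridge_distance:.2f} A")
for lig in classify_ligands([chain], chain, anchors):
    p = lig.profile
    print(f"{p.ligand_id}: n_hinge={p.n_hinge}  min_hinge={p.min_hinge_dist:.1f} A  -> {lig.type}")
```

prints

```
spatial=DFGin  dihedral=BLAminus  chelix=in
D1=9.50 A  D2=13.50 A  salt bridge=9.00 A
LIG:901: n_hinge=1  min_hinge=3.5 A  -> Type1
```

The chain was built at the BLAminus centroid with D1/D2 inside the DFGin
window and the salt bridge formed, so it classifies as the catalytically
active state; a ligand touching only the hinge is an ATP-site (Type 1)
binder.  The same run from the shell, via a structure file in the common
numbering:

```
$ kinconf -i example.cif --out out/ --assume-common-numbering
classified 1 chain(s) from 1 file(s); report: out/report.tsv

$ cat out/report.tsv
entry  chain  group  gene  spatial  dihedral  chelix  d1    d2     salt_bridge  min_centroid_distance  ligand   ligand_type
FIXT   A      -      -     DFGin    BLAminus  in      9.50  13.50  9.00         0.000                  LIG:901  Type1
```

Without `--assume-common-numbering` the CLI runs profile detection on each
chain's sequence; chains that match no kinase profile are reported as
`NotAKinase` and skipped.

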