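# Methods

## Classification model

A kinase chain is described by the geometry of its DFG motif (the residue
before it, "X-DFG", plus Asp, Phe, Gly) relative to two conserved N-lobe
residues: the β3-strand lysine and the glutamate four residues after the
C-helix glutamate ("Glu(+4)").  Three layers of labels are assigned, each
degrading to `None`/`unknown` rather than raising when atoms are missing:

1. **Spatial label.** D1 (Glu(+4) Cα → Phe Cζ) and D2 (β3-Lys Cα → Phe Cζ)
   place the Phe ring in the active site.  The clauses

       DFGin:    D1 ≤ 11 Å and D2 ≥ 11 Å
       DFGout:   D1 > 11 Å and D2 ≤ 14 Å
       DFGinter: D1 ≤ 11 Å and D2 ≤ 11 Å

   are evaluated in that order; on the shared boundary (D1 ≤ 11, D2 = 11)
   both the DFGin and DFGinter clauses hold and DFGin wins by listed order —
   it is evaluated first and is by far the majority class.  A pair matching
   no clause is an outlier (label None).

2. **Dihedral label.** The conformation vector is the six backbone torsions
   (φ, ψ of X-DFG, Asp, Phe) plus the Phe χ₁.  χ₁ is binned into 120°-wide
   sp³ rotamer windows centred on +60° (`plus`, [0°, 120°)), −60° (`minus`,
   (−120°, 0°)) and 180° (`trans`, the remaining third, boundaries
   included).  Candidate centroids are those sharing the chain's spatial
   group and rotamer bin; the chain takes the nearest centroid's name iff
   the mean angular distance

       D(i,j) = (1/6) Σ_k 2·(1 − cos(θ_k,i − θ_k,j))

   is strictly below 0.45.  A uniform offset θ on all six angles crosses the
   cutoff at θ = arccos(1 − 0.225) ≈ 38.9°, i.e. "about 40°".  Note that
   2(1 − cos Δ) = 4 sin²(Δ/2) is a *squared* chordal distance: D is
   symmetric, zero on equal vectors and bounded by 4, but it does not obey
   the triangle inequality (counterexample: uniform 60°/60°/120° offsets
   give 3 > 1 + 1); its square root is the corresponding metric on the
   6-torus.  Nothing in the classifier depends on the triangle inequality —
   only nearest-centroid comparisons against a fixed cutoff are made.

3. **C-helix disposition.** The β3-Lys Cβ to Glu(+4) Cβ distance proxies
   the conserved Lys–Glu salt bridge: ≤ 10 Å is `in`, > 10 Å is `out`.  An
   alternative convention measures β3-Lys Cα to C-helix-Glu Cα; both appear
   in the literature, the Cβ/Glu(+4) form is the default here and the Cα
   form is available via `diagnostic_distances(..., chelix_atoms="ca")`.

**Ligand typing.** A contact is a heavy-atom pair (ligand atom, atom of a
pocket residue) at ≤ 4.0 Å; hydrogens never count.  Contacts are counted as
atom pairs, not contacting residues — the rules speak of "three or more
contacts" without fixing the unit, and pair counting is the more natural
reading for a distance-based program; residue-level counting is available
via `contact_profile(..., count_residues=True)` for sensitivity checks.
The rules are applied most-specific-first so a profile satisfying several
clauses gets the most informative label (a Type 2 profile always also
satisfies Type 1.5_back):

    Allosteric      min distance to hinge > 6.5 Å and to Glu(+4) > 6.5 Å
    Type 2          ≥ 3 back-pocket contacts and ≥ 1 Type-2-only contact
    Type 3          min hinge distance > 6 Å and ≥ 3 back-pocket contacts
    Type 1.5_front  ≥ 3 back-pocket contacts and ≥ 1 C-helix N-terminal contact
    Type 1.5_back   ≥ 3 back-pocket contacts
    Type 1          everything else

Candidate ligands are all non-water hetero residues in the asymmetric unit
within 5 Å of the target chain, on any author chain, minus a documented
exclusion list of crystallisation additives and ions (`DEFAULT_EXCLUDED`).
Covalent ligands receive no special treatment (purely distance-based).

## Common numbering, anchors and profiles

All pocket definitions live in a kinase-wide "common" residue numbering in
which aligned positions share one number and the DFG motif is 1338–1340.
The shipped anchor table (`data/anchors.tsv`) fixes the other roles by a
constant offset from the Aurora A reference numbering (common = author +
1064): β3-Lys 1226, C-helix-Glu 1245, Glu(+4) 1249, hinge 1275–1277, back
pocket 1230–1257 ∪ 1260–1268 ∪ 1269–1271 ∪ 1337–1339, Type-2-only pocket
{1248, 1252, 1311, 1318}.  The C-helix span is taken as 1240–1257 and its
"N-terminal region" — not numerically fixed anywhere we know of — defaults
to the first half, 1240–1248; both are table entries and can be repointed
with `--anchors`.

Domain detection searches the chain sequence against ten per-group profile
HMMs built at load time (pyhmmer) from the shipped seed alignments.  The
shipped library (`data/seed_alignments_synthetic.fasta`) is **synthetic**:
four kinase-like sequences per group over a common 262-column scaffold with
the universally conserved motifs (G-loop, β3 Lys, C-helix Glu, HRD, DFG,
APE) pinned at reference columns and group identity carried by deterministic
signature substitutions (regenerate with `scripts/build_seed_library.py`).
It reproduces the published architecture — ten group profiles whose best
hit yields the group and the residue↔column map — without redistributing
any real alignment; for production use on arbitrary PDB chains, substitute
profiles built from a real structure-based kinase alignment via
`load_profile_library(path)`.  The acceptance threshold is 50 bits: seed
members and consensus sequences score in the hundreds of bits, while
shuffled kinase sequences and poly-alanine score near zero and are rejected
(`NotAKinase`).  Score ties break alphabetically by group and are logged.

UniProt renumbering proper requires an external residue-level mapping
(e.g. SIFTS) that this package does not consume; the `uniprot` scheme is
populated as the author numbering unless the caller sets it, and is best
treated as a placeholder.

## Centroid table

`data/centroids.tsv` carries the eight states with their spatial group,
rotamer bin and six backbone centroids.  The shipped values are a synthetic
convention of this package — circular-mean-style estimates over canonical
exemplar conformations of each state, chosen so that every centroid is
self-consistent with its own name (the table loader audits that the
Ramachandran letters of each centroid's angles and its rotamer bin spell
the state name, and that exactly the eight canonical states are present).
All round-trip tests classify fixtures built *at the table's own
centroids*, so their validity is independent of which centroid provenance
is used; a table of externally derived centroids can be supplied with
`--centroids`.

## Synthetic data generator

`kinconf.fixtures` builds chains from internal coordinates (NeRF with ideal
bond lengths/angles: N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, ω = 180°),
realising prescribed φ/ψ/χ₁ to better than 1e−6°; pseudo-anchor residues
(Cα + Cβ only) are placed to realise prescribed D1/D2/salt-bridge distances
exactly, solving the Cβ–Cβ constraint by choosing the Cα–Cα separation and
one of three Cβ offset geometries (perpendicular/inward/outward), with a
constructive error when no arrangement satisfies the triangle inequality.
Dummy ligands are placed at exact minimum distances from named pocket
regions while keeping a clearance (default 4 Å) from all other regions;
direction search is over a fixed Fibonacci sphere, so construction is
deterministic.  An equidistant placement helper puts a probe atom at equal
minimum distance from the hinge set and Glu(+4) to exercise the allosteric
screen.

What the fixtures do *not* emulate: a packed kinase fold, realistic
side-chain chemistry, crystallographic artefacts (altlocs, partial
occupancy, missing loops beyond what tests construct), or real sequence
diversity.  Passing tests therefore demonstrate that the decision rules,
metric and thresholds are implemented exactly — not that anchor detection
is robust on arbitrary deposited structures, which depends on the quality
of the profile library in use.

## Numerical choices

* All decision comparisons use an absolute tolerance of 1e−9 Å (or metric
  units) so that geometry constructed exactly on a threshold is classified
  by the printed constant rather than by last-bit float rounding; this is
  five orders of magnitude below the 0.01 Å at which thresholds are stated.
* Torsions follow the IUPAC sign convention (checked against gemmi and an
  independent projection-based oracle) and are reported in (−180°, 180°],
  at 1 decimal in reports.
* Multi-model files use model 1 only; alternate conformations keep the
  highest-occupancy altloc (ties toward 'A'); insertion codes are preserved
  in author numbering and flattened out of the uniprot/common schemes.
* Waters (HOH/DOD/WAT) are removed from hetero lists at parse time.

## Known limitations

* The shipped profiles and centroids are synthetic stand-ins (see above);
  classifying real PDB chains end-to-end requires substituting externally
  built profile alignments, or inputs already in common numbering
  (`--assume-common-numbering`).
* Ligand typing is purely geometric: no bond detection for covalent
  inhibitors, no chemistry beyond the component id, and the additive
  exclusion list is finite.
* ω angles, χ₂+, Ramachandran favoured/outlier scoring and electron-density
  validation are out of scope.
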