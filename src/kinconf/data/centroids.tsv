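# Dihedral-cluster centroid table, version 1.
# One row per conformational state: the spatial group it belongs to, the
# DFG-Phe chi1 rotamer bin of the cluster, and the six backbone dihedral
# centroids (degrees) for phi/psi of X-DFG, DFG-Asp and DFG-Phe.
# Provenance: synthetic centroid set constructed for this package as circular
# means over canonical exemplar conformations of each named state; each
# centroid is self-consistent with its state name (Ramachandran letters of
# the three residues plus the rotamer suffix).  Values are a convention of
# this package, not a published table; replace via --centroids to use
# externally derived centroids.
state	spatial	rotamer	phi_x	psi_x	phi_d	psi_d	phi_f	psi_f
BLAminus	DFGin	minus	-129.0	179.0	61.0	81.0	-97.0	20.0
BLAplus	DFGin	plus	-119.0	168.0	59.0	81.0	-92.0	7.0
ABAminus	DFGin	minus	-112.0	-8.0	-142.0	152.0	-99.0	26.0
BLBminus	DFGin	minus	-135.0	175.0	57.0	69.0	-130.0	100.0
BLBplus	DFGin	plus	-125.0	172.0	58.0	33.0	-85.0	145.0
BLBtrans	DFGin	trans	-106.0	157.0	69.0	21.0	-62.0	134.0
BABtrans	DFGinter	trans	-119.0	130.0	-90.0	-10.0	-73.0	130.0
BBAminus	DFGout	minus	-140.0	100.0	-144.0	90.0	-82.0	-12.0
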