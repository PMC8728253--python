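# Anchor and pocket definitions in common (alignment-column) residue
# numbering, version 1.
# Convention: the DFG motif occupies common numbers 1338-1340 in every
# kinase.  All other entries were derived once from the Aurora A (AURKA)
# reference numbering by the fixed offset common = author + 1064
# (AURKA DFG-Asp 274 -> 1338): beta3-Lys 162, C-helix-Glu 181, Glu(+4) 185,
# hinge 211-213, back pocket 166-193 + 196-204 + 205-207 + 273-275,
# Type-2-only pocket 184, 188, 247, 254; the C-helix span is taken as
# 176-193 and its N-terminal region as the first half of that span.
# Values may be ranges (a-b) or comma-separated lists.
role	common_numbers
x_dfg	1337
dfg_asp	1338
dfg_phe	1339
dfg_gly	1340
b3_lys	1226
chelix_glu	1245
chelix_glu_plus4	1249
hinge	1275-1277
back_pocket	1230-1257,1260-1268,1269-1271,1337-1339
type2_only	1248,1252,1311,1318
chelix	1240-1257
chelix_nterm	1240-1248
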