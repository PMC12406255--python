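# VhTI-pepitem chimera series.
#
# Scaffold: the synthesized VhTI variant (residues 5-31 of native VhTI,
# Met6 -> norleucine Z, N-acetylated, C-amidated, two disulfides with
# I-IV, II-III connectivity).  Spans below are 1-based inclusive on the
# 27-residue variant sequence.  Multi-splice designs list their splices
# C-terminal-first so every span stays in scaffold coordinates.

[scaffold]
name = "VhTI variant"
sequence = "EQCKVZCYAQRHSSPELLRRCLDNCEK"
n_term = "acetyl"
c_term = "amide"
n_disulfides = 2

[[design]]
name = "VhTI-pep 1"
splices = [{ span = [9, 14], insert = "AQGAELS" }]

[[design]]
name = "VhTI-pep 2"
splices = [{ span = [9, 14], insert = "AQGAEL" }]

[[design]]
name = "VhTI-pep 3"
splices = [{ span = [9, 14], insert = "EQGAEL" }]

[[design]]
name = "VhTI-pep 4"
splices = [{ span = [9, 14], insert = "QGAELS" }]

[[design]]
name = "VhTI-pep 5"
splices = [{ span = [9, 14], insert = "EQGALS" }]

# Full pepitem distributed over both helices and the loop:
# N-helix KVZ -> SVT, loop YAQRHSS -> EQGAEL, C-helix ELLRR -> SNEER.
[[design]]
name = "VhTI-pep 6"
splices = [
    { span = [16, 20], insert = "SNEER" },
    { span = [8, 14], insert = "EQGAEL" },
    { span = [4, 6], insert = "SVT" },
]

# The linear epitope parent peptide, free termini, no disulfides.
[[peptide]]
name = "Pepitem"
sequence = "SVTEQGAELSNEER"
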