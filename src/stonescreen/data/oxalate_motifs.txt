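# SYNTHETIC placeholder oxalate-binding motif set.
#
# The OxaBIND motif definitions are not redistributed here. This file ships
# so that the pipeline and the synthetic-data generator are runnable out of
# the box; for any real analysis, replace it with the published OxaBIND
# patterns (same one-pattern-per-line PROSITE syntax). Every report records
# the checksum of the motif file actually used.
#
# The placeholder patterns centre on lysine/arginine cores, the residues
# generally implicated in oxalate binding.
oxb1	K-x(2)-R-x(2)-K
oxb2	R-x(3)-[KR]-x-R
oxb3	K-G-x(2)-K
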