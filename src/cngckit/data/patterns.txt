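# Named diagnostic patterns, one per line: name <whitespace> pattern
# CNGC_consensus spans the phosphate-binding cassette and hinge region of
# the cyclic nucleotide-binding domain and is the family keep/reject motif.
# CaMBD is a balanced interpretation of an ambiguously printed pattern and
# is informational only (never used for classification).
CNGC_consensus	[LI]-X(2)-[GSE]-X-[VFIY]-X-G-X(0,1)-[DE]-L-L-X-W-X-[LQ]-X(10,20)-S-X-[SAR]-X(7)-[VTI]-E-[AG]-F-X-L
IQ_motif	[IV]-Q-X-X-W-R-X-X-X-[RKQ]
CaMBD	[FLY]-X(10,12)-[AFI]-R-[FY](0,1)
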