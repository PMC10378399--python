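# Placeholder candidate-gene list for targeted prioritization (workflow 2).
# One symbol per line.  The published candidate compilations for specific
# language impairment and related phenotypes are appendix material in their
# original reports; replace this file with your curated list (e.g. the
# 113-gene compilation) before a real analysis.  Genes below are drawn from
# the SLI/DLD and reading/language-disorder candidate literature.
FOXP2
FOXP1
CNTNAP2
ATP2C2
CMIP
NFXL1
BUD13
GLI3
FLNB
KMT2D
PTEN
GRIN2A
SRPX2
ROBO1
ROBO2
KIAA0319
KIAA0319L
DCDC2
DYX1C1
CYFIP1
SETBP1
TM4SF20
ERC1
OXR1
SCN9A
GNPTAB
GNPTG
NAGPA
AP4E1
CDH18
PCDH11X
AUTS2
SEMA6D
MRPL19
C2ORF3
ZNF385D
NOP9
ABCC13
FLNC
GRIN2B
NRXN1
ELKS
ATXN1
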