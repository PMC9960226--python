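# Curated reduced set of non-essential human genes (largely tissue-restricted
# or non-expressed in common cell lines).
# Subset for tests/examples only — supply full reference lists for real work.
CD4
CCR5
ACTL7A
ADAM18
ALPI
AMELX
CABP2
CDX4
CELA3A
CLRN1
CNGB3
CRX
CSN2
CYLC1
DEFB123
DRD5
FGF6
GALR3
GCG
GJA8
GPR50
HTR3C
IFNA4
IL9
INSL5
KRT35
LHX5
MAGEB1
MBL2
MC2R
MYF5
NEUROD4
OPN1SW
OR10A2
OR2T10
PGLYRP2
PRSS33
RBP3
RHO
SAGE1
SPACA1
TAS2R9
TBX22
TGM6
TNR
TRPC5
UGT1A5
VN1R2
ZAN
ZP2
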