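# Curated reduced set of constitutive-essential human genes
# (ribosome, proteasome, spliceosome, replication, translation).
# Subset for tests/examples only — supply full reference lists for real work.
RPL3
RPL4
RPL5
RPL6
RPL7
RPL8
RPL10A
RPL11
RPL13
RPL15
RPL23
RPL31
RPL37
RPS3
RPS4X
RPS6
RPS7
RPS8
RPS11
RPS13
RPS15A
RPS19
RPS27A
PSMA1
PSMA3
PSMB2
PSMB3
PSMD1
PSMD7
POLR2A
POLR2B
POLR2L
SNRPD1
SNRPF
SF3B1
SF3B3
EFTUD2
PRPF19
EIF3B
EIF4A3
EEF2
HSPE1
RAN
XPO1
CDC5L
PCNA
RPA1
POLA1
MCM2
MCM4
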