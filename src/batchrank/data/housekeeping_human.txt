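# Human housekeeping gene symbols: stably expressed reference genes commonly
# used as negative controls for unwanted-variation estimation.  Core set from
# widely used RT-qPCR reference panels plus stably-expressed genes identified
# from RNA-seq compendia (Eisenberg & Levanon 2013 style lists).
# One symbol per line; lines starting with '#' are ignored.
ACTB
GAPDH
B2M
GUSB
HPRT1
PGK1
PPIA
PPIB
RPL13A
RPLP0
RPL19
RPL27
RPL30
RPL37A
RPS18
RPS29
SDHA
TBP
TFRC
UBC
UBB
YWHAZ
HMBS
TUBB
EEF1A1
EIF4A2
POLR2A
GPI
LDHA
NONO
PGAM1
PUM1
RPL4
RPS13
RPS20
TPT1
C1orf43
CHMP2A
EMC7
PSMB2
PSMB4
RAB7A
REEP5
SNRPD3
VCP
VPS29
ALAS1
CYC1
ATP5F1B
MRPL19
PSMC4
SF3A1
CASC3
CDKN1B
GADD45A
IPO8
MT-ATP6
ABL1
ELF1
TMEM199
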