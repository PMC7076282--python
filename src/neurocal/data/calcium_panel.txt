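# Synthetic stand-in panel of 109 HGNC symbols for neuronal calcium signalling.
# Assembled from canonical gene families (VGCC, NMDA/AMPA receptors, mGluRs,
# PLC, IP3R/RyR, SERCA/PMCA/NCX, STIM/Orai, CaMK, calcium-binding proteins).
# Replace this file with a study-specific list; one symbol per line.
CACNA1A
CACNA1B
CACNA1C
CACNA1D
CACNA1E
CACNA1G
CACNA1H
CACNA1I
CACNA2D1
CACNB1
CACNB2
CACNB3
CACNB4
CACNG2
GRIN1
GRIN2A
GRIN2B
GRIN2C
GRIN2D
GRIN3A
GRIA1
GRIA2
GRIA3
GRIA4
GRIK1
GRIK2
GRM1
GRM2
GRM3
GRM4
GRM5
GRM7
GRM8
CHRNA7
P2RX2
P2RX4
P2RX7
P2RY1
P2RY2
HTR2A
CHRM1
CHRM3
ADRA1A
PLCB1
PLCB2
PLCB3
PLCB4
PLCG1
PLCG2
PLCD1
ITPR1
ITPR2
ITPR3
RYR1
RYR2
RYR3
ATP2A1
ATP2A2
ATP2A3
ATP2B1
ATP2B2
ATP2B3
ATP2B4
SLC8A1
SLC8A2
SLC8A3
SLC24A2
MCU
MICU1
MICU2
VDAC1
STIM1
STIM2
ORAI1
ORAI2
ORAI3
TRPC1
TRPC3
TRPC4
TRPC5
TRPC6
TRPV1
TRPM2
CAMK1
CAMK2A
CAMK2B
CAMK2D
CAMK2G
CAMK4
CAMKK1
CAMKK2
CALM1
CALM2
CALM3
CALB1
CALB2
PVALB
S100B
HPCA
NCS1
CABP1
CALR
CANX
CASQ1
CASQ2
PPP3CA
PPP3CB
PPP3R1
CIB1
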