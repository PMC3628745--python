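# 200-gene integrated melanoma signature, in descending global-significance order
DCD
MAGEA3
MAGEA2
MAGEA2B
CSAG3
CSAG2
GAGE12F
GAGE12G
GAGE12I
GAGE2A
GAGE2B
GAGE2C
GAGE2E
GAGE4
CTAG1B
KRT77
THRSP
CTAG1A
GAGE5
GAGE6
MAGEA12
MAGEA6
XAGE1A
XAGE1B
XAGE1C
XAGE1D
XAGE1E
PRAME
C4orf7
GAGE12B
GAGE12C
GAGE12D
GAGE12E
GAGE12H
GAGE12J
GAGE2D
GAGE8
WFDC5
IL8
COL17A1
FOXQ1
ZIC1
ELMOD1
ELOVL3
SERPINA12
DSC3
MAGEA1
DMKN
INS-IGF2
C1orf172
GAGE7
DGAT2
FGFR3
MICALCL
KRT15
CTAG2
ANK3
HMGA2
MYOZ2
AADACL2
SCGB2A2
ISG20
DST
IL13RA2
APOC2
TNC
FMN2
SHC4
FSTL5
PTPRF
KRTAP19-1
CXCL13
GAGE1
EYA1
HLA-DRB2
LOC100133484
LOC100133661
LOC100133811
LOC730415
ZNF749
KRT14
IGFL2
SCEL
GAGE3
GATA3
DSP
WNT4
TACSTD2
CAPNS2
MAL2
DGAT2L3
PIP
AKR1C2
IGF2
MPP7
IGHG1
NMU
EGFR
APOC4
MGP
DKFZP434B061
PPP1R14C
AKR1C3
C19orf33
FGFR2
IGL@
SERPINB5
CYP3A5
LEP
CHST6
TF
MIA
HLA-DQB1
GPR87
RHBDL2
SGPP2
SCARA5
SAA1
RNASE2
SLAMF7
SAA2
PPP2R2C
GBP5
AKR1C1
ENTHD1
EPHA3
KRT6B
CCDC3
BTBD16
ANKRD35
HLA-DQA1
C10orf116
JUP
IGFBP5
KRT25
SULF1
TKTL1
IL1F7
C6orf218
HEY1
MGST1
ABCA13
RAPGEFL1
TFPI2
TRIM29
ALDH1A3
ATP6V1C2
COL11A1
RSPO1
PLA1A
AQP3
C1orf116
RGS4
GRHL3
GPR115
SERPINA3
LAD1
FLI37464
HLA-DRB4
TMEM79
ZNF750
IGHV4-31
TP63
LOC124220
RASGRF1
KRT5
LAMB4
SCML4
CYP4B1
HLA-DRB3
NEBL
IGSF9
KLK11
CHP2
MAGEA10
CYP26B1
EREG
DLX1
LOC285986
TRIM7
GAD1
LOR
EXPH5
TMEM154
LASS3
HLA-DRB5
LOC100126583
CYP4F8
SDC1
SCGB1D2
RORA
SH3RF2
LGALS7
MMP1
MAGEC1
FRMD5
SERPINB7
FGF13
LOC645323
COL9A3
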