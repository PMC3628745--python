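# 12-gene diagnostic melanoma biomarker signature (driver-gene pathway subset)
EGFR
FGFR2
FGFR3
IL8
PTPRF
TNC
CXCL13
COL11A1
CHP2
SHC4
PPP2R2C
WNT4
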