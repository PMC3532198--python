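# Synthetic stand-in for a pan-cancer exclusion list: genes reported as
# differentially expressed across many cancer types (housekeeping and
# stress-response genes). Illustrative only; supply your own list for
# real analyses.
GAPDH
ACTB
TUBB
EEF1A1
RPL13A
RPS18
HSP90AA1
HSPA8
MYC
FOS
JUN
CCND1
MKI67
PCNA
TP53
VIM
KRT18
B2M
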