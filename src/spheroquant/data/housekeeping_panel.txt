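# Default 22-gene human housekeeping panel (override with --panel / panel=...)
ACTB
B2M
EEF1A1
GAPDH
GUSB
HMBS
HPRT1
IPO8
PGK1
POLR2A
PPIA
PSMB4
RAB7A
RPL13A
RPLP0
RPS18
SDHA
TBP
TFRC
TUBB
UBC
YWHAZ
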