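DR
MR
MRS
MS
MISS
MASTER
JR
SR
JNR
SNR
PROF
REV
SIR
LADY
FR
HON
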