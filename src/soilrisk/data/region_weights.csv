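region,count
GY,48
ZY,148
AS,82
LPS,21
BJ,51
QDN,151
QN,119
QXN,44
TR,75
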