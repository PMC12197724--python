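metal,value
As,10
Cd,30
Cr,2
Hg,40
Pb,5
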