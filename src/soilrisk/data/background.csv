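metal,value
As,20
Cd,0.66
Cr,95.9
Hg,0.1
Pb,35.2
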