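variable,mean,sd,min,max
As,9.08,5.38,1.19,24.87
Cd,0.36,0.16,0.08,0.75
Cr,73.06,29.21,15.97,149.82
Hg,0.13,0.06,0.02,0.29
Pb,28.14,8.09,11.42,49.38
pH,6.14,0.96,3.84,8.06
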