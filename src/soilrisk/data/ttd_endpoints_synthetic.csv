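metal,organ,value
As,neurological,3.023e-4
As,cardiovascular,3.127e-4
As,hematological,5.669e-4
Cd,renal,1.798e-4
Cd,hematological,3.596e-4
Cr,renal,4.561e-3
Cr,hematological,3.173e-3
Cr,testicular,5.213e-3
Pb,neurological,1.124e-3
Pb,renal,8.267e-4
Pb,cardiovascular,1.653e-3
Pb,hematological,1.338e-3
Pb,testicular,9.369e-3
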