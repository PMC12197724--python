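metal,pathway,rfd,sf
As,ing,3.0e-4,1.5
As,inh,4.29e-6,15.1
As,dermal,1.23e-4,1.5
Cd,ing,1.0e-3,6.1
Cd,inh,2.86e-6,6.3
Cd,dermal,2.5e-5,
Cr,ing,3.0e-3,0.5
Cr,inh,2.86e-5,0.42
Cr,dermal,3.0e-5,20
Hg,ing,3.0e-4,
Hg,dermal,2.1e-5,
Pb,ing,1.4e-3,0.0085
Pb,inh,,0.042
Pb,dermal,5.25e-4,
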