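metal,ph_class,value
As,<=5.5,30
As,"(5.5,6.5]",30
As,"(6.5,7.5]",25
As,>7.5,20
Cd,<=5.5,0.30
Cd,"(5.5,6.5]",0.4
Cd,"(6.5,7.5]",0.6
Cd,>7.5,0.8
Cr,<=5.5,250
Cr,"(5.5,6.5]",250
Cr,"(6.5,7.5]",300
Cr,>7.5,350
Hg,<=5.5,0.50
Hg,"(5.5,6.5]",0.50
Hg,"(6.5,7.5]",0.6
Hg,>7.5,1.0
Pb,<=5.5,80
Pb,"(5.5,6.5]",100
Pb,"(6.5,7.5]",140
Pb,>7.5,240
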