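population,parameter,value,kind,sd,low,high
adults,R_ing,100,normal,20,40,160
adults,R_inh,14.5,normal,2,6.5,22.5
adults,EF,350,uniform,,335,365
adults,ED,24,point,,,
adults,BW,64.4,normal,7,43.4,85.4
adults,AT_nc,8760,point,,,
adults,AT_ca,8760,point,,,
adults,SA,5700,normal,570,3990,7410
adults,AF,0.07,point,,,
adults,ABS,0.001,point,,,
adults,PEF,1360000000,point,,,
children,R_ing,200,normal,40,80,320
children,R_inh,7.5,normal,1,3.5,11.5
children,EF,350,uniform,,335,365
children,ED,6,point,,,
children,BW,19.2,normal,2.5,11.7,26.7
children,AT_nc,2190,point,,,
children,AT_ca,2190,point,,,
children,SA,2800,normal,280,1960,3640
children,AF,0.2,point,,,
children,ABS,0.001,point,,,
children,PEF,1360000000,point,,,
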