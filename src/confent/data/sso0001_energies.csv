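name,Eintra,Gsolv,minusTSconf
NAT,6.6,1.3,0.0
DEC1,0.0,17.0,7.3
DEC2,0.8,9.5,6.6
DEC3,0.9,6.6,8.7
DEC4,5.6,14.0,0.5
DEC5,8.5,0.0,7.0
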