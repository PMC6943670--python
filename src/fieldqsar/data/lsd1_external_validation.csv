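condition,parameter,threshold,comfa,comsia
1,R2,>0.6,0.855,0.861
2a,R02,close to R2,0.851,0.857
2b,R0p2,close to R2,0.847,0.755
3a,k,0.85<k<1.15,1.001,0.983
3b,kp,0.85<kp<1.15,0.998,1.010
4a,(R2-R02)/R2,<0.1,0.005,0.005
4b,(R2-R0p2)/R2,<0.1,0.009,0.123
5,|R02-R0p2|,<0.3,0.004,0.102
6,rm2,>0.5,0.799,0.804
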