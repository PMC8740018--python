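# loq = 10.0
# label = B. cereus, sandwich survey (n=1120)
lower,upper,count
ND,,1008
10,100,49
100,1000,48
1000,10000,12
10000,100000,2
100000,1000000,1
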