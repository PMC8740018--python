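# loq = 10.0
# label = E. coli, retail beef survey (n=100)
lower,upper,count
ND,,81
10,100,16
100,1000,2
1000,10000,1
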