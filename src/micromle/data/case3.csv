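# loq = 10.0
# label = Total coliforms, retail beef survey (n=100)
lower,upper,count
ND,,16
10,100,19
100,1000,34
1000,10000,22
10000,100000,8
100000,1000000,1
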