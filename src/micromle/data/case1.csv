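# loq = 10.0
# label = Total coliforms, sandwich survey (n=1120)
lower,upper,count
ND,,214
10,100,258
100,1000,368
1000,10000,234
10000,100000,44
100000,1000000,2
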