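state,safe,risky1,risky2
1,150,125,175
2,150,100,200
3,150,50,250
4,140,40,240
5,200,40,240
6,210,40,240
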