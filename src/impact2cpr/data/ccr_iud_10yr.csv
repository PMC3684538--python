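year_offset,ccr
0,1.0
1,0.85
2,0.76
3,0.68
4,0.61
5,0.54
6,0.48
7,0.42
8,0.36
9,0.30
10,0.25
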