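year_offset,ccr
0,1.0
1,0.88
2,0.77
3,0.66
4,0.55
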